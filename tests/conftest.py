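import numpy as np
import pandas as pd
import pytest

from vinespec import make_grid, simulate_campaign
from vinespec.synthetic import StreamConfig, build_design


def tiny_design():
    """Single-replicate, single-date design for cheap stream tests."""
    return build_design(blocks=1, treatments=("T0",), dates=("2015-07-23",))


def psi_for(design, values=(-1.0, -1.5, -2.0)):
    """Hand-built reference table assigning fixed psi_s per sub-unit."""
    rows = []
    for _, rep in design.replicates.iterrows():
        for s, v in zip((1, 2, 3), values):
            for date in design.dates:
                rows.append(
                    {
                        "date": date,
                        "block": int(rep["block"]),
                        "treatment": rep["treatment"],
                        "replicate_id": int(rep["replicate_id"]),
                        "sub_unit": s,
                        "vine_id": int(rep[f"tagged_vine_su{s}"]),
                        "psi_MPa": v,
                        "x": 0.0,
                        "y": float(rep["row_y"]),
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def grid():
    return make_grid(1100, 2100, 4)


@pytest.fixture(scope="session")
def campaign_2015_east():
    """One default 2015-style east-side campaign, shared across tests."""
    return simulate_campaign("2015", sides=("east",), seed=7)


@pytest.fixture(scope="session")
def clean_stream_cfg():
    """Deterministic optics: no noise, no scatter, no contamination."""
    return StreamConfig(
        contamination_fraction=0.0,
        baseline_range=(0.0, 0.0),
        scatter_range=(1.0, 1.0),
        noise_sd=0.0,
        canopy_psi_sd=0.0,
        leaf_psi_jitter_sd=0.0,
        date_effect_sd=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
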