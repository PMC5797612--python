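"""Synthetic vineyard campaign generator.

Emulates a two-season on-the-go NIR monitoring experiment in a vertically
shoot-positioned vineyard: a completely randomized block design (4 blocks x
3 irrigation regimes, 12 field replicates of 3 adjacent rows with the middle
row monitored), midday stem water potential (psi_s, MPa, negative) reference
measurements on 3 tagged vines per replicate per date, and 24 Hz spectral
streams acquired at 5 km/h from either canopy side.

Leaf spectra carry two water-absorption bands (OH overtone near 1450 nm and
OH combination near 1940 nm) whose depth is affine in psi_s, on top of a
fixed leaf-matrix background, with additive baseline and multiplicative
scatter effects plus i.i.d. channel noise.  Streams are contaminated with
wood / metal / gap archetypes at a configurable fraction, and every spectrum
is tagged with its true class and sub-unit so downstream filters can be
scored against ground truth.

Structured variability that does NOT average out over a sub-unit pass is
injected at two levels: a per-(date, replicate, sub-unit) canopy mismatch
between the spectrally sampled foliage and the single tagged leaf used for
the reference reading, and a per-date environmental drift of band depth.
These two scales set the noise floor of the whole calibration exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import SpectraBatch, Spectrum, WavelengthGrid, make_grid

__all__ = [
    "ConfigurationError",
    "FieldDesign",
    "PsiTrajectory",
    "StreamConfig",
    "Campaign",
    "build_design",
    "default_trajectories",
    "simulate_psi",
    "simulate_stream",
    "simulate_campaign",
    "vpd",
    "env_table",
    "leaf_signature",
    "DATES_2015",
    "DATES_2016",
    "TREATMENTS",
]


class ConfigurationError(ValueError):
    """Invalid campaign configuration."""


TREATMENTS = ("T0", "T1", "T2")

DATES_2015 = (
    "2015-07-23", "2015-07-28", "2015-08-06", "2015-08-12", "2015-08-19",
    "2015-08-26", "2015-09-07", "2015-09-11", "2015-09-18",
)
DATES_2016 = (
    "2016-07-07", "2016-07-13", "2016-07-20", "2016-07-28", "2016-08-11",
    "2016-08-23",
)

# solar-noon air temperature (degC) and relative humidity (%) per campaign date
_ENV = {
    "2015-07-23": (29.2, 44.0), "2015-07-28": (28.2, 35.0),
    "2015-08-06": (31.6, 37.5), "2015-08-12": (32.0, 36.5),
    "2015-08-19": (26.9, 20.0), "2015-08-26": (31.1, 33.5),
    "2015-09-07": (20.4, 42.0), "2015-09-11": (25.4, 50.0),
    "2015-09-18": (20.4, 39.0),
    "2016-07-07": (27.2, 53.0), "2016-07-13": (18.7, 48.5),
    "2016-07-20": (29.1, 40.5), "2016-07-28": (29.2, 22.5),
    "2016-08-11": (22.6, 38.0), "2016-08-23": (32.8, 32.5),
}


def vpd(air_t, rh):
    """Vapor pressure deficit (kPa) from air temperature (degC) and RH (%).

    Uses the Tetens saturation formula over liquid water:
    ``es = 0.6108 * exp(17.27 T / (T + 237.3))``; ``VPD = es * (1 - RH/100)``.
    """
    air_t = np.asarray(air_t, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must lie in [0, 100] %")
    es = 0.6108 * np.exp(17.27 * air_t / (air_t + 237.3))
    out = es * (1.0 - rh / 100.0)
    return float(out) if out.ndim == 0 else out


def env_table(season: str = "2015") -> pd.DataFrame:
    """Per-date environmental covariates (air T, RH, computed VPD)."""
    dates = DATES_2015 if str(season) == "2015" else DATES_2016
    rows = [
        {"date": d, "air_T": _ENV[d][0], "RH": _ENV[d][1],
         "VPD": vpd(*_ENV[d])}
        for d in dates
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# field design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldDesign:
    """Completely randomized block design with row geometry.

    Each replicate is three adjacent rows of 25 vines; only the middle row
    is monitored and only its middle 15 vines are measured, split into three
    5-vine sub-replicate units each holding one tagged vine.
    """

    blocks: int
    treatments: tuple[str, ...]
    dates: tuple[str, ...]
    vines_per_row: int = 25
    measured_vines: int = 15
    sub_units_per_replicate: int = 3
    tagged_per_replicate: int = 3
    vine_spacing: float = 1.20   # m between vines along the row
    row_spacing: float = 2.60    # m between rows
    rows_per_replicate: int = 3
    layout_seed: int = 0
    replicates: pd.DataFrame = field(default=None, repr=False, compare=False)

    @property
    def n_replicates(self) -> int:
        return self.blocks * len(self.treatments)

    @property
    def n_reference_slots(self) -> int:
        """Total reference psi_s measurements over the campaign."""
        return self.n_replicates * self.tagged_per_replicate * len(self.dates)

    @property
    def row_length(self) -> float:
        return self.vines_per_row * self.vine_spacing

    @property
    def measured_span(self) -> tuple[float, float]:
        """Along-row extent (m) of the measured middle vines."""
        edge = (self.vines_per_row - self.measured_vines) // 2
        return edge * self.vine_spacing, (edge + self.measured_vines) * self.vine_spacing

    def sub_unit_vines(self, sub_unit: int) -> np.ndarray:
        """Row-position indices of the vines in sub-unit ``1..3``."""
        edge = (self.vines_per_row - self.measured_vines) // 2
        per = self.measured_vines // self.sub_units_per_replicate
        start = edge + (sub_unit - 1) * per
        return np.arange(start, start + per)

    def sub_unit_centroid_x(self, sub_unit: int) -> float:
        vines = self.sub_unit_vines(sub_unit)
        return float((vines.mean() + 0.5) * self.vine_spacing)


def build_design(
    blocks: int = 4,
    treatments: tuple[str, ...] = TREATMENTS,
    dates=DATES_2015,
    tagged_per_replicate: int = 3,
    layout_seed: int = 0,
    **geometry,
) -> FieldDesign:
    """Lay out the experiment: replicates, rows, and tagged vines.

    Treatment order within each block is randomized (completely randomized
    block design) from ``layout_seed``; one tagged vine is drawn per
    sub-replicate unit.  Raises :class:`ConfigurationError` for an empty
    design.
    """
    if blocks < 1:
        raise ConfigurationError("need at least one block")
    if len(treatments) < 1:
        raise ConfigurationError("need at least one treatment")
    dates = tuple(str(d) for d in dates)
    if len(dates) == 0:
        raise ConfigurationError("need at least one campaign date")

    design = FieldDesign(
        blocks=blocks,
        treatments=tuple(treatments),
        dates=dates,
        tagged_per_replicate=tagged_per_replicate,
        layout_seed=layout_seed,
        **geometry,
    )
    rng = np.random.default_rng(layout_seed)
    rows = []
    rep = 0
    for b in range(blocks):
        order = rng.permutation(len(treatments))
        for k in order:
            # monitored middle row of the replicate's three adjacent rows
            y = (rep * design.rows_per_replicate + 1) * design.row_spacing
            tagged = {}
            for s in range(1, design.sub_units_per_replicate + 1):
                vines = design.sub_unit_vines(s)
                tagged[s] = int(rng.choice(vines))
            rows.append(
                {
                    "replicate_id": rep + 1,
                    "block": b + 1,
                    "treatment": treatments[k],
                    "row_y": y,
                    **{f"tagged_vine_su{s}": v for s, v in tagged.items()},
                }
            )
            rep += 1
    object.__setattr__(design, "replicates", pd.DataFrame(rows))
    return design


# ---------------------------------------------------------------------------
# stem water potential trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsiTrajectory:
    """Per-date psi_s distribution for one irrigation treatment.

    ``means``/``sds`` are per campaign date (MPa); draws are clipped to
    ``bounds``.  All psi_s values are negative (water under tension).
    """

    treatment: str
    dates: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    bounds: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.means) != len(self.dates) or len(self.sds) != len(self.dates):
            raise ConfigurationError("means/sds must match the date list")
        lo, hi = self.bounds
        if not (lo < hi <= 0):
            raise ConfigurationError("bounds must satisfy min < max <= 0")
        for m in self.means:
            if not (lo <= m <= hi):
                raise ConfigurationError(
                    f"trajectory mean {m} outside bounds {self.bounds}"
                )
        if any(s < 0 for s in self.sds):
            raise ConfigurationError("trajectory SDs must be non-negative")


# Defaults follow the seasonal drydown-and-recovery shape of an irrigation
# trial: irrigated vines dip toward mid-August and partly recover after
# early-September rain; unirrigated vines decline steadily.  Per-date means
# and SDs are chosen so the pooled per-treatment statistics reproduce the
# campaign summary (mean, SD, min, max per treatment and season).
_TRAJ_2015 = {
    "T0": ((-0.75, -0.78, -0.82, -0.88, -0.90, -0.92, -0.85, -0.82, -0.93),
           0.150, (-1.35, -0.55)),
    "T1": ((-0.90, -0.97, -1.08, -1.18, -1.25, -1.30, -1.28, -1.18, -1.30),
           0.190, (-1.65, -0.65)),
    "T2": ((-1.25, -1.35, -1.55, -1.68, -1.75, -1.82, -1.95, -1.85, -1.83),
           0.172, (-2.25, -1.10)),
}
_TRAJ_2016 = {
    "T0": ((-0.95, -1.00, -1.06, -1.12, -1.16, -1.19), 0.125, (-1.45, -0.75)),
    "T1": ((-1.12, -1.20, -1.28, -1.36, -1.40, -1.44), 0.114, (-1.70, -1.00)),
    "T2": ((-1.10, -1.22, -1.34, -1.45, -1.50, -1.55), 0.198, (-1.95, -0.85)),
}


def default_trajectories(season: str = "2015") -> dict[str, PsiTrajectory]:
    """Default per-treatment psi_s trajectories for a season campaign."""
    season = str(season)
    table = _TRAJ_2015 if season == "2015" else _TRAJ_2016
    dates = DATES_2015 if season == "2015" else DATES_2016
    return {
        t: PsiTrajectory(t, dates, means, (sd,) * len(dates), bounds)
        for t, (means, sd, bounds) in table.items()
    }


def simulate_psi(
    design: FieldDesign,
    trajectories: dict[str, PsiTrajectory],
    seed: int,
) -> pd.DataFrame:
    """Draw one psi_s reference per tagged vine per date.

    Values are ``mean(date) + N(0, sd(date))`` clipped to the trajectory
    bounds; reproducible from ``seed``.  Returns the reference table with
    columns ``date, block, treatment, replicate_id, sub_unit, vine_id,
    psi_MPa, x, y``.
    """
    for t in {r["treatment"] for _, r in design.replicates.iterrows()}:
        if t not in trajectories:
            raise ConfigurationError(f"no psi trajectory for treatment {t!r}")
        traj = trajectories[t]
        missing = set(design.dates) - set(traj.dates)
        if missing:
            raise ConfigurationError(
                f"trajectory for {t!r} lacks dates {sorted(missing)}"
            )
    rng = np.random.default_rng(seed)
    rows = []
    for date in design.dates:
        for _, rep in design.replicates.iterrows():
            traj = trajectories[rep["treatment"]]
            i = traj.dates.index(date)
            mu, sd = traj.means[i], traj.sds[i]
            lo, hi = traj.bounds
            for s in range(1, design.sub_units_per_replicate + 1):
                val = float(np.clip(mu + sd * rng.standard_normal(), lo, hi))
                vine = int(rep[f"tagged_vine_su{s}"])
                rows.append(
                    {
                        "date": date,
                        "block": int(rep["block"]),
                        "treatment": rep["treatment"],
                        "replicate_id": int(rep["replicate_id"]),
                        "sub_unit": s,
                        "vine_id": vine,
                        "psi_MPa": val,
                        "x": (vine + 0.5) * design.vine_spacing,
                        "y": float(rep["row_y"]),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spectral stream
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StreamConfig:
    """Geometry and optics of the on-the-go spectral stream.

    Band depth is affine in psi_s: ``depth = alpha0 + alpha1 * psi`` with
    ``alpha1 > 0`` so wetter vines (less negative psi_s) absorb more at the
    OH bands.  ``canopy_psi_sd`` is the per-(date, replicate, sub-unit)
    mismatch between the foliage the beam samples and the tagged reference
    leaf; ``date_effect_sd`` is a shared per-date drift of band depth
    (environmental conditions).  Both are in MPa-equivalent units.
    """

    acquisition_rate_hz: float = 24.0
    speed_kmh: float = 5.0
    contamination_fraction: float = 0.15
    band_centers: tuple[float, float] = (1450.0, 1940.0)
    band_sigmas: tuple[float, float] = (40.0, 60.0)
    band_ratio: float = 1.2          # 1940 nm amplitude relative to 1450 nm
    depth_alpha0: float = 0.9        # absorbance at psi = 0
    depth_alpha1: float = 0.25       # absorbance per MPa
    baseline_range: tuple[float, float] = (-0.05, 0.05)
    scatter_range: tuple[float, float] = (0.9, 1.1)
    noise_sd: float = 0.02
    canopy_psi_sd: float = 0.12
    leaf_psi_jitter_sd: float = 0.05
    date_effect_sd: float = 0.07

    def __post_init__(self) -> None:
        if self.acquisition_rate_hz <= 0:
            raise ConfigurationError("acquisition rate must be positive")
        if self.speed_kmh <= 0:
            raise ConfigurationError("vehicle speed must be positive")
        if not (0 <= self.contamination_fraction < 1):
            raise ConfigurationError("contamination fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise SD must be non-negative")

    @property
    def speed_ms(self) -> float:
        return self.speed_kmh / 3.6

    @property
    def spectra_per_meter(self) -> float:
        return self.acquisition_rate_hz / self.speed_ms


def _gauss(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def _leaf_matrix(wl: np.ndarray) -> np.ndarray:
    """Fixed leaf-matrix background: gentle slope plus two broad minor bands."""
    return (
        0.30
        + 0.05 * (wl - wl[0]) / 1000.0
        + 0.10 * _gauss(wl, 1250.0, 150.0)
        + 0.06 * _gauss(wl, 1750.0, 180.0)
    )


def _water_bands(wl: np.ndarray, cfg: StreamConfig) -> np.ndarray:
    c1, c2 = cfg.band_centers
    s1, s2 = cfg.band_sigmas
    return _gauss(wl, c1, s1) + cfg.band_ratio * _gauss(wl, c2, s2)


def _leaf_clean(wl: np.ndarray, cfg: StreamConfig, psi: np.ndarray) -> np.ndarray:
    """Noise-free leaf absorbance for psi values (vectorized over rows)."""
    depth = np.maximum(cfg.depth_alpha0 + cfg.depth_alpha1 * np.atleast_1d(psi), 0.05)
    return _leaf_matrix(wl)[None, :] + depth[:, None] * _water_bands(wl, cfg)[None, :]


def leaf_signature(
    grid: WavelengthGrid | None = None,
    cfg: StreamConfig | None = None,
    psi: float = -1.2,
) -> Spectrum:
    """Static, well-taken leaf signature spectrum used by the stream filter."""
    grid = grid or make_grid(1100, 2100, 4)
    cfg = cfg or StreamConfig()
    a = _leaf_clean(grid.wavelengths, cfg, np.array([psi]))[0]
    return Spectrum(grid, a, {"class_tag": "signature"})


# contaminant archetypes: (mean shape builder, noise SD)
def _wood(wl: np.ndarray) -> np.ndarray:
    return 0.5 + 0.25 * _gauss(wl, 1200.0, 150.0) - 0.03 * (wl - wl[0]) / 1000.0


def _metal(wl: np.ndarray) -> np.ndarray:
    return np.full_like(wl, 0.08)


def _gap(wl: np.ndarray) -> np.ndarray:
    return np.full_like(wl, 0.02)


_CONTAMINANTS = (("wood", _wood, None), ("metal", _metal, None), ("gap", _gap, 0.10))
_CONTAM_PROBS = (0.4, 0.3, 0.3)


def simulate_stream(
    design: FieldDesign,
    psi: pd.DataFrame,
    cfg: StreamConfig,
    side: str = "east",
    seed: int = 0,
    grid: WavelengthGrid | None = None,
    dates=None,
) -> SpectraBatch:
    """Emit the raw on-the-go spectral stream for one canopy side.

    Spectra are emitted in row-traversal order, one pass per (date,
    replicate), at ``round(rate * row_length / speed)`` spectra per pass
    covering the full 25-vine row (downstream allocation trims to the middle
    15 measured vines).  Each spectrum is tagged with its true class
    (leaf/wood/metal/gap) and true sub-unit (0 outside the measured span)
    for test oracles.
    """
    if len(psi) == 0:
        raise ValueError("psi reference set is empty")
    grid = grid or make_grid(1100, 2100, 4)
    wl = grid.wavelengths
    dates = tuple(dates) if dates is not None else design.dates
    rng = np.random.default_rng(seed)

    psi_lookup = psi.set_index(["date", "replicate_id", "sub_unit"])["psi_MPa"]
    n_pass = int(round(cfg.acquisition_rate_hz * design.row_length / cfg.speed_ms))
    bands = _water_bands(wl, cfg)
    matrix = _leaf_matrix(wl)

    date_effect = dict(zip(dates, cfg.date_effect_sd * rng.standard_normal(len(dates))))

    blocks_abs, blocks_meta = [], []
    for date in dates:
        for _, rep in design.replicates.iterrows():
            rid = int(rep["replicate_id"])
            try:
                su_psi = np.array(
                    [psi_lookup[(date, rid, s)]
                     for s in range(1, design.sub_units_per_replicate + 1)]
                )
            except KeyError as exc:
                raise ValueError(
                    f"no psi reference for date {date}, replicate {rid}"
                ) from exc

            pos = (np.arange(n_pass) + 0.5) * design.row_length / n_pass
            vine = np.minimum(
                (pos / design.vine_spacing).astype(int), design.vines_per_row - 1
            )
            lo, hi = design.measured_span
            per = design.measured_vines // design.sub_units_per_replicate
            edge = (design.vines_per_row - design.measured_vines) // 2
            sub_unit = np.where(
                (pos >= lo) & (pos < hi), (vine - edge) // per + 1, 0
            )

            canopy = cfg.canopy_psi_sd * rng.standard_normal(
                design.sub_units_per_replicate + 1
            )
            psi_eff = np.empty(n_pass)
            for s in range(1, design.sub_units_per_replicate + 1):
                psi_eff[sub_unit == s] = su_psi[s - 1] + canopy[s - 1]
            psi_eff[sub_unit == 0] = su_psi.mean() + canopy[-1]
            psi_eff += date_effect[date]
            psi_eff += cfg.leaf_psi_jitter_sd * rng.standard_normal(n_pass)

            depth = np.maximum(cfg.depth_alpha0 + cfg.depth_alpha1 * psi_eff, 0.05)
            baseline = rng.uniform(*cfg.baseline_range, size=n_pass)
            scatter = rng.uniform(*cfg.scatter_range, size=n_pass)
            spectra = (
                baseline[:, None]
                + scatter[:, None] * (matrix[None, :] + depth[:, None] * bands[None, :])
                + cfg.noise_sd * rng.standard_normal((n_pass, grid.n_channels))
            )

            tags = np.full(n_pass, "leaf", dtype=object)
            if cfg.contamination_fraction > 0:
                contam = rng.random(n_pass) < cfg.contamination_fraction
                kinds = rng.choice(
                    len(_CONTAMINANTS), size=int(contam.sum()), p=_CONTAM_PROBS
                )
                idx = np.flatnonzero(contam)
                for j, kind in zip(idx, kinds):
                    name, shape, noise = _CONTAMINANTS[kind]
                    nsd = cfg.noise_sd if noise is None else noise
                    spectra[j] = (
                        baseline[j]
                        + scatter[j] * shape(wl)
                        + nsd * rng.standard_normal(grid.n_channels)
                    )
                    tags[j] = name

            blocks_abs.append(spectra)
            blocks_meta.append(
                pd.DataFrame(
                    {
                        "date": date,
                        "side": side,
                        "replicate_id": rid,
                        "sub_unit": sub_unit,
                        "timestamp": pos / cfg.speed_ms,
                        "class_tag": tags,
                    }
                )
            )
    return SpectraBatch(
        grid, np.vstack(blocks_abs), pd.concat(blocks_meta, ignore_index=True)
    )


# ---------------------------------------------------------------------------
# full campaign
# ---------------------------------------------------------------------------

@dataclass
class Campaign:
    """A complete synthetic campaign: design, references, environment, streams."""

    design: FieldDesign
    reference: pd.DataFrame
    env: pd.DataFrame
    streams: dict[str, SpectraBatch]
    season: str
    seed: int


def simulate_campaign(
    season: str = "2015",
    sides: tuple[str, ...] = ("east",),
    cfg: StreamConfig | None = None,
    seed: int = 0,
    design: FieldDesign | None = None,
    trajectories: dict[str, PsiTrajectory] | None = None,
) -> Campaign:
    """Generate a full seeded campaign for one season.

    A single seed controls all randomness; per-operation sub-seeds are
    derived deterministically through :class:`numpy.random.SeedSequence`.
    """
    season = str(season)
    cfg = cfg or StreamConfig()
    if design is None:
        dates = DATES_2015 if season == "2015" else DATES_2016
        design = build_design(dates=dates, layout_seed=seed & 0x7FFFFFFF)
    trajectories = trajectories or default_trajectories(season)

    children = np.random.SeedSequence(seed).generate_state(1 + len(sides))
    children = [int(c) & 0x7FFFFFFF for c in children]
    reference = simulate_psi(design, trajectories, seed=children[0])
    streams = {
        side: simulate_stream(design, reference, cfg, side=side, seed=children[1 + i])
        for i, side in enumerate(sides)
    }
    return Campaign(design, reference, env_table(season), streams, season, seed)
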