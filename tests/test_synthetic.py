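"""Synthetic campaign generator: design counts, psi_s draws, stream optics,
environment covariates."""

import numpy as np
import pandas as pd
import pytest

from vinespec.synthetic import (
    DATES_2015,
    DATES_2016,
    ConfigurationError,
    StreamConfig,
    build_design,
    default_trajectories,
    env_table,
    simulate_psi,
    simulate_stream,
    vpd,
)

from conftest import psi_for as _psi_for, tiny_design as _tiny_design


class TestDesign:
    @pytest.mark.parametrize(
        "kwargs,slots",
        [
            (dict(dates=DATES_2015), 324),          # 12 reps x 3 tagged x 9 dates
            (dict(dates=DATES_2016), 216),
            (dict(blocks=1, treatments=("T0",), dates=("2015-07-23",)), 3),
        ],
    )
    def test_reference_slot_counts(self, kwargs, slots):
        assert build_design(**kwargs).n_reference_slots == slots

    def test_replicate_structure(self):
        d = build_design()
        assert d.n_replicates == 12
        assert len(d.replicates) == 12
        # every block holds each treatment exactly once
        counts = d.replicates.groupby(["block", "treatment"]).size()
        assert (counts == 1).all()
        # sub-units tile the 15 measured vines disjointly
        vines = np.concatenate([d.sub_unit_vines(s) for s in (1, 2, 3)])
        assert len(set(vines)) == 15
        # one tagged vine per sub-unit, inside that sub-unit
        for s in (1, 2, 3):
            tagged = d.replicates[f"tagged_vine_su{s}"]
            assert tagged.isin(d.sub_unit_vines(s)).all()

    @pytest.mark.parametrize(
        "kwargs", [dict(blocks=0), dict(dates=()), dict(treatments=())]
    )
    def test_empty_design_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            build_design(**kwargs)


class TestPsiSimulation:
    def test_pooled_statistics_match_campaign_summary(self):
        """Pooled full-irrigation draws reproduce the documented campaign
        statistics: mean -0.85 MPa within 3 SE, SD 0.161 within 10%."""
        design = build_design()
        traj = default_trajectories("2015")
        draws = []
        seeds = iter(range(1000, 2000))
        while sum(len(d) for d in draws) < 10_000 * 3:
            ref = simulate_psi(design, traj, seed=next(seeds))
            draws.append(ref[ref["treatment"] == "T0"]["psi_MPa"].to_numpy())
        pooled = np.concatenate(draws)
        se = 0.161 / np.sqrt(pooled.size)
        assert abs(pooled.mean() - (-0.85)) < 3 * se
        assert abs(pooled.std(ddof=1) - 0.161) < 0.10 * 0.161

    def test_zero_sd_reproduces_date_means(self):
        design = build_design(blocks=1)
        traj = {
            t: tr.__class__(t, tr.dates, tr.means, (0.0,) * len(tr.dates), tr.bounds)
            for t, tr in default_trajectories("2015").items()
        }
        ref = simulate_psi(design, traj, seed=0)
        for (date, treatment), g in ref.groupby(["date", "treatment"]):
            i = DATES_2015.index(date)
            assert np.allclose(g["psi_MPa"], traj[treatment].means[i])

    def test_huge_sd_respects_bounds(self):
        design = build_design(blocks=2)
        base = default_trajectories("2015")
        traj = {
            t: tr.__class__(t, tr.dates, tr.means, (5.0,) * len(tr.dates),
                            (-2.25, -0.55))
            for t, tr in base.items()
        }
        ref = simulate_psi(design, traj, seed=3)
        assert (ref["psi_MPa"] >= -2.25).all() and (ref["psi_MPa"] <= -0.55).all()

    def test_seed_reproducibility(self):
        design = build_design()
        traj = default_trajectories("2015")
        a = simulate_psi(design, traj, seed=11)
        b = simulate_psi(design, traj, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_trajectory_rejected(self):
        design = build_design()
        traj = default_trajectories("2015")
        traj.pop("T2")
        with pytest.raises(ConfigurationError):
            simulate_psi(design, traj, seed=0)


class TestVPD:
    @pytest.mark.parametrize(
        "t,rh,expected",
        [(32.0, 36.5, 3.02), (29.1, 40.5, 2.38), (28.2, 35.0, 2.46)],
    )
    def test_campaign_noon_values(self, t, rh, expected):
        assert vpd(t, rh) == pytest.approx(expected, abs=0.05)

    @pytest.mark.parametrize("t", [0.0, 15.0, 40.0])
    def test_saturation_gives_zero(self, t):
        assert vpd(t, 100.0) == 0.0

    @pytest.mark.parametrize("rh", [-1.0, 101.0])
    def test_rh_domain_enforced(self, rh):
        with pytest.raises(ValueError):
            vpd(25.0, rh)

    def test_env_table_consistent(self):
        env = env_table("2015")
        assert len(env) == 9
        assert np.allclose(env["VPD"], vpd(env["air_T"], env["RH"]))


class TestStream:
    def test_stream_geometry(self, clean_stream_cfg):
        """24 Hz at 5 km/h is 17.28 spectra per row metre; every pass emits
        round(rate * row_length / speed) spectra exactly."""
        cfg = clean_stream_cfg
        assert cfg.spectra_per_meter == pytest.approx(17.28)
        design = _tiny_design()
        stream = simulate_stream(design, _psi_for(design), cfg, seed=0)
        expected = round(24 * design.row_length / (5 / 3.6))
        counts = stream.meta.groupby(["date", "replicate_id"]).size()
        assert (counts == expected).all()

    def test_zero_contamination_all_leaf(self, clean_stream_cfg):
        design = _tiny_design()
        stream = simulate_stream(design, _psi_for(design), clean_stream_cfg, seed=0)
        assert (stream.meta["class_tag"] == "leaf").all()

    def test_band_depth_affine_in_psi(self, clean_stream_cfg):
        """With deterministic optics, a 1 MPa psi_s difference changes the
        spectrum by exactly alpha1 times the water-band shape: noiseless
        sub-unit spectra equal the corresponding leaf archetypes, and the
        1450 nm band-depth difference equals |alpha1| (evaluated at the
        nearest grid channel)."""
        from vinespec.synthetic import leaf_signature

        design = _tiny_design()
        psi = _psi_for(design, values=(-1.0, -1.5, -2.0))
        stream = simulate_stream(design, psi, clean_stream_cfg, seed=0)
        su = stream.meta["sub_unit"].to_numpy()
        sig1 = leaf_signature(stream.grid, clean_stream_cfg, psi=-1.0).absorbance
        sig3 = leaf_signature(stream.grid, clean_stream_cfg, psi=-2.0).absorbance
        assert np.allclose(stream.absorbance[su == 1][0], sig1, atol=1e-12)
        assert np.allclose(stream.absorbance[su == 3][0], sig3, atol=1e-12)
        ch = int(np.argmin(np.abs(stream.grid.wavelengths - 1450)))
        diff = stream.absorbance[su == 1, ch].mean() - stream.absorbance[su == 3, ch].mean()
        # exact against the archetype difference; within the half-channel
        # sampling offset of the nominal |alpha1| peak depth
        assert diff == pytest.approx(sig1[ch] - sig3[ch], abs=1e-12)
        assert diff == pytest.approx(clean_stream_cfg.depth_alpha1, abs=2e-3)

    def test_alpha1_scales_band_depth_variance(self, clean_stream_cfg):
        """Between-sample variance of the 1450 nm channel grows strictly
        with |alpha1| for a fixed psi_s spread."""
        design = _tiny_design()
        psi = _psi_for(design, values=(-0.8, -1.5, -2.2))
        variances = []
        for a1 in (0.1, 0.25, 0.5):
            cfg = StreamConfig(
                **{**vars(clean_stream_cfg), "depth_alpha1": a1}
            )
            stream = simulate_stream(design, psi, cfg, seed=5)
            ch = int(np.argmin(np.abs(stream.grid.wavelengths - 1450)))
            keep = stream.meta["sub_unit"] > 0
            su = stream.meta.loc[keep, "sub_unit"].to_numpy()
            vals = stream.absorbance[keep.to_numpy(), ch]
            means = [vals[su == s].mean() for s in (1, 2, 3)]
            variances.append(np.var(means))
        assert variances[0] < variances[1] < variances[2]

    def test_stream_seed_reproducibility(self, clean_stream_cfg):
        design = _tiny_design()
        psi = _psi_for(design)
        a = simulate_stream(design, psi, clean_stream_cfg, seed=9)
        b = simulate_stream(design, psi, clean_stream_cfg, seed=9)
        assert np.array_equal(a.absorbance, b.absorbance)
        pd.testing.assert_frame_equal(a.meta, b.meta)

    def test_empty_psi_rejected(self, clean_stream_cfg):
        design = _tiny_design()
        with pytest.raises(ValueError):
            simulate_stream(design, _psi_for(design).iloc[0:0], clean_stream_cfg)

    def test_campaign_classes_and_structure(self, campaign_2015_east):
        stream = campaign_2015_east.streams["east"]
        tags = set(stream.meta["class_tag"].unique())
        assert tags <= {"leaf", "wood", "metal", "gap"}
        frac = (stream.meta["class_tag"] != "leaf").mean()
        assert frac == pytest.approx(0.15, abs=0.01)
        assert set(stream.meta["sub_unit"].unique()) == {0, 1, 2, 3}
        assert len(campaign_2015_east.reference) == 324


class TestStreamConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(acquisition_rate_hz=0),
            dict(speed_kmh=-1),
            dict(contamination_fraction=1.0),
            dict(noise_sd=-0.1),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            StreamConfig(**kwargs)
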