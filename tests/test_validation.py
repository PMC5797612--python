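"""Splitting, fold construction, cross-validation schemes, side merging and
the end-to-end pipeline."""

import numpy as np
import pandas as pd
import pytest

from vinespec.dataset import CalibrationDataset
from vinespec.pls import pls_fit
from vinespec.validation import (
    SplitSpec,
    aggregate_field_replicates,
    assemble_dataset,
    balanced_merge,
    cross_validate,
    lodo_folds,
    run_campaign,
    split_calibration,
    venetian_folds,
)


def _dataset(n, dates=("d1",), treatments=("T0",), sides=("east",), seed=0, p=5):
    rng = np.random.default_rng(seed)
    labels = pd.DataFrame(
        {
            "date": np.resize(dates, n),
            "treatment": np.resize(treatments, n),
            "side": np.resize(sides, n),
            "replicate_id": np.arange(n) % 12 + 1,
            "sub_unit": np.arange(n) % 3 + 1,
        }
    )
    X = rng.normal(size=(n, p))
    y = -1.0 - np.abs(X[:, 0])
    return CalibrationDataset(X, y, labels)


class TestSplit:
    def test_single_stratum_even_split(self):
        ds = _dataset(10)
        cal, ext = split_calibration(ds, SplitSpec(calibration_fraction=0.5, seed=1))
        assert (len(cal), len(ext)) == (5, 5)

    def test_campaign_strata_give_54_external_samples(self):
        """324 samples in 27 date x treatment strata of 12 at 80/20 leave 54
        external samples."""
        dates = [f"d{i}" for i in range(9)]
        treatments = ["T0", "T1", "T2"]
        labels = pd.DataFrame(
            [
                {"date": d, "treatment": t, "side": "east",
                 "replicate_id": r, "sub_unit": s}
                for d in dates for t in treatments
                for r in range(4) for s in (1, 2, 3)
            ]
        )
        rng = np.random.default_rng(0)
        ds = CalibrationDataset(
            rng.normal(size=(324, 4)), -np.ones(324) - rng.random(324), labels
        )
        cal, ext = split_calibration(ds, SplitSpec(seed=3))
        assert len(ext) == 54
        assert len(cal) == 270

    def test_split_disjoint_and_reproducible(self):
        ds = _dataset(60, dates=("d1", "d2"))
        spec = SplitSpec(seed=9)
        cal1, ext1 = split_calibration(ds, spec)
        cal2, ext2 = split_calibration(ds, spec)
        assert len(cal1) + len(ext1) == 60
        assert np.array_equal(cal1.y, cal2.y) and np.array_equal(ext1.y, ext2.y)
        # no shared rows between calibration and external
        cal_rows = {tuple(r) for r in cal1.X.round(12).tolist()}
        ext_rows = {tuple(r) for r in ext1.X.round(12).tolist()}
        assert not cal_rows & ext_rows

    def test_tiny_stratum_warns_and_stays_in_calibration(self):
        ds = _dataset(13, dates=("d1",) * 12 + ("lonely",))
        with pytest.warns(UserWarning):
            cal, ext = split_calibration(ds, SplitSpec(seed=0))
        assert "lonely" in set(cal.labels["date"])
        assert "lonely" not in set(ext.labels["date"])


class TestFolds:
    def test_venetian_interleaving_pattern(self):
        fa = venetian_folds(10, n_folds=5)
        assert np.array_equal(np.flatnonzero(fa.fold_index == 0), [0, 5])
        assert np.array_equal(np.flatnonzero(fa.fold_index == 1), [1, 6])
        assert fa.n_folds == 5

    def test_venetian_limiting_cases(self):
        loo = venetian_folds(7, n_folds=7)
        assert all(idx.size == 1 for _, idx in loo.folds())
        with pytest.raises(ValueError):
            venetian_folds(7, n_folds=1)
        with pytest.raises(ValueError):
            venetian_folds(5, n_folds=6)

    def test_venetian_partition_property(self):
        fa = venetian_folds(103, n_folds=10)
        covered = np.concatenate([idx for _, idx in fa.folds()])
        assert sorted(covered) == list(range(103))
        sizes = [idx.size for _, idx in fa.folds()]
        assert max(sizes) - min(sizes) <= 1

    def test_lodo_one_fold_per_date(self):
        dates = [f"2015-{i:02d}" for i in range(1, 10)]
        ds = _dataset(324, dates=dates)
        fa = lodo_folds(ds)
        assert fa.n_folds == 9
        for f, idx in fa.folds():
            assert ds.labels.loc[idx, "date"].nunique() == 1
        covered = np.concatenate([idx for _, idx in fa.folds()])
        assert sorted(covered) == list(range(324))

    def test_lodo_needs_two_dates(self):
        with pytest.raises(ValueError):
            lodo_folds(_dataset(12, dates=("only",)))


class TestCrossValidate:
    def test_noiseless_linear_data_reaches_zero_cv_rmse(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 6))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 0.0, 0.0])
        ds = CalibrationDataset(
            X, y, pd.DataFrame({"date": ["d"] * 40, "side": ["east"] * 40})
        )
        cv = cross_validate(ds, venetian_folds(40, 10), None, max_lv=6)
        assert cv["cv_rmse"].min() < 1e-8

    def test_pooled_prediction_count(self):
        ds = _dataset(37, dates=("d1", "d2", "d3"))
        cv = cross_validate(ds, venetian_folds(37, 10), None, max_lv=3)
        assert len(cv) == 3
        assert (cv["cv_rmse"] > 0).all()

    def test_lodo_harder_than_venetian_on_date_confounded_data(self):
        """With a shared per-date spectral offset, leave-one-day-out cannot
        exploit within-date information and its CV-RMSE exceeds the
        venetian-blind one in >= 8 of 10 seeds."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n_dates, per = 6, 20
            n = n_dates * per
            dates = np.repeat([f"d{i}" for i in range(n_dates)], per)
            signal = rng.normal(size=n)
            # per-date spectral signature paired with a per-date response
            # shift: exploitable when folds mix dates, not when a whole
            # date is held out
            date_sig = np.repeat(rng.normal(size=n_dates), per)
            date_shift = np.repeat(rng.normal(scale=0.5, size=n_dates), per)
            X = rng.normal(scale=0.3, size=(n, 8))
            X[:, 0] += signal
            X[:, 1] += date_sig
            y = signal + date_shift + 0.1 * rng.normal(size=n)
            ds = CalibrationDataset(
                X, y, pd.DataFrame({"date": dates, "side": "east"})
            )
            ven = cross_validate(ds, venetian_folds(n, 10), None, max_lv=4)
            lodo = cross_validate(ds, lodo_folds(ds), None, max_lv=4)
            if lodo["cv_rmse"].min() >= ven["cv_rmse"].min():
                wins += 1
        assert wins >= 8


class TestBalancedMerge:
    def test_forced_small_example(self):
        east = _dataset(90, dates=("d1", "d2", "d3"), treatments=("T0", "T1", "T2"))
        west = _dataset(90, dates=("d1", "d2", "d3"), treatments=("T0", "T1", "T2"),
                        sides=("west",), seed=5)
        merged = balanced_merge(east, west, seed=0)
        assert len(merged) == 90
        counts = merged.labels.groupby("side").size()
        assert counts["east"] == 45 and counts["west"] == 45

    def test_per_cell_balance(self):
        east = _dataset(81, dates=("d1", "d2", "d3"), treatments=("T0", "T1", "T2"))
        west = _dataset(81, dates=("d1", "d2", "d3"), treatments=("T0", "T1", "T2"),
                        sides=("west",), seed=8)
        merged = balanced_merge(east, west, seed=2)
        for (_, _), cell in merged.labels.groupby(["date", "treatment"]):
            by_side = cell.groupby("side").size()
            assert abs(by_side.get("east", 0) - by_side.get("west", 0)) <= 1

    def test_seed_reproducible(self):
        east = _dataset(30, dates=("d1", "d2"))
        west = _dataset(30, dates=("d1", "d2"), sides=("west",), seed=3)
        a = balanced_merge(east, west, seed=7)
        b = balanced_merge(east, west, seed=7)
        assert np.array_equal(a.X, b.X)

    def test_empty_cell_rejected(self):
        east = _dataset(30, dates=("d1", "d2"))
        west = _dataset(30, dates=("d1",), sides=("west",))
        with pytest.raises(ValueError, match="d2"):
            balanced_merge(east, west, seed=0)


class TestPipeline:
    def test_assembled_dataset_structure(self, campaign_2015_east):
        ds = assemble_dataset(
            campaign_2015_east.streams["east"],
            campaign_2015_east.reference,
            campaign_2015_east.design,
        )
        assert len(ds) == 324
        assert (ds.y < 0).all()
        assert ds.grid.n_channels == 251
        # ordering contract for systematic folds
        lab = ds.labels
        keys = list(zip(lab["date"], lab["side"], lab["replicate_id"], lab["sub_unit"]))
        assert keys == sorted(keys)

    def test_field_replicate_aggregation(self, campaign_2015_east):
        ds = assemble_dataset(
            campaign_2015_east.streams["east"],
            campaign_2015_east.reference,
            campaign_2015_east.design,
        )
        agg = aggregate_field_replicates(ds)
        assert len(agg) == len(ds) // 3
        one = ds.labels.query("date == '2015-07-23' and replicate_id == 1").index
        row = agg.labels.query("date == '2015-07-23' and replicate_id == 1").index[0]
        assert agg.y[row] == pytest.approx(ds.y[one].mean())
        assert np.allclose(agg.X[row], ds.X[one].mean(axis=0))

    def test_full_run_is_deterministic(self, campaign_2015_east):
        r1 = run_campaign(campaign_2015_east, run_lodo=False)
        r2 = run_campaign(campaign_2015_east, run_lodo=False)
        assert r1.report == r2.report
        assert np.array_equal(
            r1.model.coefficients(), r2.model.coefficients()
        )

    def test_external_set_never_trains_the_model(self, campaign_2015_east):
        """Corrupting external-set responses changes the prediction metrics
        but leaves the fitted model untouched (no leakage)."""
        res = run_campaign(campaign_2015_east, run_lodo=False)
        ext = res.external
        model2 = pls_fit(res.calibration.X, res.calibration.y, res.report.n_lv)
        assert np.allclose(
            model2.coefficients(), res.model.coefficients(), atol=1e-12
        )
        from vinespec.pls import metrics, predict
        shuffled = np.random.default_rng(0).permutation(ext.y)
        r2_shuf, _ = metrics(shuffled, predict(res.model, ext.X))
        assert r2_shuf != pytest.approx(res.report.rp2)

    def test_field_replicate_scale_through_pipeline(self, campaign_2015_east):
        res = run_campaign(
            campaign_2015_east, scale="field_replicate", run_lodo=False, max_lv=10
        )
        assert res.report.n_total == 108
        assert res.report.rp2 <= 1.0

    def test_east_west_model_uses_balanced_sides(self):
        from vinespec import simulate_campaign

        campaign = simulate_campaign("2015", sides=("east", "west"), seed=4)
        res = run_campaign(campaign, side="east_west", run_lodo=False)
        assert res.report.n_total == 324
        sides = res.dataset.labels.groupby("side").size()
        assert abs(sides["east"] - sides["west"]) <= 27  # one per cell at most
        assert res.report.rp2 > 0.5

    def test_artifacts_persisted(self, campaign_2015_east, tmp_path):
        res = run_campaign(campaign_2015_east, outdir=tmp_path / "run")
        for name in (
            "report.csv", "qc_audit.csv", "cv_venetian.csv", "cv_lodo.csv",
            "predictions.csv", "model.json",
        ):
            assert (tmp_path / "run" / name).exists()
        audit = pd.read_csv(tmp_path / "run" / "qc_audit.csv")
        assert audit["removed"].sum() == res.report.n_removed
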