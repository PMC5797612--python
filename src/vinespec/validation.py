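"""Dataset assembly, splitting, cross-validation schemes and the end-to-end
calibration pipeline.

The pipeline mirrors the field workflow: raw stream -> trim to the measured
middle vines of each pass -> leaf-signature filter -> contiguous three-way
allocation -> per-sub-unit average spectrum -> link to the tagged vine's
psi_s -> pretreatment -> PCA Q/T2 outlier removal -> stratified 80/20
calibration/external split -> internal cross-validation (10-fold venetian
blind and leave-one-day-out) -> latent-variable selection by minimum
CV-RMSE -> refit -> external prediction.

Venetian-blind folds interleave systematically (sample at position k joins
fold ``k mod n``), mixing dates across folds; leave-one-day-out (LODO) holds
out all samples of one date per fold, emulating prediction on an unseen
day.  Outlier removal runs once on the full dataset before the split;
model means are refit inside every training fold and the external set is
only ever touched for prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import qc as qc_mod
from .dataset import CalibrationDataset
from .pls import PLSModel, metrics, pls_fit, predict, select_n_lv
from .preprocess import (
    PreprocessConfig,
    SignatureFilterConfig,
    preprocess_matrix,
    signature_filter,
)
from .spectra import SpectraBatch, allocate_stream, average_spectra
from .synthetic import (
    Campaign,
    FieldDesign,
    StreamConfig,
    leaf_signature,
    simulate_campaign,
)

__all__ = [
    "SplitSpec",
    "FoldAssignment",
    "ModelReport",
    "assemble_dataset",
    "aggregate_field_replicates",
    "split_calibration",
    "venetian_folds",
    "lodo_folds",
    "cross_validate",
    "balanced_merge",
    "run_campaign",
    "run_pipeline",
]

#: canonical sample ordering before systematic fold construction
SAMPLE_ORDER = ["date", "side", "replicate_id", "sub_unit"]


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def assemble_dataset(
    stream: SpectraBatch,
    reference: pd.DataFrame,
    design: FieldDesign,
    filter_cfg: SignatureFilterConfig | None = None,
) -> CalibrationDataset:
    """Turn a raw stream plus reference table into paired (X, psi_s) samples.

    Per (date, replicate) pass: the central measured span of the stream is
    kept (the edge vines are discarded positionally, relying on constant
    vehicle speed), the leaf-signature filter removes non-leaf spectra, the
    survivors are allocated into three contiguous groups and averaged, and
    each group average is linked to the psi_s of its sub-unit's tagged vine.
    X holds raw (untreated) mean spectra.
    """
    if filter_cfg is None:
        filter_cfg = SignatureFilterConfig(signature=leaf_signature(stream.grid))
    psi_lookup = reference.set_index(["date", "replicate_id", "sub_unit"])
    lo_frac = design.measured_span[0] / design.row_length
    hi_frac = design.measured_span[1] / design.row_length

    rows_X, rows_y, rows_lab = [], [], []
    meta = stream.meta
    for (date, rid), idx in meta.groupby(["date", "replicate_id"], sort=True).groups.items():
        idx = np.sort(np.asarray(idx))
        n = idx.size
        sel = idx[int(round(n * lo_frac)): int(round(n * hi_frac))]
        segment = stream.subset(sel)
        retained, _ = signature_filter(segment, filter_cfg)
        if len(retained) < design.sub_units_per_replicate:
            warnings.warn(
                f"pass {date}/replicate {rid}: too few leaf spectra after "
                "filtering; sample dropped"
            )
            continue
        groups = allocate_stream(retained, design.sub_units_per_replicate)
        for s, group in enumerate(groups, start=1):
            mean_spec = average_spectra(group)
            try:
                ref = psi_lookup.loc[(date, rid, s)]
            except KeyError:
                warnings.warn(f"no psi reference for {date}/rep {rid}/su {s}")
                continue
            rows_X.append(mean_spec.absorbance)
            rows_y.append(float(ref["psi_MPa"]))
            rows_lab.append(
                {
                    "date": date,
                    "side": segment.meta["side"].iloc[0],
                    "treatment": ref["treatment"],
                    "block": int(ref["block"]),
                    "replicate_id": int(rid),
                    "sub_unit": s,
                    "x": design.sub_unit_centroid_x(s),
                    "y": float(ref["y"]),
                }
            )
    if not rows_X:
        raise ValueError("no samples could be assembled from the stream")
    ds = CalibrationDataset(
        np.vstack(rows_X), np.array(rows_y), pd.DataFrame(rows_lab), stream.grid
    )
    return ds.sort_by(SAMPLE_ORDER)


def aggregate_field_replicates(dataset: CalibrationDataset) -> CalibrationDataset:
    """Average the three sub-unit spectra and psi_s per field replicate.

    The coarser spatial scale (one sample per ~30 m replicate instead of
    per ~6 m sub-unit) runs through the identical downstream pipeline with
    a third of the samples.
    """
    lab = dataset.labels
    keys = ["date", "side", "replicate_id"]
    rows_X, rows_y, rows_lab = [], [], []
    for _, idx in lab.groupby(keys, sort=True).groups.items():
        idx = np.asarray(idx)
        rows_X.append(dataset.X[idx].mean(axis=0))
        rows_y.append(dataset.y[idx].mean())
        rec = lab.iloc[idx[0]].to_dict()
        rec["sub_unit"] = 0
        rec["x"] = float(lab.iloc[idx]["x"].mean())
        rows_lab.append(rec)
    ds = CalibrationDataset(
        np.vstack(rows_X), np.array(rows_y), pd.DataFrame(rows_lab), dataset.grid
    )
    return ds.sort_by(SAMPLE_ORDER)


# ---------------------------------------------------------------------------
# splitting and folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Stratified calibration/external split specification."""

    calibration_fraction: float = 0.80
    keys: tuple[str, ...] = ("date", "treatment", "side")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.calibration_fraction < 1):
            raise ValueError("calibration fraction must lie in (0, 1)")


def split_calibration(
    dataset: CalibrationDataset, spec: SplitSpec
) -> tuple[CalibrationDataset, CalibrationDataset]:
    """Pseudorandom stratified split into calibration and external sets.

    The external fraction is honored within rounding per stratum; strata
    with fewer than two samples go wholly to calibration (with a warning).
    Original sample order is preserved within each output.
    """
    if len(dataset) == 0:
        raise ValueError("cannot split an empty dataset")
    keys = [k for k in spec.keys if k in dataset.labels.columns]
    rng = np.random.default_rng(spec.seed)
    ext_idx: list[int] = []
    groups = dataset.labels.groupby(keys, sort=True).groups if keys else {
        (): dataset.labels.index
    }
    for key, idx in groups.items():
        idx = np.sort(np.asarray(idx))
        if idx.size < 2:
            warnings.warn(f"stratum {key} has <2 samples; kept in calibration")
            continue
        n_ext = round(idx.size * (1.0 - spec.calibration_fraction))
        if n_ext == 0:
            continue
        ext_idx.extend(rng.permutation(idx)[:n_ext].tolist())
    ext_mask = np.zeros(len(dataset), dtype=bool)
    ext_mask[np.array(ext_idx, dtype=int)] = True
    return dataset.subset(~ext_mask), dataset.subset(ext_mask)


@dataclass
class FoldAssignment:
    """Per-sample fold indices for one cross-validation scheme."""

    scheme: str
    fold_index: np.ndarray
    fold_names: tuple = ()

    @property
    def n_folds(self) -> int:
        return int(self.fold_index.max()) + 1

    def folds(self):
        for f in range(self.n_folds):
            yield f, np.flatnonzero(self.fold_index == f)


def venetian_folds(n_samples, n_folds: int = 10) -> FoldAssignment:
    """Systematic interleaved folds: position k joins fold ``k mod n_folds``.

    Samples are assumed ordered by (date, side, replicate, sub_unit), so
    each fold mixes dates and treatments.
    """
    if isinstance(n_samples, CalibrationDataset):
        n_samples = len(n_samples)
    if n_folds < 2:
        raise ValueError("venetian blinds need at least 2 folds")
    if n_folds > n_samples:
        raise ValueError(
            f"cannot build {n_folds} folds from {n_samples} samples"
        )
    return FoldAssignment("venetian", np.arange(n_samples) % n_folds)


def lodo_folds(dataset: CalibrationDataset) -> FoldAssignment:
    """Leave-one-day-out: one fold per distinct measurement date."""
    dates = dataset.labels["date"].to_numpy()
    uniq = tuple(sorted(pd.unique(dates)))
    if len(uniq) < 2:
        raise ValueError("leave-one-day-out needs at least two distinct dates")
    index = {d: i for i, d in enumerate(uniq)}
    return FoldAssignment(
        "lodo", np.array([index[d] for d in dates]), fold_names=uniq
    )


def cross_validate(
    dataset: CalibrationDataset,
    folds: FoldAssignment,
    preprocess_cfg: PreprocessConfig | str | None = None,
    max_lv: int = 15,
) -> pd.DataFrame:
    """CV-RMSE and Rcv2 for every latent-variable count up to ``max_lv``.

    For each fold, a model is fitted on the remaining folds and predicts
    the held-out fold; predictions are pooled over folds before computing
    metrics.  Pretreatments act per spectrum (no parameters are estimated
    from other samples) and model means are refit inside each training
    fold, so no information leaks from the held-out samples.
    """
    X, grid = dataset.X, dataset.grid
    if preprocess_cfg is not None:
        X, grid = preprocess_matrix(X, grid, preprocess_cfg)
    y = dataset.y
    n = len(dataset)
    lv_cap = max_lv
    fold_models = []
    for f, test_idx in folds.folds():
        if test_idx.size < 1:
            raise ValueError(f"fold {f} is empty")
        train = np.setdiff1d(np.arange(n), test_idx)
        a = min(max_lv, train.size - 1, X.shape[1])
        model = pls_fit(X[train], y[train], a)
        lv_cap = min(lv_cap, model.n_lv)
        fold_models.append((model, test_idx))

    rows = []
    for a in range(1, lv_cap + 1):
        pooled = np.empty(n)
        for model, test_idx in fold_models:
            pooled[test_idx] = predict(model, X[test_idx], n_lv=a)
        r2, rmse = metrics(y, pooled)
        rows.append({"n_lv": a, "cv_rmse": rmse, "rcv2": r2})
    return pd.DataFrame(rows)


def balanced_merge(
    east: CalibrationDataset, west: CalibrationDataset, seed: int = 0
) -> CalibrationDataset:
    """Merge the two canopy sides into one balanced dataset.

    Pseudorandomly selects the same number of samples per (side, treatment,
    date) cell (up to one sample when the cell total is odd), so the merged
    dataset is as representative as a single-side one and has the size of
    one side.
    """
    rng = np.random.default_rng(seed)
    cells = sorted(
        set(map(tuple, east.labels[["date", "treatment"]].itertuples(index=False)))
        | set(map(tuple, west.labels[["date", "treatment"]].itertuples(index=False)))
    )
    pieces = []
    for date, treatment in cells:
        ie = np.flatnonzero(
            (east.labels["date"] == date) & (east.labels["treatment"] == treatment)
        )
        iw = np.flatnonzero(
            (west.labels["date"] == date) & (west.labels["treatment"] == treatment)
        )
        if ie.size == 0 or iw.size == 0:
            raise ValueError(
                f"cell (date={date}, treatment={treatment}) empty on one side"
            )
        target = ie.size
        k_e = target // 2
        k_w = target - k_e
        if target % 2 and rng.integers(2):
            k_e, k_w = k_w, k_e
        k_e, k_w = min(k_e, ie.size), min(k_w, iw.size)
        pieces.append(east.subset(np.sort(rng.permutation(ie)[:k_e])))
        pieces.append(west.subset(np.sort(rng.permutation(iw)[:k_w])))
    X = np.vstack([p.X for p in pieces])
    y = np.concatenate([p.y for p in pieces])
    labels = pd.concat([p.labels for p in pieces], ignore_index=True)
    merged = CalibrationDataset(X, y, labels, east.grid)
    return merged.sort_by(SAMPLE_ORDER)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class ModelReport:
    """Calibration / cross-validation / prediction statistics of one model."""

    season: str
    side: str
    scale: str
    preprocess: str
    n_lv: int
    n_total: int
    n_removed: int
    n_calibration: int
    n_external: int
    rc2: float
    rmse_c: float
    rcv2_venetian: float
    cv_rmse_venetian: float
    rcv2_lodo: float | None
    cv_rmse_lodo: float | None
    rp2: float
    rmse_p: float

    @property
    def removal_rate_pct(self) -> float:
        """Share of assembled samples discarded as atypical, in percent."""
        return round(100.0 * self.n_removed / self.n_total, 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])

    def __str__(self) -> str:  # compact Table-style row
        lodo = (
            f"LODO CV-RMSE={self.cv_rmse_lodo:.3f} Rcv2={self.rcv2_lodo:.2f}  "
            if self.cv_rmse_lodo is not None
            else ""
        )
        return (
            f"[{self.season} {self.side} {self.scale} {self.preprocess} "
            f"LV={self.n_lv}]  RMSEC={self.rmse_c:.3f} Rc2={self.rc2:.2f}  "
            f"10-fold CV-RMSE={self.cv_rmse_venetian:.3f} "
            f"Rcv2={self.rcv2_venetian:.2f}  {lodo}"
            f"RMSEP={self.rmse_p:.3f} Rp2={self.rp2:.2f}"
        )


@dataclass
class PipelineResult:
    """Full pipeline output: the report plus every intermediate artifact."""

    report: ModelReport
    model: PLSModel
    dataset: CalibrationDataset
    calibration: CalibrationDataset
    external: CalibrationDataset
    cv_venetian: pd.DataFrame
    cv_lodo: pd.DataFrame | None
    qc_audit: pd.DataFrame
    predictions: pd.DataFrame


def run_campaign(
    campaign: Campaign,
    side: str = "east",
    scale: str = "sub_unit",
    preprocess: str = "SNV+D1W15",
    qc_alpha: float = 0.95,
    split: SplitSpec | None = None,
    n_folds: int = 10,
    max_lv: int = 15,
    run_lodo: bool = True,
    outdir=None,
) -> PipelineResult:
    """Run the full calibration pipeline on one campaign.

    ``side`` is ``"east"``, ``"west"`` or ``"east_west"`` (balanced merge of
    both sides); ``scale`` is ``"sub_unit"`` or ``"field_replicate"``.
    """
    split = split or SplitSpec(seed=campaign.seed & 0x7FFFFFFF)
    design = campaign.design

    def side_dataset(s: str) -> CalibrationDataset:
        if s not in campaign.streams:
            raise ValueError(f"campaign has no stream for side {s!r}")
        return assemble_dataset(campaign.streams[s], campaign.reference, design)

    if side == "east_west":
        ds = balanced_merge(
            side_dataset("east"), side_dataset("west"), seed=split.seed
        )
    else:
        ds = side_dataset(side)

    if scale == "field_replicate":
        ds = aggregate_field_replicates(ds)
    elif scale != "sub_unit":
        raise ValueError(f"unknown scale {scale!r}")

    # pretreatment, then one-shot PCA Q/T2 screening of the whole dataset
    Xp, grid_p = preprocess_matrix(ds.X, ds.grid, preprocess)
    ds_p = CalibrationDataset(Xp, ds.y, ds.labels, grid_p)
    qc_model = qc_mod.fit_qc_model(ds_p.X, alpha=qc_alpha)
    clean, removed_idx, qc_res = qc_mod.flag_and_remove(ds_p, qc_model)
    qc_audit = ds_p.labels.copy()
    qc_audit["Q"] = qc_res.Q
    qc_audit["T2"] = qc_res.T2
    qc_audit["Q_limit"] = qc_res.Q_limit
    qc_audit["T2_limit"] = qc_res.T2_limit
    qc_audit["removed"] = False
    qc_audit.loc[removed_idx, "removed"] = True

    cal, ext = split_calibration(clean, split)
    if len(ext) < 2:
        raise ValueError("external set too small; adjust the split fraction")

    cv_ven = cross_validate(cal, venetian_folds(cal, n_folds), None, max_lv)
    n_lv = select_n_lv(cv_ven["cv_rmse"])
    cv_lodo = None
    if run_lodo and cal.labels["date"].nunique() > 1:
        cv_lodo = cross_validate(cal, lodo_folds(cal), None, max_lv)

    model = pls_fit(
        cal.X, cal.y, n_lv,
        meta={
            "preprocess": preprocess,
            "side": side,
            "scale": scale,
            "season": campaign.season,
            "grid": [grid_p.start, grid_p.stop, grid_p.step],
        },
    )
    rc2, rmse_c = metrics(cal.y, predict(model, cal.X))
    y_hat_ext = predict(model, ext.X)
    rp2, rmse_p = metrics(ext.y, y_hat_ext)

    def _at(cv: pd.DataFrame, a: int, col: str) -> float:
        row = cv[cv["n_lv"] == a]
        return float(row[col].iloc[0]) if len(row) else float(cv[col].iloc[-1])

    report = ModelReport(
        season=campaign.season,
        side=side,
        scale=scale,
        preprocess=preprocess,
        n_lv=model.n_lv,
        n_total=len(ds),
        n_removed=int(len(removed_idx)),
        n_calibration=len(cal),
        n_external=len(ext),
        rc2=rc2,
        rmse_c=rmse_c,
        rcv2_venetian=_at(cv_ven, n_lv, "rcv2"),
        cv_rmse_venetian=_at(cv_ven, n_lv, "cv_rmse"),
        rcv2_lodo=_at(cv_lodo, n_lv, "rcv2") if cv_lodo is not None else None,
        cv_rmse_lodo=_at(cv_lodo, n_lv, "cv_rmse") if cv_lodo is not None else None,
        rp2=rp2,
        rmse_p=rmse_p,
    )
    predictions = ext.labels.copy()
    predictions["psi_MPa"] = ext.y
    predictions["psi_pred_MPa"] = y_hat_ext

    result = PipelineResult(
        report=report,
        model=model,
        dataset=ds_p,
        calibration=cal,
        external=ext,
        cv_venetian=cv_ven,
        cv_lodo=cv_lodo,
        qc_audit=qc_audit,
        predictions=predictions,
    )
    if outdir is not None:
        _persist(result, Path(outdir))
    return result


def _persist(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.report.to_frame().to_csv(outdir / "report.csv", index=False)
    result.qc_audit.to_csv(outdir / "qc_audit.csv", index=False)
    result.cv_venetian.to_csv(outdir / "cv_venetian.csv", index=False)
    if result.cv_lodo is not None:
        result.cv_lodo.to_csv(outdir / "cv_lodo.csv", index=False)
    result.predictions.to_csv(outdir / "predictions.csv", index=False)
    result.model.to_json(outdir / "model.json")


def run_pipeline(config) -> PipelineResult:
    """Run the pipeline from a configuration mapping or YAML path.

    Minimal synthetic-campaign configuration::

        campaign:
          season: "2015"
          sides: [east]
          seed: 1
          stream: {contamination_fraction: 0.15}
        model:
          side: east
          scale: sub_unit
          preprocess: SNV+D1W15
          n_folds: 10
          max_lv: 15
        output:
          dir: runs/demo
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    camp_cfg = dict(config.get("campaign", {}))
    stream_cfg = StreamConfig(**camp_cfg.pop("stream", {}))
    model_cfg = dict(config.get("model", {}))
    side = model_cfg.pop("side", "east")
    sides = tuple(camp_cfg.pop("sides", ("east", "west") if side == "east_west" else (side,)))
    campaign = simulate_campaign(
        season=str(camp_cfg.get("season", "2015")),
        sides=sides,
        cfg=stream_cfg,
        seed=int(camp_cfg.get("seed", 0)),
    )
    outdir = config.get("output", {}).get("dir")
    split_cfg = model_cfg.pop("split", None)
    split = SplitSpec(**split_cfg) if split_cfg else None
    return run_campaign(campaign, side=side, split=split, outdir=outdir, **model_cfg)
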