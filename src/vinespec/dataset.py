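"""Paired (spectrum, psi_s) calibration dataset container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import WavelengthGrid

__all__ = ["CalibrationDataset"]


@dataclass
class CalibrationDataset:
    """Aligned X (samples x channels), y (psi_s, MPa) and sample labels.

    ``labels`` carries at least ``date, side, treatment, replicate_id,
    sub_unit`` (plus plot coordinates when available); row order matches X
    and y and defines the sample ordering used by systematic fold
    construction.
    """

    X: np.ndarray
    y: np.ndarray
    labels: pd.DataFrame
    grid: WavelengthGrid | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y row counts differ")
        if len(self.labels) != self.y.size:
            raise ValueError("labels length does not match sample count")
        self.labels = self.labels.reset_index(drop=True)

    def __len__(self) -> int:
        return self.y.size

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    def subset(self, index) -> "CalibrationDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CalibrationDataset(
            self.X[index], self.y[index], self.labels.iloc[index], self.grid
        )

    def sort_by(self, keys: list[str]) -> "CalibrationDataset":
        order = self.labels.sort_values(keys, kind="mergesort").index.to_numpy()
        return self.subset(order)
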