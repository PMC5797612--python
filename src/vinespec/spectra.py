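"""Core spectral data model: wavelength grids, spectra, batches, I/O and
stream allocation.

The instrument emulated here samples absorbance on a fixed inclusive
wavelength grid (default 1100-2100 nm in 4 nm steps, 251 channels).  A
:class:`SpectraBatch` holds an ordered stack of spectra sharing one grid,
with per-spectrum acquisition metadata; acquisition order is meaningful
because stream-to-vine allocation is positional (the vehicle moves at
constant speed along the row).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "SpectraBatch",
    "SpectraFormatError",
    "make_grid",
    "allocate_stream",
    "average_spectra",
    "read_batch",
    "write_batch",
    "concat_batches",
]

#: metadata columns carried by every batch, in CSV column order
META_COLUMNS = ("date", "side", "replicate_id", "sub_unit", "timestamp", "class_tag")


class SpectraFormatError(ValueError):
    """Raised when a spectra file does not conform to the wide-CSV layout."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Inclusive, uniformly spaced wavelength axis in nanometres."""

    start: float
    stop: float
    step: float

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError(f"stop ({self.stop}) must exceed start ({self.start})")
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")
        span = self.stop - self.start
        ratio = span / self.step
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"grid span {span} nm is not divisible by step {self.step} nm"
            )

    @property
    def n_channels(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_channels)

    def column_names(self) -> list[str]:
        return [f"a{w:g}" for w in self.wavelengths]

    def trim(self, n_left: int, n_right: int) -> "WavelengthGrid":
        """Grid with ``n_left``/``n_right`` channels dropped at either edge."""
        if n_left + n_right >= self.n_channels:
            raise ValueError("cannot trim all channels away")
        return WavelengthGrid(
            self.start + n_left * self.step,
            self.stop - n_right * self.step,
            self.step,
        )


def make_grid(start: float, stop: float, step: float) -> WavelengthGrid:
    """Build an inclusive wavelength grid; the span must divide evenly by step."""
    return WavelengthGrid(float(start), float(stop), float(step))


@dataclass
class Spectrum:
    """Single absorbance spectrum on a grid, with acquisition metadata."""

    grid: WavelengthGrid
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 1:
            raise ValueError("absorbance must be one-dimensional")
        if self.absorbance.size != self.grid.n_channels:
            raise ValueError(
                f"absorbance has {self.absorbance.size} values but the grid "
                f"defines {self.grid.n_channels} channels"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance values must be finite")


class SpectraBatch:
    """Ordered stack of spectra on a shared grid.

    Parameters
    ----------
    grid:
        Shared wavelength grid.
    absorbance:
        ``(n_spectra, n_channels)`` float array.
    meta:
        Optional per-spectrum metadata frame; missing standard columns are
        added empty.  Row order matches ``absorbance`` and encodes
        acquisition order.
    """

    def __init__(
        self,
        grid: WavelengthGrid,
        absorbance: np.ndarray,
        meta: pd.DataFrame | None = None,
    ) -> None:
        absorbance = np.asarray(absorbance, dtype=float)
        if absorbance.ndim != 2:
            raise ValueError("absorbance must be 2-D (spectra x channels)")
        if absorbance.shape[1] != grid.n_channels:
            raise ValueError(
                f"absorbance has {absorbance.shape[1]} channels, grid defines "
                f"{grid.n_channels}"
            )
        if not np.all(np.isfinite(absorbance)):
            raise ValueError("absorbance values must be finite")
        if meta is None:
            meta = pd.DataFrame(index=range(absorbance.shape[0]))
        if len(meta) != absorbance.shape[0]:
            raise ValueError("metadata length does not match spectrum count")
        meta = meta.reset_index(drop=True).copy()
        for col in META_COLUMNS:
            if col not in meta.columns:
                meta[col] = pd.NA
        self.grid = grid
        self.absorbance = absorbance
        self.meta = meta

    def __len__(self) -> int:
        return self.absorbance.shape[0]

    def __getitem__(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.absorbance[i], self.meta.iloc[i].to_dict())

    def subset(self, index) -> "SpectraBatch":
        """Batch restricted to a boolean mask or integer index array."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SpectraBatch(
            self.grid, self.absorbance[index], self.meta.iloc[index]
        )

    @classmethod
    def from_spectra(cls, spectra: list[Spectrum]) -> "SpectraBatch":
        if not spectra:
            raise ValueError("cannot build a batch from zero spectra")
        grid = spectra[0].grid
        for s in spectra[1:]:
            if s.grid != grid:
                raise ValueError("all spectra must share one wavelength grid")
        return cls(
            grid,
            np.vstack([s.absorbance for s in spectra]),
            pd.DataFrame([s.meta for s in spectra]),
        )


def concat_batches(batches: list[SpectraBatch]) -> SpectraBatch:
    """Concatenate batches in order; grids must match exactly."""
    if not batches:
        raise ValueError("no batches to concatenate")
    grid = batches[0].grid
    for b in batches[1:]:
        if b.grid != grid:
            raise ValueError("grid mismatch between batches")
    return SpectraBatch(
        grid,
        np.vstack([b.absorbance for b in batches]),
        pd.concat([b.meta for b in batches], ignore_index=True),
    )


def allocate_stream(batch: SpectraBatch, n_groups: int = 3) -> list[SpectraBatch]:
    """Partition a stream into contiguous, order-preserving groups.

    The vehicle moves at constant speed, so equal contiguous slices of the
    stream correspond to equal lengths of row: the default three groups map
    onto the three five-vine sub-replicate units of a monitored segment.
    Group sizes differ by at most one; earlier groups absorb the remainder.
    """
    n = len(batch)
    if n == 0:
        raise ValueError("cannot allocate an empty stream")
    if n_groups < 1:
        raise ValueError("n_groups must be at least 1")
    if n_groups > n:
        raise ValueError(f"cannot split {n} spectra into {n_groups} groups")
    # remainder spectra go to the earliest groups
    sizes = [n // n_groups + (1 if i < n % n_groups else 0) for i in range(n_groups)]
    out = []
    start = 0
    for size in sizes:
        out.append(batch.subset(np.arange(start, start + size)))
        start += size
    return out


def average_spectra(batch: SpectraBatch) -> Spectrum:
    """Channel-wise arithmetic mean of a batch.

    Metadata (date, side, replicate, sub-unit) is inherited from the first
    spectrum of the group; the timestamp becomes the group mean.
    """
    if len(batch) == 0:
        raise ValueError("cannot average an empty batch")
    meta = batch.meta.iloc[0].to_dict()
    ts = pd.to_numeric(batch.meta["timestamp"], errors="coerce")
    meta["timestamp"] = float(ts.mean()) if ts.notna().any() else pd.NA
    meta["class_tag"] = pd.NA
    return Spectrum(batch.grid, batch.absorbance.mean(axis=0), meta)


def write_batch(batch: SpectraBatch, path) -> None:
    """Write a batch as wide CSV.

    Layout: ``date,side,replicate_id,sub_unit,timestamp,class_tag,a1100,...``
    with absorbance printed at 17 significant digits so that the float64
    round-trip is bitwise exact.
    """
    df = batch.meta.loc[:, list(META_COLUMNS)].copy()
    values = pd.DataFrame(
        batch.absorbance, columns=batch.grid.column_names(), index=df.index
    )
    pd.concat([df, values], axis=1).to_csv(path, index=False, float_format="%.17g")


def read_batch(path) -> SpectraBatch:
    """Read a wide-CSV batch written by :func:`write_batch`."""
    try:
        # round_trip parsing keeps the 17-digit output bitwise exact
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SpectraFormatError(f"{path}: empty spectra file") from exc
    except pd.errors.ParserError as exc:
        raise SpectraFormatError(f"{path}: malformed spectra file") from exc
    if len(df) == 0:
        raise SpectraFormatError(f"{path}: spectra file contains no spectra")
    wave_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not wave_cols:
        raise SpectraFormatError(f"{path}: no wavelength columns found")
    try:
        waves = np.array([float(c.lstrip("a")) for c in wave_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: unparseable wavelength column") from exc
    if len(waves) < 2:
        raise SpectraFormatError(f"{path}: need at least two wavelength channels")
    steps = np.diff(waves)
    if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
        raise SpectraFormatError(f"{path}: wavelength columns are not uniform")
    grid = WavelengthGrid(float(waves[0]), float(waves[-1]), float(steps[0]))
    values = df[wave_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise SpectraFormatError(
            f"{path}: missing or non-numeric absorbance values "
            "(row/column count mismatch?)"
        )
    meta = df[[c for c in META_COLUMNS if c in df.columns]]
    return SpectraBatch(grid, values, meta)
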