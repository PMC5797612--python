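"""Spectral pretreatments and leaf-signature stream filtering.

Two pretreatments are supported, applied left to right in a configurable
pipeline:

* SNV (standard normal variate): per-spectrum centering and scaling,
  removing additive baseline and multiplicative scatter effects.
* Savitzky-Golay smoothing/derivative: local least-squares polynomial
  convolution.  Derivatives are expressed per nanometre (scaled by the grid
  step) and edge channels are dropped rather than padded, so a window of
  ``w`` channels shrinks the grid by ``w - 1``.

Shorthand codes follow chemometrics convention: ``"SNV+D1W15"`` means SNV
followed by a first derivative over a 15-channel window (polynomial order 2).

Stream filtering compares every raw spectrum against a static, well-taken
leaf signature: spectra are retained when their Pearson correlation with the
signature (both SNV-normalized first) reaches the threshold and their raw
mean absorbance falls inside the configured gates.  This rejects gaps in the
canopy, wood, and trellis-post metal before any averaging.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectraBatch, Spectrum, WavelengthGrid

__all__ = [
    "SNVStep",
    "SGStep",
    "PreprocessConfig",
    "SignatureFilterConfig",
    "snv",
    "savgol",
    "apply_pipeline",
    "preprocess_matrix",
    "signature_filter",
]


@dataclass(frozen=True)
class SNVStep:
    def code(self) -> str:
        return "SNV"


@dataclass(frozen=True)
class SGStep:
    window: int
    polyorder: int = 2
    deriv: int = 1

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValueError(
                f"SG window must be odd and exceed polyorder "
                f"(window={self.window}, polyorder={self.polyorder})"
            )
        if self.deriv > self.polyorder:
            raise ValueError("derivative order cannot exceed polynomial order")

    def code(self) -> str:
        return f"D{self.deriv}W{self.window}"


_SG_RE = re.compile(r"^D(\d+)W(\d+)$")


@dataclass(frozen=True)
class PreprocessConfig:
    """Ordered pretreatment pipeline; parse/emit shorthand codes."""

    steps: tuple = ()

    @classmethod
    def from_code(cls, code: str) -> "PreprocessConfig":
        code = code.strip()
        if not code or code.lower() == "none":
            return cls(())
        steps = []
        for part in code.split("+"):
            part = part.strip()
            if part.upper() == "SNV":
                steps.append(SNVStep())
                continue
            m = _SG_RE.match(part.upper())
            if not m:
                raise ValueError(f"unrecognized preprocessing code {part!r}")
            steps.append(SGStep(window=int(m.group(2)), deriv=int(m.group(1))))
        return cls(tuple(steps))

    def code(self) -> str:
        return "+".join(s.code() for s in self.steps) if self.steps else "none"


def _as_config(cfg) -> PreprocessConfig:
    return PreprocessConfig.from_code(cfg) if isinstance(cfg, str) else cfg


def _snv_rows(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("SNV undefined for a constant spectrum")
    return (x - x.mean(axis=1, keepdims=True)) / sd


def snv(spectrum):
    """Standard normal variate: per-spectrum ``(x - mean) / sd`` (sample SD).

    Accepts a :class:`Spectrum`, a :class:`SpectraBatch`, or a plain array
    (1-D spectrum or 2-D stack of row spectra); returns the same kind.
    """
    if isinstance(spectrum, Spectrum):
        return Spectrum(
            spectrum.grid, _snv_rows(spectrum.absorbance[None, :])[0],
            dict(spectrum.meta),
        )
    if isinstance(spectrum, SpectraBatch):
        return SpectraBatch(
            spectrum.grid, _snv_rows(spectrum.absorbance), spectrum.meta
        )
    x = np.asarray(spectrum, dtype=float)
    return _snv_rows(x[None, :])[0] if x.ndim == 1 else _snv_rows(x)


def _savgol_rows(
    x: np.ndarray, grid: WavelengthGrid, window: int, polyorder: int, deriv: int
) -> tuple[np.ndarray, WavelengthGrid]:
    SGStep(window=window, polyorder=polyorder, deriv=deriv)  # validate
    if window > grid.n_channels:
        raise ValueError("SG window exceeds the number of channels")
    out = savgol_filter(
        x, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=grid.step, axis=-1,
    )
    half = window // 2
    return out[..., half:-half], grid.trim(half, half)


def savgol(spectrum: Spectrum, window: int, polyorder: int = 2, deriv: int = 1) -> Spectrum:
    """Savitzky-Golay smoothing/derivative of a single spectrum.

    The derivative is per nanometre; the ``window // 2`` edge channels on
    each side are dropped.
    """
    vals, grid = _savgol_rows(
        spectrum.absorbance, spectrum.grid, window, polyorder, deriv
    )
    return Spectrum(grid, vals, dict(spectrum.meta))


def preprocess_matrix(
    x: np.ndarray, grid: WavelengthGrid, cfg
) -> tuple[np.ndarray, WavelengthGrid]:
    """Apply a pretreatment pipeline to a (samples x channels) matrix."""
    cfg = _as_config(cfg)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    for step in cfg.steps:
        if isinstance(step, SNVStep):
            x = _snv_rows(x)
        elif isinstance(step, SGStep):
            x, grid = _savgol_rows(x, grid, step.window, step.polyorder, step.deriv)
        else:  # pragma: no cover - config is closed
            raise TypeError(f"unknown preprocessing step {step!r}")
    return x, grid


def apply_pipeline(spectrum, cfg):
    """Apply a pretreatment pipeline to a Spectrum or SpectraBatch."""
    cfg = _as_config(cfg)
    if isinstance(spectrum, Spectrum):
        vals, grid = preprocess_matrix(spectrum.absorbance[None, :], spectrum.grid, cfg)
        return Spectrum(grid, vals[0], dict(spectrum.meta))
    if isinstance(spectrum, SpectraBatch):
        vals, grid = preprocess_matrix(spectrum.absorbance, spectrum.grid, cfg)
        return SpectraBatch(grid, vals, spectrum.meta)
    raise TypeError("apply_pipeline expects a Spectrum or SpectraBatch")


# ---------------------------------------------------------------------------
# leaf-signature stream filtering
# ---------------------------------------------------------------------------

@dataclass
class SignatureFilterConfig:
    """Leaf-signature comparison settings.

    ``threshold`` is the minimum Pearson correlation (on SNV-normalized
    spectra) against the signature; ``mean_gate`` bounds the raw mean
    absorbance, rejecting near-zero gap readings and saturated returns that
    could still correlate with the signature shape.
    """

    signature: Spectrum
    threshold: float = 0.90
    mean_gate: tuple[float, float] = (0.15, 1.5)

    def __post_init__(self) -> None:
        if not (-1.0 <= self.threshold <= 1.0):
            raise ValueError("correlation threshold must lie in [-1, 1]")


def signature_filter(
    batch: SpectraBatch, cfg: SignatureFilterConfig
) -> tuple[SpectraBatch, SpectraBatch]:
    """Split a raw stream into (retained leaf-like, rejected) spectra.

    The partition is exhaustive: every input spectrum lands in exactly one
    of the two output batches, in original order.
    """
    if batch.grid != cfg.signature.grid:
        raise ValueError("signature and batch are on different wavelength grids")
    p = batch.grid.n_channels
    sig = _snv_rows(cfg.signature.absorbance[None, :])[0]

    x = batch.absorbance
    sd = x.std(axis=1, ddof=1)
    safe = sd > 0
    corr = np.zeros(len(batch))
    if safe.any():
        xs = (x[safe] - x[safe].mean(axis=1, keepdims=True)) / sd[safe, None]
        # SNV'd vectors have zero mean and unit sample SD, so the Pearson
        # correlation reduces to a scaled dot product
        corr[safe] = xs @ sig / (p - 1)
    mean_abs = x.mean(axis=1)
    lo, hi = cfg.mean_gate
    keep = (corr >= cfg.threshold) & (mean_abs >= lo) & (mean_abs <= hi)
    return batch.subset(keep), batch.subset(~keep)
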