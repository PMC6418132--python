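"""Coefficient selection and mid-tread quantization.

Two thinning routes feed the quantizer:

* method (a): keep the smallest set of largest-magnitude wavelet
  coefficients whose discarded energy stays below ``tol**2`` (cumulative
  energy selection, ``slwc``), then quantize;
* method (b): quantize every coefficient and let the quantizer's dead zone
  around zero do all the thinning.

The quantizer is mid-tread uniform: ``q = floor(c/delta + 1/2)`` applied to
the signed coefficient, so values within delta/2 of zero vanish.  Signs are
split off into a binary stream (1 for +, 0 for -) and zero-quantized
entries are eliminated together with their indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dwt import CoeffVector

__all__ = [
    "SelectedCoeffs",
    "QuantizedCoeffs",
    "slwc",
    "select_all",
    "tol_from_prd0",
    "quantize",
    "dequantize",
]


@dataclass
class SelectedCoeffs:
    """Kept coefficient values and their 0-based positions in the flat vector."""

    values: np.ndarray
    indices: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if len(self.values) != len(self.indices):
            raise ValueError("values/indices length mismatch")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("indices must be distinct")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class QuantizedCoeffs:
    """Quantizer output before index packing.

    ``magnitudes`` are the absolute quantized integers (all >= 1; entries
    quantized to zero have been eliminated), ``signs`` the binary sign
    stream (1 = positive), ``indices`` the surviving 0-based coefficient
    positions, ``delta`` the quantization step.
    """

    magnitudes: np.ndarray
    signs: np.ndarray
    indices: np.ndarray
    delta: float

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.uint64)
        self.signs = np.asarray(self.signs, dtype=np.uint8)
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if not (len(self.magnitudes) == len(self.signs) == len(self.indices)):
            raise ValueError("stream lengths differ")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if len(self.magnitudes) and self.magnitudes.min() < 1:
            raise ValueError("zero magnitudes must be eliminated before storage")

    def __len__(self) -> int:
        return len(self.magnitudes)


def slwc(w: CoeffVector | np.ndarray, tol: float) -> SelectedCoeffs:
    """Selection of the largest wavelet coefficients by cumulative energy.

    Sort ``|w|`` ascending, accumulate squared magnitudes ``t(n)`` and find
    the smallest ``n`` with ``t(n) >= tol**2``; everything from that rank
    up is kept, so the discarded energy is strictly below ``tol**2``.
    Ties in ``|w|`` break toward the smaller original index, making the
    result independent of the sorting backend.

    With ``tol = 0`` every coefficient is kept.  If even the total energy
    is below ``tol**2`` the selection is empty.
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    values = w.values if isinstance(w, CoeffVector) else np.asarray(w, dtype=np.float64)
    absw = np.abs(values)
    order = np.argsort(absw, kind="stable")  # ascending; stable = index tie-break
    t = np.cumsum(absw[order] ** 2)
    first = int(np.searchsorted(t, tol * tol, side="left"))
    kept = order[first:]
    return SelectedCoeffs(values=values[kept], indices=kept)


def select_all(w: CoeffVector | np.ndarray) -> SelectedCoeffs:
    """Method (b) front end: pass every coefficient through unselected."""
    values = w.values if isinstance(w, CoeffVector) else np.asarray(w, dtype=np.float64)
    return SelectedCoeffs(values=values, indices=np.arange(len(values)))


def tol_from_prd0(signal_norm: float, prd0: float) -> float:
    """Energy tolerance giving a pre-quantization distortion of ``prd0`` percent.

    For an orthonormal transform, discarding coefficient energy below
    ``tol**2 = (prd0 * ||f|| / 100)**2`` bounds the reconstruction PRD by
    ``prd0``.
    """
    if signal_norm <= 0:
        raise ValueError("signal norm must be positive")
    if prd0 < 0:
        raise ValueError("prd0 must be non-negative")
    return prd0 * signal_norm / 100.0


def quantize(selected: SelectedCoeffs, delta: float) -> QuantizedCoeffs:
    """Mid-tread uniform quantization of signed coefficients.

    ``q(i) = floor(c(i)/delta + 1/2)``; entries with ``q = 0`` are dropped
    along with their indices.  The kept entries obey
    ``|c(i) - delta * q(i)| <= delta/2``.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    q = np.floor(selected.values / delta + 0.5).astype(np.int64)
    keep = q != 0
    q = q[keep]
    return QuantizedCoeffs(
        magnitudes=np.abs(q).astype(np.uint64),
        signs=(q > 0).astype(np.uint8),
        indices=selected.indices[keep],
        delta=float(delta),
    )


def dequantize(quantized: QuantizedCoeffs) -> SelectedCoeffs:
    """Recover coefficient values ``delta * magnitude * (2*sign - 1)``."""
    signs = 2.0 * quantized.signs.astype(np.float64) - 1.0
    values = quantized.delta * quantized.magnitudes.astype(np.float64) * signs
    return SelectedCoeffs(values=values, indices=quantized.indices)
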