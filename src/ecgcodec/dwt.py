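"""Multilevel discrete wavelet transform with flat-vector bookkeeping.

The codec operates on a single concatenated coefficient vector **w**
(approximation band first, then detail bands coarsest to finest) so that a
kept coefficient is addressed by one integer index.  This module wraps
PyWavelets for the filter-bank work and keeps the band bookkeeping needed
to invert exactly.

``cdf97`` names the 9/7-tap Cohen-Daubechies-Feauveau biorthogonal pair
(PyWavelets ``bior4.4``), the basis recommended for ECG at decomposition
level 4; ``db5``, ``sym4`` and ``coif4`` are the orthonormal alternatives
in the comparison grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .signal_io import Signal

__all__ = ["FAMILIES", "TransformSpec", "CoeffVector", "forward", "inverse", "band_lengths"]

# codec-facing family name -> PyWavelets wavelet name
FAMILIES = {
    "db5": "db5",
    "coif4": "coif4",
    "sym4": "sym4",
    "cdf97": "bior4.4",
}

ORTHONORMAL = {"db5", "coif4", "sym4"}


@dataclass(frozen=True)
class TransformSpec:
    """Wavelet family, decomposition level and boundary extension mode."""

    family: str = "cdf97"
    level: int = 4
    extension_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown wavelet family {self.family!r}; choose from {sorted(FAMILIES)}"
            )
        if self.level < 1:
            raise ValueError("decomposition level must be >= 1")

    @property
    def wavelet(self) -> pywt.Wavelet:
        return pywt.Wavelet(FAMILIES[self.family])

    @property
    def is_orthonormal(self) -> bool:
        return self.family in ORTHONORMAL


@dataclass
class CoeffVector:
    """Concatenated multilevel wavelet coefficients of one signal.

    ``values`` holds the approximation band followed by detail bands from
    coarsest to finest; ``band_lengths`` records the split points and
    ``n_signal`` the original signal length, which together suffice for
    exact inversion.
    """

    values: np.ndarray
    band_lengths: list[int]
    spec: TransformSpec
    n_signal: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if int(np.sum(self.band_lengths)) != len(self.values):
            raise ValueError(
                f"band_lengths sum {int(np.sum(self.band_lengths))} != "
                f"coefficient count {len(self.values)}"
            )

    def __len__(self) -> int:
        return len(self.values)

    def split_bands(self) -> list[np.ndarray]:
        return np.split(self.values, np.cumsum(self.band_lengths)[:-1])

    def with_values(self, values: np.ndarray) -> "CoeffVector":
        return CoeffVector(values, list(self.band_lengths), self.spec, self.n_signal)


def _max_level(n: int, spec: TransformSpec) -> int:
    return pywt.dwt_max_level(n, spec.wavelet.dec_len)


def band_lengths(n_signal: int, spec: TransformSpec) -> list[int]:
    """Band lengths of the flat vector, derivable from (N, family, level, mode).

    The decoder recomputes these instead of storing them, so the container
    only needs N and the transform descriptor.
    """
    w = spec.wavelet
    lengths_fine_to_coarse = []
    n = n_signal
    for _ in range(spec.level):
        n = pywt.dwt_coeff_len(n, w.dec_len, spec.extension_mode)
        lengths_fine_to_coarse.append(n)
    # approximation band has the same length as the coarsest detail band
    return [lengths_fine_to_coarse[-1]] + lengths_fine_to_coarse[::-1]


def forward(signal: Signal | np.ndarray, spec: TransformSpec) -> CoeffVector:
    """Multilevel forward DWT producing the flat coefficient vector."""
    data = signal.samples if isinstance(signal, Signal) else np.asarray(signal)
    data = data.astype(np.float64)
    if data.ndim != 1 or data.size < spec.wavelet.dec_len:
        raise ValueError(
            f"signal length {data.size} below filter support {spec.wavelet.dec_len}"
        )
    if spec.level > _max_level(data.size, spec):
        raise ValueError(
            f"level {spec.level} too deep for length {data.size} "
            f"(max {_max_level(data.size, spec)})"
        )
    coeffs = pywt.wavedec(data, spec.wavelet, mode=spec.extension_mode, level=spec.level)
    lengths = [len(c) for c in coeffs]
    expected = band_lengths(data.size, spec)
    assert lengths == expected, (lengths, expected)
    return CoeffVector(np.concatenate(coeffs), lengths, spec, data.size)


def inverse(coeffs: CoeffVector) -> np.ndarray:
    """Invert the transform; returns a float array of length ``n_signal``."""
    if int(np.sum(coeffs.band_lengths)) != len(coeffs.values):
        raise ValueError("band_lengths inconsistent with coefficient vector")
    if coeffs.band_lengths != band_lengths(coeffs.n_signal, coeffs.spec):
        raise ValueError("band_lengths inconsistent with spec/n_signal")
    rec = pywt.waverec(
        coeffs.split_bands(), coeffs.spec.wavelet, mode=coeffs.spec.extension_mode
    )
    # boundary extension can overshoot the original length by one sample
    return np.asarray(rec[: coeffs.n_signal], dtype=np.float64)
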