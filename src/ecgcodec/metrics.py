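"""Distortion and compression-performance metrics.

PRD (percentage root-mean-square difference) on raw stored samples is the
headline distortion number; PRDN removes the signal mean in the
denominator and is therefore baseline-independent.  CR is the plain size
ratio of uncompressed to compressed file, QS = CR / PRD the tradeoff
score.  The local prd partitions a record into consecutive length-L
segments and locates the worst-approximated stretch of signal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "prd",
    "prdn",
    "cr",
    "qs",
    "gain",
    "local_prd",
    "worst_segment",
    "uncompressed_size",
    "QualityReport",
    "evaluate",
]


def _as_float(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def prd(f, fr) -> float:
    """100 * ||f - fr|| / ||f|| on raw samples (offset included)."""
    f, fr = _as_float(f), _as_float(fr)
    if f.shape != fr.shape:
        raise ValueError("signals must have equal length")
    nf = np.linalg.norm(f)
    if nf == 0:
        raise ValueError("PRD undefined for a zero-norm signal")
    return float(100.0 * np.linalg.norm(f - fr) / nf)


def prdn(f, fr) -> float:
    """PRD with the mean of f removed from the denominator."""
    f, fr = _as_float(f), _as_float(fr)
    if f.shape != fr.shape:
        raise ValueError("signals must have equal length")
    denom = np.linalg.norm(f - f.mean())
    if denom == 0:
        raise ValueError("PRDN undefined for a constant signal")
    return float(100.0 * np.linalg.norm(f - fr) / denom)


def cr(uncompressed_bytes: float, compressed_bytes: float) -> float:
    """Compression ratio: uncompressed size over compressed size."""
    if uncompressed_bytes <= 0 or compressed_bytes <= 0:
        raise ValueError("sizes must be positive")
    return float(uncompressed_bytes) / float(compressed_bytes)


def qs(cr_value: float, prd_value: float) -> float:
    """Quality score CR / PRD."""
    if prd_value <= 0:
        raise ValueError("QS undefined for non-positive PRD")
    return float(cr_value) / float(prd_value)


def gain(cr1: float, cr2: float) -> float:
    """Relative CR gain of approach 1 over approach 2, in percent."""
    if cr2 <= 0:
        raise ValueError("reference CR must be positive")
    return 100.0 * (cr1 - cr2) / cr2


def local_prd(f, fr, segment_len: int) -> tuple[np.ndarray, float, float]:
    """Per-segment prd over consecutive length-L blocks, with mean and std.

    The record is split into Q = floor(len/L) full segments; a trailing
    partial segment is dropped.  The std uses the unbiased 1/(Q-1)
    divisor and requires Q >= 2.
    """
    if segment_len < 1:
        raise ValueError("segment length must be >= 1")
    f, fr = _as_float(f), _as_float(fr)
    if f.shape != fr.shape:
        raise ValueError("signals must have equal length")
    n_seg = len(f) // segment_len
    if n_seg < 1:
        raise ValueError("signal shorter than one segment")
    fq = f[: n_seg * segment_len].reshape(n_seg, segment_len)
    frq = fr[: n_seg * segment_len].reshape(n_seg, segment_len)
    norms = np.linalg.norm(fq, axis=1)
    if np.any(norms == 0):
        raise ValueError("a segment has zero norm; local prd undefined")
    prds = 100.0 * np.linalg.norm(fq - frq, axis=1) / norms
    mean = float(prds.mean())
    if n_seg < 2:
        raise ValueError("std requires at least two segments")
    std = float(math.sqrt(np.sum((prds - mean) ** 2) / (n_seg - 1)))
    return prds, mean, std


def worst_segment(prds: np.ndarray) -> int:
    """Index of the maximum local prd; ties break toward the smallest index."""
    return int(np.argmax(prds))


def uncompressed_size(n_samples: int, adc_bits: int = 11, convention: str = "11bit") -> int:
    """Reference uncompressed size in bytes for the CR numerator.

    Conventions: ``11bit`` packs N samples at adc_bits bits each (the
    default, matching an 11-bit ADC record); ``16bit`` counts a plain
    int16 file (2 bytes/sample); ``wfdb`` counts the on-disk format-212
    packing (3 bytes per 2 samples).
    """
    if convention == "11bit":
        return math.ceil(n_samples * adc_bits / 8)
    if convention == "16bit":
        return 2 * n_samples
    if convention == "wfdb":
        return math.ceil(n_samples * 3 / 2)
    raise ValueError(f"unknown uncompressed-size convention {convention!r}")


@dataclass
class QualityReport:
    """All evaluation quantities for one record."""

    record_id: str
    prd: float
    prdn: float
    cr: float
    qs: float
    prd_mean: float
    prd_std: float
    worst_segment: int
    segment_len: int
    n_segments: int
    local_prds: np.ndarray = field(repr=False, default=None)

    def to_row(self) -> dict:
        """Flat dict in the benchmark table's column layout."""
        return {
            "record": self.record_id,
            "prd_mean": round(self.prd_mean, 4),
            "prd_std": round(self.prd_std, 4),
            "PRD": round(self.prd, 4),
            "CR": round(self.cr, 4),
            "QS": round(self.qs, 4),
            "PRDN": round(self.prdn, 4),
        }

    def to_json(self) -> str:
        d = {k: v for k, v in asdict(self).items() if k != "local_prds"}
        return json.dumps(d, indent=2)


def evaluate(
    f,
    fr,
    uncompressed_bytes: float,
    compressed_bytes: float,
    segment_len: int = 2000,
    record_id: str = "",
) -> QualityReport:
    """Assemble the full quality report for one compressed record."""
    prds, mean, std = local_prd(f, fr, segment_len)
    prd_value = prd(f, fr)
    cr_value = cr(uncompressed_bytes, compressed_bytes)
    return QualityReport(
        record_id=record_id,
        prd=prd_value,
        prdn=prdn(f, fr),
        cr=cr_value,
        qs=qs(cr_value, prd_value),
        prd_mean=mean,
        prd_std=std,
        worst_segment=worst_segment(prds),
        segment_len=segment_len,
        n_segments=len(prds),
        local_prds=prds,
    )
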