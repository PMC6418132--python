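"""Index re-organization and the lossless coding stages.

The surviving coefficient positions are large, sparse integers.  They are
stored cheaply by sorting ascending (which re-orders magnitudes and signs
identically) and keeping first differences: the delta stream starts with
the first index written 1-based, and every later entry is the gap to the
previous index, so all entries are >= 1 and small.  Recovery is a prefix
sum.  (In-memory indices are 0-based; the 1-based shift happens inside the
delta coding so that stored deltas are strictly positive.)

Two alternative stages used for storage comparisons live here as well: a
run-length code of the binary significance map, and a canonical Huffman
code for unsigned integer symbol streams.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .coder import QuantizedCoeffs

__all__ = [
    "PackedStreams",
    "pack_indices",
    "unpack_indices",
    "rl_encode_significance",
    "rl_decode_significance",
    "HuffmanCode",
    "huffman_encode",
    "huffman_decode",
]


@dataclass
class PackedStreams:
    """Storage-ready streams: delta-coded indices with co-sorted payload."""

    delta_indices: np.ndarray
    magnitudes: np.ndarray
    signs: np.ndarray
    delta: float

    def __post_init__(self) -> None:
        self.delta_indices = np.asarray(self.delta_indices, dtype=np.uint64)
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.uint64)
        self.signs = np.asarray(self.signs, dtype=np.uint8)
        if not (
            len(self.delta_indices) == len(self.magnitudes) == len(self.signs)
        ):
            raise ValueError("stream lengths differ")
        if len(self.delta_indices) and self.delta_indices.min() < 1:
            raise ValueError("index deltas must be >= 1 (indices strictly increasing)")

    def __len__(self) -> int:
        return len(self.delta_indices)


def pack_indices(quantized: QuantizedCoeffs) -> PackedStreams:
    """Sort surviving entries by coefficient index and delta-code the indices.

    The first delta is the first (sorted) index written 1-based; subsequent
    deltas are consecutive differences, which are >= 1 because indices are
    distinct.
    """
    idx = quantized.indices
    if len(np.unique(idx)) != len(idx):
        raise ValueError("duplicate coefficient indices")
    order = np.argsort(idx, kind="stable")
    sorted_idx = idx[order].astype(np.int64)
    deltas = np.empty(len(sorted_idx), dtype=np.uint64)
    if len(sorted_idx):
        deltas[0] = sorted_idx[0] + 1  # 1-based on disk
        deltas[1:] = np.diff(sorted_idx)
    return PackedStreams(
        delta_indices=deltas,
        magnitudes=quantized.magnitudes[order],
        signs=quantized.signs[order],
        delta=quantized.delta,
    )


def unpack_indices(deltas: np.ndarray) -> np.ndarray:
    """Prefix-sum recovery of the 0-based sorted index array."""
    deltas = np.asarray(deltas, dtype=np.uint64)
    if len(deltas) == 0:
        return np.empty(0, dtype=np.int64)
    if deltas.min() < 1:
        raise ValueError("index deltas must all be >= 1")
    return np.cumsum(deltas.astype(np.int64)) - 1


# ---------------------------------------------------------------------------
# run-length baseline
# ---------------------------------------------------------------------------


def rl_encode_significance(indices: np.ndarray, n_total: int) -> np.ndarray:
    """Run-length code of the significance map.

    The map is the length-``n_total`` binary vector with ones at the given
    (0-based, sorted, distinct) positions.  Runs alternate starting with
    the leading zero-run, whose length may be 0; all other runs are >= 1.
    """
    idx = np.asarray(indices, dtype=np.int64)
    if len(idx):
        if idx.min() < 0 or idx.max() >= n_total:
            raise ValueError("index out of range of the significance map")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("indices must be sorted and distinct")
    mask = np.zeros(n_total, dtype=np.uint8)
    mask[idx] = 1
    # boundaries where the bit flips
    change = np.flatnonzero(np.diff(mask)) + 1
    bounds = np.concatenate([[0], change, [n_total]])
    runs = np.diff(bounds)
    if n_total and mask[0] == 1:
        runs = np.concatenate([[0], runs])  # leading zero-run of length 0
    return runs.astype(np.uint64)


def rl_decode_significance(runs: np.ndarray) -> tuple[np.ndarray, int]:
    """Inverse of :func:`rl_encode_significance`: (indices, n_total)."""
    runs = np.asarray(runs, dtype=np.int64)
    n_total = int(runs.sum())
    bounds = np.concatenate([[0], np.cumsum(runs)])
    idx = [
        np.arange(bounds[i], bounds[i + 1])
        for i in range(1, len(runs), 2)  # odd runs are one-runs
    ]
    indices = np.concatenate(idx) if idx else np.empty(0, dtype=np.int64)
    return indices, n_total


# ---------------------------------------------------------------------------
# canonical Huffman
# ---------------------------------------------------------------------------


@dataclass
class HuffmanCode:
    """A canonical Huffman code table.

    ``symbols`` are the distinct source symbols sorted in canonical order
    (by code length, then value); ``lengths`` the matching codeword bit
    lengths.  Canonical codes are assigned left-to-right in that order, so
    the table alone reconstructs the code.
    """

    symbols: np.ndarray
    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.uint64)
        self.lengths = np.asarray(self.lengths, dtype=np.uint8)

    def codewords(self) -> dict[int, tuple[int, int]]:
        """symbol -> (code value, bit length) under canonical assignment."""
        codes: dict[int, tuple[int, int]] = {}
        code = 0
        prev_len = int(self.lengths[0]) if len(self.lengths) else 0
        for sym, length in zip(self.symbols, self.lengths):
            code <<= int(length) - prev_len
            codes[int(sym)] = (code, int(length))
            code += 1
            prev_len = int(length)
        return codes


def _code_lengths(symbols: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Huffman code lengths from symbol frequencies (heap construction)."""
    if len(symbols) == 1:
        return np.array([1], dtype=np.uint8)
    # heap entries: (count, tiebreak, set-of-leaf-positions)
    heap = [(int(c), i, [i]) for i, c in enumerate(counts)]
    heapq.heapify(heap)
    lengths = np.zeros(len(symbols), dtype=np.uint8)
    tiebreak = len(symbols)
    while len(heap) > 1:
        c1, _, l1 = heapq.heappop(heap)
        c2, _, l2 = heapq.heappop(heap)
        merged = l1 + l2
        lengths[merged] += 1
        heapq.heappush(heap, (c1 + c2, tiebreak, merged))
        tiebreak += 1
    return lengths


def huffman_encode(symbol_stream: np.ndarray) -> tuple[np.ndarray, int, HuffmanCode]:
    """Encode an unsigned integer stream with a canonical Huffman code.

    Returns ``(packed_bytes, n_bits, code)``; the final byte is zero-padded.
    """
    stream = np.asarray(symbol_stream, dtype=np.uint64)
    if stream.size == 0:
        raise ValueError("cannot Huffman-encode an empty stream")
    symbols, inverse, counts = np.unique(stream, return_inverse=True, return_counts=True)
    lengths = _code_lengths(symbols, counts)
    canonical = np.lexsort((symbols, lengths))  # by length then symbol value
    code = HuffmanCode(symbols=symbols[canonical], lengths=lengths[canonical])
    codes = code.codewords()
    # per-distinct-symbol bit patterns, then gather per stream position
    sym_bits = {
        s: np.array([(v >> (L - 1 - b)) & 1 for b in range(L)], dtype=np.uint8)
        for s, (v, L) in codes.items()
    }
    per_symbol = [sym_bits[int(s)] for s in symbols]
    bits = np.concatenate([per_symbol[i] for i in inverse])
    return np.packbits(bits), int(bits.size), code


def huffman_decode(
    packed: np.ndarray, n_bits: int, code: HuffmanCode
) -> np.ndarray:
    """Exact inverse of :func:`huffman_encode`."""
    bits = np.unpackbits(np.asarray(packed, dtype=np.uint8))[:n_bits]
    by_len_code = {
        (L, v): s for s, (v, L) in code.codewords().items()
    }
    out = []
    acc = 0
    length = 0
    for bit in bits:
        acc = (acc << 1) | int(bit)
        length += 1
        sym = by_len_code.get((length, acc))
        if sym is not None:
            out.append(sym)
            acc = 0
            length = 0
    if length:
        raise ValueError("trailing bits do not form a codeword")
    return np.array(out, dtype=np.uint64)
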