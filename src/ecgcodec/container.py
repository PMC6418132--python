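"""Chunked, gzip-compressed HDF5 container for the packed streams.

Layout (version "1"): scalar datasets ``n_signal`` (uint32) and ``delta``
(float64); integer streams ``magnitudes`` and ``delta_indices`` stored in
the narrowest unsigned dtype that fits their maximum; the sign stream
packed 8 bits per byte in ``signs`` (bit count in attribute ``n_entries``).
The transform descriptor and signal metadata live in root attributes.
Every array dataset is chunked and DEFLATE-compressed; the chunk size and
gzip level are recorded as attributes because the achieved compression
ratio depends on them.

Two optional storage variants mirror published comparisons: Huffman coding
of the integer streams before storage (attribute ``huffman``), and a
run-length-coded significance map instead of delta-coded indices
(attribute ``index_coding`` = "rl").  All variants decode to identical
streams.

Datasets are written with HDF5 time tracking off, so identical inputs and
settings produce byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .dwt import TransformSpec
from .index_packing import (
    HuffmanCode,
    PackedStreams,
    huffman_decode,
    huffman_encode,
    rl_decode_significance,
    rl_encode_significance,
    unpack_indices,
)

__all__ = ["ContainerData", "ContainerFormatError", "write_container", "read_container"]

LAYOUT_VERSION = "1"


class ContainerFormatError(Exception):
    """The file does not conform to the expected container layout."""


@dataclass
class ContainerData:
    """Everything read back from a container file."""

    streams: PackedStreams
    n_signal: int
    delta: float
    spec: TransformSpec
    fs: float
    adc_bits: int
    baseline: int
    record_id: str
    huffman: bool
    index_coding: str
    gzip_level: int
    chunk_bytes: int


def _narrow_uint(values: np.ndarray) -> np.ndarray:
    """Narrowest unsigned dtype holding max(values); widens, never truncates."""
    hi = int(values.max()) if len(values) else 0
    for dt in (np.uint8, np.uint16, np.uint32, np.uint64):
        if hi <= np.iinfo(dt).max:
            return values.astype(dt)
    raise OverflowError("value exceeds uint64")


def _write_array(
    group: h5py.File, name: str, values: np.ndarray, gzip_level: int, chunk_bytes: int
) -> h5py.Dataset:
    values = _narrow_uint(np.asarray(values)) if values.dtype.kind == "u" else values
    if values.size == 0:
        return group.create_dataset(name, data=values, track_times=False)
    chunk = max(1, min(values.size, chunk_bytes // values.dtype.itemsize))
    return group.create_dataset(
        name,
        data=values,
        chunks=(chunk,),
        compression="gzip",
        compression_opts=gzip_level,
        shuffle=False,
        track_times=False,
    )


def write_container(
    path: str | Path,
    streams: PackedStreams,
    n_signal: int,
    spec: TransformSpec,
    *,
    fs: float = 360.0,
    adc_bits: int = 11,
    baseline: int = 0,
    record_id: str = "",
    huffman: bool = False,
    index_coding: str = "delta",
    gzip_level: int = 4,
    chunk_bytes: int = 65536,
) -> int:
    """Persist the packed streams; returns the on-disk file size in bytes."""
    if index_coding not in ("delta", "rl"):
        raise ValueError(f"unknown index coding {index_coding!r}")
    path = Path(path)
    # libver="latest" uses the compact metadata layout; container overhead
    # would otherwise dominate the compressed size of sparse payloads
    with h5py.File(path, "w", libver="latest") as f:
        f.attrs["layout_version"] = LAYOUT_VERSION
        f.attrs["family"] = spec.family
        f.attrs["level"] = np.int64(spec.level)
        f.attrs["extension_mode"] = spec.extension_mode
        f.attrs["fs"] = float(fs)
        f.attrs["adc_bits"] = np.int64(adc_bits)
        f.attrs["baseline"] = np.int64(baseline)
        f.attrs["record_id"] = record_id
        f.attrs["huffman"] = bool(huffman)
        f.attrs["index_coding"] = index_coding
        f.attrs["gzip_level"] = np.int64(gzip_level)
        f.attrs["chunk_bytes"] = np.int64(chunk_bytes)
        f.create_dataset("n_signal", data=np.uint32(n_signal), track_times=False)
        f.create_dataset("delta", data=np.float64(streams.delta), track_times=False)

        if index_coding == "delta":
            index_stream = streams.delta_indices
            index_name = "delta_indices"
        else:
            indices = unpack_indices(streams.delta_indices)
            # the map spans the whole coefficient vector; its length is
            # recoverable from n_signal+spec, but the total of the runs
            # must cover it, so encode against the coefficient count
            from .dwt import band_lengths  # local import to avoid cycle at module load

            n_coeffs = int(np.sum(band_lengths(n_signal, spec)))
            index_stream = rl_encode_significance(indices, n_coeffs)
            index_name = "runs"

        packed_signs = np.packbits(streams.signs)
        if huffman:
            for name, data in (
                ("magnitudes", streams.magnitudes),
                (index_name, index_stream),
            ):
                bits, n_bits, code = huffman_encode(data)
                _write_array(f, f"{name}_bits", bits, gzip_level, chunk_bytes)
                _write_array(
                    f, f"{name}_symbols", _narrow_uint(code.symbols), gzip_level, chunk_bytes
                )
                _write_array(f, f"{name}_codelens", code.lengths, gzip_level, chunk_bytes)
                f[f"{name}_bits"].attrs["n_bits"] = np.int64(n_bits)
        else:
            _write_array(f, "magnitudes", streams.magnitudes, gzip_level, chunk_bytes)
            _write_array(f, index_name, index_stream, gzip_level, chunk_bytes)
        ds = _write_array(f, "signs", packed_signs, gzip_level, chunk_bytes)
        ds.attrs["n_entries"] = np.int64(len(streams.signs))
    return os.path.getsize(path)


def _read_stream(f: h5py.File, name: str, huffman: bool) -> np.ndarray:
    if huffman:
        try:
            bits_ds = f[f"{name}_bits"]
            code = HuffmanCode(
                symbols=f[f"{name}_symbols"][()], lengths=f[f"{name}_codelens"][()]
            )
        except KeyError as exc:
            raise ContainerFormatError(f"missing Huffman dataset for {name!r}") from exc
        return huffman_decode(bits_ds[()], int(bits_ds.attrs["n_bits"]), code)
    try:
        return f[name][()]
    except KeyError as exc:
        raise ContainerFormatError(f"missing dataset {name!r}") from exc


def read_container(path: str | Path) -> ContainerData:
    """Read a container back into exact streams plus metadata."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        version = f.attrs.get("layout_version")
        if version != LAYOUT_VERSION:
            raise ContainerFormatError(f"unknown layout version {version!r}")
        huffman = bool(f.attrs["huffman"])
        index_coding = str(f.attrs["index_coding"])
        try:
            n_signal = int(f["n_signal"][()])
            delta = float(f["delta"][()])
        except KeyError as exc:
            raise ContainerFormatError(f"missing dataset: {exc}") from exc
        magnitudes = _read_stream(f, "magnitudes", huffman)
        if index_coding == "delta":
            delta_indices = _read_stream(f, "delta_indices", huffman)
        else:
            runs = _read_stream(f, "runs", huffman)
            indices, _ = rl_decode_significance(runs)
            delta_indices = np.empty(len(indices), dtype=np.uint64)
            if len(indices):
                delta_indices[0] = indices[0] + 1
                delta_indices[1:] = np.diff(indices)
        try:
            signs_ds = f["signs"]
        except KeyError as exc:
            raise ContainerFormatError("missing dataset 'signs'") from exc
        n_entries = int(signs_ds.attrs["n_entries"])
        signs = np.unpackbits(signs_ds[()])[:n_entries]
        spec = TransformSpec(
            family=str(f.attrs["family"]),
            level=int(f.attrs["level"]),
            extension_mode=str(f.attrs["extension_mode"]),
        )
        streams = PackedStreams(
            delta_indices=delta_indices.astype(np.uint64),
            magnitudes=magnitudes.astype(np.uint64),
            signs=signs,
            delta=delta,
        )
        return ContainerData(
            streams=streams,
            n_signal=n_signal,
            delta=delta,
            spec=spec,
            fs=float(f.attrs["fs"]),
            adc_bits=int(f.attrs["adc_bits"]),
            baseline=int(f.attrs["baseline"]),
            record_id=str(f.attrs["record_id"]),
            huffman=huffman,
            index_coding=index_coding,
            gzip_level=int(f.attrs["gzip_level"]),
            chunk_bytes=int(f.attrs["chunk_bytes"]),
        )
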