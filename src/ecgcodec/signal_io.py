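"""Reading, writing and synthesising single-channel ECG signals.

Real records come from WFDB format-212 files (the packing used by the
MIT-BIH Arrhythmia database: two 12-bit two's-complement samples in three
bytes).  Plain numeric vectors can be read from CSV (one value per line) or
raw little-endian int16 with a JSON sidecar.  A deterministic synthetic
generator produces quasi-periodic P-QRS-T morphology so the whole codec is
testable without any database download.

Samples are kept exactly as stored by the ADC: integers including the ADC
offset (1024 for an 11-bit MIT-BIH record).  No baseline subtraction or
physical-unit scaling happens at read time; distortion metrics on raw
stored values are the headline convention and baseline handling is an
explicit, separate choice downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Signal",
    "SynthConfig",
    "read_wfdb",
    "write_wfdb",
    "read_vector",
    "write_vector",
    "generate_synthetic_ecg",
]


@dataclass
class Signal:
    """A single-channel digitised signal in raw ADC units.

    Parameters
    ----------
    samples : ndarray of int
        Stored ADC integers (offset included, e.g. centred near 1024 for
        an 11-bit MIT-BIH lead).
    fs : float
        Sampling frequency in Hz.
    adc_bits : int
        ADC resolution in bits per sample.
    baseline : int
        ADC offset (stored value corresponding to 0 V), e.g. 1024.
    record_id : str
        Label for reports.
    """

    samples: np.ndarray
    fs: float
    adc_bits: int = 11
    baseline: int = 1024
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.issubdtype(self.samples.dtype, np.integer):
            if not np.allclose(self.samples, np.round(self.samples)):
                raise ValueError("samples must be integer-valued ADC units")
            self.samples = np.round(self.samples).astype(np.int64)
        lo, hi = int(self.samples.min()), int(self.samples.max())
        full = 1 << self.adc_bits
        half = full // 2
        # stored values must fit adc_bits: unsigned [0, 2^b) or
        # two's complement [-2^(b-1), 2^(b-1))
        unsigned_ok = 0 <= lo and hi < full
        signed_ok = -half <= lo and hi < half
        if not (unsigned_ok or signed_ok):
            raise ValueError(
                f"samples [{lo}, {hi}] do not fit in {self.adc_bits} bits"
            )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def norm(self) -> float:
        """Euclidean norm of the raw stored samples."""
        return float(np.linalg.norm(self.samples.astype(np.float64)))

    def with_samples(self, samples: np.ndarray) -> "Signal":
        return replace(self, samples=samples)


# ---------------------------------------------------------------------------
# WFDB format 212
# ---------------------------------------------------------------------------


def _unpack_212(raw: bytes, n_samples: int) -> np.ndarray:
    """Decode a format-212 byte stream into 12-bit two's-complement ints.

    Layout per 3-byte group: byte0 = low 8 bits of sample 1; low nibble of
    byte1 = high 4 bits of sample 1; high nibble of byte1 = high 4 bits of
    sample 2; byte2 = low 8 bits of sample 2.
    """
    need = (n_samples + 1) // 2 * 3
    if len(raw) < need:
        raise ValueError(
            f"format-212 stream too short: {len(raw)} bytes for {n_samples} samples"
        )
    b = np.frombuffer(raw[:need], dtype=np.uint8).reshape(-1, 3).astype(np.int32)
    s1 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s2 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * len(b), dtype=np.int32)
    out[0::2] = s1
    out[1::2] = s2
    out[out > 2047] -= 4096  # sign-extend 12-bit two's complement
    return out[:n_samples]


def _pack_212(samples: np.ndarray) -> bytes:
    """Inverse of :func:`_unpack_212`; pads an odd-length stream with 0."""
    s = np.asarray(samples, dtype=np.int64)
    if s.size % 2:
        s = np.concatenate([s, [0]])
    if s.min() < -2048 or s.max() > 2047:
        raise ValueError("format 212 holds 12-bit two's-complement values only")
    u = np.where(s < 0, s + 4096, s).astype(np.uint16)
    s1, s2 = u[0::2], u[1::2]
    b = np.empty((len(s1), 3), dtype=np.uint8)
    b[:, 0] = s1 & 0xFF
    b[:, 1] = ((s1 >> 8) & 0x0F) | (((s2 >> 8) & 0x0F) << 4)
    b[:, 2] = s2 & 0xFF
    return b.tobytes()


def _parse_header(header_path: Path) -> tuple[str, int, float, int, list[dict]]:
    lines = [
        ln.strip()
        for ln in header_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ValueError(f"empty header file {header_path}")
    rec = lines[0].split()
    record_name = rec[0].split("/")[0]
    n_sig = int(rec[1])
    fs = float(rec[2]) if len(rec) > 2 else 250.0
    n_samples = int(rec[3]) if len(rec) > 3 else 0
    sigs = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        fmt = tok[1].split("x")[0].split(":")[0].split("+")[0]
        gain_field = tok[2] if len(tok) > 2 else "200"
        gain_field = gain_field.split("/")[0]
        if "(" in gain_field:
            gain_field = gain_field[: gain_field.index("(")]
        adc_res = int(tok[3]) if len(tok) > 3 else 12
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        sigs.append(
            {
                "filename": tok[0],
                "format": fmt,
                "adc_res": adc_res,
                "adc_zero": adc_zero,
                "description": tok[8] if len(tok) > 8 else "",
            }
        )
    return record_name, n_sig, fs, n_samples, sigs


def read_wfdb(header_path: str | Path, channel: int = 0) -> Signal:
    """Read one channel of a WFDB format-212 record as raw ADC integers.

    No rescaling and no baseline subtraction is applied: an 11-bit MIT-BIH
    lead comes back as stored integers near 1024.

    Parameters
    ----------
    header_path : path to the ``.hea`` file.
    channel : which signal of the record to extract (default 0, first lead).
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    record_name, n_sig, fs, n_samples, sigs = _parse_header(header_path)
    if not 0 <= channel < n_sig:
        raise IndexError(f"channel {channel} out of range for {n_sig} signals")
    info = sigs[channel]
    if info["format"] != "212":
        raise ValueError(f"unsupported WFDB format {info['format']!r} (only 212)")
    dat_path = header_path.parent / info["filename"]
    if not dat_path.exists():
        raise FileNotFoundError(dat_path)
    raw = dat_path.read_bytes()
    if len(raw) % 3:
        raise ValueError(f"{dat_path}: format-212 file length not a multiple of 3")
    total = n_samples * n_sig if n_samples else (len(raw) // 3) * 2
    flat = _unpack_212(raw, total)
    samples = flat[channel::n_sig]
    return Signal(
        samples=samples,
        fs=fs,
        adc_bits=info["adc_res"],
        baseline=info["adc_zero"],
        record_id=f"{record_name}:{info['description'] or channel}",
    )


def write_wfdb(signal: Signal, header_path: str | Path) -> None:
    """Write a single-channel format-212 record (``.hea`` + ``.dat``)."""
    header_path = Path(header_path)
    name = header_path.stem
    dat = header_path.with_suffix(".dat")
    s = signal.samples.astype(np.int64)
    first = int(s[0])
    checksum = int(np.sum(s, dtype=np.int64) % 65536)
    header_path.write_text(
        f"{name} 1 {signal.fs:g} {len(s)}\n"
        f"{dat.name} 212 200 {signal.adc_bits} {signal.baseline} "
        f"{first} {checksum} 0 {signal.record_id or 'ch0'}\n"
    )
    dat.write_bytes(_pack_212(s))


# ---------------------------------------------------------------------------
# plain vectors
# ---------------------------------------------------------------------------


def read_vector(
    path: str | Path,
    format: str = "csv",
    fs: float | None = None,
    adc_bits: int | None = None,
    baseline: int | None = None,
) -> Signal:
    """Read a one-column numeric vector (CSV or raw little-endian int16).

    Binary vectors look for a ``<path>.json`` sidecar carrying fs/adc_bits/
    baseline; explicit keyword arguments override sidecar or defaults.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict = {}
    if format == "csv":
        text = path.read_text().strip()
        if not text:
            raise ValueError(f"{path} is empty")
        try:
            samples = np.array([float(x) for x in text.split()], dtype=np.float64)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric content") from exc
    elif format == "binary":
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        raw = path.read_bytes()
        if not raw:
            raise ValueError(f"{path} is empty")
        samples = np.frombuffer(raw, dtype="<i2").astype(np.int64)
    else:
        raise ValueError(f"unknown vector format {format!r}")
    return Signal(
        samples=samples,
        fs=fs if fs is not None else float(meta.get("fs", 360.0)),
        adc_bits=adc_bits if adc_bits is not None else int(meta.get("adc_bits", 12)),
        baseline=baseline if baseline is not None else int(meta.get("baseline", 0)),
        record_id=str(meta.get("record_id", path.stem)),
    )


def write_vector(signal: Signal, path: str | Path, format: str = "csv") -> None:
    path = Path(path)
    if format == "csv":
        np.savetxt(path, signal.samples, fmt="%d")
    elif format == "binary":
        path.write_bytes(signal.samples.astype("<i2").tobytes())
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "fs": signal.fs,
                    "adc_bits": signal.adc_bits,
                    "baseline": signal.baseline,
                    "record_id": signal.record_id,
                }
            )
        )
    else:
        raise ValueError(f"unknown vector format {format!r}")


# ---------------------------------------------------------------------------
# synthetic ECG
# ---------------------------------------------------------------------------


@dataclass
class SynthConfig:
    """Parameters of the Gaussian-morphology synthetic ECG generator.

    Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) placed at
    fixed offsets from the R peak, on top of slow sinusoidal baseline
    wander and white measurement noise, digitised at ``fs`` Hz to
    ``adc_bits`` bits around the ADC offset ``baseline``.  Amplitudes are
    in ADC units (an R amplitude of 600 on an 11-bit, gain-200 scale is a
    realistic ~1.5 mV R wave).  The same seed always yields bit-identical
    output.
    """

    n_beats: int = 30
    mean_rr_s: float = 0.8
    rr_jitter_s: float = 0.04
    wave_amplitudes: tuple[float, ...] = (80.0, -120.0, 600.0, -150.0, 160.0)
    wave_offsets_s: tuple[float, ...] = (-0.2, -0.028, 0.0, 0.032, 0.3)
    wave_widths_s: tuple[float, ...] = (0.035, 0.010, 0.013, 0.012, 0.07)
    baseline_wander_amp: float = 25.0
    baseline_wander_freq_hz: float = 0.33
    noise_sd: float = 6.0
    fs: float = 360.0
    adc_bits: int = 11
    baseline: int = 1024
    seed: int = 0
    record_id: str = "synth"

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.wave_widths_s):
            raise ValueError("wave widths must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_beats < 1:
            raise ValueError("need at least one beat")


def generate_synthetic_ecg(cfg: SynthConfig, n_samples: int | None = None) -> Signal:
    """Generate a quasi-periodic synthetic ECG.

    ``n_samples``, when given, trims or zero-order-extends the digitised
    output to an exact length (handy for fixed-length fixtures); otherwise
    the length follows from the generated beat train.
    """
    rng = np.random.default_rng(cfg.seed)
    rr = cfg.mean_rr_s + cfg.rr_jitter_s * rng.standard_normal(cfg.n_beats)
    rr = np.maximum(rr, 0.3)  # refractory floor
    centers = 0.5 + np.cumsum(rr) - rr[0]
    duration = centers[-1] + 0.7
    n = int(round(duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    x = np.zeros(n)
    for c in centers:
        for amp, off, width in zip(
            cfg.wave_amplitudes, cfg.wave_offsets_s, cfg.wave_widths_s
        ):
            mu = c + off
            lo = max(0, int((mu - 5 * width) * cfg.fs))
            hi = min(n, int((mu + 5 * width) * cfg.fs) + 1)
            if lo < hi:
                x[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - mu) / width) ** 2)
    if cfg.baseline_wander_amp:
        x += cfg.baseline_wander_amp * np.sin(
            2 * np.pi * cfg.baseline_wander_freq_hz * t
        )
    if cfg.noise_sd:
        x += cfg.noise_sd * rng.standard_normal(n)
    digitized = np.round(x).astype(np.int64) + cfg.baseline
    if n_samples is not None:
        if n_samples <= n:
            digitized = digitized[:n_samples]
        else:
            digitized = np.concatenate(
                [digitized, np.full(n_samples - n, cfg.baseline, dtype=np.int64)]
            )
    lo, hi = int(digitized.min()), int(digitized.max())
    if lo < 0 or hi >= (1 << cfg.adc_bits):
        raise ValueError(
            f"synthetic amplitudes exceed the {cfg.adc_bits}-bit ADC range: "
            f"[{lo}, {hi}]"
        )
    return Signal(
        samples=digitized,
        fs=cfg.fs,
        adc_bits=cfg.adc_bits,
        baseline=cfg.baseline,
        record_id=cfg.record_id,
    )
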