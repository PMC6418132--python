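import numpy as np
import pytest

from ecgcodec import Signal, SynthConfig, generate_synthetic_ecg
from ecgcodec.signal_io import (
    _pack_212,
    _unpack_212,
    read_vector,
    read_wfdb,
    write_vector,
    write_wfdb,
)


def oracle_pack_pair(s1: int, s2: int) -> bytes:
    """Bit-level format-212 packer for one pair, written independently:
    12-bit two's complement, low byte of s1, shared nibble byte, low byte of s2."""
    u1 = s1 & 0xFFF
    u2 = s2 & 0xFFF
    return bytes([u1 & 0xFF, (u1 >> 8) | ((u2 >> 8) << 4), u2 & 0xFF])


class TestFormat212:
    def test_pack_matches_bitlevel_oracle_and_roundtrips(self, rng):
        pairs = rng.integers(-2048, 2048, size=(10_000, 2))
        flat = pairs.ravel()
        packed = _pack_212(flat)
        oracle = b"".join(oracle_pack_pair(int(a), int(b)) for a, b in pairs)
        assert packed == oracle
        assert np.array_equal(_unpack_212(packed, len(flat)), flat)

    def test_extreme_values_roundtrip(self):
        v = np.array([-1024, 0, 1023])
        assert np.array_equal(_unpack_212(_pack_212(v), 3), v)

    def test_odd_length_pads_and_truncates(self):
        v = np.array([5])
        assert np.array_equal(_unpack_212(_pack_212(v), 1), v)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            _pack_212(np.array([4096]))


class TestWfdb:
    def test_two_sample_roundtrip(self, tmp_path):
        sig = Signal(np.array([1000, 1048]), fs=360, adc_bits=11, record_id="t")
        write_wfdb(sig, tmp_path / "t.hea")
        back = read_wfdb(tmp_path / "t.hea")
        assert np.array_equal(back.samples, sig.samples)
        assert back.fs == 360 and back.adc_bits == 11

    def test_header_metadata_roundtrip(self, tmp_path, short_ecg):
        write_wfdb(short_ecg, tmp_path / "r.hea")
        back = read_wfdb(tmp_path / "r.hea")
        assert len(back) == len(short_ecg)
        assert back.baseline == short_ecg.baseline
        assert np.array_equal(back.samples, short_ecg.samples)

    def test_missing_file_and_bad_channel(self, tmp_path, short_ecg):
        with pytest.raises(FileNotFoundError):
            read_wfdb(tmp_path / "absent.hea")
        write_wfdb(short_ecg, tmp_path / "r.hea")
        with pytest.raises(IndexError):
            read_wfdb(tmp_path / "r.hea", channel=1)

    def test_truncated_dat_rejected(self, tmp_path, short_ecg):
        write_wfdb(short_ecg, tmp_path / "r.hea")
        raw = (tmp_path / "r.dat").read_bytes()
        (tmp_path / "r.dat").write_bytes(raw[:-1])  # no longer a multiple of 3
        with pytest.raises(ValueError):
            read_wfdb(tmp_path / "r.hea")

    def test_two_channel_deinterleave(self, tmp_path):
        # interleaved stream ch0/ch1 packed pairwise
        ch0 = np.array([10, 30, 50, 70])
        ch1 = np.array([20, 40, 60, 80])
        flat = np.empty(8, dtype=np.int64)
        flat[0::2], flat[1::2] = ch0, ch1
        (tmp_path / "m.dat").write_bytes(_pack_212(flat))
        (tmp_path / "m.hea").write_text(
            "m 2 360 4\nm.dat 212 200 11 1024 10 0 0 MLII\n"
            "m.dat 212 200 11 1024 20 0 0 V5\n"
        )
        assert np.array_equal(read_wfdb(tmp_path / "m.hea", 0).samples, ch0)
        assert np.array_equal(read_wfdb(tmp_path / "m.hea", 1).samples, ch1)


class TestVectors:
    def test_csv_parses_one_value_per_line(self, tmp_path):
        p = tmp_path / "v.csv"
        p.write_text("1\n2\n3\n")
        assert np.array_equal(read_vector(p, "csv").samples, [1, 2, 3])

    @pytest.mark.parametrize("fmt", ["csv", "binary"])
    def test_write_read_identity(self, tmp_path, fmt):
        sig = Signal(np.array([3, -1, 4, -1, 5]), fs=250, adc_bits=12, baseline=0)
        p = tmp_path / f"v.{fmt}"
        write_vector(sig, p, fmt)
        back = read_vector(p, fmt)
        assert np.array_equal(back.samples, sig.samples)
        if fmt == "binary":  # sidecar carries the metadata
            assert back.fs == 250 and back.adc_bits == 12

    def test_empty_and_non_numeric_rejected(self, tmp_path):
        empty = tmp_path / "e.csv"
        empty.write_text("")
        with pytest.raises(ValueError):
            read_vector(empty, "csv")
        bad = tmp_path / "b.csv"
        bad.write_text("1\nfoo\n")
        with pytest.raises(ValueError):
            read_vector(bad, "csv")


class TestSignalInvariants:
    def test_samples_must_fit_adc_bits(self):
        with pytest.raises(ValueError):
            Signal(np.array([0, 2048]), fs=360, adc_bits=11)
        Signal(np.array([0, 2047]), fs=360, adc_bits=11)  # ok
        Signal(np.array([-1024, 1023]), fs=360, adc_bits=11)  # two's complement ok

    def test_bad_fs_rejected(self):
        with pytest.raises(ValueError):
            Signal(np.array([1]), fs=0)


class TestSyntheticEcg:
    def test_single_clean_beat_has_one_qrs_peak(self):
        cfg = SynthConfig(n_beats=1, noise_sd=0, baseline_wander_amp=0, seed=0)
        sig = generate_synthetic_ecg(cfg)
        r_amp = cfg.wave_amplitudes[2]
        above = sig.samples > cfg.baseline + 0.5 * r_amp
        # one contiguous run of samples above half the R amplitude
        runs = np.diff(above.astype(int))
        assert np.sum(runs == 1) == 1

    def test_seed_determinism(self):
        cfg = SynthConfig(n_beats=20, seed=42)
        a = generate_synthetic_ecg(cfg)
        b = generate_synthetic_ecg(cfg)
        assert np.array_equal(a.samples, b.samples)

    def test_mean_rr_matches_config(self):
        cfg = SynthConfig(
            n_beats=200, rr_jitter_s=0.03, noise_sd=0, baseline_wander_amp=0, seed=3
        )
        sig = generate_synthetic_ecg(cfg)
        # peak-to-peak interval oracle: R peaks are the samples above half R
        thresh = cfg.baseline + 0.5 * cfg.wave_amplitudes[2]
        above = sig.samples > thresh
        starts = np.flatnonzero(np.diff(above.astype(int)) == 1)
        rr = np.diff(starts) / cfg.fs
        se = cfg.rr_jitter_s / np.sqrt(len(rr))
        assert abs(rr.mean() - cfg.mean_rr_s) < 3 * se

    def test_amplitude_overflow_is_an_error(self):
        cfg = SynthConfig(
            n_beats=1, wave_amplitudes=(80, -120, 5000, -150, 160), seed=0
        )
        with pytest.raises(ValueError, match="ADC range"):
            generate_synthetic_ecg(cfg)

    def test_fixed_length_trim_and_pad(self):
        cfg = SynthConfig(n_beats=5, seed=1)
        short = generate_synthetic_ecg(cfg, n_samples=1000)
        assert len(short) == 1000
        long = generate_synthetic_ecg(cfg, n_samples=10_000)
        assert len(long) == 10_000 and long.samples[-1] == cfg.baseline
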