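import numpy as np
import pytest

from ecgcodec import (
    CodecConfig,
    Signal,
    TransformSpec,
    compress,
    decompress,
    tune_delta,
)
from ecgcodec import metrics

SPEC = TransformSpec("cdf97", 4)


class TestConfigValidation:
    def test_exactly_one_rate_control(self):
        with pytest.raises(ValueError):
            CodecConfig(method="b", delta=10.0, target_prd=0.5)
        with pytest.raises(ValueError):
            CodecConfig(method="b")

    def test_prd0_meaningless_for_method_b(self):
        with pytest.raises(ValueError):
            CodecConfig(method="b", delta=10.0, prd0=0.4)

    def test_method_a_delta_needs_prd0(self):
        with pytest.raises(ValueError):
            CodecConfig(method="a", delta=10.0)

    def test_default_prd0_is_75_percent_of_target(self):
        cfg = CodecConfig(method="a", target_prd=0.53)
        assert np.isclose(cfg.effective_prd0(), 0.3975)


class TestCompressDecompress:
    def test_tiny_delta_is_near_lossless(self, tmp_path, short_ecg):
        cfg = CodecConfig(method="b", delta=0.05, spec=SPEC)
        res = compress(short_ecg, cfg, tmp_path / "c.h5")
        assert res.prd < 0.01

    def test_reported_prd_equals_recomputed_metric(self, tmp_path, short_ecg):
        cfg = CodecConfig(method="b", delta=20.0, spec=SPEC)
        res = compress(short_ecg, cfg, tmp_path / "c.h5")
        fr = decompress(tmp_path / "c.h5")
        assert res.prd == metrics.prd(short_ecg.samples, fr)

    def test_method_equivalence_byte_identical(self, tmp_path, short_ecg):
        """Selection with a zero energy budget discards nothing, so method (a)
        at prd0=0 degenerates to method (b) down to the stored bytes."""
        ca = CodecConfig(method="a", delta=18.0, prd0=0.0, spec=SPEC)
        cb = CodecConfig(method="b", delta=18.0, spec=SPEC)
        compress(short_ecg, ca, tmp_path / "a.h5")
        compress(short_ecg, cb, tmp_path / "b.h5")
        assert (tmp_path / "a.h5").read_bytes() == (tmp_path / "b.h5").read_bytes()

    def test_decompress_deterministic(self, tmp_path, short_ecg):
        cfg = CodecConfig(method="b", delta=20.0, spec=SPEC)
        compress(short_ecg, cfg, tmp_path / "c.h5")
        a = decompress(tmp_path / "c.h5")
        b = decompress(tmp_path / "c.h5")
        assert np.array_equal(a, b)

    def test_zero_kept_coefficients_give_flat_zero(self, tmp_path):
        sig = Signal(np.array([1, 2, 1, 2] * 300), fs=360, adc_bits=11, baseline=0)
        cfg = CodecConfig(method="b", delta=1e6, spec=TransformSpec("cdf97", 2))
        res = compress(sig, cfg, tmp_path / "z.h5")
        assert res.n_kept == 0
        assert np.all(decompress(tmp_path / "z.h5") == 0)
        assert np.isfinite(res.cr) and res.cr > 0

    def test_coefficient_domain_error_bound(self, tmp_path, short_ecg):
        """Every kept coefficient is off by at most delta/2 after the loop."""
        from ecgcodec import dwt, read_container, unpack_indices

        delta = 25.0
        cfg = CodecConfig(method="b", delta=delta, spec=SPEC)
        compress(short_ecg, cfg, tmp_path / "c.h5")
        data = read_container(tmp_path / "c.h5")
        w = dwt.forward(short_ecg, SPEC)
        idx = unpack_indices(data.streams.delta_indices)
        rec = (
            data.delta
            * data.streams.magnitudes.astype(float)
            * (2.0 * data.streams.signs - 1.0)
        )
        assert np.max(np.abs(w.values[idx] - rec)) <= delta / 2 + 1e-9

    def test_huffman_and_rl_variants_reconstruct_identically(self, tmp_path, short_ecg):
        base = CodecConfig(method="b", delta=20.0, spec=SPEC)
        compress(short_ecg, base, tmp_path / "p.h5")
        ref = decompress(tmp_path / "p.h5")
        for kw in (dict(huffman=True), dict(index_coding="rl")):
            cfg = CodecConfig(method="b", delta=20.0, spec=SPEC, **kw)
            compress(short_ecg, cfg, tmp_path / "v.h5")
            assert np.allclose(decompress(tmp_path / "v.h5"), ref)

    def test_cr_above_one_in_operating_regime(self, tmp_path, full_length_ecg):
        cfg = CodecConfig(method="b", target_prd=0.5, spec=SPEC)
        res = compress(full_length_ecg, cfg, tmp_path / "c.h5")
        assert res.cr > 1.0

    def test_baseline_subtract_changes_prd_convention(self, tmp_path, short_ecg):
        plain = CodecConfig(method="b", delta=20.0, spec=SPEC)
        shifted = CodecConfig(method="b", delta=20.0, spec=SPEC,
                              baseline_subtract=1024)
        r1 = compress(short_ecg, plain, tmp_path / "p.h5")
        r2 = compress(short_ecg, shifted, tmp_path / "s.h5")
        # same reconstruction, smaller denominator -> larger PRD
        assert r2.prd > r1.prd
        assert np.allclose(decompress(tmp_path / "p.h5"),
                           decompress(tmp_path / "s.h5"))


class TestTuner:
    def test_fixed_point(self, tmp_path, short_ecg):
        """Tuning to the PRD achieved at a known step recovers that PRD."""
        probe = CodecConfig(method="b", delta=22.0, spec=SPEC)
        achieved = compress(short_ecg, probe, tmp_path / "p.h5").prd
        cfg = CodecConfig(method="b", target_prd=achieved, spec=SPEC)
        delta = tune_delta(short_ecg, cfg)
        res = compress(short_ecg,
                       CodecConfig(method="b", delta=delta, spec=SPEC),
                       tmp_path / "t.h5")
        assert abs(res.prd - achieved) <= 0.005

    def test_pure_sine_reaches_targets(self):
        t = np.arange(8192) / 360.0
        sig = Signal(
            np.round(500 * np.sin(2 * np.pi * 1.2 * t)).astype(int) + 1024,
            fs=360,
        )
        for target in (0.2, 1.0, 4.0):
            cfg = CodecConfig(method="b", target_prd=target, spec=SPEC)
            delta = tune_delta(sig, cfg)
            assert delta > 0

    def test_quantization_error_grows_with_delta(self, short_ecg):
        from ecgcodec import dwt, quantize, dequantize, select_all

        w = dwt.forward(short_ecg, SPEC)
        sel = select_all(w)
        errors = []
        for delta in (5.0, 20.0, 80.0):
            q = quantize(sel, delta)
            rec = np.zeros(len(w.values))
            d = dequantize(q)
            rec[d.indices] = d.values
            errors.append(float(np.sum((w.values - rec) ** 2)))
        assert errors[0] <= errors[1] <= errors[2]

    def test_unreachable_floor_reported(self):
        rng = np.random.default_rng(0)
        noisy = Signal(rng.integers(0, 2048, size=4096), fs=360)
        cfg = CodecConfig(method="b", target_prd=1e-6, spec=SPEC)
        with pytest.raises(ValueError, match="floor"):
            tune_delta(noisy, cfg)
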