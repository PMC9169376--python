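import numpy as np
import pytest
import pywt  # reference oracle only; the implementation embeds its own taps

import lithowarn as lw
from lithowarn.dwt_features import feature_length
from lithowarn.errors import ValidationError

FAMILIES = list(lw.SUPPORTED_WAVELETS)
ORTHOGONAL = ["haar", "db2", "db4", "dmey"]


class TestLoadWavelet:
    def test_haar_taps(self):
        w = lw.load_wavelet("haar")
        s = 1.0 / np.sqrt(2.0)
        assert np.allclose(np.abs(w.dec_lo), [s, s])
        assert np.allclose(sorted(np.abs(w.dec_hi)), [s, s])
        assert w.filter_length == 2 and w.orthogonal

    def test_db2_orthonormality_and_vanishing_moment(self):
        h = np.asarray(lw.load_wavelet("db2").dec_lo)
        assert len(h) == 4
        assert np.sum(h**2) == pytest.approx(1.0, abs=1e-10)
        k = np.arange(4)
        assert np.sum((-1.0) ** k * k * h[::-1]) == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("name", ORTHOGONAL)
    def test_quadrature_mirror_relation(self, name):
        w = lw.load_wavelet(name)
        lo, hi = np.asarray(w.dec_lo), np.asarray(w.dec_hi)
        qmf = ((-1.0) ** np.arange(len(lo))) * lo[::-1]
        assert np.allclose(hi, qmf, atol=1e-8) or np.allclose(hi, -qmf, atol=1e-8)

    def test_unknown_name_lists_supported(self):
        with pytest.raises(ValidationError, match="dmey"):
            lw.load_wavelet("db3.5")


class TestAnalysis:
    def test_haar_constant_signal(self):
        c = lw.dwt_single_level([1.0, 1.0, 1.0, 1.0], "haar", padding="none")
        assert np.allclose(c.approx, [np.sqrt(2.0)] * 2)
        assert np.allclose(c.detail, [0.0, 0.0])

    def test_half_length_without_padding(self):
        x = np.random.default_rng(0).random(50)
        c = lw.dwt_single_level(x, "haar", padding="none")
        assert len(c.approx) == len(c.detail) == 25

    @pytest.mark.parametrize("name", FAMILIES)
    def test_symmetric_matches_reference_library(self, name):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(size=50)
            c = lw.dwt_single_level(x, name, padding="symmetric")
            ca, cd = pywt.dwt(x, name, mode="symmetric")
            assert np.allclose(c.approx, ca, atol=1e-8)
            assert np.allclose(c.detail, cd, atol=1e-8)

    @pytest.mark.parametrize("name", ["haar", "db2", "db4", "rbio2.4"])
    def test_periodized_matches_reference_library(self, name):
        rng = np.random.default_rng(13)
        for _ in range(10):
            x = rng.normal(size=50)
            c = lw.dwt_single_level(x, name, padding="none")
            ca, cd = pywt.dwt(x, name, mode="periodization")
            assert np.allclose(c.approx, ca, atol=1e-8)
            assert np.allclose(c.detail, cd, atol=1e-8)

    def test_dmey_needs_padding_at_window_length(self):
        with pytest.raises(ValidationError, match="symmetric"):
            lw.dwt_single_level(np.zeros(50), "dmey", padding="none")

    def test_odd_length_without_padding_rejected(self):
        with pytest.raises(ValidationError, match="even"):
            lw.dwt_single_level(np.zeros(51), "haar", padding="none")

    @pytest.mark.parametrize("name", FAMILIES)
    def test_coefficient_length_formula(self, name):
        """len(cA) follows the mode's closed form for all lengths 2..64."""
        w = lw.load_wavelet(name)
        rng = np.random.default_rng(5)
        for n in range(2, 65):
            x = rng.normal(size=n)
            c = lw.dwt_single_level(x, w, padding="symmetric")
            assert len(c.approx) == (n + w.filter_length - 1) // 2
            assert len(c.approx) == feature_length(n, w) // 2
            if n % 2 == 0 and n >= w.filter_length:
                c0 = lw.dwt_single_level(x, w, padding="none")
                assert len(c0.approx) == n // 2


class TestReconstruction:
    @pytest.mark.parametrize("name", FAMILIES)
    def test_symmetric_round_trip(self, name):
        x = np.random.default_rng(3).normal(size=50)
        c = lw.dwt_single_level(x, name, padding="symmetric")
        assert np.allclose(lw.idwt_single_level(c, name), x, atol=1e-8)

    def test_haar_integer_round_trip(self):
        c = lw.dwt_single_level([1.0, 2.0, 3.0, 4.0], "haar", padding="none")
        assert np.allclose(
            lw.idwt_single_level(c, "haar"), [1, 2, 3, 4], atol=1e-9
        )

    @pytest.mark.parametrize("name", ["haar", "db2", "db4", "rbio2.4"])
    def test_periodized_round_trip(self, name):
        x = np.random.default_rng(4).normal(size=50)
        c = lw.dwt_single_level(x, name, padding="none")
        assert np.allclose(lw.idwt_single_level(c, name), x, atol=1e-8)

    def test_zero_coefficients_give_zero_signal(self):
        c = lw.dwt_single_level(np.zeros(50), "db4", padding="symmetric")
        assert np.allclose(lw.idwt_single_level(c, "db4"), 0.0, atol=1e-12)

    def test_wavelet_mismatch_rejected(self):
        c = lw.dwt_single_level(np.ones(50), "db2", padding="symmetric")
        with pytest.raises(ValidationError):
            lw.idwt_single_level(c, "db4")


class TestEnergy:
    @pytest.mark.parametrize("name", ["haar", "db2", "db4"])
    def test_orthogonal_energy_conservation(self, name):
        x = np.random.default_rng(6).normal(size=50)
        c = lw.dwt_single_level(x, name, padding="none")
        ratio = (np.sum(c.approx**2) + np.sum(c.detail**2)) / np.sum(x**2)
        assert ratio == pytest.approx(1.0, rel=1e-6)

    def test_dmey_energy_nearly_conserved(self):
        # the 62-tap discrete Meyer bank is an FIR approximation whose
        # low-pass norm is ~1.00224, so the energy ratio carries a ~2e-3 bias
        x = np.random.default_rng(7).normal(size=128)
        c = lw.dwt_single_level(x, "dmey", padding="none")
        ratio = (np.sum(c.approx**2) + np.sum(c.detail**2)) / np.sum(x**2)
        assert ratio == pytest.approx(1.0, rel=5e-3)


class TestFeatureTable:
    def test_haar_no_padding_feature_width(self, short_segments):
        segs = short_segments[:60]
        table = lw.build_feature_table(segs, "haar", padding="none")
        assert len(table) == 60
        assert all(len(f.values) == 50 for f in table)

    def test_dmey_symmetric_feature_width(self, short_segments):
        segs = short_segments[:60]
        table = lw.build_feature_table(segs, "dmey", padding="symmetric")
        width = 2 * ((50 + 61) // 2)
        assert width == 110
        assert all(len(f.values) == width for f in table)
        # cross-check the width against the reference library
        ca, cd = pywt.dwt(segs[0].values, "dmey", mode="symmetric")
        assert width == len(ca) + len(cd)

    def test_identical_segments_identical_features(self):
        seg = lw.Segment(values=np.linspace(0, 1, 50), label=1)
        table = lw.build_feature_table([seg, seg], "db4")
        assert np.array_equal(table[0].values, table[1].values)

    def test_labels_and_order_preserved(self, short_segments):
        table = lw.build_feature_table(short_segments, "db2")
        assert [f.label for f in table] == [s.label for s in short_segments]

    def test_empty_input_empty_table(self):
        assert lw.build_feature_table([], "haar") == []
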