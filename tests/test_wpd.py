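import numpy as np
import pytest

from wpdcca import (ConfigError, DataError, make_filter_bank, num_subbands,
                    subband_components, wp_decompose, wp_reconstruct)
from wpdcca.wpd import SUPPORTED_WAVELETS, fejer_korovkin_taps

EXPECTED_TAP_COUNTS = {
    "db1": 2, "db2": 4, "db3": 6,
    "sym4": 8, "sym5": 10, "sym6": 12,
    "coif1": 6, "coif2": 12, "coif3": 18,
    "fk4": 4, "fk6": 6, "fk8": 8,
}

# Published Fejér-Korovkin coefficient tables (Nielsen 2001), used as an
# independent cross-check of the spectral-factorization construction.
FK_PUBLISHED = {
    4: [0.653927555569765, 0.753272492839487, 0.0531792287790598,
        -0.0461657148152177],
    6: [0.4279150324223103, 0.8129196431842454, 0.3563695110701871,
        -0.1464386812725773, -0.0771777574069701, 0.0406258144232379],
}


class TestFilterBank:
    @pytest.mark.parametrize("name", SUPPORTED_WAVELETS)
    def test_invariants_and_tap_counts(self, name):
        bank = make_filter_bank(name)
        h, g = bank.h, bank.g
        assert bank.length == EXPECTED_TAP_COUNTS[name]
        assert float(h @ h) == pytest.approx(1.0, abs=1e-10)
        assert float(g @ g) == pytest.approx(1.0, abs=1e-10)
        assert float(h.sum()) == pytest.approx(np.sqrt(2.0), abs=1e-10)
        assert float(g.sum()) == pytest.approx(0.0, abs=1e-10)
        qmf = (-1.0) ** np.arange(bank.length) * h[::-1]
        assert min(np.abs(g - qmf).max(), np.abs(g + qmf).max()) < 1e-10

    def test_haar_taps_analytic(self):
        bank = make_filter_bank("db1")
        np.testing.assert_allclose(bank.h, [1 / np.sqrt(2)] * 2, atol=1e-14)

    @pytest.mark.parametrize("length", [4, 6])
    def test_fejer_korovkin_matches_published_tables(self, length):
        taps = np.array(fejer_korovkin_taps(length))
        np.testing.assert_allclose(taps, FK_PUBLISHED[length], atol=1e-7)

    def test_unknown_wavelet_rejected(self):
        with pytest.raises(ConfigError, match="db1"):
            make_filter_bank("db9")


class TestNumSubbands:
    @pytest.mark.parametrize("j,expected", [(1, 2), (3, 8), (4, 16), (5, 32)])
    def test_counts(self, j, expected):
        assert num_subbands(j) == expected

    def test_invalid_level(self):
        with pytest.raises(ConfigError):
            num_subbands(0)


class TestDecompose:
    def test_constant_energy_in_approximation_only(self):
        x = np.full(64, 2.5)
        for name in ("db2", "sym4", "fk6"):
            tree = wp_decompose(x, make_filter_bank(name), 2)
            for coeffs in tree.coeffs[1:]:
                assert np.abs(coeffs).max() <= 1e-10

    def test_haar_hand_computation(self):
        tree = wp_decompose(np.array([1.0, 1.0, 1.0, 1.0]), make_filter_bank("db1"), 1)
        np.testing.assert_allclose(tree.coeffs[0], [np.sqrt(2)] * 2, atol=1e-12)
        np.testing.assert_allclose(tree.coeffs[1], [0.0, 0.0], atol=1e-12)

    def test_parseval(self, rng):
        x = rng.standard_normal(1024)
        tree = wp_decompose(x, make_filter_bank("db2"), 4)
        assert tree.n_nodes == 16
        assert tree.coefficient_energy() == pytest.approx(float(x @ x), rel=1e-6)

    def test_too_short_signal(self):
        with pytest.raises(DataError):
            wp_decompose(np.zeros(7), make_filter_bank("db1"), 3)


class TestReconstruct:
    @pytest.mark.parametrize("name", SUPPORTED_WAVELETS)
    @pytest.mark.parametrize("j", [1, 3, 5])
    @pytest.mark.parametrize("n", [160, 173])  # multiple of 2**j and not
    def test_perfect_reconstruction(self, name, j, n, rng):
        x = rng.standard_normal(n)
        bank = make_filter_bank(name)
        y = wp_reconstruct(wp_decompose(x, bank, j), bank)
        assert np.abs(y - x).max() <= 1e-8 * max(1.0, np.abs(x).max())

    def test_zeroed_tree_gives_zero_signal(self, rng):
        bank = make_filter_bank("db2")
        tree = wp_decompose(rng.standard_normal(64), bank, 2)
        tree.coeffs = [np.zeros_like(c) for c in tree.coeffs]
        np.testing.assert_allclose(wp_reconstruct(tree, bank), 0.0, atol=1e-12)

    def test_low_tone_lives_in_approximation_band(self):
        # 1 Hz at 256 Hz lies inside the 0-8 Hz approximation band at j=4
        fs = 256.0
        x = np.sin(2 * np.pi * 1.0 * np.arange(4096) / fs)
        bank = make_filter_bank("db3")
        tree = wp_decompose(x, bank, 4)
        approx_only = wp_reconstruct(tree, bank, keep={0})
        assert np.corrcoef(x, approx_only)[0, 1] > 0.99

    def test_bank_tree_mismatch_rejected(self, rng):
        tree = wp_decompose(rng.standard_normal(64), make_filter_bank("db2"), 2)
        with pytest.raises(ConfigError):
            wp_reconstruct(tree, make_filter_bank("db3"))


class TestSubbandComponents:
    @pytest.mark.parametrize("j,cols", [(4, 16), (5, 32)])
    def test_column_counts(self, j, cols, rng):
        sb = subband_components(rng.standard_normal(256), make_filter_bank("db1"), j)
        assert sb.n_components == cols

    def test_row_sum_reproduces_signal(self, rng):
        x = rng.standard_normal(500)
        for name in ("db1", "sym5", "coif2", "fk8"):
            sb = subband_components(x, make_filter_bank(name), 4)
            np.testing.assert_allclose(sb.components.sum(axis=1), x, atol=1e-8)

    def test_labels_follow_s_d_convention(self, rng):
        sb = subband_components(rng.standard_normal(256), make_filter_bank("db1"), 4)
        labels = sb.labels
        assert labels[sb.approx_index] == "S15"
        assert labels[1] == "D1" and labels[15] == "D15"

    def test_tone_argmax_column_matches_nominal_band(self):
        # 44 Hz at fs 256, j=4: nominal band index floor(44 / 8) = 5
        fs = 256.0
        x = np.sin(2 * np.pi * 44.0 * np.arange(4096) / fs)
        for name in ("db1", "db3", "sym6"):
            sb = subband_components(x, make_filter_bank(name), 4, fs=fs)
            energy = (sb.components ** 2).sum(axis=0)
            assert int(np.argmax(energy)) == 5

    def test_low_band_tone_energy_concentln(self):
        # a 4 Hz tone sits mid-approximation-band; concentration is high there
        fs = 256.0
        x = np.sin(2 * np.pi * 4.0 * np.arange(4096) / fs)
        sb = subband_components(x, make_filter_bank("sym6"), 4, fs=fs)
        energy = (sb.components ** 2).sum(axis=0)
        assert energy[0] / energy.sum() >= 0.90

    def test_approx_column_has_lowest_spectral_centroid(self, rng):
        x = rng.standard_normal(2048)
        sb = subband_components(x, make_filter_bank("db3"), 3, fs=256.0)
        freqs = np.fft.rfftfreq(x.size, d=1 / 256.0)
        centroids = []
        for c in range(sb.n_components):
            spec = np.abs(np.fft.rfft(sb.components[:, c])) ** 2
            centroids.append((freqs * spec).sum() / spec.sum())
        assert int(np.argmin(centroids)) == sb.approx_index
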