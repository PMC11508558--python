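import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hsfocus import FMOptions, compute, compute_all
from hsfocus import measures as fm
from hsfocus.errors import DegenerateFrameError

import oracles


def ramp(n=5):
    return np.tile(np.arange(n, dtype=float), (n, 1))


class TestHandValues:
    """Worked examples with independently computed expected values."""

    def test_tenengrad_ramp(self):
        # horizontal ramp I(i,j)=j: every interior Sobel response is 8
        assert fm.tenengrad(ramp(), a=2, theta=0.0) == 9 * 64
        assert fm.tenengrad(ramp(), a=2, theta=100.0) == 0.0

    def test_laplacians_on_ramp_and_spike(self):
        assert fm.laplacian_energy(ramp(), "EOL") == 0.0
        assert fm.laplacian_energy(ramp(), "SML") == 0.0
        spike = np.pad([[7.0]], 2)  # single bright pixel, value 7
        assert fm.laplacian_energy(spike, "SML") == 8 * 7

    @pytest.mark.parametrize(
        "row,k,p,expected",
        [([1, 2, 3, 4], 2, 2, 8.0), ([1, 2, 3, 4], 1, 1, 3.0)],
    )
    def test_derivative_fm(self, row, k, p, expected):
        assert fm.derivative_fm(np.array([row], dtype=float), k, p, 0.0) == expected

    def test_energy_of_gradient_2x2(self):
        assert fm.energy_of_gradient(np.array([[0.0, 1.0], [2.0, 3.0]])) == 10.0

    def test_boddeke_row(self):
        assert fm.boddeke(np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])) == 12.0
        stripes = np.tile(np.array([[0.0], [5.0]]), (2, 4))  # varies down columns only
        assert fm.boddeke(stripes) == 0.0

    def test_normalized_variance(self):
        assert fm.normalized_variance(np.array([[0.0, 2.0], [0.0, 2.0]])) == 1.0
        with pytest.raises(DegenerateFrameError):
            fm.normalized_variance(np.zeros((4, 4)))

    def test_vollath_closed_forms(self):
        v, n = 3.0, 6
        const = np.full((n, n), v)
        assert fm.vollath_f4(const, axis=0) == pytest.approx(v * v * n)
        assert fm.vollath_f5(const, axis=0) == pytest.approx(-n * v * v)
        col = np.array([[1.0], [2.0], [3.0]])
        assert fm.vollath_f4(col, axis=0) == 5.0
        assert fm.vollath_f5(col, axis=0) == -4.0

    @pytest.mark.parametrize("levels,expected", [(4, 2.0), (8, 3.0)])
    def test_entropy_equal_levels(self, levels, expected):
        img = np.repeat(np.arange(levels), 16).reshape(levels, 16)
        assert fm.entropy_fm(img) == pytest.approx(expected)
        assert fm.entropy_fm(np.full((8, 8), 9)) == 0.0

    def test_log_histogram_two_bins(self):
        img = np.array([[0, 1], [1, 0]])
        e = 0 * math.log(0.5) + 1 * math.log(0.5)  # E = sum of l*ln(p_l)
        expected = ((0 - e) ** 2 + (1 - e) ** 2) * math.log(0.5)
        assert fm.log_histogram_variance(img) == pytest.approx(expected)
        assert fm.log_histogram_variance(np.full((4, 4), 7)) == 0.0

    def test_weighted_histogram_single_bright_pixel(self):
        img = np.zeros((2, 5), dtype=np.int64)
        img[0, 0] = 1000
        assert fm.weighted_histogram(img) == pytest.approx(1.0)
        assert fm.weighted_histogram(np.zeros((4, 4), dtype=np.int64)) == 0.0

    def test_fourier_constant_is_zero(self):
        assert fm.fourier_fm(np.full((8, 8), 5.0)) == 0.0

    def test_fourier_prefers_higher_frequency(self):
        x = np.arange(32)
        lo = 100 + 50 * np.cos(2 * np.pi * 2 * x / 32)
        hi = 100 + 50 * np.cos(2 * np.pi * 8 * x / 32)
        assert fm.fourier_fm(np.tile(hi, (32, 1))) > fm.fourier_fm(np.tile(lo, (32, 1)))

    def test_dct_properties(self, rng):
        import scipy.fft as sfft

        assert fm.dct_fm(np.full((8, 8), 3.0)) == pytest.approx(0.0)
        block = rng.integers(0, 100, (8, 8)).astype(float)
        coef = sfft.dctn(block, norm="ortho")
        assert np.sum(coef**2) == pytest.approx(np.sum(block**2))  # Parseval
        assert fm.dct_fm(block) == pytest.approx(np.sum(coef**2) - coef[0, 0] ** 2)
        assert fm.dct_fm(block + 40.0) == pytest.approx(fm.dct_fm(block))  # DC excluded

    def test_midfreq_dct(self):
        assert fm.midfreq_dct_fm(fm._O_MDCT) == 256.0
        assert fm.midfreq_dct_fm(np.full((6, 6), 2.0)) == 0.0
        assert fm.midfreq_dct_fm(ramp(6)) == pytest.approx(0.0)  # balanced per row-pair

    def test_wavelet_constant_annihilation(self):
        const = np.full((16, 16), 11.0)
        assert fm.wavelet_fm(const, "WL1") < 1e-9
        assert fm.wavelet_fm(const, "WL2") < 1e-12
        assert fm.wavelet_fm(const, "WL3") < 1e-12


class TestProperties:
    @given(st.integers(0, 2**31 - 1))
    def test_histogram_fms_permutation_invariant(self, seed):
        r = np.random.default_rng(seed)
        img = r.integers(0, 256, (8, 8))
        perm = r.permutation(img.ravel()).reshape(8, 8)
        for f in (fm.entropy_fm, fm.log_histogram_variance, fm.weighted_histogram):
            assert f(perm) == pytest.approx(f(img))

    def test_gradient_family_zero_on_constant(self):
        const = np.full((9, 9), 7.0)
        for res in compute_all(const):
            if res.family == "gradient":
                assert res.value == 0.0

    def test_nvr_scales_linearly(self, rng):
        img = rng.integers(1, 100, (8, 8)).astype(float)
        assert fm.normalized_variance(3.0 * img) == pytest.approx(
            3.0 * fm.normalized_variance(img)
        )

    def test_whs_monotone_in_added_bright_pixels(self, rng):
        # only the histogram matters, so an appended max-level pixel is a
        # valid "one more bright pixel" comparison
        img = rng.integers(0, 1000, (6, 6)).astype(np.int64)
        brighter = np.append(img.ravel(), img.max()).reshape(1, -1)
        assert fm.weighted_histogram(brighter) >= fm.weighted_histogram(img)

    def test_wl1_invariant_to_sign_flip_about_mean(self, rng):
        img = rng.normal(0, 50, (16, 16)) + 500
        flipped = 2 * img.mean() - img
        assert fm.wavelet_fm(flipped, "WL1") == pytest.approx(
            fm.wavelet_fm(img, "WL1"), rel=1e-9
        )

    def test_wl2_wl3_nonnegative(self, rng):
        img = rng.normal(0, 30, (16, 16))
        assert fm.wavelet_fm(img, "WL2") >= 0.0
        assert fm.wavelet_fm(img, "WL3") >= 0.0

    def test_small_frame_oracle_equivalence(self, rng):
        """Vectorized operators match naive double loops on random frames."""
        for _ in range(10):
            arr = rng.integers(0, 64, (8, 8)).astype(float)
            lst = arr.tolist()
            theta = float(rng.integers(0, 20))
            assert fm.tenengrad(arr, 2, theta) == oracles.tenengrad(lst, 2, theta)
            assert fm.tenengrad(arr, 1, theta) == oracles.tenengrad(lst, 1, theta)
            for variant in ("EOL", "SML", "DLF"):
                assert fm.laplacian_energy(arr, variant) == pytest.approx(
                    oracles.laplacian_energy(lst, variant), rel=1e-12
                )
            for k, p in ((1, 1), (1, 2), (2, 2)):
                assert fm.derivative_fm(arr, k, p, theta) == oracles.derivative_fm(
                    lst, k, p, theta
                )
            assert fm.energy_of_gradient(arr) == oracles.energy_of_gradient(lst)
            assert fm.boddeke(arr) == oracles.boddeke(lst)
            assert fm.vollath_f4(arr) == oracles.vollath_f4(lst)
            assert fm.vollath_f5(arr) == pytest.approx(oracles.vollath_f5(lst))
            assert fm.midfreq_dct_fm(arr) == oracles.midfreq_dct(lst)


class TestRegistry:
    def test_compute_all_returns_22_in_stable_order(self, rng):
        img = rng.integers(0, 4096, (16, 16)).astype(np.uint16)
        res1 = compute_all(img)
        res2 = compute_all(img)
        assert [r.fm_id for r in res1] == list(fm.FM_ORDER)
        assert len(res1) == 22
        assert [r.value for r in res1] == [r.value for r in res2]
        assert all(r.error is None for r in res1)

    def test_family_assignment(self):
        families = {f: fm.FAMILY[f] for f in fm.FM_ORDER}
        assert sum(v == "gradient" for v in families.values()) == 10
        assert sum(v == "statistics" for v in families.values()) == 6
        assert sum(v == "frequency" for v in families.values()) == 6

    def test_aliases_resolve(self):
        assert fm.canonical_id("VAR") == "LOG"
        assert fm.canonical_id("FTF") == "FFT"
        assert fm.canonical_id("MD-DCT") == "MFDCT"
        with pytest.raises(KeyError):
            fm.canonical_id("NOPE")

    def test_per_entry_error_capture(self):
        # all-zero frame: NVR undefined, everything else still reported
        res = {r.fm_id: r for r in compute_all(np.zeros((8, 8)))}
        assert res["NVR"].error is not None and math.isnan(res["NVR"].value)
        assert res["TEN1"].error is None

    def test_auto_threshold_scales_with_noise(self, rng):
        clean = np.full((32, 32), 100.0)
        noisy = clean + rng.normal(0, 10, clean.shape)
        opts = FMOptions(threshold="auto")
        # auto threshold suppresses pure-noise gradients harder than theta=0
        assert compute("ABG", noisy, opts) < compute("ABG", noisy, FMOptions())
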