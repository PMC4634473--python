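import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wristpose as wp
from wristpose.exceptions import WindowTooShortError
from wristpose.features import (
    avg_pairwise_difference,
    crossing_rates,
    spectral_features,
    time_stats,
    triad_orientation_features,
)

from conftest import make_window


def dft_amplitudes(x):
    """Direct O(n^2) one-sided DFT amplitude oracle, k = 1..floor(n/2)."""
    n = len(x)
    ks = np.arange(1, n // 2 + 1)
    amps = []
    for k in ks:
        c = np.sum(x * np.exp(-2j * np.pi * k * np.arange(n) / n))
        amps.append(abs(c))
    return np.array(amps)


class TestTimeStats:
    def test_basic_statistics(self):
        st = time_stats(np.array([1.0, 2, 3, 4, 5]))
        assert st["mean"] == 3.0
        assert st["sum"] == 15.0
        assert st["median"] == 3.0
        assert st["min"] == 1.0 and st["max"] == 5.0
        assert st["rms"] == pytest.approx(np.sqrt(11.0))
        assert st["variance"] == pytest.approx(2.5)  # n-1 denominator
        assert st["iqr"] == pytest.approx(2.0)

    def test_constant_series_fallbacks(self):
        st = time_stats(np.full(10, 2.0))
        assert st["std"] == 0 and st["skewness"] == 0
        assert st["kurtosis"] == 0 and st["iqr"] == 0

    def test_excess_kurtosis_of_gaussian_near_zero(self, rng):
        st = time_stats(rng.normal(size=200_0))
        assert abs(st["kurtosis"]) < 0.3

    def test_too_short(self):
        with pytest.raises(WindowTooShortError):
            time_stats(np.array([1.0]))


class TestAvgPairwiseDifference:
    def test_hand_example(self):
        assert avg_pairwise_difference(np.array([0.0, 1, 2])) == pytest.approx(4 / 3)

    def test_constant_is_zero(self):
        assert avg_pairwise_difference(np.full(7, 3.0)) == 0.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40))
    def test_sorted_formula_equals_double_loop_on_arbitrary_series(self, xs):
        x = np.array(xs)
        n = len(x)
        brute = np.mean([abs(x[i] - x[j]) for i in range(n) for j in range(i + 1, n)])
        assert avg_pairwise_difference(x) == pytest.approx(brute, rel=1e-9, abs=1e-9)

    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 120))
            x = rng.normal(size=n)
            brute = np.mean([abs(x[i] - x[j]) for i in range(n) for j in range(i + 1, n)])
            assert avg_pairwise_difference(x) == pytest.approx(brute, rel=1e-10)


class TestCrossingRates:
    def test_alternating_signs(self):
        cr = crossing_rates(np.array([1.0, -1, 1, -1]))
        assert cr["zero_crossing_rate"] == 1.0

    def test_constant_positive(self):
        cr = crossing_rates(np.full(10, 2.0))
        assert cr["zero_crossing_rate"] == 0 and cr["mean_crossing_rate"] == 0

    def test_mean_crossing_after_offset_removal(self):
        cr = crossing_rates(np.array([2.0, 4, 2, 4]))
        assert cr["zero_crossing_rate"] == 0
        assert cr["mean_crossing_rate"] == 1.0

    def test_exact_zeros_do_not_count(self):
        cr = crossing_rates(np.array([1.0, 0.0, 1.0, 0.0, 1.0]))
        assert cr["zero_crossing_rate"] == 0


class TestSpectralFeatures:
    def test_constant_series_all_zero(self):
        sp = spectral_features(np.full(50, 1.0), 10.0)
        assert all(v == 0 for v in sp.values())

    def test_sine_dominant_frequency(self):
        t = np.arange(50) / 10.0
        sp = spectral_features(np.sin(2 * np.pi * 2.0 * t), 10.0)
        assert sp["dominant_frequency"] == pytest.approx(2.0)

    def test_two_sinusoids_peak_difference(self):
        t = np.arange(100) / 20.0
        x = np.sin(2 * np.pi * 1.0 * t) + 0.8 * np.sin(2 * np.pi * 3.0 * t)
        sp = spectral_features(x, 20.0)
        assert sp["peak_difference"] == pytest.approx(2.0)

    def test_matches_direct_dft_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 200))
            x = rng.normal(size=n)
            amps = dft_amplitudes(x)
            sp = spectral_features(x, 100.0)
            assert sp["energy"] == pytest.approx(np.sum(amps), rel=1e-10)
            assert sp["root_sum_squares"] == pytest.approx(
                np.sqrt(np.sum(amps**2)), rel=1e-10
            )
            k_star = int(np.argmax(amps)) + 1
            assert sp["dominant_frequency"] == pytest.approx(100.0 * k_star / n)


class TestTriadFeatures:
    def test_static_window_degenerates_to_zero(self):
        accel = np.tile([0.0, -1.0, 0.0], (50, 1))
        out = triad_orientation_features(accel, np.zeros((50, 3)))
        assert out["avg_rotation_angles__ax"] == 0.0
        assert out["cagh__ax"] == 0.0
        assert out["eigenvalues__ax"] == pytest.approx(0.0, abs=1e-12)

    def test_single_axis_variance_eigenvalues(self, rng):
        accel = np.zeros((100, 3))
        accel[:, 1] = rng.normal(size=100)
        out = triad_orientation_features(accel, np.zeros((100, 3)))
        expected = np.var(accel[:, 1], ddof=1)
        assert out["eigenvalues__ax"] == pytest.approx(expected)  # largest eigenvalue
        assert out["eigenvalues__ay"] == pytest.approx(0.0, abs=1e-12)
        assert out["eigenvalues__az"] == pytest.approx(0.0, abs=1e-12)
        assert out["eigenvalues__amag"] == pytest.approx(expected)

    def test_rotation_angle_against_hand_geometry(self):
        # half the samples along +y, half at 90 degrees (+z): every sample is
        # 45 degrees away from the mean vector (y+z)/2
        accel = np.array([[0.0, 1, 0], [0.0, 0, 1]] * 25)
        out = triad_orientation_features(accel, np.zeros((50, 3)))
        assert out["avg_rotation_angles__ax"] == pytest.approx(np.pi / 4)


class TestExtractFeatures:
    @pytest.mark.parametrize("fs,n", [(100.0, 500), (50.0, 250), (10.0, 50)])
    def test_cardinality_at_all_rates(self, rng, fs, n):
        w = make_window(rng.normal(0, 0.5, (n, 3)), rng.normal(0, 20, (n, 3)), fs=fs)
        vec = wp.extract_features(w)
        assert len(vec) == 175
        assert np.all(np.isfinite(vec.to_numpy()))

    def test_all_zero_window_is_all_zero_vector(self):
        w = make_window(np.zeros((500, 3)))
        vec = wp.extract_features(w)
        assert np.all(vec.to_numpy() == 0.0)

    def test_bitwise_determinism(self, rng):
        a = rng.normal(0, 0.5, (50, 3))
        g = rng.normal(0, 20, (50, 3))
        v1 = wp.extract_features(make_window(a, g, fs=10.0))
        v2 = wp.extract_features(make_window(a.copy(), g.copy(), fs=10.0))
        assert (v1.to_numpy() == v2.to_numpy()).all()

    def test_amplitude_scaling_law(self, rng):
        a = rng.normal(0.2, 0.5, (100, 3))
        g = rng.normal(0, 20, (100, 3))
        s = 3.0
        v1 = wp.extract_features(make_window(a, g, fs=100.0))
        v2 = wp.extract_features(make_window(s * a, s * g, fs=100.0))
        for ch in wp.CHANNELS:
            for f in ("min", "max", "sum", "mean", "std", "rms", "energy"):
                if f in ("min", "max") and ch != "amag":
                    pass  # min/max scale linearly for s > 0 on any channel
                assert v2[f"{f}__{ch}"] == pytest.approx(s * v1[f"{f}__{ch}"], rel=1e-9)
            assert v2[f"variance__{ch}"] == pytest.approx(s**2 * v1[f"variance__{ch}"], rel=1e-9)
            assert v2[f"zero_crossing_rate__{ch}"] == v1[f"zero_crossing_rate__{ch}"]
            assert v2[f"dominant_frequency__{ch}"] == v1[f"dominant_frequency__{ch}"]
            assert v2[f"cagh__{ch}"] == pytest.approx(v1[f"cagh__{ch}"], abs=1e-9)
        assert v2["eigenvalues__ax"] == pytest.approx(s**2 * v1["eigenvalues__ax"], rel=1e-9)

    def test_time_shift_leaves_spectral_amplitudes_invariant(self):
        t = np.arange(200) / 100.0
        x = np.sin(2 * np.pi * 5.0 * t) + 0.5 * np.sin(2 * np.pi * 12.0 * t)
        a1 = np.column_stack([x, x, x])
        a2 = np.column_stack([np.roll(x, 37)] * 3)
        v1 = wp.extract_features(make_window(a1, fs=100.0))
        v2 = wp.extract_features(make_window(a2, fs=100.0))
        for f in ("energy", "root_sum_squares", "dominant_frequency", "first_peak"):
            assert v2[f"{f}__ax"] == pytest.approx(v1[f"{f}__ax"], rel=1e-8)
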