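import numpy as np
import pytest

from stairpower.features import (
    AXIS_FEATURES,
    extract_features,
    feature_names,
    fft_energy,
    histogram_entropy,
    lag1_autocorrelation,
    stepband_wavelet_energy,
)

from conftest import make_window


def brute_pearson(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum()))


class TestFeatureCounts:
    @pytest.mark.parametrize("sensor_set,count", [("both", 148), ("accel", 76), ("gyro", 72)])
    def test_counts_and_finiteness(self, random_window, sensor_set, count):
        fv = extract_features(random_window, sensor_set)
        assert len(fv) == count
        assert list(fv.values) == feature_names(sensor_set)
        assert np.all(np.isfinite(fv.as_array()))

    def test_gyro_request_on_accel_only_window_fails(self, rng):
        win = make_window(rng.standard_normal((75, 3)))
        with pytest.raises(ValueError, match="gyroscope"):
            extract_features(win, "both")


def test_constant_window_degenerate_conventions():
    win = make_window(np.full((75, 3), 4.2), np.full((75, 3), 4.2))
    v = extract_features(win, "both").values
    assert v["accel_x_mean"] == pytest.approx(4.2)
    assert v["accel_x_range"] == 0.0
    assert v["accel_x_variance"] == 0.0
    assert v["accel_x_hist_entropy"] == 0.0
    assert v["accel_x_zero_crossings"] == 0.0
    assert v["accel_x_autocorr_lag1"] == 0.0
    assert v["accel_xy_corr"] == 0.0


def test_sine_window_rms_and_dominant_frequency():
    fs, n = 50.0, 75
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * 2.0 * t)
    win = make_window(np.column_stack([x, x, x]))
    v = extract_features(win, "accel").values
    assert v["accel_x_rms"] == pytest.approx(1 / np.sqrt(2), abs=0.01)
    assert abs(v["accel_x_dominant_freq"] - 2.0) <= fs / n  # one FFT bin


class TestHistogramEntropy:
    def test_constant_is_zero(self):
        assert histogram_entropy(np.full(50, 3.3)) == 0.0

    def test_linear_ramp_fills_bins_uniformly(self):
        # 100 evenly spaced points -> 10 per bin -> log2(10) bits
        assert histogram_entropy(np.arange(100.0)) == pytest.approx(np.log2(10))

    def test_two_level_half_each_is_one_bit(self):
        x = np.r_[np.zeros(40), np.ones(40)]
        assert histogram_entropy(x) == pytest.approx(1.0)


class TestLag1Autocorrelation:
    def test_constant_convention(self):
        assert lag1_autocorrelation(np.full(75, 2.0)) == 0.0

    @pytest.mark.parametrize(
        "x",
        [
            np.tile([1.0, -1.0], 38)[:75],  # alternating, ~ -1
            np.arange(75.0),  # ramp, ~ +1
            np.sin(np.arange(75) * 0.3) + 0.1 * np.arange(75),
        ],
    )
    def test_matches_direct_pearson_of_shifted_copies(self, x):
        assert lag1_autocorrelation(x) == pytest.approx(
            brute_pearson(x[:-1], x[1:]), abs=1e-12
        )


class TestFftEnergy:
    def test_zero_and_dc_only_vectors(self):
        assert fft_energy(np.zeros(75), 50.0) == 0.0
        assert fft_energy(np.full(75, 5.0), 50.0) == pytest.approx(0.0, abs=1e-20)

    def test_sine_matches_brute_force_dft(self):
        fs, n = 50.0, 75
        x = np.sin(2 * np.pi * 2.0 * np.arange(n) / fs)
        # direct DFT oracle over the same non-DC one-sided bins
        ks = np.arange(1, n // 2 + 1)
        mags = [abs(sum(x[j] * np.exp(-2j * np.pi * k * j / n) for j in range(n)))
                for k in ks]
        expected = sum(m**2 for m in mags) / n
        assert fft_energy(x, fs) == pytest.approx(expected, rel=1e-9)


class TestStepbandWaveletEnergy:
    def test_zero_signal(self):
        assert stepband_wavelet_energy(np.zeros(75), 50.0) == 0.0

    def test_quadratic_homogeneity(self, rng):
        x = rng.standard_normal(75)
        e1 = stepband_wavelet_energy(x, 50.0)
        e2 = stepband_wavelet_energy(2.0 * x, 50.0)
        assert e2 == pytest.approx(4.0 * e1, rel=1e-9)

    def test_step_band_favors_low_frequency(self):
        t = np.arange(150) / 50.0
        slow = stepband_wavelet_energy(np.sin(2 * np.pi * 2.0 * t), 50.0)
        fast = stepband_wavelet_energy(np.sin(2 * np.pi * 10.0 * t), 50.0)
        assert slow > fast


SCALE_FREE = {
    "skewness", "kurtosis", "hist_entropy", "spectral_entropy",
    "autocorr_lag1", "dominant_freq", "zero_crossings",
}
QUADRATIC = {"variance", "fft_energy"}


@pytest.mark.parametrize("a", [0.5, 2.0, 7.3])
def test_amplitude_scale_equivariance(random_window, a):
    base = extract_features(random_window, "both").values
    scaled_win = make_window(a * random_window.accel, a * random_window.gyro)
    scaled = extract_features(scaled_win, "both").values
    for name, v in base.items():
        stat = name.split("_", 2)[-1]
        if name.endswith("_corr"):
            expect = v
        elif stat in SCALE_FREE:
            expect = v
        elif stat in QUADRATIC or stat == "stepband_energy":
            expect = a**2 * v
        else:  # linear statistics (mean, percentiles, std, rms, range, ...)
            expect = a * v
        assert scaled[name] == pytest.approx(expect, rel=1e-9, abs=1e-9), name


def test_swapping_y_and_z_axes_swaps_feature_values(random_window):
    base = extract_features(random_window, "both").values
    accel = random_window.accel[:, [0, 2, 1]]
    gyro = random_window.gyro[:, [0, 2, 1]]
    swapped = extract_features(make_window(accel, gyro), "both").values
    for sensor in ("accel", "gyro"):
        for f in AXIS_FEATURES:
            assert swapped[f"{sensor}_y_{f}"] == base[f"{sensor}_z_{f}"]
            assert swapped[f"{sensor}_z_{f}"] == base[f"{sensor}_y_{f}"]
        assert swapped[f"{sensor}_xy_corr"] == base[f"{sensor}_xz_corr"]
        assert swapped[f"{sensor}_xz_corr"] == base[f"{sensor}_xy_corr"]
        assert swapped[f"{sensor}_yz_corr"] == pytest.approx(base[f"{sensor}_yz_corr"])
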