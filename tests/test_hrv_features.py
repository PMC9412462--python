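import itertools
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vimshrv.hrv_features import (
    LN_POWER_FLOOR,
    ZONE_LABELS,
    FeatureConfig,
    UniformTachogram,
    ZoneConfig,
    band_powers,
    classify_zone,
    extract_features,
    features_from_nn,
    hrv_spectrum,
    ln_features,
    mean_heart_rate,
    pnn50,
    resample_tachogram,
    sdnn,
)
from vimshrv.synthetic_data import (
    ECGGenParams,
    RRGenParams,
    generate_ecg,
    generate_rr_series,
    rr_to_nn,
)

from conftest import nn_from


class TestTimeDomain:
    def test_sdnn_constant_is_zero(self):
        assert sdnn(nn_from([800.0, 800.0, 800.0])) == 0.0

    def test_sdnn_hand_value(self):
        # sample SD of deviations {0, 10, -10, 0} = sqrt(200/3)
        assert sdnn(nn_from([800.0, 810.0, 790.0, 800.0])) == pytest.approx(
            math.sqrt(200.0 / 3.0), abs=1e-9
        )
        assert sdnn(nn_from([800.0, 810.0, 790.0, 800.0])) == pytest.approx(8.165, abs=1e-3)

    def test_sdnn_order_free(self):
        a = nn_from([700.0, 900.0, 800.0, 850.0])
        b = nn_from([850.0, 700.0, 800.0, 900.0])
        assert sdnn(a) == pytest.approx(sdnn(b))

    def test_sdnn_too_short_raises(self):
        with pytest.raises(ValueError):
            sdnn(nn_from([800.0]))

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=25, deadline=None)
    def test_sdnn_scales_linearly(self, scale):
        base = [820.0, 790.0, 845.0, 760.0, 910.0]
        assert sdnn(nn_from([scale * x for x in base])) == pytest.approx(
            scale * sdnn(nn_from(base)), rel=1e-9
        )

    def test_pnn50_strict_inequality(self):
        # diffs 60, 50, 90: the exact-50 difference does not count
        assert pnn50(nn_from([800.0, 860.0, 810.0, 900.0])) == pytest.approx(200.0 / 3.0)

    def test_pnn50_constant_zero(self):
        assert pnn50(nn_from([800.0] * 10)) == 0.0

    def test_pnn50_single_pair(self):
        assert pnn50(nn_from([600.0, 1200.0])) == 100.0

    @given(
        st.lists(st.floats(min_value=600.0, max_value=1200.0), min_size=2, max_size=50)
    )
    @settings(max_examples=50, deadline=None)
    def test_pnn50_bounds(self, intervals):
        assert 0.0 <= pnn50(nn_from(intervals)) <= 100.0

    @pytest.mark.parametrize("interval,bpm", [(1000.0, 60.0), (800.0, 75.0)])
    def test_heart_rate(self, interval, bpm):
        assert mean_heart_rate(nn_from([interval] * 5)) == pytest.approx(bpm)

    def test_heart_rate_empty_raises(self):
        from vimshrv.ecg_processing import NNSeries

        with pytest.raises(ValueError):
            mean_heart_rate(NNSeries(np.empty(0), np.empty(0)))


class TestResampleTachogram:
    def test_constant_series(self):
        nn = nn_from([800.0] * 13)  # spans 9.6 s
        tach = resample_tachogram(nn)
        np.testing.assert_allclose(tach.values, 800.0, atol=1e-9)
        assert tach.fs_resample == 4.0

    def test_grid_spacing_default_quarter_second(self):
        nn = nn_from([750.0] * 20)
        tach = resample_tachogram(nn)
        np.testing.assert_allclose(np.diff(tach.times), 0.25, atol=1e-12)

    def test_passes_through_knots(self):
        # knot onsets placed exactly on the 4 Hz grid
        from vimshrv.ecg_processing import NNSeries

        rng = np.random.default_rng(1)
        values = 800.0 + rng.normal(0, 30, size=12)
        onsets = np.arange(12) * 0.5
        nn = NNSeries(values, onsets)
        tach = resample_tachogram(nn)
        grid_idx = (onsets / 0.25).astype(int)
        np.testing.assert_allclose(tach.values[grid_idx], values, atol=1e-9)

    def test_short_span_raises(self):
        with pytest.raises(ValueError):
            resample_tachogram(nn_from([300.0, 300.0, 300.0, 300.0]))

    def test_non_monotone_raises(self):
        from vimshrv.ecg_processing import NNSeries

        nn = NNSeries(
            np.array([800.0, 800.0, 800.0, 800.0]), np.array([0.0, 1.0, 0.5, 2.0])
        )
        with pytest.raises(ValueError):
            resample_tachogram(nn)


class TestSpectrum:
    def test_constant_tachogram_zero_power(self):
        tach = UniformTachogram(np.full(400, 800.0), 4.0, 0.0)
        spec = hrv_spectrum(tach)
        assert spec.total_power() < 1e-12

    def test_sinusoid_power_parseval(self):
        t = np.arange(0, 300, 0.25)
        tach = UniformTachogram(800.0 + 10.0 * np.sin(2 * np.pi * 0.25 * t), 4.0, 0.0)
        spec = hrv_spectrum(tach)
        assert spec.total_power() == pytest.approx(50.0, rel=0.10)
        var = np.var(tach.values)
        assert spec.total_power() == pytest.approx(var, rel=0.01)

    def test_psd_nonnegative_and_nyquist(self):
        rng = np.random.default_rng(0)
        tach = UniformTachogram(800 + rng.normal(0, 20, 512), 4.0, 0.0)
        spec = hrv_spectrum(tach)
        assert np.all(spec.psd >= 0)
        assert spec.freqs[-1] == pytest.approx(2.0)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            hrv_spectrum(UniformTachogram(np.full(63, 800.0), 4.0, 0.0))

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=20, deadline=None)
    def test_parseval_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        tach = UniformTachogram(800 + rng.normal(0, 25, 1200), 4.0, 0.0)
        spec = hrv_spectrum(tach)
        assert spec.total_power() == pytest.approx(np.var(tach.values), rel=0.01)


class TestBandPowers:
    def test_hf_sinusoid(self):
        t = np.arange(0, 320, 0.25)
        tach = UniformTachogram(800.0 + 10.0 * np.sin(2 * np.pi * 0.25 * t), 4.0, 0.0)
        vlf, hf = band_powers(hrv_spectrum(tach))
        assert hf == pytest.approx(50.0, rel=0.10)
        assert vlf < 0.05 * hf

    def test_vlf_sinusoid_600s(self):
        t = np.arange(0, 600, 0.25)
        tach = UniformTachogram(800.0 + 10.0 * np.sin(2 * np.pi * 0.01 * t), 4.0, 0.0)
        vlf, hf = band_powers(hrv_spectrum(tach))
        assert vlf >= 10.0 * max(hf, 1e-12)

    def test_band_sum_below_total(self):
        rng = np.random.default_rng(3)
        tach = UniformTachogram(800 + rng.normal(0, 25, 2400), 4.0, 0.0)
        spec = hrv_spectrum(tach)
        vlf, hf = band_powers(spec)
        assert vlf + hf <= spec.total_power() * (1 + 1e-9)

    def test_short_record_warns(self):
        rng = np.random.default_rng(4)
        tach = UniformTachogram(800 + rng.normal(0, 25, 256), 4.0, 0.0)  # 64 s
        with pytest.warns(UserWarning, match="VLF"):
            band_powers(hrv_spectrum(tach))

    def test_band_outside_range_raises(self):
        tach = UniformTachogram(np.full(400, 800.0), 4.0, 0.0)
        with pytest.raises(ValueError):
            band_powers(hrv_spectrum(tach), hf=(0.15, 3.0))


class TestLnFeatures:
    def test_unit_log(self):
        assert ln_features(math.e, math.e) == pytest.approx((1.0, 1.0, 1.0))

    def test_powers_of_e(self):
        assert ln_features(math.e**4, math.e**2) == pytest.approx((4.0, 2.0, 2.0))

    def test_zero_hf_floored_with_warning(self):
        with pytest.warns(UserWarning):
            ln_vlf, ln_hf, ratio = ln_features(math.e, 0.0)
        assert ln_hf == pytest.approx(math.log(LN_POWER_FLOOR))
        assert np.isfinite(ratio)

    def test_ln_hf_zero_ratio_undefined(self):
        with pytest.raises(ZeroDivisionError):
            ln_features(math.e, 1.0)

    def test_log_of_ratio_mode(self):
        _, _, r = ln_features(math.e**4, math.e**2, ratio_mode="log-of-ratio")
        assert r == pytest.approx(2.0)

    def test_negative_power_raises(self):
        with pytest.raises(ValueError):
            ln_features(-1.0, 1.0)


ZONE_SEMANTICS = {
    # independent re-statement of the zone meanings: (sympathetic, parasympathetic)
    "Zone1": ("low", "high"),
    "Zone2": ("normal", "high"),
    "Zone3": ("high", "high"),
    "Zone4": ("high", "normal"),
    "Zone5": ("high", "low"),
    "Zone6": ("normal", "low"),
    "Zone7": ("low", "low"),
    "Zone8": ("low", "normal"),
    "Reference": ("normal", "normal"),
}


class TestClassifyZone:
    config = ZoneConfig(vlf_low=-1.0, vlf_high=1.0, hf_low=-1.0, hf_high=1.0)

    def test_high_symp_low_para_is_zone5(self):
        assert classify_zone(2.0, -2.0, self.config) == "Zone5"

    def test_low_symp_high_para_is_zone1(self):
        assert classify_zone(-2.0, 2.0, self.config) == "Zone1"

    def test_center_is_reference(self):
        assert classify_zone(0.0, 0.0, self.config) == "Reference"

    def test_partition_exhaustive_grid(self):
        def level(v):
            return "low" if v < -1.0 else ("high" if v > 1.0 else "normal")

        grid = np.linspace(-3.0, 3.0, 61)
        for x, y in itertools.product(grid, grid):
            label = classify_zone(x, y, self.config)
            assert label in ZONE_LABELS
            # exactly one independent semantic predicate matches
            matches = [
                z for z, (sl, pl) in ZONE_SEMANTICS.items()
                if level(x) == sl and level(y) == pl
            ]
            assert matches == [label]

    def test_boundaries_are_normal(self):
        assert classify_zone(1.0, -1.0, self.config) == "Reference"

    def test_bad_config_raises(self):
        with pytest.raises(ValueError):
            ZoneConfig(vlf_low=1.0, vlf_high=-1.0, hf_low=0.0, hf_high=1.0)

    def test_from_reference_percentiles(self):
        rng = np.random.default_rng(0)
        v = rng.normal(6, 1, 200)
        h = rng.normal(6.5, 1, 200)
        cfg = ZoneConfig.from_reference(v, h)
        assert cfg.vlf_low == pytest.approx(np.percentile(v, 25))
        assert cfg.hf_high == pytest.approx(np.percentile(h, 75))


class TestExtractFeatures:
    def test_recovers_known_hf_power(self):
        rr = generate_rr_series(
            RRGenParams(mean_rr=850, hf_amp=15.0, hf_freq=0.25, jitter_sd=0.0,
                        duration=310.0, seed=4)
        )
        ecg, _ = generate_ecg(rr, ECGGenParams(seed=0))
        result = extract_features(ecg)
        assert result.features.ln_hf == pytest.approx(math.log(15.0**2 / 2), abs=0.15)

    def test_deterministic(self):
        rr = generate_rr_series(
            RRGenParams(mean_rr=850, hf_amp=15.0, jitter_sd=10.0, duration=310.0, seed=5)
        )
        ecg, _ = generate_ecg(rr, ECGGenParams(noise_sd=0.02, seed=1))
        r1 = extract_features(ecg)
        r2 = extract_features(ecg)
        assert r1 == r2

    def test_all_rr_outside_nn_bounds_errors(self):
        rr = generate_rr_series(RRGenParams(mean_rr=500.0, jitter_sd=0.0, duration=40.0, seed=0))
        ecg, _ = generate_ecg(rr, ECGGenParams(seed=0))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="NN"):
                extract_features(ecg)

    def test_short_record_warns(self):
        rr = generate_rr_series(RRGenParams(mean_rr=800.0, jitter_sd=5.0, duration=120.0, seed=0))
        ecg, _ = generate_ecg(rr, ECGGenParams(seed=0))
        with pytest.warns(UserWarning):
            extract_features(ecg)

    def test_end_to_end_band_power_recovery_sample(self):
        # scaled-down version of the 20-config acceptance sweep
        rng = np.random.default_rng(99)
        for _ in range(3):
            hf_amp = rng.uniform(8, 20)
            vlf_amp = rng.uniform(8, 20)
            rr = generate_rr_series(
                RRGenParams(mean_rr=850, vlf_amp=vlf_amp, vlf_freq=0.015,
                            hf_amp=hf_amp, hf_freq=0.25, jitter_sd=0.0,
                            duration=305.0, seed=int(rng.integers(1e6)))
            )
            fv = features_from_nn(rr_to_nn(rr))
            assert math.exp(fv.ln_hf) == pytest.approx(hf_amp**2 / 2, rel=0.15)
            assert math.exp(fv.ln_vlf) == pytest.approx(vlf_amp**2 / 2, rel=0.15)
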