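import numpy as np
import pytest

from vimshrv.ecg_processing import NNSeries, RRISeries
from vimshrv.synthetic_data import (
    CohortEffectParams,
    ECGGenParams,
    RRGenParams,
    generate_ecg,
    generate_cohort,
    generate_rr_series,
)


def nn_from(intervals_ms, t0=0.0):
    """Build an NNSeries with cumulative onset times from a list of intervals."""
    intervals = np.asarray(intervals_ms, dtype=float)
    onsets = t0 + np.concatenate([[0.0], np.cumsum(intervals[:-1]) / 1000.0])
    return NNSeries(intervals, onsets)


def rri_from(intervals_ms, t0=0.0):
    intervals = np.asarray(intervals_ms, dtype=float)
    onsets = t0 + np.concatenate([[0.0], np.cumsum(intervals[:-1]) / 1000.0])
    return RRISeries(intervals, onsets)


def match_peaks(detected_times, truth_times, tol=0.020):
    """Greedy nearest matching: true positives within +/- tol seconds."""
    from scipy.spatial import cKDTree

    if len(detected_times) == 0:
        return 0
    d, _ = cKDTree(np.asarray(detected_times)[:, None]).query(np.asarray(truth_times)[:, None])
    return int(np.sum(d <= tol))


@pytest.fixture(scope="session")
def clean_ecg_1hz():
    """Noise-free synthetic ECG: 60 beats at exactly 1 Hz, with ground truth."""
    rr = generate_rr_series(RRGenParams(mean_rr=1000.0, jitter_sd=0.0, duration=60.0, seed=0))
    ecg, truth = generate_ecg(rr, ECGGenParams(seed=0))
    return ecg, truth


@pytest.fixture(scope="session")
def noisy_ecg():
    """Synthetic ECG with baseline wander + mains + white noise (SNR >= 10 dB)."""
    rr = generate_rr_series(
        RRGenParams(mean_rr=800.0, vlf_amp=20.0, hf_amp=20.0, jitter_sd=30.0,
                    duration=300.0, seed=2)
    )
    params = ECGGenParams(
        baseline_wander_amp=0.07, powerline_amp=0.04, noise_sd=0.02, seed=3
    )
    ecg, truth = generate_ecg(rr, params)
    clean, _ = generate_ecg(rr, ECGGenParams(seed=3))
    noise = ecg.samples - clean.samples
    snr_db = 10 * np.log10(np.mean(clean.samples**2) / np.mean(noise**2))
    assert snr_db >= 10.0, f"fixture SNR {snr_db:.1f} dB below 10 dB"
    return ecg, truth


def large_effect_params(seed=0, scale=1.5):
    """Cohort params with programmed effects scaled up to 'large' (3 SD units)."""
    base = CohortEffectParams()
    effects = {k: v * scale for k, v in base.effects.items()}
    return CohortEffectParams(seed=seed, effects=effects)


def null_effect_params(seed=0):
    base = CohortEffectParams()
    return CohortEffectParams(seed=seed, effects={k: 0.0 for k in base.effects})


@pytest.fixture(scope="session")
def large_effect_cohort():
    return generate_cohort(large_effect_params(seed=11))


@pytest.fixture(scope="session")
def null_effect_cohort():
    return generate_cohort(null_effect_params(seed=12))
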