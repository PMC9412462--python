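"""HRV feature extraction and autonomic-balance zoning.

Time-domain indices (heart rate, SDNN, pNN50) are computed directly on NN
intervals. For the frequency domain, the NN tachogram is cubic-spline
resampled onto a uniform 4 Hz grid, a single full-segment Hann periodogram is
taken, and band powers are integrated over the VLF (0.0033-0.04 Hz,
sympathetic-linked) and HF (0.15-0.4 Hz, parasympathetic-linked) bands.
ln VLF and ln HF ("normalized HRV") locate the subject on a 3x3 grid of
autonomic-balance zones (eight labeled zones around a central reference zone).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import interpolate as spi
from scipy import signal as sps

from vimshrv.ecg_processing import (
    DetectorConfig,
    ECGRecord,
    NNSeries,
    bandpass_filter,
    compute_rri,
    detect_r_peaks,
    filter_nn,
)

__all__ = [
    "UniformTachogram",
    "HRVSpectrum",
    "FeatureVector",
    "ZoneConfig",
    "FeatureConfig",
    "ExtractionResult",
    "ZONE_LABELS",
    "LN_POWER_FLOOR",
    "sdnn",
    "pnn50",
    "mean_heart_rate",
    "resample_tachogram",
    "hrv_spectrum",
    "band_powers",
    "ln_features",
    "classify_zone",
    "extract_features",
    "features_from_nn",
]

VLF_BAND = (0.0033, 0.04)
HF_BAND = (0.15, 0.4)

#: Floor applied before taking logs so degenerate (zero-power) inputs stay finite.
LN_POWER_FLOOR = 1e-12


@dataclass(frozen=True)
class UniformTachogram:
    """NN tachogram resampled onto a uniform grid (default 4 Hz)."""

    values: np.ndarray  # ms
    fs_resample: float  # Hz
    t0: float  # s, time of the first grid point

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.size < 2:
            raise ValueError("tachogram needs at least 2 samples")
        if not self.fs_resample > 0:
            raise ValueError("resampling rate must be positive")
        object.__setattr__(self, "values", values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs_resample


@dataclass(frozen=True)
class HRVSpectrum:
    """One-sided PSD of the tachogram in ms^2/Hz."""

    freqs: np.ndarray
    psd: np.ndarray
    window: str = "hann"
    segment_length: int = 0

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        psd = np.asarray(self.psd, dtype=float)
        if freqs.shape != psd.shape:
            raise ValueError("freqs and psd must have equal length")
        if np.any(np.diff(freqs) <= 0) or freqs[0] < 0:
            raise ValueError("freqs must be non-negative ascending")
        if np.any(psd < 0):
            raise ValueError("PSD must be non-negative")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "psd", psd)

    def total_power(self) -> float:
        """Integral of the PSD over all frequencies (ms^2)."""
        return float(np.trapezoid(self.psd, self.freqs))


@dataclass(frozen=True)
class FeatureVector:
    """The six cardiac indices used throughout the pipeline."""

    heart_rate: float  # bpm
    sdnn: float  # ms
    pnn50: float  # %
    ln_vlf: float  # ln(ms^2)
    ln_hf: float  # ln(ms^2)
    ln_ratio: float  # ln VLF / ln HF (quotient of logs)

    #: order of the five classification features (heart rate excluded)
    CLASSIFICATION_FEATURES = ("sdnn", "pnn50", "ln_vlf", "ln_hf", "ln_ratio")
    ALL_FEATURES = ("heart_rate",) + CLASSIFICATION_FEATURES

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.ALL_FEATURES}


ZONE_LABELS = tuple(f"Zone{i}" for i in range(1, 9)) + ("Reference",)

# (sympathetic level, parasympathetic level) -> zone label, levels in
# {low, normal, high}; x-axis = ln VLF (sympathetic), y-axis = ln HF
# (parasympathetic)
_ZONE_GRID = {
    ("low", "high"): "Zone1",
    ("normal", "high"): "Zone2",
    ("high", "high"): "Zone3",
    ("high", "normal"): "Zone4",
    ("high", "low"): "Zone5",
    ("normal", "low"): "Zone6",
    ("low", "low"): "Zone7",
    ("low", "normal"): "Zone8",
    ("normal", "normal"): "Reference",
}


@dataclass(frozen=True)
class ZoneConfig:
    """Thresholds trisecting the (ln VLF, ln HF) plane into the 3x3 zone grid.

    ``normal`` is the closed interval [low, high] on each axis; strictly
    below/above the thresholds maps to low/high. No numeric defaults exist in
    the source method description, so thresholds are mandatory; use
    :meth:`from_reference` to derive them from a reference cohort
    (25th/75th percentiles — a documented stand-in, not a published value).
    """

    vlf_low: float
    vlf_high: float
    hf_low: float
    hf_high: float

    def __post_init__(self) -> None:
        if not (self.vlf_low < self.vlf_high and self.hf_low < self.hf_high):
            raise ValueError("zone thresholds must satisfy low < high on both axes")

    @classmethod
    def from_reference(
        cls, ln_vlf_values: np.ndarray, ln_hf_values: np.ndarray
    ) -> "ZoneConfig":
        """Thresholds at the 25th/75th percentiles of a reference cohort."""
        vq = np.percentile(np.asarray(ln_vlf_values, dtype=float), [25, 75])
        hq = np.percentile(np.asarray(ln_hf_values, dtype=float), [25, 75])
        return cls(vlf_low=vq[0], vlf_high=vq[1], hf_low=hq[0], hf_high=hq[1])


def sdnn(nn: NNSeries) -> float:
    """Sample standard deviation (n-1 denominator) of NN intervals, ms."""
    if len(nn) < 2:
        raise ValueError("SDNN needs at least 2 NN intervals")
    return float(np.std(nn.intervals, ddof=1))


def pnn50(nn: NNSeries) -> float:
    """Percentage of adjacent NN pairs differing by strictly more than 50 ms."""
    if len(nn) < 2:
        raise ValueError("pNN50 needs at least 2 NN intervals")
    diffs = np.abs(np.diff(nn.intervals))
    return float(100.0 * np.count_nonzero(diffs > 50.0) / diffs.size)


def mean_heart_rate(nn: NNSeries) -> float:
    """Mean heart rate in bpm, 60000 / mean NN interval."""
    if len(nn) < 1:
        raise ValueError("heart rate needs at least 1 NN interval")
    return float(60000.0 / np.mean(nn.intervals))


def resample_tachogram(nn: NNSeries, fs_resample: float = 4.0) -> UniformTachogram:
    """Cubic-spline resampling of (onset_time, interval) onto a uniform grid.

    The spline passes through the knots; gaps left by NN rejection are bridged
    by the spline over the surviving onset times (no re-timing).
    """
    if len(nn) < 4:
        raise ValueError("resampling needs at least 4 NN intervals")
    t = nn.onset_times
    if np.any(np.diff(t) <= 0):
        raise ValueError("onset times must be strictly increasing")
    span = t[-1] - t[0]
    if span < 2.0:
        raise ValueError(f"NN span of {span:.2f} s too short to resample")
    spline = spi.CubicSpline(t, nn.intervals)
    n = int(math.floor(span * fs_resample)) + 1
    grid = t[0] + np.arange(n) / fs_resample
    return UniformTachogram(spline(grid), fs_resample, t0=float(t[0]))


def hrv_spectrum(tach: UniformTachogram) -> HRVSpectrum:
    """Single full-segment Hann periodogram of the de-meaned tachogram.

    The PSD is one-sided with window power compensation, so its integral
    equals the variance of the de-meaned series (Parseval, within 1%).
    """
    if tach.values.size < 64:
        raise ValueError("spectrum needs at least 64 tachogram samples")
    freqs, psd = sps.periodogram(
        tach.values,
        fs=tach.fs_resample,
        window="hann",
        detrend="constant",
        scaling="density",
    )
    # exact window power compensation: rescale so the PSD integral equals the
    # variance of the de-meaned series (the raw windowed periodogram matches
    # only to within a few percent on noise-like inputs)
    variance = float(np.var(tach.values))
    integral = float(np.trapezoid(psd, freqs))
    if integral > 0 and variance > 0:
        psd = psd * (variance / integral)
    return HRVSpectrum(freqs, psd, window="hann", segment_length=tach.values.size)


def band_powers(
    spec: HRVSpectrum,
    vlf: tuple[float, float] = VLF_BAND,
    hf: tuple[float, float] = HF_BAND,
) -> tuple[float, float]:
    """Trapezoidal integration of the PSD over the closed VLF and HF bands.

    Warns when the frequency resolution cannot resolve the lower VLF edge
    (records shorter than ~1/0.0033 s ~ 300 s).
    """
    for lo, hi in (vlf, hf):
        if not (0 <= lo < hi <= spec.freqs[-1]):
            raise ValueError(f"band [{lo}, {hi}] outside spectral range")
    df = spec.freqs[1] - spec.freqs[0]
    if df > vlf[0]:
        warnings.warn(
            f"frequency resolution {df:.5f} Hz cannot resolve the {vlf[0]} Hz "
            "VLF edge; use records of >= ~300 s",
            stacklevel=2,
        )
    return _integrate_band(spec, vlf), _integrate_band(spec, hf)


def _integrate_band(spec: HRVSpectrum, band: tuple[float, float]) -> float:
    lo, hi = band
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(spec.psd[mask], spec.freqs[mask]))


def ln_features(
    vlf_power: float,
    hf_power: float,
    ratio_mode: str = "quotient-of-logs",
) -> tuple[float, float, float]:
    """Natural-log band powers and their ratio feature.

    ``ln_vlf = ln(max(vlf_power, eps))`` with floor ``eps = 1e-12`` ms^2
    (warned when hit). The ratio feature follows its literal name, the
    quotient of the logs ``ln(VLF)/ln(HF)``; ``ratio_mode="log-of-ratio"``
    switches to ``ln(VLF/HF)`` for sensitivity experiments.

    Raises
    ------
    ZeroDivisionError
        If ``ln_hf`` is exactly 0 under the quotient-of-logs mode.
    """
    if vlf_power < 0 or hf_power < 0:
        raise ValueError("band powers must be non-negative")
    if vlf_power < LN_POWER_FLOOR or hf_power < LN_POWER_FLOOR:
        warnings.warn("band power at or below the ln floor; features degenerate", stacklevel=2)
    ln_vlf = math.log(max(vlf_power, LN_POWER_FLOOR))
    ln_hf = math.log(max(hf_power, LN_POWER_FLOOR))
    if ratio_mode == "quotient-of-logs":
        if ln_hf == 0.0:
            raise ZeroDivisionError("ln HF is exactly 0: quotient-of-logs ratio undefined")
        ln_ratio = ln_vlf / ln_hf
    elif ratio_mode == "log-of-ratio":
        ln_ratio = ln_vlf - ln_hf
    else:
        raise ValueError(f"unknown ratio_mode {ratio_mode!r}")
    return ln_vlf, ln_hf, ln_ratio


def _level(value: float, low: float, high: float) -> str:
    if value < low:
        return "low"
    if value > high:
        return "high"
    return "normal"


def classify_zone(ln_vlf: float, ln_hf: float, config: ZoneConfig) -> str:
    """Map a (ln VLF, ln HF) point to one of the nine autonomic-balance zones.

    The x-axis (ln VLF) indexes sympathetic tone, the y-axis (ln HF)
    parasympathetic tone; both are trisected into low/normal/high by the
    config thresholds ("normal" is the closed interval). Zone 5 is high
    sympathetic with low parasympathetic tone; the central cell is the
    reference zone. Total over the plane: every finite point gets exactly
    one label.
    """
    symp = _level(ln_vlf, config.vlf_low, config.vlf_high)
    para = _level(ln_hf, config.hf_low, config.hf_high)
    return _ZONE_GRID[(symp, para)]


@dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the full ECG -> feature chain."""

    bandpass_low: float = 5.0
    bandpass_high: float = 15.0
    nn_low: float = 600.0
    nn_high: float = 1200.0
    fs_resample: float = 4.0
    vlf_band: tuple[float, float] = VLF_BAND
    hf_band: tuple[float, float] = HF_BAND
    ratio_mode: str = "quotient-of-logs"
    detector: DetectorConfig = field(default_factory=DetectorConfig)


@dataclass(frozen=True)
class ExtractionResult:
    """Feature vector plus QC counts from one extraction run."""

    features: FeatureVector
    n_beats: int
    n_rejected: int


def features_from_nn(nn: NNSeries, config: FeatureConfig | None = None) -> FeatureVector:
    """Compute the six-feature vector from an NN series."""
    config = config or FeatureConfig()
    if len(nn) < 4:
        raise ValueError("no (or too few) NN intervals: cannot compute features")
    tach = resample_tachogram(nn, config.fs_resample)
    spec = hrv_spectrum(tach)
    vlf_p, hf_p = band_powers(spec, config.vlf_band, config.hf_band)
    ln_vlf, ln_hf, ln_ratio = ln_features(vlf_p, hf_p, config.ratio_mode)
    return FeatureVector(
        heart_rate=mean_heart_rate(nn),
        sdnn=sdnn(nn),
        pnn50=pnn50(nn),
        ln_vlf=ln_vlf,
        ln_hf=ln_hf,
        ln_ratio=ln_ratio,
    )


def extract_features(ecg: ECGRecord, config: FeatureConfig | None = None) -> ExtractionResult:
    """Run the full chain: band-pass -> R peaks -> RRI -> NN -> features.

    Warns for records shorter than 300 s (the VLF lower band edge is then not
    resolvable). Raises if no NN intervals survive filtering.
    """
    config = config or FeatureConfig()
    if ecg.duration < 300.0:
        warnings.warn(
            f"record of {ecg.duration:.0f} s is shorter than the ~300 s needed "
            "to resolve the VLF band",
            stacklevel=2,
        )
    filtered = bandpass_filter(ecg, config.bandpass_low, config.bandpass_high)
    peaks = detect_r_peaks(filtered, config.detector, raw=ecg)
    rri = compute_rri(peaks)
    nn = filter_nn(rri, config.nn_low, config.nn_high)
    if len(nn) == 0:
        raise ValueError("no NN intervals after filtering")
    features = features_from_nn(nn, config)
    return ExtractionResult(features=features, n_beats=len(peaks), n_rejected=nn.n_rejected)
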