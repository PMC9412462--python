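"""Synthetic data generators: RR series, ECG waveforms, SSQ responses, cohorts.

Every generator is a pure function of its parameters and seed. RR modulation
is additive sinusoidal (one VLF tone + one HF tone + white jitter), which has
an exact analytic band power of a^2/2 per tone — the ground truth against
which spectral recovery is tested. ECG beats are a sum-of-Gaussians template
train (P, Q, R, S, T) with controllable baseline wander, mains interference,
and white noise; ground-truth R times are returned for detector scoring.
Cohorts emulate a within-subject 2D-vs-VR design with a programmed VR-post
effect (SDNN down, pNN50 down, ln HF down, ln VLF up) and SSQ ratings coupled
to the programmed severity through a cumulative-threshold ordinal model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from vimshrv.ecg_processing import ECGRecord, NNSeries, RRISeries
from vimshrv.hrv_features import FeatureVector, ln_features
from vimshrv.ssq_scoring import SSQ_ITEMS, SSQResponse, score_ssq

__all__ = [
    "RRGenParams",
    "ECGGenParams",
    "CohortEffectParams",
    "CohortDataset",
    "DEFAULT_BEAT_TEMPLATE",
    "generate_rr_series",
    "generate_ecg",
    "generate_ssq_response",
    "generate_cohort",
    "normal_rr_params",
    "vr_rr_params",
]

VLF_RANGE = (0.0033, 0.04)
HF_RANGE = (0.15, 0.4)


@dataclass(frozen=True)
class RRGenParams:
    """Parameters of the additive-sinusoid RR generator.

    ``RR(k) = mean_rr + vlf_amp sin(2 pi vlf_freq t_k)
            + hf_amp sin(2 pi hf_freq t_k) + eps_k``,
    ``eps_k ~ N(0, jitter_sd^2)``, with ``t_k`` the cumulative beat time.
    """

    mean_rr: float = 850.0  # ms
    vlf_amp: float = 0.0  # ms
    vlf_freq: float = 0.01  # Hz
    hf_amp: float = 0.0  # ms
    hf_freq: float = 0.25  # Hz
    jitter_sd: float = 0.0  # ms
    duration: float = 300.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_rr > 0:
            raise ValueError(f"mean_rr must be positive, got {self.mean_rr}")
        if self.vlf_amp < 0 or self.hf_amp < 0 or self.jitter_sd < 0:
            raise ValueError("amplitudes and jitter_sd must be non-negative")
        if self.duration < 2 * self.mean_rr / 1000.0:
            raise ValueError("duration too short to contain at least 2 beats")


# (amplitude mV, offset s relative to R, width s) per deflection
DEFAULT_BEAT_TEMPLATE: tuple[tuple[float, float, float], ...] = (
    (0.12, -0.22, 0.030),  # P
    (-0.12, -0.035, 0.012),  # Q
    (1.00, 0.0, 0.014),  # R
    (-0.18, 0.035, 0.012),  # S
    (0.35, 0.28, 0.070),  # T
)


@dataclass(frozen=True)
class ECGGenParams:
    """Parameters of the Gaussian-template ECG synthesizer."""

    beat_template: tuple[tuple[float, float, float], ...] = DEFAULT_BEAT_TEMPLATE
    baseline_wander_amp: float = 0.0  # mV at ~0.3 Hz
    baseline_wander_freq: float = 0.3  # Hz
    powerline_amp: float = 0.0  # mV at 60 Hz
    powerline_freq: float = 60.0  # Hz
    noise_sd: float = 0.0  # mV white noise
    fs: float = 500.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 100:
            raise ValueError(f"fs = {self.fs} Hz too low to resolve the QRS (need >= 100)")
        r_amp = max(a for a, _, _ in self.beat_template)
        positives = sorted((a for a, _, _ in self.beat_template if a > 0), reverse=True)
        if len(positives) >= 2 and positives[0] <= positives[1]:
            raise ValueError("template R amplitude must be the strictly largest positive deflection")
        if r_amp <= 0:
            raise ValueError("template must contain a positive R deflection")


def generate_rr_series(params: RRGenParams) -> RRISeries:
    """Generate an RR-interval series with known VLF/HF spectral content.

    Returns an :class:`RRISeries` whose ``onset_times`` are the cumulative
    beat times; the total span is at least ``params.duration``. Reproducible
    from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    intervals: list[float] = []
    onsets: list[float] = []
    t = 0.0
    while t < params.duration:
        rr = (
            params.mean_rr
            + params.vlf_amp * np.sin(2 * np.pi * params.vlf_freq * t)
            + params.hf_amp * np.sin(2 * np.pi * params.hf_freq * t)
            + (rng.normal(0.0, params.jitter_sd) if params.jitter_sd > 0 else 0.0)
        )
        if rr <= 0:
            raise ValueError("generated a non-positive RR interval; reduce amplitudes/jitter")
        intervals.append(rr)
        onsets.append(t)
        t += rr / 1000.0
    if len(intervals) < 2:
        raise ValueError("duration too short to contain at least 2 beats")
    return RRISeries(np.asarray(intervals), np.asarray(onsets))


def rr_to_nn(rr: RRISeries) -> NNSeries:
    """View a generated RR series as an NN series (no filtering)."""
    return NNSeries(rr.intervals, rr.onset_times, n_rejected=0)


def generate_ecg(
    rr_series: RRISeries, params: ECGGenParams | None = None
) -> tuple[ECGRecord, np.ndarray]:
    """Synthesize an ECG trace from an RR series.

    One beat template is centered at each cumulative beat time; baseline
    wander, mains interference, and white noise are added per ``params``.

    Returns
    -------
    (ECGRecord, ndarray)
        The record and the ground-truth R-peak times in seconds; the R count
        equals the number of generated beats (len(rr_series) + 1).
    """
    params = params or ECGGenParams()
    if len(rr_series) < 1:
        raise ValueError("need at least 2 beats to synthesize an ECG")
    # 0.5 s lead-in so the first beat's template is not clipped by the record edge
    beat_times = 0.5 + np.concatenate(
        [rr_series.onset_times, [rr_series.onset_times[-1] + rr_series.intervals[-1] / 1000.0]]
    )
    fs = params.fs
    t_end = beat_times[-1] + 0.5
    n = int(np.ceil(t_end * fs))
    t = np.arange(n) / fs
    sig = np.zeros(n)
    max_width = max(w for _, _, w in params.beat_template)
    for bt in beat_times:
        for amp, offset, width in params.beat_template:
            center = bt + offset
            lo = max(int((center - 5 * width) * fs), 0)
            hi = min(int((center + 5 * width) * fs) + 1, n)
            if hi <= lo:
                continue
            tt = t[lo:hi]
            sig[lo:hi] += amp * np.exp(-0.5 * ((tt - center) / width) ** 2)
    rng = np.random.default_rng(params.seed)
    if params.baseline_wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        sig += params.baseline_wander_amp * np.sin(
            2 * np.pi * params.baseline_wander_freq * t + phase
        )
    if params.powerline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        sig += params.powerline_amp * np.sin(2 * np.pi * params.powerline_freq * t + phase)
    if params.noise_sd > 0:
        sig += rng.normal(0.0, params.noise_sd, size=n)
    return ECGRecord(sig, fs), beat_times


#: thresholds of the cumulative ordinal SSQ item model on the latent scale
SSQ_THRESHOLDS = (0.5, 1.75, 3.0)


def generate_ssq_response(severity: float, seed: int | np.random.Generator = 0) -> SSQResponse:
    """Draw a 16-item SSQ response from a cumulative-threshold ordinal model.

    Each item's latent value is ``severity + N(0, 1)``; the rating is the
    number of fixed thresholds the latent exceeds, so ratings are monotone in
    severity, hit 0 as severity -> -inf and 3 as severity -> +inf.
    """
    if not np.isfinite(severity):
        raise ValueError("severity must be finite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ratings = {}
    thresholds = np.asarray(SSQ_THRESHOLDS)
    for item in SSQ_ITEMS:
        latent = severity + rng.normal()
        ratings[item] = int(np.sum(latent > thresholds))
    return SSQResponse(ratings)


_FEATURES = ("heart_rate", "sdnn", "pnn50", "ln_vlf", "ln_hf")

_DEFAULT_MEANS = {
    "heart_rate": 72.0,
    "sdnn": 50.0,
    "pnn50": 25.0,
    "ln_vlf": 6.0,
    "ln_hf": 6.5,
}
_DEFAULT_BETWEEN_SD = {
    "heart_rate": 6.0,
    "sdnn": 10.0,
    "pnn50": 8.0,
    "ln_vlf": 0.7,
    "ln_hf": 0.7,
}
# VR-post shifts in SD units; signs follow the programmed VR direction
# (SDNN down, pNN50 down, ln HF down, ln VLF up; heart rate mildly down)
_DEFAULT_EFFECTS = {
    "heart_rate": -0.3,
    "sdnn": -2.0,
    "pnn50": -2.0,
    "ln_vlf": 2.0,
    "ln_hf": -2.0,
}


@dataclass(frozen=True)
class CohortEffectParams:
    """Programmed effect structure of a synthetic 2D-vs-VR cohort."""

    n_subjects: int = 28
    effects: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_EFFECTS))
    means: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    between_sd: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_BETWEEN_SD))
    prepost_corr: float = 0.7
    ssq_coupling: float = 1.2  # slope from latent MS severity to SSQ item propensity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0 <= self.prepost_corr < 1:
            raise ValueError("prepost_corr must be in [0, 1)")
        for name in _FEATURES:
            if name not in self.means or name not in self.between_sd:
                raise ValueError(f"means/between_sd must cover feature {name!r}")
            if self.between_sd[name] <= 0:
                raise ValueError("between-subject SDs must be positive")

    @property
    def mean_abs_effect(self) -> float:
        cardiac = [abs(self.effects.get(f, 0.0)) for f in ("sdnn", "pnn50", "ln_vlf", "ln_hf")]
        return float(np.mean(cardiac))


@dataclass
class CohortDataset:
    """Subject x condition x phase table of features + SSQ scores.

    ``table`` columns: subject, condition (2D/VR), phase (pre/post), the six
    cardiac features, and the four weighted SSQ scores. In end-to-end mode
    ``records`` maps (subject, condition, phase) to the generated raw
    :class:`RRISeries` or :class:`ECGRecord` and feature columns are filled
    downstream.
    """

    table: pd.DataFrame
    records: dict[tuple[str, str, str], object] | None = None
    ground_truth: dict | None = None

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CohortDataset":
        return cls(table=pd.read_csv(path, sep="\t"))


def normal_rr_params(duration: float = 330.0, seed: int = 0, mean_rr: float = 850.0) -> RRGenParams:
    """RR regime emulating a calm (2D-viewing-like) state."""
    return RRGenParams(
        mean_rr=mean_rr,
        vlf_amp=20.0,
        vlf_freq=0.01,
        hf_amp=30.0,
        hf_freq=0.25,
        jitter_sd=30.0,
        duration=duration,
        seed=seed,
    )


def vr_rr_params(duration: float = 330.0, seed: int = 0, mean_rr: float = 850.0) -> RRGenParams:
    """RR regime emulating the programmed VR-post state.

    Relative to :func:`normal_rr_params`: VLF modulation up, HF modulation
    down, beat-to-beat jitter down (lower SDNN / pNN50).
    """
    return RRGenParams(
        mean_rr=mean_rr,
        vlf_amp=55.0,
        vlf_freq=0.01,
        hf_amp=8.0,
        hf_freq=0.25,
        jitter_sd=12.0,
        duration=duration,
        seed=seed,
    )


def _severity(cell_is_vr_post: bool, params: CohortEffectParams, rng: np.random.Generator) -> float:
    # baseline latent severity; VR-post elevation is proportional to the
    # programmed cardiac effect so zero-effect cohorts are null for SSQ too
    base = -1.2
    if cell_is_vr_post:
        base += params.ssq_coupling * params.mean_abs_effect
    return base + rng.normal(0.0, 0.4)


def generate_cohort(params: CohortEffectParams, mode: str = "features") -> CohortDataset:
    """Generate a full pre/post x 2D/VR cohort with known ground truth.

    mode="features"
        Fast path: feature vectors are drawn directly from the programmed
        effect model. Per subject and feature, all four cells share a subject
        effect with variance ``prepost_corr * sd^2`` (inducing the requested
        pre/post correlation); the programmed shift (in SD units) is added to
        the VR-post cell only.
    mode="rr" / mode="ecg"
        End-to-end path: each cell carries a raw RR series (or synthesized
        ECG); VR-post cells use the VR RR regime, all others the normal
        regime. Feature columns are left NaN for downstream extraction.

    SSQ responses are generated for every cell from a latent severity that is
    elevated only in VR-post cells, with slope ``ssq_coupling``.
    """
    if mode not in {"features", "rr", "ecg"}:
        raise ValueError(f"unknown mode {mode!r}")
    root = np.random.SeedSequence(params.seed)
    rows = []
    records: dict[tuple[str, str, str], object] = {}
    cells = [("2D", "pre"), ("2D", "post"), ("VR", "pre"), ("VR", "post")]
    for si, child in enumerate(root.spawn(params.n_subjects)):
        rng = np.random.default_rng(child)
        subject = f"S{si + 1:02d}"
        # shared subject effect per feature gives the pre/post correlation
        subj_eff = {
            f: rng.normal(0.0, np.sqrt(params.prepost_corr) * params.between_sd[f])
            for f in _FEATURES
        }
        for condition, phase in cells:
            is_vr_post = condition == "VR" and phase == "post"
            row: dict[str, object] = {"subject": subject, "condition": condition, "phase": phase}
            if mode == "features":
                values = {}
                for f in _FEATURES:
                    sd = params.between_sd[f]
                    noise = rng.normal(0.0, np.sqrt(1 - params.prepost_corr) * sd)
                    value = params.means[f] + subj_eff[f] + noise
                    if is_vr_post:
                        value += params.effects.get(f, 0.0) * sd
                    values[f] = value
                values["pnn50"] = float(np.clip(values["pnn50"], 0.0, 100.0))
                values["heart_rate"] = max(values["heart_rate"], 30.0)
                _, _, ln_ratio = ln_features(
                    float(np.exp(values["ln_vlf"])), float(np.exp(values["ln_hf"]))
                )
                row.update(values)
                row["ln_ratio"] = ln_ratio
            else:
                cell_seed = int(rng.integers(2**31))
                rr_params = (
                    vr_rr_params(seed=cell_seed)
                    if is_vr_post
                    else normal_rr_params(seed=cell_seed)
                )
                # small per-subject mean-RR variation, kept inside NN bounds
                rr_params = replace(
                    rr_params, mean_rr=float(np.clip(850.0 + subj_eff["sdnn"] * 5.0, 700, 1000))
                )
                rr = generate_rr_series(rr_params)
                if mode == "ecg":
                    ecg, _ = generate_ecg(rr, ECGGenParams(seed=cell_seed))
                    records[(subject, condition, phase)] = ecg
                else:
                    records[(subject, condition, phase)] = rr
                for f in (*_FEATURES, "ln_ratio"):
                    row[f] = np.nan
            ssq = score_ssq(generate_ssq_response(_severity(is_vr_post, params, rng), rng))
            row.update(
                ssq_n=ssq.n_score, ssq_o=ssq.o_score, ssq_d=ssq.d_score, ssq_total=ssq.total
            )
            rows.append(row)
    table = pd.DataFrame(rows)
    ground_truth = {
        "mode": mode,
        "n_subjects": params.n_subjects,
        "effects": dict(params.effects),
        "prepost_corr": params.prepost_corr,
        "ssq_coupling": params.ssq_coupling,
        "seed": params.seed,
    }
    return CohortDataset(table=table, records=records or None, ground_truth=ground_truth)


def write_ground_truth(dataset: CohortDataset, path: str | Path) -> None:
    """Dump the cohort's generating parameters as JSON."""
    with open(path, "w") as fh:
        json.dump(dataset.ground_truth or {}, fh, indent=2)
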