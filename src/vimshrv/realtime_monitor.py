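"""Sliding-window monitoring: per-window HRV features and a binary MS decision.

An offline/streaming stand-in for the interactive monitoring system: the ECG
stream is cut into overlapping windows (default 300 s, the shortest span that
resolves the lower VLF band edge, at a 10 s stride); each window runs the full
feature chain, is placed in an autonomic-balance zone, and is classified as
``MS`` or ``normal`` by a trained classifier. Windows whose extraction fails
are logged as invalid with the reason, never dropped silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from vimshrv.ecg_processing import ECGRecord
from vimshrv.hrv_features import FeatureConfig, FeatureVector, ZoneConfig, classify_zone, extract_features
from vimshrv.ms_classifier import CLASSIFICATION_FEATURES, TrainedClassifier

__all__ = ["MonitorConfig", "WindowRecord", "MonitorLog", "iter_windows", "monitor"]


@dataclass(frozen=True)
class MonitorConfig:
    """Windowing, classifier, and zoning configuration of the monitor."""

    classifier: TrainedClassifier
    zone_config: ZoneConfig
    window_length: float = 300.0  # s
    stride: float = 10.0  # s
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)

    def __post_init__(self) -> None:
        if not 0 < self.stride <= self.window_length:
            raise ValueError("need 0 < stride <= window_length")


@dataclass(frozen=True)
class WindowRecord:
    """One per-window log entry; ``features`` is None for invalid windows."""

    t_start: float
    t_end: float
    features: FeatureVector | None
    zone: str | None
    decision: str  # "MS", "normal", or "invalid"
    reason: str | None = None


@dataclass
class MonitorLog:
    records: list[WindowRecord]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {"t_start": rec.t_start, "t_end": rec.t_end, "decision": rec.decision,
                   "zone": rec.zone, "reason": rec.reason}
            if rec.features is not None:
                row.update(rec.features.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)


def iter_windows(ecg: ECGRecord, config: MonitorConfig) -> Iterator[ECGRecord]:
    """Yield windows [t, t + W) at starts 0, stride, 2*stride, ...

    Window count is floor((T - W)/stride) + 1; raises if the record is
    shorter than a single window.
    """
    T = ecg.duration
    W = config.window_length
    if T < W:
        raise ValueError(f"record of {T:.1f} s shorter than one {W:.1f} s window")
    n_windows = int(np.floor((T - W) / config.stride)) + 1
    for i in range(n_windows):
        t0 = ecg.start_time + i * config.stride
        yield ecg.slice(t0, t0 + W)


def monitor(ecg: ECGRecord, config: MonitorConfig) -> MonitorLog:
    """Run the windowed pipeline: features + zone + binary decision per window."""
    records: list[WindowRecord] = []
    for window in iter_windows(ecg, config):
        t0, t1 = window.start_time, window.start_time + config.window_length
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = extract_features(window, config.feature_config)
        except (ValueError, ZeroDivisionError) as exc:
            records.append(
                WindowRecord(t0, t1, None, None, decision="invalid", reason=str(exc))
            )
            continue
        fv = result.features
        zone = classify_zone(fv.ln_vlf, fv.ln_hf, config.zone_config)
        x = np.array([[getattr(fv, name) for name in CLASSIFICATION_FEATURES]])
        labels, _ = config.classifier.predict(x)
        decision = "MS" if labels[0] == 1 else "normal"
        records.append(WindowRecord(t0, t1, fv, zone, decision=decision))
    return MonitorLog(records=records)
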