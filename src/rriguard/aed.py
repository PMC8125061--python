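"""Autoencoder-based extrasystole detection (AED).

A beat ``t`` is screened through the window ``x_t = [r_{t-3}, r_{t-2},
r_{t-1}, r_t]``: the window is centered by its own mean, passed through the
detection autoencoder, and its reconstruction error (RE) compared with the
calibrated ceiling ``re_max``.  Anomalous beats are then classified with two
interval thresholds ``r1 < r2`` (confidence limits of normal RRIs):

* ``r_t > r2``            -> R-wave detection error (one ~doubled interval)
* ``r_t < r1``:
    * ``r_{t+1} > r2``    -> PVC (short interval then compensatory pause)
    * ``r1 <= r_{t+1} <= r2`` -> PAC (short interval, no compensation)
    * ``r_{t+1} < r1``    -> other arrhythmia (successive short intervals)
* otherwise               -> other arrhythmia

Classification therefore lags the stream by one beat, since ``r_{t+1}`` is
needed to separate PVC from PAC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .neuralnet import AEModel, reconstruction_error
from .rri_data import RRISeries, WINDOW, build_hankel, center_window

#: Beats suppressed after an ectopic label: a single event perturbs the two
#: intervals at t and t+1, which appear in windows ending up to t+4.
_COOLDOWN = 4

__all__ = [
    "DetectionThresholds",
    "BeatLabel",
    "calibrate_re_threshold",
    "calibrate_rri_limits",
    "classify_beat",
    "detect_stream",
]


@dataclass(frozen=True)
class DetectionThresholds:
    """Calibrated thresholds: RE ceiling and normal-RRI confidence limits."""

    re_max: float
    r1: float
    r2: float
    alpha: float = 99.0

    def __post_init__(self) -> None:
        if not self.re_max > 0:
            raise ValueError("re_max must be positive")
        if not self.r1 < self.r2:
            raise ValueError("need r1 < r2")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "re_max": float(self.re_max),
                    "r1": float(self.r1),
                    "r2": float(self.r2),
                    "alpha": float(self.alpha),
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "DetectionThresholds":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(re_max=d["re_max"], r1=d["r1"], r2=d["r2"], alpha=d["alpha"])


@dataclass(frozen=True)
class BeatLabel:
    beat_index: int
    label: str  # NORMAL | PVC | PAC | RDE | OTHER
    re_value: float


def _windows_centered(series: RRISeries) -> np.ndarray:
    rows = build_hankel(series).rows
    return rows - rows.mean(axis=1, keepdims=True)


def calibrate_re_threshold(model: AEModel, validation: RRISeries) -> float:
    """RE ceiling = maximum RE over held-out normal windows.

    The validation series must contain only normal beats and must not have
    been used for training; by construction the detector then produces zero
    positives on the calibration data itself.
    """
    if len(validation) < WINDOW + 49:
        raise ValueError("need at least 50 validation windows")
    res = reconstruction_error(model, _windows_centered(validation))
    return float(np.max(res))


def calibrate_rri_limits(normal: RRISeries, alpha: float = 99.0) -> tuple[float, float]:
    """Empirical two-sided alpha% confidence limits of normal RRI values."""
    if len(normal) < 500:
        raise ValueError("need at least 500 normal RRIs to set limits")
    if not 0 < alpha <= 100:
        raise ValueError("alpha must be in (0, 100]")
    lo = (100.0 - alpha) / 2.0
    hi = (100.0 + alpha) / 2.0
    r1, r2 = np.percentile(normal.rri, [lo, hi])
    return float(r1), float(r2)


def classify_beat(
    model: AEModel,
    thresholds: DetectionThresholds,
    window: np.ndarray,
    next_rri: float,
    beat_index: int = 0,
) -> BeatLabel:
    """Label beat ``t`` given its window ``[r_{t-3}..r_t]`` and ``r_{t+1}``.

    The RE test runs on the window centered by its own mean (invariant to
    baseline heart-rate shifts); the interval tests use raw ms values.
    """
    w = np.asarray(window, dtype=float)
    if w.shape != (WINDOW,):
        raise ValueError(f"window must hold {WINDOW} values")
    centered, _ = center_window(w)
    re = float(reconstruction_error(model, centered))
    r_t = float(w[-1])
    r_prev = float(w[-2])
    if re <= thresholds.re_max:
        label = "NORMAL"
    elif r_t > thresholds.r2:
        # a detection error doubles ONE interval; a long interval right
        # after a short one is a PVC compensatory pause whose short half
        # slipped under the RE ceiling -- anchor it at the previous beat
        label = "PVC" if r_prev < thresholds.r1 else "RDE"
    elif r_t < thresholds.r1:
        if next_rri > thresholds.r2:
            label = "PVC"
        elif next_rri >= thresholds.r1:
            label = "PAC"
        else:
            label = "OTHER"
    else:
        label = "OTHER"
    return BeatLabel(beat_index=beat_index, label=label, re_value=re)


def detect_stream(
    model: AEModel, thresholds: DetectionThresholds, series: RRISeries
) -> list[BeatLabel]:
    """Label every beat of a series in a single left-to-right pass.

    Beats ``t in [3, len-2]`` are evaluated (one-beat latency); the warm-up
    beats and the final beat are NORMAL by convention.  After an ectopic
    label the next few overlapping windows are suppressed so one
    physiological event yields exactly one label.
    """
    n = len(series)
    if n < WINDOW + 1:
        raise ValueError("series too short to detect on")
    rri = series.rri
    rows = build_hankel(series).rows  # row k = window ending at beat k+3
    centered = rows - rows.mean(axis=1, keepdims=True)
    res = reconstruction_error(model, centered)
    labels: list[BeatLabel] = [
        BeatLabel(i, "NORMAL", 0.0) for i in range(3)
    ]
    suppress_until = -1
    for t in range(3, n - 1):
        re = float(res[t - 3])
        if t <= suppress_until or re <= thresholds.re_max:
            labels.append(BeatLabel(t, "NORMAL", re))
            continue
        lab = classify_beat(model, thresholds, rri[t - 3 : t + 1], rri[t + 1], t)
        anchor = lab
        if lab.label == "PVC" and rri[t] > thresholds.r2:
            # late-anchored PVC: the ectopic (short) interval is at t-1
            anchor = BeatLabel(t - 1, "PVC", lab.re_value)
            labels[t - 1] = anchor
            labels.append(BeatLabel(t, "NORMAL", lab.re_value))
        else:
            labels.append(lab)
        if anchor.label != "NORMAL":
            suppress_until = anchor.beat_index + _COOLDOWN
    labels.append(BeatLabel(n - 1, "NORMAL", 0.0))
    return labels
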