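"""Windowed heart-rate-variability (HRV) features from RRI series.

Standard short-term HRV features are computed over sliding windows on
cumulative beat time (default 3 minutes), the scale at which a single
extrasystole visibly distorts autonomic indices:

time domain
    meanNN, SDNN (population SD), RMSSD, NN50 (successive differences
    exceeding 50 ms).
frequency domain
    the tachogram is resampled at 4 Hz by cubic interpolation over
    cumulative time, mean-detrended, and a Welch periodogram integrated
    over the conventional bands: LF 0.04-0.15 Hz, HF 0.15-0.40 Hz,
    TotalPower 0-0.40 Hz, plus the LF/HF ratio.

Band edges, resampling rate and window length live in :data:`HRV_CONFIG`
so alternative conventions can be swapped in one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, signal

from .rri_data import RRISeries

#: All tunable HRV conventions in one block.
HRV_CONFIG = {
    "lf_band": (0.04, 0.15),  # Hz
    "hf_band": (0.15, 0.40),  # Hz
    "total_band": (0.0, 0.40),  # Hz
    "resample_hz": 4.0,
    "nn50_threshold_ms": 50.0,
    "window_s": 180.0,
    "step_s": 1.0,
}

FEATURE_NAMES = (
    "meanNN",
    "SDNN",
    "RMSSD",
    "NN50",
    "TotalPower",
    "LF",
    "HF",
    "LF_HF",
)

__all__ = [
    "HRV_CONFIG",
    "FEATURE_NAMES",
    "HRVFrame",
    "time_domain_features",
    "frequency_domain_features",
    "sliding_hrv",
    "hrv_table",
]


@dataclass(frozen=True)
class HRVFrame:
    window_end_time: float  # s
    meanNN: float  # ms
    SDNN: float  # ms
    RMSSD: float  # ms
    NN50: int
    TotalPower: float  # ms^2
    LF: float  # ms^2
    HF: float  # ms^2
    LF_HF: float


def time_domain_features(window: RRISeries) -> tuple[float, float, float, int]:
    """(meanNN, SDNN, RMSSD, NN50) of one window."""
    rri = window.rri
    if rri.size < 2:
        raise ValueError("need at least 2 RRIs for time-domain features")
    diffs = np.diff(rri)
    mean_nn = float(rri.mean())
    sdnn = float(rri.std())  # population SD
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    nn50 = int(np.sum(np.abs(diffs) > HRV_CONFIG["nn50_threshold_ms"]))
    return mean_nn, sdnn, rmssd, nn50


def _resample_tachogram(window: RRISeries) -> tuple[np.ndarray, float]:
    fs = HRV_CONFIG["resample_hz"]
    t_s = window.t / 1000.0
    f = interpolate.CubicSpline(t_s, window.rri)
    grid = np.arange(t_s[0], t_s[-1], 1.0 / fs)
    return f(grid), fs


def frequency_domain_features(window: RRISeries) -> tuple[float, float, float, float]:
    """(TotalPower, LF, HF, LF/HF) from a Welch periodogram of the window."""
    span_s = (window.t[-1] - window.t[0]) / 1000.0
    if span_s < 120.0:
        raise ValueError("frequency-domain features need a window of >= 120 s")
    x, fs = _resample_tachogram(window)
    x = x - x.mean()
    nperseg = min(len(x), 256)
    freqs, psd = signal.welch(x, fs=fs, nperseg=nperseg)

    def band(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs <= hi)
        return float(np.trapezoid(psd[mask], freqs[mask]))

    total = band(*HRV_CONFIG["total_band"])
    lf = band(*HRV_CONFIG["lf_band"])
    hf = band(*HRV_CONFIG["hf_band"])
    ratio = lf / hf if hf > 0 else np.inf
    return total, lf, hf, ratio


def sliding_hrv(
    series: RRISeries,
    window_s: float | None = None,
    step_s: float | None = None,
) -> list[HRVFrame]:
    """One :class:`HRVFrame` per step over half-open windows [end-W, end)."""
    window_s = HRV_CONFIG["window_s"] if window_s is None else float(window_s)
    step_s = HRV_CONFIG["step_s"] if step_s is None else float(step_s)
    t_s = series.t / 1000.0
    if t_s[-1] - t_s[0] < window_s:
        raise ValueError("series shorter than one window")
    frames: list[HRVFrame] = []
    end = t_s[0] + window_s
    while end <= t_s[-1] + 1e-9:
        mask = (t_s >= end - window_s) & (t_s < end)
        idx = np.flatnonzero(mask)
        if idx.size >= 2:
            sub = RRISeries(
                rri=series.rri[idx], t=series.t[idx], subject_id=series.subject_id
            )
            mean_nn, sdnn, rmssd, nn50 = time_domain_features(sub)
            total, lf, hf, ratio = frequency_domain_features(sub)
            frames.append(
                HRVFrame(end, mean_nn, sdnn, rmssd, nn50, total, lf, hf, ratio)
            )
        end += step_s
    return frames


def hrv_table(frames: list[HRVFrame]) -> pd.DataFrame:
    """Frames as a DataFrame, one row per window end time."""
    return pd.DataFrame(
        {
            "window_end_s": [f.window_end_time for f in frames],
            **{
                name: [getattr(f, name) for f in frames]
                for name in FEATURE_NAMES
            },
        }
    )
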