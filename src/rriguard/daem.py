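"""Denoising-autoencoder-based extrasystole modification (DAEM).

When the detector flags beat ``t`` as PVC or PAC, the 4-beat window
``x = [r_{t-1}, r_t, r_{t+1}, r_{t+2}]`` (ectopic interval in the second
slot) is repaired:

1. center:      ``x' = x - mean(x)``
2. denoise:     ``xhat' = DAE(x')`` using the model matching the ectopic type
3. restore:     ``xhat = xhat' + mean(x)``
4. compensate:  ``d = sum(xhat) - sum(x)``; ``xtilde = xhat - d/4``

Step 4 spreads any time-length mismatch introduced by the network evenly
over the window, so the sum of the four modified intervals always equals
the sum of the four originals and the stream stays synchronised with real
time.  For a PAC this is also why repair is imperfect in principle: the
beat-time gap left by the uncompensated premature beat cannot be recovered
without changing total elapsed time.

R-wave detection errors and "other arrhythmia" beats are reported but not
modified in the streaming pipeline; an opt-in :func:`repair_rde` splits the
merged interval back into two using the dedicated DAE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aed import BeatLabel, DetectionThresholds, classify_beat, _COOLDOWN
from .neuralnet import AEModel, TrainConfig, forward, train
from .rri_data import RRISeries, WINDOW, center_window

__all__ = [
    "ModificationRecord",
    "modify_event",
    "run_pipeline",
    "build_dae_training_pairs",
    "train_dae_pair",
    "repair_rde",
]


@dataclass(frozen=True)
class ModificationRecord:
    beat_index: int
    type: str
    original: np.ndarray
    modified: np.ndarray
    d: float  # time-gap before compensation (ms)

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.modified) - np.sum(self.original))) > 1e-6:
            raise ValueError("modification must conserve window time")


def _repair_window(model: AEModel, x: np.ndarray) -> tuple[np.ndarray, float]:
    """Steps 1-4 above on one window; returns (xtilde, d)."""
    x_prime, x_bar = center_window(x)
    x_hat = forward(model, x_prime) + x_bar
    d = float(np.sum(x_hat) - np.sum(x))
    x_tilde = x_hat - d / WINDOW
    return x_tilde, d


def modify_event(
    models: dict[str, AEModel], label: BeatLabel, series: RRISeries
) -> ModificationRecord:
    """Repair one detected PVC/PAC in place (beats t-1 .. t+2)."""
    if label.label not in ("PVC", "PAC"):
        raise ValueError(f"modify_event handles PVC/PAC only, got {label.label}")
    t = label.beat_index
    if t - 1 < 0 or t + 2 >= len(series):
        raise ValueError(f"window around beat {t} exceeds series bounds")
    model = models[f"DAE_{label.label}"]
    x = series.rri[t - 1 : t + 3].copy()
    x_tilde, d = _repair_window(model, x)
    series.rri[t - 1 : t + 3] = x_tilde
    return ModificationRecord(
        beat_index=t, type=label.label, original=x, modified=x_tilde, d=d
    )


def run_pipeline(
    ae_model: AEModel,
    thresholds: DetectionThresholds,
    dae_models: dict[str, AEModel],
    series: RRISeries,
) -> tuple[RRISeries, list[BeatLabel], list[ModificationRecord]]:
    """Streaming detect-and-modify pass over a series.

    PVC/PAC events are repaired in place before the detector advances past
    ``t+2``, so one event cannot trigger cascading detections; RDE and OTHER
    events are only reported.  Returns the modified series, the per-beat
    labels, and one record per modification.
    """
    n = len(series)
    if n < WINDOW + 1:
        raise ValueError("series too short")
    out = series.replace(series.rri.copy())
    rri = out.rri
    labels: list[BeatLabel] = [BeatLabel(i, "NORMAL", 0.0) for i in range(3)]
    records: list[ModificationRecord] = []
    suppress_until = -1
    for t in range(3, n - 1):
        if t <= suppress_until:
            labels.append(BeatLabel(t, "NORMAL", 0.0))
            continue
        lab = classify_beat(ae_model, thresholds, rri[t - 3 : t + 1], rri[t + 1], t)
        anchor = lab
        if lab.label == "PVC" and rri[t] > thresholds.r2:
            # late-anchored PVC: the ectopic (short) interval is at t-1
            anchor = BeatLabel(t - 1, "PVC", lab.re_value)
            labels[t - 1] = anchor
            labels.append(BeatLabel(t, "NORMAL", lab.re_value))
        else:
            labels.append(lab)
        if anchor.label in ("PVC", "PAC") and anchor.beat_index + 2 < n:
            records.append(modify_event(dae_models, anchor, out))
            suppress_until = anchor.beat_index + _COOLDOWN
        elif anchor.label != "NORMAL":
            suppress_until = anchor.beat_index + _COOLDOWN
    labels.append(BeatLabel(n - 1, "NORMAL", 0.0))
    # in-place edits bypassed beat-time bookkeeping; rebuild t from the RRIs
    return out.replace(out.rri), labels, records


def build_dae_training_pairs(
    clean: RRISeries,
    ectopic_type: str,
    n_events: int = 500,
    seed: int = 0,
    H_low: float = 100.0,
    H_high: float = 370.0,
) -> tuple[np.ndarray, np.ndarray]:
    """(contaminated, clean) window pairs for denoising training.

    Each pair is a 4-beat window ``[r_{t-1}, r_t, r_{t+1}, r_{t+2}]`` around
    an injected event at ``t`` (the slot the repair step uses), both sides
    centered by the *contaminated* window's mean so that training matches
    inference-time centering.  For RDE the contaminated window holds the
    merged interval in the second slot and the clean target holds the 4
    intervals starting one beat earlier, renormalised to the same span.
    """
    if ectopic_type not in ("PVC", "PAC", "RDE"):
        raise ValueError(f"unsupported ectopic type {ectopic_type}")
    rng = np.random.default_rng(seed)
    n = len(clean)
    if n < 100:
        raise ValueError("clean series too short for pair construction")
    X_in = np.empty((n_events, WINDOW))
    X_target = np.empty((n_events, WINDOW))
    for k in range(n_events):
        t = int(rng.integers(2, n - 3))
        H = float(rng.uniform(H_low, H_high))
        if ectopic_type == "PVC":
            dirty = clean.rri[t - 1 : t + 3].copy()
            target = dirty.copy()
            dirty[1] -= H
            dirty[2] += H
        elif ectopic_type == "PAC":
            dirty = clean.rri[t - 1 : t + 3].copy()
            target = dirty.copy()
            dirty[1] -= H
        else:  # RDE: merged interval in slot 1, window loses one beat at the end
            seg = clean.rri[t - 1 : t + 4]
            dirty = np.array([seg[0], seg[1] + seg[2], seg[3], seg[4]])
            target = seg[:4].copy()
        centered_in, m = center_window(dirty)
        X_in[k] = centered_in
        X_target[k] = target - m
    return X_in, X_target


def train_dae_pair(
    clean: RRISeries,
    ectopic_type: str,
    cfg: TrainConfig = TrainConfig(),
    n_events: int = 500,
) -> AEModel:
    """Train the denoising model for one ectopic type from clean data only."""
    X_in, X_target = build_dae_training_pairs(
        clean, ectopic_type, n_events=n_events, seed=cfg.seed
    )
    return train(X_in, X_target, role=f"DAE_{ectopic_type}", cfg=cfg)


def repair_rde(
    model: AEModel, series: RRISeries, beat_index: int
) -> tuple[RRISeries, ModificationRecord]:
    """Opt-in repair of a merged interval at ``beat_index``.

    The merged interval is replaced by the two intervals the RDE model
    predicts for its window, rescaled so the pair sums exactly to the merged
    interval (total time conserved, beat count restored).
    """
    if model.role != "DAE_RDE":
        raise ValueError("repair_rde requires a DAE_RDE model")
    j = beat_index
    if j - 1 < 0 or j + 2 > len(series):
        raise ValueError("window around merged interval exceeds series bounds")
    x = series.rri[j - 1 : j + 3].copy()  # [prev, merged, next, next2]
    x_tilde, d = _repair_window(model, x)
    # slots 1 and 2 of the prediction estimate the two true intervals hidden
    # in the merged one; their ratio splits it so the pair sums exactly
    p1 = float(np.clip(x_tilde[1], 1.0, None))
    p2 = float(np.clip(x_tilde[2], 1.0, None))
    first = x[1] * p1 / (p1 + p2)
    second = x[1] - first
    rri = np.concatenate(
        [series.rri[:j], [first, second], series.rri[j + 1 :]]
    )
    # record spans the same elapsed time: the final slot aggregates the two
    # intervals following the split
    rec = ModificationRecord(
        beat_index=j,
        type="RDE",
        original=x,
        modified=np.array([x[0], first, second, x[2] + x[3]]),
        d=d,
    )
    return series.replace(rri), rec
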