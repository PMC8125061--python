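"""Surrogate RRI generation and controlled contamination with ground truth.

The generator produces sinus-rhythm-like tachograms for healthy adults: a
baseline around 650-1200 ms with low-frequency (~0.1 Hz, baroreflex) and
high-frequency (~0.25 Hz, respiratory sinus arrhythmia) modulation plus white
noise.  Contamination operators inject the three ectopic mechanisms handled
by the detector --

* **PVC** (premature ventricular contraction): the interval before the
  ectopic beat shortens by ``H`` and the one after lengthens by ``H``
  (compensatory pause), so total elapsed time is conserved.
* **PAC** (premature atrial contraction): a single interval shortens by
  ``H`` with no compensation; total elapsed time shrinks by ``H``.
* **RDE** (R-wave detection error): a missed R peak merges two adjacent
  intervals into one roughly doubled interval.

plus an **AF** surrogate (uniform +/-50 ms jitter around a constant level)
used as a negative control.  Every injection is recorded in an
:class:`EventLog` so detector output can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rri_data import RRISeries, WINDOW

EVENT_TYPES = ("PVC", "PAC", "RDE", "AF", "OTHER")

#: Ectopic pulse height bounds in ms (keeps the simulated QT physiological).
H_LOW, H_HIGH = 100.0, 370.0

__all__ = [
    "EVENT_TYPES",
    "H_LOW",
    "H_HIGH",
    "Event",
    "EventLog",
    "InjectionConfig",
    "simulate_normal_rri",
    "inject_pvc",
    "inject_pac",
    "inject_rde",
    "inject_af_segment",
    "contaminate",
    "clip_training_segments",
]


@dataclass(frozen=True)
class Event:
    beat_index: int
    type: str
    H: float | None = None

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")


@dataclass
class EventLog:
    """Ground-truth (or detected) ectopic events, sorted by beat index."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.beat_index)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def add(self, event: Event) -> None:
        self.events.append(event)
        self.events.sort(key=lambda e: e.beat_index)

    def of_type(self, type_: str) -> "EventLog":
        return EventLog([e for e in self.events if e.type == type_])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beat_index": [e.beat_index for e in self.events],
                "type": [e.type for e in self.events],
                "H_ms": [np.nan if e.H is None else e.H for e in self.events],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventLog":
        df = pd.read_csv(path)
        events = [
            Event(
                int(r.beat_index),
                str(r.type),
                None if pd.isna(r.H_ms) else float(r.H_ms),
            )
            for r in df.itertuples()
        ]
        return cls(events)


@dataclass(frozen=True)
class InjectionConfig:
    """Contamination intensity for :func:`contaminate`.

    ``rate`` is events per beat; one per ~1200 beats corresponds to the
    70-80 extrasystoles per day seen in healthy adults.  Pulse heights are
    drawn uniformly from ``(H_low, H_high)`` ms.
    """

    rate: float = 1.0 / 1200.0
    H_low: float = H_LOW
    H_high: float = H_HIGH
    min_separation: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rate < 0.1:
            raise ValueError("rate must be in (0, 0.1) events/beat")
        if not 0 < self.H_low < self.H_high:
            raise ValueError("need 0 < H_low < H_high")


def simulate_normal_rri(
    n_beats: int,
    mean_rri: float = 800.0,
    lf_amp: float = 30.0,
    hf_amp: float = 20.0,
    noise_sd: float = 20.0,
    seed: int = 0,
    subject_id: str = "synthetic",
) -> RRISeries:
    """Simulate a healthy sinus-rhythm tachogram.

    ``rri[j] = mean + lf_amp*sin(2*pi*0.1*t_j) + hf_amp*sin(2*pi*0.25*t_j)
    + N(0, noise_sd^2)`` with ``t_j`` the cumulative beat time in seconds.
    Values are floored at 300 ms so the series stays physiological.
    """
    if n_beats < WINDOW:
        raise ValueError(f"need at least {WINDOW} beats")
    if not 650.0 <= mean_rri <= 1200.0:
        raise ValueError("mean_rri must lie in the healthy range 650-1200 ms")
    if mean_rri - lf_amp - hf_amp - 5 * noise_sd <= 0:
        raise ValueError("modulation amplitudes imply non-positive RRIs")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=n_beats)
    rri = np.empty(n_beats)
    t = 0.0  # seconds
    for j in range(n_beats):
        value = (
            mean_rri
            + lf_amp * np.sin(2 * np.pi * 0.10 * t)
            + hf_amp * np.sin(2 * np.pi * 0.25 * t)
            + noise[j]
        )
        rri[j] = max(value, 300.0)
        t += rri[j] / 1000.0
    return RRISeries(rri=rri, subject_id=subject_id)


def _check_h(H: float, low: float = H_LOW, high: float = H_HIGH) -> None:
    if not low < H < high:
        raise ValueError(f"pulse height H={H} outside ({low}, {high}) ms")


def inject_pvc(series: RRISeries, beat_index: int, H: float) -> tuple[RRISeries, EventLog]:
    """Shorten rri[t] by H and lengthen rri[t+1] by H (compensatory pause)."""
    t = beat_index
    if not 1 <= t <= len(series) - 2:
        raise ValueError(f"beat_index {t} out of injectable range")
    _check_h(H)
    rri = series.rri.copy()
    if rri[t] - H <= 0:
        raise ValueError("PVC injection would produce a non-positive RRI")
    rri[t] -= H
    rri[t + 1] += H
    return series.replace(rri), EventLog([Event(t, "PVC", H)])


def inject_pac(series: RRISeries, beat_index: int, H: float) -> tuple[RRISeries, EventLog]:
    """Shorten rri[t] by H with no compensation (total time drops by H)."""
    t = beat_index
    if not 1 <= t <= len(series) - 2:
        raise ValueError(f"beat_index {t} out of injectable range")
    _check_h(H)
    rri = series.rri.copy()
    if rri[t] - H <= 0:
        raise ValueError("PAC injection would produce a non-positive RRI")
    rri[t] -= H
    return series.replace(rri), EventLog([Event(t, "PAC", H)])


def inject_rde(series: RRISeries, beat_index: int) -> tuple[RRISeries, EventLog]:
    """Merge rri[j] and rri[j+1] into one interval (missed R peak)."""
    j = beat_index
    if not 1 <= j <= len(series) - 2:
        raise ValueError(f"beat_index {j} out of injectable range")
    rri = series.rri
    merged = np.concatenate([rri[:j], [rri[j] + rri[j + 1]], rri[j + 2 :]])
    return series.replace(merged), EventLog([Event(j, "RDE", None)])


def inject_af_segment(
    series: RRISeries, start: int, duration_beats: int, seed: int = 0
) -> tuple[RRISeries, EventLog]:
    """Replace a segment with an atrial-fibrillation surrogate.

    Within the segment each RRI becomes ``c + U(-50, 50)`` ms where ``c`` is
    the segment's pre-injection mean treated as a constant level.
    """
    if start < 0 or start + duration_beats > len(series):
        raise ValueError("AF segment out of bounds")
    if duration_beats == 0:
        return series.replace(series.rri.copy()), EventLog()
    rng = np.random.default_rng(seed)
    rri = series.rri.copy()
    c = rri[start : start + duration_beats].mean()
    rri[start : start + duration_beats] = c + rng.uniform(-50.0, 50.0, duration_beats)
    events = [Event(j, "AF", None) for j in range(start, start + duration_beats)]
    return series.replace(rri), EventLog(events)


def contaminate(
    series: RRISeries,
    cfg: InjectionConfig = InjectionConfig(),
    types: tuple[str, ...] = ("PVC", "PAC"),
) -> tuple[RRISeries, EventLog]:
    """Inject ectopic events at random positions at the configured rate.

    Event positions are drawn uniformly over the series with a minimum
    separation (no successive extrasystoles, matching the healthy-adult
    assumption); types are drawn uniformly from ``types`` and pulse heights
    from ``U(H_low, H_high)``.  RDE events are applied last, from the right,
    so that earlier beat indices stay valid while beats are being removed.
    """
    if len(series) < 100:
        raise ValueError("series too short to contaminate meaningfully")
    bad = set(types) - set(("PVC", "PAC", "RDE"))
    if bad:
        raise ValueError(f"unsupported contamination types: {sorted(bad)}")
    if not types:
        return series.replace(series.rri.copy()), EventLog()
    rng = np.random.default_rng(cfg.seed)
    n = len(series)
    n_events = rng.binomial(n, cfg.rate)
    positions: list[int] = []
    guard = 0
    while len(positions) < n_events and guard < 100 * n_events + 100:
        guard += 1
        p = int(rng.integers(2, n - 2))
        if all(abs(p - q) >= cfg.min_separation for q in positions):
            positions.append(p)
    positions.sort()
    type_choices = [str(rng.choice(types)) for _ in positions]
    heights = rng.uniform(cfg.H_low, cfg.H_high, size=len(positions))

    out = series.replace(series.rri.copy())
    log = EventLog()
    # non-destructive injections first (indices unaffected)
    for p, ty, h in zip(positions, type_choices, heights):
        if ty == "PVC":
            if out.rri[p] - h <= 0:
                continue
            out, ev = inject_pvc(out, p, h)
        elif ty == "PAC":
            if out.rri[p] - h <= 0:
                continue
            out, ev = inject_pac(out, p, h)
        else:
            continue
        log.add(ev.events[0])
    # RDE removes a beat: apply right-to-left so recorded indices are exact
    rde_positions = [p for p, ty in zip(positions, type_choices) if ty == "RDE"]
    for p in sorted(rde_positions, reverse=True):
        out, ev = inject_rde(out, p)
        log.add(ev.events[0])
    return out, log


def clip_training_segments(
    series: RRISeries,
    n_segments: int = 500,
    segment_beats: int = WINDOW,
    seed: int = 0,
) -> list[RRISeries]:
    """Randomly clip contiguous segments for training-set construction."""
    if n_segments == 0:
        return []
    if len(series) < segment_beats:
        raise ValueError("series shorter than requested segment length")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, len(series) - segment_beats + 1, size=n_segments)
    return [
        RRISeries(series.rri[s : s + segment_beats].copy(), subject_id=series.subject_id)
        for s in starts
    ]
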