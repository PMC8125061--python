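"""Core R-R interval (RRI) containers, CSV I/O and window/Hankel utilities.

An RRI series is the sequence of times between consecutive heart beats, in
milliseconds (the "tachogram").  Every other module in this package consumes
either a full :class:`RRISeries` or 4-beat windows sliced from it; the window
length of 4 is fixed throughout because it is the input dimension of the
autoencoder models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Number of consecutive RRIs per analysis window (autoencoder input size).
WINDOW = 4

__all__ = [
    "WINDOW",
    "RRISeries",
    "HankelMatrix",
    "Window4",
    "read_rri_csv",
    "write_rri_csv",
    "rri_from_beat_times",
    "build_hankel",
    "center_columns",
    "center_window",
]


@dataclass(frozen=True)
class RRISeries:
    """An ordered sequence of R-R intervals with cumulative beat times.

    Parameters
    ----------
    rri:
        Interval lengths in milliseconds; all strictly positive.
    t:
        Cumulative beat times in milliseconds, ``t[j] = t[j-1] + rri[j]``.
        Reconstructed from ``rri`` when not given.
    subject_id:
        Opaque label identifying the recording.
    """

    rri: np.ndarray
    t: np.ndarray = None  # type: ignore[assignment]
    subject_id: str = ""

    def __post_init__(self) -> None:
        rri = np.asarray(self.rri, dtype=float)
        if rri.ndim != 1:
            raise ValueError("rri must be one-dimensional")
        if rri.size and not np.all(rri > 0):
            bad = int(np.flatnonzero(rri <= 0)[0])
            raise ValueError(f"non-positive RRI at beat {bad}: {rri[bad]}")
        if self.t is None:
            t = np.cumsum(rri)
        else:
            t = np.asarray(self.t, dtype=float)
            if t.shape != rri.shape:
                raise ValueError("t and rri must have equal length")
            if rri.size:
                recon = np.concatenate(([t[0]], np.diff(t)))
                # first beat time is free; all later gaps must equal the RRIs
                if not np.allclose(recon[1:], rri[1:], rtol=0, atol=1e-6):
                    raise ValueError("t increments do not match rri values")
        object.__setattr__(self, "rri", rri)
        object.__setattr__(self, "t", t)

    def __len__(self) -> int:
        return int(self.rri.size)

    @property
    def duration_ms(self) -> float:
        """Total elapsed time covered by the intervals."""
        return float(self.rri.sum())

    @property
    def duration_hours(self) -> float:
        return self.duration_ms / 3.6e6

    def replace(self, rri: np.ndarray) -> "RRISeries":
        """New series with the same subject id and rebuilt beat times."""
        return RRISeries(rri=np.asarray(rri, dtype=float), subject_id=self.subject_id)


@dataclass(frozen=True)
class Window4:
    """Exactly four consecutive RRIs starting at beat ``start_index``."""

    values: np.ndarray
    start_index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (WINDOW,):
            raise ValueError(f"window must hold exactly {WINDOW} values")
        if not np.all(v > 0):
            raise ValueError("window values must be positive")
        object.__setattr__(self, "values", v)


@dataclass
class HankelMatrix:
    """Time-delay embedding of an RRI series with window length 4.

    Row ``k`` is ``[rri[k], rri[k+1], rri[k+2], rri[k+3]]``, so a series of
    ``J`` intervals yields ``J - 3`` rows.  ``column_means`` are recorded at
    construction and survive centering, so a centered matrix can always be
    mapped back to milliseconds.
    """

    rows: np.ndarray
    column_means: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float)
        if rows.ndim != 2 or rows.shape[1] != WINDOW:
            raise ValueError(f"Hankel rows must have {WINDOW} columns")
        self.rows = rows
        if self.column_means is None:
            self.column_means = rows.mean(axis=0)
        else:
            self.column_means = np.asarray(self.column_means, dtype=float)

    @property
    def n_windows(self) -> int:
        return int(self.rows.shape[0])


def read_rri_csv(path) -> RRISeries:
    """Read an RRI series from a plain CSV file.

    Accepts two layouts: two columns ``t_ms,rri_ms`` (cumulative beat time,
    interval) or a single column of intervals, with an optional header line.
    """
    try:
        df = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"cannot parse RRI CSV {path}: {exc}") from exc
    # tolerate a header row of column names
    if df.shape[0] and isinstance(df.iloc[0, 0], str):
        first = str(df.iloc[0, 0]).strip()
        try:
            float(first)
        except ValueError:
            df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] not in (1, 2):
        raise ValueError(f"{path}: expected 1 or 2 columns, found {df.shape[1]}")
    try:
        values = df.astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path}: malformed numeric row ({exc})") from exc
    if df.shape[1] == 2 and not np.all(np.diff(values[:, 0]) > 0):
        raise ValueError(f"{path}: cumulative time column must increase")
    # the interval column is authoritative; beat times are rebuilt from it
    return RRISeries(rri=values[:, -1], subject_id=str(path))


def write_rri_csv(series: RRISeries, path) -> None:
    """Write ``t_ms,rri_ms`` rows, round-tripping the intervals exactly.

    The time column holds the cumulative time at which each interval
    starts (first row 0), matching the on-disk layout :func:`read_rri_csv`
    accepts.
    """
    df = pd.DataFrame({"t_ms": series.t - series.rri, "rri_ms": series.rri})
    df.to_csv(path, index=False, header=True)


def rri_from_beat_times(beat_times, fs: float, subject_id: str = "") -> RRISeries:
    """Convert annotated beat sample times to an RRI series.

    Parameters
    ----------
    beat_times:
        Strictly increasing beat occurrence times in samples (e.g. from a
        PhysioNet WFDB annotation file).
    fs:
        Sampling frequency in Hz.
    """
    times = np.asarray(beat_times, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if times.size < 2:
        raise ValueError("need at least two beats to form one interval")
    if not np.all(np.diff(times) > 0):
        raise ValueError("beat times must be strictly increasing")
    rri_ms = np.diff(times) / fs * 1000.0
    return RRISeries(rri=rri_ms, subject_id=subject_id)


def build_hankel(series: RRISeries) -> HankelMatrix:
    """Slide a length-4 window over the series; one row per window."""
    rri = series.rri
    if rri.size < WINDOW:
        raise ValueError(f"need at least {WINDOW} RRIs, got {rri.size}")
    rows = np.lib.stride_tricks.sliding_window_view(rri, WINDOW).copy()
    return HankelMatrix(rows=rows)


def center_columns(h: HankelMatrix) -> HankelMatrix:
    """Remove each column's mean; the original means are kept on the result."""
    if h.n_windows == 0:
        raise ValueError("cannot center an empty Hankel matrix")
    means = h.rows.mean(axis=0)
    return HankelMatrix(rows=h.rows - means, column_means=h.column_means.copy())


def center_window(values) -> tuple[np.ndarray, float]:
    """Subtract the window's own mean; returns (centered values, mean)."""
    v = np.asarray(values, dtype=float)
    m = float(v.mean())
    return v - m, m
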