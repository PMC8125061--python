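"""Comparator methods: SSA anomaly detection, PLS and LWPLS window repair.

Singular spectrum analysis (SSA) scores a 4-beat window by its distance to
the principal subspace of the normal data's Hankel embedding -- a linear
analogue of the autoencoder detector, calibrated with the same protocol
(threshold = max residual on held-out normal windows).

PLS regresses clean windows on contaminated ones globally; locally weighted
PLS (LWPLS) rebuilds a weighted PLS model per query from stored training
pairs, with Gaussian similarity weights, and discards it after use
(just-in-time modelling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .rri_data import RRISeries, WINDOW, build_hankel

__all__ = [
    "SSAModel",
    "ssa_fit",
    "ssa_score",
    "ssa_detect_stream",
    "pls_fit",
    "pls_predict",
    "LWPLSConfig",
    "lwpls_predict",
]


# --------------------------------------------------------------------------
# SSA detection baseline


@dataclass
class SSAModel:
    basis: np.ndarray  # (4, k) orthonormal columns
    k: int
    column_means: np.ndarray = None  # type: ignore[assignment]
    threshold: float | None = None

    def __post_init__(self) -> None:
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(self.k), atol=1e-8):
            raise ValueError("SSA basis must be orthonormal")
        if self.column_means is None:
            self.column_means = np.zeros(self.basis.shape[0])


def ssa_fit(normal: RRISeries, k: int = 3) -> SSAModel:
    """Principal subspace of the column-centered Hankel matrix.

    Unlike the autoencoder detector, centering uses the training column
    means, so the score is sensitive to baseline heart-rate shifts between
    subjects -- an intrinsic property of the linear subspace model.
    """
    if not 1 <= k <= WINDOW:
        raise ValueError(f"k must be in [1, {WINDOW}]")
    rows = build_hankel(normal).rows
    if rows.shape[0] < 100:
        raise ValueError("need at least 100 windows to fit SSA")
    means = rows.mean(axis=0)
    _, _, vt = np.linalg.svd(rows - means, full_matrices=False)
    return SSAModel(basis=vt[:k].T, k=k, column_means=means)


def ssa_score(model: SSAModel, window: np.ndarray) -> float | np.ndarray:
    """Residual distance of the mean-offset window to the subspace."""
    w = np.asarray(window, dtype=float)
    single = w.ndim == 1
    centered = np.atleast_2d(w) - model.column_means
    proj = centered @ model.basis @ model.basis.T
    res = np.linalg.norm(centered - proj, axis=1)
    return float(res[0]) if single else res


def ssa_calibrate(model: SSAModel, validation: RRISeries) -> SSAModel:
    """Threshold = max residual on held-out normal windows (AED protocol)."""
    res = ssa_score(model, build_hankel(validation).rows)
    model.threshold = float(np.max(res))
    return model


def ssa_detect_stream(model: SSAModel, series: RRISeries) -> list[int]:
    """Beat indices flagged anomalous, with the same 4-beat suppression the
    autoencoder detector uses."""
    if model.threshold is None:
        raise ValueError("calibrate the SSA threshold first")
    res = ssa_score(model, build_hankel(series).rows)
    flagged: list[int] = []
    suppress_until = -1
    for t in range(3, len(series) - 1):
        if t <= suppress_until:
            continue
        if res[t - 3] > model.threshold:
            flagged.append(t)
            suppress_until = t + 4
    return flagged


# --------------------------------------------------------------------------
# PLS / LWPLS modification baselines


def pls_fit(X: np.ndarray, Y: np.ndarray, n_components: int = 2) -> PLSRegression:
    """Global PLS regression of clean windows on contaminated ones."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("X and Y must be paired row-for-row")
    if not 1 <= n_components <= WINDOW:
        raise ValueError(f"n_components must be in [1, {WINDOW}]")
    if np.any(X.std(axis=0) < 1e-12):
        raise ValueError("degenerate (constant) predictor column")
    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(X, Y)
    return model


def pls_predict(model: PLSRegression, window: np.ndarray) -> np.ndarray:
    w = np.asarray(window, dtype=float)
    return model.predict(w.reshape(1, -1))[0]


@dataclass
class LWPLSConfig:
    """Stored training pairs plus locality bandwidth for just-in-time PLS.

    ``bandwidth`` defaults to the median pairwise distance of the stored
    inputs (computed lazily on first use).
    """

    X: np.ndarray
    Y: np.ndarray
    n_components: int = 2
    bandwidth: float | None = None
    _global: PLSRegression | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.shape != self.Y.shape or self.X.ndim != 2:
            raise ValueError("stored pairs must be two matching 2-D arrays")
        if not 1 <= self.n_components <= WINDOW:
            raise ValueError(f"n_components must be in [1, {WINDOW}]")
        if self.bandwidth is None:
            rng = np.random.default_rng(0)
            n = self.X.shape[0]
            idx = rng.integers(0, n, size=(min(500, n * (n - 1) // 2), 2))
            idx = idx[idx[:, 0] != idx[:, 1]]
            dists = np.linalg.norm(self.X[idx[:, 0]] - self.X[idx[:, 1]], axis=1)
            self.bandwidth = float(np.median(dists)) if dists.size else 1.0


def lwpls_predict(cfg: LWPLSConfig, query: np.ndarray) -> np.ndarray:
    """Weighted PLS fitted around the query, used once and discarded."""
    q = np.asarray(query, dtype=float)
    d2 = np.sum((cfg.X - q) ** 2, axis=1)
    w = np.exp(-d2 / (2.0 * cfg.bandwidth**2))
    if w.sum() < 1e-12:
        # query far outside the database: fall back to a global model
        if cfg._global is None:
            cfg._global = pls_fit(cfg.X, cfg.Y, cfg.n_components)
        return pls_predict(cfg._global, q)
    sw = np.sqrt(w / w.sum())
    xm = (w / w.sum()) @ cfg.X
    ym = (w / w.sum()) @ cfg.Y
    Xw = sw[:, None] * (cfg.X - xm)
    Yw = sw[:, None] * (cfg.Y - ym)
    if float(np.sum(Xw**2)) < 1e-10:
        # weights collapsed onto (nearly) one stored sample
        return ym
    local = PLSRegression(n_components=cfg.n_components, scale=False)
    local.fit(Xw, Yw)
    return local.predict((q - xm).reshape(1, -1))[0] + ym
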