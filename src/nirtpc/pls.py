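"""NIPALS PLS1 regression with full (leave-one-out) cross-validation.

PLS1 finds, factor by factor, the direction in spectral space with
maximal covariance with the concentration vector. Per factor a:

    w_a = Xᵀy / ‖Xᵀy‖          (weights)
    t_a = X w_a                 (scores)
    p_a = Xᵀt_a / t_aᵀt_a       (X loadings)
    q_a = yᵀt_a / t_aᵀt_a       (y loading)
    X ← X − t_a p_aᵀ,  y ← y − q_a t_a   (deflation)

with X and y mean-centered first (no variance scaling, the usual
convention for spectra). The regression vector on centered data is
b = W (PᵀW)⁻¹ q, so ŷ = ȳ + (x − x̄)·b.

For a single response the inner NIPALS loop converges in one pass; the
iteration guard is kept for a future multi-response extension.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import DegenerateDataError, DesignError, ParameterError

_FORMAT_VERSION = 1


@dataclass
class PLSModel:
    """Fitted PLS1 model (all matrices on centered data)."""

    x_mean: np.ndarray          # (p,)
    y_mean: float
    weights: np.ndarray         # W, (p, A)
    scores: np.ndarray          # T, (n, A)
    x_loadings: np.ndarray      # P, (p, A)
    y_loadings: np.ndarray      # q, (A,)
    coef: np.ndarray            # b, (p,)
    n_factors: int

    @property
    def n_wavenumbers(self) -> int:
        return int(self.x_mean.size)

    def truncated(self, a: int) -> "PLSModel":
        """Sub-model using only the first ``a`` factors."""
        if not 1 <= a <= self.n_factors:
            raise ParameterError(f"factor count {a} outside 1..{self.n_factors}")
        W, P, q = self.weights[:, :a], self.x_loadings[:, :a], self.y_loadings[:a]
        b = W @ np.linalg.solve(P.T @ W, q)
        return PLSModel(
            self.x_mean, self.y_mean, W, self.scores[:, :a], P, q, b, a
        )

    def to_dict(self) -> dict:
        return {
            "format_version": _FORMAT_VERSION,
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "weights": self.weights.tolist(),
            "scores": self.scores.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
            "n_factors": int(self.n_factors),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        if d.get("format_version") != _FORMAT_VERSION:
            raise ParameterError(
                f"unsupported model format version {d.get('format_version')!r}"
            )
        return cls(
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            weights=np.asarray(d["weights"], dtype=float),
            scores=np.asarray(d["scores"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            n_factors=int(d["n_factors"]),
        )

    def save(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "PLSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_nipals(
    X: np.ndarray,
    y: np.ndarray,
    max_factors: int,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PLSModel:
    """Fit a PLS1 model by NIPALS with ``max_factors`` latent variables.

    If deflation exhausts the covariance between X and y before
    ``max_factors`` (noiseless low-rank data), the model is truncated at
    the last well-defined factor.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ParameterError(f"X has {n} rows but y has {y.size} entries")
    if n < 2:
        raise DesignError("need at least two samples")
    if not 1 <= max_factors <= min(n - 1, p):
        raise ParameterError(
            f"max_factors must lie in 1..min(n-1, p) = {min(n - 1, p)}, got {max_factors}"
        )
    if np.ptp(y) == 0:
        raise DegenerateDataError("target has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    scale0 = np.linalg.norm(Xc.T @ yc)

    W = np.empty((p, max_factors))
    T = np.empty((n, max_factors))
    P = np.empty((p, max_factors))
    q = np.empty(max_factors)
    achieved = 0
    for a in range(max_factors):
        cov = Xc.T @ yc
        nrm = np.linalg.norm(cov)
        if nrm <= max(tol, 1e-14 * scale0):
            break  # signal exhausted: truncate
        w = cov / nrm
        for _ in range(max_iter):
            t = Xc @ w
            tt = t @ t
            w_new = Xc.T @ (yc * (yc @ t) / (yc @ yc))  # PLS1: proportional to cov
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        t = Xc @ w
        tt = t @ t
        if tt == 0:
            break
        p_load = Xc.T @ t / tt
        q_a = yc @ t / tt
        W[:, a], T[:, a], P[:, a], q[a] = w, t, p_load, q_a
        Xc = Xc - np.outer(t, p_load)
        yc = yc - q_a * t
        achieved = a + 1

    if achieved == 0:
        raise DegenerateDataError("no covariance between X and y; cannot fit")
    W, T, P, q = W[:, :achieved], T[:, :achieved], P[:, :achieved], q[:achieved]
    b = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(x_mean, y_mean, W, T, P, q, b, achieved)


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """ŷ = ȳ + (X_new − x̄)·b."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_wavenumbers:
        raise ParameterError(
            f"model expects {model.n_wavenumbers} wavenumbers, got {X_new.shape[1]}"
        )
    return model.y_mean + (X_new - model.x_mean) @ model.coef


@dataclass
class CalibrationMetrics:
    """Per-factor calibration and cross-validation error curves.

    ``rmsec[a-1]`` / ``rmsev[a-1]`` are the root-mean-square errors of
    the fitted and the cross-validated predictions with a factors; R²
    values are 1 − SS_res/SS_tot with SS_tot about the overall mean.
    """

    rmsec: np.ndarray
    r2_cal: np.ndarray
    rmsev: np.ndarray
    r2_val: np.ndarray
    chosen_factors: int

    @property
    def max_factors(self) -> int:
        return int(self.rmsec.size)

    def at_chosen(self) -> dict:
        a = self.chosen_factors
        return {
            "n_factors": a,
            "rmsec": float(self.rmsec[a - 1]),
            "r2_cal": float(self.r2_cal[a - 1]),
            "rmsev": float(self.rmsev[a - 1]),
            "r2_val": float(self.r2_val[a - 1]),
        }


def _cv_folds(n: int, cv: int | str) -> list[np.ndarray]:
    if cv == "loo":
        return [np.array([i]) for i in range(n)]
    k = int(cv)
    if not 2 <= k <= n:
        raise ParameterError(f"segment count must lie in 2..n, got {k}")
    return [idx for idx in np.array_split(np.arange(n), k)]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    max_factors: int,
    cv: int | str = "loo",
    selection_factor: float = 1.0,
) -> CalibrationMetrics:
    """Full cross-validation of a PLS1 calibration.

    Default is leave-one-out ("full cross validation"): each sample is
    predicted by a model fitted without it, for every factor count up to
    ``max_factors``. ``chosen_factors`` is the smallest factor count
    whose RMSEV is within ``selection_factor`` (default 1.0: the global
    minimum itself) times the minimal RMSEV.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise DesignError("cross-validation needs at least three samples")
    full = fit_nipals(X, y, max_factors)
    A = full.n_factors

    fitted = np.empty((n, A))
    for a in range(1, A + 1):
        fitted[:, a - 1] = predict(full.truncated(a), X)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    rmsec = np.sqrt(((fitted - y[:, None]) ** 2).mean(axis=0))
    r2_cal = 1.0 - (rmsec**2 * n) / ss_tot

    pred = np.full((n, A), np.nan)
    for idx in _cv_folds(n, cv):
        mask = np.ones(n, dtype=bool)
        mask[idx] = False
        sub = fit_nipals(X[mask], y[mask], min(max_factors, mask.sum() - 1))
        for a in range(1, A + 1):
            m = sub.truncated(min(a, sub.n_factors))
            pred[idx, a - 1] = predict(m, X[idx])
    rmsev = np.sqrt(((pred - y[:, None]) ** 2).mean(axis=0))
    r2_val = 1.0 - (rmsev**2 * n) / ss_tot

    best = float(rmsev.min())
    chosen = int(np.flatnonzero(rmsev <= selection_factor * best)[0]) + 1
    return CalibrationMetrics(rmsec, r2_cal, rmsev, r2_val, chosen)
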