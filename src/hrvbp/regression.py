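"""Robust multi-linear regression of the BP drop on an HRV feature
subset: ΔBP = c0 + c1·f1 + … + cn·fn + ε.

The fit is iteratively-reweighted least squares with the Tukey bisquare
weight function (tuning constant 4.685, giving 95% efficiency under
Gaussian errors).  The residual scale is the median absolute deviation
of the leverage-adjusted residuals divided by 0.6745, re-estimated each
iteration with the smallest p absolute residuals excluded; iterations
start from ordinary least squares and stop when no coefficient moves by
more than ``tol`` or after ``max_iter`` sweeps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_TUNING = 4.685


@dataclass
class RegressionModel:
    """Fitted linear model over a named feature subset."""

    c0: float
    coeffs: np.ndarray
    feature_names: tuple[str, ...]
    tuning: float = DEFAULT_TUNING
    converged: bool = True
    iterations: int = 0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.size != len(self.feature_names):
            raise ValueError("coeffs and feature_names lengths differ")
        if not np.isfinite(self.c0) or not np.all(np.isfinite(self.coeffs)):
            raise ValueError("non-finite model parameters")

    def to_json(self) -> str:
        return json.dumps({
            "c0": self.c0,
            "feature_names": list(self.feature_names),
            "coeffs": self.coeffs.tolist(),
            "tuning": self.tuning,
            "converged": self.converged,
            "iterations": self.iterations,
        }, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RegressionModel":
        d = json.loads(text)
        return cls(c0=d["c0"], coeffs=np.array(d["coeffs"], dtype=float),
                   feature_names=tuple(d["feature_names"]),
                   tuning=d.get("tuning", DEFAULT_TUNING),
                   converged=d.get("converged", True),
                   iterations=d.get("iterations", 0))


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0]), X])


def _as_matrix(features, feature_names: tuple[str, ...] | None
               ) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(features, pd.DataFrame):
        names = tuple(feature_names) if feature_names else tuple(
            features.columns)
        missing = [n for n in names if n not in features.columns]
        if missing:
            raise KeyError(f"feature columns missing: {missing}")
        return features[list(names)].to_numpy(dtype=float), names
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if feature_names is None:
        names = tuple(f"x{i + 1}" for i in range(X.shape[1]))
    else:
        names = tuple(feature_names)
        if len(names) != X.shape[1]:
            raise ValueError("feature_names length != number of columns")
    return X, names


def fit_robust(features, y, feature_names: tuple[str, ...] | None = None,
               tuning: float = DEFAULT_TUNING, tol: float = 1e-8,
               max_iter: int = 50) -> RegressionModel:
    """Fit the bisquare IRLS regression (intercept always included).

    Parameters
    ----------
    features : DataFrame or (n, k) array
        Feature matrix of at most 5 columns in routine use; no missing
        values allowed.
    y : array
        Measured ΔBP per instance (mmHg).

    Raises
    ------
    ValueError
        On a rank-deficient design (the collinear columns are named),
        missing values, or too few instances (need n > k + 1).
    """
    X, names = _as_matrix(features, feature_names)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if y.shape != (n,):
        raise ValueError("y length must match number of instances")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        bad = [names[j] for j in range(k)
               if not np.all(np.isfinite(X[:, j]))]
        raise ValueError(f"missing/non-finite values in features {bad or 'y'}")
    if n <= k + 1:
        raise ValueError(f"need more than {k + 1} instances to fit "
                         f"{k} features, got {n}")
    Xd = _design(X)
    p = k + 1
    rank = np.linalg.matrix_rank(Xd)
    if rank < p:
        # name the columns that do not increase the rank
        culprits = []
        r = np.linalg.matrix_rank(Xd[:, :1])
        for j in range(1, p):
            rj = np.linalg.matrix_rank(Xd[:, : j + 1])
            if rj == r:
                culprits.append(names[j - 1])
            r = rj
        raise ValueError(f"rank-deficient design; collinear features: "
                         f"{culprits}")

    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    # leverage from the thin QR of the (unweighted) design, as in the
    # classical robust fitting routine
    q, _ = np.linalg.qr(Xd)
    h = np.clip(np.sum(q ** 2, axis=1), 0.0, 0.9999)
    adj = 1.0 / np.sqrt(1.0 - h)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = y - Xd @ beta
        radj = resid * adj
        sorted_abs = np.sort(np.abs(radj))
        s = float(np.median(sorted_abs[min(p, n - 1):])) / 0.6745
        if s <= np.finfo(float).eps * max(1.0, float(np.abs(y).max())):
            converged = True  # (near-)exact fit; weights are irrelevant
            break
        u = radj / (tuning * s)
        w = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(Xd * sw[:, None], y * sw, rcond=None)
        delta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if delta < tol:
            converged = True
            break
    if not converged:
        log.warning("robust fit did not converge in %d iterations", max_iter)
    return RegressionModel(c0=float(beta[0]), coeffs=beta[1:],
                           feature_names=names, tuning=tuning,
                           converged=converged, iterations=it)


def predict(model: RegressionModel, features) -> np.ndarray:
    """ŷ = c0 + Σ c_j f_j.  DataFrame columns are matched by name; a
    plain array must have the model's column count."""
    X, names = _as_matrix(features, model.feature_names
                          if isinstance(features, pd.DataFrame) else None)
    if isinstance(features, pd.DataFrame):
        if names != tuple(model.feature_names):
            raise KeyError("feature name mismatch")
    elif X.shape[1] != model.coeffs.size:
        raise ValueError("feature count mismatch")
    return model.c0 + X @ model.coeffs
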