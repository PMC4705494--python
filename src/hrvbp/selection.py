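"""Exhaustive feature-subset selection under leave-one-subject-out
cross-validation, and the evaluation metrics.

Every subset of 1..max_k features is scored by the mean, across
subjects, of the regression standard error
sigma_est = sqrt(sum (Y - Y')^2 / (N - 2)) computed on each held-out
subject's instances; the minimising subset (ties: smaller subset, then
lexicographic feature order) is refitted on the whole dataset.  The
report carries the test/train/full sigma_est, the percentage of
predictions with absolute error strictly below the ΔBP measurement
error, under/over-estimation rates beyond a ±5 mmHg margin, and the
residual histogram.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FEATURE_NAMES
from .regression import RegressionModel, fit_robust, predict

log = logging.getLogger(__name__)

DEFAULT_ERROR_THRESHOLD = 4.5   # mmHg, ΔBP measurement error
DEFAULT_FPFN_MARGIN = 5.0       # mmHg


def sigma_est(measured, predicted) -> float:
    """Regression standard error sqrt(Σ(Y−Y')² / (N−2))."""
    y = np.asarray(measured, dtype=float)
    yp = np.asarray(predicted, dtype=float)
    if y.shape != yp.shape:
        raise ValueError("measured and predicted lengths differ")
    if y.size <= 2:
        raise ValueError("sigma_est needs N >= 3")
    return float(np.sqrt(np.sum((y - yp) ** 2) / (y.size - 2)))


def _sigma_guarded(y: np.ndarray, yp: np.ndarray) -> float:
    """Per-fold sigma_est; folds of N <= 2 use denominator 1."""
    dof = max(1, y.size - 2)
    return float(np.sqrt(np.sum((y - yp) ** 2) / dof))


def percent_correct(measured, predicted,
                    error_threshold: float = DEFAULT_ERROR_THRESHOLD
                    ) -> float:
    """Percentage of predictions with |Y−Y'| strictly below the
    threshold (an error exactly equal to it counts as incorrect)."""
    y = np.asarray(measured, dtype=float)
    yp = np.asarray(predicted, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    return 100.0 * float(np.mean(np.abs(y - yp) < error_threshold))


def fp_fn_rates(measured, predicted, margin: float = DEFAULT_FPFN_MARGIN
                ) -> tuple[float, float]:
    """(fn_rate, fp_rate) in percent.

    False negative: the drop was underestimated, predicted < measured −
    margin.  False positive: overestimated, predicted > measured +
    margin.
    """
    y = np.asarray(measured, dtype=float)
    yp = np.asarray(predicted, dtype=float)
    fn = 100.0 * float(np.mean(yp < y - margin))
    fp = 100.0 * float(np.mean(yp > y + margin))
    return fn, fp


def residual_histogram(residuals, bin_width: float = 2.0) -> pd.DataFrame:
    """Histogram of residuals in symmetric bins centred on 0.

    Returns a DataFrame (bin_center, percent); percentages sum to 100.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("empty residuals")
    kmax = int(np.ceil((np.abs(r).max() - bin_width / 2) / bin_width))
    kmax = max(kmax, 0)
    edges = (np.arange(-kmax - 1, kmax + 1) + 0.5) * bin_width
    counts, _ = np.histogram(r, bins=edges)
    centers = (np.arange(-kmax, kmax + 1)) * bin_width
    return pd.DataFrame({"bin_center": centers,
                         "percent": 100.0 * counts / r.size})


@dataclass
class EvaluationReport:
    """Evaluation of one feature subset."""

    best_subset: tuple[str, ...]
    sigma_est_test: float
    sigma_est_train: float
    sigma_est_full: float
    percent_correct: float
    fn_rate: float
    fp_rate: float
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    measured: np.ndarray = field(default_factory=lambda: np.empty(0))
    predicted: np.ndarray = field(default_factory=lambda: np.empty(0))
    sub_ids: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    test_ids: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def to_dict(self) -> dict:
        return {
            "best_subset": list(self.best_subset),
            "sigma_est_test": self.sigma_est_test,
            "sigma_est_train": self.sigma_est_train,
            "sigma_est_full": self.sigma_est_full,
            "percent_correct": self.percent_correct,
            "fn_rate": self.fn_rate,
            "fp_rate": self.fp_rate,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def predictions_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sub_id": self.sub_ids, "test_id": self.test_ids,
            "measured": self.measured, "predicted": self.predicted,
            "residual": self.residuals})


def _folds(df: pd.DataFrame):
    for sub in sorted(df["sub_id"].unique()):
        yield sub, df["sub_id"] != sub


def loso_cv(df: pd.DataFrame, subset, outcome: str = "delta_sys",
            cv_mode: str = "per_fold", return_details: bool = False):
    """Leave-one-subject-out score of one feature subset.

    ``per_fold`` (default) computes sigma_est on each held-out subject
    with that fold's own N and averages the per-subject values; pooled
    mode computes a single sigma_est over all held-out residuals.

    With ``return_details`` also returns (test predictions aligned to
    ``df`` order, mean train sigma_est).
    """
    subset = list(subset)
    if df["sub_id"].nunique() < 3:
        raise ValueError("LOSO needs at least 3 subjects")
    if cv_mode not in ("per_fold", "pooled"):
        raise ValueError("cv_mode must be 'per_fold' or 'pooled'")
    y = df[outcome].to_numpy(dtype=float)
    X = df[subset].to_numpy(dtype=float)
    preds = np.full(len(df), np.nan)
    fold_sigmas, train_sigmas = [], []
    for _, train_mask in _folds(df):
        tm = train_mask.to_numpy()
        model = fit_robust(X[tm], y[tm], feature_names=tuple(subset))
        yp_test = predict(model, X[~tm])
        preds[~tm] = yp_test
        fold_sigmas.append(_sigma_guarded(y[~tm], yp_test))
        train_sigmas.append(_sigma_guarded(y[tm], predict(model, X[tm])))
    if cv_mode == "per_fold":
        score = float(np.mean(fold_sigmas))
    else:
        score = sigma_est(y, preds)
    if return_details:
        return score, preds, float(np.mean(train_sigmas))
    return score


def n_subsets(n_features: int, max_k: int) -> int:
    """Number of candidate subsets of size 1..max_k."""
    return sum(math.comb(n_features, k) for k in range(1, max_k + 1))


@dataclass
class SelectionResult:
    best_subset: tuple[str, ...]
    best_score: float
    model: RegressionModel
    report: EvaluationReport
    n_subsets_evaluated: int


def exhaustive_search(df: pd.DataFrame, max_k: int = 5,
                      candidate_features: list[str] | None = None,
                      outcome: str = "delta_sys",
                      error_threshold: float = DEFAULT_ERROR_THRESHOLD,
                      margin: float = DEFAULT_FPFN_MARGIN,
                      cv_mode: str = "per_fold") -> SelectionResult:
    """Evaluate every subset of 1..max_k candidate features by LOSO
    cross-validation, select the minimiser of the mean sigma_est and
    refit it on the whole dataset.

    Subsets whose fit fails (collinearity, missing feature values) score
    +inf and are logged.  The result is independent of enumeration
    order: ties are broken toward the smaller subset, then lexicographic
    feature order.
    """
    if candidate_features is None:
        candidate_features = list(FEATURE_NAMES)
    if max_k < 1 or max_k > len(candidate_features):
        raise ValueError("max_k must be in 1..len(candidate_features)")
    # canonical enumeration order for deterministic tie-breaking
    cands = sorted(candidate_features)
    best_key: tuple | None = None
    best_subset: tuple[str, ...] | None = None
    n_eval = 0
    for k in range(1, max_k + 1):
        for comb in itertools.combinations(cands, k):
            n_eval += 1
            try:
                score = loso_cv(df, comb, outcome, cv_mode)
            except (ValueError, KeyError) as exc:
                log.info("subset %s failed (%s); scored +inf", comb, exc)
                score = float("inf")
            key = (score, k, comb)
            if best_key is None or key < best_key:
                best_key, best_subset = key, comb
    assert best_subset is not None and best_key is not None
    if not np.isfinite(best_key[0]):
        raise ValueError("every candidate subset failed to fit")

    score, preds, sigma_train = loso_cv(df, best_subset, outcome, cv_mode,
                                        return_details=True)
    y = df[outcome].to_numpy(dtype=float)
    final = fit_robust(df[list(best_subset)], y,
                       feature_names=tuple(best_subset))
    fn, fp = fp_fn_rates(y, preds, margin)
    report = EvaluationReport(
        best_subset=best_subset,
        sigma_est_test=score,
        sigma_est_train=sigma_train,
        sigma_est_full=sigma_est(y, predict(final, df[list(best_subset)])),
        percent_correct=percent_correct(y, preds, error_threshold),
        fn_rate=fn, fp_rate=fp,
        residuals=y - preds, measured=y, predicted=preds,
        sub_ids=df["sub_id"].to_numpy(int),
        test_ids=df["test_id"].to_numpy(int))
    log.info("best subset %s (mean LOSO sigma_est %.3f mmHg, %d subsets "
             "evaluated)", best_subset, score, n_eval)
    return SelectionResult(best_subset=best_subset, best_score=score,
                           model=final, report=report,
                           n_subsets_evaluated=n_eval)
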