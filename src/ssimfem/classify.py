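"""Fracture-risk classification: logistic regression under balanced k-fold
cross-validation with ROC/AUC and confusion matrices.

The predictors are the first two PLS components of the shape (SSM),
intensity (SIM) or fused shape-and-intensity (SSIM) model — or the areal
bone-mineral-density (aBMD) analog as the clinical baseline.  Within each
cross-validation fold the entire statistical model (PLS mode extraction,
including the two-level SSIM construction) is rebuilt on the training
subjects only; test subjects are projected onto the trained modes and
scored by the fold's logistic model.  Test-fold scores are pooled into one
ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.stats import rankdata

from . import pls as plsmod

__all__ = [
    "LogisticModel",
    "FoldAssignment",
    "CVReport",
    "fit_logistic",
    "predict_proba",
    "stratified_kfold",
    "roc_auc",
    "auc_ci",
    "confusion_at",
    "cross_validate",
    "MODEL_KINDS",
]

MODEL_KINDS = ("SSM", "SIM", "SSIM", "aBMD")


@dataclass
class LogisticModel:
    """Logistic regression fit: ``coefficients[0]`` is the intercept,
    the remainder one slope per predictor."""

    coefficients: np.ndarray
    converged: bool
    n_iter: int
    separation: bool = False
    ridge: float = 0.0

    @property
    def n_predictors(self) -> int:
        return self.coefficients.size - 1


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ex = np.exp(eta[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _irls(A: np.ndarray, y: np.ndarray, ridge: float,
          tol: float = 1e-8, max_iter: int = 100):
    """IRLS for logistic ML; ridge (if any) is not applied to the
    intercept.  Returns (beta, converged, n_iter, diverged)."""
    n, d = A.shape
    beta = np.zeros(d)
    pen = np.full(d, ridge)
    pen[0] = 0.0
    converged = False
    diverged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = A @ beta
        if np.max(np.abs(eta)) > 15.0:
            diverged = True   # fitted probabilities at 0/1: quasi-separation
        mu = _sigmoid(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = A.T @ (A * w[:, None]) + np.diag(pen)
        g = A.T @ (y - mu) - pen * beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(H) @ g
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        if not np.all(np.isfinite(beta)):
            diverged = True
            break
    return beta, converged, it, diverged


def fit_logistic(predictors: np.ndarray, y: np.ndarray,
                 tol: float = 1e-8, max_iter: int = 100) -> LogisticModel:
    """Maximum-likelihood logistic regression by IRLS.

    Convergence when the largest coefficient update drops below ``tol``
    (default 1e-8) or after ``max_iter`` (default 100) iterations.  On
    detected quasi-separation (fitted linear predictors running away, i.e.
    probabilities pinned at 0/1), the model is refitted with a small ridge
    penalty (1e-4) on the slopes and flagged.
    """
    X = np.atleast_2d(np.asarray(predictors, dtype=float))
    if X.shape[0] == 1 and np.asarray(predictors).ndim == 1:
        X = X.T
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("predictor rows must match y length")
    if np.unique(y).size < 2:
        raise ValueError("y contains a single class")
    A = np.column_stack([np.ones(len(y)), X])
    beta, converged, n_iter, diverged = _irls(A, y, ridge=0.0,
                                              tol=tol, max_iter=max_iter)
    if diverged or not np.all(np.isfinite(beta)):
        beta, converged, n_iter, _ = _irls(A, y, ridge=1e-4,
                                           tol=tol, max_iter=max_iter)
        return LogisticModel(beta, converged, n_iter,
                             separation=True, ridge=1e-4)
    return LogisticModel(beta, converged, n_iter)


def predict_proba(model: LogisticModel, predictors: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(predictors, dtype=float))
    if X.shape[1] != model.n_predictors:
        X = X.reshape(-1, model.n_predictors)
    A = np.column_stack([np.ones(len(X)), X])
    return _sigmoid(A @ model.coefficients)


@dataclass
class FoldAssignment:
    fold_of: np.ndarray
    k: int
    seed: int

    def train_test(self, fold: int):
        test = np.nonzero(self.fold_of == fold)[0]
        train = np.nonzero(self.fold_of != fold)[0]
        return train, test


def stratified_kfold(y: np.ndarray, k: int, seed: int) -> FoldAssignment:
    """Class-balanced fold assignment.

    Each class is shuffled (seeded) and dealt round-robin into the k folds;
    the dealing pointer carries over between classes so fold sizes stay
    within one of each other.  Per-fold class counts consequently differ by
    at most one from perfect stratification.
    """
    y = np.asarray(y).ravel()
    classes, counts = np.unique(y, return_counts=True)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smallest class count "
                         f"({counts.min()}); folds would lose a class")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(y.size, dtype=int)
    pointer = 0
    for cls in classes:
        idx = np.nonzero(y == cls)[0]
        idx = idx[rng.permutation(idx.size)]
        for j, i in enumerate(idx):
            fold_of[i] = (pointer + j) % k
        pointer = (pointer + idx.size) % k
    return FoldAssignment(fold_of, k, seed)


def roc_auc(scores: np.ndarray, y: np.ndarray):
    """ROC curve and AUC.

    AUC is the Mann-Whitney pair statistic: the fraction of
    (positive, negative) pairs in which the positive scores higher, ties
    counted 1/2 (computed via midranks, so exact under ties).  ROC points
    come from a descending-score threshold sweep with tied scores grouped;
    the curve runs from (0, 0) to (1, 1), non-decreasing in both axes.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(y).ravel().astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    order = np.argsort(-s, kind="stable")
    ys = y[order]
    ss = s[order]
    tps = np.cumsum(ys == 1)
    fps = np.cumsum(ys == 0)
    last_of_tie = np.r_[ss[1:] != ss[:-1], True]
    tpr = np.r_[0.0, tps[last_of_tie] / n_pos]
    fpr = np.r_[0.0, fps[last_of_tie] / n_neg]
    roc_points = list(zip(fpr.tolist(), tpr.tolist()))
    return roc_points, float(auc)


def auc_ci(scores: np.ndarray, y: np.ndarray, n_boot: int = 2000,
           seed: int = 0, level: float = 0.95) -> Tuple[float, float]:
    """Class-stratified bootstrap percentile interval for the AUC.

    Positives and negatives are resampled within class (so every resample
    retains both classes), the AUC recomputed ``n_boot`` times, and the
    percentile interval returned.  Seeded and deterministic.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(y).ravel().astype(int)
    pos = np.nonzero(y == 1)[0]
    neg = np.nonzero(y == 0)[0]
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos, size=pos.size, replace=True)
        ineg = rng.choice(neg, size=neg.size, replace=True)
        idx = np.r_[ip, ineg]
        _, stats[b] = roc_auc(s[idx], y[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def confusion_at(scores: np.ndarray, y: np.ndarray,
                 threshold: float = 0.5) -> np.ndarray:
    """2x2 confusion counts at a score threshold.

    Layout ``[[TN, FP], [FN, TP]]`` (row = true class, column = predicted
    class); ``score >= threshold`` predicts fracture.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(y).ravel().astype(int)
    pred = (s >= threshold).astype(int)
    out = np.zeros((2, 2), dtype=int)
    for t, p in zip(y, pred):
        out[t, p] += 1
    return out


@dataclass
class CVReport:
    model_kind: str
    fold_assignment: FoldAssignment
    pooled_scores: np.ndarray
    roc_points: List[Tuple[float, float]]
    auc: float
    auc_ci: Optional[Tuple[float, float]]
    confusion: np.ndarray
    per_fold_models: List[LogisticModel]
    n_components: int


def _fold_scores_pls(X, y, train, test, n_components):
    model = plsmod.fit_pls(X[train], y[train], m=n_components)
    logit = fit_logistic(model.components[:, :n_components], y[train])
    t_test = plsmod.project(model, X[test], m=n_components)
    return logit, predict_proba(logit, t_test)


def _fold_scores_ssim(Xs, G, y, train, test, n_components, varexp_cut):
    ssm = plsmod.fit_pls(Xs[train], y[train], varexp_target=varexp_cut)
    sim = plsmod.fit_pls(G[train], y[train], varexp_target=varexp_cut)
    m_s = plsmod.modes_to_explain(ssm, varexp_cut).n_modes
    m_i = plsmod.modes_to_explain(sim, varexp_cut).n_modes
    ssim = plsmod.fit_ssim(ssm, sim, y[train], m_shape=m_s, m_int=m_i,
                           m=min(n_components, m_s + m_i))
    logit = fit_logistic(ssim.components[:, :n_components], y[train])
    z_test = np.hstack([
        np.atleast_2d(plsmod.project(ssm, Xs[test], m=m_s)),
        np.atleast_2d(plsmod.project(sim, G[test], m=m_i)),
    ])
    t_test = plsmod.project(ssim, z_test)[:, :n_components]
    return logit, predict_proba(logit, t_test)


def cross_validate(cohort, model_kind: str, k: int = 10, seed: int = 0,
                   n_components: int = 2, varexp_cut: float = 0.9,
                   n_boot: int = 2000, ci: bool = True,
                   threshold: float = 0.5) -> CVReport:
    """Balanced k-fold cross-validated classification for one model kind.

    ``model_kind`` is one of ``'SSM'`` (shape moments), ``'SIM'`` (element
    densities), ``'SSIM'`` (two-level fusion; per fold the SSM and SIM are
    refitted to the ``varexp_cut`` X-variance cut, their training component
    matrices concatenated and a second-level PLS fitted) or ``'aBMD'``
    (areal-density scalar, no PLS).  All model fitting uses training
    subjects only; test subjects are projected and scored, and scores are
    pooled across folds into one ROC.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    y = np.asarray(cohort.status).ravel().astype(int)
    folds = stratified_kfold(y, k, seed)
    pooled = np.empty(y.size, dtype=float)
    fold_models: List[LogisticModel] = []
    for f in range(k):
        train, test = folds.train_test(f)
        if np.unique(y[train]).size < 2:
            raise ValueError(f"fold {f}: training set lost a class")
        if model_kind == "SSM":
            logit, scores = _fold_scores_pls(cohort.moments, y, train, test,
                                             n_components)
        elif model_kind == "SIM":
            logit, scores = _fold_scores_pls(cohort.element_density, y,
                                             train, test, n_components)
        elif model_kind == "SSIM":
            logit, scores = _fold_scores_ssim(cohort.moments,
                                              cohort.element_density, y,
                                              train, test, n_components,
                                              varexp_cut)
        else:  # aBMD baseline
            abmd = np.asarray(cohort.abmd_analog, dtype=float).reshape(-1, 1)
            logit = fit_logistic(abmd[train], y[train])
            scores = predict_proba(logit, abmd[test])
        pooled[test] = scores
        fold_models.append(logit)
    roc_points, auc = roc_auc(pooled, y)
    interval = auc_ci(pooled, y, n_boot=n_boot, seed=seed) if ci else None
    return CVReport(
        model_kind=model_kind,
        fold_assignment=folds,
        pooled_scores=pooled,
        roc_points=roc_points,
        auc=auc,
        auc_ci=interval,
        confusion=confusion_at(pooled, y, threshold),
        per_fold_models=fold_models,
        n_components=n_components,
    )
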