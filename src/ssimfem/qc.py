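"""Outlier screening by Cook's distance in a leave-one-out loop.

Because the raw shape/intensity matrices have far more variables than
subjects, the classical OLS Cook's distance is not defined on them
directly; the influence measure is therefore computed on the PLS-component
regression of fracture status.  For each subject the full PLS regression is
literally refitted without that subject (no shortcut formulas) and the
shift in predictions over the whole cohort is normalised by the full-model
residual mean square:

    D_i = sum_k (yhat_k - yhat_k^(-i))^2 / (p_eff * s^2),   p_eff = m + 1

with m PLS components plus the implicit intercept.

Because the PLS weights are themselves estimated from y, removing any
subject rotates the fitted directions slightly, so these refit distances
sit well above the classical OLS 1/N scale.  The default flagging
threshold is therefore the scale-free form of the usual convention,
4 * mean(D); an absolute threshold (e.g. the OLS-style 4/N) can be passed
explicitly.  The threshold actually used is logged and reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from . import pls as plsmod
from .cohort import Cohort

__all__ = ["OutlierReport", "cooks_distance_loo", "apply_exclusions"]

log = logging.getLogger(__name__)


@dataclass
class OutlierReport:
    cooks_d: np.ndarray
    threshold: float
    flagged: List[int]


def cooks_distance_loo(X: np.ndarray, y: np.ndarray, m: int = 2,
                       threshold: Optional[float] = None) -> OutlierReport:
    """Leave-one-out Cook's distances on the m-component PLS regression.

    Each of the N refits is a full PLS fit on the remaining subjects; all N
    subjects are then re-predicted through the reduced model.  With a
    perfect full-model fit (s^2 = 0) influence is undefined: all distances
    are reported as 0 with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    N = X.shape[0]
    if N < 3:
        raise ValueError("need at least 3 subjects")
    m = min(m, N - 2, X.shape[1])
    full = plsmod.fit_pls(X, y, m=m)
    yhat = plsmod.predict_y(full, X)
    p_eff = m + 1
    rss = float(np.sum((y - yhat) ** 2))
    dof = max(N - p_eff, 1)
    s2 = rss / dof
    if s2 <= 1e-14:
        warnings.warn("full PLS regression fits the response perfectly; "
                      "Cook's distances are undefined and reported as 0")
        d = np.zeros(N)
        return OutlierReport(d, threshold if threshold is not None else 0.0,
                             [])
    d = np.empty(N)
    mask = np.ones(N, dtype=bool)
    for i in range(N):
        mask[i] = False
        sub = plsmod.fit_pls(X[mask], y[mask], m=min(m, N - 3) or 1)
        yhat_i = plsmod.predict_y(sub, X)
        d[i] = float(np.sum((yhat - yhat_i) ** 2)) / (p_eff * s2)
        mask[i] = True
    if threshold is None:
        threshold = 4.0 * float(d.mean())
    flagged = np.nonzero(d > threshold)[0].tolist()
    log.info("Cook's LOO screen: threshold %.4g, %d/%d flagged",
             threshold, len(flagged), N)
    return OutlierReport(d, float(threshold), flagged)


def apply_exclusions(cohort: Cohort, report: OutlierReport) -> Cohort:
    """Drop flagged subjects from every cohort field, preserving order.

    Removing an entire class is a hard error (the classifier would be
    undefined), as is any out-of-range index.
    """
    N = cohort.n_subjects
    for i in report.flagged:
        if not 0 <= i < N:
            raise IndexError(f"flagged index {i} out of range for cohort "
                             f"of {N}")
    if not report.flagged:
        return cohort
    keep = np.setdiff1d(np.arange(N), np.asarray(report.flagged, dtype=int))
    status_kept = cohort.status[keep]
    if np.unique(status_kept).size < 2:
        raise ValueError("exclusions would remove an entire fracture-status "
                         "class")
    return cohort.subset(keep)
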