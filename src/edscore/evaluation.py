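"""Evaluation surfaces for integer risk scores against a binary outcome.

Three surfaces, computed per imputed set and pooled by plain averaging:

* **Discrimination** — AUC as the Mann-Whitney concordance probability (ties
  count 1/2) with the DeLong structural-components variance for confidence
  intervals and the paired DeLong test for comparing two correlated AUCs.
* **Calibration** — a univariable logistic model mapping the integer score to
  predicted 24-h mortality, with intercept and slope pooled across imputed
  sets; observed event fractions grouped per integer score value.
* **Clinical utility** — decision-curve analysis: at threshold probability
  p_t, net benefit = TP/N - (FP/N) * p_t/(1-p_t), standardized by dividing
  by the outcome prevalence, against treat-all and treat-none references.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .impute import PooledEstimate, pool

__all__ = [
    "RiskModel", "RocResult", "DeLongComparison", "CalibrationCurve",
    "DecisionCurve", "fit_risk_model", "compute_auc", "delong_compare",
    "calibration_curve", "decision_curve", "exchange_rate",
    "default_threshold_grid",
]

_DIRECTIONS = ("increasing", "decreasing")


def _oriented(scores: np.ndarray, direction: str) -> np.ndarray:
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")
    return scores if direction == "increasing" else -scores


# ---------------------------------------------------------------------------
# DeLong structural components


def _delong_aucs_cov(scores: np.ndarray, outcomes: np.ndarray):
    """AUCs and their DeLong covariance for k score vectors on one cohort.

    ``scores`` has shape (k, n); orientation must already be applied (higher
    value = higher risk). Ties count 1/2 via midranks.
    """
    y = np.asarray(outcomes).astype(bool)
    pos = scores[:, y]
    neg = scores[:, ~y]
    m, n_neg = pos.shape[1], neg.shape[1]
    if m == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    k = scores.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n_neg))
    aucs = np.empty(k)
    for r in range(k):
        tx = rankdata(pos[r])
        ty = rankdata(neg[r])
        tz = rankdata(np.concatenate([pos[r], neg[r]]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n_neg)
        v01[r] = (tz[:m] - tx) / n_neg
        v10[r] = 1.0 - (tz[m:] - ty) / m
    s01 = np.atleast_2d(np.cov(v01, ddof=1)) if m > 1 else np.zeros((k, k))
    s10 = np.atleast_2d(np.cov(v10, ddof=1)) if n_neg > 1 else np.zeros((k, k))
    cov = s01 / m + s10 / n_neg
    return aucs, cov


@dataclass
class RocResult:
    """AUC with DeLong variance, normal-approximation CI and the ROC curve."""

    auc: float
    se: float
    ci95: tuple
    curve: pd.DataFrame    # columns fpr, tpr, ordered from (0,0) to (1,1)
    direction: str = "increasing"
    n_cases: int = 0
    n_controls: int = 0


@dataclass
class DeLongComparison:
    """Paired comparison of two correlated AUCs on the same patients."""

    auc_a: float
    auc_b: float
    difference: float
    variance: float
    z: float
    p: float


def compute_auc(scores, outcomes, direction: str = "increasing") -> RocResult:
    """AUC (Mann-Whitney concordance, ties = 1/2) with DeLong SE and 95% CI.

    ``direction`` states whether a higher score means higher risk
    ("increasing", NEWS) or lower score means higher risk ("decreasing",
    ROX); the score is oriented before any computation.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes).astype(bool)
    oriented = _oriented(scores, direction)
    aucs, cov = _delong_aucs_cov(oriented[None, :], y)
    auc, var = float(aucs[0]), float(cov[0, 0])
    se = float(np.sqrt(max(var, 0.0)))
    ci = (max(auc - 1.959963984540054 * se, 0.0),
          min(auc + 1.959963984540054 * se, 1.0))
    fpr, tpr, _ = _sk_roc_curve(y.astype(int), oriented)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return RocResult(auc=auc, se=se, ci95=ci, curve=curve, direction=direction,
                     n_cases=int(y.sum()), n_controls=int((~y).sum()))


def delong_compare(scores_a, scores_b, outcomes,
                   direction_a: str = "increasing",
                   direction_b: str = "increasing") -> DeLongComparison:
    """Paired DeLong test for the difference of two correlated AUCs."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    y = np.asarray(outcomes).astype(bool)
    stacked = np.vstack([_oriented(a, direction_a), _oriented(b, direction_b)])
    aucs, cov = _delong_aucs_cov(stacked, y)
    diff = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    if var <= 0.0:
        z = 0.0 if diff == 0.0 else np.sign(diff) * np.inf
    else:
        z = diff / np.sqrt(var)
    p = float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if var <= 0.0 and diff == 0.0:
        p = 1.0
    return DeLongComparison(auc_a=float(aucs[0]), auc_b=float(aucs[1]),
                            difference=diff, variance=var, z=float(z), p=p)


# ---------------------------------------------------------------------------
# Risk model


@dataclass
class RiskModel:
    """Pooled univariable logistic mapping from integer score to 24-h risk.

    Per-set logistic fits (score entered sign-free as a single linear term)
    are pooled by averaging intercepts and slopes; per-set coefficients are
    retained for auditing.
    """

    name: str
    intercept: float
    slope: float
    per_set_coefs: np.ndarray       # shape (m, 2): intercept, slope per set
    intercept_pool: PooledEstimate
    slope_pool: PooledEstimate
    link: str = "logit"

    def predict(self, scores) -> np.ndarray:
        """Pooled-coefficient predicted risk for integer score values."""
        return expit(self.intercept + self.slope * np.asarray(scores, dtype=float))

    def predict_set(self, scores, set_index: int) -> np.ndarray:
        c0, c1 = self.per_set_coefs[set_index]
        return expit(c0 + c1 * np.asarray(scores, dtype=float))


def fit_risk_model(per_set_scores: Sequence[np.ndarray], outcomes,
                   name: str = "score") -> RiskModel:
    """Fit the per-set univariable logistic risk models and pool them.

    ``per_set_scores`` holds one score vector per imputed set over the same
    patients; ``outcomes`` is the shared 0/1 death flag. Raises on
    single-class outcomes or complete separation.
    """
    y = np.asarray(outcomes, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; cannot fit risk model")
    coefs = []
    for k, s in enumerate(per_set_scores):
        s = np.asarray(s, dtype=float)
        X = sm.add_constant(s)
        try:
            res = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-10, maxiter=100)
        except Exception as exc:
            raise ValueError(f"logistic fit failed for set {k} ({name}): {exc}") from exc
        if not res.mle_retvals.get("converged", True):
            raise ValueError(
                f"logistic fit did not converge for set {k} ({name}); "
                "possible complete separation")
        coefs.append(res.params)
    coefs = np.asarray(coefs)
    ipool = pool(coefs[:, 0])
    spool = pool(coefs[:, 1])
    return RiskModel(name=name, intercept=ipool.pooled, slope=spool.pooled,
                     per_set_coefs=coefs, intercept_pool=ipool, slope_pool=spool)


# ---------------------------------------------------------------------------
# Calibration


@dataclass
class CalibrationCurve:
    """Per-integer-score-value predicted vs observed 24-h mortality."""

    table: pd.DataFrame          # score, n, predicted, observed
    skipped: list = field(default_factory=list)
    min_group_size: int = 1

    @property
    def groups(self) -> pd.DataFrame:
        return self.table


def calibration_curve(model: RiskModel, scores, outcomes,
                      min_group_size: int = 1,
                      set_index: Optional[int] = None) -> CalibrationCurve:
    """Group patients by integer score value; emit predicted vs observed risk.

    Also serves as the raw observed-mortality-by-score table (the ``observed``
    and ``n`` columns). Groups smaller than ``min_group_size`` are dropped
    from the table and reported in ``skipped``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    vals = np.unique(s)
    rows, skipped = [], []
    for v in vals:
        sel = s == v
        cnt = int(sel.sum())
        pred = (model.predict([v])[0] if set_index is None
                else model.predict_set([v], set_index)[0])
        if cnt < min_group_size:
            skipped.append({"score": float(v), "n": cnt})
            continue
        rows.append({"score": float(v), "n": cnt,
                     "predicted": float(pred),
                     "observed": float(y[sel].mean())})
    table = pd.DataFrame(rows, columns=["score", "n", "predicted", "observed"])
    return CalibrationCurve(table=table, skipped=skipped,
                            min_group_size=min_group_size)


# ---------------------------------------------------------------------------
# Decision-curve analysis


def exchange_rate(p_t: float) -> float:
    """Odds weight p_t/(1-p_t) trading false positives against true positives."""
    if not 0.0 <= p_t < 1.0:
        raise ValueError(f"threshold {p_t} outside [0, 1)")
    return p_t / (1.0 - p_t)


def default_threshold_grid() -> np.ndarray:
    """0.001 to 0.100 in steps of 0.001 (covers the 3% and 5% landmarks)."""
    return np.round(np.arange(1, 101) * 0.001, 3)


@dataclass
class DecisionCurve:
    """Net benefit of 'flag if predicted risk >= p_t' across thresholds."""

    thresholds: np.ndarray
    net_benefit: np.ndarray
    standardized_net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray
    prevalence: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "net_benefit": self.net_benefit,
            "standardized_net_benefit": self.standardized_net_benefit,
            "treat_all": self.treat_all,
            "treat_none": self.treat_none,
        })


def decision_curve(predicted_risks, outcomes, thresholds=None) -> DecisionCurve:
    """Decision-curve analysis over a grid of threshold probabilities.

    At each p_t, patients with predicted risk >= p_t are flagged;
    net benefit = TP/N - (FP/N) * p_t/(1-p_t); the standardized net benefit
    divides by prevalence so 1 is the maximum attainable; treat-all equals
    prevalence - (1-prevalence) * p_t/(1-p_t) and treat-none is 0.
    """
    p = np.asarray(predicted_risks, dtype=float)
    y = np.asarray(outcomes).astype(bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted risks must lie in [0, 1]")
    thr = default_threshold_grid() if thresholds is None else np.asarray(thresholds, dtype=float)
    if np.any((thr <= 0) | (thr >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(p)
    prev = float(y.mean()) if n else 0.0
    nb = np.empty(len(thr))
    ta = np.empty(len(thr))
    for i, t in enumerate(thr):
        w = exchange_rate(float(t))
        flagged = p >= t
        tp = float(np.sum(flagged & y))
        fp = float(np.sum(flagged & ~y))
        nb[i] = tp / n - (fp / n) * w if n else 0.0
        ta[i] = prev - (1.0 - prev) * w
    snb = nb / prev if prev > 0 else np.zeros_like(nb)
    return DecisionCurve(thresholds=thr, net_benefit=nb,
                         standardized_net_benefit=snb,
                         treat_all=ta, treat_none=np.zeros_like(nb),
                         prevalence=prev)
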