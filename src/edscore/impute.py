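"""Exclusion rule, multiple imputation by chained equations, and pooling.

Records missing four or more of the five classic vitals (SBP, heart rate,
SpO2, respiratory rate, temperature) are excluded before imputation: their
missingness is treated as non-random and imputation as infeasible. The
remaining missing cells are completed m times (default 20) by chained
equations with a fixed number of sweeps per chain (default 5). Continuous
variables use Bayesian linear regression with predictive mean matching
(k = 5 donors), which keeps imputed values inside the observed physiological
range; booleans use logistic-model draws. All other vitals, age, sex, the
auxiliary labs (urea, leukocytes), ICU admission and the 24-h death outcome
serve as predictors. Downstream per-set estimates are pooled by plain
averaging, with Rubin's between/within variance components available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .cohort import AUXILIARIES, MASKABLE, VITALS, Cohort

__all__ = [
    "ImputedCohorts", "PooledEstimate", "exclude_by_missingness",
    "mice_impute", "pool",
]

#: Predictors used by every conditional model (besides the other targets).
_ALWAYS_PREDICTORS = ["age", "sex_male", "icu_admission", "died_24h"]

#: Imputation targets that are 0/1 (logistic draws rather than PMM).
_BINARY_TARGETS = {"alert"}

_PMM_K = 5


@dataclass
class ImputedCohorts:
    """m completed copies of a cohort sharing all observed values.

    ``sets`` holds complete DataFrames (same schema as ``Cohort.data``);
    cells that were observed are bit-identical across sets, cells that were
    missing differ set-to-set. ``sweeps_done`` exposes the chained-equation
    sweep count actually performed per set.
    """

    sets: list
    m: int
    iterations: int
    seed: int
    excluded: dict = field(default_factory=dict)
    sweeps_done: list = field(default_factory=list)
    source_mask: Optional[pd.DataFrame] = None


@dataclass
class PooledEstimate:
    """Per-set values with their plain-average pool and variance components."""

    per_set: np.ndarray
    pooled: float
    between_variance: float
    within_variance: Optional[float] = None

    @property
    def rubin_total_variance(self) -> Optional[float]:
        """Rubin's rules total variance W + (1 + 1/m) B, when within is known."""
        if self.within_variance is None:
            return None
        m = len(self.per_set)
        return self.within_variance + (1.0 + 1.0 / m) * self.between_variance


def exclude_by_missingness(cohort: Cohort, threshold: int = 4):
    """Drop records with >= ``threshold`` of the five classic vitals missing.

    Returns ``(retained_cohort, log)`` where the log counts inputs,
    exclusions and retained records and lists excluded patient ids. The
    operation is idempotent: retained records have <= 3 missing vitals, so a
    second application excludes nothing.
    """
    n_missing = cohort.mask[VITALS].sum(axis=1).to_numpy()
    drop = n_missing >= threshold
    retained = cohort.subset(~drop)
    retained.meta["stage"] = "post-exclusion"
    log = {
        "n_input": int(cohort.n),
        "n_excluded": int(drop.sum()),
        "n_retained": int((~drop).sum()),
        "threshold": int(threshold),
        "excluded_ids": cohort.data.loc[drop, "patient_id"].tolist(),
        "missing_vital_counts": {
            int(k): int(v)
            for k, v in zip(*np.unique(n_missing[drop], return_counts=True))
        },
    }
    return retained, log


def _design_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric working frame for the conditional models."""
    X = df[MASKABLE].astype(float).copy()
    X["age"] = df["age"].astype(float)
    X["sex_male"] = (df["sex"] == "M").astype(float)
    X["icu_admission"] = df["icu_admission"].astype(float)
    X["died_24h"] = df["died_24h"].astype(float)
    return X


def _draw_posterior_beta(X: np.ndarray, y: np.ndarray, rng) -> tuple:
    """OLS fit plus an approximate posterior draw of the coefficients."""
    n, p = X.shape
    XtX = X.T @ X + 1e-8 * np.eye(p)
    beta_hat = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    # Scale-perturbed sigma^2 draw, then Gaussian coefficient draw.
    sigma2_star = sigma2 * dof / max(rng.chisquare(dof), 1e-12)
    cov = sigma2_star * np.linalg.inv(XtX)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        L = np.sqrt(np.maximum(np.diag(cov), 0))[:, None] * np.eye(len(beta_hat))
    beta_star = beta_hat + L @ rng.standard_normal(p)
    return beta_hat, beta_star


def _pmm_draw(pred_obs: np.ndarray, y_obs: np.ndarray, pred_mis: np.ndarray,
              rng, k: int = _PMM_K) -> np.ndarray:
    """Predictive mean matching: draw each missing value from the observed
    values of the k donors whose predictions are nearest."""
    order = np.argsort(pred_obs, kind="mergesort")
    sorted_pred = pred_obs[order]
    sorted_y = y_obs[order]
    n_obs = len(sorted_pred)
    k = min(k, n_obs)
    pos = np.searchsorted(sorted_pred, pred_mis)
    out = np.empty(len(pred_mis))
    for j, (p_val, ip) in enumerate(zip(pred_mis, pos)):
        lo = max(ip - k, 0)
        hi = min(ip + k, n_obs)
        window = np.arange(lo, hi)
        dist = np.abs(sorted_pred[window] - p_val)
        donors = window[np.argsort(dist, kind="mergesort")[:k]]
        out[j] = sorted_y[donors[rng.integers(len(donors))]]
    return out


def _fit_logistic_draw(X_obs, y_obs, X_mis, rng) -> np.ndarray:
    clf = LogisticRegression(C=1e4, solver="newton-cholesky", max_iter=100,
                             tol=1e-8)
    clf.fit(X_obs, y_obs.astype(int))
    p = clf.predict_proba(X_mis)[:, 1]
    return (rng.random(len(X_mis)) < p).astype(float)


def _impute_one_chain(data: pd.DataFrame, mask: pd.DataFrame, targets: list,
                      iterations: int, rng,
                      fio2_room_air_default: bool) -> tuple:
    work = _design_frame(data)
    miss = {v: mask[v].to_numpy() for v in targets}

    # Room-air pre-fill: patients without the oxygen-therapy indicator (ICU
    # admission) default to FiO2 0.21; remaining missing FiO2 is model-imputed.
    if fio2_room_air_default and "fio2" in miss:
        room_air = miss["fio2"] & (work["icu_admission"].to_numpy() < 0.5)
        work.loc[room_air, "fio2"] = 0.21
        miss["fio2"] = miss["fio2"] & ~room_air
        if not miss["fio2"].any():
            targets = [t for t in targets if t != "fio2"]
            del miss["fio2"]

    # Initialise missing cells from the observed marginals.
    for v in targets:
        obs_vals = work.loc[~miss[v], v].to_numpy()
        if len(obs_vals) == 0:
            raise ValueError(f"variable {v!r} is 100% missing; cannot impute")
        work.loc[miss[v], v] = rng.choice(obs_vals, size=int(miss[v].sum()))

    # Visit variables in order of increasing missingness.
    order = sorted(targets, key=lambda v: miss[v].sum())
    sweeps = 0
    for _ in range(iterations):
        for v in order:
            mis_rows = miss[v]
            if not mis_rows.any():
                continue
            predictors = [c for c in work.columns if c != v]
            Xall = work[predictors].to_numpy(dtype=float)
            Xall = np.column_stack([np.ones(len(Xall)), Xall])
            y = work[v].to_numpy(dtype=float)
            X_obs, y_obs = Xall[~mis_rows], y[~mis_rows]
            X_mis = Xall[mis_rows]
            if v in _BINARY_TARGETS:
                if len(np.unique(y_obs)) < 2:
                    # Degenerate observed margin: draw the constant.
                    drawn = np.full(len(X_mis), y_obs[0])
                else:
                    drawn = _fit_logistic_draw(X_obs[:, 1:], y_obs, X_mis[:, 1:], rng)
            else:
                beta_hat, beta_star = _draw_posterior_beta(X_obs, y_obs, rng)
                drawn = _pmm_draw(X_obs @ beta_hat, y_obs, X_mis @ beta_star, rng)
            work.loc[mis_rows, v] = drawn
        sweeps += 1

    completed = data.copy()
    for v in set(targets) | ({"fio2"} if fio2_room_air_default else set()):
        if v in work.columns and v in mask.columns:
            fill = mask[v].to_numpy()
            completed.loc[fill, v] = work.loc[fill, v].to_numpy()
    return completed, sweeps


def mice_impute(cohort: Cohort, m: int = 20, iterations: int = 5,
                seed: int = 0, fio2_room_air_default: bool = True) -> ImputedCohorts:
    """Complete a cohort's missing cells m times by chained equations.

    Each of the m chains is seeded from an independent substream of ``seed``,
    initialised by random draws from the observed marginals, and swept
    ``iterations`` times; within a sweep each incomplete variable is
    regressed on all other predictors and its missing cells redrawn
    (PMM k=5 for continuous targets, logistic draws for booleans). Observed
    cells are never altered. Deterministic given ``seed``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if m < 2:
        warnings.warn("m < 2: pooling across imputations is degenerate",
                      UserWarning, stacklevel=2)
    targets = [v for v in MASKABLE if cohort.mask[v].any()]
    for v in targets:
        if cohort.mask[v].all():
            raise ValueError(f"variable {v!r} is 100% missing; cannot impute")

    streams = np.random.SeedSequence([int(seed), 2]).spawn(m)
    sets, sweeps_done = [], []
    for chain in range(m):
        rng = np.random.default_rng(streams[chain])
        if not targets:
            sets.append(cohort.data.copy())
            sweeps_done.append(0)
            continue
        completed, sweeps = _impute_one_chain(
            cohort.data, cohort.mask, list(targets), iterations, rng,
            fio2_room_air_default)
        sets.append(completed)
        sweeps_done.append(sweeps)
    return ImputedCohorts(
        sets=sets, m=m, iterations=iterations, seed=int(seed),
        excluded=dict(cohort.meta.get("exclusion_log", {})),
        sweeps_done=sweeps_done, source_mask=cohort.mask.copy(),
    )


def pool(per_set_values: Sequence[float],
         within_variances: Optional[Sequence[float]] = None) -> PooledEstimate:
    """Average an estimate across imputed sets.

    The pooled value is the arithmetic mean (the primary pipeline's pooling
    rule); the between-imputation variance, and Rubin's total variance when
    per-set within variances are supplied, are stored for auditing.
    """
    vals = np.asarray(list(per_set_values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot pool an empty list")
    between = float(np.var(vals, ddof=1)) if vals.size > 1 else 0.0
    within = None
    if within_variances is not None:
        within = float(np.mean(np.asarray(list(within_variances), dtype=float)))
    return PooledEstimate(
        per_set=vals, pooled=float(vals.mean()),
        between_variance=between, within_variance=within,
    )
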