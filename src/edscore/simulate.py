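"""Synthetic ED cohort generator.

The real registry behind this analysis is access-restricted, so every
downstream stage is exercised on synthetic cohorts that reproduce the
statistical structure the analysis assumes: a latent severity score drives a
rare 24-h death outcome, vital signs whose stratum means match the published
alive/dead marginals, supplemental oxygen and impaired consciousness
concentrated at high severity, auxiliary labs and ICU admission correlated
with severity (so imputation models have something to work with), and
per-variable missingness under MCAR, MAR or MNAR mechanisms.

Mechanism
---------
Each patient draws a latent severity ``z ~ N(0, 1)``. Death within 24 h
occurs with probability ``expit(alpha + beta * z)`` where ``beta`` is the
configured severity effect (log-odds per SD of severity) and ``alpha`` is
solved numerically so the marginal death rate equals the target prevalence.
Each vital's conditional mean is linear in ``z``, with the line chosen so
that the expectations within the alive and dead strata land exactly on the
configured stratum targets (before physiological truncation and
recording-precision rounding). Residual SDs are set so the marginal SD
matches the configured total-column SD.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq, fsolve
from scipy.special import expit, logit
from scipy.stats import gamma as gamma_dist

from .cohort import AUXILIARIES, COLUMNS, MASKABLE, VITALS, Cohort

__all__ = ["GeneratorConfig", "generate_cohort", "apply_missingness"]

# Table-derived default stratum targets (alive / dead) and total-column SDs.
DEFAULT_MEANS_ALIVE = {
    "sbp": 143.0, "heart_rate": 85.9, "respiratory_rate": 17.8,
    "spo2": 96.7, "temperature": 36.9, "fio2": 0.24,
}
DEFAULT_MEANS_DEAD = {
    "sbp": 133.0, "heart_rate": 95.5, "respiratory_rate": 23.3,
    "spo2": 93.1, "temperature": 36.4, "fio2": 0.38,
}
DEFAULT_SDS = {
    "sbp": 21.7, "heart_rate": 21.2, "respiratory_rate": 5.1,
    "spo2": 3.3, "temperature": 0.9,
}
DEFAULT_MISSINGNESS = {
    "sbp": 0.015, "heart_rate": 0.033, "respiratory_rate": 0.197,
    "spo2": 0.025, "temperature": 0.124, "fio2": 0.496, "alert": 0.681,
    "urea": 0.30, "leukocytes": 0.30,
}

# Truncation bounds applied to generated values (physiological plausibility).
TRUNCATION = {
    "sbp": (40.0, 280.0), "heart_rate": (20.0, 250.0),
    "respiratory_rate": (4.0, 60.0), "spo2": (40.0, 100.0),
    "temperature": (30.0, 43.0), "age": (18.0, 105.0),
    "urea": (0.5, 80.0), "leukocytes": (0.5, 100.0),
}

# Recording precision (decimal places) per variable, emulating chart entry.
PRECISION = {
    "sbp": 0, "heart_rate": 0, "respiratory_rate": 0, "spo2": 0,
    "temperature": 1, "fio2": 2, "age": 0, "urea": 1, "leukocytes": 1,
}

# Age and auxiliary-lab stratum targets (age from the published marginals;
# labs chosen as realistic for a mixed ED population).
AGE_ALIVE, AGE_DEAD, AGE_SD = 61.2, 74.1, 19.4
AUX_TARGETS = {
    "urea": (6.2, 12.0, 4.0),        # mmol/L: alive mean, dead mean, SD
    "leukocytes": (9.0, 13.0, 3.8),  # 10^9/L
}

# Alertness probabilities by stratum (observed-data scale).
ALERT_ALIVE, ALERT_DEAD = 0.957, 0.50

# Supplemental-oxygen amount above room air: clipped Gamma tail.
_SUPP_SHAPE, _SUPP_SCALE, _SUPP_LO, _SUPP_HI = 2.0, 0.12, 0.03, 0.79

_MECHANISMS = ("MCAR", "MAR", "MNAR")


@dataclass
class GeneratorConfig:
    """Study-condition parameters for the synthetic cohort generator.

    Defaults encode the published population marginals: 0.7% 24-h mortality,
    Table-style alive/dead stratum vital means with total-column SDs, and the
    published per-variable missingness fractions.
    """

    n_patients: int = 10_000
    target_prevalence: float = 0.007
    severity_effect: float = 2.0     # log-odds of death per SD of severity
    vital_means_alive: dict = field(default_factory=lambda: dict(DEFAULT_MEANS_ALIVE))
    vital_means_dead: dict = field(default_factory=lambda: dict(DEFAULT_MEANS_DEAD))
    vital_sds: dict = field(default_factory=lambda: dict(DEFAULT_SDS))
    missingness_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    missingness_mechanism: str = "MAR"
    discharge_fraction: float = 0.70     # among 24-h survivors
    covid_split_date: dt.date = dt.date(2020, 2, 1)
    date_window: tuple = (dt.date(2019, 1, 1), dt.date(2021, 3, 1))
    male_fraction: float = 0.506
    icu_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        for name, p in [
            ("target_prevalence", self.target_prevalence),
            ("discharge_fraction", self.discharge_fraction),
            ("male_fraction", self.male_fraction),
            ("icu_fraction", self.icu_fraction),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not np.isfinite(self.severity_effect) or abs(self.severity_effect) > 50:
            raise ValueError(
                f"severity_effect {self.severity_effect} is pathological: "
                "the prevalence equation cannot be solved reliably"
            )
        for v, sd in self.vital_sds.items():
            if sd <= 0:
                raise ValueError(f"vital_sds[{v}] must be positive")
        for v, r in self.missingness_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missingness_rates[{v}] must be in [0, 1]")
        if self.missingness_mechanism not in _MECHANISMS:
            raise ValueError(f"missingness_mechanism must be one of {_MECHANISMS}")
        if self.date_window[0] >= self.date_window[1]:
            raise ValueError("date_window start must precede end")

    def replace(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Gauss-Hermite machinery on the latent severity scale

_GH_NODES, _GH_W = np.polynomial.hermite_e.hermegauss(101)
_GH_W = _GH_W / _GH_W.sum()   # weights for E_z[f(z)], z ~ N(0, 1)


def _solve_alpha(beta: float, prevalence: float) -> float:
    """Intercept of the death model so the marginal rate hits prevalence."""
    if prevalence <= 0.0:
        return -np.inf
    if prevalence >= 1.0:
        return np.inf

    def f(a):
        return float(np.sum(_GH_W * expit(a + beta * _GH_NODES))) - prevalence

    try:
        return brentq(f, -60.0, 60.0, xtol=1e-12)
    except ValueError as exc:  # pragma: no cover - guarded by validate()
        raise ValueError(f"cannot solve prevalence intercept: {exc}") from exc


def _stratum_weights(alpha: float, beta: float):
    """Normalised quadrature weights for z | alive and z | dead."""
    p = expit(alpha + beta * _GH_NODES)
    w_dead = _GH_W * p
    w_alive = _GH_W * (1.0 - p)
    return w_alive / w_alive.sum(), w_dead / w_dead.sum()


def _stratum_z_means(alpha: float, beta: float):
    w_alive, w_dead = _stratum_weights(alpha, beta)
    return float(np.sum(w_alive * _GH_NODES)), float(np.sum(w_dead * _GH_NODES))


def _linear_loading(mean_alive, mean_dead, z_alive, z_dead, prevalence=0.0):
    """Intercept and slope of a conditional mean linear in z hitting both strata.

    With no severity signal (the strata coincide on the z scale) the two
    targets cannot both be met; the loading degenerates to the
    prevalence-weighted marginal mean with zero slope.
    """
    if abs(z_dead - z_alive) < 1e-9:
        return prevalence * mean_dead + (1 - prevalence) * mean_alive, 0.0
    slope = (mean_dead - mean_alive) / (z_dead - z_alive)
    return mean_alive - slope * z_alive, slope


def _solve_logistic_two_targets(target_alive, target_dead, w_alive, w_dead, x0):
    """(c0, c1) of expit(c0 + c1 z) hitting both stratum expectations."""

    def resid(c):
        p = expit(c[0] + c[1] * _GH_NODES)
        return [
            float(np.sum(w_alive * p)) - target_alive,
            float(np.sum(w_dead * p)) - target_dead,
        ]

    sol, info, ok, msg = fsolve(resid, x0, full_output=True)
    if ok != 1 or max(abs(r) for r in resid(sol)) > 1e-8:
        raise ValueError(f"cannot calibrate severity-linked probability: {msg}")
    return float(sol[0]), float(sol[1])


def _solve_severity_link(t_alive, t_dead, w_alive, w_dead,
                         z_alive, z_dead, prevalence, x0):
    """Severity-linked probability hitting both stratum targets, or the
    prevalence-weighted marginal with zero slope when the strata coincide."""
    if abs(z_dead - z_alive) < 1e-9:
        t = prevalence * t_dead + (1 - prevalence) * t_alive
        t = min(max(t, 1e-9), 1 - 1e-9)
        return float(np.log(t / (1 - t))), 0.0
    return _solve_logistic_two_targets(t_alive, t_dead, w_alive, w_dead, x0)


def _solve_intercept_marginal(target, slope, weights=None):
    """c0 of expit(c0 + slope*z) with a given marginal expectation."""
    w = _GH_W if weights is None else weights

    def f(c0):
        return float(np.sum(w * expit(c0 + slope * _GH_NODES))) - target

    return brentq(f, -60.0, 60.0, xtol=1e-12)


def _round_clip(x: np.ndarray, var: str) -> np.ndarray:
    lo, hi = TRUNCATION.get(var, (-np.inf, np.inf))
    return np.round(np.clip(x, lo, hi), PRECISION[var])


def truncated_normal_mean(mu, sigma, lo, hi, ngrid: int = 4001) -> float:
    """E[round-free clip(N(mu, sigma), lo, hi)] by numeric quadrature.

    Exposed so tests can build truncation-adjusted stratum-mean oracles
    independently of the sampling path.
    """
    from scipy.stats import norm

    zlo, zhi = (lo - mu) / sigma, (hi - mu) / sigma
    inner = norm.expect(lambda t: mu + sigma * t, lb=max(zlo, -12), ub=min(zhi, 12))
    return float(inner + lo * norm.cdf(zlo) + hi * norm.sf(zhi))


# ---------------------------------------------------------------------------


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a complete synthetic cohort (no missingness yet).

    Deterministic given ``config.seed``. The returned cohort retains the
    latent severity (``cohort.latent``) and a pristine copy of the data
    (``cohort.complete``) for downstream bias checks; neither is persisted
    by :func:`edscore.cohort.write_cohort`.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    n = config.n_patients

    beta = config.severity_effect
    alpha = _solve_alpha(beta, config.target_prevalence)
    z = rng.standard_normal(n)
    p_death = expit(alpha + beta * z) if np.isfinite(alpha) else np.full(n, float(alpha > 0))
    died = rng.random(n) < p_death

    if np.isfinite(alpha):
        z_alive, z_dead = _stratum_z_means(alpha, beta)
        w_alive, w_dead = _stratum_weights(alpha, beta)
    else:  # degenerate prevalence: single stratum, center loadings on z=0
        z_alive, z_dead = 0.0, 1.0
        w_alive = w_dead = _GH_W

    df = pd.DataFrame(index=pd.RangeIndex(n))
    df["patient_id"] = [f"P{i:07d}" for i in range(n)]
    df["sex"] = np.where(rng.random(n) < config.male_fraction, "M", "F")

    prev = config.target_prevalence
    a, b = _linear_loading(AGE_ALIVE, AGE_DEAD, z_alive, z_dead, prev)
    noise = np.sqrt(max(AGE_SD**2 - b**2, 0.05 * AGE_SD**2))
    df["age"] = _round_clip(a + b * z + noise * rng.standard_normal(n), "age")

    for v in VITALS:
        mu_a = config.vital_means_alive[v]
        mu_d = config.vital_means_dead[v]
        sd = config.vital_sds[v]
        a, b = _linear_loading(mu_a, mu_d, z_alive, z_dead, prev)
        noise = np.sqrt(max(sd**2 - b**2, 0.05 * sd**2))
        df[v] = _round_clip(a + b * z + noise * rng.standard_normal(n), v)

    # FiO2: room air (0.21) unless on supplemental oxygen; the probability of
    # supplemental oxygen rises with severity and is calibrated so stratum
    # means hit the configured targets.
    supp_mean = float(gamma_dist(_SUPP_SHAPE, scale=_SUPP_SCALE).expect(
        lambda x: np.clip(x, _SUPP_LO, _SUPP_HI)))
    t_alive = (config.vital_means_alive["fio2"] - 0.21) / supp_mean
    t_dead = (config.vital_means_dead["fio2"] - 0.21) / supp_mean
    c0, c1 = _solve_severity_link(t_alive, t_dead, w_alive, w_dead,
                                  z_alive, z_dead, prev, (-2.5, 1.3))
    on_oxygen = rng.random(n) < expit(c0 + c1 * z)
    extra = np.clip(rng.gamma(_SUPP_SHAPE, _SUPP_SCALE, size=n), _SUPP_LO, _SUPP_HI)
    df["fio2"] = np.round(np.where(on_oxygen, 0.21 + extra, 0.21), PRECISION["fio2"])

    c0, c1 = _solve_severity_link(ALERT_ALIVE, ALERT_DEAD, w_alive, w_dead,
                                  z_alive, z_dead, prev, (3.0, -1.2))
    df["alert"] = (rng.random(n) < expit(c0 + c1 * z)).astype(float)

    for v, (mu_a, mu_d, sd) in AUX_TARGETS.items():
        a, b = _linear_loading(mu_a, mu_d, z_alive, z_dead, prev)
        noise = np.sqrt(max(sd**2 - b**2, 0.05 * sd**2))
        df[v] = _round_clip(a + b * z + noise * rng.standard_normal(n), v)

    if 0.0 < config.icu_fraction < 1.0 and n:
        c0 = _solve_intercept_marginal(config.icu_fraction, 1.5)
        df["icu_admission"] = (rng.random(n) < expit(c0 + 1.5 * z)).astype(float)
    else:
        df["icu_admission"] = np.full(n, float(config.icu_fraction >= 1.0))

    # Disposition: deaths are always admitted (the primary-analysis assumption
    # is that discharged patients survive 24 h); survivors discharge with a
    # severity-decreasing probability hitting the configured marginal.
    if 0.0 < config.discharge_fraction < 1.0:
        c0 = _solve_intercept_marginal(config.discharge_fraction, -1.5, w_alive)
        discharged = (rng.random(n) < expit(c0 - 1.5 * z)) & ~died
    else:
        discharged = (np.full(n, config.discharge_fraction >= 1.0)) & ~died
    df["disposition"] = np.where(discharged, "discharged", "admitted")
    df["died_24h"] = died.astype(float)

    start, end = config.date_window
    span = (end - start).days
    offsets = rng.integers(0, span + 1, size=n)
    df["presentation_date"] = [start + dt.timedelta(days=int(o)) for o in offsets]

    df = df[COLUMNS]
    meta = {"config": config, "seed": int(config.seed), "stage": "generated"}
    return Cohort(data=df, meta=meta, complete=df.copy(), latent=z)


def _missingness_linear_predictor(cohort: Cohort, mechanism: str) -> np.ndarray:
    """Per-record missingness score (centered later by the intercept solve)."""
    n = cohort.n
    if mechanism == "MCAR":
        return np.zeros(n)
    if mechanism == "MAR":
        age = cohort.data["age"].to_numpy(dtype=float)
        discharged = (cohort.data["disposition"] == "discharged").to_numpy()
        # Younger and discharged patients are measured less thoroughly.
        return -0.02 * (age - 60.0) + 0.8 * discharged.astype(float)
    if mechanism == "MNAR":
        if cohort.latent is None:
            raise ValueError("MNAR missingness needs the generator's latent severity")
        # Vitals tend to be registered when patients look critically ill.
        return -0.8 * cohort.latent
    raise ValueError(f"unknown mechanism {mechanism!r}")


def apply_missingness(cohort: Cohort, config: GeneratorConfig) -> Cohort:
    """Mask cells at the configured per-variable rates; values never change.

    The per-variable marginal missing fraction equals the configured rate
    under every mechanism: the mechanism shapes *who* is missing, and the
    intercept of the missingness model is solved on the cohort so the
    marginal matches. Deterministic given ``config.seed``.
    """
    config.validate()
    if cohort.mask.to_numpy().any():
        raise ValueError("apply_missingness expects a complete (unmasked) cohort")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    out = cohort.copy()
    if cohort.n == 0:
        out.meta["stage"] = "masked"
        return out

    ell = _missingness_linear_predictor(cohort, config.missingness_mechanism)
    ell = ell - ell.mean()
    for var in MASKABLE:
        rate = float(config.missingness_rates.get(var, 0.0))
        if rate <= 0.0:
            continue
        if rate >= 1.0:
            miss = np.ones(cohort.n, dtype=bool)
        elif np.allclose(ell, 0.0):
            miss = rng.random(cohort.n) < rate
        else:
            c0 = brentq(
                lambda c, e=ell, r=rate: float(np.mean(expit(c + e))) - r,
                -60.0, 60.0, xtol=1e-12,
            )
            miss = rng.random(cohort.n) < expit(c0 + ell)
        out.data.loc[miss, var] = np.nan
        out.mask.loc[miss, var] = True
    out.meta["stage"] = "masked"
    out.meta["missingness_mechanism"] = config.missingness_mechanism
    return out
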