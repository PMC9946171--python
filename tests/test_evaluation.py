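"""Discrimination, calibration and decision-curve operations."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from edscore.evaluation import (
    RiskModel, calibration_curve, compute_auc, decision_curve, delong_compare,
    exchange_rate, fit_risk_model,
)
from edscore.impute import pool


def brute_force_auc(scores, outcomes):
    """Exhaustive pairwise concordance with ties counting 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes).astype(bool)
    cases, controls = s[y], s[~y]
    total = 0.0
    for c in cases:
        total += np.sum(c > controls) + 0.5 * np.sum(c == controls)
    return total / (len(cases) * len(controls))


def test_auc_small_worked_example():
    scores = [3, 5, 1, 2, 4]
    y = [1, 1, 0, 0, 0]
    assert compute_auc(scores, y).auc == pytest.approx(5 / 6)


def test_auc_pure_ties_is_half():
    assert compute_auc([7, 7, 7, 7], [1, 0, 1, 0]).auc == 0.5


def test_auc_perfect_separation_is_one():
    r = compute_auc([10, 9, 1, 2], [1, 1, 0, 0])
    assert r.auc == 1.0
    assert r.ci95[1] <= 1.0


def test_auc_direction_orients_risk():
    scores = [3, 5, 1, 2, 4]
    y = [1, 1, 0, 0, 0]
    inc = compute_auc(scores, y, "increasing").auc
    dec = compute_auc(scores, y, "decreasing").auc
    assert inc + dec == pytest.approx(1.0)


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        compute_auc([1, 2, 3], [1, 1, 1])


def test_auc_matches_exhaustive_concordance_and_sklearn(rng):
    for _ in range(60):
        n = rng.integers(6, 200)
        y = np.zeros(n, dtype=int)
        y[: rng.integers(1, n)] = 1
        rng.shuffle(y)
        if y.sum() in (0, n):
            continue
        scores = rng.integers(0, 12, size=n).astype(float)
        ours = compute_auc(scores, y).auc
        assert ours == pytest.approx(brute_force_auc(scores, y), abs=1e-12)
        assert ours == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


def test_auc_converges_to_binormal_closed_form(rng):
    n = 50_000
    mu1, mu0, sd = 1.0, 0.0, 1.0
    y = rng.random(n) < 0.3
    s = np.where(y, rng.normal(mu1, sd, n), rng.normal(mu0, sd, n))
    target = norm.cdf((mu1 - mu0) / (sd * np.sqrt(2)))
    r = compute_auc(s, y)
    assert abs(r.auc - target) < 3 * r.se


def test_roc_curve_shape():
    r = compute_auc([1, 3, 2, 5, 4, 2], [0, 1, 0, 1, 1, 0])
    c = r.curve
    assert (c.iloc[0]["fpr"], c.iloc[0]["tpr"]) == (0.0, 0.0)
    assert (c.iloc[-1]["fpr"], c.iloc[-1]["tpr"]) == (1.0, 1.0)
    assert (c["fpr"].diff().dropna() >= 0).all()
    assert (c["tpr"].diff().dropna() >= 0).all()


def test_delong_self_comparison_is_null():
    s = np.array([1.0, 2, 3, 4, 5, 6])
    y = np.array([0, 0, 1, 0, 1, 1])
    cmp_ = delong_compare(s, s, y)
    assert cmp_.difference == 0.0
    assert cmp_.p == 1.0


def test_delong_paired_lengths_must_match():
    with pytest.raises(ValueError):
        delong_compare([1, 2, 3], [1, 2], [1, 0, 1])


def test_delong_agrees_with_stratified_bootstrap_oracle(rng):
    """On a small paired instance the DeLong SE of the AUC difference should
    match a stratified-bootstrap estimate, and the p values should agree to
    Monte-Carlo precision."""
    n = 30
    y = np.array([1] * 12 + [0] * 18)
    a = rng.normal(y * 1.0, 1.0)
    b = rng.normal(y * 0.8, 1.0)
    cmp_ = delong_compare(a, b, y)

    boots = []
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == 0)
    for _ in range(10_000):
        idx = np.concatenate([rng.choice(cases, len(cases)),
                              rng.choice(controls, len(controls))])
        boots.append(compute_auc(a[idx], y[idx]).auc
                     - compute_auc(b[idx], y[idx]).auc)
    se_boot = np.std(boots, ddof=1)
    se_delong = np.sqrt(cmp_.variance)
    assert 0.6 < se_delong / se_boot < 1.5
    p_boot = 2 * norm.sf(abs(cmp_.difference) / se_boot)
    assert abs(cmp_.p - p_boot) < 0.15


def test_null_slope_when_outcome_independent_of_score(rng):
    n = 50_000
    score = rng.integers(0, 15, n).astype(float)
    y = (rng.random(n) < 0.05).astype(float)
    model = fit_risk_model([score], y)
    se = sm.Logit(y, sm.add_constant(score)).fit(disp=0).bse[1]
    assert abs(model.slope) < 3 * se


def test_risk_model_parameter_recovery(rng):
    n = 100_000
    score = rng.integers(0, 16, n).astype(float)
    y = (rng.random(n) < expit(-5 + 0.4 * score)).astype(float)
    model = fit_risk_model([score], y)
    se = sm.Logit(y, sm.add_constant(score)).fit(disp=0).bse[1]
    assert abs(model.slope - 0.4) < 3 * se


def test_pooling_identity_for_single_set(rng):
    score = rng.integers(0, 10, 2_000).astype(float)
    y = (rng.random(2_000) < expit(-3 + 0.3 * score)).astype(float)
    model = fit_risk_model([score], y)
    np.testing.assert_allclose(model.per_set_coefs[0],
                               [model.intercept, model.slope])


def test_pooled_slope_is_mean_of_per_set_slopes(rng):
    y = (rng.random(3_000) < 0.1).astype(float)
    sets = [rng.integers(0, 10, 3_000).astype(float) + y * 2 for _ in range(4)]
    model = fit_risk_model(sets, y)
    assert model.slope == pytest.approx(model.per_set_coefs[:, 1].mean(),
                                        abs=1e-14)
    assert model.slope == pytest.approx(pool(model.per_set_coefs[:, 1]).pooled)


def test_single_class_outcome_rejected_in_fit():
    with pytest.raises(ValueError, match="single class"):
        fit_risk_model([np.arange(10.0)], np.zeros(10))


def test_calibration_in_the_large(rng):
    """Mean predicted risk equals observed prevalence after an
    intercept-containing logistic fit, per set."""
    y = (rng.random(20_000) < 0.03).astype(float)
    sets = [rng.integers(0, 12, 20_000).astype(float) + y * 3 for _ in range(3)]
    model = fit_risk_model(sets, y)
    for k, s in enumerate(sets):
        assert abs(model.predict_set(s, k).mean() - y.mean()) < 1e-8


def test_calibration_constant_model_sits_on_identity(rng):
    prev = 0.2
    y = (rng.random(5_000) < prev).astype(float)
    model = RiskModel(name="flat", intercept=float(logit(y.mean())), slope=0.0,
                      per_set_coefs=np.array([[float(logit(y.mean())), 0.0]]),
                      intercept_pool=pool([0.0]), slope_pool=pool([0.0]))
    cal = calibration_curve(model, np.full(5_000, 7.0), y)
    assert len(cal.table) == 1
    row = cal.table.iloc[0]
    assert row["n"] == 5_000
    assert row["predicted"] == pytest.approx(row["observed"], abs=1e-12)


def test_calibration_under_well_specified_model(rng):
    n = 200_000
    score = rng.integers(0, 16, n).astype(float)
    y = (rng.random(n) < expit(-6 + 0.45 * score)).astype(float)
    model = fit_risk_model([score], y)
    cal = calibration_curve(model, score, y, min_group_size=500)
    for _, row in cal.table.iterrows():
        se = np.sqrt(max(row["predicted"] * (1 - row["predicted"]), 1e-12)
                     / row["n"])
        assert abs(row["predicted"] - row["observed"]) < 4 * se


def test_calibration_detects_constructed_miscalibration(rng):
    """A model whose predictions are artificially doubled should show
    observed mortality at about half its predicted risk."""

    class Doubled:
        def __init__(self, inner):
            self.inner = inner

        def predict(self, scores):
            return np.minimum(2.0 * self.inner.predict(scores), 1.0)

    n = 100_000
    score = rng.integers(0, 10, n).astype(float)
    y = (rng.random(n) < expit(-4 + 0.3 * score)).astype(float)
    fitted = fit_risk_model([score], y)
    cal = calibration_curve(Doubled(fitted), score, y, min_group_size=1000)
    sel = cal.table[(cal.table["predicted"] > 0.02)
                    & (cal.table["predicted"] < 0.5)]
    ratios = sel["observed"] / sel["predicted"]
    assert np.allclose(ratios, 0.5, atol=0.07)


def test_calibration_small_groups_reported_not_silently_dropped(rng):
    y = (rng.random(200) < 0.3).astype(float)
    score = np.concatenate([rng.integers(0, 4, 199).astype(float), [9.0]])
    model = fit_risk_model([score], y)
    cal = calibration_curve(model, score, y, min_group_size=20)
    assert cal.skipped == [{"score": 9.0, "n": 1}]
    assert cal.table["n"].sum() == 199


def test_exchange_rate_worked_value():
    assert exchange_rate(0.10) == pytest.approx(0.1 / 0.9)
    with pytest.raises(ValueError):
        exchange_rate(1.0)


def test_decision_curve_worked_example():
    # 100 patients, 10 events; at p_t = 0.10 all events and 20 non-events
    # are flagged: NB = 10/100 - (20/100)(0.1/0.9) = 0.0778
    risks = np.concatenate([np.full(10, 0.5), np.full(20, 0.2),
                            np.full(70, 0.01)])
    y = np.concatenate([np.ones(10), np.zeros(90)])
    dc = decision_curve(risks, y, thresholds=[0.10])
    assert dc.net_benefit[0] == pytest.approx(0.1 - 0.2 * (0.1 / 0.9))
    assert dc.standardized_net_benefit[0] == pytest.approx(
        (0.1 - 0.2 / 9) / 0.1)
    assert dc.treat_none[0] == 0.0


def test_decision_curve_limits():
    y = np.concatenate([np.ones(10), np.zeros(90)])
    everyone = np.full(100, 0.9)
    dc = decision_curve(everyone, y, thresholds=[1e-6])
    assert dc.net_benefit[0] == pytest.approx(0.1, abs=1e-5)
    assert dc.standardized_net_benefit[0] == pytest.approx(1.0, abs=1e-4)
    nobody = np.zeros(100)
    dc = decision_curve(nobody, y, thresholds=[0.5])
    assert dc.net_benefit[0] == 0.0


def test_decision_curve_rejects_bad_inputs():
    y = [1, 0]
    with pytest.raises(ValueError):
        decision_curve([0.5, 0.5], y, thresholds=[1.0])
    with pytest.raises(ValueError):
        decision_curve([1.5, 0.5], y, thresholds=[0.5])


def test_decision_curve_matches_confusion_matrix_arithmetic(rng):
    for _ in range(40):
        n = rng.integers(10, 500)
        y = (rng.random(n) < 0.3).astype(float)
        if y.sum() in (0, n):
            continue
        risks = rng.random(n)
        thr = rng.uniform(0.01, 0.9, size=5)
        dc = decision_curve(risks, y, thresholds=thr)
        for i, t in enumerate(thr):
            flagged = risks >= t
            tp = np.sum(flagged & (y == 1))
            fp = np.sum(flagged & (y == 0))
            nb = tp / n - (fp / n) * t / (1 - t)
            assert dc.net_benefit[i] == pytest.approx(nb, abs=1e-14)
            assert dc.standardized_net_benefit[i] <= 1.0 + 1e-12
            assert dc.net_benefit[i] <= y.mean() + 1e-12
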