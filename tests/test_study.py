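"""Study orchestration: splitting, sensitivity analysis, end-to-end runs."""

import datetime as dt
import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from edscore.cohort import Cohort
from edscore.simulate import GeneratorConfig, apply_missingness, generate_cohort
from edscore.study import (
    RunConfig, ScoreComparisonStudy, run_study, sensitivity_flip,
    split_subsets,
)

from conftest import make_cohort_frame


# -- split ------------------------------------------------------------------

def test_split_partitions_cohort(masked_cohort):
    split = dt.date(2020, 2, 1)
    pre, post = split_subsets(masked_cohort, split)
    assert pre.n + post.n == masked_cohort.n
    assert all(d < split for d in pre.data["presentation_date"])
    assert all(d >= split for d in post.data["presentation_date"])


def test_split_day_itself_goes_to_later_period():
    df = make_cohort_frame([
        {"presentation_date": dt.date(2020, 1, 31)},
        {"presentation_date": dt.date(2020, 2, 1)},
        {"presentation_date": dt.date(2020, 2, 2)},
    ])
    pre, post = split_subsets(Cohort(data=df), dt.date(2020, 2, 1))
    assert pre.n == 1 and post.n == 2


def test_split_all_before_gives_empty_post():
    df = make_cohort_frame([{"presentation_date": dt.date(2019, 5, 5)}] * 3)
    pre, post = split_subsets(Cohort(data=df), dt.date(2020, 2, 1))
    assert pre.n == 3 and post.n == 0


def test_split_fraction_matches_date_window(masked_cohort, default_config):
    pre, post = split_subsets(masked_cohort, default_config.covid_split_date)
    lo, hi = default_config.date_window
    expected = (default_config.covid_split_date - lo).days / ((hi - lo).days + 1)
    se = np.sqrt(expected * (1 - expected) / masked_cohort.n)
    assert abs(pre.n / masked_cohort.n - expected) < 3 * se


# -- sensitivity flip -------------------------------------------------------

def test_sensitivity_flip_zero_fraction_is_identity(masked_cohort):
    out = sensitivity_flip(masked_cohort, 0.0, seed=1)
    pd.testing.assert_frame_equal(out.data, masked_cohort.data)
    assert out.meta["sensitivity_flipped"] == 0


def test_sensitivity_flip_exact_count_and_eligibility():
    rows = [{"disposition": "discharged"}] * 10_000
    rows += [{"disposition": "admitted"}] * 500
    rows += [{"disposition": "admitted", "died_24h": 1.0}] * 50
    df = make_cohort_frame(rows)
    cohort = Cohort(data=df)
    out = sensitivity_flip(cohort, 0.0004, seed=3)
    flipped = (out.data["died_24h"] != cohort.data["died_24h"])
    assert flipped.sum() == 4
    assert (cohort.data.loc[flipped, "disposition"] == "discharged").all()
    assert (cohort.data.loc[flipped, "died_24h"] == 0.0).all()
    # nothing else changed
    pd.testing.assert_frame_equal(
        out.data.drop(columns="died_24h"), cohort.data.drop(columns="died_24h"))


def test_sensitivity_flip_rejects_fraction_of_one():
    df = make_cohort_frame([{"disposition": "discharged"}])
    with pytest.raises(ValueError):
        sensitivity_flip(Cohort(data=df), 1.0, seed=0)


# -- end-to-end -------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted_study():
    cfg = GeneratorConfig(n_patients=20_000, seed=909)
    cohort = apply_missingness(generate_cohort(cfg), cfg)
    study = ScoreComparisonStudy(cohort, m=3, iterations=3)
    return cohort, study.fit(seed=77)


def test_flow_conservation(fitted_study):
    cohort, res = fitted_study
    assert res.flow["n_input"] == cohort.n
    assert res.flow["n_excluded"] + res.flow["n_included"] == cohort.n
    for rep in res.reports.values():
        assert rep.n in (res.flow["n_included"],) or rep.subset in (
            "pre_covid", "post_covid")
    assert (res.reports["pre_covid"].n + res.reports["post_covid"].n
            == res.flow["n_included"])


def test_both_scores_discriminate_on_severity_generated_data(fitted_study):
    _, res = fitted_study
    rep = res.reports["all"]
    assert rep.scores["news"].auc > 0.75
    assert rep.scores["rox"].auc > 0.75


def test_observed_mortality_monotone_in_score_direction(fitted_study):
    _, res = fitted_study
    rep = res.reports["all"]
    for name, sign in (("news", 1), ("rox", -1)):
        t = rep.scores[name].calibration
        t = t[t["n"] >= 100]
        rho, _ = spearmanr(t["score"], t["observed"])
        assert sign * rho > 0.6, f"{name}: rho={rho}"


def test_expected_score_directions_in_risk_models(fitted_study):
    _, res = fitted_study
    rep = res.reports["all"]
    assert rep.scores["news"].model.slope > 0
    assert rep.scores["rox"].model.slope < 0


def test_sensitivity_does_not_inflate_discrimination(fitted_study):
    _, res = fitted_study
    for name in ("news", "rox"):
        primary = res.reports["all"].scores[name]
        sens = res.reports["sensitivity"].scores[name]
        assert sens.auc <= primary.auc + 3 * primary.auc_se


def test_zero_sensitivity_fraction_reproduces_primary_report():
    cfg = GeneratorConfig(n_patients=8_000, seed=31)
    cohort = apply_missingness(generate_cohort(cfg), cfg)
    res = ScoreComparisonStudy(cohort, m=2, iterations=2,
                               sensitivity_fraction=0.0).fit(seed=5)
    d = res.to_dict()["reports"]
    sens, primary = d["sensitivity"], d["all"]
    sens["subset"] = primary["subset"]
    assert json.dumps(sens, sort_keys=True, default=float) == \
        json.dumps(primary, sort_keys=True, default=float)


def test_standardized_net_benefit_bounded_by_one(fitted_study):
    _, res = fitted_study
    for rep in res.reports.values():
        for name in ("news", "rox"):
            assert np.all(rep.scores[name].decision.standardized_net_benefit
                          <= 1.0 + 1e-12)
            assert np.all(rep.scores[name].decision.treat_none == 0.0)


def test_summary_mentions_key_quantities(fitted_study):
    _, res = fitted_study
    text = res.summary()
    assert "AUC" in text and "news" in text and "rox" in text
    assert str(res.flow["n_included"]) in text


def test_plots_render(fitted_study, tmp_path):
    import matplotlib.pyplot as plt

    _, res = fitted_study
    res.plot_mortality_by_score()
    res.plot_calibration()
    res.plot_decision_curves()
    plt.close("all")


def test_run_study_writes_report_and_tables(tmp_path):
    cfg = RunConfig(m=2, iterations=2, seed=4, outdir=str(tmp_path / "out"),
                    make_plots=True)
    cfg.generator = cfg.generator.replace(n_patients=6_000, seed=4)
    res = run_study(cfg)
    out = tmp_path / "out"
    report = json.loads((out / "report.json").read_text())
    assert set(report["reports"]) == {"all", "pre_covid", "post_covid",
                                      "sensitivity"}
    for f in ("calibration.tsv", "dca.tsv", "roc.tsv",
              "mortality_by_score.png", "calibration.png",
              "decision_curves.png"):
        assert (out / f).exists()
    roc = pd.read_csv(out / "roc.tsv", sep="\t")
    assert set(roc["score_name"]) == {"news", "rox"}


def test_run_config_round_trip_from_yaml(tmp_path):
    (tmp_path / "run.yaml").write_text(
        "m: 2\niterations: 2\nseed: 9\nsplit_date: 2020-02-01\n"
        "sensitivity_fraction: 0.0004\n"
        "generator:\n  n_patients: 123\n  seed: 9\n"
        "  date_window: [2019-01-01, 2021-03-01]\n")
    cfg = RunConfig.from_yaml(tmp_path / "run.yaml")
    assert cfg.m == 2 and cfg.generator.n_patients == 123
    assert cfg.split_date == dt.date(2020, 2, 1)
    with pytest.raises(ValueError, match="unknown"):
        (tmp_path / "bad.yaml").write_text("bogus_key: 1\n")
        RunConfig.from_yaml(tmp_path / "bad.yaml")
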