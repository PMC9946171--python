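"""End-to-end study orchestration, statsmodels-style.

:class:`ScoreComparisonStudy` is the model object: it holds a cohort (loaded
or synthetic) and the analysis settings. Its :meth:`~ScoreComparisonStudy.fit`
runs the full flow — exclusion, multiple imputation, scoring, per-set risk
models, discrimination / calibration / decision-curve evaluation — and
returns a :class:`StudyResults` carrying every estimate, the cohort flow
counts, the pre/post-pandemic split-sample validation and the
discharged-death sensitivity analysis, with ``summary()``, JSON export and
plotting attached.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, VITALS, read_cohort, write_cohort
from .evaluation import (
    CalibrationCurve, DecisionCurve, RiskModel, calibration_curve,
    compute_auc, decision_curve, default_threshold_grid, delong_compare,
)
from .evaluation import fit_risk_model
from .impute import exclude_by_missingness, mice_impute
from .scoring import NewsChart, load_chart, score_cohort
from .simulate import GeneratorConfig, apply_missingness, generate_cohort

__all__ = [
    "ScoreComparisonStudy", "StudyResults", "RunConfig", "run_study",
    "sensitivity_flip", "split_subsets", "SCORE_DIRECTIONS",
]

SCORE_DIRECTIONS = {"news": "increasing", "rox": "decreasing"}


# ---------------------------------------------------------------------------
# Pipeline operations


def sensitivity_flip(cohort: Cohort, fraction: float, seed: int = 0) -> Cohort:
    """Mark a random fraction of discharged survivors as 24-h deaths.

    Exactly ``round(fraction * n_discharged_survivors)`` records, chosen
    uniformly without replacement, have their death flag set; nothing else
    changes. Emulates the possibility that some discharged patients died
    unobserved.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("sensitivity fraction must be in [0, 1)")
    out = cohort.copy()
    eligible = np.flatnonzero(
        (cohort.data["disposition"] == "discharged").to_numpy()
        & (cohort.data["died_24h"].to_numpy(dtype=float) == 0.0))
    n_flip = int(round(fraction * len(eligible)))
    if n_flip:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
        chosen = rng.choice(eligible, size=n_flip, replace=False)
        out.data.loc[chosen, "died_24h"] = 1.0
    out.meta["sensitivity_flipped"] = n_flip
    return out


def split_subsets(cohort: Cohort, split_date: dt.date):
    """Partition by presentation date: strictly before the split vs the rest.

    The split day itself belongs to the later (pandemic) period.
    """
    dates = cohort.data["presentation_date"]
    if dates.isna().any():
        raise ValueError("presentation_date missing; cannot split")
    before = np.array([d < split_date for d in dates])
    return cohort.subset(before), cohort.subset(~before)


# ---------------------------------------------------------------------------
# Per-subset evaluation


@dataclass
class ScoreEvaluation:
    """Pooled evaluation of one score on one patient subset."""

    name: str
    direction: str
    auc: float
    auc_se: float
    auc_ci95: tuple
    per_set_aucs: np.ndarray
    model: RiskModel
    calibration: pd.DataFrame        # score, n, predicted, observed (pooled)
    decision: DecisionCurve


@dataclass
class EvaluationReport:
    """All three evaluation surfaces for both scores on one subset."""

    subset: str
    n: int
    n_events: int
    prevalence: float
    scores: dict                     # name -> ScoreEvaluation
    delong: dict                     # pooled paired comparison news vs rox

    def to_dict(self) -> dict:
        d = {
            "subset": self.subset, "n": self.n, "n_events": self.n_events,
            "prevalence": self.prevalence, "delong": dict(self.delong),
            "scores": {},
        }
        for name, ev in self.scores.items():
            d["scores"][name] = {
                "direction": ev.direction,
                "auc": ev.auc, "auc_se": ev.auc_se,
                "auc_ci95": list(ev.auc_ci95),
                "per_set_aucs": [float(a) for a in ev.per_set_aucs],
                "model": {
                    "intercept": ev.model.intercept,
                    "slope": ev.model.slope,
                    "per_set_coefs": ev.model.per_set_coefs.tolist(),
                },
                "calibration": ev.calibration.to_dict(orient="list"),
                "decision_curve": {
                    "thresholds": ev.decision.thresholds.tolist(),
                    "net_benefit": ev.decision.net_benefit.tolist(),
                    "standardized_net_benefit":
                        ev.decision.standardized_net_benefit.tolist(),
                    "treat_all": ev.decision.treat_all.tolist(),
                    "prevalence": ev.decision.prevalence,
                },
            }
        return d


def _merge_calibration(tables, m: int, min_group_size: int) -> pd.DataFrame:
    cat = pd.concat(tables, ignore_index=True)
    grp = cat.groupby("score")
    merged = pd.DataFrame({
        "score": grp["n"].sum().index,
        "n": (grp["n"].sum() / m).to_numpy(),
        "predicted": (grp.apply(
            lambda g: np.average(g["predicted"], weights=g["n"]),
            include_groups=False)).to_numpy(),
        "observed": (grp.apply(
            lambda g: np.average(g["observed"], weights=g["n"]),
            include_groups=False)).to_numpy(),
    }).reset_index(drop=True)
    return merged[merged["n"] >= min_group_size].reset_index(drop=True)


def evaluate_subset(score_sets, outcomes, subset_name: str = "all",
                    thresholds=None, min_group_size: int = 20) -> EvaluationReport:
    """Pooled three-surface evaluation of NEWS and ROX on one subset.

    ``score_sets`` is one frame per imputed set (columns ``news``, ``rox``)
    over the same patients as ``outcomes``. Models, AUCs and decision curves
    are computed per set and pooled by plain averaging.
    """
    y = np.asarray(outcomes, dtype=float)
    thr = default_threshold_grid() if thresholds is None else np.asarray(thresholds)
    m = len(score_sets)
    prev = float(y.mean())
    report_scores = {}
    for name, direction in SCORE_DIRECTIONS.items():
        per_set = [s[name].to_numpy(dtype=float) for s in score_sets]
        model = fit_risk_model(per_set, y, name=name)
        aucs, variances = [], []
        cal_tables, nb, snb = [], [], []
        ta = None
        for k, s in enumerate(per_set):
            roc = compute_auc(s, y, direction=direction)
            aucs.append(roc.auc)
            variances.append(roc.se ** 2)
            cal = calibration_curve(model, s, y, min_group_size=1, set_index=k)
            cal_tables.append(cal.table)
            dca = decision_curve(model.predict_set(s, k), y, thr)
            nb.append(dca.net_benefit)
            snb.append(dca.standardized_net_benefit)
            ta = dca.treat_all
        auc = float(np.mean(aucs))
        se = float(np.sqrt(np.mean(variances)))
        pooled_dca = DecisionCurve(
            thresholds=np.asarray(thr, dtype=float),
            net_benefit=np.mean(nb, axis=0),
            standardized_net_benefit=np.mean(snb, axis=0),
            treat_all=ta, treat_none=np.zeros(len(thr)), prevalence=prev)
        report_scores[name] = ScoreEvaluation(
            name=name, direction=direction, auc=auc, auc_se=se,
            auc_ci95=(max(auc - 1.959963984540054 * se, 0.0),
                      min(auc + 1.959963984540054 * se, 1.0)),
            per_set_aucs=np.asarray(aucs), model=model,
            calibration=_merge_calibration(cal_tables, m, min_group_size),
            decision=pooled_dca)

    diffs, dvars = [], []
    for s in score_sets:
        cmp_ = delong_compare(s["news"].to_numpy(dtype=float),
                              s["rox"].to_numpy(dtype=float), y,
                              direction_a="increasing", direction_b="decreasing")
        diffs.append(cmp_.difference)
        dvars.append(cmp_.variance)
    mean_diff = float(np.mean(diffs))
    mean_var = float(np.mean(dvars))
    from scipy.stats import norm
    if mean_var > 0:
        z = mean_diff / np.sqrt(mean_var)
        p = float(2.0 * norm.sf(abs(z)))
    else:
        z, p = 0.0, 1.0
    delong = {
        "auc_news": report_scores["news"].auc,
        "auc_rox": report_scores["rox"].auc,
        "difference": mean_diff, "variance": mean_var,
        "z": float(z), "p": p,
    }
    return EvaluationReport(subset=subset_name, n=len(y),
                            n_events=int(y.sum()), prevalence=prev,
                            scores=report_scores, delong=delong)


# ---------------------------------------------------------------------------
# Model / Results


class ScoreComparisonStudy:
    """Head-to-head validation of NEWS and ROX against 24-h mortality.

    Parameters
    ----------
    cohort : Cohort
        The (possibly incomplete) analysis cohort.
    m, iterations : int
        Number of imputed sets and chained-equation sweeps per set.
    chart : NewsChart, optional
        NEWS banding chart (default: the packaged 2012 chart).
    thresholds : array-like, optional
        Decision-curve threshold grid (default 0.001..0.100 by 0.001).
    split_date : date
        Pre/post-pandemic split; the split day belongs to the later period.
    sensitivity_fraction : float
        Fraction of discharged survivors flipped to deaths in the
        sensitivity analysis (default 0.04%).
    """

    def __init__(self, cohort: Cohort, m: int = 20, iterations: int = 5,
                 chart: Optional[NewsChart] = None, thresholds=None,
                 split_date: dt.date = dt.date(2020, 2, 1),
                 sensitivity_fraction: float = 0.0004,
                 min_group_size: int = 20,
                 fio2_room_air_default: bool = True):
        self.cohort = cohort
        self.m = int(m)
        self.iterations = int(iterations)
        self.chart = chart or load_chart("news_2012")
        self.thresholds = (default_threshold_grid() if thresholds is None
                           else np.asarray(thresholds, dtype=float))
        self.split_date = split_date
        self.sensitivity_fraction = float(sensitivity_fraction)
        self.min_group_size = int(min_group_size)
        self.fio2_room_air_default = bool(fio2_room_air_default)

    @classmethod
    def from_synthetic(cls, config: Optional[GeneratorConfig] = None,
                       **kwargs) -> "ScoreComparisonStudy":
        """Generate a synthetic cohort (with missingness) and wrap it."""
        config = config or GeneratorConfig()
        cohort = apply_missingness(generate_cohort(config), config)
        return cls(cohort, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ScoreComparisonStudy":
        return cls(read_cohort(path), **kwargs)

    def fit(self, seed: int = 0) -> "StudyResults":
        """Run exclusion, imputation, scoring and all subset evaluations."""
        included, exclusion_log = exclude_by_missingness(self.cohort)
        imputed = mice_impute(included, m=self.m, iterations=self.iterations,
                              seed=seed,
                              fio2_room_air_default=self.fio2_room_air_default)
        score_sets = score_cohort(imputed, self.chart)
        y = included.data["died_24h"].to_numpy(dtype=float)
        dates = included.data["presentation_date"]

        complete_cases = int((included.mask[VITALS].sum(axis=1) == 0).sum())
        flow = {
            "n_input": exclusion_log["n_input"],
            "n_excluded": exclusion_log["n_excluded"],
            "n_included": exclusion_log["n_retained"],
            "complete_case_fraction": (complete_cases / included.n
                                       if included.n else float("nan")),
            "missing_vital_counts": exclusion_log["missing_vital_counts"],
        }

        reports = {"all": evaluate_subset(
            score_sets, y, "all", self.thresholds, self.min_group_size)}

        before = np.array([d < self.split_date for d in dates])
        for label, sel in (("pre_covid", before), ("post_covid", ~before)):
            sub_sets = [s.loc[sel].reset_index(drop=True) for s in score_sets]
            reports[label] = evaluate_subset(
                sub_sets, y[sel], label, self.thresholds, self.min_group_size)

        flipped = sensitivity_flip(included, self.sensitivity_fraction, seed)
        y_flip = flipped.data["died_24h"].to_numpy(dtype=float)
        reports["sensitivity"] = evaluate_subset(
            score_sets, y_flip, "sensitivity", self.thresholds,
            self.min_group_size)
        flow["sensitivity_flipped"] = flipped.meta["sensitivity_flipped"]

        return StudyResults(
            flow=flow, reports=reports, seed=int(seed),
            settings={
                "m": self.m, "iterations": self.iterations,
                "chart_version": self.chart.version,
                "split_date": self.split_date.isoformat(),
                "sensitivity_fraction": self.sensitivity_fraction,
                "min_group_size": self.min_group_size,
                "thresholds": [float(t) for t in self.thresholds],
            },
            cohort_meta={k: v for k, v in self.cohort.meta.items()
                         if isinstance(v, (str, int, float))},
        )


@dataclass
class StudyResults:
    """Fitted study: flow counts, per-subset evaluation reports, provenance."""

    flow: dict
    reports: dict
    seed: int
    settings: dict
    cohort_meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "flow": self.flow,
            "seed": self.seed,
            "settings": self.settings,
            "cohort_meta": self.cohort_meta,
            "reports": {k: r.to_dict() for k, r in self.reports.items()},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1,
                          default=float)

    def save_json(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")

    def summary(self) -> str:
        """Human-readable study summary table."""
        lines = []
        lines.append("24-h mortality score validation (NEWS vs ROX)")
        lines.append("=" * 64)
        f = self.flow
        lines.append(f"records in: {f['n_input']}   excluded (>=4 of 5 vitals "
                     f"missing): {f['n_excluded']}   analysed: {f['n_included']}")
        lines.append(f"complete-case fraction (5 vitals): "
                     f"{f['complete_case_fraction']:.3f}   "
                     f"imputations m={self.settings['m']} x "
                     f"{self.settings['iterations']} sweeps")
        lines.append("-" * 64)
        header = f"{'subset':<12}{'score':<7}{'AUC':>7}{'95% CI':>18}{'DeLong p':>12}"
        lines.append(header)
        for name, rep in self.reports.items():
            for score in ("news", "rox"):
                ev = rep.scores[score]
                ci = f"({ev.auc_ci95[0]:.3f}, {ev.auc_ci95[1]:.3f})"
                p = f"{rep.delong['p']:.3g}" if score == "news" else ""
                lines.append(f"{name:<12}{score:<7}{ev.auc:>7.3f}{ci:>18}{p:>12}")
        lines.append("-" * 64)
        rep = self.reports["all"]
        for score in ("news", "rox"):
            mdl = rep.scores[score].model
            lines.append(
                f"{score}: pooled logit risk = expit({mdl.intercept:+.3f} "
                f"{mdl.slope:+.4f} x {score})")
        lines.append(f"events: {rep.n_events} / {rep.n} "
                     f"(prevalence {rep.prevalence:.4f})")
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------

    def plot_mortality_by_score(self, subset: str = "all", ax=None):
        """Observed 24-h mortality and patient counts per score value."""
        import matplotlib.pyplot as plt

        rep = self.reports[subset]
        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(11, 4))
        for a, score in zip(np.ravel(ax), ("rox", "news")):
            t = rep.scores[score].calibration
            a2 = a.twinx()
            a2.bar(t["score"], t["n"], color="0.85", label="patients")
            a.plot(t["score"], 100 * t["observed"], "o-", color="tab:red")
            a.set_xlabel(f"{score.upper()} value")
            a.set_ylabel("observed 24-h mortality (%)")
            a2.set_ylabel("patients")
            a.set_zorder(a2.get_zorder() + 1)
            a.patch.set_visible(False)
        return ax

    def plot_calibration(self, subset: str = "all", ax=None):
        """Predicted vs observed 24-h mortality for both scores."""
        import matplotlib.pyplot as plt

        rep = self.reports[subset]
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        lim = 0.0
        for score, marker in (("rox", "o"), ("news", "s")):
            t = rep.scores[score].calibration
            ax.plot(t["predicted"], t["observed"], marker, ms=4,
                    label=score.upper())
            if len(t):
                lim = max(lim, t["predicted"].max(), t["observed"].max())
        lim = min(max(lim * 1.05, 0.01), 1.0)
        ax.plot([0, lim], [0, lim], "k--", lw=1, label="ideal")
        ax.set_xlabel("predicted 24-h mortality")
        ax.set_ylabel("observed 24-h mortality")
        ax.legend()
        return ax

    def plot_decision_curves(self, subset: str = "all", ax=None):
        """Standardized net benefit vs threshold for both scores."""
        import matplotlib.pyplot as plt

        rep = self.reports[subset]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        prev = rep.prevalence
        for score in ("rox", "news"):
            d = rep.scores[score].decision
            ax.plot(d.thresholds, d.standardized_net_benefit,
                    label=score.upper())
        d = rep.scores["rox"].decision
        ax.plot(d.thresholds, d.treat_all / prev if prev else d.treat_all,
                ":", color="0.4", label="treat all")
        ax.axhline(0.0, color="0.4", lw=1, ls="--", label="treat none")
        ax.set_ylim(-0.2, 1.05)
        ax.set_xlabel("threshold probability of 24-h death")
        ax.set_ylabel("standardized net benefit")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# Config-file driven runner


@dataclass
class RunConfig:
    """File-driven settings for a full study run."""

    input_csv: Optional[str] = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    m: int = 20
    iterations: int = 5
    chart_version: str = "news_2012"
    split_date: dt.date = dt.date(2020, 2, 1)
    sensitivity_fraction: float = 0.0004
    min_group_size: int = 20
    seed: int = 0
    outdir: Optional[str] = None
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        gen_kwargs = raw.pop("generator", {}) or {}
        for key in ("covid_split_date",):
            if key in gen_kwargs and isinstance(gen_kwargs[key], str):
                gen_kwargs[key] = dt.date.fromisoformat(gen_kwargs[key])
        if "date_window" in gen_kwargs:
            gen_kwargs["date_window"] = tuple(
                dt.date.fromisoformat(d) if isinstance(d, str) else d
                for d in gen_kwargs["date_window"])
        cfg = cls(generator=GeneratorConfig(**gen_kwargs))
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown run-config key {key!r}")
            if key == "split_date" and isinstance(val, str):
                val = dt.date.fromisoformat(val)
            setattr(cfg, key, val)
        return cfg


def run_study(config: RunConfig) -> StudyResults:
    """Execute the full study from a :class:`RunConfig`; optionally write
    the JSON report, plot-ready TSVs and figures to ``config.outdir``."""
    if config.input_csv:
        cohort = read_cohort(config.input_csv)
    else:
        gen = config.generator
        cohort = apply_missingness(generate_cohort(gen), gen)
    study = ScoreComparisonStudy(
        cohort, m=config.m, iterations=config.iterations,
        chart=load_chart(config.chart_version),
        split_date=config.split_date,
        sensitivity_fraction=config.sensitivity_fraction,
        min_group_size=config.min_group_size)
    results = study.fit(seed=config.seed)

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        results.save_json(out / "report.json")
        rep = results.reports["all"]
        cal = pd.concat(
            [rep.scores[s].calibration.assign(score_name=s)
             for s in ("news", "rox")], ignore_index=True)
        cal.to_csv(out / "calibration.tsv", sep="\t", index=False)
        dca = pd.concat(
            [rep.scores[s].decision.to_frame().assign(score_name=s)
             for s in ("news", "rox")], ignore_index=True)
        dca.to_csv(out / "dca.tsv", sep="\t", index=False)
        roc_rows = []
        for sub, r in results.reports.items():
            for s in ("news", "rox"):
                ev = r.scores[s]
                roc_rows.append({
                    "subset": sub, "score_name": s, "auc": ev.auc,
                    "auc_se": ev.auc_se, "ci_low": ev.auc_ci95[0],
                    "ci_high": ev.auc_ci95[1], "delong_p": r.delong["p"]})
        pd.DataFrame(roc_rows).to_csv(out / "roc.tsv", sep="\t", index=False)
        if config.make_plots:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            for fname, plot in (
                    ("mortality_by_score.png", results.plot_mortality_by_score),
                    ("calibration.png", results.plot_calibration),
                    ("decision_curves.png", results.plot_decision_curves)):
                plot()
                plt.tight_layout()
                plt.savefig(out / fname, dpi=120)
                plt.close("all")
    return results
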