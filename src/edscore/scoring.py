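"""Risk-score computation: the ROX index and the National Early Warning Score.

Both scores are computed strictly from non-missing inputs — scoring never
imputes. ROX is oxygen saturation (%) / FiO2 (fraction) / respiratory rate
(breaths/min), rounded half-up to the nearest integer; lower values mean
higher risk. NEWS sums banded points over respiratory rate, SpO2,
supplemental oxygen, temperature, systolic blood pressure, heart rate and
consciousness; higher values mean higher risk. The NEWS banding chart is
shipped as a versioned YAML asset so results stay reproducible across chart
revisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import BOUNDS, SCORING_INPUTS

__all__ = [
    "NewsChart", "load_chart", "compute_rox", "compute_news",
    "rox_scores", "news_scores", "score_cohort",
]


@dataclass(frozen=True)
class NewsChart:
    """Per-parameter threshold bands mapping a measurement to integer points.

    Bands are upper-edge intervals ``(-inf, u1], (u1, u2], ..., (u_k, inf)``,
    so they partition the real line with no gaps or overlaps by construction.
    """

    version: str
    uppers: dict          # parameter -> ndarray of finite upper edges
    points: dict          # parameter -> ndarray of points, len(uppers)+1
    supplemental_oxygen_points: int
    not_alert_points: int
    room_air_fio2: float
    max_score: int

    def parameter_points(self, parameter: str, value: float) -> int:
        """Points contributed by one vital-sign value.

        Raises ValueError when the value lies outside the physiological
        validation bounds (the chart's intended coverage).
        """
        lo, hi = BOUNDS[parameter]
        if not lo <= value <= hi:
            raise ValueError(
                f"{parameter}={value} outside chart coverage [{lo}, {hi}]")
        idx = int(np.searchsorted(self.uppers[parameter], value, side="left"))
        return int(self.points[parameter][idx])


def load_chart(version: str = "news_2012") -> NewsChart:
    """Load a versioned NEWS chart shipped with the package."""
    ref = resources.files("edscore") / "charts" / f"{version}.yaml"
    spec = yaml.safe_load(ref.read_text(encoding="utf-8"))
    uppers, points = {}, {}
    for param, block in spec["parameters"].items():
        bands = block["bands"]
        uppers[param] = np.array(
            [b["upper"] for b in bands if b["upper"] is not None], dtype=float)
        points[param] = np.array([b["points"] for b in bands], dtype=int)
        if not np.all(np.diff(uppers[param]) > 0):
            raise ValueError(f"chart bands for {param} are not ordered")
    return NewsChart(
        version=spec["version"],
        uppers=uppers,
        points=points,
        supplemental_oxygen_points=int(spec["supplemental_oxygen_points"]),
        not_alert_points=int(spec["not_alert_points"]),
        room_air_fio2=float(spec["room_air_fio2"]),
        max_score=int(spec["max_score"]),
    )


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or pd.isna(x)


def compute_rox(spo2, fio2, rr) -> Optional[int]:
    """ROX index, rounded half-up: round(SpO2[%] / FiO2 / RR).

    Returns None (an explicit missing-result marker) when any input is
    missing; raises ValueError on out-of-domain inputs.
    """
    if _is_missing(spo2) or _is_missing(fio2) or _is_missing(rr):
        return None
    if not 0.0 < spo2 <= 100.0:
        raise ValueError(f"spo2={spo2} outside (0, 100]")
    if not 0.21 <= fio2 <= 1.0:
        raise ValueError(f"fio2={fio2} outside [0.21, 1.0]")
    if rr <= 0:
        raise ValueError(f"respiratory rate {rr} must be positive")
    return int(math.floor(spo2 / fio2 / rr + 0.5))


def compute_news(record, chart: Optional[NewsChart] = None) -> Optional[int]:
    """NEWS total for one record (mapping or Series of scoring inputs).

    Sums chart points over the five banded vitals, adds the supplemental
    oxygen points when FiO2 exceeds room air and the consciousness points
    when the patient is not alert. Returns None when any input is missing.
    """
    chart = chart or _default_chart()
    values = {k: record[k] for k in SCORING_INPUTS}
    if any(_is_missing(v) for v in values.values()):
        return None
    total = sum(
        chart.parameter_points(p, float(values[p]))
        for p in ("respiratory_rate", "spo2", "temperature", "sbp", "heart_rate")
    )
    if float(values["fio2"]) > chart.room_air_fio2:
        total += chart.supplemental_oxygen_points
    if not bool(values["alert"]):
        total += chart.not_alert_points
    return int(total)


_CHART_CACHE: dict = {}


def _default_chart() -> NewsChart:
    if "news_2012" not in _CHART_CACHE:
        _CHART_CACHE["news_2012"] = load_chart("news_2012")
    return _CHART_CACHE["news_2012"]


def rox_scores(df: pd.DataFrame) -> np.ndarray:
    """Vectorised ROX over a frame; NaN marks missing inputs.

    Out-of-domain non-missing inputs raise, as in :func:`compute_rox`.
    """
    spo2 = df["spo2"].to_numpy(dtype=float)
    fio2 = df["fio2"].to_numpy(dtype=float)
    rr = df["respiratory_rate"].to_numpy(dtype=float)
    ok = ~(np.isnan(spo2) | np.isnan(fio2) | np.isnan(rr))
    if np.any((spo2[ok] <= 0) | (spo2[ok] > 100)):
        raise ValueError("spo2 outside (0, 100]")
    if np.any((fio2[ok] < 0.21) | (fio2[ok] > 1.0)):
        raise ValueError("fio2 outside [0.21, 1.0]")
    if np.any(rr[ok] <= 0):
        raise ValueError("respiratory rate must be positive")
    out = np.full(len(df), np.nan)
    out[ok] = np.floor(spo2[ok] / fio2[ok] / rr[ok] + 0.5)
    return out


def news_scores(df: pd.DataFrame, chart: Optional[NewsChart] = None) -> np.ndarray:
    """Vectorised NEWS over a frame; NaN marks missing inputs."""
    chart = chart or _default_chart()
    n = len(df)
    cols = {k: df[k].to_numpy(dtype=float) for k in SCORING_INPUTS}
    ok = ~np.any([np.isnan(cols[k]) for k in SCORING_INPUTS], axis=0)
    total = np.zeros(n)
    for p in ("respiratory_rate", "spo2", "temperature", "sbp", "heart_rate"):
        v = cols[p]
        lo, hi = BOUNDS[p]
        if np.any((v[ok] < lo) | (v[ok] > hi)):
            raise ValueError(f"{p} outside chart coverage [{lo}, {hi}]")
        idx = np.searchsorted(chart.uppers[p], v, side="left")
        total += chart.points[p][np.clip(idx, 0, len(chart.points[p]) - 1)]
    total += np.where(cols["fio2"] > chart.room_air_fio2,
                      chart.supplemental_oxygen_points, 0)
    total += np.where(cols["alert"] < 0.5, chart.not_alert_points, 0)
    out = np.full(n, np.nan)
    out[ok] = total[ok]
    return out


def score_cohort(imputed, chart: Optional[NewsChart] = None) -> list:
    """Score every completed imputation set: one frame per set.

    Parameters
    ----------
    imputed : ImputedCohorts or sequence of DataFrames
        Completed cohorts; every scoring input must be non-missing.

    Returns
    -------
    list of DataFrame
        Per set: ``patient_id``, ``news``, ``rox`` (integer dtype). Scores
        differ across sets only where inputs were imputed.
    """
    chart = chart or _default_chart()
    sets: Sequence[pd.DataFrame] = getattr(imputed, "sets", imputed)
    out = []
    for k, df in enumerate(sets):
        for var in SCORING_INPUTS:
            bad = df[var].isna()
            if bad.any():
                pid = df.loc[bad.idxmax(), "patient_id"]
                raise ValueError(
                    f"imputation set {k}: patient {pid} missing {var}; "
                    "scoring requires complete inputs")
        news = news_scores(df, chart)
        rox = rox_scores(df)
        out.append(pd.DataFrame({
            "patient_id": df["patient_id"].to_numpy(),
            "news": news.astype(int),
            "rox": rox.astype(int),
        }))
    return out
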