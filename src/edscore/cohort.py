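"""Patient-level emergency-department cohort container and delimited-text I/O.

A cohort is one row per ED visit: demographics, the five classic vital signs,
FiO2 and alertness, two auxiliary labs used only to strengthen imputation
models, disposition, ICU admission, the 24-h death flag and the presentation
date. Any vital or auxiliary may be missing; missingness is carried as an
explicit boolean mask alongside the data so downstream stages can distinguish
"observed" from "filled in".
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: The five classic vital signs counted by the exclusion rule.
VITALS = ["sbp", "heart_rate", "respiratory_rate", "spo2", "temperature"]

#: Everything the scores need per patient.
SCORING_INPUTS = VITALS + ["fio2", "alert"]

#: Auxiliary predictors carried only to strengthen imputation models.
AUXILIARIES = ["urea", "leukocytes"]

#: Variables that may be missing (and are targets for imputation).
MASKABLE = VITALS + ["fio2", "alert"] + AUXILIARIES

COLUMNS = (
    ["patient_id", "age", "sex"]
    + VITALS
    + ["fio2", "alert"]
    + AUXILIARIES
    + ["icu_admission", "disposition", "died_24h", "presentation_date"]
)

#: Physiological validation bounds (inclusive) for numeric variables.
BOUNDS = {
    "age": (18.0, 110.0),
    "sbp": (40.0, 280.0),
    "heart_rate": (20.0, 250.0),
    "respiratory_rate": (4.0, 60.0),
    "spo2": (40.0, 100.0),
    "temperature": (30.0, 43.0),
    "fio2": (0.21, 1.0),
    "urea": (0.1, 100.0),
    "leukocytes": (0.1, 300.0),
}

_NUMERIC = ["age"] + VITALS + ["fio2"] + AUXILIARIES
_BOOLEAN = ["alert", "icu_admission", "died_24h"]


@dataclass
class Cohort:
    """An ordered collection of ED visits plus a missingness mask.

    Parameters
    ----------
    data : DataFrame
        One row per visit with the columns in :data:`COLUMNS`. Missing cells
        hold NaN. ``alert``, ``icu_admission`` and ``died_24h`` are 0/1 floats
        (``alert`` may be NaN), ``sex`` is ``"M"``/``"F"``, ``disposition`` is
        ``"admitted"``/``"discharged"``, ``presentation_date`` holds
        :class:`datetime.date`.
    mask : DataFrame, optional
        Boolean frame over :data:`MASKABLE` columns, True where missing.
        Derived from ``data`` if omitted.
    meta : dict
        Provenance: generator configuration echo, seeds, processing notes.
    complete : DataFrame, optional
        Pre-masking ground truth (synthetic cohorts only; never persisted).
    latent : ndarray, optional
        Latent severity per record (synthetic cohorts only; never persisted).
    """

    data: pd.DataFrame
    mask: Optional[pd.DataFrame] = None
    meta: dict = field(default_factory=dict)
    complete: Optional[pd.DataFrame] = None
    latent: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        missing_cols = [c for c in COLUMNS if c not in self.data.columns]
        if missing_cols:
            raise ValueError(f"cohort data lacks columns: {missing_cols}")
        self.data = self.data.reset_index(drop=True)
        if self.mask is None:
            self.mask = self.data[MASKABLE].isna()
        else:
            self.mask = self.mask.reset_index(drop=True)
            if list(self.mask.columns) != MASKABLE or len(self.mask) != len(self.data):
                raise ValueError("mask shape does not match records")
        if self.latent is not None:
            self.latent = np.asarray(self.latent, dtype=float)
            if len(self.latent) != len(self.data):
                raise ValueError("latent severity length does not match records")

    @property
    def n(self) -> int:
        return len(self.data)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, keep) -> "Cohort":
        """Row-subset by boolean or positional index, preserving mask/latent."""
        keep = np.asarray(keep)
        data = self.data.loc[keep].reset_index(drop=True)
        mask = self.mask.loc[keep].reset_index(drop=True)
        complete = None
        if self.complete is not None:
            complete = self.complete.loc[keep].reset_index(drop=True)
        latent = None
        if self.latent is not None:
            if keep.dtype == bool:
                latent = self.latent[keep]
            else:
                latent = self.latent[np.asarray(keep, dtype=int)]
        return Cohort(data=data, mask=mask, meta=dict(self.meta),
                      complete=complete, latent=latent)

    def copy(self) -> "Cohort":
        return Cohort(
            data=self.data.copy(),
            mask=self.mask.copy(),
            meta=dict(self.meta),
            complete=None if self.complete is None else self.complete.copy(),
            latent=None if self.latent is None else self.latent.copy(),
        )


def _format_number(x: float) -> str:
    if pd.isna(x):
        return ""
    return "%g" % x


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to RFC-4180 CSV (UTF-8, header row, empty cell = missing).

    Dates are ISO-8601, booleans 0/1. Numeric values are written with ``%g``
    so recording-precision values round-trip exactly; byte-identical output
    for identical cohorts.
    """
    df = cohort.data
    out = pd.DataFrame(index=df.index)
    out["patient_id"] = df["patient_id"].astype(str)
    out["age"] = df["age"].map(_format_number)
    out["sex"] = df["sex"].astype(str)
    for col in VITALS + ["fio2"]:
        out[col] = df[col].map(_format_number)
    out["alert"] = df["alert"].map(lambda x: "" if pd.isna(x) else str(int(x)))
    for col in AUXILIARIES:
        out[col] = df[col].map(_format_number)
    out["icu_admission"] = df["icu_admission"].map(lambda x: str(int(x)))
    out["disposition"] = df["disposition"].astype(str)
    out["died_24h"] = df["died_24h"].map(lambda x: str(int(x)))
    out["presentation_date"] = df["presentation_date"].map(
        lambda d: d.isoformat() if isinstance(d, (dt.date, dt.datetime)) else str(d)
    )
    out = out[COLUMNS]
    out.to_csv(path, index=False, lineterminator="\n")


def _parse_numeric(raw: pd.Series, col: str, errors: list) -> pd.Series:
    vals = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
    bad = vals.isna() & (raw != "")
    for i in raw.index[bad]:
        errors.append(f"row {i + 1}: malformed {col} value {raw[i]!r}")
    lo, hi = BOUNDS[col]
    oob = vals.notna() & ((vals < lo) | (vals > hi))
    for i in raw.index[oob]:
        errors.append(
            f"row {i + 1}: {col}={vals[i]:g} outside physiological bounds [{lo:g}, {hi:g}]"
        )
    return vals


def read_cohort(path) -> Cohort:
    """Read a cohort CSV, validating schema, types and physiological bounds.

    Raises :class:`ValueError` naming the offending row (1-based data-row
    index) on malformed or non-physiological values, unknown or missing
    columns. Empty cells become missing (masked) values.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in raw.columns if c not in COLUMNS]
    if unknown:
        raise ValueError(f"unknown columns: {unknown}")
    absent = [c for c in COLUMNS if c not in raw.columns]
    if absent:
        raise ValueError(f"missing columns: {absent}")

    errors: list[str] = []
    df = pd.DataFrame(index=raw.index)
    df["patient_id"] = raw["patient_id"]
    for col in _NUMERIC:
        df[col] = _parse_numeric(raw[col], col, errors)
    for col in _BOOLEAN:
        s = raw[col]
        vals = pd.Series(np.nan, index=raw.index, dtype=float)
        ok = s.isin(["0", "1"])
        vals[ok] = s[ok].astype(float)
        for i in raw.index[~ok & (s != "")]:
            errors.append(f"row {i + 1}: {col} must be 0/1, got {s[i]!r}")
        df[col] = vals
    for col, allowed in [("sex", {"M", "F"}), ("disposition", {"admitted", "discharged"})]:
        bad = ~raw[col].isin(allowed)
        for i in raw.index[bad]:
            errors.append(f"row {i + 1}: {col} must be one of {sorted(allowed)}, got {raw[col][i]!r}")
        df[col] = raw[col]

    dates = []
    for i, s in raw["presentation_date"].items():
        try:
            dates.append(dt.date.fromisoformat(s))
        except ValueError:
            errors.append(f"row {i + 1}: unparseable date {s!r}")
            dates.append(None)
    df["presentation_date"] = dates

    required = ["age", "icu_admission", "died_24h"]
    for col in required:
        miss = df[col].isna()
        for i in df.index[miss]:
            errors.append(f"row {i + 1}: {col} may not be missing")

    if errors:
        raise ValueError("cohort validation failed:\n" + "\n".join(errors[:50]))
    return Cohort(data=df[COLUMNS], meta={"source": str(path)})
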