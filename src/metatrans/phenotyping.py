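"""Phenotype classification from raw health check-up measurements.

Converts one subject-visit row of measurements into

* a weight category (Chinese BMI cut-offs: normal [18.5, 24), overweight
  [24, 28), obese [28, ∞); BMI < 18.5 is ineligible rather than a category),
* a metabolic status (unhealthy iff ≥ 2 of 4 revised NCEP ATP III criteria:
  elevated blood pressure, elevated glucose, raised triglycerides, low HDL-C;
  abdominal obesity is deliberately not a criterion),
* the six-state phenotype cross-defined from the two, and
* six dichotomised covariates (female, middle-aged > 45 y, and elevated
  ALT > 40 U/L, AST > 40 U/L, sex-specific SCr and UA).

All thresholds follow the check-up cohort's category definitions: metabolic
criteria use closed lower bounds (≥) except HDL-C, which is a strict <;
"elevated" marker covariates use strict > so the boundary value belongs to
the normal group.  Units are fixed: pressures mmHg, glucose/lipids mmol/L,
ALT/AST U/L, SCr/UA μmol/L.  ``convert_mgdl`` can translate mg/dL inputs
before classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import PhenotypeState

__all__ = [
    "UnderweightError",
    "IncompleteRecordError",
    "CheckupRecord",
    "CovariateVector",
    "COVARIATE_NAMES",
    "CHECKUP_COLUMNS",
    "classify_weight",
    "count_metabolic_criteria",
    "classify_metabolic",
    "classify_phenotype",
    "dichotomize_covariates",
    "classify_checkups",
    "read_checkups",
    "convert_mgdl",
]


class UnderweightError(ValueError):
    """BMI < 18.5 kg/m²: underweight subjects are ineligible, not a category."""


class IncompleteRecordError(ValueError):
    """A measurement required for classification is missing."""


#: Covariate order used everywhere (panel columns, design matrices, reports).
COVARIATE_NAMES = (
    "female",
    "middle_aged",
    "alt_elevated",
    "ast_elevated",
    "scr_elevated",
    "ua_elevated",
)

#: Canonical check-up CSV column order.
CHECKUP_COLUMNS = (
    "subject_id",
    "visit_time",
    "sex",
    "age",
    "bmi",
    "sbp",
    "dbp",
    "fpg",
    "pg2h",
    "tg",
    "hdl",
    "alt",
    "ast",
    "scr",
    "ua",
    "on_antihypertensive",
    "on_hypoglycemic",
    "excluded_disease_history",
)

_REQUIRED_FOR_METABOLIC = ("sex", "sbp", "dbp", "fpg", "tg", "hdl")
_REQUIRED_FOR_COVARIATES = ("sex", "age", "alt", "ast", "scr", "ua")

# Conversion factors mg/dL -> SI for the optional loader path.
_MGDL_FACTORS = {
    "fpg": 1 / 18.016,  # glucose -> mmol/L
    "pg2h": 1 / 18.016,
    "tg": 1 / 88.57,  # triglycerides -> mmol/L
    "hdl": 1 / 38.67,  # cholesterol -> mmol/L
    "scr": 88.42,  # creatinine -> μmol/L
}


@dataclass
class CheckupRecord:
    """One subject-visit row of raw measurements and flags."""

    subject_id: object
    visit_time: float
    sex: str
    age: float
    bmi: float
    sbp: float
    dbp: float
    fpg: float
    tg: float
    hdl: float
    alt: float
    ast: float
    scr: float
    ua: float
    pg2h: float | None = None
    on_antihypertensive: bool = False
    on_hypoglycemic: bool = False
    excluded_disease_history: bool = False


@dataclass(frozen=True)
class CovariateVector:
    """Six binary covariates; reference level 0 = male / young / normal."""

    female: int
    middle_aged: int
    alt_elevated: int
    ast_elevated: int
    scr_elevated: int
    ua_elevated: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in COVARIATE_NAMES], dtype=float)


def _missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


def _check_sex(sex) -> str:
    s = str(sex).strip().lower()
    if s in ("male", "m"):
        return "male"
    if s in ("female", "f"):
        return "female"
    raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")


def classify_weight(bmi: float) -> int:
    """Weight level from BMI: 0 normal [18.5, 24), 1 overweight [24, 28), 2 obese.

    Raises :class:`UnderweightError` for BMI < 18.5 (an eligibility matter)
    and ``ValueError`` for non-finite input.
    """
    bmi = float(bmi)
    if not math.isfinite(bmi):
        raise ValueError(f"BMI must be finite, got {bmi}")
    if bmi < 18.5:
        raise UnderweightError(f"BMI {bmi} < 18.5 kg/m² is underweight-ineligible")
    if bmi < 24.0:
        return 0
    if bmi < 28.0:
        return 1
    return 2


def count_metabolic_criteria(
    *,
    sex,
    sbp,
    dbp,
    fpg,
    tg,
    hdl,
    pg2h=None,
    on_antihypertensive=False,
    on_hypoglycemic=False,
    require_pg2h: bool = False,
) -> int:
    """Number of the four metabolic-syndrome criteria met (0–4).

    Criteria: (1) SBP ≥ 130 or DBP ≥ 85 or on antihypertensive medication;
    (2) FPG ≥ 5.6 mmol/L or 2hPG ≥ 7.8 mmol/L or on hypoglycemic medication;
    (3) TG ≥ 1.7 mmol/L; (4) HDL-C < 1.0 (male) / < 1.3 (female) mmol/L.

    An absent 2hPG simply does not contribute to criterion 2 unless
    ``require_pg2h`` is set, in which case the record is incomplete.
    """
    fields = dict(sex=sex, sbp=sbp, dbp=dbp, fpg=fpg, tg=tg, hdl=hdl)
    missing = [k for k, v in fields.items() if _missing(v)]
    if require_pg2h and _missing(pg2h):
        missing.append("pg2h")
    if missing:
        raise IncompleteRecordError(f"missing fields for metabolic status: {missing}")
    sex = _check_sex(sex)
    c1 = sbp >= 130.0 or dbp >= 85.0 or bool(on_antihypertensive)
    c2 = (
        fpg >= 5.6
        or (not _missing(pg2h) and pg2h >= 7.8)
        or bool(on_hypoglycemic)
    )
    c3 = tg >= 1.7
    c4 = hdl < (1.0 if sex == "male" else 1.3)
    return int(c1) + int(c2) + int(c3) + int(c4)


def classify_metabolic(**kwargs) -> int:
    """Metabolic level: 1 (unhealthy) iff ≥ 2 criteria met, else 0 (healthy)."""
    return int(count_metabolic_criteria(**kwargs) >= 2)


def classify_phenotype(weight_level: int, metabolic_level: int) -> PhenotypeState:
    """Bijective map from (weight_level, metabolic_level) to the six states."""
    return PhenotypeState(weight_level=int(weight_level), metabolic_level=int(metabolic_level))


def dichotomize_covariates(*, sex, age, alt, ast, scr, ua) -> CovariateVector:
    """Binary covariates with strict > cut-offs (boundary stays in the
    reference group): middle-aged iff age > 45 y; ALT/AST elevated > 40 U/L;
    SCr elevated > 133 (male) / 106 (female) μmol/L; UA elevated > 420 (male)
    / 360 (female) μmol/L."""
    fields = dict(sex=sex, age=age, alt=alt, ast=ast, scr=scr, ua=ua)
    missing = [k for k, v in fields.items() if _missing(v)]
    if missing:
        raise IncompleteRecordError(f"missing fields for covariates: {missing}")
    sex = _check_sex(sex)
    female = int(sex == "female")
    return CovariateVector(
        female=female,
        middle_aged=int(age > 45.0),
        alt_elevated=int(alt > 40.0),
        ast_elevated=int(ast > 40.0),
        scr_elevated=int(scr > (106.0 if female else 133.0)),
        ua_elevated=int(ua > (360.0 if female else 420.0)),
    )


def convert_mgdl(df: pd.DataFrame) -> pd.DataFrame:
    """Convert glucose/TG/HDL from mg/dL to mmol/L and SCr from mg/dL to μmol/L."""
    out = df.copy()
    for col, factor in _MGDL_FACTORS.items():
        if col in out.columns:
            out[col] = out[col] * factor
    return out


def _normalize_sex_series(sex: pd.Series) -> pd.Series:
    s = sex.astype(str).str.strip().str.lower()
    s = s.replace({"m": "male", "f": "female"})
    bad = ~s.isin(["male", "female"])
    if bad.any():
        raise ValueError(f"unrecognised sex values: {sorted(sex[bad].unique())}")
    return s


def _flag_series(df: pd.DataFrame, col: str) -> pd.Series:
    if col not in df.columns:
        return pd.Series(False, index=df.index)
    s = df[col]
    if s.dtype == bool:
        return s
    return (
        s.astype(str)
        .str.strip()
        .str.lower()
        .isin(["1", "true", "t", "yes", "y", "1.0"])
    )


def classify_checkups(
    df: pd.DataFrame,
    *,
    units: str = "si",
    require_pg2h: bool = False,
    on_underweight: str = "raise",
) -> pd.DataFrame:
    """Vectorised classification of a check-up table.

    Returns a copy of ``df`` augmented with ``weight_level``,
    ``metabolic_level``, ``phenotype`` (label), ``state`` (1-based index) and
    the six binary covariate columns.

    ``on_underweight``: "raise" (default) or "drop" rows with BMI < 18.5 —
    normally the eligibility filter runs first so none remain.
    """
    if units not in ("si", "mgdl"):
        raise ValueError("units must be 'si' or 'mgdl'")
    out = df.copy()
    if units == "mgdl":
        out = convert_mgdl(out)

    required = set(_REQUIRED_FOR_METABOLIC) | set(_REQUIRED_FOR_COVARIATES) | {"bmi"}
    missing_cols = sorted(required - set(out.columns))
    if missing_cols:
        raise IncompleteRecordError(f"missing required columns: {missing_cols}")
    numeric = ["bmi", "sbp", "dbp", "fpg", "tg", "hdl", "age", "alt", "ast", "scr", "ua"]
    na = out[numeric].isna()
    if na.any().any():
        bad = sorted(na.any()[na.any()].index)
        raise IncompleteRecordError(f"missing values in required columns: {bad}")

    bmi = out["bmi"].to_numpy(dtype=float)
    if not np.isfinite(bmi).all():
        raise ValueError("non-finite BMI values present")
    under = bmi < 18.5
    if under.any():
        if on_underweight == "raise":
            raise UnderweightError(
                f"{int(under.sum())} records with BMI < 18.5 kg/m² (underweight-ineligible)"
            )
        out = out.loc[~under].copy()
        bmi = out["bmi"].to_numpy(dtype=float)

    sex = _normalize_sex_series(out["sex"])
    female = (sex == "female").to_numpy()

    weight = np.select([bmi < 24.0, bmi < 28.0], [0, 1], default=2)

    pg2h = (
        out["pg2h"].to_numpy(dtype=float)
        if "pg2h" in out.columns
        else np.full(len(out), np.nan)
    )
    if require_pg2h and np.isnan(pg2h).any():
        raise IncompleteRecordError("pg2h required but missing for some records")
    antihyp = _flag_series(out, "on_antihypertensive").to_numpy()
    hypogly = _flag_series(out, "on_hypoglycemic").to_numpy()

    c1 = (out["sbp"].to_numpy(float) >= 130.0) | (out["dbp"].to_numpy(float) >= 85.0) | antihyp
    with np.errstate(invalid="ignore"):
        pg2h_hit = np.nan_to_num(pg2h, nan=-np.inf) >= 7.8
    c2 = (out["fpg"].to_numpy(float) >= 5.6) | pg2h_hit | hypogly
    c3 = out["tg"].to_numpy(float) >= 1.7
    c4 = out["hdl"].to_numpy(float) < np.where(female, 1.3, 1.0)
    metabolic = ((c1.astype(int) + c2 + c3 + c4) >= 2).astype(int)

    out["weight_level"] = weight
    out["metabolic_level"] = metabolic
    state = metabolic * 3 + weight + 1
    out["state"] = state
    out["phenotype"] = np.array(
        [PhenotypeState.from_index(i).label for i in range(1, 7)]
    )[state - 1]

    out["female"] = female.astype(int)
    out["middle_aged"] = (out["age"].to_numpy(float) > 45.0).astype(int)
    out["alt_elevated"] = (out["alt"].to_numpy(float) > 40.0).astype(int)
    out["ast_elevated"] = (out["ast"].to_numpy(float) > 40.0).astype(int)
    out["scr_elevated"] = (
        out["scr"].to_numpy(float) > np.where(female, 106.0, 133.0)
    ).astype(int)
    out["ua_elevated"] = (
        out["ua"].to_numpy(float) > np.where(female, 360.0, 420.0)
    ).astype(int)
    return out


def read_checkups(
    path,
    *,
    column_map: dict | None = None,
    units: str = "si",
) -> pd.DataFrame:
    """Read a check-up CSV, applying an optional {file column -> canonical}
    rename and an optional mg/dL conversion."""
    df = pd.read_csv(path)
    if column_map:
        unknown = sorted(set(column_map) - set(df.columns))
        if unknown:
            raise KeyError(f"column_map refers to absent columns: {unknown}")
        df = df.rename(columns=column_map)
    if units == "mgdl":
        df = convert_mgdl(df)
    elif units != "si":
        raise ValueError("units must be 'si' or 'mgdl'")
    return df
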