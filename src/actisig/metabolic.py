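"""Metabolic risk indices, age/sex adjustment, and the composite health score.

Derived indices: BMI, waist:height, TC:HDL, Friedewald LDL, and HOMA insulin
resistance. Outcomes are residualized on age and sex by ordinary least
squares; the composite score averages six standardized residuals (systolic
blood pressure, triglycerides, TC:HDL, HOMA, waist:height, and the reversed
aerobic-fitness test) and is rescaled to unit SD, so higher values mean worse
metabolic health.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateInputError",
    "PMOL_PER_MU",
    "PANEL_COLUMNS",
    "COMPOSITE_OUTCOMES",
    "validate_panel",
    "derive_indices",
    "residualize",
    "adjust_outcomes",
    "composite_score",
    "read_panel_csv",
    "write_outcomes_csv",
]

#: Insulin conversion factor, pmol/L per mU/L.
PMOL_PER_MU = 6.945

#: HOMA denominator in conventional units (glucose mmol/L x insulin mU/L).
HOMA_DENOM = 22.5

#: Friedewald divisor for triglycerides in mmol/L.
FRIEDEWALD_DIVISOR = 2.2

PANEL_COLUMNS = (
    "subject_id", "sex", "age", "body_mass", "height", "waist",
    "sbp", "dbp", "tc", "hdl", "tg", "glucose", "insulin", "andersen_distance",
)

#: The six outcomes entering the composite; the fitness test is reversed.
COMPOSITE_OUTCOMES = ("sbp", "tg", "tc_hdl", "homa", "wc_height", "andersen_distance")
REVERSED_OUTCOMES = ("andersen_distance",)


class DegenerateInputError(ValueError):
    """Raised for inputs that make an estimate undefined (zero variance, etc.)."""


_POSITIVE_FIELDS = (
    "body_mass", "height", "waist", "sbp", "dbp",
    "tc", "hdl", "tg", "glucose", "insulin", "andersen_distance",
)


def validate_panel(panel: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a panel into (valid, excluded) records.

    A record is excluded if any required field is missing, any physiological
    quantity is non-positive, or HDL >= TC. Complete-case analysis downstream.
    """
    required = [c for c in PANEL_COLUMNS if c in panel.columns or c != "dbp"]
    missing_cols = set(required) - set(panel.columns)
    if missing_cols:
        raise ValueError(f"panel missing columns: {sorted(missing_cols)}")
    ok = panel[required].notna().all(axis=1)
    for col in _POSITIVE_FIELDS:
        if col in panel.columns:
            ok &= panel[col].fillna(-1.0) > 0
    ok &= panel["hdl"] < panel["tc"]
    return panel.loc[ok].copy(), panel.loc[~ok].copy()


def derive_indices(
    panel: pd.DataFrame,
    homa_mode: str = "pmol_to_mu",
    friedewald_tg_max: float = 4.5,
) -> pd.DataFrame:
    """Append bmi, wc_height, tc_hdl, ldl, and homa columns to a valid panel.

    ``homa_mode`` controls insulin units: ``"pmol_to_mu"`` (default) divides
    pmol/L insulin by 6.945 before the conventional glucose*insulin/22.5
    formula; ``"literal"`` plugs pmol/L in directly. LDL is set to NaN when
    triglycerides exceed the Friedewald validity bound.
    """
    if homa_mode not in ("pmol_to_mu", "literal"):
        raise ValueError(f"unknown homa_mode: {homa_mode!r}")
    bad = (
        (panel["height"] <= 0)
        | (panel["hdl"] <= 0)
        | (panel["glucose"] <= 0)
        | (panel["insulin"] <= 0)
    )
    if bad.any():
        raise DegenerateInputError(
            f"{int(bad.sum())} records with non-positive denominators; "
            "run validate_panel first"
        )
    out = panel.copy()
    height_m = out["height"] / 100.0
    out["bmi"] = out["body_mass"] / height_m**2
    out["wc_height"] = out["waist"] / out["height"]
    out["tc_hdl"] = out["tc"] / out["hdl"]
    ldl = out["tc"] - out["hdl"] - out["tg"] / FRIEDEWALD_DIVISOR
    out["ldl"] = ldl.where(out["tg"] <= friedewald_tg_max)
    insulin_mu = out["insulin"] / PMOL_PER_MU if homa_mode == "pmol_to_mu" else out["insulin"]
    out["homa"] = out["glucose"] * insulin_mu / HOMA_DENOM
    return out


def residualize(
    outcome: np.ndarray, age: np.ndarray, sex: np.ndarray | None
) -> np.ndarray:
    """Residuals of ``outcome`` after OLS on intercept + age + sex.

    ``sex=None`` adjusts for age only (used within single-sex strata).
    """
    y = np.asarray(outcome, dtype=float)
    age = np.asarray(age, dtype=float)
    cols = [np.ones(len(y)), age]
    if sex is not None:
        cols.append(np.asarray(sex, dtype=float))
    n = len(y)
    if n <= 3:
        raise DegenerateInputError("need n > 3 for age/sex adjustment")
    design = np.column_stack(cols)
    if np.isnan(y).any() or np.isnan(design).any():
        raise DegenerateInputError("missing values in adjustment inputs")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateInputError("rank-deficient age/sex design")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def adjust_outcomes(
    panel: pd.DataFrame,
    outcomes: Sequence[str] = COMPOSITE_OUTCOMES,
) -> pd.DataFrame:
    """Residualize each outcome column on age and sex; returns a residual frame."""
    age = panel["age"].to_numpy(dtype=float)
    sex = pd.factorize(panel["sex"], sort=True)[0].astype(float)
    if len(np.unique(sex)) < 2:  # single-sex stratum: adjust for age only
        sex = None
    data = {
        name: residualize(panel[name].to_numpy(dtype=float), age, sex)
        for name in outcomes
    }
    return pd.DataFrame(data, index=panel.index)


def composite_score(
    adjusted: pd.DataFrame,
    reverse: Sequence[str] = REVERSED_OUTCOMES,
    restandardize: bool = True,
) -> np.ndarray:
    """Mean of standardized residuals (fitness reversed), rescaled to SD 1.

    Higher scores mean worse metabolic health.
    """
    missing = set(COMPOSITE_OUTCOMES) - set(adjusted.columns)
    if missing:
        raise ValueError(f"adjusted outcomes missing: {sorted(missing)}")
    z_cols = []
    for name in COMPOSITE_OUTCOMES:
        v = adjusted[name].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if sd == 0:
            raise DegenerateInputError(f"zero-variance residual: {name}")
        z = (v - v.mean()) / sd
        if name in reverse:
            z = -z
        z_cols.append(z)
    comp = np.mean(z_cols, axis=0)
    if restandardize:
        sd = comp.std(ddof=1)
        if sd == 0:
            raise DegenerateInputError("composite has zero variance")
        comp = comp / sd
    return comp


def read_panel_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_outcomes_csv(
    panel: pd.DataFrame,
    adjusted: pd.DataFrame,
    composite: np.ndarray,
    path: str | Path,
) -> None:
    out = panel.copy()
    for name in adjusted.columns:
        out[f"{name}_adj"] = adjusted[name]
    out["composite"] = composite
    out.to_csv(path, index=False)
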