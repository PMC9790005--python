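"""Social class coding, analytic-sample filters and mobility dummies.

Occupational class (NS-SEC collapsed to three ordered levels) is coded
disadvantaged(1) < intermediate(2) < advantaged(3).  Origin is the class
of the household at age 14 (most advantaged parent); destination is the
adult household's most advantaged class.  Social mobility is the change
between origin and destination, encoded under four nested schemes used
as model covariates:

=========  ==========================================================
scheme     dummy columns
=========  ==========================================================
none       (no mobility variables)
any        mobile
direction  downward, upward
steps      down1, down2, up1, up2  (one/two class steps by direction)
=========  ==========================================================
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

CLASS_LEVELS = ["disadvantaged", "intermediate", "advantaged"]
CLASS_RANK = {c: i + 1 for i, c in enumerate(CLASS_LEVELS)}

SCHEMES = ("none", "any", "direction", "steps")
SCHEME_COLUMNS = {
    "none": [],
    "any": ["mobile"],
    "direction": ["downward", "upward"],
    "steps": ["down1", "down2", "up1", "up2"],
}


def as_class_code(values) -> pd.Categorical:
    """Coerce to the ordered three-level class categorical.

    Unrecognized labels become missing with a warning.
    """
    cat = pd.Categorical(values, categories=CLASS_LEVELS, ordered=True)
    n_bad = int(pd.isna(cat).sum() - pd.isna(pd.Series(values)).sum())
    if n_bad > 0:
        logger.warning("%d class labels outside %s coerced to missing", n_bad, CLASS_LEVELS)
    return cat


def household_max_class(member_classes) -> str | None:
    """Most advantaged class among available household members.

    Missing entries (None/NaN) are ignored; with a single available
    member that member's class is returned; with none, ``None``.
    """
    available = [c for c in member_classes if isinstance(c, str) and c in CLASS_RANK]
    if not available:
        return None
    return max(available, key=CLASS_RANK.__getitem__)


def filter_analytic_sample(
    cohort: pd.DataFrame,
    min_age: float = 25,
    required: tuple[str, ...] = ("origin", "destination", "sex", "age"),
) -> pd.DataFrame:
    """Drop under-age rows and rows with missing key variables.

    Participants below ``min_age`` (default 25) are excluded as unlikely
    to have reached occupational maturity; rows missing any of the
    ``required`` columns are dropped.  Counts removed per reason are
    logged and attached as ``result.attrs["exclusions"]``.
    """
    df = cohort.copy()
    exclusions: dict[str, int] = {"input": len(df)}
    for col in required:
        if col not in df.columns:
            raise ValidationError(f"cohort lacks required column {col!r}")
        n_before = len(df)
        df = df[df[col].notna()]
        exclusions[f"missing_{col}"] = n_before - len(df)
    n_before = len(df)
    df = df[df["age"] >= min_age]
    exclusions[f"age_below_{min_age}"] = n_before - len(df)
    exclusions["analytic_n"] = len(df)
    for reason, n in exclusions.items():
        logger.info("analytic sample: %s = %d", reason, n)
    if len(df) == 0:
        raise ValidationError("analytic sample is empty after filtering")
    df = df.reset_index(drop=True)
    df.attrs["exclusions"] = exclusions
    return df


def encode_mobility(origin: str, destination: str, scheme: str = "steps") -> dict[str, int]:
    """Mobility dummies for one origin/destination pair under a scheme."""
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown mobility scheme {scheme!r}; expected one of {SCHEMES}")
    for c in (origin, destination):
        if c not in CLASS_RANK:
            raise ValidationError(f"unknown class label {c!r}")
    step = CLASS_RANK[destination] - CLASS_RANK[origin]
    full = {
        "mobile": int(step != 0),
        "upward": int(step > 0),
        "downward": int(step < 0),
        "up1": int(step == 1),
        "up2": int(step == 2),
        "down1": int(step == -1),
        "down2": int(step == -2),
    }
    return {k: full[k] for k in SCHEME_COLUMNS[scheme]}


def add_mobility_columns(cohort: pd.DataFrame, scheme: str = "steps") -> pd.DataFrame:
    """Vectorized `encode_mobility` over a cohort table."""
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown mobility scheme {scheme!r}; expected one of {SCHEMES}")
    df = cohort.copy()
    step = df["destination"].map(CLASS_RANK) - df["origin"].map(CLASS_RANK)
    values = {
        "mobile": (step != 0),
        "upward": (step > 0),
        "downward": (step < 0),
        "up1": (step == 1),
        "up2": (step == 2),
        "down1": (step == -1),
        "down2": (step == -2),
    }
    for col in SCHEME_COLUMNS[scheme]:
        df[col] = values[col].astype(int)
    return df


def standardize_covariates(cohort: pd.DataFrame, age_col: str = "age") -> pd.DataFrame:
    """Add z-scored age and its square (squared after standardizing).

    Standardization uses the sample mean and n-1 standard deviation over
    the rows supplied, so it must be applied to the analytic sample (or
    stratum) actually modelled.  Also adds a 0/1 ``female`` dummy when a
    ``sex`` column is present.
    """
    df = cohort.copy()
    ages = df[age_col].astype(float)
    if ages.nunique() < 2:
        raise ValidationError("cannot standardize age: fewer than two distinct values")
    sd = ages.std(ddof=1)
    if sd == 0:
        raise ValidationError("cannot standardize age: zero standard deviation")
    df["z_age"] = (ages - ages.mean()) / sd
    df["z_age_sq"] = df["z_age"] ** 2
    if "sex" in df.columns:
        df["female"] = (df["sex"] == "female").astype(int)
    return df


def stratify_by_birth_year(
    cohort: pd.DataFrame, cut_year: int = 1956, young_includes_cut: bool = True
) -> dict[str, pd.DataFrame]:
    """Split a cohort into birth-cohort strata around ``cut_year``.

    By default the "young" stratum is ``birth_year >= cut_year``;
    covariates must be re-standardized within each stratum before
    modelling.
    """
    if young_includes_cut:
        young = cohort["birth_year"] >= cut_year
    else:
        young = cohort["birth_year"] > cut_year
    return {
        "old": cohort[~young].reset_index(drop=True),
        "young": cohort[young].reset_index(drop=True),
    }
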