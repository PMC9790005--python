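"""Descriptive surfaces: cross-tabs, group tests, restricted OLS contrasts.

These reproduce the descriptive layer of a mobility analysis: the 3x3
origin-by-destination cross-tabulation of mean age acceleration with
count-weighted marginals, t-test/ANOVA screening of outcome differences
across participant characteristics, and the two restricted OLS
comparisons (downward mobile vs stably advantaged; upward mobile vs
stably disadvantaged).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ValidationError
from .mobility import CLASS_LEVELS


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention of printed tables."""
    if np.isnan(x):
        return np.nan
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CrossTab:
    """3x3 origin-by-destination cell means with weighted marginals."""

    outcome_label: str
    cell_means: pd.DataFrame  # origin rows x destination columns, NaN where empty
    cell_ns: pd.DataFrame
    row_totals: pd.Series
    col_totals: pd.Series
    grand: float

    @property
    def n(self) -> int:
        return int(self.cell_ns.to_numpy().sum())

    def to_frame(self, ndigits: int | None = None) -> pd.DataFrame:
        """Means plus marginals as one table; optionally display-rounded."""
        tab = self.cell_means.copy()
        tab["Total"] = self.row_totals
        total_row = pd.concat([self.col_totals, pd.Series({"Total": self.grand})])
        tab.loc["Total"] = total_row
        if ndigits is not None:
            tab = tab.map(lambda v: round_half_away(v, ndigits))
        return tab


def marginal_from_cells(
    cell_means: pd.DataFrame, cell_ns: pd.DataFrame
) -> tuple[pd.Series, pd.Series, float]:
    """Count-weighted row totals, column totals and grand mean.

    Marginals are computed at full precision; display rounding is left
    to the caller (see :func:`round_half_away`).
    """
    means = cell_means.to_numpy(float)
    ns = cell_ns.to_numpy(float)
    if (ns < 0).any():
        raise ValidationError("negative cell counts")
    if np.any((ns > 0) & np.isnan(means)):
        raise ValidationError("cell with positive count but missing mean")
    w = np.where(ns > 0, means, 0.0) * ns
    with np.errstate(invalid="ignore"):
        row = w.sum(axis=1) / ns.sum(axis=1)
        col = w.sum(axis=0) / ns.sum(axis=0)
        grand = w.sum() / ns.sum()
    return (
        pd.Series(row, index=cell_means.index),
        pd.Series(col, index=cell_means.columns),
        float(grand),
    )


def crosstab_means(
    cohort: pd.DataFrame, outcome: str, outcome_label: str | None = None
) -> CrossTab:
    """Per-cell arithmetic means of an outcome by origin x destination."""
    if cohort[outcome].isna().any():
        raise ValidationError(f"missing values in outcome {outcome!r}")
    grouped = cohort.groupby(["origin", "destination"], observed=False)[outcome]
    means = grouped.mean().unstack().reindex(index=CLASS_LEVELS, columns=CLASS_LEVELS)
    ns = (
        grouped.size()
        .unstack()
        .reindex(index=CLASS_LEVELS, columns=CLASS_LEVELS)
        .fillna(0)
        .astype(int)
    )
    row, col, grand = marginal_from_cells(means, ns)
    return CrossTab(
        outcome_label=outcome_label or outcome,
        cell_means=means,
        cell_ns=ns,
        row_totals=row,
        col_totals=col,
        grand=grand,
    )


def group_tests(outcome: pd.Series, grouping: pd.Series) -> dict:
    """Screen an outcome against a categorical characteristic.

    Two groups: classical pooled-variance two-sample t-test.  More than
    two: one-way ANOVA F-test.  Returns the statistic, p-value and
    per-group summaries.
    """
    df = pd.DataFrame({"y": outcome, "g": grouping}).dropna()
    groups = [g["y"].to_numpy(float) for _, g in df.groupby("g", observed=True)]
    labels = [k for k, _ in df.groupby("g", observed=True)]
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValidationError("every group needs at least two observations")
    summary = pd.DataFrame(
        {
            "n": [len(g) for g in groups],
            "mean": [g.mean() for g in groups],
            "sd": [g.std(ddof=1) for g in groups],
        },
        index=labels,
    )
    if len(groups) == 2:
        stat, p = stats.ttest_ind(groups[0], groups[1], equal_var=True)
        test = "t"
    else:
        stat, p = stats.f_oneway(*groups)
        test = "F"
    return {"test": test, "statistic": float(stat), "p_value": float(p), "groups": summary}


_COMPARISONS = {
    "down_vs_stable_advantaged": {
        "exposed": lambda df: (df["_rank_dest"] < df["_rank_orig"]),
        "reference": lambda df: (df["origin"] == "advantaged") & (df["destination"] == "advantaged"),
    },
    "up_vs_stable_disadvantaged": {
        "exposed": lambda df: (df["_rank_dest"] > df["_rank_orig"]),
        "reference": lambda df: (df["origin"] == "disadvantaged")
        & (df["destination"] == "disadvantaged"),
    },
}


def restricted_mobility_ols(
    cohort: pd.DataFrame,
    outcome: str,
    comparison: str,
    covariates: tuple[str, ...] = ("female", "z_age", "z_age_sq"),
) -> dict:
    """Mobile-vs-immobile OLS contrast on a restricted subsample.

    ``comparison`` is ``down_vs_stable_advantaged`` (downward mobile vs
    immobile advantaged) or ``up_vs_stable_disadvantaged`` (upward
    mobile vs immobile disadvantaged).  The sample is restricted to the
    two groups and the outcome regressed on the group indicator plus the
    covariates; the indicator coefficient with its Wald 95% CI is the
    contrast of interest.
    """
    if comparison not in _COMPARISONS:
        raise ValidationError(
            f"unknown comparison {comparison!r}; expected one of {sorted(_COMPARISONS)}"
        )
    rank = {c: i for i, c in enumerate(CLASS_LEVELS)}
    df = cohort.copy()
    df["_rank_orig"] = df["origin"].map(rank)
    df["_rank_dest"] = df["destination"].map(rank)
    spec = _COMPARISONS[comparison]
    exposed, reference = spec["exposed"](df), spec["reference"](df)
    if exposed.sum() == 0 or reference.sum() == 0:
        raise ValidationError(
            f"comparison {comparison}: empty group "
            f"(exposed n={int(exposed.sum())}, reference n={int(reference.sum())})"
        )
    sub = df[exposed | reference].copy()
    sub["mobile_group"] = exposed[exposed | reference].astype(int)
    X = sm.add_constant(sub[["mobile_group", *covariates]].astype(float))
    fit = sm.OLS(sub[outcome].to_numpy(float), X).fit()
    lo, hi = fit.conf_int().loc["mobile_group"]
    return {
        "comparison": comparison,
        "coefficient": float(fit.params["mobile_group"]),
        "conf_int": (float(lo), float(hi)),
        "se": float(fit.bse["mobile_group"]),
        "p_value": float(fit.pvalues["mobile_group"]),
        "n_exposed": int(exposed.sum()),
        "n_reference": int(reference.sum()),
        "results": fit,
    }
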