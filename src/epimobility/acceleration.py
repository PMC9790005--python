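"""Age-acceleration residuals.

Age acceleration for a clock is the residual of an ordinary least
squares regression of DNAm age on chronological age, optionally
adjusting for plate batch (categorical, first level as reference) and
estimated white-blood-cell fractions.  A positive residual means the
sample is epigenetically "older" than expected from its chronological
age.  Residuals from an OLS fit with an intercept have mean zero over
the fitted sample and are orthogonal to every regressor, so they should
be recomputed after any sample exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cells import CellFractions
from .errors import RankError, ValidationError


@dataclass(frozen=True)
class AccelerationResult:
    """Residual age acceleration for one clock.

    ``acceleration`` is in the clock's own units (years for age-scale
    clocks, pace units for pace-of-aging predictors).
    """

    clock_name: str
    sample_ids: pd.Index
    dnam_age: np.ndarray
    acceleration: np.ndarray
    coefficients: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "clock": self.clock_name,
                "dnam_age": self.dnam_age,
                "acceleration": self.acceleration,
            }
        )


def _find_aliased(X: pd.DataFrame) -> list[str]:
    """Columns that do not increase the rank when added left to right."""
    aliased: list[str] = []
    acc = np.empty((len(X), 0))
    for col in X.columns:
        cand = np.column_stack([acc, X[col].to_numpy(float)])
        if np.linalg.matrix_rank(cand) == acc.shape[1]:
            aliased.append(str(col))
        else:
            acc = cand
    return aliased


def build_adjustment_design(
    chron_age: np.ndarray,
    plate: pd.Series | None = None,
    cells: CellFractions | None = None,
) -> pd.DataFrame:
    """Design matrix [1, age, plate dummies, cell fractions]."""
    X = pd.DataFrame({"const": np.ones(len(chron_age)), "chron_age": np.asarray(chron_age, float)})
    if plate is not None:
        dummies = pd.get_dummies(pd.Categorical(plate), prefix="plate", drop_first=True, dtype=float)
        X = pd.concat([X.reset_index(drop=True), dummies.reset_index(drop=True)], axis=1)
    if cells is not None:
        frac = cells.to_frame().reset_index(drop=True)
        frac.columns = [f"cell_{c}" for c in frac.columns]
        X = pd.concat([X.reset_index(drop=True), frac], axis=1)
    return X


def residualize_age(
    dnam_age: np.ndarray,
    chron_age: np.ndarray,
    plate: pd.Series | None = None,
    cells: CellFractions | None = None,
    sample_ids: pd.Index | None = None,
    clock_name: str = "clock",
) -> AccelerationResult:
    """OLS residuals of DNAm age on chronological age and adjustments.

    Raises
    ------
    ValidationError
        On missing values among the regressors or fewer than two distinct
        ages.
    RankError
        On a singular design (e.g. a plate level with a single sample
        aliased with a cell-fraction column), naming the aliased terms.
    """
    y = np.asarray(dnam_age, float)
    age = np.asarray(chron_age, float)
    if sample_ids is None:
        sample_ids = pd.RangeIndex(len(y)).astype(str)
    if np.isnan(y).any() or np.isnan(age).any():
        raise ValidationError("missing values among DNAm age or chronological age")
    if np.unique(age).size < 2:
        raise ValidationError("need at least two distinct chronological ages")
    X = build_adjustment_design(age, plate=plate, cells=cells)
    if X.isna().any().any():
        raise ValidationError("missing values among adjustment regressors")
    if np.linalg.matrix_rank(X.to_numpy(float)) < X.shape[1]:
        aliased = _find_aliased(X)
        raise RankError(f"singular adjustment design; aliased terms: {aliased}", aliased=aliased)
    fit = sm.OLS(y, X.to_numpy(float)).fit()
    resid = y - fit.fittedvalues
    return AccelerationResult(
        clock_name=clock_name,
        sample_ids=pd.Index(sample_ids),
        dnam_age=y,
        acceleration=resid,
        coefficients=pd.Series(fit.params, index=X.columns),
    )
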