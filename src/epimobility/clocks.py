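"""Linear DNA-methylation age predictors ("epigenetic clocks").

A clock is a named linear function of methylation beta values at a fixed
set of CpG probes:

    DNAm age_j = intercept + sum_i beta_ij * coef_i

evaluated per sample j over the clock's m probes.  Probes named by the
clock but absent from the supplied beta matrix are dropped from the sum
without rescaling or imputation, and the number dropped is reported so
that array-version mismatches (e.g. probes missing from a newer chip)
stay visible.  Missing beta values (NA) for a present probe are dropped
for that sample only, mirroring the probe-absence policy at sample
granularity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Reserved probe label marking the intercept row of a clock file.
INTERCEPT_LABEL = "(Intercept)"


@dataclass(frozen=True)
class ClockDefinition:
    """A named linear DNAm-age predictor: intercept plus per-probe weights.

    Units of the prediction are whatever the clock was trained in — years
    for age-scale clocks, pace units for pace-of-aging predictors.
    """

    name: str
    intercept: float
    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.intercept):
            raise ValidationError(f"clock {self.name!r}: intercept is not finite")
        bad = [p for p, c in self.coefficients.items() if not np.isfinite(c)]
        if bad:
            raise ValidationError(
                f"clock {self.name!r}: non-finite coefficients for probes {bad[:5]}"
            )

    @property
    def m(self) -> int:
        """Number of probes in the clock."""
        return len(self.coefficients)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.coefficients)


@dataclass(frozen=True)
class BetaMatrix:
    """Methylation fractions, probes x samples, values in [0, 1] or NaN."""

    probe_ids: pd.Index
    sample_ids: pd.Index
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"beta matrix shape {self.values.shape} inconsistent with "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if self.probe_ids.has_duplicates:
            raise ValidationError("duplicate probe IDs in beta matrix")
        if self.sample_ids.has_duplicates:
            raise ValidationError("duplicate sample IDs in beta matrix")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "BetaMatrix":
        """Build from a probes-as-rows, samples-as-columns DataFrame."""
        return cls(
            probe_ids=pd.Index(frame.index.astype(str)),
            sample_ids=pd.Index(frame.columns.astype(str)),
            values=frame.to_numpy(dtype=float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def validate_range(self, on_invalid: str = "error") -> None:
        """Check every non-missing value lies in [0, 1].

        ``on_invalid`` is ``"error"`` (raise) or ``"warn"`` (log and
        continue); values are never silently modified.
        """
        with np.errstate(invalid="ignore"):
            bad = (self.values < 0) | (self.values > 1)
        n_bad = int(np.nansum(bad))
        if n_bad:
            msg = f"{n_bad} beta values outside [0, 1]"
            if on_invalid == "error":
                raise ValidationError(msg)
            logger.warning(msg)


@dataclass(frozen=True)
class ClockResult:
    """Per-sample DNAm age for one clock, plus missing-probe accounting."""

    clock_name: str
    sample_ids: pd.Index
    dnam_age: np.ndarray
    probes_used: int
    probes_missing: int
    missing_probe_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "clock": self.clock_name, "dnam_age": self.dnam_age}
        )


def load_clock_definition(
    path,
    name: str | None = None,
    intercept_label: str = INTERCEPT_LABEL,
) -> ClockDefinition:
    """Read a clock from two-column delimited text (probe, coefficient).

    The delimiter is auto-detected among comma and tab.  Exactly one row
    must carry the reserved intercept label.
    """
    try:
        table = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:  # noqa: BLE001 - rewrap as format error
        raise FormatError(f"cannot parse clock file {path}: {exc}") from exc
    if table.shape[1] < 2:
        raise FormatError(f"clock file {path}: expected two columns (probe, coefficient)")
    probes = table.iloc[:, 0].astype(str)
    coefs = pd.to_numeric(table.iloc[:, 1], errors="coerce")
    if coefs.isna().any():
        bad = probes[coefs.isna()].tolist()
        raise FormatError(f"clock file {path}: non-numeric coefficient for {bad[:5]}")
    dup = probes[probes.duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"clock file {path}: duplicate probe rows {dup[:5]}")
    is_intercept = probes == intercept_label
    n_int = int(is_intercept.sum())
    if n_int != 1:
        raise FormatError(
            f"clock file {path}: expected exactly one {intercept_label!r} row, found {n_int}"
        )
    intercept = float(coefs[is_intercept].iloc[0])
    coefficients = dict(zip(probes[~is_intercept], coefs[~is_intercept].astype(float)))
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(path)))[0]
    return ClockDefinition(name=name, intercept=intercept, coefficients=coefficients)


def save_clock_definition(clock: ClockDefinition, path, intercept_label: str = INTERCEPT_LABEL) -> None:
    """Write a clock as two-column CSV with an intercept row."""
    rows = [(intercept_label, clock.intercept)] + list(clock.coefficients.items())
    pd.DataFrame(rows, columns=["probe", "coefficient"]).to_csv(path, index=False)


def load_beta_matrix(path) -> BetaMatrix:
    """Read a beta matrix from delimited text (first column probe ID).

    ``.gz`` paths are decompressed transparently by pandas.
    """
    frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return BetaMatrix.from_dataframe(frame)


def compute_dnam_age(
    betas: BetaMatrix,
    clock: ClockDefinition,
    on_invalid: str = "error",
) -> ClockResult:
    """Evaluate a clock on a beta matrix.

    For each sample j the predictor is the clock intercept plus the sum,
    over clock probes present in the matrix, of ``beta_ij * coef_i``.
    Clock probes absent from the matrix are excluded from the sum with no
    rescaling; NaN betas drop the corresponding term for that sample only.

    Parameters
    ----------
    betas:
        Probes x samples methylation fractions.
    clock:
        The linear predictor to evaluate.
    on_invalid:
        Policy for beta values outside [0, 1]: ``"error"`` or ``"warn"``.
    """
    betas.validate_range(on_invalid=on_invalid)
    clock_probes = pd.Index(clock.probe_ids)
    present = clock_probes[clock_probes.isin(betas.probe_ids)]
    missing = clock_probes[~clock_probes.isin(betas.probe_ids)].tolist()
    if missing:
        logger.warning(
            "clock %s: %d of %d probes absent from beta matrix; dropped from the sum",
            clock.name,
            len(missing),
            clock.m,
        )
    if clock.m > 0 and len(present) == 0:
        logger.warning(
            "clock %s: no clock probes present; DNAm age equals the intercept", clock.name
        )
        ages = np.full(betas.n_samples, clock.intercept)
    else:
        rows = betas.probe_ids.get_indexer(present)
        sub = betas.values[rows, :]
        coef = np.array([clock.coefficients[p] for p in present])
        n_nan = int(np.isnan(sub).sum())
        if n_nan:
            logger.warning(
                "clock %s: %d missing beta values; terms dropped per sample", clock.name, n_nan
            )
        terms = sub * coef[:, None]
        ages = clock.intercept + np.nansum(terms, axis=0)
    return ClockResult(
        clock_name=clock.name,
        sample_ids=betas.sample_ids,
        dnam_age=ages,
        probes_used=len(present),
        probes_missing=len(missing),
        missing_probe_ids=missing,
    )
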