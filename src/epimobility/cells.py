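"""Reference-based white-blood-cell deconvolution (Houseman-style).

Whole-blood methylation is a mixture of cell-type-specific profiles.
Given a reference matrix R (probes x cell types) of mean beta values for
sorted cell populations, each sample's cell-type fractions w are
estimated by constrained projection:

    minimize  || b - R w ||^2   subject to  w >= 0,  sum(w) <= 1

where b is the sample's beta vector on the probes shared with the
reference.  The inequality (rather than equality) on the sum follows the
original quadratic-programming formulation, leaving room for cell types
not represented in the reference.

Reference probe selection (F-test screening of discriminating CpGs) is
out of scope here: the reference is taken as given.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .clocks import BetaMatrix
from .errors import RankError, ValidationError

_SUM_TOL = 1e-6
_NEG_TOL = 1e-8


@dataclass(frozen=True)
class ReferenceProfile:
    """Mean beta values for each reference cell type (probes x K)."""

    probe_ids: pd.Index
    cell_types: list[str]
    profile: np.ndarray

    def __post_init__(self) -> None:
        if self.profile.shape != (len(self.probe_ids), len(self.cell_types)):
            raise ValidationError("reference profile shape inconsistent with ID lists")
        if len(self.cell_types) < 1:
            raise ValidationError("reference must contain at least one cell type")
        if self.probe_ids.has_duplicates:
            raise ValidationError("duplicate probe IDs in reference profile")
        if np.nanmin(self.profile) < 0 or np.nanmax(self.profile) > 1:
            raise ValidationError("reference profile values must lie in [0, 1]")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "ReferenceProfile":
        return cls(
            probe_ids=pd.Index(frame.index.astype(str)),
            cell_types=[str(c) for c in frame.columns],
            profile=frame.to_numpy(dtype=float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.profile, index=self.probe_ids, columns=self.cell_types)


@dataclass(frozen=True)
class CellFractions:
    """Estimated cell-type fractions, samples x K."""

    sample_ids: pd.Index
    cell_types: list[str]
    fractions: np.ndarray

    def __post_init__(self) -> None:
        if self.fractions.min(initial=0.0) < -_NEG_TOL:
            raise ValidationError("negative cell fraction beyond tolerance")
        if self.fractions.size and self.fractions.sum(axis=1).max() > 1 + _SUM_TOL:
            raise ValidationError("cell fractions sum above 1 beyond tolerance")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fractions, index=self.sample_ids, columns=self.cell_types)


def load_reference_profile(path) -> ReferenceProfile:
    """Read a reference matrix: first column probe ID, one column per cell type."""
    frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return ReferenceProfile.from_dataframe(frame)


def _check_rank(R: np.ndarray, cell_types: list[str]) -> None:
    if np.linalg.matrix_rank(R) < R.shape[1]:
        # identify a minimal set of columns whose removal restores full rank
        aliased = []
        for k in range(R.shape[1]):
            others = np.delete(R, k, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(R):
                aliased.append(cell_types[k])
        raise RankError(
            f"reference columns are collinear on the shared probes: {aliased}",
            aliased=aliased,
        )


def _solve_one(R: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve min ||b - Rw||^2 s.t. w >= 0, sum(w) <= 1 for one sample."""
    w, _ = optimize.nnls(R, b)
    if w.sum() <= 1 + 1e-12:
        return w
    # sum constraint active: quadratic program via SLSQP from the NNLS start
    K = R.shape[1]
    RtR = R.T @ R
    Rtb = R.T @ b

    def objective(x):
        r = R @ x - b
        return 0.5 * float(r @ r)

    def grad(x):
        return RtR @ x - Rtb

    res = optimize.minimize(
        objective,
        np.clip(w / w.sum(), 0, None),
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * K,
        constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x.sum(), "jac": lambda x: -np.ones(K)}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    return np.clip(res.x, 0.0, None)


def estimate_cell_fractions(betas: BetaMatrix, reference: ReferenceProfile) -> CellFractions:
    """Estimate per-sample cell-type fractions by constrained projection.

    Probes are matched by ID between the beta matrix and the reference;
    at least K shared probes are required and the reference must be full
    column rank on them.  Samples with missing betas on shared probes are
    solved on their observed probes only.
    """
    shared = reference.probe_ids[reference.probe_ids.isin(betas.probe_ids)]
    K = len(reference.cell_types)
    if len(shared) < K:
        raise ValidationError(
            f"only {len(shared)} probes shared between betas and reference; need >= {K}"
        )
    R = reference.profile[reference.probe_ids.get_indexer(shared), :]
    B = betas.values[betas.probe_ids.get_indexer(shared), :]
    _check_rank(R, reference.cell_types)

    out = np.empty((betas.n_samples, K))
    for j in range(betas.n_samples):
        b = B[:, j]
        mask = ~np.isnan(b)
        if mask.sum() < K:
            raise ValidationError(
                f"sample {betas.sample_ids[j]!r}: fewer observed shared probes than cell types"
            )
        w = _solve_one(R[mask], b[mask])
        # constraint set is asserted on every solve
        assert w.min(initial=0.0) >= -_NEG_TOL and w.sum() <= 1 + _SUM_TOL
        out[j] = w
    return CellFractions(
        sample_ids=betas.sample_ids, cell_types=list(reference.cell_types), fractions=out
    )
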