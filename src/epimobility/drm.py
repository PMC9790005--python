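"""Diagonal reference models (DRM) for social-mobility analysis.

The DRM treats the socially immobile — people whose origin class i and
destination class j coincide — as the benchmark groups.  A mobile
person's expected outcome is a convex combination of the two immobile
("diagonal") means, weighted by the relative importance p of the origin
class, plus ordinary covariates:

    E(Y_ij) = beta0 + p * mu_ii + (1 - p) * mu_jj + X_ij beta

with p in [0, 1]: p = 1 means the outcome tracks origin class only,
p = 0 destination class only.  Mobility variables (any-direction,
up/down, or one-/two-step dummies) may be added to X to test whether
moving, per se, matters net of origin and destination.

Identification: the intercept and three diagonal means are jointly
unidentified as written, so the diagonal means are parameterized as
beta0 + delta_k with sum-to-zero class effects delta (two free
parameters), which matches the convention of reporting three class
effects summing to ~0 alongside a constant.

Estimation is Gaussian maximum likelihood via the profile likelihood in
p: at fixed p the model is linear, so the inner problem is closed-form
least squares; the profile is evaluated on a grid over [0, 1] and the
best grid point refined by bounded scalar minimization.  This is global
in p by construction.  Standard errors come from the numerical Hessian
of the full log-likelihood at the optimum; Wald intervals for p are
suppressed when the estimate sits on the boundary.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import IdentifiabilityError, RankError, ValidationError
from .mobility import CLASS_LEVELS, SCHEME_COLUMNS, add_mobility_columns

# sum-to-zero (effect) coding rows for the three ordered classes
_EFFECT_CODING = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, -1.0]])

_Z975 = stats.norm.ppf(0.975)

DEFAULT_COVARIATES = ("female", "z_age", "z_age_sq")


@dataclass(frozen=True)
class DRMData:
    """Validated inputs for a DRM fit.

    ``origin`` and ``destination`` are integer class codes 0..2 in the
    order disadvantaged, intermediate, advantaged; ``X`` holds the plain
    covariate columns (already including any mobility dummies).
    """

    y: np.ndarray
    origin: np.ndarray
    destination: np.ndarray
    X: pd.DataFrame
    outcome_label: str = "outcome"

    def __post_init__(self) -> None:
        n = len(self.y)
        if not (len(self.origin) == len(self.destination) == n == len(self.X)):
            raise ValidationError("DRM inputs have inconsistent lengths")
        if np.isnan(self.y).any() or self.X.isna().any().any():
            raise ValidationError("DRM inputs contain missing values")
        for arr, name in ((self.origin, "origin"), (self.destination, "destination")):
            if arr.min(initial=0) < 0 or arr.max(initial=0) > 2:
                raise ValidationError(f"{name} codes outside 0..2")
        diag = set(self.origin[self.origin == self.destination])
        if len(diag) < 2:
            raise ValidationError("need immobile persons in at least two distinct classes")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        outcome: str,
        scheme: str = "none",
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        outcome_label: str | None = None,
    ) -> "DRMData":
        """Assemble DRM inputs from a cohort table.

        Mobility dummies for ``scheme`` are derived from the origin and
        destination columns and appended to the covariates.
        """
        df = add_mobility_columns(frame, scheme=scheme)
        cols = list(covariates) + SCHEME_COLUMNS[scheme]
        missing = [c for c in cols + [outcome, "origin", "destination"] if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort table lacks columns {missing}")
        origin = pd.Categorical(df["origin"], categories=CLASS_LEVELS, ordered=True).codes
        dest = pd.Categorical(df["destination"], categories=CLASS_LEVELS, ordered=True).codes
        if (origin < 0).any() or (dest < 0).any():
            raise ValidationError("origin/destination contain labels outside the class vocabulary")
        return cls(
            y=df[outcome].to_numpy(float),
            origin=origin.astype(int),
            destination=dest.astype(int),
            X=df[cols].astype(float).reset_index(drop=True),
            outcome_label=outcome_label or outcome,
        )

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_mobile(self) -> int:
        return int((self.origin != self.destination).sum())

    def swapped(self) -> "DRMData":
        """Origin and destination columns exchanged (p <-> 1 - p)."""
        return DRMData(
            y=self.y,
            origin=self.destination,
            destination=self.origin,
            X=self.X,
            outcome_label=self.outcome_label,
        )


def build_design(data: DRMData, p: float) -> tuple[np.ndarray, list[str]]:
    """Linear design at fixed mixing weight p.

    Class-effect columns are the p-weighted blend of the origin and
    destination effect codings; immobile persons contribute total weight
    1 to their own class, so their rows equal plain effect coding.
    """
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p = {p} outside [0, 1]")
    C = p * _EFFECT_CODING[data.origin] + (1.0 - p) * _EFFECT_CODING[data.destination]
    X = np.column_stack([np.ones(data.n), C, data.X.to_numpy(float)])
    names = ["const", "delta_1", "delta_2"] + [str(c) for c in data.X.columns]
    return X, names


def _rank_check(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        aliased: list[str] = []
        acc = np.empty((X.shape[0], 0))
        for k, name in enumerate(names):
            cand = np.column_stack([acc, X[:, k]])
            if np.linalg.matrix_rank(cand) == acc.shape[1]:
                aliased.append(name)
            else:
                acc = cand
        raise RankError(f"rank-deficient DRM design; aliased columns: {aliased}", aliased=aliased)


def fit_at_p(data: DRMData, p: float) -> tuple[pd.Series, float, float]:
    """Closed-form inner fit at fixed p.

    Returns the linear coefficients (const, two free class effects,
    covariates), the ML residual variance RSS/n, and the Gaussian
    log-likelihood.
    """
    X, names = build_design(data, p)
    _rank_check(X, names)
    coef, _, _, _ = np.linalg.lstsq(X, data.y, rcond=None)
    resid = data.y - X @ coef
    n = data.n
    sigma2 = float(resid @ resid) / n
    logL = _gaussian_logl(n, sigma2)
    return pd.Series(coef, index=names), sigma2, logL


def _gaussian_logl(n: int, sigma2: float) -> float:
    if sigma2 <= 0:
        return np.inf  # degenerate perfect fit; caller handles
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def _profile_rss(data: DRMData, p: float) -> float:
    X, _ = build_design(data, p)
    coef, _, _, _ = np.linalg.lstsq(X, data.y, rcond=None)
    resid = data.y - X @ coef
    return float(resid @ resid)


@dataclass
class DRMFit:
    """Result of a diagonal reference model fit."""

    outcome_label: str
    scheme: str
    n: int
    p_hat: float
    delta: pd.Series  # three class effects, sum-to-zero
    beta0: float
    beta: pd.Series  # covariate coefficients
    sigma2: float
    logL: float
    aic: float
    bic: float
    k: int
    se: pd.Series
    conf_int: pd.DataFrame
    vcov: pd.DataFrame | None
    converged: bool
    boundary: bool
    profile_p: np.ndarray = field(repr=False)
    profile_logL: np.ndarray = field(repr=False)
    flat_profile: bool = False
    y_digest: str = ""

    @property
    def destination_weight(self) -> float:
        return 1.0 - self.p_hat

    def params(self) -> pd.Series:
        """All reported estimates in table order."""
        rows = {f"class_{c}": self.delta[c] for c in CLASS_LEVELS}
        rows["origin_weight"] = self.p_hat
        rows["destination_weight"] = self.destination_weight
        rows.update({c: self.beta[c] for c in self.beta.index})
        rows["constant"] = self.beta0
        return pd.Series(rows)

    def to_dict(self) -> dict:
        ci = self.conf_int
        return {
            "outcome": self.outcome_label,
            "scheme": self.scheme,
            "n": self.n,
            "estimates": {k: float(v) for k, v in self.params().items()},
            "se": {k: (None if np.isnan(v) else float(v)) for k, v in self.se.items()},
            "conf_int": {
                k: [None if np.isnan(ci.loc[k, "lower"]) else float(ci.loc[k, "lower"]),
                    None if np.isnan(ci.loc[k, "upper"]) else float(ci.loc[k, "upper"])]
                for k in ci.index
            },
            "sigma2": float(self.sigma2),
            "logL": float(self.logL),
            "AIC": float(self.aic),
            "BIC": float(self.bic),
            "k": self.k,
            "converged": self.converged,
            "boundary": self.boundary,
        }

    def summary(self) -> str:
        """Human-readable report mirroring the usual DRM table layout."""
        lines = [
            f"Diagonal reference model — outcome: {self.outcome_label}, "
            f"mobility scheme: {self.scheme}",
            "-" * 72,
            f"{'term':<24}{'estimate':>10}{'SE':>10}{'95% CI':>24}",
        ]
        ci = self.conf_int
        for name, est in self.params().items():
            se = self.se.get(name, np.nan)
            if name in ci.index and not np.isnan(ci.loc[name, "lower"]):
                interval = f"[{ci.loc[name, 'lower']:.3f}, {ci.loc[name, 'upper']:.3f}]"
            else:
                interval = "n/a"
            se_txt = f"{se:.3f}" if not np.isnan(se) else "n/a"
            lines.append(f"{name:<24}{est:>10.3f}{se_txt:>10}{interval:>24}")
        lines += [
            "-" * 72,
            f"Observations: {self.n}   sigma2: {self.sigma2:.4f}   logL: {self.logL:.2f}",
            f"AIC: {self.aic:.1f}   BIC: {self.bic:.1f}   k: {self.k}",
        ]
        if self.boundary:
            lines.append("note: origin weight at boundary; Wald CI for the weights not applicable")
        if not self.converged:
            lines.append("WARNING: fit did not converge cleanly; interpret with caution")
        return "\n".join(lines)


def _negative_loglik(theta: np.ndarray, data: DRMData) -> float:
    """Full Gaussian negative log-likelihood in (p, d1, d2, b0, beta..., sigma2)."""
    p, d1, d2, b0 = theta[0], theta[1], theta[2], theta[3]
    beta = theta[4:-1]
    sigma2 = theta[-1]
    if sigma2 <= 0:
        return np.inf
    p = min(max(p, 0.0), 1.0)
    C = p * _EFFECT_CODING[data.origin] + (1.0 - p) * _EFFECT_CODING[data.destination]
    mu = b0 + C @ np.array([d1, d2]) + data.X.to_numpy(float) @ beta
    resid = data.y - mu
    n = data.n
    return 0.5 * n * np.log(2.0 * np.pi * sigma2) + float(resid @ resid) / (2.0 * sigma2)


def _numerical_hessian(f, x0: np.ndarray, steps: np.ndarray) -> np.ndarray:
    """Central-difference Hessian of scalar f at x0."""
    d = len(x0)
    H = np.empty((d, d))
    f0 = f(x0)
    for i in range(d):
        for j in range(i, d):
            hi, hj = steps[i], steps[j]
            if i == j:
                fp = f(x0 + _unit(d, i, hi))
                fm = f(x0 - _unit(d, i, hi))
                H[i, i] = (fp - 2 * f0 + fm) / hi**2
            else:
                fpp = f(x0 + _unit(d, i, hi) + _unit(d, j, hj))
                fpm = f(x0 + _unit(d, i, hi) - _unit(d, j, hj))
                fmp = f(x0 - _unit(d, i, hi) + _unit(d, j, hj))
                fmm = f(x0 - _unit(d, i, hi) - _unit(d, j, hj))
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hi * hj)
    return H


def _unit(d: int, i: int, h: float) -> np.ndarray:
    e = np.zeros(d)
    e[i] = h
    return e


def fit_drm(
    frame: pd.DataFrame,
    outcome: str,
    scheme: str = "none",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    grid_step: float = 0.01,
    xatol: float = 1e-6,
    compute_se: bool = True,
    outcome_label: str | None = None,
) -> DRMFit:
    """Fit a DRM by profile Gaussian maximum likelihood.

    Parameters
    ----------
    frame:
        Cohort table with ``origin``/``destination`` class labels, the
        outcome column, and the covariate columns.
    outcome:
        Name of the outcome column (an age-acceleration residual).
    scheme:
        Mobility-covariate scheme: ``none``, ``any``, ``direction`` or
        ``steps`` (the four standard model variants).
    covariates:
        Plain covariate columns entered linearly.
    grid_step:
        Profile grid spacing over p in [0, 1].
    xatol:
        Absolute tolerance on p for the bounded refinement step.
    compute_se:
        When False, skip the Hessian (used in large simulation studies
        where only point estimates and information criteria are needed).

    Raises
    ------
    IdentifiabilityError
        If the data contain no mobile person: then p multiplies nothing
        distinguishable and the mixing weight is not identified.
    """
    data = DRMData.from_frame(
        frame, outcome=outcome, scheme=scheme, covariates=covariates, outcome_label=outcome_label
    )
    if data.n_mobile == 0:
        raise IdentifiabilityError(
            "no mobile persons: the origin weight p is not identified "
            "(every row has origin == destination)"
        )

    # --- profile over the grid (minimizing RSS maximizes the Gaussian logL)
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    rss = np.array([_profile_rss(data, p) for p in grid])
    i_best = int(np.argmin(rss))  # ties resolve to the smallest p
    flat = bool(np.sum(np.isclose(rss, rss[i_best], rtol=0, atol=1e-10)) > 1)

    # --- refine within one grid cell either side of the best point
    lo = max(0.0, grid[i_best] - grid_step)
    hi = min(1.0, grid[i_best] + grid_step)
    res = optimize.minimize_scalar(
        lambda p: _profile_rss(data, p), bounds=(lo, hi), method="bounded",
        options={"xatol": xatol},
    )
    p_hat = float(res.x) if res.fun <= rss[i_best] else float(grid[i_best])
    converged = bool(res.success) or res.fun > rss[i_best]

    coef, sigma2, logL = fit_at_p(data, p_hat)
    beta0 = float(coef["const"])
    d1, d2 = float(coef["delta_1"]), float(coef["delta_2"])
    delta = pd.Series([d1, d2, -d1 - d2], index=CLASS_LEVELS)
    beta = coef.drop(["const", "delta_1", "delta_2"])

    k = 1 + 2 + 1 + len(beta) + 1  # p, free class effects, constant, covariates, sigma2
    aic = -2.0 * logL + 2.0 * k
    bic = -2.0 * logL + k * np.log(data.n)
    boundary = p_hat < 0.005 or p_hat > 0.995

    param_order = (
        [f"class_{c}" for c in CLASS_LEVELS]
        + ["origin_weight", "destination_weight"]
        + list(beta.index)
        + ["constant"]
    )
    se = pd.Series(np.nan, index=param_order)
    ci = pd.DataFrame(np.nan, index=param_order, columns=["lower", "upper"])

    if compute_se and sigma2 > 0:
        theta = np.concatenate([[p_hat, d1, d2, beta0], beta.to_numpy(), [sigma2]])
        steps = np.maximum(np.abs(theta), 0.05) * 2.2e-16 ** 0.25
        free = np.ones(len(theta), dtype=bool)
        # p cannot be perturbed symmetrically at the boundary; fix it there
        if p_hat - steps[0] < 0 or p_hat + steps[0] > 1:
            free[0] = False

        idx_free = np.flatnonzero(free)

        def nll_free(x):
            full = theta.copy()
            full[idx_free] = x
            return _negative_loglik(full, data)

        H = _numerical_hessian(nll_free, theta[idx_free], steps[idx_free])
        try:
            V = np.linalg.inv(H)
            diag = np.diag(V)
            if np.any(diag < -1e-8):
                converged = False
            se_free = np.sqrt(np.clip(diag, 0, None))
        except np.linalg.LinAlgError:
            converged = False
            V = None
            se_free = np.full(len(idx_free), np.nan)

        se_full = np.full(len(theta), np.nan)
        se_full[idx_free] = se_free
        names_full = ["p", "delta_1", "delta_2", "constant", *beta.index, "sigma2"]
        se_map = dict(zip(names_full, se_full))

        se["class_disadvantaged"] = se_map["delta_1"]
        se["class_intermediate"] = se_map["delta_2"]
        if V is not None and free[0:3].all():
            # var(-d1 - d2) from the (d1, d2) block
            pos = {name: list(np.array(names_full)[idx_free]).index(name) for name in ("delta_1", "delta_2")}
            block = V[np.ix_([pos["delta_1"], pos["delta_2"]], [pos["delta_1"], pos["delta_2"]])]
            var_adv = float(block[0, 0] + block[1, 1] + 2 * block[0, 1])
            se["class_advantaged"] = np.sqrt(max(var_adv, 0.0))
        se["origin_weight"] = se_map.get("p", np.nan)
        se["destination_weight"] = se_map.get("p", np.nan)
        se["constant"] = se_map["constant"]
        for c in beta.index:
            se[c] = se_map[c]

        est = pd.Series(
            {
                "class_disadvantaged": delta[CLASS_LEVELS[0]],
                "class_intermediate": delta[CLASS_LEVELS[1]],
                "class_advantaged": delta[CLASS_LEVELS[2]],
                "origin_weight": p_hat,
                "destination_weight": 1 - p_hat,
                **{c: beta[c] for c in beta.index},
                "constant": beta0,
            }
        )
        ci["lower"] = est - _Z975 * se
        ci["upper"] = est + _Z975 * se
        if boundary:
            # Wald intervals are invalid on the boundary of [0, 1]
            for w in ("origin_weight", "destination_weight"):
                se[w] = np.nan
                ci.loc[w] = np.nan
        vcov_df = (
            pd.DataFrame(V, index=np.array(names_full)[idx_free], columns=np.array(names_full)[idx_free])
            if V is not None
            else None
        )
    else:
        vcov_df = None

    logl_grid = np.array([_gaussian_logl(data.n, r / data.n) if r > 0 else np.inf for r in rss])
    return DRMFit(
        outcome_label=data.outcome_label,
        scheme=scheme,
        n=data.n,
        p_hat=p_hat,
        delta=delta,
        beta0=beta0,
        beta=beta,
        sigma2=sigma2,
        logL=logL,
        aic=aic,
        bic=bic,
        k=k,
        se=se,
        conf_int=ci,
        vcov=vcov_df,
        converged=converged,
        boundary=boundary,
        profile_p=grid,
        profile_logL=logl_grid,
        flat_profile=flat,
        y_digest=hashlib.sha1(np.ascontiguousarray(data.y).tobytes()).hexdigest(),
    )


def compare_models(fits: list[DRMFit]) -> pd.DataFrame:
    """Rank fits of the same outcome and sample by AIC and BIC.

    Returns a table sorted by AIC with deltas to the best model under
    each criterion.
    """
    if not fits:
        raise ValidationError("no fits to compare")
    n0, dig0, lab0 = fits[0].n, fits[0].y_digest, fits[0].outcome_label
    for f in fits[1:]:
        if f.n != n0:
            raise ValidationError("fits cover different sample sizes; not comparable")
        if f.y_digest != dig0 or f.outcome_label != lab0:
            raise ValidationError("fits use different outcomes; not comparable")
    tab = pd.DataFrame(
        {
            "scheme": [f.scheme for f in fits],
            "k": [f.k for f in fits],
            "logL": [f.logL for f in fits],
            "AIC": [f.aic for f in fits],
            "BIC": [f.bic for f in fits],
        }
    )
    tab["dAIC"] = tab["AIC"] - tab["AIC"].min()
    tab["dBIC"] = tab["BIC"] - tab["BIC"].min()
    tab["rank_AIC"] = tab["AIC"].rank(method="first").astype(int)
    tab["rank_BIC"] = tab["BIC"].rank(method="first").astype(int)
    return tab.sort_values("AIC").reset_index(drop=True)


def predict_cell_means(fit: DRMFit) -> pd.DataFrame:
    """Expected 3x3 origin-by-destination outcome table at covariate zero.

    Diagonal entries are beta0 + delta_k; off-diagonal entries blend the
    two diagonal effects with weights (p, 1 - p).
    """
    if not fit.converged:
        raise ValidationError("refusing to predict from a non-converged fit")
    d = fit.delta.to_numpy()
    p = fit.p_hat
    out = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            out[i, j] = fit.beta0 + (d[i] if i == j else p * d[i] + (1 - p) * d[j])
    return pd.DataFrame(out, index=CLASS_LEVELS, columns=CLASS_LEVELS)
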