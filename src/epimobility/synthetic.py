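"""Synthetic cohorts with the structure the mobility analysis assumes.

The generator emulates the design of the emulated household-panel
study: a 3x3 origin-by-destination class table with fixed cell counts
(defaults are the published analytic sample's counts, n = 3140), age
drawn from N(54.5, 14^2) truncated below at 25, 55.8% female, plate
batches, and an outcome generated directly under the diagonal reference
model with chosen mixing weight p*, sum-to-zero diagonal effects,
covariate effects and Gaussian noise.  Methylation beta matrices are
constructed by inverting toy linear clocks so that the whole pipeline
(clock evaluation, deconvolution, residualization, DRM fitting) runs
end-to-end with known truth.

Every generator is a pure function of its configuration, seed included:
identical configs give bitwise-identical output.  Class membership is
assigned by exact counts, not multinomial draws, so marginal checks are
exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cells import ReferenceProfile
from .clocks import BetaMatrix, ClockDefinition
from .errors import ValidationError
from .mobility import CLASS_LEVELS
from .published import CELL_NS

#: Default DRM truth for fixtures; magnitudes near those typical of
#: age-acceleration outcomes (class effects ~1 unit, sigma ~ a few units).
DEFAULT_TRUTH = {
    "p": 0.5,
    "delta": (1.0, 0.0, -1.0),
    "beta0": 0.0,
    "sigma": 1.0,
    "covariate_effects": {"female": -1.0},
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic cohort generator.

    ``cell_counts`` fixes the 3x3 origin-by-destination table exactly;
    ``delta`` must sum to zero; ``covariate_effects`` maps covariate
    column names (``female``, ``z_age``, ``z_age_sq``) to linear
    effects, and ``mobility_effects`` maps mobility dummy names
    (``mobile``, ``upward``, ``down1``, ...) to true effects on the
    outcome.
    """

    cell_counts: tuple[tuple[int, ...], ...] = tuple(map(tuple, CELL_NS.to_numpy()))
    p: float = DEFAULT_TRUTH["p"]
    delta: tuple[float, float, float] = DEFAULT_TRUTH["delta"]
    beta0: float = DEFAULT_TRUTH["beta0"]
    sigma: float = DEFAULT_TRUTH["sigma"]
    covariate_effects: dict = field(default_factory=lambda: dict(DEFAULT_TRUTH["covariate_effects"]))
    mobility_effects: dict = field(default_factory=dict)
    age_mean: float = 54.5
    age_sd: float = 14.0
    age_min: float = 25.0
    female_prop: float = 0.558
    n_plates: int = 8
    survey_year: int = 2011
    seed: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.cell_counts)
        if counts.shape != (3, 3) or (counts < 0).any():
            raise ValidationError("cell_counts must be a 3x3 table of non-negative integers")
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError("p must lie in [0, 1]")
        if abs(sum(self.delta)) > 1e-10:
            raise ValidationError("delta must sum to zero")
        if self.sigma < 0:
            raise ValidationError("sigma must be non-negative")

    @property
    def n(self) -> int:
        return int(np.asarray(self.cell_counts).sum())


def scaled_cell_counts(scale: float) -> tuple[tuple[int, ...], ...]:
    """The study's 3x3 cell counts scaled by ``scale``, ceil-rounded.

    Useful for small smoke-test cohorts that keep every cell occupied.
    """
    counts = np.ceil(CELL_NS.to_numpy() * float(scale)).astype(int)
    return tuple(map(tuple, counts))


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a cohort table with a DRM-generated outcome column ``y``.

    Origin/destination membership follows ``config.cell_counts``
    exactly; ``y`` is the DRM mean plus covariate and mobility effects
    plus N(0, sigma^2) noise.  Covariate effects are applied to age
    standardized within the generated sample.
    """
    rng = np.random.default_rng(config.seed)
    counts = np.asarray(config.cell_counts)
    origin, destination = [], []
    for i, oc in enumerate(CLASS_LEVELS):
        for j, dc in enumerate(CLASS_LEVELS):
            origin += [oc] * counts[i, j]
            destination += [dc] * counts[i, j]
    n = len(origin)

    a = (config.age_min - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a, np.inf, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    sex = np.where(rng.random(n) < config.female_prop, "female", "male")
    plate = rng.integers(1, config.n_plates + 1, size=n)

    df = pd.DataFrame(
        {
            "sample_id": [f"S{i:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "plate": [f"plate_{p:02d}" for p in plate],
            "origin": origin,
            "destination": destination,
        }
    )
    df["birth_year"] = config.survey_year - np.floor(df["age"]).astype(int)
    df["marital"] = rng.choice(
        ["single", "married", "divorced"], size=n, p=[0.133, 0.648, 0.219]
    )
    df["education"] = rng.choice(
        ["degree", "a_level", "gcse", "none"], size=n, p=[0.22, 0.309, 0.341, 0.13]
    )

    # DRM mean: immobile rows sit on their diagonal effect, mobile rows blend
    rank = {c: i for i, c in enumerate(CLASS_LEVELS)}
    delta = np.asarray(config.delta)
    mu = (
        config.beta0
        + config.p * delta[df["origin"].map(rank)]
        + (1.0 - config.p) * delta[df["destination"].map(rank)]
    )

    z_age = (df["age"] - df["age"].mean()) / df["age"].std(ddof=1)
    covariate_values = {
        "female": (df["sex"] == "female").astype(float).to_numpy(),
        "z_age": z_age.to_numpy(),
        "z_age_sq": (z_age**2).to_numpy(),
    }
    for name, eff in config.covariate_effects.items():
        if name not in covariate_values:
            raise ValidationError(f"unknown covariate effect {name!r}")
        mu = mu + eff * covariate_values[name]

    if config.mobility_effects:
        from .mobility import add_mobility_columns

        dummies = add_mobility_columns(df, scheme="steps")
        dummies["mobile"] = (df["origin"] != df["destination"]).astype(int)
        dummies["upward"] = (
            df["destination"].map(rank) > df["origin"].map(rank)
        ).astype(int)
        dummies["downward"] = (
            df["destination"].map(rank) < df["origin"].map(rank)
        ).astype(int)
        for name, eff in config.mobility_effects.items():
            if name not in dummies:
                raise ValidationError(f"unknown mobility effect {name!r}")
            mu = mu + eff * dummies[name].to_numpy()

    df["y"] = mu + rng.normal(0.0, config.sigma, size=n)
    return df


def make_toy_clock(
    name: str,
    n_probes: int = 12,
    intercept: float = 0.0,
    total: float = 120.0,
    prefix: str | None = None,
    seed: int = 0,
) -> ClockDefinition:
    """A toy clock with positive coefficients summing to ``total``.

    Predictions span [intercept, intercept + total] as betas sweep
    [0, 1], so any target in that interval is exactly invertible.
    """
    rng = np.random.default_rng(seed)
    raw = rng.uniform(0.5, 1.5, n_probes)
    coefs = raw / raw.sum() * total
    prefix = prefix or f"cg{name[:2].upper()}"
    return ClockDefinition(
        name=name,
        intercept=intercept,
        coefficients={f"{prefix}{i:04d}": float(c) for i, c in enumerate(coefs)},
    )


def generate_betas(
    targets: np.ndarray,
    clock: ClockDefinition,
    sample_ids=None,
    probe_noise: float = 0.0,
    n_filler: int = 0,
    clip_tol: float = 1e-8,
    seed: int = 0,
) -> BetaMatrix:
    """Invert a toy clock: betas whose DNAm age equals ``targets`` exactly.

    Each sample gets the base level (target - intercept)/sum(coefs) on
    every clock probe, plus a zero-sum perturbation orthogonal to the
    coefficient vector (so the clock prediction is unchanged) of typical
    magnitude ``probe_noise``, shrunk where needed to keep betas inside
    [0, 1].  Filler probes not in the clock are drawn uniform.

    Targets outside the clock's feasible interval by more than
    ``clip_tol`` raise; smaller excursions are clipped and logged.
    """
    import logging

    logger = logging.getLogger(__name__)
    rng = np.random.default_rng(seed)
    targets = np.asarray(targets, float)
    n = len(targets)
    if sample_ids is None:
        sample_ids = [f"S{i:05d}" for i in range(n)]
    coef = np.array(list(clock.coefficients.values()))
    if clock.m == 0 or (coef <= 0).any():
        raise ValidationError("toy-clock inversion needs all-positive coefficients")
    S = coef.sum()
    base = (targets - clock.intercept) / S
    overshoot = np.maximum(np.maximum(-base, base - 1.0), 0.0) * S
    if overshoot.max(initial=0.0) > clip_tol:
        raise ValidationError(
            f"{int((overshoot > clip_tol).sum())} targets outside the feasible interval "
            f"[{clock.intercept}, {clock.intercept + S}] beyond tolerance"
        )
    n_clipped = int((overshoot > 0).sum())
    if n_clipped:
        logger.warning("%d targets clipped into the feasible beta range", n_clipped)
    base = np.clip(base, 0.0, 1.0)

    values = np.tile(base, (clock.m, 1))
    if probe_noise > 0 and clock.m >= 3:
        pert = rng.normal(0.0, probe_noise, size=(clock.m, n))
        ones = np.ones(clock.m)
        # project out span{1, coef}: zero-sum and clock-invariant
        for v in (ones, coef - ones * (coef @ ones) / (ones @ ones)):
            v = v / np.linalg.norm(v)
            pert -= np.outer(v, v @ pert)
        lo = -values
        hi = 1.0 - values
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(pert > 0, hi / pert, np.where(pert < 0, lo / pert, np.inf))
        scale = np.minimum(1.0, ratio.min(axis=0))
        values = values + pert * scale

    probe_ids = list(clock.coefficients)
    if n_filler > 0:
        filler = rng.uniform(0.0, 1.0, size=(n_filler, n))
        values = np.vstack([values, filler])
        probe_ids += [f"filler_{clock.name}_{i:05d}" for i in range(n_filler)]
    return BetaMatrix(
        probe_ids=pd.Index(probe_ids), sample_ids=pd.Index(sample_ids), values=values
    )


def generate_reference_mixture(
    K: int,
    n_probes: int,
    true_fractions: np.ndarray,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[ReferenceProfile, BetaMatrix, pd.DataFrame]:
    """Reference profile plus samples mixed from it with known fractions.

    Reference columns are drawn uniform in [0.05, 0.95]; each sample is
    R @ w plus Gaussian noise, clipped to [0, 1].
    """
    w = np.atleast_2d(np.asarray(true_fractions, float))
    if w.shape[1] != K:
        raise ValidationError("true_fractions must have K columns")
    if (w < 0).any() or (w.sum(axis=1) > 1 + 1e-9).any():
        raise ValidationError("fractions must be non-negative with row sums <= 1")
    rng = np.random.default_rng(seed)
    R = rng.uniform(0.05, 0.95, size=(n_probes, K))
    B = R @ w.T + rng.normal(0.0, noise, size=(n_probes, w.shape[0]))
    B = np.clip(B, 0.0, 1.0)
    cell_types = [f"cell{k + 1}" for k in range(K)]
    probes = pd.Index([f"cgREF{i:05d}" for i in range(n_probes)])
    samples = pd.Index([f"M{i:04d}" for i in range(w.shape[0])])
    reference = ReferenceProfile(probe_ids=probes, cell_types=cell_types, profile=R)
    betas = BetaMatrix(probe_ids=probes, sample_ids=samples, values=B)
    truth = pd.DataFrame(w, index=samples, columns=cell_types)
    return reference, betas, truth


def default_toy_clocks(seed: int = 0) -> dict[str, ClockDefinition]:
    """Four toy clocks with disjoint probe sets, one pace-scale.

    The three age-scale clocks span [0, 130] years; the pace clock spans
    [0, 2.6] pace units (typical pace ~1.0).
    """
    return {
        "toy_horvath": make_toy_clock("toy_horvath", 12, 0.0, 130.0, "cgHO", seed=seed + 1),
        "toy_hannum": make_toy_clock("toy_hannum", 10, 0.0, 130.0, "cgHA", seed=seed + 2),
        "toy_phenoage": make_toy_clock("toy_phenoage", 14, 0.0, 130.0, "cgPH", seed=seed + 3),
        "toy_pace": make_toy_clock("toy_pace", 8, 0.0, 2.6, "cgPA", seed=seed + 4),
    }


def clock_targets(cohort: pd.DataFrame, clock_name: str) -> np.ndarray:
    """Target DNAm age per sample for a toy clock.

    Age-scale clocks target chronological age plus the DRM outcome
    (positive outcome = epigenetically older); the pace clock targets
    the same quantity mapped onto the pace scale around 1.0.
    """
    t = cohort["age"].to_numpy(float) + cohort["y"].to_numpy(float)
    if clock_name == "toy_pace":
        return 1.0 + (t - t.mean()) / 130.0
    return t


def generate_cohort_betas(
    cohort: pd.DataFrame,
    clocks: dict[str, ClockDefinition],
    probe_noise: float = 0.02,
    n_filler: int = 50,
    seed: int = 0,
) -> BetaMatrix:
    """One beta matrix serving several toy clocks with disjoint probes."""
    blocks = []
    ids = pd.Index(cohort["sample_id"])
    for i, (name, clock) in enumerate(clocks.items()):
        block = generate_betas(
            clock_targets(cohort, name),
            clock,
            sample_ids=ids,
            probe_noise=probe_noise,
            n_filler=0,
            seed=seed + 101 * (i + 1),
        )
        blocks.append(block.to_dataframe())
    if n_filler:
        rng = np.random.default_rng(seed + 999)
        filler = pd.DataFrame(
            rng.uniform(0.0, 1.0, size=(n_filler, len(ids))),
            index=[f"filler_{i:05d}" for i in range(n_filler)],
            columns=ids,
        )
        blocks.append(filler)
    return BetaMatrix.from_dataframe(pd.concat(blocks, axis=0))
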