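"""End-to-end analysis pipeline.

Binds the stages into the standard workflow: evaluate clocks on the
beta matrix, estimate cell composition, restrict to the analytic sample
(age >= 25, complete class data), residualize DNAm age into age
acceleration within that sample, encode mobility, fit the four DRM
variants per clock, and emit descriptive tables.  Every output is
delimited text or JSON; a run log records the analytic n after each
exclusion step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import acceleration as accel_mod
from . import cells as cells_mod
from . import clocks as clocks_mod
from . import descriptives, drm, mobility, synthetic
from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_COLUMNS = {
    "sample_id": "sample_id",
    "age": "age",
    "sex": "sex",
    "plate": "plate",
    "origin": "origin",
    "destination": "destination",
    "birth_year": "birth_year",
}

SCHEME_BY_MODEL = {1: "none", 2: "any", 3: "direction", 4: "steps"}


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    betas: str
    phenotype: str
    clocks: list[str]
    outdir: str
    reference: str | None = None
    column_map: dict = field(default_factory=lambda: dict(DEFAULT_COLUMNS))
    min_age: float = 25.0
    schemes: tuple[str, ...] = ("none", "any", "direction", "steps")
    covariates: tuple[str, ...] = drm.DEFAULT_COVARIATES
    birth_year_cut: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        """Aggregate every validation failure into one error."""
        problems: list[str] = []
        for label, p in [("betas", self.betas), ("phenotype", self.phenotype)] + [
            (f"clock[{i}]", c) for i, c in enumerate(self.clocks)
        ]:
            if not Path(p).exists():
                problems.append(f"{label}: file not found: {p}")
        if self.reference is not None and not Path(self.reference).exists():
            problems.append(f"reference: file not found: {self.reference}")
        for s in self.schemes:
            if s not in mobility.SCHEMES:
                problems.append(f"unknown mobility scheme {s!r}")
        if not self.clocks:
            problems.append("no clock files supplied")
        if problems:
            raise ValidationError("invalid configuration:\n  " + "\n  ".join(problems))


def load_phenotype(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read the phenotype table and rename columns to the canonical names."""
    df = pd.read_csv(path, sep=None, engine="python")
    cmap = dict(DEFAULT_COLUMNS)
    cmap.update(column_map or {})
    rename = {src: dst for dst, src in cmap.items() if src in df.columns}
    df = df.rename(columns=rename)
    for col in ("origin", "destination"):
        if col in df.columns:
            df[col] = pd.Series(mobility.as_class_code(df[col])).astype(object)
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write its report bundle.

    Returns a dict with the analytic cohort, acceleration table, DRM
    fits keyed ``(clock, scheme)``, per-clock model comparisons and
    cross-tabs.  Identical config and inputs give identical outputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    betas = clocks_mod.load_beta_matrix(config.betas)
    pheno = load_phenotype(config.phenotype, config.column_map)
    log_lines.append(f"phenotype rows: {len(pheno)}; beta samples: {betas.n_samples}")

    clock_defs = [clocks_mod.load_clock_definition(p) for p in config.clocks]
    clock_results = {c.name: clocks_mod.compute_dnam_age(betas, c) for c in clock_defs}
    for name, res in clock_results.items():
        log_lines.append(
            f"clock {name}: probes used {res.probes_used}, missing {res.probes_missing}"
        )

    cell_fracs = None
    if config.reference is not None:
        reference = cells_mod.load_reference_profile(config.reference)
        cell_fracs = cells_mod.estimate_cell_fractions(betas, reference)
        cell_fracs.to_frame().to_csv(outdir / "cell_fractions.csv")
        log_lines.append(f"cell fractions estimated for {len(cell_fracs.sample_ids)} samples")

    cohort = mobility.filter_analytic_sample(pheno, min_age=config.min_age)
    for reason, n in cohort.attrs["exclusions"].items():
        log_lines.append(f"analytic filter: {reason} = {n}")
    cohort = mobility.standardize_covariates(cohort)

    # residualize per clock on the analytic sample only
    sample_pos = betas.sample_ids.get_indexer(cohort["sample_id"])
    if (sample_pos < 0).any():
        raise ValidationError("analytic samples missing from the beta matrix")
    accel_frames = []
    fits: dict[tuple[str, str], drm.DRMFit] = {}
    comparisons: dict[str, pd.DataFrame] = {}
    crosstabs: dict[str, descriptives.CrossTab] = {}

    for name, res in clock_results.items():
        dnam = res.dnam_age[sample_pos]
        sub_cells = None
        if cell_fracs is not None:
            sub_cells = cells_mod.CellFractions(
                sample_ids=pd.Index(cohort["sample_id"]),
                cell_types=cell_fracs.cell_types,
                fractions=cell_fracs.fractions[sample_pos],
            )
        acc = accel_mod.residualize_age(
            dnam,
            cohort["age"].to_numpy(float),
            plate=cohort["plate"] if "plate" in cohort else None,
            cells=sub_cells,
            sample_ids=pd.Index(cohort["sample_id"]),
            clock_name=name,
        )
        accel_frames.append(acc.to_frame())
        col = f"accel_{name}"
        cohort[col] = acc.acceleration

        crosstabs[name] = descriptives.crosstab_means(cohort, col, outcome_label=name)
        crosstabs[name].to_frame(ndigits=2).to_csv(outdir / f"crosstab_{name}.csv")

        clock_fits = []
        for scheme in config.schemes:
            fit = drm.fit_drm(
                cohort, outcome=col, scheme=scheme, covariates=config.covariates,
                outcome_label=name,
            )
            fits[(name, scheme)] = fit
            clock_fits.append(fit)
            (outdir / f"drm_{name}_{scheme}.json").write_text(json.dumps(fit.to_dict(), indent=2))
            (outdir / f"drm_{name}_{scheme}.txt").write_text(fit.summary() + "\n")
            log_lines.append(f"drm {name}/{scheme}: n = {fit.n}, p_hat = {fit.p_hat:.3f}")
        comp = drm.compare_models(clock_fits)
        comparisons[name] = comp
        comp.to_csv(outdir / f"model_comparison_{name}.csv", index=False)

    accel_table = pd.concat(accel_frames, ignore_index=True)
    accel_table.to_csv(outdir / "acceleration.csv", index=False)

    restricted = []
    for name in clock_results:
        for comparison in ("down_vs_stable_advantaged", "up_vs_stable_disadvantaged"):
            r = descriptives.restricted_mobility_ols(cohort, f"accel_{name}", comparison)
            restricted.append(
                {
                    "clock": name,
                    "comparison": comparison,
                    "coefficient": r["coefficient"],
                    "ci_lower": r["conf_int"][0],
                    "ci_upper": r["conf_int"][1],
                    "p_value": r["p_value"],
                    "n_exposed": r["n_exposed"],
                    "n_reference": r["n_reference"],
                }
            )
    restricted_df = pd.DataFrame(restricted)
    restricted_df.to_csv(outdir / "restricted_ols.csv", index=False)

    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return {
        "cohort": cohort,
        "acceleration": accel_table,
        "fits": fits,
        "comparisons": comparisons,
        "crosstabs": crosstabs,
        "restricted": restricted_df,
        "log": log_lines,
    }


def simulate_to_files(
    outdir,
    config: synthetic.GeneratorConfig | None = None,
    probe_noise: float = 0.02,
    n_filler: int = 50,
    reference_k: int = 6,
) -> dict[str, str]:
    """Generate a full synthetic input bundle on disk.

    Writes a phenotype table, beta matrix, toy clock files and a cell
    reference, ready for :func:`run_pipeline`.  Returns the paths.
    """
    config = config or synthetic.GeneratorConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = synthetic.generate_cohort(config)
    clock_defs = synthetic.default_toy_clocks(seed=config.seed)
    betas = synthetic.generate_cohort_betas(
        cohort, clock_defs, probe_noise=probe_noise, n_filler=n_filler, seed=config.seed
    )

    import numpy as np

    rng = np.random.default_rng(config.seed + 77)
    w = rng.dirichlet(np.ones(reference_k) * 5.0, size=len(cohort)) * 0.98
    reference, mix_betas, truth = synthetic.generate_reference_mixture(
        reference_k, 200, w, noise=0.01, seed=config.seed + 78
    )
    # graft the mixture probes onto the cohort beta matrix so deconvolution runs
    mix = mix_betas.to_dataframe()
    mix.columns = betas.sample_ids
    combined = pd.concat([betas.to_dataframe(), mix], axis=0)

    paths = {
        "phenotype": str(outdir / "phenotype.csv"),
        "betas": str(outdir / "betas.csv"),
        "reference": str(outdir / "reference.csv"),
    }
    pheno = cohort.drop(columns=["y"])
    pheno.to_csv(paths["phenotype"], index=False)
    combined.to_csv(paths["betas"], index_label="probe_id")
    reference.to_dataframe().to_csv(paths["reference"], index_label="probe_id")
    clock_paths = []
    for name, c in clock_defs.items():
        p = str(outdir / f"{name}.csv")
        clocks_mod.save_clock_definition(c, p)
        clock_paths.append(p)
    paths["clocks"] = clock_paths
    truth_info = {
        "p": config.p,
        "delta": list(config.delta),
        "beta0": config.beta0,
        "sigma": config.sigma,
        "n": config.n,
        "seed": config.seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth_info, indent=2))
    return paths
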