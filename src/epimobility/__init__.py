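"""Diagonal reference models for lifecourse social mobility and
DNA-methylation age acceleration.

The package implements the full analysis chain: linear epigenetic-clock
evaluation on methylation beta matrices, reference-based cell-type
deconvolution, covariate-adjusted age-acceleration residuals, social
class and mobility encoding, and from-scratch profile-likelihood
estimation of diagonal reference models with mobility covariates, plus
a synthetic cohort generator that reproduces the study design so the
whole chain can be exercised without restricted microdata.
"""

from .acceleration import AccelerationResult, residualize_age
from .cells import (
    CellFractions,
    ReferenceProfile,
    estimate_cell_fractions,
    load_reference_profile,
)
from .clocks import (
    BetaMatrix,
    ClockDefinition,
    ClockResult,
    compute_dnam_age,
    load_beta_matrix,
    load_clock_definition,
)
from .descriptives import (
    CrossTab,
    crosstab_means,
    group_tests,
    marginal_from_cells,
    restricted_mobility_ols,
    round_half_away,
)
from .drm import (
    DRMData,
    DRMFit,
    build_design,
    compare_models,
    fit_at_p,
    fit_drm,
    predict_cell_means,
)
from .errors import (
    ConvergenceError,
    EpimobilityError,
    FormatError,
    IdentifiabilityError,
    RankError,
    ValidationError,
)
from .mobility import (
    CLASS_LEVELS,
    SCHEME_COLUMNS,
    SCHEMES,
    add_mobility_columns,
    encode_mobility,
    filter_analytic_sample,
    household_max_class,
    standardize_covariates,
    stratify_by_birth_year,
)
from .pipeline import RunConfig, run_pipeline, simulate_to_files
from .synthetic import (
    GeneratorConfig,
    clock_targets,
    default_toy_clocks,
    generate_betas,
    generate_cohort,
    generate_cohort_betas,
    generate_reference_mixture,
    make_toy_clock,
)

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]
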