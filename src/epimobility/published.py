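"""Published summary tables used as validation inputs.

The underlying microdata of the UK household-panel study this analysis
design emulates are restricted-access, but its published summary tables
are reproducible arithmetic: a 3x3 origin-by-destination cross-tab of
mean age acceleration per clock with count-weighted marginals, and
sample accounting by birth cohort.  These frozen values serve as inputs
to consistency checks (marginal reconstruction, sample accounting) —
they are data, not code, and are never fitted to.

All cell values are printed to two decimals; reconstructed marginals
therefore carry up to half a unit in the last printed place of rounding
error per cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mobility import CLASS_LEVELS


def _tab(values) -> pd.DataFrame:
    return pd.DataFrame(values, index=CLASS_LEVELS, columns=CLASS_LEVELS, dtype=float)


#: Origin x destination cell counts of the published analytic sample.
CELL_NS = pd.DataFrame(
    [[432, 234, 302], [467, 466, 903], [42, 76, 218]],
    index=CLASS_LEVELS,
    columns=CLASS_LEVELS,
    dtype=int,
)

#: Published per-cell mean age acceleration (rows: origin; cols: destination).
CROSSTAB_CELLS = {
    "horvath": _tab([[0.05, 0.37, 0.06], [0.02, -0.29, 0.01], [0.38, -0.55, 0.05]]),
    "hannum": _tab([[0.18, 0.30, 0.44], [-0.05, -0.64, 0.13], [-0.15, -0.90, -0.03]]),
    "phenoage": _tab([[0.97, 0.67, 0.11], [0.29, -0.76, -0.36], [0.70, 0.36, -0.57]]),
    "dunedinpoam": _tab([[0.98, 0.59, -0.37], [0.70, -0.38, -0.46], [0.20, -0.32, -0.79]]),
}

#: Published marginals: (row totals by origin, column totals by destination, grand mean).
CROSSTAB_TOTALS = {
    "horvath": ([0.13, -0.06, -0.04], [0.05, -0.11, 0.03], 0.00),
    "hannum": ([0.29, -0.11, -0.24], [0.05, -0.38, 0.17], -0.00),
    "phenoage": ([0.63, -0.30, -0.20], [0.62, -0.22, -0.29], -0.00),
    "dunedinpoam": ([0.46, -0.14, -0.56], [0.81, -0.08, -0.49], -0.00),
}

#: Birth-cohort strata of the published sample: n and mean (SD) age.
STRATA = pd.DataFrame(
    {
        "n": [1522, 1618],
        "percent": [48.5, 51.5],
        "mean_age": [66.6, 43.1],
        "sd_age": [7.46, 7.89],
    },
    index=["old", "young"],
)

#: Published total sample size and overall mean age.
TOTAL_N = 3140
OVERALL_MEAN_AGE = 54.5

#: Worst-case propagated error of a marginal reconstructed from 2-dp cells:
#: half a unit in the last place per cell plus half a unit in the printed total.
MARGINAL_RECONSTRUCTION_BOUND = 0.005 + 0.005


def published_totals_frame(clock: str) -> pd.DataFrame:
    """Printed marginals of one clock panel as a tidy frame."""
    row, col, grand = CROSSTAB_TOTALS[clock]
    return pd.DataFrame(
        {
            "margin": ["origin"] * 3 + ["destination"] * 3 + ["grand"],
            "level": CLASS_LEVELS + CLASS_LEVELS + ["all"],
            "printed_total": np.concatenate([row, col, [grand]]),
        }
    )
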