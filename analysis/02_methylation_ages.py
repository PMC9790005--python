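#!/usr/bin/env python
"""Evaluate the toy epigenetic clocks and estimate cell composition.

Reads the simulated beta matrix, applies each linear clock (reporting
how many clock probes the matrix is missing), and runs the constrained
projection deconvolution against the simulated reference.  DNAm ages
and cell fractions land in results/tables/.
"""

from pathlib import Path

import pandas as pd

from epimobility import (
    compute_dnam_age,
    estimate_cell_fractions,
    load_beta_matrix,
    load_clock_definition,
    load_reference_profile,
)

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
# per-sample intermediates are bulky; they stay in scratch/
INTERMEDIATE = ROOT / "scratch" / "intermediate"
INTERMEDIATE.mkdir(parents=True, exist_ok=True)

betas = load_beta_matrix(SIM / "betas.csv")
print(f"beta matrix: {len(betas.probe_ids)} probes x {betas.n_samples} samples")

frames = []
for clock_file in sorted(SIM.glob("toy_*.csv")):
    clock = load_clock_definition(clock_file)
    res = compute_dnam_age(betas, clock)
    frames.append(res.to_frame())
    print(
        f"{clock.name}: {res.probes_used} probes used, {res.probes_missing} missing; "
        f"mean DNAm age {res.dnam_age.mean():.2f}"
    )
ages = pd.concat(frames, ignore_index=True)
ages.to_csv(INTERMEDIATE / "dnam_ages.csv", index=False)

reference = load_reference_profile(SIM / "reference.csv")
fractions = estimate_cell_fractions(betas, reference)
fractions.to_frame().to_csv(INTERMEDIATE / "cell_fractions.csv", index_label="sample_id")
print(
    f"cell fractions: K = {len(fractions.cell_types)}, "
    f"mean total fraction {fractions.fractions.sum(axis=1).mean():.3f}"
)
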