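#!/usr/bin/env python
"""Generate every input of the analysis with known ground truth.

Writes, under results/data/: saturation assays for the four active
constructs at their published specific activities, two-site sensograms
for the two DLAR D1HSS D2 peptide scenarios, a two-site quench titration,
and a 500-frame two-rigid-domain trajectory at the DLAR inter-domain
geometry (multi-model PDB).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "analysis"))
from common import DATA_DIR, SEED, spawn_seeds  # noqa: E402

from tandemptp.scenarios import (
    SPECIFIC_ACTIVITIES,
    SPR_SCENARIOS,
    mm_scenario_spec,
    spr_scenario_spec,
    trajectory_scenario_spec,
)
from tandemptp.synthetic import (
    TitrationSpec,
    generate_mm_dataset,
    generate_sensogram,
    generate_titration,
    generate_two_domain_trajectory,
)
import numpy as np


def main() -> None:
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    seeds = iter(spawn_seeds(SEED, 16))

    for construct in sorted(SPECIFIC_ACTIVITIES):
        df = generate_mm_dataset(mm_scenario_spec(construct, seed=next(seeds)))
        path = DATA_DIR / f"assay_{construct}.csv"
        df.to_csv(path, index=False)
        print(f"{construct}: {len(df)} assay points -> {path}")

    for peptide in sorted(SPR_SCENARIOS):
        df = generate_sensogram(spr_scenario_spec(peptide, seed=next(seeds)))
        path = DATA_DIR / f"sensogram_{peptide}.csv"
        df.to_csv(path, index=False)
        print(f"{peptide}: {len(df)} sensogram points at "
              f"{df['conc_M'].nunique()} concentrations -> {path}")

    tit = generate_titration(
        TitrationSpec(
            sites=[(100.0, 40.0), (800.0, 30.0)],  # µM-scale two-site quench
            ligand_concs=list(np.geomspace(1.0, 20000.0, 18)),
            f0=100.0, noise_cv=0.01, seed=next(seeds),
        )
    )
    tit.to_csv(DATA_DIR / "titration_pnc.csv", index=False)
    print(f"PNC-style titration: {len(tit)} points -> {DATA_DIR / 'titration_pnc.csv'}")

    pdb = DATA_DIR / "trajectory_DLAR.pdb"
    generate_two_domain_trajectory(
        trajectory_scenario_spec("DLAR", seed=next(seeds), n_frames=500), pdb_path=pdb
    )
    print(f"DLAR-geometry trajectory: 500 frames -> {pdb}")


if __name__ == "__main__":
    main()
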