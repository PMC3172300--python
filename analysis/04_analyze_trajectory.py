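#!/usr/bin/env python
"""Trajectory-derived structural statistics of the two-domain system.

Reads the simulated DLAR-geometry trajectory back from its multi-model
PDB, superposes it, and computes: the RMSD equilibration point, per-residue
and per-Cα RMSF with the per-motif summary (the WPD-loop motif is jittered
hardest in the amplified scenario), the inter-domain centroid distance,
the 5 Å time-averaged contact matrix, and the buried interface area.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "analysis"))
from common import DATA_DIR, RESULTS_DIR, SEED, spawn_seeds  # noqa: E402

from tandemptp.annotations import demo_motifs
from tandemptp.contacts import compute_contact_matrix
from tandemptp.sasa import compute_buried_surface
from tandemptp.synthetic import TrajectorySpec, generate_two_domain_trajectory
from tandemptp.trajectory import (
    compute_centroid_distance,
    compute_rmsf,
    detect_equilibration,
    motif_rmsf_summary,
    read_trajectory_pdb,
    rmsd_series,
    superpose,
)


def main() -> None:
    outdir = RESULTS_DIR / "trajectory"
    outdir.mkdir(parents=True, exist_ok=True)

    traj = read_trajectory_pdb(DATA_DIR / "trajectory_DLAR.pdb")
    print(f"trajectory: {traj.n_frames} frames, {traj.n_atoms} atoms, "
          f"{traj.n_residues} residues")

    # the generated trajectory is stationary, so with a band wide enough
    # for the inter-domain breathing (±1 Å separation SD) the series is
    # equilibrated from the start
    rmsd = rmsd_series(traj, reference=0)
    start = detect_equilibration(rmsd, window=50, band=0.3)
    print(f"RMSD vs frame 0: mean {rmsd.mean():.2f} Å; "
          f"equilibrated from frame {start}")

    fitted = superpose(traj)
    profile = compute_rmsf(fitted)
    pd.DataFrame(
        {
            "residue": profile.residues["residue"],
            "chain": profile.residues["chain"],
            "res_id": profile.residues["res_id"],
            "rmsf_all_atom": profile.per_residue,
            "rmsf_ca": profile.per_ca,
        }
    ).to_csv(outdir / "rmsf_per_residue.csv", index=False)

    # motif summary on a WPD-amplified variant: the WPD-loop motif (8) is
    # given 3x the jitter of the rest, mirroring the flexibility a closing
    # catalytic loop needs
    motifs = demo_motifs(30)
    jitter = np.full(60, 0.3)
    for r in motifs.residues_by_motif()[8]:
        jitter[r] = 0.9
    amplified = generate_two_domain_trajectory(
        TrajectorySpec(
            n_frames=300, centroid_separation_mean=3.74,
            centroid_separation_sd=0.0, per_residue_jitter_sd=list(jitter),
            seed=spawn_seeds(SEED, 20)[19],
        )
    )
    amp_profile = compute_rmsf(superpose(amplified))
    table = motif_rmsf_summary(amp_profile, motifs)
    table.to_csv(outdir / "motif_rmsf.csv", index=False)
    argmax = int(table.loc[table["is_max"], "motif"].iloc[0])
    print(f"motif RMSF (WPD-amplified scenario): maximal for motif {argmax} "
          f"({table['mean_rmsf'].max():.2f} Å)")

    geom = compute_centroid_distance(traj)
    print(f"inter-domain centroid distance: {geom.mean_nm:.3f} ± {geom.sd_nm:.3f} nm")

    cm = compute_contact_matrix(traj, cutoff=5.0)
    cm.to_tsv(outdir / "contact_matrix_DLAR.tsv")
    n_contacts = int(cm.adjacency().sum() // 2)
    print(f"5 Å time-averaged contact matrix: {n_contacts} residue contacts")

    sasa = compute_buried_surface(traj, n_points=240, frames=np.arange(0, 500, 100))
    print(f"buried interface area at the DLAR separation: "
          f"{sasa['buried_area']:.1f} Å² — the compact pseudo-domains do "
          f"not touch at 3.74 nm; real PTP domains are an order of "
          f"magnitude larger and do")

    # a contact-geometry variant shows the measure responding: domains
    # close enough to occlude each other bury a positive interface
    touching = generate_two_domain_trajectory(
        TrajectorySpec(
            n_frames=2, centroid_separation_mean=1.3,
            centroid_separation_sd=0.0, per_residue_jitter_sd=0.0,
            seed=spawn_seeds(SEED, 21)[20],
        )
    )
    sasa_touch = compute_buried_surface(touching, n_points=240, frames=[0])
    print(f"buried interface area at a touching 1.3 nm separation: "
          f"{sasa_touch['buried_area']:.1f} Å²")

    (outdir / "geometry.json").write_text(
        json.dumps(
            {
                "equilibration_start_frame": start,
                "centroid_mean_nm": geom.mean_nm,
                "centroid_sd_nm": geom.sd_nm,
                "n_contacts_5A": n_contacts,
                "buried_area_A2": sasa["buried_area"],
                "buried_area_touching_A2": sasa_touch["buried_area"],
                "sasa_domain": sasa["sasa_domain"],
                "sasa_complex": sasa["sasa_complex"],
            },
            indent=2, default=float,
        )
    )
    print(f"tables -> {outdir}")


if __name__ == "__main__":
    main()
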