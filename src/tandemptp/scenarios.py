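"""Study-condition parameterisations for the DLAR / PTP99A analyses.

This module centralises the published measurement scales the synthetic
generator emulates — pNPP specific activities of the four active
constructs, SPR rate constants of the DLAR peptide interactions, the
inter-domain centroid geometry from the MD runs — plus the five
phosphopeptide substrates. Analysis drivers, tests and the acceptance
script all draw their scenario definitions from here so the conditions
are stated once.
"""

from __future__ import annotations

import numpy as np

from tandemptp.binding import SPRKineticFit
from tandemptp.synthetic import (
    KineticSite,
    MMDatasetSpec,
    SensogramSpec,
    TrajectorySpec,
)

__all__ = [
    "PEPTIDES",
    "SPECIFIC_ACTIVITIES",
    "SUBSTRATE_RANKINGS",
    "PNPP_KM_MM",
    "SPR_SCENARIOS",
    "CENTROID_DISTANCE_NM",
    "mm_scenario_spec",
    "spr_scenario_spec",
    "trajectory_scenario_spec",
    "first_site_kd_uM",
]

#: The five phosphotyrosine peptide substrates (pY = phosphotyrosine).
PEPTIDES = {
    "insulin_receptor": "TRDIpYETDYYR",
    "cuticle": "TAEPDpYGALYE",
    "nervous_fingers": "VIGDpYVCRLCK",
    "myospheroid": "CDDSpYFGNKC",
    "abelson": "RDDTpYTAHAG",
}

#: pNPP specific activities (µmol·min⁻¹·mg⁻¹) of the active constructs.
SPECIFIC_ACTIVITIES = {
    "DLAR_D1": 20.56,
    "DLAR_D1D2": 6.19,
    "PTP99A_D1": 0.22,
    "PTP99A_D1D2": 24.89,
}

#: Published substrate-preference orders (best first) per construct.
SUBSTRATE_RANKINGS = {
    "DLAR_D1D2": ["cuticle", "insulin_receptor", "nervous_fingers", "abelson", "myospheroid"],
    "PTP99A_D1D2": ["insulin_receptor", "cuticle", "myospheroid", "abelson", "nervous_fingers"],
    "DLAR_D1": ["insulin_receptor", "cuticle", "nervous_fingers", "myospheroid", "abelson"],
    "DLAR_D2": ["insulin_receptor", "nervous_fingers", "cuticle", "myospheroid", "abelson"],
    "PTP99A_D1": ["abelson", "cuticle", "nervous_fingers", "myospheroid", "insulin_receptor"],
    "PTP99A_D2": ["nervous_fingers", "abelson", "cuticle", "myospheroid", "insulin_receptor"],
}

#: Nominal pNPP Km (mM). The study reports activities, not Km values, so
#: the generator uses a typical PTP-domain pNPP Km.
PNPP_KM_MM = 2.0

#: Two-independent-site SPR scenarios for the DLAR D1HSS D2 construct.
#: Site 1 is the weak D1 site, site 2 the strong D2 site. Cuticle rates
#: are the published per-site constants; for the insulin-receptor peptide
#: only the first-site equilibrium KD (1.65 µM) is published, so the
#: scenario keeps the cuticle ka scales with kd = ka * KD, and gives the
#: second site the stronger affinity reported qualitatively (0.2 µM).
#: Rmax values are typical Biacore peptide scales (unpublished).
SPR_SCENARIOS = {
    "cuticle": {
        "sites": [
            KineticSite(ka=74.7, kd=65.4e-4, rmax=100.0),
            KineticSite(ka=2.88e4, kd=540e-4, rmax=60.0),
        ],
        "first_site_kd_uM": 87.5,
    },
    "insulin_receptor": {
        "sites": [
            KineticSite(ka=74.7, kd=74.7 * 1.65e-6, rmax=100.0),
            KineticSite(ka=2.88e4, kd=2.88e4 * 0.2e-6, rmax=60.0),
        ],
        "first_site_kd_uM": 1.65,
    },
}

#: Inter-domain centroid distance (mean, sd) in nm from the MD runs.
CENTROID_DISTANCE_NM = {"DLAR": (3.74, 0.02), "PTP99A": (3.83, 0.04)}


def mm_scenario_spec(construct: str, seed: int) -> MMDatasetSpec:
    """Saturation-assay generator spec at a construct's published
    specific activity: 12 substrate concentrations spanning 0.05-20x Km,
    3 replicates, 2% CV multiplicative noise."""
    vmax = SPECIFIC_ACTIVITIES[construct]
    concs = list(np.geomspace(0.05 * PNPP_KM_MM, 20 * PNPP_KM_MM, 12))
    return MMDatasetSpec(
        vmax=vmax, km=PNPP_KM_MM, substrate_concs=concs,
        replicates=3, noise_cv=0.02, seed=seed,
    )


def spr_scenario_spec(peptide: str, seed: int) -> SensogramSpec:
    """Sensogram generator spec for a DLAR D1HSS D2 peptide scenario:
    5 analyte concentrations over the published 50-700 µM range, 600 s
    association and dissociation, additive noise at 1% of total Rmax."""
    sites = SPR_SCENARIOS[peptide]["sites"]
    total_rmax = sum(s.rmax for s in sites)
    return SensogramSpec(
        sites=sites,
        analyte_concs=[50e-6, 150e-6, 300e-6, 500e-6, 700e-6],
        t_assoc=600.0, t_dissoc=600.0, sampling_dt=1.0,
        noise_sd=0.01 * total_rmax, seed=seed,
    )


def trajectory_scenario_spec(
    rptp: str = "DLAR", seed: int = 0, n_frames: int = 500
) -> TrajectorySpec:
    """Two-rigid-domain trajectory spec at an RPTP's published
    inter-domain geometry. The per-frame separation SD (0.1 nm) and the
    0.3 Å per-residue jitter are generator choices at realistic
    equilibrated-MD scales; the published ±0.02 nm is the uncertainty of
    the mean, which 500 frames resolve."""
    mean_nm, _ = CENTROID_DISTANCE_NM[rptp]
    return TrajectorySpec(
        n_frames=n_frames,
        centroid_separation_mean=mean_nm,
        centroid_separation_sd=0.1,
        per_residue_jitter_sd=0.3,
        seed=seed,
    )


def first_site_kd_uM(fit: SPRKineticFit) -> float:
    """Equilibrium KD (µM) of the fitted first (weak, D1) site — the
    site with the larger kd/ka among the fitted sites."""
    return max(s.kd_eq for s in fit.sites if s.rmax > 0) * 1e6
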