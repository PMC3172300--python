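"""Synthetic-data generators for every pipeline input.

Each generator draws from a model with known ground truth — a saturating
Michaelis-Menten velocity curve, a one/two-independent-site Langmuir
sensogram, a hyperbolic quench titration, or a two-rigid-domain
pseudo-trajectory — so every downstream fitting and analysis stage can be
tested for parameter recovery without external data.

Noise conventions: assay and titration signals carry multiplicative
Gaussian noise (coefficient-of-variation parameterised), sensograms carry
additive Gaussian noise in response units, trajectories carry isotropic
per-atom positional jitter. All randomness flows through one
``numpy.random.Generator`` seeded per call; nothing touches global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from tandemptp.contacts import ContactMatrix
from tandemptp.trajectory import Trajectory, write_trajectory_pdb

__all__ = [
    "KineticSite",
    "BindingSite",
    "MMDatasetSpec",
    "SensogramSpec",
    "TitrationSpec",
    "TrajectorySpec",
    "generate_mm_dataset",
    "generate_sensogram",
    "generate_titration",
    "generate_two_domain_trajectory",
    "grid_domain_template",
    "contact_matrix_from_pairs",
]


class KineticSite(NamedTuple):
    """One Langmuir binding site: association rate ka (M^-1 s^-1),
    dissociation rate kd (s^-1), saturating response rmax (RU)."""

    ka: float
    kd: float
    rmax: float


class BindingSite(NamedTuple):
    """One equilibrium site: dissociation constant kd (concentration
    units of the titration) and signal amplitude at saturation."""

    kd: float
    amplitude: float


# ---------------------------------------------------------------------------
# Michaelis-Menten assay
# ---------------------------------------------------------------------------

@dataclass
class MMDatasetSpec:
    """Ground truth for a saturation assay: velocity = vmax*S/(Km+S) with
    multiplicative Gaussian noise of fractional SD ``noise_cv``.

    Units are caller-chosen and carried through unchanged (vmax in e.g.
    µmol·min⁻¹·mg⁻¹, concentrations in mM)."""

    vmax: float
    km: float
    substrate_concs: Sequence[float]
    replicates: int = 1
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError("vmax and km must be positive")
        concs = np.asarray(self.substrate_concs, dtype=float)
        if concs.size == 0 or np.any(concs <= 0):
            raise ValueError("all substrate concentrations must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def generate_mm_dataset(spec: MMDatasetSpec) -> pd.DataFrame:
    """Generate a saturation-assay table (substrate_conc, velocity,
    replicate), reproducible under a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    concs = np.asarray(spec.substrate_concs, dtype=float)
    rows = []
    for rep in range(spec.replicates):
        v = spec.vmax * concs / (spec.km + concs)
        eps = rng.normal(0.0, spec.noise_cv, size=concs.size) if spec.noise_cv > 0 else 0.0
        rows.append(
            pd.DataFrame(
                {"substrate_conc": concs, "velocity": v * (1.0 + eps), "replicate": rep}
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# SPR sensograms
# ---------------------------------------------------------------------------

@dataclass
class SensogramSpec:
    """Ground truth for association/dissociation sensograms from one or
    two independent Langmuir sites.

    Association (site i, analyte concentration C):
        R_i(t) = Rmax_i * C/(C + kd_i/ka_i) * (1 - exp(-(ka_i*C + kd_i)*t))
    Dissociation:
        R_i(t) = R_i(t_assoc) * exp(-kd_i * (t - t_assoc))
    Total response is the sum over sites plus additive Gaussian noise.
    """

    sites: Sequence[KineticSite]
    analyte_concs: Sequence[float]
    t_assoc: float = 600.0
    t_dissoc: float = 600.0
    sampling_dt: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.sites = [KineticSite(*s) for s in self.sites]
        if not 1 <= len(self.sites) <= 2:
            raise ValueError("sites must contain 1 or 2 entries")
        for s in self.sites:
            if s.ka <= 0 or s.kd <= 0 or s.rmax < 0:
                raise ValueError("ka, kd must be positive and rmax non-negative")
        concs = np.asarray(self.analyte_concs, dtype=float)
        if concs.size == 0 or np.any(concs <= 0):
            raise ValueError("analyte concentrations must be positive")
        if self.t_assoc <= 0 or self.t_dissoc <= 0 or self.sampling_dt <= 0:
            raise ValueError("t_assoc, t_dissoc and sampling_dt must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _sensogram_response(
    sites: Sequence[KineticSite], conc: float, t: np.ndarray, t_assoc: float
) -> np.ndarray:
    total = np.zeros_like(t, dtype=float)
    for ka, kd, rmax in sites:
        kd_eq = kd / ka
        req = rmax * conc / (conc + kd_eq)
        kobs = ka * conc + kd
        r_end = req * (1.0 - np.exp(-kobs * t_assoc))
        assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, t_assoc)))
        dissoc = r_end * np.exp(-kd * np.maximum(t - t_assoc, 0.0))
        total += np.where(t <= t_assoc, assoc, dissoc)
    return total


def generate_sensogram(spec: SensogramSpec) -> pd.DataFrame:
    """Generate sensogram tables (time_s, response_RU, conc_M, phase) for
    every analyte concentration."""
    rng = np.random.default_rng(spec.seed)
    t_a = np.arange(0.0, spec.t_assoc + spec.sampling_dt / 2, spec.sampling_dt)
    t_d = np.arange(spec.t_assoc + spec.sampling_dt,
                    spec.t_assoc + spec.t_dissoc + spec.sampling_dt / 2,
                    spec.sampling_dt)
    t = np.concatenate([t_a, t_d])
    phase = np.array(["assoc"] * t_a.size + ["dissoc"] * t_d.size)
    frames = []
    for conc in np.asarray(spec.analyte_concs, dtype=float):
        r = _sensogram_response(spec.sites, conc, t, spec.t_assoc)
        if spec.noise_sd > 0:
            r = r + rng.normal(0.0, spec.noise_sd, size=r.size)
        frames.append(
            pd.DataFrame(
                {"time_s": t, "response_RU": r, "conc_M": conc, "phase": phase}
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Fluorescence quench titrations
# ---------------------------------------------------------------------------

@dataclass
class TitrationSpec:
    """Ground truth for a hyperbolic quench titration:
    F(L) = f0 - sum_i A_i * L / (KD_i + L), multiplicative CV noise."""

    sites: Sequence[BindingSite]
    ligand_concs: Sequence[float]
    f0: float = 100.0
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.sites = [BindingSite(*s) for s in self.sites]
        if not self.sites:
            raise ValueError("at least one binding site required")
        for s in self.sites:
            if s.kd <= 0:
                raise ValueError("site kd must be positive")
            if s.amplitude < 0:
                raise ValueError("site amplitude must be >= 0")
        concs = np.asarray(self.ligand_concs, dtype=float)
        if concs.size == 0 or np.any(concs < 0):
            raise ValueError("ligand concentrations must be non-negative")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def generate_titration(spec: TitrationSpec) -> pd.DataFrame:
    """Generate a titration table (ligand_conc, signal)."""
    rng = np.random.default_rng(spec.seed)
    concs = np.asarray(spec.ligand_concs, dtype=float)
    f = np.full(concs.size, spec.f0, dtype=float)
    for kd, amp in spec.sites:
        f -= amp * concs / (kd + concs)
    if spec.noise_cv > 0:
        f = f * (1.0 + rng.normal(0.0, spec.noise_cv, size=f.size))
    return pd.DataFrame({"ligand_conc": concs, "signal": f})


# ---------------------------------------------------------------------------
# Two-rigid-domain trajectories
# ---------------------------------------------------------------------------

def grid_domain_template(n_residues: int = 30, spacing: float = 3.8) -> np.ndarray:
    """Cα positions of a compact pseudo-domain: a serpentine walk on a
    3 x 3 x k cubic grid with consecutive-residue spacing ``spacing`` Å
    (the canonical Cα-Cα distance), centred at its centroid.

    The result is deliberately chemistry-free — it only provides the
    statistical structure (compactness, contiguous chain, one atom per
    residue) that contact/RMSF analyses assume.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    pts = []
    x = y = z = 0
    dx = dy = 1
    for _ in range(n_residues):
        pts.append((x, y, z))
        if 0 <= x + dx <= 2:
            x += dx
        elif 0 <= y + dy <= 2:
            y += dy
            dx = -dx
        else:
            z += 1
            dx, dy = -dx, -dy
    coords = np.asarray(pts, dtype=float) * spacing
    return coords - coords.mean(axis=0)


@dataclass
class TrajectorySpec:
    """Ground truth for a two-rigid-domain pseudo-trajectory.

    Per frame, domain 2 is translated along the inter-domain axis so the
    centroid distance is drawn from
    Normal(``centroid_separation_mean``, ``centroid_separation_sd``) (nm),
    then every atom receives isotropic Gaussian jitter with its residue's
    SD (Å). ``forced_contacts`` lists ``(res_i, res_j, target_Å)`` triples
    (global 0-based residue indices); the second residue of each pair is
    repositioned so the noise-free mean minimum atom distance equals the
    target. Repositioning beyond ``max_contact_displacement`` Å of the
    residue's template position is rejected as geometrically infeasible
    (e.g. a cross-domain contact at a separation the domains cannot
    bridge).
    """

    n_frames: int = 100
    domain_templates: tuple[np.ndarray, np.ndarray] | None = None
    centroid_separation_mean: float = 3.74  # nm
    centroid_separation_sd: float = 0.0     # nm
    per_residue_jitter_sd: float | Sequence[float] = 0.0  # Å
    forced_contacts: Sequence[tuple[int, int, float]] = field(default_factory=tuple)
    max_contact_displacement: float = 12.0  # Å
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.centroid_separation_mean <= 0:
            raise ValueError("centroid separation must be positive")
        if self.centroid_separation_sd < 0:
            raise ValueError("centroid separation sd must be >= 0")
        if np.any(np.asarray(self.per_residue_jitter_sd, dtype=float) < 0):
            raise ValueError("jitter sd must be >= 0")


def _build_templates(spec: TrajectorySpec) -> tuple[np.ndarray, np.ndarray]:
    if spec.domain_templates is not None:
        t1, t2 = (np.array(t, dtype=float) for t in spec.domain_templates)
    else:
        t1, t2 = grid_domain_template(), grid_domain_template()
    return t1 - t1.mean(axis=0), t2 - t2.mean(axis=0)


def _apply_forced_contacts(
    t1: np.ndarray, t2: np.ndarray, spec: TrajectorySpec, sep_mean: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Reposition contact partners and return (t1, t2, calibrated offset).

    Domain 2 sits at ``offset * x_hat``; the offset solves for the exact
    centroid distance after repositioning shifts domain 2's centroid.
    Fixed-point iteration converges in a few rounds because the centroid
    shift per moved residue is O(1/n_residues).
    """
    n1 = t1.shape[0]
    xhat = np.array([1.0, 0.0, 0.0])
    orig1, orig2 = t1.copy(), t2.copy()

    def offset_for(t2_now: np.ndarray) -> float:
        c2 = t2_now.mean(axis=0)
        rad2 = c2[1] ** 2 + c2[2] ** 2
        if sep_mean**2 <= rad2:
            raise ValueError("forced contacts shift domain 2 beyond the requested separation")
        return float(-c2[0] + np.sqrt(sep_mean**2 - rad2))

    offset = offset_for(t2)
    for _ in range(8):
        for i, j, target in spec.forced_contacts:
            if target <= 0:
                raise ValueError("forced contact target distance must be positive")
            if i < n1 and j < n1:  # both in domain 1
                u = orig1[j] - orig1[i]
                u = u / np.linalg.norm(u) if np.linalg.norm(u) > 1e-9 else xhat
                t1[j] = t1[i] + target * u
            elif i < n1 <= j:  # i in domain 1, j in domain 2
                t2[j - n1] = t1[i] + target * xhat - offset * xhat
            elif j < n1 <= i:
                t2[i - n1] = t1[j] + target * xhat - offset * xhat
            else:  # both in domain 2
                u = orig2[j - n1] - orig2[i - n1]
                u = u / np.linalg.norm(u) if np.linalg.norm(u) > 1e-9 else xhat
                t2[j - n1] = t2[i - n1] + target * u
        offset = offset_for(t2)

    # verify feasibility and accuracy at the noise-free mean geometry
    world = np.vstack([t1, t2 + offset * xhat])
    orig_world = np.vstack([orig1, orig2 + offset * xhat])
    moved = np.linalg.norm(world - orig_world, axis=1)
    for i, j, target in spec.forced_contacts:
        d = np.linalg.norm(world[i] - world[j])
        if abs(d - target) > 0.05:
            raise ValueError(
                f"forced contact ({i},{j}) unsatisfiable: placed at {d:.2f} Å "
                f"for target {target:.2f} Å"
            )
        if max(moved[i], moved[j]) > spec.max_contact_displacement:
            raise ValueError(
                f"forced contact ({i},{j}) infeasible: requires moving a residue "
                f"{max(moved[i], moved[j]):.1f} Å (> {spec.max_contact_displacement} Å); "
                "the domains are farther apart than the contact allows"
            )
    return t1, t2, offset


def generate_two_domain_trajectory(
    spec: TrajectorySpec, pdb_path=None
) -> Trajectory:
    """Generate a two-rigid-domain Cα pseudo-trajectory (chains A and B).

    Optionally writes a multi-model PDB to ``pdb_path``. Deterministic
    under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    t1, t2 = _build_templates(spec)
    n1, n2 = t1.shape[0], t2.shape[0]
    sep_mean = spec.centroid_separation_mean * 10.0  # nm -> Å
    sep_sd = spec.centroid_separation_sd * 10.0
    t1, t2, _ = _apply_forced_contacts(t1, t2, spec, sep_mean)

    c2 = t2.mean(axis=0)
    rad2 = c2[1] ** 2 + c2[2] ** 2

    jitter = np.asarray(spec.per_residue_jitter_sd, dtype=float)
    if jitter.ndim == 0:
        jitter = np.full(n1 + n2, float(jitter))
    if jitter.size != n1 + n2:
        raise ValueError(
            f"per_residue_jitter_sd must be scalar or length {n1 + n2}"
        )

    seps = (
        rng.normal(sep_mean, sep_sd, size=spec.n_frames)
        if sep_sd > 0
        else np.full(spec.n_frames, sep_mean)
    )
    if np.any(seps**2 <= rad2):
        raise ValueError("drawn separation smaller than domain-2 centroid offset")
    offsets = -c2[0] + np.sqrt(seps**2 - rad2)

    coords = np.empty((spec.n_frames, n1 + n2, 3))
    coords[:, :n1] = t1
    coords[:, n1:] = t2
    coords[:, n1:, 0] += offsets[:, None]
    if np.any(jitter > 0):
        noise = rng.normal(size=(spec.n_frames, n1 + n2, 3)) * jitter[None, :, None]
        coords += noise

    topo = pd.DataFrame(
        {
            "chain": ["A"] * n1 + ["B"] * n2,
            "res_id": list(range(1, n1 + 1)) + list(range(1, n2 + 1)),
            "res_name": "ALA",
            "atom_name": "CA",
            "element": "C",
        }
    )
    traj = Trajectory(coords, topo)
    if pdb_path is not None:
        write_trajectory_pdb(traj, pdb_path)
    return traj


# ---------------------------------------------------------------------------
# Synthetic contact matrices (network-stage scenarios)
# ---------------------------------------------------------------------------

def contact_matrix_from_pairs(
    n_residues: int,
    contact_pairs: Sequence[tuple[int, int]],
    contact_distance: float = 4.0,
    background_distance: float = 8.0,
    neighbor_distance: float = 3.8,
    cutoff: float = 5.0,
) -> ContactMatrix:
    """Build a synthetic time-averaged contact matrix directly from a
    prescribed contact list (all other pairs at a background distance,
    sequence neighbours at the backbone distance).

    Used to pose network-stage scenarios — e.g. a D1-like matrix in which
    active-site, WPD-loop and substrate-recognition residues touch each
    other — without simulating a trajectory.
    """
    if contact_distance >= cutoff or background_distance < cutoff:
        raise ValueError("need contact_distance < cutoff <= background_distance")
    d = np.full((n_residues, n_residues), background_distance, dtype=float)
    idx = np.arange(n_residues)
    d[idx[:-1], idx[:-1] + 1] = neighbor_distance
    d[idx[:-1] + 1, idx[:-1]] = neighbor_distance
    for i, j in contact_pairs:
        if not (0 <= i < n_residues and 0 <= j < n_residues) or i == j:
            raise ValueError(f"invalid contact pair ({i}, {j})")
        d[i, j] = d[j, i] = contact_distance
    np.fill_diagonal(d, 0.0)
    freq = (d < cutoff).astype(float)
    np.fill_diagonal(freq, 0.0)
    residues = pd.DataFrame(
        {
            "residue": np.arange(n_residues),
            "chain": "A",
            "res_id": np.arange(1, n_residues + 1),
            "res_name": "ALA",
        }
    )
    return ContactMatrix(
        mean_distance=d,
        frequency=freq,
        cutoff=cutoff,
        window=(0, 1),
        reducer="synthetic",
        residues=residues,
    )
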