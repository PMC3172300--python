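"""Trajectory container, multi-model PDB I/O, superposition and fluctuation
analysis.

Coordinates are stored in ångström throughout; inter-domain centroid
distances are reported in nanometres, the convention for domain-scale
geometry. Domains are identified by chain ID (one chain per pseudo-domain
or PTP domain).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Trajectory",
    "RMSFProfile",
    "DomainGeometry",
    "read_trajectory_pdb",
    "write_trajectory_pdb",
    "superpose",
    "rmsd_series",
    "detect_equilibration",
    "compute_rmsf",
    "motif_rmsf_summary",
    "compute_centroid_distance",
]

TOPOLOGY_COLUMNS = ["chain", "res_id", "res_name", "atom_name", "element"]


@dataclass
class Trajectory:
    """An MD-style trajectory: frames x atoms x 3 coordinates plus a flat
    per-atom topology table.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in Å.
    topology
        DataFrame with columns ``chain, res_id, res_name, atom_name,
        element`` (one row per atom). Residue numbering must be contiguous
        within each chain.
    frame_times
        Optional per-frame times in ns.
    """

    coords: np.ndarray
    topology: pd.DataFrame
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.topology) != self.coords.shape[1]:
            raise ValueError(
                f"topology has {len(self.topology)} atoms but coords has "
                f"{self.coords.shape[1]}"
            )
        missing = [c for c in TOPOLOGY_COLUMNS if c not in self.topology.columns]
        if missing:
            raise ValueError(f"topology missing columns: {missing}")
        self._check_contiguous_residues()

    def _check_contiguous_residues(self) -> None:
        for chain, sub in self.topology.groupby("chain", sort=False):
            ids = sub["res_id"].to_numpy()
            uniq = pd.unique(ids)
            if np.any(np.diff(uniq) != 1):
                raise ValueError(f"residue ids not contiguous in chain {chain!r}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def residue_index(self) -> np.ndarray:
        """Global 0-based residue index per atom, ordered by first appearance."""
        key = list(zip(self.topology["chain"], self.topology["res_id"]))
        seen: dict = {}
        out = np.empty(len(key), dtype=int)
        for i, k in enumerate(key):
            out[i] = seen.setdefault(k, len(seen))
        return out

    @property
    def n_residues(self) -> int:
        return int(self.residue_index.max()) + 1 if self.n_atoms else 0

    def residue_table(self) -> pd.DataFrame:
        """One row per residue: global index, chain, res_id, res_name."""
        df = self.topology.assign(residue=self.residue_index)
        return (
            df.drop_duplicates("residue")[["residue", "chain", "res_id", "res_name"]]
            .reset_index(drop=True)
        )

    def atom_mask(self, chain: str | None = None, atom_name: str | None = None) -> np.ndarray:
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            mask &= (self.topology["chain"] == chain).to_numpy()
        if atom_name is not None:
            mask &= (self.topology["atom_name"] == atom_name).to_numpy()
        return mask

    def slice_frames(self, frames: slice | np.ndarray) -> "Trajectory":
        times = None if self.frame_times is None else np.asarray(self.frame_times)[frames]
        return Trajectory(self.coords[frames], self.topology, times)


def _to_atom_array_stack(traj: Trajectory) -> struc.AtomArrayStack:
    stack = struc.AtomArrayStack(traj.n_frames, traj.n_atoms)
    stack.chain_id = traj.topology["chain"].to_numpy(dtype="U4")
    stack.res_id = traj.topology["res_id"].to_numpy(dtype=int)
    stack.res_name = traj.topology["res_name"].to_numpy(dtype="U5")
    stack.atom_name = traj.topology["atom_name"].to_numpy(dtype="U6")
    stack.element = traj.topology["element"].to_numpy(dtype="U2")
    stack.hetero = np.zeros(traj.n_atoms, dtype=bool)
    stack.coord = traj.coords.copy()
    return stack


def write_trajectory_pdb(traj: Trajectory, path) -> None:
    """Write a multi-model PDB (one MODEL/ENDMDL block per frame)."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array_stack(traj))
    pdb.write(str(path))


def read_trajectory_pdb(path, frame_times: np.ndarray | None = None) -> Trajectory:
    """Read a multi-model PDB into a :class:`Trajectory`."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    topo = pd.DataFrame(
        {
            "chain": stack.chain_id,
            "res_id": stack.res_id,
            "res_name": stack.res_name,
            "atom_name": stack.atom_name,
            "element": stack.element,
        }
    )
    return Trajectory(np.asarray(stack.coord, dtype=float), topo, frame_times)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rigid transform (R, t) minimising ||R @ mobile + t - target||.

    Returns a proper rotation (det = +1) via SVD with reflection correction.
    """
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = tc - rot @ mc
    return rot, trans


def _check_selection(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise ValueError("superposition selection needs at least 3 atoms")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("superposition selection is collinear or degenerate")


def superpose(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    n_mean_iterations: int = 2,
) -> Trajectory:
    """Least-squares superpose every frame onto an iterated mean structure.

    Each frame is rigidly transformed (rotation with det +1, plus
    translation) to minimise the RMSD of ``selection`` atoms to the
    reference. The reference starts as frame 0 and is refined
    ``n_mean_iterations`` times by re-fitting to the mean of the fitted
    frames, which removes the arbitrariness of the first frame.
    """
    if selection is None:
        selection = np.ones(traj.n_atoms, dtype=bool)
    sel = np.asarray(selection)
    if sel.dtype == bool:
        sel = np.flatnonzero(sel)
    _check_selection(traj.coords[0, sel])

    reference = traj.coords[0, sel]
    fitted = traj.coords
    for _ in range(max(1, n_mean_iterations)):
        out = np.empty_like(traj.coords)
        for f in range(traj.n_frames):
            rot, trans = _kabsch(traj.coords[f, sel], reference)
            out[f] = traj.coords[f] @ rot.T + trans
        fitted = out
        reference = fitted[:, sel].mean(axis=0)
    return Trajectory(fitted, traj.topology, traj.frame_times)


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray | int = 0,
    selection: np.ndarray | None = None,
    fit: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Å) of selected atoms against a reference structure.

    ``reference`` is a frame index or an ``(n_atoms, 3)`` array. With
    ``fit=True`` each frame is first optimally superposed on the reference
    over the selection, the convention used when monitoring equilibration
    against the starting model.
    """
    if selection is None:
        selection = np.ones(traj.n_atoms, dtype=bool)
    sel = np.asarray(selection)
    if sel.dtype == bool:
        sel = np.flatnonzero(sel)
    ref = traj.coords[reference] if isinstance(reference, (int, np.integer)) else np.asarray(reference)
    ref_sel = ref[sel]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        mob = traj.coords[f, sel]
        if fit:
            rot, trans = _kabsch(mob, ref_sel)
            mob = mob @ rot.T + trans
        out[f] = np.sqrt(np.mean(np.sum((mob - ref_sel) ** 2, axis=1)))
    return out


def detect_equilibration(
    series: np.ndarray,
    window: int,
    band: float,
    times: np.ndarray | None = None,
):
    """First index (or time) from which the trajectory is equilibrated.

    A series is considered equilibrated from index ``k`` when every
    forward-looking windowed mean starting at or after ``k`` stays within
    ``±band`` of the terminal windowed mean. The terminal window alone
    always matches itself, so an equilibrated stretch must begin at least
    one full window before the final one; otherwise ``None`` is returned
    ("not equilibrated").
    """
    series = np.asarray(series, dtype=float)
    if window > len(series):
        raise ValueError("window longer than series")
    if window < 1:
        raise ValueError("window must be >= 1")
    kernel = np.ones(window) / window
    wmeans = np.convolve(series, kernel, mode="valid")
    terminal = wmeans[-1]
    ok = np.abs(wmeans - terminal) <= band
    # last False, then everything after is True
    bad = np.flatnonzero(~ok)
    start = 0 if bad.size == 0 else int(bad[-1]) + 1
    if start > len(wmeans) - window:
        return None
    return start if times is None else np.asarray(times)[start]


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

@dataclass
class RMSFProfile:
    """Root-mean-square fluctuations after superposition.

    ``per_atom`` has one entry per atom; ``per_residue`` aggregates each
    residue's atoms as the RMS of their per-atom values (mass-unweighted);
    ``per_ca`` is the Cα-only profile (NaN for residues without a Cα).
    """

    per_atom: np.ndarray
    per_residue: np.ndarray
    per_ca: np.ndarray
    residues: pd.DataFrame = field(repr=False)


def compute_rmsf(traj: Trajectory) -> RMSFProfile:
    """RMSF_a = sqrt(mean_t ||x_a(t) - <x_a>||^2); expects a superposed
    trajectory (RMSF is only meaningful after removal of rigid-body
    motion)."""
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    mean = traj.coords.mean(axis=0)
    msf = np.mean(np.sum((traj.coords - mean) ** 2, axis=2), axis=0)
    per_atom = np.sqrt(msf)

    res_idx = traj.residue_index
    n_res = traj.n_residues
    per_residue = np.empty(n_res)
    for r in range(n_res):
        per_residue[r] = np.sqrt(np.mean(msf[res_idx == r]))

    per_ca = np.full(n_res, np.nan)
    ca_mask = (traj.topology["atom_name"] == "CA").to_numpy()
    per_ca[res_idx[ca_mask]] = per_atom[ca_mask]
    return RMSFProfile(per_atom, per_residue, per_ca, traj.residue_table())


def motif_rmsf_summary(profile: RMSFProfile, motifs) -> pd.DataFrame:
    """Per-motif mean and max of the per-residue RMSF.

    ``motifs`` is a :class:`tandemptp.annotations.MotifAnnotation`. Motifs
    with empty residue ranges are excluded with a warning. The returned
    table flags the motif of maximal mean RMSF (``is_max`` column) —
    in PTP domains this is expected to be the WPD-loop motif, whose
    flexibility is required for catalysis.
    """
    rows = []
    for motif_id, residues in motifs.residues_by_motif().items():
        residues = [r for r in residues if 0 <= r < len(profile.per_residue)]
        if not residues:
            warnings.warn(f"motif {motif_id} has an empty residue range; excluded")
            continue
        vals = profile.per_residue[np.asarray(residues, dtype=int)]
        rows.append(
            {
                "motif": motif_id,
                "region": motifs.region_of(motif_id),
                "n_residues": len(residues),
                "mean_rmsf": float(np.mean(vals)),
                "max_rmsf": float(np.max(vals)),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["is_max"] = table["mean_rmsf"] == table["mean_rmsf"].max()
    return table


# ---------------------------------------------------------------------------
# Inter-domain geometry
# ---------------------------------------------------------------------------

@dataclass
class DomainGeometry:
    """Inter-domain geometry summary: centroid-distance time series (nm)
    and, when computed, per-domain solvent-accessible and buried surface
    areas (Å²)."""

    centroid_series_nm: np.ndarray
    mean_nm: float
    sd_nm: float
    domains: tuple
    sasa_domain: dict | None = None
    sasa_complex: float | None = None
    buried_area: float | None = None


def compute_centroid_distance(traj: Trajectory, domains: tuple | None = None) -> DomainGeometry:
    """Per-frame distance between the unweighted atom centroids of the two
    domains (chains), reported in nm."""
    chains = list(pd.unique(traj.topology["chain"])) if domains is None else list(domains)
    if len(chains) != 2:
        raise ValueError(f"need exactly two domain labels, got {chains}")
    masks = [traj.atom_mask(chain=c) for c in chains]
    for c, m in zip(chains, masks):
        if not m.any():
            raise ValueError(f"domain {c!r} has no atoms")
    c0 = traj.coords[:, masks[0]].mean(axis=1)
    c1 = traj.coords[:, masks[1]].mean(axis=1)
    series = np.linalg.norm(c0 - c1, axis=1) / 10.0  # Å -> nm
    return DomainGeometry(
        centroid_series_nm=series,
        mean_nm=float(series.mean()),
        sd_nm=float(series.std(ddof=1)) if len(series) > 1 else 0.0,
        domains=tuple(chains),
    )
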