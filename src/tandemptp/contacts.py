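"""Time-averaged inter-residue contact matrices.

A contact map is the N x N matrix of per-frame minimum heavy-atom
distances between residues, averaged over a frame window; residues whose
averaged distance falls below a cutoff (5 Å by default) are "in contact".
Averaging the distance and then thresholding is the default; the
alternative order (threshold per frame, then average into a contact
frequency) is also computed so both conventions can be reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tandemptp.trajectory import Trajectory

__all__ = ["ContactMatrix", "compute_contact_matrix"]


@dataclass
class ContactMatrix:
    """Mean inter-residue distances plus contact adjacency at a cutoff.

    ``mean_distance[i, j]`` is the chosen per-frame residue-residue
    distance (minimum heavy-atom distance by default) averaged over the
    frame window; ``frequency[i, j]`` is the fraction of frames in which
    that distance was below the cutoff. The diagonal is zero by convention
    and never counts as a contact.
    """

    mean_distance: np.ndarray
    frequency: np.ndarray
    cutoff: float
    window: tuple[int, int]
    reducer: str
    residues: pd.DataFrame = field(repr=False)

    @property
    def n_residues(self) -> int:
        return self.mean_distance.shape[0]

    def adjacency(self, cutoff: float | None = None, mode: str = "mean",
                  min_fraction: float = 0.5) -> np.ndarray:
        """Boolean contact matrix.

        ``mode="mean"`` thresholds the time-averaged distance (default);
        ``mode="frequency"`` requires the per-frame contact to hold in at
        least ``min_fraction`` of frames.
        """
        cutoff = self.cutoff if cutoff is None else cutoff
        if mode == "mean":
            adj = self.mean_distance < cutoff
        elif mode == "frequency":
            if cutoff != self.cutoff:
                raise ValueError(
                    "frequency adjacency is defined at the cutoff used during "
                    "matrix computation"
                )
            adj = self.frequency >= min_fraction
        else:
            raise ValueError(f"unknown adjacency mode {mode!r}")
        np.fill_diagonal(adj, False)
        return adj

    def to_tsv(self, path) -> None:
        labels = [
            f"{c}:{r}" for c, r in zip(self.residues["chain"], self.residues["res_id"])
        ]
        pd.DataFrame(self.mean_distance, index=labels, columns=labels).to_csv(
            path, sep="\t", float_format="%.4f"
        )


def _residue_blocks(residue_index: np.ndarray) -> list[np.ndarray]:
    n_res = int(residue_index.max()) + 1
    return [np.flatnonzero(residue_index == r) for r in range(n_res)]


def compute_contact_matrix(
    traj: Trajectory,
    cutoff: float = 5.0,
    window: tuple[int, int] | None = None,
    reducer: str = "min",
    include_hydrogens: bool = False,
) -> ContactMatrix:
    """Compute the time-averaged inter-residue distance matrix.

    Parameters
    ----------
    traj
        Input trajectory (superposition is not required; distances are
        rotation-invariant).
    cutoff
        Contact threshold in Å (5 Å is the standard residue-contact
        convention).
    window
        ``(start, stop)`` frame window; defaults to all frames. Analyses
        of equilibrated segments should pass the post-equilibration window
        explicitly.
    reducer
        Per-frame residue-pair distance: ``"min"`` (minimum heavy-atom
        distance, default), ``"ca"`` (Cα-Cα), or ``"centroid"``
        (residue-centroid distance).
    include_hydrogens
        Whether hydrogens participate in ``"min"`` distances.
    """
    start, stop = (0, traj.n_frames) if window is None else window
    if not (0 <= start < stop <= traj.n_frames):
        raise ValueError(f"invalid frame window {window}")
    coords = traj.coords[start:stop]

    res_idx = traj.residue_index
    if reducer == "min":
        keep = np.ones(traj.n_atoms, dtype=bool)
        if not include_hydrogens:
            keep = (traj.topology["element"].str.upper() != "H").to_numpy()
        if not keep.any() or len(np.unique(res_idx[keep])) != traj.n_residues:
            missing = sorted(set(range(traj.n_residues)) - set(res_idx[keep]))
            raise ValueError(f"residues with no heavy atoms: {missing}")
        coords = coords[:, keep]
        res_idx = res_idx[keep]
        dist_stack = _min_distance_stack(coords, res_idx, traj.n_residues)
    elif reducer == "ca":
        ca = (traj.topology["atom_name"] == "CA").to_numpy()
        if len(np.unique(res_idx[ca])) != traj.n_residues:
            missing = sorted(set(range(traj.n_residues)) - set(res_idx[ca]))
            raise ValueError(f"residues with no CA atom: {missing}")
        pts = coords[:, ca]
        dist_stack = np.linalg.norm(pts[:, :, None, :] - pts[:, None, :, :], axis=-1)
    elif reducer == "centroid":
        blocks = _residue_blocks(res_idx)
        cents = np.stack([coords[:, b].mean(axis=1) for b in blocks], axis=1)
        dist_stack = np.linalg.norm(cents[:, :, None, :] - cents[:, None, :, :], axis=-1)
    else:
        raise ValueError(f"unknown reducer {reducer!r}")

    mean_distance = dist_stack.mean(axis=0)
    np.fill_diagonal(mean_distance, 0.0)
    per_frame_contact = dist_stack < cutoff
    frequency = per_frame_contact.mean(axis=0)
    np.fill_diagonal(frequency, 0.0)
    return ContactMatrix(
        mean_distance=mean_distance,
        frequency=frequency,
        cutoff=cutoff,
        window=(start, stop),
        reducer=reducer,
        residues=traj.residue_table(),
    )


def _min_distance_stack(coords: np.ndarray, res_idx: np.ndarray, n_res: int) -> np.ndarray:
    """Per-frame N x N minimum inter-atomic distance between residues."""
    n_frames, n_atoms = coords.shape[:2]
    ri = np.repeat(res_idx, n_atoms)
    rj = np.tile(res_idx, n_atoms)
    out = np.empty((n_frames, n_res, n_res))
    for f in range(n_frames):
        diff = coords[f][:, None, :] - coords[f][None, :, :]
        d = np.sqrt(np.sum(diff * diff, axis=-1)).ravel()
        frame_min = np.full((n_res, n_res), np.inf)
        np.minimum.at(frame_min, (ri, rj), d)
        out[f] = frame_min
    return out
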