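"""Superposition, RMSD/equilibration, RMSF and inter-domain geometry
against independent oracles (quaternion rotations, brute-force scans)."""

import numpy as np
import pandas as pd
import pytest

from tandemptp.annotations import demo_motifs
from tandemptp.trajectory import (
    Trajectory,
    compute_centroid_distance,
    compute_rmsf,
    detect_equilibration,
    motif_rmsf_summary,
    rmsd_series,
    superpose,
)
from conftest import make_trajectory


def random_rotation(rng):
    """Uniform random proper rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def horn_quaternion_rotation(mobile, target):
    """Independent optimal-rotation oracle (Horn's quaternion method)."""
    a = mobile - mobile.mean(axis=0)
    b = target - target.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    vals, vecs = np.linalg.eigh(k)
    w, x, y, z = vecs[:, np.argmax(vals)]
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestSuperpose:
    def test_rigid_motions_removed_exactly(self, rng):
        base = rng.normal(scale=5.0, size=(12, 3))
        frames = [base]
        for _ in range(9):
            frames.append(base @ random_rotation(rng).T + rng.normal(scale=20.0, size=3))
        traj = superpose(make_trajectory(np.stack(frames)))
        rmsd = rmsd_series(traj, reference=0, fit=False)
        assert np.max(rmsd) < 1e-6

    def test_idempotent(self, rng):
        coords = rng.normal(scale=4.0, size=(6, 10, 3))
        once = superpose(make_trajectory(coords))
        twice = superpose(once)
        assert np.allclose(once.coords, twice.coords, atol=1e-9)

    def test_rotation_matches_quaternion_oracle(self, rng):
        # 100 random 10-atom instances; both methods minimise the same
        # objective, so the fitted coordinates must agree
        from tandemptp.trajectory import _kabsch

        for _ in range(100):
            mobile = rng.normal(scale=3.0, size=(10, 3))
            target = rng.normal(scale=3.0, size=(10, 3))
            rot, trans = _kabsch(mobile, target)
            r_oracle = horn_quaternion_rotation(mobile, target)
            assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
            fitted = mobile @ rot.T + trans
            oracle_fit = (mobile - mobile.mean(axis=0)) @ r_oracle.T + target.mean(axis=0)
            assert np.allclose(fitted, oracle_fit, atol=1e-8)

    def test_degenerate_selection_rejected(self):
        line = np.stack([np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])] * 2)
        with pytest.raises(ValueError, match="collinear|degenerate"):
            superpose(make_trajectory(line))


class TestEquilibration:
    def test_constant_series_starts_at_zero(self):
        assert detect_equilibration(np.ones(50), window=5, band=0.01) == 0

    def test_step_series_detected_at_step(self):
        series = np.concatenate([np.full(20, 2.0), np.full(30, 1.0)])
        assert detect_equilibration(series, window=5, band=0.05) == 20

    def test_never_stabilizing_returns_sentinel(self):
        assert detect_equilibration(np.arange(50.0), window=5, band=0.01) is None

    def test_matches_brute_force_scan(self, rng):
        for _ in range(50):
            n = rng.integers(20, 60)
            k = int(rng.integers(0, n - 10))
            series = np.concatenate(
                [rng.uniform(2, 4, size=k), rng.normal(1.0, 0.05, size=n - k)]
            )
            window, band = 5, 0.2
            wmeans = np.array(
                [series[j : j + window].mean() for j in range(n - window + 1)]
            )
            terminal = wmeans[-1]
            expected = None
            for start in range(len(wmeans) - window + 1):
                if np.all(np.abs(wmeans[start:] - terminal) <= band):
                    expected = start
                    break
            assert detect_equilibration(series, window, band) == expected

    def test_times_are_mapped(self):
        series = np.concatenate([np.full(10, 2.0), np.full(20, 1.0)])
        times = np.linspace(0.0, 29.0, 30)
        assert detect_equilibration(series, 4, 0.05, times=times) == pytest.approx(10.0)


class TestRMSF:
    def test_static_trajectory_is_zero(self):
        coords = np.stack([np.arange(30.0).reshape(10, 3)] * 5)
        prof = compute_rmsf(make_trajectory(coords))
        assert np.all(prof.per_atom == 0)
        assert np.all(prof.per_residue == 0)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            compute_rmsf(make_trajectory(np.zeros((1, 5, 3))))

    def test_invariant_under_global_rigid_motion(self, rng):
        coords = rng.normal(scale=3.0, size=(20, 8, 3))
        prof = compute_rmsf(superpose(make_trajectory(coords)))
        rot = random_rotation(rng)
        moved = np.einsum("fij,kj->fik", coords, rot) + np.array([5.0, -3.0, 8.0])
        prof2 = compute_rmsf(superpose(make_trajectory(moved)))
        assert np.allclose(prof.per_atom, prof2.per_atom, atol=1e-8)

    def test_per_residue_aggregates_atom_msf(self, rng):
        # 2 residues x 3 atoms: per-residue RMSF is the RMS of atomic RMSFs
        coords = rng.normal(scale=2.0, size=(50, 6, 3))
        traj = make_trajectory(
            coords,
            res_ids=[1, 1, 1, 2, 2, 2],
            atom_names=["CA", "CB", "CG"] * 2,
        )
        prof = compute_rmsf(traj)
        expected = np.sqrt(np.mean(prof.per_atom.reshape(2, 3) ** 2, axis=1))
        assert np.allclose(prof.per_residue, expected)
        assert np.allclose(prof.per_ca, prof.per_atom[[0, 3]])


class TestMotifSummary:
    def _uniform_profile(self, n=30, value=1.0):
        coords = np.zeros((2, n, 3))
        traj = make_trajectory(coords)
        prof = compute_rmsf(traj)
        prof.per_residue = np.full(n, value)
        return prof

    def test_amplified_wpd_motif_is_argmax(self):
        # motif 8 (the WPD-loop motif) jittered 3x the others
        motifs = demo_motifs(30)
        prof = self._uniform_profile()
        for r in motifs.residues_by_motif()[8]:
            prof.per_residue[r] = 3.0
        table = motif_rmsf_summary(prof, motifs)
        assert int(table.loc[table["is_max"], "motif"].iloc[0]) == 8
        assert table.loc[table["motif"] == 8, "region"].iloc[0] == "tail"

    def test_uniform_profile_all_equal(self):
        table = motif_rmsf_summary(self._uniform_profile(), demo_motifs(30))
        assert table["mean_rmsf"].nunique() == 1

    def test_means_match_direct_range_average(self, rng):
        motifs = demo_motifs(30)
        prof = self._uniform_profile()
        prof.per_residue = rng.uniform(0.1, 3.0, size=30)
        table = motif_rmsf_summary(prof, motifs).set_index("motif")
        for m, residues in motifs.residues_by_motif().items():
            assert table.loc[m, "mean_rmsf"] == pytest.approx(
                np.mean(prof.per_residue[residues])
            )
            assert table.loc[m, "max_rmsf"] == pytest.approx(
                np.max(prof.per_residue[residues])
            )


class TestCentroidDistance:
    def test_coincident_domains_give_zero(self):
        coords = np.zeros((3, 6, 3))
        coords[:, :3] = [[1, 0, 0], [0, 1, 0], [0, 0, 1]]
        coords[:, 3:] = [[1, 0, 0], [0, 1, 0], [0, 0, 1]]
        traj = make_trajectory(
            coords, chains=["A"] * 3 + ["B"] * 3, res_ids=[1, 2, 3, 1, 2, 3]
        )
        geom = compute_centroid_distance(traj)
        assert geom.mean_nm == 0.0

    def test_matches_per_frame_brute_force(self, rng):
        coords = rng.normal(scale=10.0, size=(8, 10, 3))
        chains = ["A"] * 4 + ["B"] * 6
        traj = make_trajectory(coords, chains=chains, res_ids=[1, 2, 3, 4, 1, 2, 3, 4, 5, 6])
        geom = compute_centroid_distance(traj)
        expected = [
            np.linalg.norm(f[:4].mean(axis=0) - f[4:].mean(axis=0)) / 10.0
            for f in coords
        ]
        assert np.allclose(geom.centroid_series_nm, expected)
        assert geom.mean_nm == pytest.approx(np.mean(expected))

    def test_empty_domain_rejected(self):
        traj = make_trajectory(np.zeros((2, 4, 3)), chains=["A"] * 4)
        with pytest.raises(ValueError, match="no atoms"):
            compute_centroid_distance(traj, domains=("A", "B"))


def test_window_statistics_equal_full_on_stationary_trajectory():
    from tandemptp.contacts import compute_contact_matrix
    from tandemptp.synthetic import TrajectorySpec, generate_two_domain_trajectory

    spec = TrajectorySpec(
        n_frames=40, centroid_separation_mean=2.0,
        centroid_separation_sd=0.0, per_residue_jitter_sd=0.0, seed=4,
    )
    traj = generate_two_domain_trajectory(spec)
    full = compute_contact_matrix(traj)
    windowed = compute_contact_matrix(traj, window=(20, 40))
    assert np.allclose(full.mean_distance, windowed.mean_distance)
    geom_full = compute_centroid_distance(traj)
    geom_win = compute_centroid_distance(traj.slice_frames(slice(20, 40)))
    assert geom_full.mean_nm == pytest.approx(geom_win.mean_nm)
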