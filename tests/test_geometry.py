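"""Geometric kernels against brute-force and independent-method oracles."""

import numpy as np
import pytest

from photogate.geometry import (DihedralSpec, RigidTransform, center_of_mass,
                                com_distance, dihedral, kabsch_superpose,
                                rmsd_series)
from photogate.structio import Atom, Selection, Structure, Trajectory, select

from conftest import static_trajectory


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.cos(angle / 2)
    b, c, d = -axis * np.sin(angle / 2)
    return np.array([
        [a*a+b*b-c*c-d*d, 2*(b*c+a*d), 2*(b*d-a*c)],
        [2*(b*c-a*d), a*a+c*c-b*b-d*d, 2*(c*d+a*b)],
        [2*(b*d+a*c), 2*(c*d-a*b), a*a+d*d-b*b-c*c],
    ])


def quaternion_superpose(mobile, ref, weights=None):
    """Independent superposition oracle: Horn's quaternion method."""
    P = np.asarray(mobile, float)
    Q = np.asarray(ref, float)
    n = P.shape[0]
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights) / np.sum(weights)
    pc = (w[:, None] * P).sum(0)
    qc = (w[:, None] * Q).sum(0)
    P0, Q0 = P - pc, Q - qc
    M = (w[:, None, None] * np.einsum("ni,nj->nij", P0, Q0)).sum(0)
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx+Syy+Szz, Syz-Szy,     Szx-Sxz,     Sxy-Syx],
        [Syz-Szy,     Sxx-Syy-Szz, Sxy+Syx,     Szx+Sxz],
        [Szx-Sxz,     Sxy+Syx,     Syy-Sxx-Szz, Syz+Szy],
        [Sxy-Syx,     Szx+Sxz,     Syz+Szy,     Szz-Sxx-Syy],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = ((w * (P0**2).sum(1)).sum() + (w * (Q0**2).sum(1)).sum() - 2.0 * lam)
    return float(np.sqrt(max(msd, 0.0)))


# ---------------------------------------------------------------------------
# center of mass / COM distance
# ---------------------------------------------------------------------------

def test_center_of_mass_unit_and_weighted():
    coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    sel = Selection.from_indices([0, 1])
    np.testing.assert_allclose(center_of_mass(coords, sel), [1.0, 0, 0])
    np.testing.assert_allclose(
        center_of_mass(coords, sel, masses=np.array([1.0, 3.0]))[0], 1.5)


def test_center_of_mass_matches_direct_sum(rng):
    coords = rng.normal(size=(20, 3))
    masses = rng.uniform(1, 16, 20)
    sel = Selection.from_indices(range(20))
    expected = (masses[:, None] * coords).sum(0) / masses.sum()
    np.testing.assert_allclose(center_of_mass(coords, sel, masses), expected,
                               atol=1e-14)


def test_center_of_mass_empty_selection_is_error():
    with pytest.raises(ValueError, match="empty"):
        center_of_mass(np.zeros((3, 3)), Selection.from_indices([]))


def _two_group_traj(d=0.63, n_frames=4):
    atoms = [Atom(i + 1, "CA", "C", "GLY", 1 + (i > 1), "A", 12.0)
             for i in range(4)]
    coords = np.array([[0, 0.1, 0], [0, -0.1, 0], [d, 0.1, 0], [d, -0.1, 0]])
    s = Structure(atoms, coords)
    return static_trajectory(s, n_frames)


def test_com_distance_static_reference():
    traj = _two_group_traj(0.63)
    sa = select(traj.topology, "resid 1")
    sb = select(traj.topology, "resid 2")
    np.testing.assert_allclose(com_distance(traj, sa, sb), 0.63, atol=1e-12)


def test_com_distance_matches_frame_wise_oracle(rng):
    atoms = [Atom(i + 1, "CA", "C", "GLY", 1 + (i > 2), "A", float(i + 1))
             for i in range(6)]
    n_frames = 5
    frames = rng.normal(size=(n_frames, 6, 3))
    traj = Trajectory(Structure(atoms, frames[0]),
                      0.5 * np.arange(1, n_frames + 1), frames)
    sa = select(traj.topology, "resid 1")
    sb = select(traj.topology, "resid 2")
    series = com_distance(traj, sa, sb)
    m = traj.topology.masses
    for f in range(n_frames):
        ca = (m[:3, None] * frames[f, :3]).sum(0) / m[:3].sum()
        cb = (m[3:, None] * frames[f, 3:]).sum(0) / m[3:].sum()
        assert series[f] == pytest.approx(np.linalg.norm(ca - cb), abs=1e-12)


def test_com_distance_invariant_under_per_frame_isometry(rng):
    traj = _two_group_traj(0.82, n_frames=3)
    sa = select(traj.topology, "resid 1")
    sb = select(traj.topology, "resid 2")
    base = com_distance(traj, sa, sb)
    moved = traj.coords.copy()
    for f in range(traj.n_frames):
        R = rotation_matrix(rng.normal(size=3), rng.uniform(0, np.pi))
        moved[f] = moved[f] @ R.T + rng.normal(size=3)
    traj2 = Trajectory(traj.topology, traj.times_ps, moved)
    np.testing.assert_allclose(com_distance(traj2, sa, sb), base, atol=1e-12)


# ---------------------------------------------------------------------------
# dihedral
# ---------------------------------------------------------------------------

TRANS_CHAIN = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]], float)
CIS_CHAIN = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]], float)
SPEC = DihedralSpec(0, 1, 2, 3)


def test_dihedral_planar_trans_and_cis():
    assert dihedral(TRANS_CHAIN, SPEC) == pytest.approx(180.0)
    assert dihedral(CIS_CHAIN, SPEC) == pytest.approx(0.0)


def two_plane_dihedral(coords, spec):
    """Independent oracle: angle between the two bond planes + sign rule."""
    ri, rj, rk, rl = (coords[x] for x in spec.indices)
    n1 = np.cross(rj - ri, rk - rj)
    n2 = np.cross(rk - rj, rl - rk)
    cosphi = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    phi = np.degrees(np.arccos(np.clip(cosphi, -1, 1)))
    if np.dot(np.cross(n1, n2), rk - rj) < 0:
        phi = -phi
    return phi


@pytest.mark.parametrize("angle_deg", [-150, -60, -15, 25, 60, 120, 179])
def test_dihedral_matches_two_plane_oracle(angle_deg):
    a = np.radians(angle_deg)
    coords = np.array([
        [np.cos(np.radians(110)), np.sin(np.radians(110)), 0.0],
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        [1.0 + np.cos(np.radians(70)),
         np.cos(a) * np.sin(np.radians(70)),
         np.sin(a) * np.sin(np.radians(70))],
    ])
    got = dihedral(coords, SPEC)
    assert got == pytest.approx(two_plane_dihedral(coords, SPEC), abs=1e-9)


def test_dihedral_invariant_under_rigid_transform_and_flips_under_mirror(rng):
    coords = rng.normal(size=(4, 3))
    base = dihedral(coords, SPEC)
    R = rotation_matrix(rng.normal(size=3), 1.1)
    moved = coords @ R.T + np.array([1.0, -2.0, 0.5])
    assert dihedral(moved, SPEC) == pytest.approx(base, abs=1e-9)
    mirrored = coords * np.array([1.0, 1.0, -1.0])
    assert dihedral(mirrored, SPEC) == pytest.approx(-base, abs=1e-9)


def test_dihedral_collinear_is_error():
    coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]], float)
    with pytest.raises(ValueError, match="collinear"):
        dihedral(coords, SPEC)


def test_dihedral_spec_rejects_duplicates():
    with pytest.raises(ValueError, match="distinct"):
        DihedralSpec(0, 1, 1, 2)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def test_kabsch_identity():
    pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    T, rmsd = kabsch_superpose(pts, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-10)


def test_kabsch_removes_rotation_and_translation(rng):
    pts = rng.normal(size=(7, 3))
    R = rotation_matrix([0, 0, 1], np.pi / 2)
    moved = pts @ R.T + np.array([3.0, -1.0, 2.0])
    T, rmsd = kabsch_superpose(moved, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-10)
    np.testing.assert_allclose(T.apply(moved), pts, atol=1e-10)


def test_kabsch_matches_quaternion_oracle(rng):
    for _ in range(5):
        pts = rng.normal(size=(10, 3))
        noisy = pts @ rotation_matrix(rng.normal(size=3), 0.7).T \
            + rng.normal(size=3) + 0.05 * rng.normal(size=(10, 3))
        w = rng.uniform(1, 12, 10)
        _, rmsd = kabsch_superpose(noisy, pts, weights=w)
        assert rmsd == pytest.approx(quaternion_superpose(noisy, pts, w),
                                     abs=1e-10)


def test_kabsch_is_symmetric(rng):
    a = rng.normal(size=(8, 3))
    b = a + 0.1 * rng.normal(size=(8, 3))
    _, r1 = kabsch_superpose(a, b)
    _, r2 = kabsch_superpose(b, a)
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_kabsch_degenerate_inputs_are_errors():
    with pytest.raises(ValueError, match="3 points"):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
    with pytest.raises(ValueError, match="collinear|degenerate"):
        kabsch_superpose(line, line)


def test_rigid_transform_rejects_reflection():
    with pytest.raises(ValueError, match="proper"):
        RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


# ---------------------------------------------------------------------------
# RMSD series
# ---------------------------------------------------------------------------

def test_rmsd_series_zero_for_rigidly_moved_frames(peptide, rng):
    n_frames = 4
    frames = np.empty((n_frames, len(peptide), 3))
    for f in range(n_frames):
        R = rotation_matrix(rng.normal(size=3), rng.uniform(0, np.pi))
        frames[f] = peptide.coords @ R.T + rng.normal(size=3)
    traj = Trajectory(peptide, 0.5 * np.arange(1, n_frames + 1), frames)
    sel = select(peptide, "backbone")
    np.testing.assert_allclose(rmsd_series(traj, peptide, sel), 0.0, atol=1e-10)


def test_rmsd_series_first_frame_as_reference(peptide, rng):
    frames = np.tile(peptide.coords, (3, 1, 1))
    frames[1:] += 0.02 * rng.normal(size=frames[1:].shape)
    traj = Trajectory(peptide, np.array([1.0, 2.0, 3.0]), frames)
    sel = select(peptide, "backbone")
    series = rmsd_series(traj, peptide.with_coords(frames[0]), sel)
    assert series[0] == pytest.approx(0.0, abs=1e-12)
    assert np.all(series[1:] > 0)


def test_rmsd_series_matches_frame_wise_kabsch(peptide, rng):
    frames = np.tile(peptide.coords, (3, 1, 1)) \
        + 0.03 * rng.normal(size=(3, len(peptide), 3))
    traj = Trajectory(peptide, np.array([1.0, 2.0, 3.0]), frames)
    sel = select(peptide, "all")
    series = rmsd_series(traj, peptide, sel, mass_weighted=True)
    for f in range(3):
        _, rmsd = kabsch_superpose(frames[f], peptide.coords,
                                   weights=peptide.masses)
        assert series[f] == pytest.approx(rmsd, abs=1e-12)
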