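"""Geometric kernels: centers of mass, torsions, Kabsch superposition, RMSD.

These are the primitives behind every structural descriptor in the package:
the Y488–G688 clamshell distance, the CNNC torsion of the azobenzene
photoswitch, backbone-RMSD traces and the D1 alignment used by the virtual
dimer.  All lengths are nm, all angles degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import Selection, Structure, Trajectory

__all__ = [
    "RigidTransform",
    "DihedralSpec",
    "center_of_mass",
    "com_distance",
    "dihedral",
    "kabsch_superpose",
    "rmsd_series",
]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid-body transform ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ np.asarray(self.rotation).T + self.translation


@dataclass(frozen=True)
class DihedralSpec:
    """Four atom indices (i, j, k, l) defining the torsion about bond j–k."""

    i: int
    j: int
    k: int
    l: int

    def __post_init__(self) -> None:
        idx = (self.i, self.j, self.k, self.l)
        if len(set(idx)) != 4:
            raise ValueError(f"dihedral indices must be distinct, got {idx}")
        if any(x < 0 for x in idx):
            raise ValueError(f"dihedral indices must be non-negative, got {idx}")

    @property
    def indices(self) -> tuple[int, int, int, int]:
        return (self.i, self.j, self.k, self.l)


def _weights(sel: Selection, masses: np.ndarray | None, geometric: bool) -> np.ndarray:
    if geometric or masses is None:
        return np.ones(len(sel))
    w = np.asarray(masses, float)[sel.indices]
    if np.any(w <= 0):
        raise ValueError("masses must be positive")
    return w


def center_of_mass(
    coords: np.ndarray,
    sel: Selection,
    masses: np.ndarray | None = None,
    geometric: bool = False,
) -> np.ndarray:
    """Mass-weighted (or geometric) mean of the selected coordinates (nm)."""
    if len(sel) == 0:
        raise ValueError("center_of_mass of an empty selection is undefined")
    w = _weights(sel, masses, geometric)
    pts = np.asarray(coords, float)[sel.indices]
    return (w[:, None] * pts).sum(axis=0) / w.sum()


def com_distance(
    traj: Trajectory,
    sel_a: Selection,
    sel_b: Selection,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Per-frame Euclidean distance (nm) between two selection COMs."""
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError("com_distance requires two non-empty selections")
    masses = traj.topology.masses if mass_weighted else None
    wa = _weights(sel_a, masses, not mass_weighted)
    wb = _weights(sel_b, masses, not mass_weighted)
    A = traj.coords[:, sel_a.indices, :]
    B = traj.coords[:, sel_b.indices, :]
    coma = (wa[None, :, None] * A).sum(axis=1) / wa.sum()
    comb = (wb[None, :, None] * B).sum(axis=1) / wb.sum()
    return np.linalg.norm(coma - comb, axis=1)


def dihedral(coords: np.ndarray, spec: DihedralSpec) -> float:
    """Signed IUPAC torsion angle in degrees, range (−180, 180].

    Planar *cis* arrangements give 0°, planar *trans* (anti) 180°; the sign
    is positive for a clockwise rotation of l relative to i when viewed
    along j→k.
    """
    coords = np.asarray(coords, float)
    ri, rj, rk, rl = (coords[x] for x in spec.indices)
    b1, b2, b3 = rj - ri, rk - rj, rl - rk
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    scale = max(np.linalg.norm(b1), np.linalg.norm(b2), np.linalg.norm(b3))
    if scale == 0.0:
        raise ValueError("dihedral undefined: coincident consecutive atoms")
    if np.linalg.norm(n1) < 1e-10 * scale**2 or np.linalg.norm(n2) < 1e-10 * scale**2:
        raise ValueError("dihedral undefined: collinear i-j-k or j-k-l atoms")
    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    phi = np.degrees(np.arctan2(y, x))
    if phi <= -180.0:
        phi += 360.0
    return phi


def kabsch_superpose(
    mobile: np.ndarray,
    ref: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Optimal weighted least-squares superposition of ``mobile`` onto ``ref``.

    Returns the proper rotation + translation (reflections are excluded by
    the usual determinant sign correction) and the post-fit weighted RMSD in
    nm.  Requires at least 3 non-collinear points.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(ref, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and ref must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    pc = (w[:, None] * P).sum(axis=0)
    qc = (w[:, None] * Q).sum(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    H = P0.T @ (w[:, None] * Q0)
    U, S, Vt = np.linalg.svd(H)
    # collinear point sets leave the rotation about the line undetermined
    if S[1] < 1e-12 * max(S[0], 1e-300):
        raise ValueError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    msd = float((w * np.einsum("ij,ij->i", diff, diff)).sum())
    return RigidTransform(R, t), float(np.sqrt(max(msd, 0.0)))


def rmsd_series(
    traj: Trajectory,
    ref: Structure,
    fit_sel: Selection,
    measure_sel: Selection | None = None,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (nm) to a reference after superposition.

    Each frame is superposed onto ``ref`` over ``fit_sel``; the RMSD is then
    evaluated over ``measure_sel`` (defaults to ``fit_sel``), the standard
    protocol behind backbone-RMSD stability traces.
    """
    if measure_sel is None:
        measure_sel = fit_sel
    if len(fit_sel) == 0 or len(measure_sel) == 0:
        raise ValueError("rmsd_series requires non-empty selections")
    masses = traj.topology.masses
    wfit = masses[fit_sel.indices] if mass_weighted else None
    wm = masses[measure_sel.indices] if mass_weighted else np.ones(len(measure_sel))
    wm = wm / wm.sum()
    ref_fit = ref.coords[fit_sel.indices]
    ref_meas = ref.coords[measure_sel.indices]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        T, _ = kabsch_superpose(traj.coords[f, fit_sel.indices], ref_fit, wfit)
        moved = T.apply(traj.coords[f, measure_sel.indices])
        diff = moved - ref_meas
        out[f] = np.sqrt((wm * np.einsum("ij,ij->i", diff, diff)).sum())
    return out
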