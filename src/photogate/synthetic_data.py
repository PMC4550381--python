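"""Synthetic ground-truth generators for every pipeline input.

The production observables of an LBD photoswitch study live on 500-ns
all-atom trajectories that a desk cannot recompute.  This module generates
the equivalent desk-scale inputs with *known* ground truth instead:

* quartic double-well free-energy surfaces for the clamshell coordinate,
  parameterised by the minima and barrier heights reported for the
  trans-bound (0.76 / 1.20 nm, 1.5 kcal/mol) and cis-bound
  (0.93 / 1.28 nm, 1.6 kcal/mol) complexes;
* a 3-D two-lobe bead clamshell whose tip–tip distance diffuses on such a
  surface, exercising the geometry/descriptor stack;
* scripted hydrogen-bond presence trajectories with prescribed occupancies;
* a toy monomer/dimer pair with an exact linear clamshell→linker map plus
  Gaussian noise, for the gating-correlation analysis;
* an idealized planar trans-azobenzene geometry that supplies the torsional
  photoswitch model's moment of inertia.

Every generator is bit-reproducible given its seed, and returns its ground
truth alongside the data so tests never re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structio import Atom, Selection, Structure, Trajectory, mass_of_element, select
from .sampling import Potential1D, brownian_1d
from .units import kcal_to_kj

__all__ = [
    "DoubleWellSpec",
    "ToyClamshell",
    "make_surface",
    "clamshell_trajectory",
    "contact_script",
    "toy_dimer",
    "azobenzene_geometry",
    "cnnc_indices",
    "random_rigid_transform",
]

#: (m1 nm, m2 nm, barrier kcal/mol) of the bundled reference surfaces.
SURFACE_PARAMS = {
    "trans_like": (0.76, 1.20, 1.5),
    "cis_like": (0.93, 1.28, 1.6),
}


@dataclass(frozen=True)
class DoubleWellSpec:
    """Quartic double well U(x) = b·((x−c)²−w²)²/w⁴ (b in kJ/mol).

    c = (m1+m2)/2 and w = (m2−m1)/2, so U(m1) = U(m2) = 0 and U(c) equals
    the barrier.  The quartic form is the minimal smooth interpolant of the
    only facts reported for such surfaces: two minima and a barrier height.
    """

    m1: float
    m2: float
    barrier_kcal: float

    def __post_init__(self) -> None:
        if self.m2 <= self.m1:
            raise ValueError(f"m2 must exceed m1, got {self.m1}, {self.m2}")
        if self.barrier_kcal <= 0:
            raise ValueError("barrier must be > 0")

    @property
    def center(self) -> float:
        return 0.5 * (self.m1 + self.m2)

    @property
    def half_width(self) -> float:
        return 0.5 * (self.m2 - self.m1)

    def to_potential(self) -> Potential1D:
        b = kcal_to_kj(self.barrier_kcal)
        c, w = self.center, self.half_width
        w4 = w**4

        def energy(x):
            x = np.asarray(x, float)
            return b * ((x - c) ** 2 - w**2) ** 2 / w4

        def grad(x):
            x = np.asarray(x, float)
            return 4.0 * b * ((x - c) ** 2 - w**2) * (x - c) / w4

        return Potential1D(energy, grad, tag="double_well",
                           params={"m1": self.m1, "m2": self.m2,
                                   "barrier_kcal": self.barrier_kcal})


def make_surface(kind: str = "trans_like", m1: float | None = None,
                 m2: float | None = None, barrier_kcal: float | None = None) -> Potential1D:
    """Bundled clamshell free-energy surfaces, or a custom double well."""
    if kind in SURFACE_PARAMS:
        spec = DoubleWellSpec(*SURFACE_PARAMS[kind])
    elif kind == "custom":
        if None in (m1, m2, barrier_kcal):
            raise ValueError("custom surface needs m1, m2 and barrier_kcal")
        spec = DoubleWellSpec(m1, m2, barrier_kcal)
    else:
        raise ValueError(f"unknown surface kind {kind!r}; "
                         f"choose from {sorted(SURFACE_PARAMS)} or 'custom'")
    pot = spec.to_potential()
    pot.params["kind"] = kind
    return pot


# ---------------------------------------------------------------------------
# Toy clamshell
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyClamshell:
    """Two rigid 5-bead lobes hinged at the origin.

    The hinge angle θ maps bijectively onto the tip–tip distance
    d(θ) = 2·L·sin(θ/2), with the lobe tips carrying residue numbers 488
    (upper lobe) and 688 (lower lobe) so descriptor code addresses them the
    way the receptor's clamshell tips are addressed.  Beads have unit mass
    except the tips (heavier, so COM arithmetic is exercised non-trivially).
    The default hinge-to-tip length L = 0.9 nm makes d span ≈(0, 1.8) nm,
    covering every reference distance; pass a larger L for the wide-open
    collapse regime (> 2.5 nm).
    """

    n_beads_per_lobe: int = 5
    lobe_length: float = 0.9
    bead_mass: float = 1.0
    tip_mass: float = 16.0

    def d_from_theta(self, theta: float | np.ndarray) -> np.ndarray:
        return 2.0 * self.lobe_length * np.sin(np.asarray(theta) / 2.0)

    def theta_from_d(self, d: float | np.ndarray) -> np.ndarray:
        d = np.asarray(d, float)
        arg = d / (2.0 * self.lobe_length)
        if np.any(arg <= 0) or np.any(arg >= 1):
            raise ValueError(
                f"distance outside the reachable range (0, {2 * self.lobe_length}) nm"
            )
        return 2.0 * np.arcsin(arg)

    @property
    def d_range(self) -> tuple[float, float]:
        return (0.0, 2.0 * self.lobe_length)

    def topology(self) -> Structure:
        atoms = [Atom(1, "HNG", "C", "HNG", 1, "A", self.bead_mass)]
        n = self.n_beads_per_lobe
        for k in range(n):  # upper lobe, tip resid 488
            resid = 488 - (n - 1) + k
            tip = k == n - 1
            atoms.append(Atom(2 + k, "CA", "C", "TYR" if tip else "GLY", resid, "A",
                              self.tip_mass if tip else self.bead_mass))
        for k in range(n):  # lower lobe, tip resid 688
            resid = 688 - (n - 1) + k
            tip = k == n - 1
            atoms.append(Atom(2 + n + k, "CA", "C", "GLY", resid, "A",
                              self.tip_mass if tip else self.bead_mass))
        return Structure(atoms, self.build(np.pi / 2.0))

    def build(self, theta: float) -> np.ndarray:
        """Bead coordinates for hinge angle θ (symmetric about the x-axis)."""
        n = self.n_beads_per_lobe
        coords = [np.zeros(3)]
        for sign in (+1.0, -1.0):
            ang = sign * theta / 2.0
            u = np.array([np.cos(ang), np.sin(ang), 0.0])
            for k in range(1, n + 1):
                coords.append(u * self.lobe_length * k / n)
        return np.array(coords)

    def build_at_distance(self, d: float) -> np.ndarray:
        return self.build(float(self.theta_from_d(d)))


def random_rigid_transform(rng: np.random.Generator,
                           max_translation: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation and a bounded random translation."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-max_translation, max_translation, 3)
    return Q, t


def clamshell_trajectory(
    model: ToyClamshell,
    surface: Potential1D,
    n_frames: int = 500,
    dt_ps: float = 0.05,
    temperature: float = 300.0,
    friction: float = 10.0,
    seed: int = 0,
    d0: float | None = None,
    substeps: int = 10,
    rigid_motion: bool = False,
) -> tuple[Trajectory, dict]:
    """A 3-D clamshell trajectory whose tip–tip distance diffuses on ``surface``.

    The 1-D coordinate evolves by overdamped Langevin dynamics (``substeps``
    integrator steps per saved frame); frames are consistent 3-D bead
    coordinates, optionally subjected to a random per-frame rigid transform
    to exercise superposition code.  Returns the trajectory plus a ground
    truth dict holding the exact d(t) series and the surface parameters.
    """
    top = model.topology()
    if d0 is None:
        d0 = surface.params.get("m1", 0.5 * sum(model.d_range))
    lo, hi = model.d_range
    rng = np.random.default_rng(seed)
    sub_seed = int(rng.integers(2**31 - 1))
    chain = brownian_1d(surface, float(d0), dt_ps / substeps, n_frames * substeps,
                        temperature, friction, seed=sub_seed)
    d_series = chain[substeps - 1 :: substeps]
    d_series = np.clip(d_series, lo + 1e-3, hi - 1e-3)
    frames = np.empty((n_frames, len(top), 3))
    for i, d in enumerate(d_series):
        xyz = model.build_at_distance(float(d))
        if rigid_motion:
            R, t = random_rigid_transform(rng)
            xyz = xyz @ R.T + t
        frames[i] = xyz
    times = dt_ps * np.arange(1, n_frames + 1)
    truth = {"d": d_series.copy(), "surface": dict(surface.params),
             "seed": seed, "dt_ps": dt_ps}
    return Trajectory(top, times, frames), truth


# ---------------------------------------------------------------------------
# Scripted contacts
# ---------------------------------------------------------------------------

def contact_script(
    labels: list[str],
    occupancies: list[float],
    n_frames: int = 2000,
    mode: str = "bernoulli",
    seed: int = 0,
    on_distance: float = 0.28,
    off_distance: float = 0.60,
    persistence: float = 0.9,
) -> tuple[Trajectory, list, dict]:
    """Donor/acceptor bead pairs toggled to prescribed contact occupancies.

    For each label a donor bead sits at ``on_distance`` (inside the default
    H-bond cutoff) or ``off_distance`` (outside) from its acceptor bead,
    following either an i.i.d. Bernoulli(p) script or a two-state Markov
    chain with stationary probability p and the given one-step persistence
    (dwell-time structure, as real H-bond series have).  Returns the
    trajectory, ready-made ContactSpecs and the ground-truth scripts.
    """
    from .interactions import ContactSpec  # deferred: avoids module cycle

    if len(labels) != len(occupancies):
        raise ValueError("labels and occupancies must align")
    if mode not in ("bernoulli", "two_state_markov"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    states = np.empty((len(labels), n_frames), dtype=bool)
    for i, p in enumerate(occupancies):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"occupancy must be in [0, 1], got {p}")
        if mode == "bernoulli":
            states[i] = rng.random(n_frames) < p
        else:
            # two-state chain with stationary p: stay-prob mixes persistence
            s = rng.random() < p
            for tstep in range(n_frames):
                states[i, tstep] = s
                flip_to_on = (1 - persistence) * p
                flip_to_off = (1 - persistence) * (1 - p)
                u = rng.random()
                s = (u < flip_to_on) if not s else (u >= flip_to_off)
    atoms = []
    base = np.zeros((2 * len(labels), 3))
    for i in range(len(labels)):
        atoms.append(Atom(2 * i + 1, "OD", "O", "ACC", 10 + i, "L", mass_of_element("O")))
        atoms.append(Atom(2 * i + 2, "ND", "N", "DNR", 100 + i, "L", mass_of_element("N")))
        base[2 * i] = [0.0, 2.0 * i, 0.0]
    top = Structure(atoms, base)
    frames = np.tile(base, (n_frames, 1, 1))
    for i in range(len(labels)):
        dist = np.where(states[i], on_distance, off_distance)
        frames[:, 2 * i + 1, :] = base[2 * i] + np.stack(
            [dist, np.zeros(n_frames), np.zeros(n_frames)], axis=1
        )
    times = 1.0 * np.arange(1, n_frames + 1)
    traj = Trajectory(top, times, frames)
    specs = [
        ContactSpec(
            label=lab,
            donor_sel=select(top, f"resid {100 + i}"),
            acceptor_sel=select(top, f"resid {10 + i}"),
            kind="hbond",
        )
        for i, lab in enumerate(labels)
    ]
    truth = {"occupancies": list(occupancies), "states": states, "mode": mode,
             "seed": seed}
    return traj, specs, truth


# ---------------------------------------------------------------------------
# Toy dimer
# ---------------------------------------------------------------------------

_LINKER_RESIDS = (544, 545, 546, 667)
_LINKER_RESNAMES = ("LYS", "GLY", "THR", "PRO")


def _monomer_atoms(chain: str, serial0: int) -> list[Atom]:
    atoms = []
    s = serial0
    for resid in range(1, 7):  # D1 anchor beads
        atoms.append(Atom(s, "CA", "C", "ALA", resid, chain, 12.011))
        s += 1
    atoms.append(Atom(s, "CA", "C", "TYR", 488, chain, 12.011)); s += 1
    atoms.append(Atom(s, "CA", "C", "GLY", 688, chain, 12.011)); s += 1
    for resid, rname in zip(_LINKER_RESIDS, _LINKER_RESNAMES):
        atoms.append(Atom(s, "CA", "C", rname, resid, chain, 12.011))
        s += 1
    return atoms


_D1_LOCAL = np.array([
    [0.0, 0.0, 0.0], [0.4, 0.0, 0.0], [0.0, 0.4, 0.0],
    [0.0, 0.0, 0.4], [0.4, 0.4, 0.0], [0.2, 0.1, 0.5],
])

# linker bead offsets about their COM (sum to zero, non-degenerate)
_LINKER_OFFSETS = np.array([
    [0.05, 0.05, 0.0], [-0.05, 0.05, 0.0], [0.05, -0.05, 0.0], [-0.05, -0.05, 0.0],
])


def _monomer_coords(d: float, slope: float, intercept: float,
                    linker2_com: np.ndarray, noise: float = 0.0) -> np.ndarray:
    """Monomer-1 coordinates: rigid D1, tips d apart, linker COM on the map."""
    tip_base = np.array([1.2, 0.6, 0.0])
    tip1 = tip_base + np.array([0.0, +d / 2.0, 0.0])
    tip2 = tip_base + np.array([0.0, -d / 2.0, 0.0])
    linker_com = linker2_com + np.array([intercept - slope * d + noise, 0.0, 0.0])
    linker = linker_com + _LINKER_OFFSETS
    return np.vstack([_D1_LOCAL, tip1, tip2, linker])


def toy_dimer(
    noise_sd: float = 0.0,
    n_frames: int = 500,
    seed: int = 0,
    slope: float = 1.0,
    intercept: float = 3.5,
    d_range: tuple[float, float] = (0.6, 1.6),
    d_ref: float = 1.0,
):
    """A dynamic monomer + static template dimer with a known gating map.

    Monomer 1's clamshell distance d (tips 488/688) varies over ``d_range``;
    its linker COM is placed so the linker–linker distance is exactly
    ``intercept − slope·d`` plus Gaussian noise of ``noise_sd`` nm along the
    inter-linker axis.  Frames are scrambled by random rigid transforms, so
    only D1 alignment recovers the construction.  Returns
    (trajectory, DimerTemplate, ground truth).
    """
    from .virtual_dimer import DimerTemplate  # deferred: avoids module cycle

    if slope <= 0:
        raise ValueError("slope must be > 0")
    rng = np.random.default_rng(seed)
    linker2_com = np.array([0.0, 0.0, 0.0])

    atoms_a = _monomer_atoms("A", 1)
    atoms_b = _monomer_atoms("B", 1 + len(atoms_a))
    coords_a_ref = _monomer_coords(d_ref, slope, intercept, linker2_com)
    # static monomer 2: displaced copy, its linker centered at linker2_com
    coords_b = _monomer_coords(d_ref, slope, intercept, linker2_com) * 0.0
    coords_b[:6] = _D1_LOCAL + np.array([-1.5, 0.0, 0.8])
    coords_b[6] = [-1.5, 0.9, 0.8]
    coords_b[7] = [-1.5, -0.3, 0.8]
    coords_b[8:] = linker2_com + _LINKER_OFFSETS
    template = Structure(atoms_a + atoms_b, np.vstack([coords_a_ref, coords_b]))

    top = Structure(atoms_a, coords_a_ref)
    d_series = rng.uniform(d_range[0], d_range[1], n_frames)
    noise = rng.normal(0.0, noise_sd, n_frames) if noise_sd > 0 else np.zeros(n_frames)
    frames = np.empty((n_frames, len(atoms_a), 3))
    for i in range(n_frames):
        xyz = _monomer_coords(float(d_series[i]), slope, intercept,
                              linker2_com, float(noise[i]))
        R, t = random_rigid_transform(rng)
        frames[i] = xyz @ R.T + t
    times = 1.0 * np.arange(1, n_frames + 1)
    traj = Trajectory(top, times, frames)

    tmpl = DimerTemplate(
        template=template,
        d1_sel=select(template, "chain A and resid 1-6"),
        linker_sel_1=select(template, "chain A and resid 544-546 667"),
        linker_sel_2=select(template, "chain B and resid 544-546 667"),
    )
    var_signal = slope**2 * np.var(d_series)
    expected_r = -np.sqrt(var_signal / (var_signal + noise_sd**2)) if var_signal else 0.0
    truth = {"slope": slope, "intercept": intercept, "noise_sd": noise_sd,
             "d": d_series, "noise": noise, "expected_r": float(expected_r),
             "seed": seed}
    return traj, tmpl, truth


# ---------------------------------------------------------------------------
# Idealized azobenzene
# ---------------------------------------------------------------------------

#: Idealized bond lengths (nm) and the CNN angle used for the geometry.
AZO_BOND_NN = 0.125
AZO_BOND_CN = 0.141
AZO_BOND_CC = 0.139
AZO_BOND_CH = 0.108
AZO_ANGLE_CNN_DEG = 114.0


def azobenzene_geometry() -> Structure:
    """Idealized planar *trans* azobenzene (CNNC exactly 180°).

    The two phenyl rings lie in the xy-plane on opposite sides of the N=N
    bond (anti arrangement), built from standard bond lengths.  This
    geometry supplies the photoswitch rotor's moment of inertia.
    """
    a = np.deg2rad(AZO_ANGLE_CNN_DEG)
    n1 = np.array([0.0, 0.0, 0.0])
    n2 = np.array([AZO_BOND_NN, 0.0, 0.0])
    d1 = np.array([np.cos(np.pi - a), np.sin(np.pi - a), 0.0])   # from N1
    d2 = np.array([-np.cos(np.pi - a), -np.sin(np.pi - a), 0.0])  # from N2 (anti)

    def ring(npos: np.ndarray, direction: np.ndarray):
        ipso = npos + AZO_BOND_CN * direction
        perp = np.array([-direction[1], direction[0], 0.0])
        center = ipso + AZO_BOND_CC * direction
        carbons, hydrogens = [], []
        for k in range(6):
            ang = np.pi * k / 3.0
            radial = np.cos(ang) * (-direction) + np.sin(ang) * perp
            carbons.append(center + AZO_BOND_CC * radial)
            if k != 0:  # ipso position carries the N, no H
                hydrogens.append(center + (AZO_BOND_CC + AZO_BOND_CH) * radial)
        return carbons, hydrogens

    c1, h1 = ring(n1, d1)
    c2, h2 = ring(n2, d2)
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    serial = 1

    def add(name: str, element: str, xyz: np.ndarray) -> None:
        nonlocal serial
        atoms.append(Atom(serial, name, element, "AZO", 1, "A",
                          mass_of_element(element)))
        coords.append(xyz)
        serial += 1

    add("N1", "N", n1)
    add("N2", "N", n2)
    for k, xyz in enumerate(c1, start=1):
        add(f"C{k}", "C", xyz)
    for k, xyz in enumerate(h1, start=2):
        add(f"H{k}", "H", xyz)
    for k, xyz in enumerate(c2, start=7):
        add(f"C{k}", "C", xyz)
    for k, xyz in enumerate(h2, start=8):
        add(f"H{k}", "H", xyz)
    return Structure(atoms, np.array(coords))


def cnnc_indices(structure: Structure) -> tuple[int, int, int, int]:
    """Atom indices (C_ipso1, N1, N2, C_ipso2) of the CNNC torsion."""
    names = [a.name for a in structure.atoms]
    return (names.index("C1"), names.index("N1"),
            names.index("N2"), names.index("C7"))
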