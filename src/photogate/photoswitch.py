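"""Forced trans→cis photoswitching of the azobenzene CNNC torsion.

Photoexcitation of an azobenzene is mimicked classically by a strong
torsional bias that turns the trans minimum (φ = 180°) into a hill and the
cis minimum (φ = 0°) into the only valley:

    V_bias(φ) = ½ K (1 − cos φ),   K = 320 kJ/mol by default,

applied for a fixed duration (500 fs by default) and then discarded.  The
torsion itself is an underdamped Langevin rotor on a two-term cosine
ground-state potential with cis/trans minima and a 100 kJ/mol isomerization
barrier.

The rotor's moment of inertia is derived from a packaged idealized
azobenzene geometry.  Two reductions are available: the rigid
counter-rotation of the two phenyl-bearing fragments about the N=N axis
(``phenyl_fragment_inertia``, ≈3 amu·nm²), and the pedal-like motion in
which the light diazo bridge rotates about the ipso–ipso carbon axis while
the bulky phenyls stay put (``pedal_inertia``, ≈0.11 amu·nm²).  Ultrafast
experiments and excited-state simulations agree that azobenzene isomerizes
by the pedal-type pathway on the 100-fs scale — a rigid-phenyl rotor is an
order of magnitude too sluggish to leave the trans hilltop inside the bias
window — so ``default_rotor`` uses the pedal inertia.

Torsional angles are degrees in (−180, 180] at the API; times are fs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structio import Structure
from .synthetic_data import azobenzene_geometry
from .units import KB_KJ_PER_MOL_K as KB

__all__ = [
    "SwitchingPotential",
    "RotorModel",
    "SwitchTrajectory",
    "bias_energy",
    "default_rotor",
    "pedal_inertia",
    "phenyl_fragment_inertia",
    "run_switch",
    "run_ensemble",
    "switch_time",
    "post_switch_stats",
]


def _wrap_deg(phi: np.ndarray) -> np.ndarray:
    """Wrap degrees into (−180, 180]."""
    w = np.mod(np.asarray(phi) + 180.0, 360.0) - 180.0
    return np.where(w == -180.0, 180.0, w)


@dataclass(frozen=True)
class SwitchingPotential:
    """The excited-state-mimicking torsional bias.

    For ``target='cis'`` the energy is ½K(1−cos φ): zero at the cis
    configuration, K at trans.  ``target='trans'`` mirrors it.  The bias is
    switched off after ``duration_fs``.
    """

    K: float = 320.0
    duration_fs: float = 500.0
    target: str = "cis"

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be > 0")
        if self.duration_fs <= 0:
            raise ValueError("duration_fs must be > 0")
        if self.target not in ("cis", "trans"):
            raise ValueError("target must be 'cis' or 'trans'")

    @property
    def target_deg(self) -> float:
        return 0.0 if self.target == "cis" else 180.0


def bias_energy(phi_deg: float | np.ndarray, pot: SwitchingPotential) -> float | np.ndarray:
    """Bias energy (kJ/mol) at torsion φ (degrees); 360°-periodic and even."""
    phi = np.deg2rad(np.asarray(phi_deg, float))
    if pot.target == "cis":
        val = 0.5 * pot.K * (1.0 - np.cos(phi))
    else:
        val = 0.5 * pot.K * (1.0 + np.cos(phi))
    return float(val) if np.isscalar(phi_deg) else val


@dataclass(frozen=True)
class RotorModel:
    """Underdamped Langevin rotor for the CNNC torsion.

    ``barrier`` (kJ/mol) is the cis↔trans isomerization barrier of the
    ground-state potential; ``well_curvature`` (kJ/mol/rad²) its curvature
    at both minima.  The two-term cosine
    U(φ) = c₁(1−cos 2φ) + c₂(1−cos 4φ) realises any barrier = 2c₁ with
    curvature 4c₁ + 16c₂ without creating spurious minima as long as the
    curvature stays in (0, 2·barrier].  The default curvature 40 kJ/mol/rad²
    matches the ≈100 cm⁻¹ azobenzene torsional frequency at the pedal
    inertia.
    """

    inertia: float
    friction: float = 10.0
    temperature: float = 300.0
    barrier: float = 100.0
    well_curvature: float = 40.0

    def __post_init__(self) -> None:
        if self.inertia <= 0:
            raise ValueError("inertia must be > 0")
        if self.friction < 0 or self.temperature < 0:
            raise ValueError("friction and temperature must be >= 0")
        if not 0.0 < self.well_curvature <= 2.0 * self.barrier:
            raise ValueError(
                "well_curvature must be in (0, 2*barrier] to keep exactly two minima"
            )

    @property
    def _c1(self) -> float:
        return 0.5 * self.barrier

    @property
    def _c2(self) -> float:
        return (self.well_curvature - 2.0 * self.barrier) / 16.0

    def ground_energy(self, phi_deg: float | np.ndarray) -> float | np.ndarray:
        """Ground-state torsional potential (kJ/mol); minima at 0° and 180°."""
        phi = np.deg2rad(np.asarray(phi_deg, float))
        val = self._c1 * (1 - np.cos(2 * phi)) + self._c2 * (1 - np.cos(4 * phi))
        return float(val) if np.isscalar(phi_deg) else val

    def _ground_torque(self, phi_rad: float) -> float:
        return -(2 * self._c1 * math.sin(2 * phi_rad)
                 + 4 * self._c2 * math.sin(4 * phi_rad))


@dataclass
class SwitchTrajectory:
    """A CNNC(t) trace from a switching run (times in fs, angles degrees)."""

    times_fs: np.ndarray
    phi_deg: np.ndarray
    bias_active: np.ndarray
    target: str = "cis"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (len(self.times_fs) == len(self.phi_deg) == len(self.bias_active)):
            raise ValueError("trajectory arrays must have equal length")
        if self.times_fs[0] != 0.0:
            raise ValueError("trajectory times must start at 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_fs": self.times_fs,
            "phi_deg": self.phi_deg,
            "bias_active": self.bias_active.astype(int),
        })


# ---------------------------------------------------------------------------
# Moments of inertia from the packaged geometry
# ---------------------------------------------------------------------------

def _axis_inertia(coords: np.ndarray, masses: np.ndarray,
                  p0: np.ndarray, p1: np.ndarray) -> float:
    u = (p1 - p0) / np.linalg.norm(p1 - p0)
    v = coords - p0
    perp = v - np.outer(v @ u, u)
    return float((masses * np.einsum("ij,ij->i", perp, perp)).sum())


def _partition(structure: Structure):
    """Indices of (N atoms, fragment-1 atoms, fragment-2 atoms)."""
    elements = np.array([a.element for a in structure.atoms])
    n_idx = np.nonzero(elements == "N")[0]
    if n_idx.size != 2:
        raise ValueError("geometry must contain exactly two azo nitrogens")
    coords = structure.coords
    d1 = np.linalg.norm(coords - coords[n_idx[0]], axis=1)
    d2 = np.linalg.norm(coords - coords[n_idx[1]], axis=1)
    others = np.array([i for i in range(len(structure)) if i not in n_idx])
    frag1 = others[d1[others] <= d2[others]]
    frag2 = others[d1[others] > d2[others]]
    return n_idx, frag1, frag2


def phenyl_fragment_inertia(structure: Structure | None = None) -> float:
    """Reduced inertia (amu·nm²) of the two phenyl fragments about the N=N axis.

    Brute force Σmᵢdᵢ² per fragment, combined as I₁I₂/(I₁+I₂) for the
    counter-rotation that a rigid-fragment torsion implies.
    """
    s = structure if structure is not None else azobenzene_geometry()
    n_idx, frag1, frag2 = _partition(s)
    m = s.masses
    p0, p1 = s.coords[n_idx[0]], s.coords[n_idx[1]]
    i1 = _axis_inertia(s.coords[frag1], m[frag1], p0, p1)
    i2 = _axis_inertia(s.coords[frag2], m[frag2], p0, p1)
    return i1 * i2 / (i1 + i2)


def pedal_inertia(structure: Structure | None = None) -> float:
    """Effective inertia (amu·nm²) of the pedal-type CNNC motion.

    The diazo bridge (the two N atoms) rotates about the axis through the
    two ipso carbons while the phenyl bodies counter-balance; the reduced
    inertia is I_NN·I_phenyls/(I_NN+I_phenyls), dominated by the light
    bridge.
    """
    s = structure if structure is not None else azobenzene_geometry()
    n_idx, frag1, frag2 = _partition(s)
    # ipso carbon of each fragment: heavy atom closest to its nitrogen
    def ipso(frag: np.ndarray, n_i: int) -> int:
        heavy = [i for i in frag if s.atoms[i].element != "H"]
        d = np.linalg.norm(s.coords[heavy] - s.coords[n_i], axis=1)
        return heavy[int(np.argmin(d))]

    a0 = s.coords[ipso(frag1, n_idx[0])]
    a1 = s.coords[ipso(frag2, n_idx[1])]
    m = s.masses
    i_bridge = _axis_inertia(s.coords[n_idx], m[n_idx], a0, a1)
    rest = np.concatenate([frag1, frag2])
    i_rest = _axis_inertia(s.coords[rest], m[rest], a0, a1)
    return i_bridge * i_rest / (i_bridge + i_rest)


def default_rotor(temperature: float = 300.0, friction: float = 10.0) -> RotorModel:
    """Rotor with the pedal-mode inertia of the packaged azobenzene geometry."""
    return RotorModel(inertia=pedal_inertia(), friction=friction,
                      temperature=temperature)


# ---------------------------------------------------------------------------
# Langevin integration
# ---------------------------------------------------------------------------

_VELOCITY_BLOWUP = 1.0e5  # rad/ps; far beyond any physical torsional speed


def run_switch(
    model: RotorModel,
    pot: SwitchingPotential,
    dt_fs: float = 0.1,
    total_fs: float = 1000.0,
    seed: int = 0,
    thermalize_ps: float = 1.0,
    phi0_deg: float | None = None,
    v0_rad_per_ps: float | None = None,
) -> SwitchTrajectory:
    """Underdamped Langevin (BAOAB) switching run; bit-reproducible per seed.

    The rotor is first thermalized for ``thermalize_ps`` in the starting
    isomer's well (trans for a cis-target bias) with the bias off; the bias
    then acts from t = 0 until ``pot.duration_fs``.  Pass ``phi0_deg`` /
    ``v0_rad_per_ps`` to skip thermalization and start deterministically.
    """
    if dt_fs > 0.5:
        raise ValueError("dt_fs must be <= 0.5 for a stable torsional step")
    if total_fs < pot.duration_fs:
        raise ValueError("total_fs must cover the bias duration")
    rng = np.random.default_rng(seed)
    dt = dt_fs * 1e-3  # ps
    I = model.inertia
    kT = KB * model.temperature
    c = math.exp(-model.friction * dt) if model.friction > 0 else 1.0
    s_noise = math.sqrt(kT / I * (1.0 - c * c)) if kT > 0 else 0.0

    start = math.pi if pot.target == "cis" else 0.0
    if phi0_deg is not None:
        phi = math.radians(phi0_deg)
        v = 0.0 if v0_rad_per_ps is None else float(v0_rad_per_ps)
    else:
        phi = start
        v = rng.normal(0.0, math.sqrt(kT / I)) if kT > 0 else 0.0
        n_th = int(round(thermalize_ps / dt))
        noise_th = rng.standard_normal(n_th) if kT > 0 else np.zeros(n_th)
        for i in range(n_th):
            f = model._ground_torque(phi)
            v += 0.5 * dt * f / I
            phi += 0.5 * dt * v
            v = c * v + s_noise * noise_th[i]
            phi += 0.5 * dt * v
            v += 0.5 * dt * model._ground_torque(phi) / I
            if not math.isfinite(phi) or abs(v) > _VELOCITY_BLOWUP:
                raise RuntimeError(
                    "integration unstable during thermalization; reduce dt_fs"
                )
        if v0_rad_per_ps is not None:
            v = float(v0_rad_per_ps)

    n_steps = int(round(total_fs / dt_fs))
    noise = rng.standard_normal(n_steps) if kT > 0 else np.zeros(n_steps)
    times = dt_fs * np.arange(n_steps + 1)
    phis = np.empty(n_steps + 1)
    active = np.empty(n_steps + 1, dtype=bool)
    phis[0] = phi
    active[0] = True

    def torque(p: float, biased: bool) -> float:
        f = model._ground_torque(p)
        if biased:
            sgn = 1.0 if pot.target == "cis" else -1.0
            f += -sgn * 0.5 * pot.K * math.sin(p)
        return f

    for i in range(n_steps):
        biased = times[i] < pot.duration_fs
        f = torque(phi, biased)
        v += 0.5 * dt * f / I
        phi += 0.5 * dt * v
        v = c * v + s_noise * noise[i]
        phi += 0.5 * dt * v
        biased_next = times[i + 1] < pot.duration_fs
        v += 0.5 * dt * torque(phi, biased_next) / I
        if not math.isfinite(phi) or abs(v) > _VELOCITY_BLOWUP:
            raise RuntimeError(
                f"integration unstable at t = {times[i + 1]:.1f} fs; reduce dt_fs"
            )
        phis[i + 1] = phi
        active[i + 1] = biased_next
    active[0] = 0.0 < pot.duration_fs
    return SwitchTrajectory(times, _wrap_deg(np.degrees(phis)), active,
                            target=pot.target, seed=seed)


def switch_time(traj: SwitchTrajectory, threshold_deg: float = 10.0) -> float | None:
    """First time (fs) |φ − φ_target| ≤ threshold, or None if never reached."""
    if not 0.0 < threshold_deg < 90.0:
        raise ValueError("threshold must be in (0, 90) degrees")
    target = 0.0 if traj.target == "cis" else 180.0
    dev = np.abs(_wrap_deg(traj.phi_deg - target))
    hits = np.nonzero(dev <= threshold_deg)[0]
    return float(traj.times_fs[hits[0]]) if hits.size else None


def post_switch_stats(
    traj: SwitchTrajectory,
    window: tuple[float, float] = (100.0, 500.0),
) -> tuple[float, float]:
    """Mean |φ| and circular standard deviation of φ over a time window.

    Angles are handled on the circle: the deviation is measured from the
    target isomer and the spread via the circular variance.
    """
    t0, t1 = window
    mask = (traj.times_fs >= t0) & (traj.times_fs <= t1)
    if not np.any(mask):
        raise ValueError(f"window {window} fs contains no samples")
    target = 0.0 if traj.target == "cis" else 180.0
    dev = np.deg2rad(_wrap_deg(traj.phi_deg[mask] - target))
    mean_abs = float(np.degrees(np.mean(np.abs(dev))))
    R = float(np.abs(np.mean(np.exp(1j * dev))))
    circ_sd = float(np.degrees(math.sqrt(max(-2.0 * math.log(max(R, 1e-300)), 0.0))))
    return mean_abs, circ_sd


def run_ensemble(
    model: RotorModel,
    pot: SwitchingPotential,
    seeds: list[int],
    dt_fs: float = 0.1,
    total_fs: float = 1000.0,
    threshold_deg: float = 10.0,
) -> pd.DataFrame:
    """Seeded switching runs summarised per seed.

    Columns: seed, switch_time_fs (NaN if never switched), mean_abs_phi_deg
    and circ_sd_deg over the post-switch half of the run.
    """
    rows = []
    for seed in seeds:
        traj = run_switch(model, pot, dt_fs=dt_fs, total_fs=total_fs, seed=seed)
        st = switch_time(traj, threshold_deg)
        half = (0.5 * total_fs, total_fs)
        mean_abs, sd = post_switch_stats(traj, half)
        rows.append({
            "seed": seed,
            "switch_time_fs": np.nan if st is None else st,
            "mean_abs_phi_deg": mean_abs,
            "circ_sd_deg": sd,
        })
    return pd.DataFrame(rows)
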