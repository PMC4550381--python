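"""Virtual-dimer construction and the linker-distance gating proxy.

Simulations of a single ligand-binding-domain monomer say nothing directly
about the ion channel, which responds to the *relative* arrangement of two
monomers.  The virtual-dimer trick recovers a crude proxy: every trajectory
frame is superposed, via its D1 (upper-lobe) backbone, onto monomer 1 of a
crystallographic dimer template; together with the untouched template
monomer 2 this yields a dimer with one dynamic and one static monomer.  The
COM distance between the two linker segments (the four residues
K544-G-T-P667 that replace the transmembrane domain in LBD constructs) then
proxies channel gating, and its correlation with the clamshell distance
quantifies how lobe closure transduces into gating force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import center_of_mass, kabsch_superpose
from .structio import Selection, Structure, Trajectory

__all__ = [
    "DimerTemplate",
    "VirtualDimerFrames",
    "GateCorrelation",
    "build_virtual_dimer",
    "linker_distance",
    "gate_correlation",
]


@dataclass
class DimerTemplate:
    """A two-chain template dimer and the selections the proxy needs.

    ``d1_sel`` anchors the alignment on monomer 1's D1 lobe;
    ``linker_sel_1`` / ``linker_sel_2`` are the four-residue linker segments
    of monomers 1 and 2.
    """

    template: Structure
    d1_sel: Selection
    linker_sel_1: Selection
    linker_sel_2: Selection

    def __post_init__(self) -> None:
        for name in ("d1_sel", "linker_sel_1", "linker_sel_2"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        chains_1 = {self.template.atoms[i].chain_id for i in self.linker_sel_1}
        chains_2 = {self.template.atoms[i].chain_id for i in self.linker_sel_2}
        if chains_1 & chains_2:
            raise ValueError("linker selections must come from different chains")


def _match_atoms(
    template: Structure,
    sel: Selection,
    topology: Structure,
) -> np.ndarray:
    """Map template atoms (by residue number + atom name) onto a topology."""
    lookup = {
        (a.residue_seq, a.name): i for i, a in enumerate(topology.atoms)
    }
    matched = []
    missing: list[int] = []
    for i in sel:
        a = template.atoms[i]
        j = lookup.get((a.residue_seq, a.name))
        if j is None:
            missing.append(a.residue_seq)
        else:
            matched.append(j)
    if missing:
        raise KeyError(
            "trajectory topology lacks template atoms in residues "
            + ", ".join(str(r) for r in sorted(set(missing)))
        )
    return np.array(matched, dtype=int)


@dataclass
class VirtualDimerFrames:
    """Aligned dynamic-monomer coordinates next to the static template."""

    times_ps: np.ndarray
    dynamic_coords: np.ndarray  # (F, N, 3), trajectory atoms after D1 alignment
    topology: Structure
    template: DimerTemplate

    @property
    def n_frames(self) -> int:
        return self.times_ps.size


def build_virtual_dimer(traj: Trajectory, tmpl: DimerTemplate) -> VirtualDimerFrames:
    """Superpose every frame's D1 onto the template monomer's D1.

    The per-frame rigid transform fitted on the D1 anchor is applied to the
    *whole* dynamic monomer; monomer 2 stays at its template coordinates.
    Idempotent: aligning already-aligned frames changes nothing.
    """
    traj_d1 = _match_atoms(tmpl.template, tmpl.d1_sel, traj.topology)
    ref = tmpl.template.coords[tmpl.d1_sel.indices]
    weights = tmpl.template.masses[tmpl.d1_sel.indices]
    aligned = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        T, _ = kabsch_superpose(traj.coords[f, traj_d1], ref, weights)
        aligned[f] = T.apply(traj.coords[f])
    return VirtualDimerFrames(traj.times_ps.copy(), aligned, traj.topology, tmpl)


def linker_distance(frames: VirtualDimerFrames, tmpl: DimerTemplate | None = None) -> np.ndarray:
    """Per-frame COM distance (nm) between the dynamic and static linkers."""
    tmpl = tmpl if tmpl is not None else frames.template
    traj_linker = _match_atoms(tmpl.template, tmpl.linker_sel_1, frames.topology)
    sel1 = Selection.from_indices(traj_linker)
    masses = frames.topology.masses
    com2 = center_of_mass(tmpl.template.coords, tmpl.linker_sel_2,
                          tmpl.template.masses)
    out = np.empty(frames.n_frames)
    for f in range(frames.n_frames):
        com1 = center_of_mass(frames.dynamic_coords[f], sel1, masses)
        out[f] = np.linalg.norm(com1 - com2)
    return out


@dataclass
class GateCorrelation:
    """Pearson correlation between linker distance and clamshell distance."""

    r: float
    paired: pd.DataFrame
    hist2d: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray


def gate_correlation(
    linker_series: np.ndarray,
    clamshell_series: np.ndarray,
    n_bins: int = 40,
) -> GateCorrelation:
    """Correlate the gating proxy with the clamshell descriptor.

    Returns the Pearson r, the paired series and a 2-D histogram for a
    density plot of the joint distribution.
    """
    x = np.asarray(clamshell_series, float)
    y = np.asarray(linker_series, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and equally long")
    if x.size < 3:
        raise ValueError("need at least 3 paired samples")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("correlation undefined for zero-variance series")
    r = float(np.corrcoef(x, y)[0, 1])
    H, xe, ye = np.histogram2d(x, y, bins=n_bins)
    paired = pd.DataFrame({"clamshell_nm": x, "linker_nm": y})
    return GateCorrelation(r, paired, H, xe, ye)
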