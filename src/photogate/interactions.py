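"""Geometric hydrogen-bond / salt-bridge detection and occupancy tables.

Contacts are detected with community-standard geometric criteria (the
source trajectories' own criteria are not part of the record):

* hydrogen bond: any donor–acceptor heavy-atom pair within ``da_cutoff``
  (0.35 nm default); when donor hydrogens are available, additionally a
  D–H⋯A deviation from linearity ≤ ``angle_cutoff_deg`` (30° default);
* salt bridge: opposing charged-group centroids within ``salt_cutoff``
  (0.45 nm default).

Occupancy is the percentage of trajectory frames in which a contact is
present, the quantity H-bond tables in MD studies report.  A hydrogen bond
"to a carboxyl group" is satisfied by either carboxylate oxygen, the two
being chemically equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structio import Selection, SelectionError, Structure, Trajectory, select

__all__ = [
    "HBondCriterion",
    "ContactSpec",
    "detect_contacts",
    "occupancy",
    "timeline",
    "standard_contact_set",
    "STANDARD_CONTACT_LABELS",
]


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric criteria for contact detection (distances nm, angles deg)."""

    da_cutoff: float = 0.35
    angle_cutoff_deg: float = 30.0
    heavy_only: bool = True
    salt_cutoff: float = 0.45

    def __post_init__(self) -> None:
        if self.da_cutoff <= 0 or self.salt_cutoff <= 0:
            raise ValueError("distance cutoffs must be > 0")
        if not 0.0 < self.angle_cutoff_deg <= 90.0:
            raise ValueError("angle_cutoff_deg must be in (0, 90]")


@dataclass(frozen=True)
class ContactSpec:
    """One labelled contact: donor group, acceptor group, detection kind."""

    label: str
    donor_sel: Selection
    acceptor_sel: Selection
    kind: str = "hbond"
    donor_hydrogens: Selection | None = None

    def __post_init__(self) -> None:
        if len(self.donor_sel) == 0 or len(self.acceptor_sel) == 0:
            raise ValueError(f"contact {self.label!r}: selections must be non-empty")
        if self.kind not in ("hbond", "salt_bridge"):
            raise ValueError(f"contact {self.label!r}: unknown kind {self.kind!r}")


def _pair_distances(coords: np.ndarray, sel_a: Selection, sel_b: Selection) -> np.ndarray:
    A = coords[sel_a.indices]
    B = coords[sel_b.indices]
    return np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)


def detect_contacts(
    coords: np.ndarray,
    spec: ContactSpec,
    crit: HBondCriterion = HBondCriterion(),
) -> bool:
    """Whether the contact is present in a single frame's coordinates."""
    coords = np.asarray(coords, float)
    if spec.kind == "salt_bridge":
        ca = coords[spec.donor_sel.indices].mean(axis=0)
        cb = coords[spec.acceptor_sel.indices].mean(axis=0)
        return bool(np.linalg.norm(ca - cb) <= crit.salt_cutoff)
    dda = _pair_distances(coords, spec.donor_sel, spec.acceptor_sel)
    within = dda <= crit.da_cutoff
    if not within.any():
        return False
    if crit.heavy_only or spec.donor_hydrogens is None:
        return True
    hcoords = coords[spec.donor_hydrogens.indices]
    for i, j in zip(*np.nonzero(within)):
        d = coords[spec.donor_sel.atom_indices[i]]
        a = coords[spec.acceptor_sel.atom_indices[j]]
        dh = np.linalg.norm(hcoords - d, axis=1)
        for h in hcoords[dh <= 0.12]:  # hydrogens covalently bound to this donor
            v1 = d - h
            v2 = a - h
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if 180.0 - ang <= crit.angle_cutoff_deg:
                return True
    return False


def timeline(
    traj: Trajectory,
    specs: list[ContactSpec],
    crit: HBondCriterion = HBondCriterion(),
) -> pd.DataFrame:
    """Binary presence matrix: one 0/1 column per contact label, plus time_ps."""
    if traj.n_frames < 1:
        raise ValueError("timeline of an empty trajectory is undefined")
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("contact labels must be unique")
    data = {"time_ps": traj.times_ps}
    for spec in specs:
        data[spec.label] = np.array([
            int(detect_contacts(traj.coords[f], spec, crit))
            for f in range(traj.n_frames)
        ])
    return pd.DataFrame(data)


def occupancy(
    traj: Trajectory,
    specs: list[ContactSpec],
    crit: HBondCriterion = HBondCriterion(),
    simulation_id: str | int | None = None,
) -> pd.DataFrame:
    """Per-contact occupancy: 100 × (frames present) / (total frames).

    Returns a tidy table with columns label, simulation, occupancy_percent.
    """
    tl = timeline(traj, specs, crit)
    rows = [
        {"label": spec.label,
         "simulation": simulation_id,
         "occupancy_percent": 100.0 * float(tl[spec.label].mean())}
        for spec in specs
    ]
    return pd.DataFrame(rows)


#: Labels of the standard ligand–protein and interdomain contact set, as the
#: interaction-pattern figures name them.
STANDARD_CONTACT_LABELS = (
    "P516", "A518", "R523", "A689 (alpha)", "A689 (gamma)", "T690", "E738",
    "E440-N721",
)


def _must_select(structure: Structure, expr: str, spec_label: str) -> Selection:
    sel = select(structure, expr)
    if len(sel) == 0:
        raise SelectionError(
            f"contact {spec_label!r}: selection {expr!r} matches no atoms"
        )
    return sel


def standard_contact_set(
    structure: Structure,
    variant: str = "trans",
    ligand_resname: str = "LIG",
) -> list[ContactSpec]:
    """The seven ligand–protein contacts plus the E440–N721 interdomain bond.

    The ligand is expected to expose a glutamate-like head group with atom
    names N (α-amino nitrogen), O1/O2 (α-carboxylate oxygens) and O3/O4
    (γ-carboxylate oxygens); protein residues use standard PDB atom names.
    The same set applies to the trans-, cis- and glutamate-bound variants —
    the variants differ in which contacts are *occupied*, not in which are
    defined.
    """
    if variant not in ("trans", "cis", "glutamate"):
        raise ValueError(f"unknown variant {variant!r}")
    lig = f"resname {ligand_resname}"

    def sel(expr: str, label: str) -> Selection:
        return _must_select(structure, expr, label)

    specs = [
        ContactSpec("P516",
                    sel(f"{lig} and name N", "P516"),
                    sel("resid 516 and name O", "P516")),
        ContactSpec("A518",
                    sel("resid 518 and name N", "A518"),
                    sel(f"{lig} and name O1 O2", "A518")),
        ContactSpec("R523",
                    sel("resid 523 and name NE NH1 NH2", "R523"),
                    sel(f"{lig} and name O1 O2", "R523"),
                    kind="salt_bridge"),
        ContactSpec("A689 (alpha)",
                    sel("resid 689 and name N", "A689 (alpha)"),
                    sel(f"{lig} and name O1 O2", "A689 (alpha)")),
        ContactSpec("A689 (gamma)",
                    sel("resid 689 and name N", "A689 (gamma)"),
                    sel(f"{lig} and name O3 O4", "A689 (gamma)")),
        ContactSpec("T690",
                    sel("resid 690 and name N OG1", "T690"),
                    sel(f"{lig} and name O3 O4", "T690")),
        ContactSpec("E738",
                    sel(f"{lig} and name N", "E738"),
                    sel("resid 738 and name OE1 OE2", "E738"),
                    kind="salt_bridge"),
        ContactSpec("E440-N721",
                    sel("resid 721 and name ND2", "E440-N721"),
                    sel("resid 440 and name OE1 OE2", "E440-N721")),
    ]
    return specs
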