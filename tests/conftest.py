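"""Shared fixtures: small programmatically built structures and trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from photogate.structio import Atom, Structure, Trajectory, mass_of_element


def make_peptide(n_residues: int = 5, chain_id: str = "A",
                 first_resid: int = 1, serial0: int = 1) -> tuple[list[Atom], np.ndarray]:
    """Backbone-only peptide chain: N, CA, C, O per residue on a zig-zag."""
    atoms, coords = [], []
    s = serial0
    for r in range(n_residues):
        resid = first_resid + r
        base = np.array([0.35 * r, 0.02 * (r % 2), 0.0])
        for k, (name, element) in enumerate(
                [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]):
            atoms.append(Atom(s, name, element, "ALA", resid, chain_id,
                              mass_of_element(element)))
            coords.append(base + np.array([0.08 * k, 0.05 * (k % 2), 0.01 * k]))
            s += 1
    return atoms, np.array(coords)


@pytest.fixture
def peptide() -> Structure:
    atoms, coords = make_peptide(5)
    return Structure(atoms, coords)


@pytest.fixture
def two_chain_structure() -> Structure:
    atoms_a, coords_a = make_peptide(3, "A", first_resid=10, serial0=1)
    atoms_b, coords_b = make_peptide(2, "B", first_resid=30, serial0=13)
    coords_b = coords_b + np.array([0.0, 1.0, 0.0])
    return Structure(atoms_a + atoms_b, np.vstack([coords_a, coords_b]))


def static_trajectory(structure: Structure, n_frames: int = 4,
                      dt_ps: float = 0.5) -> Trajectory:
    times = dt_ps * np.arange(1, n_frames + 1)
    coords = np.tile(structure.coords, (n_frames, 1, 1))
    return Trajectory(structure, times, coords)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
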