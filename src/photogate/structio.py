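"""Structure and trajectory I/O plus the shared atom/selection model.

This module owns the coordinate conventions every other module consumes:
coordinates in nm (PDB files are converted from Å on read), 0-based atom
indices internally, residue numbers kept exactly as printed in the source
file (crystallographic author numbering, e.g. Y488 of GluK2).

Supported formats are a deliberately small, plain-text subset:

* PDB ``ATOM``/``HETATM``/``TER``/``END(MDL)`` records.  Only the first
  MODEL of a multi-model file is read and alternate locations other than
  blank/'A' are dropped — trajectories travel in XYZ, PDB is topology and
  reference only.
* An extended-XYZ dialect for trajectories: per frame an atom-count line, a
  comment line carrying ``time_ps=<float>``, then ``name x y z`` with
  coordinates in nm.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .units import NM_PER_ANGSTROM

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "Selection",
    "PDBFormatError",
    "XYZFormatError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "read_xyz_traj",
    "write_xyz_traj",
    "select",
    "mass_of_element",
]


class PDBFormatError(ValueError):
    """Raised for malformed or unusable PDB input."""


class XYZFormatError(ValueError):
    """Raised for malformed extended-XYZ trajectory input."""


class SelectionError(ValueError):
    """Raised for invalid selection expressions or unresolvable selections."""


#: Average atomic masses (amu) for the elements this package encounters.
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "ZN": 65.38, "SE": 78.971, "BR": 79.904, "I": 126.904,
}

_TWO_LETTER = {"NA", "MG", "CL", "MN", "FE", "ZN", "SE", "BR"}

#: Backbone atom names used by the ``backbone`` selection keyword.
BACKBONE_NAMES = ("N", "CA", "C", "O")


def mass_of_element(element: str) -> float:
    """Mass (amu) of an element symbol; raises KeyError for unknown symbols."""
    m = ATOMIC_MASSES.get(element.upper())
    if m is None:
        raise KeyError(f"no mass tabulated for element {element!r}")
    return m


def guess_element(name: str) -> str:
    """Guess the element from a PDB/XYZ atom name.

    Digits are stripped; a leading two-letter metal/halogen symbol is
    recognised only when the full stripped name equals it (so protein "CA"
    is carbon-alpha, not calcium).
    """
    stripped = re.sub(r"[^A-Za-z]", "", name).upper()
    if not stripped:
        raise ValueError(f"cannot guess element from atom name {name!r}")
    if stripped in _TWO_LETTER:
        return stripped
    return stripped[0]


@dataclass(frozen=True)
class Atom:
    """Identity of one atom: naming, residue bookkeeping and mass."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    mass: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial}: mass must be > 0, got {self.mass}")
        if not self.element:
            raise ValueError(f"atom {self.serial}: element must be non-empty")


class Structure:
    """An ordered atom list plus per-atom coordinates in nm."""

    def __init__(self, atoms: Sequence[Atom], coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(atoms), 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match {len(atoms)} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        serials = [a.serial for a in atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within a structure")
        self.atoms: list[Atom] = list(atoms)
        self.coords = coords

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def copy(self) -> "Structure":
        return Structure(list(self.atoms), self.coords.copy())

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(list(self.atoms), coords)


class Trajectory:
    """Time-ordered frames over a fixed atom set.

    ``topology`` supplies atom identities (its own coordinates are ignored);
    ``times_ps`` must be strictly increasing and every frame must carry the
    topology's atom count.
    """

    def __init__(self, topology: Structure, times_ps: np.ndarray, coords: np.ndarray):
        times_ps = np.asarray(times_ps, dtype=float)
        coords = np.asarray(coords, dtype=float)
        if times_ps.ndim != 1:
            raise ValueError("times_ps must be 1-D")
        if np.any(times_ps < 0):
            raise ValueError("frame times must be >= 0")
        if times_ps.size and np.any(np.diff(times_ps) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if coords.shape != (times_ps.size, len(topology), 3):
            raise ValueError(
                f"coords shape {coords.shape} inconsistent with "
                f"{times_ps.size} frames x {len(topology)} atoms"
            )
        self.topology = topology
        self.times_ps = times_ps
        self.coords = coords

    @property
    def n_frames(self) -> int:
        return self.times_ps.size

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class Selection:
    """An ordered, duplicate-free set of 0-based atom indices."""

    atom_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = self.atom_indices
        if len(set(idx)) != len(idx):
            raise ValueError("selection indices must be unique")
        if any(i < 0 for i in idx):
            raise ValueError("selection indices must be non-negative")

    @classmethod
    def from_indices(cls, indices: Iterable[int]) -> "Selection":
        return cls(tuple(int(i) for i in indices))

    @property
    def indices(self) -> np.ndarray:
        return np.array(self.atom_indices, dtype=int)

    def __len__(self) -> int:
        return len(self.atom_indices)

    def __iter__(self):
        return iter(self.atom_indices)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int, serial_fallback: int) -> tuple[Atom, np.ndarray, str]:
    try:
        serial_s = line[6:11].strip()
        serial = int(serial_s) if serial_s else serial_fallback
        name = line[12:16].strip()
        altloc = line[16:17]
        residue_name = line[17:20].strip()
        chain_id = line[21:22]
        residue_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = guess_element(name)
    try:
        mass = mass_of_element(element)
    except KeyError:
        mass = mass_of_element(guess_element(name))
        element = guess_element(name)
    atom = Atom(serial, name, element.upper(), residue_name, residue_seq, chain_id, mass)
    return atom, np.array([x, y, z]) * NM_PER_ANGSTROM, altloc


def read_pdb(path: str | Path) -> Structure:
    """Read the first MODEL of a PDB file into a :class:`Structure` (nm).

    Alternate locations other than blank/'A' are dropped; residue numbering
    and chain identifiers are preserved exactly as printed.
    """
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    seen_serials: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                atom, xyz, altloc = _parse_atom_line(line, lineno, len(atoms) + 1)
                if altloc not in (" ", "", "A"):
                    continue
                if atom.serial in seen_serials:
                    atom = replace(atom, serial=max(seen_serials) + 1)
                seen_serials.add(atom.serial)
                atoms.append(atom)
                coords.append(xyz)
            elif rec.startswith("ENDMDL"):
                break  # first MODEL only
    if not atoms:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records found")
    return Structure(atoms, np.array(coords))


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a structure as standard ATOM records (nm → Å, 3 decimals)."""
    lines = []
    for atom, xyz in zip(structure.atoms, structure.coords):
        if atom.residue_seq > 9999:
            raise ValueError(
                f"residue_seq {atom.residue_seq} exceeds the PDB 4-column limit"
            )
        if atom.serial > 99999:
            raise ValueError(f"atom serial {atom.serial} exceeds the PDB 5-column limit")
        name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
        x, y, z = xyz / NM_PER_ANGSTROM
        lines.append(
            f"ATOM  {atom.serial:>5d} {name:4s} {atom.residue_name:>3s} "
            f"{atom.chain_id:1s}{atom.residue_seq:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{atom.element:>2s}\n"
        )
    lines.append("TER\nEND\n")
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# Extended XYZ trajectories
# ---------------------------------------------------------------------------

_TIME_RE = re.compile(r"time_ps=([-+0-9.eE]+)")


def write_xyz_traj(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory in the extended-XYZ dialect (nm, ``time_ps=`` tag)."""
    names = [a.name for a in traj.topology.atoms]
    with open(path, "w") as fh:
        for t, frame in zip(traj.times_ps, traj.coords):
            fh.write(f"{len(names)}\n")
            fh.write(f"time_ps={t:.9f}\n")
            for name, (x, y, z) in zip(names, frame):
                fh.write(f"{name} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz_traj(path: str | Path, topology: Structure | None = None) -> Trajectory:
    """Read an extended-XYZ trajectory.

    If ``topology`` is omitted a minimal one is synthesised from the atom
    names (each atom its own residue); pass the matching PDB topology for
    residue-aware analyses.
    """
    frames: list[np.ndarray] = []
    times: list[float] = []
    names0: list[str] | None = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise XYZFormatError(
                f"line {i + 1}: expected atom count for frame {frame_no}"
            ) from exc
        if i + 1 >= len(lines):
            raise XYZFormatError(f"frame {frame_no}: missing comment line")
        m = _TIME_RE.search(lines[i + 1])
        if m is None:
            raise XYZFormatError(
                f"frame {frame_no}: comment line lacks the required time_ps=<float> tag"
            )
        times.append(float(m.group(1)))
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise XYZFormatError(f"frame {frame_no}: truncated, expected {n} atom lines")
        names: list[str] = []
        xyz = np.empty((n, 3))
        for k, raw in enumerate(block):
            parts = raw.split()
            if len(parts) < 4:
                raise XYZFormatError(
                    f"line {i + 3 + k}: expected 'name x y z', got {raw!r}"
                )
            names.append(parts[0])
            xyz[k] = [float(p) for p in parts[1:4]]
        if names0 is None:
            names0 = names
        elif names != names0:
            raise XYZFormatError(
                f"frame {frame_no}: atom names/count differ from the first frame"
            )
        frames.append(xyz)
        i += 2 + n
    if not frames:
        raise XYZFormatError(f"{path}: no frames found")
    if topology is not None:
        if len(topology) != len(names0):
            raise XYZFormatError(
                f"topology has {len(topology)} atoms but trajectory frames have {len(names0)}"
            )
    else:
        atoms = []
        for k, name in enumerate(names0):
            el = guess_element(name)
            atoms.append(Atom(k + 1, name, el, "UNK", k + 1, "A", mass_of_element(el)))
        topology = Structure(atoms, np.zeros((len(atoms), 3)))
    order = np.argsort(times, kind="stable")
    times_arr = np.array(times)[order]
    coords = np.array(frames)[order]
    return Trajectory(topology, times_arr, coords)


# ---------------------------------------------------------------------------
# Selection expressions
# ---------------------------------------------------------------------------

_KEYWORDS = {"all", "none", "backbone", "name", "resname", "resid", "chain",
             "element", "and", "or", "not"}

_GRAMMAR_HELP = (
    "supported grammar: all | none | backbone | name <N...> | resname <R...> | "
    "resid <i>[-<j>] ... | chain <C...> | element <E...>, combined with "
    "'and', 'or', 'not' and parentheses"
)


def _tokenize(expr: str) -> list[str]:
    expr = expr.replace("(", " ( ").replace(")", " ) ")
    return expr.split()


class _Parser:
    def __init__(self, tokens: list[str], structure: Structure):
        self.tokens = tokens
        self.pos = 0
        self.s = structure

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError(f"unexpected end of expression; {_GRAMMAR_HELP}")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(
                f"unexpected token {self.peek()!r}; {_GRAMMAR_HELP}"
            )
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.next()
            return ~self.factor()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.primary()

    def _args(self) -> list[str]:
        args = []
        while (tok := self.peek()) is not None and tok.lower() not in _KEYWORDS and tok not in "()":
            args.append(self.next())
        if not args:
            raise SelectionError(f"keyword needs at least one argument; {_GRAMMAR_HELP}")
        return args

    def primary(self) -> np.ndarray:
        tok = self.next().lower()
        atoms = self.s.atoms
        n = len(atoms)
        if tok == "all":
            return np.ones(n, bool)
        if tok == "none":
            return np.zeros(n, bool)
        if tok == "backbone":
            return np.array([a.name in BACKBONE_NAMES for a in atoms])
        if tok == "name":
            args = set(self._args())
            return np.array([a.name in args for a in atoms])
        if tok == "resname":
            args = {a.upper() for a in self._args()}
            return np.array([a.residue_name.upper() in args for a in atoms])
        if tok == "chain":
            args = set(self._args())
            return np.array([a.chain_id in args for a in atoms])
        if tok == "element":
            args = {a.upper() for a in self._args()}
            return np.array([a.element.upper() in args for a in atoms])
        if tok == "resid":
            wanted: set[int] = set()
            for arg in self._args():
                try:
                    if "-" in arg[1:]:
                        lo, hi = arg[:1] + arg[1:].split("-", 1)[0], arg[1:].split("-", 1)[1]
                        wanted.update(range(int(lo), int(hi) + 1))
                    else:
                        wanted.add(int(arg))
                except ValueError as exc:
                    raise SelectionError(f"bad resid token {arg!r}") from exc
            return np.array([a.residue_seq in wanted for a in atoms])
        raise SelectionError(f"unknown keyword {tok!r}; {_GRAMMAR_HELP}")


def select(structure: Structure, expr: str) -> Selection:
    """Evaluate a selection expression on a structure.

    Deterministic and order-stable: indices are returned in atom order.  An
    empty result is a valid (empty) selection, not an error.
    """
    tokens = _tokenize(expr)
    if not tokens:
        raise SelectionError(f"empty selection expression; {_GRAMMAR_HELP}")
    mask = _Parser(tokens, structure).parse()
    return Selection.from_indices(np.nonzero(mask)[0])
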