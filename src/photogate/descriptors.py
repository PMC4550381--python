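"""Clamshell-opening descriptors and the closing-degree statistic.

The ligand-binding domain of an ionotropic glutamate receptor is a
two-lobed clamshell that closes around agonists.  Its opening state is
tracked by the center-of-mass distance |d| between two residues near the
lobe tips (Y488 and G688 in GluK2 numbering) and summarised by the closing
degree

    CD = (|d|_open − |d|) / (|d|_open − |d|_closed),

a linear map sending the crystallographic open reference (1.15 nm,
antagonist-bound GluK1, whose Y505/G704 correspond to Y488/G688) to 0 and
the closed, glutamate-bound reference (0.63 nm) to 1.  Values outside
[0, 1] are legal — a clamshell can open wider than the antagonist reference
— and are flagged rather than clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import center_of_mass, com_distance
from .structio import Selection, Structure, Trajectory, select

__all__ = [
    "ClosingDegreeResult",
    "ClamshellSeries",
    "closing_degree",
    "clamshell_series",
    "reference_distance",
    "D_OPEN_DEFAULT",
    "D_CLOSED_DEFAULT",
]

#: Crystallographic reference distances (nm): antagonist-bound (open) and
#: glutamate-bound (closed) states.
D_OPEN_DEFAULT: float = 1.15
D_CLOSED_DEFAULT: float = 0.63


@dataclass(frozen=True)
class ClosingDegreeResult:
    """|d|, its references and the resulting closing degree."""

    d: float
    d_open: float
    d_closed: float
    cd: float

    @property
    def percent(self) -> float:
        return 100.0 * self.cd

    @property
    def outside_reference_range(self) -> bool:
        """True when |d| falls outside [closed, open], i.e. CD outside [0, 1]."""
        return not 0.0 <= self.cd <= 1.0


def closing_degree(
    d: float,
    d_open: float = D_OPEN_DEFAULT,
    d_closed: float = D_CLOSED_DEFAULT,
) -> ClosingDegreeResult:
    """Closing degree of a clamshell distance against the crystal references."""
    if not np.isfinite(d):
        raise ValueError("d must be finite")
    if d_open <= d_closed:
        raise ValueError(
            f"d_open ({d_open}) must exceed d_closed ({d_closed})"
        )
    cd = (d_open - d) / (d_open - d_closed)
    return ClosingDegreeResult(float(d), float(d_open), float(d_closed), float(cd))


def _residue_selection(structure: Structure, resid: int) -> Selection:
    sel = select(structure, f"resid {resid}")
    if len(sel) == 0:
        raise KeyError(f"residue {resid} not present in topology")
    return sel


@dataclass
class ClamshellSeries:
    """Per-frame clamshell distance plus a windowed summary."""

    times_ps: np.ndarray
    distance_nm: np.ndarray
    mean: float
    sd: float
    window: tuple[float, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times_ps,
                             "distance_nm": self.distance_nm})


def clamshell_series(
    traj: Trajectory,
    residue_pair: tuple[int, int] = (488, 688),
    mass_weighted: bool = True,
    window: tuple[float, float] | None = None,
) -> ClamshellSeries:
    """Per-frame COM distance (nm) of the clamshell residue pair.

    The summary (mean, sd) is taken over ``window`` = (t0, t1) in ps when
    given, otherwise over the full series; the series itself is never
    windowed.
    """
    res_a, res_b = residue_pair
    sel_a = _residue_selection(traj.topology, res_a)
    sel_b = _residue_selection(traj.topology, res_b)
    series = com_distance(traj, sel_a, sel_b, mass_weighted=mass_weighted)
    if window is None:
        sub = series
    else:
        mask = (traj.times_ps >= window[0]) & (traj.times_ps <= window[1])
        if not np.any(mask):
            raise ValueError(f"summary window {window} ps contains no frames")
        sub = series[mask]
    return ClamshellSeries(traj.times_ps.copy(), series,
                           float(np.mean(sub)), float(np.std(sub)), window)


def reference_distance(
    structure: Structure,
    res_a: int,
    res_b: int,
    mass_weighted: bool = True,
) -> float:
    """Single-structure COM distance (nm) between two residues.

    Used to recompute the crystallographic reference distances from
    deposited structures (the closed, partially-closed and open references),
    with author residue numbering taken verbatim from the file.
    """
    sel_a = _residue_selection(structure, res_a)
    sel_b = _residue_selection(structure, res_b)
    masses = structure.masses if mass_weighted else None
    a = center_of_mass(structure.coords, sel_a, masses, geometric=not mass_weighted)
    b = center_of_mass(structure.coords, sel_b, masses, geometric=not mass_weighted)
    return float(np.linalg.norm(a - b))
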