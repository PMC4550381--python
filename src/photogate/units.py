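"""Unit conventions and physical constants.

Internal units throughout the package: lengths in nm, times in ps (the
photoswitch module labels its outputs in fs), energies in kJ/mol, masses in
amu and angles in degrees at API boundaries (radians internally where noted).
In this unit system 1 amu·nm²·ps⁻² equals exactly 1 kJ/mol, so Langevin
integrators need no hidden conversion factors.  kcal/mol appears only in
display layers and in the free-energy profile type, via the factor 4.184.
"""

#: Boltzmann constant, kJ mol⁻¹ K⁻¹ (CODATA 2018, exact SI definition).
KB_KJ_PER_MOL_K: float = 0.00831446261815324

#: kJ per kcal (thermochemical calorie).
KJ_PER_KCAL: float = 4.184

#: nm per Å.
NM_PER_ANGSTROM: float = 0.1


def kcal_to_kj(x: float) -> float:
    """Convert kcal/mol (or kcal·mol⁻¹·nm⁻²) to kJ-based units."""
    return x * KJ_PER_KCAL


def kj_to_kcal(x: float) -> float:
    """Convert kJ/mol (or kJ·mol⁻¹·nm⁻²) to kcal-based units."""
    return x / KJ_PER_KCAL
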