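# Methods

This note documents the models behind `photogate`, the parameter choices
that matter, what the synthetic generators do and do not emulate, and the
numerical decisions a user should know before trusting a number.

## Units and conventions

Internally: nm, ps, kJ/mol, amu, degrees for torsions (radians inside
integrators).  In this system 1 amu·nm²·ps⁻² = 1 kJ/mol exactly, so the
Langevin integrators carry no unit conversions.  kcal/mol appears only at
display boundaries (factor 4.184): free-energy profiles and barrier heights
are reported in kcal/mol because that is how clamshell PMFs are
conventionally printed, and the umbrella force constant default
2092 kJ·mol⁻¹·nm⁻² is the round 500 kcal·mol⁻¹·nm⁻².  Atom indices are
0-based internally; residue numbers are kept exactly as the source PDB
prints them (crystallographic author numbering such as Y488/G688, or
Y505/G704 in the GluK1 open-reference numbering) and are never remapped.

## Structure and trajectory I/O

The PDB reader handles the ATOM/HETATM/TER/END(MDL) subset only: first
MODEL, altloc blank/'A' kept, Å→nm on read, malformed records reported with
their line number.  Trajectories travel in an extended-XYZ dialect (atom
count, a comment line carrying `time_ps=<float>`, then `name x y z` in nm)
that round-trips losslessly to 1e-6 nm.  No mmCIF, no binary formats, no
bond perception, no hydrogen placement.  The selection language
(`backbone`, `name`, `resid` with ranges, `resname`, `chain`, `element`,
boolean operators) is deliberately tiny; it exists so residue-level
descriptors can be expressed declaratively, not to replace a general
selection engine.

## Geometry kernels

Center of mass is mass-weighted over all atoms of the named residues by
default.  Whether the original clamshell descriptor used mass-weighted or
geometric centers (or backbone-only atoms) is not derivable from the
record; "center of mass" is read literally, and a `geometric`/selection
flag exposes the variants.  Torsions follow the IUPAC sign convention
(atan2 form; planar cis = 0°, trans = 180°, range (−180°, 180°]).
Superposition is weighted Kabsch via SVD with the determinant sign
correction excluding reflections; collinear point sets are rejected rather
than silently resolved.  RMSD traces fit and measure on the backbone by
default — the usual protocol when the fit/measure sets are unstated.

## The photoswitch rotor

The trans→cis photoisomerization is modelled as a 1-D underdamped Langevin
rotor on the CNNC torsion:

* **Bias.**  V(φ) = ½K(1 − cos φ), K = 320 kJ/mol, applied for 500 fs and
  then discarded.  This form has its minimum at the cis target; the
  commonly quoted form ½K(1 + cos φ) is the same potential under a
  φ → φ−180° convention and, taken literally with φ_trans = 180°, could not
  drive trans→cis at all, so the physically consistent sign is implemented
  (targets `cis` and `trans` mirror each other).
* **Ground-state potential.**  U(φ) = c₁(1−cos 2φ) + c₂(1−cos 4φ) with
  barrier 2c₁ = 100 kJ/mol (the right order for azobenzene thermal
  isomerization) and well curvature 4c₁+16c₂ = 40 kJ/mol/rad², which
  matches the ≈100 cm⁻¹ azobenzene torsional frequency at the default
  inertia.  Within 0 < curvature ≤ 2·barrier the form has exactly two
  minima (0° and 180°) and no spurious wells.
* **Inertia.**  Computed at load time from a packaged idealized planar
  trans-azobenzene (standard bond lengths, CNN angle 114°).  Two reductions
  are provided.  Rigid counter-rotation of the two phenyl fragments about
  the N=N axis gives ≈3.0 amu·nm²; with that inertia the biased rotor
  cannot leave the trans hilltop inside the 500-fs bias window (escape rate
  ≈3 ps⁻¹), i.e. a rigid-phenyl rotor is qualitatively wrong for ultrafast
  switching.  Azobenzene actually isomerizes by a pedal-like motion in
  which the light diazo bridge rotates about the ipso–ipso carbon axis
  while the heavy phenyls barely move; the corresponding reduced inertia,
  ≈0.11 amu·nm², is the `default_rotor` value.
* **Integration.**  BAOAB splitting, dt = 0.1 fs (≥1000 steps per torsional
  period; dt ≤ 0.5 fs enforced), friction 10 ps⁻¹, T = 300 K, 1 ps
  thermalization in the starting well before the bias switches on, explicit
  seeds everywhere, bit-reproducible.

**Known limitation — switch-time scale.**  With these defaults the ensemble
median first passage to |φ| ≤ 10° is ≈160 fs, with all runs completing
within the bias window but a tail extending to ≈350–420 fs.  Sub-100-fs
completion, as observed in all-atom excited-state-mimicking simulations, is
not reachable by *any* thermodynamically consistent 1-D rotor started from
a thermalized trans well: escape from the inverted top costs
λ⁻¹·ln(π/θ₀) ≈ 100 fs before the fall even begins (λ_eff ≈ 28 ps⁻¹ here,
θ₀ the thermal spread).  Multidimensional excited-state dynamics bypasses
this delay; the surrogate reproduces the right phenomenology (complete,
irreversible switching on the 100-fs scale with post-switch fluctuation of
≈10° about cis) but overshoots the literal 100-fs completion time by
roughly a factor of 1.6.  The 10° threshold itself is this package's
operationalization of "switched"; no angular criterion is part of the
original record.

## Closing degree

CD is affine in |d| by construction; values outside [0, 1] (clamshell wider
than the antagonist-bound reference) are legal and flagged, never clipped.
When several simulations are averaged, the per-simulation mean distances
are averaged first and CD evaluated once on the pooled mean — applied to
the cis-bound means 1.04/0.90/0.89 nm this yields 39.7% ≈ 40%.  Note a
documented inconsistency in the printed record for the corresponding
trans-bound value: the same protocol on the printed trans means
(0.97, 0.75 nm) gives ≈56%, not the printed 62%, and the kainate-bound
0.82 nm gives ≈63%, not 50%.  The averaging protocol behind those two
printed values is not stated; this package documents the discrepancy and
does not attempt to patch it.

## Hydrogen bonds and salt bridges

Community-standard geometric criteria (the source study's criteria are
unstated): donor–acceptor heavy-atom distance ≤ 0.35 nm; when hydrogens
exist and `heavy_only` is off, D–H⋯A deviation from linearity ≤ 30°;
salt bridges by charged-group centroid distance ≤ 0.45 nm.  A bond "to a
carboxyl group" accepts either carboxylate oxygen.  Occupancy percentages
from 500-ns production trajectories are trajectory-specific and cannot be
recomputed without those trajectories; the occupancy machinery is therefore
validated on scripted Bernoulli/Markov contact trajectories with prescribed
rates, where recovery converges as 1/√n.

## Virtual dimer

The D1 residue partition used for alignment is not enumerated in the
record, so the alignment anchor is a configurable selection
(`DimerTemplate.d1_sel`); the toy dimer's anchor is a six-bead rigid body.
Linker COMs use all atoms of the four residues K544, G, T, P667.  The
static-monomer construction systematically overestimates the linker
response (the real dimer interface flexes); it is a proxy for qualitative
comparison, and the toy generator encodes exactly such a linear map
(linker = a − b·d plus Gaussian noise), for which the attenuated
correlation −1/√(1+σ²/var(signal)) is known analytically.

## Umbrella sampling and WHAM

* **Surfaces.**  U(x) = b·((x−c)²−w²)²/w⁴ — the minimal smooth interpolant
  of the only published facts (two minima, one barrier).  Bundled
  parameters: trans-like 0.76/1.20 nm with 1.5 kcal/mol; cis-like
  0.93/1.28 nm with 1.6 kcal/mol.
* **Dynamics.**  Overdamped Langevin, m = 1 amu, γ = 10 ps⁻¹
  (D = k_BT/mγ ≈ 0.25 nm²/ps), Euler–Maruyama by default with stability
  bound dt ≪ mγ/max|U''|.  Umbrella windows default to the
  Leimkuhler–Matthews (BAOAB-limit) variant: under the stiff
  2092 kJ·mol⁻¹·nm⁻² bias the Euler–Maruyama configurational error at
  dt = 5·10⁻⁴ ps is visible (≈5% variance inflation) while the
  BAOAB-limit scheme is O(dt²)-accurate at identical cost.
* **Windows.**  19 windows (21 for the cis-like surface) uniformly spaced
  on 0.5–1.4 nm — spacing is unstated in the record, uniform is the
  neutral choice; 20% of each window discarded as equilibration.
* **Pulling.**  Moving-restraint Brownian pull; the function default rate
  10⁻⁵ nm/ps mirrors gentle production practice, while tests and the demo
  pull at 10⁻³ nm/ps — for a memoryless 1-D walker the rate only needs to
  be slow against the window relaxation time (≈5·10⁻³ ps), so this is
  pure problem-sizing, not a physical approximation.
* **WHAM.**  Standard self-consistent iteration on binned samples
  (90 bins over 0.5–1.4 nm, tol 10⁻⁶ kJ/mol on the window free energies,
  max 10⁵ iterations, T = 300 K).  Empty bins are masked (NaN), never ∞;
  the profile is shifted so its global minimum is zero; non-overlapping
  neighbouring windows and non-convergence are hard errors naming the
  culprit.  Convergence is reported as profiles from growing fractions of
  the data, with the deviation metric evaluated below a 5 kcal/mol ceiling:
  the steep, rarely visited walls would otherwise dominate the metric with
  pure counting noise.
* **Validation.**  The full pull→windows→WHAM pipeline recovers the bundled
  double wells' minima within 0.03 nm and barriers within 0.3 kcal/mol,
  matches the analytic profile of a harmonic well within 0.1 kcal/mol, and
  agrees with direct Boltzmann inversion of a long unbiased run within
  0.2 kcal/mol over well-sampled bins.

## Problem sizes

Desk-scale defaults were chosen so the full validation suite runs in about
a minute of CPU: 19–21 windows × 20k–120k overdamped steps (10–24 ps per
window), 25-seed switching ensembles of 1 ps each, 2000–5000-frame scripted
contact and dimer trajectories.  These sizes are the package's own choice
of statistical resolution: every tolerance quoted above was checked against
the corresponding estimator's sampling error at these sizes.

## What the synthetic models do not show

The generators emulate coordinates and statistics, not physics: no
solvent, no ligand chemistry, no real protein elasticity, no coupling
between the clamshell coordinate and the contact network.  Passing tests
demonstrate that the *analysis machinery* is correct and statistically
calibrated — they say nothing new about GluK2 itself.  Real-trajectory
quantities (specific occupancy percentages, specific correlation
coefficients, all-atom PMFs) require the original trajectories and are out
of scope by design.
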