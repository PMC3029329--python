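# Methods

This note documents the models, conventions and numerical choices behind
`permeopath`, and what the synthetic validation systems do and do not show
about real trajectories.

## Scope and data model

The package analyzes coordinates only: a `Structure` is an ordered atom list
with role tags (protein / ligand / water / lipid / ion) assigned from
residue-name rules, and a `Trajectory` is a frame-indexed coordinate stack
over a fixed topology with strictly increasing times. Input is PDB-dialect
text (`ATOM`/`HETATM`, `MODEL`/`ENDMDL`); sequence numbering follows the PDB
field verbatim. Frame spacing is supplied per file (simulation protocols mix
strides — e.g. 2 ps during pulling, 5 ps during equilibration, 10 ps
snapshots — so it is configuration, not something inferred). Hydrogens are
read if present but excluded from contact and RMSD analyses by default.

Generic transmembrane numbering assigns position 50 to the most conserved
residue (anchor) of each TM helix; residue *r* in TM *t* with anchor *a* is
labelled `t.(50 + r − a)`, and loop residues carry the loop name. The
anchor table is configuration: conservation analysis is out of scope.

## Contact occupancy and pathway statistics

A residue–ligand contact in a frame means the minimum distance over all
heavy-atom pairs is ≤ the cutoff (default 3.5 Å). Site membership requires
occupancy strictly above the threshold fraction (default 5%) of analyzed
frames, after dropping an equilibration prefix and subsampling at a stride.
Hydrogen-inclusive contact mode exists but is not the default, since typical
deposited structures lack hydrogens.

Pathway classification uses the windowed percentage
*n*<sub>seen</sub> / (last − first + 1) per trajectory. The inclusive
denominator is deliberate: the open form (last − first) exceeds 100% for
continuous contact and is undefined for a single-frame contact, while the
inclusive form is bounded by 1, equals the open form asymptotically, and
makes a single-frame contact 100% by convention. Residues already assigned
to a binding site are excluded from pathway lists. Both statistics are exact
integer arithmetic — on scripted trajectories they must reproduce the
script exactly, which is how they are tested.

## Steering-force profiles

Pulling-force series are smoothed with a centered moving average (odd
window); pockets along the path appear as strict local minima of the
smoothed series, reported at least one window apart (deepest kept). Force
units are treated as opaque: the SMD metadata (velocity, spring constant)
is carried as provenance, and no free-energy estimate is attempted.

## Superposition

`kabsch_fit` is the weighted SVD solution with the determinant corrected so
the rotation is always proper; collinear point sets are rejected (the
rotation is not unique). The iterative per-residue-weighted alignment runs
one uniform-weight pass followed by `n_iter` (default 3) refinement passes
with *w<sub>i</sub>* = 1/(RMSD<sub>i</sub>² + ε), ε = 0.01 Å². The inverse-
square form is the simplest update with the required behavior (lower-RMSD
residues dominate subsequent fits); the exact weighting of the original
interactive tools is unpublished, so the scheme and ε are echoed in output
metadata. Counting refinements (rather than raw fits) matters: from a
uniform start the third raw fit still carries visible arm contamination,
while three refinements converge the rigid core to < 0.01 Å on the
two-domain benchmark. Per-residue RMSD uses backbone N, CA, C (O excluded;
CA-only available). Rigidity labels use ≤ 2 Å (rigid) and ≥ 3 Å (mobile),
the gap being "intermediate".

The two-domain benchmark is an ideal helix split into a 16-residue core and
an 8-residue arm swung 120° about a hinge through the junction CA. A 25°
swing moves the near-hinge arm residues by roughly the same magnitude as
residual fit noise, so no reweighting scheme of this family can separate
the domains there; the 120° condition produces an unambiguous partition
(core < 0.01 Å, arm > 3 Å) and is the documented benchmark condition.

Difference distance matrices are computed on Cα distances and are
superposition-free; they are antisymmetric under state exchange by
construction.

## Helix kink geometry

A segment's long axis is estimated from second differences of the Cα trace:
the second difference at each residue points toward the helix axis, so
cross products of consecutive second differences lie along the axis; their
normalized mean, oriented N→C, is the direction. This estimator is exact on
ideal helices at any length ≥ 6 residues. A principal-component fit of the
(smoothed) trace was evaluated first and rejected: at the default 7-residue
window the helical wobble biases it by several degrees, more than the whole
error budget.

The bend angle is the angle between the pre- and post-pivot axes. For the
face shift, the post segment is rotated about the pivot Cα by the minimal
rotation taking its axis onto the pre axis (parallel transport, which adds
no spurious twist), and each segment's Cα azimuths about its own axis are
fitted linearly against residue index (the axis location in the
perpendicular plane is the least-squares circle center of the projected
trace). The face shift is the difference of the two phase fits evaluated at
the anchor point used in the classical protocol, the mean position of the
(pivot−3) and (pivot−4) residues; it is reported in (−180°, 180°]. Pre and
post windows default to the 7 residues adjacent to the pivot on each side,
pivot excluded; both are configurable per TM. Imposed kinks on ideal
helices (bend 10–50°, face shift 0 to ±90°) are recovered to machine
precision; on noisy real helices the accuracy is set by the axis fit and
the tests bound it at 2° (bend) and 3° (face shift). Per-frame series are
summarized as mean ± sample std; the face-shift mean is taken after
re-centering on the first frame to avoid the ±180° seam, which biases the
summary only if a trajectory genuinely straddles that seam.

## Solvation

Water profiles count water oxygens per z-bin (z = 0 at the membrane
center), averaged over the selected late frames of a trajectory previously
aligned to a common reference, optionally restricted to a lateral cylinder
(the "pathway region" is geometric configuration — default a 10 Å-radius
cylinder is suggested, but the demo systems count everything).

SASA is Shrake–Rupley quadrature on a Fibonacci sphere point set (default
960 points, ≤ 2% error on isolated spheres; 1920 halves it), Bondi vdW
radii, probe 1.4 Å. "Exposed to lipid counts as buried" is realized simply
by including lipid (and ion) atoms as occluders; waters never occlude.
Per-residue fractions divide by the residue type's SASA in an extended
(φ = ψ = ω = 180°) Gly-X-Gly tripeptide computed with the same engine —
internally consistent by construction, though numerically different from
the historical published reference tables. The tripeptide backbone is built
by internal-coordinate chain extension and side chains are grafted from
idealized residue templates (biotite's CCD set) superimposed on N/CA/C.

## Energetics

Pair energies use the Coulomb + 12-6 Lennard-Jones form with
*C* = 332.0636 kcal·Å/(mol·e²), dielectric 1, Lorentz–Berthelot combination
(ε<sub>ij</sub> = √(ε<sub>i</sub>ε<sub>j</sub>),
r<sub>min,ij</sub> = (r<sub>min</sub>/2)<sub>i</sub> + (r<sub>min</sub>/2)<sub>j</sub>).
Group–group energies sum all cross pairs; no cutoff, switching function, or
periodic images by default — the exact summation is reproducible and the
convention is recorded in output metadata. Force-field parameters are user
input (`TYPE charge epsilon rmin_half` per line); a small built-in set
(TIP3P-like water, neutral dummy ligand) ships for tests only —
redistributing a force field is out of scope.

## Torsion statistics

Torsions use the standard atan2 construction with the IUPAC sign convention
on (−180°, 180°]; collinear triples are rejected. χ1/χ2 accept the common
γ/δ atom-name variants. Rotamer states partition χ1 as (0°, 120°] → g+,
(120°, 180°] ∪ (−180°, −120°] → t, (−120°, 0°] → g− (the standard
convention; the partition is exhaustive and exclusive). Spearman's ρ is the
Pearson correlation of mid-ranks (ties averaged); both series are unwrapped
(±360° at jumps > 180°) before ranking so a rotation crossing the seam is
not read as a rank reversal. A constant series has undefined ρ, reported as
NaN, never 0. A seeded permutation p-value (default 10⁴ permutations) is
available but not computed by default.

## Synthetic systems: what they show and what they do not

Every generator is deterministic given its seed and emits only finite
coordinates. The scripted-ligand system realizes contact scripts *exactly*
(nearest heavy atom at cutoff − 0.5 Å in scripted frames, ≥ cutoff + 2 Å
otherwise) by spacing residues far apart — which is precisely why it
validates the statistics: any deviation is an implementation bug, not
noise. The water slab places exact per-bin counts; the two-domain ensemble
and imposed kinks are rigid constructions. None of these emulate force-field
physics, thermal ensembles, periodicity, or correlated noise; passing tests
demonstrates the correctness of the measurement layer, not the realism of
any simulation. Conversely, published per-residue numbers from any specific
study depend on that study's trajectories and are not reproducible from
synthetic data; the pipeline reproduces the *protocols* (thresholds,
windows, strides, exclusion rules) rather than the numbers.

## Pipeline

A single INI-style config drives the full suite in a fixed order: align →
sites → pathway → water profile → SASA → energy → dihedrals/correlation →
kinks → per-residue RMSD → distances. Stage failures abort with the stage
name. Outputs are TSV with `#` provenance headers (config SHA-256, seed,
package and numpy versions, and every numeric convention in effect); no
timestamps are written, so a rerun with the same config and seed is
byte-identical. The demo problem sizes (100-frame contact script, 40-residue
helix, 24-residue two-domain ensemble, ~20-water systems, 480-point SASA
quadrature) were chosen as the smallest systems on which every statistic is
non-trivially exercised.
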