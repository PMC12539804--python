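# Methods

`twistgate` implements the mechanics analysis behind the twist-to-open
picture of tethered mechanosensitive channel gating: how force applied to
the intracellular ankyrin-repeat (AR) spring of a NOMPC-like channel is
distributed across residue pairs, decomposed at the TRP domain into
membrane-parallel (twisting) and membrane-normal (pushing) components,
and related to the torsional elasticity of the AR bundle. This note
documents the models, conventions, parameters and numerical choices, and
what the synthetic study conditions do and do not establish.

## Units and sign conventions

Internally: nm, ps, kJ/mol, elementary charge, radians. Forces are
kJ mol⁻¹ nm⁻¹; the single conversion constant to piconewton,
1 kJ mol⁻¹ nm⁻¹ = 1.66054 pN (division by Avogadro's number), lives in
`twistgate.units` and is used everywhere a pN figure is reported.

One global sign convention ties the geometric readouts together: the
membrane normal +z points extracellular; positive rotation and positive
torque about +z follow the right-hand rule, which is the rotation that
appears **clockwise when viewed from the intracellular side**. A torque
whose vector points extracellular therefore drives the clockwise TRP
rotation associated with gating, and `rotation_angle`,
`torque_about_axis` and `rotation_tilt_angles` all agree on the sign.

## Pairwise force engine

For given frames the engine evaluates, per atom pair, the bonded
(harmonic bond, harmonic angle, periodic dihedral), Coulomb and 12-6
Lennard-Jones forces, and sums them within residue pairs to give the
residue-residue force table F(ri,rj), classed by interaction. Forces are
stored for the pair ordered by (chain, resid); the reverse entry is the
exact negation (Newton's third law is structural, not numerical).

Nonbonded terms use a potential-switch: U(r) is multiplied by a quintic
smoothstep S(r) that falls from 1 at the switch-on radius (default
1.0 nm) to 0 at the cutoff (default 1.2 nm) with zero slope at both
ends, and the force is the analytic −d(U·S)/dr — continuous everywhere,
exactly zero beyond the cutoff, and below switch-on exactly Coulomb's
law (ke = 138.935458 kJ mol⁻¹ nm e⁻²) or the 12-6 force. The exact
switching polynomial is a package choice; it is constrained by the
tested property that the force matches −dU/dr of the switched potential
by central finite difference to 1e-4 relative.

Electrostatics are short-range pairwise only. A reciprocal-space (PME)
contribution has no pairwise decomposition and is deliberately absent;
this is a known deviation shared with pairwise force-distribution
tooling generally. Entropic contributions are likewise not part of any
pairwise force decomposition.

Exclusions follow the CHARMM-style convention by default: 1-2 and 1-3
bonded neighbours excluded from nonbonded sums, 1-4 included unscaled;
the policy is configurable in the parameter file. Combination rule:
Lorentz–Berthelot by default, geometric available.

Angle and dihedral forces are decomposed into central pairwise
contributions over the participating atoms by solving the small linear
system that equates the pairwise sums to the analytic per-term atomic
forces (for ≤4 atoms with zero net force and torque such a central
decomposition always exists). The reconstruction is exact and is tested
against an independent finite-difference oracle.

## Net (condition-difference) force analysis

The net force table is mean(forced replicates) − mean(free replicates),
per pair and per interaction class, with replicates weighted equally
regardless of frame counts (a frame-weighted option exists but is off by
default, matching the equal-replicate form of the difference). With two
replicates per condition this reduces to (A1 + A2 − B1 − B2)/2.

Because the channel is a C4 homotetramer, net tables can be
rotationally symmetrized: each pair entry is mapped to its three
chain-cycle images, the vectors rotated about the pore axis by the
corresponding multiples of −90° into the reference-chain frame, and
averaged. The output is the full C4-symmetric completion (reference
average plus its exact rotated images), which makes the operation
idempotent. Residues correspond across chains by identical author
residue id unless an offset is configured. Class-resolved tables are
symmetrized and classes summed afterwards; with linear operations
throughout, the order does not affect the class-summed result.

Display filtering drops entries whose class-summed vector magnitude is
strictly below a pN threshold (the conventional display filter is 5 pN;
an entry exactly at the threshold survives). Domain aggregation sums,
for each residue of a target domain, the net vectors exerted by all
residues of a source domain (e.g. total force on the TRP domain from the
linker-helices domain); aggregation and thresholding commute only at
threshold zero, which is documented rather than hidden.

## Mechanical readouts and elasticity fits

Per-subunit local frames: z is the membrane normal; x is the TRP-helix
axis component perpendicular to z, sign-oriented from the pore center
toward the helix centroid (pore → membrane); y = z × x. The helix axis
is the principal axis of the selection's Cα coordinates oriented N→C.
Force decomposition into this frame is an orthonormal projection and
exactly invertible.

Rotation angles use the in-plane least-squares closed form ("norm
method"): with a_i, b_i the in-plane components of reference and current
positions about the axis, φ = atan2(Σ(a_i×b_i)·n, Σ a_i·b_i), unwrapped
across frames. Bundle length is the distance between mass-unweighted
centroids of the two end groups (the "centroid" readout is unweighted by
convention here; a mass-weighted option would change values only if
masses differ across the group).

Elasticity of the AR spring:

* **Torsion coefficient c** from M = c·φ, fitted through the origin —
  the law as stated has no intercept; an intercept option exists for
  diagnostics only. Standard error from the one-parameter residuals.
* **Compression–twist coupling k_ct** from L = L0 − k_ct·φ (ordinary
  least squares); k_ct > 0 means the bundle shortens as it twists, and a
  negative estimate is flagged `extension_coupled` rather than silently
  reported.

Default analysis windows mirror the stepwise twist protocol: snapshots
at 2.5° increments up to 10°, each window relaxed and its torque/length
readouts averaged over the window before fitting.

## Hydrogen bonds and force/occupancy correlation

A hydrogen bond is counted when donor–acceptor distance ≤ 0.35 nm and
the H–donor–acceptor angle ≤ 30° — the common trajectory-analysis
default, used because occupancies are conventionally printed without
their criteria; both are configurable and recorded in output metadata.
Occupancy of a residue pair is the fraction of frames with at least one
bond in either direction. Donor/acceptor role tables include both side
chain and backbone atoms when supplied from a full structure.

The correlation analysis vectorizes AR-unit sub-blocks of the
(symmetric) non-bonded net-force magnitude matrix and the occupancy
matrix and computes a Pearson coefficient per unit pair, giving a
unit × unit grid (21 × 21 for a 21-unit AR range). Within-residue
diagonal entries are excluded from blocks; blocks with fewer than
`min_pairs` entries or zero variance are flagged undefined, not zero.
The grid function is filter-agnostic: applying the 5 pN filter first is
an explicit upstream step, not an implicit one. Grid summaries report
mean ± sd over the diagonal (intra-unit) and the first off-diagonals
(inter-unit).

## Structural geometry

Superposition is least-squares rigid (Kabsch, proper rotation), done via
`scipy.spatial.transform.Rotation.align_vectors`; degenerate inputs
(< 3 points, collinear sets) raise rather than return a garbage frame.

TRP-helix rotation/tilt between two states: state 2 is superposed onto
state 1 via the shared S1–S4 scaffold, then the helix axes are compared.
Rotation is the signed angle between the in-plane axis projections about
the membrane normal (+ = clockwise from intracellular); tilt change is
the difference of axis elevations above the membrane plane, with
"tilt-up" meaning the C-terminal end moves extracellular — an
interpretation that must be stated in any cross-channel comparison,
since the anchoring terminus convention is not universal. Axes within 5°
of the normal make the in-plane projection meaningless and raise a
degeneracy error. Rotation is an axis property (projected axis angle),
not a per-atom in-plane fit; the two differ only when the helix deforms.

The pore profiler is a simplified slice-based reimplementation of
sphere-fitting pore programs: at each axial position the in-plane center
is optimized (Nelder–Mead, warm-started from the previous slice) to
maximize the minimal sphere clearance min_i(|c − atom_i| − vdW_i) over
atoms within 0.6 nm of the slice. Radii are floored at zero; slices with
no nearby atoms are flagged undefined rather than reported as zero. vdW
radii default to a bundled Bondi-style element table, overridable per
atom. This is an approximation of full Monte-Carlo sphere tracing; on
cylindrically constructed fixtures it is exact to better than 0.01 nm,
which is the validated regime. It is not intended to reproduce any
specific pore program bit-for-bit.

## Synthetic study conditions

The `synthetic_data` module is first-class, tested code that generates
every input the pipeline needs, deterministically from a seed, each with
a machine-readable truth manifest:

* **Toy force systems** (≤100 atoms) with charges, LJ parameters and a
  small bonded graph, sized so a brute-force double-loop oracle is
  cheap.
* **Paired forced/free pairwise-force series**: the free condition is
  zero-mean Gaussian noise per pair per frame; the forced condition adds
  a known Δ on designated LH→TRP interface pairs, concentrated on two
  residues to emulate the two major points of force application. Noise
  sigma is a fraction (default 0.1) of the largest |Δ|.
* **A C4 channel**: four chains built by exact 90° rotations, radial TRP
  helices whose winding is orthogonalized against the axial trend so the
  constructed principal axis is exactly the intended direction, a
  pore-lining segment and an LH block; centroid exactly at the origin.
* **The bead-spring AR bundle** under the stepwise twist protocol:
  29 AR beads + 2 LH beads per chain on a helical path, four chains;
  twist applied as a rigid rotation of the lower (AR1–8) block,
  compression as axial scaling — mirroring the protocol's two controlled
  ends (lower block driven, upper end restrained). Generator truths
  default to the fitted study values c = 2300 kJ mol⁻¹ rad⁻¹ and
  k_ct = 1.32 nm rad⁻¹ with L0 = 10 nm. Each window emulates a long
  restrained relaxation: per-sample torque/length noise (sigma = 10% of
  the signal scale) is averaged over 100 samples per window, as the
  protocol's every-2-ps readouts are averaged per window. A single
  un-averaged draw at that noise level would make the 4-point coupling
  slope unidentifiable (slope SE ≈ 36%), which no fitter could rescue;
  the window-mean model is the faithful description of the readout.
* **H-bond frames** realizing prescribed occupancies exactly
  (round(target × n frames) valid frames, seeded subset); defaults are
  the three printed interface occupancies 57%, 71%, 24%.
* **Cylindrical pores** from stacked atom rings spaced 0.5 nm so no ring
  shadows the sphere clearance at its neighbour's height, making the
  analytic accessible radius exact; a dilating variant widens the gate
  linearly from 0.08 to 0.25 nm through the 0.2 nm opening threshold.
* **Helix pairs** with known rotation/tilt on a rigid scaffold, plus a
  random global rigid-body motion so only scaffold superposition can
  recover the angles.

What passing on these conditions shows — and what it does not: the
generators exercise the estimators under known truth with Gaussian
noise, exact symmetry, rigid scaffolds and idealized geometry. They do
not emulate force-field realism, correlated MD noise, partial occupancy
geometry (bonds are broken by distance, never by angle drift), membrane
deformation, or protein flexibility during superposition. Agreement here
validates the machinery, not the biology; conclusions about a real
channel require real trajectories through the same interfaces.

## Problem sizes and numerics

Analyses run at desk scale by design: toy force systems of 20–50 atoms,
100-frame force series, 4 twist windows × 100 samples, 124-atom
channels, 3-unit/33-residue correlation blocks (~1089 entries per
block, the block size of a 737-residue/21-unit analysis). The engine's
O(N²) frame loop and the per-slice Nelder–Mead (xatol 1e-5) are sized
for these inputs; nothing in the package requires cluster-scale data to
execute the full logic.

Numerical choices worth knowing: the angle force uses a guarded arccos
with an explicit collinearity branch (zero force only when the term sits
at its equilibrium); fits with ≤2 points report zero standard error
rather than dividing by a zero degree-of-freedom count; threshold
comparisons are strict-less-than so boundary entries survive; rotation
unwrapping uses the standard phase-unwrap over frames; the pore
optimizer inherits the previous slice's center, so a profile across a
long pore tracks a curved centerline.

## Known limitations

* Coulomb forces are cutoff/switched pairwise; absolute electrostatics
  beyond the cutoff (reciprocal space) are not represented. Condition
  differences of short-range interface forces are the intended use.
* Whether an upstream force rerun used plain cutoff or reaction-field
  short-range electrostatics is generally not reported with published
  occupancy/force figures; numerical agreement of absolute Coulomb
  magnitudes with any specific rerun is therefore not guaranteed.
* The profiler's slice maximization can under-report radii in strongly
  non-convex cross-sections (local maximum of the clearance field); the
  warm start mitigates but does not eliminate this.
* H-bond criteria and donor/acceptor definitions (side chain vs
  backbone) change printed occupancies; outputs record the criteria used
  so comparisons are explicit.
* `rotation_tilt_angles` assumes the reference state is membrane-aligned;
  antisymmetry under state swap holds only in that frame.
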