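# Methods

## Coordinate and beam conventions

Patient coordinates are fixed package-wide: x = patient-left,
y = patient-posterior, z = superior; voxel (i, j, k) is centered at
`origin + (i, j, k) · spacing`. The beam direction for gantry angle g is
`(sin g, cos g, 0)`: gantry 180 is a posterior field traveling
(0, −1, 0), and 210/150 are the posterior obliques symmetric about it.
Couch and collimator are fixed at 0. The beam frame (u, v, w) uses
u = `(cos g, −sin g, 0)`, v = z, w = the beam direction.

## Synthetic phantom

The phantom emulates an abdominal stereotactic proton case: an
elliptical water body (semi-axes 150 × 110 mm, HU 0) on air (−1000 HU),
a GTV ellipsoid (default semi-axes 16 × 14 × 12 mm → 11.3 mL, inside
the 7.6–82.2 mL cohort envelope) centered 40 mm anterior of the body
center so that its distal surface lies 164 mm beneath the posterior
skin (envelope: 160–190 mm), and a duodenum surrogate — a bowed
vertical tube (radius 8 mm, 30 HU) abutting the GTV anterior surface
(gap 0), which places it distal to the GTV for posterior beams, the
worst case for distal falloff. Optional stomach/bowel/kidney ellipsoids
are seeded-jitter placed; that jitter is the pipeline's only source of
randomness. The default grid is 2 mm isotropic, 256 × 256 × 80 voxels:
desk-scale memory while resolving 2 mm margins.

What the phantom does *not* emulate: heterogeneous anatomy (bone, gas),
breathing motion, and CT noise. Passing tests on it validate the
margin/robustness *logic* — which margins survive which perturbations —
not absolute patient dosimetry.

HU → relative stopping power uses a 4-node piecewise-linear calibration
(air 0.001, lung-ish 0.26, water 1.0, bone-ish 1.85), clamped at the
ends; a true stoichiometric fit is out of scope.

## WET ray tracing

`trace_wet` computes the exact line integral of the piecewise-constant
voxel RSP field (voxel-walk splitting at every boundary crossing) from
the grid entry to a point. Field computations use `BeamWETMap`: RSP is
resampled trilinearly on a beam-aligned (u, v, w) grid (lateral step
2 mm, depth step 0.5 mm, starting upstream of the body) and cumulatively
integrated along depth; WET at arbitrary points is interpolated from
that table. The two agree to within one depth step in smooth media; the
exact tracer is the reference for voxel-scale heterogeneity. Rays
outside the body integrate air RSP as-is.

## Target volumes

Uniform expansion measures Euclidean distance to the voxelized GTV
*solid*: the structure is supersampled to ~0.5 mm in a cropped box
before the distance transform, removing the half-voxel inward bias of a
center-to-center transform; a voxel joins the margin if its center is
within the margin distance (center-sampling convention).

The beam-specific OTV works per lateral ray of the beam grid: the GTV
depth interval is extended to `WET_distal · (1 + f)` distally and
`WET_proximal · (1 − f)` proximally (f = 0.035), i.e. water-equivalent
margins converted to geometric length by marching the cumulative WET
table, then an optional geometric margin along the beam axis for the
setup-error component (the union-of-scenarios construction of
beam-specific target volumes; 0 by default at the operation level, set
to the 2 mm setup tolerance in the study pipeline — without it, a
combined anterior shift + range undershoot geometrically defeats the
margin), then a 2 mm lateral-only dilation in the beam's-eye-view plane.
Per-ray margins are the default; a single worst-case margin per beam is
available by flag. The proximal margin uses the proximal WET (an
interpretation; the distal-WET alternative would only widen it).

Overlap exclusion (`exclude_overlap`) removes named OAR voxels from an
OTV with GTV precedence. The *study default is no exclusion*: the margin
plans deliberately carry full dose into the margin even where it
overlaps the duodenum — that overlap is precisely the mechanism that
makes the beam-specific margin robust, and matches the observed behavior
of margin plans dosing the duodenum progressively with margin size.
Exclusion remains config-exposed (`exclude_oars`).

## Dose engine

Dose factorizes as `bragg(R, s·WET(x + δ)) · exp(−d_lat²/2σ²)` per spot
(scenario shift δ, range scale s, lateral sigma σ = 5 mm constant with
depth). The analytic Bragg curve has a ~30% entrance plateau, its
global maximum exactly at the nominal range, a Gaussian proximal rise
(sigma = max(0.07·R, 2) mm) and a Gaussian distal edge
(sigma = 2.6·R/160 mm, floor 0.6 mm → ~3 mm 80–20 falloff at 160 mm
range, < 1% of peak within 5% of range beyond the peak). This preserves
the contracts the study logic needs — exact linearity in weights, sharp
distal falloff, and the 1/s range-shift law under RSP scaling — and
nothing more: no nuclear halo, no MCS-driven lateral distortions, no
Monte Carlo.

Spots sit on a hexagonal lateral lattice (5 mm spacing) per energy
layer (5 mm WET spacing spanning the target's WET range); each layer
keeps lattice positions within one spacing of the projection of the
target voxels within one layer spacing in depth. Scenario setup shifts
are applied as a rigid shift of the dose sampling (shifted WET lookup),
not a re-trace of heterogeneities — adequate for a near-homogeneous
phantom; range scaling is a global WET multiplication, identical in
optimization and evaluation.

The dense influence matrix API thresholds entries below 1e-4 of the
per-spot maximum (sparse-storage convention). The pipeline itself uses
a factorized operator (per-layer depth factor × shared lateral Gaussian
over unique lattice positions) that never materializes the matrix; the
two paths are tested for agreement.

## Optimization

The objective is a weighted sum of voxel-count-normalized quadratic
penalties: one-sided for minimum/maximum dose, two-sided for uniform
dose. Defaults (config-exposed; reference doses as fractions of the
per-beam prescription share): min at 103% with weight 1000, uniform at
105% with weight 10, max at 115% with weight 5, duodenum max at 60%
with weight 2. The min-dose goal sits above the evaluation goal and
carries a dominant weight because the pass/fail criterion is an
absolute V(Rx): clinical optimizers treat minimum target dose as a
near-hard constraint, and a bare-100% edge has no headroom against
perturbation.

The solver is projected gradient descent with backtracking line search
(iteration cap 500, relative tolerance 1e-5): weights remain
nonnegative after every iteration and the objective is monotonically
non-increasing. Initialization is uniform weights scaled to put the
mean target dose at its reference; the solver is deterministic.

Single-field optimization solves each beam independently against its
own OTV at the per-beam share (equal 50/50 split). Robust optimization
concatenates both beams' weights and minimizes the maximum over
scenarios of the summed per-beam objectives on the *GTV* (so each field
stays uniform, and single-scenario robust optimization degenerates
exactly to SFO), via iterative worst-case selection: solve against the
active scenario set (descending on the pointwise max), re-evaluate all
scenarios, add the new worst, stop when the worst case stops improving;
the best iterate by full worst-case value is returned, making the outer
trace monotone. The robust scenario set defaults to 21 (nominal + 6
cardinal shifts × 3 range scalings); a 42-scenario option exists. RO
reuses the beam-specific placement volume for its spot lattice — robust
weights can only cover scenarios the lattice reaches.

## Evaluation

The 42-scenario evaluation set is {nominal + anterior, posterior,
right, left, inferior + 8 diagonal corners} × {1−f, 1, 1+f}, every
shift normalized to exactly 2 mm total displacement ("2 mm setup
tolerance" read as a total displacement); the literal direction list
omits "superior", and a 15-shift (45-scenario) variant is selectable.
The bandwidth set is 6 cardinal shifts at nominal range plus the
unshifted isocenter at 1±f (8 scenarios). Bandwidth `Wd` counts
perturbation scenarios only (the nominal is the reference, not a
sample) and is evaluated at D98/D50 for the GTV and V20 for the
duodenum. DVH bins are 0.05 Gy(RBE).

The dose spread function samples a 0.5 mm line dose through the closest
approach between the 100% isodose surface and the duodenum, extended
12 mm into the isodose and 18 mm past the OAR surface. The fit family
is a Gaussian edge-spread profile `base + amp/2 · erfc((r−r₀)/σ√2)`
(4 parameters), chosen over a logistic because its derivative is
exactly Gaussian — the DSF peak widths are then analytic (FWHM =
2σ√(2 ln 2), FW20M = 2σ√(2 ln 5)) and recover the generating sigma of
error-function falloffs exactly; a logistic family is available by
flag. Two width readings are reported side by side and never conflated:
the DSF peak widths, and the dose-drop widths w(100→50)/w(100→20)
measured on the fitted profile from the observed plateau level (clamped
into the fit's range) to its 50%/20% crossings. Fits whose RMS residual
exceeds 5% of the profile amplitude are flagged and returned with the
raw numerical derivative.

## Degenerate inputs and tie-breaks

Zero-margin expansion returns the GTV unchanged; a beam that misses the
GTV, an empty scenario set, an empty structure mask, an underdosed plan
(empty isodose) and an infeasible objective (max cap below min target on
one structure) all raise before any computation; overlapping
isodose/OAR still define an abutment segment (centroid direction).
Nominal-scenario evaluation reproduces the nominal dose exactly.

## Problem sizes

The default study uses the 2 mm / 256 × 256 × 80 phantom, ~480–650
spots per beam per scheme, 21 scenarios in robust optimization and 42
in evaluation; the full four-scheme study completes in about two
minutes on one CPU, which keeps the acceptance run and the test suite
comfortably reproducible on a laptop.

## Known limitations

The dose model omits nuclear buildup, secondary halo and
heterogeneity-induced lateral scatter, so absolute OAR doses are
indicative only; the phantom's near-homogeneity makes the
shifted-WET-lookup scenario model exact there but approximate for real
CTs; plan quality metrics are reported for a single synthetic case, not
a cohort, so no between-scheme statistics are computed.
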