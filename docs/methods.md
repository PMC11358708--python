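# Methods

This note documents the models, defaults, and numerical choices behind
`vesiclepatterns`, and what the synthetic data do and do not establish.

## Geometric model

A vesicle is a sphere of radius R_v (μm). Each solid domain is a spherical
cap of half-angle α about a unit centre vector; its flat-plate diameter is
D_d = 2 R_v sin α and its cap area 2π R_v² (1 − cos α). For N monodisperse
caps at solid area fraction φ, α = arccos(1 − 2φ/N) realises φ exactly (the
cap-area and flat-disk definitions of φ agree to O(α²)). Caps never overlap:
pairwise angular separations are at least the sum of cap half-angles
(checked with the chord-based 2·arcsin formula, accurate at small angles).

Excess area A_xs = A/((4π)^(1/3)(3V)^(2/3)) and reduced volume
v_r = A_xs^(−3/2) are dimensionless; deflating a sphere by a volume fraction
f at fixed area gives A_xs = (1 − f)^(−2/3).

### Aspiration shape reconstruction

The micropipette shape model is the classic low-suction decomposition: an
outer sphere of radius R_v truncated at the pipette mouth (cap height
h = R_v − √(R_v² − R_p²)), a cylinder of radius R_p and length L − R_p, and
a hemispherical cap at the projection tip. This reconstruction is this
package's own; it is validated against an independent quadrature oracle of
the same axisymmetric profile (1e−6 relative) and against the isoperimetric
bound A_xs ≥ 1. The inverse (projection length for a target A_xs) uses
Brent root finding on the bracket [R_p, 4 R_v]; monotonicity of A_xs in L is
verified on a coarse grid before solving, and the root must reproduce the
target to 1e−9. No membrane-tension or bending-modulus estimation is
attempted, and no fluctuation corrections to the apparent area are applied.

### Hexagonal-cell separations

Edge–edge separations of an ideal lattice use one disk per planar hexagonal
cell: D_ee/D_d = √(π/(2√3 φ)) − 1. Spherical corrections to the cell area
are deliberately ignored — the planar form reproduces the reference values
(1.18/1.31/1.45 at φ = 0.19/0.17/0.15) and is the convention the measured
separations are compared against. The distinct uniform-spreading identity
D_cc/D_v = √(4/N) (hence D_ee/D_d = √(1/φ) − 1) is documented in
`lattice_spacing_ratio` but never conflated with the hexagonal-cell value.

## Synthetic generators (the study conditions)

Defaults encode the experimental regime: φ = 0.17, vesicle diameters
15–40 μm, N = 12–48 for lattices and the disordered state, N = 5–10 for
chains (the chain-feasible range at φ = 0.17; a single belt holds at most
π²/(4φ) ≈ 14.5 plates, and the default 0.2-diameter gaps reduce that to
~10). Per-class excess areas are drawn uniformly from windows encoding the
observed exclusivity: lattice [1.025, 1.30], associated [1.001, 1.015],
disordered [1.01, 1.05]. All generators are bit-deterministic in their
integer seed; there is no global random state.

* **Lattice** — spherical Fibonacci initialisation relaxed by projected
  gradient descent (backtracking line search) on the pairwise
  inverse-distance repulsion until the largest accepted step moves no point
  more than 1e−6 (unit-sphere units). This yields quasi-uniform
  configurations with hexagonal local order and the five-neighbour
  topological defects a sphere requires (N = 12 relaxes to an icosahedral
  arrangement). Tangential Gaussian jitter of sd jitter·D_cc (default
  jitter = 0.03) is applied and resampled (≤100×) until overlap-free.
* **Chain** — plates along the equator with uniform edge–edge geodesic gap
  gap_ratio·D_d (default 0.2: closely associated but untouching; the value
  is a package default, not a measured number). Requests beyond the belt
  capacity raise an error naming the π·D_v/D_d limit. Default tangential
  jitter 0.02 in the pipeline keeps views non-collinear.
* **Plaque** — staggered concentric rings with hexagonal capacities
  (1, 6, 12, …) at ring spacing equal to the chain step. A uniform
  hexagonal patch cannot be embedded on a sphere, so ring radii are
  inflated minimally where a ring's circumference cannot hold its caps at
  the target gap; the nearest-neighbour gap is therefore ≥ the target
  everywhere and exact for the inner ring (N = 7 is the exact
  centre-plus-ring case). At φ = 0.17 plaques need N ≳ 10 (larger caps do
  not fit a hemispherical patch) — consistent with small-N associated
  states being chains.
* **Disordered** — random sequential placement of caps uniformly on the
  sphere with a minimum centre separation of 1.5 cap diameters (≤10⁴
  attempts per cap). The exclusion factor stands in for the soft repulsion
  between freely diffusing plates and was calibrated once by simulation so
  the ensemble-mean limited CV falls inside the disordered band; plain
  hard-core placement (factor 1.0) produces Poisson-like spacing statistics
  whose CV overlaps the associated band.
* **Brownian steps** — tangential Gaussian displacements of total sd
  √(4 D dt) (2D diffusion law), re-projected to the sphere; overlapping
  proposals are resampled (≤100×), and a blocked domain stays put with a
  logged warning. Convenience diffusivities: the dynamic state translates
  one plate diameter in ~3 min (D = D_d²/720 μm²/s); persistent patterns
  move 5% of a diameter in 5 min.

## Measurement stage

Views are orthographic projections of all domains within a polar focal band.
The default band half-angle adapts to N (cos θmax = 1 − 20/N, clamped to
[30°, 90°]): it targets ~10 visible plates so that the central plate's full
neighbour ring is in view, narrowing toward 30° for N ≈ 100. A fixed band
can be configured.

Selection follows the limited-triangulation protocol: central plate =
nearest the view pole (ties broken by lowest index, logged); neighbours =
the central plate's Delaunay-adjacent plates in the full-view triangulation,
capped at the six nearest. Surrounding plates need not be the strictly
nearest ones: a five-coordinated central plate contributes five ring
neighbours rather than pulling in a second-shell plate at ~1.6× the lattice
spacing (strict six-nearest selection would misclassify a large fraction of
small-N lattices for exactly this reason). Views of ≤4 plates use all of
them. A plain k-nearest rule remains available (`method="nearest"`).

CV uses the sample (n−1) standard deviation over **all** triangulation edge
lengths, hull edges included; at n = 12 edges the n vs n−1 choice shifts CV
by <3%. When measuring a focal-plane view, edge lengths are curvature
corrected by default: the planar Delaunay fixes the topology, each length is
the geodesic obtained by lifting the projected points to the upper
hemisphere (z = √(R_v² − x² − y²)). Within a 30° band the correction is at
most 12% of the planar distance; in the wider bands needed at small N it is
what keeps foreshortening from inflating lattice CVs. Relative edge-length
variation below 1e−14 reports as CV = 0 exactly, so equal-length
configurations are exact zeros irrespective of coordinate rounding.

Class bands: lattice CV < 0.20, disordered 0.23–0.33, associated > 0.34;
the gaps [0.20, 0.23] and [0.33, 0.34] map to `indeterminate` — the bands
are empirical clusters, not a partition, and forcing a nearest band would
fabricate certainty. LP = CV/√2.

Edge–edge separations treat plates as geodesic caps of arc radius R_v·α
(the flat-plate vs cap discrepancy is O(α²)): for each domain within the
central half of the band, D_ee = geodesic − R_v(α_i + α_j) is averaged over
its first-shell neighbours (centre distance ≤ 1.3× its nearest) and
normalised by the view's mean plate diameter. First-shell averaging rather
than single-nearest sampling avoids a minimum-statistics bias that would
systematically displace lattice separations below the hexagonal-cell value;
for chains the shell holds only the adjacent plates, so the construction
gap is recovered exactly. Pair overlaps within 1% of a diameter clamp to
zero silently; larger overlaps clamp with a warning.

Rendering (optional) draws the vesicle as a bright disk (tracer-containing
fluid) with dark foreshortened ellipses at the projected plate positions,
0.34 μm/pixel by default, with optional additive Gaussian and Poisson shot
noise. Ellipses are centred on the projected cap apex (the stored ground
truth) rather than the projected rim-circle centre; the two differ by
R_v sin θ (1 − cos α), well under a pixel except for the very largest
plates. Detection is Otsu thresholding for the disk (holes filled), Otsu
again inside it for the dark patches, connected-component centroids and
equivalent-disk radii, discarding rim-touching components.

## State space

Per-vesicle records carry both the generated class and the measured CV
label. The boundary estimator is the empirical gap
[max A_xs among associated, min A_xs among lattice] — how one reads the
scatter plot; no parametric classifier is fitted, and an inverted interval
is returned flagged rather than silently reordered. Boundary, histograms,
and the step-function summary use the generated class by default (the
measured label is available via `class_column`): the protocol this emulates
classifies vesicles by persistent appearance with CV as confirmation, and
synthetic disordered CV tails would otherwise leak single dynamic vesicles
into the persistent classes. Condition mixtures (neutral: lattice+disordered
dominant; inflated: associated+disordered dominant) are package defaults
reproducing the qualitative osmotic shift only — they are not measured
frequencies. Viewing poles are random (seed-determined) for the isotropic
classes, the arc midpoint for chains, and the patch centre for plaques.

## What the synthetic data do not show

The generators emulate geometry, not mechanics: there is no bending-energy
model, no parameterised pair potential, and no prediction of *which* class a
given (A_xs, N) produces — class membership is assigned, then measured. The
excess-area windows are inputs, so boundary-recovery tests validate the
bookkeeping and estimator, not the physics of the transition. Vesicles
remain perfect spheres (deflated vesicles in experiments can be irregular
ellipsoids); chains cannot bend out of plane on a rigid sphere; plaque gap
uniformity is only approximate (see above); rendered micrographs contain
none of the real contrast gradients, defocus, or tether artefacts. Passing
tests therefore demonstrate that the measurement chain recovers known
ground truth under controlled conditions, not that it would perform
identically on archived experimental images.

## Problem sizes

Default test-suite ensembles are 200 seeds per persistent class for
classifier separability, 200 seeds for the disordered CV band, 100 pipeline
runs (8 vesicles each) for boundary recovery, and 3×100-domain lattices for
the separation convergence check — sizes chosen so the full suite completes
in about a minute on one core while keeping Monte-Carlo margins far from
the pass thresholds.
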