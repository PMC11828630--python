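# Methods

This note documents the models, numerical choices and limitations of
`csfequiv`. It is the place to look when a default looks arbitrary or a
test tolerance looks magic.

## Problem

Diffusion-approximation (DA) forward solvers are the workhorse of fNIRS
/ DOT analysis because they are fast and deterministic, but the
diffusion equation is invalid in the cerebrospinal fluid (CSF), a
low-scattering layer wrapped around the cortex. The common workaround
assigns the CSF an *equivalent* reduced scattering coefficient
(historically mus' = 0.3 mm^-1) so that a DA solver can be used at all.
`csfequiv` quantifies what that substitution costs — and what pair
(mua, mus') actually minimizes the DA-vs-Monte-Carlo mismatch — by:

1. computing a gold-standard Monte Carlo (MC) solution with the CSF at
   its assumed physiological properties,
2. sweeping the CSF (mua, mus') used by the DA solver over a grid,
3. mapping the signed percent error eps = (M_DA - M_MC)/M_MC x 100 of
   four metrics over that grid, and
4. extracting the zero-error contours and their intersections.

The four metrics: gray-matter energy deposition `Egm` (the
photobiomodulation dose), detected fluence `Phi_d` at a source-detector
separation, total gray-matter sensitivity `Sgm` (the summed absorption
Jacobian, via forward x adjoint fields), and the gray-matter
sensitivity fraction `Fgm = Sgm / S_total`.

## Geometry

The head is a four-region layered slab — combined scalp/skull
(11.25 mm), CSF (2.73 mm), gray matter (3.29 mm), white matter filling
the remainder — on a structured isotropic voxel grid shared verbatim by
both solvers, so that any DA-vs-MC discrepancy is physics, not
discretization mismatch. Default extent is 120 mm laterally and 40 mm
deep: at least three transport mean free paths of margin beyond the
farthest (35 mm) detector. A concentric-sphere analog with the same
shell thicknesses provides a curved-surface variant.

A voxel takes the label of the layer containing its center, so layer
thicknesses are realized to the voxel: at 1-mm spacing the layers
become 11 / 3.0 / 3.0 mm, at 0.5 mm they are 11 / 3.0 / 3.5 mm. The
CSF-sensitive metrics care about the spacing well beyond this label
rounding: the detected-fluence error at 35 mm moves by ~10 percentage
points between 1 and 0.5 mm, because the enhancement of long-range
transport by a transparent CSF layer ("light piping") is carried by
steep near-surface and near-interface fluence gradients that the
solver pair must resolve. **The reference configuration for headline
numbers is therefore 0.5-mm spacing**; 1 mm remains the default for
exploratory work.

The probe is a pencil-beam source at the center of the top face with a
linear detector array at geodesic separations 8.4 (short), 20, 25, 30
and 35 mm, detector radius 1.5 mm.

## Optical properties

Per-tissue (mua, mus', g) at 690 and 830 nm are hard-coded from the
standard literature compilation used for this model family. The tables
carry no refractive indices, which leaves the boundary condition an
open modeling choice with two conventions:

* **index-matched** (n = 1 everywhere): no Fresnel trapping at the
  surface, diffusion boundary coefficient A = 1;
* **mismatched tissue** (n = 1.37 against air): Fresnel internal
  reflection at the surface, A ~ 3.05.

The choice matters a lot for the CSF question. Surface trapping feeds
the lateral path *through the scalp/skull*, while the CSF piping path
dives below the surface and is barely affected; the mismatched
convention therefore dilutes the relative piping enhancement and
roughly halves the headline errors (eps(Egm) −3.5% vs −9%, eps(Phi,
35 mm) −26% vs −38% in our measurements). The published layered-model
error figures are reproduced under the index-matched convention, so
that is the package default (`reference_properties(n_tissue=1.0)`);
n = 1.37 is one keyword away, and internal interfaces are
index-matched in either case. Two CSF ground-truth choices exist: "low" (mus' = 0.001 mm^-1, essentially transparent) and
"semidiffusive" (0.16 mm^-1, accounting for subarachnoid trabeculae,
tabulated at 830 nm). Derived quantities: mus = mus'/(1-g),
D = 1/(3(mua + mus')) (a config switch drops mua), mueff = sqrt(mua/D).

The sweep grid is inclusive 0..0.04 mm^-1 in steps of 0.002 for mua and
0..0.4 mm^-1 in steps of 0.02 for mus' (21 x 21 = 441 cells); the
degenerate cell (0, 0), where the diffusion operator would be singular,
instead simulates mus' = 0.001.

## Monte Carlo solver

Weighted-packet voxel MC with:

* free paths -ln(xi)/mut re-scaled across tissue boundaries (the
  remaining optical depth is preserved when mut changes);
* Henyey-Greenstein scattering with the local g; azimuth sampled by
  rejection on the unit disk;
* absorption by weight attenuation (albedo mus/mut per collision), with
  a per-tissue collision-estimator tally of absorbed weight;
* fluence by the track-length estimator (sum of weight x path length
  per voxel / voxel volume / photons), which is unbiased as mua -> 0 —
  required because the CSF cell mua = 0 is part of the sweep;
* Fresnel reflection/refraction at the tissue-air boundary only;
  transmitted packets are terminated and tallied as escaped; the
  normal-incidence specular loss is charged at launch;
* Russian roulette below 1e-3 of the launch weight with survival
  probability 0.1. The threshold is three decades below launch weight
  while the packets that reach the farthest detector carry ~1e-2..1e-1;
  tracking into the fourth decade doubles runtime for no measurable
  change in any reported metric;
* a per-photon splitmix64 counter RNG keyed on (seed, photon index):
  results are bit-reproducible and independent of execution order.

Energy bookkeeping (absorbed + escaped + roulette discrepancy =
launched) closes to ~1e-11 relative on every run and is asserted in the
test suite at 1e-6.

The default photon budget is 1e7 per run. The original-scale
simulations behind the reference surfaces used 1e9 GPU photons; at desk
scale the weakly-sampled quantity is the detected fluence at 35 mm,
whose track-length estimate in a single voxel column is dominated by
rare, high-weight packets piped through the CSF. Two variance reducers
keep its stochastic error at the few-percent level:

* **mirror folding**: the slab with a centered normal source is exactly
  symmetric under both lateral reflections (the detector-sourced
  adjoint field under one); averaging the field with its mirror images
  is free statistics;
* **disk-averaged readings**: the detector reading is the fluence
  averaged over the physical 1.5-mm detector disk (trilinear samples on
  a fixed sub-grid) rather than a single point. This is still fluence
  sampling — not a photon-exit tally — and the identical rule is
  applied to the DA field, so the comparison stays apples-to-apples.

## Diffusion solver

Cell-centered 7-point finite differences on the same grid:
face conductances use the harmonic mean of the adjacent cells' D (the
flux-continuous choice for piecewise-constant coefficients), absorption
is mua V on the diagonal, and every tissue-air face carries the Robin
(partial-current) condition Phi + 2 A D dPhi/dn = 0 with
A = (1 + R_eff)/(1 - R_eff), R_eff from the standard polynomial fit in
the relative index (A = 1 for the index-matched default, ~3.05 at
n = 1.37). The collimated fiber source
becomes an isotropic point sunk 1/mus' of the *surface* tissue below
the entry point (the only physically sensible choice for a
scalp-mounted fiber; the sweep never changes the scalp, so the sink
depth is stable across the sweep), spread trilinearly onto the eight
surrounding voxel centers with unit total power.

The operator is symmetric positive definite; solves use Jacobi-
preconditioned conjugate gradients to relative residual 1e-10
(deterministic, ~1-3 s at 576k unknowns, tens of seconds at 4.6M).
Discrete reciprocity between forward and adjoint solves holds to the
solver tolerance, and the homogeneous infinite-medium solution matches
exp(-mueff r)/(4 pi D r) within 5% for r = 5..30 mm at 1-mm spacing.

## Detector readings

Fields live at voxel centers, so a boundary detector sits half a voxel
above the first center plane. The reading convention (class
`DetectorSampler`) is: average trilinear samples over the detector disk
on the first two center planes and extrapolate linearly to the surface
— the grid analog of sampling a surface-node solution at the exact
detector coordinate. The same functional is applied to MC and DA
fields. The error metrics are ratios, but the two solvers' near-surface
profiles differ (that is precisely the DA boundary-layer error being
measured), so the sampling plane is part of the measurand; surface
extrapolation is the convention that corresponds to solvers with
boundary nodes.

## Validation strategy

The solver pair is validated where the diffusion approximation is
known-good, then trusted where it is not:

* MC vs the analytic homogeneous diffusion Green's function within 3
  sigma (r >= 3 transport mean free paths);
* DA vs the same analytic solution within 5%;
* MC vs DA on the full head model with the CSF overridden to a
  diffusive medium (mus' = 1): detected fluence at 20-35 mm agrees to
  a few percent (noise-limited at desk-scale photon budgets; 0.6% in
  the best-sampled check) — this certifies the pair's long-range
  consistency, so that
  the large errors that appear with a transparent CSF are attributable
  to the physics of the CSF layer, not solver bias;
* adjoint-product Jacobian vs a finite-difference perturbation oracle
  (single-voxel mua bump) within 5%;
* forward/adjoint reciprocity in both solvers (exact for DA at the
  sunken points; within 3 sigma for MC).

## Numerical choices and edge cases

* Degenerate sweep cell: (mua=0, mus'=0) simulates mus' = 0.001.
* Zero-thickness layers are allowed (the region is simply absent;
  region metrics raise unless explicitly allowed to return 0).
* Contours: marching squares at level 0 with linear edge interpolation;
  vertices are exact zeros of the bilinear interpolant. When a surface
  has no sign change, the |eps|-argmin cell is refined by a quadratic
  fit over its 3x3 neighborhood (fall back to the cell center when the
  fit is not convex).
* Intersections: exact segment-segment solutions (shapely), vertices
  deduplicated at 1e-9; the recommendation is the unweighted centroid
  of pooled pairwise intersections, or the pooled-|eps| minimizer
  (flagged inexact) when no contours intersect.
* Error maps mask voxels whose MC fluence is below a configurable
  absolute floor; they carry no reliable reference.
* On-plane launch tie: a source placed exactly on a voxel boundary
  plane deposits its exactly-in-plane track segments into the upper
  adjacent voxel (floor convention). The artifact is confined to the
  source-column voxels (~0.5% of a half-volume integral), cancels
  under mirror folding, and does not touch any reported metric; the
  symmetry test excludes the two central slices for this reason.
* Grid-refinement behavior depends on the boundary convention: the
  surface detector reading changes by ~5% per spacing halving (1 ->
  0.5 mm) under the mismatched convention and ~6% under the matched
  one, whose Robin extrapolation length (2D ~ 0.25 mm in scalp) is
  comparable to the half-spacing. Volume metrics converge much
  faster.

## What the synthetic geometry does and does not capture

The slab reproduces the layer structure, thicknesses and optical
contrast that drive the CSF modeling error, and the concentric-sphere
analog adds surface curvature. Neither captures cortical folding
(sulci), spatially varying layer thickness, or anatomical asymmetry of
a real head; published atlas-based results show differently shaped
error surfaces even though the qualitative conclusions (zero contours
below mus' = 0.3, recommendation around 0.15 with physiological mua)
agree. Results here quantify the layered-model idealization only.

## Problem sizes used by the shipped runs

The acceptance script runs the headline comparison at 0.5-mm spacing
with 8e6 photons per MC run (forward + one adjoint), which puts the
disk-averaged 35-mm reading's stochastic error near 2-3% and each
error estimate within ~2 percentage points (1 sigma). The test suite
uses coarser grids and smaller budgets chosen per test so that each
check's tolerance is dominated by the quantity under test, not by
noise.

## Known limitations

* Continuous-wave only; no time- or frequency-domain sources.
* Single Fresnel interface (tissue-air); internal index mismatches
  (e.g. CSF at n = 1.33) are not modeled.
* Voxelized geometry: layer thicknesses are realized to the nearest
  voxel; use 0.5-mm spacing when exact thicknesses matter.
* The MC detector model is fluence sampling at the detector location;
  numerical-aperture and coupling effects are out of scope.
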