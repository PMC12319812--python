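# Methods

This package reconstructs MEG source activity without an individual MRI:
a template anatomical volume is affinely warped to a 3D surface scan of
the subject's head (a "pseudo-MRI"), a wearable triaxial OPM array is
coregistered to it, and the usual beamformer analyses are run on top.
Everything can be exercised end to end on digital phantoms with known
ground truth. This note documents the models, the numerical choices and
what the synthetic validation does and does not show.

## Coordinate conventions

World coordinates are RAS millimetres. Homogeneous 4x4 transforms act on
column vectors, `p' = A [p; 1]`, and are stored/exchanged as plain-text
row-major world-to-world matrices (not the voxel-convention matrices of
external registration tools). Voxel indices are 0-based with the voxel
centre at the integer index; all inside/outside voxelisation decisions
use the voxel centre. Field computations convert geometry to SI metres
internally; dipole moments are in A·m and fields in tesla.

## Pseudo-MRI generation

Pipeline (in `warp.generate_pseudo_mri`):

1. **Template scalp extraction.** The outer isosurface of the largest
   supra-threshold component, by marching cubes. The default threshold
   is 15% of the robust (99th-percentile) maximum, i.e. just above air,
   so the whole head is one solid component whose outer surface is the
   scalp.
2. **Rigid scan-to-template alignment.** A landmark (quasi-fiducial)
   Kabsch seed followed by point-to-point ICP onto the template scalp.
   Point-to-point ICP converges slowly on smooth surfaces, so the
   default budget is generous (400 iterations, tolerance 1e-7 mm of
   mean-distance improvement); iterations are cheap (one k-d-tree query
   each).
3. **Cropping to common coverage.** Both surfaces are cut by an axial
   plane at a configurable fraction (default 0.12) of the template
   scalp's height — an inion-level cut — and the template points are
   additionally restricted to lie within `coverage_margin` (default
   8 mm) of some scan point, so a partially cropped scan is compared
   like for like. The crop rule is deliberately configurable: real
   acquisitions differ in how much of the face and neck they capture.
4. **Convex-hull binarisation.** Both point sets are voxelised on the
   template grid by a voxel-centre-in-convex-hull test. The template
   scalp is *re-digitised* first: it is sampled area-uniformly with the
   same number of points as the scan, so both hulls carry the same
   inward sampling bias (hulls of finite samples are slightly smaller
   than hulls of the underlying surface; matching the sampling cancels
   the bias, which otherwise costs 1–2 mm of spurious scale).
5. **12-DOF affine mask registration** (below), template mask onto scan
   mask.
6. **Resampling.** The grey-level template is pulled through the
   composed transform (trilinear) onto an axis-aligned grid in the
   scan's frame covering the warped template.

An optional uniform `cap_offset` (mm) can inflate the scalp to absorb
cap/hair thickness; the default is 0.

## Affine mask registration

The cost is the correlation ratio `1 − explained variance` of the fixed
intensities given binned moving intensities over the overlapping field
of view (2 bins for binary masks, more for grey-level images). For
efficiency and sharpness the optimiser evaluates it on a boundary band
of the fixed mask (default ±3 voxels, subsampled above 40k voxels): for
a binary head mask every discriminative voxel sits at the surface. For
grey-level images (brain-to-brain registration) the evaluation domain is
the object support plus a margin, and 32 bins are used.

The 12 parameters are 3 translations, 3 Euler rotations, 3 log-scales
and 3 shears, composed as `T · Rz Ry Rx · Shear · Scale` about the fixed
image centroid. The search strategy exploits the moment structure of the
problem:

* matching the mask centroids and second-moment tensors fixes 9 of the
  12 degrees of freedom exactly; the residual unknown is a rotation in
  moment-whitened coordinates. The *symmetric* inverse-square-root
  whitening is used deliberately: it needs no eigenframe, so it stays
  stable when two moment eigenvalues are nearly degenerate (where
  eigen-whitening makes the residual rotation arbitrary), and it keeps
  that rotation close to the polar rotation of the underlying
  transform — small and bounded;
* the rotation is estimated two ways: deterministically, by Kabsch
  alignment of rotation-equivariant third-moment (skewness) vectors —
  a head's facial asymmetry determines these well — and by a bounded
  two-level Euler-grid search (±40° coarse, then a fine grid around the
  best cells, then Powell) with the cost evaluated on a few thousand
  subsampled voxels;
* a coarse rotation grid with centroid matching (inside the configured
  ±90° bounds) provides additional seeds, and all candidates are
  re-scored at full resolution before committing to a basin — coarse
  smoothing hides exactly the features that disambiguate orientation on
  a near-ellipsoidal head;
* the best candidate is polished by a Gauss–Newton least-squares pass on
  Gaussian-smoothed (σ = 1 voxel) images, which converges to well below
  a tenth of a voxel, then settled onto the nearby optimum of the
  correlation ratio itself when not already converged. If the polished
  cost remains high the grid search is re-run at a denser pitch and the
  extra candidates polished too — the correlation-ratio basin around
  the true transform is only a few degrees wide in whitened-rotation
  space, so a candidate must land close before local methods converge.

The final cost is guarded never to exceed that of the initial transform.
The 6-DOF (rigid) mode used for brain-to-brain alignment keeps the
classic coarse-to-fine Powell schedule. On seeded phantom pairs (scales
0.9–1.1, rotations ≤ 20°, translations ≤ 10 mm, shears ≤ 0.05, 2 mm
grid) the recovered scalp-surface RMS error is typically below 0.1 mm
with worst cases near 1 mm.

## Forward models

**Sphere.** The closed-form field of a current dipole in a spherically
symmetric conductor (volume currents included). Radial dipoles and
central dipoles produce exactly zero external field. The implementation
is validated against an independent oracle that solves the interior
electric potential on the boundary (insulated-Neumann condition,
spherical-harmonic expansion) and evaluates the volume-current field via
the Geselowitz surface integral; agreement is ~0.2%.

**Single shell.** Outside any bounded conductor the quasi-static field
is curl-free, so the total field is the gradient of a scalar potential,
harmonic in the exterior. That potential is expanded in exterior solid
harmonics about the shell centroid (order configurable, default 10) and
fitted, by area-weighted least squares over the shell faces, to the
magnetic boundary condition that the surface-normal field component
equals that of the primary (infinite-medium) dipole term — volume
currents contribute nothing normally (exact on a sphere, the standard
single-shell approximation otherwise). Basis gradients are obtained by
central differences with step 1e-3 of the shell radius (truncation error
~1e-6 relative). On a spherical shell the solver matches the closed form
to ~0.2% at order 10, and the boundary residual decreases monotonically
with expansion order. The expansion converges for sources whose
eccentricity (distance from centroid over local shell radius) is well
below 1; very superficial sources would need higher orders.

The sphere conductor is fitted to the brain-mask surface by algebraic
least squares; it approximates the inner-skull volume, so source grids
are restricted to 95–97% of the fitted radius. The sphere is the default
in the phantom-twin study (it is exact for the oracle and an order of
magnitude faster); the single shell is the realistic-geometry option.

## Beamforming

Covariance matrices are computed over retained trials of band-filtered
data with the per-trial-window channel mean removed, `C = XX'/(n−1)`,
and regularised as `C + λI` with λ = 5% of the largest eigenvalue.

Source orientation at each location maximises the noise-normalised
projected power — the generalised Rayleigh quotient of
`A = LᵀC⁻¹L` against `B = LᵀC⁻²L`, solved as a generalised eigenproblem
with a tiny ridge (1e-8 of trace) on B. The ridge removes the silent
orientation (for a spherical conductor the radial lead-field column
vanishes, so naive power maximisation would select it) and reduces to
the dominant right-singular direction of L when A ∝ B (white
covariance). Unit-gain weights are `w = C⁻¹l/(lᵀC⁻¹l)`.

Task modulation is summarised per source as the pseudo-T contrast
`(P_active − P_control)/(P_active + P_control)` with window powers
`wᵀC_win w`. This normalisation is bounded in [−1, 1] and cancels the
depth-dependent gain of the weights; beta desynchronisation appears as
negative values and image extrema are taken at the most negative voxel
(ties break to the lowest source index). Virtual-electrode time courses
use broadband-covariance weights at the fixed optimal orientation,
divided by ‖w‖ for a noise-normalised amplitude scale.

With only a focal source and sensor noise the normalised contrast is
nearly flat across the brain (every location reconstructs a scaled copy
of the single source); localisation is only defined in the presence of
background activity, which the phantom provides (below). Distributed
background also gives the contrast a depth-dependent dilution and hence
a small (~1 voxel) superficial bias of the peak — a property of
normalised beamformer contrasts generally, shared by both pipelines in
the twin experiment and therefore largely cancelling in their
comparison.

## Spectral analysis and connectivity

Time-frequency spectrograms: per band (default centres 3–99 Hz every
2 Hz, half-width 2.5 Hz), zero-phase bandpass, Hilbert envelope, average
over trials, and relative change `(E − B̄)/B̄` against the 2.5–3.0 s
baseline window. Band edges and trial edges carry filter transients; the
interior of the spectrogram is the meaningful part.

The AEC connectome orthogonalises each ordered pair at zero lag
(`y − x(xᵀy)/(xᵀx)`; by linearity the analytic signal of the residual is
formed without re-running the Hilbert transform), computes both
envelopes, block-averages them to 120 Hz (non-overlapping means — 
deterministic and anti-aliased), Pearson-correlates, and symmetrises by
averaging the two directions. Residuals numerically indistinguishable
from zero (duplicated signals) are recorded as 0 with a warning rather
than correlating rounding noise. Regional signals are beamformed at the
region medoids (the member voxel centre minimising summed member
distance, mm metric, lowest-linear-index tie-break), trials cropped to
0.1–3.4 s and concatenated. Global connectivity is the sum of all
off-diagonal entries.

A note on scale: the planted "envelope correlation" of the generator
modulates source amplitudes, but measured envelopes also contain the
independent stochastic envelope of each narrowband carrier, so measured
AEC is an attenuated version of the planted modulation correlation. The
leakage-free oracle used in tests is therefore the envelope correlation
of the clean, unmixed signals, processed identically.

## Preprocessing

Recording-level order: notch (50/100/150 Hz, zero-phase IIR, Q=30) →
1–150 Hz Butterworth bandpass (4th-order design run forward-backward,
i.e. an effective 8th-order zero-phase magnitude response — the standard
reading of "non-causal 4th order") → homogeneous field correction →
epoching → variance-based trial rejection (per-trial statistic: mean
over channels of per-channel variance; single-pass threshold at
mean + 3 SD). HFC builds the channels × 3 orientation matrix M and
projects data onto the orthogonal complement, `D' = (I − M M⁺) D`; the
projector is idempotent and symmetric and nulls a spatially uniform
field exactly. ICA is out of scope (a manual step in practice); a hook
accepts externally supplied artifact time courses and regresses them
out. Every step appends to the object's provenance log.

## The phantom generator

`synthetic.make_phantom_anatomy` builds a layered head: nested
ellipsoids (adult half-axes 72/88/80 mm with ±4% per-seed jitter; skull
6 mm, brain 12 mm below the scalp) perturbed by a smooth random radial
field (8 lobes, 2% amplitude) plus deterministic face-like asymmetries —
a nose, a chin and a flattened occiput. The brain carries internal
T1-like contrast (brighter white-matter core, dark ventricles, an
interhemispheric fissure) defined in shape-normalised coordinates so
structures correspond across subjects. These asymmetries are not
decoration: binary masks of unperturbed ellipsoids make both surface
and brain registration rotationally ill-posed, which real heads are
not. The parcellation divides the outer cortical shell into 78 Voronoi
cells of farthest-point-sampled seeds.

Scans are area-uniform surface samples with isotropic Gaussian jitter,
an optional outward cap/hair offset, a rigid scanner-frame transform and
a crop plane. Helmet arrays are farthest-point-sampled sensor sites on
the upper scalp, offset 6.5 mm outward (cell standoff), each carrying an
orthonormal triad with one axis along the local normal — 64 sensors give
192 channels. The paradigm alternates index/little-finger stimulation:
0.5 s on, 3 s rest, 41 trials per finger, 287 s total.

Recordings sum: (i) task sources — beta-band (13–30 Hz) filtered noise
(induced, non-phase-locked) whose envelope drops by the ERD depth during
stimulation, with a 0.3 s post-stimulus carry-over reflecting the
sluggish beta rebound so the 0.3–0.8 s analysis window overlaps the
effect; (ii) optional envelope-correlated source networks (shared slow
latent factors at a specified ρ); (iii) ~100 unmodulated broadband
background dipoles of 5 nAm scattered through the brain — without
ongoing background activity the normalised pseudo-T contrast cannot
localise at all; (iv) white sensor noise, set directly in tesla or via a
target SNR defined as the strongest channel's task-signal RMS over the
noise SD; and (v) homogeneous interference, a slowly varying uniform
field vector projected through the channel orientations — exactly the
model HFC nulls, enabling an exactness test. All randomness derives from
one seed; identical seeds give bitwise-identical recordings.

What the phantoms do *not* emulate: realistic tissue conductivity
profiles and skull anisotropy, cortical folding (sources are not
constrained to a sheet with normal orientations), head movement,
physiological artifacts (cardiac, ocular, muscle), scanner-specific scan
artifacts (holes, specular dropouts), and 1/f spectral structure of the
background. Passing phantom tests therefore demonstrates the internal
consistency and numerical correctness of the pipeline under its own
assumptions, not performance on real data.

## The twin experiment

`twin.run_twin_study` mirrors the validation design: per subject, a
random-anatomy phantom provides ground truth; one simulated recording is
analysed twice with identical pipelines — once with the true anatomy and
once with the pseudo-MRI built from a noisy, cropped, rigidly displaced
scan of that subject. The template is itself a phantom (fixed seed) that
doubles as the atlas: its parcellation is carried into each anatomy by
12-DOF grey-level brain registration (individual side) or by the known
template-to-subject warp (pseudo side). Each pipeline carries its own
estimated optical coregistration (ICP of an independent scan onto the
anatomy), so coregistration error enters realistically; the
`isolate_coregistration` mode rigidly aligns the individual brain to the
pseudo-MRI and reuses one coregistration, removing that error source —
on phantoms this roughly halves the medoid discrepancy and raises the
connectome correlation, reproducing the finding that coregistration
error dominates anatomy error.

Reported per subject: median medoid distance between the two
parcellations, beta-peak separation and per-pipeline peak error against
the planted source, pseudo-T map correlation (nearest-point pairing of
the two grids), virtual-electrode TFS correlation, AEC connectome
correlation and global connectivity.

Problem sizes are chosen for a desk-scale run: 80³ voxels at 2.4 mm,
32 sensors (96 channels), 12 trials per condition at 600 Hz, a 6 mm
source grid and a sphere conductor per pipeline; five subjects complete
in a few minutes on one core. The acceptance script runs exactly this
study.

## Known limitations

* The affine warp is global: local shape differences (and the missing
  nonlinear component of real template-to-subject anatomy) are not
  captured, exactly as in the affine variant of the original method.
* Skull stripping is not implemented; phantoms provide brain masks
  analytically and real use must supply them.
* The single-shell solver assumes a star-shaped, reasonably smooth inner
  surface; deep sulcal detail would require the full boundary-element
  treatment that is out of scope.
* Quasi-fiducials assume an approximately upright head in the scanner
  frame (they are stand-ins for manual feature clicks).
* Sphere-conductor analyses are blind to radial source components; the
  phantom plants tangential task sources accordingly.
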