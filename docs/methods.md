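# Methods

`warp4d` implements quasi-4D path-integrated dose accumulation for
respiratory-phase CT and the plan-quality statistics used to compare it
against conventional static (3D) dose evaluation, exercised end to end on a
deformable digital liver phantom with analytic ground-truth motion.

## The problem

A conformal liver SBRT plan is computed once, on a static planning image
(usually the average intensity projection, AIP, of a 10-phase 4D CT). The
liver, however, moves 7–17 mm superior–inferiorly over the breathing cycle.
Tissue therefore samples the static dose distribution along its breathing
trajectory, and the dose a tissue element actually accumulates is the
time-weighted average of the dose field along that path. Where the dose
gradient is steep (the PTV penumbra), static evaluation overestimates
target coverage and homogeneity and underestimates dose to the surrounding
normal liver. The 4D methodology quantifies this: register each phase to a
reference phase (end-expiration, 50%), warp each phase's dose back to the
reference anatomy through the resulting deformation vector fields (DVFs),
and average with equal weights (the phases are equal time bins):

    D_4D(x) = (1/N) * sum_k D_k(x + u_k(x))

with `u_k` the pull-back DVF of phase k (zero for the reference phase).

## Pipeline stages

1. **Phantom generation** (`phantom`): a 10-phase digital liver phantom
   (below) or externally supplied phase volumes in NRRD/MetaImage.
2. **Target construction** (`grid`): ITV = union of the extreme-phase GTVs
   (see Design choices), PTV = ITV + 5 mm isotropic margin (Euclidean
   voxel-center dilation), normal liver = liver − GTV (reference-phase
   contours) or liver − ITV (AIP contours).
3. **Registration** (`registration`): each non-reference phase is
   registered to the reference phase by multi-resolution Horn–Schunck
   optical flow (below).
4. **Warping and accumulation** (`accumulate`): trilinear pull-back
   resampling of each phase dose through its DVF, then the equal-weighted
   voxel-wise mean; reduced-phase subsets p2 = {0%, 50%},
   p3 = {30%, 60%, 90%}, p5even, p5odd are accumulated the same way.
5. **Metrics** (`dvh`): cumulative DVHs, Dx, Dmean, HI = D2/D98, DVH-based
   BED, fractional-volume-ratio convergence curves, centroid motion vector.
6. **Report** (`study`): per-structure metrics under 3DREF, 3DAIP, 4D and
   the subsets; percent differences reported as (3D − 4D)/4D × 100.

## The digital phantom

Nested analytic shapes on a 96³ grid at 3 mm spacing (≈29 cm cube): a
soft-tissue body ellipsoid (40 HU) containing a liver ellipsoid (60 HU)
with an embedded 18 mm-radius spherical tumor (100 HU, ≈24 cm³), in air
(−1000 HU), plus seeded i.i.d. Gaussian noise (SD 10 HU per phase).

Motion model: the phase-k deformation of a reference point x is
`phi_k(x) = x + w_k · e(x) · A` where

* `A` = per-axis amplitude (LR, AP, SI) in mm. The default (1.1, 1.6, 10.5)
  mm and four further presets are taken from the measured per-lesion
  centroid displacements of the study patients (named presets A–E), tying
  the synthetic motion to clinically observed liver excursions.
* `w_k = (1 + cos(2πk/10))/2` — 1 at phase 0% (end-inspiration), 0 at the
  reference phase 50% (end-expiration). A cos⁴ option mimics the longer
  end-expiration dwell of real breathing. Real breathing traces were not
  recorded per patient, so any waveform is a stand-in; the manifest flags
  this.
* `e(x)` — a smoothstep envelope of the normalized body-ellipsoid radius:
  1 inside the liver-bearing core (radius fraction ≤ 0.6), falling smoothly
  to 0 at the body surface, so the body outline stays (nearly) fixed and
  registration has a static boundary. The envelope gradient keeps
  `|∇(w e A)| < 1`, making phi_k an analytic diffeomorphism.

Phase images and masks are generated by exact pull-back: the inverse of
phi_k is solved per voxel by fixed-point iteration (a contraction; default
tolerance 1e-4 mm, far below voxel size). GTV ⊂ liver holds on every phase
by construction, and the GTV volume is conserved across phases to within
5% (the envelope is ≈1 over the tumor's full excursion).

**Static dose cloud.** A clinical study recalculates the plan on each phase
with the treatment planning system. This package instead holds one
conformal dose distribution fixed in room coordinates across all phases:
`D(x) = Dmax · exp(−max(0, s(x) + t)² / 2σ²)` with `s` the signed Euclidean
distance to the PTV surface, σ = 5 mm penumbra, `Dmax` = prescription /
covering isodose (42 Gy / 0.80 = 52.5 Gy, the typical SBRT 125% hot
center), and the core depth `t` calibrated so D95(PTV) equals the
prescription by construction. This is the main fidelity gap versus a dose
engine: in liver, density changes over the cycle are small and the
quantity under study — the interplay of motion with the dose gradient — is
preserved, but per-phase beam-path effects (attenuation changes, surface
curvature) are absent. Consequently the 3DREF and 3DAIP arms share the
dose volume and differ only in the structure set used to evaluate it.

**Ground truth.** Because the motion is analytic, the true accumulated
dose `sum_k w_k D(x + u_k(x))` is computed without any registration; every
pipeline estimate is validated against it.

## Registration

Multi-resolution Horn–Schunck optical flow, written for this package:

* intensities are windowed to [−200, 300] HU and rescaled to [0, 1]
  (bracketing liver/soft-tissue contrast), then Gaussian pre-smoothed
  (default σ 4.5 mm) to suppress voxel noise in the nearly piecewise-
  constant phantom;
* 3 pyramid levels (halving per level); the coarsest level puts a ~10 mm
  liver excursion inside the linearization capture range;
* at each level, Jacobi iterations of the regularized flow equations act
  on the **total** field with the data term linearized at the last warp
  (re-warped every 20 iterations, 200 iterations per level, convergence
  when the mean update drops below 0.002 mm). Updating the total field
  matters: where the image is flat the update reduces to a neighbor
  average, so flow diffuses from edges into texture-free interiors
  instead of stalling;
* smoothness weight α = 0.005 (windowed intensity per mm) and a 1.5 mm
  Gaussian smoothing of the field after each re-warp block;
* a robust noise floor: the residual image's noise SD is estimated by the
  MAD of its nonzero values (exact zeros — clipped air, identical regions
  — are not noise samples); residuals below 4 estimated SDs carry no data
  term, and when fewer than 0.5% of voxels exceed the floor the pair is
  declared aligned within noise and iteration stops. Two images that
  differ only by noise therefore return an exactly zero field;
* a zero-displacement anchor wherever both images sit at the window floor
  (air): those voxels carry no signal, and anchoring prevents the
  regularization from drifting displacement across the body outline.

A diffusion-regularized (demons-like) variant is available behind the same
interface (`method="demons"`): per-iteration normalized symmetric-force
updates `-diff·∇I/(|∇I|² + diff²)` with Gaussian field smoothing. Its
normalization is contrast-invariant (weak organ edges pull as strongly as
the body outline); on the phantom both variants recover known transforms,
and Horn–Schunck is the default.

Defaults were chosen by known-transform recovery experiments on the
phantom (translation recovery and end-to-end accumulation accuracy) and
are recorded in every output manifest. The solver is fully deterministic
(zero initialization, no randomness). The DVF is pull-back
(`x_source = x + u(x)`), the convention dose warping consumes directly.

Diagnostics follow 4D-CT practice: difference maps (HU) and whole-volume
Pearson cross-correlation before/after registration (computed on the
window-rescaled intensities the solver actually works with; raw-HU
correlation is dominated by sub-voxel jitter across the ±1000 HU air
edge); an inverse-consistency residual (compose A→B with B→A) is
available as a check. On the default phantom the post-registration
cross-correlation exceeds 0.99 for every phase. For the extreme phase the
pre-registration value already sits at the still-region noise ceiling, so
improvement over it is not guaranteed — per the result contract the
solver warns rather than fails when post < pre.

What passing on this phantom does **not** show: real livers carry vascular
texture that aids DIR in the organ interior, but also sliding at the chest
wall, hysteresis, and intensity artifacts that hinder it. The phantom's
uniform liver interior is informed only by the organ and tumor boundaries,
so interior DVF accuracy here is pessimistic in texture and optimistic in
artifact terms. Dose-space accuracy is what the acceptance checks bound:
errors concentrate where DVF error meets steep dose gradient, i.e. near
the target, where the tumor boundary constrains the flow well.

## Reduced-phase convergence on this phantom

The max |fractional-volume ratio − 1| of each subset accumulation against
the full 10-phase PTV curve, over the 10-phase D98–D50 dose range, is
monotone in phase count on the default phantom (p2 ≈ 12%, p3 ≈ 6%,
p5even/p5odd ≈ 2–3%, p10 = 0), and the same numbers emerge when the
subsets are accumulated through the analytic ground-truth fields — the
deviations are a property of sampling the breathing waveform at few time
points, not of registration error. Note that the phantom's static dose
cloud gives the accumulated PTV DVH a much longer cold tail (D98–D50
spanning roughly 12–49 Gy) than clinical liver SBRT DVHs, so percentage
deviations over this range read larger here than the ~few-percent values
typical of patient data; the monotone ordering is the transferable
result.

## Numerical choices

* Axis order (x = LR, y = AP, z = SI), 0-based indices,
  world = origin + index·spacing; no rotated grids.
* Trilinear interpolation everywhere; out-of-grid dose samples are 0 Gy
  (conservative, physically sensible far from the target), CT samples
  clamp to the edge value (avoids spurious air at the boundary).
* DVH bin width 0.01 Gy (makes Dx discretization ≪ the 0.1 Gy printing
  precision of clinical tables); Dx = largest dose received by ≥ x% of
  the volume, linearly interpolated between bin edges; Dmean is the voxel
  mean (identical to the DVH mean up to binning).
* BED per differential-DVH bin: `BED_i = n d_i (1 + d_i/(α/β))` with
  `d_i` = bin dose / n fractions; α/β = 10 Gy for target structures, 2 Gy
  for normal liver (late toxicity). BEDmean is the volume-weighted mean
  over bins (bin centers), so it carries an O(half-bin) discretization
  error; for uniform dose it reduces to `D(1 + D/(n·α/β))`.
* HI3D/4D% is computed from unrounded HI values; re-dividing the rounded
  table HIs can drift in the last printed digit (a rounding artifact of
  published tables, not of this code).
* Max point-dose differences are normalized to the prescription by
  default (a local-dose normalization is available), since published
  difference-map percentages do not state their normalization.

## Design choices where the design was open

* **ITV = union of the extreme-phase GTVs** (default). The clinical
  description the pipeline mirrors says "intersection", but its reported
  ITV volumes strictly exceed the GTV volumes, which only a union (the
  standard motion-envelope ITV) produces. `itv_mode="intersection"`
  preserves the literal reading.
* **Consolidated CLI**: one `warp4d` entry point with `phantom`,
  `register`, `accumulate`, `aip`, `study` subcommands, instead of
  separate per-stage executables.
* **Problem sizes**: the bundled study runs at 96³ × 3 mm with all 9
  registrations; the registration-parameter recovery tests use 64³
  blobs; the determinism check uses a 48³ × 6 mm study. These sizes keep
  the full suite and the reproduction script desk-scale while leaving
  >10 voxels across every structure of interest.

## Known limitations

* Static dose cloud (no per-phase dose recalculation) — see above.
* No hysteresis (inhale and exhale follow the same path), no sliding
  interfaces, no CT texture libraries; noise is i.i.d. per phase.
* Single-session (intrafraction) accumulation only; no interfraction
  adaptation, no TCP/NTCP beyond BED.
* Masks only (no polygon contours); axis-aligned grids only; DICOM-RT is
  deliberately unsupported — convert to NRRD/MetaImage first.
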