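# Methods

## The measurement

`edgemtf` estimates the in-plane spatial resolution of a CT acquisition
directly from the scan itself, using the patient's (or phantom's)
skin–air interface as a naturally occurring edge target.  The summary
statistic is **f50**, the spatial frequency (mm⁻¹) at which the
modulation transfer function (MTF) falls to 0.5.

The chain is:

1. **Volume conditioning.** The DICOM series is read into an HU volume;
   10 mm are cropped from both longitudinal ends (lines cast near the
   stack ends would otherwise run out of support), and everything more
   than 50 pixels × s_x posterior of the volume center is excluded as
   CT table.
2. **Segmentation and meshing.** Otsu's threshold separates body from
   air; the largest connected component is kept and internal cavities
   are filled so only the external skin surface remains.  Marching
   cubes on the binary mask yields a triangle mesh (element size at
   most about one voxel), which is Taubin-smoothed — 100 shrink/dilate
   pairs, passband 0.05 — to remove the voxelization staircase while
   preserving enclosed volume.
3. **ESF sampling.** Through each triangle centroid a 3-D Bresenham
   line is cast along the inward normal; raw voxel values (no
   interpolation) form one edge-spread-function (ESF) curve per face.
   Each sample's abscissa is its signed distance to the surface:
   a kd-tree over face centroids shortlists eight candidate faces and
   the exact point-to-triangle minimum over the shortlist is taken,
   signed by body-mask membership.  Lines tilted more than 10° out of
   the axial plane cross slices and are discarded.  Samples beyond
   ±18 mm are trimmed so oblique lines carry the same physical support
   as axis-aligned ones.
4. **Per-curve conditioning.** The first differences ΔE are
   soft-thresholded, D = √(ΔE² + ΔĒ²) − ΔĒ with ΔĒ the mean |ΔE|;
   the contiguous run with D ≥ 20 HU containing the largest D is the
   transition region, and its flanks are the air and tissue tails.
   A filter battery then rejects contaminated curves (see below).
   Surviving curves are tail-replaced (each tail flattened to the mean
   of its 2 mm near-edge window), fitted with the logistic
   f(x) = a/(1+e^{−c(x−b)}) + d from the fixed start (1000, 0, 1.0,
   −1000), and centered: X′ = X − b, E′ = E − (a/2 + d).
5. **Aggregation.** All accepted samples are pooled into bins of
   0.1 × s_x mm; the central 70 % of the binned curve is kept; isotonic
   regression (pool-adjacent-violators) enforces the monotone ascent;
   the line spread function is the first difference and the MTF the
   normalized |FFT|.  f50 is read off by linear interpolation at the
   first downward crossing of 0.5.

### Filter battery

Pre-centering (on the raw curve and its decomposition):

| rule | condition for rejection | what it catches |
|---|---|---|
| clothing | any air-tail sample ≥ −950 HU | material in contact with the skin-side air gap |
| in-air artifact | Σ ΔE over the air tail < −100 HU | masks/towels entered but not exited in the tail |
| ancillary | Σ ΔE over the tissue tail < −300 HU | air–tissue–air paths (ear, nose, armpit) |
| transition check | transition outside (0.2 N, 0.8 N) or not strictly ascending (0.5 HU tolerance) | displaced interface, double edges |

Post-centering: a bounding box (X′ ∈ [−20, 20] mm, E′ ∈ [−600, 600] HU)
catching mis-fit coefficients, and a contrast range check
(max − min ∈ [900, 1200] HU).  The clothing and in-plane rules are the
legacy baseline; the rest are the robustness additions.  *Reference
mode* (`--mode reference`) disables the additions, Taubin smoothing,
the head-and-neck slab and the 70 % trim, reproducing the baseline
behaviour for paired comparisons.

### Head-and-neck handling

Thermoplastic immobilization masks hug the anterior surface and
contaminate most curves there.  Under the `hn` protocol only faces
inside a 75-voxel-wide anterior–posterior slab about the volume center
(the lateral "ear" band, where mask contact is least) are sampled, and
the retained faces are subdivided at their longest edges until the
count roughly doubles, recovering curve statistics.

## Numerical choices

* **Centering shift.** Aligning each curve by its own fitted `b`
  self-aligns steep edges: the estimate correlates with the curve's own
  sample phase, and pooling such curves concentrates the transition
  into an artificially sharp aggregate (≈ +11 % f50 at the sharp end of
  the band on synthetic data).  Purely geometric centering (b = 0)
  errs the other way, blurring by the residual surface ripple.  The
  applied shift is therefore the mean fitted `b` over all clean fitted
  curves whose face centroids lie within 2 mm
  (`center_smooth_radius_mm`; 0 restores strictly per-curve centering).
  The real edge-position error of the mesh varies smoothly on that
  scale and is preserved; the per-curve jitter averages out.  2 mm is
  roughly the staircase-ripple correlation length and spans many
  distinct sub-voxel phases.
* **Distance lookup.** A nearest-*vertex* lookup folds a tangential
  offset of up to half the vertex spacing into every distance
  (√(d²+u²)), which acts as an extra ≈ 0.2 mm blur on the pooled ESF.
  The exact point-to-triangle distance over a kd-tree shortlist removes
  that floor at negligible cost.
* **Logistic solve.** Unconstrained Levenberg–Marquardt with an
  analytic Jacobian and a clipped exponent; the physical bounds
  (a ∈ [500, 2000] HU, c > 0, |b| ≤ half line length) are validated
  after the solve, so degenerate or sign-flipped solutions reject the
  curve ("fit failure") instead of being coerced.
* **Line support.** Half-length 18 mm: long enough for both tails and
  the 2 mm plateau windows, short enough that a correctly centered
  curve sits inside the ±20 mm bounding box with ~2 mm slack for `b`.
* **Empty bins** in the oversampled ESF are linearly interpolated from
  their neighbours (the isotonic stage needs a complete grid); empty
  interior bins are rare (< 1 %) at the default bin width.
* **FFT length** equals the LSF length (no zero-padding by default;
  `fft_zero_pad` enables 4× padding for a finer f50 interpolation
  grid).  The modulus of the complex spectrum is used, as standard.
* **Decimation** (the mesh-resampling study) is shortest-edge midpoint
  collapse with a link-condition check and a volume-preserving vertex
  placement: after each collapse the merged vertex is shifted along the
  ring's area vector to cancel the chordal volume loss.  Face count
  lands within ±5 % of the requested fraction and enclosed volume
  within 2 % down to 10 % resampling.
* **Tie-breaks / degenerate inputs.** Uniform volumes raise
  "degenerate histogram"; empty masks "no surface"; flat curves "fit
  failure"; a curve with fewer than 8 samples on either side of the
  interface is "short curve".  Adjacent equal transition values are
  tolerated within 0.5 HU so floating-point plateaus do not fail the
  ascent check.

## The synthetic phantoms

The generator emulates a radiotherapy CT simulation of a
water-equivalent body (cylinder or head-like ellipsoid, 0 HU) in air
(−1000 HU), imaged by a system with Gaussian in-plane blur of known σ.
Voxel values are **point samples of the analytic blurred profile**
hu_air + ΔHU·Φ(d/σ) at the voxel centers (d = signed distance to the
body surface, Φ the normal CDF) — the correct model of linear FBP
reconstruction, which point-samples a band-limited continuous image.
This makes the ground truth exact: the system MTF is
exp(−2π²σ²f²) and f50 = √(ln 2 / 2)/(πσ).  Setup artifacts share the
same blur: a thermoplastic mask shell (offset shell over a chosen
angular range), a towel slab, fiducial spheres and a flat couch slab.
Gaussian HU noise (default 5 HU) is added last, seeded.

What the phantoms deliberately do **not** model: projection/
reconstruction physics (no sinograms, no kernel structure — a Gaussian
stands in for the kernel), beam hardening, motion, anatomical texture
beneath the skin, and vendor-specific mask cell structure (the shell is
solid over its angular range).  Passing the synthetic suite therefore
demonstrates the estimator's correctness and its robustness mechanism,
not performance on any particular scanner.

Default geometry is desk-scale so the whole validation runs on one CPU
in minutes: 0.977 mm pixels and 2 mm slices as in a 500 mm FOV / 512
matrix protocol, but 128–192 voxel matrices with 45–60 mm radii and
26–40 slices.  The bodies span the full stack (as a patient does), so
the mesh is open at the crop planes and no artificial end caps enter
the distance lookups.

## Validated behaviour

All quantitative claims below are computed by the test suite and
`scripts/acceptance.py` at run time, on the synthetic phantoms:

* f50 recovery within 5 % of the closed-form oracle at 0.2, 0.3, 0.5
  and 0.7 mm⁻¹ (the validated band; accuracy degrades above it, as
  expected from sampling limits at sub-voxel blurs).
* With the anterior mask shell on the head phantom, the modified
  algorithm's f50 moves < 10 % relative to its paired no-mask run; the
  reference baseline's bias is strictly larger (it accepts
  shell-contaminated curves whose air tails pass the clothing check).
* Decimating the mesh to 50 % changes f50 by < 5 % on the body fixture.
* Invariants: MTF(0) = 1; the regularized oversampled ESF is monotone
  and the LSF non-negative; per-stage curve counts are conserved
  (accepted + rejections = in-plane); f50 scales as 1/σ.

## Known limitations

* The isotonic (monotone) constraint biases genuinely non-monotone
  MTFs, e.g. edge-enhancing kernels; those are outside the validated
  band.
* The clothing rule's strictest reading (any air sample ≥ −950 HU) is
  used; tight-fitting, high-density immobilization devices may cause
  over-rejection, and solid (cell-free) masks are not modelled.
* Accuracy above 0.7 mm⁻¹ is sampling-limited: with ~1 mm pixels the
  transition occupies a single sample and both the centering and the
  binning operate at their information limit.
* Only single-frame axial CT series are supported (no tilted gantry,
  no multi-frame enhanced DICOM).
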