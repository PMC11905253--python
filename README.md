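# edgemtf

Automated measurement of CT spatial resolution — the modulation
transfer function (MTF) and its half-value frequency **f50** — directly
from the skin–air interface of an arbitrary CT image stack.

Phantom-based quality control characterizes the scanner, not the scan:
protocol, positioning and setup devices (thermoplastic masks, towels,
fiducials, the couch) all change the resolution actually delivered in a
radiotherapy CT simulation, and remote or resource-limited clinics may
have no phantom program at all.  `edgemtf` treats every scan as its own
resolution target: the body's edge against air is a step input, and the
pooled, sub-voxel-binned edge spread function (ESF) across the whole
body surface yields the system MTF.

## Method in brief

For a volume of Hounsfield units with pixel pitch s_x:

1. Otsu segmentation → marching-cubes skin mesh → Taubin smoothing
   (100 iterations, passband 0.05); 10 mm longitudinal crop and a
   table crop 50 px posterior of center.
2. One Bresenham line per triangle along the inward normal, sampled
   without interpolation; sample abscissae are signed nearest-surface
   distances (kd-tree); lines > 10° out of plane are discarded.
3. Each curve is split into air / transition / tissue by the
   soft-thresholded derivative D = √(ΔE² + ΔĒ²) − ΔĒ (transition:
   D ≥ 20 HU), screened by robustness filters (clothing, in-air
   artifact, ancillary region, transition check), tail-replaced, fitted
   with the logistic a/(1+e^{−c(x−b)}) + d and centered by
   X′ = X − b, E′ = E − (a/2 + d), then screened again (bounding box,
   contrast range).
4. Accepted samples are pooled into 0.1·s_x bins, trimmed to the
   central 70 %, made monotone by isotonic regression, differentiated
   to the LSF and Fourier-transformed:
   MTF(f) = |FFT(LSF)| / |FFT(LSF)|₀, and f50 solves MTF(f50) = 0.5.

A bundled synthetic-phantom generator produces volumes whose true
resolution is known in closed form (Gaussian blur σ ⇒
f50 = √(ln 2 / 2)/(πσ)), including radiotherapy setup artifacts, so the
entire pipeline is testable without scan data.  See
[docs/methods.md](docs/methods.md) for the full model and its
assumptions.

## Worked example

```python
import edgemtf as em

# a water cylinder in air, blurred so the true f50 is 0.30 mm^-1
spec = em.clean_cylinder(sigma_mm=em.sigma_for_f50(0.30), seed=7,
                         dims=(128, 128, 26), radius_mm=40.0)
vol = em.generate_phantom(spec)
report = em.run_pipeline(vol, protocol="body")
print(f"f50 = {report.f50:.4f} mm^-1 (truth 0.3000)")
print(f"curves: {report.curves_total} faces, {report.curves_in_plane} in-plane, "
      f"{report.curves_accepted} accepted")
```

prints (exactly reproducible with this seed):

```
f50 = 0.2985 mm^-1 (truth 0.3000)
curves: 9854 faces, 9854 in-plane, 9850 accepted
```

i.e. the measured f50 is within 0.5 % of the analytic ground truth; on
this open cylinder every surface triangle faces radially, so all 9 854
candidate curves are in-slice and 9 850 survive the filter battery.

The same measurement from a shell:

```bash
edgemtf simulate --preset masked-head --sigma 0.94 --seed 1 --out /tmp/head
edgemtf measure /tmp/head --protocol hn --report report.json --mtf-csv mtf.csv
edgemtf sensitivity /tmp/head --protocol hn     # one-filter-at-a-time study
edgemtf resample /tmp/head --protocol hn        # f50 vs mesh decimation
```

`measure` exits 2 on input errors, 3 when too few curves survive, 4
when the MTF never crosses 0.5.  Every threshold is overridable via
`--config file.yaml` or `--set key=value` (see
`edgemtf.config.PipelineConfig`).

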