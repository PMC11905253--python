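"""Synthetic CT phantoms with analytically known spatial resolution.

A phantom is a water-equivalent body (cylinder or head-like ellipsoid,
~0 HU) in air (-1000 HU) imaged by a system whose in-plane point spread
is Gaussian with known sigma.  Voxel values are point samples of the
analytic blurred image at the voxel centers:

    HU(p) = hu_air + (hu_tissue - hu_air) * Phi(d(p) / sigma)

where d is the signed distance to the body surface (positive inside)
and Phi the standard normal CDF.  This is the correct emulation of
linear (FBP) reconstruction, which yields point samples of a
band-limited continuous image, and it makes the ground truth exact: the
system MTF is exp(-2 pi^2 sigma^2 f^2) and its half point is

    f50 = sqrt(ln 2 / 2) / (pi * sigma).

Radiotherapy setup artifacts (thermoplastic mask shell, towel slab,
fiducial spheres, flat couch slab) are composited in the same way, so
they share the system blur.  Gaussian HU noise is added last, seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr  # standard normal CDF

from .errors import EdgeMTFError
from .volume import CTVolume


@dataclass
class MaskShell:
    """Concentric immobilization-mask shell, offset from the skin."""

    gap_mm: float = 3.0
    thickness_mm: float = 2.0
    hu: float = 200.0
    coverage_deg: float = 360.0  # angular range centered on anterior


@dataclass
class TowelSlab:
    """Folded towel hovering over the anterior surface."""

    gap_mm: float = 3.0
    thickness_mm: float = 10.0
    width_mm: float = 100.0
    hu: float = -940.0


@dataclass
class FiducialSpheres:
    """Localization markers resting just off the skin."""

    radius_mm: float = 2.0
    gap_mm: float = 1.0
    hu: float = 300.0
    angles_deg: tuple[float, ...] = (0.0, 90.0, -90.0)  # from anterior


@dataclass
class CouchSlab:
    """Flat couch top posterior of the body."""

    distance_mm: float = 80.0
    thickness_mm: float = 40.0
    hu: float = -300.0


@dataclass
class PhantomSpec:
    shape: str = "cylinder"  # "cylinder" | "head-ellipsoid"
    radius_mm: float = 60.0
    semi_axes_mm: tuple[float, float, float] = (65.0, 80.0, 120.0)
    length_mm: float = 200.0  # > stack extent: body runs through the scan
    hu_tissue: float = 0.0
    hu_air: float = -1000.0
    blur_sigma_mm: float = 0.94
    noise_sigma_hu: float = 5.0
    spacing: tuple[float, float, float] = (0.977, 0.977, 2.0)
    dims: tuple[int, int, int] = (192, 192, 40)
    artifacts: tuple = ()
    seed: int = 0


def analytic_f50(sigma: float) -> float:
    """Exact f50 of a Gaussian system MTF exp(-2 pi^2 sigma^2 f^2)."""
    if sigma <= 0:
        raise EdgeMTFError("invalid sigma")
    return math.sqrt(math.log(2.0) / 2.0) / (math.pi * sigma)


def sigma_for_f50(target_f50: float) -> float:
    """Gaussian blur sigma whose MTF half-point is ``target_f50``."""
    if target_f50 <= 0:
        raise EdgeMTFError("invalid f50")
    return math.sqrt(math.log(2.0) / 2.0) / (math.pi * target_f50)


def _cdf(d: np.ndarray, sigma: float) -> np.ndarray:
    if sigma > 0:
        return ndtr(d / sigma)
    return np.where(d > 0, 1.0, np.where(d < 0, 0.0, 0.5))


def _grids(spec: PhantomSpec):
    nx, ny, nz = spec.dims
    sx, sy, sz = spec.spacing
    x = (np.arange(nx) - (nx - 1) / 2.0) * sx
    y = (np.arange(ny) - (ny - 1) / 2.0) * sy
    z = (np.arange(nz) - (nz - 1) / 2.0) * sz
    return np.meshgrid(x, y, z, indexing="ij")


def _body_sdf(spec: PhantomSpec, X, Y, Z) -> np.ndarray:
    """Signed distance to the body surface, positive inside, mm."""
    if spec.shape == "cylinder":
        r = np.hypot(X, Y)
        return np.minimum(spec.radius_mm - r, spec.length_mm / 2.0 - np.abs(Z))
    if spec.shape == "head-ellipsoid":
        a, b, c = spec.semi_axes_mm
        q = np.sqrt((X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2)
        grad = np.sqrt((X / a**2) ** 2 + (Y / b**2) ** 2 + (Z / c**2) ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(grad > 0, q * (1.0 - q) / np.where(grad > 0, grad, 1.0), a)
        return d
    raise EdgeMTFError(f"unknown phantom shape: {spec.shape!r}")


def _lateral_extent(spec: PhantomSpec) -> float:
    if spec.shape == "cylinder":
        return spec.radius_mm
    return max(spec.semi_axes_mm[0], spec.semi_axes_mm[1])


def _artifact_weight(art, spec: PhantomSpec, X, Y, Z, body_sdf) -> np.ndarray:
    """Occupancy in [0, 1] of one artifact, blurred like the body."""
    s = spec.blur_sigma_mm
    if isinstance(art, MaskShell):
        if art.gap_mm <= 0:
            raise EdgeMTFError("invalid gap")
        t = -body_sdf  # distance outside the skin
        w = _cdf(t - art.gap_mm, s) - _cdf(t - art.gap_mm - art.thickness_mm, s)
        if art.coverage_deg < 360.0:
            # angle from the anterior (-y) direction
            theta = np.degrees(np.arctan2(np.abs(X), -Y))
            w = np.where(theta <= art.coverage_deg / 2.0, w, 0.0)
        return w
    if isinstance(art, TowelSlab):
        y_front = -_lateral_extent(spec)  # anterior skin extreme
        y1 = y_front - art.gap_mm
        y0 = y1 - art.thickness_mm
        wy = _cdf(Y - y0, s) - _cdf(Y - y1, s)
        wx = _cdf(X + art.width_mm / 2.0, s) - _cdf(X - art.width_mm / 2.0, s)
        return wy * wx
    if isinstance(art, FiducialSpheres):
        w = np.zeros_like(X)
        rad = _lateral_extent(spec) + art.gap_mm + art.radius_mm
        for ang in art.angles_deg:
            cx = rad * math.sin(math.radians(ang))
            cy = -rad * math.cos(math.radians(ang))
            dist = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + Z**2)
            w = np.maximum(w, _cdf(art.radius_mm - dist, s))
        return w
    if isinstance(art, CouchSlab):
        y0 = art.distance_mm
        wy = _cdf(Y - y0, s) - _cdf(Y - y0 - art.thickness_mm, s)
        return wy
    raise EdgeMTFError(f"unknown artifact: {type(art).__name__}")


def generate_phantom(spec: PhantomSpec) -> CTVolume:
    """Rasterize a phantom spec into a :class:`CTVolume` (deterministic
    for a fixed spec and seed).

    Raises ``"phantom clipped"`` if the body comes within 20 mm of a
    lateral volume border.
    """
    nx, ny, _ = spec.dims
    sx, sy, _ = spec.spacing
    half_fov = min((nx - 1) / 2.0 * sx, (ny - 1) / 2.0 * sy)
    if _lateral_extent(spec) + 20.0 > half_fov:
        raise EdgeMTFError("phantom clipped")

    X, Y, Z = _grids(spec)
    d = _body_sdf(spec, X, Y, Z)
    vol = spec.hu_air + (spec.hu_tissue - spec.hu_air) * _cdf(d, spec.blur_sigma_mm)
    for art in spec.artifacts:
        vol = vol + (art.hu - spec.hu_air) * _artifact_weight(art, spec, X, Y, Z, d)
    if spec.noise_sigma_hu > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sigma_hu, size=vol.shape)

    origin = np.array(
        [
            -(nx - 1) / 2.0 * sx,
            -(ny - 1) / 2.0 * sy,
            -(spec.dims[2] - 1) / 2.0 * spec.spacing[2],
        ]
    )
    return CTVolume(voxels=vol.astype(np.float32), spacing=spec.spacing, origin=origin)


def add_mask_shell(vol: CTVolume, spec: PhantomSpec, shell: MaskShell) -> CTVolume:
    """Composite an immobilization-mask shell onto an existing phantom
    volume (the shell shares the system blur of ``spec``)."""
    X, Y, Z = _grids(spec)
    d = _body_sdf(spec, X, Y, Z)
    w = _artifact_weight(shell, spec, X, Y, Z, d)
    voxels = vol.voxels + (shell.hu - spec.hu_air) * w
    return replace(vol, voxels=voxels.astype(np.float32))


# ---------------------------------------------------------------------------
# Fixture presets.  Sizes are desk-scale versions of the clinical geometry
# (0.977 mm pixels, 2 mm slices); the true f50 is set through blur_sigma_mm.


def clean_cylinder(sigma_mm: float = 0.94, seed: int = 0, **overrides) -> PhantomSpec:
    """Uniform water cylinder in air: the oracle-recovery fixture."""
    return replace(
        PhantomSpec(shape="cylinder", blur_sigma_mm=sigma_mm, seed=seed), **overrides
    )


def masked_head(sigma_mm: float = 0.94, seed: int = 0, with_mask: bool = True, **overrides) -> PhantomSpec:
    """Head-like ellipsoid with a thermoplastic mask shell over the
    anterior face; the lateral (ear) band is left free, as for a real
    perforated mask."""
    artifacts = (MaskShell(gap_mm=3.0, thickness_mm=2.0, hu=200.0, coverage_deg=160.0),) if with_mask else ()
    return replace(
        PhantomSpec(
            shape="head-ellipsoid",
            semi_axes_mm=(55.0, 70.0, 120.0),
            blur_sigma_mm=sigma_mm,
            artifacts=artifacts,
            seed=seed,
        ),
        **overrides,
    )


def toweled_pelvis(sigma_mm: float = 0.94, seed: int = 0, **overrides) -> PhantomSpec:
    """Cylinder with towel, fiducial markers, and couch slab."""
    return replace(
        PhantomSpec(
            shape="cylinder",
            radius_mm=60.0,
            blur_sigma_mm=sigma_mm,
            artifacts=(TowelSlab(), FiducialSpheres(), CouchSlab()),
            seed=seed,
        ),
        **overrides,
    )


PRESETS = {
    "clean-cylinder": clean_cylinder,
    "masked-head": masked_head,
    "toweled-pelvis": toweled_pelvis,
}
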