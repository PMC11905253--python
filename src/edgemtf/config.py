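"""Pipeline configuration: every threshold of the measurement in one place.

Defaults are the published operating point of the method; the
``reference`` constructor reproduces the earlier skin-edge baseline
(no robustness filters, no Taubin smoothing, no head-and-neck slab, no
oversampled-ESF trimming) for paired comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

#: robustness-filter rules introduced by the modified method, in the
#: order they are applied (after the legacy clothing rule)
MODIFIED_FILTERS = ("in_air_artifact", "ancillary", "transition_check", "bounding_box", "max_min")
#: rules carried over from the foundational method
LEGACY_FILTERS = ("clothing",)
ALL_FILTERS = LEGACY_FILTERS + MODIFIED_FILTERS


@dataclass
class PipelineConfig:
    # volume cropping
    crop_margin_mm: float = 10.0
    table_crop: bool = True
    table_crop_pixels: int = 50

    # meshing
    taubin_iterations: int = 100
    taubin_passband: float = 0.05
    hn_slab_voxels: int = 75
    hn_oversample_factor: int = 2

    # sampling
    half_length_mm: float = 18.0
    in_plane_max_deg: float = 10.0
    min_side_samples: int = 8

    # transition decomposition (derivative sparsification)
    eq_threshold_hu: float = 20.0

    # pre-centering filters
    clothing_max_air_hu: float = -950.0
    artifact_air_sum_hu: float = -100.0
    ancillary_tissue_sum_hu: float = -300.0
    transition_band: tuple[float, float] = (0.2, 0.8)
    monotone_tol_hu: float = 0.5

    # tail replacement
    tail_window_mm: float = 2.0

    # logistic fit
    fit_init: tuple[float, float, float, float] = (1000.0, 0.0, 1.0, -1000.0)
    fit_a_bounds: tuple[float, float] = (500.0, 2000.0)
    # centering shift = mean fitted b over surface neighbours within this
    # radius (0 disables; per-curve b is then used directly).  Averaging
    # keeps the real, spatially smooth edge-position offsets while
    # decorrelating the per-curve fit jitter that otherwise self-aligns
    # steep edges into an artificially sharp pooled ESF.
    center_smooth_radius_mm: float = 2.0

    # post-centering filters
    bbox_x_mm: tuple[float, float] = (-20.0, 20.0)
    bbox_e_hu: tuple[float, float] = (-600.0, 600.0)
    range_hu: tuple[float, float] = (900.0, 1200.0)

    # aggregation / MTF
    bin_fraction: float = 0.1
    trim_fraction: float = 0.70
    min_curves: int = 100
    fft_zero_pad: int = 1

    # which filter rules run; None = all of ALL_FILTERS
    enabled_filters: tuple[str, ...] | None = None
    # smoothing / slab / trimming toggles (reference mode turns them off)
    use_taubin: bool = True
    use_hn_slab: bool = True
    use_trim: bool = True
    mode: str = "modified"

    def filters(self) -> tuple[str, ...]:
        return ALL_FILTERS if self.enabled_filters is None else tuple(self.enabled_filters)

    @classmethod
    def reference(cls, **overrides) -> "PipelineConfig":
        """Baseline configuration: legacy clothing + in-plane filters only,
        no Taubin smoothing, no HN slab, no oESF trimming."""
        cfg = cls(
            enabled_filters=LEGACY_FILTERS,
            use_taubin=False,
            use_hn_slab=False,
            use_trim=False,
            mode="reference",
        )
        return replace(cfg, **overrides)

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "PipelineConfig":
        if mode == "reference":
            return cls.reference(**overrides)
        if mode == "modified":
            return replace(cls(), **overrides)
        raise ValueError(f"unknown mode: {mode!r}")
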