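"""Per-curve ESF conditioning: transition decomposition, robustness
filters, tail replacement, logistic centering.

Each curve is decomposed into air / transition / tissue regions by a
soft-thresholded derivative,

    D(x) = sqrt(dE(x)^2 + dE_bar^2) - dE_bar,

where dE are the first differences of the curve and dE_bar is the mean
absolute first difference.  D suppresses derivatives comparable to the
curve's baseline fluctuation while passing large steps almost
unchanged; samples with D >= 20 HU (contiguous run containing the
largest D) form the transition region.

A battery of filters then rejects curves contaminated by immobilization
masks, towels, clothing, ancillary anatomy (air-tissue-air paths) or a
mis-placed transition.  Surviving curves are tail-replaced (flattening
depth-dependent tissue drift), fitted to the four-parameter logistic

    f(x) = a / (1 + exp(-c (x - b))) + d,      init (1000, 0, 1.0, -1000)

and re-expressed about the logistic midpoint: X' = X - b,
E' = E - (a/2 + d).  Post-centering filters check the centered curve
against a +/-20 mm x +/-600 HU bounding box and a [900, 1200] HU
air-to-skin contrast range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .config import PipelineConfig
from .errors import CurveRejected
from .sampling import ESFCurve

#: evaluation order of the pre-centering rules (first failing wins)
PRE_RULES = ("clothing", "in_air_artifact", "ancillary", "transition_check")
POST_RULES = ("bounding_box", "max_min")


@dataclass
class TransitionDecomposition:
    """Air / transition / tissue split of one ESF curve."""

    a_s: int  # index of first transitional sample
    a_e: int  # index of last transitional sample
    mean_derivative: float  # dE_bar, HU per sample
    D: np.ndarray  # sparsified derivative, HU, length N-1

    def regions(self, n: int):
        air = np.arange(0, self.a_s + 1)
        trans = np.arange(self.a_s, self.a_e + 1)
        tissue = np.arange(self.a_e, n)
        return air, trans, tissue


@dataclass
class LogisticFit:
    a: float
    b: float
    c: float
    d: float
    converged: bool
    residual: float  # RMS, HU


@dataclass
class CenteredESF:
    distances: np.ndarray  # X', mm; logistic midpoint at 0
    values: np.ndarray  # E', HU; midpoint at 0
    source_id: int


def sparsified_derivative(delta: np.ndarray, mean_abs: float) -> np.ndarray:
    """Soft-threshold transform D = sqrt(dE^2 + dE_bar^2) - dE_bar."""
    return np.sqrt(delta**2 + mean_abs**2) - mean_abs


def transition_decompose(curve: ESFCurve, threshold_hu: float = 20.0) -> TransitionDecomposition:
    """Locate the transition region of a curve.

    The transitional samples are the contiguous run of D >= threshold
    that contains the largest D; the flanks are air and tissue.  Raises
    ``CurveRejected("no transition")`` when no derivative clears the
    threshold.
    """
    values = np.asarray(curve.values, dtype=float)
    if len(values) < 16:
        raise CurveRejected("short curve")
    delta = np.diff(values)
    mean_abs = float(np.mean(np.abs(delta)))
    D = sparsified_derivative(delta, mean_abs)
    above = D >= threshold_hu
    if not above.any():
        raise CurveRejected("no transition")
    peak = int(np.argmax(D))
    s = peak
    while s > 0 and above[s - 1]:
        s -= 1
    e = peak
    while e < len(D) - 1 and above[e + 1]:
        e += 1
    # D[i] sits between samples i and i+1 -> samples s .. e+1 transition
    return TransitionDecomposition(a_s=s, a_e=e + 1, mean_derivative=mean_abs, D=D)


def precentering_filters(
    curve: ESFCurve,
    decomp: TransitionDecomposition,
    cfg: PipelineConfig | None = None,
) -> dict[str, bool]:
    """Evaluate every pre-centering rule; True = rule fails (reject).

    Rules, in application order:

    clothing
        any air-region sample at or above -950 HU (material touching
        the skin-side air gap).
    in_air_artifact
        net drop of the air tail, sum dE over air < -100 HU (a mask or
        towel entered but not exited within the tail).
    ancillary
        net drop of the tissue tail, sum dE < -300 HU (the line exits
        through the far side: ear, nose, armpit).
    transition_check
        the transition must sit in the central (0.2 N, 0.8 N) index band
        and ascend strictly (0.5 HU tolerance).
    """
    cfg = cfg or PipelineConfig()
    values = np.asarray(curve.values, dtype=float)
    n = len(values)
    delta = np.diff(values)
    out = {}
    air_idx, trans_idx, _ = decomp.regions(n)

    out["clothing"] = bool(np.any(values[air_idx] >= cfg.clothing_max_air_hu))
    out["in_air_artifact"] = bool(np.sum(delta[: decomp.a_s]) < cfg.artifact_air_sum_hu)
    out["ancillary"] = bool(np.sum(delta[decomp.a_e :]) < cfg.ancillary_tissue_sum_hu)

    lo, hi = cfg.transition_band
    in_band = np.all((trans_idx > lo * n) & (trans_idx < hi * n))
    ascending = np.all(np.diff(values[trans_idx]) > -cfg.monotone_tol_hu)
    out["transition_check"] = not (bool(in_band) and bool(ascending))
    return out


def first_failing(rules: dict[str, bool], enabled, order) -> str | None:
    for name in order:
        if name in enabled and rules.get(name):
            return name
    return None


def tail_replace(
    curve: ESFCurve,
    decomp: TransitionDecomposition,
    window_mm: float = 2.0,
) -> ESFCurve:
    """Flatten both tails to their near-edge plateau means.

    Tissue samples after the transition are replaced by the mean of the
    tissue samples within ``window_mm`` past the transition end; air
    samples more than ``window_mm`` before the transition start are
    replaced by the mean of the near-edge air window.  Transition
    samples are untouched.
    """
    d = np.asarray(curve.distances, dtype=float)
    v = np.asarray(curve.values, dtype=float).copy()
    a_s, a_e = decomp.a_s, decomp.a_e

    tis = np.arange(a_e + 1, len(v))
    tis_win = tis[d[tis] <= d[a_e] + window_mm]
    if len(tis_win) == 0:
        raise CurveRejected("tissue tail too short")
    v[tis] = float(np.mean(v[tis_win]))

    air = np.arange(0, a_s)
    air_win = air[d[air] >= d[a_s] - window_mm]
    air_far = air[d[air] < d[a_s] - window_mm]
    if len(air_win) and len(air_far):
        v[air_far] = float(np.mean(v[air_win]))

    return ESFCurve(distances=d, values=v, face_id=curve.face_id, direction=curve.direction)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(np.clip(-z, -500.0, 500.0)))


def _logistic(x, a, b, c, d):
    return a * _sigmoid(c * (x - b)) + d


def fit_logistic(curve: ESFCurve, cfg: PipelineConfig | None = None) -> LogisticFit:
    """Nonlinear least squares of the 4-parameter logistic to the curve.

    The solve is unconstrained Levenberg-Marquardt with an analytic
    Jacobian; physicality constraints (a in [500, 2000] HU, c > 0, |b|
    within the line half-length) are validated afterwards, so
    sign-flipped or degenerate solutions reject the curve.  Flat curves
    and non-converged solves raise ``CurveRejected("fit failure")``.
    """
    cfg = cfg or PipelineConfig()
    x = np.asarray(curve.distances, dtype=float)
    y = np.asarray(curve.values, dtype=float)
    if float(np.ptp(y)) < 1.0:
        raise CurveRejected("fit failure")
    half = max(abs(x[0]), abs(x[-1]))

    def resid(p):
        return _logistic(x, *p) - y

    def jac(p):
        a, b, c, _ = p
        s = _sigmoid(c * (x - b))
        w = s * (1.0 - s)
        return np.column_stack([s, -a * c * w, a * (x - b) * w, np.ones_like(x)])

    try:
        res = least_squares(resid, np.asarray(cfg.fit_init, dtype=float), jac=jac, method="lm", max_nfev=400)
    except Exception as exc:
        raise CurveRejected("fit failure") from exc
    a, b, c, d = (float(v) for v in res.x)
    ok = (
        res.success
        and np.all(np.isfinite(res.x))
        and cfg.fit_a_bounds[0] <= a <= cfg.fit_a_bounds[1]
        and c > 0
        and abs(b) <= half
    )
    if not ok:
        raise CurveRejected("fit failure")
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return LogisticFit(a=a, b=b, c=c, d=d, converged=True, residual=rms)


def center_curve(curve: ESFCurve, fit: LogisticFit) -> CenteredESF:
    """Shift the curve so the logistic midpoint lands at (0, 0):
    X' = X - b, E' = E - (a/2 + d)."""
    return CenteredESF(
        distances=np.asarray(curve.distances, dtype=float) - fit.b,
        values=np.asarray(curve.values, dtype=float) - (fit.a / 2.0 + fit.d),
        source_id=curve.face_id,
    )


def postcentering_filters(curve: CenteredESF, cfg: PipelineConfig | None = None) -> dict[str, bool]:
    """Evaluate the post-centering rules; True = rule fails.

    bounding_box
        every sample must fall inside X' in [-20, 20] mm and
        E' in [-600, 600] HU (mis-fit coefficients push it out).
    max_min
        the full value range must lie in [900, 1200] HU, the expected
        air-to-skin contrast.
    """
    cfg = cfg or PipelineConfig()
    x, e = curve.distances, curve.values
    out = {}
    out["bounding_box"] = bool(
        np.any(x < cfg.bbox_x_mm[0])
        or np.any(x > cfg.bbox_x_mm[1])
        or np.any(e < cfg.bbox_e_hu[0])
        or np.any(e > cfg.bbox_e_hu[1])
    )
    rng = float(np.max(e) - np.min(e))
    out["max_min"] = not (cfg.range_hu[0] <= rng <= cfg.range_hu[1])
    return out


@dataclass
class CurveRecord:
    """All conditioning outcomes of one curve, independent of which
    filters are enabled; verdicts under any filter set derive from it."""

    curve: ESFCurve
    structural: str | None = None  # non-filter rejection reason
    decomp: TransitionDecomposition | None = None
    rules: dict[str, bool] | None = None  # rule name -> failed?
    tail_replaced: ESFCurve | None = None
    fit: LogisticFit | None = None
    b_used: float | None = None  # centering shift actually applied
    centered: CenteredESF | None = None

    def verdict(self, enabled_filters) -> str | None:
        """Rejection reason under a filter set, or None if accepted."""
        if self.structural is not None:
            return self.structural
        enabled = set(enabled_filters)
        return first_failing(self.rules, enabled, PRE_RULES + POST_RULES)


def recenter(rec: CurveRecord, b: float, cfg: PipelineConfig | None = None) -> CurveRecord:
    """Re-apply the centering with shift ``b`` (e.g. a neighbourhood-
    averaged edge offset) and refresh the post-centering rule outcomes."""
    cfg = cfg or PipelineConfig()
    shifted = LogisticFit(
        a=rec.fit.a, b=b, c=rec.fit.c, d=rec.fit.d,
        converged=rec.fit.converged, residual=rec.fit.residual,
    )
    rec.b_used = b
    rec.centered = center_curve(rec.tail_replaced, shifted)
    rec.rules.update(postcentering_filters(rec.centered, cfg))
    return rec


def condition_curve(curve: ESFCurve, cfg: PipelineConfig | None = None) -> CurveRecord:
    """Run the full conditioning chain on one curve, recording every rule
    outcome (so filter subsets can be re-evaluated without resampling)."""
    cfg = cfg or PipelineConfig()
    rec = CurveRecord(curve=curve, rules={})
    try:
        rec.decomp = transition_decompose(curve, cfg.eq_threshold_hu)
    except CurveRejected as exc:
        rec.structural = exc.reason
        return rec
    rec.rules.update(precentering_filters(curve, rec.decomp, cfg))
    try:
        rec.tail_replaced = tail_replace(curve, rec.decomp, cfg.tail_window_mm)
        rec.fit = fit_logistic(rec.tail_replaced, cfg)
    except CurveRejected as exc:
        rec.structural = exc.reason
        return rec
    rec.b_used = rec.fit.b
    rec.centered = center_curve(rec.tail_replaced, rec.fit)
    rec.rules.update(postcentering_filters(rec.centered, cfg))
    return rec
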