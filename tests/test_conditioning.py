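"""Transition decomposition, filter rules, tail replacement and the
logistic centering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import edgemtf as em
from edgemtf.conditioning import (
    PRE_RULES,
    CenteredESF,
    recenter,
    sparsified_derivative,
)
from edgemtf.config import PipelineConfig
from edgemtf.errors import CurveRejected
from edgemtf.sampling import ESFCurve


def _curve(values, spacing=1.0, offset=None):
    values = np.asarray(values, dtype=float)
    n = len(values)
    if offset is None:
        offset = -(n - 1) / 2.0 * spacing
    d = offset + np.arange(n) * spacing
    return ESFCurve(distances=d, values=values, face_id=0, direction=np.array([1.0, 0.0, 0.0]))


def _sigmoid_curve(n=37, a=1000.0, b=0.0, c=2.0, d=-1000.0, spacing=1.0):
    x = (np.arange(n) - (n - 1) / 2.0) * spacing
    return ESFCurve(
        distances=x,
        values=a / (1 + np.exp(-c * (x - b))) + d,
        face_id=0,
        direction=np.array([1.0, 0.0, 0.0]),
    )


class TestSparsifiedDerivative:
    def test_hand_worked_values(self):
        assert sparsified_derivative(np.array([50.0]), 10.0)[0] == pytest.approx(
            np.sqrt(2600) - 10, abs=1e-9
        )  # ~40.99, transitional
        assert sparsified_derivative(np.array([10.0]), 10.0)[0] == pytest.approx(
            np.sqrt(200) - 10, abs=1e-9
        )  # ~4.14, suppressed

    def test_soft_threshold_properties(self):
        """D <= |dE| always; D/|dE| -> 1 for large steps; D ~ dE^2/(2 dE_bar)
        for small ones."""
        de = np.linspace(-2000, 2000, 8001)
        for mbar in (2.0, 20.0, 80.0):
            D = sparsified_derivative(de, mbar)
            assert np.all(D <= np.abs(de) + 1e-12)
            big = np.abs(de) > 100 * mbar
            if big.any():
                assert np.allclose(D[big] / np.abs(de)[big], 1.0, atol=0.01)
            small = (np.abs(de) > 0) & (np.abs(de) < 0.1 * mbar)
            if small.any():
                assert np.allclose(D[small], de[small] ** 2 / (2 * mbar), rtol=0.01)


class TestTransitionDecompose:
    def test_flat_curve_has_no_transition(self):
        with pytest.raises(CurveRejected, match="no transition"):
            em.transition_decompose(_curve(np.full(32, -1000.0)))

    def test_sigmoid_regions_partition(self):
        cur = _sigmoid_curve()
        dec = em.transition_decompose(cur)
        assert 0 <= dec.a_s <= dec.a_e <= cur.N - 1
        air, trans, tissue = dec.regions(cur.N)
        joined = np.unique(np.concatenate([air, trans, tissue]))
        assert np.array_equal(joined, np.arange(cur.N))
        # the transition straddles the steep center
        assert dec.a_s < cur.N // 2 < dec.a_e

    def test_transition_contains_largest_step(self):
        cur = _sigmoid_curve()
        dec = em.transition_decompose(cur)
        peak = int(np.argmax(np.abs(np.diff(cur.values))))
        assert dec.a_s <= peak <= dec.a_e


class TestPrecenteringRules:
    def test_clean_sigmoid_passes_all(self):
        cur = _sigmoid_curve()
        dec = em.transition_decompose(cur)
        rules = em.precentering_filters(cur, dec)
        assert not any(rules.values())

    def test_air_bump_with_net_drop_flags_in_air_artifact(self):
        # towel bump (+300/-300) followed by a slow drift leaves the air
        # tail 320 HU below its start before the real skin transition
        vals = np.concatenate(
            [
                np.full(5, -1000.0),
                [-700.0, -1000.0],
                -1000.0 - 40.0 * np.arange(1, 9),  # drift to -1320
                np.full(3, -1320.0),
                [-800.0, -400.0, -100.0],
                np.full(20, 0.0),
            ]
        )
        cur = _curve(vals)
        dec = em.transition_decompose(cur)
        rules = em.precentering_filters(cur, dec)
        assert rules["in_air_artifact"]
        # oracle: signed sum over the air tail
        assert np.sum(np.diff(vals)[: dec.a_s]) < -100

    def test_exit_through_far_side_flags_ancillary(self):
        vals = np.concatenate(
            [np.full(14, -1000.0), [-600, -200], np.full(10, 0.0), np.linspace(0, -1000, 15)]
        )
        cur = _curve(vals)
        dec = em.transition_decompose(cur)
        rules = em.precentering_filters(cur, dec)
        assert rules["ancillary"]
        assert np.sum(np.diff(vals)[dec.a_e :]) < -300

    def test_off_center_transition_flags_transition_check(self):
        n = 40
        vals = np.full(n, 0.0)
        vals[:3] = [-1000.0, -600.0, -200.0]  # transition at ~0.05 N
        cur = _curve(vals)
        dec = em.transition_decompose(cur)
        rules = em.precentering_filters(cur, dec)
        assert rules["transition_check"]

    def test_non_monotone_transition_flags_transition_check(self):
        vals = np.concatenate(
            [np.full(16, -1000.0), [-700, -300, -600, -100, 0], np.full(16, 0.0)]
        )
        cur = _curve(vals)
        dec = em.transition_decompose(cur)
        assert em.precentering_filters(cur, dec)["transition_check"]

    def test_clothing_rule_fires_on_warm_air_tail(self):
        cur = _sigmoid_curve()
        vals = cur.values.copy()
        vals[3] = -930.0  # clothing in contact with the air gap
        cur2 = _curve(vals)
        dec = em.transition_decompose(cur2)
        assert em.precentering_filters(cur2, dec)["clothing"]

    def test_verdict_reports_first_failing_rule_in_order(self):
        from edgemtf.conditioning import CurveRecord

        rec = CurveRecord(curve=_sigmoid_curve(), rules={r: True for r in PRE_RULES})
        assert rec.verdict(PRE_RULES) == "clothing"
        rec.rules["clothing"] = False
        assert rec.verdict(PRE_RULES) == "in_air_artifact"


class TestTailReplace:
    def _drifting(self):
        x = np.arange(41) - 20.0
        vals = np.where(x < -1, -1000.0, 0.0)
        vals[19:22] = [-600, -300, -100]
        drift = np.clip(x - 2, 0, None) / 18.0 * -80.0  # tissue drifts 0 -> -80
        return _curve(vals + np.where(x > 2, drift, 0.0))

    def test_drift_replaced_by_near_edge_plateau(self):
        cur = self._drifting()
        dec = em.transition_decompose(cur)
        out = em.tail_replace(cur, dec)
        tissue = np.arange(dec.a_e + 1, cur.N)
        window = tissue[cur.distances[tissue] <= cur.distances[dec.a_e] + 2.0]
        expected = cur.values[window].mean()
        assert np.allclose(out.values[tissue], expected)

    def test_flat_tails_unchanged(self):
        cur = _sigmoid_curve(c=5.0)
        dec = em.transition_decompose(cur)
        out = em.tail_replace(cur, dec)
        # plateaus are already flat: sub-HU change at most
        assert np.allclose(out.values, cur.values, atol=1.0)

    def test_transition_untouched(self):
        cur = self._drifting()
        dec = em.transition_decompose(cur)
        out = em.tail_replace(cur, dec)
        trans = np.arange(dec.a_s, dec.a_e + 1)
        np.testing.assert_array_equal(out.values[trans], cur.values[trans])


class TestFitLogistic:
    def test_exact_parameter_recovery(self):
        cur = _sigmoid_curve(a=1000, b=0.3, c=2.0, d=-1000)
        fit = em.fit_logistic(cur)
        assert fit.a == pytest.approx(1000, rel=1e-4)
        assert fit.b == pytest.approx(0.3, abs=1e-4)
        assert fit.c == pytest.approx(2.0, rel=1e-4)
        assert fit.d == pytest.approx(-1000, rel=1e-4)

    def test_noisy_recovery_of_center_within_tenth_mm(self):
        rng = np.random.default_rng(11)
        errs = []
        for _ in range(100):
            cur = _sigmoid_curve(a=1000, b=0.3, c=2.0, d=-1000)
            noisy = ESFCurve(
                distances=cur.distances,
                values=cur.values + rng.normal(0, 5, cur.N),
                face_id=0,
                direction=cur.direction,
            )
            errs.append(em.fit_logistic(noisy).b - 0.3)
        assert np.sqrt(np.mean(np.square(errs))) < 0.1

    def test_constant_curve_fails(self):
        with pytest.raises(CurveRejected, match="fit failure"):
            em.fit_logistic(_curve(np.full(41, -1000.0)))


class TestCentering:
    def test_midpoint_maps_to_origin(self):
        # distances include x = 0.3 exactly, where the value is -500
        x = 0.3 + np.arange(-18, 19) * 1.0
        vals = 1000 / (1 + np.exp(-2.0 * (x - 0.3))) - 1000
        cur = _curve(vals, offset=x[0])
        assert vals[18] == pytest.approx(-500.0)
        fit = em.fit_logistic(cur)
        cen = em.center_curve(cur, fit)
        # the midpoint sample lands at (0, 0) after centering
        k = np.argmin(np.abs(cen.distances))
        assert cen.distances[k] == pytest.approx(0.0, abs=1e-5)
        assert cen.values[k] == pytest.approx(0.0, abs=1e-3)

    def test_already_centered_is_identity(self):
        cur = _sigmoid_curve(a=1000, b=0.0, c=2.0, d=-500)
        fit = em.LogisticFit(a=1000, b=0.0, c=2.0, d=-500, converged=True, residual=0.0)
        cen = em.center_curve(cur, fit)
        np.testing.assert_allclose(cen.distances, cur.distances)
        np.testing.assert_allclose(cen.values, cur.values)

    def test_air_plateau_maps_to_minus_half_amplitude(self):
        cur = _sigmoid_curve(a=1000, b=0.0, c=5.0, d=-1000)
        fit = em.fit_logistic(cur)
        cen = em.center_curve(cur, fit)
        assert cen.values[0] == pytest.approx(-500.0, abs=1.0)

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.floats(500, 2000),
        b=st.floats(-5, 5),
        d=st.floats(-1500, 0),
    )
    def test_centering_is_invertible(self, a, b, d):
        cur = _sigmoid_curve()
        fit = em.LogisticFit(a=a, b=b, c=1.0, d=d, converged=True, residual=0.0)
        cen = em.center_curve(cur, fit)
        np.testing.assert_allclose(cen.distances + b, cur.distances, atol=1e-9)
        np.testing.assert_allclose(cen.values + (a / 2 + d), cur.values, atol=1e-9)


class TestPostcenteringRules:
    def test_nominal_contrast_accepted(self):
        x = np.linspace(-15, 15, 41)
        cen = CenteredESF(x, 1000 / (1 + np.exp(-2 * x)) - 500, 0)
        assert not any(em.postcentering_filters(cen).values())

    def test_bone_range_flags_max_min(self):
        x = np.linspace(-15, 15, 41)
        cen = CenteredESF(x, 1400 / (1 + np.exp(-2 * x)) - 500, 0)
        assert em.postcentering_filters(cen)["max_min"]

    def test_shifted_fit_flags_bounding_box(self):
        x = np.linspace(-15, 15, 41) - 30.0  # b off by 30 mm
        cen = CenteredESF(x, 1000 / (1 + np.exp(-2 * x)) - 500, 0)
        assert em.postcentering_filters(cen)["bounding_box"]


class TestConditionCurve:
    def test_record_is_pure_and_complete(self):
        cur = _sigmoid_curve()
        r1 = em.condition_curve(cur)
        r2 = em.condition_curve(cur)
        assert r1.rules == r2.rules and r1.structural == r2.structural
        assert r1.verdict(PipelineConfig().filters()) is None
        assert r1.centered is not None and r1.fit is not None

    def test_recenter_overrides_shift_and_refreshes_rules(self):
        rec = em.condition_curve(_sigmoid_curve(b=0.4))
        recenter(rec, 30.0)
        assert rec.b_used == 30.0
        assert rec.rules["bounding_box"]
        recenter(rec, rec.fit.b)
        assert not rec.rules["bounding_box"]
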