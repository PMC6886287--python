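import numpy as np
import pytest

import autofmo as af
from autofmo.autoplan import (
    CompensationState,
    FACTOR_CEILING,
    MODEL_K_DEFAULTS,
    correction_factor,
    evaluate_plan,
)


class TestCorrectionFactors:
    def test_min_dose_ratio(self):
        c = af.Constraint(structure="ptv", type="min_dose", limit_gy=74.0)
        assert correction_factor(c, np.array([70.0, 90.0]), "ptv_coverage") == pytest.approx(
            74.0 / 70.0
        )

    def test_max_dose_ratio(self):
        c = af.Constraint(structure="s", type="max_dose", limit_gy=50.0)
        assert correction_factor(c, np.array([40.0, 60.0])) == pytest.approx(60.0 / 50.0)

    def test_mean_dose_ptv_symmetric_vs_oar_oriented(self):
        c = af.Constraint(structure="s", type="mean_dose", limit_gy=78.0)
        # PTV form: max/min >= 1 whichever side misses
        assert correction_factor(c, np.full(3, 80.0), "ptv_coverage") == pytest.approx(80 / 78)
        assert correction_factor(c, np.full(3, 76.0), "ptv_coverage") == pytest.approx(78 / 76)
        # OAR form: below-prescription mean de-emphasizes
        assert correction_factor(c, np.full(3, 39.0), "oar_sparing") == pytest.approx(0.5)

    def test_dv_max_volume_ratio(self):
        c = af.Constraint(structure="s", type="dv_max", dose_gy=50.0, volume_pct=40.0)
        d = np.concatenate([np.full(5, 60.0), np.full(5, 30.0)])  # V50 = 50%
        assert correction_factor(c, d) == pytest.approx(1.25)
        d = np.concatenate([np.full(3, 60.0), np.full(7, 30.0)])  # V50 = 30%
        assert correction_factor(c, d) == pytest.approx(0.75)

    def test_dv_min_inverse_ratio(self):
        c = af.Constraint(structure="s", type="dv_min", dose_gy=50.0, volume_pct=40.0)
        d = np.concatenate([np.full(5, 60.0), np.full(5, 30.0)])  # V50 = 50%
        assert correction_factor(c, d) == pytest.approx(0.8)

    def test_geud_orientation_by_exponent(self):
        oar = af.Constraint(structure="s", type="geud", limit_gy=60.0, exponent_a=2.0)
        assert correction_factor(oar, np.full(4, 66.0)) == pytest.approx(1.1)
        ptv = af.Constraint(structure="s", type="geud", limit_gy=78.0, exponent_a=0.5)
        assert correction_factor(ptv, np.full(4, 39.0), "ptv_coverage") == pytest.approx(2.0)

    def test_ntcp_identity_when_met_exactly(self):
        c = af.Constraint(
            structure="s", type="ntcp", probability=0.5, td50=76.9, m=0.13, n=0.09
        )
        assert correction_factor(c, np.full(4, 76.9)) == pytest.approx(1.0)

    def test_zero_denominator_clamps_with_warning(self):
        c = af.Constraint(structure="ptv", type="min_dose", limit_gy=74.0)
        with pytest.warns(UserWarning):
            assert correction_factor(c, np.zeros(3), "ptv_coverage") == FACTOR_CEILING

    def test_clamp_range(self):
        c = af.Constraint(structure="s", type="max_dose", limit_gy=1.0)
        assert correction_factor(c, np.full(2, 1e6)) == FACTOR_CEILING

    def test_tcp_requires_evaluator(self):
        c = af.Constraint(structure="s", type="tcp", probability=0.8)
        with pytest.raises(ValueError):
            correction_factor(c, np.ones(2))
        assert correction_factor(
            c, np.ones(2), tcp_evaluator=lambda d: 0.4
        ) == pytest.approx(2.0)

    def test_monotone_pressure(self):
        """Worse violation never yields a smaller factor."""
        c_min = af.Constraint(structure="p", type="min_dose", limit_gy=74.0)
        assert correction_factor(c_min, np.array([66.0]), "ptv_coverage") > correction_factor(
            c_min, np.array([70.0]), "ptv_coverage"
        )
        c_dv = af.Constraint(structure="s", type="dv_max", dose_gy=50.0, volume_pct=40.0)
        worse = np.concatenate([np.full(8, 60.0), np.full(2, 30.0)])
        better = np.concatenate([np.full(5, 60.0), np.full(5, 30.0)])
        assert correction_factor(c_dv, worse) > correction_factor(c_dv, better)


class TestUpdateWeights:
    def test_hand_example_k1(self):
        w = af.update_weights(np.array([0.5, 0.5]), [1.2, 0.8], [1.0, 1.0])
        np.testing.assert_allclose(w, [1.7 / 3.0, 1.3 / 3.0])

    def test_hand_example_k2_on_first(self):
        w = af.update_weights(np.array([0.5, 0.5]), [1.2, 0.8], [2.0, 1.0])
        np.testing.assert_allclose(w, [2.9 / 4.2, 1.3 / 4.2])

    def test_symmetry_preserved(self):
        w = af.update_weights(np.array([0.25, 0.25, 0.25, 0.25]), [1.1] * 4, [1.0] * 4)
        np.testing.assert_allclose(w, 0.25)

    def test_normalization_tight(self, rng):
        for _ in range(10):
            w0 = af.normalize_weights(rng.uniform(0.1, 1.0, 6))
            w = af.update_weights(w0, rng.uniform(0.01, 100, 6), np.ones(6))
            assert abs(w.sum() - 1.0) < 1e-12
            assert ((w > 0) & (w < 1)).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            af.update_weights(np.array([0.5, 0.5]), [1.0], [1.0])


class TestCompensationState:
    @pytest.mark.parametrize("model", ["dv", "geud", "ntcp"])
    def test_arithmetic_schedule(self, model):
        k0, step = MODEL_K_DEFAULTS[model]
        st = CompensationState(k0=k0, steplength=step)
        ks = []
        for i in range(1, 11):
            st.iteration = i
            ks.append(st.k)
        np.testing.assert_allclose(ks, k0 + step * np.arange(10))

    def test_k_is_one_before_engagement(self):
        assert CompensationState(k0=10.0, steplength=5.0).k == 1.0


class TestEvaluatePlan:
    def _spec(self, prescription):
        return af.build_objective_spec(prescription.constraints, "dv")

    def test_all_satisfied_no_targets(self, phantom, prescription):
        dose = np.zeros(np.prod(phantom.grid_shape))
        dose[phantom.masks["ptv"].ravel()] = 80.0
        ev = evaluate_plan(dose, prescription, phantom, self._spec(prescription))
        assert ev.ptv_satisfied and ev.all_satisfied
        assert ev.compensation_targets == []

    def test_ptv_coverage_failure_targets_ptv_subscores(self, phantom, prescription):
        dose = np.zeros(np.prod(phantom.grid_shape))
        ptv_idx = np.flatnonzero(phantom.masks["ptv"].ravel())
        dose[ptv_idx] = 80.0
        n_cold = int(np.ceil(0.08 * ptv_idx.size))  # 8% below the minimum dose
        dose[ptv_idx[:n_cold]] = 70.0
        ev = evaluate_plan(dose, prescription, phantom, self._spec(prescription))
        assert not ev.ptv_satisfied
        assert ev.compensation_targets == [0, 1]

    def test_high_dose_oar_criterion_selected_first(self, phantom, prescription):
        dose = np.zeros(np.prod(phantom.grid_shape))
        dose[phantom.masks["ptv"].ravel()] = 80.0
        dose[phantom.masks["rectum"].ravel()] = 76.0  # violates every rectum criterion
        spec = self._spec(prescription)
        ev = evaluate_plan(dose, prescription, phantom, spec)
        assert ev.ptv_satisfied and not ev.all_satisfied
        (target,) = ev.compensation_targets
        c = spec.subscores[target].constraint
        assert c.structure == "rectum" and c.dose_gy == 75.0

    def test_strict_inequality_on_volume(self, phantom, prescription):
        # rectum V50 exactly at the bound is a violation (strict <)
        dose = np.zeros(np.prod(phantom.grid_shape))
        dose[phantom.masks["ptv"].ravel()] = 80.0
        r_idx = np.flatnonzero(phantom.masks["rectum"].ravel())
        dose[r_idx[: r_idx.size // 2]] = 55.0  # V50 = 50% exactly
        ev = evaluate_plan(dose, prescription, phantom, self._spec(prescription))
        row = next(c for c in ev.criteria if c["structure"] == "rectum" and c["dose_gy"] == 50.0)
        assert row["value_pct"] == 50.0 and not row["satisfied"]


class TestRunAutomatic:
    def test_early_exit_when_prescription_satisfied(self, dv_result, prescription):
        loop = af.LoopConfig()
        assert dv_result.acceptable
        assert dv_result.k_final == 1.0
        assert dv_result.history.n_solves == loop.inner_adjust_iters  # stage I only

    def test_solve_budget_invariant(self, dv_result, geud_result, ntcp_result):
        loop = af.LoopConfig()
        cap = loop.inner_adjust_iters * (1 + loop.max_compensation_iters)
        for res in (dv_result, geud_result, ntcp_result):
            assert res.history.n_solves <= cap

    def test_weights_normalized_every_update(self, dv_result):
        for rec in dv_result.history.records:
            w = rec["weights_updated"]
            assert abs(w.sum() - 1.0) < 1e-12
            assert ((w > 0) & (w < 1)).all()

    def test_reproducible(self, phantom, influence, prescription, dv_result):
        again = af.run_automatic(phantom, influence, prescription, model="dv")
        np.testing.assert_array_equal(again.plan.dose, dv_result.plan.dose)
        np.testing.assert_array_equal(again.weights, dv_result.weights)

    def test_impossible_prescription_exhausts_budget(self, phantom, influence, prescription):
        """An unachievable criterion drives compensation to N_max, then flags failure."""
        pres = prescription.model_copy(
            update={
                "evaluation_criteria": prescription.evaluation_criteria
                + [af.EvaluationCriterion(structure="rectum", dose_gy=1.0, volume_pct=0.5)]
            }
        )
        loop = af.LoopConfig()
        res = af.run_automatic(phantom, influence, pres, model="dv", loop=loop)
        assert not res.acceptable
        k0, step = MODEL_K_DEFAULTS["dv"]
        assert res.k_final == k0 + (loop.max_compensation_iters - 1) * step
        assert res.history.n_solves == loop.inner_adjust_iters * (
            1 + loop.max_compensation_iters
        )

    def test_compensation_k_applied_to_targets_only(self, phantom, influence, prescription):
        pres = prescription.model_copy(
            update={
                "evaluation_criteria": prescription.evaluation_criteria
                + [af.EvaluationCriterion(structure="rectum", dose_gy=1.0, volume_pct=0.5)]
            }
        )
        loop = af.LoopConfig(max_compensation_iters=2)
        res = af.run_automatic(phantom, influence, pres, model="dv", loop=loop)
        ks = sorted({rec["k"] for rec in res.history.records})
        assert ks == [1.0, 2.0]  # stage I, then k0=1 and k0+step=2
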