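import numpy as np
import pytest
from scipy import sparse
from scipy.stats import norm

import autofmo as af
from autofmo.objectives import (
    ObjectiveFunction,
    ObjectiveSpec,
    SubscoreSpec,
    grad_f_dvmax,
    grad_f_geud,
    grad_f_mean,
    grad_f_min,
    grad_f_ntcp,
)


class TestSubscoreValues:
    def test_f_min_hand_value(self):
        assert af.f_min(np.array([70.0, 80.0]), 74.0) == 8.0

    def test_f_min_satisfied_and_boundary(self):
        assert af.f_min(np.array([74.0, 80.0]), 74.0) == 0.0  # strict H: H(0) = 0
        assert af.f_min(np.array([80.0, 90.0]), 74.0) == 0.0

    def test_f_mean_hand_value(self):
        assert af.f_mean(np.array([76.0, 80.0]), 78.0) == 4.0

    def test_f_mean_shift_invariance(self, rng):
        d = rng.uniform(60, 90, 20)
        c = 7.3
        assert af.f_mean(d + c, 78.0 + c) == pytest.approx(af.f_mean(d, 78.0), rel=1e-12)

    def test_compute_d2_rank(self):
        d = np.array([40.0, 55.0, 60.0, 70.0])
        assert af.compute_d2(d, 25.0) == 70.0
        assert af.compute_d2(d, 100.0) == 40.0
        assert af.compute_d2(np.full(6, 55.0), 30.0) == 55.0

    def test_f_dvmax_hand_value(self):
        d = np.array([40.0, 55.0, 60.0, 70.0])
        # voxel at 70 = D2 excluded by the strict step
        assert af.f_dvmax(d, 50.0, 70.0) == pytest.approx(31.25)

    def test_f_dvmax_zero_when_satisfied(self):
        d = np.array([40.0, 55.0, 60.0, 70.0])
        assert af.f_dvmax(d, 75.0, af.compute_d2(d, 25.0)) == 0.0  # all below D1
        # V(D1) <= V1 already -> D2 <= D1 -> empty window
        d2 = af.compute_d2(d, 25.0)
        assert d2 <= 70.0 and af.f_dvmax(d, 70.0, d2) == 0.0

    def test_f_geud_linear_overshoot(self):
        d = np.full(4, 65.0)
        assert af.f_geud(d, 60.0, 2.0) == pytest.approx(5.0, rel=1e-12)
        assert af.f_geud(np.full(4, 58.0), 60.0, 2.0) == 0.0
        assert af.f_geud(np.full(4, 70.0), 60.0, 2.0) == pytest.approx(
            2 * af.f_geud(d, 60.0, 2.0), rel=1e-12
        )

    def test_f_ntcp_log_value(self):
        td50, m, n = 76.9, 0.13, 0.09
        d_at_10pct = td50 + norm.ppf(0.10) * m * td50
        score = af.f_ntcp(np.full(6, d_at_10pct), 0.05, td50, m, n)
        assert score == pytest.approx(np.log(0.95) - np.log(0.90), abs=1e-9)
        assert score == pytest.approx(0.054067, abs=1e-6)

    def test_f_ntcp_zero_when_met(self):
        td50, m, n = 76.9, 0.13, 0.09
        d_at_5pct = td50 + norm.ppf(0.05) * m * td50
        assert af.f_ntcp(np.full(6, d_at_5pct), 0.05, td50, m, n) == 0.0

    def test_f_ntcp_monotone_above_threshold(self):
        td50, m, n = 76.9, 0.13, 0.09
        scores = [af.f_ntcp(np.full(4, u), 0.05, td50, m, n) for u in (70, 74, 78)]
        assert scores[0] < scores[1] < scores[2]

    def test_total_objective(self):
        assert af.total_objective([8.0, 4.0], [0.5, 0.5]) == 6.0
        assert af.total_objective([0.0, 0.0], [0.3, 0.7]) == 0.0
        with pytest.raises(ValueError):
            af.total_objective([1.0], [0.5, 0.5])

    def test_normalize_weights(self):
        w = af.normalize_weights([2.0, 2.0, 4.0])
        np.testing.assert_allclose(w, [0.25, 0.25, 0.5])
        with pytest.raises(ValueError):
            af.normalize_weights([1.0, 0.0])


def _random_instance(seed, n_vox=24, n_beam=6):
    rng = np.random.default_rng(seed)
    A = sparse.csr_matrix(rng.uniform(0.2, 1.0, (n_vox, n_beam)))
    u = rng.uniform(1.5, 3.0, n_beam)
    mask = np.zeros(n_vox, dtype=bool)
    mask[: n_vox // 2] = True
    return A, u, {"s": mask}


def _fd_gradient(objfun, u, w, d2s, h_rel=1e-4):
    g = np.zeros_like(u)
    for j in range(u.size):
        h = h_rel * max(abs(u[j]), 1.0)
        up, um = u.copy(), u.copy()
        up[j] += h
        um[j] -= h
        fp, _ = objfun.value_and_grad_u(up, w, d2s)
        fm, _ = objfun.value_and_grad_u(um, w, d2s)
        g[j] = (fp - fm) / (2 * h)
    return g


class TestGradients:
    """Analytic gradients against a central finite-difference oracle."""

    @pytest.mark.parametrize(
        "ctype,kwargs",
        [
            ("min_dose", dict(limit_gy=18.0)),
            ("mean_dose", dict(limit_gy=15.0)),
            ("max_dose", dict(limit_gy=12.0)),
            ("dv_max", dict(dose_gy=10.0, volume_pct=30.0)),
            ("geud", dict(limit_gy=8.0, exponent_a=4.0)),
            ("ntcp", dict(probability=0.02, td50=30.0, m=0.15, n=0.25)),
        ],
    )
    def test_matches_finite_differences(self, ctype, kwargs):
        failures = 0
        for seed in range(20):
            A, u, masks = _random_instance(seed)
            c = af.Constraint(structure="s", type=ctype, **kwargs)
            spec = ObjectiveSpec(model="dv", subscores=[SubscoreSpec(c, "oar_sparing", 0)])
            objfun = ObjectiveFunction(spec, masks, A)
            w = np.array([1.0])
            dose0 = np.asarray(A @ (u**2)).ravel()
            d2s = objfun.refresh_d2(dose0)
            _, g = objfun.value_and_grad_u(u, w, d2s)
            g_fd = _fd_gradient(objfun, u, w, d2s)
            denom = max(np.linalg.norm(g_fd), 1e-12)
            if np.linalg.norm(g - g_fd) / denom >= 1e-5:
                failures += 1
        assert failures == 0

    def test_gradient_zero_at_zero_fluence(self):
        A, _, masks = _random_instance(0)
        c = af.Constraint(structure="s", type="mean_dose", limit_gy=15.0)
        spec = ObjectiveSpec(model="dv", subscores=[SubscoreSpec(c, "oar_sparing", 0)])
        objfun = ObjectiveFunction(spec, masks, A)
        _, g = objfun.value_and_grad_u(np.zeros(A.shape[1]), np.array([1.0]), {})
        np.testing.assert_array_equal(g, 0.0)

    def test_subgradients_zero_where_condition_met(self, rng):
        d = rng.uniform(60, 90, 10)
        np.testing.assert_array_equal(grad_f_min(d, 50.0), 0.0)
        np.testing.assert_array_equal(grad_f_dvmax(d, 95.0, af.compute_d2(d, 20.0)), 0.0)
        np.testing.assert_array_equal(grad_f_geud(d, 200.0, 2.0), 0.0)
        np.testing.assert_array_equal(
            grad_f_ntcp(d, 0.5, 500.0, 0.13, 0.09), 0.0
        )

    def test_f_mean_gradient_points_toward_target(self):
        d = np.array([70.0, 90.0])
        g = grad_f_mean(d, 80.0)
        assert g[0] < 0 < g[1]


class TestBuildObjectiveSpec:
    def test_dv_model_composition(self, prescription):
        spec = af.build_objective_spec(prescription.constraints, "dv")
        types = [s.constraint.type for s in spec.subscores]
        assert types[:2] == ["min_dose", "mean_dose"]
        assert all(t == "dv_max" for t in types[2:])
        assert len({s.index for s in spec.subscores}) == len(spec)

    def test_geud_and_ntcp_models(self, prescription):
        for model, t in (("geud", "geud"), ("ntcp", "ntcp")):
            spec = af.build_objective_spec(prescription.constraints, model)
            assert [s.constraint.type for s in spec.subscores[2:]] == [t, t]

    def test_missing_ptv_constraints_rejected(self):
        c = [af.Constraint(structure="r", type="dv_max", dose_gy=50.0, volume_pct=40.0)]
        with pytest.raises(ValueError):
            af.build_objective_spec(c, "dv")


class TestWeightRescalingInvariance:
    def test_same_argmin_after_rescale(self, phantom, influence, prescription):
        """Scaling all importance factors then renormalizing leaves the optimum unchanged."""
        spec = af.build_objective_spec(prescription.constraints, "dv")
        objfun = ObjectiveFunction(spec, phantom.masks, influence.entries)
        x0 = af.initial_fluence(influence, phantom.masks["ptv"], 78.0)
        w = af.uniform_weights(len(spec))
        p1 = af.solve_fmo(influence, objfun, w, x0)
        p2 = af.solve_fmo(influence, objfun, af.normalize_weights(7.0 * w), x0)
        np.testing.assert_allclose(p1.dose, p2.dose, rtol=1e-10, atol=1e-10)
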