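"""Phase-plane analysis: nullclines, fixed points, stability, regimes."""

import numpy as np
import pytest

from lddm import (
    CircuitState,
    GainMatrix,
    ModelParams,
    attractor_type,
    classify_regime,
    find_equilibria,
    jacobian,
    lddm_derivatives,
    nullcline,
    persistent_equilibria,
    regime_map,
)
from lddm.dynamics import integrate
from lddm.equilibria import _Proto, _Stage


def closed_form_equilibria(V, alpha, beta, B_R=0.0, B_G=0.0):
    """Independent oracle for the two-option circuit with omega = 1.

    Symmetric root: (2 - beta) r^2 + (1 + B_G - alpha) r - (V + B_R) = 0.
    Asymmetric pair (beta > 0): coordinates are the positive roots of
    (beta - 1) x^2 - (1 + B_G - alpha) x + (V + B_R)(beta - 1)/beta = 0,
    which satisfy R1 R2 = (V + B_R) / beta.
    """
    VB = V + B_R
    c0 = 1.0 + B_G - alpha
    pts = []
    roots = np.roots([2.0 - beta, c0, -VB])
    for r in roots:
        if abs(r.imag) < 1e-12 and r.real > 0:
            pts.append((r.real, r.real))
    if beta > 0 and abs(beta - 1.0) > 1e-12:
        roots = np.roots([beta - 1.0, -c0, VB * (beta - 1.0) / beta])
        real = [r.real for r in roots if abs(r.imag) < 1e-12 and r.real > 0]
        if len(real) == 2 and abs(real[0] - real[1]) > 1e-9:
            a, b = sorted(real)
            pts.append((a, b))
            pts.append((b, a))
    # dedupe (asymmetric pair can collapse onto the symmetric root)
    out = []
    for p in pts:
        if not any(np.hypot(p[0] - q[0], p[1] - q[1]) < 1e-6 for q in out):
            out.append(p)
    return sorted(out)


class TestNullcline:
    def test_minimum_matches_calculus_oracle(self, omega2):
        # min over R1 of V/R1 + (beta-1)R1 + (alpha-1) at alpha=15, beta=2.5:
        # 2 sqrt(250 * 1.5) + 14
        p = ModelParams(alpha=15.0, beta=2.5)
        grid = np.geomspace(0.5, 200.0, 40000)
        curve = nullcline(0, grid, [250.0, 250.0], p, omega2)
        assert curve.min() == pytest.approx(2.0 * np.sqrt(375.0) + 14.0, rel=1e-6)

    def test_beta_equal_omega_reduces_to_shifted_hyperbola(self, omega2):
        p = ModelParams(alpha=3.0, beta=1.0, B_R=5.0, B_G=2.0)
        grid = np.geomspace(0.1, 50.0, 100)
        curve = nullcline(0, grid, [100.0, 100.0], p, omega2, beta_now=1.0)
        expected = (100.0 + 5.0) / grid - (1.0 + 2.0 - 3.0)
        np.testing.assert_allclose(curve, expected, rtol=1e-12)

    def test_rejects_singular_grid(self, wta_params, omega2):
        with pytest.raises(ValueError):
            nullcline(0, [0.0, 1.0], [250.0, 250.0], wta_params, omega2)


class TestFindEquilibria:
    def test_gated_circuit_has_three_equilibria(self, wta_params, omega2):
        eqs = find_equilibria([250.0, 250.0], wta_params, omega2, beta_now=0.9)
        assert len(eqs) == 3
        Rs = sorted(p.R[0] for p in eqs.points)
        assert Rs[0] == pytest.approx(2.015, abs=5e-3)
        assert Rs[1] == pytest.approx(250.0 / 11.0, rel=1e-9)
        assert Rs[2] == pytest.approx(137.98, abs=5e-2)
        assert eqs.diagnostic == (3, 2, 1)

    def test_silent_gate_single_stable_point(self, wta_params, omega2):
        eqs = find_equilibria([250.0, 250.0], wta_params, omega2, beta_now=0.0)
        assert eqs.diagnostic == (1, 1, 0)

    def test_strong_gate_no_intersections(self, wta_params, omega2):
        eqs = find_equilibria([250.0, 250.0], wta_params, omega2, beta_now=2.5,
                              search_box=(1e-3, 1e4))
        assert len(eqs) == 0

    def test_residuals_below_tolerance(self, wta_params, omega2):
        eqs = find_equilibria([250.0, 250.0], wta_params, omega2, beta_now=0.9)
        for pt in eqs.points:
            d = lddm_derivatives(
                CircuitState(pt.R, pt.G, pt.D), [250.0, 250.0], wta_params,
                omega2, beta_now=0.9,
            )
            for arr in (d.R, d.G, d.D):
                assert np.abs(arr).max() < 1e-8

    def test_matches_closed_form_oracle_on_random_draws(self, omega2, rng):
        n_checked = 0
        for _ in range(200):
            alpha = rng.uniform(0.0, 30.0)
            beta = rng.uniform(0.0, 3.0)
            V = rng.uniform(50.0, 400.0)
            expected = closed_form_equilibria(V, alpha, beta)
            if any(max(p) > 5e3 or min(p) < 5e-3 for p in expected):
                continue  # outside the numeric search box
            p = ModelParams(alpha=alpha, beta=beta)
            eqs = find_equilibria([V, V], p, omega2, beta_now=beta,
                                  search_box=(1e-3, 1e4))
            found = sorted((pt.R[0], pt.R[1]) for pt in eqs.points)
            assert len(found) == len(expected), (alpha, beta, V)
            for f, e in zip(found, expected):
                np.testing.assert_allclose(f, e, rtol=1e-6, atol=1e-6)
            n_checked += 1
        assert n_checked > 150


class TestJacobian:
    def test_agrees_with_finite_differences(self, wta_params, omega2):
        V = np.array([260.0, 240.0])
        R = np.array([30.0, 12.0])
        p = wta_params
        J = jacobian(R, V, p, omega2, beta_now=0.9)

        def F(x):
            s = CircuitState(x[[0, 3]], x[[1, 4]], x[[2, 5]])
            d = lddm_derivatives(s, V, p, omega2, beta_now=0.9)
            return np.array([d.R[0], d.G[0], d.D[0], d.R[1], d.G[1], d.D[1]])

        G = omega2.matrix @ R + p.B_G - 0.9 * R
        x0 = np.array([R[0], G[0], 0.9 * R[0], R[1], G[1], 0.9 * R[1]])
        h = 1e-6
        J_num = np.empty((6, 6))
        for j in range(6):
            e = np.zeros(6)
            e[j] = h
            J_num[:, j] = (F(x0 + e) - F(x0 - e)) / (2 * h)
        np.testing.assert_allclose(J, J_num, rtol=1e-5, atol=1e-5)

    def test_stable_at_value_coding_point(self, value_params, omega2):
        eqs = find_equilibria([250.0, 250.0], value_params, omega2, beta_now=0.0)
        assert len(eqs) == 1
        assert eqs.points[0].stability == "stable"

    def test_requires_positive_rates(self, wta_params, omega2):
        with pytest.raises(ValueError):
            jacobian([0.0, 10.0], [250.0, 250.0], wta_params, omega2)


class TestRegimes:
    @pytest.mark.parametrize(
        "alpha,beta,territory,function",
        [
            (15.0, 0.9, "blue", "WTA"),
            (5.0, 0.0, "dark_green", "normalization"),
            (15.0, 2.5, "red", "WTA"),
            (0.5, 1.01, "green", "normalization"),
            (0.0, 1.434, "yellow", "WTA"),
            (15.0, 1.1, "yellow", "WTA"),
        ],
    )
    def test_territory_classification(self, alpha, beta, territory, function,
                                      omega2):
        lab = classify_regime(alpha, beta, ModelParams(sigma=0.0), omega2,
                              [250.0, 250.0])
        assert lab.territory == territory
        assert lab.function == function

    def test_beta_sweep_crosses_blue_yellow_red_in_order(self, omega2):
        p = ModelParams(sigma=0.0)
        seen = []
        for beta in np.arange(0.1, 2.55, 0.05):
            lab = classify_regime(15.0, float(beta), p, omega2, [250.0, 250.0])
            if not seen or seen[-1] != lab.territory:
                seen.append(lab.territory)
        assert seen == ["dark_green", "blue", "yellow", "red"]

    def test_wta_requires_positive_beta(self, omega2):
        # at beta = 0 the circuit never selects, for any recurrence strength
        p = ModelParams(sigma=0.0)
        for alpha in (0.0, 5.0, 15.0, 30.0):
            lab = classify_regime(alpha, 0.0, p, omega2, [250.0, 250.0])
            assert lab.function == "normalization"

    def test_refined_map_contains_all_five_territories(self, omega2):
        p = ModelParams(sigma=0.0)
        df = regime_map(
            [0.5, 5.0, 15.0, 25.0],
            [0.0, 0.8, 0.9, 1.01, 1.3, 2.5],
            p, omega2, [250.0, 250.0],
        )
        assert set(df["territory"]) == {
            "dark_green", "blue", "green", "yellow", "red"
        }


class TestPersistentActivity:
    def test_line_attractor_constant_sum(self, omega2):
        pa = persistent_equilibria(ModelParams(alpha=15.0, B_G=0.0), omega2,
                                   beta_now=0.0)
        assert pa.kind == "line"
        assert pa.sum_level == pytest.approx(14.0)

    def test_no_elevated_activity_below_threshold_recurrence(self, omega2):
        pa = persistent_equilibria(ModelParams(alpha=1.0), omega2, beta_now=0.0)
        assert pa.kind == "none"

    def test_per_unit_share_scales_inversely_with_set_size(self):
        levels = {}
        for n in (2, 5):
            om = GainMatrix(n)
            pa = persistent_equilibria(ModelParams(alpha=15.0), om, beta_now=0.0)
            levels[n] = pa.sum_level / n
        assert levels[5] == pytest.approx(levels[2] * 2 / 5)
        assert persistent_equilibria(
            ModelParams(alpha=15.0), GainMatrix(5), beta_now=0.0
        ).sum_level == pytest.approx(14.0)

    def test_gated_winner_level(self, omega2):
        pa = persistent_equilibria(ModelParams(alpha=15.0, beta=0.4), omega2,
                                   beta_now=0.4)
        assert pa.kind == "corner"
        assert pa.winner_level == pytest.approx(14.0 / 0.6)

    def test_degenerate_gain_matrix_rejected(self):
        om = GainMatrix(2, w=0.0, v=0.0)
        with pytest.raises(ValueError):
            persistent_equilibria(ModelParams(alpha=15.0), om, beta_now=0.0)


class TestAttractorProbes:
    def test_silent_gate_line_attractor(self, omega2):
        p = ModelParams(alpha=15.0, beta=0.4, sigma=0.0)
        assert attractor_type(p, omega2, beta_now=0.0) == "line"

    def test_gated_corner_wta(self, omega2):
        p = ModelParams(alpha=15.0, beta=0.4, sigma=0.0)
        assert attractor_type(p, omega2, beta_now=0.4) == "corner"

    def test_weak_lateral_weights_point_attractor(self):
        p = ModelParams(alpha=10.0, beta=0.0, sigma=0.0)
        om = GainMatrix(2, w=1.0, v=0.7)
        assert attractor_type(p, om, beta_now=0.0) == "point"

    def test_line_attractor_preserves_ratio_and_sum(self, omega2):
        # withdraw inputs from the value-coding equilibrium; the persistent
        # state keeps sum R = (alpha - 1 - B_G) / omega and the input ratio
        p = ModelParams(alpha=15.0, beta=0.0, sigma=0.0)
        eqs = find_equilibria([300.0, 150.0], p, omega2, beta_now=0.0)
        pt = eqs.points[0]
        st_ = CircuitState(pt.R, pt.G, pt.D)
        proto = _Proto([_Stage(10.0, np.zeros(2), False)])
        traj = integrate(lddm_derivatives, st_, proto, p, omega2, dt=0.001)
        end = traj.R[-1]
        assert abs(end.sum() - 14.0) / 14.0 < 1e-3
        ratio0 = pt.R[0] / pt.R[1]
        assert abs(end[0] / end[1] - ratio0) / ratio0 < 1e-3
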