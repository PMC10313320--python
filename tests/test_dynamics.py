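"""Unit tests for the circuit ODE systems and the RK4/OU integrator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lddm import (
    CircuitState,
    GainMatrix,
    LCAParams,
    ModelParams,
    MotifFlags,
    RNMParams,
    dnm_derivatives,
    integrate,
    lca_derivatives,
    lddm_derivatives,
    motif_derivatives,
    ou_noise_step,
    rnm_derivatives,
    rnm_transfer,
)
from lddm.equilibria import jacobian
from lddm.tasks import make_protocol


def equal_input_protocol(S, duration, n=2, coherence=0.0):
    return make_protocol("representation", S=S, coherence=coherence,
                         duration=duration, n_options=n)


class TestLDDMDerivatives:
    def test_origin_is_equilibrium_without_inputs(self, omega2):
        p = ModelParams(alpha=15.0, beta=1.0, B_R=0.0, B_G=0.0)
        d = lddm_derivatives(CircuitState.zeros(2), [0.0, 0.0], p, omega2)
        for arr in (d.R, d.G, d.D):
            assert np.all(arr == 0.0)

    def test_symmetric_fixed_point_matches_quadratic_reduction(self, omega2):
        # with alpha=15, beta=0, B=0, V=250 the symmetric rate solves
        # 2 r^2 - 14 r - 250 = 0, i.e. r = (14 + sqrt(2196)) / 4
        r = (14.0 + np.sqrt(2196.0)) / 4.0
        p = ModelParams(alpha=15.0, beta=0.0)
        st_ = CircuitState([r, r], [2 * r, 2 * r], [0.0, 0.0])
        d = lddm_derivatives(st_, [250.0, 250.0], p, omega2, beta_now=0.0)
        assert np.abs(d.R).max() < 1e-6
        assert np.abs(d.G).max() < 1e-6
        assert np.abs(d.D).max() < 1e-6

    def test_gated_symmetric_point_is_unstable(self, wta_params, omega2):
        # under active disinhibition the equal-input fixed point repels
        # along the R1 - R2 difference direction
        r = 250.0 / 11.0
        R = np.array([r, r])
        J = jacobian(R, [250.0, 250.0], wta_params, omega2, beta_now=0.9)
        assert np.max(np.linalg.eigvals(J).real) > 0

    def test_dimension_and_sign_validation(self, wta_params, omega2):
        with pytest.raises(ValueError):
            lddm_derivatives(CircuitState.zeros(2), [1.0, 1.0, 1.0],
                             wta_params, omega2)
        with pytest.raises(ValueError):
            lddm_derivatives(CircuitState.zeros(2), [-1.0, 1.0],
                             wta_params, omega2)


class TestMotifModel:
    def test_all_loops_off_recovers_dnm(self, omega2, rng):
        p = ModelParams(alpha=0.0, beta=0.0, B_R=30.0, B_G=0.0)
        flags = MotifFlags(False, False, False, False)
        for _ in range(20):
            R, G, D = rng.uniform(0, 50, (3, 2))
            sm = CircuitState(R, G, D, np.zeros(2), np.zeros(2))
            sd = CircuitState(R, G, D)
            dm = motif_derivatives(sm, [100.0, 80.0], p, omega2, flags)
            dd = dnm_derivatives(sd, [100.0, 80.0], p, omega2)
            np.testing.assert_allclose(dm.R, dd.R, atol=1e-12)
            np.testing.assert_allclose(dm.G, dd.G, atol=1e-12)

    def test_sixteen_distinct_variants(self):
        combos = MotifFlags.enumerate()
        assert len(combos) == 16
        keys = {
            (f.use_self_excitation, f.use_local_disinhibition,
             f.use_cross_inhibition, f.use_lateral_boost)
            for f in combos
        }
        assert len(keys) == 16

    def test_alpha_beta_loops_reduce_to_lddm(self, omega2, rng):
        p = ModelParams(alpha=12.0, beta=1.3, B_R=10.0, B_G=5.0)
        flags = MotifFlags(True, True, False, False)
        for _ in range(100):
            R, G, D = rng.uniform(0, 80, (3, 2))
            sm = CircuitState(R, G, D, np.zeros(2), np.zeros(2))
            dm = motif_derivatives(sm, [150.0, 90.0], p, omega2, flags)
            dl = lddm_derivatives(CircuitState(R, G, D), [150.0, 90.0], p, omega2)
            np.testing.assert_allclose(dm.R, dl.R, atol=1e-12)
            np.testing.assert_allclose(dm.G, dl.G, atol=1e-12)
            np.testing.assert_allclose(dm.D, dl.D, atol=1e-12)


class TestDNM:
    def test_fixed_point_zeroes_derivatives(self, omega2):
        # R_i = V_i / (1 + sum R_j): sum solves s^2 + s - (V1 + V2) = 0
        V = np.array([120.0, 60.0])
        s = 0.5 * (-1.0 + np.sqrt(1.0 + 4.0 * V.sum()))
        R = V / (1.0 + s)
        p = ModelParams(alpha=0.0, beta=0.0, B_R=0.0)
        st_ = CircuitState(R, np.full(2, s), np.zeros(2))
        d = dnm_derivatives(st_, V, p, omega2)
        assert np.abs(d.R).max() < 1e-10
        assert np.abs(d.G).max() < 1e-10

    def test_decays_to_origin_without_input(self, omega2):
        p = ModelParams(alpha=0.0, beta=0.0, B_R=0.0, sigma=0.0)
        proto = equal_input_protocol(0.0, 2.0)
        st_ = CircuitState([40.0, 10.0], [20.0, 20.0], [0.0, 0.0])
        traj = integrate(dnm_derivatives, st_, proto, p, omega2)
        assert traj.R[-1].max() < 1e-3
        assert traj.G[-1].max() < 1e-3


class TestRNM:
    def test_transfer_function_removable_singularity(self):
        p = RNMParams()
        assert rnm_transfer(p.b / p.a, p) == pytest.approx(1.0 / p.d)
        # continuity around the singular point
        eps = 1e-7
        assert rnm_transfer(p.b / p.a + eps, p) == pytest.approx(1.0 / p.d, rel=1e-4)

    def test_gating_decay_without_drive(self):
        p = RNMParams(JN_same=0.0, JN_diff=0.0, I0=0.0, mu0=0.0)
        S = np.array([0.5, 0.3])
        dt = 1e-4
        for _ in range(int(0.1 / dt)):
            dS, _ = rnm_derivatives(S, [0.0, 0.0], p)
            S = S + dt * dS
        # H(0) is ~1e-5 Hz, so decay is essentially exponential with tau_S
        np.testing.assert_allclose(
            S, np.array([0.5, 0.3]) * np.exp(-0.1 / p.tau_S), rtol=1e-2
        )

    def test_wta_sign_pattern_with_unequal_inputs(self):
        p = RNMParams(sigma_noise=0.0)
        S = np.array([0.1, 0.1])
        dt = 1e-3
        inputs = np.array([p.mu0 * 1.512, p.mu0 * 0.488])
        rates = []
        for _ in range(2000):
            dS, H = rnm_derivatives(S, inputs, p)
            S = np.clip(S + dt * dS, 0.0, 1.0)
            rates.append(H)
        r = np.array(rates)
        assert r[-1, 0] > 20.0          # winner ramps to high rate
        assert r[-1, 1] < r[200, 1]     # loser is suppressed below its start


class TestLCA:
    def test_leaky_integrator_fixed_point(self):
        p = LCAParams(k=1.0, beta_inh=0.0, sigma=0.0, threshold=10.0)
        x = np.zeros(2)
        dt = 1e-3
        for _ in range(20000):
            x = np.maximum(x + dt * lca_derivatives(x, [1.0, 1.0], p), 0.0)
        np.testing.assert_allclose(x, [1.0, 1.0], atol=1e-6)

    def test_symmetry_preserved_without_noise(self):
        p = LCAParams(sigma=0.0)
        x = np.zeros(2)
        dt = 1e-3
        for _ in range(3000):
            x = np.maximum(x + dt * lca_derivatives(x, [1.0, 1.0], p), 0.0)
            assert x[0] == x[1]

    def test_stronger_input_crosses_first(self):
        p = LCAParams(k=1.0, beta_inh=2.0, sigma=0.0, threshold=0.6)
        x = np.zeros(2)
        dt = 1e-3
        crossed = None
        for _ in range(20000):
            x = np.maximum(x + dt * lca_derivatives(x, [1.512, 0.488], p), 0.0)
            if x.max() >= p.threshold:
                crossed = int(np.argmax(x))
                break
        assert crossed == 0


class TestOUNoise:
    def test_deterministic_decay_when_silent(self, rng):
        n = np.array([3.0, -2.0])
        out = ou_noise_step(n, 1e-4, 0.0, 2e-3, rng)
        np.testing.assert_allclose(out, n * (1.0 - 1e-4 / 2e-3))

    def test_zero_mean_and_stationary_sd(self, rng):
        # stationary SD of the discretized process approaches sigma/sqrt(2)
        sigma, tau, dt = 4.0, 2e-3, 1e-4
        n = np.zeros(5000)
        samples = []
        for i in range(3000):
            n = ou_noise_step(n, dt, sigma, tau, rng)
            if i > 500:
                samples.append(n.copy())
        flat = np.concatenate(samples)
        assert abs(flat.mean()) < 3.0 * flat.std() / np.sqrt(5000)
        assert abs(flat.std() - sigma / np.sqrt(2)) / (sigma / np.sqrt(2)) < 0.05


class TestIntegrate:
    def test_remains_at_attracting_fixed_point(self, omega2):
        r = (14.0 + np.sqrt(196.0 + 8.0 * 320.0)) / 4.0  # fig-3 preset root
        p = ModelParams(alpha=15.0, beta=0.0, B_R=70.0, sigma=0.0)
        st_ = CircuitState([r, r], [2 * r, 2 * r], [0.0, 0.0])
        traj = integrate(lddm_derivatives, st_, equal_input_protocol(250.0, 1.0),
                         p, omega2)
        assert np.abs(traj.R - r).max() < 1e-6

    def test_rk4_step_halving_converged(self, value_params, omega2):
        proto = equal_input_protocol(250.0, 1.0)
        ends = []
        for dt in (1e-3, 5e-4):
            traj = integrate(lddm_derivatives, CircuitState.zeros(2), proto,
                             value_params, omega2, dt=dt)
            ends.append(traj.R[-1])
        assert np.abs(ends[0] - ends[1]).max() < 1e-6

    def test_rk4_fourth_order_error_scaling(self, value_params, omega2):
        proto = equal_input_protocol(250.0, 0.2)
        ref = integrate(lddm_derivatives, CircuitState.zeros(2), proto,
                        value_params, omega2, dt=1e-4).R[-1]
        errs = []
        for dt in (4e-3, 2e-3):
            end = integrate(lddm_derivatives, CircuitState.zeros(2), proto,
                            value_params, omega2, dt=dt).R[-1]
            errs.append(np.abs(end - ref).max())
        ratio = errs[0] / errs[1]
        assert 8.0 < ratio < 40.0  # ~2^4 with slack for the clamp step

    def test_transient_peak_then_sustained_plateau(self, value_params, omega2):
        # stimulus onset produces a phasic peak that relaxes to a lower
        # sustained level of normalized value coding
        traj = integrate(lddm_derivatives, CircuitState.zeros(2),
                         equal_input_protocol(250.0, 2.0), value_params, omega2)
        peak = traj.R[:, 0].max()
        plateau = traj.R[-1, 0]
        assert peak > 1.3 * plateau
        assert traj.R[:, 0].argmax() < len(traj.t) // 4

    def test_bit_identical_given_seed(self, omega2):
        p = ModelParams(alpha=15.0, beta=0.0, B_R=70.0, sigma=5.0)
        proto = equal_input_protocol(250.0, 0.5)
        a = integrate(lddm_derivatives, CircuitState.zeros(2), proto, p,
                      omega2, seed=11)
        b = integrate(lddm_derivatives, CircuitState.zeros(2), proto, p,
                      omega2, seed=11)
        assert np.array_equal(a.R, b.R)
        assert np.array_equal(a.G, b.G)

    @given(
        alpha=st.floats(0.0, 20.0),
        beta=st.floats(0.0, 2.5),
        sigma=st.floats(0.0, 30.0),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_activities_never_negative(self, alpha, beta, sigma, seed):
        p = ModelParams(alpha=alpha, beta=beta, sigma=sigma)
        proto = make_protocol("rt_motion", S=250.0, coherence=0.128, cutoff=0.2)
        st_ = CircuitState([32.0, 32.0], [0.0, 0.0], [0.0, 0.0])
        traj = integrate(lddm_derivatives, st_, proto, p, GainMatrix(2),
                         seed=seed,
                         stop_when=lambda s: np.max(s.R) > 1e4)
        assert traj.R.min() >= 0.0
        assert traj.G.min() >= 0.0
        assert traj.D.min() >= 0.0
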