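"""Circuit ODE systems and their numerical integration.

All models are firing-rate equations integrated with a fixed-step
Runge-Kutta 4 scheme (default step 1 ms) on the deterministic part;
Ornstein-Uhlenbeck noise terms, one per unit, are advanced each step and
added in an Euler fashion.  Activities are clamped non-negative after each
full step, reflecting the constraint that spike rates cannot be negative.

LDDM (per option i):

    tau_R dR_i/dt = -R_i + (V_i + alpha R_i + B_R) / (1 + G_i)
    tau_G dG_i/dt = -G_i + sum_j omega_ij R_j + B_G - D_i
    tau_D dD_i/dt = -D_i + beta R_i

The DNM is the special case alpha = beta = B_G = 0 with the D units removed;
the generalized motif model adds optional cross-inhibition (I units) and
lateral gain-boost (E units) loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import (
    CircuitState,
    GainMatrix,
    LCAParams,
    ModelParams,
    MotifFlags,
    RNMParams,
)

__all__ = [
    "lddm_derivatives",
    "dnm_derivatives",
    "motif_derivatives",
    "rnm_transfer",
    "rnm_derivatives",
    "lca_derivatives",
    "ou_noise_step",
    "integrate",
    "Trajectory",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""

    def __init__(self, step: int, t: float):
        self.step = step
        self.t = t
        super().__init__(f"non-finite state at step {step} (t = {t:.4f} s)")


def _check_inputs(state: CircuitState, V, omega: GainMatrix):
    V = np.atleast_1d(np.asarray(V, dtype=float))
    n = state.n_options
    if V.shape[0] != n:
        raise ValueError(f"V has length {V.shape[0]}, expected {n}")
    if np.any(V < 0):
        raise ValueError("value inputs V must be non-negative")
    if omega.matrix.shape != (n, n):
        raise ValueError("omega dimension does not match the state")
    return V


def lddm_derivatives(
    state: CircuitState,
    V,
    params: ModelParams,
    omega: GainMatrix,
    beta_now: float | None = None,
) -> CircuitState:
    """Time derivatives of the LDDM at ``state``.

    ``beta_now`` is the effective disinhibition weight at this instant
    (``params.beta`` while the gate is on, 0 while it is off); it defaults
    to ``params.beta``.
    """
    V = _check_inputs(state, V, omega)
    b = params.beta if beta_now is None else float(beta_now)
    R, G, D = state.R, state.G, state.D
    dR = (-R + (V + params.alpha * R + params.B_R) / (1.0 + G)) / params.tau_R
    dG = (-G + omega.matrix @ R + params.B_G - D) / params.tau_G
    dD = (-D + b * R) / params.tau_D
    return CircuitState(dR, dG, dD)


def dnm_derivatives(
    state: CircuitState,
    V,
    params: ModelParams,
    omega: GainMatrix,
    beta_now: float | None = None,
) -> CircuitState:
    """Dynamic normalization model: no self-excitation, no disinhibition.

    The D units are carried along with zero drive so that DNM and LDDM
    trajectories are directly comparable.
    """
    V = _check_inputs(state, V, omega)
    R, G, D = state.R, state.G, state.D
    dR = (-R + (V + params.B_R) / (1.0 + G)) / params.tau_R
    dG = (-G + omega.matrix @ R) / params.tau_G
    dD = -D / params.tau_D
    return CircuitState(dR, dG, dD)


def motif_derivatives(
    state: CircuitState,
    V,
    params: ModelParams,
    omega: GainMatrix,
    flags: MotifFlags,
    beta_now: float | None = None,
    tau_I: float | None = None,
    tau_E: float | None = None,
) -> CircuitState:
    """Generalized motif model with four optional competition loops.

    With only the self-excitation and local-disinhibition loops active this
    reduces exactly to :func:`lddm_derivatives`; with all loops off and
    alpha = beta = 0 it reduces to the DNM.  The I (cross-inhibition) and E
    (lateral boost) interneurons default to the G-unit time constant.
    """
    V = _check_inputs(state, V, omega)
    R, G, D = state.R, state.G, state.D
    I = state.I if state.I is not None else np.zeros_like(R)
    E = state.E if state.E is not None else np.zeros_like(R)
    tau_I = params.tau_G if tau_I is None else tau_I
    tau_E = params.tau_G if tau_E is None else tau_E

    alpha = params.alpha if flags.use_self_excitation else 0.0
    beta = (params.beta if beta_now is None else float(beta_now))
    beta = beta if flags.use_local_disinhibition else 0.0
    eta = flags.eta if flags.use_cross_inhibition else 0.0
    gam = flags.gamma_lat if flags.use_lateral_boost else 0.0

    # loop terms are fully disconnected (not just undriven) when a flag is off
    lateral_I = (I.sum() - I) if flags.use_cross_inhibition else 0.0
    lateral_R = R.sum() - R
    D_term = D if flags.use_local_disinhibition else 0.0
    E_term = E if flags.use_lateral_boost else 0.0
    dR = (-R + (V + alpha * R + params.B_R - lateral_I) / (1.0 + G)) / params.tau_R
    dG = (-G + omega.matrix @ R + params.B_G + E_term - D_term) / params.tau_G
    dD = (-D + beta * R) / params.tau_D
    dI = (-I + eta * R) / tau_I
    dE = (-E + gam * lateral_R) / tau_E
    return CircuitState(dR, dG, dD, dI, dE)


def rnm_transfer(x, params: RNMParams):
    """Single-cell input-output function H(x) of the reduced RNM.

    H(x) = (a x - b) / (1 - exp(-d (a x - b))), with the removable
    singularity at a x = b filled by its limit 1/d.
    """
    x = np.asarray(x, dtype=float)
    u = params.a * x - params.b
    out = np.empty_like(u)
    small = np.abs(u) < 1e-9
    with np.errstate(over="ignore"):
        denom = 1.0 - np.exp(-params.d * u)
    out = np.where(small, 1.0 / params.d, u / np.where(small, 1.0, denom))
    return out


def rnm_derivatives(S, inputs, params: RNMParams, I_noise=0.0):
    """Reduced RNM: two NMDA gating variables S with WTA coupling.

    ``inputs`` are the stimulus currents to the two populations
    (``mu0 * (1 +/- c')``); returns (dS, rates).
    """
    S = np.asarray(S, dtype=float)
    inputs = np.asarray(inputs, dtype=float)
    if S.shape != inputs.shape:
        raise ValueError("S and inputs must have equal shape")
    J = np.full((S.shape[0], S.shape[0]), -params.JN_diff)
    np.fill_diagonal(J, params.JN_same)
    x = J @ S + params.I0 + inputs + I_noise
    H = rnm_transfer(x, params)
    dS = -S / params.tau_S + (1.0 - S) * params.gamma_kin * H
    return dS, H


def lca_derivatives(x, rho, params: LCAParams):
    """Leaky competing accumulator drift (deterministic part).

    dx_i/dt = (rho_i - k x_i - beta_inh * sum_{j != i} x_j) / tau
    """
    x = np.asarray(x, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if x.shape != rho.shape:
        raise ValueError("x and rho must have equal shape")
    lateral = x.sum() - x
    return (rho - params.k * x - params.beta_inh * lateral) / params.tau


def ou_noise_step(noise, dt: float, sigma: float, tau_noise: float, rng):
    """One step of the Ornstein-Uhlenbeck noise process.

    n <- n (1 - dt/tau) + sigma sqrt(dt/tau) N(0, 1)

    which discretizes tau dn/dt = -n + sqrt(tau sigma^2) xi(t) with xi white;
    the stationary standard deviation is sigma / sqrt(2).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    noise = np.asarray(noise, dtype=float)
    k = dt / tau_noise
    if sigma == 0.0:
        return noise * (1.0 - k)
    return noise * (1.0 - k) + sigma * np.sqrt(k) * rng.standard_normal(noise.shape)


@dataclass
class Trajectory:
    """Recorded time course of a simulation.

    ``t`` is the time grid (seconds); unit activities are (T, N) arrays.
    ``events`` maps labels (stage names, "threshold_crossing") to times.
    """

    t: np.ndarray
    R: np.ndarray
    G: np.ndarray
    D: np.ndarray
    I: np.ndarray | None = None
    E: np.ndarray | None = None
    dt: float = 0.001
    events: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not (len(self.t) == len(self.R) == len(self.G) == len(self.D)):
            raise ValueError("inconsistent array lengths")

    @property
    def n_options(self) -> int:
        return self.R.shape[1]

    def index_at(self, t: float) -> int:
        return int(round((t - self.t[0]) / self.dt))

    def to_frame(self):
        """Trajectory as a tidy DataFrame (t, R1..RN, G1..GN, D1..DN)."""
        import pandas as pd

        n = self.n_options
        data = {"t": self.t}
        for name, arr in (("R", self.R), ("G", self.G), ("D", self.D)):
            for i in range(n):
                data[f"{name}{i + 1}"] = arr[:, i]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def integrate(
    deriv_fn,
    initial: CircuitState,
    protocol,
    params: ModelParams,
    omega: GainMatrix,
    dt: float = 0.001,
    seed: int | None = None,
    noise_placement: str = "units",
    stop_when=None,
    stop_after: float = 0.0,
    **deriv_kwargs,
) -> Trajectory:
    """Integrate a circuit over the stages of a stimulus protocol.

    ``protocol`` must provide ``stages``: an ordered list of objects with
    ``duration`` (s), ``V`` (input vector) and ``beta_on`` (bool).  The
    deterministic part is advanced by classical RK4; each unit carries an
    independent OU noise term added as an Euler increment, and all
    activities are clamped at zero after each full step.  With a fixed
    ``seed`` the trajectory is bit-reproducible.

    ``stop_when(state)`` may end the run early (evaluated after each step
    once ``t >= stop_after``); ``noise_placement`` is "units" (default,
    noise in each rate equation) or "input" (noise added to the value
    inputs of the R units).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if noise_placement not in ("units", "input"):
        raise ValueError("noise_placement must be 'units' or 'input'")
    rng = np.random.default_rng(seed)
    state = initial.copy()
    has_ie = state.I is not None

    names = ["R", "G", "D"] + (["I", "E"] if has_ie else [])
    taus = {
        "R": params.tau_R,
        "G": params.tau_G,
        "D": params.tau_D,
        "I": params.tau_G,
        "E": params.tau_G,
    }
    noise = {k: np.zeros_like(state.R) for k in ("R", "G", "D")}
    noise_V = np.zeros_like(state.R)

    n_steps_total = sum(int(round(st.duration / dt)) for st in protocol.stages)
    rec = {k: np.empty((n_steps_total + 1, state.n_options)) for k in names}
    t_grid = np.empty(n_steps_total + 1)
    for k in names:
        rec[k][0] = getattr(state, k)
    t_grid[0] = 0.0

    events: dict[str, float] = {}
    step = 0
    t = 0.0
    stopped = False
    for stage in protocol.stages:
        n_steps = int(round(stage.duration / dt))
        if n_steps <= 0:
            continue
        V = np.atleast_1d(np.asarray(stage.V, dtype=float))
        beta_now = params.beta if stage.beta_on else 0.0
        label = getattr(stage, "label", None)
        if label:
            events.setdefault(label, t)
        for _ in range(n_steps):
            V_eff = V + noise_V if noise_placement == "input" else V

            k1 = deriv_fn(state, V_eff, params, omega, beta_now=beta_now, **deriv_kwargs)
            s2 = _axpy(state, k1, dt / 2.0)
            k2 = deriv_fn(s2, V_eff, params, omega, beta_now=beta_now, **deriv_kwargs)
            s3 = _axpy(state, k2, dt / 2.0)
            k3 = deriv_fn(s3, V_eff, params, omega, beta_now=beta_now, **deriv_kwargs)
            s4 = _axpy(state, k3, dt)
            k4 = deriv_fn(s4, V_eff, params, omega, beta_now=beta_now, **deriv_kwargs)

            for name in names:
                x = getattr(state, name)
                incr = (dt / 6.0) * (
                    getattr(k1, name)
                    + 2.0 * getattr(k2, name)
                    + 2.0 * getattr(k3, name)
                    + getattr(k4, name)
                )
                x = x + incr
                if params.sigma > 0 and noise_placement == "units" and name in noise:
                    noise[name] = ou_noise_step(
                        noise[name], dt, params.sigma, params.tau_noise, rng
                    )
                    x = x + (dt / taus[name]) * noise[name]
                np.maximum(x, 0.0, out=x)
                setattr(state, name, x)
            if params.sigma > 0 and noise_placement == "input":
                noise_V = ou_noise_step(noise_V, dt, params.sigma, params.tau_noise, rng)

            step += 1
            t = step * dt
            for name in names:
                rec[name][step] = getattr(state, name)
            t_grid[step] = t
            if not np.all(np.isfinite(state.R)):
                raise IntegrationError(step, t)
            if stop_when is not None and t >= stop_after and stop_when(state):
                stopped = True
                break
        if stopped:
            break

    last = step + 1
    return Trajectory(
        t=t_grid[:last],
        R=rec["R"][:last],
        G=rec["G"][:last],
        D=rec["D"][:last],
        I=rec["I"][:last] if has_ie else None,
        E=rec["E"][:last] if has_ie else None,
        dt=dt,
        events=events,
    )


def _axpy(state: CircuitState, deriv: CircuitState, h: float) -> CircuitState:
    """state + h * deriv (no clamping; used inside RK4 sub-stages)."""
    return CircuitState(
        state.R + h * deriv.R,
        state.G + h * deriv.G,
        state.D + h * deriv.D,
        None if state.I is None else state.I + h * (deriv.I if deriv.I is not None else 0.0),
        None if state.E is None else state.E + h * (deriv.E if deriv.E is not None else 0.0),
    )
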