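"""Stimulus/gating protocols for the standard decision paradigms.

A protocol is an ordered list of stages, each holding a duration, a vector
of value inputs and the state of the disinhibition gate.  Motion inputs
follow the coherence rule V = S (1 + c') for option 1 and S (1 - c') for
the other options.  Reaction-time trials include a 90 ms gap at stimulus
onset (no input, gate off) modelling the initial input-untuned dip, and
30 ms of motor delay is added to the threshold-crossing time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import Trajectory, integrate, lddm_derivatives
from .params import CircuitState, GainMatrix, ModelParams

__all__ = [
    "Stage",
    "StimulusProtocol",
    "TrialOutcome",
    "coherence_inputs",
    "make_protocol",
    "detect_decision",
    "ramping_rate",
    "inhibitory_potentiation",
    "PRESETS",
    "get_preset",
]

GAP_DURATION = 0.090
MOTOR_DELAY = 0.030
DECISION_THRESHOLD = 70.0
TRIAL_CUTOFF = 5.0


@dataclass
class Stage:
    duration: float
    V: np.ndarray
    beta_on: bool
    label: str = ""

    def __post_init__(self):
        if self.duration < 0:
            raise ValueError("stage duration must be >= 0")
        self.V = np.atleast_1d(np.asarray(self.V, dtype=float))


@dataclass
class StimulusProtocol:
    """Ordered stages of value input and disinhibition gating."""

    n_options: int
    stages: list
    coherence: float = 0.0
    paradigm: str = ""

    def __post_init__(self):
        if self.n_options < 2:
            raise ValueError("n_options must be >= 2")
        if not 0.0 <= self.coherence <= 1.0:
            raise ValueError("coherence must be in [0, 1]")
        for st in self.stages:
            if st.V.shape[0] != self.n_options:
                raise ValueError("stage input length must equal n_options")

    @property
    def total_duration(self) -> float:
        return sum(st.duration for st in self.stages)

    def stage_onset(self, label: str) -> float:
        t = 0.0
        for st in self.stages:
            if st.label == label:
                return t
            t += st.duration
        raise KeyError(f"no stage labelled {label!r}")


@dataclass
class TrialOutcome:
    """Decision read out from one trajectory."""

    choice: int | None
    RT: float | None
    correct: bool | None
    crossed: bool


def coherence_inputs(S: float, coherence: float, n_options: int = 2) -> np.ndarray:
    """Motion inputs S (1 + c') for option 1 and S (1 - c') for the rest."""
    if not 0.0 <= coherence <= 1.0:
        raise ValueError("coherence must be in [0, 1]")
    V = np.full(n_options, S * (1.0 - coherence))
    V[0] = S * (1.0 + coherence)
    return V


def make_protocol(paradigm: str, **settings) -> StimulusProtocol:
    """Build the stimulus/gating protocol of one experimental paradigm.

    Paradigms
    ---------
    representation
        A single stimulus stage with the gate off (value-coding regime).
    rt_motion
        Pre-motion equal inputs (gate off), 90 ms gap (no input, gate off),
        then motion inputs with the gate on until ``cutoff``.
    fixed_duration
        Pre-motion, gap, a fixed stimulus-viewing stage with the gate off,
        then the gate switches on at the instruction cue.
    delayed_response
        Stimulus (gate off), a no-input delay (gate off), then the gate
        switches on at the cue with no input (choice from persistent
        activity).
    multi_alternative
        rt_motion generalized to N options (option 1 gets S (1 + c')).
    persistent
        Stimulus stage then input withdrawal; ``gate_in_delay`` selects the
        disinhibition state during the delay.
    """
    S = float(settings.get("S", 250.0))
    cp = float(settings.get("coherence", 0.0))
    n = int(settings.get("n_options", 2))
    pre = float(settings.get("premotion_duration", 0.0))
    cutoff = float(settings.get("cutoff", TRIAL_CUTOFF))
    gap = float(settings.get("gap_duration", GAP_DURATION))
    V_eq = np.full(n, S)
    V_mot = coherence_inputs(S, cp, n)
    zeros = np.zeros(n)

    stages: list[Stage] = []
    if paradigm == "representation":
        dur = float(settings.get("duration", 2.0))
        stages = [Stage(dur, V_mot, beta_on=False, label="stimulus")]
    elif paradigm in ("rt_motion", "multi_alternative"):
        if pre > 0:
            stages.append(Stage(pre, V_eq, beta_on=False, label="premotion"))
        stages.append(Stage(gap, zeros, beta_on=False, label="stimulus"))
        dip = float(settings.get("dip_duration", 0.0))
        if dip > 0:
            S_dip = float(settings.get("S_dip", S))
            stages.append(Stage(dip, coherence_inputs(S_dip, cp, n), beta_on=True, label="motion"))
            stages.append(Stage(cutoff - dip, V_mot, beta_on=True, label="motion_full"))
        else:
            stages.append(Stage(cutoff, V_mot, beta_on=True, label="motion"))
    elif paradigm == "fixed_duration":
        stim = float(settings.get("stimulus_duration", 1.0))
        post = float(settings.get("choice_duration", cutoff))
        if pre > 0:
            stages.append(Stage(pre, V_eq, beta_on=False, label="premotion"))
        stages.append(Stage(gap, zeros, beta_on=False, label="stimulus"))
        stages.append(Stage(stim, V_mot, beta_on=False, label="viewing"))
        stages.append(Stage(post, V_mot, beta_on=True, label="cue"))
    elif paradigm == "delayed_response":
        stim = float(settings.get("stimulus_duration", 1.0))
        delay = float(settings.get("delay_duration", 1.0))
        post = float(settings.get("choice_duration", cutoff))
        if pre > 0:
            stages.append(Stage(pre, V_eq, beta_on=False, label="premotion"))
        stages.append(Stage(stim, V_mot, beta_on=False, label="stimulus"))
        stages.append(Stage(delay, zeros, beta_on=False, label="delay"))
        stages.append(Stage(post, zeros, beta_on=True, label="cue"))
    elif paradigm == "persistent":
        stim = float(settings.get("stimulus_duration", 1.0))
        delay = float(settings.get("delay_duration", 10.0))
        gate = bool(settings.get("gate_in_delay", False))
        stages.append(Stage(stim, V_mot, beta_on=False, label="stimulus"))
        stages.append(Stage(delay, zeros, beta_on=gate, label="delay"))
    else:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    return StimulusProtocol(n, stages, coherence=cp, paradigm=paradigm)


def detect_decision(
    traj: Trajectory,
    threshold: float = DECISION_THRESHOLD,
    motor_delay: float = MOTOR_DELAY,
    cutoff: float | None = None,
    onset_label: str = "stimulus",
    coherence: float | None = None,
    rng=None,
) -> TrialOutcome:
    """Read the choice and reaction time off a trajectory.

    The first R unit whose activity reaches ``threshold`` (first grid step
    at-or-above, no interpolation) wins; RT is the crossing time relative
    to stimulus onset plus the motor delay.  Trials that never cross are
    returned with ``crossed=False``.  Correctness: option 1 is correct for
    c' > 0; at c' = 0 it is assigned by coin flip (pass ``rng`` for that).
    """
    t0 = traj.events.get(onset_label, 0.0)
    i0 = traj.index_at(t0)
    i_end = len(traj.t) if cutoff is None else min(len(traj.t), i0 + int(round(cutoff / traj.dt)) + 1)
    seg = traj.R[i0:i_end]
    hit = np.any(seg >= threshold, axis=1)
    if not hit.any():
        return TrialOutcome(choice=None, RT=None, correct=None, crossed=False)
    k = int(np.argmax(hit))
    choice = int(np.argmax(seg[k]))
    rt = k * traj.dt + motor_delay
    if coherence is None:
        correct = None
    elif coherence > 0:
        correct = choice == 0
    else:
        rng = np.random.default_rng() if rng is None else rng
        correct = bool(rng.integers(2))
    return TrialOutcome(choice=choice, RT=rt, correct=correct, crossed=True)


def ramping_rate(traj: Trajectory, window: tuple) -> np.ndarray:
    """Least-squares slope (Hz/s) of each R unit over a time window."""
    t0, t1 = window
    if t0 < traj.t[0] or t1 > traj.t[-1] or t1 <= t0:
        raise ValueError("window must lie inside the trajectory")
    i0, i1 = traj.index_at(t0), traj.index_at(t1)
    tt = traj.t[i0 : i1 + 1]
    A = np.vstack([tt, np.ones_like(tt)]).T
    coef, *_ = np.linalg.lstsq(A, traj.R[i0 : i1 + 1], rcond=None)
    return coef[0]


def inhibitory_potentiation(
    params: ModelParams, omega: GainMatrix, factor: float
) -> tuple[ModelParams, GainMatrix]:
    """Potentiate the inhibitory projections of the circuit by ``factor``.

    Models a pharmacological enhancement (e.g. a GABAergic agonist) of all
    GABAergic synapses in the circuit: the G -> R gain-control synapse and
    the D -> G disinhibitory synapse, both by ``factor``.  By the change of
    variables G' = factor * G, D' = factor^2 * D this is exactly equivalent
    to scaling (omega -> factor * omega, B_G -> factor * B_G,
    beta -> factor^2 * beta), which is how it is applied here.  Stronger
    inhibition deepens divisive suppression during representation while
    relatively stronger disinhibition accelerates the WTA bifurcation
    during choice, speeding decisions at a cost in accuracy.  ``factor`` = 1
    leaves the circuit unchanged.
    """
    if factor < 0:
        raise ValueError("factor must be >= 0")
    return (
        params.with_(beta=params.beta * factor * factor,
                     B_G=params.B_G * factor),
        omega.scaled(factor),
    )


def _p(**kw) -> ModelParams:
    return ModelParams(**kw)


#: Named parameter/protocol presets for the published figure settings.
PRESETS: dict[str, dict] = {
    # normalized value coding: transient peak then relative-value plateau
    "fig3": dict(
        params=_p(alpha=15.0, beta=0.0, B_R=70.0, sigma=0.0),
        omega=GainMatrix(2), paradigm="representation", S=250.0,
    ),
    # reaction-time WTA with phase-plane structure
    "fig5": dict(
        params=_p(alpha=15.0, beta=0.9, sigma=0.0),
        omega=GainMatrix(2), paradigm="rt_motion", S=250.0,
    ),
    # multi-alternative choice; identical parameters for 2 and 4 options
    "fig7_2alt": dict(
        params=_p(alpha=0.0, beta=1.5, sigma=0.0),
        omega=GainMatrix(2), paradigm="multi_alternative",
        S=640.0, S_dip=427.0, dip_duration=0.190, n_options=2,
    ),
    "fig7_4alt": dict(
        params=_p(alpha=0.0, beta=1.5, sigma=0.0),
        omega=GainMatrix(4), paradigm="multi_alternative",
        S=640.0, S_dip=427.0, dip_duration=0.190, n_options=4,
    ),
    # persistent activity: line attractor (gate off) vs categorical (gate on)
    "fig8_2item": dict(
        params=_p(alpha=15.0, beta=0.4, sigma=0.0),
        omega=GainMatrix(2), paradigm="persistent", S=250.0, n_options=2,
    ),
    "fig8_5item": dict(
        params=_p(alpha=37.5, beta=0.1, sigma=0.0),
        omega=GainMatrix(5), paradigm="persistent", S=50.0, n_options=5,
    ),
    # task-timing flexibility (gate at stimulus / instruction cue / delay end)
    "fig9a": dict(
        params=_p(alpha=15.0, beta=1.1, sigma=0.0),
        omega=GainMatrix(2), paradigm="rt_motion", S=250.0,
        premotion_duration=0.5,
    ),
    "fig9b": dict(
        params=_p(alpha=15.0, beta=1.1, sigma=0.0),
        omega=GainMatrix(2), paradigm="fixed_duration", S=250.0,
        premotion_duration=0.5, stimulus_duration=1.0,
    ),
    "fig9c": dict(
        params=_p(alpha=15.0, beta=1.1, sigma=0.0),
        omega=GainMatrix(2), paradigm="delayed_response", S=250.0,
        premotion_duration=0.5, stimulus_duration=1.0, delay_duration=1.0,
    ),
    # inhibitory potentiation contrasts
    "fig10_lddm_a": dict(
        params=_p(alpha=5.0, beta=1.4, sigma=0.0),
        omega=GainMatrix(2), paradigm="rt_motion", S=256.0,
        potentiation_control=1.0, potentiation=3.8,
    ),
    "fig10_lddm": dict(
        params=_p(alpha=10.0, beta=1.1, sigma=2.0),
        omega=GainMatrix(2), paradigm="rt_motion", S=256.0,
        potentiation_control=1.0, potentiation=1.8,
    ),
    "fig10_rnm": dict(
        params=None, omega=None, paradigm="rt_motion", model="rnm",
        potentiation_control=1.0, potentiation=1.8,
    ),
    # best fit to the reaction-time motion-discrimination behavior
    "behavior_bestfit": dict(
        params=_p(alpha=0.0, beta=1.434, sigma=25.36,
                  tau_R=0.1853, tau_G=0.2244, tau_D=0.3231),
        omega=GainMatrix(2), paradigm="rt_motion", S=3251.0,
    ),
}


def get_preset(name: str) -> dict:
    try:
        return {k: v for k, v in PRESETS[name].items()}
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def run_trial(
    preset: str | dict,
    coherence: float = 0.0,
    seed: int | None = None,
    dt: float = 0.001,
    initial_R: float = 32.0,
    cutoff: float = TRIAL_CUTOFF,
    threshold: float = DECISION_THRESHOLD,
    stop_at_threshold: bool = True,
) -> tuple[Trajectory, TrialOutcome]:
    """Simulate one trial of a preset and read out the decision."""
    cfg = get_preset(preset) if isinstance(preset, str) else dict(preset)
    params: ModelParams = cfg["params"]
    omega: GainMatrix = cfg["omega"]
    n = cfg.get("n_options", omega.n_options)
    proto_kw = {
        k: cfg[k]
        for k in ("S", "S_dip", "dip_duration", "premotion_duration",
                  "stimulus_duration", "delay_duration", "gate_in_delay")
        if k in cfg
    }
    proto = make_protocol(
        cfg["paradigm"], coherence=coherence, n_options=n, cutoff=cutoff, **proto_kw
    )
    state = CircuitState(np.full(n, float(initial_R)), np.zeros(n), np.zeros(n))
    # threshold crossings only count once the disinhibition gate is on;
    # transient peaks during pre-motion representation must not end the trial
    gate_start = None
    t_acc = 0.0
    for s in proto.stages:
        if s.beta_on:
            gate_start = t_acc
            break
        t_acc += s.duration
    stop = None
    if stop_at_threshold and gate_start is not None:
        stop = lambda st: np.max(st.R) >= threshold  # noqa: E731
    traj = integrate(lddm_derivatives, state, proto, params, omega, dt=dt,
                     seed=seed, stop_when=stop,
                     stop_after=gate_start if gate_start is not None else 0.0)
    outcome = detect_decision(
        traj, threshold=threshold, onset_label="stimulus",
        coherence=coherence, rng=np.random.default_rng(seed),
    )
    return traj, outcome
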