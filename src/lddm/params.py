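"""Parameter containers for the circuit models.

The local disinhibition decision model (LDDM) is a rate model in which each
choice option is represented by a trio of units: an excitatory *R* unit
receiving value input, an inhibitory gain-control *G* unit implementing
divisive normalization, and a disinhibitory *D* unit that inhibits the local
*G* unit.  Gated disinhibition (the R->D coupling ``beta``) switches the
circuit between normalized value coding and winner-take-all selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np

__all__ = [
    "ModelParams",
    "GainMatrix",
    "MotifFlags",
    "RNMParams",
    "LCAParams",
    "CircuitState",
]


@dataclass
class ModelParams:
    """Constants of the LDDM / DNM circuit.

    Parameters
    ----------
    alpha : float
        Recurrent self-excitation weight on the R units (dimensionless).
    beta : float
        Local disinhibition weight (R -> D coupling).  This is the *gated*
        value used while the disinhibition gate is on; during value
        representation the effective beta is zero.
    B_R, B_G : float
        Non-selective baseline inputs to the R and G units.
    sigma : float
        Ornstein-Uhlenbeck noise amplitude (model units); the stationary
        standard deviation of each unit's noise term is ``sigma / sqrt(2)``.
    tau_R, tau_G, tau_D : float
        Time constants of the three unit types, in seconds.
    tau_noise : float
        Time constant of the OU noise process, in seconds (default 2 ms).
    S : float
        Input value scale: motion inputs are ``S * (1 + c')`` and
        ``S * (1 - c')`` for coherence ``c'``.
    """

    alpha: float = 15.0
    beta: float = 1.1
    B_R: float = 0.0
    B_G: float = 0.0
    sigma: float = 0.0
    tau_R: float = 0.1
    tau_G: float = 0.1
    tau_D: float = 0.1
    tau_noise: float = 0.002
    S: float = 250.0

    def __post_init__(self) -> None:
        for name in ("tau_R", "tau_G", "tau_D", "tau_noise"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("alpha", "beta", "B_R", "B_G", "sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)


@dataclass
class GainMatrix:
    """R -> G coupling matrix omega.

    By default the matrix has the local weight ``w`` on the diagonal and the
    lateral weight ``v`` off-diagonal; an arbitrary matrix may be supplied
    instead.
    """

    n_options: int = 2
    w: float = 1.0
    v: float = 1.0
    matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_options < 2:
            raise ValueError("n_options must be >= 2")
        if self.matrix is None:
            if self.w < 0 or self.v < 0:
                raise ValueError("w and v must be >= 0")
            m = np.full((self.n_options, self.n_options), float(self.v))
            np.fill_diagonal(m, float(self.w))
            self.matrix = m
        else:
            self.matrix = np.asarray(self.matrix, dtype=float)
            if self.matrix.shape != (self.n_options, self.n_options):
                raise ValueError("matrix must be N x N")
            self.w = float(self.matrix[0, 0])
            self.v = float(self.matrix[0, 1]) if self.n_options > 1 else 0.0

    def scaled(self, factor: float) -> "GainMatrix":
        """Scale all inhibitory-projection weights by ``factor``."""
        if factor < 0:
            raise ValueError("factor must be >= 0")
        return GainMatrix(self.n_options, matrix=self.matrix * factor)


@dataclass
class MotifFlags:
    """Active/inactive states of the four competition-enhancing loops.

    The generalized motif model augments the dynamic normalization circuit
    with four optional loops: recurrent self-excitation (alpha), local
    disinhibition (beta), cross inhibition via I units (eta), and a lateral
    gain-control boost via E units (gamma_lat).  The 2**4 = 16 on/off
    combinations enumerate the candidate model family.
    """

    use_self_excitation: bool = True
    use_local_disinhibition: bool = True
    use_cross_inhibition: bool = False
    use_lateral_boost: bool = False
    eta: float = 0.0
    gamma_lat: float = 0.0

    def __post_init__(self) -> None:
        if self.eta < 0 or self.gamma_lat < 0:
            raise ValueError("eta and gamma_lat must be >= 0")

    @staticmethod
    def enumerate() -> list["MotifFlags"]:
        """All 16 distinct on/off combinations of the four loops."""
        combos = []
        for se, ld, ci, lb in product([False, True], repeat=4):
            combos.append(
                MotifFlags(
                    use_self_excitation=se,
                    use_local_disinhibition=ld,
                    use_cross_inhibition=ci,
                    use_lateral_boost=lb,
                    eta=1.0 if ci else 0.0,
                    gamma_lat=1.0 if lb else 0.0,
                )
            )
        return combos


@dataclass
class RNMParams:
    """Reduced two-variable recurrent network model (mean-field form).

    ``JN_same``/``JN_diff`` are the self and cross synaptic couplings (nA),
    ``I0`` the non-selective background current (nA), ``mu0`` the stimulus
    input scale, ``gamma_kin`` the synaptic kinetic factor, ``H0`` the
    initial gating value, ``tau_S`` the NMDA gating time constant (s) and
    ``sigma_noise`` the OU noise amplitude on the background current.  The
    single-cell transfer-function constants a, b, d and the AMPA noise time
    constant are fixed.
    """

    JN_same: float = 0.2609
    JN_diff: float = 0.0497
    I0: float = 0.3255
    mu0: float = 0.0156  # J_A,ext * mu0 lumped: input current at c' = 0
    gamma_kin: float = 0.641
    H0: float = 0.0
    tau_S: float = 0.1
    sigma_noise: float = 0.02
    threshold: float = 15.0  # decision threshold on the firing rate (Hz)
    # fixed single-cell constants
    a: float = 270.0
    b: float = 108.0
    d: float = 0.154
    tau_AMPA: float = 0.002

    def __post_init__(self) -> None:
        for name in ("JN_same", "JN_diff", "I0", "mu0", "gamma_kin",
                     "tau_S", "sigma_noise", "threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tau_S <= 0 or self.tau_AMPA <= 0:
            raise ValueError("time constants must be > 0")


@dataclass
class LCAParams:
    """Leaky competing accumulator with two nodes.

    ``k`` is the net leakage, ``beta_inh`` the mutual inhibition weight,
    ``sigma`` the per-step Gaussian noise SD and ``threshold`` the decision
    bound in (arbitrary) activity units.  The time constant is fixed at
    100 ms and the non-decision time at 120 ms.
    """

    k: float = 1.5
    beta_inh: float = 3.0
    sigma: float = 0.25
    threshold: float = 0.5
    tau: float = 0.1
    T0: float = 0.120

    def __post_init__(self) -> None:
        for name in ("k", "beta_inh", "sigma", "threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CircuitState:
    """Activities of all units of one circuit at one instant.

    R, G, D are per-option vectors; I and E exist only in the generalized
    motif model.  All activities are clamped non-negative after each
    integration step.
    """

    R: np.ndarray
    G: np.ndarray
    D: np.ndarray
    I: np.ndarray | None = None
    E: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.R = np.atleast_1d(np.asarray(self.R, dtype=float))
        self.G = np.atleast_1d(np.asarray(self.G, dtype=float))
        self.D = np.atleast_1d(np.asarray(self.D, dtype=float))
        n = self.R.shape[0]
        if self.G.shape[0] != n or self.D.shape[0] != n:
            raise ValueError("R, G, D must have equal length")
        for name in ("I", "E"):
            val = getattr(self, name)
            if val is not None:
                val = np.atleast_1d(np.asarray(val, dtype=float))
                if val.shape[0] != n:
                    raise ValueError(f"{name} must have length {n}")
                setattr(self, name, val)

    @property
    def n_options(self) -> int:
        return self.R.shape[0]

    @classmethod
    def zeros(cls, n: int, motif: bool = False) -> "CircuitState":
        z = np.zeros(n)
        if motif:
            return cls(z.copy(), z.copy(), z.copy(), z.copy(), z.copy())
        return cls(z.copy(), z.copy(), z.copy())

    def copy(self) -> "CircuitState":
        return CircuitState(
            self.R.copy(), self.G.copy(), self.D.copy(),
            None if self.I is None else self.I.copy(),
            None if self.E is None else self.E.copy(),
        )
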