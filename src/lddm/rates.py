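"""Equilibrium firing-rate predictions and fits to trinary value coding.

The value-representation experiment presents up to three reward targets
(values in microliters, omitted targets coded 0) and records the mean rate
of a neuron whose response field holds option 1.  At equilibrium with the
disinhibition gate off, the LDDM predicts divisively normalized rates

    R_i = Rmax (V_i + B_R) / (1 + B_G - alpha + sum_j R_j)

which reduces to the dynamic normalization model (DNM) when B_G - alpha = 0.
Because alpha and B_G enter only through their difference they cannot be
identified separately; fits estimate the combined term.  The reduced RNM,
expanded to three selective pools with subtractive inhibition, is the
comparison model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dynamics import rnm_transfer
from .params import RNMParams

__all__ = [
    "NormalizationDataset",
    "NormFitResult",
    "equilibrium_rates",
    "fit_normalization",
    "rnm_trinary_rates",
    "default_design",
]

REWARD_LEVELS = (0.0, 50.0, 100.0, 200.0, 250.0)
#: normalization constant for mapping reward values onto RNM input currents
RNM_VALUE_SCALE = 250.0


def default_design() -> pd.DataFrame:
    """A 28-condition trinary design over the declared reward levels.

    Each of the four non-zero direct values V1 is crossed with seven
    contextual (V2, V3) pairs spanning omitted, low and high alternatives.
    """
    pairs = [(0, 0), (0, 100), (0, 250), (100, 100), (100, 250),
             (250, 250), (50, 200)]
    rows = [
        {"V1_ul": float(v1), "V2_ul": float(v2), "V3_ul": float(v3)}
        for v1 in (50.0, 100.0, 200.0, 250.0)
        for v2, v3 in pairs
    ]
    return pd.DataFrame(rows)


@dataclass
class NormalizationDataset:
    """Condition-mean firing rates of the trinary reward design."""

    table: pd.DataFrame

    REQUIRED = ("V1_ul", "V2_ul", "V3_ul", "rate_hz")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        vals = self.table[["V1_ul", "V2_ul", "V3_ul"]].to_numpy()
        if np.any(vals < 0):
            raise ValueError("reward values must be non-negative")
        if np.any(self.table["rate_hz"] < 0):
            raise ValueError("rates must be non-negative")

    @property
    def conditions(self) -> np.ndarray:
        return self.table[["V1_ul", "V2_ul", "V3_ul"]].to_numpy()

    @property
    def rates(self) -> np.ndarray:
        return self.table["rate_hz"].to_numpy()

    @classmethod
    def from_csv(cls, path) -> "NormalizationDataset":
        return cls(pd.read_csv(path, comment="#", float_precision="round_trip"))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def equilibrium_rates(
    model: str,
    params: dict,
    condition,
    alpha: float | None = None,
    B_G: float | None = None,
) -> float:
    """Steady-state rate of unit 1 for one (V1, V2, V3) condition.

    ``params`` holds ``B_R``, ``Rmax`` and, for the LDDM, the combined
    ``bg_minus_alpha`` term (alternatively pass ``alpha`` and ``B_G``
    separately; only their difference matters).  The trinary fixed point
    has the closed form

        s = sum_j R_j solves s^2 + c0 s - Rmax sum_j (V_j + B_R) = 0,
        R_1 = Rmax (V_1 + B_R) / (c0 + s)

    with c0 = 1 for the DNM and c0 = 1 + B_G - alpha for the LDDM (the
    disinhibition units are silent during representation, beta = 0).
    """
    V = np.atleast_1d(np.asarray(condition, dtype=float))
    B_R = float(params["B_R"])
    Rmax = float(params["Rmax"])
    if model.lower() == "dnm":
        c0 = 1.0
    elif model.lower() == "lddm":
        if alpha is not None or B_G is not None:
            c0 = 1.0 + (B_G or 0.0) - (alpha or 0.0)
        else:
            c0 = 1.0 + float(params["bg_minus_alpha"])
    else:
        raise ValueError("model must be 'dnm' or 'lddm'")
    T = Rmax * float(np.sum(V + B_R))
    disc = c0 * c0 + 4.0 * T
    s = 0.5 * (-c0 + np.sqrt(disc))
    denom = c0 + s
    if denom <= 0 or not np.isfinite(denom):
        raise ValueError("no positive equilibrium for these parameters")
    return float(Rmax * (V[0] + B_R) / denom)


def _predict_all(model, params, conditions):
    return np.array([equilibrium_rates(model, params, c) for c in conditions])


@dataclass
class NormFitResult:
    model: str
    params: dict
    sse: float
    r_squared: float
    n_starts: int = 1
    predicted: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self):
        return {"model": self.model, "params": self.params,
                "sse": self.sse, "r_squared": self.r_squared}


_NORM_BOUNDS = {
    "dnm": {"B_R": (0.0, 300.0), "Rmax": (1e-3, 300.0)},
    "lddm": {"B_R": (0.0, 300.0), "Rmax": (1e-3, 300.0),
             "bg_minus_alpha": (-20.0, 60.0)},
    "rnm": {"JN_same": (1e-4, 0.5), "JN_diff": (1e-4, 0.5),
            "I0": (0.1, 0.6), "S_scale": (1e-2, 50.0)},
}


def fit_normalization(
    data: NormalizationDataset,
    model: str = "lddm",
    bounds: dict | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> NormFitResult:
    """Least-squares fit of a model's equilibrium rates to condition means.

    DNM has two free parameters (B_R, Rmax), the LDDM three (B_R, Rmax,
    B_G - alpha) and the trinary RNM four (JN_same, JN_diff, I0, a rate
    scale).  Multi-start trust-region least squares; reports SSE and
    R^2 = 1 - SSE / SST.
    """
    if len(data.table) == 0:
        raise ValueError("dataset is empty")
    model = model.lower()
    bounds = bounds or _NORM_BOUNDS[model]
    names = list(bounds)
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    conditions = data.conditions
    y = data.rates
    rng = np.random.default_rng(seed)

    def residuals(x):
        p = dict(zip(names, x))
        try:
            if model == "rnm":
                pred = _rnm_trinary_batch(p, conditions)
            else:
                pred = _predict_all(model, p, conditions)
        except ValueError:
            return np.full_like(y, 1e6)
        return pred - y

    best = None
    for s in range(n_starts):
        x0 = lo + (hi - lo) * (0.5 if s == 0 else rng.random(len(names)))
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-12,
                                ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all least-squares starts failed")

    params = dict(zip(names, (float(v) for v in best.x)))
    pred = residuals(best.x) + y
    sse = float(np.sum((pred - y) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else 0.0)
    return NormFitResult(model=model, params=params, sse=sse, r_squared=r2,
                         n_starts=n_starts, predicted=pred)


def _rnm_trinary_batch(
    params: dict,
    conditions,
    dt: float = 0.001,
    t_max: float = 10.0,
    tol: float = 1e-7,
) -> np.ndarray:
    """Steady-state Pool-1 rates for a whole condition table (noiseless)."""
    base = RNMParams(JN_same=float(params["JN_same"]),
                     JN_diff=float(params["JN_diff"]),
                     I0=float(params["I0"]), sigma_noise=0.0)
    scale = float(params.get("S_scale", 1.0))
    V = np.atleast_2d(np.asarray(conditions, dtype=float))
    I_ext = 5.2e-4 * 30.0 * V / RNM_VALUE_SCALE
    S = np.zeros_like(V)
    J = np.full((3, 3), -base.JN_diff)
    np.fill_diagonal(J, base.JN_same)
    n_steps = int(round(t_max / dt))
    for _ in range(n_steps):
        x = S @ J.T + base.I0 + I_ext
        H = rnm_transfer(x, base)
        dS = -S / base.tau_S + (1.0 - S) * base.gamma_kin * H
        S = np.clip(S + dt * dS, 0.0, 1.0)
        if np.max(np.abs(dS)) < tol:
            break
    else:
        raise ValueError("trinary RNM did not reach steady state")
    x = S @ J.T + base.I0 + I_ext
    return scale * rnm_transfer(x, base)[:, 0]


def rnm_trinary_rates(
    params: dict,
    condition,
    dt: float = 0.001,
    t_max: float = 10.0,
    tol: float = 1e-7,
) -> float:
    """Steady-state Pool-1 rate of the three-pool reduced RNM (noiseless).

    The two-variable reduced model is expanded to three selective pools
    wired by the same rules: self coupling ``JN_same``, cross coupling
    ``-JN_diff`` to both other pools.  Reward values are normalized by
    250 ul and injected as stimulus current via the standard external gain;
    the fitted ``S_scale`` rescales the predicted rate.  Integration stops
    at convergence; failure to converge by ``t_max`` raises.
    """
    return float(_rnm_trinary_batch(params, np.atleast_2d(condition),
                                    dt=dt, t_max=t_max, tol=tol)[0])
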