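"""Fitting the circuit models to choice/reaction-time behavior by QMLE.

Quantile maximum likelihood treats the RT distribution at each coherence as
a multinomial over quantile bins: nine empirical quantiles (0.1 ... 0.9)
split correct and error trials into ten bins each, and the model's bin
probabilities come from Monte-Carlo simulation.  Correct and error trials
are normalized jointly per coherence (together with the censored mass), so
choice accuracy is estimated implicitly.  The negative log-likelihood is
minimized by multi-start bounded Nelder-Mead with common random numbers per
evaluation, replacing the stochastic objective by a quasi-deterministic one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from . import _kernels
from .params import GainMatrix, LCAParams, ModelParams, RNMParams
from .tasks import (
    DECISION_THRESHOLD,
    GAP_DURATION,
    MOTOR_DELAY,
    TRIAL_CUTOFF,
    coherence_inputs,
)

__all__ = [
    "CANONICAL_COHERENCES",
    "RTDataset",
    "QuantileBinning",
    "FitResult",
    "simulate_rt_distribution",
    "qmle_nll",
    "fit_model",
    "summaries",
]

CANONICAL_COHERENCES = (0.0, 0.032, 0.064, 0.128, 0.256, 0.512)
DEFAULT_QUANTILES = tuple(np.round(np.arange(0.1, 0.95, 0.1), 10))
INITIAL_R = 32.0


@dataclass
class RTDataset:
    """Trial-level behavioral data: coherence, choice, correctness, RT (s)."""

    trials: pd.DataFrame

    REQUIRED = ("coherence", "choice", "correct", "rt_s")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.trials.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if (self.trials["rt_s"] <= 0).any():
            raise ValueError("all RTs must be positive")

    @property
    def coherences(self) -> np.ndarray:
        return np.sort(self.trials["coherence"].unique())

    def cell(self, coherence: float, correct: bool) -> np.ndarray:
        m = (self.trials["coherence"] == coherence) & (
            self.trials["correct"].astype(bool) == correct
        )
        return self.trials.loc[m, "rt_s"].to_numpy()

    def counts(self) -> pd.Series:
        return self.trials.groupby("coherence").size()

    @classmethod
    def from_csv(cls, path) -> "RTDataset":
        return cls(pd.read_csv(path, float_precision="round_trip"))

    def to_csv(self, path) -> None:
        df = self.trials.copy()
        if "trial_id" not in df.columns:
            df.insert(0, "trial_id", np.arange(len(df)))
        df.to_csv(path, index=False)


@dataclass
class QuantileBinning:
    """Empirical quantile edges and bin counts per (coherence, correctness).

    Cells with fewer than ``min_cell`` trials get a single bin (their count
    against the model's total probability of that response type), keeping
    small error cells at high coherence usable without unstable quantiles.
    """

    probs: tuple = DEFAULT_QUANTILES
    cells: dict = field(default_factory=dict)
    n_per_coherence: dict = field(default_factory=dict)
    min_cell: int = 10

    @classmethod
    def from_dataset(
        cls, data: RTDataset, probs=DEFAULT_QUANTILES, min_cell: int = 10
    ) -> "QuantileBinning":
        binning = cls(probs=tuple(probs), min_cell=min_cell)
        for coh in data.coherences:
            n_tot = 0
            for corr in (True, False):
                rts = data.cell(coh, corr)
                n = len(rts)
                n_tot += n
                if n == 0:
                    continue
                if n < min_cell:
                    edges, counts = None, np.array([n])
                else:
                    edges = np.quantile(rts, probs)  # type-7 interpolation
                    counts = np.histogram(rts, np.r_[-np.inf, edges, np.inf])[0]
                binning.cells[(coh, corr)] = {"edges": edges, "counts": counts, "n": n}
            binning.n_per_coherence[coh] = n_tot
        return binning

    @property
    def coherences(self):
        return sorted(self.n_per_coherence)


def _correct_mask(choice: np.ndarray, coherence: float, rng) -> np.ndarray:
    """Option 1 is correct for c' > 0; at c' = 0 correctness is a coin flip."""
    if coherence > 0:
        return choice == 0
    return rng.integers(2, size=choice.shape).astype(bool)


def simulate_rt_distribution(
    params,
    coherences=CANONICAL_COHERENCES,
    n_reps: int = 1024,
    seed: int = 0,
    model: str = "lddm",
    omega: GainMatrix | None = None,
    dt: float = 0.001,
    cutoff: float = TRIAL_CUTOFF,
    gap: float = GAP_DURATION,
    initial_R: float = INITIAL_R,
    threshold: float | None = None,
    motor_delay: float = MOTOR_DELAY,
) -> dict:
    """Monte-Carlo RT samples per coherence for one parameter set.

    Returns ``{coherence: {"rt_correct", "rt_error", "n_censored",
    "n_total"}}``.  Trials start from R = 32 Hz (LDDM) with a 90 ms gap
    before motion onset; identical seeds give identical samples.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    coherences = [float(c) for c in coherences]
    n_cells = len(coherences)
    V1 = np.empty(n_cells * n_reps)
    V2 = np.empty(n_cells * n_reps)
    gap_steps = int(round(gap / dt))
    max_steps = gap_steps + int(round(cutoff / dt))

    if model == "lddm":
        p: ModelParams = params
        om = omega if omega is not None else GainMatrix(2)
        thr = DECISION_THRESHOLD if threshold is None else threshold
        for i, c in enumerate(coherences):
            v = coherence_inputs(p.S, c, 2)
            V1[i * n_reps : (i + 1) * n_reps] = v[0]
            V2[i * n_reps : (i + 1) * n_reps] = v[1]
        rt, choice = _kernels.lddm_trials(
            V1, V2, p.alpha, p.beta, p.B_R, p.B_G, om.w, om.v, p.sigma,
            p.tau_R, p.tau_G, p.tau_D, p.tau_noise, initial_R, dt,
            gap_steps, max_steps, thr, motor_delay, seed % 2**31,
        )
    elif model == "rnm":
        p: RNMParams = params
        thr = p.threshold if threshold is None else threshold
        for i, c in enumerate(coherences):
            V1[i * n_reps : (i + 1) * n_reps] = p.mu0 * (1.0 + c)
            V2[i * n_reps : (i + 1) * n_reps] = p.mu0 * (1.0 - c)
        rt, choice = _kernels.rnm_trials(
            V1, V2, p.JN_same, p.JN_diff, p.I0, p.gamma_kin, p.H0, p.tau_S,
            p.sigma_noise, p.a, p.b, p.d, p.tau_AMPA, dt, gap_steps,
            max_steps, thr, motor_delay, seed % 2**31,
        )
    elif model == "lca":
        p: LCAParams = params
        thr = p.threshold if threshold is None else threshold
        for i, c in enumerate(coherences):
            V1[i * n_reps : (i + 1) * n_reps] = 1.0 + c
            V2[i * n_reps : (i + 1) * n_reps] = 1.0 - c
        rt, choice = _kernels.lca_trials(
            V1, V2, p.k, p.beta_inh, p.sigma, thr, p.tau, p.T0, dt,
            int(round(cutoff / dt)), seed % 2**31,
        )
    else:
        raise ValueError(f"unknown model {model!r}")

    rng = np.random.default_rng(seed + 7919)
    out = {}
    for i, c in enumerate(coherences):
        sl = slice(i * n_reps, (i + 1) * n_reps)
        rt_c, ch_c = rt[sl], choice[sl]
        crossed = ch_c >= 0
        corr = np.zeros_like(crossed)
        corr[crossed] = _correct_mask(ch_c[crossed], c, rng)
        out[c] = {
            "rt_correct": rt_c[crossed & corr],
            "rt_error": rt_c[crossed & ~corr],
            "n_censored": int((~crossed).sum()),
            "n_total": int(n_reps),
        }
    return out


def qmle_nll(binning: QuantileBinning, predicted: dict) -> float:
    """Negative log multinomial likelihood of observed bin counts.

    Predicted bin probabilities are computed against the *observed* quantile
    edges, jointly normalized per coherence over correct bins, error bins
    and the censored mass, floored at eps = 1 / (10 n_reps) and
    renormalized.  Coherences with no observed trials are skipped with a
    warning.
    """
    nll = 0.0
    for coh in binning.coherences:
        if binning.n_per_coherence.get(coh, 0) == 0:
            warnings.warn(f"no observed trials at coherence {coh}; skipped")
            continue
        if coh not in predicted:
            raise KeyError(f"prediction missing coherence {coh}")
        cell = predicted[coh]
        total = cell["n_total"]
        eps = 1.0 / (10.0 * total)
        p_parts, n_parts = [], []
        for corr, key in ((True, "rt_correct"), (False, "rt_error")):
            obs = binning.cells.get((coh, corr))
            if obs is None:
                continue
            pred_rts = cell[key]
            if obs["edges"] is None:
                p = np.array([len(pred_rts) / total])
            else:
                p = np.histogram(pred_rts, np.r_[-np.inf, obs["edges"], np.inf])[0] / total
            p_parts.append(p)
            n_parts.append(obs["counts"])
        # censored mass participates in normalization but carries no
        # observed count (empirical datasets contain only completed trials)
        p_all = np.concatenate(p_parts + [[cell["n_censored"] / total]])
        p_all = np.maximum(p_all, eps)
        p_all /= p_all.sum()
        n_all = np.concatenate(n_parts + [[0.0]])
        nll -= float(np.sum(n_all * np.log(p_all)))
    return nll


# ---------------------------------------------------------------------------
# model fitting

# name -> (lo, hi, scale); scale "log" fits the parameter on a log grid
_BOUNDS = {
    "lddm": {
        "alpha": (0.0, 45.0, "lin"),
        "beta": (0.1, 3.0, "lin"),
        "sigma": (1.0, 80.0, "log"),
        "S": (250.0, 10000.0, "log"),
        "tau_R": (0.05, 0.5, "log"),
        "tau_G": (0.05, 0.5, "log"),
        "tau_D": (0.05, 0.5, "log"),
    },
    "rnm": {
        "JN_same": (0.05, 0.5, "lin"),
        "JN_diff": (0.01, 0.3, "lin"),
        "I0": (0.1, 0.6, "lin"),
        "sigma_noise": (0.001, 0.1, "log"),
        "mu0": (0.005, 0.1, "log"),
        "gamma_kin": (0.1, 2.0, "log"),
        "H0": (0.0, 0.5, "lin"),
        "tau_S": (0.02, 0.5, "log"),
    },
    "lca": {
        "k": (0.0, 10.0, "lin"),
        "beta_inh": (0.0, 10.0, "lin"),
        "sigma": (0.01, 2.0, "log"),
        "threshold": (0.1, 10.0, "log"),
    },
}


def _profile_grids(profile_groups, names, x_best, n_profile):
    """Slice grids for the collinear-direction profiling stages.

    Single-coordinate groups get a global grid over the unit interval;
    coordinate pairs get a local star of offsets around the incumbent.
    """
    out = []
    for group in profile_groups:
        group = tuple(group)
        if any(nm not in names for nm in group):
            continue
        if len(group) == 1:
            grid = [(v,) for v in np.linspace(0.05, 0.95, n_profile)]
        else:
            idx = [names.index(nm) for nm in group]
            center = x_best[idx]
            offsets = [(-0.15, 0.0), (0.15, 0.0), (0.0, -0.15), (0.0, 0.15),
                       (-0.15, -0.15), (-0.15, 0.15), (0.15, -0.15),
                       (0.15, 0.15)]
            grid = [tuple(np.clip(center + np.asarray(o), 0.0, 1.0))
                    for o in offsets]
        out.append((group, grid))
    return out


def _theta_to_params(theta, bounds):
    vals = {}
    for th, (name, (lo, hi, scale)) in zip(theta, bounds.items()):
        th = min(max(float(th), 0.0), 1.0)
        if scale == "log":
            vals[name] = float(np.exp(np.log(lo) + th * (np.log(hi) - np.log(lo))))
        else:
            vals[name] = float(lo + th * (hi - lo))
    return vals


def _make_model(model: str, vals: dict):
    if model == "lddm":
        return ModelParams(B_R=0.0, B_G=0.0, **vals)
    if model == "rnm":
        return RNMParams(**vals)
    if model == "lca":
        return LCAParams(**vals)
    raise ValueError(model)


@dataclass
class FitResult:
    """Best parameters of a behavioral fit with its likelihood and AIC."""

    model: str
    params: dict
    nll: float
    aic: float
    n_free: int
    n_starts: int
    n_reps: int
    seed: int
    starts: list = field(default_factory=list)
    settings: dict = field(default_factory=dict)

    def model_params(self):
        return _make_model(self.model, self.params)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "nll": self.nll,
            "aic": self.aic,
            "n_free": self.n_free,
            "n_starts": self.n_starts,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "settings": self.settings,
        }


def fit_model(
    observed: RTDataset,
    model: str = "lddm",
    bounds: dict | None = None,
    n_starts: int = 8,
    n_reps: int = 1024,
    seed: int = 1,
    maxfev: int = 150,
    n_screen: int = 128,
    screen_reps: int | None = None,
    polish_scales: tuple = (0.3, 0.15, 0.08, 0.04),
    polish_maxfev: int = 300,
    profile_groups=(),
    n_profile: int = 6,
    profile_maxfev: int = 90,
    dt: float = 0.001,
    cutoff: float = TRIAL_CUTOFF,
) -> FitResult:
    """Multi-start QMLE fit of one model to trial-level RT data.

    ``n_screen`` Latin-hypercube candidates are first scored at a reduced
    Monte-Carlo size (``screen_reps``, default ``n_reps // 4``) and the best
    ``n_starts`` seed local Nelder-Mead searches at the full ``n_reps``
    (bounded via a unit-cube reparameterization, log scale for scale-like
    parameters), followed by simplex restarts around the incumbent at
    decreasing scales.  ``profile_groups`` optionally adds
    profile-likelihood scans over collinear coordinate groups
    (``"__auto__"`` selects the LDDM's documented ridges).  Every objective
    evaluation reuses one fixed simulation seed (common random numbers),
    so the whole fit is deterministic given ``seed``.
    """
    bounds = bounds or _BOUNDS[model]
    names = list(bounds)
    k = len(names)
    if profile_groups == "__auto__":
        # optional profiling over the LDDM's documented collinear
        # directions; the comparison models have no analogous ridges
        profile_groups = (("alpha",), ("S", "tau_R")) if model == "lddm" else ()
    elif profile_groups is None:
        profile_groups = ()
    binning = QuantileBinning.from_dataset(observed)
    coherences = [float(c) for c in observed.coherences]
    sim_seed = int((seed * 69069 + 12345) % 2**31)
    screen_reps = screen_reps or max(n_reps // 4, 64)

    def objective(theta, reps=n_reps):
        vals = _theta_to_params(theta, bounds)
        try:
            p = _make_model(model, vals)
            pred = simulate_rt_distribution(
                p, coherences, n_reps=reps, seed=sim_seed, model=model,
                dt=dt, cutoff=cutoff,
            )
        except (ValueError, FloatingPointError):
            return 1e12
        return qmle_nll(binning, pred)

    sampler = qmc.LatinHypercube(d=k, seed=seed)
    cand = sampler.random(max(n_screen, n_starts))
    scores = np.array([objective(th, reps=screen_reps) for th in cand])
    order = np.argsort(scores)

    starts_log = []
    best = None
    for rank in range(n_starts):
        x0 = cand[order[rank]]
        res = minimize(
            objective, x0, method="Nelder-Mead",
            bounds=[(0.0, 1.0)] * k,
            options={"maxfev": maxfev, "xatol": 2e-3, "fatol": 0.1,
                     "adaptive": True},
        )
        starts_log.append(
            {"x0": x0.tolist(), "nll": float(res.fun),
             "params": _theta_to_params(res.x, bounds),
             "nfev": int(res.nfev), "success": bool(res.success)}
        )
        if best is None or res.fun < best.fun:
            best = res

    x_best, f_best = best.x, float(best.fun)

    # Collinear parameters (for the LDDM the recurrence alpha, and the
    # input scale S against the excitatory time constant tau_R) carve
    # long, nearly flat valleys with shallow sub-basins; a plain local
    # search settles into whichever sub-basin its start feeds.  Profile
    # the likelihood over each collinear direction in turn: fix those
    # coordinates on a grid and re-optimize the remaining parameters from
    # the incumbent, keeping the best slice found.
    for group in profile_groups:
        grids = _profile_grids([group], names, x_best, n_profile)
        if not grids:
            continue
        group, grid = grids[0]
        idx = [names.index(nm) for nm in group]
        mask = np.ones(k, dtype=bool)
        mask[idx] = False
        for point in grid:
            x0 = x_best.copy()
            x0[idx] = point

            def cond_obj(theta_rest):
                x = x0.copy()
                x[mask] = theta_rest
                return objective(x)

            res = minimize(
                cond_obj, x0[mask], method="Nelder-Mead",
                bounds=[(0.0, 1.0)] * int(mask.sum()),
                options={"maxfev": profile_maxfev, "xatol": 2e-3,
                         "fatol": 0.1, "adaptive": True},
            )
            x_slice = x0.copy()
            x_slice[mask] = np.clip(res.x, 0.0, 1.0)
            f_slice = float(res.fun)
            starts_log.append(
                {"profile": {nm: float(v) for nm, v in zip(group, point)},
                 "nll": f_slice, "params": _theta_to_params(x_slice, bounds),
                 "nfev": int(res.nfev), "success": bool(res.success)}
            )
            if f_slice < f_best:
                x_best, f_best = x_slice, f_slice

    # final polish: restart the full-dimensional simplex around the
    # incumbent at decreasing scales so it can track the valley instead of
    # collapsing inside it
    for scale in polish_scales:
        simplex = np.clip(
            np.vstack([x_best] + [x_best + scale * e for e in np.eye(k)]),
            0.0, 1.0,
        )
        res = minimize(
            objective, x_best, method="Nelder-Mead",
            bounds=[(0.0, 1.0)] * k,
            options={"maxfev": polish_maxfev, "xatol": 1e-3, "fatol": 0.05,
                     "adaptive": True, "initial_simplex": simplex},
        )
        if res.fun < f_best:
            x_best, f_best = res.x, float(res.fun)
        starts_log.append(
            {"polish_scale": scale, "nll": float(res.fun),
             "params": _theta_to_params(res.x, bounds),
             "nfev": int(res.nfev), "success": bool(res.success)}
        )

    params = _theta_to_params(x_best, bounds)
    nll = f_best
    return FitResult(
        model=model, params=params, nll=nll, aic=2.0 * k + 2.0 * nll,
        n_free=k, n_starts=n_starts, n_reps=n_reps, seed=seed,
        starts=starts_log,
        settings={"maxfev": maxfev, "n_screen": n_screen, "dt": dt,
                  "cutoff": cutoff, "bounds": {n: b[:2] for n, b in bounds.items()}},
    )


def summaries(data, probs=DEFAULT_QUANTILES) -> pd.DataFrame:
    """Psychometric / chronometric / quantile summary per coherence.

    Accepts an :class:`RTDataset` or the dict returned by
    :func:`simulate_rt_distribution`.  Returns one row per coherence with
    accuracy, mean correct/error RT and the RT quantiles by correctness.
    """
    if isinstance(data, RTDataset):
        cells = {}
        for coh in data.coherences:
            cells[float(coh)] = {
                "rt_correct": data.cell(coh, True),
                "rt_error": data.cell(coh, False),
                "n_censored": 0,
            }
    else:
        cells = data
    rows = []
    for coh in sorted(cells):
        c = cells[coh]
        rc, re_ = np.asarray(c["rt_correct"]), np.asarray(c["rt_error"])
        n = len(rc) + len(re_)
        row = {
            "coherence": coh,
            "n_trials": n,
            "n_censored": c.get("n_censored", 0),
            "accuracy": len(rc) / n if n else np.nan,
            "mean_rt_correct": rc.mean() if len(rc) else np.nan,
            "mean_rt_error": re_.mean() if len(re_) else np.nan,
        }
        for side, arr in (("correct", rc), ("error", re_)):
            qs = np.quantile(arr, probs) if len(arr) else np.full(len(probs), np.nan)
            for p, q in zip(probs, qs):
                row[f"q{int(round(p * 100))}_{side}"] = q
        rows.append(row)
    return pd.DataFrame(rows)
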