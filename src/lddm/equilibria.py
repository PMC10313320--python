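"""Fixed points, nullclines, Jacobians, stability and regime maps.

For a two-option circuit with gain weights w (local) and v (lateral), the
steady state of each R unit reduces to a nullcline in the (R1, R2) plane:

    v R2 = (V1 + B_R) / R1 - (w - beta) R1 - (1 + B_G - alpha)

(and symmetrically for R2).  Intersections of the two nullclines in the
positive quadrant are the equilibria of the full 3N-dimensional system;
their stability follows from the eigenvalues of the analytic Jacobian.
Counting equilibria by stability partitions the (alpha, beta) plane into
five territories, two of which implement normalized value coding and three
winner-take-all selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .dynamics import integrate, lddm_derivatives
from .params import CircuitState, GainMatrix, ModelParams

__all__ = [
    "EquilibriumPoint",
    "EquilibriumSet",
    "RegimeLabel",
    "nullcline",
    "find_equilibria",
    "jacobian",
    "classify_regime",
    "regime_map",
    "persistent_equilibria",
    "PersistentActivity",
    "attractor_type",
]

STABILITY_TOL = 1e-6

#: territory -> (n_equilibria, n_stable, n_unstable) and circuit function
TERRITORY_TABLE = {
    (1, 1, 0): ("dark_green", "normalization"),
    (3, 2, 1): ("blue", "WTA"),
    (3, 1, 2): ("green", "normalization"),
    (1, 0, 1): ("yellow", "WTA"),
    (0, 0, 0): ("red", "WTA"),
}


@dataclass
class EquilibriumPoint:
    """A fixed point of the circuit with its linear stability."""

    R: np.ndarray
    G: np.ndarray
    D: np.ndarray
    eigenvalues: np.ndarray
    stability: str  # "stable" | "unstable" | "marginal"

    @property
    def max_real(self) -> float:
        return float(np.max(self.eigenvalues.real))


@dataclass
class EquilibriumSet:
    """All equilibria found in a search box, deduplicated."""

    points: list
    search_box: tuple
    V: np.ndarray
    beta_now: float

    def __len__(self) -> int:
        return len(self.points)

    def count(self, stability: str) -> int:
        return sum(1 for p in self.points if p.stability == stability)

    @property
    def diagnostic(self) -> tuple:
        return (len(self.points), self.count("stable"), self.count("unstable"))


@dataclass
class RegimeLabel:
    alpha: float
    beta: float
    territory: str
    function: str
    diagnostic: tuple


def nullcline(
    which_R: int,
    grid,
    V,
    params: ModelParams,
    omega: GainMatrix,
    beta_now: float | None = None,
):
    """Complementary-R values along the nullcline of one R unit (N = 2).

    For ``which_R = 0``, returns R2 such that dR1/dt = 0 on each grid value
    of R1.  Grid points at or below zero are rejected (the nullcline is
    singular at R = 0).
    """
    if omega.n_options != 2:
        raise ValueError("nullclines are defined for the two-option circuit")
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("grid values must be positive (R = 0 is singular)")
    V = np.atleast_1d(np.asarray(V, dtype=float))
    b = params.beta if beta_now is None else float(beta_now)
    w, v = omega.w, omega.v
    c0 = 1.0 + params.B_G - params.alpha
    i = int(which_R)
    return ((V[i] + params.B_R) / grid - (w - b) * grid - c0) / v


def _full_point(R, params, omega, beta_now):
    R = np.asarray(R, dtype=float)
    D = beta_now * R
    G = omega.matrix @ R + params.B_G - D
    return R, G, D


def jacobian(
    R,
    V,
    params: ModelParams,
    omega: GainMatrix,
    beta_now: float | None = None,
) -> np.ndarray:
    """Analytic Jacobian of the LDDM at a candidate fixed point (3N x 3N).

    Rows are scaled by the respective 1/tau so the matrix is the true
    linearization; the scaling leaves the signs of the eigenvalue real
    parts, hence all stability conclusions, unchanged.  State ordering is
    (R1, G1, D1, R2, G2, D2, ...).
    """
    b = params.beta if beta_now is None else float(beta_now)
    R = np.atleast_1d(np.asarray(R, dtype=float))
    if np.any(R <= 0):
        raise ValueError("Jacobian requires strictly positive R (clamp-free)")
    n = R.shape[0]
    V = np.atleast_1d(np.asarray(V, dtype=float))
    _, G, _ = _full_point(R, params, omega, b)
    J = np.zeros((3 * n, 3 * n))
    for i in range(n):
        r, g, d = 3 * i, 3 * i + 1, 3 * i + 2
        J[r, r] = (-1.0 + params.alpha / (1.0 + G[i])) / params.tau_R
        J[r, g] = -(V[i] + params.B_R + params.alpha * R[i]) / (1.0 + G[i]) ** 2 / params.tau_R
        for j in range(n):
            J[g, 3 * j] = omega.matrix[i, j] / params.tau_G
        J[g, g] = -1.0 / params.tau_G
        J[g, d] = -1.0 / params.tau_G
        J[d, r] = b / params.tau_D
        J[d, d] = -1.0 / params.tau_D
    return J


def _stability(eigs: np.ndarray) -> str:
    re = eigs.real
    if np.all(re < -STABILITY_TOL):
        return "stable"
    if np.any(re > STABILITY_TOL):
        return "unstable"
    return "marginal"


def find_equilibria(
    V,
    params: ModelParams,
    omega: GainMatrix,
    beta_now: float | None = None,
    search_box: tuple = (1e-3, 300.0),
    n_scan: int = 2000,
) -> EquilibriumSet:
    """All positive-quadrant equilibria of the two-option circuit.

    Scans R1 over a log-spaced grid, maps each value through the
    R1-nullcline to a candidate R2, and polishes sign changes of the
    R2-nullcline residual with Brent's method.  An empty set is a valid
    result (the "red" territory).  Boundary (clamped) equilibria are
    excluded by construction.
    """
    if omega.n_options != 2:
        raise ValueError("find_equilibria operates on the two-option circuit")
    b = params.beta if beta_now is None else float(beta_now)
    V = np.atleast_1d(np.asarray(V, dtype=float))
    w, v = omega.w, omega.v
    c0 = 1.0 + params.B_G - params.alpha

    def R2_of(R1):
        return ((V[0] + params.B_R) / R1 - (w - b) * R1 - c0) / v

    def resid(R1):
        R2 = R2_of(R1)
        return (V[1] + params.B_R) / R2 - (w - b) * R2 - c0 - v * R1

    lo, hi = search_box
    grid = np.geomspace(lo, hi, n_scan)
    R2g = R2_of(grid)
    valid = R2g > 0
    h = np.full(n_scan, np.nan)
    h[valid] = (V[1] + params.B_R) / R2g[valid] - (w - b) * R2g[valid] - c0 - v * grid[valid]

    roots: list[float] = []
    for a_idx in range(n_scan - 1):
        ha, hb = h[a_idx], h[a_idx + 1]
        if not (np.isfinite(ha) and np.isfinite(hb)):
            continue
        if ha == 0.0:
            roots.append(grid[a_idx])
        elif ha * hb < 0:
            roots.append(brentq(resid, grid[a_idx], grid[a_idx + 1], xtol=1e-12, rtol=1e-14))

    points: list[EquilibriumPoint] = []
    for r1 in roots:
        r2 = R2_of(r1)
        if r2 <= 0:
            continue
        R = np.array([r1, r2])
        if any(np.linalg.norm(R - p.R) < 1e-4 for p in points):
            continue
        Rf, G, D = _full_point(R, params, omega, b)
        eigs = np.linalg.eigvals(jacobian(Rf, V, params, omega, b))
        points.append(EquilibriumPoint(Rf, G, D, eigs, _stability(eigs)))
    points.sort(key=lambda p: p.R[0])
    return EquilibriumSet(points, search_box, V, b)


def classify_regime(
    alpha: float,
    beta: float,
    params: ModelParams,
    omega: GainMatrix,
    V_equal,
    search_box: tuple = (1e-3, 1e4),
) -> RegimeLabel:
    """Territory and circuit function at one (alpha, beta) point.

    Classification is performed under equal inputs, the critical test of
    whether the circuit can select an option.  Diagnostic tuples outside
    the five known patterns are surfaced as "unclassified".
    """
    p = params.with_(alpha=float(alpha), beta=float(beta))
    eqs = find_equilibria(V_equal, p, omega, beta_now=beta, search_box=search_box)
    diag = eqs.diagnostic
    territory, function = TERRITORY_TABLE.get(diag, ("unclassified", "unclassified"))
    return RegimeLabel(float(alpha), float(beta), territory, function, diag)


def regime_map(
    alpha_grid,
    beta_grid,
    params: ModelParams,
    omega: GainMatrix,
    V_equal,
    search_box: tuple = (1e-3, 1e4),
):
    """Classify every (alpha, beta) grid cell; returns a DataFrame."""
    import pandas as pd

    rows = []
    for a in np.asarray(alpha_grid, dtype=float):
        for b in np.asarray(beta_grid, dtype=float):
            lab = classify_regime(a, b, params, omega, V_equal, search_box)
            rows.append(
                {
                    "alpha": a,
                    "beta": b,
                    "territory": lab.territory,
                    "function": lab.function,
                    "n_eq": lab.diagnostic[0],
                    "n_stable": lab.diagnostic[1],
                    "n_unstable": lab.diagnostic[2],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PersistentActivity:
    """Analytic description of the no-input fixed-point structure."""

    kind: str  # "none" | "line" | "point" | "corner"
    sum_level: float | None = None  # line: conserved sum of R activities
    point_level: float | None = None  # point: common per-unit activity
    winner_level: float | None = None  # corner: activity of the winning unit
    bounded: bool = True


def persistent_equilibria(
    params: ModelParams,
    omega: GainMatrix,
    beta_now: float | None = None,
) -> PersistentActivity:
    """Fixed-point structure after input withdrawal (V = 0).

    Case analysis on the elevated-activity condition alpha > 1 + B_G, the
    gain-weight symmetry (v vs w) and the disinhibition state:

    - alpha <= 1 + B_G: activity decays, no elevated fixed point.
    - beta = 0, v = w: line attractor, sum R* = (alpha - 1 - B_G) / w.
    - beta = 0, v < w: point attractor, R_i* = (alpha - 1 - B_G) / (w + v).
    - beta = 0, v > w: WTA corners, winner at (alpha - 1 - B_G) / w.
    - 0 < beta < w (symmetric weights): WTA corners, winner at
      (alpha - 1 - B_G) / (w - beta).
    - beta >= w: WTA with unbounded winner activity.
    """
    b = params.beta if beta_now is None else float(beta_now)
    w, v = omega.w, omega.v
    if w + v == 0:
        raise ValueError("degenerate gain matrix: w + v = 0")
    excess = params.alpha - 1.0 - params.B_G
    if excess <= 0:
        return PersistentActivity("none")
    if b == 0:
        if np.isclose(v, w):
            return PersistentActivity("line", sum_level=excess / w)
        if v < w:
            return PersistentActivity("point", point_level=excess / (w + v))
        return PersistentActivity("corner", winner_level=excess / w)
    if b < w:
        return PersistentActivity("corner", winner_level=excess / (w - b))
    return PersistentActivity("corner", winner_level=np.inf, bounded=False)


@dataclass
class _Stage:
    duration: float
    V: np.ndarray
    beta_on: bool
    label: str = ""


@dataclass
class _Proto:
    stages: list


def attractor_type(
    params: ModelParams,
    omega: GainMatrix,
    beta_now: float | None = None,
    initial_ratios=(0.25, 0.5, 0.8, 1.25, 2.0, 4.0),
    total_level: float = 10.0,
    duration: float = 20.0,
    dt: float = 0.001,
    rel_tol: float = 1e-3,
) -> str:
    """Probe the no-input attractor structure by simulation.

    Noiseless trajectories are launched from several initial R1/R2 ratios;
    endpoints classify the attractor: "line" (distinct endpoints, common
    sum), "point" (coincident endpoints), "corner" (one-hot winner-take-all
    patterns) or "none" (no convergence / decay to zero).
    """
    b = params.beta if beta_now is None else float(beta_now)
    p = params.with_(sigma=0.0)
    n = omega.n_options
    endpoints = []
    for ratio in initial_ratios:
        R0 = np.full(n, total_level / n)
        R0[0] = ratio * R0[-1]
        R0 *= total_level / R0.sum()
        D0 = b * R0
        G0 = omega.matrix @ R0 + p.B_G - D0
        state = CircuitState(R0, np.maximum(G0, 0.0), D0)
        proto = _Proto([_Stage(duration, np.zeros(n), beta_on=b > 0)])
        p_run = p.with_(beta=b if b > 0 else p.beta)
        traj = integrate(
            lddm_derivatives, state, proto, p_run, omega, dt=dt,
            stop_when=lambda s: np.max(s.R) > 1e5,
        )
        end = traj.R[-1]
        rate = np.abs(traj.R[-1] - traj.R[-2]) / dt
        converged = np.all(rate < 1e-3) or np.max(end) > 1e5
        endpoints.append((end, converged))

    ends = np.array([e for e, _ in endpoints])
    if not all(c for _, c in endpoints):
        return "none"
    # activity decaying toward zero (alpha <= 1 + B_G decays algebraically,
    # so endpoints after finite time are small but nonzero)
    if np.all(ends.sum(axis=1) < 0.01 * total_level):
        return "none"
    # corner: all mass on one unit
    shares = ends / np.maximum(ends.sum(axis=1, keepdims=True), 1e-300)
    if np.all(shares.max(axis=1) > 0.99):
        return "corner"
    spread = ends.std(axis=0).max() / max(ends.mean(), 1e-300)
    if spread < rel_tol:
        return "point"
    sums = ends.sum(axis=1)
    if (sums.max() - sums.min()) / sums.mean() < rel_tol:
        return "line"
    return "none"
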