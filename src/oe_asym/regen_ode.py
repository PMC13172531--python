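"""Four-compartment ODE model of injury-induced stem-cell activation.

Horizontal basal cells (HBCs) of the olfactory epithelium are split into
cell-cycle compartments H1 (G1), H2 (S) and H3 (G2/M), with D the
abundance of differentiated cells produced at division:

    dH1/dt = -k1 H1 + k3 H3
    dH2/dt =  k1 H1 - k2 H2
    dH3/dt =  k2 H2 - k3 H3
    dD/dt  =  k3 H3 - gamma D

The G1->S rate carries negative feedback from the differentiated-cell
pool through a Hill function, k1 = k_max / (1 + (D/K)^h): once the tissue
has regenerated, accumulated D slows further stem-cell activation.  An
activation delay tau holds the system at its basal state for t < tau
after injury.  H2 (the S-phase fraction) is the model readout compared
against measured p63+/EdU+ fractions.

H1 + H2 + H3 is conserved exactly (the first three right-hand sides sum
to zero), which every simulation asserts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from scipy.stats import qmc

__all__ = [
    "RegenParams",
    "RegenState",
    "Trajectory",
    "EdUTimecourse",
    "FitConfig",
    "RegenFit",
    "IntegrationError",
    "hill_rate",
    "basal_state",
    "simulate_trajectory",
    "fit_edu_timecourse",
    "cell_phase_durations",
    "DEFAULT_PARAMS",
]

#: Basal p63+/EdU+ fraction observed in uninjured tissue.
BASAL_S_FRACTION = 0.065

HOURS_PER_DAY = 24.0


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails or breaches its tolerances."""


@dataclass(frozen=True)
class RegenParams:
    """Rate and feedback constants of the regeneration model.

    k_max : maximal G1->S rate at D = 0, per day
    K     : feedback half-saturation of the differentiated-cell signal, a.u.
    h     : Hill coefficient (dimensionless, >= 1)
    k2    : S -> G2/M transition rate, per day (1/k2 = S-phase duration)
    k3    : G2/M division rate, per day (1/k3 = G2/M duration)
    gamma : differentiated-cell turnover rate, per day
    tau   : post-injury activation delay, days
    """

    k_max: float = 2.27
    K: float = 0.4
    h: float = 2.0
    k2: float = 1.33
    k3: float = 6.0
    gamma: float = 0.06
    tau: float = 0.8

    def __post_init__(self) -> None:
        for name in ("k_max", "K", "k2", "k3", "gamma"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.h < 1:
            raise ValueError("Hill coefficient h must be >= 1")
        if self.tau < 0:
            raise ValueError("delay tau must be >= 0")


#: Parameter vector estimated from the post-injury EdU time course.
DEFAULT_PARAMS = RegenParams()


@dataclass(frozen=True)
class RegenState:
    """HBC cell-cycle fractions (H1, H2, H3) and differentiated pool D."""

    H1: float
    H2: float
    H3: float
    D: float = 0.0

    def __post_init__(self) -> None:
        for name in ("H1", "H2", "H3", "D"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total_hbc(self) -> float:
        return self.H1 + self.H2 + self.H3

    def as_array(self) -> np.ndarray:
        return np.array([self.H1, self.H2, self.H3, self.D], dtype=float)


@dataclass
class Trajectory:
    """Solution sampled on a time grid (days)."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 4): columns H1, H2, H3, D
    params: RegenParams

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, 4):
            raise ValueError("states must have shape (len(times), 4)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def H1(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def H2(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def H3(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def D(self) -> np.ndarray:
        return self.states[:, 3]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "H1": self.H1, "H2": self.H2,
             "H3": self.H3, "D": self.D}
        )


@dataclass
class EdUTimecourse:
    """Observed EdU-labelling fractions by day post injury.

    Rows carry either raw counts (n_total scored p63+ cells, n_positive of
    them EdU+) or a precomputed fraction.
    """

    table: pd.DataFrame  # columns: day, fraction [, n_total, n_positive]

    def __post_init__(self) -> None:
        t = self.table
        if "fraction" not in t.columns:
            if not {"n_total", "n_positive"} <= set(t.columns):
                raise ValueError("need either 'fraction' or counts columns")
            if (t["n_positive"] > t["n_total"]).any() or (t["n_positive"] < 0).any():
                raise ValueError("need 0 <= n_positive <= n_total")
            t = t.assign(fraction=t["n_positive"] / t["n_total"])
        if (t["day"] < 0).any():
            raise ValueError("days must be >= 0")
        if ((t["fraction"] < 0) | (t["fraction"] > 1)).any():
            raise ValueError("fractions must lie in [0, 1]")
        self.table = t.sort_values("day").reset_index(drop=True)

    @property
    def days(self) -> np.ndarray:
        return self.table["day"].to_numpy(dtype=float)

    @property
    def fractions(self) -> np.ndarray:
        return self.table["fraction"].to_numpy(dtype=float)

    @classmethod
    def from_counts(cls, day, n_total, n_positive) -> "EdUTimecourse":
        return cls(pd.DataFrame(
            {"day": day, "n_total": n_total, "n_positive": n_positive}))

    @classmethod
    def from_fractions(cls, day, fraction) -> "EdUTimecourse":
        return cls(pd.DataFrame({"day": day, "fraction": fraction}))


def hill_rate(D, params: RegenParams):
    """Feedback-modulated G1->S rate k1 = k_max / (1 + (D/K)^h).

    Strictly decreasing in D, equal to k_max at D = 0 (no differentiated
    cells: fastest activation) and to k_max/2 at D = K.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("differentiated-cell abundance D must be >= 0")
    out = params.k_max / (1.0 + (D / params.K) ** params.h)
    return float(out) if out.ndim == 0 else out


def basal_state(h2_basal: float = BASAL_S_FRACTION,
                params: RegenParams = DEFAULT_PARAMS) -> RegenState:
    """Quasi-steady basal state given an observed S-phase fraction.

    Sets H2 = h2_basal, balances the S -> G2/M flux (H3 = (k2/k3) H2),
    puts the remainder in G1, and starts with no differentiated cells.
    """
    if not 0 < h2_basal < 1:
        raise ValueError("h2_basal must be in (0, 1)")
    H2 = h2_basal
    H3 = (params.k2 / params.k3) * h2_basal
    H1 = 1.0 - H2 - H3
    if H1 <= 0:
        raise ValueError(
            f"basal fractions H2={H2:.3g}, H3={H3:.3g} leave no G1 mass")
    return RegenState(H1=H1, H2=H2, H3=H3, D=0.0)


def _rhs(t, y, p: RegenParams):
    H1, H2, H3, D = y
    k1 = p.k_max / (1.0 + (max(D, 0.0) / p.K) ** p.h)
    return (
        -k1 * H1 + p.k3 * H3,
        k1 * H1 - p.k2 * H2,
        p.k2 * H2 - p.k3 * H3,
        p.k3 * H3 - p.gamma * D,
    )


def simulate_trajectory(
    init: RegenState,
    params: RegenParams,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    conservation_tol: float = 1e-8,
) -> Trajectory:
    """Integrate the model on a time grid starting at day 0.

    The state is held at ``init`` for t < tau (activation delay) and then
    integrated with an adaptive explicit Runge-Kutta scheme.  Raises
    :class:`IntegrationError` if the solver fails, a component goes
    negative beyond tolerance, or H1+H2+H3 drifts by more than
    ``conservation_tol``.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise ValueError("times must be a nonempty 1-D grid")
    if times[0] != 0:
        raise ValueError("time grid must start at day 0 (injury)")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    y0 = init.as_array()
    states = np.tile(y0, (times.size, 1))
    tau = params.tau
    after = times > tau
    t_end = times[-1]
    if t_end > tau:
        t_eval = times[after]
        sol = solve_ivp(
            _rhs, (tau, t_end), y0, t_eval=t_eval, args=(params,),
            method="RK45", rtol=rtol, atol=atol, dense_output=False,
        )
        if not sol.success:
            raise IntegrationError(f"ODE solver failed: {sol.message}")
        ys = sol.y.T
        neg = ys.min()
        if neg < -100 * atol:
            raise IntegrationError(f"negative component {neg:.3e} in solution")
        states[after] = np.clip(ys, 0.0, None)

    total0 = y0[:3].sum()
    drift = np.abs(states[:, :3].sum(axis=1) - total0).max()
    if drift > conservation_tol:
        raise IntegrationError(
            f"H1+H2+H3 drift {drift:.3e} exceeds tolerance {conservation_tol:.1e}")
    return Trajectory(times=times, states=states, params=params)


def cell_phase_durations(params: RegenParams = DEFAULT_PARAMS) -> dict[str, dict[str, float]]:
    """Mean phase durations implied by the rates, in days and hours.

    S phase lasts 1/k2, G2/M lasts 1/k3, and the minimal G1 duration (at
    D = 0, i.e. maximal activation) is 1/k_max.
    """
    days = {"G1_min": 1.0 / params.k_max, "S": 1.0 / params.k2,
            "G2M": 1.0 / params.k3}
    return {
        "days": days,
        "hours": {k: v * HOURS_PER_DAY for k, v in days.items()},
    }


@dataclass
class FitConfig:
    """Configuration of the least-squares fit of H2 to EdU fractions."""

    n_starts: int = 16
    h_grid: tuple[int, ...] = (1, 2, 3, 4)
    bounds: dict = field(default_factory=lambda: {
        "k_max": (1e-3, 10.0), "K": (1e-3, 5.0), "gamma": (1e-3, 2.0),
        "tau": (0.0, None),  # None -> max observed day
    })
    h2_basal: float = BASAL_S_FRACTION
    weighted: bool = False  # binomial weights 1/sqrt(p(1-p)/n)
    seed: int | None = None
    max_nfev: int = 80
    solver_rtol: float = 1e-8
    solver_atol: float = 1e-10


@dataclass
class RegenFit:
    """Best-fit parameters with diagnostics."""

    params: RegenParams
    objective: float  # sum of squared residuals at the optimum
    residuals: np.ndarray
    converged: bool
    non_identifiable: bool
    n_local_fits: int
    local_solutions: list[dict] = field(default_factory=list)


def fit_edu_timecourse(
    data: EdUTimecourse,
    config: FitConfig | None = None,
    params_template: RegenParams = DEFAULT_PARAMS,
    starts: np.ndarray | None = None,
) -> RegenFit:
    """Fit (k_max, K, gamma, tau, h) by least squares of H2 to EdU fractions.

    k2 and k3 stay fixed at the template values (they are pinned by the
    directly measured S and G2/M durations).  The four continuous
    parameters are fitted by multi-start trust-region least squares from
    Latin-hypercube starting points within bounds (or explicit ``starts``
    rows of k_max, K, gamma, tau); the integer Hill coefficient h is
    optimized over ``h_grid``.  The best objective wins,
    ties broken by the smallest parameter-vector norm.  If several
    distinct optima are indistinguishable in objective, the fit is
    flagged non-identifiable instead of silently picking one.
    """
    cfg = config or FitConfig()
    days = data.days
    fracs = data.fractions
    if days.size < 5:
        raise ValueError("need at least 5 time points to fit")
    tmax = float(days.max())
    bounds = dict(cfg.bounds)
    lo_tau, hi_tau = bounds["tau"]
    bounds["tau"] = (lo_tau, tmax if hi_tau is None else hi_tau)
    names = ("k_max", "K", "gamma", "tau")
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])

    if cfg.weighted:
        n_tot = data.table.get("n_total")
        if n_tot is None:
            raise ValueError("weighted fit needs n_total counts")
        p = np.clip(fracs, 1e-3, 1 - 1e-3)
        w = 1.0 / np.sqrt(p * (1 - p) / n_tot.to_numpy(dtype=float))
    else:
        w = np.ones_like(fracs)

    grid = days.copy()
    if grid[0] != 0:
        grid = np.concatenate([[0.0], grid])
        sel = slice(1, None)
    else:
        sel = slice(None)

    def residuals(x, h):
        p = replace(params_template, k_max=x[0], K=x[1], gamma=x[2],
                    tau=x[3], h=float(h))
        init = basal_state(cfg.h2_basal, p)
        try:
            traj = simulate_trajectory(
                init, p, grid, rtol=cfg.solver_rtol, atol=cfg.solver_atol)
        except IntegrationError:
            return np.full(fracs.size, 1e3)
        return w * (traj.H2[sel] - fracs)

    if starts is None:
        sampler = qmc.LatinHypercube(d=4, seed=cfg.seed)
        starts = qmc.scale(sampler.random(cfg.n_starts), lo, hi)
    else:
        starts = np.atleast_2d(np.asarray(starts, dtype=float))

    solutions = []
    for h in cfg.h_grid:
        for x0 in starts:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = least_squares(
                    residuals, x0, args=(h,), bounds=(lo, hi),
                    method="trf", max_nfev=cfg.max_nfev, xtol=1e-10,
                )
            solutions.append({
                "h": int(h),
                **dict(zip(names, res.x)),
                "objective": float(np.sum(res.fun**2)),
                "success": bool(res.success),
                "x": res.x,
            })

    converged = any(s["success"] for s in solutions)
    pool = [s for s in solutions if s["success"]] or solutions
    best = min(pool, key=lambda s: (s["objective"], float(np.linalg.norm(s["x"]))))
    params = replace(
        params_template, k_max=best["k_max"], K=best["K"],
        gamma=best["gamma"], tau=best["tau"], h=float(best["h"]),
    )
    resid = residuals(best["x"], best["h"])

    # non-identifiability: essentially-equal objectives reached from
    # parameter vectors that differ grossly in k_max or tau
    thresh = best["objective"] + max(1e-8, 1e-4 * best["objective"])
    near = [s for s in pool if s["objective"] <= thresh]
    kspread = max(s["k_max"] for s in near) - min(s["k_max"] for s in near)
    tspread = max(s["tau"] for s in near) - min(s["tau"] for s in near)
    non_identifiable = bool(kspread > 0.5 * best["k_max"] + 1e-9 or
                            tspread > 1.0)

    for s in solutions:
        s.pop("x")
    return RegenFit(
        params=params,
        objective=best["objective"],
        residuals=resid,
        converged=converged,
        non_identifiable=non_identifiable,
        n_local_fits=len(solutions),
        local_solutions=sorted(solutions, key=lambda s: s["objective"])[:10],
    )
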