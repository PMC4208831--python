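"""Parameter estimation against observation tables.

Four fitters mirror how the preset parameter values were originally
obtained from experiments:

``fit_growth``
    (Gamma_0, alpha) of the volume-damped growth law from an untreated
    tumor-volume time course.
``fit_shedding``
    the shedding rate constant k_s (optionally permeability-switch and
    decay parameters) from steady-state shed-antigen concentrations in
    ECS and blood across tumor volumes.
``fit_translocation``
    the endosomal degradation rate chi_ce (equivalently the translocated
    fraction omega with k_t fixed) from a treated tumor-volume course.
``fit_endocytosis``
    the endocytosis rate k_e from an in-vitro internalization time
    course of surface-labeled immunotoxin.

Concentration and volume observations span decades and carry
multiplicative error, so all residuals are formed in log space.
Optimization uses bounded trust-region least squares with log-scale
parameterization; the shedding fit multi-starts when three or more
parameters are freed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .params import ModelParameters, with_overrides
from .simulator import (SolverOptions, run_simulation,
                        steady_state_shed_antigen)

__all__ = ["ObservationSet", "FitResult", "fit_growth", "fit_shedding",
           "fit_translocation", "fit_endocytosis",
           "internalized_fraction", "bootstrap_fit"]

OBSERVATION_KINDS = ("shed_ecs_vs_volume", "shed_blood_vs_volume",
                     "volume_vs_time", "internalization_vs_time")

# fields of the shedding forward model that may be freed, with bounds
_SHED_FREE_FIELDS = {
    "k_s": ("receptor.k_s", 1e-6, 10.0),
    "P_low": ("permeability.P_low_cm_s", 1e-9, 1e-4),
    "P_high": ("permeability.P_high_cm_s", 1e-9, 1e-3),
    "V_c": ("permeability.V_c_mm3", 1.0, 5e3),
    "a": ("permeability.a_per_mm3", 1e-4, 1.0),
    "chi_efR": ("ecs_deg.chi_efR", 1e-4, 100.0),
    "chi_bfR": ("blood.chi_bfR", 1e-2, 1e3),
}


@dataclass
class ObservationSet:
    """(x, y, sigma) observation tuples of one kind.

    ``sigma`` is the lognormal noise scale of each point (dimensionless,
    in log units); it weights the log-space residuals.
    """

    kind: str
    x: np.ndarray
    y: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if sigma.ndim == 0:
            sigma = np.full_like(self.y, float(sigma))
        self.sigma = sigma
        if self.kind not in OBSERVATION_KINDS:
            raise ValueError(f"unknown observation kind {self.kind!r}")
        if not (self.x.shape == self.y.shape == self.sigma.shape):
            raise ValueError("x, y, sigma must have equal length")
        if np.any(self.y < 0):
            raise ValueError("observations must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"kind": self.kind, "x": self.x, "y": self.y,
                             "sigma": self.sigma})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path,
                 kind: str | None = None) -> "ObservationSet":
        df = pd.read_csv(path)
        if kind is not None:
            df = df[df["kind"] == kind]
        kinds = df["kind"].unique()
        if len(kinds) != 1:
            raise ValueError(f"expected one observation kind, found {kinds}")
        return cls(kind=kinds[0], x=df["x"].to_numpy(),
                   y=df["y"].to_numpy(), sigma=df["sigma"].to_numpy())


@dataclass
class FitResult:
    """Point estimates plus fit diagnostics."""

    estimates: dict[str, float]
    loss: float
    n_evals: int
    converged: bool
    flags: list[str] = field(default_factory=list)
    bootstrap_ci: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.converged and not math.isfinite(self.loss):
            raise ValueError("converged fit must have finite loss")


def _log_residuals(model: np.ndarray, obs: ObservationSet,
                   floor: float = 1e-30) -> np.ndarray:
    m = np.maximum(model, floor)
    y = np.maximum(obs.y, floor)
    return np.log(m / y) / obs.sigma


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def _grow(V0: float, Gamma_0: float, alpha: float,
          t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    sol = solve_ivp(lambda tt, v: Gamma_0 * np.exp(-alpha * v) * v,
                    (min(0.0, t.min()), t.max()), [V0], t_eval=np.sort(t),
                    method="LSODA", rtol=1e-9, atol=1e-12)
    order = np.argsort(np.argsort(t))
    return sol.y[0][order]


def fit_growth(obs: ObservationSet, fix_alpha: float | None = None,
               ) -> FitResult:
    """Fit (Gamma_0, alpha) of dV/dt = Gamma_0 exp(-alpha V) V.

    The initial volume is fitted as a nuisance parameter anchored at the
    first observation.  With ``fix_alpha=0`` the model reduces to pure
    exponential growth and Gamma_0 is the log-slope.
    """
    if obs.kind != "volume_vs_time":
        raise ValueError("fit_growth expects volume_vs_time observations")
    if obs.x.size < 4:
        raise ValueError("need at least 4 time points")
    i0 = int(np.argmin(obs.x))
    V0_init = max(obs.y[i0], 1e-6)
    g0_init = 0.02

    free_alpha = fix_alpha is None

    def theta_to_params(theta):
        g0 = math.exp(theta[0])
        V0 = math.exp(theta[1])
        al = math.exp(theta[2]) if free_alpha else fix_alpha
        return g0, al, V0

    def resid(theta):
        g0, al, V0 = theta_to_params(theta)
        return _log_residuals(_grow(V0, g0, al, obs.x), obs)

    x0 = [math.log(g0_init), math.log(V0_init)]
    if free_alpha:
        x0.append(math.log(1e-3))
    sol = least_squares(resid, x0, method="trf", xtol=1e-12, ftol=1e-12)
    g0, al, V0 = theta_to_params(sol.x)
    return FitResult(
        estimates={"Gamma_0": g0, "alpha": al, "V0": V0},
        loss=float(2 * sol.cost), n_evals=int(sol.nfev),
        converged=bool(sol.success))


# ---------------------------------------------------------------------------
# shedding
# ---------------------------------------------------------------------------

def fit_shedding(obs_sets: Sequence[ObservationSet], params: ModelParameters,
                 free: Sequence[str] = ("k_s",), n_shells: int = 25,
                 n_starts: int = 5, seed: int = 0) -> FitResult:
    """Fit shedding/permeability parameters to steady-state antigen scans.

    ``obs_sets`` holds shed_ecs_vs_volume and/or shed_blood_vs_volume
    observations (x = tumor volume, mm³).  Only the parameters named in
    ``free`` are estimated (default: k_s alone, permeability held at the
    preset — the procedure used for the CD25 system); the rest stay at
    their values in ``params``.  Multi-start is used for fits with three
    or more free parameters.
    """
    for o in obs_sets:
        if o.kind not in ("shed_ecs_vs_volume", "shed_blood_vs_volume"):
            raise ValueError(f"unsupported kind {o.kind} for fit_shedding")
    unknown = [f for f in free if f not in _SHED_FREE_FIELDS]
    if unknown:
        raise ValueError(f"unknown free parameters {unknown}; "
                         f"choose from {sorted(_SHED_FREE_FIELDS)}")
    paths = [_SHED_FREE_FIELDS[f][0] for f in free]
    lo = np.log([_SHED_FREE_FIELDS[f][1] for f in free])
    hi = np.log([_SHED_FREE_FIELDS[f][2] for f in free])

    def current(f):
        path = _SHED_FREE_FIELDS[f][0]
        obj = params
        for part in path.split("."):
            obj = getattr(obj, part)
        if obj is None and f == "chi_bfR":
            obj = params.chi_bfR
        return float(obj)

    volumes = np.unique(np.concatenate([o.x for o in obs_sets]))

    def forward(theta):
        p = with_overrides(params,
                           dict(zip(paths, np.exp(theta))))
        table = {v: steady_state_shed_antigen(p, v, n_shells)
                 for v in volumes}
        out = []
        for o in obs_sets:
            if o.kind == "shed_ecs_vs_volume":
                model = np.array([table[v].ecs_avg_nM for v in o.x])
            else:
                model = np.array([table[v].blood_nM for v in o.x])
            out.append(_log_residuals(model, o))
        return np.concatenate(out)

    x0 = np.log([max(current(f), 1.01e-6 if f == "k_s" else 1e-8)
                 for f in free])
    starts = [x0]
    if len(free) >= 3:
        rng = np.random.default_rng(seed)
        for _ in range(n_starts - 1):
            starts.append(lo + rng.random(len(free)) * (hi - lo))

    best = None
    n_evals = 0
    for s in starts:
        sol = least_squares(forward, np.clip(s, lo, hi), bounds=(lo, hi),
                            method="trf", xtol=1e-12, ftol=1e-12)
        n_evals += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol

    flags = []
    if best.jac is not None and best.jac.size:
        sv = np.linalg.svd(best.jac, compute_uv=False)
        cond = sv[0] / max(sv[-1], 1e-300)
        if cond > 1e6:
            flags.append("non_identifiable")
        at_bound = np.isclose(best.x, lo) | np.isclose(best.x, hi)
        if at_bound.any():
            flags.append("at_bound:" + ",".join(
                np.array(free)[at_bound]))
    est = dict(zip(free, np.exp(best.x)))
    return FitResult(estimates=est, loss=float(2 * best.cost),
                     n_evals=n_evals, converged=bool(best.success),
                     flags=flags)


# ---------------------------------------------------------------------------
# translocation (chi_ce)
# ---------------------------------------------------------------------------

def fit_translocation(obs: ObservationSet, params: ModelParameters,
                      schedule: Sequence[tuple[float, float]],
                      V0_mm3: float,
                      options: SolverOptions | None = None) -> FitResult:
    """Fit the endosomal degradation rate chi_ce to a treated volume course.

    One-dimensional log-scale fit; each evaluation integrates the full
    delivery model under the given dose schedule.  Reported alongside is
    the implied translocated fraction omega = k_t / (chi_ce + k_t).
    """
    if obs.kind != "volume_vs_time":
        raise ValueError("fit_translocation expects volume_vs_time data")
    options = options or SolverOptions(n_shells=9)
    t_end = float(obs.x.max())

    def resid(theta):
        p = with_overrides(params, {"receptor.chi_ce": math.exp(theta[0])})
        traj = run_simulation(p, schedule, V0_mm3, t_end, options)
        model = np.interp(obs.x, traj.times, traj.volumes)
        return _log_residuals(model, obs)

    x0 = [math.log(max(params.receptor.chi_ce, 1e-3))]
    sol = least_squares(resid, x0, bounds=([math.log(1e-3)], [math.log(1e4)]),
                        method="trf", xtol=1e-8, ftol=1e-10, diff_step=0.05)
    chi = math.exp(sol.x[0])
    kt = params.receptor.k_t
    return FitResult(
        estimates={"chi_ce": chi, "omega": kt / (chi + kt)},
        loss=float(2 * sol.cost), n_evals=int(sol.nfev),
        converged=bool(sol.success))


# ---------------------------------------------------------------------------
# endocytosis
# ---------------------------------------------------------------------------

def internalized_fraction(t, k_e: float, k_d: float):
    """Two-compartment surface -> internal model for labeling assays.

    Surface-bound label B (B(0) = 1) is internalized at k_e or released
    at k_d; internal label I accumulates without recycling.  The assay
    reads the internalized fraction of cell-associated label,
    I / (I + B), which rises from 0 toward 1.
    """
    t = np.asarray(t, dtype=float)
    k = k_e + k_d
    if k == 0:
        return np.zeros_like(t)
    B = np.exp(-k * t)
    I = k_e / k * (1.0 - B)
    with np.errstate(invalid="ignore"):
        f = np.where(I + B > 0, I / (I + B), 1.0 if k_e > 0 else 0.0)
    return f


def fit_endocytosis(obs: ObservationSet, k_d: float,
                    k_e_bounds: tuple[float, float] = (1e-6, 100.0)
                    ) -> FitResult:
    """Fit k_e to an internalized-fraction time course (k_d held fixed)."""
    if obs.kind != "internalization_vs_time":
        raise ValueError("fit_endocytosis expects internalization_vs_time")

    def resid(theta):
        f = internalized_fraction(obs.x, math.exp(theta[0]), k_d)
        # fractions are bounded; use additive residuals weighted by sigma
        return (f - obs.y) / obs.sigma

    sol = least_squares(resid, [math.log(0.1)],
                        bounds=([math.log(k_e_bounds[0])],
                                [math.log(k_e_bounds[1])]),
                        method="trf", xtol=1e-14, ftol=1e-14)
    ke = math.exp(sol.x[0])
    flags = []
    if np.isclose(sol.x[0], math.log(k_e_bounds[0]), atol=1e-6):
        flags.append("at_lower_bound")
    return FitResult(estimates={"k_e": ke}, loss=float(2 * sol.cost),
                     n_evals=int(sol.nfev), converged=bool(sol.success),
                     flags=flags)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_fit(fitter: Callable[[Sequence[ObservationSet]], FitResult],
                  obs_sets: Sequence[ObservationSet], n_resamples: int = 100,
                  seed: int = 0, level: float = 0.9) -> dict[str, tuple[float, float]]:
    """Nonparametric case-resampling bootstrap confidence intervals.

    ``fitter`` maps a list of observation sets to a FitResult; points are
    resampled with replacement within each set.
    """
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {}
    for _ in range(n_resamples):
        resampled = []
        for o in obs_sets:
            idx = rng.integers(0, o.x.size, o.x.size)
            resampled.append(ObservationSet(kind=o.kind, x=o.x[idx],
                                            y=o.y[idx], sigma=o.sigma[idx]))
        res = fitter(resampled)
        for k, v in res.estimates.items():
            draws.setdefault(k, []).append(v)
    q = (1.0 - level) / 2.0
    return {k: (float(np.quantile(v, q)), float(np.quantile(v, 1 - q)))
            for k, v in draws.items()}
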