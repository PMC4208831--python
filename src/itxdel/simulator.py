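"""Method-of-lines simulator for the representative-unit delivery model.

The tumor is a collection of m identical cylindrical representative units
(RUs) sharing one well-mixed blood compartment; the tumor volume is m
times the RU volume, so blood/tissue exchange scales with V(t) while all
RUs stay identical.  Within an RU, three extracellular species (free
immunotoxin, free shed antigen, and their complex) diffuse radially and
exchange with blood through the vessel wall under a Robin boundary
condition with the sigmoidal volume-dependent permeability.  Cells carry
surface, endosomal, and cytosolic toxin pools and progress irreversibly
from un-intoxicated through intoxicated to dead.

State layout (n = number of radial shells), all ECS fields ECS-referenced
in nM, per-cell pools in molecules/cell, and type-2/3 pools as per-tissue-
volume totals (molecules/cm³ = per-cell value × density) to avoid
singularities when a population density passes through zero:

    [C_efT(n), C_efR(n), C_ecR(n),
     rho1(n), rho2(n), rho3(n),
     B1(n), Ten1(n), Tcc1(n),
     W2R(n), W2B(n), W2en(n), W2cc(n),
     W3R(n), W3B(n),
     C_bT, C_bfR, C_bcR, V]

Free surface receptors on type-1 cells are not a state: synthesis pins
R_free1 + B1 = R*.  Bolus doses are instantaneous jumps of the blood
immunotoxin concentration at hard integration breakpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.integrate import solve_ivp

from . import kinetics
from .geometry import (RadialGrid, apply_diffusion, build_radial_grid,
                       robin_wall_coupling)
from .params import ModelParameters, with_overrides

__all__ = [
    "SolverOptions", "Trajectory", "SimulationError", "ShedSteadyState",
    "run_simulation", "simulate_untreated_growth", "steady_state_shed_antigen",
    "shed_antigen_steady_profile", "compare_shedding_scenarios",
    "sweep_antigen_density", "species_totals", "StateLayout", "initial_state",
]

_NM_TO_NMOL_PER_CM3 = 1e-3
N_AVOGADRO = 6.02214076e23


class SimulationError(RuntimeError):
    """Integrator failure or an inadmissible state excursion."""


@dataclass(frozen=True)
class SolverOptions:
    """Numerical settings for the stiff method-of-lines integration."""

    n_shells: int = 25
    method: str = "BDF"
    rtol: float = 1e-6
    atol_conc: float = 1e-9       # nM fields (ECS + blood)
    atol_count: float = 1e-5      # per-cell molecule counts
    atol_density: float = 1.0     # cells/cm³ and molecules/cm³ totals
    atol_volume: float = 1e-6     # mm³
    points_per_hour: float = 1.0
    equilibrate_shed: bool = True
    negative_tolerance_scale: float = 1e-3  # fraction of the atol scale class
    max_step: float = math.inf
    # volumes below this are treated as eradication (well under one cell);
    # integration stops and the final state is held for remaining outputs
    V_stop_mm3: float = 1e-8


class StateLayout:
    """Index bookkeeping for the packed state vector."""

    FIELDS = ("C_efT", "C_efR", "C_ecR", "rho1", "rho2", "rho3",
              "B1", "Ten1", "Tcc1", "W2R", "W2B", "W2en", "W2cc",
              "W3R", "W3B")

    def __init__(self, n_shells: int):
        self.n = n_shells
        self.size = 15 * n_shells + 4
        self.i_CbT = 15 * n_shells
        self.i_CbfR = 15 * n_shells + 1
        self.i_CbcR = 15 * n_shells + 2
        self.i_V = 15 * n_shells + 3

    def sl(self, name: str) -> slice:
        k = self.FIELDS.index(name)
        return slice(k * self.n, (k + 1) * self.n)

    def view(self, y: np.ndarray, name: str) -> np.ndarray:
        return y[self.sl(name)]

    def unpack(self, y: np.ndarray) -> dict[str, np.ndarray | float]:
        out: dict[str, np.ndarray | float] = {
            name: y[self.sl(name)] for name in self.FIELDS}
        out["C_bT"] = y[self.i_CbT]
        out["C_bfR"] = y[self.i_CbfR]
        out["C_bcR"] = y[self.i_CbcR]
        out["V"] = y[self.i_V]
        return out


class _Context:
    """Precomputed constants and the packed right-hand side."""

    def __init__(self, params: ModelParameters, options: SolverOptions):
        self.p = params
        self.opts = options
        g = params.geometry
        self.grid: RadialGrid = build_radial_grid(
            g.r_b_cm, g.r_o_cm, options.n_shells)
        self.lay = StateLayout(options.n_shells)
        self.phi_e = g.phi_e
        self.bridge = params.count_to_nM  # nM per (molecules/cm³)
        self.D = params.molecule.D_efT_cm2_hr
        self.lam_T = params.molecule.lambda_it_blood
        self.lam_R = params.chi_bfR
        self.lam_C = params.lambda_complex_blood
        self.V_blood = params.blood.V_blood_ml
        # total vessel wall area per mm³ of tumor: A_w = aw_fac * V[mm³] (cm²)
        self.aw_fac = 2.0 * g.r_b_cm * 1e-3 / g.r_o_cm**2
        self.area_w = self.grid.shell_areas / self.grid.shell_areas.sum()
        self.backperm_complex = params.permeability.backperm_complex
        self.blood_binding = params.blood.blood_binding
        self.wall_gamma = self.phi_e * self.D / (0.5 * self.grid.dr)

    # -- state scales (atol vector, negativity guard) ----------------------

    def atol_vector(self) -> np.ndarray:
        o, lay = self.opts, self.lay
        atol = np.empty(lay.size)
        for name in ("C_efT", "C_efR", "C_ecR"):
            atol[lay.sl(name)] = o.atol_conc
        for name in ("rho1", "rho2", "rho3"):
            atol[lay.sl(name)] = o.atol_density * self.p.cells.rho_star * 1e-9
        for name in ("B1", "Ten1", "Tcc1"):
            atol[lay.sl(name)] = o.atol_count
        for name in ("W2R", "W2B", "W2en", "W2cc", "W3R", "W3B"):
            atol[lay.sl(name)] = o.atol_count * self.p.cells.rho_star * 1e-3
        atol[lay.i_CbT] = atol[lay.i_CbfR] = atol[lay.i_CbcR] = o.atol_conc
        atol[lay.i_V] = o.atol_volume
        return atol

    def negative_floor(self) -> np.ndarray:
        scale = np.empty(self.lay.size)
        lay = self.lay
        for name in ("C_efT", "C_efR", "C_ecR"):
            scale[lay.sl(name)] = 1.0
        for name in ("rho1", "rho2", "rho3"):
            scale[lay.sl(name)] = self.p.cells.rho_star
        for name in ("B1", "Ten1", "Tcc1"):
            scale[lay.sl(name)] = max(self.p.receptor.R_star, 1.0)
        for name in ("W2R", "W2B", "W2en", "W2cc", "W3R", "W3B"):
            scale[lay.sl(name)] = max(
                self.p.receptor.R_star * self.p.cells.rho_star, 1.0)
        scale[lay.i_CbT] = scale[lay.i_CbfR] = scale[lay.i_CbcR] = 1.0
        scale[lay.i_V] = 1.0
        return -self.opts.negative_tolerance_scale * scale

    # -- right-hand side ----------------------------------------------------

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        p, lay, grid = self.p, self.lay, self.grid
        n = lay.n
        C_T = y[0:n]; C_R = y[n:2 * n]; C_C = y[2 * n:3 * n]
        rho1 = y[3 * n:4 * n]; rho2 = y[4 * n:5 * n]; rho3 = y[5 * n:6 * n]
        B1 = y[6 * n:7 * n]; Ten1 = y[7 * n:8 * n]; Tcc1 = y[8 * n:9 * n]
        W2R = y[9 * n:10 * n]; W2B = y[10 * n:11 * n]
        W2en = y[11 * n:12 * n]; W2cc = y[12 * n:13 * n]
        W3R = y[13 * n:14 * n]; W3B = y[14 * n:15 * n]
        CbT = y[lay.i_CbT]; CbR = y[lay.i_CbfR]; CbC = y[lay.i_CbcR]
        V = max(y[lay.i_V], 1e-12)

        ka = p.binding.k_a; kd = p.binding.k_d
        ks = p.receptor.k_s; ke = p.receptor.k_e; kt = p.receptor.k_t
        xce = p.receptor.chi_ce; xcc = p.receptor.chi_cc
        Rstar = p.receptor.R_star
        cells = p.cells

        P = float(kinetics.permeability_at_volume(V, p.permeability))
        PC = P if self.backperm_complex else 0.0

        # vessel-wall Robin fluxes (nM·cm/hr, positive into tissue), with
        # the half-cell diffusion conductance in series
        gam = self.wall_gamma
        fT, _ = robin_wall_coupling(CbT, C_T[0], P, P, gam)
        fR, _ = robin_wall_coupling(CbR, C_R[0], P, P, gam)
        fC, _ = robin_wall_coupling(CbC, C_C[0], PC, PC, gam)

        dC_T = apply_diffusion(C_T, self.D, grid, fT, self.phi_e)
        dC_R = apply_diffusion(C_R, self.D, grid, fR, self.phi_e)
        dC_C = apply_diffusion(C_C, self.D, grid, fC, self.phi_e)

        # solution-phase binding of toxin to shed antigen
        net_sol = ka * C_T * C_R - kd * C_C
        dC_T -= net_sol
        dC_R -= net_sol
        dC_C += net_sol

        # surface pools: type-1 per-cell, type-2/3 per-volume totals
        Rfree1 = Rstar - B1
        Rtot = rho1 * Rfree1 + W2R + W3R   # molecules/cm³ of free receptors
        Btot = rho1 * B1 + W2B + W3B       # molecules/cm³ of bound toxin
        dC_T -= self.bridge * (ka * C_T * Rtot - kd * Btot)
        dC_R += self.bridge * ks * Rtot
        dC_C += self.bridge * ks * Btot

        # ECS degradation
        dC_T -= p.ecs_deg.chi_efT * C_T
        dC_R -= p.ecs_deg.chi_efR * C_R
        dC_C -= p.ecs_deg.chi_ecR * C_C

        # type-1 per-cell toxin pools
        dB1 = ka * C_T * Rfree1 - (kd + ke + ks) * B1
        dTen1 = ke * B1 - (xce + kt) * Ten1
        dTcc1 = kt * Ten1 - xcc * Tcc1

        # population kinetics and the space-filling closure
        kap = kinetics.intoxication_rate(Tcc1, cells.kappa_max, cells.T_0)
        Gam = cells.Gamma_0 * math.exp(-cells.alpha * V)
        g = (Gam * rho1 - cells.Chi_clear * rho3) / cells.rho_star
        drho1 = Gam * rho1 - kap * rho1 - g * rho1
        drho2 = kap * rho1 - cells.Delta * rho2 - g * rho2
        drho3 = cells.Delta * rho2 - cells.Chi_clear * rho3 - g * rho3

        # type-2 totals: influx from intoxicating type-1 cells carries their
        # per-cell load; death and RU advection remove totals proportionally
        loss2 = cells.Delta + g
        dW2R = kap * rho1 * Rfree1 - (ke + ks) * W2R + kd * W2B \
            - ka * C_T * W2R - loss2 * W2R
        dW2B = kap * rho1 * B1 + ka * C_T * W2R - (kd + ke + ks) * W2B \
            - loss2 * W2B
        dW2en = kap * rho1 * Ten1 + ke * W2B - (xce + kt) * W2en - loss2 * W2en
        dW2cc = kap * rho1 * Tcc1 + kt * W2en - xcc * W2cc - loss2 * W2cc

        # type-3 totals: no endocytosis; clearance removes cells with load
        loss3 = cells.Chi_clear + g
        dW3R = cells.Delta * W2R - ks * W3R + kd * W3B - ka * C_T * W3R \
            - loss3 * W3R
        dW3B = cells.Delta * W2B + ka * C_T * W3R - (kd + ks) * W3B \
            - loss3 * W3B

        dV = V * float(np.dot(g, self.area_w))

        # blood pools (nM): exchange is antisymmetric with the wall fluxes
        exch = self.aw_fac * V / self.V_blood  # hr⁻¹ per unit permeability·conc
        dCbT = -self.lam_T * CbT - exch * fT
        dCbR = -self.lam_R * CbR - exch * fR
        dCbC = -self.lam_C * CbC - exch * fC
        if self.blood_binding:
            net_b = ka * CbT * CbR - kd * CbC
            dCbT -= net_b
            dCbR -= net_b
            dCbC += net_b

        out = np.empty_like(y)
        out[0:n] = dC_T; out[n:2 * n] = dC_R; out[2 * n:3 * n] = dC_C
        out[3 * n:4 * n] = drho1; out[4 * n:5 * n] = drho2
        out[5 * n:6 * n] = drho3
        out[6 * n:7 * n] = dB1; out[7 * n:8 * n] = dTen1
        out[8 * n:9 * n] = dTcc1
        out[9 * n:10 * n] = dW2R; out[10 * n:11 * n] = dW2B
        out[11 * n:12 * n] = dW2en; out[12 * n:13 * n] = dW2cc
        out[13 * n:14 * n] = dW3R; out[14 * n:15 * n] = dW3B
        out[lay.i_CbT] = dCbT; out[lay.i_CbfR] = dCbR
        out[lay.i_CbcR] = dCbC; out[lay.i_V] = dV
        return out

    # -- Jacobian sparsity (generous superset of the true pattern) ----------

    def jac_sparsity(self) -> sparse.csr_matrix:
        lay = self.lay
        n = lay.n
        N = lay.size
        rows: list[int] = []
        cols: list[int] = []

        def add(r: Iterable[int], c: Iterable[int]) -> None:
            for i in r:
                for j in c:
                    rows.append(i)
                    cols.append(j)

        for i in range(n):
            shell = [k * n + i for k in range(15)]
            add(shell, shell)
            for k in range(3):  # ECS diffusion couples radial neighbors
                if i > 0:
                    add([k * n + i], [k * n + i - 1])
                if i < n - 1:
                    add([k * n + i], [k * n + i + 1])
            # V drives permeability (wall shells), growth/advection (cells)
            add(shell, [lay.i_V])
        wall = [0, n, 2 * n]
        add(wall, [lay.i_CbT, lay.i_CbfR, lay.i_CbcR])
        blood = [lay.i_CbT, lay.i_CbfR, lay.i_CbcR]
        add(blood, blood + wall + [lay.i_V])
        add([lay.i_V], [3 * n + i for i in range(n)]
            + [5 * n + i for i in range(n)] + [lay.i_V])
        data = np.ones(len(rows), dtype=np.int8)
        return sparse.csr_matrix((data, (rows, cols)), shape=(N, N))


# ---------------------------------------------------------------------------
# steady state of the no-toxin shed-antigen subsystem
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShedSteadyState:
    """Steady shed-antigen levels at a fixed tumor volume (no toxin)."""

    V_mm3: float
    ecs_profile_nM: np.ndarray
    blood_nM: float
    shell_areas: np.ndarray
    ecs_wall_nM: float = float("nan")  # value at r_b from the Robin coupling

    @property
    def ecs_avg_nM(self) -> float:
        """Shell-area-weighted mean ECS concentration."""
        return float(np.average(self.ecs_profile_nM,
                                weights=self.shell_areas))


def shed_antigen_steady_profile(params: ModelParameters, V_mm3: float,
                                n_shells: int = 25
                                ) -> tuple[np.ndarray, float, RadialGrid]:
    """Solve the linear no-toxin shed-antigen subsystem at fixed volume.

    With no immunotoxin present, un-intoxicated cells keep a full surface
    pool R*, so shedding is a constant volumetric source; diffusion, ECS
    degradation, vessel-wall exchange, and blood clearance are linear.
    The discrete steady state is obtained by a direct linear solve on the
    same finite-volume operator the time integrator uses.
    """
    if V_mm3 <= 0:
        raise SimulationError("tumor volume must be positive")
    g = params.geometry
    grid = build_radial_grid(g.r_b_cm, g.r_o_cm, n_shells)
    n = n_shells
    D = params.molecule.D_efT_cm2_hr
    P = float(kinetics.permeability_at_volume(V_mm3, params.permeability))
    S = params.receptor.k_s * params.receptor_ecs_nM  # nM/hr production
    chi = params.ecs_deg.chi_efR
    lam = params.chi_bfR
    aw = 2.0 * g.r_b_cm * 1e-3 / g.r_o_cm**2 * V_mm3  # cm² wall area
    exch = aw / params.blood.V_blood_ml

    gamma = g.phi_e * D / (0.5 * grid.dr)
    beta = gamma / (gamma + P)  # series-conductance wall factor
    M = np.zeros((n + 1, n + 1))
    # diffusion operator columns
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        M[:n, j] = apply_diffusion(e, D, grid, 0.0, g.phi_e)
    w0 = grid.vessel_perimeter / (g.phi_e * grid.shell_areas[0])
    M[0, 0] += -beta * P * w0
    M[0, n] += beta * P * w0
    M[:n, :n] -= chi * np.eye(n)
    # blood row: gains from the tissue wall flux, loses lam*C_b
    M[n, 0] = exch * beta * P
    M[n, n] = -(lam + exch * beta * P)
    b = np.zeros(n + 1)
    b[:n] = -S
    x = np.linalg.solve(M, b)
    if not np.all(np.isfinite(x)):
        raise SimulationError("shed-antigen steady state did not converge "
                              f"(residual {np.abs(M @ x - b).max():.3g})")
    return x[:n], float(x[n]), grid


def steady_state_shed_antigen(params: ModelParameters, V_mm3: float,
                              n_shells: int = 25) -> ShedSteadyState:
    """Steady shed-antigen concentrations in ECS and blood at volume V."""
    prof, blood, grid = shed_antigen_steady_profile(params, V_mm3, n_shells)
    g = params.geometry
    D = params.molecule.D_efT_cm2_hr
    P = float(kinetics.permeability_at_volume(V_mm3, params.permeability))
    gamma = g.phi_e * D / (0.5 * grid.dr)
    _, c_wall = robin_wall_coupling(blood, float(prof[0]), P, P, gamma)
    return ShedSteadyState(V_mm3=float(V_mm3), ecs_profile_nM=prof,
                           blood_nM=blood, shell_areas=grid.shell_areas,
                           ecs_wall_nM=float(c_wall))


# ---------------------------------------------------------------------------
# initial condition
# ---------------------------------------------------------------------------

def initial_state(params: ModelParameters, V0_mm3: float,
                  options: SolverOptions | None = None) -> np.ndarray:
    """Pre-dose state: all cells un-intoxicated, toxin-free fields zero,
    and (by default) the shed-antigen subsystem equilibrated at V0."""
    options = options or SolverOptions()
    lay = StateLayout(options.n_shells)
    y = np.zeros(lay.size)
    lay.view(y, "rho1")[:] = params.cells.rho_star
    y[lay.i_V] = V0_mm3
    if options.equilibrate_shed and params.receptor.k_s > 0:
        prof, blood, _ = shed_antigen_steady_profile(
            params, V0_mm3, options.n_shells)
        lay.view(y, "C_efR")[:] = prof
        y[lay.i_CbfR] = blood
    return y


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-indexed record of a simulation run."""

    times: np.ndarray                 # hr
    states: np.ndarray                # (n_times, n_states)
    layout: StateLayout
    grid: RadialGrid
    params: ModelParameters
    dose_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    solver_stats: dict = field(default_factory=dict)

    @property
    def volumes(self) -> np.ndarray:
        return self.states[:, self.layout.i_V]

    @property
    def blood_toxin(self) -> np.ndarray:
        return self.states[:, self.layout.i_CbT]

    @property
    def blood_shed_antigen(self) -> np.ndarray:
        return self.states[:, self.layout.i_CbfR]

    @property
    def blood_complex(self) -> np.ndarray:
        return self.states[:, self.layout.i_CbcR]

    def field_mean(self, name: str) -> np.ndarray:
        """Area-weighted radial mean of one per-shell field vs time."""
        w = self.grid.shell_areas / self.grid.shell_areas.sum()
        return self.states[:, self.layout.sl(name)] @ w

    def field_at(self, name: str, t: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.times - t)))
        return self.states[i, self.layout.sl(name)].copy()

    def volume_at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.volumes))

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-time summary (volume, blood pools, ECS means)."""
        return pd.DataFrame({
            "time_hr": self.times,
            "volume_mm3": self.volumes,
            "blood_toxin_nM": self.blood_toxin,
            "blood_shed_antigen_nM": self.blood_shed_antigen,
            "blood_complex_nM": self.blood_complex,
            "ecs_toxin_mean_nM": self.field_mean("C_efT"),
            "ecs_shed_antigen_mean_nM": self.field_mean("C_efR"),
            "ecs_complex_mean_nM": self.field_mean("C_ecR"),
        })

    def profile_frame(self, t: float) -> pd.DataFrame:
        """Radial snapshot of the ECS species nearest to time ``t``."""
        i = int(np.argmin(np.abs(self.times - t)))
        rows = []
        for name, label in (("C_efT", "free_toxin"),
                            ("C_efR", "free_shed_antigen"),
                            ("C_ecR", "shed_complex")):
            vals = self.states[i, self.layout.sl(name)]
            for r, v in zip(self.grid.r_centers, vals):
                rows.append({"time_hr": self.times[i], "r_um": r * 1e4,
                             "species": label, "value_nM": v})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simulation drivers
# ---------------------------------------------------------------------------

def _normalize_schedule(schedule: Sequence[tuple[float, float]] | None,
                        t_end: float) -> list[tuple[float, float]]:
    if not schedule:
        return []
    sched = sorted((float(t), float(d)) for t, d in schedule)
    for t, d in sched:
        if t < 0 or t > t_end:
            raise SimulationError(f"dose time {t} outside [0, {t_end}]")
        if d < 0:
            raise SimulationError("doses must be non-negative")
    return sched


def run_simulation(params: ModelParameters,
                   schedule: Sequence[tuple[float, float]] | None,
                   V0_mm3: float, t_end_hr: float,
                   options: SolverOptions | None = None,
                   shedding: bool | None = None,
                   backperm_complex: bool | None = None) -> Trajectory:
    """Integrate the full model under a bolus dose schedule.

    ``schedule`` is a list of (time_hr, dose_nM) pairs; each dose is an
    instantaneous jump of the blood immunotoxin concentration.  The
    ``shedding``/``backperm_complex`` toggles override the preset (used by
    the scenario comparisons).
    """
    if V0_mm3 <= 0:
        raise SimulationError("initial volume must be positive")
    options = options or SolverOptions()
    overrides: dict[str, object] = {}
    if shedding is not None and not shedding:
        overrides["receptor.k_s"] = 0.0
    if backperm_complex is not None:
        overrides["permeability.backperm_complex"] = backperm_complex
    if overrides:
        params = with_overrides(params, overrides)

    ctx = _Context(params, options)
    sched = _normalize_schedule(schedule, t_end_hr)
    breakpoints = sorted({0.0, t_end_hr, *(t for t, _ in sched)})
    dose_at = {}
    for t, d in sched:
        dose_at[t] = dose_at.get(t, 0.0) + d

    y = initial_state(params, V0_mm3, options)
    atol = ctx.atol_vector()
    floor = ctx.negative_floor()
    sp = ctx.jac_sparsity()

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    nfev = njev = 0
    dt_out = 1.0 / options.points_per_hour

    def eradicated(t, yy):
        return yy[ctx.lay.i_V] - options.V_stop_mm3
    eradicated.terminal = True
    eradicated.direction = -1

    stopped = False
    for t0, t1 in zip(breakpoints[:-1], breakpoints[1:]):
        if t0 in dose_at:
            y = y.copy()
            y[ctx.lay.i_CbT] += dose_at[t0]
        t_eval = np.arange(t0, t1, dt_out)
        if t_eval.size == 0 or t_eval[-1] < t1:
            t_eval = np.append(t_eval, t1)
        if stopped:
            # tumor below the eradication floor: hold the last state
            times_out.append(t_eval)
            states_out.append(np.tile(y, (t_eval.size, 1)))
            continue
        sol = solve_ivp(ctx.rhs, (t0, t1), y, method=options.method,
                        rtol=options.rtol, atol=atol, t_eval=t_eval,
                        jac_sparsity=sp, max_step=options.max_step,
                        events=eradicated)
        if not sol.success and sol.status != 1:
            raise SimulationError(
                f"integrator failed at t={sol.t[-1] if sol.t.size else t0} hr: "
                f"{sol.message}; last volume "
                f"{sol.y[ctx.lay.i_V, -1] if sol.t.size else y[ctx.lay.i_V]}")
        nfev += sol.nfev
        njev += sol.njev
        Y = sol.y.T
        if Y.size and np.any(Y < floor):
            worst = (Y / np.abs(floor)).min()
            raise SimulationError(
                f"negative state excursion beyond tolerance (min scaled "
                f"value {worst:.3g})")
        Y = np.maximum(Y, 0.0)
        first = not times_out
        if sol.t.size:
            times_out.append(sol.t if first else sol.t[1:])
            states_out.append(Y if first else Y[1:])
        if sol.status == 1:  # eradication event fired inside this segment
            stopped = True
            y = np.maximum(sol.y_events[0][0], 0.0)
            missing = t_eval[t_eval > (sol.t[-1] if sol.t.size else t0)]
            if missing.size:
                times_out.append(missing)
                states_out.append(np.tile(y, (missing.size, 1)))
            continue
        y = sol.y[:, -1]

    if t_end_hr in dose_at:  # dose exactly at the horizon: record the jump
        states_out[-1][-1, ctx.lay.i_CbT] += dose_at[t_end_hr]

    return Trajectory(
        times=np.concatenate(times_out),
        states=np.vstack(states_out),
        layout=ctx.lay, grid=ctx.grid, params=params,
        dose_times=np.array(sorted(dose_at)),
        solver_stats={"nfev": nfev, "njev": njev},
    )


def simulate_untreated_growth(params: ModelParameters, V0_mm3: float,
                              t_end_hr: float,
                              points_per_hour: float = 1.0) -> Trajectory:
    """Fast path for the untreated tumor: the scalar volume ODE
    dV/dt = Gamma_0 exp(-alpha V) V."""
    if V0_mm3 <= 0:
        raise SimulationError("initial volume must be positive")
    c = params.cells

    def rhs(t, v):
        return c.Gamma_0 * np.exp(-c.alpha * v) * v

    t_eval = np.linspace(0.0, t_end_hr,
                         max(2, int(round(t_end_hr * points_per_hour)) + 1))
    sol = solve_ivp(rhs, (0.0, t_end_hr), [V0_mm3], method="LSODA",
                    rtol=1e-9, atol=1e-9, t_eval=t_eval)
    if not sol.success:
        raise SimulationError(f"growth integration failed: {sol.message}")
    lay = StateLayout(3)
    states = np.zeros((sol.t.size, lay.size))
    states[:, lay.i_V] = sol.y[0]
    for i in range(sol.t.size):
        states[i, lay.sl("rho1")] = params.cells.rho_star
    g = params.geometry
    return Trajectory(times=sol.t, states=states, layout=lay,
                      grid=build_radial_grid(g.r_b_cm, g.r_o_cm, 3),
                      params=params)


def compare_shedding_scenarios(params: ModelParameters,
                               schedule: Sequence[tuple[float, float]],
                               V0_mm3: float, t_end_hr: float,
                               options: SolverOptions | None = None
                               ) -> dict[str, Trajectory]:
    """Three runs under identical dosing: shedding off, shedding with
    complex back-permeation (current model), and shedding without it
    (predecessor model)."""
    return {
        "no_shedding": run_simulation(params, schedule, V0_mm3, t_end_hr,
                                      options, shedding=False),
        "shedding_backperm": run_simulation(params, schedule, V0_mm3,
                                            t_end_hr, options, shedding=True,
                                            backperm_complex=True),
        "shedding_no_backperm": run_simulation(params, schedule, V0_mm3,
                                               t_end_hr, options,
                                               shedding=True,
                                               backperm_complex=False),
    }


def sweep_antigen_density(params: ModelParameters,
                          schedule: Sequence[tuple[float, float]],
                          r_star_grid: Sequence[float],
                          k_e_values: Sequence[float] = (0.08, 0.22),
                          k_s_values: Sequence[float | None] = (0.0, None),
                          V0_mm3: float = 110.0,
                          t_end_hr: float | None = None,
                          options: SolverOptions | None = None
                          ) -> pd.DataFrame:
    """Endpoint tumor volumes over a grid of surface antigen densities.

    ``k_s_values`` entries of None use the preset shedding rate.  The
    endpoint is the volume at ``t_end_hr`` (default: 48 h after the last
    dose, i.e. two days after the third injection for the standard
    every-other-day schedule).
    """
    if not len(r_star_grid):
        raise SimulationError("R* grid must be nonempty")
    sched = _normalize_schedule(schedule, math.inf)
    if t_end_hr is None:
        t_end_hr = (sched[-1][0] + 48.0) if sched else 144.0
    dose = sched[0][1] if sched else 0.0
    rows = []
    for ke in k_e_values:
        for ks in k_s_values:
            ks_eff = params.receptor.k_s if ks is None else ks
            for rstar in r_star_grid:
                pp = with_overrides(params, {"receptor.R_star": float(rstar),
                                             "receptor.k_e": float(ke),
                                             "receptor.k_s": float(ks_eff)})
                traj = run_simulation(pp, sched, V0_mm3, t_end_hr, options)
                rows.append({"R_star": float(rstar), "k_e": float(ke),
                             "k_s": float(ks_eff), "dose_nM": dose,
                             "endpoint_volume_mm3": float(traj.volumes[-1])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mass audits
# ---------------------------------------------------------------------------

def species_totals(y: np.ndarray, params: ModelParameters,
                   grid: RadialGrid) -> dict[str, float]:
    """Whole-tumor molar totals (nmol) for mass-balance audits.

    Per-unit-length per-RU tissue contents are scaled by m·h =
    V / (pi r_o²), which removes the arbitrary cylinder height.  Toxin is
    counted across blood, ECS (free + complexed), surface, endosome, and
    cytosol; antigen across surface free + bound and shed free + complexed
    (type-1 surface antigen is excluded: synthesis makes it an open pool).
    """
    lay = StateLayout(grid.n_shells)
    s = lay.unpack(y)
    g = params.geometry
    V_cm3 = float(s["V"]) * 1e-3
    scale = V_cm3 / (np.pi * g.r_o_cm**2)  # = m · h, cm
    A = grid.shell_areas
    phi_e = g.phi_e

    def ecs_nmol(name: str) -> float:
        return float(np.dot(s[name], A)) * phi_e * _NM_TO_NMOL_PER_CM3 * scale

    def count_nmol(arr: np.ndarray) -> float:
        # molecules/cm³ tissue × cm² × scale -> molecules; / N_A ×1e9 -> nmol
        return float(np.dot(arr, A)) * scale / N_AVOGADRO * 1e9

    rho1 = s["rho1"]
    cell_toxin = (rho1 * (s["B1"] + s["Ten1"] + s["Tcc1"])
                  + s["W2B"] + s["W2en"] + s["W2cc"] + s["W3B"])
    cell_antigen_23 = s["W2R"] + s["W2B"] + s["W3R"] + s["W3B"]
    blood_nmol = params.blood.V_blood_ml * _NM_TO_NMOL_PER_CM3
    return {
        "toxin_ecs": ecs_nmol("C_efT") + ecs_nmol("C_ecR"),
        "toxin_cells": count_nmol(cell_toxin),
        "toxin_blood": (float(s["C_bT"]) + float(s["C_bcR"])) * blood_nmol,
        "antigen_ecs": ecs_nmol("C_efR") + ecs_nmol("C_ecR"),
        "antigen_cells_type23": count_nmol(cell_antigen_23),
        "antigen_blood": (float(s["C_bfR"]) + float(s["C_bcR"])) * blood_nmol,
    }


def total_toxin(y: np.ndarray, params: ModelParameters,
                grid: RadialGrid) -> float:
    t = species_totals(y, params, grid)
    return t["toxin_ecs"] + t["toxin_cells"] + t["toxin_blood"]


def total_antigen_type23(y: np.ndarray, params: ModelParameters,
                         grid: RadialGrid) -> float:
    t = species_totals(y, params, grid)
    return t["antigen_ecs"] + t["antigen_cells_type23"] + t["antigen_blood"]
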