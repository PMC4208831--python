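"""Local rate laws of the delivery model.

Every nonlinearity of the model lives in one of the small functions below:
the sigmoidal volume-dependent vascular permeability, the Gompertz-like
growth law, the Michaelis-Menten intoxication rate, mass-action binding in
solution and on the cell surface, antigen shedding, receptor-mediated
endocytosis and endosome-to-cytosol translocation, the three-state tumor
cell population kinetics, and the well-mixed blood pools.

All functions are ufunc-friendly: they accept scalars or NumPy arrays and
never allocate hidden state, so the PDE right-hand side can call them
shell-by-shell in vectorized form.

Cell types: 1 = un-intoxicated (proliferating, receptor synthesis keeps
the surface pool at R*), 2 = intoxicated (protein synthesis arrested;
endocytosis and shedding continue), 3 = dead (only shedding and surface
binding continue, until cleared).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.special import expit

from .params import PermeabilityParams, receptors_to_ecs_concentration

__all__ = [
    "permeability_at_volume", "growth_rate", "intoxication_rate",
    "solution_binding_rates", "surface_binding_rates", "shedding_rates",
    "trafficking_rates", "receptor_balance", "cell_state_rates",
    "blood_decay_rate", "SolutionBindingRates", "SurfaceBindingRates",
    "SheddingRates", "TraffickingRates", "CellStateRates",
]


def permeability_at_volume(V_mm3, p: PermeabilityParams):
    """Vascular permeability P(V) in cm/hr.

    P(V) = P_low + (P_high - P_low) / (1 + exp(a (V - V_c))): high in small
    tumors, low in large ones, equal to the mean of the two plateaus at V_c.
    """
    S = expit(-p.a_per_mm3 * (np.asarray(V_mm3, dtype=float) - p.V_c_mm3))
    return p.P_low_cm_hr + (p.P_high_cm_hr - p.P_low_cm_hr) * S


def growth_rate(V_mm3, Gamma_0: float, alpha: float):
    """Volume-damped specific growth rate Gamma(V) = Gamma_0 exp(-alpha V)."""
    return Gamma_0 * np.exp(-alpha * np.asarray(V_mm3, dtype=float))


def intoxication_rate(T_cc, kappa_max: float, T_0: float):
    """Michaelis-Menten intoxication rate in the cytosolic toxin count.

    kappa = kappa_max * T_cc / (T_0 + T_cc); zero at zero, saturating at
    kappa_max, half-maximal at T_cc = T_0.
    """
    T = np.maximum(np.asarray(T_cc, dtype=float), 0.0)
    return kappa_max * T / (T_0 + T)


class SolutionBindingRates(NamedTuple):
    dC_efT: np.ndarray  # nM/hr
    dC_efR: np.ndarray
    dC_ecR: np.ndarray


def solution_binding_rates(C_efT, C_efR, C_ecR, k_a: float,
                           k_d: float) -> SolutionBindingRates:
    """Mass-action association of free toxin with shed antigen in the ECS.

    Net complex formation k_a C_efT C_efR - k_d C_ecR, with matching
    depletion of both free species; toxin and antigen are conserved.
    """
    net = k_a * np.asarray(C_efT, float) * np.asarray(C_efR, float) \
        - k_d * np.asarray(C_ecR, float)
    return SolutionBindingRates(dC_efT=-net, dC_efR=-net, dC_ecR=net)


class SurfaceBindingRates(NamedTuple):
    dC_efT_ecs: np.ndarray   # nM/hr, ECS-referenced
    dB_per_cell: np.ndarray  # molecules/cell/hr
    dR_free_per_cell: np.ndarray


def surface_binding_rates(C_efT, R_free, B, rho_type, k_a: float, k_d: float,
                          phi_e: float) -> SurfaceBindingRates:
    """Binding of ECS free toxin to surface receptors on one cell type.

    The per-cell gain k_a C_efT R_free - k_d B is mirrored exactly by an
    ECS loss after the per-cell -> molar unit bridge, so no toxin is
    created or destroyed by the exchange.
    """
    net = k_a * np.asarray(C_efT, float) * np.asarray(R_free, float) \
        - k_d * np.asarray(B, float)
    ecs_rate = -receptors_to_ecs_concentration(1.0, 1.0, phi_e) \
        * np.asarray(rho_type, float) * net
    return SurfaceBindingRates(dC_efT_ecs=ecs_rate, dB_per_cell=net,
                               dR_free_per_cell=-net)


class SheddingRates(NamedTuple):
    dR_free_per_cell: np.ndarray
    dB_per_cell: np.ndarray
    dC_efR_ecs: np.ndarray  # nM/hr
    dC_ecR_ecs: np.ndarray


def shedding_rates(R_free, B, k_s: float, rho_type,
                   phi_e: float) -> SheddingRates:
    """Proteolytic release of surface antigen into the ECS.

    Free receptors shed at k_s R_free appear as free shed antigen; bound
    complexes shed at k_s B appear as shed antigen-toxin complex.  Antigen
    and toxin counts are conserved across the conversion.
    """
    bridge = receptors_to_ecs_concentration(1.0, 1.0, phi_e) \
        * np.asarray(rho_type, float)
    lR = k_s * np.asarray(R_free, float)
    lB = k_s * np.asarray(B, float)
    return SheddingRates(dR_free_per_cell=-lR, dB_per_cell=-lB,
                         dC_efR_ecs=bridge * lR, dC_ecR_ecs=bridge * lB)


class TraffickingRates(NamedTuple):
    dT_en: np.ndarray
    dT_cc: np.ndarray
    dB_endocytosis: np.ndarray  # loss from the surface pool


def trafficking_rates(B, T_en, T_cc, k_e: float, k_t: float, chi_ce: float,
                      chi_cc: float, cell_type: int) -> TraffickingRates:
    """Endocytosis, endosomal degradation, and cytosolic translocation.

    dT_en/dt = k_e B - (chi_ce + k_t) T_en  and
    dT_cc/dt = k_t T_en - chi_cc T_cc.  Endocytosis operates on cell types
    1 and 2 only; dead cells (type 3) no longer internalize.
    """
    if cell_type not in (1, 2, 3):
        raise ValueError("cell_type must be 1, 2, or 3")
    ke = k_e if cell_type in (1, 2) else 0.0
    uptake = ke * np.asarray(B, float)
    dT_en = uptake - (chi_ce + k_t) * np.asarray(T_en, float)
    dT_cc = k_t * np.asarray(T_en, float) - chi_cc * np.asarray(T_cc, float)
    return TraffickingRates(dT_en=dT_en, dT_cc=dT_cc, dB_endocytosis=-uptake)


def receptor_balance(cell_type: int, R_free, B, C_efT, k_a: float, k_d: float,
                     k_e: float, k_s: float, R_star: float | None = None):
    """Rate of change of the free surface receptor pool for one cell type.

    Type 1 keeps the surface total R_free + B pinned at R* by instantaneous
    synthesis, so dR_free/dt = -dB/dt.  Types 2 and 3 have no synthesis:
    the pool decays by shedding (and endocytosis for type 2) and exchanges
    with the bound pool by the on/off reaction.
    """
    if cell_type not in (1, 2, 3):
        raise ValueError("cell_type must be 1, 2, or 3")
    R_free = np.asarray(R_free, float)
    B = np.asarray(B, float)
    net_bind = k_a * np.asarray(C_efT, float) * R_free - k_d * B
    if cell_type == 1:
        # dB/dt = net_bind - (k_e + k_s) B ; synthesis keeps R_free + B = R*
        return -(net_bind - (k_e + k_s) * B)
    ke = k_e if cell_type == 2 else 0.0
    return -(ke + k_s) * R_free - net_bind


class CellStateRates(NamedTuple):
    drho_1: np.ndarray
    drho_2: np.ndarray
    drho_3: np.ndarray
    g: np.ndarray  # local net volume production rate, hr⁻¹


def cell_state_rates(rho_1, rho_2, rho_3, kappa, Delta: float,
                     Chi_clear: float, Gamma, rho_star: float,
                     check_closure: bool = True) -> CellStateRates:
    """Three-state population kinetics under the space-filling closure.

    Transitions: un-intoxicated -> intoxicated at kappa, intoxicated ->
    dead at Delta, dead removed at Chi.  Proliferation Gamma rho_1 and
    clearance Chi rho_3 produce a net local volume production rate
    g = (Gamma rho_1 - Chi rho_3)/rho*; cells advect out of (or into) the
    RU at g carrying the local composition, which keeps
    rho_1 + rho_2 + rho_3 = rho* exactly.
    """
    rho_1 = np.asarray(rho_1, float)
    rho_2 = np.asarray(rho_2, float)
    rho_3 = np.asarray(rho_3, float)
    if check_closure:
        total = rho_1 + rho_2 + rho_3
        if np.any(np.abs(total - rho_star) > 1e-6 * rho_star):
            raise ValueError("cell densities do not sum to rho_star")
    kappa = np.asarray(kappa, float)
    Gamma = np.asarray(Gamma, float)
    g = (Gamma * rho_1 - Chi_clear * rho_3) / rho_star
    d1 = Gamma * rho_1 - kappa * rho_1 - g * rho_1
    d2 = kappa * rho_1 - Delta * rho_2 - g * rho_2
    d3 = Delta * rho_2 - Chi_clear * rho_3 - g * rho_3
    return CellStateRates(drho_1=d1, drho_2=d2, drho_3=d3, g=g)


def blood_decay_rate(t_half_min: float) -> float:
    """First-order elimination rate (hr⁻¹) from a blood half-life in minutes."""
    if t_half_min <= 0:
        raise ValueError("half-life must be positive")
    return float(np.log(2.0) * 60.0 / t_half_min)
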