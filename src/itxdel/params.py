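"""Model parameters for immunotoxin delivery to solid tumors.

The model treats a vascularized tumor as a collection of identical
cylindrical representative units (RUs), each centered on a capillary.
Every parameter of the delivery model lives here, grouped by the physical
process it controls: geometry of the RU, molecular properties of the
immunotoxin and its shed antigen, surface binding, receptor trafficking,
extracellular degradation, vascular permeability, tumor-cell population
kinetics, and the systemic (blood) compartment.

Two complete presets are provided:

``SS1P``
    anti-mesothelin immunotoxin acting on A431/H9 xenografts
    (high antigen density, fast shedding, fast endocytosis).
``LMB2``
    anti-CD25 immunotoxin acting on ATAC-4 xenografts
    (low antigen density, negligible shedding, slow endocytosis).

Unit conventions: rate constants in hr⁻¹, concentrations in nM, per-cell
quantities in molecules/cell, volumes in mm³ (tumor) and mL (plasma),
lengths in µm at the interface and cm internally, permeabilities entered
in cm/s and converted to cm/hr where used.
"""

from __future__ import annotations

import copy
import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

N_AVOGADRO = 6.02214076e23
SEC_PER_HR = 3600.0
MIN_PER_HR = 60.0

__all__ = [
    "GeometryParams",
    "MoleculeParams",
    "BindingParams",
    "ReceptorParams",
    "EcsDegradationParams",
    "PermeabilityParams",
    "CellPopulationParams",
    "BloodParams",
    "ModelParameters",
    "ParameterError",
    "UnknownPresetError",
    "build_preset",
    "preset_names",
    "derive_association_rate",
    "translocated_fraction",
    "chi_ce_from_omega",
    "vessel_radius_from_blood_fraction",
    "dose_to_plasma_concentration",
    "receptors_to_ecs_concentration",
    "with_overrides",
]


class ParameterError(ValueError):
    """An invariant on the parameter set is violated."""


class UnknownPresetError(KeyError):
    """Requested preset label does not exist."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass
class GeometryParams:
    """Cylindrical representative-unit geometry.

    The RU is an annulus between the capillary wall at ``r_b`` and the
    outer symmetry radius ``r_o`` (half the inter-capillary distance).
    ``phi_e`` is the extracellular volume fraction of the extravascular
    tissue; ``blood_fraction`` is the vascular volume fraction of the RU,
    consistent with r_b = r_o * sqrt(blood_fraction).
    """

    r_b_um: float = 11.0
    r_o_um: float = 50.0
    blood_fraction: float = 0.05
    phi_e: float = 0.1

    def __post_init__(self) -> None:
        _require(0 < self.r_b_um < self.r_o_um, "need 0 < r_b < r_o")
        _require(0 < self.phi_e < 1, "phi_e must lie in (0, 1)")
        _require(0 < self.blood_fraction < 1, "blood_fraction must lie in (0, 1)")

    @property
    def r_b_cm(self) -> float:
        return self.r_b_um * 1e-4

    @property
    def r_o_cm(self) -> float:
        return self.r_o_um * 1e-4


@dataclass
class MoleculeParams:
    """Molecular weights, diffusion, and blood half-lives."""

    mw_it_kda: float
    mw_ag_kda: float
    D_efT_cm2_s: float = 2.5e-8
    t_half_it_blood_min: float = 24.0
    t_half_ag_blood_min: float = 3.0

    def __post_init__(self) -> None:
        for name in ("mw_it_kda", "mw_ag_kda", "D_efT_cm2_s",
                     "t_half_it_blood_min", "t_half_ag_blood_min"):
            _require(getattr(self, name) > 0, f"{name} must be positive")

    @property
    def D_efT_cm2_hr(self) -> float:
        return self.D_efT_cm2_s * SEC_PER_HR

    @property
    def lambda_it_blood(self) -> float:
        """First-order blood elimination rate of the immunotoxin, hr⁻¹."""
        return math.log(2.0) / (self.t_half_it_blood_min / MIN_PER_HR)

    @property
    def lambda_ag_blood(self) -> float:
        """First-order blood elimination rate of the shed antigen, hr⁻¹."""
        return math.log(2.0) / (self.t_half_ag_blood_min / MIN_PER_HR)


@dataclass
class BindingParams:
    """Immunotoxin-antigen binding: K_D = k_d / k_a.

    The association rate is always derived from (k_d, K_D) so the affinity
    identity holds exactly.
    """

    k_d: float  # hr⁻¹
    K_D: float  # nM

    def __post_init__(self) -> None:
        _require(self.K_D > 0, "K_D must be positive")
        _require(self.k_d >= 0, "k_d must be non-negative")

    @property
    def k_a(self) -> float:
        """Association rate constant, hr⁻¹ nM⁻¹."""
        return derive_association_rate(self.k_d, self.K_D)


@dataclass
class ReceptorParams:
    """Surface receptor pool and intracellular trafficking rates.

    On un-intoxicated cells the surface receptor total is held at
    ``R_star`` by synthesis/recycling (steady-state receptor turnover).
    Internalized toxin is degraded in the endosome at ``chi_ce`` or
    translocated to the cytosol at ``k_t``; the surviving fraction is
    omega = k_t / (chi_ce + k_t). Cytosolic toxin decays at ``chi_cc``
    (no printed value exists for this rate; default 0, i.e. cytosolic
    toxin persists until the cell dies).
    """

    R_star: float
    k_s: float
    k_e: float
    k_t: float = 0.69
    chi_ce: float = 9.9
    chi_cc: float = 0.0

    def __post_init__(self) -> None:
        for name in ("R_star", "k_s", "k_e", "k_t", "chi_ce", "chi_cc"):
            _require(getattr(self, name) >= 0, f"{name} must be non-negative")
        _require(self.k_t + self.chi_ce > 0, "k_t and chi_ce cannot both be zero")

    @property
    def omega(self) -> float:
        """Fraction of endocytosed toxin translocated to the cytosol."""
        return translocated_fraction(self.k_t, self.chi_ce)


@dataclass
class EcsDegradationParams:
    """First-order loss of extracellular species, hr⁻¹."""

    chi_efT: float = 0.1
    chi_efR: float = 0.1
    chi_ecR: float = 0.1

    def __post_init__(self) -> None:
        for name in ("chi_efT", "chi_efR", "chi_ecR"):
            _require(getattr(self, name) >= 0, f"{name} must be non-negative")


@dataclass
class PermeabilityParams:
    """Sigmoidal volume-dependent vascular permeability.

    P(V) = P_low + (P_high - P_low) * S(V), S(V) = 1 / (1 + exp(a (V - V_c))),
    so permeability drops from P_high in small tumors to P_low in large
    ones, crossing the midpoint at V_c.  ``backperm_complex`` enables
    vessel-wall exchange of the shed antigen-immunotoxin complex (on in
    the current model; off reproduces the predecessor model where only
    the free shed antigen could back-permeate).
    """

    P_low_cm_s: float = 7.1e-7
    P_high_cm_s: float = 8.0e-6
    V_c_mm3: float = 250.0
    a_per_mm3: float = 0.04
    backperm_complex: bool = True

    def __post_init__(self) -> None:
        _require(0 < self.P_low_cm_s <= self.P_high_cm_s,
                 "need 0 < P_low <= P_high")
        _require(self.a_per_mm3 > 0, "a must be positive")
        _require(self.V_c_mm3 > 0, "V_c must be positive")

    @property
    def P_low_cm_hr(self) -> float:
        return self.P_low_cm_s * SEC_PER_HR

    @property
    def P_high_cm_hr(self) -> float:
        return self.P_high_cm_s * SEC_PER_HR


@dataclass
class CellPopulationParams:
    """Tumor cell density, growth, intoxication, death, and clearance.

    Growth follows Gamma(V) = Gamma_0 exp(-alpha V), a Gompertz-like law
    damped in volume rather than time.  Intoxication of un-intoxicated
    cells is Michaelis-Menten in the per-cell cytosolic toxin count with
    maximum rate ``kappa_max`` and half-saturation count ``T_0``.
    """

    rho_star: float = 0.5e9
    Gamma_0: float = 0.0301
    alpha: float = 0.00127
    kappa_max: float = 0.252
    T_0: float = 400.0
    Delta: float = 0.17
    Chi_clear: float = 0.23

    def __post_init__(self) -> None:
        _require(self.rho_star > 0, "rho_star must be positive")
        for name in ("Gamma_0", "alpha", "kappa_max", "T_0", "Delta", "Chi_clear"):
            _require(getattr(self, name) >= 0, f"{name} must be non-negative")


@dataclass
class BloodParams:
    """Systemic compartment: plasma distribution volume and clearances.

    ``V_blood_ml`` and ``body_mass_kg`` default to the mouse values that
    jointly reproduce both printed dose conversions (200 µg/kg -> 62 nM
    at 64 kDa and 160 µg/kg -> 51 nM at 63 kDa) to within rounding.
    ``chi_bfR`` (blood decay of shed free antigen) defaults to
    ln2 / t_half(shed antigen).

    The shed antigen-immunotoxin complex has no measured blood half-life
    of its own.  Both constituents clear quickly (renal filtration for the
    42-45 kDa antigen, 13-24 min half-lives for the ~64 kDa toxin), but
    the intact ~106 kDa complex sits above the glomerular cutoff, so by
    default it has no intrinsic first-order elimination
    (``t_half_complex_blood_min = None``): it leaves the plasma by
    dissociating (mass-action binding operates in blood, controlled by
    ``blood_binding``) or by permeating back into the tumor.  Setting a
    finite half-life replaces this with first-order elimination of the
    intact complex.
    """

    V_blood_ml: float = 1.0
    body_mass_kg: float = 0.020
    chi_bfR: float | None = None
    t_half_complex_blood_min: float | None = None
    blood_binding: bool = True

    def __post_init__(self) -> None:
        _require(self.V_blood_ml > 0, "V_blood must be positive")
        _require(self.body_mass_kg > 0, "body mass must be positive")


@dataclass
class ModelParameters:
    """Complete, validated parameter set for one immunotoxin/tumor system."""

    name: str
    geometry: GeometryParams
    molecule: MoleculeParams
    binding: BindingParams
    receptor: ReceptorParams
    ecs_deg: EcsDegradationParams = field(default_factory=EcsDegradationParams)
    permeability: PermeabilityParams = field(default_factory=PermeabilityParams)
    cells: CellPopulationParams = field(default_factory=CellPopulationParams)
    blood: BloodParams = field(default_factory=BloodParams)

    # -- derived quantities -------------------------------------------------

    @property
    def chi_bfR(self) -> float:
        """Blood decay rate of the shed free antigen, hr⁻¹."""
        if self.blood.chi_bfR is not None:
            return self.blood.chi_bfR
        return self.molecule.lambda_ag_blood

    @property
    def lambda_complex_blood(self) -> float:
        """Intrinsic blood elimination rate of the intact shed complex, hr⁻¹.

        Zero by default: the intact complex is too large for renal
        clearance and disappears from plasma by dissociation (see
        BloodParams).
        """
        t = self.blood.t_half_complex_blood_min
        if t is None:
            return 0.0
        return math.log(2.0) / (t / MIN_PER_HR)

    @property
    def receptor_ecs_nM(self) -> float:
        """Total surface receptor pool expressed as an ECS concentration."""
        return receptors_to_ecs_concentration(
            self.receptor.R_star, self.cells.rho_star, self.geometry.phi_e
        )

    @property
    def count_to_nM(self) -> float:
        """nM (ECS-referenced) per (molecules per cm³ extravascular tissue)."""
        return 1e12 / (N_AVOGADRO * self.geometry.phi_e)

    def validate(self) -> None:
        """Re-run every invariant check (useful after field mutation)."""
        for sub in (self.geometry, self.molecule, self.binding, self.receptor,
                    self.ecs_deg, self.permeability, self.cells, self.blood):
            sub.__post_init__()
        ka = self.binding.k_a
        _require(abs(ka * self.binding.K_D - self.binding.k_d)
                 <= 1e-9 * max(self.binding.k_d, 1e-300),
                 "K_D identity violated")
        om = self.receptor.omega
        _require(0.0 <= om <= 1.0, "omega outside [0, 1]")

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParameters":
        return cls(
            name=d["name"],
            geometry=GeometryParams(**d["geometry"]),
            molecule=MoleculeParams(**d["molecule"]),
            binding=BindingParams(**d["binding"]),
            receptor=ReceptorParams(**d["receptor"]),
            ecs_deg=EcsDegradationParams(**d["ecs_deg"]),
            permeability=PermeabilityParams(**d["permeability"]),
            cells=CellPopulationParams(**d["cells"]),
            blood=BloodParams(**d["blood"]),
        )

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "ModelParameters":
        with open(path) as fh:
            obj = cls.from_dict(yaml.safe_load(fh))
        obj.validate()
        return obj


# ---------------------------------------------------------------------------
# elementary parameter operations
# ---------------------------------------------------------------------------

def derive_association_rate(k_d: float, K_D: float) -> float:
    """Association rate k_a = k_d / K_D, in hr⁻¹ nM⁻¹."""
    if K_D <= 0:
        raise ParameterError("K_D must be positive")
    return k_d / K_D


def translocated_fraction(k_t: float, chi_ce: float) -> float:
    """Fraction of endocytosed toxin escaping the endosome to the cytosol.

    omega = k_t / (chi_ce + k_t); 1 when there is no endosomal degradation.
    """
    if k_t < 0 or chi_ce < 0:
        raise ParameterError("rates must be non-negative")
    if k_t + chi_ce == 0:
        raise ParameterError("k_t and chi_ce cannot both be zero")
    return k_t / (chi_ce + k_t)


def chi_ce_from_omega(k_t: float, omega: float) -> float:
    """Invert the translocated fraction: chi_ce = k_t (1 - omega) / omega."""
    if not 0 < omega <= 1:
        raise ParameterError("omega must lie in (0, 1]")
    if k_t < 0:
        raise ParameterError("k_t must be non-negative")
    return k_t * (1.0 - omega) / omega


def vessel_radius_from_blood_fraction(blood_fraction: float, r_o_um: float) -> float:
    """Capillary radius (µm) implied by a vascular volume fraction.

    For concentric cylinders, blood_fraction = (r_b/r_o)², so
    r_b = r_o * sqrt(blood_fraction).
    """
    if not 0 < blood_fraction < 1:
        raise ParameterError("blood_fraction must lie strictly in (0, 1)")
    if r_o_um <= 0:
        raise ParameterError("r_o must be positive")
    return r_o_um * math.sqrt(blood_fraction)


def dose_to_plasma_concentration(dose_ug_per_kg: float, mw_it_kda: float,
                                 body_mass_kg: float = 0.020,
                                 V_blood_ml: float = 1.0) -> float:
    """Peak plasma concentration (nM) of an i.v. bolus dose in µg/kg."""
    if dose_ug_per_kg < 0:
        raise ParameterError("dose must be non-negative")
    if mw_it_kda <= 0 or body_mass_kg <= 0 or V_blood_ml <= 0:
        raise ParameterError("molecular weight, body mass, and plasma volume "
                             "must be positive")
    # µg / (kDa = kg/mol) -> nmol ; / mL -> µM ; ×1e3 -> nM
    return dose_ug_per_kg * body_mass_kg / mw_it_kda / V_blood_ml * 1e3


def receptors_to_ecs_concentration(R_star: float, rho: float, phi_e: float) -> float:
    """Express a per-cell surface count as an ECS molar concentration (nM).

    ``R_star`` molecules/cell at density ``rho`` cells per cm³ of
    extravascular tissue, dissolved in the ECS fraction ``phi_e`` of that
    volume.
    """
    if phi_e <= 0:
        raise ParameterError("phi_e must be positive")
    if R_star < 0 or rho < 0:
        raise ParameterError("counts and densities must be non-negative")
    return R_star * rho * 1e12 / (N_AVOGADRO * phi_e)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _ss1p() -> ModelParameters:
    return ModelParameters(
        name="SS1P",
        geometry=GeometryParams(),
        molecule=MoleculeParams(mw_it_kda=64.0, mw_ag_kda=42.0,
                                t_half_it_blood_min=24.0,
                                t_half_ag_blood_min=3.0),
        binding=BindingParams(k_d=0.61, K_D=1.2),
        receptor=ReceptorParams(R_star=1.0e6, k_s=0.2, k_e=0.22,
                                k_t=0.69, chi_ce=9.9),
        cells=CellPopulationParams(Gamma_0=0.0301, alpha=0.00127),
    )


def _lmb2() -> ModelParameters:
    return ModelParameters(
        name="LMB2",
        geometry=GeometryParams(),
        molecule=MoleculeParams(mw_it_kda=63.0, mw_ag_kda=45.0,
                                t_half_it_blood_min=13.0,
                                t_half_ag_blood_min=5.0),
        binding=BindingParams(k_d=0.71, K_D=1.4),
        receptor=ReceptorParams(R_star=2.0e5, k_s=0.0020, k_e=0.08,
                                k_t=0.69, chi_ce=56.8),
        cells=CellPopulationParams(Gamma_0=0.0170, alpha=0.00197),
    )


_PRESETS = {"SS1P": _ss1p, "LMB2": _lmb2}


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def build_preset(name: str) -> ModelParameters:
    """Return a fully populated, validated parameter set for a known system."""
    key = name.upper().replace("-", "")
    if key not in _PRESETS:
        raise UnknownPresetError(
            f"unknown preset {name!r}; available: {preset_names()}")
    p = _PRESETS[key]()
    p.validate()
    return p


# ---------------------------------------------------------------------------
# dotted-path overrides (used by the scenario runner and the fitters)
# ---------------------------------------------------------------------------

def with_overrides(params: ModelParameters,
                   overrides: dict[str, Any]) -> ModelParameters:
    """Deep-copy ``params`` applying ``{"receptor.k_s": 0.0}``-style overrides.

    Raises ParameterError naming the offending key when a path does not
    correspond to an existing field.
    """
    out = copy.deepcopy(params)
    for path, value in overrides.items():
        parts = path.split(".")
        target: Any = out
        for part in parts[:-1]:
            if not hasattr(target, part):
                raise ParameterError(f"unknown parameter path {path!r}")
            target = getattr(target, part)
        leaf = parts[-1]
        if not hasattr(target, leaf) or not dataclasses.is_dataclass(target):
            raise ParameterError(f"unknown parameter path {path!r}")
        if leaf not in {f.name for f in dataclasses.fields(target)}:
            raise ParameterError(f"{path!r} is a derived quantity, not a field")
        setattr(target, leaf, value)
    out.validate()
    return out
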