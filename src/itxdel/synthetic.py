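"""Synthetic observation sets with the structure of the in-vivo data.

Three generators emulate the measurement designs behind the calibration
procedures, so parameter-recovery studies run with no external data:

* steady-state shed-antigen concentration scans over tumor volume, in
  ECS and in blood (the design used to fit k_s and the permeability
  switch);
* tumor-volume time courses, untreated or under a bolus schedule (the
  design used to fit growth and translocation parameters);
* in-vitro internalization time courses (the design used to fit k_e).

Every generator is a pure function of its spec: the same seed yields the
same dataset bit-for-bit, and sigma = 0 returns the forward-model values
exactly.  Noise is lognormal (median equal to the model value) so
observations stay positive, with scale sigma defaulting to 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibration import ObservationSet, internalized_fraction
from .params import ModelParameters, build_preset
from .simulator import (SolverOptions, run_simulation,
                        simulate_untreated_growth, steady_state_shed_antigen)

__all__ = ["SyntheticSpec", "generate_shed_scan", "generate_tumor_course",
           "generate_internalization_course"]

_KIND_SALT = {"shed_ecs_vs_volume": 1, "shed_blood_vs_volume": 2,
              "volume_vs_time": 3, "internalization_vs_time": 4}


@dataclass
class SyntheticSpec:
    """Design of one synthetic observation set."""

    preset: str = "SS1P"
    kind: str = "shed_ecs_vs_volume"
    design: np.ndarray = field(
        default_factory=lambda: np.geomspace(50.0, 1000.0, 10))
    sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        if self.design.size == 0:
            raise ValueError("design must be nonempty")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.kind not in _KIND_SALT:
            raise ValueError(f"unknown observation kind {self.kind!r}")

    def rng(self) -> np.random.Generator:
        # salt by kind so paired ECS/blood scans get independent noise
        return np.random.default_rng([self.seed, _KIND_SALT[self.kind]])

    def params(self) -> ModelParameters:
        return build_preset(self.preset)


def _noisy(model: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    if spec.sigma == 0:
        return model.copy()
    z = spec.rng().standard_normal(model.size)
    return model * np.exp(spec.sigma * z)


def generate_shed_scan(spec: SyntheticSpec,
                       params: ModelParameters | None = None,
                       n_shells: int = 25) -> ObservationSet:
    """Steady-state shed-antigen scan over tumor volumes (mm³).

    ``spec.kind`` selects the ECS or the blood readout; the forward model
    is the no-toxin steady state of the delivery model.
    """
    if spec.kind not in ("shed_ecs_vs_volume", "shed_blood_vs_volume"):
        raise ValueError("spec.kind must be a shed-antigen scan kind")
    if np.any((spec.design < 10.0) | (spec.design > 1500.0)):
        raise ValueError("scan volumes must lie within [10, 1500] mm³")
    p = params or spec.params()
    model = np.empty(spec.design.size)
    for i, v in enumerate(spec.design):
        ss = steady_state_shed_antigen(p, float(v), n_shells)
        model[i] = ss.ecs_avg_nM if spec.kind == "shed_ecs_vs_volume" \
            else ss.blood_nM
    return ObservationSet(kind=spec.kind, x=spec.design.copy(),
                          y=_noisy(model, spec),
                          sigma=np.full(model.size, max(spec.sigma, 1e-6)))


def generate_tumor_course(spec: SyntheticSpec,
                          schedule: Sequence[tuple[float, float]] | None = None,
                          V0_mm3: float = 110.0,
                          params: ModelParameters | None = None,
                          options: SolverOptions | None = None
                          ) -> ObservationSet:
    """Tumor-volume time course (hr), untreated or under bolus doses."""
    if spec.kind != "volume_vs_time":
        raise ValueError("spec.kind must be volume_vs_time")
    p = params or spec.params()
    t_end = float(spec.design.max())
    if schedule:
        traj = run_simulation(p, schedule, V0_mm3, t_end, options)
    else:
        traj = simulate_untreated_growth(p, V0_mm3, t_end)
    model = np.interp(spec.design, traj.times, traj.volumes)
    return ObservationSet(kind=spec.kind, x=spec.design.copy(),
                          y=_noisy(model, spec),
                          sigma=np.full(model.size, max(spec.sigma, 1e-6)))


def generate_internalization_course(spec: SyntheticSpec,
                                    k_e: float | None = None,
                                    k_d: float | None = None
                                    ) -> ObservationSet:
    """Internalized-fraction time course (hr) of surface-labeled toxin."""
    if spec.kind != "internalization_vs_time":
        raise ValueError("spec.kind must be internalization_vs_time")
    p = spec.params()
    ke = p.receptor.k_e if k_e is None else k_e
    kd = p.binding.k_d if k_d is None else k_d
    model = internalized_fraction(spec.design, ke, kd)
    y = model.copy()
    if spec.sigma > 0:
        z = spec.rng().standard_normal(model.size)
        y = np.clip(model + spec.sigma * z * np.maximum(model, 0.05), 0.0, 1.0)
    return ObservationSet(kind=spec.kind, x=spec.design.copy(), y=y,
                          sigma=np.full(model.size, max(spec.sigma, 1e-6)))
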