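import numpy as np
import pytest

from itxdel.params import with_overrides
from itxdel.simulator import (SimulationError, SolverOptions, StateLayout,
                              initial_state, run_simulation,
                              simulate_untreated_growth,
                              steady_state_shed_antigen, total_toxin,
                              total_antigen_type23, _Context)

SCHED = [(0.0, 62.0), (48.0, 62.0), (96.0, 62.0)]


def closed_sinks(params):
    """Variant with every toxin/antigen sink and all transport to or from
    the blood disabled (sealed vessel wall)."""
    return with_overrides(params, {
        "ecs_deg.chi_efT": 0.0, "ecs_deg.chi_efR": 0.0,
        "ecs_deg.chi_ecR": 0.0, "receptor.chi_ce": 0.0,
        "receptor.chi_cc": 0.0,
        "permeability.P_low_cm_s": 1e-30, "permeability.P_high_cm_s": 1e-30,
        "blood.chi_bfR": 0.0,
        "cells.Gamma_0": 0.0, "cells.Delta": 0.0, "cells.Chi_clear": 0.0,
        "molecule.t_half_it_blood_min": 1e12,
        "molecule.t_half_ag_blood_min": 1e12,
    })


def test_untreated_pde_matches_scalar_growth_ode(ss1p, fast_opts):
    """With no toxin the full radial model collapses onto the scalar
    volume ODE dV/dt = Gamma_0 exp(-alpha V) V."""
    full = run_simulation(ss1p, [], 110.0, 144.0, fast_opts)
    fast = simulate_untreated_growth(ss1p, 110.0, 144.0)
    v_full = np.interp(fast.times, full.times, full.volumes)
    assert np.max(np.abs(v_full - fast.volumes) / fast.volumes) < 0.005
    assert np.all(np.diff(full.volumes) > 0)


def test_untreated_closed_forms(ss1p):
    """alpha = 0 gives pure exponential growth; Gamma_0 = 0 freezes V."""
    p = with_overrides(ss1p, {"cells.alpha": 0.0})
    tr = simulate_untreated_growth(p, 110.0, 24.0)
    assert tr.volumes[-1] == pytest.approx(110.0 * np.exp(0.0301 * 24),
                                           rel=1e-6)
    p0 = with_overrides(ss1p, {"cells.Gamma_0": 0.0})
    tr0 = simulate_untreated_growth(p0, 110.0, 100.0)
    assert tr0.volumes[-1] == pytest.approx(110.0, rel=1e-9)


def test_shedding_off_keeps_shed_fields_empty(ss1p, fast_opts):
    tr = run_simulation(ss1p, SCHED[:1], 110.0, 24.0, fast_opts,
                        shedding=False)
    assert np.all(tr.states[:, tr.layout.sl("C_efR")] == 0.0)
    assert np.all(tr.states[:, tr.layout.sl("C_ecR")] == 0.0)
    assert np.all(tr.blood_shed_antigen == 0.0)


def test_treatment_always_slows_growth(ss1p, fast_opts):
    """Toxin can only kill: the treated volume sits below the untreated
    one at every time beyond the first day."""
    treated = run_simulation(ss1p, SCHED, 110.0, 144.0, fast_opts)
    control = simulate_untreated_growth(ss1p, 110.0, 144.0)
    vc = np.interp(treated.times, control.times, control.volumes)
    late = treated.times > 24
    assert np.all(treated.volumes[late] < vc[late])


def test_determinism_bit_for_bit(ss1p, fast_opts):
    a = run_simulation(ss1p, SCHED[:2], 110.0, 72.0, fast_opts)
    b = run_simulation(ss1p, SCHED[:2], 110.0, 72.0, fast_opts)
    assert np.array_equal(a.states, b.states)


def test_dose_jump_and_blood_half_life(ss1p):
    """A 62 nM bolus decays to 31 nM in one 24-minute half-life once the
    tumor sink is made negligible (tiny tumor, shedding off)."""
    tr = run_simulation(ss1p, [(0.0, 62.0)], 1e-3, 2.0,
                        SolverOptions(n_shells=9, points_per_hour=10),
                        shedding=False)
    c0 = tr.blood_toxin[0]
    assert c0 == pytest.approx(62.0, rel=1e-6)
    c_half = np.interp(0.4, tr.times, tr.blood_toxin)
    assert c_half == pytest.approx(31.0, rel=0.01)


def test_invalid_inputs_raise(ss1p, fast_opts):
    with pytest.raises(SimulationError):
        run_simulation(ss1p, SCHED, -5.0, 144.0, fast_opts)
    with pytest.raises(SimulationError):
        run_simulation(ss1p, [(-1.0, 62.0)], 110.0, 24.0, fast_opts)
    with pytest.raises(SimulationError):
        run_simulation(ss1p, [(100.0, 62.0)], 110.0, 24.0, fast_opts)


def test_toxin_conservation_short_run(ss1p):
    """Sealed wall, no sinks: total toxin across ECS, surface, endosome,
    and cytosol is invariant (short-horizon version of the audit)."""
    p = closed_sinks(ss1p)
    opts = SolverOptions(n_shells=9, rtol=1e-10, equilibrate_shed=False)
    lay = StateLayout(9)
    y0 = initial_state(p, 110.0, opts)
    y0[lay.sl("C_efT")] = 10.0
    ctx = _Context(p, opts)
    from scipy.integrate import solve_ivp
    sol = solve_ivp(ctx.rhs, (0, 24), y0, method="BDF", rtol=1e-10,
                    atol=ctx.atol_vector() * 1e-3,
                    jac_sparsity=ctx.jac_sparsity())
    assert sol.success
    t0 = total_toxin(y0, p, ctx.grid)
    t1 = total_toxin(sol.y[:, -1], p, ctx.grid)
    assert abs(t1 - t0) / t0 < 1e-9


def test_antigen_conservation_dead_cells(ss1p):
    """All-dead tumor, sealed wall, sinks off: surface + shed antigen is
    invariant while shedding converts one form into the other."""
    p = closed_sinks(ss1p)
    opts = SolverOptions(n_shells=9, rtol=1e-10, equilibrate_shed=False)
    lay = StateLayout(9)
    y0 = initial_state(p, 110.0, opts)
    y0[lay.sl("rho1")] = 0.0
    y0[lay.sl("rho3")] = p.cells.rho_star
    y0[lay.sl("W3R")] = p.receptor.R_star * p.cells.rho_star
    ctx = _Context(p, opts)
    from scipy.integrate import solve_ivp
    sol = solve_ivp(ctx.rhs, (0, 48), y0, method="BDF", rtol=1e-10,
                    atol=ctx.atol_vector() * 1e-3,
                    jac_sparsity=ctx.jac_sparsity())
    assert sol.success
    a0 = total_antigen_type23(y0, p, ctx.grid)
    a1 = total_antigen_type23(sol.y[:, -1], p, ctx.grid)
    assert abs(a1 - a0) / a0 < 1e-9
    # shed antigen did actually appear
    assert sol.y[lay.sl("C_efR"), -1].min() > 0


def test_nonnegativity_of_recorded_states(ss1p, fast_opts):
    tr = run_simulation(ss1p, SCHED, 110.0, 144.0, fast_opts)
    assert tr.states.min() >= 0.0


def test_steady_state_monotone_in_volume(ss1p, lmb2):
    """Shed-antigen levels in ECS and blood rise with tumor volume for
    both systems (the permeability switch at work)."""
    for p in (ss1p, lmb2):
        vols = np.geomspace(10, 1000, 8)
        ecs = [steady_state_shed_antigen(p, v).ecs_avg_nM for v in vols]
        blood = [steady_state_shed_antigen(p, v).blood_nM for v in vols]
        assert np.all(np.diff(ecs) > 0)
        assert np.all(np.diff(blood) > 0)


def test_steady_state_no_shedding_is_zero(ss1p):
    p = with_overrides(ss1p, {"receptor.k_s": 0.0})
    ss = steady_state_shed_antigen(p, 100.0)
    assert ss.ecs_avg_nM == pytest.approx(0.0, abs=1e-12)
    assert ss.blood_nM == pytest.approx(0.0, abs=1e-12)


def test_steady_state_production_ratio_between_systems(ss1p, lmb2):
    """ECS levels scale with k_s R* (linearity of the shed subsystem):
    the mesothelin/CD25 ratio is (0.2·10⁶)/(0.002·2×10⁵) = 500."""
    for v in (50.0, 500.0):
        r = steady_state_shed_antigen(ss1p, v).ecs_avg_nM / \
            steady_state_shed_antigen(lmb2, v).ecs_avg_nM
        assert r == pytest.approx(500.0, rel=0.2)


def test_binding_site_barrier_monotone_in_receptor_number(ss1p):
    """More surface receptors (no shedding) capture toxin near the vessel
    and lower the free-toxin level at the outer rim at 24 h."""
    opts = SolverOptions(n_shells=9)
    outer = []
    for rstar in (1e6, 3e6, 1e7):
        p = with_overrides(ss1p, {"receptor.R_star": rstar,
                                  "receptor.k_s": 0.0})
        tr = run_simulation(p, [(0.0, 62.0)], 110.0, 24.0, opts)
        outer.append(tr.field_at("C_efT", 24.0)[-1])
    assert outer[0] > outer[1] > outer[2]


def test_dose_monotonicity(ss1p, lmb2, fast_opts):
    """Endpoint volume is non-increasing in dose."""
    for p, doses in ((ss1p, (0.0, 31.0, 62.0, 124.0)), (lmb2, (0.0, 62.0))):
        vols = []
        for d in doses:
            sched = [(t, d) for t in (0.0, 48.0, 96.0)] if d > 0 else []
            vols.append(run_simulation(p, sched, 110.0, 144.0,
                                       fast_opts).volumes[-1])
        assert np.all(np.diff(vols) <= 1e-9)


def test_trajectory_export_shapes(ss1p, fast_opts):
    tr = run_simulation(ss1p, SCHED[:1], 110.0, 12.0, fast_opts)
    df = tr.to_frame()
    assert list(df.columns[:2]) == ["time_hr", "volume_mm3"]
    assert len(df) == tr.times.size
    prof = tr.profile_frame(12.0)
    assert set(prof.species) == {"free_toxin", "free_shed_antigen",
                                 "shed_complex"}
    assert len(prof) == 3 * fast_opts.n_shells
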