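import numpy as np
import pytest

from itxdel.calibration import (FitResult, ObservationSet, bootstrap_fit,
                                fit_endocytosis, fit_growth, fit_shedding,
                                fit_translocation, internalized_fraction)
from itxdel.params import with_overrides
from itxdel.simulator import SolverOptions
from itxdel.synthetic import (SyntheticSpec, generate_internalization_course,
                              generate_shed_scan, generate_tumor_course)


def shed_obs(preset, sigma, seed, n=10):
    vols = np.geomspace(50, 1000, n)
    e = generate_shed_scan(SyntheticSpec(preset=preset,
                                         kind="shed_ecs_vs_volume",
                                         design=vols, sigma=sigma, seed=seed))
    b = generate_shed_scan(SyntheticSpec(preset=preset,
                                         kind="shed_blood_vs_volume",
                                         design=vols, sigma=sigma, seed=seed))
    return [e, b]


class TestObservationSet:
    def test_csv_roundtrip(self, tmp_path):
        obs = ObservationSet("volume_vs_time", [0, 24, 48], [110, 150, 200],
                             0.1)
        path = tmp_path / "obs.csv"
        obs.to_csv(path)
        back = ObservationSet.from_csv(path)
        assert back.kind == obs.kind
        np.testing.assert_allclose(back.y, obs.y)
        np.testing.assert_allclose(back.sigma, [0.1] * 3)

    def test_validation(self):
        with pytest.raises(ValueError):
            ObservationSet("bogus_kind", [1], [1], 0.1)
        with pytest.raises(ValueError):
            ObservationSet("volume_vs_time", [1, 2], [1], 0.1)
        with pytest.raises(ValueError):
            ObservationSet("volume_vs_time", [1], [-1], 0.1)

    def test_converged_requires_finite_loss(self):
        with pytest.raises(ValueError):
            FitResult(estimates={}, loss=float("nan"), n_evals=1,
                      converged=True)


class TestGrowthFit:
    def test_noiseless_recovery(self):
        """Noiseless self-generated data returns the generating
        (Gamma_0, alpha) to well under 1%."""
        spec = SyntheticSpec(kind="volume_vs_time",
                             design=np.linspace(0, 240, 11), sigma=0.0)
        res = fit_growth(generate_tumor_course(spec))
        assert res.converged
        assert res.estimates["Gamma_0"] == pytest.approx(0.0301, rel=0.01)
        assert res.estimates["alpha"] == pytest.approx(0.00127, rel=0.01)

    def test_pure_exponential_log_slope(self):
        """With alpha fixed to 0, Gamma_0 is the log-slope of the data."""
        t = np.linspace(0, 100, 6)
        y = 50.0 * np.exp(0.025 * t)
        res = fit_growth(ObservationSet("volume_vs_time", t, y, 0.1),
                         fix_alpha=0.0)
        assert res.estimates["Gamma_0"] == pytest.approx(0.025, rel=1e-6)

    def test_noisy_recovery(self):
        spec = SyntheticSpec(kind="volume_vs_time",
                             design=np.linspace(0, 240, 10), sigma=0.1,
                             seed=11)
        res = fit_growth(generate_tumor_course(spec))
        assert res.estimates["Gamma_0"] == pytest.approx(0.0301, rel=0.15)
        assert res.estimates["alpha"] == pytest.approx(0.00127, rel=0.30)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_growth(ObservationSet("volume_vs_time", [0, 1, 2],
                                      [1, 2, 3], 0.1))


class TestSheddingFit:
    def test_noiseless_recovery_is_exact(self, ss1p):
        res = fit_shedding(shed_obs("SS1P", 0.0, 0), ss1p)
        assert res.estimates["k_s"] == pytest.approx(0.2, rel=1e-4)

    def test_ss1p_recovery_with_noise(self, ss1p):
        res = fit_shedding(shed_obs("SS1P", 0.1, 42), ss1p)
        assert res.converged
        assert res.estimates["k_s"] == pytest.approx(0.20, rel=0.05)

    def test_lmb2_recovery_with_noise(self, lmb2):
        res = fit_shedding(shed_obs("LMB2", 0.1, 42), lmb2)
        assert res.estimates["k_s"] == pytest.approx(0.002, rel=0.10)

    def test_flat_scan_flags_non_identifiable_switch(self, ss1p):
        """Data generated with constant permeability carry no information
        about the switch parameters (V_c, a): the fit is flagged."""
        flat = with_overrides(ss1p, {"permeability.P_low_cm_s": 8.0e-6})
        vols = np.geomspace(50, 1000, 10)
        e = generate_shed_scan(SyntheticSpec(kind="shed_ecs_vs_volume",
                                             design=vols, sigma=0.0),
                               params=flat)
        res = fit_shedding([e], flat, free=("k_s", "V_c", "a"), n_starts=2)
        assert res.flags  # non-identifiable and/or bound-hugging

    def test_objective_invariant_to_order_and_sigma_scale(self, ss1p):
        obs = shed_obs("SS1P", 0.1, 3)
        r1 = fit_shedding(obs, ss1p)
        perm = [ObservationSet(o.kind, o.x[::-1], o.y[::-1], o.sigma[::-1])
                for o in obs]
        r2 = fit_shedding(perm, ss1p)
        assert r2.estimates["k_s"] == pytest.approx(r1.estimates["k_s"],
                                                    rel=1e-8)
        scaled = [ObservationSet(o.kind, o.x, o.y, o.sigma * 7.0)
                  for o in obs]
        r3 = fit_shedding(scaled, ss1p)
        assert r3.estimates["k_s"] == pytest.approx(r1.estimates["k_s"],
                                                    rel=1e-6)

    def test_unknown_free_parameter(self, ss1p):
        with pytest.raises(ValueError):
            fit_shedding(shed_obs("SS1P", 0.0, 0), ss1p, free=("bogus",))


class TestTranslocationFit:
    def test_recovery_from_treated_course(self, ss1p):
        """chi_ce is recovered from a synthetic treated volume course
        (flat 1-D objective; coarse grid keeps the forward model fast)."""
        opts = SolverOptions(n_shells=9)
        sched = [(0.0, 62.0), (48.0, 62.0)]
        spec = SyntheticSpec(kind="volume_vs_time",
                             design=np.linspace(6, 96, 8), sigma=0.0)
        obs = generate_tumor_course(spec, schedule=sched, params=ss1p,
                                    options=opts)
        start = with_overrides(ss1p, {"receptor.chi_ce": 5.0})
        res = fit_translocation(obs, start, sched, 110.0, opts)
        assert res.converged
        assert res.estimates["chi_ce"] == pytest.approx(9.9, rel=0.10)
        assert res.estimates["omega"] == pytest.approx(0.065, abs=0.01)


class TestEndocytosisFit:
    def test_internalized_fraction_limits(self):
        t = np.array([0.0, 1.0, 1e6])
        f = internalized_fraction(t, 0.22, 0.61)
        assert f[0] == 0.0
        assert f[-1] == pytest.approx(1.0)
        assert np.all(internalized_fraction(t, 0.0, 0.61) == 0.0)
        # monotone in k_e at fixed time
        assert internalized_fraction(4.0, 0.22, 0.61) > \
            internalized_fraction(4.0, 0.08, 0.61)

    def test_noiseless_recovery_is_exact(self):
        spec = SyntheticSpec(kind="internalization_vs_time",
                             design=np.linspace(0.25, 6, 12), sigma=0.0)
        obs = generate_internalization_course(spec)  # preset k_e = 0.22
        res = fit_endocytosis(obs, k_d=0.61)
        assert res.estimates["k_e"] == pytest.approx(0.22, rel=1e-4)

    def test_slow_system_recovery_with_noise(self):
        spec = SyntheticSpec(kind="internalization_vs_time",
                             design=np.linspace(0.5, 12, 12), sigma=0.05,
                             seed=5)
        obs = generate_internalization_course(spec, k_e=0.08, k_d=0.71)
        res = fit_endocytosis(obs, k_d=0.71)
        assert res.estimates["k_e"] == pytest.approx(0.08, rel=0.10)

    def test_zero_uptake_hits_lower_bound(self):
        spec = SyntheticSpec(kind="internalization_vs_time",
                             design=np.linspace(0.5, 6, 8), sigma=0.0)
        obs = generate_internalization_course(spec, k_e=0.0)
        res = fit_endocytosis(obs, k_d=0.61)
        assert res.estimates["k_e"] <= 1e-5
        assert "at_lower_bound" in res.flags


def test_bootstrap_interval_covers_truth(ss1p):
    """A residual bootstrap around the k_s fit brackets the generating
    value (single seeded replicate; the interval is also ordered)."""
    obs = shed_obs("SS1P", 0.1, 42)
    ci = bootstrap_fit(lambda o: fit_shedding(o, ss1p), obs,
                       n_resamples=30, seed=1)
    lo, hi = ci["k_s"]
    assert lo < 0.2 < hi
    assert hi / lo < 1.5  # tight at 10% noise with 20 points
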