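"""Coupled integration: conservation, determinism, analytic limits."""

import numpy as np
import pytest

from lagcomp import (
    AdaptiveBS32,
    MonodParams,
    SimulationConfig,
    chemostat_steady_state,
    compartmentize,
    integrate_adaptive,
    run_mixing,
    run_parcel_mixing,
    run_protocol,
)
from lagcomp.simulator import SimulationError


class TestIntegratorCore:
    def test_third_order_on_smooth_problem(self):
        """y' = -y integrated far below tolerance."""
        y = integrate_adaptive(lambda t, y: -y, 0.0, np.array([1.0]), 5.0,
                               rel_tol=1e-6, abs_tol=1e-12, dt_max=1.0)
        assert y[0] == pytest.approx(np.exp(-5.0), rel=1e-5)

    def test_step_cap_respected(self):
        steps = []
        solver = AdaptiveBS32(lambda t, y: -y, 1e-3, 1e-12, dt_max=0.25)
        solver.integrate(0.0, np.array([1.0]), 2.0,
                         on_accept=lambda t0, t1, y, f0, f1: steps.append(t1 - t0))
        assert max(steps) <= 0.25 + 1e-12

    def test_nonfinite_state_aborts(self):
        with pytest.raises(SimulationError):
            integrate_adaptive(lambda t, y: y**2, 0.0, np.array([1.0]), 10.0,
                               rel_tol=1e-6, abs_tol=1e-12, dt_max=1.0)


class TestMixingProtocol:
    def test_tracer_mass_conserved_and_homogenizes(self, coarse_model):
        cfg = SimulationConfig(mode="mixing", duration=200.0, n_parcels=0)
        res = run_mixing(coarse_model, cfg)
        assert res.threshold_reached
        assert res.tau95_com > 0 and res.tau95_probe > 0
        # well past the homogeneity threshold by the end of the run
        assert res.com[-1] < 0.0283 / 10

    def test_single_compartment_already_mixed(self, base_field):
        model = compartmentize(base_field, "A1R1T1")
        cfg = SimulationConfig(mode="mixing", duration=1.0, n_parcels=0)
        res = run_mixing(model, cfg)
        assert res.tau95_probe == 0.0
        assert res.tau95_com == res.times[0]

    def test_two_box_probe_matches_closed_form(self, two_box_model):
        """Symmetric two-box tracer decays as exp(-2 phi t / M)."""
        cfg = SimulationConfig(mode="mixing", duration=20.0, n_parcels=0,
                               rel_tol=1e-6, abs_tol=1e-12,
                               injection_point=(0.2, 0.0, 0.0),
                               probe_point=(0.8, 0.0, 0.0))
        two_box_model._geometry = _FakeGeo()
        res = run_mixing(two_box_model, cfg, dt_max=0.05)
        rate = 2 * 500.0 / 1000.0
        expected = 1.0 - np.exp(-rate * res.times)  # probe / mean, mean = 0.5
        np.testing.assert_allclose(res.probe, expected, atol=1e-5)

    def test_parcel_mixing_floor_with_few_parcels(self, coarse_model):
        cfg = SimulationConfig(mode="parcel_mixing", duration=60.0, n_parcels=50,
                               seed=2, dt_max=0.03)
        res = run_parcel_mixing(coarse_model, cfg)
        assert not res.threshold_reached
        assert np.isnan(res.tau95_com)
        # counting-noise floor for equal-ish compartments
        assert res.com[-1] > 0.0283

    def test_single_parcel_never_mixes(self, coarse_model):
        cfg = SimulationConfig(mode="parcel_mixing", duration=5.0, n_parcels=1,
                               seed=2, dt_max=0.03)
        res = run_parcel_mixing(coarse_model, cfg)
        assert not res.threshold_reached


class _FakeGeo:
    liquid_height = 1.0
    radius = 1.0


class TestReactiveProtocols:
    def test_chemostat_reaches_analytic_steady_state(self, base_field):
        model = compartmentize(base_field, "A1R1T1")
        cfg = SimulationConfig(mode="blackbox_euler", duration=200.0, n_parcels=0,
                               dt_max=1.0)
        traj = run_protocol(model, cfg)
        cs_star = chemostat_steady_state(cfg.monod, cfg.feed_rate_g_m3_s)
        assert traj.final_cs[0] == pytest.approx(cs_star, rel=1e-3)

    def test_conservation_audit(self, coarse_model):
        cfg = SimulationConfig(mode="blackbox_lagrange", duration=30.0,
                               n_parcels=300, seed=4, dt_max=0.03)
        traj = run_protocol(coarse_model, cfg)
        assert traj.audit["balance_relative_error"] < 1e-6
        pop = traj.final_population
        assert pop.n_parcels == 300
        # fixed-biomass protocol: per-parcel biomass untouched
        np.testing.assert_allclose(pop.biomass, pop.biomass[0])

    def test_bit_identical_reruns(self, coarse_model):
        outs = []
        for _ in range(2):
            cfg = SimulationConfig(mode="blackbox_lagrange", duration=10.0,
                                   n_parcels=200, seed=8, dt_max=0.03,
                                   n_lifelines=5)
            traj = run_protocol(coarse_model, cfg)
            outs.append(traj)
        np.testing.assert_array_equal(outs[0].final_cs, outs[1].final_cs)
        np.testing.assert_array_equal(outs[0].final_population.compartment,
                                      outs[1].final_population.compartment)
        np.testing.assert_array_equal(outs[0].lifelines.ratio, outs[1].lifelines.ratio)

    def test_tolerance_refinement_converges(self, coarse_model):
        finals = []
        for rel in (1e-3, 5e-4):
            cfg = SimulationConfig(mode="blackbox_euler", duration=30.0,
                                   n_parcels=0, rel_tol=rel, dt_max=0.03)
            finals.append(run_protocol(coarse_model, cfg).cs_mean_vol[-1])
        assert abs(finals[1] - finals[0]) < 1e-3 * abs(finals[1])

    def test_parcel_registered_mean_below_volumetric(self, base_model):
        """Parcels sit where uptake is active, so they read lower Cs."""
        cfg = SimulationConfig(mode="blackbox_lagrange", duration=150.0,
                               n_parcels=1000, seed=6, dt_max=0.03,
                               output_interval=1.0)
        traj = run_protocol(base_model, cfg)
        w = traj.times >= 75.0
        assert traj.cs_mean_parcel[w].mean() <= traj.cs_mean_vol[w].mean()

    def test_fedbatch_biomass_grows(self, coarse_model):
        cfg = SimulationConfig(mode="fedbatch", duration=60.0, n_parcels=50,
                               seed=5, cx_g_kg=14.0, dt_max=0.03,
                               output_interval=20.0)
        traj = run_protocol(coarse_model, cfg)
        assert np.all(np.diff(traj.cx_g_kg) > 0)
        assert traj.audit["balance_relative_error"] < 1e-6

    def test_fedbatch_constant_mu_is_exponential(self, base_field):
        """With growth pinned, Cx(t) follows Cx0 e^(mu t) exactly."""
        from lagcomp import DemoPoolModel

        class PinnedMu(DemoPoolModel):
            MU = 1e-4  # 1/s, fast enough to resolve in 60 s

            def growth_rate(self, cs, pools):
                return np.full(np.shape(cs), self.MU)

        model = compartmentize(base_field, "A1R1T1")
        cfg = SimulationConfig(mode="fedbatch", duration=60.0, n_parcels=10,
                               seed=1, cx_g_kg=14.0, dt_max=0.5)
        traj = run_protocol(model, cfg, kinetic_model=PinnedMu.tu_a())
        expected = 14.0 * np.exp(PinnedMu.MU * traj.times[-1])
        assert traj.cx_g_kg[-1] == pytest.approx(expected, rel=1e-6)

    def test_mode_validation(self, coarse_model):
        with pytest.raises(SimulationError):
            SimulationConfig(mode="bogus")
        with pytest.raises(SimulationError):
            run_protocol(coarse_model, SimulationConfig(mode="mixing"))
        with pytest.raises(SimulationError):
            run_protocol(coarse_model,
                         SimulationConfig(mode="blackbox_lagrange", n_parcels=0))


class TestStepSizeBiasInMixing:
    def test_larger_steps_mix_slower(self, base_model):
        """The one-jump-per-step bias slows apparent mixing at coarse dt."""
        com_at_t = []
        t_star = 30.0
        for dt in (0.3, 0.01):
            cfg = SimulationConfig(mode="parcel_mixing", duration=t_star,
                                   n_parcels=20000, seed=3, dt_max=dt)
            res = run_parcel_mixing(base_model, cfg)
            com_at_t.append(res.com[-1])
        assert com_at_t[0] > com_at_t[1]
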