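"""Unit and property tests for the landscape models and Brownian sampler."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import permflux as pf
from permflux.membrane1d import _PRESETS


class TestGroundTruthModel:
    @pytest.mark.parametrize(
        "preset, barrier",
        [("dopc-like", 40.0), ("normal-0chl-like", 62.0),
         ("normal-33chl-like", 70.0)],
    )
    def test_preset_barrier_heights(self, preset, barrier):
        model = pf.make_membrane_model(preset)
        assert model.potential(0.0) == pytest.approx(barrier, abs=1e-5)

    def test_flat_landscape_is_flat(self):
        model = pf.make_membrane_model(barrier_height=0.0, bulk_diffusivity=3e-3,
                                       core_diffusivity=3e-3)
        z = np.linspace(-2.5, 2.5, 101)
        assert np.allclose(model.potential(z), 0.0, atol=1e-12)
        assert np.allclose(model.diffusivity(z), 3e-3)

    def test_potential_vanishes_at_support_edges(self):
        model = pf.make_membrane_model("normal-0chl-like")
        assert abs(model.potential(model.half_width)) < 1e-6
        assert abs(model.potential(-model.half_width)) < 1e-6

    def test_analytic_gradients_match_finite_differences(self):
        model = pf.make_membrane_model("normal-0chl-like", well_depth=3.0)
        z = np.linspace(-2.4, 2.4, 41)
        h = 1e-6
        dw_fd = (model.potential(z + h) - model.potential(z - h)) / (2 * h)
        dd_fd = (model.diffusivity(z + h) - model.diffusivity(z - h)) / (2 * h)
        assert np.allclose(model.potential_grad(z), dw_fd, atol=1e-5)
        assert np.allclose(model.diffusivity_grad(z), dd_fd, atol=1e-8)

    @pytest.mark.parametrize("bad", [dict(barrier_width=-0.1),
                                     dict(core_diffusivity=0.0),
                                     dict(bulk_diffusivity=-1e-3)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            pf.make_membrane_model(**bad)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            pf.make_membrane_model("no-such-membrane")


class TestReferencePermeability:
    def test_flat_landscape_closed_form(self, thermo):
        # W == 0, D = 0.046 nm^2/ps over 4.6 nm -> P = D/L = 0.01 nm/ps = 10 m/s
        model = pf.make_membrane_model("flat", bulk_diffusivity=0.046,
                                       core_diffusivity=0.046)
        p = pf.reference_permeability(model, thermo, -2.3, 2.3)
        assert p == pytest.approx(10.0, rel=1e-9)

    def test_square_barrier_closed_form(self, thermo):
        class SquareBarrier:
            def potential(self, z):
                z = np.asarray(z, dtype=float)
                return np.where(np.abs(z) < 0.5, 10.0, 0.0)

            def diffusivity(self, z):
                return np.full_like(np.asarray(z, dtype=float), 4.6e-3)

        p = pf.reference_permeability(SquareBarrier(), thermo, -2.3, 2.3,
                                      n_quad=400_001)
        w, d0, span = 1.0, 4.6e-3, 4.6
        exact = d0 / (w * np.exp(10.0 / thermo.RT) + (span - w)) * 1e3
        assert p == pytest.approx(exact, rel=1e-4)

    def test_stable_under_quadrature_refinement(self, thermo):
        model = pf.make_membrane_model("normal-0chl-like")
        p1 = pf.reference_permeability(model, thermo, n_quad=20_001)
        p2 = pf.reference_permeability(model, thermo, n_quad=40_001)
        assert abs(p2 / p1 - 1) < 1e-3

    def test_agrees_with_adaptive_quadrature_oracle(self, thermo):
        from scipy.integrate import quad

        model = pf.make_membrane_model("normal-0chl-like")
        integrand = lambda z: float(
            np.exp(model.potential(z) / thermo.RT) / model.diffusivity(z))
        r, _ = quad(integrand, -2.3, 2.3, limit=400)
        oracle = (1.0 / r) * 1e3
        assert pf.reference_permeability(model, thermo) == pytest.approx(
            oracle, rel=1e-6)

    def test_monotone_in_barrier_and_linear_in_diffusivity(self, thermo):
        ps = [
            pf.reference_permeability(
                pf.make_membrane_model(barrier_height=w0), thermo)
            for w0 in (10.0, 20.0, 40.0)
        ]
        assert ps[0] > ps[1] > ps[2]
        base = pf.make_membrane_model(barrier_height=20.0)
        scaled = pf.make_membrane_model(
            barrier_height=20.0, bulk_diffusivity=2 * base.bulk_diffusivity,
            core_diffusivity=2 * base.core_diffusivity)
        assert pf.reference_permeability(scaled, thermo) == pytest.approx(
            2 * pf.reference_permeability(base, thermo), rel=1e-9)

    def test_symmetric_model_symmetric_limits(self, thermo):
        model = pf.make_membrane_model("dopc-like")
        p_fwd = pf.reference_permeability(model, thermo, -1.7, 2.3)
        p_rev = pf.reference_permeability(model, thermo, -2.3, 1.7)
        assert p_fwd == pytest.approx(p_rev, rel=1e-9)


class TestSimulateWindow:
    def test_equipartition_in_harmonic_well(self, thermo, ou_window):
        # sample variance -> RT/k_u for a restrained particle on W == 0
        assert ou_window.positions.var() == pytest.approx(
            thermo.RT / 1000.0, rel=0.05)

    def test_recorded_force_is_total_systematic_force(self, thermo):
        model = pf.make_membrane_model("dopc-like", well_depth=2.0)
        cfg = pf.LangevinConfig(n_steps=2_000, equilibration_steps=100, seed=5)
        w = pf.simulate_window(model, 0.8, 500.0, cfg, thermo)
        expected = -model.potential_grad(w.positions) - 500.0 * (w.positions - 0.8)
        assert np.allclose(w.forces, expected, atol=1e-10)

    def test_same_seed_identical_trajectories(self, thermo):
        model = pf.make_membrane_model("flat")
        cfg = pf.LangevinConfig(n_steps=5_000, equilibration_steps=100, seed=123)
        w1 = pf.simulate_window(model, 0.3, 1000.0, cfg, thermo)
        w2 = pf.simulate_window(model, 0.3, 1000.0, cfg, thermo)
        assert np.array_equal(w1.positions, w2.positions)
        assert np.array_equal(w1.forces, w2.forces)

    def test_free_diffusion_msd(self, thermo):
        # mean squared displacement ~ 2 D t without landscape or umbrella
        d0 = 5e-3
        model = pf.GroundTruthModel(half_width=50.0, barrier_height=0.0,
                                    bulk_diffusivity=d0, core_diffusivity=d0)
        cfg = pf.LangevinConfig(timestep=0.01, n_steps=400_000,
                                equilibration_steps=0, seed=9)
        traj = pf.membrane1d.simulate_free(model, 0.0, cfg, thermo)
        for lag in (10, 100, 1000):
            msd = np.mean((traj[lag:] - traj[:-lag]) ** 2)
            assert msd == pytest.approx(2 * d0 * lag * cfg.timestep, rel=0.1)

    def test_boltzmann_distribution_ks(self, thermo, ou_window):
        # biased density on a flat landscape is Gaussian with var RT/k_u
        sd = np.sqrt(thermo.RT / 1000.0)
        ks_small = stats.kstest(ou_window.positions[:2_000], "norm",
                                args=(0.0, sd)).statistic
        ks_large = stats.kstest(ou_window.positions[:200_000], "norm",
                                args=(0.0, sd)).statistic
        assert ks_large < 0.012
        assert ks_large < ks_small

    def test_drift_correction_keeps_boltzmann_under_varying_d(self, thermo):
        # strongly varying D with W == 0 must leave the stationary density
        # flat; without the D'(z) Ito correction it would pile up ~ 1/D.
        model = pf.GroundTruthModel(half_width=0.5, barrier_height=0.0,
                                    bulk_diffusivity=5e-3, core_diffusivity=5e-4,
                                    diffusivity_transition_width=0.15)
        cfg = pf.LangevinConfig(timestep=0.005, n_steps=20_000_000,
                                equilibration_steps=100_000, sample_stride=20,
                                seed=13)
        traj = pf.membrane1d.simulate_free(model, 0.0, cfg, thermo)
        counts, edges = np.histogram(traj, bins=10, range=(-0.5, 0.5))
        dens = counts / counts.mean()
        assert np.all(np.abs(dens - 1.0) < 0.25)
        # a missing drift term would give core/edge density ratio ~ D_w/D_m = 10
        core = dens[4:6].mean()
        edge = (dens[0] + dens[-1]) / 2.0
        assert core / edge < 1.5

    def test_oversized_timestep_rejected(self, thermo):
        model = pf.make_membrane_model("normal-0chl-like", barrier_width=0.05)
        cfg = pf.LangevinConfig(timestep=1.0, n_steps=1_000)
        with pytest.raises(ValueError, match="timestep"):
            pf.simulate_window(model, 0.0, 1000.0, cfg, thermo)

    def test_center_outside_support_rejected(self, thermo):
        model = pf.make_membrane_model("flat")
        with pytest.raises(ValueError, match="support"):
            pf.simulate_window(model, 5.0, 1000.0, pf.LangevinConfig(), thermo)


class TestGenerateWindowSet:
    @pytest.mark.parametrize(
        "zmin, zmax, spacing, expected",
        [(-2.5, 2.5, 0.1, 51), (-2.3, 2.3, 0.1, 47)],
    )
    def test_window_count(self, thermo, zmin, zmax, spacing, expected):
        model = pf.make_membrane_model("flat")
        cfg = pf.LangevinConfig(n_steps=100, equilibration_steps=10, seed=1)
        ws = pf.generate_window_set(model, zmin, zmax, spacing=spacing,
                                    config=cfg, thermo=thermo)
        assert len(ws) == expected

    def test_replicates_multiply_window_count(self, thermo):
        model = pf.make_membrane_model("flat")
        cfg = pf.LangevinConfig(n_steps=100, equilibration_steps=10, seed=1)
        ws = pf.generate_window_set(model, -2.5, 2.5, n_replicates=3,
                                    config=cfg, thermo=thermo)
        assert len(ws) == 153
        assert ws.replicate_ids == ["rep0", "rep1", "rep2"]

    def test_invalid_spacing_rejected(self, thermo):
        model = pf.make_membrane_model("flat")
        with pytest.raises(ValueError, match="spacing"):
            pf.generate_window_set(model, -1.0, 1.0, spacing=-0.1, thermo=thermo)


class TestFirstPassage:
    def test_free_diffusion_classic_result(self, thermo):
        # reflecting at 0, absorbing at L: MFPT = L^2 / (2 D)
        model = pf.make_membrane_model("flat")
        cfg = pf.LangevinConfig(timestep=0.01, seed=11)
        mean, sem = pf.first_passage_time(model, thermo, cfg, start=0.0,
                                          absorbing=1.0, reflecting=0.0,
                                          n_particles=300)
        expected = 1.0**2 / (2 * 5e-3)
        assert abs(mean - expected) < 3 * sem + 0.02 * expected

    def test_absorbing_at_start_is_zero(self, thermo):
        model = pf.make_membrane_model("flat")
        mean, sem = pf.first_passage_time(model, thermo, pf.LangevinConfig(),
                                          start=1.0, absorbing=1.0,
                                          reflecting=0.0, n_particles=5)
        assert mean == 0.0 and sem == 0.0

    def test_too_few_particles_rejected(self, thermo):
        model = pf.make_membrane_model("flat")
        with pytest.raises(ValueError, match="n_particles"):
            pf.first_passage_time(model, thermo, pf.LangevinConfig(),
                                  start=0.0, absorbing=1.0, reflecting=0.0,
                                  n_particles=1)


class TestSimulateUptake:
    def test_noiseless_values(self):
        k = 2e-4
        times = np.array([0.0, np.log(2) / k, 5e4])
        s = pf.simulate_uptake(k, times, noise_sd=0.0)
        assert s.values[0] == pytest.approx(0.0)
        assert s.values[1] == pytest.approx(0.5)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            pf.simulate_uptake(1e-4, [0.0, 10.0, 10.0])

    def test_seeded_noise_reproducible(self):
        t = np.linspace(0, 1e4, 20)
        a = pf.simulate_uptake(1e-4, t, noise_sd=0.05, seed=3)
        b = pf.simulate_uptake(1e-4, t, noise_sd=0.05, seed=3)
        assert np.array_equal(a.values, b.values)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(w0=st.floats(0.0, 80.0), scale=st.floats(0.2, 5.0))
def test_permeability_scaling_property(w0, scale):
    """P is monotone decreasing in barrier height and exactly linear in a
    global scaling of D."""
    thermo = pf.ThermoState()
    base = pf.make_membrane_model(barrier_height=w0)
    scaled = pf.make_membrane_model(
        barrier_height=w0, bulk_diffusivity=scale * base.bulk_diffusivity,
        core_diffusivity=scale * base.core_diffusivity)
    p0 = pf.reference_permeability(base, thermo, n_quad=2001)
    assert pf.reference_permeability(scaled, thermo, n_quad=2001) == pytest.approx(
        scale * p0, rel=1e-9)
    higher = pf.make_membrane_model(barrier_height=w0 + 5.0)
    assert pf.reference_permeability(higher, thermo, n_quad=2001) < p0
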