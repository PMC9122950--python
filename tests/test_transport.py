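import numpy as np
import pandas as pd
import pytest

from mnsox import ProfileTruth, make_profiles
from mnsox.profiles import DepthProfile
from mnsox.transport import (
    AbundanceProfile,
    ModelConfig,
    ModelResult,
    SulfideTransportModel,
    interpolate_abundance,
    oxidation_horizon,
    run_to_steady_state,
    sink_coefficient_profile,
    stability_timestep,
    step,
)


def _linear_profile(cfg):
    z = cfg.grid
    return cfg.c_top + (cfg.c_bottom - cfg.c_top) * (z - cfg.depth_top) / (
        cfg.depth_bottom - cfg.depth_top
    )


class TestStep:
    def test_linear_profile_is_stationary_without_sink(self):
        cfg = ModelConfig(sink_mode="none")
        c = _linear_profile(cfg)
        out = step(c, cfg)
        assert np.allclose(out, c, atol=1e-14)

    def test_pure_decay_of_uniform_field(self):
        # uniform field kills the diffusion term; a -1e-3 s^-1 sink over one
        # 1 s step leaves 0.999 uM
        cfg = ModelConfig(sink_mode="chemical", k_chem=-1e-3, sink_max_depth=1e9,
                          boundary="noflux", dt=1.0)
        c = np.ones(len(cfg.grid))
        out = step(c, cfg, dt=1.0)
        assert np.allclose(out, 0.999, atol=1e-12)

    def test_hand_computed_five_cell_stencil(self):
        # dx = 0.2, D = 1e-6, dt = 4000 -> lambda = 0.1; Dirichlet ends held.
        # interior by hand: 2 + 0.1(4-4+1) = 2.1; 4 + 0.1(3-8+2) = 3.7;
        # 3 + 0.1(5-6+4) = 3.3
        cfg = ModelConfig(depth_top=100.0, depth_bottom=100.8, dx=0.2,
                          diffusivity=1e-6, sink_mode="none",
                          c_top=1.0, c_bottom=5.0, dt=4000.0)
        out = step(np.array([1.0, 2.0, 4.0, 3.0, 5.0]), cfg, dt=4000.0)
        assert np.allclose(out, [1.0, 2.1, 3.7, 3.3, 5.0], atol=1e-12)

    def test_unstable_timestep_rejected(self):
        cfg = ModelConfig(sink_mode="none", dt=1e6)
        with pytest.raises(ValueError, match="stability"):
            run_to_steady_state(cfg)


class TestSteadyState:
    def test_no_sink_matches_analytic_line(self):
        cfg = ModelConfig(sink_mode="none", tolerance=1e-15)
        res = run_to_steady_state(cfg)
        assert res.converged
        assert np.max(np.abs(res.concentration - _linear_profile(cfg))) <= 1e-6

    def test_uniform_sink_matches_sinh_closed_form(self):
        # uniform kappa over the whole 200-cell domain: the steady state is
        # C(z) = C_b sinh(m (z - z_top)) / sinh(m L), m = sqrt(kappa/D)
        d, length = 1e-6, 40.0
        m = 3.0 / length
        cfg = ModelConfig(sink_mode="chemical", k_chem=-(m**2) * d,
                          diffusivity=d, sink_max_depth=1e9, tolerance=1e-13)
        res = run_to_steady_state(cfg)
        z = res.depth
        closed = cfg.c_bottom * np.sinh(m * (z - cfg.depth_top)) / np.sinh(m * length)
        rel = np.abs(res.concentration[1:] - closed[1:]) / closed[1:]
        assert res.converged
        assert rel.max() <= 0.005

    def test_mass_conserved_with_noflux_and_no_sink(self):
        cfg = ModelConfig(sink_mode="none", boundary="noflux")
        rng = np.random.default_rng(1)
        c = rng.uniform(0.0, 10.0, len(cfg.grid))
        total0 = c.sum()
        dt = stability_timestep(cfg)
        for _ in range(100_000):
            c = step(c, cfg, dt=dt)
        assert abs(c.sum() - total0) / total0 < 1e-8

    def test_nonnegativity_under_stability_rule(self):
        cfg = ModelConfig(sink_mode="chemical", k_chem=-1e-5, sink_max_depth=1e9)
        rng = np.random.default_rng(2)
        c = rng.uniform(0.0, 10.0, len(cfg.grid))
        for _ in range(500):
            c = step(c, cfg)
            assert np.all(c >= 0.0)

    def test_steady_state_monotone_with_depth(self, synthetic_profile):
        for mode in ("biological", "chemical"):
            cfg = ModelConfig(sink_mode=mode, tolerance=1e-12)
            prof = synthetic_profile if mode == "biological" else None
            res = SulfideTransportModel(cfg, prof).solve()
            assert np.all(np.diff(res.concentration) >= -1e-9)

    def test_steady_state_independent_of_initialization(self):
        cfg = ModelConfig(sink_mode="chemical", tolerance=1e-13)
        res_zero = run_to_steady_state(cfg)
        res_linear = run_to_steady_state(cfg, initial=_linear_profile(cfg))
        assert res_zero.converged and res_linear.converged
        assert np.max(np.abs(res_zero.concentration - res_linear.concentration)) < 1e-3

    def test_grid_refinement_consistency(self):
        coarse = ModelConfig(sink_mode="chemical", dx=0.2, tolerance=1e-12)
        fine = ModelConfig(sink_mode="chemical", dx=0.1, tolerance=1e-12)
        rc = run_to_steady_state(coarse)
        rf = run_to_steady_state(fine)
        on_coarse = np.interp(rc.depth, rf.depth, rf.concentration)
        rel = np.max(np.abs(on_coarse - rc.concentration)) / rc.concentration.max()
        assert rel < 0.01


class TestSinkStructure:
    def test_rate_dominance_at_peak_abundance(self):
        # at 4e7 cells/l the biological coefficient exceeds |k_chem| tenfold
        cfg = ModelConfig(sink_mode="biological")
        ab = AbundanceProfile(depth=cfg.grid,
                              cells_per_l=np.full(len(cfg.grid), 4e7),
                              fraction=0.96)
        kappa = sink_coefficient_profile(cfg, ab)
        shallow = cfg.grid <= cfg.sink_max_depth
        assert np.all(np.abs(kappa[shallow]) >= 10 * abs(cfg.k_chem))

    def test_sink_inactive_below_max_depth(self, synthetic_profile):
        cfg = ModelConfig(sink_mode="both")
        ab = interpolate_abundance(synthetic_profile, cfg.grid)
        kappa = sink_coefficient_profile(cfg, ab)
        assert np.all(kappa[cfg.grid > cfg.sink_max_depth] == 0.0)
        assert np.all(kappa <= 0.0)

    def test_biological_profile_more_linear_than_chemical(self, synthetic_profile):
        # the hallmark contrast: an abundance peak at the euxinic boundary
        # confines oxidation there, keeping the profile nearly linear below,
        # while a uniform chemical sink bends it over the whole sink zone
        def curvature_r2(res):
            # linearity over the sulfidic part of the profile (C > 0.1 uM)
            mask = res.concentration > 0.1
            z, c = res.depth[mask], res.concentration[mask]
            fitted = np.polyval(np.polyfit(z, c, 1), z)
            return 1.0 - np.sum((c - fitted) ** 2) / np.sum((c - c.mean()) ** 2)

        bio = SulfideTransportModel(
            ModelConfig(sink_mode="biological", tolerance=1e-12), synthetic_profile
        ).solve()
        chem = SulfideTransportModel(
            ModelConfig(sink_mode="chemical", tolerance=1e-12)
        ).solve()
        assert (1 - curvature_r2(bio.result)) < 0.2 * (1 - curvature_r2(chem.result))


class TestOxidationHorizon:
    @staticmethod
    def _result_with_rate(rate, cfg):
        return ModelResult(
            depth=cfg.grid, concentration=np.ones(len(cfg.grid)),
            oxidation_rate=rate, iterations=1, converged=True,
            dt_used=1.0, config=cfg,
        )

    def test_delta_sink_horizon_spans_one_cell(self):
        cfg = ModelConfig(sink_mode="none")
        rate = np.zeros(len(cfg.grid))
        i = 50
        rate[i] = 1.0
        z_top, z_bot = oxidation_horizon(self._result_with_rate(rate, cfg))
        z_cell = cfg.grid[i]
        assert z_cell - cfg.dx <= z_top <= z_cell
        assert z_cell <= z_bot <= z_cell + cfg.dx

    def test_uniform_zone_matches_trapezoidal_oracle(self):
        from scipy.integrate import cumulative_trapezoid

        cfg = ModelConfig(sink_mode="none")
        z = cfg.grid
        rate = np.where((z >= 95.0) & (z <= 105.0), 2.5, 0.0)
        z_top, z_bot = oxidation_horizon(self._result_with_rate(rate, cfg))
        cum = cumulative_trapezoid(rate, z, initial=0.0)
        expect_top = np.interp(0.025 * cum[-1], cum, z)
        expect_bot = np.interp(0.975 * cum[-1], cum, z)
        assert z_top == pytest.approx(expect_top, abs=1e-9)
        assert z_bot == pytest.approx(expect_bot, abs=1e-9)

    def test_chemical_horizon_at_least_three_times_broader(self, synthetic_profile):
        bio = SulfideTransportModel(
            ModelConfig(sink_mode="biological", tolerance=1e-12), synthetic_profile
        ).solve()
        chem = SulfideTransportModel(
            ModelConfig(sink_mode="chemical", tolerance=1e-12)
        ).solve()
        bio_width = np.diff(bio.horizon())[0]
        chem_width = np.diff(chem.horizon())[0]
        assert chem_width >= 3.0 * bio_width

    def test_zero_total_oxidation_rejected(self):
        cfg = ModelConfig(sink_mode="none")
        res = self._result_with_rate(np.zeros(len(cfg.grid)), cfg)
        with pytest.raises(ValueError, match="zero total oxidation"):
            oxidation_horizon(res)


class TestAbundanceInterpolation:
    def test_identity_on_sample_grid(self, synthetic_profile):
        grid = synthetic_profile.depth
        ab = interpolate_abundance(synthetic_profile, grid)
        expected = (synthetic_profile.column("ca_epsy914_cells_per_l")
                    * synthetic_profile.column("f_sulfurimonas"))
        assert np.allclose(ab.effective, expected, rtol=1e-12)

    def test_log_linear_geometric_midpoint(self):
        df = pd.DataFrame({"depth_m": [90.0, 110.0],
                           "ca_epsy914_cells_per_l": [1e6, 1e8]})
        prof = DepthProfile(data=df)
        ab = interpolate_abundance(prof, np.array([100.0]))
        assert ab.effective[0] == pytest.approx(1e7, rel=1e-9)

    def test_constant_extrapolation_beyond_samples(self):
        df = pd.DataFrame({"depth_m": [90.0, 110.0],
                           "ca_epsy914_cells_per_l": [1e6, 1e8]})
        ab = interpolate_abundance(DepthProfile(data=df), np.array([80.0, 120.0]))
        assert ab.effective[0] == pytest.approx(1e6, rel=1e-9)
        assert ab.effective[1] == pytest.approx(1e8, rel=1e-9)

    def test_gaussian_truth_recovered_within_ten_percent(self):
        truth = ProfileTruth(depth_step=2.0)
        coarse = make_profiles(truth)
        fine_grid = np.arange(80.0, 120.0 + 0.1, 0.2)
        ab = interpolate_abundance(coarse, fine_grid)
        true_eff = truth.f_sulfurimonas * (
            truth.abundance_background
            + truth.abundance_peak
            * np.exp(-((fine_grid - truth.abundance_peak_depth) ** 2)
                     / (2 * truth.peak_width**2))
        )
        rel = np.abs(ab.effective - true_eff) / true_eff
        assert rel.max() < 0.10

    def test_empty_profile_rejected(self):
        df = pd.DataFrame({"depth_m": [100.0], "ca_epsy914_cells_per_l": [1e6]})
        with pytest.raises(ValueError):
            interpolate_abundance(DepthProfile(data=df), np.array([100.0]))


def test_summary_reports_convergence(synthetic_profile):
    res = SulfideTransportModel(
        ModelConfig(sink_mode="biological", tolerance=1e-10), synthetic_profile
    ).solve()
    text = res.summary()
    assert "converged" in text and "horizon" in text
    assert res.converged
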