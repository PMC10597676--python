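import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sizespectra as ss
from sizespectra.metrics import MetricsResult, SET_METRICS
from helpers import FISH, ZOO, fish_on_zoo_config, powerlaw_prey_state


class TestBiomassAndCV:
    def test_two_point_formula(self):
        mean, cv, inv = ss.biomass_and_cv([1.0, 3.0])
        assert mean == 2.0
        assert cv == pytest.approx(math.sqrt(2.0) / 2.0)
        assert inv == pytest.approx(1.0 / cv)

    def test_constant_series_has_infinite_stability(self):
        mean, cv, inv = ss.biomass_and_cv([5.0] * 10)
        assert cv == 0.0 and inv == math.inf

    @settings(deadline=None)
    @given(st.floats(0.01, 100.0))
    def test_cv_is_scale_invariant(self, c):
        x = np.array([1.0, 2.0, 4.5, 3.0])
        _, cv1, _ = ss.biomass_and_cv(x)
        _, cv2, _ = ss.biomass_and_cv(c * x)
        assert cv2 == pytest.approx(cv1, rel=1e-9)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            ss.biomass_and_cv([0.0, 0.0])


class TestProductionAndTurnover:
    def test_zero_growth_zero_production(self, default_sim):
        st_ = default_sim.initial_state()
        growth = {n: np.zeros(default_sim.grid.group_slices[n].stop
                              - default_sim.grid.group_slices[n].start)
                  for n in st_.N}
        assert ss.production(st_, growth=growth) == 0.0

    def test_single_bin_reduction(self, default_sim):
        st_ = default_sim.initial_state()
        for n in st_.N:
            st_.N[n][:] = 0.0
        s = default_sim.grid.group_slices[FISH]
        k = s.start + 5
        st_.N[FISH][k] = 2.0
        growth = {n: np.zeros(s_.stop - s_.start)
                  for n, s_ in default_sim.grid.group_slices.items()
                  if n in st_.N}
        growth[FISH][5] = 3.0
        expected = 3.0 * 2.0 * default_sim.grid.dw[k]
        assert ss.production(st_, growth=growth) == pytest.approx(expected)

    def test_linearity_in_density_at_fixed_growth_field(self, default_sim):
        st_ = default_sim.initial_state()
        growth = {n: r[0] for n, r in default_sim.rates(st_).items()}
        p1 = ss.production(st_, growth=growth)
        for n in st_.N:
            st_.N[n] *= 2.0
        assert ss.production(st_, growth=growth) == pytest.approx(2 * p1)

    def test_turnover_reciprocal(self):
        assert ss.turnover_time(1.0, 0.5) == 2.0
        assert ss.turnover_time(3.0, 3.0) == 1.0
        assert ss.turnover_time(1.0, 1.0) == 0.5 * ss.turnover_time(1.0, 0.5)
        assert ss.turnover_time(1.0, 0.0) == math.inf


class TestSpectrumFit:
    def test_exact_power_law_recovered(self, default_sim):
        st_ = default_sim.initial_state()
        for n in st_.N:
            s = default_sim.grid.group_slices[n]
            st_.N[n][:] = 0.0
            st_.N[n][s] = 100.0 * default_sim.grid.w_centers[s] ** -2.0
        # groups overlap; restrict to one to keep the sum an exact power law
        for n in st_.N:
            if n != FISH:
                st_.N[n][:] = 0.0
        slope, intercept = ss.spectrum_slope_intercept(st_)
        assert slope == pytest.approx(-2.0, abs=1e-10)
        assert intercept == pytest.approx(2.0, abs=1e-10)

    def test_log_space_shift_moves_intercept_only(self, default_sim):
        st_ = default_sim.initial_state()
        s1, i1 = ss.spectrum_slope_intercept(st_)
        for n in st_.N:
            st_.N[n] *= 10.0
        s2, i2 = ss.spectrum_slope_intercept(st_)
        assert s2 == pytest.approx(s1, abs=1e-12)
        assert i2 == pytest.approx(i1 + 1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, default_sim, rng):
        st_ = default_sim.initial_state()
        s = default_sim.grid.group_slices[FISH]
        for n in st_.N:
            st_.N[n][:] = 0.0
        vals = rng.lognormal(0.0, 1.0, s.stop - s.start)
        st_.N[FISH][s] = vals
        slope, intercept = ss.spectrum_slope_intercept(st_)
        x = default_sim.grid.log10_centers[s]
        y = np.log10(vals)
        A = np.vstack([x, np.ones_like(x)]).T
        beta = np.linalg.solve(A.T @ A, A.T @ y)   # normal equations
        assert slope == pytest.approx(beta[0], rel=1e-9)
        assert intercept == pytest.approx(beta[1], rel=1e-9)

    def test_too_few_bins_rejected(self, default_sim):
        st_ = default_sim.initial_state()
        for n in st_.N:
            st_.N[n][:] = 0.0
        st_.N[FISH][default_sim.grid.group_slices[FISH].start] = 1.0
        with pytest.raises(ValueError, match="3"):
            ss.spectrum_slope_intercept(st_)


class TestTrophicPosition:
    def test_pure_herbivore_sits_at_tp_2(self):
        cfg = fish_on_zoo_config()
        sim = ss.Simulation(cfg)
        st_ = sim.initial_state()
        tp, resid = ss.trophic_positions(sim, st_)
        assert resid < 1e-10
        zoo_tp = tp[ZOO]
        assert np.allclose(zoo_tp[np.isfinite(zoo_tp)], 2.0, atol=1e-9)

    def test_two_link_chain_fish_at_tp_3(self):
        cfg = fish_on_zoo_config()
        sim = ss.Simulation(cfg)
        st_ = sim.initial_state()
        tp, _ = ss.trophic_positions(sim, st_)
        fish_tp = tp[FISH]
        ok = np.isfinite(fish_tp)
        assert ok.any()
        assert np.allclose(fish_tp[ok], 3.0, atol=1e-9)

    def test_half_half_diet_gives_tp_2_5(self):
        """50/50 biomass shares on TP-1 and TP-2 prey average to TP 2.5."""
        cfg = fish_on_zoo_config()
        # widen zooplankton so it overlays the phytoplankton range exactly
        cfg.groups[ZOO] = cfg.groups[ZOO].copy(w_min=1e-13, w_mat=1e-8)
        off = {n: 0.0 for n in list(ss.GROUP_NAMES) + ["phytoplankton"]}
        cfg.groups[FISH] = cfg.groups[FISH].copy(
            w_min=1e-4, w_mat=1e-2, w_max=1.0, beta0=1000.0,
            interaction=dict(off, zooplankton=1.0, phytoplankton=1.0))
        sim = ss.Simulation(cfg)
        st_ = sim.initial_state()
        for n in st_.N:
            st_.N[n][:] = 0.0
        sz = sim.grid.group_slices[ZOO]
        st_.N[ZOO][sz] = st_.phyto_density[sz]   # equal biomass everywhere
        tp, _ = ss.trophic_positions(sim, st_)
        fish_tp = tp[FISH]
        ok = np.isfinite(fish_tp)
        assert ok.any()
        assert np.allclose(fish_tp[ok], 2.5, atol=1e-6)

    def test_relative_baseline_subtracts(self):
        cfg = fish_on_zoo_config()
        sim = ss.Simulation(cfg)
        st_ = sim.initial_state()
        _, tp_abs = ss.relative_trophic_position(sim, st_, FISH)
        _, tp_rel = ss.relative_trophic_position(sim, st_, FISH, baseline=1.0)
        ok = np.isfinite(tp_abs)
        assert np.allclose(tp_abs[ok] - 1.0, tp_rel[ok])


class TestRealisedPPMR:
    def test_delta_diet_recovers_preferred_ratio(self, default_cfg):
        """A point diet at w' = w/beta realises exactly PPMR = beta."""
        cfg = fish_on_zoo_config()
        sim = ss.Simulation(cfg)
        st_ = sim.initial_state()
        for n in st_.N:
            st_.N[n][:] = 0.0
        st_.phyto_density = np.zeros_like(st_.phyto_density)
        fish = cfg.groups[FISH]
        # prey delta exactly at the preferred ratio below a fish bin center
        s = sim.grid.group_slices[FISH]
        iw = s.start + 25
        w = sim.grid.w_centers[iw]
        sz = sim.grid.group_slices[ZOO]
        kk = int(np.argmin(np.abs(sim.grid.w_centers - w / fish.beta0)))
        assert sz.start <= kk < sz.stop
        st_.N[ZOO][kk] = 1.0
        x, rp = ss.realised_ppmr(sim, st_, FISH)
        got = rp[iw - s.start]
        assert got == pytest.approx(w / sim.grid.w_centers[kk], rel=1e-12)

    def test_powerlaw_prey_shift_matches_gaussian_moment(self, default_sim,
                                                         default_cfg):
        """Realised PPMR = beta*exp(-sigma^2 (b+2)) on an N = a w^b prey field."""
        cfg = fish_on_zoo_config()
        sim = ss.Simulation(cfg)
        b = -1.7
        st_ = powerlaw_prey_state(sim, ZOO, 1e-3, b)
        x, rp = ss.realised_ppmr(sim, st_, FISH)
        fish = cfg.groups[FISH]
        i = int(np.argmin(np.abs(x - (-1.0))))   # fish of 0.1 g
        expected = fish.beta0 * math.exp(-fish.sigma ** 2 * (b + 2))
        assert rp[i] == pytest.approx(expected, rel=0.02)

    def test_empty_diet_is_nan(self, default_sim):
        st_ = default_sim.initial_state()
        for n in st_.N:
            st_.N[n][:] = 0.0
        st_.phyto_density = np.zeros_like(st_.phyto_density)
        _, rp = ss.realised_ppmr(default_sim, st_, FISH)
        assert np.all(np.isnan(rp))


class TestRMSE:
    def test_identical_curves_zero(self):
        x = np.linspace(-2, 2, 9)
        y = x ** 2
        assert ss.rmse((x, y), (x, y)) == 0.0

    def test_constant_offset(self):
        x = np.linspace(-2, 2, 9)
        assert ss.rmse((x, x * 0.0), (x, x * 0.0 + 1.3)) == pytest.approx(1.3)

    def test_three_point_hand_example(self):
        obs = (np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 5.0]))
        model = (np.array([0.0, 4.0]), np.array([2.0, 2.0]))
        assert ss.rmse(model, obs) == pytest.approx(math.sqrt(3.0))

    def test_out_of_support_observations_excluded_and_counted(self):
        model = (np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        obs = (np.array([0.5, 5.0]), np.array([2.0, 9.0]))
        err, used, excl = ss.rmse(model, obs, full=True)
        assert (used, excl) == (1, 1)
        assert err == pytest.approx(1.0)


def _fake_metrics(label, **scalars):
    base = dict(total_biomass=1.0, production=0.5, cv_biomass=0.2,
                inv_cv=5.0, turnover_time=2.0, pb_rate=0.5,
                spectrum_slope=-2.0, spectrum_intercept=1.0)
    base.update(scalars)
    return MetricsResult(label=label, sweep_coords={}, **base)


class TestCompareSets:
    def test_identical_sets_all_zero(self):
        res = [_fake_metrics(f"r{i}") for i in range(3)]
        comp = ss.compare_sets(res, res)
        assert all(v == 0.0 for v in comp.values())

    def test_seven_percent_decline(self):
        ref = [_fake_metrics("a", total_biomass=b) for b in (1.0, 2.0, 3.0)]
        trt = [_fake_metrics("b", total_biomass=b * 0.93)
               for b in (1.0, 2.0, 3.0)]
        comp = ss.compare_sets(ref, trt)
        assert comp["total_biomass"] == pytest.approx(-7.0)

    def test_median_not_mean_drives_change(self):
        ref = [_fake_metrics("a", production=p) for p in (1.0, 2.0, 100.0)]
        trt = [_fake_metrics("b", production=4.0)] * 3
        comp = ss.compare_sets(ref, trt)
        assert comp["production"] == pytest.approx(100.0 * (4 - 2) / 2)

    def test_sign_antisymmetry_up_to_denominator(self):
        ref = [_fake_metrics("a", total_biomass=2.0)] * 3
        trt = [_fake_metrics("b", total_biomass=3.0)] * 3
        fwd = ss.compare_sets(ref, trt)["total_biomass"]
        bwd = ss.compare_sets(trt, ref)["total_biomass"]
        assert fwd > 0 > bwd
        # same absolute difference, different denominator
        assert fwd / 100 * 2.0 == pytest.approx(-bwd / 100 * 3.0)


def test_evaluate_run_invariants(short_run):
    """turnover_time * (P/B) = 1 and curves are present per group."""
    sim, res = short_run
    m = ss.evaluate_run(res, sim=sim)
    assert m.turnover_time * m.pb_rate == pytest.approx(1.0, rel=1e-12)
    assert m.inv_cv == pytest.approx(1.0 / m.cv_biomass, rel=1e-12)
    assert set(m.rtp) == set(ss.GROUP_NAMES)
    for nme, (x, tp) in m.rtp.items():
        ok = np.isfinite(tp)
        # consumers with a non-empty diet sit at least one level above algae
        assert np.all(tp[ok] >= 2.0 - 1e-9)
    summary = ss.summarize_set([m])
    assert set(summary) == set(SET_METRICS)
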