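"""Boltzmann/exponential fits, gating energetics, mutant cycle, statistics."""

import numpy as np
import pytest

from crankshaft.ephys import (
    ActivationDataset,
    ConstructEnergetics,
    HCN2_PROTOCOL,
    SaturatedDataWarning,
    boltzmann,
    camp_shift,
    compare_groups,
    construct_energetics,
    delta_g_app,
    fit_boltzmann,
    fit_exponential,
    mean_activation,
    mutant_cycle,
)
from crankshaft.synth import (
    make_activation_dataset,
    make_current_trace,
    make_energy_table,
)


class TestProtocol:
    def test_hcn2_voltages(self):
        v = HCN2_PROTOCOL.voltages
        assert v[0] == -40 and v[-1] == -130
        assert len(v) == 10
        np.testing.assert_allclose(np.diff(v), -10)


class TestFitBoltzmann:
    def test_noiseless_inversion_is_exact(self):
        cells = make_activation_dataset(
            v_half=-96.7, k_slope=8.0, amplitude=500.0,
            protocol=HCN2_PROTOCOL, noise_frac=0.0, n_cells=1, seed=0)
        fit = fit_boltzmann(cells[0])
        assert fit.v_half == pytest.approx(-96.7, abs=1e-6)
        assert fit.k_slope == pytest.approx(8.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(500.0, rel=1e-6)

    def test_monte_carlo_recovery_with_noise(self):
        """100 cells at 2% amplitude noise: mean V1/2 within 1 mV of truth."""
        cells = make_activation_dataset(
            v_half=-96.7, k_slope=8.0, amplitude=500.0,
            protocol=HCN2_PROTOCOL, noise_frac=0.02, n_cells=100, seed=1)
        fits = [fit_boltzmann(c) for c in cells]
        summary = mean_activation(fits)
        assert summary.v_half_mean == pytest.approx(-96.7, abs=1.0)

    @pytest.mark.parametrize("v_half,k", [(-80, 6), (-95, 8), (-110, 10)])
    def test_parameter_recovery_bias_below_half_millivolt(self, v_half, k):
        cells = make_activation_dataset(
            v_half=v_half, k_slope=k, amplitude=400.0,
            protocol=HCN2_PROTOCOL, noise_frac=0.02, n_cells=200,
            seed=abs(v_half) + k)
        fits = [fit_boltzmann(c) for c in cells]
        s = mean_activation(fits)
        assert abs(s.v_half_mean - v_half) < 0.5
        assert abs(s.k_mean - k) < 0.5

    def test_constant_amplitudes_flagged_saturated(self):
        ds = ActivationDataset(
            cell_id="c0", construct="wt", condition="control",
            voltage_mV=np.array([-40.0, -60, -80, -100]),
            tail_pA=np.full(4, 321.0))
        with pytest.warns(SaturatedDataWarning):
            fit = fit_boltzmann(ds)
        assert fit.saturated

    def test_gradient_vanishes_at_optimum(self):
        """Finite-difference gradient of the RSS is zero at the fit."""
        cells = make_activation_dataset(
            v_half=-95.0, k_slope=8.0, amplitude=500.0,
            noise_frac=0.02, n_cells=1, seed=3)
        fit = fit_boltzmann(cells[0])
        v, i = cells[0].voltage_mV, cells[0].tail_pA

        def rss(p):
            return float(((i - boltzmann(v, *p)) ** 2).sum())

        p0 = np.array([fit.v_half, fit.k_slope, fit.amplitude])
        base = rss(p0)
        scale = max(base, 1.0)
        for d in range(3):
            h = 1e-5 * max(abs(p0[d]), 1.0)
            step = np.zeros(3)
            step[d] = h
            grad = (rss(p0 + step) - rss(p0 - step)) / (2 * h)
            assert abs(grad) * h < 1e-6 * scale

    def test_requires_four_voltages(self):
        with pytest.raises(ValueError, match=">= 4"):
            ActivationDataset("c", "wt", "control",
                              np.array([-40.0, -60, -80]),
                              np.array([1.0, 2, 3]))


class TestMeanActivation:
    def test_single_fit_sem_is_nan(self):
        cells = make_activation_dataset(-90, 8, 300, noise_frac=0, n_cells=1)
        s = mean_activation([fit_boltzmann(cells[0])])
        assert s.n == 1
        assert np.isnan(s.v_half_sem)

    def test_two_fit_arithmetic(self):
        f1 = fit_boltzmann(make_activation_dataset(-90, 8, 300,
                                                   noise_frac=0)[0])
        f2 = fit_boltzmann(make_activation_dataset(-100, 8, 300,
                                                   noise_frac=0)[0])
        s = mean_activation([f1, f2])
        assert s.v_half_mean == pytest.approx(-95.0, abs=1e-5)
        assert s.v_half_sem == pytest.approx(5.0, abs=1e-5)

    def test_many_cells_mean_within_clt_bound(self):
        cells = make_activation_dataset(-95, 8, 500, noise_frac=0.02,
                                        n_cells=50, seed=4)
        s = mean_activation([fit_boltzmann(c) for c in cells])
        assert abs(s.v_half_mean + 95) < 5 * s.v_half_sem + 0.1


class TestFitExponential:
    def test_noiseless_recovery_near_machine_precision(self):
        t, i = make_current_trace(i0=500.0, tau=0.5, duration=5.0,
                                  rate=5000.0, noise=0.0)
        fit = fit_exponential(t, i)
        assert fit.tau == pytest.approx(0.5, rel=1e-9)
        assert fit.i0 == pytest.approx(500.0, rel=1e-9)

    def test_tail_current_with_noise_within_two_percent(self):
        """Deactivation-style tail window after a pulse, 1% noise."""
        t, i = make_current_trace(i0=400.0, tau=0.35, duration=5.0,
                                  rate=5000.0, noise=4.0, seed=5)
        fit = fit_exponential(t, i, window=(0.0, 2.0))
        assert fit.tau == pytest.approx(0.35, rel=0.02)

    def test_window_with_too_few_samples_rejected(self):
        t, i = make_current_trace(duration=1.0, rate=100.0)
        with pytest.raises(ValueError, match=">= 10"):
            fit_exponential(t, i, window=(0.0, 0.04))

    def test_trace_value_at_tau_is_i0_over_e(self):
        t, i = make_current_trace(i0=500.0, tau=0.5, duration=5.0,
                                  rate=5000.0, noise=0.0)
        idx = np.argmin(np.abs(t - 0.5))
        assert i[idx] == pytest.approx(500.0 / np.e, rel=1e-6)


class TestDeltaGApp:
    def test_zero_v_half_gives_zero(self):
        assert delta_g_app(0.0, 8.0, 298.0) == 0.0

    def test_worked_magnitude(self):
        """V1/2 = -96.7 mV, k = 8 mV, 298 K -> -7.157 kcal/mol."""
        dg = delta_g_app(-96.7, 8.0, 298.0)
        assert dg == pytest.approx(1.987e-3 * 298.0 * (-96.7 / 8.0), rel=1e-12)
        assert dg == pytest.approx(-7.157, abs=1e-3)

    def test_ratio_invariance(self):
        assert delta_g_app(-96.7, 8.0) == pytest.approx(
            delta_g_app(-967.0, 80.0), rel=1e-12)

    def test_zero_slope_rejected(self):
        with pytest.raises(ZeroDivisionError):
            delta_g_app(-90.0, 0.0)


class TestMutantCycle:
    def _wt(self):
        return ConstructEnergetics("wt", -96.7, 8.0)

    def test_additive_energies_give_zero_coupling(self):
        table = make_energy_table(self._wt(), dg_p1=1.2, dg_p2=-0.8,
                                  coupling=0.0)
        cycle = mutant_cycle(*table)
        assert cycle.ddg == pytest.approx(0.0, abs=1e-12)
        assert not cycle.coupled

    def test_injected_coupling_recovered_exactly(self):
        table = make_energy_table(self._wt(), dg_p1=1.2, dg_p2=-0.8,
                                  coupling=-2.0)
        cycle = mutant_cycle(*table)
        assert cycle.ddg == pytest.approx(-2.0, abs=1e-12)
        assert cycle.coupled

    def test_swapping_singles_leaves_ddg_unchanged(self):
        wt, s1, s2, dd = make_energy_table(self._wt(), 1.2, -0.8,
                                           coupling=-2.0)
        assert mutant_cycle(wt, s1, s2, dd).ddg == pytest.approx(
            mutant_cycle(wt, s2, s1, dd).ddg)

    def test_coupling_sign_flip_flips_ddg(self):
        plus = mutant_cycle(*make_energy_table(self._wt(), 1.0, 1.0, 2.0))
        minus = mutant_cycle(*make_energy_table(self._wt(), 1.0, 1.0, -2.0))
        assert plus.ddg == pytest.approx(-minus.ddg)

    def test_invariant_to_constant_energy_offset(self):
        """Adding a constant to every dG_app leaves ddG unchanged."""
        table = make_energy_table(self._wt(), 1.2, -0.8, coupling=-2.0)
        shifted = [
            ConstructEnergetics(c.construct,
                                c.v_half + 3.0 * c.k_slope / (1.987e-3 * 298),
                                c.k_slope, c.temperature)
            for c in table
        ]
        assert mutant_cycle(*shifted).ddg == pytest.approx(
            mutant_cycle(*table).ddg, abs=1e-9)

    def test_path_sums_equal_plus_minus_ddg(self):
        cycle = mutant_cycle(*make_energy_table(self._wt(), 1.2, -0.8, -2.0))
        keys = list(cycle.dg_p)
        route1 = cycle.dg_p[keys[0]] - cycle.dg_p[keys[3]]
        assert route1 == pytest.approx(-cycle.ddg, abs=1e-9)

    def test_temperature_mismatch_rejected(self):
        wt, s1, s2, dd = make_energy_table(self._wt(), 1.0, 1.0, 0.0)
        warm = ConstructEnergetics(dd.construct, dd.v_half, dd.k_slope, 310.0)
        with pytest.raises(ValueError, match="temperature"):
            mutant_cycle(wt, s1, s2, warm)


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        g = {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]}
        res = compare_groups(g)
        assert res.p_value > 0.05
        assert not res.significant

    def test_power_for_separated_groups(self):
        """N(0,1) vs N(5,1), n=20: significant in >= 99% of seeds."""
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            g = {"a": rng.normal(0, 1, 20), "b": rng.normal(5, 1, 20)}
            if compare_groups(g).significant:
                hits += 1
        assert hits >= 99

    def test_f_statistic_matches_textbook_formula(self):
        rng = np.random.default_rng(6)
        groups = {c: rng.normal(i, 1, 12) for i, c in enumerate("abc")}
        res = compare_groups(groups)
        data = list(groups.values())
        grand = np.concatenate(data).mean()
        ss_b = sum(len(d) * (d.mean() - grand) ** 2 for d in data)
        ss_w = sum(((d - d.mean()) ** 2).sum() for d in data)
        f = (ss_b / 2) / (ss_w / (36 - 3))
        assert res.statistic == pytest.approx(f, rel=1e-10)
        assert res.method == "anova+lsd"

    def test_lsd_only_after_significant_anova(self):
        rng = np.random.default_rng(7)
        same = {c: rng.normal(0, 1, 10) for c in "abc"}
        res_same = compare_groups(same)
        if not res_same.significant:
            assert res_same.pairwise is None
        apart = {c: rng.normal(5 * i, 1, 10) for i, c in enumerate("abc")}
        res_apart = compare_groups(apart)
        assert res_apart.significant
        assert len(res_apart.pairwise) == 3

    def test_degenerate_variance_flagged(self):
        g = {"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0, 2.0]}
        assert compare_groups(g).degenerate


class TestCampShift:
    def test_identical_summaries_shift_zero(self):
        cells = make_activation_dataset(-95, 8, 500, noise_frac=0.02,
                                        n_cells=5, seed=8)
        s = mean_activation([fit_boltzmann(c) for c in cells])
        shift, sem = camp_shift(s, s)
        assert shift == 0.0

    def test_worked_shift_arithmetic(self):
        """Means -96.7 and -81.0 mV give a +15.7 mV depolarizing shift."""
        a = mean_activation([fit_boltzmann(c) for c in make_activation_dataset(
            -96.7, 8, 500, noise_frac=0, n_cells=2, seed=0)])
        b = mean_activation([fit_boltzmann(c) for c in make_activation_dataset(
            -81.0, 8, 500, noise_frac=0, n_cells=2, seed=0)])
        shift, _ = camp_shift(a, b)
        assert shift == pytest.approx(15.7, abs=1e-4)

    def test_sem_adds_in_quadrature(self):
        from crankshaft.ephys import ActivationSummary
        a = ActivationSummary(5, -96.0, 1.0, 8.0, 0.2)
        b = ActivationSummary(5, -80.0, 1.0, 8.0, 0.2)
        shift, sem = camp_shift(a, b)
        assert sem == pytest.approx(np.sqrt(2.0))
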