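"""Synthetic-data generators: closed forms, noise model, determinism."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from vesiflux import (
    SimConfig,
    classify_phenotype,
    fold_accumulation,
    internal_concentration,
    simulate_coupled_uptake,
    simulate_displacement,
    simulate_gated_trace,
    simulate_iv,
    simulate_mm_rates,
    simulate_passive_uptake,
    summarize_time_course,
)
from vesiflux.synthetic import coupled_mean_concentration, passive_mean_concentration

V_BENCH = 7.49e-8  # L


def ode_oracle(t_grid, c_out, k_eq, leak):
    """Independent numerical integration of dC/dt = k_eq(c_out - C) - leak*C."""
    sol = solve_ivp(
        lambda t, c: k_eq * (c_out - c[0]) - leak * c[0],
        (0, t_grid[-1]), [0.0], t_eval=t_grid, rtol=1e-11, atol=1e-14,
    )
    return sol.y[0]


class TestPassiveModel:
    def test_closed_form_matches_ode(self):
        t = np.linspace(0.5, 120, 40)
        for k_eq, leak in [(0.2, 0.0), (0.1, 0.05), (0.5, 0.2)]:
            analytic = passive_mean_concentration(t, 0.5, k_eq, leak)
            numeric = ode_oracle(t, 0.5, k_eq, leak)
            assert np.allclose(analytic, numeric, rtol=1e-8)

    def test_no_leak_closed_form(self):
        t = np.array([1.0, 5.0, 30.0])
        c = passive_mean_concentration(t, 0.5, 0.2, 0.0)
        assert np.allclose(c, 0.5 * (1 - np.exp(-0.2 * t)), rtol=1e-12)

    def test_equilibrium_fold_is_one(self):
        c = passive_mean_concentration(np.array([1e6]), 0.5, 0.2, 0.0)[0]
        assert fold_accumulation(c, 0.5) == pytest.approx(1.0, abs=1e-9)

    def test_never_concentrative(self):
        """Without a coupling term the mean fold never exceeds 1 + 1e-6."""
        rng = np.random.default_rng(99)
        t = np.linspace(0, 500, 200)
        for _ in range(50):
            c_out = rng.uniform(0.01, 10)
            k_eq = rng.uniform(0.001, 5)
            leak = rng.uniform(0, 1)
            c = passive_mean_concentration(t, c_out, k_eq, leak)
            assert np.all(c / c_out <= 1 + 1e-6)

    def test_integrity_factor_creates_peak_without_concentration(self):
        cfg = SimConfig(seed=1, noise_cv=0.0)
        tc = simulate_passive_uptake(0.5, 0.3, V_BENCH, cfg,
                                     integrity_decay=0.02, integrity_floor=0.5)
        peak, plateau, *_ = summarize_time_course(tc)
        assert peak > plateau  # overshoot shape
        c_peak = internal_concentration(peak * 1e-9, V_BENCH)
        assert fold_accumulation(c_peak, 0.5) <= 1 + 1e-6


class TestCoupledModel:
    def test_reaches_fold_limit(self):
        c = coupled_mean_concentration(np.array([1e4]), 2.5e-3, 150.0, 0.2)[0]
        assert c == pytest.approx(150 * 2.5e-3, rel=1e-9)  # ~375 uM in mM

    def test_fold_limit_one_degenerates_to_passive(self):
        t = np.linspace(0, 100, 30)
        coupled = coupled_mean_concentration(t, 0.5, 1.0, 0.2)
        passive = passive_mean_concentration(t, 0.5, 0.2, 0.0)
        assert np.allclose(coupled, passive, rtol=1e-12)

    def test_seeded_reproducibility(self):
        cfg = SimConfig(seed=77)
        a = simulate_coupled_uptake(2.5e-3, 150, 0.2, V_BENCH, cfg)
        b = simulate_coupled_uptake(2.5e-3, 150, 0.2, V_BENCH, cfg)
        assert np.array_equal(a.amounts, b.amounts)
        assert np.array_equal(a.times, b.times)


class TestNoiseModel:
    def test_mm_rates_midpoint_exact_when_noise_free(self):
        table = simulate_mm_rates(8.0, 100.0, SimConfig(seed=0, noise_cv=0.0),
                                  grid=np.array([2.0, 8.0, 20.0, 50.0]))
        at_km = table.rate[np.isclose(table.substrate_conc, 8.0)]
        assert np.allclose(at_km, 50.0)

    def test_noise_cv_calibration(self):
        """Empirical per-point CV of heavily replicated rates ~= configured CV."""
        cfg = SimConfig(seed=123, noise_cv=0.05, n_replicates=4000)
        table = simulate_mm_rates(8.69, 100.4, cfg, grid=np.array([1.0, 10.0]))
        for conc in (1.0, 10.0):
            vals = table.rate[np.isclose(table.substrate_conc, conc)]
            cv = vals.std(ddof=1) / vals.mean()
            assert cv == pytest.approx(0.05, abs=3 * 0.05 / np.sqrt(len(vals)) + 0.003)

    def test_mean_converges_to_noise_free_curve(self):
        """Mean of 10^4 noisy realizations per point is within 3*CV/sqrt(n)."""
        n = 10_000
        cfg = SimConfig(seed=5, noise_cv=0.05, n_replicates=n)
        table = simulate_mm_rates(8.69, 100.4, cfg, grid=np.array([5.0]))
        truth = 100.4 * 5.0 / (8.69 + 5.0)
        tol = 3 * 0.05 / np.sqrt(n)
        assert abs(table.rate.mean() - truth) / truth < tol

    def test_displacement_background_channel(self):
        dr = simulate_displacement(3.5e-3, SimConfig(seed=9, noise_cv=0.0),
                                  top=1000.0, background=200.0)
        # at saturating ligand the residual specific signal sits on the background
        residual = 1000.0 / (1.0 + dr.ligand_conc[-1] / 3.5e-3)
        assert dr.signal[-1] == pytest.approx(200.0 + residual, rel=1e-9)
        assert np.allclose(dr.background, 200.0)
        assert np.allclose(dr.corrected_signal(), dr.signal - 200.0)


class TestGating:
    def test_gating_off_gives_exact_line(self):
        cfg = SimConfig(seed=2)
        iv = simulate_iv(92.0, cfg, open_prob=1.0, baseline_noise_pA=0.0)
        assert np.allclose(iv.current, 0.092 * iv.voltage, atol=1e-12)

    def test_multichannel_trace_has_n_plus_one_levels(self):
        cfg = SimConfig(seed=8)
        _, _, n_open = simulate_gated_trace(92.0, 100.0, cfg, open_prob=0.5,
                                            n_channels=3, n_samples=5000)
        assert set(np.unique(n_open)) == {0, 1, 2, 3}

    def test_stationary_open_probability(self):
        cfg = SimConfig(seed=4)
        _, _, n_open = simulate_gated_trace(92.0, 100.0, cfg, open_prob=0.8,
                                            n_channels=1, n_samples=20000)
        assert n_open.mean() == pytest.approx(0.8, abs=0.05)

    def test_reversal_potential_recovered(self):
        cfg = SimConfig(seed=6)
        iv = simulate_iv(92.0, cfg, v_rev=10.0, open_prob=1.0, baseline_noise_pA=0.0)
        from vesiflux import conductance_from_iv
        fit = conductance_from_iv(iv)
        assert fit.reversal_potential == pytest.approx(10.0, abs=1e-9)


class TestPipelineRecovery:
    def test_phenotype_calls_across_seeds(self):
        """Passive data classify channel-like, coupled (fold 150) concentrative."""
        for seed in range(10):
            cfg = SimConfig(seed=seed)
            passive = simulate_passive_uptake(0.5, 0.2, V_BENCH, cfg)
            peak, plat, *_ = summarize_time_course(passive)
            rep = classify_phenotype(
                internal_concentration(peak * 1e-9, V_BENCH),
                internal_concentration(plat * 1e-9, V_BENCH), 0.5)
            assert rep.call == "channel-like"

            coupled = simulate_coupled_uptake(2.5e-3, 150.0, 0.2, V_BENCH, cfg)
            peak, plat, *_ = summarize_time_course(coupled)
            rep = classify_phenotype(
                internal_concentration(peak * 1e-9, V_BENCH),
                internal_concentration(plat * 1e-9, V_BENCH), 2.5e-3)
            assert rep.call == "concentrative"
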