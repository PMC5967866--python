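"""Initial rates, Michaelis-Menten, turnover and displacement fitting."""

import numpy as np
import pytest

from vesiflux import (
    AssaySpec,
    DoseResponse,
    FitError,
    RateTable,
    SimConfig,
    UptakeTimeCourse,
    fit_displacement,
    fit_michaelis_menten,
    initial_rate,
    kcat_from_vmax,
    mw_from_sequence,
    simulate_displacement,
    simulate_mm_rates,
)

KM_TRUE = 8.69      # mM
VMAX_TRUE = 100.4   # umol/mg/min
GRID = np.geomspace(0.5, 50, 8)


class TestInitialRate:
    def assay(self, protein_ug=2.0):
        return AssaySpec(0.02, 100, 0.5, protein_mass=protein_ug)

    def test_exact_line(self):
        # slope 0.01 nmol/s over 2 ug protein -> 0.01/2*60 = 0.3 umol/mg/min
        tc = UptakeTimeCourse(times=[0, 1, 2, 3, 4, 5], amounts=np.arange(6) * 0.01)
        assert initial_rate(tc, self.assay()) == pytest.approx(0.3, rel=1e-12)

    def test_default_window_excludes_late_points(self):
        t = np.array([0, 1, 2, 3, 4, 5, 60.0])
        a = 0.01 * t.copy()
        a[-1] = 0.2  # saturated late point must not bias the slope
        tc = UptakeTimeCourse(times=t, amounts=a)
        assert initial_rate(tc, self.assay()) == pytest.approx(0.3, rel=1e-12)

    def test_saturating_curve_small_kt(self):
        """A(t) = A_inf(1 - e^-kt): early slope ~= A_inf*k for small kt."""
        a_inf, k = 1.0, 0.004  # kt <= 0.02 over the 5-s window
        t = np.array([0, 1, 2, 3, 4, 5.0])
        tc = UptakeTimeCourse(times=t, amounts=a_inf * (1 - np.exp(-k * t)))
        rate = initial_rate(tc, self.assay())
        expected = a_inf * k / 2.0 * 60.0
        assert rate == pytest.approx(expected, rel=0.02)

    def test_missing_protein_mass(self):
        tc = UptakeTimeCourse(times=[0, 1, 2], amounts=[0, 1, 2])
        with pytest.raises(FitError, match="protein_mass"):
            initial_rate(tc, AssaySpec(0.02, 100, 0.5))

    def test_too_few_points_in_window(self):
        tc = UptakeTimeCourse(times=[0, 30, 60], amounts=[0, 1, 2])
        with pytest.raises(FitError):
            initial_rate(tc, self.assay())


class TestMichaelisMenten:
    def test_noise_free_exact_recovery(self):
        v = VMAX_TRUE * GRID / (KM_TRUE + GRID)
        fit = fit_michaelis_menten(RateTable(GRID, v))
        assert fit.converged
        assert fit.km == pytest.approx(KM_TRUE, rel=1e-6)
        assert fit.vmax == pytest.approx(VMAX_TRUE, rel=1e-6)

    def test_half_maximal_at_km(self):
        v = VMAX_TRUE * GRID / (KM_TRUE + GRID)
        fit = fit_michaelis_menten(RateTable(GRID, v))
        assert fit.predict(fit.km) == pytest.approx(fit.vmax / 2, rel=1e-9)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        v = VMAX_TRUE * GRID / (KM_TRUE + GRID) * (1 + 0.03 * rng.standard_normal(len(GRID)))
        f1 = fit_michaelis_menten(RateTable(GRID, v))
        f2 = fit_michaelis_menten(RateTable(GRID, 3.0 * v))
        assert f2.vmax == pytest.approx(3.0 * f1.vmax, rel=1e-8)
        assert f2.km == pytest.approx(f1.km, rel=1e-8)

    def test_too_few_concentrations(self):
        with pytest.raises(FitError):
            fit_michaelis_menten(RateTable([1.0, 2.0, 4.0], [10.0, 20.0, 30.0]))

    def test_recovery_under_replicate_noise(self):
        """Median |Km error| < 10% across 25 seeded 5%-CV simulations."""
        errs = []
        for seed in range(25):
            table = simulate_mm_rates(KM_TRUE, VMAX_TRUE, SimConfig(seed=seed, noise_cv=0.05))
            fit = fit_michaelis_menten(table)
            errs.append(abs(fit.km - KM_TRUE) / KM_TRUE)
        assert np.median(errs) < 0.10

    def test_nls_optimum_confirmed_by_grid_search(self):
        """On 5 noisy datasets the NLS SSR beats a 100x100 parameter grid."""
        for seed in range(5):
            table = simulate_mm_rates(KM_TRUE, VMAX_TRUE, SimConfig(seed=100 + seed))
            fit = fit_michaelis_menten(table)
            kms = np.geomspace(KM_TRUE / 4, KM_TRUE * 4, 100)
            vmaxs = np.geomspace(VMAX_TRUE / 4, VMAX_TRUE * 4, 100)
            s, v = table.substrate_conc, table.rate
            pred = vmaxs[None, :, None] * s[None, None, :] / (kms[:, None, None] + s[None, None, :])
            ssr_grid = ((v[None, None, :] - pred) ** 2).sum(axis=2)
            assert fit.residual_ss <= ssr_grid.min() + 1e-9


class TestTurnoverAndMass:
    def test_unit_identity(self):
        assert kcat_from_vmax(1.0, 60000.0) == pytest.approx(1.0)

    def test_benchmark_turnover(self):
        # protomer mass back-computed from the published (vmax, kcat) pair
        assert kcat_from_vmax(100.4, 27729.0) == pytest.approx(46.4, rel=1e-4)

    def test_zero_vmax(self):
        assert kcat_from_vmax(0.0, 30000.0) == 0.0

    def test_round_trip(self):
        kcat = kcat_from_vmax(100.4, 27729.0)
        assert kcat * 60000.0 / 27729.0 == pytest.approx(100.4, rel=1e-12)

    @pytest.mark.parametrize("seq, mw", [("G", 75.07), ("GG", 132.12)])
    def test_mw_from_sequence(self, seq, mw):
        assert mw_from_sequence(seq) == pytest.approx(mw, abs=0.05)

    def test_mw_rejects_bad_input(self):
        with pytest.raises(FitError):
            mw_from_sequence("")
        with pytest.raises(FitError):
            mw_from_sequence("GXZ1")


class TestDisplacement:
    def test_midpoint_definition(self):
        dr = simulate_displacement(3.51e-3, SimConfig(seed=11, noise_cv=0.0))
        fit = fit_displacement(dr)
        mid = fit.predict(fit.ec50_or_ic50)
        assert mid == pytest.approx((fit.top + fit.bottom) / 2, rel=1e-9)

    def test_noise_free_exact_recovery(self):
        dr = simulate_displacement(3.51e-3, SimConfig(seed=0, noise_cv=0.0))
        fit = fit_displacement(dr)
        assert fit.ec50_or_ic50 == pytest.approx(3.51e-3, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("x50, mode", [(3.51e-3, "homologous_dilution"),
                                           (0.74e-3, "heterologous_inhibition")])
    def test_recovery_with_noise(self, x50, mode):
        """Seeded 3%-CV isotherms recover the midpoint within 15% (median of 20)."""
        errs = []
        for seed in range(20):
            dr = simulate_displacement(x50, SimConfig(seed=seed, noise_cv=0.03))
            fit = fit_displacement(dr, mode=mode)
            errs.append(abs(fit.ec50_or_ic50 - x50) / x50)
        assert np.median(errs) < 0.15

    def test_scale_invariance(self):
        dr = simulate_displacement(1e-3, SimConfig(seed=3, noise_cv=0.02))
        f1 = fit_displacement(dr)
        scaled = DoseResponse(dr.ligand_conc, 5.0 * dr.signal, 5.0 * dr.background)
        f2 = fit_displacement(scaled)
        assert f2.ec50_or_ic50 == pytest.approx(f1.ec50_or_ic50, rel=1e-6)

    def test_fixed_hill(self):
        dr = simulate_displacement(2e-3, SimConfig(seed=5, noise_cv=0.02), hill=1.0)
        fit = fit_displacement(dr, fix_hill=1.0)
        assert fit.hill == 1.0
        assert fit.hill_se == 0.0
        assert fit.ec50_or_ic50 == pytest.approx(2e-3, rel=0.15)

    def test_flat_curve_rejected(self):
        conc = np.geomspace(1e-5, 1e-1, 8)
        with pytest.raises(FitError, match="flat"):
            fit_displacement(DoseResponse(conc, np.full(8, 500.0), 500.0))
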