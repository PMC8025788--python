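import numpy as np
import pytest

import recakin as rk
from recakin.inference import (
    SITE_LENGTH_UM,
    ScanSpec,
    align_coverage_ensemble,
    chi2_objective,
    compute_BN,
    fit_nucleation_density,
)
from recakin.kinetics import RateParams
from recakin.simulate import DomainKinetics
from recakin.synth import make_coverage_traces
from recakin.wlc import CoverageCurve

L0 = 12.0


class TestBN:
    def test_constant_free_length_rectangle(self):
        t = np.arange(0.0, 1001.0, 1.0)
        curve = CoverageCurve.from_length(t, np.full_like(t, L0), L0)
        recs = compute_BN([curve], [[1000.0]], units="um")
        assert recs[0].B_N == pytest.approx(L0 * 1000.0, rel=1e-12)
        recs_sites = compute_BN([curve], [[1000.0]])
        assert recs_sites[0].B_N == pytest.approx(L0 / SITE_LENGTH_UM * 1000.0, rel=1e-12)

    def test_forced_trace_matches_exact_integral(self):
        """On a sampling grid containing the break times the trapezoidal
        B_1 equals the exact integral of the piecewise-linear free
        length."""
        d = DomainKinetics(t_nuc=200.0, x_nuc=0.4, v_fast=6e-4, v_slow=2e-4,
                          fast_side="left")
        pw = rk.propagate_exact([d])
        t = np.unique(np.concatenate([np.arange(0.0, 4000.0, 1.0), pw.knot_t]))
        curve = CoverageCurve.from_length(t, L0 * (1 + pw.phi_at(t) / 2), L0)
        t_N = 3000.0
        # exact: trapezoid over the (linear-in-between) knot set
        knots = np.unique(np.concatenate([pw.knot_t, [0.0, t_N]]))
        knots = knots[knots <= t_N]
        lf = (L0 - L0 * pw.phi_at(knots)) / SITE_LENGTH_UM
        exact = np.trapezoid(lf, knots)
        rec = compute_BN([curve], [[t_N]])[0]
        assert rec.B_N == pytest.approx(exact, rel=1e-8)

    def test_nucleation_before_protein_addition_rejected(self):
        t = np.arange(0.0, 100.0, 1.0)
        curve = CoverageCurve.from_length(t, np.full_like(t, L0), L0)
        with pytest.raises(ValueError):
            compute_BN([curve], [[-5.0]], t0=0.0)

    def test_exact_linear_data_recovers_density(self):
        n0 = 1.3e-7
        recs = [rk.BNRecord(0, N, N / n0) for N in (1, 2, 3)]
        fit = fit_nucleation_density(recs)
        assert fit.n_hat == pytest.approx(n0, rel=1e-10)
        assert fit_nucleation_density(recs, through_origin=True).n_hat == pytest.approx(n0)

    def test_paper_scale_conversion(self):
        """n = 13e-8 per site per second on an 11800-site molecule gives
        a per-molecule nucleation rate of 1.5e-3 per second."""
        kn = 13e-8 * 11800
        assert float(f"{kn:.2g}") == 1.5e-3

    def test_poisson_oracle_recovers_density(self):
        """Nucleation times drawn from the inhomogeneous Poisson process
        with density n on a decaying free length: the B_N regression
        recovers n within 3 SE (time-rescaling construction)."""
        rng = np.random.default_rng(2024)
        n_true = 1.0e-7  # per site per s
        t = np.arange(0.0, 60001.0, 2.0)
        lf_sites = (L0 / SITE_LENGTH_UM) * np.exp(-t / 20000.0)
        curve = CoverageCurve.from_length(
            t, 1.5 * L0 - 0.5 * lf_sites * SITE_LENGTH_UM, L0
        )
        cum = np.concatenate([[0.0], np.cumsum(np.diff(t) * 0.5 * (lf_sites[1:] + lf_sites[:-1]))])
        curves, times = [], []
        for _ in range(200):
            arr = np.cumsum(rng.exponential(1.0 / n_true, size=3))
            # the profile must absorb every arrival: truncating would
            # condition on fast nucleations and bias the estimate
            assert arr[-1] < cum[-1]
            times.append(list(np.interp(arr, cum, t)))
            curves.append(curve)
        recs = compute_BN(curves, times)
        fit = fit_nucleation_density(recs)
        assert abs(fit.n_hat - n_true) < 3 * fit.n_se

    def test_intercept_negligible_on_well_specified_data(self):
        rng = np.random.default_rng(7)
        n0 = 2e-7
        # B_N of a homogeneous Poisson process is Gamma(N, 1/n0)
        recs = [
            rk.BNRecord(e, N, rng.gamma(N, 1.0 / n0))
            for e in range(100)
            for N in (1, 2, 3)
        ]
        free = fit_nucleation_density(recs)
        origin = fit_nucleation_density(recs, through_origin=True)
        assert abs(free.n_hat - origin.n_hat) < free.n_se

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_nucleation_density([rk.BNRecord(0, 1, 1e7)])


class TestChi2:
    def test_identical_curves_zero(self):
        m = np.linspace(0, 1, 50)
        assert chi2_objective(m, np.full(50, 0.1), 5, m, np.full(50, 0.1), 100) == 0.0

    def test_one_sigma_offset_gives_T(self):
        T, n, M = 40, 5, 1000
        m = np.linspace(0, 1, T)
        se = np.sqrt(0.2**2 / n + 0.15**2 / M)
        c = chi2_objective(m + se, np.full(T, 0.2), n, m, np.full(T, 0.15), M)
        assert c == pytest.approx(T, rel=1e-12)

    def test_calibrated_at_generating_parameters(self):
        """With correct per-point dispersions the statistic follows a
        chi-square with one dof per grid point."""
        rng = np.random.default_rng(99)
        T, n = 500, 20
        m = 1 - np.exp(-np.linspace(0, 4, T))
        sd = np.full(T, 0.15)
        exp_mean = m + rng.normal(0.0, 0.15 / np.sqrt(n), size=T)
        c = chi2_objective(exp_mean, sd, n, m, np.zeros(T), 10**9)
        assert abs(c - T) < 3 * np.sqrt(2 * T)

    def test_zero_variance_floor_logged(self):
        m = np.linspace(0, 1, 10)
        with pytest.warns(RuntimeWarning):
            c = chi2_objective(m, np.zeros(10), 5, m, np.zeros(10), 10)
        assert c == 0.0


class TestGridScan:
    def test_single_point_scan_returns_it(self, paper_rates):
        curves, t_first = make_coverage_traces(paper_rates, 3, seed=5, t_max=15000.0)
        scan = ScanSpec(
            kn_grid=np.array([1e-3]),
            kg_fast_grid=np.array([5e-4]),
            r_grid=np.array([0.1]),
            M_schedule=(50, 50, 200),
        )
        res = rk.grid_scan_fit(curves, scan, seed=1, t_first=t_first)
        assert (res.kn_hat, res.kg_fast_hat, res.r_hat) == (1e-3, 5e-4, 0.1)
        assert np.isfinite(res.chi2_min)
        assert np.isnan(res.errors["r"])

    def test_symmetric_growth_recovered_at_grid_top(self):
        """An ensemble generated with symmetric fronts drives the fit to
        the top of the r grid, i.e. a vanishing asymmetry energy."""
        truth = RateParams(1e-3, 3e-4, 1.0)
        curves, t_first = make_coverage_traces(truth, 5, seed=42, t_max=20000.0)
        scan = ScanSpec(
            kn_grid=np.geomspace(5e-4, 2e-3, 3),
            kg_fast_grid=np.geomspace(1.5e-4, 6e-4, 3),
            r_grid=np.array([0.25, 0.5, 0.75, 1.0]),
            M_schedule=(400, 1500, 1500),
        )
        res = rk.grid_scan_fit(curves, scan, seed=2, t_first=t_first)
        assert res.r_hat >= 0.75
        assert res.dE_asym <= rk.energy_asym(0.75) + 1e-9

    def test_alignment_detection_matches_ground_truth(self, paper_rates):
        curves, t_first = make_coverage_traces(paper_rates, 4, seed=9, t_max=15000.0)
        auto = align_coverage_ensemble(curves, grid_dt=5.0)
        told = align_coverage_ensemble(curves, t_first=t_first, grid_dt=5.0)
        assert np.abs(auto.mean - told.mean[: auto.mean.size]).max() < 0.02

    def test_fit_result_derived_quantities_consistent(self):
        res = rk.FitResult(
            kn_hat=1.05e-3, kg_fast_hat=5.27e-4, r_hat=0.10,
            errors={"r": 0.05}, chi2_min=0.0, n_points=10,
            M_schedule=(1, 1, 1), on_boundary=False, n_evaluations=1,
            n_sites=10700,
        )
        assert res.kg_hat == pytest.approx(5.27e-4 * 1.10)
        assert res.n_hat * 10700 == pytest.approx(res.kn_hat)
        assert res.v_hat == pytest.approx(res.kg_hat * 10700)
        assert res.fast_slow_ratio == pytest.approx(10.0)
        assert res.dE_asym == pytest.approx(rk.energy_asym(0.10))
        assert round(res.dE_coop, 1) == 17.9
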