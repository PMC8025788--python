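import numpy as np
import pytest

import recakin as rk
from recakin.decompose import (
    block_average,
    classify_breaks,
    dedupe_mirror,
    domain_count,
    enumerate_scenarios,
    fit_piecewise_linear,
    seed_breaks,
    solve_scenario,
)
from recakin.simulate import DomainKinetics
from recakin.wlc import CoverageCurve

L0 = 12.0


def _curve_from(pw, t):
    return CoverageCurve.from_length(t, L0 * (1.0 + pw.phi_at(t) / 2.0), L0)


class TestBreakFitting:
    def test_noiseless_bilinear_break_recovered(self):
        t = np.arange(0.0, 300.0, 1.0)
        y = np.where(t < 100.0, 0.01 * t, 1.0 + 0.002 * (t - 100.0))
        fit = fit_piecewise_linear(t, y, [80.0])
        assert fit.converged
        assert fit.t_breaks[0] == pytest.approx(100.0, abs=1.0)
        assert fit.slopes[0] == pytest.approx(0.01, rel=1e-3)
        assert fit.slopes[1] == pytest.approx(0.002, rel=1e-3)

    def test_pure_line_flagged_degenerate(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 400.0, 1.0)
        y = 0.005 * t + rng.normal(0, 0.01, t.size)
        fit = fit_piecewise_linear(t, y, [200.0])
        assert fit.slopes[0] == pytest.approx(fit.slopes[1], abs=5e-4)
        assert fit.degenerate[0]

    def test_greedy_seeding_plus_refinement_recovers_breaks(self):
        d = DomainKinetics(t_nuc=300.0, x_nuc=0.35, v_fast=6e-4, v_slow=1.5e-4,
                          fast_side="left")
        pw = rk.propagate_exact([d])
        t = np.arange(0.0, pw.knot_t[-1] + 800.0, 10.0)
        y = L0 * (1.0 + pw.phi_at(t) / 2.0)
        fit = fit_piecewise_linear(t, y, seed_breaks(t, y, 3))
        assert np.abs(fit.t_breaks - pw.t_breaks).max() < 1.0

    def test_block_average(self):
        t = np.arange(10.0)
        tb, yb = block_average(t, 2 * t, 5)
        assert tb.size == 2 and yb[0] == pytest.approx(2 * tb[0])


class TestScenarioEnumeration:
    def test_complete_trace_domain_count(self):
        assert domain_count(5) == 2
        assert domain_count(3) == 1
        with pytest.raises(ValueError):
            domain_count(4)

    def test_single_domain_two_scenarios_mirror_collapse(self):
        scens = enumerate_scenarios(["+", "-", "-"])
        assert len(scens) == 2  # which front stopped first
        assert len(dedupe_mirror(scens)) == 1

    def test_two_domain_pattern(self):
        """The five-break pattern (nucleation, collision, nucleation,
        collision, collision) admits four scenarios, including both the
        internal-collision and end-collision interpretation of the
        fourth break."""
        scens = enumerate_scenarios(["+", "-", "+", "-", "-"])
        assert len(scens) == 4
        kinds4 = {s.events[3].kind for s in scens}
        assert kinds4 == {"domain-domain", "domain-end"}

    def test_no_breaks_no_scenarios(self):
        assert enumerate_scenarios([]) == []

    def test_inconsistent_pattern_empty(self):
        assert enumerate_scenarios(["-", "+", "-"]) == []
        assert enumerate_scenarios(["+", "-"]) == []


class TestScenarioSolving:
    def test_round_trip_and_unphysical_rejection(self, two_domain_truth, two_domain_curve):
        curve, pw = two_domain_curve
        init = pw.t_breaks + np.array([30.0, -40.0, 25.0, -35.0, 20.0])
        res = rk.decompose_curve(curve, init)
        # the unphysical alternatives are rejected through negative velocities
        assert len(res.solutions) == 2  # truth and its mirror image
        assert all("negative front velocity" in s.reason for s in res.infeasible)
        assert len(res.infeasible) == 2
        # one feasible solution matches the generating kinetics exactly
        best_err = np.inf
        for sol in res.solutions:
            for flip in (False, True):
                err = 0.0
                for k_true, k_fit in zip(two_domain_truth, sol.kinetics):
                    x_fit = 1.0 - k_fit.x_nuc if flip else k_fit.x_nuc
                    err = max(
                        err,
                        abs(k_fit.v_fast - k_true.v_fast) / k_true.v_fast,
                        abs(k_fit.v_slow - k_true.v_slow) / k_true.v_slow,
                        abs(x_fit - k_true.x_nuc),
                    )
                best_err = min(best_err, err)
        assert best_err < 1e-6

    def test_active_velocity_sum_rule(self, two_domain_curve):
        """Twice each segment slope (in naked-length units) equals the sum
        of the solved front velocities active in that segment."""
        curve, pw = two_domain_curve
        init = pw.t_breaks + np.array([30.0, -40.0, 25.0, -35.0, 20.0])
        res = rk.decompose_curve(curve, init)
        sol = res.best
        fit = res.fit
        nuc = sol.scenario.nucleation_break()
        stop = sol.scenario.stop_break()
        for j, slope in enumerate(fit.interior_slopes):
            total = 0.0
            for d in range(len(sol.kinetics)):
                if nuc[d] <= j:
                    if stop.get((d, "left"), fit.Q) > j:
                        total += sol.v_left[d]
                    if stop.get((d, "right"), fit.Q) > j:
                        total += sol.v_right[d]
            assert total == pytest.approx(2.0 * slope / L0, rel=1e-4, abs=1e-9)

    def test_single_domain_round_trip(self):
        d = DomainKinetics(t_nuc=300.0, x_nuc=0.35, v_fast=6e-4, v_slow=1.5e-4,
                          fast_side="left")
        pw = rk.propagate_exact([d])
        t = np.arange(0.0, pw.knot_t[-1] + 800.0, 1.0)
        curve = _curve_from(pw, t)
        init = pw.t_breaks + np.array([25.0, -30.0, 20.0])
        res = rk.decompose_curve(curve, init)
        assert res.fit.n_domains == 1
        vf = [s.kinetics[0].v_fast for s in res.solutions]
        assert any(abs(v - 6e-4) / 6e-4 < 1e-6 for v in vf)

    def test_underdetermined_scenario_flagged(self, two_domain_curve):
        curve, pw = two_domain_curve
        fit = fit_piecewise_linear(curve.t, curve.L, pw.t_breaks)
        scen = enumerate_scenarios(["+", "-", "+", "-", "-"])[0]
        # remove one closure equation's information by collapsing two breaks
        fit.t_breaks[1] = fit.t_breaks[0]
        sol = solve_scenario(scen, fit, L0)
        assert isinstance(sol.feasible, bool)  # solved or cleanly flagged


class TestReconstruction:
    def test_round_trip_length(self, two_domain_truth, two_domain_curve):
        curve, _ = two_domain_curve
        rec = rk.reconstruct_length(two_domain_truth, curve.t, L0)
        assert np.abs(rec.L - curve.L).max() < 1e-8

    def test_empty_kinetics_constant_length(self):
        t = np.arange(0.0, 100.0, 1.0)
        rec = rk.reconstruct_length([], t, L0)
        assert np.all(rec.L == L0)

    def test_saturating_kinetics_reach_expected_length(self):
        d = DomainKinetics(t_nuc=0.0, x_nuc=0.5, v_fast=1e-3, v_slow=1e-3,
                          fast_side="left")
        t = np.arange(0.0, 2000.0, 1.0)
        rec = rk.reconstruct_length([d], t, L0)
        assert rec.L[-1] == pytest.approx(1.5 * L0, abs=1e-9)

    def test_virtual_saturation_break_completes_truncated_trace(self):
        """A trace ending before full coverage is completed by a break at
        the extrapolated saturation time, after which the single-domain
        kinetics solve exactly."""
        d = DomainKinetics(t_nuc=300.0, x_nuc=0.35, v_fast=6e-4, v_slow=1.5e-4,
                          fast_side="left")
        pw = rk.propagate_exact([d])
        t_cut = 0.6 * pw.knot_t[-1]  # stop well before the slow front arrives
        t = np.arange(0.0, t_cut, 1.0)
        curve = _curve_from(pw, t)
        init = pw.t_breaks[:2] + np.array([25.0, -30.0])
        res = rk.decompose_curve(curve, init, extrapolate_saturation=True)
        assert res.fit.Q == 3
        assert res.fit.t_breaks[-1] == pytest.approx(pw.t_breaks[-1], rel=1e-6)
        vf = [s.kinetics[0].v_fast for s in res.solutions]
        assert any(abs(v - 6e-4) / 6e-4 < 1e-6 for v in vf)

    def test_truth_always_feasible_on_noiseless_data(self, two_domain_curve):
        curve, pw = two_domain_curve
        res = rk.decompose_curve(curve, pw.t_breaks)
        assert res.solutions  # velocity filter never rejects the truth
        assert res.fit.n_domains == domain_count(res.fit.Q)
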