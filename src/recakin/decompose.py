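"""Decompose a measured L(t) into individual-domain front kinetics.

A stepwise contour-length trace carries the history of the assembly: an
increase in the slope of L(t) marks a nucleation (two new fronts start
moving), a decrease marks a collision (a front stops at a neighbouring
domain or at a molecule end).  For a complete trace with Q break points
the number of domains is N_t = (Q - 1)/2.  Because the trace records
only the *total* length, several collision scenarios can be consistent
with one break pattern; each scenario yields a linear system relating
the segment slopes and break times to the per-domain nucleation
positions and front velocities, and scenarios whose solution contains a
negative velocity (which would mean disassembly, negligible with the
non-hydrolysable ATP analogue) are rejected as unphysical.

Pipeline: :func:`fit_piecewise_linear` (break refinement) ->
:func:`enumerate_scenarios` (combinatorial event assignment) ->
:func:`solve_scenario` (linear solve + feasibility filter) ->
:func:`reconstruct_length` (forward replay for residual ranking).

Internally the solver works in fractions of the naked contour length;
``L(t)`` slopes are converted with d(phi)/dt = 2 (dL/dt)/L(0), i.e. each
L(t) slope equals half the sum of the active front velocities (covering
dx of naked contour adds dx/2 to the total length, a direct consequence
of the 1.5x extension).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import f as f_dist

from .simulate import DomainKinetics, propagate_exact
from .wlc import CoverageCurve

__all__ = [
    "BreakPointFit",
    "Scenario",
    "ScenarioEvent",
    "SolvedScenario",
    "DecompositionResult",
    "domain_count",
    "block_average",
    "seed_breaks",
    "append_saturation_break",
    "fit_piecewise_linear",
    "classify_breaks",
    "enumerate_scenarios",
    "dedupe_mirror",
    "solve_scenario",
    "reconstruct_length",
    "decompose_curve",
]

END_L = ("end", "left")
END_R = ("end", "right")


def domain_count(Q: int) -> int:
    """Total number of domains N_t = (Q - 1)/2 of a complete trace."""
    if Q < 1 or Q % 2 == 0:
        raise ValueError("a complete trace has an odd number of break points")
    return (Q - 1) // 2


def block_average(t: np.ndarray, y: np.ndarray, window: int):
    """Block-average consecutive samples (noise reduction before fitting).

    Each block of ``window`` samples is replaced by its mean, displayed at
    the mid-point of the block's time interval.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = (len(t) // window) * window
    tb = np.asarray(t, float)[:n].reshape(-1, window).mean(axis=1)
    yb = np.asarray(y, float)[:n].reshape(-1, window).mean(axis=1)
    return tb, yb


@dataclass
class BreakPointFit:
    """Continuous piecewise-linear fit of L(t).

    ``t_breaks`` are the Q refined break times; ``slopes`` has Q + 1
    entries covering the flat lead-in, the Q - 1 inter-break segments
    and the tail.  ``degenerate`` flags breaks whose slope change is not
    statistically significant (two-segment vs one-segment F-test).
    """

    t_breaks: np.ndarray
    slopes: np.ndarray
    coef: np.ndarray
    residual: float
    converged: bool
    t: np.ndarray
    y: np.ndarray
    degenerate: np.ndarray | None = None

    @property
    def Q(self) -> int:
        return len(self.t_breaks)

    @property
    def n_domains(self) -> int:
        return domain_count(self.Q)

    @property
    def interior_slopes(self) -> np.ndarray:
        """Slopes v_j of the Q - 1 segments between consecutive breaks."""
        return self.slopes[1:-1]

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = self.coef[0] + self.coef[1] * t
        for b, c in zip(self.t_breaks, self.coef[2:]):
            out = out + c * np.clip(t - b, 0.0, None)
        return out


def _two_segment_sse(tw, yw, b):
    X = np.column_stack([np.ones_like(tw), tw - b, np.clip(tw - b, 0.0, None)])
    coef, res, *_ = np.linalg.lstsq(X, yw, rcond=None)
    sse = float(res[0]) if res.size else float(np.sum((yw - X @ coef) ** 2))
    return sse


def _global_refit(t, y, breaks):
    X = np.column_stack(
        [np.ones_like(t), t] + [np.clip(t - b, 0.0, None) for b in breaks]
    )
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = float(np.sum((y - X @ coef) ** 2))
    slopes = coef[1] + np.concatenate([[0.0], np.cumsum(coef[2:])])
    return coef, slopes, resid


def fit_piecewise_linear(
    t,
    y,
    init_breaks,
    max_iter: int = 20,
    min_sep: int = 3,
    alpha: float = 0.01,
) -> BreakPointFit:
    """Iteratively refine break times of a continuous piecewise-linear fit.

    Starting from break-time guesses (typically read off the trace by
    eye or from :func:`seed_breaks`), each break is refit by scanning a
    local bilinear least-squares fit over the window between its
    neighbouring breaks; the sweep repeats until no break moves by more
    than one sample interval (or ``max_iter``).  Convergence typically
    takes a handful of iterations.  A non-convergent fit is returned
    with ``converged=False``.

    ``alpha`` is the significance level of the per-break F-test used to
    flag degenerate breaks (no real slope change).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    breaks = np.sort(np.asarray(init_breaks, dtype=float))
    if breaks.size < 1:
        raise ValueError("need at least one initial break (>= 2 segments)")
    dt_samp = float(np.median(np.diff(t)))

    converged = False
    for _ in range(max_iter):
        moved = 0.0
        for j in range(len(breaks)):
            lo = breaks[j - 1] if j > 0 else t[0] - dt_samp
            hi = breaks[j + 1] if j < len(breaks) - 1 else t[-1] + dt_samp
            m = (t > lo) & (t < hi)
            tw, yw = t[m], y[m]
            if tw.size < 2 * min_sep + 2:
                continue
            cands = tw[min_sep:-min_sep]
            sses = [_two_segment_sse(tw, yw, b) for b in cands]
            ib = int(np.argmin(sses))
            # continuous sub-sample refinement around the best candidate
            lo_b = cands[max(ib - 1, 0)]
            hi_b = cands[min(ib + 1, len(cands) - 1)]
            if hi_b > lo_b:
                opt = minimize_scalar(
                    lambda b: _two_segment_sse(tw, yw, b),
                    bounds=(lo_b, hi_b),
                    method="bounded",
                    options={"xatol": dt_samp * 1e-9},
                )
                best = float(opt.x)
            else:
                best = float(cands[ib])
            moved = max(moved, abs(best - breaks[j]))
            breaks[j] = best
        breaks = np.sort(breaks)
        if moved < dt_samp:
            converged = True
            break

    coef, slopes, resid = _global_refit(t, y, breaks)

    # per-break significance: does a knot improve on a single line locally?
    degenerate = np.zeros(len(breaks), dtype=bool)
    for j in range(len(breaks)):
        lo = breaks[j - 1] if j > 0 else t[0] - dt_samp
        hi = breaks[j + 1] if j < len(breaks) - 1 else t[-1] + dt_samp
        m = (t > lo) & (t < hi)
        tw, yw = t[m], y[m]
        if tw.size < 5:
            continue
        X1 = np.column_stack([np.ones_like(tw), tw])
        c1, _, _, _ = np.linalg.lstsq(X1, yw, rcond=None)
        sse1 = float(np.sum((yw - X1 @ c1) ** 2))
        sse2 = _two_segment_sse(tw, yw, breaks[j])
        dof = tw.size - 4
        if dof <= 0 or sse2 <= 0:
            continue
        F = (sse1 - sse2) / 2.0 / (sse2 / dof)
        degenerate[j] = f_dist.sf(F, 2, dof) > alpha

    return BreakPointFit(
        t_breaks=breaks,
        slopes=slopes,
        coef=coef,
        residual=resid,
        converged=converged,
        t=t,
        y=y,
        degenerate=degenerate,
    )


def seed_breaks(t, y, n_breaks: int, min_sep: int = 5) -> np.ndarray:
    """Greedy binary-segmentation seeding of initial break times.

    Repeatedly adds the knot that most reduces the global continuous
    piecewise-linear SSE.  A convenience replacement for reading break
    times off the trace by eye; reliable when segment durations are
    comparable, but traces mixing very short and very long segments may
    need inspection-based initial values (the primary workflow), after
    which :func:`fit_piecewise_linear` refines them.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    breaks: list[float] = []
    cands = t[min_sep:-min_sep]
    for _ in range(n_breaks):
        best_b, best_sse = None, np.inf
        for b in cands:
            if any(abs(b - e) < min_sep * np.median(np.diff(t)) for e in breaks):
                continue
            _, _, sse = _global_refit(t, y, np.sort(breaks + [b]))
            if sse < best_sse:
                best_b, best_sse = b, sse
        if best_b is None:
            break
        breaks.append(best_b)
    return np.sort(breaks)


def append_saturation_break(fit: BreakPointFit, L_saturation: float) -> BreakPointFit:
    """Append a virtual terminal break at the extrapolated saturation time.

    Some traces end before full coverage; if the final fitted segment is
    still growing, the last collision (the surviving front reaching its
    end) can be placed where the extrapolated L(t) meets the saturation
    length 1.5 L(0), completing the break pattern for scenario analysis.
    The data themselves are left untouched.
    """
    s_end = float(fit.slopes[-1])
    if s_end <= 0:
        raise ValueError("final segment not growing; nothing to extrapolate")
    y_end = float(fit.predict(fit.t[-1]))
    if y_end >= L_saturation:
        raise ValueError("trace already reaches saturation")
    t_star = float(fit.t[-1]) + (L_saturation - y_end) / s_end
    return BreakPointFit(
        t_breaks=np.append(fit.t_breaks, t_star),
        slopes=np.append(fit.slopes, 0.0),
        coef=np.append(fit.coef, -s_end),
        residual=fit.residual,
        converged=fit.converged,
        t=fit.t,
        y=fit.y,
        degenerate=np.append(fit.degenerate, False)
        if fit.degenerate is not None
        else None,
    )


def classify_breaks(fit: BreakPointFit) -> list[str]:
    """'+' (nucleation) or '-' (collision) for each break, by slope change."""
    d = np.diff(fit.slopes)
    return ["+" if dv > 0 else "-" for dv in d]


@dataclass(frozen=True)
class ScenarioEvent:
    """One break-point assignment within a scenario.

    ``kind`` is 'nucleation', 'domain-domain' or 'domain-end'.  ``gap``
    is the free interval involved, given by its two boundaries; a
    boundary is ('end', side) or (domain_id, side).  For a nucleation,
    ``domain`` is the id of the domain created inside ``gap``.
    """

    kind: str
    gap: tuple
    domain: int | None = None


@dataclass(frozen=True)
class Scenario:
    """A complete assignment of break points to physical events."""

    events: tuple

    @property
    def n_domains(self) -> int:
        return sum(1 for e in self.events if e.kind == "nucleation")

    def nucleation_break(self) -> dict:
        """domain id -> break index of its nucleation."""
        return {
            e.domain: k for k, e in enumerate(self.events) if e.kind == "nucleation"
        }

    def stop_break(self) -> dict:
        """(domain id, side) -> break index where that front stopped."""
        out = {}
        for k, e in enumerate(self.events):
            if e.kind == "nucleation":
                continue
            for b in e.gap:
                if b[0] != "end":
                    out[b] = k
        return out


def enumerate_scenarios(signs, max_scenarios: int = 10000) -> list[Scenario]:
    """Enumerate all event assignments consistent with a break pattern.

    ``signs`` is a BreakPointFit or a sequence of '+'/'-' labels.  The
    free substrate is tracked as a set of gaps: a nucleation splits the
    gap it lands in, a collision closes a gap (domain-domain if both
    boundaries are fronts, domain-end otherwise).  A scenario is complete
    when every gap has closed, which for N nucleations requires N + 1
    collisions (Q = 2N + 1 break points).  An inconsistent pattern
    yields an empty list.
    """
    if isinstance(signs, BreakPointFit):
        signs = classify_breaks(signs)
    signs = list(signs)
    results: list[Scenario] = []

    def rec(k: int, gaps: tuple, events: tuple, next_dom: int) -> None:
        if len(results) >= max_scenarios:
            return
        if k == len(signs):
            if not gaps:
                results.append(Scenario(events))
            return
        # each remaining '-' closes one gap, each '+' opens one
        remaining = signs[k:]
        if len(gaps) + remaining.count("+") != remaining.count("-"):
            return
        if signs[k] == "+":
            for gi, g in enumerate(gaps):
                d = next_dom
                new = (
                    gaps[:gi]
                    + ((g[0], (d, "left")), ((d, "right"), g[1]))
                    + gaps[gi + 1 :]
                )
                rec(k + 1, new, events + (ScenarioEvent("nucleation", g, d),), d + 1)
        else:
            for gi, g in enumerate(gaps):
                bl, br = g
                if bl[0] == "end" and br[0] == "end":
                    continue  # a bare molecule cannot produce a collision
                kind = (
                    "domain-domain"
                    if bl[0] != "end" and br[0] != "end"
                    else "domain-end"
                )
                rec(
                    k + 1,
                    gaps[:gi] + gaps[gi + 1 :],
                    events + (ScenarioEvent(kind, g),),
                    next_dom,
                )

    rec(0, ((END_L, END_R),), (), 0)
    return results


def _mirror_boundary(b):
    return ("end", "right" if b[1] == "left" else "left") if b[0] == "end" else (
        b[0],
        "right" if b[1] == "left" else "left",
    )


def dedupe_mirror(scenarios: list[Scenario]) -> list[Scenario]:
    """Collapse scenarios equivalent under the left/right mirror symmetry.

    The experiment cannot orient the molecule, so a scenario and its
    mirror image describe the same physics; the first representative of
    each pair is kept.
    """
    seen = set()
    out = []
    skey = lambda b: (str(b[0]), b[1])
    for s in scenarios:
        key = tuple(
            (e.kind, tuple(sorted((e.gap[0], e.gap[1]), key=skey))) for e in s.events
        )
        mkey = tuple(
            (
                e.kind,
                tuple(
                    sorted(
                        (_mirror_boundary(e.gap[1]), _mirror_boundary(e.gap[0])),
                        key=skey,
                    )
                ),
            )
            for e in s.events
        )
        if key in seen or mkey in seen:
            continue
        seen.add(key)
        out.append(s)
    return out


@dataclass
class SolvedScenario:
    """Linear-system solution of one scenario (possibly infeasible)."""

    scenario: Scenario
    feasible: bool
    reason: str
    x: np.ndarray
    v_left: np.ndarray
    v_right: np.ndarray
    kinetics: list = field(default_factory=list)
    lstsq_residual: float = np.nan
    reconstruction_sse: float = np.nan


def solve_scenario(
    scenario: Scenario,
    fit: BreakPointFit,
    L_initial: float,
    velocity_tol: float = 1e-9,
) -> SolvedScenario:
    """Solve one scenario for nucleation positions and front velocities.

    Builds the linear system in (x_i, v_i^L, v_i^R): one equation per
    inter-break segment (sum of active front velocities = 2 * slope in
    naked-length units) and one position-closure equation per collision
    (the stopped front's travel distance equals the gap it crossed).
    The system is solved by least squares; with exact break data it is
    consistent and exact.  Solutions with a negative velocity, an
    out-of-range nucleation position, or a nucleation outside its open
    gap are marked infeasible; a rank-deficient system is flagged
    ambiguous and not solved.
    """
    Q = fit.Q
    if len(scenario.events) != Q:
        raise ValueError("scenario and fit have different break counts")
    N = scenario.n_domains
    tb = fit.t_breaks
    s_phi = 2.0 * fit.interior_slopes / L_initial  # fraction/s per segment

    nuc_break = scenario.nucleation_break()
    stop = scenario.stop_break()
    t_nuc = {d: tb[k] for d, k in nuc_break.items()}

    def col(d, what):  # unknown ordering: x_d, vL_d, vR_d
        return 3 * d + {"x": 0, "vl": 1, "vr": 2}[what]

    rows, rhs = [], []
    # segment slope equations
    for j in range(Q - 1):
        row = np.zeros(3 * N)
        for d in range(N):
            if nuc_break[d] > j:
                continue
            if stop.get((d, "left"), Q) > j:
                row[col(d, "vl")] = 1.0
            if stop.get((d, "right"), Q) > j:
                row[col(d, "vr")] = 1.0
        rows.append(row)
        rhs.append(s_phi[j])
    # position-closure equations
    for k, e in enumerate(scenario.events):
        if e.kind == "nucleation":
            continue
        bl, br = e.gap
        row = np.zeros(3 * N)
        if bl == END_L:  # front (d, left) reached the left end
            d = br[0]
            row[col(d, "x")] = 1.0
            row[col(d, "vl")] = -(tb[k] - t_nuc[d])
            rows.append(row)
            rhs.append(0.0)
        elif br == END_R:
            d = bl[0]
            row[col(d, "x")] = 1.0
            row[col(d, "vr")] = tb[k] - t_nuc[d]
            rows.append(row)
            rhs.append(1.0)
        else:  # facing fronts of domains a (right) and b (left) met
            a, b = bl[0], br[0]
            row[col(a, "x")] = 1.0
            row[col(a, "vr")] = tb[k] - t_nuc[a]
            row[col(b, "x")] = -1.0
            row[col(b, "vl")] = tb[k] - t_nuc[b]
            rows.append(row)
            rhs.append(0.0)

    A = np.array(rows)
    b = np.array(rhs)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    resid = float(np.sum((A @ sol - b) ** 2))

    x = sol[0::3]
    vl = sol[1::3]
    vr = sol[2::3]

    if rank < 3 * N:
        return SolvedScenario(
            scenario, False, "underdetermined (ambiguous scenario)", x, vl, vr
        )
    if np.any(vl < -velocity_tol) or np.any(vr < -velocity_tol):
        return SolvedScenario(
            scenario,
            False,
            "negative front velocity (would require disassembly)",
            x,
            vl,
            vr,
            lstsq_residual=resid,
        )
    if np.any(x < -1e-6) or np.any(x > 1.0 + 1e-6):
        return SolvedScenario(
            scenario, False, "nucleation position outside molecule", x, vl, vr,
            lstsq_residual=resid,
        )
    # nucleation must land inside its gap as open at that time
    for k, e in enumerate(scenario.events):
        if e.kind != "nucleation":
            continue
        d = e.domain
        bl, br = e.gap
        lo = 0.0 if bl == END_L else x[bl[0]] + max(vr[bl[0]], 0.0) * (
            tb[k] - t_nuc[bl[0]]
        )
        hi = 1.0 if br == END_R else x[br[0]] - max(vl[br[0]], 0.0) * (
            tb[k] - t_nuc[br[0]]
        )
        if not (lo - 1e-6 <= x[d] <= hi + 1e-6):
            return SolvedScenario(
                scenario, False, "nucleation outside its open gap", x, vl, vr,
                lstsq_residual=resid,
            )

    kin = []
    for d in range(N):
        a, c = max(vl[d], 0.0), max(vr[d], 0.0)
        kin.append(
            DomainKinetics(
                t_nuc=float(t_nuc[d]),
                x_nuc=float(np.clip(x[d], 0.0, 1.0)),
                v_fast=float(max(a, c)),
                v_slow=float(min(a, c)),
                fast_side="left" if a >= c else "right",
            )
        )
    return SolvedScenario(
        scenario, True, "", x, vl, vr, kinetics=kin, lstsq_residual=resid
    )


def reconstruct_length(kinetics, t_eval, L_initial: float) -> CoverageCurve:
    """Forward L(t) replay of solved domain kinetics.

    Propagates the domains deterministically (exact event-driven fronts)
    and maps coverage back to total contour length L = L0 (1 + phi/2).
    Used to score competing feasible scenarios by reconstruction
    residual.  An empty kinetics list yields the constant L(0).
    """
    t_eval = np.asarray(t_eval, dtype=float)
    kin = sorted(kinetics, key=lambda k: k.t_nuc)
    if not kin:
        return CoverageCurve.from_length(t_eval, np.full_like(t_eval, L_initial), L_initial)
    pw = propagate_exact(kin, t_end=float(t_eval[-1]))
    L = L_initial * (1.0 + pw.phi_at(t_eval) / 2.0)
    return CoverageCurve.from_length(t_eval, L, L_initial)


@dataclass
class DecompositionResult:
    """Full decomposition of one trace: fit, scenarios, ranked solutions."""

    fit: BreakPointFit
    scenarios: list
    solutions: list  # feasible SolvedScenario, ranked by reconstruction SSE
    infeasible: list

    @property
    def best(self) -> SolvedScenario | None:
        return self.solutions[0] if self.solutions else None


def decompose_curve(
    curve: CoverageCurve,
    init_breaks,
    velocity_tol: float = 1e-9,
    extrapolate_saturation: bool = False,
    **fit_kwargs,
) -> DecompositionResult:
    """End-to-end decomposition of a coverage curve.

    Fits the piecewise-linear model to L(t), classifies the breaks,
    enumerates every consistent collision scenario, solves each, and
    ranks the feasible ones by the residual of their forward-replayed
    L(t) against the data.  The ranking is a heuristic: the measurement
    alone often cannot single out one scenario.  With
    ``extrapolate_saturation`` a trace that ends before full coverage is
    completed by a virtual terminal break at the extrapolated
    saturation time (see :func:`append_saturation_break`).
    """
    fit = fit_piecewise_linear(curve.t, curve.L, init_breaks, **fit_kwargs)
    if extrapolate_saturation:
        fit = append_saturation_break(fit, 1.5 * curve.L_initial)
    scenarios = enumerate_scenarios(fit)
    feasible, infeasible = [], []
    for sc in scenarios:
        sol = solve_scenario(sc, fit, curve.L_initial, velocity_tol=velocity_tol)
        if not sol.feasible:
            infeasible.append(sol)
            continue
        rec = reconstruct_length(sol.kinetics, curve.t, curve.L_initial)
        sol.reconstruction_sse = float(np.sum((rec.L - curve.L) ** 2))
        feasible.append(sol)
    feasible.sort(key=lambda s: s.reconstruction_sse)
    return DecompositionResult(fit, scenarios, feasible, infeasible)
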