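"""Stochastic few-nuclei nucleation-and-growth simulator.

The intermediate regime kg/kn ~ 1 produces only a handful of RecA
domains per dsDNA molecule, so neither the many-nuclei sigmoid nor the
single-nucleus closed form applies and the coverage kinetics must be
simulated.  The model: at every time step a nucleation event occurs with
probability kn*(1-phi)*dt at a uniform point of the undecorated part of
the substrate; each domain then grows by kg_fast*dt at its fast front
and r*kg_fast*dt at its slow front, the fast side being chosen by a fair
coin at nucleation.  Fronts stop at the molecule ends and merging
domains keep their outer fronts.  Positions are fractions of the naked
contour length.

Two engines are provided:

* :func:`simulate_once` / :func:`simulate_ensemble` - the stochastic
  stepper (compiled hot loop for ensembles), with full event logs and
  per-domain ground truth from the Python path;
* :func:`propagate_exact` / :func:`forced_scenario` - deterministic,
  event-driven propagation of a given nucleation list, exact to floating
  point; used as ground truth for synthetic data and as the oracle for
  trace decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _engine
from .kinetics import RateParams

__all__ = [
    "SimConfig",
    "SimResult",
    "SimRun",
    "DomainKinetics",
    "Event",
    "PiecewiseCoverage",
    "simulate_once",
    "simulate_ensemble",
    "propagate_exact",
    "forced_scenario",
]

TIME_ORIGINS = ("protein_addition", "first_nucleation")


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    ``time_origin='first_nucleation'`` places the first nucleus at t = 0
    (the convention for slow-nucleation comparisons, where trajectories
    are aligned at the first nucleation event); ``'protein_addition'``
    starts with a bare molecule and a stochastic waiting time.

    ``boundary`` selects the substrate topology: ``'ends'`` is the
    tethered linear molecule (fronts stop at the ends; the experimental
    situation and the default), ``'periodic'`` a circular substrate,
    which is the topology assumed by the mean-field (many-nuclei) limit
    and is used when checking convergence to it.
    """

    rates: RateParams
    t_max: float
    dt: float = 0.5
    time_origin: str = "protein_addition"
    M: int = 1000
    seed: int = 0
    boundary: str = "ends"

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_max <= 0:
            raise ValueError("dt and t_max must be positive")
        if self.time_origin not in TIME_ORIGINS:
            raise ValueError(f"time_origin must be one of {TIME_ORIGINS}")
        if self.boundary not in ("ends", "periodic"):
            raise ValueError("boundary must be 'ends' or 'periodic'")
        if self.M < 1:
            raise ValueError("M must be >= 1")

    @property
    def n_grid(self) -> int:
        return int(round(self.t_max / self.dt)) + 1

    @property
    def t_grid(self) -> np.ndarray:
        return np.arange(self.n_grid) * self.dt


@dataclass(frozen=True)
class DomainKinetics:
    """Ground truth / inferred kinetics of one domain.

    Positions are fractions of the naked contour length, velocities in
    fractions per second.  ``fast_side`` is 'left' or 'right'.
    """

    t_nuc: float
    x_nuc: float
    v_fast: float
    v_slow: float
    fast_side: str = "left"

    def __post_init__(self) -> None:
        if not 0.0 <= self.x_nuc <= 1.0:
            raise ValueError("x_nuc must lie in [0, 1]")
        if self.v_slow < 0 or self.v_fast < self.v_slow:
            raise ValueError("require v_fast >= v_slow >= 0")
        if self.fast_side not in ("left", "right"):
            raise ValueError("fast_side must be 'left' or 'right'")

    @property
    def v_left(self) -> float:
        return self.v_fast if self.fast_side == "left" else self.v_slow

    @property
    def v_right(self) -> float:
        return self.v_slow if self.fast_side == "left" else self.v_fast

    def velocities_recA_per_s(self, n_sites: int) -> tuple[float, float]:
        """(v_fast, v_slow) converted to RecA monomers per second."""
        return self.v_fast * n_sites, self.v_slow * n_sites


@dataclass(frozen=True)
class Event:
    """One nucleation or collision event.

    ``kind`` is 'nucleation', 'domain-domain' or 'domain-end';
    ``domains`` lists (domain_id, side) participants; ``position`` is the
    substrate fraction where the event happened.
    """

    kind: str
    t: float
    position: float
    domains: tuple = ()
    fast_side: str | None = None


@dataclass
class SimRun:
    """Trajectory, event log and ground-truth kinetics of a single run."""

    t: np.ndarray
    phi: np.ndarray
    events: list
    domains: list
    config: SimConfig

    @property
    def nucleations(self) -> list:
        return [e for e in self.events if e.kind == "nucleation"]


@dataclass
class SimResult:
    """Ensemble mean coverage phi_bar(t) with dispersion."""

    t: np.ndarray
    phi_mean: np.ndarray
    phi_sd: np.ndarray
    phi_se: np.ndarray
    M: int
    config: SimConfig
    phi_runs: np.ndarray | None = None


def _draw_side(u: float) -> str:
    return "left" if u < 0.5 else "right"


def simulate_once(config: SimConfig, rng: np.random.Generator | None = None) -> SimRun:
    """One stochastic run with full event bookkeeping.

    Collision and end-arrival times are interpolated linearly inside the
    step in which they are detected (this affects the event log only,
    not the coverage trajectory).  Returns the exact ground-truth
    :class:`DomainKinetics` of every nucleus, usable directly by the
    synthetic-data generator and as decomposition truth.
    """
    if config.boundary != "ends":
        raise NotImplementedError(
            "event-level bookkeeping is implemented for the linear "
            "molecule only; use simulate_ensemble for periodic runs"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    kn = config.rates.kn
    vf = config.rates.kg_fast
    vs = config.rates.r * vf
    dt = config.dt
    n_grid = config.n_grid

    # position-sorted parallel lists; ids index the `domains` output list
    left: list[float] = []
    right: list[float] = []
    vl: list[float] = []
    vr: list[float] = []
    ids: list[int] = []

    events: list[Event] = []
    domains: list[DomainKinetics] = []
    phi = 0.0
    out = np.zeros(n_grid)

    def nucleate(t_nuc: float, forced_first: bool = False) -> None:
        free = 1.0 - phi
        target = rng.random() * free
        pos = -1.0
        prev = 0.0
        idx = len(left)
        for i in range(len(left)):
            gap = left[i] - prev
            if target <= gap:
                pos = prev + target
                idx = i
                break
            target -= gap
            prev = right[i]
        if pos < 0.0:
            pos = prev + target
        side = _draw_side(rng.random())
        left.insert(idx, pos)
        right.insert(idx, pos)
        vl.insert(idx, vf if side == "left" else vs)
        vr.insert(idx, vs if side == "left" else vf)
        ids.insert(idx, len(domains))
        domains.append(
            DomainKinetics(t_nuc=t_nuc, x_nuc=pos, v_fast=vf, v_slow=vs, fast_side=side)
        )
        events.append(
            Event("nucleation", t_nuc, pos, ((len(domains) - 1, None),), side)
        )

    if config.time_origin == "first_nucleation":
        nucleate(0.0)

    for g in range(1, n_grid):
        t_prev = (g - 1) * dt
        if phi < 1.0 and rng.random() < kn * (1.0 - phi) * dt:
            nucleate(t_prev)

        # growth with end clipping (arrival time interpolated for the log)
        for i in range(len(left)):
            if vl[i] > 0.0:
                new = left[i] - vl[i] * dt
                if new <= 0.0:
                    t_hit = t_prev + left[i] / vl[i]
                    events.append(Event("domain-end", t_hit, 0.0, ((ids[i], "left"),)))
                    left[i] = 0.0
                    vl[i] = 0.0
                else:
                    left[i] = new
            if vr[i] > 0.0:
                new = right[i] + vr[i] * dt
                if new >= 1.0:
                    t_hit = t_prev + (1.0 - right[i]) / vr[i]
                    events.append(Event("domain-end", t_hit, 1.0, ((ids[i], "right"),)))
                    right[i] = 1.0
                    vr[i] = 0.0
                else:
                    right[i] = new

        # merge overlapping neighbours
        i = 0
        while i < len(left) - 1:
            if right[i] >= left[i + 1]:
                gap_before = (left[i + 1] + vl[i + 1] * dt) - (right[i] - vr[i] * dt)
                speed = vr[i] + vl[i + 1]
                t_col = t_prev + (gap_before / speed if speed > 0 else 0.0)
                pos = min(right[i], left[i + 1] + 0.5 * max(right[i] - left[i + 1], 0.0))
                events.append(
                    Event(
                        "domain-domain",
                        t_col,
                        pos,
                        ((ids[i], "right"), (ids[i + 1], "left")),
                    )
                )
                if right[i + 1] >= right[i]:
                    right[i] = right[i + 1]
                    vr[i] = vr[i + 1]
                del left[i + 1], right[i + 1], vl[i + 1], vr[i + 1], ids[i + 1]
            else:
                i += 1

        phi = min(sum(r_ - l_ for l_, r_ in zip(left, right)), 1.0)
        out[g] = phi
        if phi >= 1.0:
            out[g + 1 :] = 1.0
            break

    return SimRun(config.t_grid, out, events, domains, config)


def simulate_ensemble(
    config: SimConfig,
    run_seeds: np.ndarray | None = None,
    keep_runs: bool = False,
) -> SimResult:
    """Mean and dispersion of phi over M independent replicates.

    Per-run seeds are spawned from ``config.seed`` (reproducible); an
    explicit ``run_seeds`` array overrides them.  The compiled stepper is
    used run by run; ``keep_runs`` additionally stores the full phi
    matrix (M x n_grid).
    """
    if run_seeds is None:
        if config.M < 1:
            raise ValueError("M must be >= 1")
        run_seeds = (
            np.random.SeedSequence(config.seed).generate_state(config.M) % (2**31)
        ).astype(np.int64)
    else:
        run_seeds = np.asarray(run_seeds, dtype=np.int64)
    M = run_seeds.size
    origin_first = config.time_origin == "first_nucleation"
    periodic = config.boundary == "periodic"
    n_grid = config.n_grid
    kn, vf, r = config.rates.kn, config.rates.kg_fast, config.rates.r

    if keep_runs:
        runs = np.empty((M, n_grid))
        for l, s in enumerate(run_seeds):
            np.random.seed(int(s) % (2**31))
            runs[l] = _engine.run_coverage(
                kn, vf, r, config.dt, n_grid, origin_first, periodic
            )
        mean = runs.mean(axis=0)
        sd = runs.std(axis=0, ddof=1) if M > 1 else np.zeros(n_grid)
    else:
        runs = None
        mean, sd = _engine.ensemble_coverage(
            kn, vf, r, config.dt, n_grid, run_seeds, origin_first, periodic
        )
    se = sd / np.sqrt(M)
    return SimResult(config.t_grid, mean, sd, se, M, config, runs)


@dataclass
class PiecewiseCoverage:
    """Exact piecewise-linear coverage trajectory.

    ``knot_t``/``knot_phi`` are the event times and coverages; between
    knots phi is linear.  Flat before the first and after the last knot.
    """

    knot_t: np.ndarray
    knot_phi: np.ndarray
    events: list

    def phi_at(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.knot_t, self.knot_phi)

    @property
    def t_breaks(self) -> np.ndarray:
        """Times where the coverage slope changes (nucleations/collisions)."""
        return np.array([e.t for e in self.events])


class _Dom:
    __slots__ = ("id", "left", "right", "vl", "vr", "l_alive", "r_alive")

    def __init__(self, id_, x, vl, vr):
        self.id = id_
        self.left = x
        self.right = x
        self.vl = vl
        self.vr = vr
        self.l_alive = True
        self.r_alive = True


def propagate_exact(nuclei, t_end: float | None = None) -> PiecewiseCoverage:
    """Deterministic, event-driven propagation of a given nucleation set.

    ``nuclei`` is an iterable of :class:`DomainKinetics` (or (t, x,
    v_left, v_right) tuples) with non-decreasing nucleation times.
    Fronts move at constant velocity from nucleation until they meet a
    neighbour or a molecule end; collision times are solved exactly, so
    the returned trajectory is exact piecewise-linear coverage.

    Raises
    ------
    ValueError
        If a nucleation falls inside the already-covered region at its
        time, or nucleation times decrease.
    """
    pend = []
    for nd in nuclei:
        if isinstance(nd, DomainKinetics):
            pend.append((nd.t_nuc, nd.x_nuc, nd.v_left, nd.v_right))
        else:
            t, x, vlv, vrv = nd
            pend.append((float(t), float(x), float(vlv), float(vrv)))
    if any(pend[i][0] > pend[i + 1][0] for i in range(len(pend) - 1)):
        raise ValueError("nucleation times must be non-decreasing")
    if pend and pend[0][0] < 0:
        raise ValueError("nucleation times must be >= 0")

    doms: list[_Dom] = []
    events: list[Event] = []
    knot_t = [0.0]
    knot_phi = [0.0]
    T = 0.0
    next_id = 0
    k = 0  # pending index
    INF = np.inf

    def coverage() -> float:
        return min(sum(d.right - d.left for d in doms), 1.0)

    while True:
        # next event time
        t_next = INF
        kind: tuple = ()
        if k < len(pend) and pend[k][0] < t_next:
            t_next = pend[k][0]
            kind = ("nuc",)
        if doms:
            d0 = doms[0]
            if d0.l_alive and d0.vl > 0:
                tt = T + d0.left / d0.vl
                if tt < t_next:
                    t_next = tt
                    kind = ("end", "left")
            dl = doms[-1]
            if dl.r_alive and dl.vr > 0:
                tt = T + (1.0 - dl.right) / dl.vr
                if tt < t_next:
                    t_next = tt
                    kind = ("end", "right")
        for i in range(len(doms) - 1):
            a, b = doms[i], doms[i + 1]
            s = (a.vr if a.r_alive else 0.0) + (b.vl if b.l_alive else 0.0)
            if s > 0:
                tt = T + max(b.left - a.right, 0.0) / s
                if tt < t_next:
                    t_next = tt
                    kind = ("col", i)

        if t_next is INF or (t_end is not None and t_next > t_end):
            break

        # advance live fronts to t_next
        dt = t_next - T
        for d in doms:
            if d.l_alive:
                d.left = max(d.left - d.vl * dt, 0.0)
            if d.r_alive:
                d.right = min(d.right + d.vr * dt, 1.0)
        T = t_next

        if kind[0] == "nuc":
            t_n, x, vlv, vrv = pend[k]
            k += 1
            for d in doms:
                if d.left < x < d.right or (d.left == x == d.right):
                    raise ValueError(
                        f"nucleation at x={x} falls inside covered region at t={T}"
                    )
            newd = _Dom(next_id, x, vlv, vrv)
            next_id += 1
            i = 0
            while i < len(doms) and doms[i].left < x:
                i += 1
            doms.insert(i, newd)
            events.append(Event("nucleation", T, x, ((newd.id, None),)))
        elif kind[0] == "end":
            if kind[1] == "left":
                d = doms[0]
                d.left = 0.0
                d.l_alive = False
                events.append(Event("domain-end", T, 0.0, ((d.id, "left"),)))
            else:
                d = doms[-1]
                d.right = 1.0
                d.r_alive = False
                events.append(Event("domain-end", T, 1.0, ((d.id, "right"),)))
        else:  # collision of neighbours i, i+1
            i = kind[1]
            a, b = doms[i], doms[i + 1]
            pos = 0.5 * (a.right + b.left)
            a.right = pos
            b.left = pos
            events.append(
                Event("domain-domain", T, pos, ((a.id, "right"), (b.id, "left")))
            )
            merged = _Dom(a.id, 0.0, 0.0, 0.0)
            merged.left = a.left
            merged.vl = a.vl
            merged.l_alive = a.l_alive
            merged.right = b.right
            merged.vr = b.vr
            merged.r_alive = b.r_alive
            doms[i : i + 2] = [merged]

        knot_t.append(T)
        knot_phi.append(coverage())

    # terminal knot: extend to t_end with the residual slope (if any)
    if t_end is not None and t_end > T:
        slope = sum(
            (d.vl if d.l_alive else 0.0) + (d.vr if d.r_alive else 0.0) for d in doms
        )
        knot_t.append(t_end)
        knot_phi.append(min(coverage() + slope * (t_end - T), 1.0))

    return PiecewiseCoverage(np.array(knot_t), np.array(knot_phi), events)


def forced_scenario(config: SimConfig, nucleations) -> SimRun:
    """Deterministic replay of a prescribed nucleation list.

    ``nucleations`` is a list of (t, x, fast_side) with increasing times;
    front velocities come from ``config.rates``.  Returns a
    :class:`SimRun` sampled on the config time grid, with the exact
    event log from :func:`propagate_exact`.
    """
    vf = config.rates.kg_fast
    vs = config.rates.r * vf
    kin = [
        DomainKinetics(t_nuc=t, x_nuc=x, v_fast=vf, v_slow=vs, fast_side=side)
        for (t, x, side) in nucleations
    ]
    pw = propagate_exact(kin, t_end=config.t_max)
    t = config.t_grid
    run = SimRun(t, pw.phi_at(t), pw.events, kin, config)
    run.piecewise = pw  # type: ignore[attr-defined]
    return run
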