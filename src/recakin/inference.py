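"""Rate-constant inference: nucleation statistics and chi^2 grid-scan fit.

Two independent estimators of the assembly rates are implemented.

1. The B_N method.  Nucleation is a Poisson process on the undecorated
   DNA with density n per binding site per second, so the expected count
   of nuclei after integrating the free length satisfies N = n * B_N
   with B_N = integral of L_free(t) from protein addition t0 to the time
   of the N-th nucleation.  Across experiments the slope of mean(B_N)
   vs N is therefore 1/n.

2. Simulation-based chi^2 fit.  The few-nuclei Monte-Carlo model's mean
   coverage is compared with the experimental ensemble mean on a common
   grid (time origin at the first nucleation event) through

       chi^2 = sum_t (phi_exp - phi_mod)^2 / (SE_exp^2 + SE_mod^2),

   and the minimum over (kn, kg', r) is located by an iterative grid
   scan with increasing ensemble sizes (gradient-based optimizers are
   avoided: the stochastic objective produces spurious local minima).
   Scan-step sizes double as (conservative) parameter error bars.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from . import _engine
from .kinetics import RateParams, energy_asym, energy_coop
from .wlc import CoverageCurve

__all__ = [
    "BNRecord",
    "NucleationFit",
    "AlignedEnsemble",
    "ScanSpec",
    "FitResult",
    "compute_BN",
    "fit_nucleation_density",
    "align_coverage_ensemble",
    "chi2_objective",
    "grid_scan_fit",
]

#: naked contour length of one 3-bp binding site, um
SITE_LENGTH_UM = 3 * 0.34 / 1000.0


@dataclass(frozen=True)
class BNRecord:
    """Integrated free length up to the N-th nucleation of one experiment."""

    experiment: int
    N: int
    B_N: float  # site*s (or um*s if units='um')


def compute_BN(
    curves,
    nucleation_times,
    t0: float = 0.0,
    units: str = "sites",
    site_length_um: float = SITE_LENGTH_UM,
) -> list[BNRecord]:
    """Trapezoidal B_N = integral of L_free from t0 to each nucleation time.

    ``curves`` is a list of :class:`CoverageCurve`; ``nucleation_times``
    the matching list of per-experiment nucleation-time lists (from the
    trace decomposition).  With ``units='sites'`` the free length is
    expressed in binding sites so that 1/slope of mean(B_N) vs N is the
    nucleation density in site^-1 s^-1.
    """
    if units not in ("sites", "um"):
        raise ValueError("units must be 'sites' or 'um'")
    records: list[BNRecord] = []
    for eid, (curve, t_ns) in enumerate(zip(curves, nucleation_times)):
        lfree = np.clip(curve.L_free, 0.0, None)
        if units == "sites":
            lfree = lfree / site_length_um
        cum = cumulative_trapezoid(lfree, curve.t, initial=0.0)
        b0 = float(np.interp(t0, curve.t, cum))
        for N, t_n in enumerate(sorted(t_ns), start=1):
            if t_n < t0:
                raise ValueError("nucleation time before protein addition")
            records.append(
                BNRecord(eid, N, float(np.interp(t_n, curve.t, cum)) - b0)
            )
    return records


@dataclass(frozen=True)
class NucleationFit:
    """Estimate of the nucleation rate density from B_N statistics."""

    n_hat: float
    n_se: float
    slope: float
    slope_se: float
    intercept: float
    N_values: tuple
    B_means: tuple


def fit_nucleation_density(
    records, through_origin: bool = False
) -> NucleationFit:
    """Linear fit of mean(B_N) on N; the nucleation density is 1/slope.

    B_N values are first averaged across experiments at each N.  When
    every N is represented by at least two experiments, the fit is
    weighted least squares with the known point variances (the
    across-experiment standard error of each mean), and the slope
    standard error comes from the exact WLS covariance; otherwise it
    falls back to residual-based ordinary least squares.  The standard
    error of n is propagated from the slope (SE_n = SE_slope/slope^2).
    """
    by_n: dict[int, list[float]] = {}
    for rec in records:
        by_n.setdefault(rec.N, []).append(rec.B_N)
    Ns = np.array(sorted(by_n), dtype=float)
    if Ns.size < 2:
        raise ValueError("need at least two distinct N values")
    groups = [np.asarray(by_n[int(N)], dtype=float) for N in Ns]
    B = np.array([g.mean() for g in groups])
    counts = np.array([g.size for g in groups])
    if np.all(counts > 1):
        se = np.array([g.std(ddof=1) / np.sqrt(g.size) for g in groups])
        w = 1.0 / np.maximum(se, 1e-300) ** 2
    else:
        w = None

    if through_origin:
        if w is None:
            slope = float(np.sum(B * Ns) / np.sum(Ns**2))
            resid = B - slope * Ns
            dof = max(Ns.size - 1, 1)
            slope_se = float(np.sqrt(np.sum(resid**2) / dof / np.sum(Ns**2)))
        else:
            swx2 = float(np.sum(w * Ns**2))
            slope = float(np.sum(w * B * Ns) / swx2)
            slope_se = float(np.sqrt(1.0 / swx2))
        intercept = 0.0
    else:
        A = np.column_stack([Ns, np.ones_like(Ns)])
        if w is None:
            coef, _, _, _ = np.linalg.lstsq(A, B, rcond=None)
            resid = B - A @ coef
            dof = max(Ns.size - 2, 1)
            s2 = float(np.sum(resid**2) / dof)
            cov = s2 * np.linalg.inv(A.T @ A)
        else:
            Aw = A * np.sqrt(w)[:, None]
            coef, _, _, _ = np.linalg.lstsq(Aw, B * np.sqrt(w), rcond=None)
            cov = np.linalg.inv(A.T @ (w[:, None] * A))
        slope, intercept = float(coef[0]), float(coef[1])
        slope_se = float(np.sqrt(cov[0, 0]))

    n_hat = 1.0 / slope
    n_se = slope_se / slope**2
    return NucleationFit(
        n_hat, n_se, slope, slope_se, intercept, tuple(Ns), tuple(B)
    )


@dataclass
class AlignedEnsemble:
    """Experimental ensemble mean coverage on a common aligned grid."""

    t: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    se: np.ndarray
    n: int


def align_coverage_ensemble(
    curves,
    t_first=None,
    grid_dt: float = 5.0,
    detect_threshold: float = 0.01,
) -> AlignedEnsemble:
    """Align coverage curves at their first nucleation and average.

    Each curve is shifted so that t = 0 is its first nucleation event
    (given explicitly via ``t_first``, otherwise detected as the first
    sample with phi above ``detect_threshold``), linearly interpolated
    onto a common grid, and held at its end values beyond its range.
    The grid is truncated once every trace has reached full coverage
    (beyond that point the between-trace variance is identically zero
    and carries no information).
    """
    ts, phis = [], []
    for c in curves:
        if isinstance(c, CoverageCurve):
            ts.append(np.asarray(c.t, float))
            phis.append(np.asarray(c.phi, float))
        else:
            t, p = c
            ts.append(np.asarray(t, float))
            phis.append(np.asarray(p, float))
    n = len(ts)
    if t_first is None:
        t_first = [
            t[np.argmax(p > detect_threshold)] if np.any(p > detect_threshold) else t[0]
            for t, p in zip(ts, phis)
        ]
    aligned_t = [t - t1 for t, t1 in zip(ts, t_first)]
    t_end = max(float(t[-1]) for t in aligned_t)
    grid = np.arange(0.0, t_end + 0.5 * grid_dt, grid_dt)
    mat = np.vstack([np.interp(grid, t, p) for t, p in zip(aligned_t, phis)])

    done = np.all(mat >= 1.0 - 1e-9, axis=0)
    if np.any(done):
        last = int(np.argmax(done)) + 1
        grid, mat = grid[:last], mat[:, :last]

    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    return AlignedEnsemble(grid, mean, sd, sd / np.sqrt(n), n)


def chi2_objective(
    exp_mean,
    exp_sd,
    n_exp: int,
    mod_mean,
    mod_sd,
    n_mod: int,
    sd_ref=None,
    var_floor: float = 1e-12,
) -> float:
    """chi^2 including both experimental and model (Monte-Carlo) errors.

        chi^2 = sum_t (phi_exp - phi_mod)^2 / (SD_exp^2/n + SD_mod^2/M)

    ``sd_ref`` is an optional *parameter-independent* per-time floor on
    the experimental between-trace SD (typically the model's run-to-run
    SD evaluated once at a reference parameter point).  With only a
    handful of traces the empirical SD can collapse to zero near t = 0
    and near saturation, which would give those points quasi-infinite
    weight; the floor must not depend on the parameter point being
    evaluated, or the minimisation would reward models that merely
    predict large fluctuations.  Grid points where the combined variance
    still vanishes are regularised by ``var_floor`` (logged) so
    identical curves give chi^2 = 0, not 0/0.
    """
    exp_mean = np.asarray(exp_mean, float)
    mod_mean = np.asarray(mod_mean, float)
    exp_sd = np.asarray(exp_sd, float)
    mod_sd = np.asarray(mod_sd, float)
    if sd_ref is not None:
        exp_sd = np.maximum(exp_sd, np.asarray(sd_ref, float))
    var = exp_sd**2 / n_exp + mod_sd**2 / n_mod
    if np.any(var < var_floor):
        warnings.warn(
            "zero combined variance at some grid points; variance floor applied",
            RuntimeWarning,
            stacklevel=2,
        )
        var = np.maximum(var, var_floor)
    return float(np.sum((exp_mean - mod_mean) ** 2 / var))


@dataclass(frozen=True)
class ScanSpec:
    """Geometry and averaging schedule of the chi^2 grid scan.

    kn and kg' grids are logarithmically spaced (decade-scale prior
    uncertainty), the r grid linear on (0, 1].  ``M_schedule`` gives the
    ensemble size of the coarse map, the sub-threshold refinement and
    the final evaluation; ``threshold_frac`` keeps stage-1 points within
    (1 + threshold_frac) of the coarse minimum, capped at
    ``refine_top`` points.
    """

    kn_grid: np.ndarray
    kg_fast_grid: np.ndarray
    r_grid: np.ndarray
    M_schedule: tuple = (1000, 10000, 100000)
    threshold_frac: float = 0.10
    refine_top: int = 10
    dt: float = 0.5
    grid_stride: int = 10

    @classmethod
    def default(cls, M_schedule=(1000, 10000, 100000)) -> "ScanSpec":
        return cls(
            kn_grid=np.geomspace(2.5e-4, 4e-3, 5),
            kg_fast_grid=np.geomspace(1.25e-4, 2e-3, 5),
            r_grid=np.round(np.arange(0.1, 1.001, 0.1), 3),
            M_schedule=M_schedule,
        )


@dataclass
class FitResult:
    """Best-fit rates from the grid scan, with scan-step error bars."""

    kn_hat: float
    kg_fast_hat: float
    r_hat: float
    errors: dict
    chi2_min: float
    n_points: int
    M_schedule: tuple
    on_boundary: bool
    n_evaluations: int
    n_sites: int | None = None

    @property
    def rates(self) -> RateParams:
        return RateParams(self.kn_hat, self.kg_fast_hat, self.r_hat, self.n_sites)

    @property
    def kg_hat(self) -> float:
        return self.rates.kg

    @property
    def fast_slow_ratio(self) -> float:
        """v_fast / v_slow = 1/r at the fit."""
        return 1.0 / self.r_hat

    @property
    def n_hat(self) -> float:
        return self.rates.n

    @property
    def v_hat(self) -> float:
        return self.rates.v

    @property
    def dE_coop(self) -> float:
        return energy_coop(self.rates) if self.n_sites else float("nan")

    @property
    def dE_asym(self) -> float:
        return energy_asym(self.r_hat)

    def summary(self) -> dict:
        out = {
            "kn_hat": self.kn_hat,
            "kg_fast_hat": self.kg_fast_hat,
            "kg_hat": self.kg_hat,
            "r_hat": self.r_hat,
            "fast_slow_ratio": self.fast_slow_ratio,
            "chi2_min": self.chi2_min,
            "errors": self.errors,
            "dE_asym_kBT": self.dE_asym,
            "on_boundary": self.on_boundary,
        }
        if self.n_sites:
            out.update(
                n_hat=self.n_hat, v_hat=self.v_hat, dE_coop_kBT=self.dE_coop,
                n_sites=self.n_sites,
            )
        return out


def _model_curve(kn, kgf, r, dt, n_grid_model, stride, seeds):
    mean, sd = _engine.ensemble_coverage(
        kn, kgf, r, dt, n_grid_model, seeds, True, False
    )
    return mean[::stride], sd[::stride]


def _stage_seeds(seed: int, stage: int, M: int) -> np.ndarray:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stage,))
    return (ss.generate_state(M) % (2**31)).astype(np.int64)


def grid_scan_fit(
    curves,
    scan: ScanSpec,
    seed: int = 0,
    t_first=None,
    n_sites: int | None = None,
    history: list | None = None,
    surface: list | None = None,
) -> FitResult:
    """Three-stage zoom scan of the chi^2 surface over (kn, kg', r).

    Stage 1 maps the full coarse grid with the smallest ensemble size;
    stage 2 re-evaluates the sub-threshold region, refined by half a
    scan step in every direction (geometric half-steps for the log-
    spaced rate axes, arithmetic for r), with the intermediate ensemble
    size; stage 3 re-evaluates the best point with the final ensemble
    size.  Within each stage every grid point shares the same per-run
    random seeds (common random numbers), which makes the arg-min far
    more stable at small M.  chi^2 weights use the empirical
    between-trace variance of the aligned experimental curves plus the
    model's Monte-Carlo error.  Final half-step sizes are reported as
    the parameter errors.  A minimum on the coarse-grid boundary is
    flagged (``on_boundary``) - the ranges should then be widened.
    """
    M1, M2, M3 = scan.M_schedule
    ens = align_coverage_ensemble(
        curves, t_first=t_first, grid_dt=scan.dt * scan.grid_stride
    )
    n_grid_model = (ens.t.size - 1) * scan.grid_stride + 1
    n_evals = 0

    def objective(kn, kgf, r, seeds):
        nonlocal n_evals
        n_evals += 1
        mod_mean, mod_sd = _model_curve(
            kn, kgf, r, scan.dt, n_grid_model, scan.grid_stride, seeds
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            chi2 = chi2_objective(
                ens.mean, ens.sd, ens.n, mod_mean, mod_sd, seeds.size
            )
        if surface is not None:
            surface.append((float(kn), float(kgf), float(r), chi2, int(seeds.size)))
        return chi2

    # stage 1: coarse map with common random numbers
    seeds1 = _stage_seeds(seed, 1, M1)
    coarse = []
    for kn, kgf, r in itertools.product(
        scan.kn_grid, scan.kg_fast_grid, scan.r_grid
    ):
        coarse.append(
            ((float(kn), float(kgf), float(r)), objective(kn, kgf, r, seeds1))
        )
    coarse.sort(key=lambda kv: kv[1])
    chi2_best_coarse = coarse[0][1]
    candidates = [
        p
        for p, c in coarse
        if c <= chi2_best_coarse * (1.0 + scan.threshold_frac)
    ][: scan.refine_top]
    if history is not None:
        history.append(("stage1", len(coarse), chi2_best_coarse))

    # stage 2: half-step refinement around the sub-threshold region
    f_kn = (scan.kn_grid[1] / scan.kn_grid[0]) ** 0.5 if scan.kn_grid.size > 1 else 1.0
    f_kg = (
        (scan.kg_fast_grid[1] / scan.kg_fast_grid[0]) ** 0.5
        if scan.kg_fast_grid.size > 1
        else 1.0
    )
    dr = (scan.r_grid[1] - scan.r_grid[0]) / 2.0 if scan.r_grid.size > 1 else 0.0
    r_max = float(np.max(scan.r_grid))
    refined = set()
    for kn, kgf, r in candidates:
        for a, b, c in itertools.product((-1, 0, 1), repeat=3):
            rr = round(r + c * dr, 9)
            if rr <= 0 or rr > r_max:
                continue
            refined.add((round(kn * f_kn**a, 12), round(kgf * f_kg**b, 12), rr))
    seeds2 = _stage_seeds(seed, 2, M2)
    stage2 = [(p, objective(*p, seeds2)) for p in sorted(refined)]
    stage2.sort(key=lambda kv: kv[1])
    best_point = stage2[0][0]
    if history is not None:
        history.append(("stage2", len(stage2), stage2[0][1]))

    # stage 3: final evaluation of the minimum
    seeds3 = _stage_seeds(seed, 3, M3)
    chi2_min = objective(*best_point, seeds3)
    if history is not None:
        history.append(("stage3", 1, chi2_min))

    kn_hat, kg_fast_hat, r_hat = best_point
    on_boundary = (
        kn_hat <= scan.kn_grid[0] * 1.0001
        or kn_hat >= scan.kn_grid[-1] * 0.9999
        or kg_fast_hat <= scan.kg_fast_grid[0] * 1.0001
        or kg_fast_hat >= scan.kg_fast_grid[-1] * 0.9999
        or r_hat >= r_max - 1e-12
        or r_hat <= float(np.min(scan.r_grid)) - dr + 1e-12
    )
    if on_boundary:
        warnings.warn(
            "chi^2 minimum on the scan boundary; widen the scan ranges",
            RuntimeWarning,
            stacklevel=2,
        )
    errors = {
        "kn": kn_hat * (f_kn - 1.0),
        "kg_fast": kg_fast_hat * (f_kg - 1.0),
        "r": dr if dr > 0 else float("nan"),
    }
    return FitResult(
        kn_hat=kn_hat,
        kg_fast_hat=kg_fast_hat,
        r_hat=r_hat,
        errors=errors,
        chi2_min=chi2_min,
        n_points=int(ens.t.size),
        M_schedule=scan.M_schedule,
        on_boundary=on_boundary,
        n_evaluations=n_evals,
        n_sites=n_sites,
    )
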