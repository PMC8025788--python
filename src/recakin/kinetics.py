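"""Closed-form and mean-field models of RecA coverage kinetics.

Three analytically tractable limits of the nucleation-and-growth process
are implemented, together with the rate-constant conversions that link
the macroscopic (per-molecule) rates to microscopic (per-binding-site)
quantities and the Arrhenius activation-energy differences.

Rates
-----
kn       nucleation rate per molecule, 1/s
kg_fast  growth rate of the fast front (kg'), 1/s
r        slow/fast front asymmetry ratio, 0 <= r <= 1
kg       total domain growth rate, kg = kg_fast * (1 + r)
n        nucleation rate density per binding site, kn = n * (L0/a)
v        domain growth velocity in monomers/s, kg = v / (L0/a)

Limits
------
* fast nucleation (kg/kn << 1): coverage follows the KJMA-type sigmoid
  phi(t) = 1 - exp(-1/2 kn kg t^2), which solves the mean-field ODE pair
  dN/dt = kn (1-phi) - kg N^2/(1-phi), dphi/dt = kg N.
* slow nucleation (kg/kn >> 1): a single domain nucleated at a uniform
  position x covers the molecule with a piecewise-linear phi(t); its
  ensemble average has an exact three-branch closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "RateParams",
    "EnergyDeltas",
    "convert_rates",
    "ode_mean_field",
    "coverage_fast",
    "coverage_slow_realization",
    "coverage_slow_mean",
    "energy_coop",
    "energy_asym",
    "energy_deltas",
]


@dataclass(frozen=True)
class RateParams:
    """Nucleation/growth rate constants of one assembly condition.

    ``n_sites`` (the binding-site count L0/a) is optional; it is required
    only for the microscopic conversions ``n``, ``v`` and for
    :func:`energy_coop`.
    """

    kn: float
    kg_fast: float
    r: float
    n_sites: int | None = None

    def __post_init__(self) -> None:
        if self.kn < 0 or self.kg_fast < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("asymmetry ratio r must lie in [0, 1]")
        if self.n_sites is not None and self.n_sites <= 0:
            raise ValueError("n_sites must be positive")

    @property
    def kg(self) -> float:
        """Total domain growth rate kg = kg_fast * (1 + r), 1/s."""
        return self.kg_fast * (1.0 + self.r)

    @property
    def n(self) -> float:
        """Nucleation rate density, per binding site per second."""
        self._require_sites()
        return self.kn / self.n_sites

    @property
    def v(self) -> float:
        """Domain growth velocity, RecA monomers per second."""
        self._require_sites()
        return self.kg * self.n_sites

    def _require_sites(self) -> None:
        if self.n_sites is None:
            raise ValueError("n_sites is required for microscopic rates")


@dataclass(frozen=True)
class EnergyDeltas:
    """Arrhenius activation-energy differences, in kBT units.

    dE_coop = E_n - E_g^f  (nucleation vs fast-front growth barrier)
    dE_asym = E_g^s - E_g^f (slow vs fast front barrier)
    """

    dE_coop: float
    dE_asym: float


def convert_rates(
    *,
    kn: float | None = None,
    n: float | None = None,
    kg: float | None = None,
    kg_fast: float | None = None,
    v: float | None = None,
    r: float = 0.0,
    n_sites: int | None = None,
) -> RateParams:
    """Build :class:`RateParams` from any consistent rate specification.

    Exactly one of ``kn`` (per molecule) or ``n`` (per site) must be
    given, and exactly one of ``kg`` (domain), ``kg_fast`` (fast front)
    or ``v`` (monomers/s).  Conversions use kn = n*(L0/a), kg = v/(L0/a)
    and kg = kg_fast*(1+r).
    """
    if (kn is None) == (n is None):
        raise ValueError("specify exactly one of kn or n")
    if sum(x is not None for x in (kg, kg_fast, v)) != 1:
        raise ValueError("specify exactly one of kg, kg_fast or v")
    if n_sites is not None and n_sites <= 0:
        raise ValueError("n_sites must be positive")
    if kn is None:
        if n_sites is None:
            raise ValueError("n_sites required to convert n -> kn")
        kn = n * n_sites
    if v is not None:
        if n_sites is None:
            raise ValueError("n_sites required to convert v -> kg")
        kg = v / n_sites
    if kg is not None:
        kg_fast = kg / (1.0 + r)
    return RateParams(kn=kn, kg_fast=kg_fast, r=r, n_sites=n_sites)


def ode_mean_field(
    params: RateParams,
    t_grid: np.ndarray,
    include_nucleation_coverage: bool = False,
    rtol: float = 1e-8,
):
    """Integrate the mean-field domain-count/coverage ODE system.

        dN/dt   = kn (1 - phi) - kg N^2 / (1 - phi)
        dphi/dt = kg N  [+ kn (1 - phi) if include_nucleation_coverage]

    The first term creates nuclei on the undecorated part; the second
    removes domains when their fronts collide.  The optional extra
    coverage term accounts for the sites consumed by nucleation itself;
    it is negligible unless the number of nuclei is comparable to the
    number of binding sites, and is off by default (so that the solution
    matches the closed-form sigmoid exactly).

    Returns ``(N, phi)`` on ``t_grid``.  phi is clamped at 1 - 1e-12
    during integration to keep the collision term finite; once the
    substrate is exhausted both arrays are held constant.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid[0] != 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must increase from 0")
    kn, kg = params.kn, params.kg
    cap = 1.0 - 1e-12

    def rhs(_t, state):
        N, phi = state
        phi = min(phi, cap)
        dN = kn * (1.0 - phi) - kg * N * N / (1.0 - phi)
        dphi = kg * N
        if include_nucleation_coverage:
            dphi += kn * (1.0 - phi)
        return (dN, dphi)

    def exhausted(_t, state):
        return state[1] - cap

    exhausted.terminal = True
    exhausted.direction = 1.0

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        (0.0, 0.0),
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=1e-12,
        events=exhausted,
    )
    N = np.full_like(t_grid, sol.y[0, -1] if sol.y.size else 0.0)
    phi = np.ones_like(t_grid)
    m = sol.t.size
    N[:m] = sol.y[0]
    phi[:m] = np.minimum(sol.y[1], 1.0)
    return N, phi


def coverage_fast(params: RateParams, t):
    """Fast-nucleation (many-nuclei) coverage sigmoid.

    phi(t) = 1 - exp(-1/2 kn kg_fast (1+r) t^2); depends on the rates
    only through the product kn*kg, so nucleation and growth cannot be
    separated in this regime.
    """
    t = np.asarray(t, dtype=float)
    out = 1.0 - np.exp(-0.5 * params.kn * params.kg_fast * (1.0 + params.r) * t**2)
    return float(out) if out.ndim == 0 else out


def coverage_slow_realization(kg_fast: float, r: float, x: float, t):
    """Single-domain coverage for a nucleus at position fraction ``x``.

    The domain nucleates at t = 0; the fast front moves toward the near
    end at velocity kg_fast (in substrate fractions per second) and the
    slow front toward the far end at r*kg_fast.  Returns ``(phi_dot,
    phi)``; the rate drops by kg_fast when the fast front reaches its end
    (t*kg_fast >= x) and by r*kg_fast when the slow one arrives
    (r*t*kg_fast >= 1-x).
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError("nucleation position fraction must lie in [0, 1]")
    t = np.asarray(t, dtype=float)
    phi_dot = (
        (r + 1.0) * kg_fast
        - kg_fast * (t * kg_fast >= x)
        - kg_fast * r * (r * t * kg_fast >= (1.0 - x))
    )
    phi = np.minimum(kg_fast * t, x) + np.minimum(r * kg_fast * t, 1.0 - x)
    if phi.ndim == 0:
        return float(phi_dot), float(phi)
    return phi_dot, phi


def coverage_slow_mean(kg_fast: float, r: float, t):
    """Ensemble-averaged single-domain coverage (slow-nucleation limit).

    Average of :func:`coverage_slow_realization` over a uniform
    nucleation position; exact three-branch piecewise form with
    breakpoints 1/kg_fast and 1/(r*kg_fast), continuous at both.

    ``r = 0`` is rejected: the second breakpoint diverges (the slow front
    never reaches the far end and the molecule saturates only as
    t -> infinity).
    """
    if r <= 0:
        raise ValueError("coverage_slow_mean requires r > 0")
    t = np.asarray(t, dtype=float)
    k = kg_fast
    early = k * (1.0 + r) * t - 0.5 * k * k * t * t * (1.0 + r * r)
    mid = k * r * t - 0.5 * k * k * r * r * t * t + 0.5
    out = np.where(t < 1.0 / k, early, np.where(t < 1.0 / (r * k), mid, 1.0))
    return float(out) if out.ndim == 0 else out


def energy_coop(params: RateParams) -> float:
    """Cooperativity energy dE_coop = E_n - E_g^f in kBT units.

    From the Arrhenius forms kn ~ (L0/a) exp(-E_n/kBT) and
    kg' ~ (a/L0) exp(-E_g^f/kBT):

        dE_coop = ln( kg / ((1+r) kn) * (L0/a)^2 )
                = ln( kg_fast / kn * (L0/a)^2 ).
    """
    params._require_sites()
    if params.kn <= 0 or params.kg_fast <= 0:
        raise ValueError("energy_coop requires strictly positive rates")
    return float(np.log(params.kg_fast / params.kn * params.n_sites**2))


def energy_asym(r: float) -> float:
    """Front-asymmetry energy dE_asym = E_g^s - E_g^f = -ln(r), kBT units."""
    if not r > 0:
        raise ValueError("energy_asym requires r > 0")
    return float(-np.log(r))


def energy_deltas(params: RateParams) -> EnergyDeltas:
    """Both activation-energy differences for one parameter set."""
    return EnergyDeltas(dE_coop=energy_coop(params), dE_asym=energy_asym(params.r))
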