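"""Hot loop of the few-nuclei Monte-Carlo simulator.

Plain-Python/numpy stepper compiled with numba when available; the same
functions run uncompiled otherwise.  Kept free of Python objects so the
chi^2 grid scan can evaluate ~1e6 runs on one CPU.

State is the set of *gaps* (free intervals) rather than domains: the
coverage and the nucleation process depend only on gap lengths, and each
gap shrinks at the sum of the closing speeds of its two bounding fronts
(zero at a molecule end).  A nucleation picks a gap with probability
proportional to its length and splits it; a gap that shrinks to zero is
a collision and is removed.  This is exactly equivalent to tracking
front positions on the substrate, works unchanged for the linear
('ends') and circular ('periodic') topologies, and clips any within-step
overshoot at the collision point.  RNG is the seeded legacy numpy global
generator so compiled and uncompiled paths draw identical streams.
"""

from __future__ import annotations

import numpy as np

MAX_GAPS = 128


def _run_coverage(kn, kg_fast, r, dt, n_grid, origin_first, periodic):
    """One stochastic run; returns phi on the n_grid-point time grid.

    Per step: one Bernoulli nucleation attempt with probability
    kn*(1-phi)*dt at a uniform point of the undecorated set (fast side
    chosen by fair coin), then every fast front advances kg_fast*dt and
    every slow front r*kg_fast*dt.  With origin_first the first nucleus
    is placed at t = 0 (trajectories aligned at first nucleation);
    otherwise t = 0 is protein addition and the wait is stochastic.
    """
    g = np.zeros(MAX_GAPS)  # gap lengths (substrate fractions)
    sl = np.zeros(MAX_GAPS)  # closing speed of each gap's left boundary
    sr = np.zeros(MAX_GAPS)  # ... and right boundary
    vslow = r * kg_fast
    out = np.zeros(n_grid)

    bare = True  # no nucleus yet
    ng = 0
    if not periodic:
        g[0] = 1.0
        ng = 1
    phi = 0.0

    if origin_first:
        # first nucleus at t = 0: same draws as the generic branch below
        u = np.random.random()  # position within the free substrate
        fast_left = np.random.random() < 0.5
        a = kg_fast if fast_left else vslow  # left-front speed
        b = vslow if fast_left else kg_fast
        if periodic:
            g[0] = 1.0
            sl[0] = b  # single circular gap: left bound = right front
            sr[0] = a
            ng = 1
        else:
            g[1] = 1.0 - u
            sl[1] = b
            sr[1] = sr[0]
            g[0] = u
            sr[0] = a
            ng = 2
        bare = False

    for step in range(1, n_grid):
        # nucleation attempt (phi from the previous step)
        if phi < 1.0 and ng < MAX_GAPS - 1:
            if np.random.random() < kn * (1.0 - phi) * dt:
                free = 1.0 - phi
                target = np.random.random() * free
                fast_left = np.random.random() < 0.5
                a = kg_fast if fast_left else vslow
                b = vslow if fast_left else kg_fast
                if bare and periodic:
                    g[0] = 1.0
                    sl[0] = b
                    sr[0] = a
                    ng = 1
                else:
                    idx = ng - 1
                    for i in range(ng):
                        if target <= g[i]:
                            idx = i
                            break
                        target -= g[i]
                    # split gap idx at offset `target`
                    for j in range(ng, idx + 1, -1):
                        g[j] = g[j - 1]
                        sl[j] = sl[j - 1]
                        sr[j] = sr[j - 1]
                    g[idx + 1] = g[idx] - target
                    sl[idx + 1] = b
                    sr[idx + 1] = sr[idx]
                    g[idx] = target
                    sr[idx] = a
                    ng += 1
                bare = False

        # growth: every gap shrinks; zero-length gaps are collisions
        i = 0
        while i < ng:
            g[i] -= (sl[i] + sr[i]) * dt
            if g[i] <= 0.0:
                for j in range(i, ng - 1):
                    g[j] = g[j + 1]
                    sl[j] = sl[j + 1]
                    sr[j] = sr[j + 1]
                ng -= 1
            else:
                i += 1

        s = 0.0
        for i in range(ng):
            s += g[i]
        phi = 0.0 if bare else 1.0 - s
        if phi > 1.0:
            phi = 1.0
        out[step] = phi
        if not bare and ng == 0:
            for h in range(step + 1, n_grid):
                out[h] = 1.0
            break

    return out


def _ensemble_coverage(kn, kg_fast, r, dt, n_grid, seeds, origin_first, periodic):
    """Mean and SD of phi over len(seeds) independent runs."""
    M = seeds.shape[0]
    s1 = np.zeros(n_grid)
    s2 = np.zeros(n_grid)
    for l in range(M):
        np.random.seed(seeds[l])
        ph = _run_coverage(kn, kg_fast, r, dt, n_grid, origin_first, periodic)
        for k in range(n_grid):
            s1[k] += ph[k]
            s2[k] += ph[k] * ph[k]
    mean = s1 / M
    sd = np.zeros(n_grid)
    if M > 1:
        for k in range(n_grid):
            var = s2[k] / M - mean[k] * mean[k]
            if var < 0.0:
                var = 0.0
            sd[k] = np.sqrt(var * M / (M - 1.0))
    return mean, sd


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    # rebind so the compiled ensemble resolves the compiled single-run kernel
    _run_coverage = njit(cache=True)(_run_coverage)
    _ensemble_coverage = njit(cache=True)(_ensemble_coverage)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

run_coverage = _run_coverage
ensemble_coverage = _ensemble_coverage
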