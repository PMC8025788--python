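# recakin

Nucleation-and-growth kinetics of RecA filaments on double-stranded DNA,
from force-clamp optical-tweezers traces.

RecA polymerizes on dsDNA in domains: a nucleus forms on the bare DNA at
rate constant k_n and each domain then elongates at its two fronts, a
fast one at rate k_g′ and a slow one at r·k_g′ (0 ≤ r ≤ 1), so the total
domain growth rate is k_g = k_g′(1+r).  Because each RecA monomer
extends its 3-bp binding site ~1.5×, the contour length L(t) of a
tethered molecule held at ~0.8 pN grows as protein assembles, and a
force-clamp trace records the entire assembly history of a *single*
molecule.  In the regime k_g/k_n ≈ 1 only a few domains form, L(t) is a
stepwise sequence of linear segments, and each abrupt slope change (a
*break point*) is a nucleation (slope up) or a front collision (slope
down).  This package turns such traces into per-domain front kinetics
and ensemble-level rate constants.  It is written for single-molecule
biophysicists analysing protein–DNA filament assembly (RecA, Rad51 and
relatives) and for anyone who needs a tested reference implementation of
few-nuclei nucleation-and-growth inference in one dimension.

## What it computes

* **Mechanics** (`recakin.wlc`) — worm-like-chain force–extension for a
  mixed-stiffness filament (naked persistence length A₀ ≈ 50 nm,
  decorated A_R ≈ 1200 nm).  In the large-force regime the decorated
  contour length follows from the trap–anchor distance z as

      L_R = (z − L(0)(1 − C₀)) / (1/3 + (2/3)C₀ − C_R),
      C₀ = √(k_BT/4FA₀),  C_R = √(k_BT/4FA_R),

  giving L(t) = L(0) + L_R/3 and the coverage fraction
  φ = 2(L/L(0) − 1).
* **Kinetic limits** (`recakin.kinetics`) — the many-nuclei sigmoid
  φ(t) = 1 − exp(−½ k_n k_g t²) (KJMA-type, solves the mean-field ODE
  pair), the exact single-domain average with asymmetric fronts, rate
  conversions k_n = n·(L₀/a), k_g = v/(L₀/a), and the Arrhenius barrier
  differences ΔE_coop = ln(k_g′/k_n · (L₀/a)²) and ΔE_asym = −ln r (in
  k_BT).
* **Simulator** (`recakin.simulate`) — stochastic few-nuclei Monte
  Carlo with asymmetric fronts (δt = 0.5 s), ensemble mean/SD, a
  compiled hot loop, and an exact event-driven propagator for
  deterministic replays.
* **Trace decomposition** (`recakin.decompose`) — piecewise-linear
  break-point refinement, exhaustive enumeration of collision
  scenarios, per-scenario linear solve for nucleation positions and
  front velocities, rejection of unphysical (negative-velocity)
  scenarios, and forward reconstruction for ranking.
* **Rate inference** (`recakin.inference`) — the B_N method (the
  integral of undecorated length up to the N-th nucleation; the slope
  of B̄_N vs N is 1/n̄) and a χ² grid-scan fit of the simulator's mean
  coverage to a trace ensemble over (k_n, k_g′, r).
* **Synthetic data** (`recakin.synth`) — ground-truth experiments
  emulating the assay (variable L(0), clamp jitter, position noise) so
  every stage is testable end to end.

## Worked example

```python
import numpy as np
import recakin as rk

# macroscopic best-fit rates -> microscopic values and barriers
rates = rk.convert_rates(kn=1.05e-3, kg=5.8e-4, r=0.10, n_sites=10700)
print(f"kg' = {rates.kg_fast:.2e} 1/s (fast front)")
print(f"v   = {rates.v:.1f} RecA/s")
print(f"n   = {rates.n:.2e} per site per s")
print(f"dE_coop = {rk.energy_coop(rates):.1f} kBT")
print(f"dE_asym = {rk.energy_asym(rates.r):.1f} kBT")

# decompose a noiseless synthetic two-domain trace (L(0) = 12 um)
d1 = rk.DomainKinetics(t_nuc=500.0, x_nuc=0.2, v_fast=8e-4, v_slow=1.0e-4, fast_side="left")
d2 = rk.DomainKinetics(t_nuc=1200.0, x_nuc=0.7, v_fast=8e-4, v_slow=0.7e-4, fast_side="left")
pw = rk.propagate_exact([d1, d2])
t = np.arange(0.0, pw.knot_t[-1] + 1500.0, 1.0)
curve = rk.CoverageCurve.from_length(t, 12.0 * (1 + pw.phi_at(t) / 2), 12.0)
res = rk.decompose_curve(curve, init_breaks=pw.t_breaks + 25.0)
print(f"breaks Q = {res.fit.Q}, domains N_t = {res.fit.n_domains}")
print(f"scenarios: {len(res.scenarios)} enumerated, {len(res.solutions)} feasible")
k = res.best.kinetics[0]
print(f"domain 1: v_fast = {k.v_fast*10700:.1f} RecA/s, v_slow = {k.v_slow*10700:.2f} RecA/s")
```

prints

```
kg' = 5.27e-04 1/s (fast front)
v   = 6.2 RecA/s
n   = 9.81e-08 per site per s
dE_coop = 17.9 kBT
dE_asym = 2.3 kBT
breaks Q = 5, domains N_t = 2
scenarios: 4 enumerated, 2 feasible
domain 1: v_fast = 8.6 RecA/s, v_slow = 1.07 RecA/s
```

The five break points encode N_t = (Q−1)/2 = 2 domains.  Four collision
scenarios are consistent with the break pattern; two are rejected
because their solution would require a negative front velocity
(disassembly, negligible with a non-hydrolysable ATP analogue), and the
two survivors are mirror images of each other (the molecule's
orientation is unobservable).  The recovered per-front velocities show
the strong fast/slow asymmetry directly.

A thin CLI mirrors the pipeline stages
(`recakin synth|simulate|decompose|bn|fit`, YAML configs, TSV/JSON
outputs); see `recakin --help`.

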