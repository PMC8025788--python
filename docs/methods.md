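# Methods

This note documents the models, estimators and numerical choices behind
`recakin`, and what the synthetic-data tests do and do not demonstrate
about real force-clamp data.

## Mechanical model: trace → coverage

A tethered dsDNA molecule under a ~0.8 pN clamp is described as two
worm-like-chain segments in series carrying the same tension: a naked
segment (persistence length `A0`, default 50 nm) and a RecA-decorated
segment (`AR`, default 1200 nm, measured on fully covered molecules;
molecule-to-molecule variation exists but only a scalar is exposed).
Thermal energy is computed from temperature (4.282 pN·nm at 310.15 K).
In the large-force regime F ≫ k_BT/A each segment contributes its
contour length times the fractional extension 1 − √(k_BT/4FA), which
gives the closed-form inversion for the decorated contour length L_R
implemented in `decorated_length_from_trace`.  Note the square-root
form: the large-force expansion of the interpolation formula
F = (k_BT/A)[z/L + 1/4(1−z/L)² − 1/4] requires C = √(k_BT/4FA), and this
form reproduces the known ~84% fractional extension of naked dsDNA at
0.8 pN; a regression test compares it against full numerical inversion
of the interpolation formula (agreement ~2% at 0.8 pN, the size of the
neglected terms).  The trap–anchor distance y is used for the
end-to-end distance z; bead radius, bead displacement in the trap and
trap height nearly cancel, and a constant `offset` parameter (default
0) is available.  Coverage values pushed past [0, 1] by noise are
clipped with a warning, not rejected.

Bookkeeping identities (extension factor 1.5 per 3-bp site,
0.34 nm/bp): L(t) = L(0) + L_R/3, φ = 2(L/L(0) − 1),
L_free = 3L(0) − 2L.

## Kinetic models

Rates: `kn` (nucleation per molecule, s⁻¹), `kg_fast` = k_g′ (fast
front, s⁻¹), `r` ∈ [0,1] (slow/fast ratio), with k_g = k_g′(1+r), and
microscopic counterparts n = k_n/(L₀/a), v = k_g·(L₀/a).

* Many-nuclei (fast-nucleation) limit: φ(t) = 1 − exp(−½k_n k_g t²).
  This solves the mean-field pair dN/dt = k_n(1−φ) − k_g N²/(1−φ),
  dφ/dt = k_g N exactly (the collision-term grouping is verified by a
  unit test substituting the closed form).  An optional extra coverage
  term k_n(1−φ) accounts for sites consumed by nucleation itself; it is
  off by default because it matters only when the nucleus count is
  comparable to the site count (~10⁴ sites vs <10 nuclei here).
* Single-domain (slow-nucleation) limit: a domain nucleated at uniform
  x covers min(k_g′t, x) + min(r k_g′t, 1−x); averaging over x gives the
  exact three-branch piecewise mean with breakpoints 1/k_g′ and
  1/(r k_g′) (continuous at both; r = 0 is rejected since the second
  breakpoint diverges).
* Arrhenius barrier differences, in k_BT: ΔE_coop = ln(k_g′/k_n·(L₀/a)²)
  (from k_n ∝ (L₀/a)e^(−E_n/k_BT), k_g′ ∝ (a/L₀)e^(−E_g^f/k_BT)) and
  ΔE_asym = −ln r.

## Stochastic simulator

Per step of δt = 0.5 s (default; halving changes the mean coverage by
<1%, verified by test): one Bernoulli nucleation attempt with
probability k_n(1−φ)δt at a uniform point of the undecorated set, fast
side chosen by fair coin; each fast front advances k_g′δt, each slow
front r·k_g′δt; fronts clip at the molecule ends and merging domains
keep their outer fronts.  The compiled engine tracks *gap lengths*
(free intervals with the closing speeds of their two bounding fronts)
rather than positions — exactly equivalent for the coverage, simpler,
and topology-agnostic.  Two substrate topologies are provided:

* `ends` (default): the tethered linear molecule.  Used for all data
  analysis and for comparison with the single-domain limit (itself an
  interval model).
* `periodic`: a circular substrate, the topology the many-nuclei
  mean-field limit assumes.  On the linear substrate that limit shows a
  genuine boundary deficit (sup-norm ~0.04 at k_g/k_n = 0.1; ~0.01 on
  the circle), so convergence checks against the sigmoid use
  `periodic`.

Time origin: `protein_addition` starts a bare molecule (stochastic
wait); `first_nucleation` places the first nucleus at t = 0, the
convention used when aligning trajectories at the first nucleation
event.  Reproducibility: a master seed spawns independent per-run
streams; identical per-run seeds give identical runs.  The Python
stepper (`simulate_once`) additionally logs events (collision times
interpolated within the step) and exact per-domain ground truth; the
event-driven propagator (`propagate_exact`) solves front trajectories
and collision times in closed form and is the reference for replays,
synthetic data and reconstruction.

## Trace decomposition

L(t) is fitted by a continuous piecewise-linear function.  Break times
are refined by coordinate descent (local bilinear least squares on the
window between neighbouring breaks, discrete candidate scan plus
bounded continuous refinement), converging when no break moves by more
than one sample interval — typically a handful of sweeps.  Raw data are
block-averaged before fitting (window configurable; the effective
choice depends on trace duration).  A break is flagged degenerate when
a two-segment fit fails an F-test against one segment at α = 0.01 on
its window — the significance threshold is the main bespoke decision
(the original analysis classified by eye) and is tunable.  For traces
ending before saturation, an optional virtual terminal break at the
extrapolated saturation time completes the pattern.

Scenario enumeration tracks the free substrate as a set of gaps:
nucleations (slope up) split a gap, collisions (slope down) close one
(domain–domain if both boundaries are fronts, domain–end otherwise);
complete traces close every gap, which forces Q = 2N_t + 1 break
points.  Each scenario yields a linear system in (x_i, v_i^L, v_i^R):
2N segment-slope equations (the sum of active front velocities equals
2·dL/dt/L(0) in naked-length fractions — covering dx of naked contour
adds dx/2 to L) plus N+1 position-closure equations, solved by least
squares (consistent and exact on noiseless data; rank-deficient systems
are flagged ambiguous).  Solutions with negative velocities,
out-of-range positions, or a nucleation outside its open gap are
rejected as unphysical; the remainder are ranked by the residual of the
forward-reconstructed L(t), an explicitly heuristic ranking since
mirror-image scenarios reproduce the data identically (the molecule's
orientation is unobservable; `dedupe_mirror` collapses such pairs).

## Rate inference

**B_N method.**  Nucleation is Poisson with density n per site·s on the
free length, so N = n·B_N with B_N the time integral of L_free (in
sites) from protein addition to the N-th nucleation (trapezoidal;
exact on grids containing the break times).  B_N is averaged across
experiments at each N and regressed on N; n̂ = 1/slope.  When every N
has ≥2 experiments the fit is weighted least squares with the known
across-experiment standard errors and the slope error comes from the
exact WLS covariance — a residual-based error from the few aggregated
points would be badly anti-conservative.

**χ² grid scan.**  Experimental coverage curves are aligned at their
first nucleation (ground-truth times if available, else a small
threshold crossing), interpolated to a common 5-s grid (model δt = 0.5 s
downsampled 10×), held at their end values, and truncated once every
trace has completed.  The objective is
χ² = Σ_t (φ̄_exp − φ̄_mod)²/(SD_exp²/n + SD_mod²/M) with the empirical
between-trace SD on the experimental side and the Monte-Carlo SD on the
model side (zero combined variance is floored at 1e-12 and logged).
The minimum is located by a three-stage zoom — coarse map (default 5
log-spaced k_n values × 5 log-spaced k_g′ values × linear r grid, step
0.1) at the smallest M, half-step refinement of the sub-threshold
region (coarse minimum + 10%, capped at 10 points; final r step 0.05),
and a final evaluation — with common random numbers within each stage
to stabilise the arg-min, and never gradient-based optimisers (the
stochastic objective produces spurious minima for them).  Scan steps
double as conservative error bars; a minimum on the coarse boundary is
flagged.

*Small-sample behaviour.*  With only 5 traces the estimator has known
quirks, mapped by simulation at the generating truth: after alignment
the early coverage growth of every trace is deterministic, so
near-zero-variance points effectively pin the *total* k_g = k_g′(1+r);
and because completion times are right-skewed, a 5-trace mean is
typically free of stragglers, which favours slightly larger r.  At the
default scan geometry the recovered r sits one scan step above a 0.10
truth (0.15, i.e. a fast:slow ratio of ~6.7 rather than 10) highly
reproducibly, while k_g is recovered within a few percent.
Sample-independent (model-SD-referenced) and floored weighting schemes
were evaluated and found substantially less stable at this sample size;
the empirical weighting above is what ships.  Conclusions about r from
ensembles this small should quote the scan-step error (±0.05).

## Synthetic data

`SynthSpec` defaults define the emulated study conditions: 5
experiments; naked lengths uniform on 10–17 μm (non-specific tethering
of λ-DNA shortens constructs); rates k_n = 1.05e-3 s⁻¹,
k_g′ = 5.27e-4 s⁻¹, r = 0.10 (so k_g = 5.8e-4 s⁻¹); 0.8 pN clamp with a
slow reflected random-walk jitter within ±0.1 pN (σ = 0.005 pN/sample),
mimicking periodic clamp adjustment; additive Gaussian position noise
σ = 0.05 μm on y only (per-trace noise amplitude is not otherwise
constrained; this value keeps most traces decomposable); 1 Hz sampling
(the instrument's 20 kHz stream is not emulated — data are generated
directly at the averaged-down rate).  The forward model is exact:
stochastic nucleation set → event-driven coverage → two-segment WLC at
the jittered force → noise; exact ground truth (coverage and domain
kinetics) is serialized alongside, and generation is byte-reproducible
given the seed.

Passing tests on these data demonstrate correctness of the inversion,
decomposition and inference *given the model*; they do not probe
baseline drift, tether rupture, bead-surface interactions, force-
calibration error, or RecA dissociation (binding is treated as
irreversible, the ATPγS situation), none of which the generator
emulates.

## Problem sizes and determinism

Default test and reproduction runs use ensembles of M = 1e3 (coarse
map) to 1e4 (refinement and final evaluation), 5-trace synthetic
ensembles, 100-replicate noise studies, and 200-replicate Poisson
checks; these sizes give scan-step-limited parameter resolution and
sub-percent Monte-Carlo error on mean coverage.  Every stochastic
output is reproducible from a single integer seed.

## Known limitations

* The fast-front direction (5′→3′ vs 3′→5′) is not identified — the
  measurement cannot orient the molecule; only speeds are inferred.
* Scenario multiplicity grows quickly with domain count; beyond ~3
  domains many feasible scenarios survive and the residual ranking is
  only a heuristic.
* `A_R` is a single scalar; molecule-to-molecule stiffness variation
  propagates directly into coverage scale errors.
* The χ² fit assumes all traces share one (k_n, k_g′, r); real
  constructs differ in L(0) and hence in per-molecule rates.
* Parameter errors are scan steps, i.e. upper bounds, not confidence
  intervals from χ² level sets.
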