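"""Ground-truth synthetic experiments emulating the force-clamp assay.

No public deposition of the raw traces exists, so every pipeline stage
is exercised against synthetic experiments whose statistical structure
mirrors the study conditions: lambda-DNA-scale constructs with variable
naked contour length (non-specific tethering), a 0.8 pN force clamp
with slow +/-0.1 pN adjustment jitter, stepwise L(t) growth produced by
a few asymmetric nucleation-and-growth domains, saturation at
1.5 L(0), additive Gaussian position noise, and an effective 1-10 Hz
sampling rate.

The forward model is exact: a stochastic run of the simulator supplies
the nucleation set, the event-driven propagator turns it into an exact
piecewise-linear coverage trajectory, the two-segment WLC maps coverage
to end-to-end distance at the jittered clamp force, and Gaussian noise
is added to the trap-anchor distance only.  The exact ground truth
(coverage curve and per-domain kinetics) is returned/serialized next to
each trace.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kinetics import RateParams
from .simulate import DomainKinetics, SimConfig, propagate_exact, simulate_once
from .wlc import (
    CoverageCurve,
    FilamentGeometry,
    ForceExtensionTrace,
    WLCParams,
    two_segment_extension,
)

__all__ = [
    "SynthSpec",
    "SyntheticExperiment",
    "make_experiment",
    "make_ensemble",
    "make_coverage_traces",
]


@dataclass(frozen=True)
class SynthSpec:
    """Study-condition defaults for the synthetic-experiment generator.

    Defaults reproduce the measured assembly conditions: rates at the
    Monte-Carlo best fit (kn = 1.05e-3 1/s, kg' = 5.27e-4 1/s, r = 0.10,
    so kg = kg'(1+r) = 5.8e-4 1/s), force clamped at 0.8 +/- 0.1 pN, and
    naked contour lengths drawn uniformly from 10-17 um (tethering at
    internal lambda-DNA sites shortens the construct).  ``noise_sd`` is
    a free parameter of the emulation (per-trace noise amplitude is not
    reported); 0.05 um keeps the break-point decomposition solvable on
    most traces, mirroring the fraction of analyzable experiments.
    """

    n_experiments: int = 5
    L_initial_range: tuple = (10.0, 17.0)
    rates: RateParams = field(
        default_factory=lambda: RateParams(kn=1.05e-3, kg_fast=5.27e-4, r=0.10)
    )
    force_clamp: float = 0.8
    force_jitter: float = 0.1
    force_walk_sd: float = 0.005  # pN per sample: slow clamp-adjustment wander
    noise_sd: float = 0.05
    sample_rate_hz: float = 1.0
    dt: float = 0.5
    t_max: float = 20000.0
    seed: int = 0
    wlc: WLCParams = field(default_factory=WLCParams)

    def __post_init__(self) -> None:
        if self.n_experiments < 1 or self.sample_rate_hz <= 0 or self.noise_sd < 0:
            raise ValueError("invalid synthetic spec")


def make_coverage_traces(
    rates: RateParams,
    n_traces: int,
    seed: int,
    t_max: float = 20000.0,
    dt: float = 0.5,
):
    """Raw simulator coverage traces for ensemble-level fitting.

    Runs ``n_traces`` independent stochastic assemblies (time origin at
    protein addition) and returns ``(curves, t_first)`` where each curve
    is a ``(t, phi)`` pair and ``t_first`` the ground-truth time of the
    first nucleation event, used to align the traces.  This is the
    coverage-level counterpart of :func:`make_experiment` (no mechanics
    or noise layer), the input the chi^2 grid-scan fit expects.
    """
    rng = np.random.default_rng(seed)
    curves, t_first = [], []
    for _ in range(n_traces):
        cfg = SimConfig(rates=rates, t_max=t_max, dt=dt, seed=int(rng.integers(2**31)))
        run = simulate_once(cfg, np.random.default_rng(cfg.seed))
        curves.append((run.t, run.phi))
        t_first.append(run.nucleations[0].t if run.nucleations else 0.0)
    return curves, t_first


@dataclass
class SyntheticExperiment:
    """One synthetic construct: raw trace plus exact ground truth."""

    trace: ForceExtensionTrace
    curve: CoverageCurve  # noise-free ground truth
    kinetics: list  # ground-truth DomainKinetics (fractions of L0)
    geometry: FilamentGeometry
    seed: int


def make_experiment(spec: SynthSpec, rng: np.random.Generator) -> SyntheticExperiment:
    """Generate one synthetic force-clamp experiment.

    simulate_once supplies the stochastic nucleation set; the exact
    propagator yields phi(t); the two-segment WLC (naked part of contour
    L0 (1-phi), decorated part 1.5 phi L0) gives z(t) at the jittered
    force; y = z + Gaussian noise.
    """
    seed = int(rng.integers(2**31))
    sub = np.random.default_rng(seed)
    L0 = float(sub.uniform(*spec.L_initial_range))
    geom = FilamentGeometry(L_initial=L0)

    config = SimConfig(rates=spec.rates, t_max=spec.t_max, dt=spec.dt, seed=seed)
    run = simulate_once(config, sub)
    kin = run.domains
    t_done = run.t[np.argmax(run.phi >= 1.0)] if np.any(run.phi >= 1.0) else spec.t_max
    pw = propagate_exact(kin, t_end=float(t_done))

    t = np.arange(0.0, t_done + 1e-9, 1.0 / spec.sample_rate_hz)
    phi = pw.phi_at(t)
    L = L0 * (1.0 + phi / 2.0)
    curve = CoverageCurve.from_length(t, L, L0)

    # slow clamp-adjustment force wander, reflected into the +/- jitter band
    steps = sub.normal(0.0, spec.force_walk_sd, size=t.size)
    F = spec.force_clamp + np.clip(
        np.cumsum(steps), -spec.force_jitter, spec.force_jitter
    )
    L_free_naked = L0 * (1.0 - phi)
    L_R = 1.5 * phi * L0
    z = two_segment_extension(F, L_free_naked, L_R, spec.wlc)
    y = z + sub.normal(0.0, spec.noise_sd, size=t.size)
    trace = ForceExtensionTrace(t, F, y)
    return SyntheticExperiment(trace, curve, kin, geom, seed)


def make_ensemble(spec: SynthSpec, outdir: str | Path | None = None):
    """Generate ``spec.n_experiments`` experiments plus a manifest.

    Deterministic given ``spec.seed`` (same seed -> byte-identical
    files).  With ``outdir`` set, writes per-experiment trace TSVs,
    ground-truth coverage TSVs and kinetics JSONs, and a manifest
    listing every file with its SHA-256 checksum and the seeds used.
    Returns ``(experiments, manifest)``.
    """
    rng = np.random.default_rng(spec.seed)
    experiments = [make_experiment(spec, rng) for _ in range(spec.n_experiments)]

    manifest: dict = {
        "seed": spec.seed,
        "n_experiments": spec.n_experiments,
        "rates": {
            "kn": spec.rates.kn,
            "kg_fast": spec.rates.kg_fast,
            "r": spec.rates.r,
        },
        "experiment_seeds": [e.seed for e in experiments],
        "files": {},
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, e in enumerate(experiments):
            stem = f"exp{i:02d}"
            e.trace.to_tsv(outdir / f"{stem}_trace.tsv")
            e.curve.to_tsv(
                outdir / f"{stem}_truth.tsv",
                sidecar={"seed": e.seed, "n_sites": e.geometry.n_sites},
            )
            truth = {
                "L_initial_um": e.geometry.L_initial,
                "domains": [dataclasses.asdict(k) for k in e.kinetics],
            }
            (outdir / f"{stem}_kinetics.json").write_text(json.dumps(truth, indent=1))
        for p in sorted(outdir.iterdir()):
            if p.name == "manifest.json":
                continue
            manifest["files"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return experiments, manifest
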