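"""Worm-like-chain mechanics of partially RecA-decorated dsDNA.

RecA polymerizes on double-stranded DNA, extending each occupied 3-bp
binding site to about 1.5x its naked contour length and stiffening the
filament (persistence length ~1200 nm vs ~50 nm for naked dsDNA).  In a
force-clamp optical-tweezers experiment the trap-anchor distance ``y(t)``
and the clamp force ``F(t)`` are recorded while protein assembles; this
module converts such traces into the total contour length ``L(t)`` and the
coverage fraction ``phi(t)`` using a two-segment (mixed-stiffness)
worm-like-chain model.

Conventions
-----------
* contour lengths and extensions in micrometres (um)
* persistence lengths in nanometres (nm)
* forces in piconewtons (pN); thermal energy kBT in pN*nm
* coverage ``phi`` is the decorated fraction of the *naked* contour length.

With ``L(0)`` the naked contour length and ``L_R`` the contour length of
the decorated (RecA-coated) portion, the bookkeeping identities are::

    L(t)    = L(0) + L_R/3          (each decorated unit is 1.5x longer)
    phi     = 2*(L/L(0) - 1)
    L_free  = 3*L(0) - 2*L          (undecorated naked length)

so full coverage corresponds to L = 1.5*L(0).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "KB_PN_NM",
    "BP_NM",
    "WLCParams",
    "FilamentGeometry",
    "ForceExtensionTrace",
    "CoverageCurve",
    "wlc_force",
    "wlc_extension",
    "fractional_extension_large_force",
    "two_segment_extension",
    "decorated_length_from_trace",
    "coverage_from_length",
]

#: Boltzmann constant in pN*nm/K (1.380649e-23 J/K).
KB_PN_NM = 1.380649e-2

#: Contour rise per base pair of naked B-form dsDNA, nm.
BP_NM = 0.34


@dataclass(frozen=True)
class WLCParams:
    """Elastic parameters of the naked and RecA-coated filament.

    Parameters
    ----------
    A0 : float
        Persistence length of naked dsDNA, nm.
    AR : float
        Persistence length of the fully decorated RecA-dsDNA filament, nm.
        Must exceed ``A0`` (the filament is much stiffer than bare DNA).
    temperature : float
        Absolute temperature, K.  The default (310.15 K = 37 C) is the
        assembly temperature used throughout.
    """

    A0: float = 50.0
    AR: float = 1200.0
    temperature: float = 310.15

    def __post_init__(self) -> None:
        if not self.A0 > 0:
            raise ValueError("A0 must be positive")
        if not self.AR > self.A0:
            raise ValueError("AR must exceed A0 (decorated filament is stiffer)")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")

    @property
    def kBT(self) -> float:
        """Thermal energy, pN*nm."""
        return KB_PN_NM * self.temperature


@dataclass(frozen=True)
class FilamentGeometry:
    """Geometry of one dsDNA construct.

    Parameters
    ----------
    L_initial : float
        Naked contour length L(0), um.  Varies between constructs because
        tethering can occur at internal sites of the lambda-DNA.
    site_length_bp : int
        Binding-site size of one RecA monomer in base pairs (default 3).
    extension_factor : float
        Decorated/naked contour-length ratio per occupied site (default 1.5).
    """

    L_initial: float
    site_length_bp: int = 3
    extension_factor: float = 1.5

    def __post_init__(self) -> None:
        if not self.L_initial > 0:
            raise ValueError("L_initial must be positive")
        if not self.extension_factor > 1:
            raise ValueError("extension_factor must exceed 1")

    @property
    def site_length_um(self) -> float:
        """Naked contour length of one binding site, um."""
        return self.site_length_bp * BP_NM / 1000.0

    @property
    def n_sites(self) -> int:
        """Number of RecA binding sites, L0/a."""
        return int(round(self.L_initial / self.site_length_um))


@dataclass
class ForceExtensionTrace:
    """Raw force-clamp trace: time, force, trap-anchor distance.

    The end-to-end distance z is approximated by the measured trap-anchor
    distance ``y`` (bead radius, bead displacement in the trap and trap
    height corrections nearly cancel and are neglected; an optional
    constant ``offset`` is available).
    """

    t: np.ndarray
    F: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.F.shape == self.y.shape):
            raise ValueError("t, F, y must have equal length")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")

    def in_clamp_band(self, F0: float = 0.8, tol: float = 0.1) -> np.ndarray:
        """Boolean mask of samples inside the force-clamp band F0 +/- tol."""
        return np.abs(self.F - F0) <= tol

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"t_s": self.t, "F_pN": self.F, "y_um": self.y}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ForceExtensionTrace":
        df = pd.read_csv(path, sep="\t")
        return cls(df["t_s"].to_numpy(), df["F_pN"].to_numpy(), df["y_um"].to_numpy())


@dataclass
class CoverageCurve:
    """Contour-length and coverage kinetics of one construct."""

    t: np.ndarray
    L: np.ndarray
    phi: np.ndarray
    L_free: np.ndarray
    L_initial: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.L_free = np.asarray(self.L_free, dtype=float)

    @classmethod
    def from_length(cls, t, L, L_initial: float) -> "CoverageCurve":
        """Build a curve from L(t), filling phi and L_free by the identities."""
        L = np.asarray(L, dtype=float)
        phi = coverage_from_length(L, L_initial)
        L_free = 3.0 * L_initial - 2.0 * L
        return cls(np.asarray(t, float), L, phi, L_free, float(L_initial))

    def to_tsv(self, path: str | Path, sidecar: dict | None = None) -> None:
        """Write the curve as TSV plus a JSON sidecar with metadata."""
        path = Path(path)
        pd.DataFrame(
            {"t_s": self.t, "L_um": self.L, "phi": self.phi, "Lfree_um": self.L_free}
        ).to_csv(path, sep="\t", index=False)
        meta = {"L_initial_um": self.L_initial}
        if sidecar:
            meta.update(sidecar)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CoverageCurve":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            df["t_s"].to_numpy(),
            df["L_um"].to_numpy(),
            df["phi"].to_numpy(),
            df["Lfree_um"].to_numpy(),
            float(meta["L_initial_um"]),
        )


def wlc_force(z_rel, params: WLCParams, A: float):
    """Interpolation formula for the WLC force at relative extension z/L.

    F = kBT/A * [ z/L + 1/(4 (1 - z/L)^2) - 1/4 ]   (pN, A in nm)

    Strictly increasing in ``z_rel``; diverges as z/L -> 1, so ``z_rel``
    must lie in [0, 1).
    """
    z_rel = np.asarray(z_rel, dtype=float)
    if np.any(z_rel < 0) or np.any(z_rel >= 1):
        raise ValueError("relative extension must satisfy 0 <= z/L < 1")
    out = params.kBT / A * (z_rel + 0.25 / (1.0 - z_rel) ** 2 - 0.25)
    return float(out) if out.ndim == 0 else out


def wlc_extension(F: float, A: float, L: float, params: WLCParams) -> float:
    """Numerically invert the WLC interpolation formula.

    Returns the unique end-to-end distance z in [0, L) with
    ``wlc_force(z/L) = F`` (bracketed root finding, relative tolerance
    1e-10).  ``F`` must be positive.
    """
    if not F > 0:
        raise ValueError("force must be positive")
    f = lambda x: params.kBT / A * (x + 0.25 / (1.0 - x) ** 2 - 0.25) - F
    x = brentq(f, 0.0, 1.0 - 1e-14, rtol=1e-12, xtol=1e-15)
    return x * L


def fractional_extension_large_force(F, params: WLCParams, A: float):
    """Large-force fractional extension 1 - sqrt(kBT / (4 F A)).

    This is the closed-form branch of the WLC used throughout the
    mixed-filament inversion; at the 0.8 pN clamp it gives the familiar
    ~84% fractional extension of naked dsDNA.
    """
    F = np.asarray(F, dtype=float)
    out = 1.0 - np.sqrt(params.kBT / (4.0 * F * A))
    return float(out) if out.ndim == 0 else out


def two_segment_extension(F, L_free_naked, L_R, params: WLCParams):
    """End-to-end distance of a mixed naked/decorated filament.

    Both segments carry the same tension ``F``; in the large-force regime
    each contributes its contour length times its fractional extension:

        z = L_free * (1 - C0) + L_R * (1 - CR),
        C0 = sqrt(kBT / (4 F A0)),  CR = sqrt(kBT / (4 F AR)).

    ``L_free_naked`` is the undecorated naked contour length (um) and
    ``L_R`` the decorated contour length (um).  This is the exact forward
    counterpart of :func:`decorated_length_from_trace`.
    """
    c0 = 1.0 - fractional_extension_large_force(F, params, params.A0)
    cR = 1.0 - fractional_extension_large_force(F, params, params.AR)
    out = np.asarray(L_free_naked, float) * (1.0 - c0) + np.asarray(L_R, float) * (1.0 - cR)
    return float(out) if out.ndim == 0 else out


def coverage_from_length(L, L_initial: float):
    """Coverage fraction phi = 2 (L/L0 - 1), clipped to [0, 1].

    Measurement noise can push L slightly below L0 or past the 1.5*L0
    saturation value; such samples are clipped (with a one-time warning)
    rather than rejected.
    """
    L = np.asarray(L, dtype=float)
    phi = 2.0 * (L / L_initial - 1.0)
    if np.any(phi < -1e-9) or np.any(phi > 1.0 + 1e-9):
        warnings.warn(
            "coverage outside [0, 1] clipped (noise beyond L0 or saturation)",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.clip(phi, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def decorated_length_from_trace(
    trace: ForceExtensionTrace,
    geom: FilamentGeometry,
    params: WLCParams,
    offset: float = 0.0,
) -> CoverageCurve:
    """Convert a force-clamp trace into contour-length/coverage kinetics.

    Inverts the two-segment large-force WLC model sample by sample:

        L_R = (z - L(0) (1 - C0)) / (1/3 + (2/3) C0 - CR)

    with C0, CR as in :func:`two_segment_extension`, then maps to the
    total contour length L = L(0) + L_R/3 and the coverage fraction.
    The end-to-end distance is taken as ``z = y + offset`` (default
    offset 0; bead-size and trap-height corrections nearly cancel).

    Raises
    ------
    ValueError
        If the denominator is not positive (AR <= A0 or force too low for
        the large-force branch).
    """
    z = trace.y + offset
    c0 = np.sqrt(params.kBT / (4.0 * trace.F * params.A0))
    cR = np.sqrt(params.kBT / (4.0 * trace.F * params.AR))
    denom = 1.0 / 3.0 + (2.0 / 3.0) * c0 - cR
    if np.any(denom <= 0):
        raise ValueError(
            "two-segment inversion denominator <= 0: requires AR > A0 and a "
            "force high enough for the large-force WLC branch"
        )
    L_R = (z - geom.L_initial * (1.0 - c0)) / denom
    L = geom.L_initial + L_R / 3.0
    return CoverageCurve.from_length(trace.t, L, geom.L_initial)
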