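"""Worm-like-chain mechanics and tether geometry.

A DNA molecule is tethered to a surface by both ends (anchor separation
``D``) and pulled at its midpoint, perpendicular to the anchor line, by a
protein ring.  The chain tension follows the Marko–Siggia interpolation
formula for a worm-like chain; the force transmitted through the ring is
set by the V-shaped geometry of the stretched tether.  A second geometry,
in which the ring couples the surface-tethered DNA to a second DNA pulled
from the bead side, is described by a five-equation nonlinear system that
this module reduces to a single monotone scalar equation and solves with
a safeguarded bracketing root finder.

Internal units are pN, nm and s throughout; thermal energy defaults to
k_B·T = 4.114 pN·nm (298 K).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "KBT_ROOM_PN_NM",
    "OVERSTRETCH_MARGIN",
    "WLCParams",
    "LAMBDA_DNA",
    "M13_PLASMID",
    "TetherGeometry",
    "TwoDnaState",
    "OverstretchError",
    "TwoDnaConvergenceError",
    "wlc_force",
    "tether_geometry",
    "solve_two_dna",
    "two_dna_residuals",
]

#: Thermal energy at 298 K in pN·nm.
KBT_ROOM_PN_NM = 4.114

#: Relative margin below the contour length beyond which the inextensible
#: chain model is considered invalid (lengths in [L0*(1-margin), L0] raise
#: :class:`OverstretchError` rather than being clamped).
OVERSTRETCH_MARGIN = 1e-6


class OverstretchError(ValueError):
    """Chain extension at or beyond the worm-like-chain validity limit."""


class TwoDnaConvergenceError(RuntimeError):
    """Two-DNA solver failed to reach the requested residual tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (last residual {residual:.3e})")
        self.residual = residual


@dataclass(frozen=True)
class WLCParams:
    """Worm-like chain parameters of one DNA tether.

    Defaults are those of a λ-DNA tether: persistence length 50 nm,
    contour length 16.32 µm.
    """

    persistence_length_nm: float = 50.0
    contour_length_nm: float = 16320.0

    def __post_init__(self) -> None:
        if not self.persistence_length_nm > 0:
            raise ValueError("persistence_length_nm must be positive")
        if not self.contour_length_nm > 0:
            raise ValueError("contour_length_nm must be positive")

    @property
    def max_length_nm(self) -> float:
        """Largest extension accepted before an overstretch error."""
        return self.contour_length_nm * (1.0 - OVERSTRETCH_MARGIN)


#: λ-DNA defaults used throughout the pulling experiments.
LAMBDA_DNA = WLCParams()

#: 7.2 kb M13mp18 plasmid (0.34 nm/bp), the second DNA captured by the ring
#: and pulled from the bead side in the two-DNA geometry.
M13_PLASMID = WLCParams(persistence_length_nm=50.0, contour_length_nm=2450.0)


@dataclass(frozen=True)
class TetherGeometry:
    """Resolved state of a single doubly-tethered DNA pulled at its middle.

    ``half_angle_rad`` is the angle α between each DNA arm and the anchor
    line; the ring force is ``2 F_DNA sin α``.
    """

    anchor_distance_nm: float
    displacement_nm: float
    dna_length_nm: float
    half_angle_rad: float
    dna_tension_pn: float
    ring_force_pn: float


@dataclass(frozen=True)
class TwoDnaState:
    """Solution of the coupled two-DNA geometry.

    DNA-1 is the bead-proximal chain pulled straight toward the bead;
    DNA-2 is the surface-tethered chain forming the V.  ``(π/2 − α)`` is
    the angle between the two DNAs at the ring.
    """

    f1_pn: float
    l1_nm: float
    f2_pn: float
    l2_nm: float
    half_angle_rad: float
    displacement_nm: float
    residual_norm: float


def _wlc_force_raw(length_frac, kbt_over_p):
    """Marko–Siggia force at fractional extension ``length_frac`` = L/L0.

    No domain checks; used by the vectorised simulator on pre-screened
    inputs.  Accepts scalars or arrays.
    """
    one_minus = 1.0 - length_frac
    return kbt_over_p * (0.25 / (one_minus * one_minus) - 0.25 + length_frac)


def wlc_force(wlc: WLCParams, length_nm, thermal_energy_pn_nm: float = KBT_ROOM_PN_NM):
    """Tension of a worm-like chain at end-to-end extension ``length_nm``.

    Implements the Marko–Siggia interpolation
    ``F = (kBT/P) * (1/(4 (1 - L/L0)^2) - 1/4 + L/L0)``,
    which is zero at L = 0, strictly increasing, and diverges as L → L0.

    Parameters
    ----------
    wlc : WLCParams
    length_nm : float or ndarray
        Extension, 0 ≤ L < L0.
    thermal_energy_pn_nm : float
        k_B·T in pN·nm.

    Returns
    -------
    float or ndarray
        Tension in pN.
    """
    if thermal_energy_pn_nm <= 0:
        raise ValueError("thermal_energy_pn_nm must be positive")
    length_nm = np.asarray(length_nm, dtype=float)
    if np.any(length_nm < 0):
        raise ValueError("extension must be non-negative")
    if np.any(length_nm >= wlc.max_length_nm):
        raise OverstretchError(
            "extension at or beyond contour length: overstretched beyond WLC validity"
        )
    out = _wlc_force_raw(
        length_nm / wlc.contour_length_nm,
        thermal_energy_pn_nm / wlc.persistence_length_nm,
    )
    return float(out) if out.ndim == 0 else out


def tether_geometry(
    anchor_distance_nm: float,
    displacement_nm: float,
    wlc: WLCParams = LAMBDA_DNA,
    thermal_energy_pn_nm: float = KBT_ROOM_PN_NM,
) -> TetherGeometry:
    """Resolve the V-geometry of a doubly-anchored DNA pulled at its middle.

    The chain length follows from the anchor separation ``D`` and the
    perpendicular midpoint displacement ``x`` as ``L = 2 sqrt((D/2)^2 + x^2)``;
    the half-angle obeys ``tan α = 2x/D`` and the force on the ring is
    ``2 F_DNA sin α``.  A signed displacement is accepted (the geometry is
    mirror symmetric); |x| is used.
    """
    if anchor_distance_nm <= 0:
        raise ValueError("anchor_distance_nm must be positive")
    x = abs(float(displacement_nm))
    d = float(anchor_distance_nm)
    length = float(np.hypot(d, 2.0 * x))
    if length >= wlc.max_length_nm:
        raise OverstretchError(
            f"tether length {length:.1f} nm reaches the contour length "
            f"{wlc.contour_length_nm:.1f} nm: pull exceeds the inextensible-chain limit"
        )
    f_dna = wlc_force(wlc, length, thermal_energy_pn_nm)
    sin_a = 2.0 * x / length
    return TetherGeometry(
        anchor_distance_nm=d,
        displacement_nm=x,
        dna_length_nm=length,
        half_angle_rad=float(np.arcsin(min(sin_a, 1.0))),
        dna_tension_pn=f_dna,
        ring_force_pn=2.0 * f_dna * sin_a,
    )


def _two_dna_l2(anchor_distance_nm, x_minus_l1):
    # eqs 4 & 5 of the system imply L2 = sqrt(D^2 + 4 (x - L1)^2) exactly:
    # the surface chain forms the same V as the single-tether case, with the
    # apex displaced by (x - L1).
    return np.hypot(anchor_distance_nm, 2.0 * x_minus_l1)


def solve_two_dna(
    anchor_distance_nm: float,
    displacement_nm: float,
    wlc1: WLCParams = LAMBDA_DNA,
    wlc2: WLCParams = LAMBDA_DNA,
    thermal_energy_pn_nm: float = KBT_ROOM_PN_NM,
    tol: float = 1e-8,
) -> TwoDnaState:
    """Solve the coupled two-DNA pulling geometry.

    The ring couples a straight bead-proximal chain (DNA-1, extension L1,
    tension F1) to the surface-tethered V (DNA-2, extension L2, tension F2).
    The five relations are::

        F1 = WLC1(L1)
        F2 = WLC2(L2)
        F1 = 2 F2 sin α          (force balance at the ring)
        (L2/2) sin α + L1 = x    (geometric closure)
        tan α = 2 (x - L1) / D

    The last two eliminate L2 and α in closed form, leaving one strictly
    increasing scalar equation in L1 that is bracket-solved with Brent's
    method.  The returned ``residual_norm`` is the maximum scaled residual
    of the five equations at the solution.

    Raises
    ------
    OverstretchError
        If no root exists with both chains below their contour lengths.
    TwoDnaConvergenceError
        If the root does not satisfy ``residual_norm <= tol``.
    """
    if anchor_distance_nm <= 0:
        raise ValueError("anchor_distance_nm must be positive")
    if displacement_nm < 0:
        raise ValueError("displacement_nm must be non-negative")
    if tol <= 0:
        raise ValueError("tol must be positive")
    d = float(anchor_distance_nm)
    x = float(displacement_nm)
    kbt = thermal_energy_pn_nm

    if d >= wlc2.max_length_nm:
        raise OverstretchError("anchor separation exceeds DNA-2 contour length")

    if x == 0.0:
        # Slack configuration: no force through the ring, DNA-2 spans D.
        state = TwoDnaState(
            f1_pn=0.0,
            l1_nm=0.0,
            f2_pn=wlc_force(wlc2, d, kbt),
            l2_nm=d,
            half_angle_rad=0.0,
            displacement_nm=0.0,
            residual_norm=0.0,
        )
        return state

    def g(l1: float) -> float:
        xm = x - l1
        l2 = _two_dna_l2(d, xm)
        sin_a = 2.0 * xm / l2
        f1 = _wlc_force_raw(l1 / wlc1.contour_length_nm, kbt / wlc1.persistence_length_nm)
        f2 = _wlc_force_raw(l2 / wlc2.contour_length_nm, kbt / wlc2.persistence_length_nm)
        return f1 - 2.0 * f2 * sin_a

    lo = 0.0
    # If at L1 = 0 the surface chain would be overstretched, raise the lower
    # bracket to the point where L2 = L2_max (F2 → ∞ there, so g < 0 still).
    l2_at_zero = _two_dna_l2(d, x)
    if l2_at_zero >= wlc2.max_length_nm:
        lo = x - 0.5 * np.sqrt(wlc2.max_length_nm**2 - d * d)
    hi = min(x, wlc1.max_length_nm)
    if not lo < hi:
        raise OverstretchError(
            "no physical two-DNA configuration: both chains at contour length"
        )
    # Nudge off the singular endpoints.
    eps = 1e-12 * max(x, d)
    lo = lo + eps if lo > 0 else lo
    hi = hi - eps
    if g(hi) < 0.0:  # pragma: no cover - hi is either x (g>0) or L1 overstretched
        raise OverstretchError("no root: bead-proximal chain at contour length")

    l1 = brentq(g, lo, hi, xtol=1e-12 * max(x, 1.0), rtol=8.9e-16, maxiter=200)
    xm = x - l1
    l2 = _two_dna_l2(d, xm)
    sin_a = 2.0 * xm / l2
    alpha = float(np.arcsin(min(sin_a, 1.0)))
    f1 = wlc_force(wlc1, l1, kbt)
    f2 = wlc_force(wlc2, l2, kbt)
    state = TwoDnaState(
        f1_pn=f1,
        l1_nm=float(l1),
        f2_pn=f2,
        l2_nm=float(l2),
        half_angle_rad=alpha,
        displacement_nm=x,
        residual_norm=0.0,
    )
    res = float(
        np.max(np.abs(two_dna_residuals(state, d, x, wlc1, wlc2, kbt)))
    )
    state = dataclasses.replace(state, residual_norm=res)
    if res > tol:
        raise TwoDnaConvergenceError("two-DNA solve did not meet tolerance", res)
    return state


def two_dna_residuals(
    state: TwoDnaState,
    anchor_distance_nm: float,
    displacement_nm: float,
    wlc1: WLCParams = LAMBDA_DNA,
    wlc2: WLCParams = LAMBDA_DNA,
    thermal_energy_pn_nm: float = KBT_ROOM_PN_NM,
) -> np.ndarray:
    """Scaled residuals of the five two-DNA equations at a candidate state.

    Force-balance residuals are scaled by (1 + |F|), length residuals by
    (1 + x); used both as the solver's convergence check and as an
    independent self-consistency probe in tests.
    """
    d = anchor_distance_nm
    x = displacement_nm
    f1, l1, f2, l2, a = state.f1_pn, state.l1_nm, state.f2_pn, state.l2_nm, state.half_angle_rad
    sin_a, tan_a = np.sin(a), np.tan(a)
    r = np.array(
        [
            (f1 - wlc_force(wlc1, l1, thermal_energy_pn_nm)) / (1.0 + abs(f1)),
            (f2 - wlc_force(wlc2, l2, thermal_energy_pn_nm)) / (1.0 + abs(f2)),
            (f1 - 2.0 * f2 * sin_a) / (1.0 + abs(f1)),
            (0.5 * l2 * sin_a + l1 - x) / (1.0 + x),
            (tan_a - 2.0 * (x - l1) / d) / (1.0 + tan_a),
        ]
    )
    return r
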