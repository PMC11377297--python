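"""Monte-Carlo simulation of ring rupture under constant-velocity pulling.

Each simulated pulling event advances the perpendicular displacement ``x``
of the ring by ``v·dt`` per time step, resolves the tether geometry to get
the force transmitted through the ring, converts that force to a
dissociation rate with the Bell model ``k(F) = k0·exp(δ F / kBT)``, draws a
candidate detachment time ``t_detach = -ln(1 - r)/k`` from a uniform
variate ``r``, and records a rupture in the first step where
``t_detach <= dt``.  The anchor separation ``D`` is redrawn per event from
a truncated normal distribution.

The engine is vectorised over events; one uniform variate is consumed per
event slot per step regardless of how many events are still running, so
two runs with the same seed see an identical random field even when the
bond parameters differ (common random numbers, which the fitting module
relies on).

Two pulling geometries are supported: the single-DNA V geometry, and the
two-DNA geometry in which the ring couples a bead-proximal chain to the
surface-tethered V (solved per step via the monotone scalar reduction of
the five-equation system, warm-started from the previous step).  A
constant-force-ramp mode that bypasses the polymer mechanics entirely is
provided as a closed-form testbed (Bell–Evans theory applies there).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .polymer import (
    KBT_ROOM_PN_NM,
    LAMBDA_DNA,
    M13_PLASMID,
    WLCParams,
    _wlc_force_raw,
)

__all__ = [
    "BondModel",
    "PullingProtocol",
    "RuptureEvent",
    "RuptureSample",
    "MAX_BELL_EXPONENT",
    "dissociation_rate",
    "detachment_time",
    "simulate_single_pull",
    "simulate_rupture_distribution",
    "simulate_two_dna_pull",
    "simulate_constant_ramp",
    "bell_evans_most_probable_force",
    "PAPER_PROTOCOL",
]

logger = logging.getLogger(__name__)

#: Bell exponent above which the rate is capped (rupture is then certain
#: within any reasonable time step); prevents floating-point overflow.
MAX_BELL_EXPONENT = 500.0


@dataclass(frozen=True)
class BondModel:
    """Bell-model parameters of the ring's load-bearing interface.

    ``k0_per_s`` is the spontaneous (zero-force) disengagement rate and
    ``delta_nm`` the mechanical displacement parameter coupling force to
    the rate: ``k(F) = k0 exp(δ F / kBT)``.
    """

    k0_per_s: float
    delta_nm: float

    def __post_init__(self) -> None:
        if not self.k0_per_s > 0:
            raise ValueError("k0_per_s must be positive")
        if self.delta_nm < 0:
            raise ValueError("delta_nm must be non-negative")


@dataclass(frozen=True)
class PullingProtocol:
    """Constant-velocity pulling protocol and anchor-distance statistics.

    Defaults reproduce the optical-tweezers assay conditions: pulling
    speed 0.16 µm/s, anchor separation ~ Normal(8.8, 0.5) µm truncated to
    (0.1, 0.95) of the contour length, time step 0.01 s, thermal energy
    4.114 pN·nm, ring starting on the anchor line (x0 = 0).
    """

    velocity_nm_per_s: float = 160.0
    dt_s: float = 0.01
    anchor_distance_mean_nm: float = 8800.0
    anchor_distance_sd_nm: float = 500.0
    thermal_energy_pn_nm: float = KBT_ROOM_PN_NM
    initial_displacement_nm: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.velocity_nm_per_s > 0:
            raise ValueError("velocity_nm_per_s must be positive")
        if not self.dt_s > 0:
            raise ValueError("dt_s must be positive")
        if self.anchor_distance_sd_nm < 0:
            raise ValueError("anchor_distance_sd_nm must be non-negative")
        if not self.thermal_energy_pn_nm > 0:
            raise ValueError("thermal_energy_pn_nm must be positive")


#: Protocol with all published experimental settings.
PAPER_PROTOCOL = PullingProtocol()


@dataclass(frozen=True)
class RuptureEvent:
    """A single simulated pulling event."""

    rupture_force_pn: float
    rupture_time_s: float
    displacement_at_rupture_nm: float
    anchor_distance_nm: float
    orientation_delta_nm: float
    censored: bool = False


@dataclass
class RuptureSample:
    """A collection of rupture forces with summary statistics.

    ``forces_pn`` holds the uncensored rupture forces; events that reached
    the chain-extension limit without rupturing are excluded but counted
    in ``n_censored``.  ``events`` optionally carries the full per-event
    table (columns ``event_id, force_pN, time_s, D_um, delta_nm,
    censored``).
    """

    forces_pn: np.ndarray
    n_censored: int = 0
    events: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.forces_pn = np.asarray(self.forces_pn, dtype=float).ravel()

    @property
    def n(self) -> int:
        return self.forces_pn.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.forces_pn))

    @property
    def std(self) -> float:
        return float(np.std(self.forces_pn, ddof=1))

    @property
    def median(self) -> float:
        return float(np.median(self.forces_pn))

    @classmethod
    def from_forces(cls, forces, n_censored: int = 0) -> "RuptureSample":
        return cls(forces_pn=np.asarray(forces, dtype=float), n_censored=n_censored)


def dissociation_rate(
    bond: BondModel, force_pn, thermal_energy_pn_nm: float = KBT_ROOM_PN_NM
):
    """Bell-model dissociation rate ``k0 exp(δ F / kBT)``.

    Exponents above :data:`MAX_BELL_EXPONENT` are capped with a warning;
    the returned large rate makes rupture certain within one step.
    """
    force_pn = np.asarray(force_pn, dtype=float)
    if np.any(force_pn < 0):
        raise ValueError("force_pn must be non-negative")
    expo = bond.delta_nm * force_pn / thermal_energy_pn_nm
    if np.any(expo > MAX_BELL_EXPONENT):
        warnings.warn(
            "Bell exponent exceeds cap; dissociation rate truncated "
            f"at k0*exp({MAX_BELL_EXPONENT:g})",
            RuntimeWarning,
            stacklevel=2,
        )
        expo = np.minimum(expo, MAX_BELL_EXPONENT)
    out = bond.k0_per_s * np.exp(expo)
    return float(out) if out.ndim == 0 else out


def detachment_time(rate_per_s, r):
    """Candidate detachment time ``-ln(1 - r)/k`` for uniform variate ``r``.

    This inverts the exponential waiting-time CDF at probability ``r``;
    detachment occurs within the current step iff the result is <= dt.
    """
    rate_per_s = np.asarray(rate_per_s, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(rate_per_s <= 0):
        raise ValueError("rate_per_s must be positive")
    if np.any((r < 0) | (r >= 1)):
        raise ValueError("uniform variate r must lie in [0, 1)")
    out = -np.log1p(-r) / rate_per_s
    return float(out) if out.ndim == 0 else out


def _draw_anchor_distances(
    n: int, protocol: PullingProtocol, contour_nm: float, rng: np.random.Generator
) -> np.ndarray:
    """Truncated-normal anchor separations on (0.1, 0.95) of the contour."""
    lo, hi = 0.1 * contour_nm, 0.95 * contour_nm
    d = rng.normal(protocol.anchor_distance_mean_nm, protocol.anchor_distance_sd_nm, n)
    bad = (d <= lo) | (d >= hi)
    while np.any(bad):  # at the published settings this essentially never loops
        d[bad] = rng.normal(
            protocol.anchor_distance_mean_nm, protocol.anchor_distance_sd_nm, bad.sum()
        )
        bad = (d <= lo) | (d >= hi)
    return d


@dataclass
class _EngineResult:
    force_pn: np.ndarray
    time_s: np.ndarray
    displacement_nm: np.ndarray
    anchor_nm: np.ndarray
    delta_nm: np.ndarray
    censored: np.ndarray
    trace: list | None


def _run_pull_engine(
    n: int,
    k0_per_s,
    delta_nm,
    protocol: PullingProtocol,
    wlc: WLCParams,
    rng: np.random.Generator,
    *,
    two_dna: bool = False,
    wlc2: WLCParams | None = None,
    record_trace: bool = False,
) -> _EngineResult:
    """Vectorised time-stepping engine shared by all pulling modes.

    ``k0_per_s`` and ``delta_nm`` may be scalars or per-event arrays.  In
    two-DNA mode ``wlc`` is the bead-proximal chain and ``wlc2`` the
    surface-tethered chain; the recorded force is the bead-side tension
    F1, which is also the tension transmitted through the ring.
    """
    k0 = np.broadcast_to(np.asarray(k0_per_s, dtype=float), (n,))
    delta = np.broadcast_to(np.asarray(delta_nm, dtype=float), (n,))
    kbt = protocol.thermal_energy_pn_nm
    dt = protocol.dt_s
    v = protocol.velocity_nm_per_s

    if two_dna:
        wlc2 = wlc2 or wlc
        d_contour = wlc2.contour_length_nm
    else:
        d_contour = wlc.contour_length_nm
    anchors = _draw_anchor_distances(n, protocol, d_contour, rng)

    alive = np.ones(n, dtype=bool)
    censored = np.zeros(n, dtype=bool)
    out_force = np.zeros(n)
    out_time = np.zeros(n)
    out_x = np.zeros(n)
    trace: list | None = [] if record_trace else None

    kbt_p1 = kbt / wlc.persistence_length_nm
    inv_l01 = 1.0 / wlc.contour_length_nm
    max1 = wlc.max_length_nm
    if two_dna:
        kbt_p2 = kbt / wlc2.persistence_length_nm
        inv_l02 = 1.0 / wlc2.contour_length_nm
        max2 = wlc2.max_length_nm
        l1_prev = np.zeros(n)
        max2_sq = max2 * max2

    x = protocol.initial_displacement_nm
    t = 0.0
    while np.any(alive):
        x += v * dt
        t += dt
        # Full-width draw keeps the random field aligned across parameter
        # sets (common random numbers).
        u = rng.random(n)
        idx = np.flatnonzero(alive)
        d_sub = anchors[idx]

        if not two_dna:
            length = np.hypot(d_sub, 2.0 * x)
            over = length >= max1
            if np.any(over):
                censored[idx[over]] = True
                alive[idx[over]] = False
                keep = ~over
                idx = idx[keep]
                if idx.size == 0:
                    continue
                d_sub = d_sub[keep]
                length = length[keep]
            f_dna = _wlc_force_raw(length * inv_l01, kbt_p1)
            force = 4.0 * f_dna * x / length  # 2 F_DNA sin(alpha)
        else:
            # Reduced scalar equation g(L1) = F1(L1) - 2 F2(L2(L1)) sin(a);
            # root advances by at most v*dt per step (dL1/dx <= 1), so a
            # short warm-started bracket suffices.
            lo = l1_prev[idx].copy()
            l2_at_lo = np.hypot(d_sub, 2.0 * (x - lo))
            need_raise = l2_at_lo >= max2
            if np.any(need_raise):
                lo_bound = x - 0.5 * np.sqrt(max2_sq - d_sub[need_raise] ** 2)
                lo[need_raise] = np.maximum(lo[need_raise], lo_bound)
            hi_cap = min(x, max1)
            dead = lo >= hi_cap
            if np.any(dead):
                censored[idx[dead]] = True
                alive[idx[dead]] = False
                keep = ~dead
                idx = idx[keep]
                if idx.size == 0:
                    continue
                d_sub = d_sub[keep]
                lo = lo[keep]
            hi = np.minimum(lo + 2.0 * v * dt, hi_cap)
            for _ in range(26):
                mid = 0.5 * (lo + hi)
                xm = x - mid
                l2 = np.hypot(d_sub, 2.0 * xm)
                sin_a = 2.0 * xm / l2
                g = _wlc_force_raw(mid * inv_l01, kbt_p1) - 2.0 * sin_a * _wlc_force_raw(
                    l2 * inv_l02, kbt_p2
                )
                pos = g > 0.0
                hi = np.where(pos, mid, hi)
                lo = np.where(pos, lo, mid)
            l1 = 0.5 * (lo + hi)
            l1_prev[idx] = l1
            force = _wlc_force_raw(l1 * inv_l01, kbt_p1)

        expo = np.minimum(delta[idx] * force / kbt, MAX_BELL_EXPONENT)
        rate = k0[idx] * np.exp(expo)
        t_det = -np.log1p(-u[idx]) / rate
        rupt = t_det <= dt
        if record_trace:
            trace.append((t, x, force[0] if 0 in idx else np.nan))
        if np.any(rupt):
            hit = idx[rupt]
            out_force[hit] = force[rupt]
            out_time[hit] = t
            out_x[hit] = x
            alive[hit] = False

    if np.any(censored):
        logger.info("censored %d/%d events at the chain-extension limit", censored.sum(), n)
    return _EngineResult(
        force_pn=out_force,
        time_s=out_time,
        displacement_nm=out_x,
        anchor_nm=anchors,
        delta_nm=np.array(delta, dtype=float, copy=True),
        censored=censored,
        trace=trace,
    )


def _events_frame(res: _EngineResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": np.arange(res.force_pn.size),
            "force_pN": np.where(res.censored, np.nan, res.force_pn),
            "time_s": np.where(res.censored, np.nan, res.time_s),
            "D_um": res.anchor_nm / 1000.0,
            "delta_nm": res.delta_nm,
            "censored": res.censored,
        }
    )


def _sample_from_engine(res: _EngineResult) -> RuptureSample:
    return RuptureSample(
        forces_pn=res.force_pn[~res.censored],
        n_censored=int(res.censored.sum()),
        events=_events_frame(res),
    )


def simulate_single_pull(
    protocol: PullingProtocol,
    bond: BondModel,
    wlc: WLCParams = LAMBDA_DNA,
    rng: np.random.Generator | None = None,
) -> RuptureEvent:
    """Simulate one constant-velocity pulling event on the single-DNA tether."""
    rng = np.random.default_rng(protocol.seed) if rng is None else rng
    res = _run_pull_engine(1, bond.k0_per_s, bond.delta_nm, protocol, wlc, rng)
    return RuptureEvent(
        rupture_force_pn=float(res.force_pn[0]),
        rupture_time_s=float(res.time_s[0]),
        displacement_at_rupture_nm=float(res.displacement_nm[0]),
        anchor_distance_nm=float(res.anchor_nm[0]),
        orientation_delta_nm=bond.delta_nm,
        censored=bool(res.censored[0]),
    )


def simulate_rupture_distribution(
    protocol: PullingProtocol,
    bond: BondModel,
    wlc: WLCParams = LAMBDA_DNA,
    n: int = 10_000,
    rng: np.random.Generator | None = None,
) -> RuptureSample:
    """Simulate ``n`` independent single-DNA rupture events.

    Reproducible given (protocol.seed, n, dt); censored events (chain at
    its extension limit before rupture) are excluded from the force
    sample and counted in ``n_censored``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(protocol.seed) if rng is None else rng
    res = _run_pull_engine(n, bond.k0_per_s, bond.delta_nm, protocol, wlc, rng)
    return _sample_from_engine(res)


def _normalize_delta_choices(
    delta_choices: Mapping[float, float] | Sequence[float] | float,
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(delta_choices, Mapping):
        vals = np.array(list(delta_choices.keys()), dtype=float)
        probs = np.array(list(delta_choices.values()), dtype=float)
    elif np.isscalar(delta_choices):
        vals, probs = np.array([float(delta_choices)]), np.array([1.0])
    else:
        vals = np.asarray(list(delta_choices), dtype=float)
        probs = np.full(vals.size, 1.0 / vals.size)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError(f"delta_choices probabilities must sum to 1 (got {probs.sum()})")
    return vals, probs


def simulate_two_dna_pull(
    protocol: PullingProtocol,
    bond_k0_per_s: float,
    delta_choices: Mapping[float, float] | Sequence[float] | float,
    wlc1: WLCParams = M13_PLASMID,
    wlc2: WLCParams = LAMBDA_DNA,
    n: int = 10_000,
    rng: np.random.Generator | None = None,
) -> RuptureSample:
    """Simulate rupture events with the force applied through a second DNA.

    Per event, the orientation parameter δ is drawn from ``delta_choices``
    (a mapping δ→probability, a sequence of equiprobable values, or a
    single value), modelling the ring disengaging in either a head-like or
    hinge-like orientation.  Each step solves the coupled two-DNA geometry
    and applies the Bell rate to the bead-side tension F1, which is also
    the recorded rupture force.

    ``wlc1`` is the bead-proximal chain and defaults to the 7.2 kb plasmid
    captured as the second DNA; ``wlc2`` is the surface-tethered λ-DNA.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if bond_k0_per_s <= 0:
        raise ValueError("bond_k0_per_s must be positive")
    rng = np.random.default_rng(protocol.seed) if rng is None else rng
    vals, probs = _normalize_delta_choices(delta_choices)
    delta = rng.choice(vals, size=n, p=probs)
    res = _run_pull_engine(
        n, bond_k0_per_s, delta, protocol, wlc1, rng, two_dna=True, wlc2=wlc2
    )
    return _sample_from_engine(res)


def simulate_constant_ramp(
    bond: BondModel,
    force_rate_pn_per_s: float,
    dt_s: float = 0.01,
    n: int = 10_000,
    thermal_energy_pn_nm: float = KBT_ROOM_PN_NM,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> RuptureSample:
    """Rupture forces under a linear force ramp ``F = Fdot * t``.

    Bypasses the polymer mechanics entirely; in this mode Bell–Evans
    theory gives the most probable rupture force in closed form,
    ``F* = (kBT/δ) ln(δ Fdot / (k0 kBT))``, which serves as an analytic
    oracle for the stochastic stepping scheme.
    """
    if force_rate_pn_per_s <= 0:
        raise ValueError("force_rate_pn_per_s must be positive")
    rng = np.random.default_rng(seed) if rng is None else rng
    alive = np.ones(n, dtype=bool)
    forces = np.zeros(n)
    t = 0.0
    while np.any(alive):
        t += dt_s
        f = force_rate_pn_per_s * t
        u = rng.random(n)
        expo = min(bond.delta_nm * f / thermal_energy_pn_nm, MAX_BELL_EXPONENT)
        rate = bond.k0_per_s * np.exp(expo)
        rupt = alive & (-np.log1p(-u) / rate <= dt_s)
        forces[rupt] = f
        alive &= ~rupt
    return RuptureSample.from_forces(forces)


def bell_evans_most_probable_force(
    bond: BondModel,
    force_rate_pn_per_s: float,
    thermal_energy_pn_nm: float = KBT_ROOM_PN_NM,
) -> float:
    """Closed-form Bell–Evans mode of the rupture-force distribution under
    a linear ramp: ``(kBT/δ) ln(δ Fdot / (k0 kBT))``."""
    kbt = thermal_energy_pn_nm
    return (kbt / bond.delta_nm) * np.log(
        bond.delta_nm * force_rate_pn_per_s / (bond.k0_per_s * kbt)
    )
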