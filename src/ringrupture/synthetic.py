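"""Synthetic datasets emulating the pulling experiments.

The experimental rupture-force datasets behind the published
distributions are not deposited, so every downstream consumer of this
package is exercised against synthetic stand-ins generated here: rupture
force samples at the experimental sample sizes, the bimodal 50/50 mixture
produced by hinge-crosslinked complexes, two-DNA rupture samples with
randomized pulling orientation, full force–displacement (FD) traces, and
ring-occupancy tables for the bead-attachment model.

Every generator is a pure function of its specification and seed, and
each scenario writes a JSON provenance sidecar that fully determines
regeneration.  No measurement noise is added to rupture forces by
default (the disengagement model itself has none); optional Gaussian
noise is available for fitter robustness studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .polymer import LAMBDA_DNA, M13_PLASMID, WLCParams
from .simulate import (
    BondModel,
    PullingProtocol,
    RuptureSample,
    _run_pull_engine,
    _sample_from_engine,
)

__all__ = [
    "ScenarioSpec",
    "SCENARIOS",
    "generate_scenario",
    "generate_fd_trace",
    "generate_occupancy",
]

#: Fitted bond parameters and experimental sample sizes for the published
#: pulling scenarios.  The mixture scenario draws each event's bond pair
#: with the stated weights (hinge-crosslinked complexes rupture at ~20 pN
#: or ~70 pN with roughly equal probability); the two-DNA scenario pulls
#: through the captured 7.2 kb plasmid with per-event orientation delta.
SCENARIOS: dict[str, dict[str, Any]] = {
    "head": {"components": [(BondModel(0.0027, 1.23), 1.0)], "n_events": 89},
    "hinge": {"components": [(BondModel(0.0025, 1.61), 1.0)], "n_events": 21},
    "head_crosslinked": {"components": [(BondModel(0.0022, 1.22), 1.0)], "n_events": 24},
    "hinge_crosslinked_mixture": {
        "components": [(BondModel(0.0021, 1.23), 0.5), (BondModel(2.7e-5, 0.8), 0.5)],
        "n_events": 25,
    },
    "two_dna": {
        "k0_per_s": 2e-3,
        "delta_choices": {1.23: 0.5, 1.61: 0.5},
        "n_events": 41,
    },
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Fully-specified synthetic rupture-force scenario.

    ``components`` is a list of (BondModel, weight) pairs for single-DNA
    scenarios; the two-DNA scenario instead carries ``k0_per_s`` and
    ``delta_choices``.  ``noise_sd_pn`` optionally adds Gaussian
    measurement noise to the recorded forces (default none).
    """

    name: str
    n_events: int
    components: tuple = ()
    k0_per_s: float | None = None
    delta_choices: Mapping[float, float] | None = None
    protocol: PullingProtocol = field(default_factory=PullingProtocol)
    wlc: WLCParams = LAMBDA_DNA
    wlc_bead_side: WLCParams = M13_PLASMID
    noise_sd_pn: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.components:
            total = sum(w for _, w in self.components)
            if not np.isclose(total, 1.0):
                raise ValueError(f"component weights must sum to 1 (got {total})")

    @classmethod
    def from_name(
        cls, name: str, n_events: int | None = None, seed: int = 0, **overrides
    ) -> "ScenarioSpec":
        """Build the published configuration for a named scenario."""
        if name not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {name!r}; valid names: {sorted(SCENARIOS)}"
            )
        preset = SCENARIOS[name]
        kwargs: dict[str, Any] = {
            "name": name,
            "n_events": n_events if n_events is not None else preset["n_events"],
            "seed": seed,
        }
        if "components" in preset:
            kwargs["components"] = tuple(preset["components"])
        else:
            kwargs["k0_per_s"] = preset["k0_per_s"]
            kwargs["delta_choices"] = dict(preset["delta_choices"])
        kwargs.update(overrides)
        return cls(**kwargs)

    def provenance(self) -> dict[str, Any]:
        """JSON-serialisable record that fully determines regeneration."""
        rec: dict[str, Any] = {
            "scenario": self.name,
            "n_events": self.n_events,
            "seed": self.seed,
            "noise_sd_pn": self.noise_sd_pn,
            "protocol": {
                "velocity_nm_per_s": self.protocol.velocity_nm_per_s,
                "dt_s": self.protocol.dt_s,
                "anchor_distance_mean_nm": self.protocol.anchor_distance_mean_nm,
                "anchor_distance_sd_nm": self.protocol.anchor_distance_sd_nm,
                "thermal_energy_pn_nm": self.protocol.thermal_energy_pn_nm,
                "initial_displacement_nm": self.protocol.initial_displacement_nm,
            },
            "wlc": {
                "persistence_length_nm": self.wlc.persistence_length_nm,
                "contour_length_nm": self.wlc.contour_length_nm,
            },
        }
        if self.components:
            rec["components"] = [
                {"k0_per_s": b.k0_per_s, "delta_nm": b.delta_nm, "weight": w}
                for b, w in self.components
            ]
        else:
            rec["k0_per_s"] = self.k0_per_s
            rec["delta_choices"] = {str(k): v for k, v in self.delta_choices.items()}
            rec["wlc_bead_side"] = {
                "persistence_length_nm": self.wlc_bead_side.persistence_length_nm,
                "contour_length_nm": self.wlc_bead_side.contour_length_nm,
            }
        return rec


def generate_scenario(spec: ScenarioSpec) -> tuple[RuptureSample, dict[str, Any]]:
    """Generate a rupture-force sample for a scenario.

    Returns the sample together with its provenance record.  Mixture
    scenarios draw each event's bond parameters from the component
    weights; the two-DNA scenario runs the coupled-geometry engine with
    per-event orientation δ.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events
    if spec.name == "two_dna" or (not spec.components and spec.delta_choices):
        vals = np.array(list(spec.delta_choices.keys()), dtype=float)
        probs = np.array(list(spec.delta_choices.values()), dtype=float)
        delta = rng.choice(vals, size=n, p=probs)
        res = _run_pull_engine(
            n,
            spec.k0_per_s,
            delta,
            spec.protocol,
            spec.wlc_bead_side,
            rng,
            two_dna=True,
            wlc2=spec.wlc,
        )
    else:
        bonds = [b for b, _ in spec.components]
        weights = np.array([w for _, w in spec.components])
        pick = rng.choice(len(bonds), size=n, p=weights)
        k0 = np.array([bonds[i].k0_per_s for i in pick])
        delta = np.array([bonds[i].delta_nm for i in pick])
        res = _run_pull_engine(n, k0, delta, spec.protocol, spec.wlc, rng)
    if spec.noise_sd_pn > 0:
        noise = rng.normal(0.0, spec.noise_sd_pn, n)
        res.force_pn = np.maximum(res.force_pn + noise, 0.0)
    sample = _sample_from_engine(res)
    return sample, spec.provenance()


def generate_fd_trace(
    protocol: PullingProtocol,
    bond: BondModel,
    wlc: WLCParams = LAMBDA_DNA,
    seed: int | None = None,
    n_post_rupture_steps: int = 50,
) -> pd.DataFrame:
    """Simulate one full force–displacement trace.

    The trace records (time, displacement, force) at every step of a
    single pulling event up to and including the rupture step, then
    continues the displacement ramp with zero force (the tether is gone).
    The rupture force equals the force of ``simulate_single_pull`` at the
    same seed: both run the identical engine path.
    """
    rng = np.random.default_rng(seed if seed is not None else protocol.seed)
    res = _run_pull_engine(
        1, bond.k0_per_s, bond.delta_nm, protocol, wlc, rng, record_trace=True
    )
    rows = [(t, x, f) for t, x, f in res.trace]
    t_last, x_last = rows[-1][0], rows[-1][1]
    dt, v = protocol.dt_s, protocol.velocity_nm_per_s
    for i in range(1, n_post_rupture_steps + 1):
        rows.append((t_last + i * dt, x_last + i * v * dt, 0.0))
    df = pd.DataFrame(rows, columns=["time_s", "displacement_nm", "force_pN"])
    df.attrs["rupture_force_pn"] = float(res.force_pn[0])
    df.attrs["censored"] = bool(res.censored[0])
    return df


def generate_occupancy(
    n_dna: int,
    mean_cohesins: float,
    dna_length_um: float = 16.32,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic ring-occupancy table: Poisson counts, uniform positions.

    A stand-in for the unpublished experimental occupancy distribution;
    returns a table with columns ``dna_id`` and ``position_um`` (DNAs
    with zero complexes contribute no rows).
    """
    if mean_cohesins < 0:
        raise ValueError("mean_cohesins must be non-negative")
    if n_dna < 1:
        raise ValueError("n_dna must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mean_cohesins, n_dna)
    dna_id = np.repeat(np.arange(n_dna), counts)
    positions = rng.uniform(0.0, dna_length_um, counts.sum())
    return pd.DataFrame({"dna_id": dna_id, "position_um": positions})
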