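"""Monte Carlo integrated process model (IPM).

Each simulation cycle draws one operating condition per PP, converts the
deviation from setpoint into a CQA change via the linearized severity
slopes, and chains the unit operations in process order down to drug
substance (DS).  The out-of-specification (OOS) probability is the
fraction of cycles whose DS CQA violates the specification limit.

Two propagation modes are provided.  ``per_cycle`` chains each cycle
through all unit operations, carrying the full error propagation.
``mean_transfer`` starts every unit operation's cycles from the mean of
the previous unit operation's output distribution; the DS mean coincides
with per_cycle (the model is additive) but the DS variance, and hence the
OOS probability, is smaller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np

from .linearization import LinearEffect, linear_effect
from .occurrence import operating_distribution, sample, substream
from .ra_model import (Direction, RiskAssessment, UnitOperationAssessment,
                       validate, RAValidationError)

__all__ = ["SimulationConfig", "IPMResult", "simulate_unit_operation",
           "run_ipm", "oos_probability", "resolve_specs"]

PropagationMode = Literal["per_cycle", "mean_transfer"]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that parameterizes one IPM run.

    ``ds_lower_spec_pct`` / ``ds_upper_spec_pct`` default to the starting
    CQA minus/plus 10 % for yield-like / impurity-like CQAs respectively
    (OOS when the DS CQA has moved by at least 10 %).  Exactly the limit
    matching the CQA direction is used.
    """

    n_cycles: int = 1000
    seed: int = 0
    propagation_mode: PropagationMode = "per_cycle"
    ds_lower_spec_pct: float | None = None
    ds_upper_spec_pct: float | None = None
    metric: Literal["mean_cqa_reduction", "oos_reduction", "both"] = "both"
    loo_mode: Literal["common_random_numbers", "independent"] = "common_random_numbers"
    severity_reference: int | None = None
    occurrence_reference: int | None = None
    uniform_at_max: bool = False

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if self.propagation_mode not in ("per_cycle", "mean_transfer"):
            raise ValueError(f"unknown propagation mode {self.propagation_mode!r}")


@dataclass(frozen=True)
class IPMResult:
    """Outcome of one IPM run."""

    ds_values: np.ndarray
    uo_means: dict[str, float]
    per_uo_oos: dict[str, float]
    oos_probability: float
    spec_limit: float
    config: SimulationConfig

    @property
    def mean_ds(self) -> float:
        return float(np.mean(self.ds_values))


def resolve_specs(ra: RiskAssessment, config: SimulationConfig) -> float:
    """The single DS specification limit appropriate to the CQA direction."""
    if ra.direction is Direction.higher_is_better:
        if config.ds_lower_spec_pct is not None:
            return config.ds_lower_spec_pct
        return ra.starting_cqa_pct - 10.0
    if config.ds_upper_spec_pct is not None:
        return config.ds_upper_spec_pct
    return ra.starting_cqa_pct + 10.0


def simulate_unit_operation(
    y_in: float,
    uo: UnitOperationAssessment,
    draws: Mapping[str, float],
    effects: Mapping[str, LinearEffect],
    direction: Direction = Direction.higher_is_better,
) -> float:
    """Propagate one CQA value through one unit operation for given draws.

    For each PP the deviation of the drawn condition from the setpoint is
    multiplied by the side-appropriate slope magnitude; the summed change
    is subtracted for yield-like CQAs and added for impurity-like ones.
    """
    total = 0.0
    for pp in uo.pps:
        x = draws[pp.pp_name]
        if not (pp.judged_lower <= x <= pp.judged_upper):
            raise ValueError(
                f"{uo.uo_id}/{pp.pp_name}: draw {x} outside judged range "
                f"[{pp.judged_lower}, {pp.judged_upper}]")
        eff = effects[pp.pp_name]
        dev = x - pp.setpoint
        total += dev * eff.beta_upper if dev > 0 else -dev * eff.beta_lower
    return y_in - total if direction is Direction.higher_is_better else y_in + total


def _contributions(ra: RiskAssessment, config: SimulationConfig,
                   seed_labels: tuple[str, ...] = ()) -> tuple[list, np.ndarray]:
    """Per-PP per-cycle CQA-change magnitudes, one row per PP in RA order.

    Row i is |x_i - setpoint_i| * beta_i(side) across cycles.  Extra
    ``seed_labels`` shift every substream (used for independent LOO
    re-simulation).
    """
    pps = list(ra.iter_pps())
    contrib = np.empty((len(pps), config.n_cycles))
    for i, (uo, pp) in enumerate(pps):
        eff = linear_effect(pp, uo, ra.scale,
                            severity_reference=config.severity_reference)
        dist = operating_distribution(pp, ra.scale,
                                      occurrence_reference=config.occurrence_reference,
                                      uniform_at_max=config.uniform_at_max)
        rng = substream(config.seed, *seed_labels, uo.uo_id, pp.pp_name)
        x = sample(dist, config.n_cycles, rng)
        dev = x - pp.setpoint
        contrib[i] = np.where(dev > 0, dev * eff.beta_upper, -dev * eff.beta_lower)
    return pps, contrib


def _propagate(ra: RiskAssessment, contrib: np.ndarray, pps: list,
               config: SimulationConfig,
               exclude: int | None = None) -> tuple[np.ndarray, dict, dict]:
    """Chain unit operations; return DS values and per-UO means/OOS fractions.

    ``exclude`` zeroes one PP row (common-random-numbers leave-one-out).
    Per-UO OOS is recorded against that unit operation's acceptance
    boundary (mean input CQA minus its critical delta) for reporting only;
    trajectories are never censored.
    """
    sign = -1.0 if ra.direction is Direction.higher_is_better else 1.0
    n = config.n_cycles
    uo_of_row = np.array([u_idx for u_idx, uo in enumerate(ra.uos)
                          for _ in uo.pps])
    y = np.full(n, ra.starting_cqa_pct)
    uo_means: dict[str, float] = {}
    per_uo_oos: dict[str, float] = {}
    for u_idx, uo in enumerate(ra.uos):
        rows = np.flatnonzero(uo_of_row == u_idx)
        if exclude is not None:
            rows = rows[rows != exclude]
        uo_change = contrib[rows].sum(axis=0) if len(rows) else np.zeros(n)
        y_in_mean = float(np.mean(y))
        if config.propagation_mode == "mean_transfer":
            y = y_in_mean + sign * uo_change
        else:
            y = y + sign * uo_change
        uo_means[uo.uo_id] = float(np.mean(y))
        boundary = y_in_mean + sign * uo.critical_delta_cqa_pct
        if ra.direction is Direction.higher_is_better:
            per_uo_oos[uo.uo_id] = float(np.mean(y < boundary))
        else:
            per_uo_oos[uo.uo_id] = float(np.mean(y > boundary))
    return y, uo_means, per_uo_oos


def run_ipm(ra: RiskAssessment, config: SimulationConfig) -> IPMResult:
    """Run the full Monte Carlo integrated process model."""
    diags = validate(ra)
    if diags:
        raise RAValidationError(diags)
    pps, contrib = _contributions(ra, config)
    ds, uo_means, per_uo_oos = _propagate(ra, contrib, pps, config)
    spec = resolve_specs(ra, config)
    if ra.direction is Direction.higher_is_better:
        oos = oos_probability(ds, spec_lower=spec, direction=ra.direction)
    else:
        oos = oos_probability(ds, spec_upper=spec, direction=ra.direction)
    return IPMResult(ds_values=ds, uo_means=uo_means, per_uo_oos=per_uo_oos,
                     oos_probability=oos, spec_limit=spec, config=config)


def oos_probability(
    ds_values: Sequence[float] | np.ndarray,
    spec_lower: float | None = None,
    spec_upper: float | None = None,
    direction: Direction = Direction.higher_is_better,
) -> float:
    """Fraction of DS CQA values out of specification (strict violation)."""
    ds = np.asarray(ds_values, dtype=float)
    if ds.size == 0:
        raise ValueError("ds_values must be non-empty")
    if direction is Direction.higher_is_better:
        if spec_lower is None:
            raise ValueError("spec_lower required for a higher-is-better CQA")
        return float(np.mean(ds < spec_lower))
    if spec_upper is None:
        raise ValueError("spec_upper required for a lower-is-better CQA")
    return float(np.mean(ds > spec_upper))
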