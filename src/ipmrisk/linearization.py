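"""Severity linearization: ordinal severity scores to linear CQA effect slopes.

The maximum acceptable CQA loss at a unit operation (critical delta-CQA)
anchors the slope of the worst-case PP effect over half the judged range;
each PP's actual slope scales that critical slope linearly with its
severity score.  Off-center setpoints yield distinct per-side slopes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ra_model import (ProcessParameterAssessment, RiskAssessment, ScoreScale,
                       UnitOperationAssessment)

__all__ = ["LinearEffect", "critical_slope", "current_severity", "linear_effect",
           "max_severity_in"]


@dataclass(frozen=True)
class LinearEffect:
    """Per-PP effect magnitudes, in % CQA per PP unit.

    ``beta_lower`` applies when the operating condition falls below the
    setpoint, ``beta_upper`` above it.  Both are magnitudes; the CQA
    direction decides whether deviations subtract (yield) or add
    (impurity).
    """

    beta_lower: float
    beta_upper: float

    def __post_init__(self) -> None:
        if self.beta_lower < 0 or self.beta_upper < 0:
            raise ValueError("effect slopes are magnitudes and must be >= 0")


def critical_slope(delta_cqa_pct: float, half_width: float) -> float:
    """Slope of the maximum-severity effect: critical loss over half the judged range."""
    if half_width <= 0:
        raise ValueError(f"half_width must be > 0, got {half_width}")
    if delta_cqa_pct < 0:
        raise ValueError(f"delta_cqa_pct must be >= 0, got {delta_cqa_pct}")
    return delta_cqa_pct / half_width


def current_severity(crit_slope: float, severity: int, s_max: int) -> float:
    """Scale the critical slope linearly by the PP's severity score."""
    if not 1 <= severity <= s_max:
        raise ValueError(f"severity {severity} outside [1, {s_max}]")
    return crit_slope * severity / s_max


def max_severity_in(ra: RiskAssessment) -> int:
    """Highest severity score actually present in the RA (alternative reference)."""
    return max(pp.severity for _, pp in ra.iter_pps())


def linear_effect(
    pp: ProcessParameterAssessment,
    uo: UnitOperationAssessment,
    scale: ScoreScale,
    *,
    severity_reference: int | None = None,
) -> LinearEffect:
    """Per-side effect slopes for one PP.

    ``severity_reference`` overrides the severity normalizer (default: the
    scale maximum; pass ``max_severity_in(ra)`` to normalize against the
    highest score actually assigned).  A one-sided ``harm_side`` zeroes the
    opposite slope.
    """
    s_ref = scale.s_max if severity_reference is None else severity_reference
    lo_width = pp.setpoint - pp.judged_lower
    up_width = pp.judged_upper - pp.setpoint
    if lo_width <= 0 or up_width <= 0:
        raise ValueError(
            f"{pp.uo_id}/{pp.pp_name}: setpoint {pp.setpoint} coincides with a judged "
            f"bound [{pp.judged_lower}, {pp.judged_upper}]; zero-width side has no slope")
    delta = uo.critical_delta_cqa_pct
    beta_lower = current_severity(critical_slope(delta, lo_width), pp.severity, s_ref)
    beta_upper = current_severity(critical_slope(delta, up_width), pp.severity, s_ref)
    if pp.harm_side == "below":
        beta_upper = 0.0
    elif pp.harm_side == "above":
        beta_lower = 0.0
    return LinearEffect(beta_lower=beta_lower, beta_upper=beta_upper)
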