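"""Leave-one-out criticality attribution and the severity-occurrence grid.

Each PP's criticality is measured by re-running the integrated process
model without it: the rise in mean DS CQA (mean CQA reduction attributable
to the PP) and the drop in OOS probability (OOS reduction).  By default
both runs share the same random draws per PP (common random numbers), so
the attribution is free of leave-one-out resampling noise and exact for
the additive effect model; literal independent re-simulation is available
via ``SimulationConfig(loo_mode="independent")``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ipm_engine import SimulationConfig, _contributions, _propagate, oos_probability, resolve_specs
from .ra_model import Direction, RAValidationError, RiskAssessment, ScoreScale, validate
from .rpn_compare import rpn

__all__ = ["leave_one_out", "classify", "so_contour"]


def _oos(ds: np.ndarray, spec: float, direction: Direction) -> float:
    if direction is Direction.higher_is_better:
        return oos_probability(ds, spec_lower=spec, direction=direction)
    return oos_probability(ds, spec_upper=spec, direction=direction)


def leave_one_out(ra: RiskAssessment, config: SimulationConfig) -> pd.DataFrame:
    """Criticality table: one row per PP with its mean CQA reduction,
    OOS reduction, RPN, and ascending rank in the ranking metric.

    mean_cqa_reduction_pct is the magnitude of the shift in mean DS CQA
    caused by including the PP; oos_reduction is OOS(all) - OOS(without
    the PP).  Ranks run 1..n ascending in mean_cqa_reduction_pct.
    """
    diags = validate(ra)
    if diags:
        raise RAValidationError(diags)
    pps, contrib = _contributions(ra, config)
    ds_all, _, _ = _propagate(ra, contrib, pps, config)
    spec = resolve_specs(ra, config)
    mean_all = float(np.mean(ds_all))
    oos_all = _oos(ds_all, spec, ra.direction)

    rows = []
    for i, (uo, pp) in enumerate(pps):
        if config.loo_mode == "independent":
            # literal re-simulation of the process without this PP, on
            # fresh draw streams
            ra_wo = ra.without_pp(uo.uo_id, pp.pp_name)
            pps_wo, contrib_wo = _contributions(
                ra_wo, config, seed_labels=("loo", uo.uo_id, pp.pp_name))
            ds_wo, _, _ = _propagate(ra_wo, contrib_wo, pps_wo, config)
        else:
            ds_wo, _, _ = _propagate(ra, contrib, pps, config, exclude=i)
        reduction = abs(float(np.mean(ds_wo)) - mean_all)
        oos_wo = _oos(ds_wo, spec, ra.direction)
        rows.append({
            "uo": uo.uo_id,
            "pp": pp.pp_name,
            "severity": pp.severity,
            "occurrence": pp.occurrence,
            "detectability": pp.detectability,
            "mean_cqa_reduction_pct": reduction,
            "oos_reduction": oos_all - oos_wo,
            "rpn": rpn(pp.severity, pp.occurrence, pp.detectability),
        })
    table = pd.DataFrame(rows)
    order = table["mean_cqa_reduction_pct"].rank(method="first").astype(int)
    table["rank"] = order
    table["is_critical"] = False
    table["block_id"] = pd.array([pd.NA] * len(table), dtype="Int64")
    return table


def classify(table: pd.DataFrame, threshold: float,
             metric: str = "mean_cqa_reduction_pct") -> pd.DataFrame:
    """Flag PPs whose criticality metric reaches the (per-CQA) threshold."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    if metric not in table.columns:
        raise ValueError(f"metric column {metric!r} not in table")
    out = table.copy()
    out["is_critical"] = out[metric] >= threshold
    return out


def so_contour(
    scale: ScoreScale,
    judged_lower: float = 6.0,
    judged_upper: float = 8.0,
    setpoint: float = 7.0,
    critical_delta_cqa_pct: float = 10.0,
    config: SimulationConfig | None = None,
    starting_cqa_pct: float = 100.0,
) -> pd.DataFrame:
    """Mean CQA reduction over the full severity-by-occurrence grid.

    Builds a process holding one PP per (S, O) combination — all sharing
    the given judged range, setpoint and critical delta — runs the
    leave-one-out attribution, and pivots to a grid (rows = severity,
    columns = occurrence).  The grid is non-decreasing along both axes:
    the slope grows with S and the spread of the operating condition with
    O.
    """
    from .synthetic_ra import InsilicoDesign, make_insilico_study

    config = config or SimulationConfig()
    n = scale.s_max * scale.o_max
    design = InsilicoDesign(
        s_max=scale.s_max, o_max=scale.o_max,
        pps_per_uo=(max(n // 2, 1), n - max(n // 2, 1)) if n > 1 else (1, 0),
        judged_lower=judged_lower, judged_upper=judged_upper, setpoint=setpoint,
        critical_delta_cqa_pct=critical_delta_cqa_pct,
        starting_cqa_pct=starting_cqa_pct,
    )
    ra = make_insilico_study(design)
    table = leave_one_out(ra, config)
    grid = table.pivot(index="severity", columns="occurrence",
                       values="mean_cqa_reduction_pct")
    return grid.sort_index().sort_index(axis=1)
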