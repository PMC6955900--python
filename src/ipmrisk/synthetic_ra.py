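"""Synthetic risk assessments for validation and examples.

Three generators: the full-factorial severity-by-occurrence design used
to characterize the algorithm (every S x O combination once, identical
judged ranges, two unit operations); the four-PP worked-example RA; and
randomized RAs emulating the structure of a multi-step vaccine
purification process (heterogeneous judged-range magnitudes, optional
off-center setpoints).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ra_model import (Direction, ProcessParameterAssessment, RiskAssessment,
                       ScoreScale, UnitOperationAssessment)

__all__ = ["InsilicoDesign", "make_insilico_study", "table1_fixture",
           "make_random_ra", "TABLE2_STRUCTURE"]


@dataclass(frozen=True)
class InsilicoDesign:
    """Full-factorial S x O characterization design.

    Defaults: 1-5 scales, 25 PPs split 10/15 over two unit operations,
    every PP sharing judged range [6, 8] with setpoint 7, a 10 % critical
    delta-CQA per unit operation, and a starting CQA of 100 %.  Because
    slopes scale as delta-CQA over half-width, the common judged range is
    immaterial for reductions expressed in % CQA.
    """

    s_max: int = 5
    o_max: int = 5
    pps_per_uo: tuple[int, ...] = (10, 15)
    judged_lower: float = 6.0
    judged_upper: float = 8.0
    setpoint: float = 7.0
    critical_delta_cqa_pct: float = 10.0
    starting_cqa_pct: float = 100.0

    @property
    def n_combinations(self) -> int:
        return self.s_max * self.o_max


def make_insilico_study(design: InsilicoDesign | None = None) -> RiskAssessment:
    """Deterministic RA with one PP per (S, O) combination.

    PPs are laid out row-major (severity outer, occurrence inner) and
    named ``PP_S{s}O{o}``; the first ``pps_per_uo[0]`` go to UO1 and so
    on.  The allocation does not affect mean-reduction rankings (losses
    are additive across unit operations).
    """
    d = design or InsilicoDesign()
    if sum(d.pps_per_uo) != d.n_combinations:
        raise ValueError(
            f"pps_per_uo {d.pps_per_uo} must sum to s_max*o_max = {d.n_combinations}")
    combos = [(s, o) for s in range(1, d.s_max + 1) for o in range(1, d.o_max + 1)]
    uos = []
    pos = 0
    for k, n_pps in enumerate(d.pps_per_uo, start=1):
        uo_id = f"UO{k}"
        pps = tuple(
            ProcessParameterAssessment(
                uo_id=uo_id, pp_name=f"PP_S{s}O{o}",
                judged_lower=d.judged_lower, judged_upper=d.judged_upper,
                setpoint=d.setpoint, severity=s, occurrence=o,
            )
            for s, o in combos[pos:pos + n_pps])
        pos += n_pps
        if not pps:
            continue
        uos.append(UnitOperationAssessment(
            uo_id=uo_id, order_index=len(uos) + 1,
            critical_delta_cqa_pct=d.critical_delta_cqa_pct, pps=pps))
    return RiskAssessment(
        cqa_name="CQA", uos=tuple(uos),
        direction=Direction.higher_is_better,
        scale=ScoreScale(s_max=d.s_max, o_max=d.o_max),
        starting_cqa_pct=d.starting_cqa_pct)


def table1_fixture() -> RiskAssessment:
    """The four-PP, two-unit-operation worked-example RA (with detectability)."""
    uo1 = UnitOperationAssessment(
        uo_id="UO-1", order_index=1, critical_delta_cqa_pct=10.0,
        pps=(
            ProcessParameterAssessment("UO-1", "PP1", 6.0, 8.0, 7.0, 4, 3, 2),
            ProcessParameterAssessment("UO-1", "PP2", 30.0, 70.0, 50.0, 3, 4, 2),
        ))
    uo2 = UnitOperationAssessment(
        uo_id="UO-2", order_index=2, critical_delta_cqa_pct=10.0,
        pps=(
            ProcessParameterAssessment("UO-2", "PP1", 6.8, 7.6, 7.2, 5, 2, 2),
            ProcessParameterAssessment("UO-2", "PP2", 32.0, 38.0, 35.0, 2, 4, 4),
        ))
    return RiskAssessment(cqa_name="CQA1", uos=(uo1, uo2))


# Unit operations in scope for a representative multi-step purification
# process (name, number of assessed PPs).
TABLE2_STRUCTURE: tuple[tuple[str, int], ...] = (
    ("Filt", 5), ("Conc1", 7), ("Conc2", 7), ("Chr1", 8), ("Chr2", 7),
)


def make_random_ra(
    structure: tuple[tuple[str, int], ...] = TABLE2_STRUCTURE,
    scale: ScoreScale | None = None,
    seed: int = 0,
    *,
    with_detectability: bool = True,
    off_center_prob: float = 0.2,
    width_range: tuple[float, float] = (0.5, 100.0),
    delta_range: tuple[float, float] = (5.0, 15.0),
    direction: Direction = Direction.higher_is_better,
) -> RiskAssessment:
    """Randomized RA with the given per-unit-operation PP counts.

    Judged-range widths are drawn log-uniformly over ``width_range`` to
    exercise unit-scale invariance; setpoints are centered except with
    probability ``off_center_prob``, where they land uniformly in the
    middle 60 % of the judged range.  Deterministic in ``seed``.
    PP names follow the ``<uo>_Var<i>`` convention.
    """
    scale = scale or ScoreScale()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5A11]))
    uos = []
    for k, (uo_name, n_pps) in enumerate(structure, start=1):
        delta = float(np.round(rng.uniform(*delta_range), 1))
        pps = []
        for i in range(1, n_pps + 1):
            width = float(np.exp(rng.uniform(np.log(width_range[0]),
                                             np.log(width_range[1]))))
            lower = float(rng.uniform(0.0, 10.0)) * width
            upper = lower + width
            if rng.uniform() < off_center_prob:
                setpoint = float(rng.uniform(lower + 0.2 * width, upper - 0.2 * width))
            else:
                setpoint = 0.5 * (lower + upper)
            pps.append(ProcessParameterAssessment(
                uo_id=uo_name, pp_name=f"{uo_name}_Var{i}",
                judged_lower=lower, judged_upper=upper, setpoint=setpoint,
                severity=int(rng.integers(1, scale.s_max + 1)),
                occurrence=int(rng.integers(1, scale.o_max + 1)),
                detectability=int(rng.integers(1, scale.d_max + 1))
                if with_detectability else None,
            ))
        uos.append(UnitOperationAssessment(
            uo_id=uo_name, order_index=k,
            critical_delta_cqa_pct=delta, pps=tuple(pps)))
    return RiskAssessment(cqa_name="CQA", uos=tuple(uos), direction=direction,
                          scale=scale)
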