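"""Domain model for FMEA-style risk assessments and their CSV dialect.

A risk assessment (RA) scores every process parameter (PP) of every unit
operation (UO) against one critical quality attribute (CQA) with severity,
occurrence and (optionally) detectability on small ordinal scales, and
records the judged operating range, the setpoint, and the maximum
acceptable CQA loss per unit operation (the critical delta-CQA).  These
objects are the single source of truth for the downstream simulation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import IO, Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "Direction",
    "ScoreScale",
    "ProcessParameterAssessment",
    "UnitOperationAssessment",
    "RiskAssessment",
    "Diagnostic",
    "RAFormatError",
    "RAValidationError",
    "read_risk_assessment",
    "write_risk_assessment",
    "validate",
    "write_criticality_table",
    "read_criticality_table",
    "CRITICALITY_COLUMNS",
]


class RAFormatError(ValueError):
    """The input stream does not follow the expected tabular format."""


class RAValidationError(ValueError):
    """The parsed risk assessment violates a domain invariant."""

    def __init__(self, diagnostics: Sequence["Diagnostic"]):
        self.diagnostics = list(diagnostics)
        msg = "; ".join(str(d) for d in self.diagnostics) or "invalid risk assessment"
        super().__init__(msg)


class Direction(str, Enum):
    """Whether the CQA should stay high (yield) or low (impurity)."""

    higher_is_better = "higher_is_better"
    lower_is_better = "lower_is_better"


@dataclass(frozen=True)
class ScoreScale:
    """Maxima of the ordinal scoring scales (scores run from 1 to the maximum)."""

    s_max: int = 5
    o_max: int = 5
    d_max: int = 5

    def __post_init__(self) -> None:
        for name in ("s_max", "o_max", "d_max"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")


# Harm-side values for a one-sided effect model: harm only below or only
# above the setpoint; the opposite slope is zero.  None means symmetric.
HARM_SIDES = (None, "below", "above", "both")


@dataclass(frozen=True)
class ProcessParameterAssessment:
    """One scored (unit operation, process parameter) row of the RA.

    Construction is deliberately permissive; :func:`validate` reports
    invariant violations as diagnostics so that malformed assessments can
    be inspected rather than silently rejected.
    """

    uo_id: str
    pp_name: str
    judged_lower: float
    judged_upper: float
    setpoint: float
    severity: int
    occurrence: int
    detectability: int | None = None
    harm_side: str | None = None

    @property
    def judged_width(self) -> float:
        return self.judged_upper - self.judged_lower

    @property
    def is_centered(self) -> bool:
        mid = 0.5 * (self.judged_lower + self.judged_upper)
        half = 0.5 * self.judged_width
        tol = 1e-9 * max(1.0, abs(half))
        return abs(self.setpoint - mid) <= tol


@dataclass(frozen=True)
class UnitOperationAssessment:
    """All scored PPs of one unit operation plus its critical delta-CQA.

    ``critical_delta_cqa_pct`` is the maximum acceptable CQA loss (in % of
    the starting CQA) at this unit operation before the step is considered
    out of specification; it calibrates the maximum-severity slope.
    """

    uo_id: str
    order_index: int
    critical_delta_cqa_pct: float
    pps: tuple[ProcessParameterAssessment, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "pps", tuple(self.pps))


@dataclass(frozen=True)
class RiskAssessment:
    """An ordered sequence of unit-operation assessments for one CQA."""

    cqa_name: str
    uos: tuple[UnitOperationAssessment, ...]
    direction: Direction = Direction.higher_is_better
    scale: ScoreScale = field(default_factory=ScoreScale)
    starting_cqa_pct: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "uos", tuple(self.uos))
        if isinstance(self.direction, str) and not isinstance(self.direction, Direction):
            object.__setattr__(self, "direction", Direction(self.direction))

    def iter_pps(self) -> Iterator[tuple[UnitOperationAssessment, ProcessParameterAssessment]]:
        for uo in self.uos:
            for pp in uo.pps:
                yield uo, pp

    @property
    def n_pps(self) -> int:
        return sum(len(uo.pps) for uo in self.uos)

    def without_pp(self, uo_id: str, pp_name: str) -> "RiskAssessment":
        """A copy with one PP removed (used by literal leave-one-out)."""
        uos = []
        for uo in self.uos:
            if uo.uo_id == uo_id:
                pps = tuple(p for p in uo.pps if p.pp_name != pp_name)
                uo = replace(uo, pps=pps)
            uos.append(uo)
        return replace(self, uos=tuple(uos))


@dataclass(frozen=True)
class Diagnostic:
    """A single validation finding, addressed to a UO and (optionally) a PP."""

    uo_id: str | None
    pp_name: str | None
    rule: str
    message: str

    def __str__(self) -> str:
        where = "/".join(x for x in (self.uo_id, self.pp_name) if x)
        return f"[{self.rule}] {where}: {self.message}" if where else f"[{self.rule}] {self.message}"


def _is_int_score(v) -> bool:
    try:
        return float(v) == int(v)
    except (TypeError, ValueError):
        return False


def validate(ra: RiskAssessment) -> list[Diagnostic]:
    """Check every domain invariant; return diagnostics (empty iff valid)."""
    out: list[Diagnostic] = []
    add = out.append

    if not ra.starting_cqa_pct > 0:
        add(Diagnostic(None, None, "starting_cqa_positive",
                       f"starting CQA must be > 0, got {ra.starting_cqa_pct}"))
    if not ra.uos:
        add(Diagnostic(None, None, "non_empty", "risk assessment has no unit operations"))

    indices = [uo.order_index for uo in ra.uos]
    if len(set(indices)) != len(indices):
        add(Diagnostic(None, None, "unique_order", f"duplicate order indices {indices}"))
    if indices != sorted(indices):
        add(Diagnostic(None, None, "sorted_order", f"unit operations not sorted: {indices}"))
    if any(i < 1 for i in indices):
        add(Diagnostic(None, None, "order_ge_1", f"order indices must be >= 1: {indices}"))

    s_max, o_max, d_max = ra.scale.s_max, ra.scale.o_max, ra.scale.d_max
    for uo in ra.uos:
        if not uo.critical_delta_cqa_pct > 0:
            add(Diagnostic(uo.uo_id, None, "delta_cqa_positive",
                           f"critical delta-CQA must be > 0, got {uo.critical_delta_cqa_pct}"))
        if not uo.pps:
            add(Diagnostic(uo.uo_id, None, "non_empty_uo", "unit operation has no PPs"))
        names = [p.pp_name for p in uo.pps]
        for name in sorted({n for n in names if names.count(n) > 1}):
            add(Diagnostic(uo.uo_id, name, "unique_pp", "duplicate PP name within unit operation"))
        for pp in uo.pps:
            if pp.uo_id != uo.uo_id:
                add(Diagnostic(uo.uo_id, pp.pp_name, "uo_id_consistent",
                               f"PP carries uo_id {pp.uo_id!r}"))
            if not pp.judged_lower < pp.judged_upper:
                add(Diagnostic(uo.uo_id, pp.pp_name, "range_order",
                               f"judged range [{pp.judged_lower}, {pp.judged_upper}] has zero or negative width"))
            elif not (pp.judged_lower <= pp.setpoint <= pp.judged_upper):
                add(Diagnostic(uo.uo_id, pp.pp_name, "setpoint_in_range",
                               f"setpoint {pp.setpoint} outside judged range "
                               f"[{pp.judged_lower}, {pp.judged_upper}]"))
            if not (_is_int_score(pp.severity) and 1 <= pp.severity <= s_max):
                add(Diagnostic(uo.uo_id, pp.pp_name, "severity_range",
                               f"severity {pp.severity!r} not an integer in [1, {s_max}]"))
            if not (_is_int_score(pp.occurrence) and 1 <= pp.occurrence <= o_max):
                add(Diagnostic(uo.uo_id, pp.pp_name, "occurrence_range",
                               f"occurrence {pp.occurrence!r} not an integer in [1, {o_max}]"))
            if pp.detectability is not None and not (
                _is_int_score(pp.detectability) and 1 <= pp.detectability <= d_max
            ):
                add(Diagnostic(uo.uo_id, pp.pp_name, "detectability_range",
                               f"detectability {pp.detectability!r} not an integer in [1, {d_max}]"))
            if pp.harm_side not in HARM_SIDES:
                add(Diagnostic(uo.uo_id, pp.pp_name, "harm_side",
                               f"harm_side {pp.harm_side!r} not one of {HARM_SIDES}"))
    return out


# ---------------------------------------------------------------------------
# CSV dialect
#
# Canonical header: uo,pp,judged_lower,judged_upper,setpoint,severity,
# occurrence,detectability,critical_delta_cqa_pct.  The uo cell and the
# critical delta may be given once per UO block (blank elsewhere); both are
# filled within the block.  Detectability may be absent entirely.
# ---------------------------------------------------------------------------

_REQUIRED = ["uo", "pp", "judged_lower", "judged_upper", "setpoint", "severity",
             "occurrence", "critical_delta_cqa_pct"]
_ALIASES = {
    "unit_operation": "uo",
    "process_parameter": "pp",
    "judged_range_lower": "judged_lower",
    "judged_range_upper": "judged_upper",
    "critical_delta_cqa": "critical_delta_cqa_pct",
}


def _norm_col(name: str) -> str:
    key = name.strip().lower().replace(" ", "_").replace("(%)", "").rstrip("_")
    return _ALIASES.get(key, key)


def read_risk_assessment(
    source: str | IO[str],
    cqa_name: str = "CQA",
    *,
    direction: Direction | str = Direction.higher_is_better,
    scale: ScoreScale | None = None,
    starting_cqa_pct: float = 100.0,
) -> RiskAssessment:
    """Parse the RA CSV dialect into a validated :class:`RiskAssessment`.

    ``source`` is a path or an open text stream.  Row order defines PP
    order; first appearance defines UO order.  Raises
    :class:`RAFormatError` for structural problems and
    :class:`RAValidationError` when a domain invariant fails.
    """
    scale = scale or ScoreScale()
    df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    df.columns = [_norm_col(c) for c in df.columns]
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise RAFormatError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        raise RAFormatError("risk assessment contains no PP rows")

    has_d = "detectability" in df.columns
    df["uo"] = df["uo"].ffill()
    if df["uo"].isna().any():
        raise RAFormatError("first row has no unit-operation id")

    def _num(row_idx: int, col: str, caster, required: bool = True):
        raw = df.at[row_idx, col] if col in df.columns else None
        if raw is None or (isinstance(raw, float) and pd.isna(raw)) or pd.isna(raw):
            if required:
                raise RAFormatError(f"row {row_idx + 2}: empty value in column {col!r}")
            return None
        try:
            return caster(raw)
        except ValueError as exc:
            raise RAValidationError([Diagnostic(
                df.at[row_idx, "uo"], df.at[row_idx, "pp"], f"{col}_numeric",
                f"row {row_idx + 2}: cannot parse {col}={raw!r}")]) from exc

    def _score(raw: str) -> int:
        v = float(raw)
        if v != int(v):
            raise ValueError(raw)
        return int(v)

    uo_order: list[str] = []
    pps_by_uo: dict[str, list[ProcessParameterAssessment]] = {}
    delta_by_uo: dict[str, float] = {}
    for i in range(len(df)):
        uo_id = str(df.at[i, "uo"]).strip()
        if uo_id not in uo_order:
            uo_order.append(uo_id)
        delta = _num(i, "critical_delta_cqa_pct", float, required=False)
        if delta is not None:
            prev = delta_by_uo.get(uo_id)
            if prev is not None and prev != delta:
                raise RAFormatError(
                    f"row {i + 2}: conflicting critical delta-CQA for {uo_id!r} "
                    f"({prev} vs {delta})")
            delta_by_uo[uo_id] = delta
        pp_raw = df.at[i, "pp"]
        if pd.isna(pp_raw):
            # a delta-only row (Table-style trailing row of a UO block)
            continue
        pp = ProcessParameterAssessment(
            uo_id=uo_id,
            pp_name=str(pp_raw).strip(),
            judged_lower=_num(i, "judged_lower", float),
            judged_upper=_num(i, "judged_upper", float),
            setpoint=_num(i, "setpoint", float),
            severity=_num(i, "severity", _score),
            occurrence=_num(i, "occurrence", _score),
            detectability=_num(i, "detectability", _score, required=False) if has_d else None,
        )
        pps_by_uo.setdefault(uo_id, []).append(pp)

    if not any(pps_by_uo.values()):
        raise RAFormatError("risk assessment contains no PP rows")
    uos = []
    for k, uo_id in enumerate(uo_order, start=1):
        if uo_id not in delta_by_uo:
            raise RAFormatError(f"unit operation {uo_id!r} has no critical delta-CQA value")
        uos.append(UnitOperationAssessment(
            uo_id=uo_id,
            order_index=k,
            critical_delta_cqa_pct=delta_by_uo[uo_id],
            pps=tuple(pps_by_uo.get(uo_id, ())),
        ))
    ra = RiskAssessment(cqa_name=cqa_name, uos=tuple(uos),
                        direction=Direction(direction), scale=scale,
                        starting_cqa_pct=starting_cqa_pct)
    diags = validate(ra)
    if diags:
        raise RAValidationError(diags)
    return ra


def write_risk_assessment(ra: RiskAssessment, sink: str | IO[str]) -> None:
    """Serialize a RiskAssessment back to the CSV dialect (delta on every row)."""
    rows = []
    for uo, pp in ra.iter_pps():
        rows.append({
            "uo": uo.uo_id, "pp": pp.pp_name,
            "judged_lower": pp.judged_lower, "judged_upper": pp.judged_upper,
            "setpoint": pp.setpoint, "severity": pp.severity,
            "occurrence": pp.occurrence, "detectability": pp.detectability,
            "critical_delta_cqa_pct": uo.critical_delta_cqa_pct,
        })
    df = pd.DataFrame(rows)
    if df["detectability"].isna().all():
        df = df.drop(columns=["detectability"])
    df.to_csv(sink, index=False)


# Criticality-table serialization ------------------------------------------

CRITICALITY_COLUMNS = [
    "uo", "pp", "severity", "occurrence", "detectability",
    "mean_cqa_reduction_pct", "oos_reduction", "rpn", "rank",
    "is_critical", "block_id",
]


def write_criticality_table(table: pd.DataFrame, sink: str | IO[str],
                            metric: str = "mean_cqa_reduction_pct") -> None:
    """Write a criticality table, one row per PP, ascending in the ranking metric."""
    cols = [c for c in CRITICALITY_COLUMNS if c in table.columns]
    out = table[cols].copy() if len(table) else pd.DataFrame(columns=CRITICALITY_COLUMNS)
    if len(out) and metric in out.columns:
        out = out.sort_values(metric, kind="mergesort")
    out.to_csv(sink, index=False)


def read_criticality_table(source: str | IO[str]) -> pd.DataFrame:
    df = pd.read_csv(source)
    missing = [c for c in ("uo", "pp", "mean_cqa_reduction_pct") if c not in df.columns]
    if missing:
        raise RAFormatError(f"criticality table missing column(s): {', '.join(missing)}")
    return df
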