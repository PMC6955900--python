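"""Risk-assessment domain types, CSV parsing, and validation diagnostics."""

import dataclasses
import io

import pandas as pd
import pytest

from ipmrisk import (
    Direction,
    ProcessParameterAssessment,
    RAFormatError,
    RAValidationError,
    RiskAssessment,
    ScoreScale,
    UnitOperationAssessment,
    read_criticality_table,
    read_risk_assessment,
    validate,
    write_criticality_table,
    write_risk_assessment,
)
from ipmrisk.ra_model import Diagnostic


class TestReadRiskAssessment:
    def test_worked_example_parses_fully(self, table1_csv):
        ra = read_risk_assessment(table1_csv, cqa_name="CQA1")
        assert [uo.uo_id for uo in ra.uos] == ["UO-1", "UO-2"]
        assert ra.n_pps == 4
        assert all(uo.critical_delta_cqa_pct == 10.0 for uo in ra.uos)
        pp = ra.uos[1].pps[1]
        assert (pp.judged_lower, pp.judged_upper, pp.setpoint) == (32.0, 38.0, 35.0)
        assert (pp.severity, pp.occurrence, pp.detectability) == (2, 4, 4)

    def test_delta_forward_filled_within_uo_block(self, table1_csv):
        ra = read_risk_assessment(table1_csv)
        # delta appears once per block yet both UOs carry it
        assert [uo.critical_delta_cqa_pct for uo in ra.uos] == [10.0, 10.0]

    def test_row_order_defines_pp_order(self, table1_csv):
        ra = read_risk_assessment(table1_csv)
        assert [pp.pp_name for pp in ra.uos[0].pps] == ["PP1", "PP2"]

    def test_read_is_deterministic(self):
        from tests.conftest import TABLE1_CSV

        ra1 = read_risk_assessment(io.StringIO(TABLE1_CSV))
        ra2 = read_risk_assessment(io.StringIO(TABLE1_CSV))
        assert ra1 == ra2

    def test_missing_column_names_the_column(self):
        src = io.StringIO("uo,pp,judged_lower,judged_upper,setpoint,severity\nU,P,0,1,0.5,3\n")
        with pytest.raises(RAFormatError, match="occurrence"):
            read_risk_assessment(src)

    def test_empty_table_rejected(self):
        src = io.StringIO(
            "uo,pp,judged_lower,judged_upper,setpoint,severity,occurrence,"
            "critical_delta_cqa_pct\n")
        with pytest.raises(RAFormatError, match="no PP rows"):
            read_risk_assessment(src)

    def test_setpoint_outside_judged_range_is_cited(self):
        src = io.StringIO(
            "uo,pp,judged_lower,judged_upper,setpoint,severity,occurrence,"
            "critical_delta_cqa_pct\nUO-1,PPx,6,8,9,3,3,10\n")
        with pytest.raises(RAValidationError, match="PPx"):
            read_risk_assessment(src)

    def test_non_integer_score_rejected(self):
        src = io.StringIO(
            "uo,pp,judged_lower,judged_upper,setpoint,severity,occurrence,"
            "critical_delta_cqa_pct\nUO-1,PPx,6,8,7,3.5,3,10\n")
        with pytest.raises(RAValidationError):
            read_risk_assessment(src)

    def test_missing_delta_for_uo_rejected(self):
        src = io.StringIO(
            "uo,pp,judged_lower,judged_upper,setpoint,severity,occurrence,"
            "critical_delta_cqa_pct\nUO-1,PPx,6,8,7,3,3,\n")
        with pytest.raises(RAFormatError, match="UO-1"):
            read_risk_assessment(src)

    def test_round_trip_preserves_assessment(self, table1_ra):
        buf = io.StringIO()
        write_risk_assessment(table1_ra, buf)
        buf.seek(0)
        ra = read_risk_assessment(buf, cqa_name=table1_ra.cqa_name)
        assert ra == table1_ra


def _pp(**kw):
    base = dict(uo_id="U", pp_name="P", judged_lower=6.0, judged_upper=8.0,
                setpoint=7.0, severity=3, occurrence=3)
    base.update(kw)
    return ProcessParameterAssessment(**base)


def _ra_with(pp):
    uo = UnitOperationAssessment("U", 1, 10.0, (pp,))
    return RiskAssessment("CQA", (uo,))


class TestValidate:
    def test_worked_example_is_clean(self, table1_ra):
        assert validate(table1_ra) == []

    @pytest.mark.parametrize(
        "pp, rule",
        [
            (_pp(severity=6), "severity_range"),
            (_pp(occurrence=0), "occurrence_range"),
            (_pp(detectability=9), "detectability_range"),
            (_pp(judged_lower=8.0, judged_upper=8.0), "range_order"),
            (_pp(setpoint=9.0), "setpoint_in_range"),
            (_pp(harm_side="sideways"), "harm_side"),
        ],
    )
    def test_single_violation_yields_one_diagnostic(self, pp, rule):
        diags = validate(_ra_with(pp))
        assert len(diags) == 1
        assert diags[0].rule == rule
        assert diags[0].uo_id == "U"

    def test_duplicate_pp_names_flagged(self):
        uo = UnitOperationAssessment("U", 1, 10.0, (_pp(), _pp()))
        diags = validate(RiskAssessment("CQA", (uo,)))
        assert any(d.rule == "unique_pp" for d in diags)

    def test_empty_uo_flagged(self):
        uo = UnitOperationAssessment("U", 1, 10.0, ())
        diags = validate(RiskAssessment("CQA", (uo,)))
        assert any(d.rule == "non_empty_uo" for d in diags)

    def test_unsorted_order_indices_flagged(self):
        uo1 = UnitOperationAssessment("A", 2, 10.0, (_pp(uo_id="A"),))
        uo2 = UnitOperationAssessment("B", 1, 10.0, (_pp(uo_id="B"),))
        diags = validate(RiskAssessment("CQA", (uo1, uo2)))
        assert any(d.rule == "sorted_order" for d in diags)

    def test_diagnostic_is_addressable(self):
        d = Diagnostic("U", "P", "some_rule", "broken")
        assert "U/P" in str(d) and "some_rule" in str(d)


class TestCriticalityTableIO:
    def _table(self):
        return pd.DataFrame({
            "uo": ["A", "A"], "pp": ["p1", "p2"],
            "severity": [1, 2], "occurrence": [1, 2], "detectability": [1, 1],
            "mean_cqa_reduction_pct": [3.25, 1.5], "oos_reduction": [0.1, 0.0],
            "rpn": [1, 4], "rank": [2, 1], "is_critical": [False, False],
            "block_id": [1, 1],
        })

    def test_rows_sorted_ascending_by_metric(self):
        buf = io.StringIO()
        write_criticality_table(self._table(), buf)
        buf.seek(0)
        out = pd.read_csv(buf)
        assert list(out["pp"]) == ["p2", "p1"]
        assert out["mean_cqa_reduction_pct"].is_monotonic_increasing

    def test_empty_table_writes_header_only(self):
        buf = io.StringIO()
        write_criticality_table(pd.DataFrame(), buf)
        text = buf.getvalue().strip().splitlines()
        assert len(text) == 1 and "mean_cqa_reduction_pct" in text[0]

    def test_round_trip_preserves_values(self):
        table = self._table()
        table.loc[0, "mean_cqa_reduction_pct"] = 3.141592653589793
        buf = io.StringIO()
        write_criticality_table(table, buf)
        buf.seek(0)
        out = read_criticality_table(buf).sort_values("pp").reset_index(drop=True)
        assert out["mean_cqa_reduction_pct"].iloc[0] == pytest.approx(
            3.141592653589793, rel=1e-9)

    def test_read_requires_core_columns(self):
        with pytest.raises(RAFormatError, match="mean_cqa_reduction_pct"):
            read_criticality_table(io.StringIO("uo,pp\nA,p1\n"))


def test_direction_accepts_string_aliases():
    ra = RiskAssessment("CQA", (), direction="lower_is_better")
    assert ra.direction is Direction.lower_is_better


def test_without_pp_removes_exactly_one(table1_ra):
    ra = table1_ra.without_pp("UO-1", "PP2")
    assert ra.n_pps == 3
    assert [pp.pp_name for pp in ra.uos[0].pps] == ["PP1"]
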