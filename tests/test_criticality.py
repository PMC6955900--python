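"""Leave-one-out attribution, classification, and the S x O grid."""

import numpy as np
import pandas as pd
import pytest

from ipmrisk import (
    ScoreScale,
    SimulationConfig,
    classify,
    expected_abs_deviation,
    leave_one_out,
    linear_effect,
    make_insilico_study,
    operating_distribution,
    run_ipm,
    so_contour,
)
from ipmrisk.ra_model import (ProcessParameterAssessment, RiskAssessment,
                              UnitOperationAssessment)
from ipmrisk.synthetic_ra import InsilicoDesign


class TestLeaveOneOut:
    def test_single_pp_reduction_matches_quadrature_oracle(self):
        pp = ProcessParameterAssessment("U", "P", 6.0, 8.0, 7.0, 4, 3)
        uo = UnitOperationAssessment("U", 1, 10.0, (pp,))
        ra = RiskAssessment("CQA", (uo,))
        config = SimulationConfig(n_cycles=10_000, seed=9)
        table = leave_one_out(ra, config)
        eff = linear_effect(pp, uo, ra.scale)
        predicted = eff.beta_upper * expected_abs_deviation(
            operating_distribution(pp, ra.scale))
        res = run_ipm(ra, config)
        se = np.std(res.ds_values) / np.sqrt(config.n_cycles)
        assert abs(table["mean_cqa_reduction_pct"].iloc[0] - predicted) < 4 * se
        # a lone PP owns the entire mean loss
        assert table["mean_cqa_reduction_pct"].iloc[0] == pytest.approx(
            ra.starting_cqa_pct - res.mean_ds)

    def test_one_sided_pp_reduction_halves_under_crn(self, fast_config):
        # harm only above the setpoint: under common random numbers the
        # one-sided PP's reduction is exactly the upper-side part of its
        # symmetric twin's reduction (same draws, lower slope zeroed)
        one_sided = ProcessParameterAssessment("U", "Pz", 6.0, 8.0, 7.0, 5, 5,
                                               harm_side="above")
        symmetric = ProcessParameterAssessment("U", "Pz", 6.0, 8.0, 7.0, 5, 5)
        uo_1 = UnitOperationAssessment("U", 1, 10.0, (one_sided,))
        uo_2 = UnitOperationAssessment("U", 1, 10.0, (symmetric,))
        red_1 = leave_one_out(RiskAssessment("CQA", (uo_1,)), fast_config)[
            "mean_cqa_reduction_pct"].iloc[0]
        red_2 = leave_one_out(RiskAssessment("CQA", (uo_2,)), fast_config)[
            "mean_cqa_reduction_pct"].iloc[0]
        assert 0.0 < red_1 < red_2

    def test_reductions_nonnegative_under_crn(self, insilico_ra, fast_config):
        table = leave_one_out(insilico_ra, fast_config)
        assert (table["mean_cqa_reduction_pct"] >= 0).all()
        assert (table["oos_reduction"] >= 0).all()

    def test_additivity_of_reductions_is_exact_under_crn(self, insilico_ra,
                                                         fast_config):
        table = leave_one_out(insilico_ra, fast_config)
        res = run_ipm(insilico_ra, fast_config)
        total_loss = insilico_ra.starting_cqa_pct - res.mean_ds
        assert table["mean_cqa_reduction_pct"].sum() == pytest.approx(
            total_loss, abs=1e-9)

    def test_extreme_score_combinations_bracket_the_ranking(self, insilico_ra,
                                                            fast_config):
        table = leave_one_out(insilico_ra, fast_config).set_index("pp")
        red = table["mean_cqa_reduction_pct"]
        assert red.idxmin() == "PP_S1O1"
        assert red.idxmax() == "PP_S5O5"

    def test_ranks_are_a_permutation_ascending_in_metric(self, insilico_ra,
                                                         fast_config):
        table = leave_one_out(insilico_ra, fast_config)
        assert sorted(table["rank"]) == list(range(1, len(table) + 1))
        ordered = table.sort_values("rank")
        assert ordered["mean_cqa_reduction_pct"].is_monotonic_increasing

    def test_independent_loo_agrees_with_crn_within_mc_error(self, table1_ra):
        crn = leave_one_out(table1_ra, SimulationConfig(n_cycles=20_000, seed=4))
        ind = leave_one_out(table1_ra, SimulationConfig(
            n_cycles=20_000, seed=4, loo_mode="independent"))
        merged = crn.merge(ind, on=["uo", "pp"], suffixes=("_crn", "_ind"))
        diff = (merged["mean_cqa_reduction_pct_crn"]
                - merged["mean_cqa_reduction_pct_ind"]).abs()
        assert (diff < 0.3).all()

    def test_allocation_invariance_of_mean_reductions(self):
        """Reassigning PPs among unit operations leaves per-PP mean
        reductions unchanged up to Monte Carlo error (additive model)."""
        n = 20_000
        base = make_insilico_study()
        moved = make_insilico_study(InsilicoDesign(pps_per_uo=(15, 10)))
        ta = leave_one_out(base, SimulationConfig(n_cycles=n, seed=6)).set_index("pp")
        tb = leave_one_out(moved, SimulationConfig(n_cycles=n, seed=6)).set_index("pp")
        diff = (ta["mean_cqa_reduction_pct"] - tb["mean_cqa_reduction_pct"]).abs()
        # 4 x (standard error of a difference of two independent means);
        # sd(|x - s| * beta) <= beta * half_range
        worst_se = 10.0 * 1.0 / np.sqrt(n)
        assert (diff < 4 * np.sqrt(2) * worst_se).all()
        assert abs(ta["mean_cqa_reduction_pct"].sum()
                   - tb["mean_cqa_reduction_pct"].sum()) < 0.5


class TestClassify:
    def test_threshold_flags_at_or_above(self):
        table = pd.DataFrame({"pp": list("abc"),
                              "mean_cqa_reduction_pct": [12.0, 8.0, 11.0]})
        out = classify(table, 10.0)
        assert list(out["is_critical"]) == [True, False, True]

    def test_zero_threshold_flags_everything(self, insilico_ra, fast_config):
        table = leave_one_out(insilico_ra, fast_config)
        assert classify(table, 0.0)["is_critical"].all()

    def test_threshold_above_max_flags_nothing(self, insilico_ra, fast_config):
        table = leave_one_out(insilico_ra, fast_config)
        hi = table["mean_cqa_reduction_pct"].max() + 1
        assert not classify(table, hi)["is_critical"].any()

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify(pd.DataFrame({"mean_cqa_reduction_pct": [1.0]}), -1.0)


@pytest.fixture(scope="module")
def grid():
    return so_contour(ScoreScale(), config=SimulationConfig(n_cycles=4000, seed=2))


class TestSoContour:
    def test_corners_are_the_extremes(self, grid):
        assert grid.loc[1, 1] == grid.values.min()
        assert grid.loc[5, 5] == grid.values.max()

    def test_monotone_in_severity_at_fixed_occurrence(self, grid):
        assert (grid.diff(axis=0).iloc[1:] >= 0).all().all()

    def test_monotone_in_occurrence_at_fixed_severity(self, grid):
        assert (grid.diff(axis=1).iloc[:, 1:] >= 0).all().all()

    def test_cells_match_separable_quadrature_prediction(self, grid):
        # cell (s, o) ~ (s/s_max) * critical_slope * E|X_o - setpoint|
        n = 4000
        for s in (1, 3, 5):
            for o in (1, 3, 5):
                pp = ProcessParameterAssessment("U", "P", 6.0, 8.0, 7.0, s, o)
                dist = operating_distribution(pp, ScoreScale())
                predicted = (s / 5) * 10.0 * expected_abs_deviation(dist)
                se = (s / 5) * 10.0 * 1.0 / np.sqrt(n)  # sd(|x-s|) <= half-range
                assert abs(grid.loc[s, o] - predicted) < 4 * se

    def test_small_scale_grid(self):
        grid = so_contour(ScoreScale(s_max=2, o_max=2),
                          config=SimulationConfig(n_cycles=2000, seed=3))
        assert grid.shape == (2, 2)
        assert grid.loc[2, 2] > grid.loc[1, 1]
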