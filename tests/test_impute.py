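import math

import numpy as np
import pandas as pd
import pytest

from lfqpipe.impute import (
    BRANCH_DOWNSHIFT,
    BRANCH_MIN,
    BRANCH_NONE,
    ImputationParams,
    average_minimum_log_intensity,
    compute_sample_stats,
    impute,
    impute_condition_absent,
    impute_downshifted,
)
from lfqpipe.preprocess import filter_for_quantification

from conftest import make_log_table


class TestSampleStats:
    def test_mean_sd_over_observed_only(self, design):
        table = make_log_table(
            {
                "P1": [20, 21, 22, 20, 21, 22],
                "P2": [22, 23, 24, 22, 23, 24],
                "P3": [None, 19, 20, 19, 20, None],
            },
            design,
        )
        stats = compute_sample_stats(table)
        s1 = design.sample_ids[0]  # observed 20, 22
        assert stats.at[s1, "mean"] == 21.0
        assert stats.at[s1, "sd"] == pytest.approx(math.sqrt(2))
        assert stats.at[s1, "min"] == 20.0
        assert stats.at[s1, "n_obs"] == 2

    def test_column_with_single_observation_fatal(self, design):
        table = make_log_table(
            {"P1": [18, 20, 21, 20, 21, 22], "P2": [None, 20, 21, 20, 21, 22]},
            design,
        )
        table.loc["P1", design.sample_ids[0]] = np.nan
        with pytest.raises(ValueError, match=design.sample_ids[0]):
            compute_sample_stats(table)

    def test_constant_column_flagged_not_fatal(self, design, caplog):
        table = make_log_table(
            {"P1": [20, 21, 22, 20, 21, 22], "P2": [20, 23, 24, 22, 23, 24]},
            design,
        )
        with caplog.at_level("WARNING"):
            stats = compute_sample_stats(table)
        assert stats.at[design.sample_ids[0], "sd"] == 0.0
        assert "zero observed SD" in caplog.text


class TestConditionAbsentBranch:
    def test_fill_is_mean_of_sample_minima(self, design):
        # per-sample minima planted as 18, 18.5, 19, 20, 20.5, 21 -> mean 19.5
        minima = [18, 18.5, 19, 20, 20.5, 21]
        table = make_log_table(
            {
                "A1": minima,
                "A2": [m + 2 for m in minima],
                "SS": [19, 19.5, 20, None, None, None],
            },
            design,
        )
        stats = compute_sample_stats(table)
        fill = average_minimum_log_intensity(stats)
        assert fill == pytest.approx(19.5)
        out = impute_condition_absent(table, ["SS"], fill)
        filled = out.loc["SS", design.sample_ids[3:]].to_numpy()
        assert filled == pytest.approx([19.5] * 3)
        assert not out.isna().any().any()

    def test_equal_minima_give_that_value(self, design):
        table = make_log_table(
            {"A1": [17] * 6, "A2": [20] * 6, "SS": [None, None, None, 18, 19, 20]},
            design,
        )
        fill = average_minimum_log_intensity(compute_sample_stats(table))
        assert fill == 17.0


class TestDownshiftedBranch:
    def _stats(self, design, mean=25.0, sd=2.0):
        return pd.DataFrame(
            {"mean": mean, "sd": sd, "min": mean - 3 * sd, "n_obs": 10},
            index=design.sample_ids,
        )

    def test_draws_match_downshifted_normal(self, design):
        """With sample mean 25 and SD 2, fills come from Normal(21.4, 0.6^2)."""
        n = 4000
        rows = {f"P{i:05d}": [None, 21, 22, 23, 24, 25] for i in range(n)}
        table = make_log_table(rows, design)
        out = impute_downshifted(
            table, list(rows), ImputationParams(seed=7), stats=self._stats(design)
        )
        draws = out[design.sample_ids[0]].to_numpy()
        assert np.mean(draws) == pytest.approx(25 - 1.8 * 2, abs=0.05)
        assert np.std(draws, ddof=1) == pytest.approx(0.3 * 2, abs=0.05)

    def test_fill_mean_sits_downshift_sds_below_sample_mean(self, design):
        n = 2000
        rows = {f"P{i:05d}": [None, 21, 22, 23, 24, 25] for i in range(n)}
        table = make_log_table(rows, design)
        params = ImputationParams(width=0.5, downshift=2.5, seed=3)
        out = impute_downshifted(table, list(rows), params, stats=self._stats(design))
        draws = out[design.sample_ids[0]].to_numpy()
        assert np.mean(draws) == pytest.approx(25 - 2.5 * 2, abs=0.1)

    def test_observed_cells_bit_identical(self, design):
        rows = {"P1": [None, 21, 22, 23, 24, 25], "P2": [20, 21, 22, 23, 24, 25]}
        table = make_log_table(rows, design)
        out = impute_downshifted(
            table, ["P1"], ImputationParams(seed=0), stats=self._stats(design)
        )
        observed = table.notna()
        assert (out.to_numpy()[observed.to_numpy()]
                == table.to_numpy()[observed.to_numpy()]).all()

    def test_seed_determinism(self, design):
        rows = {f"P{i}": [None, 21, 22, None, 24, 25] for i in range(20)}
        table = make_log_table(rows, design)
        a = impute_downshifted(table, list(rows), ImputationParams(seed=11),
                               stats=self._stats(design))
        b = impute_downshifted(table, list(rows), ImputationParams(seed=11),
                               stats=self._stats(design))
        pd.testing.assert_frame_equal(a, b)
        c = impute_downshifted(table, list(rows), ImputationParams(seed=12),
                               stats=self._stats(design))
        assert not a.equals(c)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ImputationParams(width=0.0)
        with pytest.raises(ValueError):
            ImputationParams(downshift=-1.0)


class TestImputeRouting:
    def _dataset(self, design):
        table = make_log_table(
            {
                "COMPLETE": [24, 25, 26, 24, 25, 26],
                "ONE_MISS": [None, 25, 26, 24, 25, 26],
                "TWO_MISS": [24, 25, 26, None, 25, None],
                "MG_ONLY": [22, 23, 24, None, None, None],
                "R_ONLY": [None, None, None, 22, 23, 24],
                "ANCHOR1": [20, 21, 22, 20, 21, 22],
                "ANCHOR2": [26, 27, 28, 26, 27, 28],
            },
            design,
        )
        return table, filter_for_quantification(table, design)

    def test_partition_and_completeness(self, design):
        table, qs = self._dataset(design)
        out, audit = impute(table, qs)
        assert not out.isna().any().any()
        assert audit.loc["COMPLETE", "branch"] == BRANCH_NONE
        assert audit.loc["ONE_MISS", "branch"] == BRANCH_DOWNSHIFT
        assert audit.loc["TWO_MISS", "branch"] == BRANCH_DOWNSHIFT
        assert audit.loc["MG_ONLY", "branch"] == BRANCH_MIN
        assert audit.loc["R_ONLY", "branch"] == BRANCH_MIN
        # branches partition the retained set
        assert audit["branch"].isin([BRANCH_NONE, BRANCH_DOWNSHIFT, BRANCH_MIN]).all()
        assert len(audit) == len(qs.retained_ids)

    def test_complete_protein_unchanged(self, design):
        table, qs = self._dataset(design)
        out, _ = impute(table, qs)
        pd.testing.assert_series_equal(out.loc["COMPLETE"], table.loc["COMPLETE"])

    def test_stage_specific_cells_share_one_value(self, design):
        table, qs = self._dataset(design)
        out, _ = impute(table, qs)
        mg_fill = out.loc["MG_ONLY", design.sample_ids[3:]].to_numpy()
        r_fill = out.loc["R_ONLY", design.sample_ids[:3]].to_numpy()
        assert len(set(mg_fill)) == 1
        assert mg_fill[0] == r_fill[0]

    def test_full_impute_deterministic_under_seed(self, design):
        table, qs = self._dataset(design)
        out1, _ = impute(table, qs, ImputationParams(seed=5))
        out2, _ = impute(table, qs, ImputationParams(seed=5))
        pd.testing.assert_frame_equal(out1, out2)
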