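import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lfqpipe.differential import (
    INVARIANT,
    PUTATIVELY_INVARIANT,
    Thresholds,
    adjust_fdr,
    category_labels,
    classify,
    log2_ratio,
    permutation_fdr,
    run_differential,
    two_sample_test,
)
from lfqpipe.preprocess import filter_for_quantification

from conftest import bh_oracle, make_log_table


def _table(design, mg, r, pid="P1"):
    return make_log_table({pid: list(mg) + list(r)}, design)


class TestLog2Ratio:
    def test_difference_of_group_means(self, design):
        t = _table(design, (19, 20, 21), (20, 21, 22))
        assert log2_ratio(t, design)["P1"] == pytest.approx(1.0)

    def test_identical_groups_give_zero(self, design):
        t = _table(design, (20, 21, 22), (20, 21, 22))
        assert log2_ratio(t, design)["P1"] == 0.0

    def test_swapping_conditions_negates(self, design):
        a = _table(design, (19, 20, 21), (22, 23, 25))
        b = _table(design, (22, 23, 25), (19, 20, 21))
        assert log2_ratio(a, design)["P1"] == pytest.approx(
            -log2_ratio(b, design)["P1"]
        )

    def test_incomplete_table_rejected(self, design):
        t = make_log_table({"P1": [None, 20, 21, 20, 21, 22]}, design)
        with pytest.raises(ValueError, match="complete"):
            log2_ratio(t, design)


class TestTwoSampleTest:
    def test_pooled_t_closed_form(self, design):
        """MG=(10,11,12) vs R=(13,14,15): pooled SD 1, t = 3/sqrt(2/3),
        df = 4; compared against the textbook formula evaluated directly."""
        t_stat, p = two_sample_test(_table(design, (10, 11, 12), (13, 14, 15)),
                                    design, flavor="student")
        expected_t = 3.0 / math.sqrt(2.0 / 3.0)
        expected_p = 2 * sps.t.sf(expected_t, df=4)
        assert t_stat["P1"] == pytest.approx(expected_t, abs=1e-10)
        assert t_stat["P1"] == pytest.approx(3.6742, abs=1e-4)
        assert p["P1"] == pytest.approx(expected_p, abs=1e-10)
        assert p["P1"] == pytest.approx(0.0213, abs=5e-4)

    def test_identical_groups_degenerate_contract(self, design):
        t_stat, p = two_sample_test(_table(design, (20, 20, 20), (20, 20, 20)),
                                    design)
        assert t_stat["P1"] == 0.0
        assert p["P1"] == 1.0

    def test_zero_variance_unequal_means_flagged(self, design):
        t_stat, p = two_sample_test(_table(design, (20, 20, 20), (22, 22, 22)),
                                    design)
        assert p["P1"] == 0.0
        assert np.isposinf(t_stat["P1"])

    def test_student_equals_welch_at_equal_variance(self, design):
        t = _table(design, (10, 11, 12), (14, 15, 16))
        ts, ps = two_sample_test(t, design, flavor="student")
        tw, pw = two_sample_test(t, design, flavor="welch")
        assert ts["P1"] == pytest.approx(tw["P1"], abs=1e-12)
        assert ps["P1"] == pytest.approx(pw["P1"], abs=1e-12)

    def test_unknown_flavor_rejected(self, design):
        with pytest.raises(ValueError, match="flavor"):
            two_sample_test(_table(design, (1, 2, 3), (4, 5, 6)), design, "anova")


class TestBenjaminiHochberg:
    def test_worked_example(self):
        p = pd.Series([0.01, 0.02, 0.03, 0.04])
        q = adjust_fdr(p)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        q = adjust_fdr(pd.Series([1.0, 1.0, 1.0]))
        assert (q == 1.0).all()

    def test_matches_bruteforce_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            q = adjust_fdr(pd.Series(p)).to_numpy()
            np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)

    def test_step_up_monotonicity(self):
        rng = np.random.default_rng(1)
        p = pd.Series(rng.random(100))
        q = adjust_fdr(p)
        order = np.argsort(p.to_numpy())
        assert (np.diff(q.to_numpy()[order]) >= -1e-12).all()

    def test_empty_input(self):
        assert len(adjust_fdr(pd.Series(dtype=float))) == 0


class TestPermutationFdr:
    def test_strong_effects_get_small_q(self, design):
        rng = np.random.default_rng(2)
        n, n_eff = 200, 20
        base = rng.normal(25, 2, n)
        fc = np.zeros(n)
        fc[:n_eff] = 3.0
        vals = np.empty((n, 6))
        vals[:, :3] = base[:, None] + rng.normal(0, 0.2, (n, 3))
        vals[:, 3:] = (base + fc)[:, None] + rng.normal(0, 0.2, (n, 3))
        table = pd.DataFrame(vals, index=[f"P{i}" for i in range(n)],
                             columns=design.sample_ids)
        t_stat, _ = two_sample_test(table, design)
        q = permutation_fdr(table, design, t_stat)
        assert (q.iloc[:n_eff] < 0.2).all()
        assert q.iloc[n_eff:].median() > 0.3

    def test_monotone_in_abs_t(self, design):
        rng = np.random.default_rng(3)
        vals = rng.normal(25, 1, (100, 6))
        table = pd.DataFrame(vals, index=[f"P{i}" for i in range(100)],
                             columns=design.sample_ids)
        t_stat, _ = two_sample_test(table, design)
        q = permutation_fdr(table, design, t_stat)
        order = np.argsort(-t_stat.abs().to_numpy())
        assert (np.diff(q.to_numpy()[order]) >= -1e-12).all()


class TestClassify:
    thresholds = Thresholds()

    @pytest.mark.parametrize(
        "ratio,q,stage,expected",
        [
            (0.70, 0.01, "none", "R45-enriched"),
            (-0.70, 0.01, "none", "MG30-enriched"),
            (0.70, 0.20, "none", PUTATIVELY_INVARIANT),
            (0.30, 0.001, "none", INVARIANT),
            (0.58, 0.001, "none", INVARIANT),  # boundary: closed invariant wins
            (-0.58, 0.001, "none", INVARIANT),
            (5.0, 0.9, "MG30", "MG30-specific"),
            (-5.0, float("nan"), "R45", "R45-specific"),
        ],
    )
    def test_category_assignment(self, design, ratio, q, stage, expected):
        assert classify(ratio, q, stage, design, self.thresholds) == expected

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            Thresholds(logfc_cut=0.0)
        with pytest.raises(ValueError):
            Thresholds(fdr_cut=1.5)


class TestRunDifferential:
    def _quantify(self, design, table):
        from lfqpipe.impute import impute

        qs = filter_for_quantification(table, design)
        completed, _ = impute(table, qs)
        return run_differential(completed, qs, design)

    def test_overwhelming_effect_called_enriched(self, design):
        rng = np.random.default_rng(4)
        rows = {f"N{i}": list(rng.normal(25, 0.1, 6)) for i in range(30)}
        rows["HIT"] = [20.0, 20.05, 19.95, 22.0, 22.05, 21.95]
        table = make_log_table(rows, design)
        diff = self._quantify(design, table)
        assert diff.loc["HIT", "category"] == "R45-enriched"

    def test_stage_specific_routing(self, design):
        rng = np.random.default_rng(5)
        rows = {f"N{i}": list(rng.normal(25, 0.3, 6)) for i in range(10)}
        rows["RSPEC"] = [None, None, None, 24.0, 24.1, 23.9]
        table = make_log_table(rows, design)
        diff = self._quantify(design, table)
        assert diff.loc["RSPEC", "category"] == "R45-specific"
        assert np.isnan(diff.loc["RSPEC", "q_value"])

    def test_categories_partition_retained_set(self, design):
        rng = np.random.default_rng(6)
        vals = rng.normal(24, 2, (200, 6))
        vals[rng.random(vals.shape) < 0.15] = np.nan
        table = pd.DataFrame(vals, index=[f"P{i}" for i in range(200)],
                             columns=design.sample_ids)
        from lfqpipe.impute import impute

        qs = filter_for_quantification(table, design)
        completed, _ = impute(table, qs)
        diff = run_differential(completed, qs, design)
        counts = diff["category"].value_counts()
        assert counts.sum() == len(qs.retained_ids)
        assert set(counts.index) <= set(category_labels(design))

    def test_enriched_sign_matches_ratio(self, design):
        rng = np.random.default_rng(7)
        vals = rng.normal(24, 2, (150, 6))
        fc = rng.choice([-2.0, 0.0, 2.0], 150)
        vals[:, 3:] += fc[:, None]
        table = pd.DataFrame(vals, index=[f"P{i}" for i in range(150)],
                             columns=design.sample_ids)
        qs = filter_for_quantification(table, design)
        diff = run_differential(table, qs, design)
        up = diff[diff["category"] == "R45-enriched"]
        down = diff[diff["category"] == "MG30-enriched"]
        assert (up["log2_ratio"] > 0).all()
        assert (down["log2_ratio"] < 0).all()
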