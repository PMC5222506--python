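"""Cohort statistics against the packaged per-eye study table.

The published group summaries, t-test p-values and the packing-index /
vessel-density correlation were all verified against the per-case rows
before being frozen here.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coneflow.cohort import (
    CohortSchemaError,
    group_summary,
    load_cohort_csv,
    packaged_table1_path,
    reproduce_table1,
    spearman,
    t_test_pooled,
)
from oracles import spearman_hand


@pytest.fixture(scope="module")
def table1():
    return load_cohort_csv(packaged_table1_path())


class TestGroupSummary:
    def test_density_means_and_sds_match_published(self, table1):
        s = group_summary(table1, "dcp_density_pct")
        assert s["normal_dcp"]["mean"] == pytest.approx(60.14, abs=0.005)
        assert s["normal_dcp"]["sd"] == pytest.approx(2.91, abs=0.005)
        assert s["dcp_nonflow"]["n"] == 7  # one eye lacks OCTA density
        assert s["dcp_nonflow"]["mean"] == pytest.approx(50.21, abs=0.005)
        assert s["dcp_nonflow"]["sd"] == pytest.approx(5.21, abs=0.005)

    def test_hpi_group_means_match_published(self, table1):
        s = group_summary(table1, "hpi")
        assert s["normal_dcp"]["mean"] == pytest.approx(0.431, abs=0.0005)
        assert s["dcp_nonflow"]["mean"] == pytest.approx(0.358, abs=0.0005)

    def test_nonflow_hpi_dispersion_is_sd_of_per_case_values(self, table1):
        """Self-consistency: the SD of the eight non-flow packing-index
        values is ~0.039 (the published dispersion label for this cell
        matches their standard error instead and is not targeted)."""
        s = group_summary(table1, "hpi")
        assert s["dcp_nonflow"]["sd"] == pytest.approx(0.0394, abs=0.001)
        se = s["dcp_nonflow"]["sd"] / np.sqrt(s["dcp_nonflow"]["n"])
        assert se == pytest.approx(0.013, abs=0.001)

    def test_degenerate_equal_values_have_zero_sd(self):
        t = pd.DataFrame({"group": ["normal_dcp"] * 3 + ["dcp_nonflow"] * 2,
                          "hpi": [0.4, 0.4, 0.4, 0.3, 0.35]})
        assert group_summary(t, "hpi")["normal_dcp"]["sd"] == pytest.approx(
            0.0, abs=1e-12)

    def test_unknown_variable_rejected(self, table1):
        with pytest.raises(ValueError, match="unknown variable"):
            group_summary(table1, "not_a_column")


class TestTTest:
    def test_published_p_values_reproduced(self, table1):
        assert (t_test_pooled(table1, "dcp_density_pct").p_two_tailed
                == pytest.approx(0.016, abs=0.0005))
        assert (t_test_pooled(table1, "hpi").p_two_tailed
                == pytest.approx(0.013, abs=0.0005))

    def test_demographics_not_significant_as_published(self, table1):
        assert round(t_test_pooled(table1, "age_y").p_two_tailed, 2) == 0.54
        assert round(t_test_pooled(table1, "duration_y").p_two_tailed, 2) == 0.99
        assert (t_test_pooled(table1, "hba1c_pct").p_two_tailed
                == pytest.approx(0.084, abs=0.0005))

    def test_pooled_df_is_n1_plus_n2_minus_2(self, table1):
        comp = t_test_pooled(table1, "hpi")
        assert comp.df == comp.n1 + comp.n2 - 2 == 9

    def test_identical_groups_give_t_zero_p_one(self):
        t = pd.DataFrame({"group": ["normal_dcp"] * 3 + ["dcp_nonflow"] * 3,
                          "hpi": [0.3, 0.4, 0.5, 0.3, 0.4, 0.5]})
        comp = t_test_pooled(t, "hpi")
        assert comp.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert comp.p_two_tailed == pytest.approx(1.0)

    def test_swapping_group_labels_negates_t_preserves_p(self, table1):
        comp = t_test_pooled(table1, "hpi")
        swapped = table1.copy()
        swapped["group"] = swapped["group"].map(
            {"normal_dcp": "dcp_nonflow", "dcp_nonflow": "normal_dcp"})
        comp2 = t_test_pooled(swapped, "hpi")
        assert comp2.t_statistic == pytest.approx(-comp.t_statistic)
        assert comp2.p_two_tailed == pytest.approx(comp.p_two_tailed)

    def test_welch_flag_changes_df(self, table1):
        welch = t_test_pooled(table1, "dcp_density_pct", equal_var=False)
        assert welch.df != welch.n1 + welch.n2 - 2

    def test_single_member_group_rejected(self):
        t = pd.DataFrame({"group": ["normal_dcp", "dcp_nonflow",
                                    "dcp_nonflow"],
                          "hpi": [0.4, 0.3, 0.35]})
        with pytest.raises(ValueError, match="n >= 2"):
            t_test_pooled(t, "hpi")


class TestSpearman:
    def test_published_correlation_over_complete_pairs(self, table1):
        """r = 0.681, p = 0.030 over the 10 eyes with both modalities."""
        res = spearman(table1, "hpi", "dcp_density_pct")
        assert res.n == 10
        assert res.spearman_r == pytest.approx(0.681, abs=0.0005)
        assert res.p_two_tailed == pytest.approx(0.030, abs=0.0005)

    def test_monotone_function_gives_unit_correlation(self):
        t = pd.DataFrame({"x": [1.0, 2.0, 5.0, 9.0],
                          "y": [0.1, 0.2, 0.9, 3.0]})
        assert spearman(t, "x", "y").spearman_r == pytest.approx(1.0)

    def test_tied_ranks_match_hand_computation(self):
        """Average-rank Pearson on {(1,2),(2,2),(3,1)} equals the
        explicit hand-ranked computation."""
        t = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 2.0, 1.0]})
        res = spearman(t, "x", "y")
        assert res.spearman_r == pytest.approx(
            spearman_hand([1, 2, 3], [2, 2, 1]), abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_strictly_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        t = pd.DataFrame({"x": x, "y": y})
        t2 = pd.DataFrame({"x": np.exp(x), "y": y**3})
        assert (spearman(t, "x", "y").spearman_r
                == pytest.approx(spearman(t2, "x", "y").spearman_r, abs=1e-12))

    def test_exact_permutation_p_matches_enumeration_probability(self):
        """Exact-permutation p at n=5 with a perfectly monotone pair:
        only the identity and the full reversal of the 120 orderings
        achieve |r| = 1, so p = 2/120."""
        t = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0],
                          "y": [2.0, 4.0, 6.0, 8.0, 10.0]})
        res = spearman(t, "x", "y", exact=True)
        assert res.spearman_r == pytest.approx(1.0)
        assert res.p_two_tailed == pytest.approx(2 / 120)

    def test_zero_rank_variance_is_error(self):
        t = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="zero variance"):
            spearman(t, "x", "y")

    def test_fewer_than_three_pairs_rejected(self):
        t = pd.DataFrame({"x": [1.0, 2.0], "y": [2.0, 1.0]})
        with pytest.raises(ValueError, match="3 complete pairs"):
            spearman(t, "x", "y")


class TestReproduceTable1:
    def test_row_and_group_bookkeeping(self, table1):
        assert len(table1) == 11
        assert (table1["group"] == "normal_dcp").sum() == 3
        assert (table1["group"] == "dcp_nonflow").sum() == 8

    def test_published_medians(self, table1):
        assert table1["age_y"].median() == 43
        assert table1["duration_y"].median() == 8

    def test_full_report_flags_no_mismatch(self):
        report = reproduce_table1()
        assert report["all_ok"], [c for c in report["checks"] if not c["ok"]]

    def test_perturbed_table_is_flagged(self, tmp_path, table1):
        bad = table1.copy()
        bad.loc[0, "dcp_density_pct"] = 99.0
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        report = reproduce_table1(path)
        assert not report["all_ok"]

    def test_malformed_csv_names_offending_fields(self, tmp_path, table1):
        bad = table1.copy()
        bad.loc[2, "hpi"] = 3.5  # outside [-1, 1]
        path = tmp_path / "schema.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(CohortSchemaError, match="hpi"):
            load_cohort_csv(path)

    def test_missing_column_rejected(self, tmp_path, table1):
        path = tmp_path / "missing.csv"
        table1.drop(columns=["hpi"]).to_csv(path, index=False)
        with pytest.raises(CohortSchemaError, match="hpi"):
            load_cohort_csv(path)
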