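"""Fold-change calling, occurrence counting, selection, clustering, concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from agescreen.io import ComparisonDesign, ExpressionMatrix, ProbeGeneMap
from agescreen.occurrence import (
    SelectionRule,
    apply_selection,
    cluster_samples,
    collapse_to_genes,
    concordance,
    count_occurrences,
    fold_change_calls,
    linkage_to_newick,
    majority_cutoff,
)
from agescreen.simulate import DesignSpec, PlantedSpec, gen_expression

from conftest import make_design


def matrix_from_ratios(ratios):
    """One probe; comparison i has treated/control ratio ratios[i]."""
    n = len(ratios)
    cols = {}
    rows = []
    for i, r in enumerate(ratios):
        cols[f"c{i}"] = [10.0]
        cols[f"t{i}"] = [10.0 * r]
        rows.append((f"cmp{i}", "EG1", f"t{i}", f"c{i}", "M"))
    m = ExpressionMatrix(pd.DataFrame(cols, index=["p"]))
    d = ComparisonDesign(
        pd.DataFrame(rows, columns=["comparison_id", "group", "treated", "control", "model"])
    )
    return m, d


class TestFoldChangeCalls:
    @pytest.mark.parametrize(
        "treated,control,signed,call",
        [
            (10.0, 10.0, 1.0, 0),      # unchanged
            (15.0, 10.0, 1.5, 1),      # inclusive up threshold
            (10.0, 15.0, -1.5, -1),    # reciprocal symmetry, inclusive down
            (14.9, 10.0, 1.49, 0),
            (30.0, 10.0, 3.0, 1),
        ],
    )
    def test_signed_fold_convention(self, treated, control, signed, call):
        m = ExpressionMatrix(pd.DataFrame({"c": [control], "t": [treated]}, index=["p"]))
        d = ComparisonDesign(
            pd.DataFrame(
                [["c1", "EG1", "t", "c", "M"]],
                columns=["comparison_id", "group", "treated", "control", "model"],
            )
        )
        calls = fold_change_calls(m, d)
        assert calls.signed_fold.loc["p", "c1"] == pytest.approx(signed, rel=1e-9)
        assert calls.calls.loc["p", "c1"] == call

    def test_zero_intensities_are_eps_clamped(self):
        m = ExpressionMatrix(pd.DataFrame({"c": [0.0], "t": [0.0]}, index=["p"]))
        d = ComparisonDesign(
            pd.DataFrame(
                [["c1", "EG1", "t", "c", "M"]],
                columns=["comparison_id", "group", "treated", "control", "model"],
            )
        )
        calls = fold_change_calls(m, d)
        assert calls.signed_fold.loc["p", "c1"] == 1.0

    def test_invalid_parameters_rejected(self, tiny_matrix, tiny_design):
        with pytest.raises(ValueError, match="threshold"):
            fold_change_calls(tiny_matrix, tiny_design, threshold=0.5)
        with pytest.raises(ValueError, match="eps"):
            fold_change_calls(tiny_matrix, tiny_design, eps=0.0)


class TestCountOccurrences:
    def test_all_unchanged_counts_zero(self):
        m, d = matrix_from_ratios([1.0, 1.1, 0.9])
        occ = count_occurrences(fold_change_calls(m, d), d)
        assert occ.table.loc["p"].tolist() == [0, 0, 0, 0, 0, 0, 0]

    def test_hand_counted_five_comparison_fixture(self):
        # signed folds (+2.0, -1.6, +1.4, +1.5, -1.2) -> up 2, down 1, total 3
        m, d = matrix_from_ratios([2.0, 1 / 1.6, 1.4, 1.5, 1 / 1.2])
        occ = count_occurrences(fold_change_calls(m, d), d)
        row = occ.table.loc["p"]
        assert (row["eg1_up"], row["eg1_down"], row["eg1_total"]) == (2, 1, 3)

    def test_combined_total_is_sum_of_four_direction_counts(self):
        # the published worked example: counts (7, 7, 6, 7) combine to 27
        table = pd.DataFrame(
            {"eg1_up": [7], "eg1_down": [7], "eg2_up": [6], "eg2_down": [7]},
            index=["KIAA0101"],
        )
        table["eg1_total"] = table["eg1_up"] + table["eg1_down"]
        table["eg2_total"] = table["eg2_up"] + table["eg2_down"]
        table["combined_total"] = table["eg1_total"] + table["eg2_total"]
        assert table.loc["KIAA0101", "combined_total"] == 27

    @settings(max_examples=30, deadline=None)
    @given(
        st.integers(1, 8),
        st.integers(1, 6),
        st.integers(0, 2**31 - 1),
    )
    def test_counts_match_brute_force_recount(self, n_probes, n_comparisons, seed):
        """Vectorized counting equals a double loop over probes and comparisons."""
        rng = np.random.default_rng(seed)
        ratios = rng.uniform(0.3, 3.0, size=(n_probes, n_comparisons))
        cols = {}
        rows = []
        groups = ["EG1", "EG2"]
        for j in range(n_comparisons):
            cols[f"c{j}"] = np.full(n_probes, 10.0)
            cols[f"t{j}"] = 10.0 * ratios[:, j]
            rows.append((f"cmp{j}", groups[j % 2], f"t{j}", f"c{j}", "M"))
        m = ExpressionMatrix(
            pd.DataFrame(cols, index=[f"p{i}" for i in range(n_probes)])
        )
        d = ComparisonDesign(
            pd.DataFrame(rows, columns=["comparison_id", "group", "treated", "control", "model"])
        )
        occ = count_occurrences(fold_change_calls(m, d), d)

        for i in range(n_probes):
            expect = {"EG1": [0, 0], "EG2": [0, 0]}
            for j in range(n_comparisons):
                r = ratios[i, j]
                signed = r if r >= 1 else -1 / r
                g = groups[j % 2]
                if signed >= 1.5:
                    expect[g][0] += 1
                elif signed <= -1.5:
                    expect[g][1] += 1
            row = occ.table.loc[f"p{i}"]
            assert [row["eg1_up"], row["eg1_down"]] == expect["EG1"]
            assert [row["eg2_up"], row["eg2_down"]] == expect["EG2"]

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_raising_threshold_never_increases_counts(self, seed):
        rng = np.random.default_rng(seed)
        ratios = rng.uniform(0.2, 5.0, size=(6, 4))
        cols, rows = {}, []
        for j in range(4):
            cols[f"c{j}"] = np.full(6, 10.0)
            cols[f"t{j}"] = 10.0 * ratios[:, j]
            rows.append((f"cmp{j}", "EG1", f"t{j}", f"c{j}", "M"))
        m = ExpressionMatrix(pd.DataFrame(cols, index=[f"p{i}" for i in range(6)]))
        d = ComparisonDesign(
            pd.DataFrame(rows, columns=["comparison_id", "group", "treated", "control", "model"])
        )
        low = count_occurrences(fold_change_calls(m, d, threshold=1.5), d)
        high = count_occurrences(fold_change_calls(m, d, threshold=2.0), d)
        assert (high.table["combined_total"] <= low.table["combined_total"]).all()
        # direction exclusivity: up + down never exceeds group n
        assert (low.table["eg1_total"] <= d.n_eg1).all()


class TestCollapseAndSelection:
    def test_single_probe_gene_identity(self, tiny_matrix, tiny_design):
        occ = count_occurrences(fold_change_calls(tiny_matrix, tiny_design), tiny_design)
        pmap = ProbeGeneMap(
            pd.DataFrame({"probe_id": ["p1"], "gene_symbol": ["g1"]})
        )
        collapsed = collapse_to_genes(occ, pmap)
        assert collapsed.table.loc["g1"].equals(occ.table.loc["p1"])

    def test_max_policy_takes_larger_probe_count(self):
        table = pd.DataFrame(
            {
                "eg1_up": [3, 7, 1],
                "eg1_down": [0, 0, 0],
                "eg2_up": [0, 0, 2],
                "eg2_down": [0, 0, 0],
            },
            index=["pA1", "pA2", "pB1"],
        )
        for g in ("eg1", "eg2"):
            table[f"{g}_total"] = table[f"{g}_up"] + table[f"{g}_down"]
        table["combined_total"] = table["eg1_total"] + table["eg2_total"]
        from agescreen.occurrence import OccurrenceTable

        occ = OccurrenceTable(table, {"EG1": 10, "EG2": 10})
        pmap = ProbeGeneMap(
            pd.DataFrame(
                {"probe_id": ["pA1", "pA2", "pB1"], "gene_symbol": ["gA", "gA", "gB"]}
            )
        )
        collapsed = collapse_to_genes(occ, pmap, policy="max")
        assert len(collapsed.table) == 2
        assert collapsed.table.loc["gA", "eg1_up"] == 7
        best = collapse_to_genes(occ, pmap, policy="best_probe")
        assert best.table.loc["gA", "eg1_up"] == 7

    def test_empty_map_warns_and_passes_through(self, tiny_matrix, tiny_design):
        occ = count_occurrences(fold_change_calls(tiny_matrix, tiny_design), tiny_design)
        with pytest.warns(UserWarning, match="identity"):
            collapsed = collapse_to_genes(occ, None)
        assert collapsed.table.equals(occ.table)

    @pytest.mark.parametrize("n,cutoff", [(17, 9), (18, 10), (4, 3), (5, 3)])
    def test_majority_cutoff_is_strictly_more_than_half(self, n, cutoff):
        assert majority_cutoff(n) == cutoff

    def test_selection_rules_on_hand_table(self):
        from agescreen.occurrence import OccurrenceTable

        design = make_design(17, 18)
        table = pd.DataFrame(
            {
                "eg1_up": [9, 0, 6, 4],
                "eg1_down": [0, 0, 0, 4],
                "eg2_up": [6, 10, 0, 5],
                "eg2_down": [3, 0, 0, 4],
            },
            index=["hit_eg1", "hit_eg2", "screen_only", "combined17"],
        )
        for g in ("eg1", "eg2"):
            table[f"{g}_total"] = table[f"{g}_up"] + table[f"{g}_down"]
        table["combined_total"] = table["eg1_total"] + table["eg2_total"]
        occ = OccurrenceTable(table, {"EG1": 17, "EG2": 18})

        majority = apply_selection(occ, SelectionRule("per_group_majority"), design)
        assert set(majority) == {"hit_eg1", "hit_eg2"}
        # combined_total 17 misses the >= 18 combined rule (boundary)
        combined = apply_selection(occ, SelectionRule("combined_at_least", 18), design)
        assert set(combined) == {"hit_eg1"}
        screen = apply_selection(occ, SelectionRule("screen_at_least", 6), design)
        assert set(screen) == {"hit_eg1", "hit_eg2", "screen_only", "combined17"}

    def test_threshold_above_n_rejected(self):
        from agescreen.occurrence import OccurrenceTable

        design = make_design(2, 2)
        table = pd.DataFrame(
            {c: [0] for c in
             ["eg1_up", "eg1_down", "eg2_up", "eg2_down",
              "eg1_total", "eg2_total", "combined_total"]},
            index=["p"],
        )
        occ = OccurrenceTable(table, {"EG1": 2, "EG2": 2})
        with pytest.raises(ValueError, match="threshold"):
            apply_selection(occ, SelectionRule("combined_at_least", 99), design)


class TestPlantedRecovery:
    def test_majority_rule_recovers_planted_genes(self):
        """f = 3, phi = 0.8, noise_sd = 0.1: precision and recall >= 0.9."""
        world = gen_expression(
            m_probes=1_000,
            design_spec=DesignSpec(),
            planted_spec=PlantedSpec(n_genes=30, fold=3.0, penetrance=0.8),
            noise_sd=0.1,
            seed=11,
            probes_per_gene=1,
        )
        calls = fold_change_calls(world.matrix, world.design)
        occ = count_occurrences(calls, world.design)
        gene_level = collapse_to_genes(occ, world.probe_gene_map)
        selected = set(
            apply_selection(gene_level, SelectionRule("per_group_majority"), world.design)
        )
        truth = set(world.truth.gene_ids)
        recall = len(selected & truth) / len(truth)
        precision = len(selected & truth) / max(1, len(selected))
        assert recall >= 0.9
        assert precision >= 0.9


class TestClustering:
    def test_identical_samples_merge_at_height_zero(self):
        m = ExpressionMatrix(
            pd.DataFrame({"s1": [1.0, 2.0], "s2": [1.0, 2.0], "s3": [9.0, 9.0]},
                         index=["pa", "pb"])
        )
        Z, labels = cluster_samples(m, top_k_by_variance=2)
        assert Z[0, 2] == 0.0
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_upgma_hand_example_one_dimension(self):
        # samples at 0, 1, 10: merge (0,1) at height 1, then at (9+10)/2 = 9.5
        m = ExpressionMatrix(
            pd.DataFrame({"a": [0.0], "b": [1.0], "c": [10.0]}, index=["p"])
        )
        Z, labels = cluster_samples(m, top_k_by_variance=1)
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(9.5)
        nwk = linkage_to_newick(Z, labels)
        assert nwk.endswith(";") and "a" in nwk

    def test_variance_filter_keeps_top_k(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.uniform(1, 100, size=(50, 4)),
                          index=[f"p{i}" for i in range(50)],
                          columns=["s1", "s2", "s3", "s4"])
        m = ExpressionMatrix(df)
        Z_small, _ = cluster_samples(m, top_k_by_variance=10)
        Z_all, _ = cluster_samples(m, top_k_by_variance=50)
        assert Z_small.shape == Z_all.shape == (3, 4)

    def test_single_sample_rejected(self):
        m = ExpressionMatrix(pd.DataFrame({"s1": [1.0]}, index=["p"]))
        with pytest.raises(ValueError, match="2 samples"):
            cluster_samples(m)


class TestConcordance:
    def test_collinear_data_r_one_all_within(self):
        x = np.arange(1.0, 6.0)
        res = concordance(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.n_within == res.n_total == 5

    def test_against_hand_ols_oracle(self):
        """x = 1..5, y = x with y3 -> 10, checked against closed-form OLS."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 10.0, 4.0, 5.0])
        # closed form: slope = Sxy/Sxx, r = Sxy/sqrt(Sxx*Syy)
        xb, yb = x.mean(), y.mean()
        sxx = ((x - xb) ** 2).sum()
        syy = ((y - yb) ** 2).sum()
        sxy = ((x - xb) * (y - yb)).sum()
        slope = sxy / sxx
        intercept = yb - slope * xb
        r = sxy / np.sqrt(sxx * syy)
        res = concordance(x, y)
        assert res.slope == pytest.approx(slope)
        assert res.intercept == pytest.approx(intercept)
        assert res.r == pytest.approx(r)
        # hand prediction-interval count: residuals vs t(0.975, 3) * se_pred
        from scipy import stats

        resid = y - (intercept + slope * x)
        s = np.sqrt((resid**2).sum() / 3)
        se = s * np.sqrt(1 + 1 / 5 + (x - xb) ** 2 / sxx)
        expected_within = int((np.abs(resid) <= stats.t.ppf(0.975, 3) * se).sum())
        assert res.n_within == expected_within

    def test_report_format_counts_pairs(self):
        x = np.arange(1.0, 11.0)
        res = concordance(x, x)
        assert "of 10" in str(res) and "95% prediction interval" in str(res)

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            concordance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
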