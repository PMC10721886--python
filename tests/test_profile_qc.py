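"""Replicate QC, enrichment-efficiency metrics, abundance summaries, and
robust-change clustering."""

import numpy as np
import pandas as pd
import pytest

from ubiquant import (
    make_design,
    ibaq_summary,
    replicate_qc,
    robust_change_set,
    to_log_matrix,
    ubiquitin_fraction,
    zscore_hcluster,
)
from ubiquant.io_tables import PeptideTable


def log_matrix(values, design):
    df = pd.DataFrame(
        values, index=[f"P{i:03d}" for i in range(len(values))], columns=list(design.samples)
    )
    return to_log_matrix(np.exp2(df), design)


class TestReplicateQc:
    def test_duplicated_sample_perfect_correlation(self):
        design = make_design([("A", 2)])
        rng = np.random.default_rng(0)
        col = rng.normal(30, 2, 50)
        m = log_matrix(np.column_stack([col, col]), design)
        qc = replicate_qc(m, design)
        assert qc.pearson.loc["A_1", "A_2"] == pytest.approx(1.0)

    def test_negated_centred_column_anticorrelated(self):
        design = make_design([("A", 2)])
        rng = np.random.default_rng(1)
        col = rng.normal(0, 1, 50) + 30
        m = log_matrix(np.column_stack([col, 60 - col]), design)
        qc = replicate_qc(m, design)
        assert qc.pearson.loc["A_1", "A_2"] == pytest.approx(-1.0)

    def test_pearson_symmetric_unit_diagonal(self):
        design = make_design([("A", 3), ("B", 3)])
        rng = np.random.default_rng(2)
        m = log_matrix(rng.normal(30, 2, (80, 6)), design)
        qc = replicate_qc(m, design)
        p = qc.pearson.to_numpy()
        np.testing.assert_allclose(p, p.T)
        np.testing.assert_allclose(np.diag(p), 1.0)

    def test_cv_zero_for_constant_group(self):
        design = make_design([("A", 3)])
        m = log_matrix(np.log2([[10.0, 10.0, 10.0]]), design)
        qc = replicate_qc(m, design)
        assert qc.cv.loc["P000", "A"] == pytest.approx(0.0)

    def test_too_few_joint_rows_undefined(self):
        design = make_design([("A", 2)])
        lin = np.array([[4.0, 0.0], [0.0, 8.0], [2.0, 2.0]])
        df = pd.DataFrame(lin, index=["P0", "P1", "P2"], columns=list(design.samples))
        qc = replicate_qc(to_log_matrix(df, design), design)
        assert np.isnan(qc.pearson.loc["A_1", "A_2"])

    def test_pca_separates_groups(self):
        design = make_design([("A", 3), ("B", 3)])
        rng = np.random.default_rng(3)
        base = rng.normal(30, 2, (100, 1))
        X = base + rng.normal(0, 0.1, (100, 6))
        X[:30, 3:] += 2.0  # group B shift on a subset
        qc = replicate_qc(log_matrix(X, design), design)
        pc1 = qc.pca_scores["PC1"]
        a = pc1[list(design.samples_of("A"))].to_numpy()
        b = pc1[list(design.samples_of("B"))].to_numpy()
        between = abs(a.mean() - b.mean())
        within = max(a.std(), b.std(), 1e-12)
        assert between > 5 * within


class TestUbiquitinFraction:
    def make_peptides(self, rows, design):
        return PeptideTable(
            df=pd.DataFrame(rows, columns=["peptide_sequence", "protein_ids", "sample", "intensity"]),
            design=design,
        )

    def test_ninety_percent(self):
        design = make_design([("A", 1)])
        pep = self.make_peptides(
            [("u1", "UBB", "A_1", 90.0), ("p1", "P1", "A_1", 10.0)], design
        )
        pct, _ = ubiquitin_fraction(pep, {"UBB"}, design)
        assert pct["A_1"] == pytest.approx(90.0)

    def test_zero_and_hundred(self):
        design = make_design([("A", 1)])
        pep = self.make_peptides([("p1", "P1", "A_1", 10.0)], design)
        pct, _ = ubiquitin_fraction(pep, {"UBB"}, design)
        assert pct["A_1"] == 0.0
        pep_all = self.make_peptides([("u1", "UBB;P9", "A_1", 10.0)], design)
        pct_all, _ = ubiquitin_fraction(pep_all, {"UBB"}, design)
        assert pct_all["A_1"] == 100.0

    def test_disjoint_subsets_add(self):
        design = make_design([("A", 1)])
        rows = [("u1", "UBB", "A_1", 30.0), ("u2", "UBC", "A_1", 20.0), ("p1", "P1", "A_1", 50.0)]
        pep = self.make_peptides(rows, design)
        a, _ = ubiquitin_fraction(pep, {"UBB"}, design)
        b, _ = ubiquitin_fraction(pep, {"UBC"}, design)
        both, _ = ubiquitin_fraction(pep, {"UBB", "UBC"}, design)
        assert both["A_1"] == pytest.approx(a["A_1"] + b["A_1"])

    def test_zero_total_warns_nan(self):
        design = make_design([("A", 2)])
        pep = self.make_peptides([("p1", "P1", "A_1", 10.0)], design)
        with pytest.warns(UserWarning, match="A_2"):
            pct, _ = ubiquitin_fraction(pep, {"UBB"}, design)
        assert np.isnan(pct["A_2"])

    def test_empty_accession_set_fatal(self):
        design = make_design([("A", 1)])
        pep = self.make_peptides([("p1", "P1", "A_1", 1.0)], design)
        with pytest.raises(ValueError):
            ubiquitin_fraction(pep, set(), design)


class TestIbaqSummary:
    def test_median_and_range(self):
        ibaq = pd.DataFrame({"s1": [1e6, 1e7, 1e8]}, index=["P1", "P2", "P3"])
        out = ibaq_summary(ibaq)
        assert out["median_log10"] == pytest.approx(7.0)
        assert out["dynamic_range_fold"] == pytest.approx(100.0)

    def test_single_protein_unit_range(self):
        out = ibaq_summary(pd.DataFrame({"s1": [5e4]}, index=["P1"]))
        assert out["dynamic_range_fold"] == pytest.approx(1.0)

    def test_scaling_shifts_median_not_range(self):
        rng = np.random.default_rng(4)
        ibaq = pd.DataFrame({"s1": rng.lognormal(15, 2, 50)})
        a = ibaq_summary(ibaq)
        b = ibaq_summary(ibaq * 10)
        assert b["median_log10"] == pytest.approx(a["median_log10"] + 1.0)
        assert b["dynamic_range_fold"] == pytest.approx(a["dynamic_range_fold"])

    def test_empty_subset_fatal(self):
        with pytest.raises(ValueError):
            ibaq_summary(pd.DataFrame({"s1": [0.0]}, index=["P1"]))


class TestRobustChange:
    design = make_design([("G1", 4), ("G2", 4), ("G3", 4)])

    def test_stated_rule_example(self):
        row = [5.0] * 4 + [1.0] * 4 + [3.0] * 4
        m = log_matrix([row], self.design)
        assert robust_change_set(m, self.design) == ["P000"]

    def test_constant_row_excluded(self):
        m = log_matrix([[2.0] * 12], self.design)
        assert robust_change_set(m, self.design) == []

    def test_no_group_fully_below_excluded(self):
        # G1 entirely above the median, but no group entirely below
        row = [5.0] * 4 + [1.0, 3.5, 3.5, 3.5] + [1.0, 3.5, 3.5, 3.5]
        m = log_matrix([row], self.design)
        assert robust_change_set(m, self.design) == []

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(30, 3, (40, 12))
        m = log_matrix(X, self.design)
        base = robust_change_set(m, self.design)
        # strictly increasing transform: exp scaled
        m2 = log_matrix(np.exp(X / 10.0), self.design)
        assert robust_change_set(m2, self.design) == base

    def test_needs_two_groups(self):
        m = log_matrix([[1.0] * 12], self.design)
        with pytest.raises(ValueError):
            robust_change_set(m, self.design, groups=["G1"])


class TestZscoreCluster:
    def test_rows_standardized(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(30, 2, (20, 6)),
                          index=[f"P{i:02d}" for i in range(20)],
                          columns=[f"s{j}" for j in range(6)])
        res = zscore_hcluster(df)
        np.testing.assert_allclose(res.z_matrix.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(res.z_matrix.std(axis=1, ddof=0), 1.0, atol=1e-9)

    def test_identical_rows_merge_first(self):
        df = pd.DataFrame(
            [[1.0, 2, 3, 4], [1.0, 2, 3, 4], [4.0, 3, 2, 1]],
            index=["Pa", "Pb", "Pc"],
            columns=list("wxyz"),
        )
        res = zscore_hcluster(df)
        first_merge = set(res.row_linkage[0, :2].astype(int))
        labels = {list(res.z_matrix.index).index("Pa"), list(res.z_matrix.index).index("Pb")}
        assert first_merge == labels
        assert res.row_linkage[0, 2] == pytest.approx(0.0)

    def test_recovers_four_templates(self):
        rng = np.random.default_rng(9)
        templates = np.array(
            [[3, 3, 0, 0, 0, 0], [0, 0, 3, 3, 0, 0], [0, 0, 0, 0, 3, 3], [3, 0, 0, 3, 0, 3]],
            dtype=float,
        )
        rows, truth = [], []
        for t_i, tpl in enumerate(templates):
            for _ in range(10):
                rows.append(tpl + rng.normal(0, 0.1, 6))
                truth.append(t_i)
        df = pd.DataFrame(rows, index=[f"P{i:02d}" for i in range(40)],
                          columns=[f"s{j}" for j in range(6)])
        res = zscore_hcluster(df, n_clusters=4)
        labels = res.cluster_labels.reindex(df.index)
        truth = pd.Series(truth, index=df.index)
        for t_i in range(4):
            members = labels[truth == t_i]
            assert members.nunique() == 1  # template rows stay together
        assert labels.nunique() == 4

    def test_zero_variance_row_excluded_with_warning(self):
        df = pd.DataFrame(
            [[1.0, 1, 1, 1], [1.0, 2, 3, 4], [4.0, 3, 2, 1]],
            index=["Pflat", "Pa", "Pb"],
            columns=list("wxyz"),
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            res = zscore_hcluster(df)
        assert "Pflat" not in res.z_matrix.index
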