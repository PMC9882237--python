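"""Count ingestion, filtering, NT normalization, L2FC, null scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lethaldyn.screen import (
    NONTARGETING,
    collapse_genes,
    compute_l2fc,
    concordance_test,
    filter_guides,
    make_pseudo_genes,
    normalize_depth,
    read_counts,
    score_vs_null,
    write_counts,
    CountMatrix,
)
from conftest import toy_count_matrix


class TestReadWrite:
    def _write_toy(self, tmp_path, counts_text=None):
        counts = tmp_path / "counts.tsv"
        counts.write_text(counts_text or (
            "sgRNA\tgene\tT0_r1\tuntreated_r1\ttreated_r1\n"
            "sg1\tGENEA\t10\t20\t30\n"
            "sg2\tGENEA\t5\t6\t7\n"
            "sg3\tNONTARGETING\t100\t100\t100\n"
        ))
        sheet = tmp_path / "samples.csv"
        sheet.write_text(
            "sample_id,condition,replicate\n"
            "T0_r1,T0,1\nuntreated_r1,untreated,1\ntreated_r1,treated,1\n"
        )
        return counts, sheet

    def test_roundtrip_bit_identical(self, tmp_path):
        counts, sheet = self._write_toy(tmp_path)
        cm = read_counts(counts, sheet)
        out = tmp_path / "again.tsv"
        write_counts(cm, out)
        assert out.read_text() == counts.read_text()

    def test_negative_count_names_cell(self, tmp_path):
        counts, sheet = self._write_toy(
            tmp_path,
            "sgRNA\tgene\tT0_r1\tuntreated_r1\ttreated_r1\n"
            "sg1\tGENEA\t10\t-3\t30\n",
        )
        with pytest.raises(ValueError, match="sg1.*untreated_r1"):
            read_counts(counts, sheet)

    def test_missing_t0_warns_but_builds(self, tmp_path):
        counts, _ = self._write_toy(tmp_path)
        sheet = tmp_path / "s.csv"
        sheet.write_text(
            "sample_id,condition,replicate\n"
            "T0_r1,untreated,1\nuntreated_r1,untreated,2\ntreated_r1,treated,1\n"
        )
        with pytest.warns(UserWarning, match="T0"):
            cm = read_counts(counts, sheet)
        assert cm.n_guides == 3

    def test_duplicate_sgrna_rejected(self, tmp_path):
        counts, sheet = self._write_toy(
            tmp_path,
            "sgRNA\tgene\tT0_r1\tuntreated_r1\ttreated_r1\n"
            "sg1\tGENEA\t1\t1\t1\nsg1\tGENEB\t2\t2\t2\n",
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_counts(counts, sheet)

    def test_unknown_condition_rejected(self, tmp_path):
        counts, _ = self._write_toy(tmp_path)
        sheet = tmp_path / "s.csv"
        sheet.write_text(
            "sample_id,condition,replicate\n"
            "T0_r1,T0,1\nuntreated_r1,mock,1\ntreated_r1,treated,1\n"
        )
        with pytest.raises(ValueError, match="mock"):
            read_counts(counts, sheet)


class TestFilterGuides:
    def test_removes_exactly_five_percent(self):
        cm = toy_count_matrix(n_genes=20, guides_per_gene=2, n_nt=60)  # 100 guides
        cm.counts.iloc[:10, :] = np.arange(1, 11)[:, None]  # 10 low guides
        out = filter_guides(cm)
        assert cm.n_guides == 100 and out.n_guides == 95
        assert out.log["filter_guides"]["n_trimmed_low_count"] == 5
        # the five lowest-total guides are gone
        assert set(cm.counts.index[:5]).isdisjoint(out.counts.index)

    def test_tie_break_lexicographic(self):
        cm = toy_count_matrix(n_genes=20, guides_per_gene=2, n_nt=60)
        # all guides tied: the 5 lexicographically smallest ids are removed
        out = filter_guides(cm)
        removed = set(cm.counts.index) - set(out.counts.index)
        assert removed == set(sorted(cm.counts.index)[:5])

    def test_mirna_removal_is_noop_without_mirnas(self):
        cm = toy_count_matrix()
        assert filter_guides(cm).log["filter_guides"]["n_mirna_removed"] == 0

    def test_mirna_guides_removed(self):
        cm = toy_count_matrix()
        cm.guides.loc["sg_G0_0", "is_mirna"] = True
        out = filter_guides(cm)
        assert "sg_G0_0" not in out.counts.index

    def test_bottleneck_guard(self):
        cm = toy_count_matrix(n_genes=10, guides_per_gene=1, n_nt=60)
        # zero out enough single-guide genes that >20% of genes vanish
        cm.counts.loc[[f"sg_G{i}_0" for i in range(5)], :] = 0
        with pytest.raises(ValueError, match="bottleneck"):
            filter_guides(cm)


class TestNormalizeDepth:
    def test_doubled_sample_ratio_two_to_one(self):
        cm = toy_count_matrix(n_nt=60)
        cm.counts["treated_r1"] *= 2
        cm.counts["treated_r2"] *= 2
        out = normalize_depth(cm)
        sf = out.size_factors
        assert sf["treated_r1"] / sf["T0_r1"] == pytest.approx(2.0, rel=1e-12)
        # normalized matrices equal across samples again
        np.testing.assert_allclose(out.counts["treated_r1"], out.counts["T0_r1"],
                                   rtol=1e-12)

    def test_identical_samples_unit_factors(self):
        out = normalize_depth(toy_count_matrix())
        np.testing.assert_allclose(out.size_factors, 1.0, rtol=1e-12)

    def test_targeting_gene_change_leaves_factors(self):
        cm = toy_count_matrix()
        base = normalize_depth(toy_count_matrix()).size_factors
        cm.counts.loc["sg_G0_0"] *= 10  # non-NT guide
        out = normalize_depth(cm)
        np.testing.assert_allclose(out.size_factors, base, rtol=1e-12)

    def test_idempotent(self):
        cm = toy_count_matrix()
        cm.counts["T0_r1"] *= 3
        once = normalize_depth(cm)
        again = normalize_depth(
            CountMatrix(counts=once.counts, guides=once.guides, samples=once.samples)
        )
        np.testing.assert_allclose(again.size_factors, 1.0, rtol=1e-12)

    def test_all_zero_nt_sample_errors(self):
        cm = toy_count_matrix()
        nt = cm.guides.index[cm.guides["is_nontargeting"]]
        cm.counts.loc[nt, "T0_r1"] = 0
        with pytest.raises(ValueError, match="zero"):
            normalize_depth(cm)


class TestL2FCAndCollapse:
    def test_l2fc_examples(self, toy_cm):
        cm = normalize_depth(toy_cm)
        cm.counts.loc["sg_G0_0", ["treated_r1", "treated_r2"]] = 400.0
        cm.counts.loc["sg_G0_0", ["untreated_r1", "untreated_r2"]] = 100.0
        l2fc = compute_l2fc(cm, ("treated", "untreated"), pseudocount=0)
        assert l2fc["sg_G0_0"] == pytest.approx(2.0)
        assert l2fc["sg_G1_0"] == pytest.approx(0.0)

    def test_zero_with_pseudocount(self, toy_cm):
        cm = normalize_depth(toy_cm)
        cm.counts.loc["sg_G0_0", ["treated_r1", "treated_r2"]] = 0.0
        l2fc = compute_l2fc(cm, ("treated", "untreated"), pseudocount=1)
        assert l2fc["sg_G0_0"] == pytest.approx(np.log2(1 / 101), rel=1e-9)

    def test_collapse_mean_and_counts(self):
        l2fc = pd.Series([-1.0, 0.0, 1.0, 0.7], index=["a", "b", "c", "d"])
        genes = pd.Series(["G1", "G1", "G1", "G2"], index=l2fc.index)
        out = collapse_genes(l2fc, genes)
        assert out.loc["G1", "l2fc"] == pytest.approx(0.0)
        assert out.loc["G1", "n_guides"] == 3
        assert out.loc["G2", "l2fc"] == pytest.approx(0.7)  # single guide

    def test_scaling_one_gene_by_two_gives_plus_one(self, toy_cm):
        cm = normalize_depth(toy_cm)
        g0 = cm.guides.index[cm.guides["gene"] == "G0"]
        cm.counts.loc[g0, ["treated_r1", "treated_r2"]] *= 2
        l2fc = compute_l2fc(cm, ("treated", "untreated"), pseudocount=0)
        gene = collapse_genes(l2fc[~cm.guides["is_nontargeting"]], cm.guides["gene"])
        assert gene.loc["G0", "l2fc"] == pytest.approx(1.0, rel=1e-12)
        assert gene.loc["G1", "l2fc"] == pytest.approx(0.0, abs=1e-12)


class TestPseudoGenes:
    def test_thousand_nt_gives_166(self):
        ids = [f"nt{i:04d}" for i in range(1000)]
        labels = make_pseudo_genes(ids, guides_per_gene=6, seed=1)
        assert labels.nunique() == 166
        assert len(labels) == 996  # 4 leftovers discarded

    def test_deterministic_under_seed(self):
        ids = [f"nt{i}" for i in range(100)]
        a = make_pseudo_genes(ids, seed=5)
        b = make_pseudo_genes(ids, seed=5)
        c = make_pseudo_genes(ids, seed=6)
        pd.testing.assert_series_equal(a, b)
        assert not a.equals(c)

    def test_exactly_one_pseudo_gene(self):
        labels = make_pseudo_genes([f"nt{i}" for i in range(6)], seed=0)
        assert labels.nunique() == 1

    def test_too_few_errors(self):
        with pytest.raises(ValueError):
            make_pseudo_genes(["nt1"], guides_per_gene=6)


class TestScoreVsNull:
    def test_null_mean_scores_zero(self):
        rng = np.random.default_rng(0)
        null = rng.normal(0, 1, 500)
        vals = pd.Series([null.mean()], index=["g"])
        out = score_vs_null(vals, null, n_boot=5000, seed=1)
        assert out["z"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert out["p_empiric"].iloc[0] > 0.9

    def test_three_sigma_tail_matches_normal(self):
        rng = np.random.default_rng(2)
        null = rng.normal(0, 1, 200_000)
        vals = pd.Series([null.mean() + 3 * null.std(ddof=1)], index=["g"])
        out = score_vs_null(vals, null, n_boot=200_000, seed=3)
        assert out["p_empiric"].iloc[0] == pytest.approx(0.0027, abs=0.001)

    def test_bh_monotone_after_sorting_by_p(self):
        rng = np.random.default_rng(4)
        null = rng.normal(0, 1, 300)
        vals = pd.Series(rng.normal(0, 2, 50))
        out = score_vs_null(vals, null, n_boot=2000, seed=5).sort_values("p_empiric")
        assert (np.diff(out["fdr"]) >= -1e-12).all()
        assert (out["fdr"] >= out["p_empiric"] - 1e-12).all()

    def test_degenerate_null_errors(self):
        with pytest.raises(ValueError):
            score_vs_null(pd.Series([1.0]), np.ones(50))


class TestConcordance:
    def test_odds_ratio_81(self):
        res = concordance_test([[9, 1], [1, 9]])
        assert res.odds_ratio == pytest.approx(81.0)
        assert not res.haldane_corrected
        assert res.p_value == pytest.approx(
            stats.fisher_exact([[9, 1], [1, 9]], alternative="greater")[1]
        )

    def test_symmetric_table(self):
        res = concordance_test([[5, 5], [5, 5]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value > 0.5  # enrichment tail of a symmetric table

    def test_haldane_correction(self):
        res = concordance_test([[10, 0], [0, 10]])
        assert res.haldane_corrected
        assert res.odds_ratio == pytest.approx(441.0)

    def test_rejects_bad_table(self):
        with pytest.raises(ValueError):
            concordance_test([[1, 2, 3], [4, 5, 6]])
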