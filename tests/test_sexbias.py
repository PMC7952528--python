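"""BH adjustment, the NB Wald DE test, directional binomial tests, intron
usage LRT, term enrichment, PCA and ohnolog concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import silhouette_score

from ohnokit import pipeline
from ohnokit.models import ExpressionMatrix, IntronCluster, OhnologPair
from ohnokit.sexbias import (de_recovery, de_test, direction_bias_test,
                             filter_clusters, intron_usage_test,
                             ohnolog_sexbias_concordance, pca_summary,
                             term_enrichment)
from ohnokit.simulate import (simulate_intron_clusters, simulate_sex_counts,
                              simulate_wgd_genome)
from ohnokit.stats import bh_adjust


def _sex_matrix(counts, n_per_sex):
    samples = [f"M{i}" for i in range(n_per_sex)] + [f"F{i}" for i in range(n_per_sex)]
    meta = pd.DataFrame({"sex": ["male"] * n_per_sex + ["female"] * n_per_sex},
                        index=pd.Index(samples, name="sample"))
    genes = [f"g{i}" for i in range(np.asarray(counts).shape[0])]
    return ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=samples), meta)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_stepup_forces_equal_values(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_quadratic_direct_implementation(self, ps):
        adj = bh_adjust(ps)
        m = len(ps)
        order = sorted(range(m), key=lambda i: ps[i])
        direct = [None] * m
        for rank_pos, i in enumerate(order):
            # min over j >= i (in sorted order) of m*p_j/(rank of j)
            direct[i] = min(1.0, min(m * ps[j] / (k + 1)
                                     for k, j in enumerate(order) if k >= rank_pos))
        assert adj == pytest.approx(direct)
        # adjusted never below raw; monotone non-decreasing in sorted order
        assert all(a >= p - 1e-12 for a, p in zip(adj, ps))
        sorted_adj = adj[np.argsort(ps, kind="stable")]
        assert (np.diff(sorted_adj) >= -1e-12).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(0, 1, 200)
        assert bh_adjust(p) == pytest.approx(multipletests(p, method="fdr_bh")[1])


class TestDETest:
    def test_identical_counts_in_both_groups_are_null(self):
        counts = np.tile([[40], [7], [100]], (1, 8))
        mat = _sex_matrix(counts, 4)
        de = de_test(mat)
        assert de["log2_fold_change"].abs().max() == pytest.approx(0.0)
        assert (de["p_value"] > 0.9).all()
        assert (de["direction"] == "none").all()

    def test_single_sex_rejected(self):
        counts = np.tile([[40]], (1, 6))
        samples = [f"M{i}" for i in range(6)]
        meta = pd.DataFrame({"sex": ["male"] * 6}, index=pd.Index(samples, name="sample"))
        mat = ExpressionMatrix(pd.DataFrame(counts, index=["g0"], columns=samples), meta)
        with pytest.raises(ValueError):
            de_test(mat)

    def test_all_zero_genes_excluded_from_testing(self, rng):
        counts = rng.poisson(30, (50, 12))
        counts[7] = 0
        de = de_test(_sex_matrix(counts, 6))
        assert "g7" not in de.index
        assert len(de) == 49

    def test_recovery_on_simulated_truth(self, bundle):
        de = de_test(bundle.sex_counts)
        rec = de_recovery(de, bundle.truth.true_sex_biased)
        assert rec["sensitivity"] >= 0.6
        assert rec["fdr"] <= 0.1

    def test_significant_directions_partition(self, bundle):
        de = de_test(bundle.sex_counts)
        sig = de[de["p_adjusted"] < 0.05]
        assert ((sig["direction"] == "male") | (sig["direction"] == "female")).all()
        bias = direction_bias_test(de)
        assert bias["n_male"] + bias["n_female"] == len(sig)


class TestDirectionBias:
    def test_majority_female_transcriptome_scenario(self):
        res = direction_bias_test((1969, 3689))
        assert res["p_value"] < 1e-4

    def test_male_skewed_immune_scenario(self):
        res = direction_bias_test((158, 269))
        assert res["p_value"] < 0.03

    def test_even_split_gives_p_one(self):
        assert direction_bias_test((20, 40))["p_value"] == pytest.approx(1.0)

    def test_empty_subset_reported_na(self):
        assert direction_bias_test((0, 0))["p_value"] is None


class TestIntronUsage:
    def test_identical_proportions_give_zero_lrt(self):
        counts = np.tile([[30], [60], [10]], (1, 12))
        cl = IntronCluster("c1", [("chr1", 0, 100, "+")] * 3, counts)
        res = intron_usage_test([cl], ["male"] * 6 + ["female"] * 6)
        assert res.loc["c1", "lrt"] == pytest.approx(0.0)
        assert res.loc["c1", "p_value"] == pytest.approx(1.0)

    def test_low_read_cluster_filtered(self):
        counts = np.tile([[2], [2]], (1, 10))  # 40 total reads < 50
        cl = IntronCluster("c1", [("chr1", 0, 100, "+")] * 2, counts)
        assert filter_clusters([cl]) == []

    def test_long_intron_and_sparse_intron_dropped(self):
        counts = np.tile([[10], [10], [0]], (1, 10))
        introns = [("chr1", 0, 100, "+"), ("chr1", 0, 600_000, "+"), ("chr1", 0, 80, "+")]
        kept = filter_clusters([IntronCluster("c1", introns, counts)])
        assert kept == []  # long intron + zero-read intron leave a single intron

    def test_too_few_samples_per_group_untestable(self):
        counts = np.tile([[30], [60]], (1, 8))
        cl = IntronCluster("c1", [("chr1", 0, 100, "+")] * 2, counts)
        res = intron_usage_test([cl], ["male"] * 4 + ["female"] * 4,
                                min_samples_per_group=5)
        assert np.isnan(res.loc["c1", "p_value"])

    def test_invariant_to_intron_relabeling(self, rng):
        counts = rng.poisson(20, (4, 12)) + 1
        sexes = ["male"] * 6 + ["female"] * 6
        cl = IntronCluster("c1", [("chr1", i, i + 50, "+") for i in range(4)], counts)
        perm = rng.permutation(4)
        cl2 = IntronCluster("c1", [cl.introns[i] for i in perm], counts[perm])
        r1 = intron_usage_test([cl], sexes)
        r2 = intron_usage_test([cl2], sexes)
        assert r1.loc["c1", "lrt"] == pytest.approx(r2.loc["c1", "lrt"])

    def test_detects_simulated_usage_shift(self):
        clusters, sexes, perturbed = simulate_intron_clusters(
            60, 12, seed=8, effect_clusters=20, effect_size=3.0)
        res = intron_usage_test(filter_clusters(clusters), sexes)
        sig = set(res.index[res["p_adjusted"] < 0.05])
        hits = len(sig & perturbed)
        assert hits / 20 >= 0.6
        assert len(sig - perturbed) <= 5


class TestTermEnrichment:
    def _annotation(self, rng, n_genes=300, n_terms=8, per_gene=3):
        rows = []
        terms = [f"T{i}" for i in range(n_terms)]
        for g in range(n_genes):
            for t in rng.choice(terms, per_gene, replace=False):
                rows.append((f"g{g}", t))
        return pd.DataFrame(rows, columns=["gene_id", "term_id"])

    def test_proportional_representation_is_null(self, rng):
        annot = self._annotation(rng)
        gene_set = {f"g{i}" for i in range(0, 300, 3)}  # unrelated to terms
        res = term_enrichment(annot, gene_set=gene_set, report_all=True)
        assert (res["p_value"] > 0.01).all()

    def test_small_terms_skipped_by_node_size(self):
        rows = ([(f"g{i}", "BIG") for i in range(25)]
                + [(f"g{i}", "SMALL") for i in range(19)])
        annot = pd.DataFrame(rows, columns=["gene_id", "term_id"])
        res = term_enrichment(annot, gene_set={"g1", "g2"}, node_size=20, report_all=True)
        assert set(res["term_id"]) == {"BIG"}

    def test_fisher_p_equals_hypergeometric_tail(self, rng):
        annot = self._annotation(rng)
        gene_set = set(rng.choice([f"g{i}" for i in range(300)], 60, replace=False))
        res = term_enrichment(annot, gene_set=gene_set, report_all=True)
        background = annot["gene_id"].nunique()
        for row in res.itertuples(index=False):
            expected = stats.hypergeom.sf(row.n_hit - 1, background, len(gene_set), row.n_term)
            assert row.p_value == pytest.approx(expected, rel=1e-9)

    def test_ks_mode_detects_shifted_scores(self, rng):
        annot = self._annotation(rng)
        scores = pd.Series(rng.uniform(0, 1, 300), index=[f"g{i}" for i in range(300)])
        target = annot.loc[annot["term_id"] == "T0", "gene_id"].unique()
        scores.loc[target] = rng.uniform(0, 0.05, len(target))
        res = term_enrichment(annot, scores=scores, mode="ks", report_all=True)
        res = res.set_index("term_id")
        assert res.loc["T0", "p_value"] < 0.001
        assert res.loc["T0", "p_value"] == res["p_value"].min()

    def test_invariant_to_gene_renaming(self, rng):
        annot = self._annotation(rng)
        gene_set = set(rng.choice([f"g{i}" for i in range(300)], 50, replace=False))
        res1 = term_enrichment(annot, gene_set=gene_set, report_all=True)
        rename = {f"g{i}": f"zz{i}" for i in range(300)}
        annot2 = annot.assign(gene_id=annot["gene_id"].map(rename))
        res2 = term_enrichment(annot2, gene_set={rename[g] for g in gene_set}, report_all=True)
        assert res1["p_value"].tolist() == pytest.approx(res2["p_value"].tolist())


class TestPCA:
    def test_duplicate_samples_coincide(self, rng):
        counts = rng.poisson(50, (80, 6))
        counts[:, 5] = counts[:, 4]  # exact duplicate library
        mat = _sex_matrix(counts, 3)
        res = pca_summary(mat)
        scores = res["scores"]
        assert np.allclose(scores.iloc[4], scores.iloc[5], atol=1e-8)

    def test_variance_fractions_well_formed(self, bundle):
        res = pca_summary(bundle.sex_counts)
        ev = np.array(res["explained_variance"])
        assert ev.sum() <= 1.0 + 1e-9
        assert (np.diff(ev) <= 1e-12).all()

    def test_strong_sex_effect_separates_on_pc1(self):
        from ohnokit.config import SimConfig
        cfg = SimConfig(seed=3, frac_sex_biased=0.5, lfc_mean=2.0, n_genes=200)
        _, dup, truth = simulate_wgd_genome(cfg)
        mat = simulate_sex_counts(dup, truth, cfg)
        res = pca_summary(mat)
        pc1 = res["scores"]["PC1"].to_numpy().reshape(-1, 1)
        labels = (mat.sample_meta["sex"] == "male").astype(int)
        assert silhouette_score(pc1, labels) > 0.5


class TestConcordance:
    def _de(self, directions):
        return pd.DataFrame({"direction": pd.Series(directions)})

    def test_same_direction_concordant(self):
        df, summary = ohnolog_sexbias_concordance(
            self._de({"a": "male", "b": "male"}), [OhnologPair("a", "b")])
        assert df["label"].iloc[0] == "concordant"
        assert summary["concordant_fraction"] == 1.0

    def test_opposite_directions_discordant_with_roles(self, divergence_reports):
        reports, _ = divergence_reports
        rep = reports[0]
        de = self._de({rep.conserved_copy: "male", rep.diverged_copy: "female"})
        df, _ = ohnolog_sexbias_concordance(de, [rep.pair], [rep])
        assert df["label"].iloc[0] == "discordant"
        assert set(df[["role_1", "role_2"]].iloc[0]) == {"conserved", "diverged"}

    def test_inherited_sex_effect_gives_concordant_pairs(self, bundle, called_pairs):
        de = de_test(bundle.sex_counts)
        _, summary = ohnolog_sexbias_concordance(
            de, [p for p in called_pairs if p.called])
        assert summary["n_doubly_significant"] >= 10
        assert summary["concordant_fraction"] >= 0.9
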