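"""End-to-end orchestration of the analysis cascade on simulated or file-based
inputs: homology confidence filtering, ohnolog calling, divergence reports,
atlas analyses and the two-sex analyses."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import atlas as atlas_mod
from . import divergence as div_mod
from . import ohnologs as ohno_mod
from . import sexbias as sex_mod
from .config import SimConfig
from .homology import confidence_filter, score_candidates
from .models import (DivergenceReport, ExpressionMatrix, GeneModel,
                     OhnologPair, OrthologCandidate, ParalogCandidate, TruthSet)
from .simulate import (simulate_annotation, simulate_candidate_tables,
                       simulate_expression_atlas, simulate_sex_counts,
                       simulate_wgd_genome)


@dataclass
class SimBundle:
    """Everything the cascade consumes, generated in memory."""

    config: SimConfig
    outgroup: list[GeneModel]
    duplicated: list[GeneModel]
    truth: TruthSet
    ortholog_candidates: list[OrthologCandidate]
    paralog_candidates: list[ParalogCandidate]
    atlas: ExpressionMatrix
    sex_counts: ExpressionMatrix
    annotation: pd.DataFrame
    dup_by_id: dict[str, GeneModel] = field(default_factory=dict)
    out_by_id: dict[str, GeneModel] = field(default_factory=dict)

    def __post_init__(self):
        self.dup_by_id = {g.gene_id: g for g in self.duplicated}
        self.out_by_id = {g.gene_id: g for g in self.outgroup}


def simulate_bundle(config: SimConfig) -> SimBundle:
    outgroup, duplicated, truth = simulate_wgd_genome(config)
    orth_df, para_df = simulate_candidate_tables(outgroup, duplicated, truth, config)
    orth = [OrthologCandidate(r.gene_a, r.gene_b, wga_score=float(r.wga_score))
            for r in orth_df.itertuples(index=False)]
    para = [ParalogCandidate(r.gene_1, r.gene_2, duplication_timing=r.duplication_timing)
            for r in para_df.itertuples(index=False)]
    return SimBundle(
        config=config,
        outgroup=outgroup,
        duplicated=duplicated,
        truth=truth,
        ortholog_candidates=orth,
        paralog_candidates=para,
        atlas=simulate_expression_atlas(duplicated, truth, config),
        sex_counts=simulate_sex_counts(duplicated, truth, config),
        annotation=simulate_annotation(duplicated, truth, config),
    )


def run_homology(bundle: SimBundle) -> list[OrthologCandidate]:
    """Score the cross-species candidate table (GOC + percent identity) and
    apply the three-threshold high-confidence rule."""
    score_candidates(bundle.ortholog_candidates, bundle.duplicated, bundle.outgroup)
    return confidence_filter(bundle.ortholog_candidates)


def run_ohnolog_calling(bundle: SimBundle,
                        high_confidence: list[OrthologCandidate] | None = None,
                        window: int = 10, min_support: int = 2,
                        enforce_collinearity: bool = False) -> list[OhnologPair]:
    if high_confidence is None:
        high_confidence = run_homology(bundle)
    proteins = {g.gene_id: g.protein_seq for g in bundle.duplicated}
    ohno_mod.annotate_pair_identity(bundle.paralog_candidates, proteins)
    wgd = ohno_mod.subset_wgd_paralogs(bundle.paralog_candidates)
    pairs = ohno_mod.map_two_to_one(wgd, high_confidence)
    ohno_mod.collinearity_support(pairs, bundle.duplicated + bundle.outgroup,
                                  window=window, min_support=min_support,
                                  enforce=enforce_collinearity)
    return pairs


def run_divergence(bundle: SimBundle, pairs: list[OhnologPair]) -> tuple[list[DivergenceReport], dict]:
    reports = div_mod.build_reports(pairs, bundle.dup_by_id, bundle.out_by_id)
    stats = div_mod.compare_pair_metrics(reports) if len(reports) >= 3 else {}
    return reports, stats


def run_atlas(bundle: SimBundle, pairs: list[OhnologPair], seed: int = 0) -> dict:
    matrix = bundle.atlas
    atlas_mod.size_factors(matrix)
    presence, presence_summary = atlas_mod.presence_matrix(
        matrix, gene_set=bundle.truth.immune_genes & set(matrix.genes))
    immune_vs_rest = atlas_mod.compare_immune_abundance(
        matrix, bundle.truth.immune_genes & set(matrix.genes))
    called = [p for p in pairs if p.called]
    pair_genes = {g for p in called for g in (p.copy_1, p.copy_2)}
    assignments = atlas_mod.cluster_coexpression(matrix, gene_set=pair_genes, seed=seed)
    pair_labels, pair_summary = atlas_mod.classify_pair_profiles(assignments, called)
    return {
        "presence": presence, "presence_summary": presence_summary,
        "immune_vs_rest": immune_vs_rest,
        "assignments": assignments,
        "pair_labels": pair_labels, "pair_summary": pair_summary,
    }


def run_sexbias(bundle: SimBundle, pairs: list[OhnologPair],
                reports: list[DivergenceReport] | None = None,
                alpha: float = 0.05) -> dict:
    de = sex_mod.de_test(bundle.sex_counts, alpha=alpha)
    bias_all = sex_mod.direction_bias_test(de, alpha=alpha)
    immune = bundle.truth.immune_genes & set(de.index)
    bias_immune = sex_mod.direction_bias_test(de, subset=immune, alpha=alpha)
    significant = set(de.index[de["direction"] != "none"])
    enrichment = sex_mod.term_enrichment(bundle.annotation, gene_set=significant,
                                         mode="fisher", report_all=True)
    pca = sex_mod.pca_summary(bundle.sex_counts)
    called = [p for p in pairs if p.called]
    concordance, concordance_summary = sex_mod.ohnolog_sexbias_concordance(de, called, reports)
    return {
        "de": de, "bias_all": bias_all, "bias_immune": bias_immune,
        "enrichment": enrichment, "pca": pca,
        "concordance": concordance, "concordance_summary": concordance_summary,
    }


def run_all(config: SimConfig, seed: int = 0) -> dict:
    """The full cascade on one simulated bundle; returns every intermediate."""
    bundle = simulate_bundle(config)
    high_conf = run_homology(bundle)
    pairs = run_ohnolog_calling(bundle, high_conf)
    reports, pair_stats = run_divergence(bundle, pairs)
    atlas_results = run_atlas(bundle, pairs, seed=seed)
    sex_results = run_sexbias(bundle, pairs, reports)
    return {
        "bundle": bundle, "high_confidence": high_conf, "pairs": pairs,
        "reports": reports, "pair_stats": pair_stats,
        "atlas": atlas_results, "sexbias": sex_results,
        "recovery": ohno_mod.pair_recovery(pairs, bundle.truth.true_pairs),
    }
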