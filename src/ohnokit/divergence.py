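"""Per-pair functional divergence: protein distance to the outgroup ortholog,
conserved/diverged copy assignment, NG86 dN/dS, and the paired comparisons of
domain counts, omega and protein length between copies.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import stats

from .codon import ng86_dnds
from .homology import align_global
from .models import DivergenceReport, GeneModel, OhnologPair

logger = logging.getLogger(__name__)


def protein_distance(seq_a: str, seq_b: str, correction: str | None = None) -> float | None:
    """Amino-acid substitutions per 100 residues over gap-free aligned columns.

    The default is the uncorrected p-distance; correction="jc" applies the
    20-state Jukes-Cantor-type correction.  None when no gap-free column
    exists or the correction is inapplicable.  Arguments are ordered
    lexicographically before alignment so the distance is exactly symmetric.
    """
    alignment = align_global(*sorted((seq_a, seq_b)))
    row_a, row_b = alignment[0], alignment[1]
    compared = mismatches = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        return None
    p = mismatches / compared
    if correction is None:
        return 100.0 * p
    if correction == "jc":
        if p >= 0.95:
            return None
        return 100.0 * (-0.95 * math.log1p(-p / 0.95))
    raise ValueError(f"unknown correction: {correction!r}")


def codon_alignment(cds_a: str, cds_b: str, protein_a: str, protein_b: str) -> tuple[str, str]:
    """Project the global protein alignment onto the codon sequences
    (protein-guided back-translation; gaps become '---')."""
    alignment = align_global(protein_a, protein_b)
    row_a, row_b = alignment[0], alignment[1]
    out_a, out_b = [], []
    ia = ib = 0
    for x, y in zip(row_a, row_b):
        out_a.append("---" if x == "-" else cds_a[3 * ia : 3 * ia + 3])
        out_b.append("---" if y == "-" else cds_b[3 * ib : 3 * ib + 3])
        ia += x != "-"
        ib += y != "-"
    return "".join(out_a), "".join(out_b)


def assign_conserved_diverged(pair: OhnologPair, dist_copy1: float | None,
                              dist_copy2: float | None) -> DivergenceReport:
    """Label the copy with the smaller distance to the outgroup as conserved.

    Exactly equal distances set tie_flag and fall back to the
    lexicographically smaller gene id.  A pair with an undefined distance is
    returned unlabeled (excluded from paired analyses).
    """
    report = DivergenceReport(pair, dist_copy1=dist_copy1, dist_copy2=dist_copy2)
    if dist_copy1 is None or dist_copy2 is None:
        logger.warning("pair %s/%s: undefined distance, excluded from paired analyses",
                       pair.copy_1, pair.copy_2)
        return report
    if dist_copy1 < dist_copy2:
        report.conserved_copy, report.diverged_copy = pair.copy_1, pair.copy_2
    elif dist_copy2 < dist_copy1:
        report.conserved_copy, report.diverged_copy = pair.copy_2, pair.copy_1
    else:
        report.tie_flag = True
        first, second = sorted((pair.copy_1, pair.copy_2))
        report.conserved_copy, report.diverged_copy = first, second
    return report


def build_reports(pairs: list[OhnologPair], dup_genes: dict[str, GeneModel],
                  out_genes: dict[str, GeneModel],
                  distance_correction: str | None = None) -> list[DivergenceReport]:
    """Full per-pair divergence reports for called pairs with an outgroup gene."""
    reports = []
    for pair in pairs:
        if not pair.called or pair.outgroup_gene is None:
            continue
        g1, g2 = dup_genes[pair.copy_1], dup_genes[pair.copy_2]
        og = out_genes[pair.outgroup_gene]
        d1 = protein_distance(g1.protein_seq, og.protein_seq, distance_correction)
        d2 = protein_distance(g2.protein_seq, og.protein_seq, distance_correction)
        report = assign_conserved_diverged(pair, d1, d2)
        for label, gene in (("copy1", g1), ("copy2", g2)):
            aligned_g, aligned_o = codon_alignment(gene.cds_seq, og.cds_seq,
                                                   gene.protein_seq, og.protein_seq)
            res = ng86_dnds(aligned_g, aligned_o)
            if label == "copy1":
                report.ng86_copy1, report.omega_copy1 = res, res.omega
            else:
                report.ng86_copy2, report.omega_copy2 = res, res.omega
        report.domain_count_1 = g1.domain_count
        report.domain_count_2 = g2.domain_count
        report.protein_len_1 = len(g1.protein_seq)
        report.protein_len_2 = len(g2.protein_seq)
        reports.append(report)
    return reports


def _per_role(report: DivergenceReport, attr_1: str, attr_2: str):
    """(conserved value, diverged value) for a per-copy attribute pair."""
    v1, v2 = getattr(report, attr_1), getattr(report, attr_2)
    if report.conserved_copy == report.pair.copy_1:
        return v1, v2
    return v2, v1


def compare_pair_metrics(reports: list[DivergenceReport]) -> dict:
    """The pairwise conserved-vs-diverged comparisons.

    Returns a dict with (a) a two-sided rank-sum test of domain counts,
    (b) a paired t-test of omega (diverged minus conserved; dS = 0 / undefined
    omegas excluded), (c) a paired t-test of protein lengths, and (d) counts
    of pairs with unequal domain numbers and which role has fewer.
    """
    labeled = [r for r in reports if r.conserved_copy is not None]
    if len(labeled) < 3:
        raise ValueError("need >= 3 labeled pairs")
    out: dict = {"n_pairs": len(labeled)}

    dom = [(c, d) for c, d in (_per_role(r, "domain_count_1", "domain_count_2") for r in labeled)
           if c is not None and d is not None]
    if dom:
        cons, div = zip(*dom)
        if len(set(cons + div)) == 1:
            out["domain_rank_sum"] = {"statistic": float("nan"), "p_value": 1.0}
        else:
            stat = stats.mannwhitneyu(cons, div, alternative="two-sided")
            out["domain_rank_sum"] = {"statistic": float(stat.statistic),
                                      "p_value": float(stat.pvalue)}
        differing = [(c, d) for c, d in dom if c != d]
        out["n_domain_differ"] = len(differing)
        out["n_diverged_fewer_domains"] = sum(1 for c, d in differing if d < c)
        out["n_conserved_fewer_domains"] = sum(1 for c, d in differing if c < d)

    omegas = [(c, d) for c, d in (_per_role(r, "omega_copy1", "omega_copy2") for r in labeled)
              if c is not None and d is not None]
    if len(omegas) >= 3:
        cons, div = map(np.asarray, zip(*omegas))
        if np.allclose(cons, div):
            out["omega_paired_t"] = {"statistic": 0.0, "p_value": 1.0,
                                     "p_one_sided": 0.5, "n": len(omegas),
                                     "mean_diff": 0.0}
        else:
            res = stats.ttest_rel(div, cons)
            one_sided = res.pvalue / 2 if res.statistic > 0 else 1 - res.pvalue / 2
            out["omega_paired_t"] = {"statistic": float(res.statistic),
                                     "p_value": float(res.pvalue),
                                     "p_one_sided": float(one_sided),
                                     "n": len(omegas),
                                     "mean_diff": float(np.mean(div - cons))}
    else:
        out["omega_paired_t"] = None

    lens = [(c, d) for c, d in (_per_role(r, "protein_len_1", "protein_len_2") for r in labeled)
            if c is not None and d is not None]
    if len(lens) >= 3:
        cons, div = map(np.asarray, zip(*lens))
        if np.all(cons == div):
            out["length_paired_t"] = {"statistic": 0.0, "p_value": 1.0, "n": len(lens)}
        else:
            res = stats.ttest_rel(div, cons)
            out["length_paired_t"] = {"statistic": float(res.statistic),
                                      "p_value": float(res.pvalue), "n": len(lens)}
    return out


def diverged_label_accuracy(reports: list[DivergenceReport],
                            truth_diverged: dict[str, str]) -> float:
    """Fraction of labeled pairs whose diverged call matches simulator truth."""
    hits = total = 0
    truth_set = set(truth_diverged.values())
    for r in reports:
        if r.diverged_copy is None:
            continue
        if r.pair.copy_1 in truth_set or r.pair.copy_2 in truth_set:
            total += 1
            hits += r.diverged_copy in truth_set
    return hits / total if total else float("nan")
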