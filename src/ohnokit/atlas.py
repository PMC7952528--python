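"""Tissue-atlas expression analysis: median-of-ratios library-size correction,
presence calls, immune vs non-immune abundance comparison, a co-expression
clustering stand-in (z-score profiles, silhouette-selected k-means, tightness
radius), and per-pair expression-profile classification.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .models import ExpressionMatrix, OhnologPair
from .stats import bh_adjust

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


def size_factors(matrix: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Reference genes are those with positive counts in every sample; when none
    exists the total-count ratio is used instead (with a warning)."""
    counts = matrix.counts.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if positive.any():
        ref = counts[positive]
        geomean = np.exp(np.log(ref).mean(axis=1))
        factors = np.median(ref / geomean[:, None], axis=0)
    else:
        logger.warning("no gene with positive counts in all samples; "
                       "falling back to total-count size factors")
        totals = counts.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("sample with zero total counts")
        factors = totals
    factors = factors / np.exp(np.mean(np.log(factors)))
    result = pd.Series(factors, index=matrix.samples, name="size_factor")
    matrix.size_factors = result
    return result


def _ensure_factors(matrix: ExpressionMatrix) -> None:
    if matrix.size_factors is None:
        size_factors(matrix)


def tissue_means(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Normalized expression per tissue (mean over replicate samples)."""
    _ensure_factors(matrix)
    if "tissue" not in matrix.sample_meta.columns:
        raise ValueError("sample metadata lacks a 'tissue' column")
    norm = matrix.normalized()
    return norm.T.groupby(matrix.sample_meta["tissue"]).mean().T


def presence_matrix(matrix: ExpressionMatrix, threshold: float = 0.0,
                    gene_set: set[str] | None = None) -> tuple[pd.DataFrame, dict]:
    """Boolean gene x tissue presence table plus summary statistics.

    A gene is present in a tissue when its normalized count exceeds
    `threshold`.  Summaries (per-tissue counts, expressed-in-any/all counts
    and percentages) are computed for `gene_set` when given, else all genes.
    """
    expr = tissue_means(matrix)
    present = expr > threshold
    genes = present.index if gene_set is None else present.index.intersection(sorted(gene_set))
    if gene_set is not None and len(genes) < len(gene_set):
        missing = set(gene_set) - set(genes)
        raise ValueError(f"gene set members absent from matrix: {sorted(missing)[:5]} ...")
    sub = present.loc[genes]
    n = len(sub)
    summary = {
        "n_genes": n,
        "per_tissue": sub.sum(axis=0).to_dict(),
        "n_expressed_any": int(sub.any(axis=1).sum()),
        "n_expressed_all": int(sub.all(axis=1).sum()),
    }
    summary["pct_expressed_any"] = round(100.0 * summary["n_expressed_any"] / n, 1) if n else float("nan")
    summary["pct_expressed_all"] = round(100.0 * summary["n_expressed_all"] / n, 1) if n else float("nan")
    return present, summary


def compare_immune_abundance(matrix: ExpressionMatrix, immune_set: set[str],
                             min_group: int = 3) -> pd.DataFrame:
    """Per-tissue two-sided rank-sum test of normalized expression, immune vs
    non-immune genes, BH-adjusted across tissues with direction labels."""
    expr = tissue_means(matrix)
    immune = expr.index.intersection(sorted(immune_set))
    other = expr.index.difference(immune)
    if len(immune) == 0:
        raise ValueError("immune set is empty or absent from the matrix")
    if len(other) == 0:
        raise ValueError("immune set covers every gene; no background left")
    rows = []
    for tissue in expr.columns:
        a, b = expr.loc[immune, tissue], expr.loc[other, tissue]
        if min(len(a), len(b)) < min_group:
            rows.append({"tissue": tissue, "p_value": np.nan, "statistic": np.nan,
                         "direction": "underpowered"})
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"tissue": tissue, "statistic": float(res.statistic),
                     "p_value": float(res.pvalue),
                     "direction": "immune_higher" if a.median() > b.median() else "immune_lower"})
    df = pd.DataFrame(rows).set_index("tissue")
    tested = df["p_value"].notna()
    df["p_adjusted"] = np.nan
    if tested.any():
        df.loc[tested, "p_adjusted"] = bh_adjust(df.loc[tested, "p_value"].to_numpy())
    return df


def cluster_coexpression(matrix: ExpressionMatrix, gene_set: set[str] | None = None,
                         flatness_threshold: float = 1.0, k_range: tuple[int, int] = (2, 12),
                         radius_factor: float = 1.5, seed: int = 0) -> pd.DataFrame:
    """Co-expression cluster assignment over tissue profiles.

    Genes that are zero in every tissue, or whose log2 profile spans less than
    `flatness_threshold` (max - min), are unassigned.  The remaining genes'
    z-scored log2 profiles are k-means clustered with K chosen by maximal mean
    silhouette over k_range; genes farther than radius_factor times their
    cluster's mean within-distance from the centroid are unassigned
    (non-exhaustive assignment).  Returns a DataFrame indexed by gene with a
    'cluster' column ('unassigned' or 'C<k>') plus the z-scored profile.
    """
    expr = tissue_means(matrix)
    if gene_set is not None:
        expr = expr.loc[expr.index.intersection(sorted(gene_set))]
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 tissues")
    logexpr = np.log2(expr + 1.0)
    flat = (logexpr.max(axis=1) - logexpr.min(axis=1)) < flatness_threshold
    silent = (expr <= 0).all(axis=1)
    assignable = logexpr.loc[~(flat | silent)]

    result = pd.DataFrame(index=expr.index, data={"cluster": UNASSIGNED})
    z = assignable.sub(assignable.mean(axis=1), axis=0).div(
        assignable.std(axis=1, ddof=0), axis=0)
    k_min, k_max = k_range
    if len(assignable) <= k_min:
        logger.warning("fewer assignable genes (%d) than k_min; all unassigned",
                       len(assignable))
        return result.join(z)

    best_k, best_score, best_labels = None, -np.inf, None
    for k in range(k_min, min(k_max, len(assignable) - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(z.to_numpy())
        if len(set(labels)) < 2:
            continue
        score = silhouette_score(z.to_numpy(), labels)
        if score > best_score:
            best_k, best_score, best_labels = k, score, labels
    km = KMeans(n_clusters=best_k, n_init=10, random_state=seed).fit(z.to_numpy())
    labels = km.labels_
    dists = np.linalg.norm(z.to_numpy() - km.cluster_centers_[labels], axis=1)
    assigned = np.ones(len(labels), dtype=bool)
    for k in range(best_k):
        mask = labels == k
        mean_dist = dists[mask].mean()
        if mean_dist > 0:
            assigned[mask & (dists > radius_factor * mean_dist)] = False
    names = np.where(assigned, [f"C{l + 1}" for l in labels], UNASSIGNED)
    result.loc[assignable.index, "cluster"] = names
    return result.join(z)


def classify_pair_profiles(assignments: pd.DataFrame,
                           pairs: list[OhnologPair]) -> tuple[pd.DataFrame, dict]:
    """Label each pair conserved (same cluster), divergent (different
    clusters), partial (one copy assigned) or unassigned."""
    clusters = assignments["cluster"]
    rows = []
    for pair in pairs:
        if isinstance(pair, OhnologPair):
            g1, g2 = pair.copy_1, pair.copy_2
        else:
            g1, g2 = sorted(pair)
        c1 = clusters.get(g1)
        c2 = clusters.get(g2)
        if c1 is None or c2 is None:
            label, reason = UNASSIGNED, "member_absent_from_matrix"
        else:
            a1, a2 = c1 != UNASSIGNED, c2 != UNASSIGNED
            reason = ""
            if a1 and a2:
                label = "conserved" if c1 == c2 else "divergent"
            elif a1 or a2:
                label = "partial"
            else:
                label = UNASSIGNED
        rows.append({"copy_1": g1, "copy_2": g2, "cluster_1": c1, "cluster_2": c2,
                     "label": label, "reason": reason})
    df = pd.DataFrame(rows)
    summary = {lab: int((df["label"] == lab).sum())
               for lab in ("conserved", "divergent", "partial", UNASSIGNED)}
    summary["total"] = len(df)
    return df, summary


def profile_recovery(pair_labels: pd.DataFrame, truth_divergent: set[str],
                     pair_by_ancestor: dict[str, frozenset]) -> dict:
    """Sensitivity/specificity of the 'divergent' label against simulator truth."""
    label_by_pair = {frozenset((r.copy_1, r.copy_2)): r.label
                     for r in pair_labels.itertuples(index=False)}
    tp = fn = tn = fp = 0
    for anc, pair in pair_by_ancestor.items():
        label = label_by_pair.get(pair)
        if label is None:
            continue
        if anc in truth_divergent:
            tp += label == "divergent"
            fn += label != "divergent"
        else:
            fp += label == "divergent"
            tn += label != "divergent"
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "n_true_divergent": tp + fn,
        "n_true_conserved": tn + fp,
    }
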