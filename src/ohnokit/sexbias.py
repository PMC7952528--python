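"""Two-group (male/female) expression analyses.

A negative-binomial Wald test with moment-estimated dispersion stands in for
the usual shrinkage-based DE machinery; significance is controlled with
Benjamini-Hochberg at alpha = 0.05.  Directional bias is assessed with a
two-sided exact binomial test, differential intron usage with a per-cluster
multinomial likelihood-ratio test, and term enrichment with one-sided Fisher
or Kolmogorov-Smirnov tests over a GO-style annotation table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .atlas import size_factors as _size_factors
from .models import DivergenceReport, ExpressionMatrix, IntronCluster, OhnologPair
from .stats import bh_adjust

logger = logging.getLogger(__name__)

LOG2 = np.log(2.0)


# ---------------------------------------------------------------------------
# differential expression


def de_test(matrix: ExpressionMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene NB Wald test of male vs female normalized means.

    Dispersion is the pooled method-of-moments estimate
    alpha_g = max(0, (s^2 - m) / m^2); the log2 fold change uses a 0.5
    pseudocount and its standard error comes from the delta method on the NB
    variance m + alpha_g m^2.  Genes with all-zero counts are excluded from
    testing and from the BH denominator.  Direction is labeled only for
    BH-significant genes.
    """
    if "sex" not in matrix.sample_meta.columns:
        raise ValueError("sample metadata lacks a 'sex' column")
    sexes = matrix.sample_meta["sex"]
    males = matrix.samples[sexes == "male"]
    females = matrix.samples[sexes == "female"]
    if len(males) == 0 or len(females) == 0:
        raise ValueError("both sexes must be present")
    if matrix.size_factors is None:
        _size_factors(matrix)
    norm = matrix.normalized()
    tested = norm.loc[(matrix.counts.sum(axis=1) > 0)]

    nm = tested[males].to_numpy()
    nf = tested[females].to_numpy()
    mean_m, mean_f = nm.mean(axis=1), nf.mean(axis=1)
    base_mean = tested.to_numpy().mean(axis=1)

    # pooled within-group variance and moment NB dispersion
    var_pool = (nm.var(axis=1, ddof=1) * (nm.shape[1] - 1)
                + nf.var(axis=1, ddof=1) * (nf.shape[1] - 1)) / (nm.shape[1] + nf.shape[1] - 2)
    m_pool = np.maximum((mean_m + mean_f) / 2.0, 0.5)  # small-count floor
    disp = np.maximum(0.0, (var_pool - m_pool) / m_pool**2)

    mm, mf = mean_m + 0.5, mean_f + 0.5
    lfc = np.log2(mm / mf)
    var_mean_m = (mm + disp * mm**2) / nm.shape[1]
    var_mean_f = (mf + disp * mf**2) / nf.shape[1]
    se = np.sqrt(var_mean_m / mm**2 + var_mean_f / mf**2) / LOG2
    z = np.where(se > 0, lfc / se, 0.0)
    # Wald statistic referred to a t distribution with n_M + n_F - 2 df: the
    # moment variance estimate has finite degrees of freedom, and the normal
    # reference is visibly anticonservative at ~12 samples per group
    df_resid = nm.shape[1] + nf.shape[1] - 2
    p = 2.0 * stats.t.sf(np.abs(z), df=df_resid)
    padj = bh_adjust(p)
    direction = np.where(padj < alpha, np.where(lfc > 0, "male", "female"), "none")

    return pd.DataFrame({
        "base_mean": base_mean, "log2_fold_change": lfc, "lfc_se": se,
        "wald_z": z, "p_value": p, "p_adjusted": padj, "direction": direction,
    }, index=tested.index)


def de_recovery(de: pd.DataFrame, truth_biased: dict[str, str], alpha: float = 0.05) -> dict:
    """Sensitivity and observed false-discovery proportion of DE calls
    against simulator truth (direction must match to count as a true call)."""
    sig = de[de["p_adjusted"] < alpha]
    hits = sum(1 for g, d in sig["direction"].items() if truth_biased.get(g) == d)
    testable = [g for g in truth_biased if g in de.index]
    return {
        "n_significant": len(sig),
        "sensitivity": hits / len(testable) if testable else float("nan"),
        "fdr": 1.0 - hits / len(sig) if len(sig) else 0.0,
    }


def direction_bias_test(de_or_counts, subset: set[str] | None = None,
                        alpha: float = 0.05) -> dict:
    """Two-sided exact binomial test of directional bias among significant
    genes (null: each direction equally likely).

    Accepts either a de_test result frame (optionally restricted to `subset`)
    or a pre-computed (n_biased_one_way, n_significant) tuple.
    """
    if isinstance(de_or_counts, tuple):
        k, n = de_or_counts
    else:
        de = de_or_counts
        if subset is not None:
            de = de.loc[de.index.intersection(sorted(subset))]
        sig = de[de["direction"] != "none"]
        n = len(sig)
        k = int((sig["direction"] == "male").sum())
    if n == 0:
        return {"n_male": None, "n_female": None, "p_value": None, "note": "no significant genes"}
    result = stats.binomtest(k, n, 0.5, alternative="two-sided")
    return {"n_male": k, "n_female": n - k, "n_significant": n,
            "p_value": float(result.pvalue)}


# ---------------------------------------------------------------------------
# differential intron usage


MAX_INTRON_LEN = 500_000
MIN_CLUSTER_READS = 50
MIN_INTRON_READS = 5


def filter_clusters(clusters: list[IntronCluster],
                    min_cluster_reads: int = MIN_CLUSTER_READS,
                    min_intron_reads: int = MIN_INTRON_READS,
                    max_intron_len: int = MAX_INTRON_LEN) -> list[IntronCluster]:
    """Apply the intron-cluster filters: drop introns longer than
    max_intron_len or with fewer than min_intron_reads total reads, then drop
    clusters with < 2 surviving introns or < min_cluster_reads total reads."""
    out = []
    for cl in clusters:
        keep = [i for i, (chrom, start, end, strand) in enumerate(cl.introns)
                if (end - start) <= max_intron_len and cl.counts[i].sum() >= min_intron_reads]
        if len(keep) < 2:
            continue
        counts = cl.counts[keep]
        if counts.sum() < min_cluster_reads:
            continue
        out.append(IntronCluster(cl.cluster_id, [cl.introns[i] for i in keep], counts))
    return out


def _multinomial_loglik(counts: np.ndarray, props: np.ndarray) -> float:
    mask = counts > 0
    return float((counts[mask] * np.log(props[mask])).sum())


def intron_usage_test(clusters: list[IntronCluster], sexes: list[str],
                      min_samples_per_group: int = 5) -> pd.DataFrame:
    """Per-cluster multinomial likelihood-ratio test of intron usage between
    the sexes.

    Null: one usage proportion vector shared by both sexes; alternative:
    separate per-sex vectors.  2*(l_alt - l_null) is compared to chi-square
    with K-1 degrees of freedom (K introns).  A cluster is testable only when
    at least min_samples_per_group samples per sex have nonzero cluster
    totals.  p-values are BH-adjusted across tested clusters.
    """
    sexes = np.asarray(sexes)
    rows = []
    for cl in clusters:
        if cl.n_introns < 2:
            continue
        totals = cl.counts.sum(axis=0)
        ok = all((totals[sexes == s] > 0).sum() >= min_samples_per_group
                 for s in ("male", "female"))
        if not ok:
            rows.append({"cluster_id": cl.cluster_id, "n_introns": cl.n_introns,
                         "lrt": np.nan, "p_value": np.nan, "note": "too few samples"})
            continue
        agg_m = cl.counts[:, sexes == "male"].sum(axis=1).astype(float)
        agg_f = cl.counts[:, sexes == "female"].sum(axis=1).astype(float)
        pooled = agg_m + agg_f
        p_null = pooled / pooled.sum()
        ll_null = _multinomial_loglik(agg_m, p_null) + _multinomial_loglik(agg_f, p_null)
        ll_alt = 0.0
        for agg in (agg_m, agg_f):
            if agg.sum() > 0:
                ll_alt += _multinomial_loglik(agg, agg / agg.sum())
        lrt = max(0.0, 2.0 * (ll_alt - ll_null))
        p = stats.chi2.sf(lrt, df=cl.n_introns - 1)
        rows.append({"cluster_id": cl.cluster_id, "n_introns": cl.n_introns,
                     "lrt": lrt, "p_value": p, "note": ""})
    df = pd.DataFrame(rows).set_index("cluster_id") if rows else pd.DataFrame(
        columns=["n_introns", "lrt", "p_value", "note"])
    tested = df["p_value"].notna() if len(df) else pd.Series(dtype=bool)
    df["p_adjusted"] = np.nan
    if len(df) and tested.any():
        df.loc[tested, "p_adjusted"] = bh_adjust(df.loc[tested, "p_value"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# term enrichment


def term_enrichment(annotation: pd.DataFrame, gene_set: set[str] | None = None,
                    scores: pd.Series | None = None, mode: str = "fisher",
                    node_size: int = 20, alpha: float = 0.05,
                    report_all: bool = False) -> pd.DataFrame:
    """Term enrichment over a gene -> term annotation table.

    fisher mode: one-sided (enrichment) Fisher exact test of `gene_set`
    membership against term membership, background = all annotated genes.
    ks mode: one-sided two-sample Kolmogorov-Smirnov test that term genes have
    stochastically smaller `scores` (e.g. DE p-values) than the rest.
    Terms annotating fewer than node_size genes are skipped; BH adjustment is
    applied across tested terms and only adjusted p < alpha rows are returned
    unless report_all.
    """
    if annotation.empty:
        raise ValueError("empty annotation table")
    background = pd.Index(sorted(annotation["gene_id"].unique()))
    if mode == "fisher":
        if gene_set is None:
            raise ValueError("fisher mode needs a gene set")
        in_set = background.isin(gene_set)
    elif mode == "ks":
        if scores is None:
            raise ValueError("ks mode needs per-gene scores")
        scores = scores.reindex(background).dropna()
        background = scores.index
    else:
        raise ValueError(f"unknown mode: {mode!r}")

    rows = []
    for term, members in annotation.groupby("term_id")["gene_id"]:
        members = background.intersection(members.unique())
        if len(members) < node_size:
            continue
        if mode == "fisher":
            is_member = background.isin(members)
            a = int((is_member & in_set).sum())
            b = int((~is_member & in_set).sum())
            c = int((is_member & ~in_set).sum())
            d = int((~is_member & ~in_set).sum())
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            rows.append({"term_id": term, "n_term": len(members), "n_hit": a,
                         "odds_ratio": odds, "p_value": p})
        else:
            term_scores = scores.loc[members]
            rest = scores.loc[background.difference(members)]
            # one-sided: term-gene scores stochastically smaller
            res = stats.ks_2samp(term_scores, rest, alternative="greater")
            rows.append({"term_id": term, "n_term": len(members),
                         "statistic": float(res.statistic), "p_value": float(res.pvalue)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
    df = df.sort_values("p_adjusted").reset_index(drop=True)
    return df if report_all else df[df["p_adjusted"] < alpha].reset_index(drop=True)


# ---------------------------------------------------------------------------
# PCA summary and ohnolog concordance


def pca_summary(matrix: ExpressionMatrix, n_components: int = 5) -> dict:
    """SVD of gene-standardized log2(normalized + 1) counts.

    Returns explained-variance fractions and per-sample scores; NA for a
    constant matrix."""
    if matrix.counts.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    if matrix.size_factors is None:
        _size_factors(matrix)
    logn = np.log2(matrix.normalized() + 1.0)
    sd = logn.std(axis=1, ddof=0)
    usable = logn.loc[sd > 0]
    if usable.empty:
        return {"explained_variance": None, "scores": None, "note": "constant matrix"}
    z = usable.sub(usable.mean(axis=1), axis=0).div(usable.std(axis=1, ddof=0), axis=0)
    n_components = min(n_components, len(matrix.samples) - 1, len(usable))
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(z.T.to_numpy())
    return {
        "explained_variance": pca.explained_variance_ratio_.tolist(),
        "scores": pd.DataFrame(scores, index=matrix.samples,
                               columns=[f"PC{i + 1}" for i in range(n_components)]),
    }


def ohnolog_sexbias_concordance(de: pd.DataFrame, pairs: list[OhnologPair],
                                reports: list[DivergenceReport] | None = None) -> tuple[pd.DataFrame, dict]:
    """For pairs with both copies significantly DE: concordant when both are
    biased toward the same sex; discordant rows note which copy role
    (conserved/diverged, when divergence reports are supplied) goes with
    which sex."""
    role = {}
    for r in reports or []:
        if r.conserved_copy:
            role[r.conserved_copy] = "conserved"
            role[r.diverged_copy] = "diverged"
    rows = []
    for pair in pairs:
        g1, g2 = pair.copy_1, pair.copy_2
        if g1 not in de.index or g2 not in de.index:
            continue
        d1, d2 = de.loc[g1, "direction"], de.loc[g2, "direction"]
        if d1 == "none" or d2 == "none":
            continue
        rows.append({
            "copy_1": g1, "copy_2": g2,
            "direction_1": d1, "direction_2": d2,
            "role_1": role.get(g1, ""), "role_2": role.get(g2, ""),
            "label": "concordant" if d1 == d2 else "discordant",
        })
    df = pd.DataFrame(rows, columns=["copy_1", "copy_2", "direction_1", "direction_2",
                                     "role_1", "role_2", "label"])
    n = len(df)
    summary = {
        "n_doubly_significant": n,
        "n_concordant": int((df["label"] == "concordant").sum()) if n else 0,
        "n_discordant": int((df["label"] == "discordant").sum()) if n else 0,
    }
    summary["concordant_fraction"] = summary["n_concordant"] / n if n else float("nan")
    return df, summary
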