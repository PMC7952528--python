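"""Ohnolog-pair calling against a non-duplicated outgroup.

The cascade: keep WGD-timed paralog pairs with >= 85% within-pair protein
identity, then require a single outgroup gene orthologous to exactly the two
duplicates with both outgroup-copy identities >= 85% (the 2:1 test), then
annotate each called pair with collinearity support from neighboring called
pairs.  Uncalled pairs are kept with reason codes rather than discarded.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from collections import defaultdict

from .homology import GenomeIndex, percent_identity
from .models import GeneModel, OhnologPair, OrthologCandidate, ParalogCandidate

logger = logging.getLogger(__name__)

WGD_TIMING = "ancestral_wgd"
IDENTITY_THRESHOLD = 85.0


def annotate_pair_identity(paralogs: list[ParalogCandidate],
                           proteins: dict[str, str]) -> list[ParalogCandidate]:
    """Fill pair_identity from protein sequences where missing."""
    for p in paralogs:
        if p.pair_identity is None:
            a, b = proteins.get(p.gene_1), proteins.get(p.gene_2)
            if a and b:
                p.pair_identity = percent_identity(a, b)
    return paralogs


def subset_wgd_paralogs(paralogs: list[ParalogCandidate],
                        min_identity: float = IDENTITY_THRESHOLD) -> list[ParalogCandidate]:
    """Retain paralog pairs timed to the WGD ancestor with within-pair
    identity >= min_identity; records missing a timing label are skipped."""
    kept = []
    for p in paralogs:
        if p.duplication_timing is None:
            logger.warning("paralog %s-%s skipped: missing duplication timing",
                           p.gene_1, p.gene_2)
            continue
        if p.duplication_timing != WGD_TIMING:
            continue
        if p.pair_identity is None or p.pair_identity < min_identity:
            continue
        kept.append(p)
    return kept


def map_two_to_one(paralogs: list[ParalogCandidate],
                   outgroup_orthologs: list[OrthologCandidate],
                   min_identity: float = IDENTITY_THRESHOLD) -> list[OhnologPair]:
    """Call ohnolog pairs by the 2:1 outgroup-mapping rule.

    A pair (A, B) is called iff exactly one outgroup gene P is orthologous to
    both copies at >= min_identity identity, and P has no third duplicate
    partner at that identity.  Output includes uncalled pairs with reason
    codes; no gene joins more than one called pair (higher mean identity wins,
    ties broken by outgroup gene id).
    """
    strong = [c for c in outgroup_orthologs
              if c.pct_identity is not None and c.pct_identity >= min_identity]
    by_dup: dict[str, dict[str, float]] = defaultdict(dict)   # dup gene -> {outgroup: identity}
    by_out: dict[str, set[str]] = defaultdict(set)            # outgroup -> dup partners
    for c in strong:
        by_dup[c.gene_a][c.gene_b] = c.pct_identity
        by_out[c.gene_b].add(c.gene_a)

    pairs: list[OhnologPair] = []
    for p in paralogs:
        g1, g2 = sorted((p.gene_1, p.gene_2))
        pair = OhnologPair(g1, g2, identity_12=p.pair_identity)
        shared = set(by_dup.get(g1, ())) & set(by_dup.get(g2, ()))
        if not shared:
            pair.reason = "no_shared_outgroup"
        elif len(shared) > 1:
            pair.reason = "multiple_outgroups"
        else:
            out = shared.pop()
            pair.outgroup_gene = out
            pair.identity_o1 = by_dup[g1][out]
            pair.identity_o2 = by_dup[g2][out]
            if by_out[out] - {g1, g2}:
                pair.reason = "not_2to1"
            else:
                pair.called = True
                pair.reason = "ok"
        pairs.append(pair)

    # enforce: no gene in more than one called pair
    claims: dict[str, OhnologPair] = {}
    for pair in sorted(
            (p for p in pairs if p.called),
            key=lambda p: (-_mean_identity(p), p.outgroup_gene or "", p.copy_1, p.copy_2)):
        if pair.copy_1 in claims or pair.copy_2 in claims:
            pair.called = False
            pair.reason = "gene_already_paired"
            continue
        claims[pair.copy_1] = pair
        claims[pair.copy_2] = pair
    return pairs


def _mean_identity(pair: OhnologPair) -> float:
    vals = [v for v in (pair.identity_12, pair.identity_o1, pair.identity_o2) if v is not None]
    return sum(vals) / len(vals) if vals else 0.0


def collinearity_support(pairs: list[OhnologPair], genes: list[GeneModel],
                         window: int = 10, min_support: int = 2,
                         enforce: bool = False) -> list[OhnologPair]:
    """Count, for each called pair, the other called pairs whose members lie
    within `window` ordinal positions on both chromosomes (in either copy
    orientation).  Pairs with support < min_support are flagged by setting
    collinearity_support; they are only dropped when enforce=True."""
    index = GenomeIndex(genes)
    called = [p for p in pairs if p.called]
    # per-chromosome sorted ordinal lists of called-pair gene placements
    placements: dict[str, list[tuple[int, int]]] = defaultdict(list)  # chrom -> (ordinal, pair idx)
    pos = {}
    for i, p in enumerate(called):
        for gid in (p.copy_1, p.copy_2):
            g = index.by_id[gid]
            placements[g.chromosome].append((g.ordinal_index, i))
            pos[gid] = (g.chromosome, g.ordinal_index)
    for chrom in placements:
        placements[chrom].sort()

    def nearby(gid: str) -> set[int]:
        chrom, ordinal = pos[gid]
        entries = placements[chrom]
        lo = bisect_left(entries, (ordinal - window, -1))
        hi = bisect_right(entries, (ordinal + window, len(called)))
        return {idx for o, idx in entries[lo:hi]}

    for i, p in enumerate(called):
        support = (nearby(p.copy_1) & nearby(p.copy_2)) - {i}
        p.collinearity_support = len(support)
        if enforce and p.collinearity_support < min_support:
            p.called = False
            p.reason = "low_collinearity"
    return pairs


def crossref_pairs(pairs: list[OhnologPair] | list[frozenset],
                   external_pairs: list[frozenset]) -> dict:
    """Overlap report between two pair sets (duplicate entries collapsed).

    shared_fraction is |shared| / |set_a|, the convention used when set_a is
    the comparable subset of this study's calls."""
    set_a = {p.genes if isinstance(p, OhnologPair) else frozenset(p) for p in pairs}
    set_b = {frozenset(p) for p in external_pairs}
    shared = set_a & set_b
    return {
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_shared": len(shared),
        "n_unique_a": len(set_a - set_b),
        "n_unique_b": len(set_b - set_a),
        "shared_fraction": len(shared) / len(set_a) if set_a else float("nan"),
    }


def pair_recovery(pairs: list[OhnologPair], true_pairs: set[frozenset]) -> dict:
    """Precision/recall of called pairs against simulator truth."""
    called = {p.genes for p in pairs if p.called}
    tp = len(called & true_pairs)
    return {
        "n_called": len(called),
        "n_true": len(true_pairs),
        "precision": tp / len(called) if called else float("nan"),
        "recall": tp / len(true_pairs) if true_pairs else float("nan"),
    }
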