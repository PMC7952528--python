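"""Homology evidence and the three-threshold high-confidence ortholog rule.

A candidate ortholog pair is kept as "high confidence" when all three scores
clear 50: the gene-order-conservation (GOC) score computed from the four
closest chromosomal neighbors, the externally supplied whole-genome-alignment
score, and global protein percent identity.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import edlib
import networkx as nx
from Bio.Align import PairwiseAligner, substitution_matrices

from .models import GeneModel, OrthologCandidate

logger = logging.getLogger(__name__)

GAP_OPEN = -10.0
GAP_EXTEND = -0.5


@lru_cache(maxsize=1)
def _aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    aligner.mode = "global"
    return aligner


def align_global(seq_a: str, seq_b: str):
    """Best global alignment (BLOSUM62, affine gaps: a gap of length L costs
    10 + 0.5*(L-1)); returns the aligner's first optimal alignment."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    return _aligner().align(seq_a.upper(), seq_b.upper())[0]


def percent_identity(seq_a: str, seq_b: str, denominator: str = "alignment") -> float:
    """Global-alignment percent identity between two protein sequences.

    denominator="alignment" divides identical columns by the total number of
    alignment columns (gap columns included); "shorter" divides by the shorter
    sequence length.  'X' never counts as a match.  The alignment is computed
    on lexicographically ordered arguments so the result is exactly symmetric
    even when co-optimal alignments differ.
    """
    alignment = align_global(*sorted((seq_a, seq_b)))
    row_a, row_b = alignment[0], alignment[1]
    identical = sum(1 for x, y in zip(row_a, row_b) if x == y and x not in ("-", "X"))
    if denominator == "alignment":
        denom = len(row_a)
    elif denominator == "shorter":
        denom = min(len(seq_a), len(seq_b))
    else:
        raise ValueError(f"unknown denominator convention: {denominator!r}")
    return 100.0 * identical / denom


class GenomeIndex:
    """Ordinal gene-order lookups for one or more gene sets."""

    def __init__(self, genes: list[GeneModel]):
        self.by_id = {g.gene_id: g for g in genes}
        self.by_chrom: dict[str, dict[int, str]] = {}
        for g in genes:
            slot = self.by_chrom.setdefault(g.chromosome, {})
            if g.ordinal_index in slot:
                raise ValueError(f"duplicate ordinal {g.ordinal_index} on {g.chromosome}")
            slot[g.ordinal_index] = g.gene_id

    def neighbors(self, gene_id: str, window: int = 2) -> list[str]:
        """Up to `window` genes on each side by ordinal index (strand ignored)."""
        g = self.by_id[gene_id]
        chrom = self.by_chrom[g.chromosome]
        out = []
        for delta in range(-window, window + 1):
            if delta == 0:
                continue
            neighbor = chrom.get(g.ordinal_index + delta)
            if neighbor is not None:
                out.append(neighbor)
        return out

    def within_window(self, gene_id: str, other_id: str, window: int) -> bool:
        g, o = self.by_id[gene_id], self.by_id[other_id]
        return (g.chromosome == o.chromosome
                and 1 <= abs(g.ordinal_index - o.ordinal_index) <= window)


def goc_score(gene: GeneModel, ortholog: GeneModel,
              ortholog_map: dict[str, set[str]],
              index_a: GenomeIndex, index_b: GenomeIndex) -> int:
    """Gene-order-conservation score in {0, 25, 50, 75, 100}.

    Each of the four closest neighbors of `gene` (two per side) contributes 25
    when any of its mapped orthologs lies within two ordinal positions of
    `ortholog` on the same chromosome.  Missing neighbors at chromosome ends
    count as non-matches (the denominator stays 4).
    """
    matches = 0
    for neighbor in index_a.neighbors(gene.gene_id, window=2):
        for mapped in ortholog_map.get(neighbor, ()):  # may be absent
            if mapped in index_b.by_id and index_b.within_window(
                    ortholog.gene_id, mapped, window=2):
                matches += 1
                break
    return 25 * min(matches, 4)


def score_candidates(candidates: list[OrthologCandidate],
                     genes_a: list[GeneModel], genes_b: list[GeneModel],
                     compute_identity: bool = True) -> list[OrthologCandidate]:
    """Populate goc_score and pct_identity for a candidate table.

    The neighbor ortholog map used for GOC is built from the candidate table
    itself (every listed pair relates the two species' gene orders)."""
    index_a, index_b = GenomeIndex(genes_a), GenomeIndex(genes_b)
    ortholog_map: dict[str, set[str]] = {}
    for c in candidates:
        ortholog_map.setdefault(c.gene_a, set()).add(c.gene_b)
    for c in candidates:
        if c.gene_a not in index_a.by_id or c.gene_b not in index_b.by_id:
            continue
        gene, orth = index_a.by_id[c.gene_a], index_b.by_id[c.gene_b]
        c.goc_score = goc_score(gene, orth, ortholog_map, index_a, index_b)
        if compute_identity and gene.protein_seq and orth.protein_seq:
            c.pct_identity = percent_identity(gene.protein_seq, orth.protein_seq)
    return candidates


def confidence_filter(candidates: list[OrthologCandidate],
                      min_goc: float = 50, min_wga: float = 50,
                      min_identity: float = 50) -> list[OrthologCandidate]:
    """Keep candidates passing all three thresholds (inclusive).

    Candidates with a missing score are rejected with a reason code; every
    candidate gets its high_confidence flag and reject_reason set in place.
    """
    kept = []
    for c in candidates:
        reason = None
        if c.goc_score is None or c.wga_score is None or c.pct_identity is None:
            missing = [name for name, v in (("goc", c.goc_score), ("wga", c.wga_score),
                                            ("identity", c.pct_identity)) if v is None]
            reason = "missing_" + "+".join(missing)
            logger.warning("candidate %s-%s rejected: %s", c.gene_a, c.gene_b, reason)
        elif c.goc_score < min_goc:
            reason = "low_goc"
        elif c.wga_score < min_wga:
            reason = "low_wga"
        elif c.pct_identity < min_identity:
            reason = "low_identity"
        c.high_confidence = reason is None
        c.reject_reason = reason
        if c.high_confidence:
            kept.append(c)
    return kept


def _edlib_prescreen(seq_a: str, seq_b: str, max_norm_dist: float = 0.6) -> bool:
    """Cheap edit-distance screen: can this pair possibly reach ~50% identity?"""
    res = edlib.align(seq_a, seq_b, mode="NW", k=int(max_norm_dist * max(len(seq_a), len(seq_b))))
    return res["editDistance"] != -1


def build_orthogroups(genes: list[GeneModel], min_identity: float = 50.0) -> list[set[str]]:
    """Partition genes into orthogroups by connected components of the
    >= min_identity percent-identity graph (all-vs-all, cross- and
    within-species edges; an edit-distance prescreen skips hopeless pairs)."""
    species = {g.species for g in genes}
    if len(species) < 2:
        raise ValueError("at least two species required")
    graph = nx.Graph()
    graph.add_nodes_from(g.gene_id for g in genes)
    with_seq = [g for g in genes if g.protein_seq]
    for i, a in enumerate(with_seq):
        for b in with_seq[i + 1:]:
            if min_identity > 100:
                continue
            if not _edlib_prescreen(a.protein_seq, b.protein_seq):
                continue
            if percent_identity(a.protein_seq, b.protein_seq) >= min_identity:
                graph.add_edge(a.gene_id, b.gene_id)
    return [set(c) for c in nx.connected_components(graph)]


def single_copy_orthologs(orthogroups: list[set[str]],
                          genes: list[GeneModel]) -> set[str]:
    """Genes in orthogroups containing exactly one gene of each species."""
    species_of = {g.gene_id: g.species for g in genes}
    n_species = len(set(species_of.values()))
    out = set()
    for group in orthogroups:
        if len(group) == n_species and len({species_of[g] for g in group}) == n_species:
            out |= group
    return out
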