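"""Core domain containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class GeneModel:
    """A gene with its genomic placement and sequences.

    ordinal_index is the 0-based rank of the gene along its chromosome by
    start coordinate; neighbor-based scores (GOC, collinearity) operate on
    ordinal positions, not base-pair coordinates.
    """

    gene_id: str
    species: str
    chromosome: str
    ordinal_index: int
    strand: str = "+"
    protein_seq: str | None = None
    cds_seq: str | None = None
    domain_count: int | None = None


@dataclass
class OrthologCandidate:
    """A cross-species gene pair with its homology-confidence evidence.

    wga_score (whole-genome-alignment score) is an input taken from an
    external resource, never computed here.
    """

    gene_a: str
    gene_b: str
    wga_score: float | None = None
    goc_score: int | None = None
    pct_identity: float | None = None
    high_confidence: bool | None = None
    reject_reason: str | None = None


@dataclass
class ParalogCandidate:
    """A within-species duplicate pair with a duplication-timing label."""

    gene_1: str
    gene_2: str
    duplication_timing: str | None = None
    pair_identity: float | None = None


@dataclass
class OhnologPair:
    """Two within-species WGD duplicates plus their single outgroup ortholog."""

    copy_1: str
    copy_2: str
    outgroup_gene: str | None = None
    identity_12: float | None = None
    identity_o1: float | None = None
    identity_o2: float | None = None
    collinearity_support: int | None = None
    called: bool = False
    reason: str | None = None

    @property
    def genes(self) -> frozenset:
        return frozenset((self.copy_1, self.copy_2))


@dataclass
class DivergenceReport:
    """Per-pair functional divergence summary versus the outgroup ortholog."""

    pair: OhnologPair
    dist_copy1: float | None = None
    dist_copy2: float | None = None
    conserved_copy: str | None = None
    diverged_copy: str | None = None
    tie_flag: bool = False
    omega_copy1: float | None = None
    omega_copy2: float | None = None
    ng86_copy1: object | None = None
    ng86_copy2: object | None = None
    domain_count_1: int | None = None
    domain_count_2: int | None = None
    protein_len_1: int | None = None
    protein_len_2: int | None = None

    @property
    def dist_conserved(self) -> float | None:
        if self.conserved_copy is None:
            return None
        return self.dist_copy1 if self.conserved_copy == self.pair.copy_1 else self.dist_copy2

    @property
    def dist_diverged(self) -> float | None:
        if self.diverged_copy is None:
            return None
        return self.dist_copy1 if self.diverged_copy == self.pair.copy_1 else self.dist_copy2


@dataclass
class ExpressionMatrix:
    """Gene x sample raw counts with sample metadata and size factors.

    counts: DataFrame indexed by gene id, one column per sample.
    sample_meta: DataFrame indexed by sample id; recognised columns are
    'tissue' and 'sex'.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    size_factors: pd.Series | None = None

    def __post_init__(self):
        if not self.counts.columns.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.loc[self.counts.columns]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValueError("size factors not computed; call atlas.size_factors first")
        return self.counts.div(self.size_factors, axis=1)


@dataclass
class IntronCluster:
    """A set of introns sharing splice sites, with per-sample read counts.

    Coordinates are half-open 0-based. counts has one row per intron (same
    order as `introns`) and one column per sample."""

    cluster_id: str
    introns: list[tuple[str, int, int, str]]
    counts: "object"  # numpy array, introns x samples

    @property
    def n_introns(self) -> int:
        return len(self.introns)


@dataclass
class TruthSet:
    """Simulator ground truth used by the recovery tests.

    Pair ids are the ancestral gene ids; true_pairs holds the surviving
    duplicate gene-id pairs, and single_copy_orthologs the duplicated-species
    gene ids whose other copy was lost (single copy in both species).
    """

    true_pairs: set[frozenset] = field(default_factory=set)
    lost_copies: set[str] = field(default_factory=set)
    single_copy_orthologs: set[str] = field(default_factory=set)
    true_sex_biased: dict[str, str] = field(default_factory=dict)
    true_divergent_pairs: set[str] = field(default_factory=set)
    immune_genes: set[str] = field(default_factory=set)
    diverged_copy: dict[str, str] = field(default_factory=dict)
    pair_by_ancestor: dict[str, frozenset] = field(default_factory=dict)
    silent_genes: set[str] = field(default_factory=set)
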