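"""Readers and writers for the pipeline's on-disk formats.

FASTA via Bio.SeqIO; GFF3 (1-based inclusive, `ID=` attribute) written here
and read back through pyranges; all tabular formats are plain TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pyranges
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (ExpressionMatrix, GeneModel, IntronCluster,
                     OrthologCandidate, ParalogCandidate, TruthSet)

# simulated gene footprint: each gene occupies ~1 kb of ordinal spacing
_GENE_SPACING = 2000


def _records(genes, attr):
    for g in genes:
        seq = getattr(g, attr)
        if seq:
            yield SeqRecord(Seq(seq), id=g.gene_id, description="")


def write_protein_fasta(genes: list[GeneModel], path) -> None:
    SeqIO.write(_records(genes, "protein_seq"), str(path), "fasta")


def write_cds_fasta(genes: list[GeneModel], path) -> None:
    SeqIO.write(_records(genes, "cds_seq"), str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.ordinal_index)):
            start = g.ordinal_index * _GENE_SPACING + 1
            end = start + (len(g.cds_seq) if g.cds_seq else 999) - 1
            fh.write("\t".join([
                g.chromosome, "ohnokit", "gene", str(start), str(end), ".",
                g.strand, ".", f"ID={g.gene_id}",
            ]) + "\n")


def read_gff3(path, species: str = "") -> list[GeneModel]:
    """Read gene records from GFF3, assigning ordinal indices by start
    coordinate per chromosome."""
    df = pyranges.read_gff3(str(path)).df
    df = df[df.Feature == "gene"].copy()
    genes = []
    for chrom, sub in df.groupby("Chromosome", observed=True):
        sub = sub.sort_values("Start")
        for ordinal, row in enumerate(sub.itertuples()):
            genes.append(GeneModel(str(row.ID), species, str(chrom), ordinal,
                                   str(row.Strand)))
    return sorted(genes, key=lambda g: g.gene_id)


def attach_sequences(genes: list[GeneModel], proteins: dict | None = None,
                     cds: dict | None = None, domains: pd.Series | None = None) -> list[GeneModel]:
    for g in genes:
        if proteins is not None:
            g.protein_seq = proteins.get(g.gene_id)
        if cds is not None:
            g.cds_seq = cds.get(g.gene_id)
        if domains is not None and g.gene_id in domains.index:
            g.domain_count = int(domains.loc[g.gene_id])
    return genes


def read_gene_models(gff_path, protein_fasta=None, cds_fasta=None,
                     domain_tsv=None, species: str = "") -> list[GeneModel]:
    genes = read_gff3(gff_path, species=species)
    proteins = read_fasta(protein_fasta) if protein_fasta else None
    cds = read_fasta(cds_fasta) if cds_fasta else None
    domains = None
    if domain_tsv:
        domains = pd.read_csv(domain_tsv, sep="\t").set_index("gene_id")["domain_count"]
    return attach_sequences(genes, proteins, cds, domains)


def read_ortholog_candidates(path) -> list[OrthologCandidate]:
    df = pd.read_csv(path, sep="\t")
    cands = []
    for row in df.itertuples(index=False):
        cands.append(OrthologCandidate(
            gene_a=str(row.gene_a), gene_b=str(row.gene_b),
            wga_score=float(row.wga_score) if hasattr(row, "wga_score") and pd.notna(row.wga_score) else None,
            goc_score=int(row.goc_score) if hasattr(row, "goc_score") and pd.notna(row.goc_score) else None,
            pct_identity=float(row.pct_identity) if hasattr(row, "pct_identity") and pd.notna(row.pct_identity) else None,
        ))
    return cands


def write_ortholog_candidates(cands: list[OrthologCandidate], path) -> None:
    pd.DataFrame([{
        "gene_a": c.gene_a, "gene_b": c.gene_b, "wga_score": c.wga_score,
        "goc_score": c.goc_score, "pct_identity": c.pct_identity,
        "high_confidence": c.high_confidence, "reject_reason": c.reject_reason,
    } for c in cands]).to_csv(path, sep="\t", index=False)


def read_paralog_candidates(path) -> list[ParalogCandidate]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(ParalogCandidate(
            gene_1=str(row.gene_1), gene_2=str(row.gene_2),
            duplication_timing=str(row.duplication_timing) if pd.notna(row.duplication_timing) else None,
            pair_identity=float(row.pair_identity) if hasattr(row, "pair_identity") and pd.notna(row.pair_identity) else None,
        ))
    return out


def write_pairs(pairs, path) -> None:
    from .models import OhnologPair
    pd.DataFrame([{
        "copy_1": p.copy_1, "copy_2": p.copy_2, "outgroup_gene": p.outgroup_gene,
        "identity_12": p.identity_12, "identity_o1": p.identity_o1,
        "identity_o2": p.identity_o2, "collinearity_support": p.collinearity_support,
        "called": p.called, "reason": p.reason,
    } for p in pairs]).to_csv(path, sep="\t", index=False)


def read_pairs(path, called_only: bool = False):
    from .models import OhnologPair
    df = pd.read_csv(path, sep="\t")
    pairs = []
    for row in df.itertuples(index=False):
        p = OhnologPair(
            copy_1=str(row.copy_1), copy_2=str(row.copy_2),
            outgroup_gene=str(row.outgroup_gene) if pd.notna(row.outgroup_gene) else None,
            identity_12=float(row.identity_12) if pd.notna(row.identity_12) else None,
            identity_o1=float(row.identity_o1) if pd.notna(row.identity_o1) else None,
            identity_o2=float(row.identity_o2) if pd.notna(row.identity_o2) else None,
            collinearity_support=int(row.collinearity_support) if pd.notna(row.collinearity_support) else None,
            called=bool(row.called),
            reason=str(row.reason) if pd.notna(row.reason) else None,
        )
        if not called_only or p.called:
            pairs.append(p)
    return pairs


def read_expression_matrix(counts_tsv, meta_tsv) -> ExpressionMatrix:
    counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    meta = pd.read_csv(meta_tsv, sep="\t", index_col=0)
    return ExpressionMatrix(counts, meta)


def read_gene_set(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_junctions(path) -> tuple[list[IntronCluster], list[str]]:
    """Junction-count TSV (chrom, start, end, strand, cluster_id, one column
    per sample) -> intron clusters plus the sample-id order."""
    df = pd.read_csv(path, sep="\t")
    fixed = ["chrom", "start", "end", "strand", "cluster_id"]
    samples = [c for c in df.columns if c not in fixed]
    clusters = []
    for cid, sub in df.groupby("cluster_id", sort=True):
        introns = [(str(r.chrom), int(r.start), int(r.end), str(r.strand))
                   for r in sub.itertuples(index=False)]
        clusters.append(IntronCluster(str(cid), introns, sub[samples].to_numpy(dtype=np.int64)))
    return clusters, samples


def write_junctions(clusters: list[IntronCluster], samples: list[str], path) -> None:
    rows = []
    for cl in clusters:
        for i, (chrom, start, end, strand) in enumerate(cl.introns):
            rows.append([chrom, start, end, strand, cl.cluster_id, *cl.counts[i].tolist()])
    pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "cluster_id", *samples]) \
        .to_csv(path, sep="\t", index=False)


def write_truth(truth: TruthSet, pairs_path, genes_path, all_genes: list[GeneModel]) -> None:
    pair_rows = []
    for anc, pair in sorted(truth.pair_by_ancestor.items()):
        g1, g2 = sorted(pair)
        pair_rows.append({
            "ancestor": anc, "copy_1": g1, "copy_2": g2,
            "divergent_profile": anc in truth.true_divergent_pairs,
            "diverged_copy": truth.diverged_copy.get(anc, ""),
        })
    pd.DataFrame(pair_rows).to_csv(pairs_path, sep="\t", index=False)

    gene_rows = []
    for g in sorted(all_genes, key=lambda g: g.gene_id):
        gene_rows.append({
            "gene_id": g.gene_id,
            "species": g.species,
            "immune": g.gene_id in truth.immune_genes,
            "silent": g.gene_id in truth.silent_genes,
            "single_copy_ortholog": g.gene_id in truth.single_copy_orthologs,
            "sex_direction": truth.true_sex_biased.get(g.gene_id, ""),
        })
    pd.DataFrame(gene_rows).to_csv(genes_path, sep="\t", index=False)


def read_truth(pairs_path, genes_path) -> TruthSet:
    truth = TruthSet()
    pairs = pd.read_csv(pairs_path, sep="\t")
    for row in pairs.itertuples(index=False):
        pair = frozenset((str(row.copy_1), str(row.copy_2)))
        truth.true_pairs.add(pair)
        truth.pair_by_ancestor[str(row.ancestor)] = pair
        if bool(row.divergent_profile):
            truth.true_divergent_pairs.add(str(row.ancestor))
        if isinstance(row.diverged_copy, str) and row.diverged_copy:
            truth.diverged_copy[str(row.ancestor)] = str(row.diverged_copy)
    genes = pd.read_csv(genes_path, sep="\t")
    for row in genes.itertuples(index=False):
        gid = str(row.gene_id)
        if bool(row.immune):
            truth.immune_genes.add(gid)
        if bool(row.silent):
            truth.silent_genes.add(gid)
        if bool(row.single_copy_ortholog):
            truth.single_copy_orthologs.add(gid)
        if isinstance(row.sex_direction, str) and row.sex_direction:
            truth.true_sex_biased[gid] = row.sex_direction
    # lost ancestors are those whose surviving copy is a single-copy ortholog
    for gid in truth.single_copy_orthologs:
        if gid.startswith("dup"):
            truth.lost_copies.add(f"anc{gid[3:7]}")
    return truth
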