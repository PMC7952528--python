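"""Synthetic post-WGD genome, annotation and expression simulator.

Emulates the data structure the downstream analyses assume: an ancestral gene
order duplicated into two collinear subgenomes with stochastic reversion to
single copy; a non-duplicated outgroup; per-copy codon-level divergence with a
tunable dN/dS; domain-count erosion of diverged copies; an eight-tissue
expression atlas built from latent expression programs; and a two-sex
negative-binomial count matrix with a directional sex bias.  Ground truth for
every stochastic choice is returned in a TruthSet so recovery can be scored.

Sequence evolution is per-site independent codon substitution with a fixed
transition/transversion ratio of 2 and no indels; dN/dS is tuned by
accept/reject on proposed substitutions, with acceptance probabilities
calibrated against the ancestral sequence's NG86 site counts so the realized
NG86 omega tracks the configured target.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .codon import (NUCLEOTIDES, SENSE_CODONS, STOP_CODONS, TRANSITIONS,
                    codon_sites, is_synonymous)
from .config import SimConfig
from .models import ExpressionMatrix, GeneModel, IntronCluster, TruthSet

OUTGROUP_SPECIES = "outgroup"
DUP_SPECIES = "duplicated"

_TISSUES = ["gill", "spleen", "head_kidney", "liver", "brain", "heart", "muscle", "skin"]

# distinct streams per generator stage, all derived from config.seed
_STREAM_GENOME, _STREAM_ATLAS, _STREAM_SEX, _STREAM_ANNOT, _STREAM_BUNDLE = range(5)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def tissue_names(n_tissues: int) -> list[str]:
    names = list(_TISSUES[:n_tissues])
    while len(names) < n_tissues:
        names.append(f"tissue{len(names) + 1}")
    return names


# ---------------------------------------------------------------------------
# codon-level sequence evolution


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random sense-codon CDS starting with ATG (no stop codons)."""
    codons = ["ATG"] + [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons - 1)]
    return "".join(codons)


def _acceptance_probs(cds: str, omega: float) -> tuple[float, float]:
    """(p_accept_synonymous, p_accept_nonsynonymous) for an accept/reject
    substitution process targeting NG86 omega == `omega` on this sequence.

    pi_S / pi_N are the proposal-weighted synonymous / nonsynonymous mutation
    opportunities (ts weight 2, tv weight 1, stop-creating proposals excluded);
    N / S are the sequence's NG86 site counts.  Setting the acceptance ratio to
    omega * (pi_S * N) / (pi_N * S) makes pN/pS track omega.
    """
    pi_s = pi_n = 0.0
    n_sites = s_sites = 0.0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        n, s = codon_sites(codon)
        n_sites += n
        s_sites += s
        for pos in range(3):
            for alt in NUCLEOTIDES:
                if alt == codon[pos]:
                    continue
                weight = 2.0 if TRANSITIONS[codon[pos]] == alt else 1.0
                mutant = codon[:pos] + alt + codon[pos + 1 :]
                if mutant in STOP_CODONS:
                    continue
                if is_synonymous(codon, mutant):
                    pi_s += weight
                else:
                    pi_n += weight
    if pi_n == 0 or s_sites == 0:
        return 1.0, min(1.0, omega)
    ratio = omega * (pi_s * n_sites) / (pi_n * s_sites)
    if ratio <= 1.0:
        return 1.0, ratio
    return 1.0 / ratio, 1.0


def evolve_cds(cds: str, rate: float, omega: float, rng: np.random.Generator) -> str:
    """Evolve a CDS by `rate` expected accepted substitutions per nucleotide
    site under the calibrated accept/reject process (no indels)."""
    p_syn, p_non = _acceptance_probs(cds, omega)
    seq = list(cds)
    n_events = rng.poisson(rate * len(seq))
    accepted = 0
    tries = 0
    max_tries = 200 * (n_events + 10)
    while accepted < n_events and tries < max_tries:
        tries += 1
        pos = int(rng.integers(0, len(seq)))
        cur = seq[pos]
        if rng.random() < 0.5:
            alt = TRANSITIONS[cur]
        else:
            alt = [n for n in NUCLEOTIDES if n != cur and n != TRANSITIONS[cur]][int(rng.integers(0, 2))]
        codon_start = 3 * (pos // 3)
        codon = "".join(seq[codon_start : codon_start + 3])
        mutant = codon[: pos - codon_start] + alt + codon[pos - codon_start + 1 :]
        if mutant in STOP_CODONS:
            continue
        p_accept = p_syn if is_synonymous(codon, mutant) else p_non
        if rng.random() < p_accept:
            seq[pos] = alt
            accepted += 1
    return "".join(seq)


def translate(cds: str) -> str:
    return str(Seq(cds).translate()).rstrip("*")


# ---------------------------------------------------------------------------
# genome simulation


def simulate_wgd_genome(config: SimConfig) -> tuple[list[GeneModel], list[GeneModel], TruthSet]:
    """Simulate the outgroup and the duplicated genome plus ground truth.

    Each ancestral gene yields one outgroup copy and two duplicated-species
    copies on two collinear subgenomes ('a' and 'b' chromosomes preserving
    ancestral order); with probability loss_prob one duplicate is lost and the
    ancestral gene becomes a single-copy ortholog in both species.  One copy
    per retained pair is designated "diverged" and evolves at the faster rate
    and higher omega; it may also lose a functional domain.
    """
    rng = _rng(config, _STREAM_GENOME)
    truth = TruthSet()

    chrom_of = np.sort(rng.integers(0, config.n_chromosomes, config.n_genes))
    outgroup: list[GeneModel] = []
    duplicated: list[GeneModel] = []
    per_chrom_out: dict[str, int] = {}
    per_chrom_dup: dict[str, int] = {}

    ancestors = []
    for i in range(config.n_genes):
        anc_id = f"anc{i:04d}"
        n_codons = max(60, int(rng.poisson(config.mean_protein_len)))
        anc_cds = random_cds(n_codons, rng)
        domain_base = 1 + int(rng.poisson(2.0))
        immune = rng.random() < config.frac_immune
        diverged_label = "a" if rng.random() < 0.5 else "b"
        lost = rng.random() < config.loss_prob
        lost_label = ("a" if rng.random() < 0.5 else "b") if lost else None
        divergent_profile = (not lost) and (rng.random() < config.frac_divergent_profiles)
        ancestors.append((anc_id, int(chrom_of[i]), anc_cds, domain_base, immune,
                          diverged_label, lost_label, divergent_profile))

    for anc_id, chrom, anc_cds, domain_base, immune, diverged_label, lost_label, divergent in ancestors:
        idx = int(anc_id[3:])
        out_id = f"out{idx:04d}"
        out_chrom = f"chrO{chrom + 1}"
        out_cds = evolve_cds(anc_cds, config.divergence_rate_conserved, config.omega_conserved, rng)
        ord_out = per_chrom_out.setdefault(out_chrom, 0)
        per_chrom_out[out_chrom] += 1
        outgroup.append(GeneModel(out_id, OUTGROUP_SPECIES, out_chrom, ord_out,
                                  "+" if rng.random() < 0.5 else "-",
                                  translate(out_cds), out_cds, domain_base))

        surviving = []
        for label in ("a", "b"):
            if label == lost_label:
                continue
            gene_id = f"dup{idx:04d}{label}"
            dup_chrom = f"chr{chrom + 1}{label.upper()}"
            if label == diverged_label:
                rate, omega = config.divergence_rate_diverged, config.omega_diverged
                domains = domain_base
                if rng.random() < config.domain_loss_prob:
                    domains = max(0, domain_base - 1)
                is_diverged = True
            else:
                rate, omega = config.divergence_rate_conserved, config.omega_conserved
                domains = domain_base
                is_diverged = False
            cds = evolve_cds(anc_cds, rate, omega, rng)
            ordinal = per_chrom_dup.setdefault(dup_chrom, 0)
            per_chrom_dup[dup_chrom] += 1
            duplicated.append(GeneModel(gene_id, DUP_SPECIES, dup_chrom, ordinal,
                                        "+" if rng.random() < 0.5 else "-",
                                        translate(cds), cds, domains))
            surviving.append(gene_id)
            if immune:
                truth.immune_genes.add(gene_id)
            if is_diverged and lost_label is None:
                truth.diverged_copy[anc_id] = gene_id
        if immune:
            truth.immune_genes.add(out_id)

        if lost_label is None:
            pair = frozenset(surviving)
            truth.true_pairs.add(pair)
            truth.pair_by_ancestor[anc_id] = pair
            if divergent:
                truth.true_divergent_pairs.add(anc_id)
        else:
            truth.lost_copies.add(anc_id)
            truth.single_copy_orthologs.add(surviving[0])

    # silent genes (never expressed anywhere), drawn over duplicated genes
    dup_ids = [g.gene_id for g in duplicated]
    n_silent = int(round(config.frac_silent * len(dup_ids)))
    if n_silent:
        truth.silent_genes = set(rng.choice(dup_ids, size=n_silent, replace=False).tolist())

    # sex-biased genes: drawn per ancestral gene so both copies inherit the
    # same direction; silent genes are not eligible
    for anc_id, _, _, _, _, _, lost_label, _ in ancestors:
        idx = int(anc_id[3:])
        members = [f"dup{idx:04d}{lab}" for lab in ("a", "b") if lab != lost_label]
        members = [m for m in members if m not in truth.silent_genes]
        if not members:
            continue
        if rng.random() < config.frac_sex_biased:
            direction = "female" if rng.random() < config.bias_direction_prob else "male"
            for m in members:
                truth.true_sex_biased[m] = direction
    return outgroup, duplicated, truth


# ---------------------------------------------------------------------------
# expression simulation


def _nb_draw(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial counts with Var = m + dispersion * m^2 (Poisson when
    dispersion == 0)."""
    mean = np.clip(mean, 1e-12, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def simulate_expression_atlas(genes: list[GeneModel], truth: TruthSet,
                              config: SimConfig) -> ExpressionMatrix:
    """Gene x tissue counts (one library per tissue) for the duplicated species.

    Every ancestral gene draws a baseline tissue profile from one of
    n_archetypes latent expression programs (times a gene-specific abundance
    and jitter); both copies of a retained pair share that profile unless the
    pair is a true divergent-profile pair, in which case the diverged copy
    draws an independent program.  Silent genes emit exact zeros.
    """
    if config.n_tissues < 2:
        raise ValueError("n_tissues must be >= 2")
    rng = _rng(config, _STREAM_ATLAS)
    tissues = tissue_names(config.n_tissues)
    archetypes = rng.lognormal(mean=0.0, sigma=0.8, size=(config.n_archetypes, config.n_tissues))

    def draw_profile():
        k = int(rng.integers(0, config.n_archetypes))
        jitter = rng.lognormal(0.0, 0.15, config.n_tissues)
        return k, archetypes[k] * jitter

    gene_ids = [g.gene_id for g in genes]
    anc_of = {gid: f"anc{gid[3:7]}" for gid in gene_ids}
    profiles: dict[str, np.ndarray] = {}
    anc_ids = sorted({anc_of[g] for g in gene_ids})
    anc_profile = {}
    anc_mu = {}
    for anc in anc_ids:
        k, prof = draw_profile()
        anc_profile[anc] = (k, prof)
        anc_mu[anc] = rng.lognormal(math.log(100.0), 1.0)
    for gid in gene_ids:
        anc = anc_of[gid]
        k, prof = anc_profile[anc]
        if anc in truth.true_divergent_pairs and truth.diverged_copy.get(anc) == gid:
            k2, prof2 = draw_profile()
            while k2 == k:  # guarantee a genuinely different program
                k2, prof2 = draw_profile()
            prof = prof2
        profiles[gid] = anc_mu[anc] * prof

    counts = np.zeros((len(gene_ids), config.n_tissues), dtype=np.int64)
    for i, gid in enumerate(gene_ids):
        if gid in truth.silent_genes:
            continue
        counts[i] = _nb_draw(profiles[gid], config.nb_dispersion, rng)
    mat = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=tissues)
    meta = pd.DataFrame({"tissue": tissues}, index=pd.Index(tissues, name="sample"))
    return ExpressionMatrix(mat, meta)


def simulate_sex_counts(genes: list[GeneModel], truth: TruthSet,
                        config: SimConfig) -> ExpressionMatrix:
    """Gene x sample liver counts for n_samples_per_sex males and females.

    True sex-biased genes get a log2 fold change of mean magnitude lfc_mean
    (gamma-distributed, shape 4) in their truth direction, split symmetrically
    between the sexes; library-size multipliers are log-normal(0, 0.25)."""
    if config.n_samples_per_sex < 3:
        raise ValueError("n_samples_per_sex must be >= 3")
    rng = _rng(config, _STREAM_SEX)
    gene_ids = [g.gene_id for g in genes]
    n = config.n_samples_per_sex
    samples = [f"M{i + 1:02d}" for i in range(n)] + [f"F{i + 1:02d}" for i in range(n)]
    sexes = ["male"] * n + ["female"] * n
    lib = rng.lognormal(0.0, 0.25, 2 * n)

    mu = rng.lognormal(math.log(100.0), 1.0, len(gene_ids))
    lfc = np.zeros(len(gene_ids))
    for i, gid in enumerate(gene_ids):
        direction = truth.true_sex_biased.get(gid)
        if direction is None:
            continue
        magnitude = rng.gamma(4.0, config.lfc_mean / 4.0)
        lfc[i] = magnitude if direction == "male" else -magnitude

    mean_male = mu * np.power(2.0, lfc / 2.0)
    mean_female = mu * np.power(2.0, -lfc / 2.0)
    silent = np.array([gid in truth.silent_genes for gid in gene_ids])
    counts = np.zeros((len(gene_ids), 2 * n), dtype=np.int64)
    for j in range(2 * n):
        base = mean_male if sexes[j] == "male" else mean_female
        counts[:, j] = _nb_draw(base * lib[j], config.nb_dispersion, rng)
    counts[silent] = 0
    mat = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    meta = pd.DataFrame({"sex": sexes}, index=pd.Index(samples, name="sample"))
    return ExpressionMatrix(mat, meta)


def simulate_annotation(genes: list[GeneModel], truth: TruthSet, config: SimConfig,
                        n_terms: int = 40) -> pd.DataFrame:
    """GO-style gene -> term annotation table; two designated terms are
    preferentially attached to immune genes so enrichment has signal."""
    rng = _rng(config, _STREAM_ANNOT)
    gene_ids = [g.gene_id for g in genes]
    terms = [f"TERM:{i:04d}" for i in range(n_terms)]
    rows = []
    for gid in gene_ids:
        for t in rng.choice(terms, size=min(n_terms, rng.poisson(3)), replace=False):
            rows.append((gid, t))
        if gid in truth.immune_genes:
            for t in terms[:2]:
                if rng.random() < 0.5:
                    rows.append((gid, t))
    df = pd.DataFrame(rows, columns=["gene_id", "term_id"]).drop_duplicates()
    return df.sort_values(["gene_id", "term_id"]).reset_index(drop=True)


def simulate_intron_clusters(n_clusters: int, n_samples_per_sex: int,
                             seed: int, mean_cluster_reads: float = 80.0,
                             effect_clusters: int = 0,
                             effect_size: float = 2.0) -> tuple[list[IntronCluster], list[str], set[str]]:
    """Synthetic intron clusters for differential-usage testing.

    Each cluster has 2-5 introns with Dirichlet usage proportions shared by
    both sexes; the first `effect_clusters` clusters get a perturbed
    proportion vector in males (one intron's weight multiplied by
    `effect_size`).  Returns (clusters, per-sample sex labels, ids of
    perturbed clusters)."""
    rng = np.random.default_rng([seed, 17])
    n = n_samples_per_sex
    sexes = ["male"] * n + ["female"] * n
    clusters = []
    perturbed: set[str] = set()
    for c in range(n_clusters):
        k = int(rng.integers(2, 6))
        props = rng.dirichlet(np.full(k, 5.0))
        props_m = props.copy()
        cid = f"clu_{c + 1}"
        if c < effect_clusters:
            props_m[0] *= effect_size
            props_m /= props_m.sum()
            perturbed.add(cid)
        introns = [(f"chr{c % 5 + 1}", 1000 * c + 100 * i, 1000 * c + 100 * i + 80, "+")
                   for i in range(k)]
        counts = np.zeros((k, 2 * n), dtype=np.int64)
        for j in range(2 * n):
            total = rng.poisson(mean_cluster_reads)
            p = props_m if sexes[j] == "male" else props
            counts[:, j] = rng.multinomial(total, p)
        clusters.append(IntronCluster(cid, introns, counts))
    return clusters, sexes, perturbed


# ---------------------------------------------------------------------------
# fixture bundle


def simulate_candidate_tables(outgroup: list[GeneModel], duplicated: list[GeneModel],
                              truth: TruthSet, config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ortholog- and paralog-candidate tables for the simulated genomes.

    Ortholog candidates pair every duplicate with its true outgroup ortholog
    (whole-genome-alignment score ~100 minus exponential noise, mimicking a
    score the pipeline consumes but never computes) plus random decoy pairs
    with low scores.  Paralog candidates carry the true WGD pairs labeled
    ancestral_wgd plus random decoy pairs with mixed timing labels."""
    rng = _rng(config, _STREAM_BUNDLE)
    out_ids = [g.gene_id for g in outgroup]
    dup_ids = [g.gene_id for g in duplicated]
    rows = []
    for g in duplicated:
        out_id = f"out{g.gene_id[3:7]}"
        wga = min(100.0, 100.0 - rng.exponential(2.0))
        rows.append((g.gene_id, out_id, round(wga, 1)))
    n_decoys = int(0.2 * config.n_genes)
    for _ in range(n_decoys):
        a = dup_ids[int(rng.integers(0, len(dup_ids)))]
        b = out_ids[int(rng.integers(0, len(out_ids)))]
        if b == f"out{a[3:7]}":
            continue
        rows.append((a, b, round(float(rng.uniform(0, 45)), 1)))
    orth = pd.DataFrame(rows, columns=["gene_a", "gene_b", "wga_score"]).drop_duplicates(
        subset=["gene_a", "gene_b"])

    prows = []
    for anc, pair in sorted(truth.pair_by_ancestor.items()):
        g1, g2 = sorted(pair)
        prows.append((g1, g2, "ancestral_wgd"))
    timings = ["ancestral_wgd", "species", "genus", "older"]
    for _ in range(int(0.15 * config.n_genes)):
        a, b = rng.choice(dup_ids, size=2, replace=False)
        if frozenset((a, b)) in truth.true_pairs:
            continue
        prows.append((min(a, b), max(a, b), timings[int(rng.integers(0, 4))]))
    para = pd.DataFrame(prows, columns=["gene_1", "gene_2", "duplication_timing"]).drop_duplicates(
        subset=["gene_1", "gene_2"])
    return orth, para


def write_fixture_bundle(config: SimConfig, outdir) -> dict:
    """Run the full simulator and write the on-disk fixture bundle.

    Emits protein/CDS FASTA and GFF3 for both species, the ortholog- and
    paralog-candidate TSVs (with fabricated whole-genome-alignment scores:
    ~100 for true orthologs, low for decoys), domain counts, both count
    matrices with metadata, the annotation table and the truth tables.
    Re-running with the same config is byte-identical."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outgroup, duplicated, truth = simulate_wgd_genome(config)
    atlas = simulate_expression_atlas(duplicated, truth, config)
    sexmat = simulate_sex_counts(duplicated, truth, config)
    annotation = simulate_annotation(duplicated, truth, config)
    orth, para = simulate_candidate_tables(outgroup, duplicated, truth, config)

    from . import io as okio  # local import to avoid a cycle at module load

    paths = {}
    paths["config"] = outdir / "config.yaml"
    config.to_yaml(paths["config"])
    for species, genes in ((OUTGROUP_SPECIES, outgroup), (DUP_SPECIES, duplicated)):
        paths[f"{species}_proteins"] = outdir / f"{species}_proteins.faa"
        paths[f"{species}_cds"] = outdir / f"{species}_cds.fna"
        paths[f"{species}_gff"] = outdir / f"{species}.gff3"
        okio.write_protein_fasta(genes, paths[f"{species}_proteins"])
        okio.write_cds_fasta(genes, paths[f"{species}_cds"])
        okio.write_gff3(genes, paths[f"{species}_gff"])

    paths["ortholog_candidates"] = outdir / "ortholog_candidates.tsv"
    orth.to_csv(paths["ortholog_candidates"], sep="\t", index=False)
    paths["paralog_candidates"] = outdir / "paralog_candidates.tsv"
    para.to_csv(paths["paralog_candidates"], sep="\t", index=False)

    domains = pd.DataFrame(
        [(g.gene_id, g.domain_count) for g in outgroup + duplicated],
        columns=["gene_id", "domain_count"])
    paths["domain_counts"] = outdir / "domain_counts.tsv"
    domains.to_csv(paths["domain_counts"], sep="\t", index=False)

    paths["atlas_counts"] = outdir / "atlas_counts.tsv"
    paths["atlas_meta"] = outdir / "atlas_meta.tsv"
    atlas.counts.to_csv(paths["atlas_counts"], sep="\t")
    atlas.sample_meta.to_csv(paths["atlas_meta"], sep="\t")
    paths["sex_counts"] = outdir / "sex_counts.tsv"
    paths["sex_meta"] = outdir / "sex_meta.tsv"
    sexmat.counts.to_csv(paths["sex_counts"], sep="\t")
    sexmat.sample_meta.to_csv(paths["sex_meta"], sep="\t")

    paths["annotation"] = outdir / "annotation.tsv"
    annotation.to_csv(paths["annotation"], sep="\t", index=False)
    paths["immune_genes"] = outdir / "immune_genes.txt"
    with open(paths["immune_genes"], "w") as fh:
        for gid in sorted(truth.immune_genes):
            fh.write(gid + "\n")

    paths["truth_pairs"] = outdir / "truth_pairs.tsv"
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    okio.write_truth(truth, paths["truth_pairs"], paths["truth_genes"],
                     all_genes=outgroup + duplicated)
    return paths
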