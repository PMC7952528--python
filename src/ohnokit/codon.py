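"""Codon-level utilities: genetic code tables and the Nei-Gojobori (1986)
counting estimator of dN/dS.

The NG86 estimator counts, for every codon, how many of its three nucleotide
positions are (fractionally) synonymous vs nonsynonymous "sites", and resolves
observed codon differences into synonymous/nonsynonymous substitutions by
averaging over all minimal mutational pathways.  Proportions are corrected for
multiple hits with the Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p).

Conventions fixed here (and shared by the simulator):

* Mutations that would create a stop codon count as nonsynonymous in the
  per-codon site tally, so N_sites + S_sites == 3 exactly for every codon.
* Pathways that pass through a stop codon are excluded when resolving
  multi-position codon differences; if every pathway is blocked, all pathways
  are used (the codon pair is still comparable).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"
TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(standard_dna_table.forward_table))
GENETIC_CODE = dict(standard_dna_table.forward_table)


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon, '*' for a stop."""
    return GENETIC_CODE.get(codon, "*")


def is_synonymous(codon_a: str, codon_b: str) -> bool:
    return translate_codon(codon_a) == translate_codon(codon_b)


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts for one sense codon.

    Each position contributes fractionally according to how many of its three
    possible single-nucleotide changes are synonymous; changes to stop codons
    count as nonsynonymous.  The two values always sum to 3.
    """
    if codon in STOP_CODONS or len(codon) != 3:
        raise ValueError(f"not a sense codon: {codon!r}")
    syn = 0.0
    for pos in range(3):
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant not in STOP_CODONS and is_synonymous(codon, mutant):
                syn += 1.0 / 3.0
    return 3.0 - syn, syn


@lru_cache(maxsize=None)
def codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) substitution counts between two sense codons.

    Multi-position differences are resolved by averaging over all minimal
    mutational pathways (orderings of the differing positions); pathways that
    pass through a stop codon are dropped unless that would drop all of them.
    Symmetric in its arguments.
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_positions):
        current = codon_a
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            steps.append((current, nxt))
            current = nxt
        pathways.append((blocked, steps))
    usable = [steps for blocked, steps in pathways if not blocked]
    if not usable:
        usable = [steps for _, steps in pathways]
    nd = sd = 0.0
    for steps in usable:
        for a, b in steps:
            if is_synonymous(a, b):
                sd += 1.0
            else:
                nd += 1.0
    k = len(usable)
    return nd / k, sd / k


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None when inapplicable (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


@dataclass(frozen=True)
class NG86Result:
    """Counts and rates from one pairwise NG86 comparison."""

    n_sites: float
    s_sites: float
    nd: float
    sd: float
    n_codons: int
    dn: float | None
    ds: float | None
    omega: float | None


def _comparable_codons(cds_a: str, cds_b: str):
    if len(cds_a) != len(cds_b):
        raise ValueError("coding sequences must have equal length")
    if len(cds_a) % 3:
        raise ValueError("coding sequence length must be a multiple of 3")
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3].upper(), cds_b[i : i + 3].upper()
        if any(c not in NUCLEOTIDES for c in ca + cb):
            continue  # gap or ambiguity: codon skipped pairwise
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        yield ca, cb


def ng86_dnds(cds_a: str, cds_b: str) -> NG86Result:
    """Nei-Gojobori (1986) dN, dS and omega for two aligned coding sequences.

    Codons containing gaps, ambiguity codes or stop codons are skipped
    pairwise.  Site counts are averaged over the two sequences.  omega is
    None when dS is zero/undefined or the JC correction is inapplicable.
    """
    n_sites = s_sites = nd = sd = 0.0
    n_codons = 0
    for ca, cb in _comparable_codons(cds_a, cds_b):
        na, sa = codon_sites(ca)
        nb, sb = codon_sites(cb)
        n_sites += (na + nb) / 2.0
        s_sites += (sa + sb) / 2.0
        d_n, d_s = codon_differences(ca, cb)
        nd += d_n
        sd += d_s
        n_codons += 1
    if n_codons == 0:
        return NG86Result(0.0, 0.0, 0.0, 0.0, 0, None, None, None)
    pn = nd / n_sites if n_sites > 0 else 0.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    dn = jukes_cantor(pn)
    ds = jukes_cantor(ps)
    omega = None
    if dn is not None and ds is not None and ds > 0:
        omega = dn / ds
    return NG86Result(n_sites, s_sites, nd, sd, n_codons, dn, ds, omega)
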