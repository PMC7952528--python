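"""Protein distances, conserved/diverged assignment, NG86 dN/dS and the
paired copy comparisons."""

import itertools

import numpy as np
import pytest
from Bio.Data.CodonTable import standard_dna_table

from ohnokit.codon import SENSE_CODONS, ng86_dnds
from ohnokit.divergence import (assign_conserved_diverged, compare_pair_metrics,
                                diverged_label_accuracy, protein_distance)
from ohnokit.models import DivergenceReport, OhnologPair
from ohnokit.simulate import evolve_cds, random_cds

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# independent brute-force NG86 oracle (pathway enumeration, no caching)

_CODE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)


def _aa(codon):
    return _CODE.get(codon, "*")


def _oracle_sites(codon):
    syn = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            if mut not in _STOPS and _aa(mut) == _aa(codon):
                syn += 1 / 3
    return 3 - syn, syn


def _oracle_diffs(c1, c2):
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        cur, steps, through_stop = c1, [], False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            through_stop = through_stop or nxt in _STOPS
            steps.append((cur, nxt))
            cur = nxt
        paths.append((through_stop, steps))
    ok = [s for blocked, s in paths if not blocked] or [s for _, s in paths]
    nd = sum(sum(1 for a, b in s if _aa(a) != _aa(b)) for s in ok) / len(ok)
    sd = sum(sum(1 for a, b in s if _aa(a) == _aa(b)) for s in ok) / len(ok)
    return nd, sd


def oracle_ng86_counts(cds_a, cds_b):
    n = s = nd = sd = 0.0
    codons = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        if set(ca + cb) - set("ACGT") or ca in _STOPS or cb in _STOPS:
            continue
        na, sa = _oracle_sites(ca)
        nb, sb = _oracle_sites(cb)
        n += (na + nb) / 2
        s += (sa + sb) / 2
        d_n, d_s = _oracle_diffs(ca, cb)
        nd += d_n
        sd += d_s
        codons += 1
    return n, s, nd, sd, codons


def random_codon_seq(n_codons, rng):
    return "".join(SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons))


# ---------------------------------------------------------------------------
# protein distance


def test_distance_zero_for_identical():
    assert protein_distance("MKTAYIAKQR", "MKTAYIAKQR") == 0.0


def test_distance_counts_mismatches_per_100(rng):
    base = list("".join(rng.choice(list(AA), 100)))
    mutated = base.copy()
    for pos in (3, 17, 42, 61, 88):
        mutated[pos] = next(a for a in AA if a != base[pos])
    # alignment of equal-length sequences with 5 substitutions is gap-free
    assert protein_distance("".join(base), "".join(mutated)) == pytest.approx(5.0)


def test_distance_symmetric_on_random_pairs(rng):
    for _ in range(50):
        a = "".join(rng.choice(list(AA), 40))
        b = "".join(rng.choice(list(AA), int(rng.integers(30, 50))))
        assert protein_distance(a, b) == pytest.approx(protein_distance(b, a))


def test_jc_correction_exceeds_p_distance(rng):
    a = "".join(rng.choice(list(AA), 60))
    b = "".join(rng.choice(list(AA), 60))
    p = protein_distance(a, b)
    if p and p < 90:
        assert protein_distance(a, b, correction="jc") > p


# ---------------------------------------------------------------------------
# conserved/diverged assignment


def test_smaller_distance_is_conserved():
    rep = assign_conserved_diverged(OhnologPair("g1", "g2"), 10.0, 20.0)
    assert rep.conserved_copy == "g1" and rep.diverged_copy == "g2"
    assert not rep.tie_flag
    assert rep.dist_conserved == 10.0 and rep.dist_diverged == 20.0


def test_equal_distances_set_tie_flag():
    rep = assign_conserved_diverged(OhnologPair("g2", "g1"), 12.5, 12.5)
    assert rep.tie_flag
    assert rep.conserved_copy == "g1"  # lexicographic fallback


def test_undefined_distance_leaves_pair_unlabeled():
    rep = assign_conserved_diverged(OhnologPair("g1", "g2"), None, 5.0)
    assert rep.conserved_copy is None


def test_faster_evolving_copy_labeled_diverged(bundle, divergence_reports):
    reports, _ = divergence_reports
    assert diverged_label_accuracy(reports, bundle.truth.diverged_copy) >= 0.9


# ---------------------------------------------------------------------------
# NG86


def test_identical_sequences_have_zero_rates(rng):
    seq = random_codon_seq(100, rng)
    res = ng86_dnds(seq, seq)
    assert res.dn == 0.0 and res.ds == 0.0 and res.omega is None
    assert res.n_sites + res.s_sites == pytest.approx(3 * res.n_codons)


def test_synonymous_only_divergence_gives_omega_zero(rng):
    seq = random_codon_seq(320, rng)
    mutated = list(seq)
    changed = 0
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        for alt in SENSE_CODONS:
            if alt != codon and _aa(alt) == _aa(codon) and sum(
                    x != y for x, y in zip(alt, codon)) == 1:
                mutated[i:i + 3] = alt
                changed += 1
                break
        if changed >= 40:
            break
    mutated = "".join(mutated)
    res = ng86_dnds(seq, mutated)
    assert res.nd == 0.0 and res.dn == 0.0
    assert res.sd > 0 and res.omega == 0.0


def test_ng86_symmetric_and_site_conservation(rng):
    for _ in range(20):
        a = random_codon_seq(60, rng)
        b = evolve_cds(a, 0.1, 0.5, rng)
        r1, r2 = ng86_dnds(a, b), ng86_dnds(b, a)
        assert r1.nd == pytest.approx(r2.nd)
        assert r1.sd == pytest.approx(r2.sd)
        assert r1.n_sites == pytest.approx(r2.n_sites)
        assert r1.n_sites + r1.s_sites == pytest.approx(3 * r1.n_codons)


def test_gapped_and_stop_codons_skipped_pairwise(rng):
    a = random_codon_seq(50, rng)
    b = evolve_cds(a, 0.05, 0.5, rng)
    res_full = ng86_dnds(a, b)
    a2 = a[:30] + "---" + a[33:]
    res_gap = ng86_dnds(a2, b)
    assert res_gap.n_codons == res_full.n_codons - 1
    with pytest.raises(ValueError):
        ng86_dnds(a, b[:-3])


def test_ng86_counts_match_pathway_enumeration_oracle(rng):
    for _ in range(25):
        a = random_codon_seq(80, rng)
        b = evolve_cds(a, 0.2, 0.8, rng)
        res = ng86_dnds(a, b)
        n, s, nd, sd, codons = oracle_ng86_counts(a, b)
        assert res.n_sites == pytest.approx(n)
        assert res.s_sites == pytest.approx(s)
        assert res.nd == pytest.approx(nd)
        assert res.sd == pytest.approx(sd)
        assert res.n_codons == codons


@pytest.mark.parametrize("target", [0.1, 0.5, 1.0])
def test_mean_omega_recovered_within_tolerance(target, rng):
    omegas = []
    for _ in range(50):
        anc = random_codon_seq(500, rng)
        der = evolve_cds(anc, 0.05, target, rng)
        res = ng86_dnds(anc, der)
        if res.omega is not None:
            omegas.append(res.omega)
    assert abs(np.mean(omegas) - target) <= 0.15


# ---------------------------------------------------------------------------
# paired comparisons


def _report(c1, c2, d1, d2, om1, om2, dom1, dom2, len1=200, len2=200):
    rep = assign_conserved_diverged(OhnologPair(c1, c2), d1, d2)
    rep.omega_copy1, rep.omega_copy2 = om1, om2
    rep.domain_count_1, rep.domain_count_2 = dom1, dom2
    rep.protein_len_1, rep.protein_len_2 = len1, len2
    return rep


def test_identical_pairs_give_null_statistics():
    reports = [_report(f"a{i}", f"b{i}", 5.0, 5.0, 0.1, 0.1, 3, 3) for i in range(10)]
    out = compare_pair_metrics(reports)
    assert out["domain_rank_sum"]["p_value"] == 1.0
    assert out["n_domain_differ"] == 0
    assert out["omega_paired_t"]["p_value"] == 1.0
    assert out["length_paired_t"]["p_value"] == 1.0


def test_higher_omega_in_diverged_copies_detected(divergence_reports):
    _, stats = divergence_reports
    t = stats["omega_paired_t"]
    assert t["n"] >= 100
    assert t["mean_diff"] > 0
    assert t["p_one_sided"] < 0.05


def test_domain_difference_counting_matches_printed_scenario(rng):
    # 434 pairs, 42 with unequal domain counts, diverged copy fewer in most
    reports = []
    for i in range(434):
        dom = 3
        if i < 42:
            d1, d2 = (dom, dom - 1) if i < 35 else (dom - 1, dom)
        else:
            d1, d2 = dom, dom
        reports.append(_report(f"a{i}", f"b{i}", 2.0, 6.0, 0.05, 0.15, d1, d2))
    out = compare_pair_metrics(reports)
    assert out["n_domain_differ"] == 42
    assert out["n_diverged_fewer_domains"] > out["n_conserved_fewer_domains"]


def test_label_permutation_symmetrizes_t_sign(rng):
    diffs = rng.normal(0.05, 0.02, 60)  # per-pair omega offsets
    signs = []
    for _ in range(200):
        flip = rng.random(60) < 0.5
        d = np.where(flip, -diffs, diffs)
        signs.append(np.sign(d.mean()))
    frac_positive = np.mean(np.asarray(signs) > 0)
    assert 0.35 <= frac_positive <= 0.65
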