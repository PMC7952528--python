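# Methods

ohnokit implements the analytical cascade used to characterise an immune gene
repertoire after a lineage-specific whole-genome duplication (WGD): homology
confidence filtering against an outgroup, ohnolog-pair calling, per-pair
functional-divergence measures (protein distance, dN/dS, domain architecture,
co-expression), and two-sex differential-expression analyses. Because the
package is validated end-to-end on simulated data, this note describes both
the analysis methods and the generative model behind the simulator, with the
numerical conventions and their rationale.

## Homology evidence and the high-confidence rule

**Percent identity.** Global protein alignment with BLOSUM62 and affine gap
penalties (gap open 10, extension 0.5 per additional gapped position; end gaps
penalised). Identity is the number of identical aligned columns divided by the
total number of alignment columns, gap columns included — a conservative,
symmetric convention; dividing by the shorter sequence length is available as
an option. `X` residues never count as matches. Arguments are ordered
lexicographically before alignment so that the score and identity are exactly
symmetric even when several alignments are co-optimal; when co-optimal
alignments disagree about identity, the aligner's first optimum is reported.

**Gene-order conservation (GOC).** For a candidate ortholog pair, each of the
four closest neighbours of the query gene (two per side, by ordinal position
along the chromosome; strand ignored) scores 25 points when any of its mapped
orthologs lies within two ordinal positions of the candidate ortholog on the
same chromosome. Genes at chromosome ends keep the denominator of four —
missing neighbours count as non-matches — so short contigs cannot inflate
confidence.

**Confidence filter.** A candidate is high confidence when GOC ≥ 50,
whole-genome-alignment (WGA) score ≥ 50 and percent identity ≥ 50, all
inclusive. The WGA score is consumed from the input candidate table, never
computed: it originates from genome-alignment resources outside desk scale.
Candidates with missing scores are rejected with a logged reason code.

**Orthogroups.** For single-copy-ortholog bookkeeping on synthetic data,
orthogroups are connected components of the ≥ 50% identity graph over all
genes of both species (an edit-distance prescreen skips pairs that cannot
reach the threshold). This is a deliberately simple similarity-graph
partition, not a tree-aware orthology method.

## Ohnolog calling

Within-species paralog candidates carry a duplication-timing label; only pairs
timed to the WGD ancestor with within-pair protein identity ≥ 85% (inclusive,
"at least 85%") enter calling. A pair (A, B) is called when exactly one
outgroup gene is orthologous to both copies at ≥ 85% identity and that
outgroup gene has no third duplicate partner (the 2:1 rule). Uncalled pairs
are retained with reason codes (`no_shared_outgroup`, `multiple_outgroups`,
`not_2to1`, …) rather than discarded. No gene may join two called pairs; if
identity noise ever creates a conflict, the pair with the higher mean identity
wins, ties broken by the lexicographically smaller outgroup id, so output is
deterministic.

**Collinearity support** counts, for each called pair, the other called pairs
with one member within a window (default 10 ordinal positions) of copy 1 on
its chromosome and the other member within the window of copy 2 on its
chromosome. It is a diagnostic by default (pairs are flagged, not dropped;
`enforce` removes pairs below `min_support = 2`) because collinearity is used
as a global sanity check on calls, not a calling criterion. With gene losses,
window 2 occasionally leaves an isolated true pair unsupported; from window 5
upward every true called pair in the simulations has support ≥ 1.

## Divergence measures

**Protein distance** is the uncorrected p-distance over gap-free aligned
columns, reported as substitutions per 100 residues; a Jukes–Cantor-type
20-state correction is available behind a flag. The copy with the smaller
distance to the outgroup ortholog is labelled *conserved*, the other
*diverged*; exact ties set a flag and fall back to the lexicographically
smaller gene id. Pairs with an undefined distance are excluded from paired
analyses and logged.

**dN/dS** uses Nei–Gojobori (1986) counting on codon alignments obtained by
projecting the protein alignment onto the coding sequences. Per-codon
synonymous/nonsynonymous site fractions are averaged over the two sequences;
observed multi-position codon differences are resolved by averaging over all
minimal mutational pathways with equal weights (classic NG86), excluding
pathways through stop codons unless all are blocked. Proportions are
Jukes–Cantor corrected; ω = dN/dS is undefined when dS = 0 or a proportion
reaches 3/4. Two conventions are fixed deliberately: (i) mutations that would
create a stop codon count as nonsynonymous in site counting, which keeps
N_sites + S_sites = 3 × compared codons exactly; (ii) dS = 0 pairs are
excluded from the paired ω comparison rather than assigned infinity, keeping
the t-test defined. Codons containing gaps, ambiguity codes or stops are
skipped pairwise.

**Paired comparisons** between conserved and diverged copies: a two-sided
rank-sum test of domain counts, a paired t-test of ω (with the one-sided
p-value for the directional question also reported), a paired t-test of
protein lengths, and counts of pairs with unequal domain numbers and of which
copy has fewer. In the simulations, sequences stay length-aligned to the
ancestor (no indels), so the length comparison is exactly null by
construction.

## Expression atlas

**Size factors** are median-of-ratios: per sample, the median over reference
genes (positive counts in every sample) of count divided by the gene's
geometric mean, rescaled to geometric mean one; with no reference gene the
total-count ratio is used with a warning. Normalisation divides counts by the
factors and therefore preserves within-sample rank order.

**Presence** calls a gene expressed in a tissue when its normalised count
exceeds a threshold, default 0 — the loosest rule. The simulator emits exact
zeros for silent genes, so any threshold below one count behaves identically;
with real data the threshold is a tunable parameter.

**Immune vs non-immune abundance** is a per-tissue two-sided rank-sum test on
normalised expression with BH adjustment across tissues and a direction
label; groups under three genes are reported as underpowered.

**Co-expression clustering** stands in for non-exhaustive cluster extraction
tools: genes that are zero everywhere or whose log2 profile spans less than
the flatness threshold (default 1.0, i.e. under one twofold change) are
unassigned; remaining genes are z-scored across tissues and k-means clustered
with K chosen by maximal mean silhouette over K ∈ [2, 12] at a fixed seed;
genes farther than 1.5 × their cluster's mean within-distance from the
centroid become unassigned. The two decisive behaviours of the original
approach — flat-gene exclusion and non-exhaustive assignment — are retained;
exact cluster counts are algorithm-dependent and are not treated as
meaningful outputs. Pair profiles are then labelled conserved (same cluster),
divergent (different clusters), partial (one copy assigned) or unassigned;
the four labels partition the pairs and are invariant to cluster relabelling.

## Two-sex analyses

**Differential expression.** Per gene, normalised group means for males and
females; pooled method-of-moments NB dispersion α = max(0, (s² − m)/m²) with
the mean floored at 0.5 counts; log2 fold change with a 0.5 pseudocount; the
delta-method standard error from the NB variance m + αm²; and a Wald
statistic referred to a t distribution with n_M + n_F − 2 degrees of freedom.
The t reference (rather than the standard normal) reflects the finite degrees
of freedom of the moment variance estimate; with twelve samples per sex the
normal reference is visibly anticonservative (~7% type-I at nominal 5%),
while the t reference restores ~5%. BH adjustment runs over tested genes
only; all-zero genes are excluded from testing and from the BH denominator.
This moment-based test is self-contained and calibration-testable by
simulation; it is not claimed to reproduce the gene lists of shrinkage-based
DE tools.

**BH adjustment** is the standard step-up (sort ascending, adj_i = min over
j ≥ i of m·p_j/j, capped at one, order restored). Note that BH is not
idempotent: re-adjusting already-adjusted values can only raise them.

**Directional bias** is a two-sided exact binomial test of the larger
direction count among significant genes against 0.5, with the two-sided
p-value defined by summing point probabilities no larger than that of the
observed count (conventions for two-sided binomial tests differ; this one is
stated explicitly and matches scipy's).

**Differential intron usage.** Intron clusters are filtered by the standard
junction rules: intron length ≤ 500 kb, per-intron total reads ≥ 5, cluster
total reads ≥ 50, ≥ 2 surviving introns; a cluster is testable when at least
five samples per sex have nonzero cluster totals. The test is a multinomial
likelihood-ratio test — one shared usage-proportion vector versus per-sex
vectors — with 2·(ℓ_alt − ℓ_null) against chi-square on K − 1 degrees of
freedom and BH across clusters. The multinomial LRT captures the same
null/alternative contrast as Dirichlet-multinomial splicing models but
ignores biological overdispersion between samples of the same sex: on real
data it would be anticonservative for highly variable clusters. Under the
simulator's multinomial sampling it is correctly calibrated (~5% type-I).

**Term enrichment** over a GO-style gene→term table: terms annotating fewer
than 20 genes (node size) are skipped; fisher mode is a one-sided enrichment
Fisher exact test on the 2×2 of set membership × term membership (equal to
the hypergeometric tail); ks mode is a one-sided two-sample
Kolmogorov–Smirnov test that term genes have stochastically smaller scores
(e.g. DE p-values). No graph-aware decorrelation across nested terms is
attempted; p-values of overlapping terms are correlated and should be read
term by term.

**PCA** is an SVD of gene-standardised log2(normalised + 1) counts — a simple
variance-stabilisation stand-in — reporting explained-variance fractions and
sample scores without any claim about which covariate separates.

**Ohnolog concordance**: among pairs with both copies significantly DE, a
pair is concordant when both copies are biased toward the same sex; for
discordant pairs the conserved/diverged roles of the two copies are reported.

## The simulator

The generator's defaults define the study conditions used by the tests and
the acceptance script: 300 ancestral genes on 5 chromosomes; one copy lost
with probability 0.4 per gene (the gene always keeps at least one copy, so a
"lost" ancestor becomes a single-copy ortholog in both species); mean protein
length 200 codons; per-copy divergence of 0.02 (conserved) and 0.05
(diverged) accepted substitutions per nucleotide site with target ω of 0.10
and 0.20 — both copies under purifying selection, the diverged copy
measurably less so; the outgroup lineage evolves at the conserved rate. The
duplicated genome is emitted as two subgenomes on distinct chromosomes
preserving ancestral order, which makes collinearity support testable by
construction. Diverged copies lose one functional domain with probability
0.1. 30% of genes are labelled immune. The fabricated WGA score is ~100
minus exponential noise for true orthologs and uniform on [0, 45] for decoy
candidate rows, because the analysis consumes this score rather than
computing it.

**Sequence evolution** is per-site independent codon substitution with a
fixed transition/transversion ratio of 2 and no indels. ω is tuned by
accept/reject: synonymous proposals are accepted with probability p_s,
nonsynonymous with p_n, where the ratio p_n/p_s is calibrated per ancestral
sequence as ω·(π_S·N)/(π_N·S) — π the proposal-weighted mutation
opportunities, N/S the sequence's NG86 site counts — so the *realised* NG86
ω tracks the configured target (within 0.15 across targets 0.1–1.0 at ≥ 300
codons). A plain "accept nonsynonymous with probability ω" rule would
undershoot under transition bias, because transitions are enriched for
synonymous changes relative to the NG86 uniform-mutation site counts.
Proposals creating stop codons are always rejected.

**Expression.** Tissue profiles come from a small set of latent expression
programs ("archetypes", default 6): each ancestral gene draws a program, a
log-normal abundance and mild jitter; both copies of a pair share the profile
unless the pair is a divergent-profile pair (probability 0.2), in which case
the diverged copy draws a different program. This gives the atlas a genuine
cluster structure for the co-expression stand-in to recover. Counts are
negative binomial (dispersion 0.1) with one library per tissue (eight
tissues). Five percent of genes are silent (exact zeros everywhere). The
two-sex matrix has twelve samples per sex with log-normal(0, 0.25) library
sizes; 20% of ancestral genes carry a sex effect inherited by both copies,
with |log2 FC| gamma-distributed around a mean of 1.5 and direction female
with probability 0.7 (a directional majority, mirroring the female-skewed
transcriptome the analysis is designed to detect).

**What the simulator does not emulate** — and hence what passing tests do not
show about real data: indels and alignment error (sequences stay
length-aligned, so protein-length comparisons are exactly null);
tandem/segmental duplications and genomic rearrangement (collinearity is
clean by construction); expression overdispersion beyond a single NB
dispersion shared by all genes; batch structure or tank effects beyond
library-size variation; annotation error in duplication-timing labels (they
are trusted, as in the real pipeline); and the GO term graph (terms are
independent labels).

## Problem sizes and determinism

All simulations used by the tests and the acceptance script run at the
default study conditions (300 ancestral genes, ~490 duplicated-species genes,
8 tissues, 24 sex samples) or smaller; null calibrations use 2,000 genes and
500 intron clusters. Every stochastic step takes an explicit seed, and one
seed fixes the entire cascade byte-for-byte, including the fixture bundle on
disk. The acceptance script derives all sub-seeds from its `--seed` argument.

## Known limitations

Orthology here is similarity-graph based and intended for the synthetic
setting; real repertoire characterisation should take orthology calls and
duplication timing from a dedicated resource, as the pipeline's input tables
assume. The DE test deliberately trades the efficiency of shrinkage
estimators for auditability; at small fold changes or very low counts it is
less sensitive than state-of-the-art tools. The intron LRT ignores
between-sample overdispersion. The co-expression stand-in's cluster count is
selected by silhouette and is not comparable across datasets.
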