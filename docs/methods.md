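# Methods

## Scope and model of the data

The package analyses a staged tumour cohort: a genes × samples count
matrix whose samples carry one label from {normal, SI, SII, SIII, SIV}.
Every statistic downstream of differential expression is a function of
the *signed stage-membership matrix* (per gene and stage: +1
up-regulated, −1 down-regulated, 0 neither), which makes the set
algebra exact and auditable. Somatic mutations travel as MAF-style
single-base substitution records with read counts; sequences as FASTA
with 0-based half-open coordinates.

## Differential expression

Normalization is median-of-ratios: per-sample size factor = median over
genes of the ratio to the gene's geometric-mean reference, with genes
containing any zero excluded from factor estimation (their log
geometric mean is undefined). The factors come out scaled so that their
geometric mean is 1.

The test engine is a two-sided Mann–Whitney rank-sum per gene
(asymptotic, tie-corrected), Benjamini–Hochberg adjusted across tested
genes. A gene is de-regulated only under the dual cut-off
**padj ≤ 0.05 AND |log2FC| ≥ 1.5**; the fold change uses a +1
pseudocount on normalized group means so zero-mean genes stay finite.
The engine is injectable (`call_de(engine=...)`) so a count-model
backend can replace the rank-sum test without touching the thresholds,
which are what the downstream modules depend on. Deliberately out of
scope: negative-binomial dispersion shrinkage and independent filtering
— the simplified engine trades a little power for transparency, which
the Monte-Carlo tests quantify (a 4-fold planted effect at n = 20 per
group is recovered with the right stage assignment in ≥ 95% of seeds).

## Set algebra

*Constitutive* = de-regulated in all stages with a uniform direction
(the per-direction intersection); mixed-direction all-stage genes fall
into the multi-stage bucket, since the direction-resolved intersection
is what the per-direction Venn analysis computes. *Stage-specific(i)* =
de-regulated in stage i and nowhere else; this is the evaluated form of
the piecewise stage-difference formula (subtracting every pairwise
intersection from GS_i leaves exactly the genes flagged only in i), and
the property tests assert equivalence against the literal formula on
random instances. Constitutive ∪ stage-specific(·) ∪ multi-stage
partitions the de-regulated universe — tested as disjoint and covering.

Classification precedence is DaP > PiG > miRNA > DaCG, keeping the
categories disjoint. Curated interaction links are treated as
symmetric. Genes missing from the annotation are logged and bucketed as
coding differentiation-associated (conservative default).

## Enrichment

Ranking is signal-to-noise `(μ₁−μ₂)/(σ₁′+σ₂′)` with each standard
deviation floored at `0.2·|μ|` (plus a 1e−12 absolute floor), ties
broken lexicographically on gene id for cross-run stability. The
enrichment score is the weighted (p = 1) Kolmogorov–Smirnov running
sum; a set equal to the whole universe has no misses and scores 0 by
convention; when the running sum's positive and negative extrema tie in
magnitude the first index wins. The leading edge is the members at or
before the positive peak (at or after the negative one).

Significance uses gene-set permutation by default (random same-size
sets, nulls cached per set size), with phenotype permutation available
for whole-matrix cohorts. NES divides ES by the mean same-sign null
|ES|; the empirical p is same-sign; FDR q follows the same-sign
pooled-null procedure with *both* the null and observed fractions
conditioned on the sign of NES — the conditioning is what makes
q ≥ p hold structurally when all sets share one null. Retention is
inclusive (q ≤ 0.25, |ES| ≥ 0.50, |NES| ≥ 1.5) followed by a top-30 cut
on |NES|; the filter-then-top-k order is the default and the reverse
order is a flag, since the tool chain being emulated is ambiguous on
this point.

## The three metrics

Degree of differentiation and degree of pleiotropy are the same
functional: the mean over modules of `G/P` (G = distinct genes in ≥ 2
retained terms, P = terms containing at least one such gene), computed
at full precision; modules with no retained terms drop out of the
denominator count. Published tables in this field mix truncation and
rounding at the third decimal, so comparisons against printed values
should allow ±0.001 — the package itself never truncates. The SD/SL
ratio returns 0 when no SD signature is retained and +inf when SD
signatures exist without SL ones; tissue-class labels are input
metadata on gene sets, never inferred from set names.

## Gene regulatory networks

Within one stage, expression is binarized at the per-gene median
(strictly above → 1), so a constant gene becomes all-zero and is
removed (with a warning) before structure search. The structure learner
is greedy hill climbing over add/delete/reverse moves maximizing the
decomposable BIC for binary variables (log-likelihood from contingency
counts minus `(ln N / 2) · 2^|parents|` per node), with acyclicity
enforced and exact ties resolved lexicographically. Plain greedy search
can stall one repair-move short of the optimum (a wrong early edge
makes the true chain unreachable by single moves even though it scores
higher), so the default runs 6 seeded climbs — one from the empty graph,
five from random DAGs — and keeps the best-scoring local optimum; this
lifts planted 5-node chain skeleton recovery from ~80% to ~95% at
n = 500. An optional block-splitting mode (learn per overlapping
variable block, union edges, skip cycle-closing edges deterministically)
is exposed behind `split_blocks` and off by default, as the splitting
strategy it emulates is under-documented.

Edges are then filtered on z-scored normalized expression: drop when
neither Pearson nor Spearman reaches p ≤ 0.05; confidence thin (one
significant), medium (both, either |coefficient| < 0.89), thick (both
significant, both ≥ 0.89); evidence `curated` when the pair appears in
the curated link table in either orientation. Parallel edge types are
modelled as one edge with an evidence attribute because parallel edges
would corrupt density. Topology: density `m/(n(n−1))` on the directed
simple graph after self-loop removal; degree centrality on the directed
graph (in+out); betweenness, closeness, eigenvector and subgraph
centralities on the undirected projection (the convention of the common
desktop network analyzers). Pseudogene knock-out removes pseudogene
nodes and incident edges before recomputation.

## Stratification

Per sample, the medians of the binarized up-DaP and down-DaP states use
the standard midpoint convention, so an even down-DaP count split 50/50
gives 0.5 and fails the strict `= 0` test — a documented edge case.
Binarization medians are computed over tumour samples only, matching
the within-stage discretization used for the networks (configurable
upstream by passing a different sample subset).

## Mutation analytics

Purine-reference SNVs are reverse-complemented onto the pyrimidine
strand (context included) before any classification; the map is
idempotent and tested as such. APOBEC motif fractions (tCw, cCw with
w ∈ {A, T}, split by C>T / C>G) are reported relative to all of a
sample's SNVs. Kataegis uses the rainfall-tool convention — maximal
non-overlapping runs of ≥ 6 substitutions whose mean inter-mutation
distance is ≤ 1 kb — with both thresholds exposed as flags; the scan
re-extends past temporary violations because a run's mean spacing can
recover. MATH is `100 · 1.4826 · MAD / median` of the VAFs (the scaled
MAD makes the score comparable to a coefficient of variation under
normality); it is scale- and order-invariant by construction.

Signatures: Frobenius multiplicative-update NMF per rank with seeded
restarts (default 20); consensus over restarts clusters samples by
dominant exposure, and the cophenetic correlation of the consensus
matrix is the stability curve. The selected rank is the last one before
the curve first materially falls (drop > 1e−3): stability is ~1 up to
the true rank and degrades beyond it, and this "begins to fall"
criterion is robust to the slow tail decay that defeats a
largest-single-drop rule. A constant consensus matrix (rank 1, or
perfect stability) scores cophenetic 1.0 by convention. Matching
against a user-supplied catalogue is by best cosine per extracted
signature; no catalogue is bundled.

## Motif sequence preparation

TSS windows are 2000 bp either side of the TSS (4001 bp); a TSS at the
sequence start or end gets the one-sided 4000 bp extension instead, and
sequences too short for the full window are clamped into bounds so the
TSS is always covered. Sliding windows are 462 bp at step 410 (52 bp
overlap); the final window is end-anchored so no suffix is lost, at the
price of a larger overlap with its predecessor — full coverage is the
point, since motifs near truncation boundaries must stay discoverable.
The 462 bp default reflects the smallest pseudogene sequence in the
motivating analysis and is a flag.

## Synthetic data: what it emulates, and what it does not

Counts are gamma-Poisson (negative binomial, Var = μ + αμ², default
α = 0.15) around log-normal per-gene baselines (median ≈ 100 counts),
the standard bulk RNA-seq model; planted effects multiply group means
by 2^effect so effect sizes align with the log2FC threshold. Dependence
for the network tests is planted via latent binary activity states
sampled ancestrally over a DAG (root fair coin; child active with
probability 0.9 given an active parent majority, 0.1 otherwise) with an
8-fold expression multiplier, which survives median binarization.
VAFs are Beta(2, 8) (median ≈ 0.2, typical of impure tumours) converted
to read counts at depth 100. MAF backgrounds are uniform over a seeded
uniform-base toy genome; APOBEC context quotas are met by placing the
quota at reference-strand motif sites. The bundled pipeline scenario
uses 240 genes, 10 samples per group, 2 × 500 kb reference contigs and
40 background mutations per sample — sizes chosen so the whole chain
runs in seconds while background runs stay too sparse to mimic the
planted kataegis cluster.

Not emulated: realistic library-size variation, gene-length effects,
germline variation, copy number, strand-asymmetric mutational
processes, linkage between expression and mutation beyond the planted
designs. Passing recovery tests therefore demonstrates algorithmic
correctness on the stated generative model, not performance on cohort
data.

## Determinism and numerical conventions

Every stochastic component takes a seed and draws from its own
`numpy.random.default_rng` stream in fixed iteration order; identical
seeds give byte-identical outputs. Tie-breaks are lexicographic
throughout (ranking, hill-climbing candidate scan, edge iteration).
Degenerate inputs have defined behaviour: all-zero count matrices and
empty gene lists raise; constant genes binarize to zero and are dropped
from structure learning with a warning; contig-edge MAF records are
dropped with a warning; empty strata warn.

## Problem sizes used by the test suite

Recovery tests run at desk scale: DE recovery at n = 20/group over
40–50 genes (60 Monte-Carlo seeds), FDR control at 100 permuted-label
replicates, chain recovery at 50 seeds × 500 samples, kataegis recall
at 100 single-cluster simulations, signature recovery at 20 seeds × 30
samples × ~500 mutations each, window tiling at 500 random lengths.
The full suite completes in well under a minute of CPU apart from the
NMF block (~15 s).
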