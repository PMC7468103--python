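# Methods

## Data model

All expression data live in a dense transcripts × samples TPM matrix
with a total transcript → gene mapping and a partial transcript →
protein-isoform mapping. Missing or NA cells are coerced to 0 TPM at
load; duplicate ids, negative or non-numeric values are hard errors.
Interaction edge lists accept either real scores in [0, 1] or
STRING-style integers in 0–999; any score above 1 switches the whole
file to the integer dialect, which is divided by 1000. Edges are stored
once, lexicographically ordered, keeping the maximum score over
duplicate orientations; self-loops are dropped with a warning. Region
files follow the BED convention (0-based half-open), variant positions
are 1-based; the conversion happens exactly once at load. Adjacent
same-sample single-nucleotide variants are merged into one
multi-nucleotide variant as maximal runs of consecutive positions;
indels never merge. A variant overlapping several functional regions
produces one record per region — the simplest rule that loses no
information; downstream group assignment de-duplicates anyway.

## Isoform-specific interaction network

Only proteins whose sequence is byte-identical between the network's
FASTA and the annotation FASTA are used; domain coordinates are only
trustworthy on identical sequences. An edge is physical when at least
one pair of domain instances (one per endpoint) belongs to a physically
interacting domain-family pair, in either orientation; homotypic
families pair every instance on one side with every instance on the
other. For each alternative isoform and each physical edge of its
gene's canonical protein, the canonical sequence of every supporting
domain instance on the isoform's side is tested for exact substring
presence in the isoform sequence. The interaction persists when **any**
instance matches — an edge usually survives if one of its binding
surfaces survives — and the matched instances are recorded for audit.
Matching is exact: no alignment, no tolerance. Only the isoform's own
side is assessed; the partner is assumed canonical, so per-isoform
status is independent of partner expression, and joint effects are a
per-sample question handled downstream.

## Dominance calling

Per gene and sample the top transcript is the MDT when top ≥ 2× the
runner-up and top clears the role's noise floor: 2.0 TPM in tumors
(an empirical ceiling for background expression of tissue-restricted
genes) and 0.2 TPM in normals (relaxed so that low-expressed normal
dominance remains visible). A tied top pair never yields an MDT — the
fold rule cannot hold at a tie.

Relative expression of a transcript is its TPM divided by the summed
TPM of its gene's transcripts in the same sample — the only definition
bounded in [0, 1] that supports comparing a tumor value with a
per-transcript normal median; it is undefined for silent genes and such
samples are excluded from cohort statistics.

The sign test compares one tumor value against every matched normal
sample, counting strictly higher and strictly lower comparisons; exact
ties are excluded from both counts (standard sign-test practice). The
counts enter an exact two-sided binomial test at p = 0.5. The two-sided
p-value is the minimum-likelihood construction (the sum of outcome
probabilities no larger than the observed one), matching standard exact
binomial tests; a twice-the-smaller-tail variant is available behind a
flag. Zero informative comparisons give p = 1.

p-values for **all** tumor MDTs of one cancer type form one
Benjamini–Hochberg family; the four cMDT criteria are then applied:
transcript never an MDT in the normal compendium (a matched-cohort-only
scope is available — the appropriate scope depends on how broad the
normal compendium is, so both are exposed), gene with an MDT of any
identity in ≥ 50 % of matched normals, q below threshold (default
0.01), and relative expression above the transcript's median over all
matched normal samples with defined values (not only those where the
gene had an MDT; the broader denominator is the more conservative
reference).

## Impact scoring

**Network density score.** NDS(a) = int(a) + Σ_{s=1..3} Σ_b 2⁻ˢ ·
int(b) · score(b, parent(b)), where int(·) is the interactor count.
The neighbourhood sum is interpreted as a visit-once breadth-first
traversal: every node contributes once, at its shortest depth, weighted
by the score of the edge to its BFS parent; among equal-depth parents
the lexicographically smallest id wins. This is the only reading of the
neighbourhood sum that is finite, deterministic, and consistent with a
node "being s interaction nodes apart". Scores enter on the [0, 1]
scale. Ranking is ascending with relative position i/(N−1) and ties
sharing the mean position. The graph used for NDS and for census
proximity is the full high-confidence functional network (score ≥ 0.9),
not only its physical subset.

**Census proximity** is a multi-source BFS from all census proteins;
unreachable queries carry a −1 sentinel and are excluded from rank-sum
comparisons. The random control draws uniformly, with replacement,
among proteins expressed at ≥ 2 TPM in at least one cohort sample whose
gene has ≥ 2 annotated isoforms — the same eligibility the switches
themselves had.

**Enrichment.** The disrupted edges of one sample form a graph whose
connected components are the tested subnetworks — the minimal structure
in which disruptions share one or both partners. Per component and
gene-set term: upper-tail hypergeometric p with the isoform-network
proteins as the universe, BH across terms within the component, and
only the most significant term kept (ties resolved to the smallest term
id). Gene sets are supplied as GMT files so results stay version-pinned.

## Mutation association

A sample is *Mutated* for a transcript when its gene carries ≥ 1
variant in any of the six cis functional classes (promoter core,
promoter domain, 5′UTR, CDS, splice site, 3′UTR) in that sample. At
least 5 mutated samples are required; transcripts need ≥ 1 non-zero
value in each group and non-constant pooled expression (the statistic
is undefined otherwise). The two-sided rank-sum test enumerates the
exact permutation distribution (valid under ties) when both groups have
≤ 8 observations and otherwise uses the tie-corrected normal
approximation with continuity correction; BH correction is per cancer
type with significance at q ≤ 0.01. Switch load versus variant load
uses Spearman correlation with average ranks; constant inputs return
NaN.

## Synthetic worlds

The generator emulates the statistical structure the detector assumes:
canonical proteins are random amino-acid sequences with 1–3 embedded
domain instances of globally unique sequence (8–15 residues;
regenerated in the vanishingly rare collision), so substring tests
cannot match by accident. Alternative isoforms are the canonical
sequence with whole domain instances deleted — interaction persistence
is therefore known exactly at generation time. Edges form an
Erdős–Rényi-style graph over canonical proteins (density 0.15, scores
uniform in [0.9, 0.999]); 80 % receive a supporting domain-family pair,
the rest stay non-physical.

Expression: per gene and sample, a lognormal total (median 50 TPM,
log-sd 0.5) is split over isoforms by planted proportions —
canonical 0.75 in unswitched genes; in switch genes the alternative
transcript carries 0.5 + gap/2 in tumors and 0.5 − gap/2 in normals
(gap default 0.6) — perturbed by multiplicative lognormal noise
(sd 0.25) and renormalized per sample, preserving TPM semantics.
Configurations whose gap cannot satisfy the 2× rule on both sides for
two-transcript genes (gap < 1/3) or whose noise routinely crosses the
gap (noise_sd > gap/2) are rejected before emission. Planted cis
associations multiply a gene's expression 10-fold in ⌈n_tumor/2⌉ ≥ 5
tumor samples carrying a CDS variant; proportions are untouched, so
dominance calls are unaffected. All draws flow from a single seed;
identical configurations emit byte-identical files.

The default study uses 50 genes, 10 tumor vs 20 normal samples, switch
fraction 0.2. Null calibrations use 200 replicates of 12-gene,
4-vs-12-sample worlds (dominance FDR) and 1,000 replicates of 10
transcripts over 24 samples (rank-sum FDR) — sizes chosen to give the
binomial error bounds quoted in the tests while each replicate remains
a complete, independent dataset.

What the toy worlds do **not** emulate: correlated isoform usage across
genes, realistic splicing graphs (isoforms differ only by whole-domain
deletions), read-level quantification error and length biases,
tissue-specific expression programmes, scale-free topology of real
interaction networks, and mutational signatures. Passing tests
therefore demonstrate correctness of the decision rules and statistics
under their stated assumptions, not robustness to the quantification
noise or network biases of real cohorts.

## Numerical choices and degenerate inputs

Exact binomial and hypergeometric tails come from scipy; BH from
statsmodels. TPM values are rounded to 6 decimals at generation so that
files round-trip bit-for-bit. Empty normal cohorts, empty census sets,
zero control draws, unknown samples and non-physical edges passed to
the persistence assessor are errors; genes without a retained canonical
protein, enrichment components without annotated proteins, and
transcripts filtered from association testing are skipped and counted.

## Known limitations

Persistence is a sequence-presence proxy: a domain can be present yet
misfolded, or an interaction can survive a lost domain through another
interface. Only the switching side of an edge is assessed. The NDS
neighbourhood sum is one defensible reading of an ambiguous definition;
alternatives (per-path accumulation) would weight hubs differently. The
density-score and proximity graphs inherit study bias in interaction
databases: well-studied disease genes are denser. Enrichment treats
components independently although they share a sample.
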