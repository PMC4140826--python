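# Methods

## Scope and data model

The package analyses three kinds of records: strand-aware genomic intervals
with exon chains (genes and lncRNAs; 0-based half-open coordinates
internally, BED externally), biallelic SNVs with per-disease association
p-values (1-based in tables, converted on read), and evidence tables
(regulatory scores, cis-eQTLs, iHS, genotype dosages, RepeatMasker `.out`
annotations, FPKM matrices). Unstranded records may participate only in
strand-agnostic operations; strand-aware classification rejects them
explicitly.

## Locus classification

A lncRNA and a gene are compared at the gene-span level. Same-strand overlap
of ≥ 1 nt is *sense intersecting*; a lncRNA span fully contained in the gene
span on the same strand is additionally *sense 100% overlapping* (a subset of
intersecting — the nesting is asserted on every run). Opposite-strand overlap
of ≥ 1 nt is *antisense intersecting*. Non-overlapping pairs whose span gap
is ≤ the flank (default 5 kb, inclusive at the boundary, matching
bedtools-window semantics) are *flanking*, split by strand match; the signed
distance is oriented by the gene strand (negative upstream of the gene
start). The per-lncRNA category against a whole gene set resolves multiple
relations by the fixed precedence sense exonic > sense non-exonic >
antisense > intergenic > unassociated, where "exonic" means the lncRNA span
overlaps at least one annotated exon. Candidate pairs are pruned with a
per-chromosome interval tree padded by flank + 1; the classification of each
surviving pair is identical to the brute-force all-pairs scan (tested).

Whether the antisense regime should additionally require the 5 kb window was
genuinely open; it is treated as overlap-only, with flanking relations
reported separately.

## Variant mapping

Variants are filtered per disease at strict p < alpha (default 0.01, the
conventional nominal cut-off) — strictness is asserted at the boundary — and
mapped to every lncRNA whose span contains the position. Intronic hits are
retained and flagged rather than dropped, so downstream stages can report
them as unscoreable. Exonic hits carry a spliced-transcript offset; for
minus-strand genes offsets count from the 3' genomic end so they index the
transcript in sense orientation.

## Folding engine

Base-pair probabilities come from an exact inside–outside partition function
over a deliberately simple ensemble: every admissible pair (AU, UA, GC, CG,
and the GU/UG wobbles unless `wobble=False`) contributes the same Boltzmann
weight `w = exp(2 / RT)` (−2 kcal/mol per pair at 37 °C, a compromise between
strong GC and weak AU stacks); hairpin loops enclose ≥ 3 unpaired bases;
**lone pairs are forbidden** — every helix stacks ≥ 2 pairs, the `--noLP`
simplification of thermodynamic folders. The no-lone-pair rule matters: in a
model where an isolated pair is a full-value structure, a substitution that
*creates* one new pairing partner perturbs the ensemble as strongly as one
that *breaks* a planted 10-bp stem, and structure-disruption calls carry no
signal. Requiring two stacked pairs restores the helix cooperativity that
makes disruption detectable; it is the one deliberate departure from the
barest uniform-pair model.

The inside recursion uses an unambiguous four-quantity decomposition
(general span / helix-outer pair / helix continuation / helix-terminating
interior); the outside pass inverts it, and pair probabilities are emitted at
the two pair-producing rules. Numbers are rescaled per position
(Vienna-style) with a retry ladder of scale factors so partition functions
stay in double range up to the 2,000-nt input cap; sequences with no
admissible pair short-circuit to the zero matrix. The engine is
deterministic, JIT-compiled with numba, and equal to Boltzmann-weighted
exhaustive structure enumeration to < 1e-12 for sequences up to length 25
(the enumeration oracle generates all nested pair sets and filters lone
pairs independently of the DP).

Two caveats documented rather than hidden: (1) with wobble pairs enabled,
the matrix of a sequence and that of its reverse complement are *not* exact
mirrors (a GU pair reverse-complements to the non-pairing AC); the mirror
symmetry holds exactly in wobble-free mode and on AU-only/GC-only sequences.
(2) A full thermodynamic engine can be substituted behind
`base_pair_probabilities` without changing any downstream contract; absolute
d values would change, the empirical p-values recalibrate automatically.

## Disruption score and empirical p-value

The fold window is ±200 nt of spliced transcript around the variant, clipped
(never discarded) at transcript ends; minus-strand genomic alleles are
complemented before substitution. The local-region search maximizes the
length-normalized Euclidean distance between upper-triangle pair
probabilities over all regions of ≥ 50 nt containing the variant, computed
with 2-D prefix sums; ties break to the smallest region start, then end
(for d ≡ 0 this yields the lexicographically first admissible region, which
is also the shortest one containing the variant whenever the variant offset
is below the minimum region length). The region floor of 50 and the
normalization are explicit configuration: the underlying screen defines
"local region of maximal change" but not its search space, so these choices
make the maximization well-defined.

The empirical p-value resamples the null directly — `n_background` random
substitutions in the same window, each scored with the identical region
search — with add-one smoothing, `p = (1 + #{d_bg ≥ d_obs}) / (n + 1)`, so
p ∈ [1/(n+1), 1] and a zero-distance observation gets p = 1. Calibration is
verified by a KS test: when the "observed" variant is itself a null draw, the
p-values are uniform. The calibration utility precomputes the disruption
distance of *every* possible substitution in the window once and samples
replicates from that table; since the background draw is iid uniform over
(position, alternative) and the engine is deterministic, this is exactly the
distribution of per-replicate recomputation at a small fraction of the cost.
A variant is called structure-disruptive at p ≤ 0.2 (inclusive).

## Evidence ranking

Annotation never changes the variant set: missing regulatory scores become
"unknown", missing iHS leaves the selection flag false, and eQTL rows are
pruned to the inclusive ±1 Mb TSS window. Selection uses |iHS| ≥ 2.5
(inclusive). LD is the squared Pearson correlation of genotype dosages
(composite LD) — a documented divergence from haplotype-based r², since
phase is not modelled; it is symmetric and invariant to allele recoding.
Ranking is lexicographic in the order the evidence types are prioritized:
regulatory score ascending (unknown last, vocabulary configurable so score
revisions never touch code), any cis-eQTL before none, under selection
before not, disruption p ascending, then (chrom, pos, id) so the order is
total and reproducible. Whether the original ranking weighted or nested the
keys is not stated anywhere authoritative; hierarchical sorting in the
listed order is the reproducible reading.

## Composition and expression statistics

GC content excludes ambiguity codes from numerator and denominator and is
reported per gene (unweighted). Welch's t statistic, the Welch–Satterthwaite
df, the χ² goodness-of-fit statistic against background proportions, and
tie-aware Spearman correlation are implemented from their formulas (scipy
provides only the t/χ² distribution tails); each is tested against the scipy
reference to 1e-9, keeping implementation and oracle distinct.
"Standardized residuals" are computed as adjusted residuals
`(O_i − E_i)/sqrt(E_i (1 − p_i))` — the formula behind the usual |z| > 1.96
flag — with plain Pearson residuals behind a flag, since the residual
convention is not otherwise pinned down. Repeat–lncRNA overlap is
strand-agnostic (genomic repeats are annotated irrespective of transcript
strand); class percentages are over total repeat hits. Expression uses the
strict FPKM > 1 across-all-tissues filter; correlations are computed on
ranks, which the reporting log10 transform cannot change.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of its configuration (single seed fanned
out to stages by stable blake2b hashing, so adding a stage never perturbs
another's draws). Ground truth is built by construction:

* **Locus architecture** — genes (3 exons of 200–400 bp, 12–16 kb introns)
  spaced 60 kb apart across four chromosomes, far enough that each lncRNA
  relates only to the gene it is placed against; lncRNAs (220–350 nt
  transcripts, 90% spliced into two exons over multi-kb spans) are placed to
  satisfy their assigned category exactly, with a third of sense-exonic
  lncRNAs straddling the gene start so full overlaps nest strictly inside
  intersections.
* **Variants** — 2,000 by default, ~8% inside lncRNA spans (the
  within-lncRNA fraction observed in genome-wide variant sets), half
  nominally significant (log-uniform below 0.01); five planted
  stem-breaking variants sit mid-stem in 10-bp GC hairpins embedded in
  poly-A (pairing-free) transcripts on distinct host genes. The pairing-free
  background is essential: in a uniformly random transcript the ensemble
  fluctuation of any substitution matches a single broken stem pair and no
  planted truth would exist — which is itself the fixture's honest statement
  about the method: disruption calls are informative for variants in locally
  well-defined structures, not in unstructured sequence.
* **Evidence** — regulatory scores for ~60% of variants, iHS for ~50% with a
  configurable extreme fraction, cis-eQTLs placed within 2 Mb so the 1 Mb
  window pruning is exercised; dosage pairs from haplotype frequencies set
  by `D = r·sqrt(p(1−p)q(1−q))` under HWE.
* **Expression** — log-normal FPKM over 14 tissues; planted lncRNA/host
  pairs share a latent effect with loading `2·sin(π·ρ_s/6)` (the
  Spearman-to-Pearson conversion for bivariate normals) so the expected rank
  correlation equals the target; 60% of unplanted lncRNAs are centred low to
  leave a realistic not-detected fraction.

The fixtures do **not** emulate: real genome base composition or repeat
sequences, LD structure beyond single pairs, isoform diversity,
population-level iHS computation, or expression covariance beyond one latent
factor. Passing tests therefore demonstrate correctness of the algorithms and
calibration of the statistics under known truth, not biological discovery on
real data.

## Problem sizes and numerical choices

Default study size is 200 genes / 500 lncRNAs / 2,000 variants with 200
background substitutions per scored variant — sizes chosen so a full
end-to-end run takes a few minutes on one CPU while every stage still
processes hundreds of records. Engine tolerance against enumeration is 1e-9;
matrix symmetry and row-sum invariants are checked at 1e-9/1e-12; the χ²
type-I error band [0.03, 0.07] corresponds to ±2 binomial standard errors
around 0.05 at 500 replicates. Degenerate inputs are errors, not silent
results: empty sequences, constant vectors (LD, Spearman), single-class χ²,
zero-variance Welch samples, reference-allele mismatches.

## Known limitations

* The uniform pair energy ignores stack identity, loop-length entropy and
  dangles; absolute d values are not comparable to thermodynamic tools.
* Composite (dosage) LD understates haplotype r² under departures from HWE.
* Gene-level (span) classification ignores isoform structure; a lncRNA
  overlapping only a skipped exon of one isoform counts as exonic.
* Empirical p-values are granular at 1/(n_background + 1); with the default
  pipeline n_background = 200 the smallest attainable p is ~0.005.
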