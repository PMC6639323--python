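# Methods

This note documents the models and procedures implemented in `soma`, the
parameters that matter, the numerical choices, what the synthetic-cohort
generator does and does not emulate, and the design decisions taken where the
methodology left genuine freedom.

## Substitution catalogs and strand conventions

SNVs are tabulated on the pyrimidine strand: a mutation with a purine reference
base is complemented and its trinucleotide context reverse-complemented before
binning, giving the conventional 96-channel layout (substitution blocks C>A,
C>G, C>T, T>A, T>C, T>G; within each block the 16 flanking contexts in
alphabetical order, labels `A[C>A]A` … `T[T>G]T`). Context comes from an indexed
FASTA or, for simulated data, from a sidecar table the generator writes — the
"uniform-context" mode — so no reference genome is ever required. Catalog rows
conserve counts: the row sum equals the number of SNVs with valid context, and a
reference-base mismatch is an error rather than a silent skip.

Dinucleotide substitutions are tallied separately (member SNVs stay in the
single-base catalog): two same-sample SNVs at adjacent positions form one event,
canonicalized by reverse complement only when the reference pair contains no
pyrimidine (so GG>AA reports as CC>TT, while mixed pairs such as CT>AC keep
their printed orientation).

Transcriptional strand bias uses transcript footprints with strand: a mutation
whose pyrimidine base lies on the coding strand is "untranscribed", on the
template strand "transcribed"; mutations outside footprints are excluded and
counted. Overlap ties resolve by first-in-file precedence. The per-class
two-sided test is the conditional Poisson (exact binomial with p = ½) comparison
of the two strand counts.

## Signature extraction (NMF) and stability

The extraction wrapper follows the bootstrap-and-cluster approach standard for
mutational-signature discovery. For each rank k the catalog is resampled
`n_bootstrap` times (each sample's mutations redrawn multinomially), each
resample factorized by multiplicative-update NMF under KL divergence (best of
`n_restarts` random initializations; the core factorization is
scikit-learn's `NMF(solver="mu", beta_loss="kullback-leibler")`, max 1000
iterations, tolerance 1e-6). The pooled per-resample profiles are clustered into
k groups (k-means on L2-normalized profiles; cosine silhouette as the stability
score), and each cluster's normalized centroid is the consensus signature. The
reconstruction error reported is the relative Frobenius error of refitting the
original catalog on the consensus signatures.

Rank selection is deliberately *reported, not chosen*: the stability/error
profile across k is returned and the caller picks k. Defaults
(`n_restarts=20`, `n_bootstrap=50`) are desk-scale; the acceptance benchmarks
use 3 restarts × 10 bootstraps, which already recovers well-separated planted
signatures (pairwise cosine < 0.4) with cosine ≥ 0.99 at 30 samples × 2 000
mutations.

## Exposure refitting and the <10 % rule

Exposures solve a simplex-constrained least-squares problem on the L1-normalized
catalog row. Numerically this is a non-negative least squares warm start
followed by an SLSQP polish with analytic gradient (`ftol` 1e-16); on
well-conditioned systems the solution is accurate to ~1e-9, and the test suite
checks it against an exhaustive active-set enumeration oracle.

The over-fitting guard removes signatures contributing less than `min_prop`
(default 0.10) of a sample and refits on the remainder. The published
description does not say whether this is applied once or repeatedly; it is
iterated to a fixed point here, which is the only variant that guarantees the
stated post-condition (every retained exposure ≥ 10 %). If a round would remove
every signature, the single signature with the lowest refit residual is kept.
Dropped signatures are reported with their pre-drop exposures.

## Kataegis

Inter-mutation distances are computed per sample per chromosome (positions
deduplicated; the first mutation of a chromosome has no IMD). Whether
segmentation should run per chromosome or on a genome-wide concatenation is not
specified by the source methodology; per chromosome is implemented, consistent
with ordering "by chromosome and position".

Segmentation is exact penalized least squares on log₁₀(IMD): minimize the sum of
within-segment squared deviations plus γ per segment, each segment ≥ `kmin`
points, solved by an O(n²) dynamic program (vectorized over split points; ties
broken toward the earliest split, so results are deterministic). γ = 25 and
`kmin` = 2 follow the segmentation convention of the breast-cancer rainfall
methodology this reimplements; both are exposed as parameters. A segment of m
IMDs covers m + 1 mutations (the chromosome's first mutation belongs to the
first segment), making "six or more consecutive mutations" exact; a segment is
called when it covers ≥ 6 mutations with mean raw IMD ≤ 1000 bp, and adjacent
called segments merge into one locus whose mean IMD is recomputed as
(end − start)/(n − 1). The per-chromosome locus count is the number of merged
called segments.

A consequence of the penalty worth knowing: two hypermutation loci separated by
only a handful of background mutations are merged into a single segment whose
mean IMD reflects the background gaps, and are therefore *not* called. This is
the correct behaviour of the segmentation (isolating each locus would pay 2γ for
a small residual gain), but it means sensitivity benchmarks must plant loci far
enough apart to be independent targets. The cohort helper therefore separates
planted loci by 20 background inter-mutation spacings (20 Mb at the benchmark's
1 SNV/Mb background) on 150 Mb chromosomes; the planting rule itself only
requires 10 × `max_imd` from existing mutations.

## Rearrangement classification and clustering statistics

Size bins are half-open `[low, high)`; a duplication of exactly 10 kb falls in
the 10–100 kb bin. Spans below 1 kb (caller artifacts; the published bins start
at 1 kb) fold into the lowest bin with a logged warning. Translocations carry no
size bin, giving 2 × (3 × 5 + 1) = 32 categories.

The clustered-breakpoint rule is operationalized literally: a breakpoint is
clustered iff *some* 1 Mb genomic window containing it holds ≥ 10 of that
sample's breakpoints (pooled per sample per chromosome), computed by a
two-pointer sweep over sorted positions and verified against a quadratic
anchored-window oracle. An SV is clustered when either end is (the OR convention
makes a translocation joining two clusters clustered). Whether the original
study pooled windows per chromosome or genome-wide is unknowable from the text;
per sample per chromosome is implemented.

The "non-random distribution" chromosome test is a one-sample Kolmogorov–Smirnov
test of breakpoint positions against Uniform(0, chromosome length), exact
p-values via the Kolmogorov distribution, flagged at the stringent P < 10⁻⁵; the
cited prior work names no specific statistic, so KS is a declared substitute,
and chromosomes with fewer than 5 breakpoints report p = 1 to avoid vacuous
significance. Under uniform simulation the flag rate at 10⁻⁵ is ≤ 3 × 10⁻⁵
(checked on 100 000 simulated chromosomes). Outlier chromosomes exceed
Q75 + 1.5·IQR of the sample's per-chromosome breakpoints/Mb rates (quantiles by
linear interpolation, type 7 — documented because the IQR rule is sensitive to
the convention; rates over all chromosomes of the genome index, zero included)
with a hard floor of 35 breakpoints. High-translocation chromosomes carry ≥ 10
translocation breakpoints, a translocation counting once for each of its two
chromosomes.

Consensus clustering mean-centers the per-sample signature proportions, then
repeatedly (default 1000, benchmarks 200) subsamples ⌈0.9·n⌉ samples and
⌈0.9·p⌉ features, clusters by average linkage on 1 − Pearson correlation, and
accumulates co-assignment frequencies; the final partition cuts an
average-linkage tree of 1 − consensus at k. The reported `chosen_k` is the
largest k whose minimum per-cluster mean consensus is ≥ 0.8 — note that tight
groups keep sub-splitting with consensus ≈ 1, so for group counts the full
report (consensus matrices and per-cluster means across k) should be inspected
rather than trusting `chosen_k` blindly; the published analysis likewise reports
the clustering without an explicit selection rule. Identical samples are a
documented degenerate case (all-ones consensus, warning).

## Telomere length

A read counts as telomeric when it contains ≥ 5 *tandem* copies of the repeat on
either strand; the tool being reimplemented does not document its copy rule, so
the threshold is exposed (`min_tandem_copies`). The canonical human repeat
TTAGGG is the default; the source text prints "TTAAGG", presumed typographical,
and that motif remains selectable for strict replication. Relative telomere
length is log₂((tumor reads / tumor coverage)/(normal reads / normal coverage)),
undefined (an error) when any term is zero; mean genomic coverage is an input
scalar, not computed here (BAM traversal is out of scope — a precomputed count
table keeps real-data use possible). Group tests are two-sided Mann–Whitney U,
exact for combined n ≤ 20 without ties, otherwise the tie-corrected normal
approximation, with direction reported from the median difference.

## Filtering, genotyping, QC

The tiered exclusion clauses are implemented with the printed strict/non-strict
operators verbatim, even where they overlap oddly (e.g. VAF > 0.15 with < 5
supporting reads can exclude records the VAF < 0.05 clause never reaches);
fidelity is preferred over rationalizing the rule set. VAF is recomputed from
alt/depth whenever counts are present, removing caller-specific rounding. A
record is excluded iff any clause fires; all firing reasons are listed in rule
order, and verdicts are order-independent across records. The population filter
excludes AF strictly > 0.01 (missing AF = 0); the panel-of-normals filter
excludes positions with ≥ 3 alt reads in ≥ 2 unrelated normals (positions absent
from the pileup count as zero). Whether "depth" in the VAF<0.20/depth<20 clause
means total or alt-supporting depth is unstated; total tumor depth is used.

Genotypes from VAF use the printed thresholds with inclusive boundaries exactly
as printed (VAF = 0.2 → 0/0; VAF = 0.8 → 1/1), missing below 10× coverage.
Variant QC drops missingness > 0.1 or MAF < 0.05 (MAF over non-missing calls).
LD pruning is the common greedy idiom — left-to-right in position order,
removing the later variant of any pair with dosage r² > 0.2 within 50 kb
(windows by base-pair distance, not variant count); zero-variance variants are
removed first; the post-condition (no retained linked pair within the window) is
itself asserted in the test suite. Known high-LD regions can be excluded via a
user-supplied BED; no region list is bundled. PCA mean-imputes missing dosages
per variant, standardizes columns, decomposes by SVD, orders components by
eigenvalue, and fixes each component's sign by making its largest-magnitude
loading positive (repeated runs byte-identical). Projection mode fits axes on
reference genotypes and transforms study samples; the merged mode is simply
passing the concatenated matrix.

Copy-number inputs are per-gene tables (gene, total CN, minor CN); categories
are CN 0 = deletion, CN 1 = loss, CN ≥ 6 = amplification, CN ≥ 2 with minor
allele 0 = copy-neutral LOH, else neutral/gain. Segmented copy-number calling is
out of scope.

## The synthetic-cohort generator

The generator defines the study conditions for all benchmarks:

- **SNVs** are drawn i.i.d. from the sample's signature mixture Σₖ eₖ·Sₖ over
  the 96 channels, positions uniform over the genome without replacement, and
  are written on the purine strand with probability ½ so the catalog builder's
  canonicalization is always exercised. Empirical channel frequencies satisfy a
  χ² goodness-of-fit against the mixture (α = 0.01, n = 10 000, ≤ 1 rejection in
  20 seeds).
- **Kataegis loci** are runs of C>T/C>G mutations at TpC context with spacings
  uniform on [1, max_imd] (default 300 bp), placed ≥ 10·max_imd from existing
  mutations and ≥ `min_locus_separation` from each other (see above).
- **SVs** are generated from requested per-category counts. All clustered events
  of a sample share one uniformly placed 1 Mb window (small events contribute
  both ends, large events and translocations one end — a request summing to
  fewer than 10 in-window breakpoints is a generation error, since the window
  rule could not fire); every non-clustered breakpoint is separated from every
  other event's breakpoints by more than the window. Generated labels therefore
  equal the classifier's output by construction, which the tests verify in full.
- **Telomere counts** follow tumor = normal·(covT/covN)·2^log2ratio, optionally
  Poisson-noised on both sides.
- **The filter toyset** contains one record per exclusion clause (constructed so
  exactly the intended clauses fire), one multi-clause record, boundary and
  missing-AF population cases, panel-of-normals hit and near-miss, and
  passing records.
- **Genotype cohorts** are Balding–Nichols two-population draws (ancestral
  frequencies uniform on [0.1, 0.9], divergence parameter Fst, genotypes
  Binomial(2, p)).

What the generator does *not* emulate — and hence what passing benchmarks do not
show about real data: sequencing error and mapping artifacts, mutation-rate
variation along the genome (replication timing, chromatin), signature profiles
estimated with COSMIC-level fidelity (the bundled catalog is a stylized
synthetic stand-in), SV breakpoint microhomology and complex multi-breakpoint
events, LD structure within populations (variants are independent given
population frequencies), and indels throughout. Benchmark problem sizes (30 × 2 000
mutations for extraction, 5 cohorts on 3 × 150 Mb genomes for kataegis, 200
consensus repetitions, 100 000 chromosomes for KS calibration) were chosen as
desk-scale versions of the corresponding analyses; all are parameters, not
constants.

## Known limitations

- KL-NMF stability depends on signature separation; near-collinear (flat)
  profiles are not identifiable at these mutation loads, and the <10 % rule will
  reassign mass among them (see the README's worked example).
- The PCF penalty couples detection sensitivity to local background density;
  loci embedded in dense background or adjacent to other loci merge (by design).
- The clustered-breakpoint rule is scale-fixed (1 Mb/10 breakpoints); no
  multi-scale clustering or chromothripsis/BFB mechanism calling is attempted.
- Exact Mann–Whitney p-values are only used for small tie-free samples;
  elsewhere the tie-corrected normal approximation applies.
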