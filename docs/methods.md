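# Methods

## The screening model

`indelmark` operationalizes a marker-development screen for a small panel
of resequenced accessions. Its unit of analysis is a biallelic InDel locus
with one diploid genotype call per accession, each call carrying read
depth (DP) and Phred-scaled genotype quality (GQ). All positions are
1-based as in VCF, and alleles are stored left-anchored (shared leading
base), so the assayable size difference is |len(REF) − len(ALT)|.
Multi-allelic VCF records are split into one biallelic record per ALT;
genotypes that involve neither REF nor that ALT are treated as missing,
because the three-digit classification below is defined only for a
REF/ALT dichotomy.

### Two-stage filtering

The filter follows vcftools-style masking-then-locus semantics:

- **Relaxed pass.** A genotype with DP < `min_depth` (default 10) or
  GQ < `min_gq` (default 30) is set to missing — the call is discarded,
  never the locus. A locus is then removed if its missing fraction
  exceeds `max_missing_fraction` (default 0.2), or if all remaining
  non-missing calls agree on one homozygous class (monomorphic; masked
  calls carry no allele information, so they are excluded from this
  test).
- **Strict pass.** Any heterozygous or missing call disqualifies the
  locus. Survivors are fully homozygous with at least one accession per
  allele (monomorphic loci were already removed), which is exactly the
  precondition for a middle-digit-zero polymorphic-type code.

Tightening any threshold can only shrink the survivor set, and the
survivor set is independent of record order; both properties are tested.

### Polymorphic types and candidate selection

A locus across *n* accessions is coded "hma": counts of hom-ref, het and
hom-alt calls. Codes are digit-limited (counts > 9 raise). When
classification is run on relaxed-only data, missing calls count toward no
digit and are reported separately, preserving the digit-sum = informative
calls invariant. Grouping tables count loci per code overall and at size
thresholds (≥ 15/20/25 bp by default) with a totals row; threshold columns
are monotone non-increasing by construction.

Candidate selection keeps loci whose code equals `target_code`
(default '303' — for six accessions the balanced, maximally informative
split), whose size difference lies in the **inclusive** window
[`min_size_diff`, `max_size_diff`] = [15, 100] bp, and which lie strictly
more than `min_edge_distance` = 200 bp from either contig end. The window
is inclusive at 15 and exclusive above 100 because a screen counting
"≥ 15 bp" candidates and then discarding a 107 bp event is only
consistent under that reading. Edge distance is the number of reference
bases between the variant's leftmost (or last) affected base and the
nearer contig end, min(pos − 1, contig_len − end) on 1-based inclusive
coordinates; `edge_distance ≥ flank_len` is then exactly the condition
for a `flank_len` primer flank to fit. Direction is insertion when ALT is
longer than REF. Expected per-accession fragment sizes assume a primer
pair at the flank boundaries: fragment = 2·flank + allele length.
Candidates are emitted in (contig, position) order; each exclusion is
itemized with the first rule it failed.

### Codominant allele calling

Gel scoring maps observed fragment sizes to calls. A fragment within
`fragment_tolerance` (default ± 5 bp, roughly agarose resolution;
configurable) of the expected reference size is A, of the alternative
size B; both fragments together are H; no fragment is a null. A single
fragment at least `novel_allele_threshold` (default 30 bp) larger than
*both* expected sizes is a novel allele: distinct novel sizes are
lettered C, D, … in order of first detection across accessions
(M01 → M06 scoring order); sizes within tolerance of a known novel class
reuse its letter. Letters continue alphabetically past D (skipping H) if
more classes ever appear. Any other pattern — e.g. a single fragment
between the two expected sizes — is flagged ambiguous and never silently
assigned.

Band scoring expands the call matrix to one A-column and one B-column per
marker plus one column per observed novel class; H lights both parental
columns (the codominant reading of 1/0 band scoring), null lights none. A
dominant single-column-per-marker encoding is available as an option,
since gel-based matrices are sometimes scored that way.

### Similarity, trees, minimum sets

Jaccard similarity over band columns is S = n₁₁/(n₁₁+n₁₀+n₀₁), excluding
joint absences (a simple-matching variant is provided for comparison); a
pair with an empty band union is an error, not a silent 0. UPGMA
agglomerates d = 1 − S with size-weighted arithmetic-mean cluster
distances and node height = join distance / 2, giving an ultrametric
tree; distance ties are broken by joining the pair whose smallest leaf
labels sort first, making the tree deterministic. The implementation is
checked against a naive O(n³) re-agglomeration and against scipy's
average-linkage cophenetic distances in the tests.

The minimum discriminating set is found by exhaustive search over subset
sizes 1, 2, … (lexicographically first among equal-size solutions) for
panels of ≤ 25 markers; larger panels use greedy partition refinement and
the result is explicitly labeled heuristic. Optimality for small panels
is verified against full subset enumeration in the tests.

### Phenotype statistics

Traits are plant height (cm), seed weight (g), flower-head number, seed
weight per flower head (g), spine length (mm) and plant color at harvest
(ordinal 1 = green, 2 = brown, 3 = green-brown, treated as numeric
throughout, as the source tables do). Summaries report mean and sample SD
(n − 1), rounded half-up to one decimal. Subset-vs-population contrasts
use Welch's two-sample t-test — the conservative default for unequal n
and variance; the underlying screen did not name its test, so the
significance flags it printed are treated as illustrative, not as exact
targets. PCA is an eigendecomposition of the trait **correlation** matrix
(units are incommensurable); loadings are component–trait correlations
(eigenvector × √eigenvalue), each component sign-flipped so its
largest-magnitude loading is positive; explained variance is
eigenvalue / n_traits. Clustering is Ward (minimum variance, Ward.D2
updates via scipy) on Euclidean distances of z-scored traits.

## Synthetic data: what it emulates, what it does not

`SimSpec` fixes everything about a simulated dataset, including the seed;
identical specs give byte-identical FASTA/VCF/TSV output. Defaults encode
the study conditions the package targets: 6 accessions, 8 × 150 kb
uniform-composition contigs, 300 loci distributed over the fully
homozygous codes in the proportions observed in the motivating
six-accession screen ('105'/'204'/'303'/'402'/'501' =
46/32/33/59/130, the 30,845-locus composition rescaled by largest
remainder), an InDel length spectrum heavily skewed to short events with
a usable ≥ 15 bp tail and a few > 100 bp events, DP ~ N(30, 8) and
GQ ~ N(60, 15) truncated at 0 and integer-rounded, 2 % heterozygote
flips, 5 % missing calls, and 5 % of loci deliberately placed within
200 bp of a contig end. Noise is applied in a fixed order — het flips,
then missing masking — so expected post-noise counts are computable in
closed form. Every locus's pre-noise code, size difference, direction and
edge distance are recorded as ground truth.

Phenotype tables are multivariate-normal draws with requested means, SDs
and correlation (PSD-checked), optional cluster offsets along random
directions, physical traits clipped at zero, and the color trait
discretized to {1, 2, 3}. The discretization and clipping intentionally
distort that trait's moments — tests that assert moment recovery exclude
it.

What the generator does **not** emulate: read-level artifacts (no
FASTQ/alignment simulation), linkage between loci, non-normal trait
distributions, genotype-call errors correlated with DP/GQ, or structural
variants. Passing tests therefore demonstrate correctness of the
screening arithmetic and algorithms under controlled conditions, not
robustness to caller-specific error modes in real data.

## Numerical choices and degenerate inputs

- Report rounding is half-up (ties away from zero) via decimal
  arithmetic, matching how sequencing-report tables round; plain float
  rounding (banker's) would differ on .5 ties.
- Percentages in totals rows are recomputed from summed counts, never by
  averaging row percentages.
- Zero total reads, equal-length "InDels", non-symmetric distance
  matrices, non-PSD correlations, k > n clusters, flanks overrunning a
  contig, and > 9 accessions per genotype class all raise immediately
  with named errors.
- PCA drops numerically zero eigenvalues (rank deficiency) rather than
  emitting noise components; it requires n > p.
- Correlation of a zero-variance trait yields NaN (flagged) rather than
  aborting the whole matrix.

## Problem sizes

The test suite and the acceptance script run simulations of ~300 loci ×
6 accessions and phenotype populations of 220 accessions — large enough
that binomial/SE bounds in the tests are tight, and everything completes
in seconds on one CPU. The exhaustive minimum-set search is bounded
(≤ 25 markers) with a documented greedy fallback beyond.

## Known limitations

- The minimum-set search optimizes discriminating power only; a wet-lab
  set would also weigh band sharpness and reproducibility, which are not
  modeled.
- UPGMA tie-breaking is a convention; on tied inputs other software may
  return a different (equally valid) topology.
- The validation-summary module tallies externally supplied wet-lab
  outcomes; it cannot predict amplification failure.
- Primer design itself is out of scope: the package emits
  Primer3-compatible region records, not primers.
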