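# Methods

## PAM patterns and GC content

PAMs are modelled as IUPAC-degenerate strings.  Matching semantics
follow the standard expansion (N = A/C/G/T, V = A/C/G, ...), and
reverse complementation maps degenerate codes through their set
complements (V ↔ B, R ↔ Y, S ↔ S), so the reverse-strand scan of a
pattern is the forward-strand scan of its reverse complement.

The GC content of a PAM is defined over its informative positions: N
positions are removed from numerator and denominator (an N carries no
base preference, so including it would dilute every pattern toward the
genome background).  For partially degenerate codes the definition is
the expected GC under a uniform choice among the allowed bases (V
contributes 2/3, S contributes 1, W contributes 0).  This fractional
convention reduces to simple counting for concrete patterns — NGG is
100% GC, NGAG is 67% — and equals the mean GC of the pattern's concrete
expansion, a property the test suite verifies by enumeration.  An
enzyme's overall GC pools positions across all of its PAMs rather than
averaging per-PAM values, so longer PAMs weigh proportionally more.

The shipped registry lists 21 widely used enzymes (16 Cas9, 5 Cas12a)
with the PAMs reported as efficient in their primary characterizations.
It is a plain TSV so users can substitute their own panel; none of the
package's logic depends on its size.  One enzyme-specific rule is
encoded: xCas9 recognizes NG, GAA, and GAT, but every GAA/GAT site
implies an NG site one position upstream, so only NG is used when
ranking segments (the `ranking_pams` field).

## Segmentation

Chromosomes are concatenated end to end and cut into a fixed number of
consecutive half-open segments of length ceil(total/n); the final
segment absorbs the remainder.  For the GRCh37 autosomes
(2,881,033,286 bp, n = 20,000) this yields 144,052 bp segments with a
137,338 bp tail.  Per-segment GC is adjusted for assembly gaps:
GC = (G+C)/(length − N), and segments that are entirely N are flagged
and excluded from ranking and downstream analysis.

Conventions chosen where a rule had to be fixed:

* Coordinates are 0-based half-open internally; 1-based positions occur
  only at VCF/BIM-facing I/O.  A SNP at a segment's end coordinate
  belongs to the next segment.
* Soft-masked (lowercase) bases count as their base, not as N — repeat
  regions carry real PAM sites.
* Segments may span chromosome junctions (the concatenation has no
  junction rule); `plan_segments_by_chrom` provides junction-respecting
  segmentation for users who prefer it.  At 144 kb scale the difference
  is 21 junction segments out of 20,000.
* Motif occurrences must lie fully within a segment; boundary-straddling
  windows are not counted (at most |pattern|−1 sites per boundary).

## PAM counting and Cas ranking

Occurrences are counted on both strands with overlapping windows all
reported; windows containing N never match.  A forward hit and a
reverse hit at the same offset are distinct targetable sites and both
count.  For a multi-PAM enzyme, the segment score is the size of the
union of (offset, strand) windows over its ranking PAMs, so a window
matched by two PAMs of the same enzyme is counted once.  Top-k
selection (default k = 10% of eligible segments) breaks count ties by
ascending segment index, making region sets deterministic.

Matching is regex-based (per-position character classes with a
lookahead for overlaps).  The test suite checks equivalence against two
independent oracles: concrete k-mer expansion with window scanning, and
a vectorized positionwise allowed-base table, across random
N-containing sequences for every registry PAM.

## Stratified LD score regression

The stratified polygenic model assumes the causal-effect variance of
SNP j is Σ_c τ_c a_jc over annotations c containing j, which implies

    E[χ²_j] = 1 + N Σ_c τ_c ℓ(j,c),    ℓ(j,c) = Σ_{k∈c} r²(j,k)

with the LD score summed over SNPs of c within a genetic-window (1 cM
default) of j.  The implementation:

* **r² estimator** — r²_adj = r² − (1 − r²)/(n − 2), the standard
  small-panel bias adjustment; for unlinked SNPs the adjusted score
  averages to its own term (≈1) instead of inflating by (m−1)/n.  A
  SNP's own term is always 1.  Monomorphic SNPs are excluded with a
  warning and receive NaN.
* **Regression** — weighted least squares of χ² on N·ℓ columns with a
  free intercept (deviation from 1 absorbs confounding).  Default
  weights are the inverse squared predicted mean of χ²
  (Var(χ²) ≈ 2·E[χ²]² under normality), seeded by an aggregate h²
  estimate M(mean χ² − 1)/mean(N ℓ) clipped to [0, 1]; unweighted and
  user-supplied weights are available.  Rank-deficient designs raise an
  error naming collinear columns.
* **Partition** — per-SNP h² is Σ_c τ̂_c a_jc; an annotation's h² sums
  this over its members (overlapping annotations deliberately
  double-count, as in the standard partitioned model), and enrichment
  is h² share over SNP share.  Negative τ̂ can give negative shares;
  they are reported untruncated.
* **Uncertainty** — delete-one block jackknife over contiguous SNP
  blocks (200 by default) on both τ̂ and the enrichment ratio;
  two-sided Wald tests against τ = 0 and enrichment = 1;
  Benjamini–Hochberg step-up flags at q = 0.05, poolable across an
  annotation × trait grid.

A caveat observed in synthetic experiments: when LD is homogeneous the
base LD score is nearly constant and the intercept is weakly separated
from the base coefficient; point estimates remain unbiased and the
jackknife reflects the inflated variance, but intercept calibration
tests need designs with LD-score variance.

## Overlap statistics

Fisher's exact test on the 2×2 joint-membership table of two binary
annotations.  The reported odds ratio is the sample cross-product
(a·d)/(b·c) — the reproducible default for heat-map values — with the
conditional MLE behind a flag; zero cells yield 0/∞ with a degeneracy
flag and no continuity correction.  The p-value is the exact two-sided
hypergeometric tail (summing all tables at most as probable as the
observed), verified against full enumeration for small tables.

Pearson correlations are tested via Fisher's Z: z = atanh(r)·√(n−3)
against a standard normal, requiring n ≥ 4 and non-constant input; |r|
= 1 underflows and is reported as p = 0.

Off-target sites are assigned to segments by half-open interval
membership; unmappable sites are dropped and counted.  Per-segment site
counts and mean cleavage frequencies can then be correlated against PAM
counts.

## Synthetic data

The generators are pure functions of spec + seed (byte-identical
reruns) and emulate exactly the moments the estimators consume:

* **Genome** — i.i.d. bases at a target GC per block over a background
  (default GC 0.41, the human genome-wide value), exact N-run
  placement (N overrides planted motifs, with a warning), and Poisson
  motif planting with per-instance concretization of degenerate codes.
  Real genomes' isochore autocorrelation and repeat structure are not
  modelled; tests that depend only on block-level GC contrasts are
  unaffected, but base-pair-scale sequence statistics are not
  realistic.
* **Genotypes** — haplotypes from a Gaussian threshold model:
  equicorrelated latents (correlation ρ) within fixed-size LD blocks,
  thresholded at each SNP's allele-frequency quantile; diploid dosages
  are sums of two haplotypes.  This yields tunable within-block r²,
  independence across blocks, and MAF-dependent LD — but no LD decay
  within blocks and no demography.  The genetic map is uniform
  (default 1 cM/Mb); tests use denser maps (10–50 cM/Mb) so a 1 cM
  window spans many blocks at small m.
* **Summary statistics** — model-level mode draws
  Z_j ~ N(0, √(1 + N Σ τ ℓ)) from supplied LD scores: exactly
  calibrated to the regression model and fast, at the cost of ignoring
  Z-score correlation along the genome.  Genotype-level mode draws
  per-SNP causal effects, builds phenotypes on the panel, and computes
  marginal Z — validating the full chain at smaller m.  Target
  enrichments are converted to τ by giving annotated SNPs per-SNP
  variance E·h²/M, so the realized h² share is exactly E·(SNP share).
* **Functional annotations** — SNP membership Bernoulli with logistic
  probability in the z-scored segment GC (slope 0 ⇒ independence).
* **Off-target sites** — segments sampled ∝ count^coupling, positions
  uniform within segment, cleavage frequencies Beta(1.5, 20)
  independent of PAM content.

Because model-level sumstats use the same LD scores as estimation,
recovery tests certify the estimator and its uncertainty, not
robustness to LD-score estimation error in the GWAS population — that
requires the genotype-level mode or real data.

## Test and experiment scales

Desk-scale checks run on ≤10 kb sequences and ≤300 kb genomes.  The
pipeline recovery experiment uses a 5 Mb genome in 100 segments (top 10
ranked), m = 20,000 SNPs, a 200-individual reference panel with
25-SNP LD blocks (ρ = 0.8) on a 10 cM/Mb map, N_GWAS = 50,000,
h² = 0.5, and 200 jackknife blocks: planted enrichments of 2.0 and 3.5
are covered within ±3 jackknife SE in ≥90% of 50 replicates, and a null
annotation is BH-flagged in ≤10% of 100 replicates.  These sizes keep
the whole suite under half a minute while leaving the estimator
non-trivially identified (jackknife SEs ≈ 0.14 at enrichment 3.5,
matching the empirical replicate spread).

## Known limitations

* The registry is a curation; PAM preferences of engineered variants
  are activity-dependent and the table simplifies them to the reported
  efficient set.
* Binary annotations only; continuous annotations (e.g. conservation
  scores) are out of scope at desk scale.
* The enrichment p-value uses a normal approximation on the jackknifed
  ratio; for annotations with very few SNPs the ratio is skewed and
  the approximation degrades.
* Genome-scale runs are single-threaded; counting all registry PAMs
  over 20,000 × 144 kb segments is an hours-long batch job.
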