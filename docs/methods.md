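# Methods

## The scan model

The package contrasts two sample groups — males and hermaphrodites — over
tiled genomic windows. All internal coordinates are 0-based half-open; the
1-based inclusive conventions of VCF and GFF3 are converted exactly once at
the I/O boundary, and a single exhaustive property test pins the overlap
rule (a 1-based gene [s, e] overlaps a half-open window [w0, w1) iff
s ≤ w1 and e > w0).

Genotypes are reduced to alt-allele dosages in {0, 1, 2}; phase is
discarded because no statistic here uses it. Missing genotypes shrink the
called-haplotype count n at a site rather than being imputed, which keeps
every estimator unbiased under missingness-at-random and matches standard
diversity estimators.

**Per-site diversity** is the mean pairwise difference
2j(n−j)/(n(n−1)) for j alt alleles among n called haplotypes; windows
report the sum over variant sites divided by the window length in bp.
Using bp (not variant-site count) as the denominator makes the
male/hermaphrodite ratio comparable across windows, which matters because
ROD = 1 − π_male/π_herm mixes the two groups within one window. ROD is
undefined (NaN, never ±inf) when π_herm = 0.

**F_ST** defaults to Hudson's two-population estimator,
num = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1),
den = p1(1−p2) + p2(1−p1),
windowed as Σnum/Σden (ratio-of-sums, robust to rare variants). The
Weir–Cockerham (1984) variance components (a, b, c; window value
Σa/Σ(a+b+c)) are available by flag. The two bracket common practice and
the tests pin both against independent oracles: Hudson against explicit
haplotype-pair counting (1 − Hw/Hb), Weir–Cockerham against a literal
scalar transcription of the 1984 equations. A window needs at least
`min_sites` = 5 informative sites (default) for a defined value;
negative window values are reported as computed, not clamped, because
clamping would bias the empirical null.

**Significance.** A reported "cutoff" like 1e−5 is ambiguous between an
absolute F_ST (uselessly permissive), an empirical top fraction and a
permutation p-value, so all three are explicit `threshold_mode`s:

- `quantile` (default): the value is the top fraction of defined windows,
  floor of one window; ties broken by higher F_ST then coordinate.
- `permutation`: sex labels are permuted across samples and each window's
  p is (1 + #{permutation max F_ST ≥ observed})/(1 + permutations); using
  the genome-wide maximum as the null statistic controls family-wise
  error.
- `absolute`: plain F_ST ≥ value.

Windows are 10 kb non-overlapping by default; 20 kb and sliding steps are
supported. Significant windows merge into regions across gaps ≤
`merge_gap`; genes qualify on ≥ 1 bp of overlap with a region (no promoter
extension — no flanking rule is asserted by the data), and the filtered
candidate view keeps genes with max overlapping-window F_ST strictly
above `gene_fst_cutoff` (default 0.2).

## Hemizygosity from depth

Each sample's windowed depth (1-kb windows by default) is divided by that
sample's genome-wide median window depth, so a diploid-typical window sits
near 1 regardless of library size; calls are therefore invariant to
per-sample scaling. Group summaries use the median across samples
(robust to single-sample dropouts). A window is hermaphrodite-absent when
the hermaphrodite group median is ≤ 0.1 and the male median ≥ 0.3;
maximal runs merge across ≤ 1-window gaps and must span ≥ 5 kb. The 0.3
male floor gives margin below the ≈ 0.5 expected for a hemizygous single
copy, while 0.1 tolerates stray mismapped reads in the absent sex; both
are exposed in the API/CLI. The herm_max < male_min ordering makes
herm-absent and male-absent calls mutually exclusive by construction.

## Expression screen

Counts are RPKM-normalized (counts × 10⁹ / (gene length × library
size)). The two-group screen classifies genes by the log2 fold change of
group-mean RPKM with a pseudocount of 1 RPKM (zero handling; configurable)
and a two-sided label-permutation p-value; a gene is called only when
|log2FC| ≥ 1 and p ≤ α. This is a deliberately assumption-light contrast
with the same interface a negative-binomial differential-expression model
would have; it does not shrink dispersions and is conservative at small
group sizes, which the null-calibration test quantifies (observed
positive rate well under α).

## Closed-form summaries

Percentage reproductions round half-away-from-zero at the reported
precision (79/303 → 26.07 → 26.1), matching how such tables are
conventionally typeset. The 1:1 segregation test is the Pearson
goodness-of-fit χ² with 1 df, equal to 2(n_male − n̄)²/n̄. Genome size
from a k-mer histogram uses the valley convention: the error tail is the
initial monotonically decreasing head, its end the first depth after
which counts rise; the peak is the modal depth beyond the valley and
size = Σ depth·count (beyond the valley) / peak. A spectrum with no
interior peak (insufficient coverage) is an error, not a number.

## The simulator

`SimConfig` defaults encode the study conditions: 55 diploid samples in 5
demes of 11 (29 males, 26 hermaphrodites, interleaved so the sexes are
balanced within demes), two contigs (300 kb carrying the sex region,
200 kb neutral), ~20 SNPs/kb, between-deme F_ST 0.2, a 24-kb sex region
at scaffold_25:120,000 with per-site divergence probability d = 0.8,
~25× mean depth with 20% CV, and an 18-sample expression design (4 male
flowers / 6 hermaphroditic flowers / 8 fruits). Contig lengths and SNP
density are scaled down from a full genome so the whole pipeline runs in
seconds; the planted region, sample design and rate parameters are kept
at study scale.

Neutral frequencies follow the Balding–Nichols island model: deme
frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral
p ~ U(0.05, 0.95), dosages Binomial(2, p_deme). This reproduces
F_ST-scale structure analytically (realized Hudson F_ST equals the target
F within sampling noise, verified at ±0.02 over 50,000 sites) at a tiny
fraction of coalescent cost; it has no linkage disequilibrium, no site
frequency spectrum realism and no recombination map, so passing tests
demonstrate estimator correctness and pipeline recovery, not robustness
to genealogical correlation. Divergent sex-region sites are fixed
different between sexes, with males encoded as homozygous dosage 2 — the
genotype a diploid caller emits for a hemizygous single-copy allele.
Depth noise is gamma (zero-CV limit exactly the mean); expression counts
are gamma-Poisson with log-normal baselines. Every generator is
bit-reproducible given (config, seed), and the file exporter writes a
JSON sidecar recording both.

## Problem sizes and numerical choices

The default test/acceptance sizes — 10,000 SNPs over 500 kb, 500 depth
windows, 2,000 genes × 1,000 permutations, 1,000 χ² replicates, 100-kb
genome at 40× for the k-mer check — were chosen so each check isolates
one property at comfortable statistical power while the full suite runs
in seconds. Undefined statistics are NaN throughout and written as `NA`
(tables state their six-significant-digit precision in the header, so
write/read round trips are exact at that precision). Ties in window
ranking break by higher F_ST, then coordinate, for determinism.

## Known limitations

- The scan assumes biallelic SNPs and two sex groups; no multi-contrast
  or haplotype statistics.
- The permutation null permutes individuals, so it assumes exchangeability
  across demes under the null; strong sex-by-deme confounding would
  inflate it (the default design balances sexes within demes).
- Depth calling is window-median based and cannot genotype individual
  samples for a deletion, nor detect breakpoints below window resolution.
- The expression screen is a fold-change + permutation stand-in, not a
  shrinkage-based count model; with very few replicates it is
  conservative rather than anticonservative.
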