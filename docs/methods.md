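# Methods

## Occupancy model

All coordinates are 0-based half-open (BED convention); any 1-based
annotation input is converted at load time via a dialect flag, and the
default interpretation of external peak tables as 0-based is a documented
choice, not an assertion about their provenance.

Raw occupancy at base pair *b* is the count of fragments whose interval
contains *b*; the total track mass therefore equals the summed fragment
lengths exactly, which the tests assert.  Each chromosome is divided by its
own mean so the average occupancy per nucleotide is 1 (to 1e-9), making
samples of different sequencing depth comparable; a chromosome with zero
signal is left at zero with a warning, since its mean is undefined.
Replicates are normalized first and then merged as the per-bp arithmetic
mean — merging normalized tracks rather than pooling reads gives each
replicate equal weight regardless of depth.  Epitope-tagged remodeler
samples are corrected by subtracting the normalized untagged-strain track;
negative corrected values are kept because difference maps are signed.
Intervals around tDNAs (250 bp) can be masked to zero before TBP
quantification so that Pol III-associated TBP peaks do not leak into
promoter windows; quantification in windows disjoint from the masks is
unchanged, which a test verifies.

Dyad densities place a unit count at the midpoint of each MNase fragment of
nucleosome size (125–175 bp); the even-length midpoint tie-break is
floor((start+end)/2).  Averaged dyad profiles are smoothed with a centered
moving average of span 31 bp; at array edges the window truncates to the
available positions (zero padding was rejected because it depresses signal
at chromosome ends).  The order of operations is fixed: average across
sites first, then smooth.

Anchor-aligned matrices take the track value at anchor+p for p in
[−flank, +flank]; interval features anchor at their midpoint (floor
tie-break), rows of minus-strand features are reversed only when
strand-orientation is requested (TSS-anchored gene profiles are oriented;
activator-motif profiles are not, since the motif is near-palindromic and
plotted in genomic orientation).  Windows running off a chromosome are
padded with NaN and excluded from column means — zero filling would bias
averages downward at boundary-proximal features.  Default motif/summit
flanks are 1000 bp, where averaged profiles have converged to baseline.

## Quantification and partitions

Occupancy per nucleotide over a window is the mean of per-bp normalized
values (peak interval, anchor ± 100 bp, or CDS).  log2 columns and fold
changes share one pseudocount, by default half the smallest positive
occupancy in the table — scale-aware rather than a fixed magic constant —
recorded in the table metadata.  With a shared pseudocount, ranking by
ratio and ranking by log-ratio are order-equivalent, which a test asserts.

Fold-change rankings are ascending in (mut+pc)/(wt+pc) with feature-id
tie-breaks.  The quartile-set rule assigns ceil(n/4) items to each outer
set and the remainder to the middle set; this is the simplest rule giving
30/57/30 at n = 117.  Deciles are contiguous rank bins whose sizes differ by
at most one, larger bins first; halves put the first ceil(n/2) ranked items
in the High bin.  Summit-to-gene assignment takes the same-chromosome
summit minimizing |summit − TSS| with equidistant ties going to the lower
coordinate, and replaces manual curation with a configurable maximum
distance (default 500 bp) beyond which assignments are reported but flagged.

## Statistics

Mann–Whitney–Wilcoxon tests are two-sided; the p-value is exact (full
enumeration of the null rank distribution) when both groups have at most 8
observations and no ties, otherwise the tie-corrected normal approximation
is used, and the mode is recorded in each result.  Star codes are a pure
threshold function of p with inclusive boundaries (\*\*\*\* ≤ 1e-4,
\*\*\* ≤ 1e-3, \*\* ≤ 0.01, \* ≤ 0.05, ns otherwise).  Pearson correlations
use the t-distribution p-value and reject zero-variance input.  Box
summaries use linear-interpolation quartiles (the dominant default in
scientific software, so independent oracles agree) and the conventional
95% median notch 1.57·IQR/√n.  Sector scatter classification assigns points
on an axis to the non-negative side and reports an on-axis tally.

## Synthetic data generator

The generator emulates the regulatory architecture the analyses are designed
for, on a deliberately small genome (2 chromosomes × 150 kb, 128 gene units
at 2.3 kb spacing, 117 5' sites, 6 ORF sites, 5 highly expressed RPG-like
genes):

* **Promoters.** Each gene has a 120 bp NDR whose center carries the
  activator motif of 5' sites; −1/+1 nucleosome dyads sit at ±133 bp from
  the center (NDR edge plus a 73 bp core half-length) and genic dyads
  follow at 165 bp spacing.  ORF-site motifs sit in the linker between
  genic nucleosomes 2 and 3.  The TSS lies 27 bp inside the +1 nucleosome.
* **Binding.** Per-site binding strength β = 24·s·m·j where s is a
  motif-score-derived scale (scores ~ N(18, 3), β ∝ (score/18)^1.5, giving
  the expected positive occupancy–score correlation), m a (site class ×
  strain) multiplier, and j a small lognormal jitter.  Induction multiplies
  β by 8; the activator-null strain has β = 0.  The three planted site
  classes encode distinct remodeler dependence: RSC-dependent (double
  mutant 0.45×, snf2-null 1.0×), SWI/SNF-inhibited (0.60× / 1.7×) and
  Ino80C-dependent (1.00× / 2.0×, ino80-null 0.55×).  Class sizes follow
  the outer-quartile rule (30/57/30 at 117) and are shuffled over the
  genome.
* **Eviction.** On induction, promoter-nucleosome occupancy is scaled by
  (1 − ε) with ε = 0.7 in WT; strain multipliers (snf2 or sth1 single
  mutants 0.65, double mutant 0.2, ino80 0.75) plant the eviction defects.
* **TBP, Pol II, remodelers.** TBP is a 60 bp-half-width kernel 130 bp
  downstream of each 5' motif with amplitude ∝ β/(β+12)·(0.3+0.7ε) — a
  saturating recruitment that reproduces the qualitative uncoupling of high
  activator binding from low TBP when eviction fails, without claiming a
  mechanism.  Pol II (Rpb3) covers the CDS in proportion to a transcription
  rate with the same saturating form; constitutive genes get a fixed
  lognormal rate (RPG-like genes a high one) so expression deciles are
  meaningful.  Tagged remodelers use a triangular kernel at motifs with a
  linear coupling to sat(β) — a stated modeling choice, not an inference —
  plus a weak TSS-proximal component; the untagged control is pure
  background.  tDNA positions carry large condition-independent TBP peaks
  so masking has something to remove.
* **Fragments.** Midpoints are drawn from the per-bp landscape
  (background 1 plus kernels; triangular factor kernels of 100 bp
  half-width, raised-cosine 147 bp nucleosome footprints for sonicated H3,
  Gaussians of sd 18 bp at dyads for MNase); lengths are uniform 300–500 bp
  (sonicated) or truncated-normal mean 150 sd 10 clipped to 100–200 bp
  (MNase).  Per-sample RNG streams are derived by hashing (metadata, master
  seed), so replicates are independent but every run is bit-reproducible.

### Planted truth and recovery

Normalized ChIP signal is compositional: multiplying every site's β by a
constant changes nothing after per-chromosome normalization, and strong
sites slightly depress the normalized values of all others.  The planted
per-site truth is therefore defined as the *expected normalized window
occupancy* computed exactly from the landscape — including the smearing of
the midpoint density by the fragment-length coverage kernel
w(d) = P(fragment covers offset d) — so the recovery harness measures the
pipeline's sampling error rather than model mismatch.  The harness checks
(i) median absolute error of per-site log2 induction estimates, (ii)
elevated H3 at motifs in the eviction-defective double mutant
(Mann–Whitney), (iii) −1/+1 dyad-peak positions, and (iv) the TBP profile
maximum; each check is flagged underpowered (rather than failed) below
5×10^4 fragments per sample or fewer than 30 sites.

### TBP summit localization

Coverage by 300–500 bp fragments of a point source is exactly flat within
±150 bp (every fragment covers the summit region), so an averaged coverage
profile cannot localize a summit to ±10 bp.  Summits are therefore located
from fragment-*midpoint* density (the dyad-density primitive with the
sonicated length window, smoothed with span 31), the same idea peak callers
use for summit estimation; the coverage profile is still produced for
display.

## Problem sizes and defaults

The demo and acceptance runs use the generator defaults: 117 5' sites,
5×10^5 fragments per sample, 2 replicates, 21 target × strain × condition ×
prep combinations.  The `analysis/` drivers use 10^5 fragments per sample,
which is ample for their narrative outputs.  Unit tests use a 12-site,
2×30 kb configuration.

## What passing tests do and do not show

The simulator plants clean, well-separated effects on a small genome with
no mappability artifacts, no PCR duplicates, no copy-number variation, no
antibody-efficiency differences between samples and no biological
replicate-to-replicate variability beyond sampling noise.  Passing recovery
tests therefore demonstrate that the pipeline's arithmetic and statistics
are correct and unbiased at realistic depths — not that real ChIP-seq data
of this design would yield effects of the planted magnitude.  Duplicate
removal, alignment and peak calling are assumed upstream and out of scope;
peak/summit/motif catalogs are consumed as annotations.

## Known limitations

* The simulator has no sequence level (no FASTQ, no mappability) and no
  H2A.Z dynamics.
* Difference heat maps are produced as numeric matrices; image rendering is
  intentionally left to the user (color-scale choices are arbitrary and
  untested).
* The Mann–Whitney exact/asymptotic switch (n ≤ 8, no ties) is logged per
  result but not configurable per call.
* Whether normalization should precede or follow replicate merging is
  settled here as normalize-then-merge; the merge refuses unnormalized
  input rather than offering both orders.
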