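# Methods

## Setting

Two DNA pools ("bulks") of phenotypically extreme lines from a
biparental RIL population are sequenced; at every biallelic SNP each
bulk contributes a pair of allelic read depths `(n_ref, n_alt)` taken
from the VCF `AD` field. All inference is built on the contrast between
the two bulks' allele-frequency estimates.

## Per-SNP statistics

Let `f_A = n_alt,A / n_A` and `f_B = n_alt,B / n_B` be the alt-read
fractions (SNP-indices) of the two bulks.

* **ΔSNP-index** `Δ = f_high − f_low`. The sign is meaningful only after
  polarization (ALT = allele of the designated high-trait parent), which
  is done from homozygous parental genotype calls when parent samples
  are present; with bulks only, the ALT allele of the VCF defines the
  orientation and `|Δ|` should be used. Sites with a heterozygous or
  missing parent call are flagged unpolarizable and excluded from
  signed-Δ scans while remaining valid for `|Δ|`, G and ED.
* **G statistic** — the likelihood-ratio statistic of the 2×2
  allele-by-bulk table with expected counts from the marginals
  (natural log, `0·ln 0 ≡ 0`; a table with a zero allele margin gives
  G = 0; a fully empty table is undefined and carried as NaN).
* **ED / ED⁴** — the Euclidean distance over both allele axes,
  `ED = √2 |f_A − f_B|` at a biallelic site, raised to the fourth power.
  The √2 factor (distance over both allele coordinates rather than the
  single frequency difference) follows the distance's usual definition;
  it cancels in any threshold-relative decision but changes raw values,
  so it is stated here explicitly.

Undefined values are NaN throughout (and `.` in TSV output) — never 0,
which would silently look like a perfectly balanced site.

## Filtering and coordinates

Sites are restricted to biallelic SNPs by default (indels can be
re-admitted; the statistics are allele-length-agnostic, but the default
matches the usual SNP-based scans). Records with malformed or missing
AD in either bulk are dropped and counted, never zero-filled: a
zero-filled site would sail through the depth filter and contribute a
spurious extreme frequency. The depth filter removes sites with total
depth strictly below 10× in either bulk (totals of exactly 10 are
kept).

VCF positions stay 1-based in the site table. Window arithmetic is
0-based half-open internally (a SNP at 1-based `pos` is in window
`[start, start+W)` iff `start ≤ pos−1 < start+W`); window tables keep
the half-open convention, interval calls are reported 1-based inclusive
and BED output is 0-based half-open per the BED convention.

## Smoothing

* **G′**: at each SNP, the tricube-weighted mean of G over all SNPs
  within `h` bp on the same chromosome,
  `w(d) = (1 − (|d|/h)³)³` for `|d| ≤ h`. The bandwidth defaults to
  half the window size (500 kb) so that G′ and the window means share a
  1 Mb footprint; it is configurable.
* **Windows**: means of Δ, G, G′ and ED⁴ over windows of 1 Mb advanced
  in 100 kb steps, anchored at coordinate 0 on every chromosome.
  Windows with fewer than `min_snps_per_window` SNPs (default 1) are
  omitted.

Both smoothers are computed through sparse linear operators (a window
membership matrix and a row-normalized tricube kernel), which makes
recomputing the pipeline for tens of thousands of permutation
replicates a handful of sparse matrix products.

## Permutation thresholds

Significance is empirical: bulk labels are permuted at every site, the
full smoothing pipeline is recomputed, and thresholds are the requested
genome-wide quantiles (default 95% and 99%) of the pooled null window
values. Default 100,000 replicates; analyses in the test suite use
200–1,000, which is sufficient for a pooled quantile because each
replicate contributes every window to the pool.

Two permutation schemes are provided:

* **reads** (default): at each site the pooled reads of both bulks are
  re-partitioned between the bulks by a hypergeometric draw conditional
  on each bulk's coverage and on the pooled allele counts. This is the
  classic conditional permutation null of the 2×2 table: it preserves
  each site's per-bulk depth and total allele counts while breaking the
  bulk–allele association, and it perturbs all three statistics.
* **swap**: each site's two depth pairs are exchanged with probability
  1/2. Swapping whole-bulk labels once per genome would produce exactly
  two distinct datasets, so the swap must be per-site to give a
  Monte-Carlo null; note however that G and ED are symmetric in the two
  bulks, so a pure swap leaves them numerically unchanged at every site
  and is informative only for the signed ΔSNP-index. It is retained
  because it is the minimal "label permutation" and gives the exact
  degenerate null (threshold 0 for |Δ|) when the two bulks are
  identical.

Thresholding is window-level and two-sided for Δ (`|mean Δ|` is
compared against the quantile of the null `|mean Δ|`); G′ and ED⁴ are
one-sided by construction. A per-replicate genome-wide-maximum variant
(`pooling="max"`) gives family-wise control; pooled quantiles are the
default as they correspond to the single horizontal threshold line
customarily drawn on BSA scans. The pooled null is kept exact up to a
cap of 10⁷ values and reservoir-subsampled beyond it. Thresholds are
bit-reproducible for a fixed (seed, replicate count, input).

Significant windows are merged into candidate intervals when their
starts are at most two steps apart (i.e. runs of significant windows,
tolerating a single non-significant step); with overlapping 1 Mb/100 kb
windows a full-span overlap rule would bridge runs up to a whole window
apart. The interval is the union of its windows; the peak is the
midpoint of the highest one.

## Segregation tests

Observed two-class phenotype counts are tested against `1:(4ⁿ−1)`
(recessive class of interest) or `(4ⁿ−1):1` ratios for n = 1..4 genes
with Pearson's χ², df = 1, no continuity correction, p from the upper
χ²₁ tail. The published table this mirrors is reproducible without the
correction to < 0.5% at every entry except one (a 3-gene white:pink
entry printed as 1.312 where the exact Pearson value is 1.2727 — the
printed value evidently used rounded intermediate expected counts);
the implementation always returns the exact Pearson value.

## Simulator

The generator emulates the study design the scan assumes, at the level
of allele frequencies rather than sequences:

* **RIL genetics**: each line's genotype along a chromosome is a
  two-state Markov chain over the marker grid. Adjacent loci at map
  distance d cM (Haldane, `r = (1 − e^(−2d/100))/2`; default map
  density 1 cM/Mb) are recombinant in a selfed-to-fixation RIL with
  probability `R = 2r/(1+2r)`. Residual heterozygosity is
  `(1/2)^(generation−1)` per locus independently (0.0625 at the default
  F5), a deliberate simplification of identity tracts that is adequate
  for frequency-level statistics; a heterozygous locus contributes
  dosage 0.5.
* **Bulk composition**: selection is modelled at the line level — a
  line sorted into the high bulk carries the high allele at a QTL with
  probability `effect` ∈ (0.5, 1], the low bulk symmetrically. This
  directly emulates pooling phenotypically stable selected lines
  without an explicit phenotype model. Default 20 lines per bulk. One
  QTL per chromosome.
* **Reads**: per-site per-bulk depth is fixed (default 40×) or Poisson;
  alt reads are binomial(depth, true bulk frequency). No sequencing
  error, mapping bias or genotype-likelihood modelling.

Everything is deterministic under the scenario seed.

### What the simulator does and does not establish

Passing calibration and recovery tests on simulated data shows the
pipeline's statistics, smoothing, null and interval logic behave as
designed under the stated sampling model. Real data additionally
contain variant-calling artefacts, depth heterogeneity, reference bias
and marker-density variation that the generator deliberately omits.

One genuine limitation surfaced by the simulator is worth stating: with
small bulks (e.g. 20 lines) the lines' sampled genotypes drift from the
population expectation, and this drift is *correlated along the
chromosome*. Per-site label permutation — reads or swap, and indeed any
per-site scheme — models only read-sampling noise conditional on the
observed counts, so window-level thresholds are anti-conservative
against drift and QTL-free chromosomes show more threshold crossings
than the nominal rate. True QTL peaks under strong selection exceed the
threshold by an order of magnitude, so candidate ranking by peak value
is robust; bare exceedance of the threshold is not a calibrated
genome-wide error rate for small bulks. The calibration tests therefore
use an exchangeable null (both bulks binomial around the same
frequency), where the permutation null is exact and the observed 95%
exceedance is 5% within Monte-Carlo error.

## Numerical and scale choices

* Quantiles use numpy's default linear interpolation.
* Permutations run in fixed batches of 256 replicates so the RNG stream
  depends only on the seed.
* Test-suite and acceptance problem sizes — 2,000-SNP null chromosomes
  with 500 permutations × 20 replicates for calibration; a 1,000-marker
  25 Mb chromosome with 200 permutations × 20 replicates for recovery —
  were chosen as the smallest sizes at which the pooled-quantile
  thresholds and coverage rates are stable, and complete in seconds to
  a few minutes on a single CPU.
* The CLI records every run's parameters (`params.json`) and ingest
  accounting (`ingest_report.json`) beside its outputs for provenance.
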