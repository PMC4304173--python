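# Methods

## The problem and the model

`txmap` integrates probe-level expression measurements from heterogeneous
microarray platforms into one pooled transcriptome map per biological
condition and compares two conditions along the genome. The unit of
information is the *data point*: one probe-spot measurement of one locus in
one sample. A condition's expression value for a locus is the unweighted
mean of all its data points across all samples of the pool — a sample
measured by three probes for a locus contributes three points where a
one-probe sample contributes one. This flattening convention is what makes
per-locus data-point counts exceed sample counts, and it is applied in one
stage (no per-sample pre-averaging).

The differential map is built from the per-locus ratio of pooled means,
A/B, over loci measured in both pools. Three read-outs follow:

1. **Segment map.** Fixed windows of 500,000 bp shifted by 250,000 bp
   (50% overlap; an interior locus belongs to exactly two windows via its
   start coordinate). A locus is an *extreme gene* when its ratio falls in
   the highest or lowest 2.5th percentile of the ratio distribution. Each
   occupied window is scored by the hypergeometric upper-tail probability
   of containing k flagged loci among its n members, drawn from N loci of
   which K are flagged genome-wide; q-values correct the full family of
   window × tail tests (Benjamini–Hochberg by default, Bonferroni
   optional). A segment is called over/under-expressed when q < 0.05 *and*
   it holds at least 3 extreme genes. Overlapping calls whose flagged-gene
   sets share more than half of the smaller set are collapsed to the
   lowest-q segment (ties: larger |log ratio|). The segment ratio is the
   ratio of member means, not the mean of member ratios.
2. **Single-gene map.** The same test at a 12,500-bp window (half-window
   shift) with a 1-gene minimum. When a significant window holds several
   loci, the call attaches to a flagged locus only if its pooled value — in
   the pool where it is higher — strictly exceeds every co-member's value
   (the *prevail* rule); otherwise the call is reported as dropped.
   A structural consequence of correcting across the whole window family:
   an isolated flagged locus has p ≈ K/N ≈ 0.025 at best, so significant
   gene windows arise only where two or more flagged loci co-locate —
   which is precisely the situation the prevail rule adjudicates.
3. **Chromosome table.** Per chromosome, the median of member ratios
   (midpoint convention). On a trisomic chromosome the expected gene-dosage
   median is ~1.5.

Ranked most over-/under-expressed gene lists are restricted to loci with at
least 5 data points in both pools and sorted by ratio.

## Normalization

Per sample, in order: (i) *linearization* of log2/log10/ln deposits;
(ii) *zero substitution* — values ≤ 0 receive 95% of the sample's minimum
positive value, so ratios remain defined while below-detection signal still
registers as low; (iii) *percent-of-mean* intra-sample scaling (output mean
exactly 100). Substitution precedes the mean so that non-positive values
cannot distort it. Finally, *scaled quantile normalization* runs jointly
across all samples of the two compared pools, so pooled ratios share one
scale: each sample's empirical quantile function (midrank ties, plotting
positions (r−1)/(m−1)) is averaged pointwise into a reference curve, and
every value maps to the reference curve at its own within-sample quantile.
Platforms of different sizes are accommodated because the reference is a
curve over [0,1], not a vector of fixed length.

Numerical choice: the probability grid is the union of
`quantile_grid_size` (default 1001) equally spaced points and every
sample's own quantile knots j/(m−1). The mean of piecewise-linear quantile
curves is piecewise linear with knots in that union, so evaluation is exact
rather than grid-approximate: identical samples are fixed points, and
equal-length samples acquire identical sorted vectors.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window` / `shift` | 500,000 / 250,000 bp | segment grid |
| `gene_window` | 12,500 bp | single-gene grid (≈ quarter of a mean gene length) |
| `tail` | 0.025 | extreme-gene percentile per side |
| `q_threshold` | 0.05 | corrected significance level |
| `min_extreme_genes` | 3 | minimum flagged members of a called segment |
| `min_data_points` | 5 | eligibility filter for ranked gene lists |
| `correction` | `bh` | BH step-up; `bonferroni` available |
| `nonpositive_factor` | 0.95 | zero-substitution fraction |
| `quantile_grid_size` | 1001 | seed grid for the reference quantile curve |

Ties sitting exactly on a percentile threshold are flagged (inclusive
comparison — conservative toward flagging and deterministic). `tail = 0`
is the degenerate no-flagging case. Percentiles use the standard linear
(type-7) empirical quantile; with distinct ratios this flags exactly the
nominal fraction in each tail.

## Synthetic studies and what they do (not) show

The generator emulates the structure of pooled public microarray studies:
several platforms covering 60–100% of loci with 1–3 probes per covered
locus and ~1% unmapped control probes; per-platform multiplicative scale
offsets (ln-σ 0.5) removed by normalization; per-point log-normal noise
(ln-σ 0.2); 2% missing and 1% non-positive values (MCAR); one platform
depositing log2 values. True signal enters as a dosage chromosome
(factor 1.5), injected co-regulated clusters inside one window, and
single sex-biased loci.

Reference conditions: pools A (trisomic, 12 samples) vs B (euploid, 10
samples); three 50-Mb background chromosomes of 1,700 loci each plus a
10-Mb dosage chromosome of 300 loci; one 6-gene, 10× over-expressed
cluster on chr2. Null sweeps (false-call rate) use a lighter geometry —
three 50-Mb chromosomes of 700 loci, 8 vs 8 samples — chosen as a
problem size at which 20 independent replicates remain cheap while each
map still tests ~600 windows.

The generator draws independent log-normal intensities per locus; it does
not model probe-sequence effects, correlated gene programs, batch
structure beyond platform offsets, or intensity-dependent missingness.
Passing recovery tests therefore demonstrates that the pipeline's
*mechanics* (normalization, pooling, windowing, testing, calling) recover
known effects under realistic noise — not that any biological conclusion
from real arrays is correct.

Two observed behaviours worth knowing: quantile normalization compresses
very large injected folds (a 10× cluster typically surfaces with a segment
ratio of ~2.5–5 — rank-preserving, call unaffected), and percent-of-mean
scaling slightly attenuates dosage ratios when many loci shift together
(the 1.5× chromosome medians land near 1.44–1.46).

## Degenerate inputs and tie-breaks

* A sample with no positive value is an error (no meaningful substitution).
* Loci measured in only one pool are excluded from the differential map.
* Windows with zero member loci emit no test; the single-gene stage
  enumerates only occupied windows (equivalent to the full grid for this
  reason, and much cheaper).
* A window significant in both tails takes the lower-q tail; exact ties go
  to the side of its ratio.
* Pool-swap symmetry holds throughout: comparing B vs A inverts every
  ratio, swaps over/under flags and swaps segment calls.

## Known limitations

* The inter-sample normalization is this package's documented definition
  of scaled quantile normalization; other implementations of the idea may
  differ in grid or tie conventions.
* Probes mapping to multiple loci are not supported (one locus per probe).
* The hypergeometric test conditions on the flagged count K; it does not
  add a separate test on the segment's ratio magnitude.
* Cytobands are consumed from the annotation, never inferred from
  coordinates.
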