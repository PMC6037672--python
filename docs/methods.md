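# Methods

## Problem and model

Chromatin-associated proteins and histone marks (e.g. H3K4me3 at active
promoters) are profiled by ChIP-seq; comparing the same mark between two
cell types identifies regions of cell-type-biased binding, and transcription
factors (TFs) whose binding sites preferentially coincide with those regions
are candidate co-factors of the bias. `comotif` implements this comparison
as three coupled stages.

### Stage 1 — quantitative two-sample normalization

For each peak with raw read counts `(c1, c2)` in the two samples,

    M = log2((c1 + p) / (c2 + p))
    A = 1/2 * log2((c1 + p) * (c2 + p))

with pseudocount `p` (default 1 read) keeping both finite at zero counts.
Peaks *common* to both samples (>= 1 bp overlap, half-open coordinates) are
assumed equally bound on average, so the systematic trend of M against A
over common peaks reflects technical bias — sequencing depth, IP
efficiency. The trend `M = a + b*A` is fitted on the pooled common peaks of
both samples by iteratively reweighted least squares with Huber weights
(tuning constant 1.345, MAD residual scale, at most 50 iterations,
coefficient tolerance 1e-8); pooling both samples' common peaks makes the
fit exactly antisymmetric under sample exchange. Every peak (common and
unique) of both samples is then assigned `M_normalized = M - (a + b*A)`.

Per-peak significance uses a rescaled symmetric binomial model: sample 2's
count is brought onto sample 1's scale, `c2' = round(c2 * 2^(a + b*A))`
(round-half-to-even for platform determinism), and

    P = min(1, 2 * P(X >= max(c1, c2'))),   X ~ Binomial(c1 + c2', 1/2)

with `P = 1` when both counts are zero. Peaks with
`|M_normalized| >= m_cutoff` (default 1.0, i.e. 2-fold) and
`P <= p_cutoff` (default 0.01) are classed as biased toward the sample
with the higher intensity; everything else is unbiased.

Notes on this stage:

- The intercept `a` is the trend extrapolated to `A = 0`, far below where
  peak data live (A ~ 5-10 at typical depths). Because the pseudocount
  shrinks M toward 0 at low counts, the M-A relation is slightly curved and
  the extrapolated intercept can be offset by ~0.1-0.2 from the global
  log2 depth ratio even when the trend is removed essentially perfectly
  where the data are. The meaningful recovery statements — trend value at
  the common peaks' mean A, and mean normalized M of common peaks — are the
  ones the tests assert.
- The per-peak rescaling rounds `c2'` to an integer on one side only, so
  P-values under sample exchange agree exactly only when the rescaling
  factor is lossless (e.g. the identity model); otherwise they can differ
  by one count quantum. M-values and fitted coefficients are exactly
  antisymmetric.
- When a substantial fraction of common peaks carries a genuine shift (the
  situation the association stage is designed to detect), the robust fit
  absorbs part of that shift into the trend: with 20% of common peaks
  shifted by +0.8, the recovered carrier-vs-rest difference is ~0.65-0.72.
  This attenuation is inherent to normalizing on a contaminated common-peak
  set and is visible in the acceptance output (`carrier_m_shift_recovered`).

### Stage 2 — motif scanning with exact-null thresholds

JASPAR-format position frequency matrices are converted to log2-odds
matrices against a 0-order background (by default estimated from the
scanned peak sequences themselves, floored at 1e-3 per base):

    p(i, n) = (count(i, n) + f * bg(n)) / (rowsum(i) + f),
    LO(i, n) = log2(p(i, n) / bg(n))

with background-proportional pseudocount fraction `f` (default 0.01). Each
entry is quantized **upward** to a lattice of 1/1000 bit; the quantized
matrix is the canonical scoring matrix. The exact distribution of the total
score of a random background word is obtained by convolving the
per-position score distributions on the integer lattice, and the hit
threshold is the smallest lattice score whose null tail probability is at
most `threshold_pvalue` (default 1e-4 per window per strand). Because
scanning scores with the same quantized matrix, the guarantee
`P(hit | background) <= threshold_pvalue` is exact, and since quantized
scores upper-bound raw scores (by at most 0.001 bit per position) it also
holds for raw log-odds scores. Both strands of every window are scored;
windows containing non-ACGT characters never hit; all passing windows are
counted (no overlap pruning — the association stage uses only the binary
presence view, so multiple or palindromic double hits are immaterial
downstream). External TF binding sites (e.g. the TF's own ChIP-seq peaks)
can replace scanning: occupancy is then the count of sites overlapping each
peak.

### Stage 3 — motif-association ranking

For each motif, peaks are split by the binary presence flag and their
normalized M compared with (i) a Welch unequal-variance t test and (ii) a
Wilcoxon rank-sum test (normal approximation, tie and continuity
corrected), each one-sided in both directions. P-values are
Benjamini-Hochberg adjusted across motifs separately within each one-sided
family, and motifs are ranked by

    score = max(q_t, q_rank)

on the requested side (right-sided for sample-1-biased binding, since
sample-1-biased peaks have positive normalized M). The max combination is
deliberately conservative: a motif must be supported by both the parametric
and the non-parametric route. Ties are broken by |t| descending, then motif
ID. Degenerate groups are handled deterministically: all-carrier or
all-non-carrier motifs return P = 1 flagged "unavailable"; zero-variance
equal-mean groups give t = 0, P = 0.5.

The traditional baseline — Fisher's one-sided exact test of motif presence
in biased vs other peaks, Haldane +0.5 odds ratios when a cell is zero, BH
across motifs — and a generic two-sided Fisher gene-set enrichment (target
vs reference within a background universe) are provided for comparison and
for promoter/expression integration. Peak-to-gene assignment uses a
strand-oriented TSS window (default 2000 bp each side, configurable);
when a gene-level M summary is needed, the assigned peak with the largest
A wins, leftmost start breaking ties. "Active promoter" genes are those
with an activating-mark peak and no repressive-mark peak at the promoter.

## Coordinates and formats

0-based half-open coordinates everywhere internally. BED (3 or 6 column) is
native; MACS-style tab tables with a header and 1-based inclusive
coordinates are converted on ingest, with the summit column read as the
0-based offset from the peak start. Reads are consumed as BED intervals
(BAM conversion is upstream of this tool); a read is counted in a peak when
its fragment midpoint — start + extension/2 on +, end − extension/2 on −,
geometric midpoint when unstranded, extension default 100 bp — falls inside
the peak. The midpoint rule makes counts exactly additive over any tiling
partition of a region. Peaks on chromosomes absent from the genome FASTA
are dropped with a logged warning.

## Synthetic data

The generator inverts the pipeline's assumptions. Chromosomes are i.i.d.
background sequence; fixed-width peaks (300 bp) are placed on a shuffled
non-overlapping slot grid away from chromosome ends. Per-peak baseline
intensity is log-normal around `mean_reads` (sigma 0.5 in log2 units,
emulating the heavy tail of real ChIP enrichment); sample 2 sees every peak
it covers at `depth_ratio` times baseline. A `planted_fraction` of sample-1
peaks (common and sample-1-unique alike — a co-factor of sample-1-biased
binding co-occurs with both) are carriers: their sample-1 intensity is
multiplied by `2^planted_m_shift` and the planted motif's consensus is
written into the genome at the peak center. Counts are Poisson (or
gamma-Poisson negative binomial); reads are 36 bp, fair-coin stranded,
placed so their 100 bp-fragment midpoints are uniform in the peak, plus a
uniform genome-wide background at 10% of peak density. Decoy motifs are
random width-8 PFMs with ~1 bit of information per position. Everything
derives from one integer seed; identical configs give byte-identical files.

What the generator does *not* emulate: fragment-size distributions, GC and
mappability bias, peak-width variation, correlated occupancy between
motifs, and continuous biological variation of true M beyond the two-level
carrier shift. Consequently, passing tests demonstrate correctness of the
statistical machinery under the stated model, not performance on real data;
in particular the attainable correlation between normalized M and the
generator's true M is bounded by the two-level truth structure (~0.85 at
the default depth), which is why recovery is asserted through the carrier
difference and the motif ranking rather than a correlation threshold.

## Numerical choices

- Score lattice 1/1000 bit, ceiling quantization (conservative: reported
  null tails upper-bound raw-score tails). Scan comparisons use a 1e-9
  float tolerance against the threshold.
- Huber IRLS falls back to the unweighted least-squares solution when the
  MAD scale collapses below 1e-12 (perfect fits, e.g. two points or M = 0).
- Fewer than 2 common peaks, or all A identical, is a hard "degenerate
  fit" error; the CLI exits non-zero.
- BH is the standard step-up, applied across motifs only, never across
  test families.
- All output tables render floats at 6 significant digits; outputs are
  written to a temp file and atomically renamed, so a failed stage leaves
  no partial table.

## Problem sizes

Defaults used throughout the tests and the acceptance script: 500 common
peaks (+50 unique per sample) for normalization recovery; 2000 peaks, 100
decoy motifs and 20 seeds for the association power and null-calibration
simulations; 1000 replicates for type-I error; complete enumeration for the
exact-test oracles (binomial totals <= 40, motif widths <= 6, Fisher tables
n <= 200, rank-sum groups <= 8). The end-to-end bundle uses a 2 x 200 kb
genome, which scanning covers in a few seconds.

## Known limitations

- Two samples only; no input/IgG correction, no spike-in normalization.
- The binomial per-peak P-value model and the max(q_t, q_rank) combination
  are this package's declared conventions; both are sealed behind their
  function interfaces so alternative models can be swapped in.
- 0-order background only for motif scanning; no de-novo motif discovery;
  JASPAR redundancy is not clustered.
- Gene-expression classes and curated annotation sets are consumed as
  given; the package supplies the enrichment machinery, not the
  annotations.
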