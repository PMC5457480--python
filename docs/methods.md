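# Methods

## The analysis problem

A segmental duplication places part of a chromosome arm in extra copies
(here: two extra copies of a repeat segment of the short arm of rice
chromosome 11, so repeat-region genes sit at 4 copies against the
diploid 2). Two questions follow:

1. **Where is the copy-number breakpoint?** Localized by qPCR on an
   ordered panel of marker genes along the arm: the relative template
   amount of each marker in the variant versus the originating line is
   estimated by the 2^−ΔΔCT method, and the boundary appears as a step
   from ratio ≈ 1 to ratio ≈ 2 between two adjacent markers.
2. **Do duplicated genes show a dosage effect or dosage compensation?**
   Answered from one control and one variant expression library
   (FPKM-like per-gene values). The per-gene ratio score
   r_g = variant/control is profiled along chromosomes (sliding-window
   medians), binned into a ratio histogram per region, and summarized
   per region as up- (r ≥ 2) and down-regulated (r ≤ 0.5) fractions.
   A ratio distribution with its mode near 2.0 indicates a proportional
   dosage effect; a mode near 1.0 indicates compensation.

## Ratio scores and classification

Ratios are defined only for genes with positive expression in both
samples. A gene expressed only in the variant is counted as up-regulated
and one expressed only in the control as down-regulated (extreme events
with no finite ratio; they enter the count summaries but not the
histograms or window profiles). "Expressed" for counting purposes means
positive in at least one sample; this keeps the per-region count table
and the both-positive ratio distributions simultaneously consistent.
Thresholds are inclusive (r ≥ 2, r ≤ 0.5) with a strict-inequality
option. Percentages are rounded half-up to two decimals using exact
decimal arithmetic, so tabulated values are reproduced digit-for-digit.

The sliding window (default 100 genes, step 1) moves over the
coordinate-ordered genes with defined ratios, per chromosome, never
spanning chromosomes; the median is the standard order statistic. The
profile is invariant to interleaving genes with undefined ratios.

Ratio histograms use right-open bins of width 0.05 with an overflow bin
at ratio ≥ 5. The compensation call takes the modal bin center (ties to
the smaller center; an overflow-dominated histogram uses the cap as a
nominal center) and flags a peak near 1.0 or 2.0 within a tolerance of
±0.10 — "a peak around a ratio of 1" is inherently qualitative, so the
tolerance is an explicit parameter.

## Region statistics

- **KS tests** (scipy): by default a region's variant expression values
  are compared against the same genes' control values, two-sided, with
  the sign of the median shift reported separately. An alternative mode
  compares a region's ratio distribution against the rest of the genome.
  The p-value uses exact enumeration when the effective sample size
  n_x·n_y/(n_x+n_y) is below 35, the asymptotic Kolmogorov distribution
  otherwise. Note the asymptotic two-sample p converges at O(n^−1/2):
  at balanced n = 100 it can differ from the exact p by a few percent in
  the mid-range (measured mean |Δp| ≈ 0.02), reaching ≈ 0.004 by n = 500.
- **Fisher's exact test** (scipy) on 2×2 up-vs-rest tables between
  regions, two-sided by the minimum-likelihood criterion; the sample
  odds ratio (ad)/(bc) is reported.
- **Binomial proportions** for cytological counts use Wilson 95%
  intervals (statsmodels), appropriate at n ≤ 30.

The test suite validates both tests against independent oracles: a
brute-force ECDF-supremum for the KS statistic and an exact-rational
hypergeometric enumeration for the Fisher p.

## qPCR quantification and breakpoint detection

ΔCT = Ct(target) − Ct(reference) within a sample; ΔΔCT = ΔCT(test) −
ΔCT(origin); relative quantity R = 2^−ΔΔCT. Replicates are averaged on
the Ct scale (cycle noise is additive there), one R per experiment, and
a marker's R is the mean over experiments with the SD as dispersion.

Breakpoint detection fits a single-step mean model to log2 R by
exhaustive scan over all n−1 changepoints (ties to the smaller index),
compared against the no-step model by BIC; a step is called only when
the two-segment model wins. Fitted levels are reported raw and snapped
(in log2 distance) to the candidate set {1.0, 2.0}, i.e. the 2:2 vs 2:4
copy interpretation. The single-changepoint model is deliberate: the
biology is one breakpoint; multi-step profiles are out of scope. SSE is
floored at 1e−12 inside the BIC so noiseless profiles are handled
without logs of zero (a noiseless step yields SSE 0 for the two-segment
model and wins; a constant profile yields SSE 0 for both and the
one-parameter model wins).

## Synthetic data: what it emulates and what it does not

The raw libraries of the motivating experiment are not public, so the
generator reproduces
the *statistical structure* the analysis assumes, with known truth:

- one control + one variant library, no replicates;
- per-region expressed-gene counts matching the reference design
  (23,604 genes; repeat region 211 expressed genes) placed at evenly
  spaced coordinates, the repeat span at 5.4–12.1 Mb of Chr11;
- control expression log-normal: natural-log mean 1.6, sd 1.5 (FPKM-like
  scale spanning orders of magnitude, median ≈ 5);
- duplicated-region multipliers: a fraction pi_dosage = 0.346 at the
  full 2× dosage, pi_compensated (default 0, as no compensation peak was
  observed) at 1×, the remainder partial in (1, 2);
- background trans-effects outside duplicated regions: up fraction
  5.55% with multipliers in (2, 4), down fraction 4.18% in (0.25, 0.5);
- multiplicative log-normal noise, sd 0.25 (no FPKM noise model is
  given for the real data; this is an assumption, not an inference);
- qPCR: 21 markers, step after marker 10 by default, levels (1, 2),
  Gaussian Ct noise sd 0.1 per well, 4 experiments × 3 replicates,
  shared reference wells per sample/experiment.

Class counts are assigned exactly (round(fraction × n) genes per class,
at random positions) rather than by Bernoulli draws, so the noiseless
dosage fraction equals pi_dosage up to integer rounding —
round(0.346 × 211)/211 = 73/211 = 34.60% exactly. Random streams are
split per component (control draws, class assignment, noise) so
enlarging one component does not perturb the others; outputs are
bit-reproducible from the seed.

What the generator does **not** emulate: count-level sequencing noise
(no negative-binomial model), gene-length and GC effects, correlated
expression along chromosomes, mappability artifacts, or biological
replicates. Passing tests therefore demonstrate correctness of the
pipeline's arithmetic and its recovery behavior under the stated noise
model — not robustness to the full error structure of real RNA-seq.

### A note on threshold-classifier bias

Under symmetric multiplicative noise, a gene at exactly 2× crosses the
inclusive r ≥ 2 threshold with probability 1/2, and partial-effect genes
cross with probability ≈ 0.19 at noise sd 0.25. The naive dosage-effect
fraction therefore estimates the *threshold-crossing probability*
(≈ 0.28 under the default conditions), not pi_dosage itself; the two
coincide only in the noiseless limit. The tests check the noisy estimate
against a quadrature oracle for this crossing probability and exact
recovery at zero noise. Interpreting an observed up-fraction as a
dosage-gene fraction on real data carries the same caveat.

## Numerical choices

- Coordinates are 1-based inclusive internally; BED is converted on
  read/write, so BED round-trips are lossless. Region membership uses
  the gene *start* coordinate only (deterministic for straddling genes);
  boundaries are inclusive. Sort order (chrom, start, gene_id) is total.
- Expression TSVs are written with shortest round-trippable float
  representations and parsed with correctly rounded conversion, so file
  round-trips preserve ratios exactly (noiseless plateaus stay exactly
  2.0 through the file-based pipeline).
- Count-matched fixtures use dyadic-rational control values and
  multipliers, making every fixture ratio exact in binary floating
  point. Simulated partial-effect multipliers can differ from the
  reconstructed ratio (variant/control) by one ulp; multipliers 1 and 2
  are exact.
- Pipeline reports contain no timestamps; re-running a configuration
  produces byte-identical outputs.

## Problem sizes

Default analyses run the full 23,604-gene genome (seconds). Monte-Carlo
checks use 200 simulated plates for breakpoint recovery and 30 seeds
for dosage-fraction recovery on a reduced genome with a full-size repeat
region; these sizes give the binomial resolution the assertions need
while keeping the suite fast.

## Known limitations

- No amplification-efficiency correction in qPCR (plain 2^−ΔΔCT), no
  melt-curve QC, single-changepoint model only.
- No replicate-based differential expression, no normalization beyond
  the input FPKM values, no multiple-testing correction (none is
  performed in the underlying design).
- The genome-wide KS p-values of the original data are not recoverable
  without the unreleased libraries; the qualitative pattern (duplicated
  region significant, others not) is validated on synthetic data.
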