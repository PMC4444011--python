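# Methods

`pausewave` implements the computational stages of a transcription-elongation
study design in which two perturbations — pharmacological CDK9 inhibition
(DRB) and siRNA depletion of hnRNP A1/A2 — are expected to act through the
same axis: reduced P-TEFb activity, promoter-proximal Pol II pausing on
dependent genes, and a slower or stalled elongation wave. This note records
the models, parameter choices and numerical decisions; every number quoted
here is recomputed by the test suite or the acceptance script, never asserted
from memory.

## Coordinates and gene models

All internal coordinates are 0-based half-open; GFF3's 1-based closed
intervals are converted at the parse boundary only. Genes with multiple
transcripts collapse to the union of their exons, and the TSS is the most
extreme annotated start (leftmost exon start on `+`, rightmost exon end on
`-`). Minus-strand genes are never rewritten: profiles are reflected about
the TSS at extraction time, which makes strand symmetry a testable identity
rather than a parsing convention. Coverage is held as contiguous fixed-width
bins with bedGraph semantics; the bin width is a run parameter (default
25 bp) because deposited ChIP densities may be per-base or binned.

## Expression stage

**RPKM.** `count / (exonic kb) / (library size in millions)`, with library
size the total of uniquely mapped reads (which may exceed the exonic column
sum).

**TMM.** Between-sample composition factors from trimmed, precision-weighted
log-ratios of library-size-scaled counts: genes zero in either sample are
dropped, the extreme 30% of M-values and 5% of A-values (each tail) are
trimmed by rank, and the factor is 2 to the delta-method-weighted mean of
the surviving M-values, with all factors rescaled to geometric mean 1. The
reference sample, when not named, is the one whose upper-quartile abundance
is closest to the cohort mean. The implementation is validated against an
independently coded loop oracle and against Bioconductor edgeR to ~1e-10.
One caveat found while testing: exact invariance to rescaling one library
holds only for the unweighted trimmed mean — the precision weights depend
weakly on depth (edgeR behaves identically), so the property is asserted at
the 2% level.

**Corrected log2 fold change.** The calling statistic is

    corrected_l2fc = sign(l2fc) * (|l2fc| + gamma^-(exp - offset))

with `gamma = 5`, `offset = 0`, and `exp` the base-10 log of the
contrast-average RPKM (floored at a pseudo-RPKM of 0.1, which also floors
numerator and denominator of the fold change). The additive term lets
weakly expressed genes clear a fold-change threshold and vanishes as
`exp -> inf`. Two genuinely open points are resolved as defaults with the
alternative exposed:

* *Sign policy.* The printed form adds a positive correction to the signed
  value, which would treat down-regulation asymmetrically; the default
  applies the correction to the magnitude with the sign restored (an odd
  function of `l2fc`), and `literal=True` reproduces the asymmetric form.
* *Threshold.* The default reactive threshold is `|corrected_l2fc| >= 1`
  (2-fold); the stricter `>= 2` reading is a parameter.

A consequence worth stating plainly: for genes with average RPKM below 1 the
correction alone exceeds 1, so at the 2-fold threshold such genes are called
reactive regardless of their measured fold change. The statistic is
deliberately liberal at low expression; downstream concordance statistics
handle this (below), and callers who want a conservative screen should use
the raw `l2fc` mode or a stricter universe.

## Overlap stage

The 2x2 partition of a declared universe (default: genes with RPKM at or
above the pseudo-floor in every sample — the universe is always an explicit,
logged choice) is tested with a Fisher exact test computed from
hypergeometric tail sums in log space via log-gamma, so p-values stay exact
for 10^4-gene universes. The default alternative is one-sided enrichment
(`greater`), since an overlap claim is inherently directional; two-sided
sums all tables with point probability at most the observed one's
(1 + 1e-7 tie guard). Concordance of effect sizes is the squared Pearson
correlation of the two contrasts' corrected log2 fold changes over shared
reactive genes; by default only shared genes with a raw 2-fold change in
both contrasts enter the correlation — genes admitted purely through the
low-expression correction carry mostly counting noise and would otherwise
dilute R^2 toward zero.

## Pausing stage

Profiles are TSS-anchored, strand-oriented, binned means over a span of
5 kb (default; chosen to stay promoter-proximal and avoid 3'-end effects).
The pausing index is mean promoter density over `[0, W)` divided by mean
body density over `[W, span)`, with `W = 500` bp by default and 175 bp as
the common narrower extent; a zero body yields an undefined (NaN) index,
never infinity. Library scaling divides densities by the per-sample total
of uniquely mapped reads and cancels in the index itself. Classification of
a treated-vs-control pair uses promoter and body fold changes:
`paused_repressed` requires a promoter gain of at least 1.5x with no body
gain (body fold change at most 1), `stimulated` requires both regions to
gain at least 1.5x, `unchanged` requires both within [1/1.5, 1.5]. The
boundaries are parameters, not claims about any particular gene list: the
published per-gene extents are figure annotations, so the classifier is
exercised against planted synthetic cohorts instead.

## Elongation stage

The recovery of pre-mRNA signal after inhibitor washout is modeled as a
propagating wave:

    S(x, t) = plateau * (b + (1 - b) * clamp((t - x/v) / tau, 0, 1))

with rate `v` (kbp/min), fill time `tau` (min) and residual baseline
fraction `b`. Each position's recovery is summarized by `t50`, the first
crossing of `baseline + 0.5 * (plateau - baseline)`, located by linear
interpolation between bracketing time points after replicate averaging;
baseline is the first time point's signal and the plateau is the mean of
the final two points (both windows configurable, and an external plateau —
e.g. the control condition's — can be supplied so that non-recovering
positions return the no-recovery sentinel instead of a spurious early
crossing). On the wave model `t50(x) = x/v + tau/2` exactly, so ordinary
least squares of position (kbp) on `t50` (min) returns slope `v` and time
intercept `tau/2`: the estimator validates itself on noiseless data. That
identity requires the time grid to resolve the linear ramp (spacing at most
`tau/2`); on coarser grids the interpolated chord crosses the clamp kinks
and picks up a bounded bias (about 2% of the rate on the default 5-minute
grid — well inside the noise-level tolerance, which is why the default grid
is kept for rate estimation while exactness checks use a 2-minute grid).

Positions that never recover are excluded from the fit but reported — that
is the expected phenotype of the depleted condition at distal positions,
not an error. Condition comparison reports per-position treated/control
signal ratios and a one-sided Welch t-test on per-replicate end-point
recovery, Holm-adjusted across positions (family-wise error 0.05).

**Bootstrap CI.** With only three replicates an analytic slope CI would
lean on strong assumptions, so the 95% CI resamples replicates within each
position (1000 draws, seeded) and takes percentiles, with two small-sample
corrections applied to the deviations around the point estimate: the
bootstrap of an n-replicate mean underestimates its variance by
`(n-1)/n` (inflate by `sqrt(n/(n-1))`), and the percentile interval behaves
like a z-interval although replicate noise is estimated on few degrees of
freedom (inflate by `t_{0.975, P*(n-1)} / z_{0.975}`, with `P` positions).
Both corrections are standard and fixed, not tuned; empirical coverage of
the true simulator rate is checked by the acceptance suite.

## qPCR helpers

`ddcq_fold_change` is `efficiency^-ddCq` with multiple references combined
as the geometric mean of their quantities (equivalently the arithmetic mean
of their Cq values); it is exactly reciprocal under swapping test and
control. `percent_of_input` is
`100 * input_fraction * efficiency^(Cq_input - Cq_ip)`, with optional
subtraction of a no-antibody background percent; values above 100% are
carried with a warning, never clipped. Reference normalization of
time-courses divides the target quantity by the geometric mean (default;
arithmetic available) of the reference-gene quantities at the same time
point, and a missing reference is an error naming gene and time point.

## What the generators emulate — and what they do not

* `simulate_counts` plants the three-condition design with one library per
  condition (the study sequenced no RNA-seq replicates; replicates are
  supported but default to 1). Mock means are lognormal, median 100 counts,
  log10 sd 1 (roughly four decades over +/-2 sd), negative-binomial size 50.
  Responder fractions are 3% shared, 3% DRB-only, 2% depletion-only, so the
  shared fraction of the depletion set sits near the published ~0.5–0.6
  regime; shared responders receive bivariate-normal log2 effects (sd 2)
  correlated at 0.83, the R^2 ~ 0.69 regime. Not emulated: batch effects,
  GC/length bias, isoform structure, and any dependence between genes —
  passing tests show the estimators recover planted structure, not that
  real libraries behave this way.
* `simulate_chip_coverage` plants step-function promoter/body densities
  (2.0 / 0.5 reads per bp, promoter gain 2x, body loss 0.5x for paused
  genes) with Poisson noise per 25-bp bin. Real Pol II profiles taper
  rather than step, and background, mappability and fragment-length effects
  are absent.
* `simulate_recovery` uses the clamped-ramp wave with multiplicative
  lognormal noise (CV 0.1 by default — qPCR error is multiplicative; the
  source assay states no noise model). The exact amplicon grid of the
  long-gene assay is not printed in the main text, so the default grid is
  synthetic: every 10 kb from +854 bp (the printed proximal amplicon) to
  +80.9 kb (an ~87-kb-gene scale), times 0–60 min every 5 min, triplicates.
  Pre-mRNA degradation, co-transcriptional splicing and position-dependent
  primer efficiency are not modeled.

All generators are bit-reproducible under a fixed seed.

## Problem sizes

The shipped checks use 10^4-gene count matrices (20 seeded runs for the
concordance suite), a 500-gene ChIP cohort (100 paused / 100 stimulated /
300 null), exhaustive Fisher enumeration to universe size 50, and 200
seeded elongation runs with 1000 bootstrap draws each — sizes at which
every stochastic acceptance band was chosen, and which keep the whole suite
in the minutes range on one CPU.

## Known limitations

* The corrected statistic's low-expression liberality (above) is inherent
  to the published formula; the package documents and exposes it rather than
  masking it.
* The pausing classifier assumes a single promoter window per run; genes
  with unusually wide or narrow pause regions are classified against the
  common window.
* `t50` takes the *first* half-plateau crossing; heavy-tailed noise spikes
  before the wave front could in principle trigger it early (not observed
  at the default CV, and guarded by replicate averaging).
* The Fisher p-value underflows to exactly 0 below ~1e-308; callers needing
  log-p at that extreme should use the tail helper directly.
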