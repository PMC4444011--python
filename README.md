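# pausewave

Analysis toolkit for transcription-elongation studies built around RNA
polymerase II promoter-proximal pausing: differential expression with a
low-expression-corrected fold-change statistic, treatment-concordance
overlap statistics, Pol II pausing profiling from ChIP coverage, and
elongation-rate estimation from inhibitor-release (DRB washout) pre-mRNA
time-courses. Every stage ships with a seeded synthetic-data generator, so
the whole pipeline is exercisable end to end with no external data.

It is written for computational biologists analyzing designs in which two
perturbations (e.g. a CDK9 inhibitor and the depletion of a pausing-release
factor) are expected to act through the same elongation axis, and who need
the supporting arithmetic — RPKM, TMM normalization, Fisher exact overlap,
pausing indices, t50 wave fits, delta-delta-Cq — under one tested roof.

## The statistics at the core

**Corrected log2 fold change.** A gene's contrast score is

```
corrected_l2fc = sign(l2fc) · (|l2fc| + γ^−(exp − offset))
```

with `γ = 5`, `offset = 0`, and `exp = log10` of the contrast-average RPKM
(pseudo-floored). The additive term lets weakly expressed genes clear a
fold-change threshold and vanishes for well-expressed genes; a gene is
*reactive* when `|corrected_l2fc| ≥ 1` (2-fold, default) against the
untreated sample. Fold changes are computed on TMM-rescaled RPKM.

**Concordance.** Reactive sets of two treatments over an explicit gene
universe are partitioned (Venn), tested for overlap enrichment with a
one-sided Fisher exact test (hypergeometric tails summed in log space), and
their corrected fold changes correlated (Pearson R²) over the shared genes
with a genuine 2-fold change.

**Pausing.** Per gene, the pausing index is PI = mean Pol II density over
the first 500 bp downstream of the TSS divided by the mean gene-body
density (strand-aware, library-scaled). A treated/control promoter gain
≥ 1.5× without a body gain classifies a gene `paused_repressed`; joint
promoter+body gain is `stimulated`.

**Elongation rate.** After washout of an elongation block, signal at
position *x* recovers once the polymerase wave arrives at *x*/*v* minutes.
Each position's half-plateau crossing time t50 is located by linear
interpolation; ordinary least squares of position (kbp) on t50 (min) gives
the rate *v* in kbp/min (on the wave model, t50(x) = x/v + τ/2 exactly),
with a replicate-resampling bootstrap CI.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

```python
from pausewave import (WaveSimParams, simulate_recovery,
                       fit_elongation_rate)
from pausewave.elongation import estimate_recovery_time

tc = simulate_recovery(WaveSimParams(seed=1))   # default 2.3 kbp/min wave
t50 = [estimate_recovery_time(tc, p) for p in tc.positions]
fit = fit_elongation_rate(tc.positions, t50, timecourse=tc,
                          n_boot=1000, seed=1)
print(f"{fit.slope_kbp_per_min:.2f} kbp/min, CI {fit.ci_slope}")
```

Running `python examples/04_elongation_rate.py` prints (seed 1):

```
position (bp) ->  t50 (min)
     854          2.56
   10854          7.32
   ...
   80854         37.49
elongation rate: 2.35 kbp/min (95% CI 2.31-2.38), R^2 = 0.9982
time intercept:  2.39 min (= half the fill time on the wave model)
```

The nine positions' recovery times line up on a straight line whose slope
recovers the simulated 2.3 kbp/min rate within noise; the time intercept
estimates half the fill time (τ/2 = 2 min). The script then halves the
distal signal of a second condition and shows the per-position deficit
report flagging exactly the distal positions — the expected phenotype of
impaired elongation with intact initiation.

The other example scripts cover reactive-gene calling
(`01_reactive_genes.py`), treatment concordance with Fisher p and R²
(`02_treatment_concordance.py`), pausing classification on a planted
cohort (`03_pausing_profiles.py`) and the qPCR helpers
(`05_qpcr_helpers.py`). A thin CLI mirrors the library
(`pausewave --help`).

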