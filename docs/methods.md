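# Methods

This note records the statistical models, the defaults and why they were
chosen, what the synthetic generators do and do not emulate, and the
numerical edge-case rules. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Interaction scoring

BioID spectral counts are treated as Poisson per run. A prey in one
bait-condition is summarized by its summed bait-run counts `s_b` (over
`n_b` runs) and summed control-run counts `s_c` (over `n_c` runs); per-run
factorial terms cancel between hypotheses and are dropped.

Two generative components:

* **Background (contamination/carry-over).** A single rate shared by bait
  and control runs, drawn from Gamma(a₀, b₀). The prior is fitted by
  moments across all preys' per-run control rates, with the rate variance
  floored at mean²/50 so the prior never carries more than ~50 pseudo-runs
  of weight. This is the empirical-Bayes element: the model knows what
  typical contamination looks like, so a low-count prey that happens to
  show zero in two control runs is not mistaken for a strong interactor.
* **Interaction.** Controls keep the contaminant prior; bait runs draw an
  independent rate from a diffuse Gamma(0.5, 0.02) (prior mean 25
  counts/run, prior weight 0.02 runs). The diffuseness is an Occam factor:
  the component is only rewarded when the bait counts genuinely demand
  their own rate.

Both marginal likelihoods are conjugate closed forms. The mixture weight
π (the fraction of genuine interactions among scored preys) is estimated
by EM, clipped to [0.001, 0.5]. The reported confidence is

    prob = P(interaction | data) × P(λ_bait > λ_ctrl | data),

where the directional factor has the closed Beta-tail form
`P(Beta(s_b+a₁, s_c+a₀) > (n_b+b₁)/(n_b+b₁+n_c+b₀))`. The product keeps
enrichment directional: a prey depleted in bait runs can win the
interaction component on likelihood but is suppressed by the tail factor.

On tables with fewer than 50 preys the mixture weight and contaminant
prior cannot be estimated stably; the scorer falls back to π = 0.5 (equal
priors) and the weak Gamma(pseudo_rate, 1) prior for both components
(`pseudo_rate` default 0.1). Under that fallback the smoothed control
rate is exactly `(s_c + pseudo_rate)/(n_c + 1)`. Consequences worth
knowing: counts exactly equal to the controls score ≤ 0.5; strong
enrichment over empty controls scores near 1; and prob is monotone
non-decreasing in the bait counts at fixed controls (checked as a property
test over count grids).

**BFDR.** SAINT convention: rank by decreasing prob (ties broken by higher
average count, then prey name, for determinism), then
`BFDR(k) = mean over top-k of (1 − prob)`. Because the summand is
non-decreasing along the ranking the BFDR is non-decreasing by
construction (asserted on every call). Because prob is an honest
posterior — the mixture weight is estimated rather than fixed at 1/2 —
gating at BFDR ≤ α controls the expected false-discovery proportion near
α; the acceptance script measures the realized proportion at the 1% gate
(pooled over 20 simulation seeds, since an FDR is an expectation and
single-draw proportions fluctuate).

**Replicate QC.** Squared Pearson correlation of per-prey counts for every
pair of runs of a condition, over the union of preys (absent = 0), on raw
counts (no transform is prescribed for this gate). Pass at mean R² > 0.9.
Anti-correlated pairs (r < 0) still contribute r² but are flagged in the
report. A constant run (zero variance) has undefined correlation and is
scored r² = 0 unless the two runs are identical (then 1).

## Differential analysis

* **Bait normalization.** Spectral counts scale with the abundance of the
  tagged bait itself (a destabilized mutant bait yields globally fewer
  counts; proteasome inhibition roughly doubles mutant self-counts), so
  condition `c` is rescaled by `self(ref)/self(c)` using the bait gene's
  mean self-counts. Multiplying a condition's counts and its self-count by
  one constant is a no-op (tested). High-confidence sets are taken from
  scoring the raw counts; BFDR is not recomputed after scaling, because
  rescaling all counts of a condition by a constant would alter the
  Poisson model's evidence without adding information.
* **Fold change.** `log2((alt + 0.5)/(ref + 0.5))`. The 0.5 pseudocount is
  a common spectral-count convention and keeps presence/absence calls
  finite; boundary values exactly at ± the threshold count as gained/lost.
* **Pairwise classes** operate on preys high-confidence in at least one of
  the two conditions (others are excluded with a warning); this matches
  working on the high-confidence networks. Antisymmetry under condition
  swap is exact because the fold change only changes sign.
* **Triplet classes** (WT, mutant, mutant+drug), in order of precedence:
  *restored* — in the WT high-confidence set, lost in the mutant (not high
  confidence there, or down ≥ threshold in log2), and high confidence
  under drug; *attenuated* — up ≥ threshold in mutant vs WT and down ≥
  threshold under drug vs mutant; *non-responsive* — up ≥ threshold in the
  mutant and |drug effect| < threshold; *other* otherwise. Precedence
  makes the labels single-valued, so restored ∩ attenuated = ∅ by
  construction (asserted). "Elevated in the mutant" is defined as
  log2FC(mut vs WT) ≥ +threshold, mirroring the attenuated clause.
* **Volcano statistics.** Welch (unequal-variance) t-test on log2(count+1)
  across replicate runs — the safer default when only "Student's t-test"
  is prescribed; the effect size is the difference of condition means on
  the same scale. Zero variance in both groups: p = 1 if the means agree,
  else p is floored at the machine minimum with a warning. Flags at
  log2FC ≥ +0.4 (green) / ≤ −0.4 (red). Raw p-values are reported (the
  plot convention); BH q-values are computed separately in the enrichment
  module.
* **Over-representation.** One-sided hypergeometric tail per category
  against a user-supplied annotation file (two-column or GMT), with BH
  q-values alongside. This is a generic stand-in for external GO services;
  no term hierarchy propagation.

## Localization profiling

Set-based Jaccard distance between the query's high-confidence prey set
and each marker bait's prey set, after removing an optional user-supplied
exclusion list from both sides (mirroring the manual removal of preys with
no curated function). Markers are ranked ascending with lexicographic
tie-break. A weighted (min/max) variant is available for quantitative
profiles but set-based is the default, matching the "prey profile"
convention. The distance is a metric on sets; symmetry and the triangle
inequality are property-tested on random triples.

## Imaging

* Background per channel = centre of the most populated histogram bin
  (bin width 1 intensity unit by default; for integer data this is the
  modal pixel value, ties to the lowest bin) over a demarcated cell-free
  region, or the whole image when no region is supplied — valid when
  cells cover a minority of pixels, which the generator guarantees and
  real fields should be checked for. Regions under 100 pixels are
  rejected. Dark noise is absorbed into the background term; no separate
  camera offset is subtracted.
* Thresholding keeps pixels with `(value − background) > k × background`
  and carries the background-subtracted values; "k× over background" is
  read as above-background (the alternative raw-value reading
  `value > k × background` is a one-line change in `threshold_channel`).
  Defaults k = 7 (surface) and 20 (total), each relative to its own
  channel's background. A zero background makes the cutoff vacuous and
  warns.
* One ratio per field = mean(retained surface)/mean(retained total) — the
  ratio of channel means, not a mean of pixelwise ratios. A field where
  either channel retains nothing is invalid and excluded with a warning.
* Aggregation hierarchy pixels → field → experiment → condition.
  Normalization to control and the two-sided Student t-test are done on
  experiment-level means (n = experiments, typically 3), matching the
  error-bar convention of replicated imaging experiments; the control
  condition normalizes to exactly 1.

## FLIPR traces

F0 is the mean fluorescence over the first 180 s (the 3-minute baseline
read; configurable, must end by the agonist addition, ≥ 3 samples).
ΔF/F0 = (F − F0)/F0 is exactly invariant to rescaling the raw trace. The
peak is the raw maximum sample in (agonist, inhibitor] — no smoothing by
default; a moving-average width is available for noisy traces. The
post-inhibitor level is the mean over the final 20% of post-inhibitor
samples (the trace has settled there under the generator's time
constants), and the inhibitor-sensitive fraction is (peak − post)/peak: 1
for a fully channel-dependent response, ≈ 0 for an inhibitor-insensitive
one. Non-positive peaks flag the trace as "no agonist response" (the
uninduced/trafficking-dead phenotype) rather than erroring.

## Synthetic generators

* **Counts.** Conditions WT, dF508, dF508+Orkambi with bait self-counts
  100/50/50 (the mutant bait is half as abundant, so normalization is
  exercised); 2 biological × 2 technical replicates per condition and 2
  control runs. 60 true preys with base rates uniform on 10–80 counts/run
  — the range of a typical high-confidence BioID prey, and high enough
  that default tables pass the replicate-QC gate by construction — and
  600 background contaminants at 2 counts/run in every run including
  controls. True preys are absent from controls by default. Planted
  effects multiply rates by 2^log2FC; the default scenario plants, at
  |log2FC| = 3: 10 gained, 10 lost, and 10 each of
  restored/attenuated/non-responsive triplets (10 preys stay flat). Runs
  of one biological replicate share a lognormal(sd 0.2) rate multiplier,
  inducing realistic between-replicate correlation. Not emulated: peptide
  identification, run-order effects, prey-specific detectability, or
  compositional competition between preys — so passing tests show the
  statistics are right under the stated model, not that any MS pipeline
  upstream is.
* **Images.** Non-overlapping disk cells (radius 8 px on a 192×192 field,
  30 cells ≈ 16% coverage) with interior intensity 8000 in the total
  channel and a 2.5 px membrane annulus at ratio × 8000 in the surface
  channel, over background 100, optional Poisson shot noise, and a
  cell-free mask. The constructed per-field ratio equals the configured
  truth exactly in the noise-free case. Not emulated: PSF blur, uneven
  illumination, cell-to-cell expression variability.
* **Traces.** Flat baseline (level 1000), first-order rise (τ = 20 s)
  after the agonist at 180 s to baseline × (1 + amplitude), exponential
  decay (τ = 30 s) after the inhibitor at 480 s toward
  baseline × (1 + amplitude × residual), Gaussian noise sd 0.01 × baseline,
  sampled every 10 s (a typical kinetic plate-read interval) for 720 s.
  Truth peak = amplitude × (1 − e^−300/20) ≈ amplitude; truth fraction =
  1 − residual up to the same rise-shortfall correction.

All generators are deterministic given their seed.

## Problem sizes in tests and acceptance

The acceptance script uses 20 seeds × 3 conditions for scoring
calibration (~3 100 gated interactions), 10 seeds for differential
recovery (~500 planted gained/lost calls, 300 trio labels), 100 random
lists for the BFDR oracle, 500 preys for the volcano null, 100 seeds for
marker recovery, 3 × 20 seeds × 25 fields for imaging, and 20 traces for
FLIPR — sizes at which the measured proportions are stable to well inside
the tolerances being checked, while the whole script runs in tens of
seconds.

## Known limitations

* The scorer is a documented stand-in, not SAINTexpress: it reproduces the
  qualitative behavior (enrichment over controls → prob near 1, honest
  FDR at the 1% gate) but will not match SAINT scores numerically.
* With only two control runs the contaminant prior leans heavily on the
  cross-prey moment fit; tables whose contamination is strongly
  prey-specific (e.g. sticky beads for one protein family) violate the
  exchangeability this assumes.
* Technical and biological replicates are treated as exchangeable at
  scoring time (the alternative — averaging technical replicates first —
  halves n and was not prescribed); the QC report is the place where
  replicate structure problems surface.
* The imaging module is field-level, not cell-level: no segmentation, no
  per-cell statistics, no nuclear-count normalization.
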