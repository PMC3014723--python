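# Methods

## The protocol being modelled

Terrestrial invertebrate samples from pan and pitfall traps routinely hold
hundreds to thousands of specimens. `subtray` models a fixed-area laboratory
subsampling workflow built around a circular turntable plate (22.9 cm inner
diameter, 412 cm²) fitted with a 2.54 cm square grid. The grid yields 45
complete cells; expressed in cell areas the whole plate holds 63.6
cell-equivalents, which is the estimator's extrapolation multiplier. The
partial cells along the wall are never counted, so the model pools them into
a single "edge" region of 63.6 − 45 = 18.6 cell-equivalents.

Processing has three phases:

1. **Sieve.** The sample is passed through a 4 mm mesh; retained large
   specimens are counted and identified exhaustively. The model treats this
   phase as lossless.
2. **Subsample.** The remainder is spread evenly on the plate and k cells
   (16 by default, 25% of the plate) are drawn uniformly without replacement
   and counted. Each individual in a counted cell is seen independently with
   its taxon's `p_detect_cell`; misses stay on the tray.
3. **Quick scan.** The uncounted remainder is scanned for taxa not yet seen.
   A taxon with m undetected individuals anywhere on the tray is noticed
   with probability 1 − (1 − q)^m, with q its per-individual scan
   probability. The scan records presence only: it feeds richness, never
   abundance.

The plug-in abundance estimator is (observed total / k) × 63.6 for the
on-tray portion, plus the phase-1 count. Percent accuracy divides the
extrapolated phase-2 estimate by the true on-tray count (total minus the
sieve pool) × 100. Taxa richness is the union over the three phases.
A decision rule flags sparse trays: if the mean count per cell after 10
cells is below 4 (≈ 250 individuals per plate), full counting is
recommended instead of extrapolation.

The multiplier 63.6 is stored as a configurable constant rather than
derived: the raw quotient 412/6.45 ≈ 63.9 differs slightly from the
published working value because both areas are rounded, and the working
value is what the estimator uses. All geometry fields can be overridden for
other trays.

## Synthetic communities

No field samples are distributed, so the package ships a generator that
reproduces their statistical structure, plus six calibrated presets —
`{pan,pitfall}_{low,moderate,high}`:

* **Sample totals** are drawn log-uniformly over each category's envelope
  (pan: 122–237, 286–375, 676–5,337; pitfall: 93–164, 314–384, 504–813).
  Log-uniform is the least-informative choice for ranges spanning an order
  of magnitude; only the ranges are known.
* **Rank-abundance structure** is a deterministic lognormal: taxon weights
  are lognormal quantiles at ranks (i − ½)/T, so a preset community is
  identical in every run. The lognormal σ is calibrated per preset so the
  expected number of taxa present at the category's mean total matches the
  category's mean richness (pan, 30 taxa: σ = 2.577, 2.679, 3.190 for
  13.6, 15.5, 18.7 expected taxa; pitfall, 43 taxa: σ = 2.540, 2.804,
  2.657 for 15.4, 18.6, 23.7). A single σ per trap type cannot match all
  three category means simultaneously, so each preset is its own community.
  Individual samples spread well beyond these means — that is a property of
  multinomial sampling, not a calibration error.
* **Sieve fractions.** Large-bodied taxa (carabids, grasshoppers, crickets,
  odonates, …) carry `large_fraction` 0.3–0.9; everything else 0. The sieve
  split is binomial thinning, so the two portions always sum to the truth.
* **Detection.** Default `p_detect_cell` is 1. Five small, pale taxa
  (aphids, spittlebugs, spiderlings, springtails, thrips) get
  `p_detect_cell` = 0.7 and scan probability 0.05; all other taxa get scan
  probability 0.5 per remaining individual. These values are calibrated,
  not measured: with them the simulated three-phase detection lands at
  81–91% across the six presets, matching the published per-category range,
  and the flagged taxa dominate the miss table as reported for small pale
  specimens.
* **Spatial placement.** Individuals land in regions (45 cells + edge) with
  probability proportional to area — the "evenly brushed" assumption. A
  Dirichlet-multinomial clustered mode (`clustering_theta`, concentration
  spread over the area weights; ∞ = uniform) is provided as a sensitivity
  knob: clustering leaves the estimator unbiased but widens its confidence
  intervals. The default is uniform because even spreading is part of the
  protocol, not an empirical claim about unbrushed trays.

## Monte-Carlo evaluation

`run_evaluation` simulates n samples, runs the protocol once per sample
with an ordered 16-cell selection, and evaluates the estimator on nested
prefixes k = 1..16 — matching how effort curves are produced at the bench
and yielding smooth, positively correlated curves across k. Per (category,
k) it reports the mean, SE and normal 95% CI (mean ± 1.96·SE) of percent
accuracy and percent richness, the quick-scan increment at k = 16, and a
per-taxon miss-frequency table (fraction of samples containing the taxon in
which all three phases missed it; taxa never present are reported as NaN,
not 0). Samples whose on-tray truth is empty have undefined accuracy; they
are excluded and counted. CI non-overlap (shared endpoints count as
overlap) is the significance convention.

Default problem size is 1,000 replicates per preset, which resolves the
mean accuracy to roughly ±0.2–0.7 percentage points (SE) depending on the
preset and runs in a few seconds.

## Numerical and design choices

* Category boundaries are literal: < 250 low, 250–500 moderate (both
  endpoints), > 500 high. The full-count rule is literal too: mean = 4.0
  proceeds with estimation.
* Percent accuracy is defined on the phase-2 portion only; a clearly
  labelled whole-sample variant (`total_percent_accuracy`) is provided as a
  convenience but is not the published statistic.
* Accuracy is the mean of per-sample ratios (each sample's percent accuracy
  averaged across replicates), not a ratio of pooled counts, matching how
  per-sample means with CIs are presented.
* Random state is a NumPy `Generator`; a config seed reproduces a
  realization bit for bit, and multi-preset runs derive independent child
  seeds via `SeedSequence.spawn`.
* Stochastic tests use 3-SE/3-SD tolerances at stated replicate counts;
  joint per-cell checks widen to 4 SD (Bonferroni over 45 cells).

## What the simulator does and does not show

Passing tests demonstrate the estimator's design properties — unbiasedness
under even spread, precision plateauing beyond ~10 cells, concave richness
accumulation with a quick-scan boost, higher relative error in sparse
samples — under communities whose totals, richness, and detection rates
match the published envelopes. They do not reproduce the empirical field
accuracies (e.g. the ~20% overestimation of sparse pitfall samples), which
belong to undeposited samples and have no stated mechanism; hypothesised
mechanisms (clumping, edge-density deficits) can be explored via
`clustering_theta` but are not asserted as the cause. Processing-time
comparisons are out of scope entirely. Real tally sheets can be fed through
the same estimators via the documented CSV format, skipping all detection
modelling.
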