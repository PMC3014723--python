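# subtray

Fixed-area laboratory subsampling of terrestrial invertebrate samples:
simulation, estimation, and sampling-design evaluation.

Pan and pitfall traps routinely capture hundreds to thousands of
invertebrates per sample, and counting everything is what makes community
and biodiversity studies expensive. `subtray` implements a three-phase
gridded-tray subsampling protocol and the statistics built on it, for
ecologists and entomologists who want to know **how many cells are enough**
before committing a lab season:

1. **sieve** — large specimens retained on a 4 mm mesh are counted in full;
2. **subsample** — k random cells of a 45-cell grid (16 by default, 25% of
   the plate) are counted under the microscope;
3. **quick scan** — the remainder is swept for taxa not yet seen
   (presence only).

The abundance estimator is the plug-in extrapolation

```
N̂ = (observed total / k) × E + L
```

where `E` = 63.6 is the plate area in cell-equivalents and `L` the sieve
count. Percent accuracy is `100 × N̂₂ / N₂` (phase-2 estimate over true
on-tray count); taxa richness is the union over the three phases. A
decision rule recommends full counting when the mean is < 4 per cell after
10 cells (≈ 250 individuals per plate).

Because the original field samples are not public, the package ships a
calibrated synthetic-community generator (six presets spanning 93–5,337
individuals and 13.6–23.7 mean taxa per sample, with sieve-retained and
hard-to-see taxa) and a Monte-Carlo engine that evaluates accuracy,
precision, and richness recovery as functions of subsampling effort
(k = 1..16), stratified by abundance category. Real tally sheets in the
documented CSV format run through the same estimators.

## Worked example

```python
import numpy as np
from subtray import (preset, draw_sample, run_protocol,
                     percent_accuracy, taxa_richness)
from subtray.estimators import estimate_abundance

rng = np.random.default_rng(42)
community = preset("pitfall_high")          # calibrated trap preset
sample = draw_sample(community, rng=rng)    # ground-truth tray
result = run_protocol(sample, k=16, rng=rng)
est = estimate_abundance(result)

print(sample.true_total, sample.true_phase2_total)
print(round(est.mean_per_cell, 2), round(est.total_estimate, 1))
print(round(percent_accuracy(est.phase2_estimate, sample.true_phase2_total), 1))
print(taxa_richness(result), sample.true_richness)
```

prints

```
730 724
10.06 646.0
88.4
20 22
```

— a high-abundance pitfall sample with 730 individuals (724 on the tray
after sieving out 6 large specimens) whose 16-cell count of 10.06 per cell
extrapolates to 646 individuals, an 88.4% accuracy score for this single
draw (under 100% = underestimate), with 20 of 22 taxa recovered by the
three phases.

Design evaluation, aggregated over 1,000 simulated samples:

```python
from subtray import run_evaluation
s = run_evaluation(preset("pitfall_high", perfect_detection=True),
                   n_reps=1000, seed=0)
print(s.summary())
```

```
category: high  (n = 1000)
  k  accuracy%             95% CI  richness%             95% CI
  1       99.2 [   97.1,   101.2]       32.3 [   31.9,    32.8]
  4      100.2 [   99.2,   101.2]       50.2 [   49.7,    50.7]
 10       99.9 [   99.3,   100.5]       66.1 [   65.6,    66.6]
 16       99.7 [   99.2,   100.1]       74.8 [   74.3,    75.3]
  quick scan at k=16: +5.98 taxa -> 100.0% of true richness
```

(excerpt) — the estimator is unbiased at every k and the CI stops narrowing
appreciably beyond ~10 cells, which is the basis for the 10-cell
recommendation.

## Command line

```sh
subtray simulate --preset pan_moderate --n-samples 10 --seed 5 --out run/
subtray protocol --truth run/truth.csv --preset pan_moderate --k 16 --seed 6 --out run/
subtray estimate --tally run/tally.csv --truth-summary run/truth_summary.csv --out run/estimates.csv
subtray evaluate --preset pan_high --reps 1000 --kmax 16 --seed 42 --plots --out eval/
```

All outputs are CSV/PNG with a provenance header (version, config hash,
seed); every option can come from a YAML `--config` file.

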