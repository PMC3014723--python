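"""Monte-Carlo evaluation of the subsampling design.

For each simulated sample one ordered 16-cell (generally ``k_max``-cell)
selection is drawn and the estimator is evaluated on its nested prefixes
k = 1..k_max — exactly what a technician produces by counting cells one at a
time. Replicates are aggregated into per-k means, standard errors, and normal
95% confidence intervals (mean ± 1.96·SE) of:

* percent accuracy of the phase-2 abundance estimate, and
* percent taxa richness (phase-1 taxa plus taxa seen in the first k cells),
  with the phase-3 quick-scan increment reported at k_max,

stratified by abundance category, plus a per-taxon miss-frequency table (the
fraction of samples containing a taxon in which all three phases failed to
detect it).

Samples whose on-tray truth is empty have no defined percent accuracy; they
are excluded and counted in ``n_excluded_empty``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import CommunityConfig, draw_sample, preset
from .estimators import classify_abundance, percent_accuracy
from .geometry import TrayGeometry
from .protocol import run_protocol

__all__ = [
    "EvaluationSummary",
    "run_evaluation",
    "accuracy_curve",
    "richness_curve",
    "taxon_missrate_table",
    "ci_nonoverlap",
    "evaluate_presets",
]

Z95 = 1.96  # normal 95% CI half-width in SE units


@dataclass
class EvaluationSummary:
    """Aggregated Monte-Carlo results for one community preset.

    ``curves`` has one row per (category, k) with columns
    ``n, accuracy_mean, accuracy_se, accuracy_sd, accuracy_ci_low/high,
    richness_mean, richness_se, richness_ci_low/high`` and, on the k = k_max
    row only, ``scan_gain_taxa`` (mean extra taxa found by the quick scan)
    and ``richness_with_scan_mean/se/ci_*`` (three-phase percent richness).

    ``miss_rates`` has one row per taxon with ``n_present, n_missed,
    miss_rate`` (NaN where the taxon never occurred).
    """

    preset: str
    curves: pd.DataFrame
    miss_rates: pd.DataFrame
    n_reps: int
    k_max: int
    n_excluded_empty: int = 0
    seed: int | None = None

    def accuracy_ci(self, k: int, category: str | None = None
                    ) -> tuple[float, float]:
        row = self._row(k, category)
        return float(row["accuracy_ci_low"]), float(row["accuracy_ci_high"])

    def ci_width(self, k: int, category: str | None = None) -> float:
        lo, hi = self.accuracy_ci(k, category)
        return hi - lo

    def _row(self, k: int, category: str | None = None) -> pd.Series:
        df = self.curves
        if category is not None:
            df = df[df["category"] == category]
        df = df[df["k"] == k]
        if len(df) != 1:
            raise KeyError(f"no unique row for k={k}, category={category}")
        return df.iloc[0]

    def summary(self) -> str:
        """Human-readable per-k table, one block per abundance category."""
        lines = [f"Subsampling evaluation - preset {self.preset!r}, "
                 f"{self.n_reps} replicates"
                 + (f", seed {self.seed}" if self.seed is not None else "")]
        if self.n_excluded_empty:
            lines.append(f"  ({self.n_excluded_empty} samples with empty "
                         "phase-2 truth excluded)")
        for cat, block in self.curves.groupby("category", sort=False):
            lines.append(f"\ncategory: {cat}  (n = {int(block['n'].iloc[0])})")
            lines.append(f"{'k':>3} {'accuracy%':>10} {'95% CI':>18} "
                         f"{'richness%':>10} {'95% CI':>18}")
            for _, r in block.iterrows():
                lines.append(
                    f"{int(r['k']):>3} {r['accuracy_mean']:>10.1f} "
                    f"[{r['accuracy_ci_low']:>7.1f},{r['accuracy_ci_high']:>8.1f}] "
                    f"{r['richness_mean']:>10.1f} "
                    f"[{r['richness_ci_low']:>7.1f},{r['richness_ci_high']:>8.1f}]")
            last = block[block["k"] == self.k_max].iloc[0]
            if np.isfinite(last.get("richness_with_scan_mean", np.nan)):
                lines.append(
                    f"  quick scan at k={self.k_max}: "
                    f"+{last['scan_gain_taxa']:.2f} taxa -> "
                    f"{last['richness_with_scan_mean']:.1f}% of true richness")
        return "\n".join(lines)


def _agg(values: np.ndarray) -> tuple[float, float, float]:
    """(mean, se, sd) of a replicate vector."""
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else float("nan")
    se = sd / np.sqrt(len(values))
    return mean, se, sd


def run_evaluation(community: CommunityConfig,
                   geometry: TrayGeometry | None = None,
                   k_max: int = 16,
                   n_reps: int = 1000,
                   rng: np.random.Generator | None = None,
                   seed: int | None = None) -> EvaluationSummary:
    """Simulate ``n_reps`` samples and aggregate the nested-prefix curves."""
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if geometry is None:
        geometry = TrayGeometry()
    if not 1 <= k_max <= geometry.n_complete_cells:
        raise ValueError("k_max outside [1, n_complete_cells]")
    if rng is None:
        rng = np.random.default_rng(seed)

    taxon_ids = community.taxon_ids
    T = len(taxon_ids)
    acc = np.empty((n_reps, k_max))
    rich_pct = np.empty((n_reps, k_max))
    rich_scan_pct = np.empty(n_reps)
    scan_gain = np.empty(n_reps)
    categories: list[str] = []
    n_present = np.zeros(T, dtype=int)
    n_missed = np.zeros(T, dtype=int)
    n_excluded = 0

    r = 0
    max_draws = 100 * n_reps
    while r < n_reps:
        if n_excluded >= max_draws:
            raise RuntimeError(
                "community produces (almost) no samples with on-tray "
                "individuals; percent accuracy is undefined for it")
        sample = draw_sample(community, geometry, rng)
        if sample.true_phase2_total == 0:
            n_excluded += 1
            continue
        result = run_protocol(sample, k=k_max, rng=rng)
        truth2 = sample.true_phase2_total
        eq = geometry.equivalent_cells

        cum = np.cumsum(result.subsample.observed_counts, axis=0)  # (k, T)
        ks = np.arange(1, k_max + 1)
        est = cum.sum(axis=1) / ks * eq
        acc[r] = 100.0 * est / truth2

        present = (sample.small_totals + sample.large_counts) > 0
        true_rich = int(present.sum())
        p1 = result.large_counts > 0
        detected_k = p1[None, :] | (cum > 0)  # (k, T)
        rich_pct[r] = 100.0 * detected_k.sum(axis=1) / true_rich

        scan_mask = np.isin(np.asarray(taxon_ids), sorted(result.scan_taxa))
        detected_full = detected_k[-1] | scan_mask
        scan_gain[r] = int(scan_mask.sum())
        rich_scan_pct[r] = 100.0 * detected_full.sum() / true_rich

        n_present += present
        n_missed += present & ~detected_full
        categories.append(classify_abundance(sample.true_total).value)
        r += 1

    cat_arr = np.array(categories)
    rows = []
    for cat in pd.unique(cat_arr):
        idx = cat_arr == cat
        n = int(idx.sum())
        for j, k in enumerate(range(1, k_max + 1)):
            a_mean, a_se, a_sd = _agg(acc[idx, j])
            r_mean, r_se, _ = _agg(rich_pct[idx, j])
            row = dict(preset=community.name, category=cat, k=k, n=n,
                       accuracy_mean=a_mean, accuracy_se=a_se,
                       accuracy_sd=a_sd,
                       accuracy_ci_low=a_mean - Z95 * a_se,
                       accuracy_ci_high=a_mean + Z95 * a_se,
                       richness_mean=r_mean, richness_se=r_se,
                       richness_ci_low=r_mean - Z95 * r_se,
                       richness_ci_high=r_mean + Z95 * r_se,
                       scan_gain_taxa=np.nan,
                       richness_with_scan_mean=np.nan,
                       richness_with_scan_se=np.nan,
                       richness_with_scan_ci_low=np.nan,
                       richness_with_scan_ci_high=np.nan)
            if k == k_max:
                s_mean, s_se, _ = _agg(rich_scan_pct[idx])
                row.update(scan_gain_taxa=float(scan_gain[idx].mean()),
                           richness_with_scan_mean=s_mean,
                           richness_with_scan_se=s_se,
                           richness_with_scan_ci_low=s_mean - Z95 * s_se,
                           richness_with_scan_ci_high=s_mean + Z95 * s_se)
            rows.append(row)
    curves = pd.DataFrame(rows)

    with np.errstate(invalid="ignore"):
        rates = np.where(n_present > 0, n_missed / np.maximum(n_present, 1),
                         np.nan)
    miss = pd.DataFrame(dict(preset=community.name, taxon_id=list(taxon_ids),
                             n_present=n_present, n_missed=n_missed,
                             miss_rate=rates))

    return EvaluationSummary(preset=community.name, curves=curves,
                             miss_rates=miss, n_reps=n_reps, k_max=k_max,
                             n_excluded_empty=n_excluded, seed=seed)


def accuracy_curve(community: CommunityConfig, k_max: int = 16,
                   n_reps: int = 1000, rng=None, seed=None,
                   geometry: TrayGeometry | None = None) -> EvaluationSummary:
    """Percent-accuracy-vs-k evaluation (accuracy columns of the summary)."""
    return run_evaluation(community, geometry, k_max, n_reps, rng, seed)


def richness_curve(community: CommunityConfig, k_max: int = 16,
                   n_reps: int = 1000, rng=None, seed=None,
                   geometry: TrayGeometry | None = None) -> EvaluationSummary:
    """Percent-richness-vs-k evaluation (richness columns of the summary)."""
    return run_evaluation(community, geometry, k_max, n_reps, rng, seed)


def taxon_missrate_table(community: CommunityConfig, k: int = 16,
                         n_reps: int = 1000, rng=None, seed=None,
                         geometry: TrayGeometry | None = None) -> pd.DataFrame:
    """Per-taxon miss frequencies at the full protocol (all three phases)."""
    return run_evaluation(community, geometry, k, n_reps, rng,
                          seed).miss_rates


def ci_nonoverlap(interval_a: tuple[float, float],
                  interval_b: tuple[float, float]) -> bool:
    """True iff two confidence intervals are disjoint.

    Non-overlap is the published significance criterion; a shared endpoint
    counts as overlap (not significant).
    """
    (a_lo, a_hi), (b_lo, b_hi) = interval_a, interval_b
    if a_lo > a_hi or b_lo > b_hi:
        raise ValueError("interval bounds out of order")
    return a_hi < b_lo or b_hi < a_lo


def evaluate_presets(names, k_max: int = 16, n_reps: int = 1000,
                     seed: int | None = None, clustering_theta=np.inf,
                     perfect_detection: bool = False,
                     geometry: TrayGeometry | None = None
                     ) -> dict[str, EvaluationSummary]:
    """Evaluate several named presets with independent child seeds."""
    ss = np.random.SeedSequence(seed)
    out = {}
    for name, child in zip(names, ss.spawn(len(names))):
        community = preset(name, clustering_theta=clustering_theta,
                           perfect_detection=perfect_detection)
        out[name] = run_evaluation(community, geometry, k_max, n_reps,
                                   rng=np.random.default_rng(child),
                                   seed=seed)
    return out
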