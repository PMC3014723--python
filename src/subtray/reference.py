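"""Published reference constants for cross-checks.

Per-category three-phase taxa-detection percentages reported for the two
trap types (percent of a sample's true taxa recovered by sieve + 16-cell
subsample + quick scan). Their unweighted mean is the headline average
detection figure. These are empirical field-sample values used as reference
points; the simulator does not target them.
"""

from __future__ import annotations

__all__ = ["REPORTED_DETECTION_PCT", "mean_reported_detection_pct"]

REPORTED_DETECTION_PCT: dict[str, dict[str, float]] = {
    "pan": {"low": 82.0, "moderate": 90.0, "high": 93.0},
    "pitfall": {"low": 91.0, "moderate": 87.0, "high": 89.0},
}


def mean_reported_detection_pct(rounded: bool = True) -> float:
    """Unweighted mean of the six per-category detection percentages."""
    values = [pct for trap in REPORTED_DETECTION_PCT.values()
              for pct in trap.values()]
    mean = sum(values) / len(values)
    return round(mean) if rounded else mean
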