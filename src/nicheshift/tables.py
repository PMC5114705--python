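"""Bundled published range-shift summary tables for five *Kinosternon* species.

Three small CSVs ship with the package: the model-comparison table
(log-likelihood, AICc, weights, AUC per candidate model), the
suprathreshold-area table (area, % change, overlap with current, %
retained per scenario) and the centroid-shift table (distance, 16-wind
direction and km/decade rate per scenario).  They serve as fixed inputs
for exercising the reporting arithmetic — percent change, retention,
AICc ranking, rate conversion, cross-scenario medians — against known
published numbers.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_range_areas", "load_centroid_shifts", "load_model_scores"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("nicheshift.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_range_areas() -> pd.DataFrame:
    """Per-species, per-scenario suprathreshold areas (km²) and overlap metrics.

    'current' rows carry the present-day area; the 40 scenario rows carry
    the projected area, % change, area common to current and % retained.
    """
    return _load("range_areas.csv")


def load_centroid_shifts() -> pd.DataFrame:
    """Centroid displacement (km), compass direction and km/decade rate per scenario."""
    return _load("centroid_shifts.csv")


def load_model_scores() -> pd.DataFrame:
    """Top candidate models per species: log-likelihood, AICc, ΔAICc, weight, AUC."""
    return _load("model_scores.csv")
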