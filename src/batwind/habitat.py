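"""Habitat classes from training-omission thresholds.

A seasonal suitability raster is reclassified into three classes using two
thresholds read off the training presences: the suitability value at the
lower omission rate (10% by default) separates unsuitable from
low-to-moderate habitat, and the value at the upper rate (50%) separates
low-to-moderate from high habitat.  An r-omission threshold is the
(⌊r·m⌋+1)-th smallest training suitability, so at most ⌊r·m⌋ training
presences fall strictly below it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import ORDINAL, RasterLayer

__all__ = [
    "UNSUITABLE",
    "LOW_MODERATE",
    "HIGH",
    "HABITAT_CLASS_NAMES",
    "OmissionThresholds",
    "HabitatClassMap",
    "omission_threshold",
    "thresholds_from_training",
    "classify_habitat",
]

UNSUITABLE, LOW_MODERATE, HIGH = 0, 1, 2
HABITAT_CLASS_NAMES = {UNSUITABLE: "unsuitable",
                       LOW_MODERATE: "low_to_moderate",
                       HIGH: "high"}


@dataclass(frozen=True)
class OmissionThresholds:
    t_low: float
    t_high: float
    m: int
    rate_low: float = 0.10
    rate_high: float = 0.50

    def __post_init__(self) -> None:
        if self.t_low > self.t_high:
            raise ValueError("t_low must be <= t_high")


@dataclass
class HabitatClassMap:
    classes: RasterLayer
    thresholds: OmissionThresholds
    season: str


def omission_threshold(training_suitability: np.ndarray, rate: float) -> float:
    """Suitability value at a training omission rate (order-statistic rule).

    Returns the (⌊rate·m⌋+1)-th smallest training value; the count of
    training values strictly below it is ≤ ⌊rate·m⌋.  Deterministic under
    ties.
    """
    values = np.asarray(training_suitability, float)
    if values.size == 0:
        raise ValueError("need at least one training suitability value")
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    ordered = np.sort(values)
    return float(ordered[int(np.floor(rate * values.size))])


def thresholds_from_training(training_suitability: np.ndarray,
                             rate_low: float = 0.10,
                             rate_high: float = 0.50) -> OmissionThresholds:
    return OmissionThresholds(
        t_low=omission_threshold(training_suitability, rate_low),
        t_high=omission_threshold(training_suitability, rate_high),
        m=len(np.asarray(training_suitability)),
        rate_low=rate_low, rate_high=rate_high,
    )


def classify_values(values: np.ndarray, thresholds: OmissionThresholds) -> np.ndarray:
    """Apply the class rule to plain values: s < t_low → 0; t_low ≤ s < t_high → 1; s ≥ t_high → 2."""
    values = np.asarray(values, float)
    out = np.full(values.shape, LOW_MODERATE, dtype=np.int32)
    out[values < thresholds.t_low] = UNSUITABLE
    out[values >= thresholds.t_high] = HIGH
    return out


def classify_habitat(suitability: RasterLayer, thresholds: OmissionThresholds,
                     season: str = "") -> HabitatClassMap:
    """Three-class habitat map; NoData propagates."""
    valid = suitability.valid_mask()
    vals = suitability.values.astype(float)
    if vals[valid].size and (vals[valid].min() < 0 or vals[valid].max() > 1):
        raise ValueError("suitability must lie in [0, 1]")
    classes = classify_values(vals, thresholds)
    nodata = -1
    classes = np.where(valid, classes, nodata).astype(np.int32)
    layer = RasterLayer(suitability.grid, classes, nodata=nodata, kind=ORDINAL)
    return HabitatClassMap(classes=layer, thresholds=thresholds, season=season)
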