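"""Geometric and comparative crowding metrics.

Stimuli are scaled rigidly with the gap: the target diameter is 5 times the
gap size, and flankers sit at a centre-to-centre separation of 1.1 times
the stimulus diameter (the separation regarded as optimal for robust
crowding measurement).  A gap-size threshold therefore converts
deterministically into the spatial extent of crowding (the centre-to-centre
separation at threshold, 5.5 x gap), the edge-to-edge separation, and the
relative metrics (flanked/unflanked ratio and difference) used by prior
developmental studies — the conversions on which the cross-study
meta-analysis rests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DIAMETER_PER_GAP",
    "CENTRE_TO_CENTRE_PER_DIAMETER",
    "WEBER_CONTRAST",
    "METRIC_KINDS",
    "StimulusGeometry",
    "ThresholdRecord",
    "geometry_from_gap",
    "crowding_magnitude",
    "spatial_extent",
    "release_percentage",
    "convert_to_study_metric",
    "normalize_to_reference",
]

DIAMETER_PER_GAP = 5.0
CENTRE_TO_CENTRE_PER_DIAMETER = 1.1
WEBER_CONTRAST = 0.75

METRIC_KINDS = (
    "gap_acuity",
    "diameter",
    "centre_to_centre",
    "edge_to_edge",
    "flanked_over_unflanked",
    "flanked_minus_unflanked",
)


@dataclass(frozen=True)
class StimulusGeometry:
    """Stimulus dimensions implied by a gap size (all in arcmin)."""

    gap: float
    diameter: float
    centre_to_centre: float | None
    edge_to_edge: float | None
    weber_contrast: float = WEBER_CONTRAST
    flanker_polarity: str = "none"  # none | same | different


def geometry_from_gap(gap: float, polarity: str = "none") -> StimulusGeometry:
    """Scale the stimulus from its gap: diameter = 5 x gap; flanker
    centre-to-centre = 1.1 x diameter; edge-to-edge = centre-to-centre minus
    one diameter.  Unflanked stimuli (polarity "none") have no flanker
    separations."""
    if not gap > 0:
        raise ValueError(f"gap must be positive, got {gap}")
    if polarity not in ("none", "same", "different"):
        raise ValueError(f"unknown flanker polarity {polarity!r}")
    diameter = DIAMETER_PER_GAP * gap
    if polarity == "none":
        return StimulusGeometry(gap, diameter, None, None, flanker_polarity=polarity)
    c2c = CENTRE_TO_CENTRE_PER_DIAMETER * diameter
    return StimulusGeometry(
        gap, diameter, c2c, c2c - diameter, flanker_polarity=polarity
    )


def crowding_magnitude(flanked: float, unflanked: float) -> tuple[float, float]:
    """Magnitude of crowding as ``(ratio, difference)`` of thresholds."""
    if not (flanked > 0 and unflanked > 0):
        raise ValueError("thresholds must be positive")
    return flanked / unflanked, flanked - unflanked


def spatial_extent(flanked_gap) -> np.ndarray | float:
    """Spatial extent of crowding: centre-to-centre separation at the
    flanked threshold, ``1.1 * 5 * gap``."""
    gap = np.asarray(flanked_gap, dtype=float)
    if np.any(gap <= 0):
        raise ValueError("flanked_gap must be positive")
    out = CENTRE_TO_CENTRE_PER_DIAMETER * DIAMETER_PER_GAP * gap
    return float(out) if out.ndim == 0 else out


def release_percentage(unflanked: float, flanked_same: float, flanked_diff: float) -> float:
    """Release from crowding: percentage reduction of the flanked-same
    threshold elevation when flankers differ from the target.

    ``100 * (flanked_same - flanked_diff) / (flanked_same - unflanked)``;
    0 means no benefit of the flanker difference, 100 means crowding fully
    abolished.  Values outside [0, 100] (possible with noisy threshold
    estimates) trigger a warning and are clipped to the reporting range
    [-50, 150].
    """
    if flanked_same <= unflanked:
        raise ValueError(
            "release undefined: flanked_same must exceed unflanked "
            f"(got {flanked_same} <= {unflanked})"
        )
    pct = 100.0 * (flanked_same - flanked_diff) / (flanked_same - unflanked)
    if not 0.0 <= pct <= 100.0:
        warnings.warn(f"release {pct:.1f}% outside [0, 100]; clipping to [-50, 150]")
        pct = float(np.clip(pct, -50.0, 150.0))
    return pct


@dataclass(frozen=True)
class ThresholdRecord:
    """Per-participant gap-size thresholds (arcmin) by condition."""

    participant_id: str
    age: float
    thresholds: Mapping[str, float]  # condition -> threshold_gap

    def get(self, condition: str) -> float:
        if condition not in self.thresholds:
            raise KeyError(
                f"record {self.participant_id} lacks condition {condition!r} "
                "required by the requested metric"
            )
        return float(self.thresholds[condition])


def convert_to_study_metric(record: ThresholdRecord, metric_kind: str) -> float:
    """Express a participant's thresholds in another study's metric.

    Size-type metrics (gap_acuity, diameter, centre_to_centre, edge_to_edge)
    are linear in a single condition's gap threshold; the relative metrics
    combine the flanked-same and unflanked thresholds.
    """
    if metric_kind == "gap_acuity":
        return record.get("unflanked")
    if metric_kind == "diameter":
        return DIAMETER_PER_GAP * record.get("flanked_same")
    if metric_kind == "centre_to_centre":
        return float(spatial_extent(record.get("flanked_same")))
    if metric_kind == "edge_to_edge":
        g = geometry_from_gap(record.get("flanked_same"), polarity="same")
        assert g.edge_to_edge is not None
        return g.edge_to_edge
    if metric_kind == "flanked_over_unflanked":
        return crowding_magnitude(record.get("flanked_same"), record.get("unflanked"))[0]
    if metric_kind == "flanked_minus_unflanked":
        return crowding_magnitude(record.get("flanked_same"), record.get("unflanked"))[1]
    raise ValueError(f"unknown metric_kind {metric_kind!r}; choose from {METRIC_KINDS}")


def normalize_to_reference(
    values: Sequence[float], ref_min: float, ref_max: float
) -> np.ndarray:
    """Affine min-max normalization of one study's values onto a reference range.

    Maps ``min(values) -> ref_min`` and ``max(values) -> ref_max``; order
    preserving, and idempotent once applied.  Used to put the crowding
    metrics of different studies on a common scale before pooling.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.isclose(v.max(), v.min()):
        raise ValueError("normalization needs at least 2 distinct values")
    if not ref_max > ref_min:
        raise ValueError("ref_max must exceed ref_min")
    return ref_min + (v - v.min()) * (ref_max - ref_min) / (v.max() - v.min())
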