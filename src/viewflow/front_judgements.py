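"""Analysis of "which view is the front?" angular judgements.

Observers rotate an object freely and stop at the azimuth they consider its
front. Responses live on the circle, so concentration is summarized by the
mean resultant length and the central tendency by the circular mode on the
viewpoint grid. The substantive question is whether chosen fronts sit where
the optical-flow curve is locally flat (peaks/troughs, |gradient| small):
per object we compare the mean |gradient| at ever-selected viewpoints with
the mean |gradient| at never-selected viewpoints, and test the difference
across objects with a paired Wilcoxon signed-rank test.

Response tables are DataFrames with columns
``participant, object, chosen_azimuth_deg``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .discrimination import ExclusionCriteria, StatResult, wilcoxon_signed_rank
from .errors import ValidationError
from .flow_model import FlowCurve, curve_gradients

__all__ = [
    "FRONT_COLUMNS",
    "CircularSummary",
    "mean_resultant_length",
    "circular_mode",
    "circular_distance_deg",
    "snap_to_grid",
    "front_exclusion",
    "front_vs_nonfront_gradient",
]

FRONT_COLUMNS = ("participant", "object", "chosen_azimuth_deg")


@dataclass(frozen=True)
class CircularSummary:
    """Concentration and central tendency of a set of angular responses."""

    mean_resultant_length: float
    circular_mode: float
    n: int


def mean_resultant_length(angles_deg: Iterable[float]) -> float:
    """R̄ = |mean unit vector| ∈ [0, 1]; 1 iff all angles coincide."""
    angles = np.asarray(list(angles_deg), float)
    if angles.size == 0:
        raise ValidationError("need at least one angle")
    rad = np.radians(angles)
    return float(np.hypot(np.cos(rad).mean(), np.sin(rad).mean()))


def circular_mode(angles_deg: Iterable[float], bin_deg: float = 5.0) -> float:
    """Center of the most populated circular bin; ties go to the lowest angle.

    Bins are centered on multiples of ``bin_deg`` (the viewpoint grid), with
    wraparound, so a response at 359° supports the 0° bin when bins are wide
    enough.
    """
    angles = np.asarray(list(angles_deg), float)
    if angles.size == 0:
        raise ValidationError("need at least one angle")
    if not math.isclose(360.0 / bin_deg, round(360.0 / bin_deg)):
        raise ValidationError("bin width must divide 360")
    n_bins = int(round(360.0 / bin_deg))
    # nearest bin center, circular
    idx = np.round((angles % 360.0) / bin_deg).astype(int) % n_bins
    counts = np.bincount(idx, minlength=n_bins)
    return float(np.argmax(counts) * bin_deg)  # argmax takes lowest on ties


def circular_distance_deg(a: float | np.ndarray, b: float | np.ndarray) -> np.ndarray:
    """Shortest angular distance, min(|Δ|, 360 − |Δ|) ∈ [0, 180]."""
    delta = np.abs(np.asarray(a, float) - np.asarray(b, float)) % 360.0
    return np.minimum(delta, 360.0 - delta)


def snap_to_grid(angles_deg: np.ndarray, step_deg: float = 5.0) -> np.ndarray:
    """Snap angles to the nearest grid azimuth in [0, 360)."""
    return (np.round(np.asarray(angles_deg, float) / step_deg) * step_deg) % 360.0


def summarize(responses: pd.DataFrame, bin_deg: float = 5.0) -> pd.DataFrame:
    """Per-object circular summaries of the chosen front angles."""
    rows = []
    for obj, grp in responses.groupby("object"):
        ang = grp["chosen_azimuth_deg"].to_numpy(float)
        rows.append(
            {
                "object": obj,
                "mean_resultant_length": mean_resultant_length(ang),
                "circular_mode": circular_mode(ang, bin_deg),
                "n": len(ang),
            }
        )
    return pd.DataFrame(rows)


def front_exclusion(
    responses: pd.DataFrame,
    veridical_front: Mapping[str, float],
    criteria: ExclusionCriteria = ExclusionCriteria(),
) -> tuple[pd.DataFrame, dict]:
    """Drop familiar-object responses farther than the tolerance (45°) from
    the veridical front; novel objects (no veridical front) are untouched.
    """
    missing = set(responses.columns).symmetric_difference(FRONT_COLUMNS) & set(
        FRONT_COLUMNS
    )
    if missing:
        raise ValidationError(f"front-response table missing columns: {sorted(missing)}")
    familiar = responses["object"].isin(veridical_front)
    verid = responses.loc[familiar, "object"].map(veridical_front).to_numpy(float)
    dist = circular_distance_deg(
        responses.loc[familiar, "chosen_azimuth_deg"].to_numpy(float), verid
    )
    drop_idx = responses.index[familiar][dist > criteria.front_tolerance_deg]
    kept = responses.drop(index=drop_idx)
    report = {
        "n_input": len(responses),
        "n_retained": len(kept),
        "n_front_excluded": len(drop_idx),
    }
    return kept, report


def front_vs_nonfront_gradient(
    responses: pd.DataFrame,
    curves: Mapping[str, FlowCurve],
) -> tuple[pd.DataFrame, StatResult]:
    """Mean |flow gradient| at selected vs never-selected viewpoints.

    Responses are snapped to the grid; per object the *set* of distinct
    selected viewpoints (across all retained participants) is compared with
    its complement, so duplicate choices of the same view carry no extra
    weight. Objects whose participants covered all viewpoints have an empty
    complement and are dropped (flagged in the output). The across-object
    comparison is a paired Wilcoxon signed-rank test with effect size r.
    """
    rows = []
    for obj, grp in responses.groupby("object"):
        if obj not in curves:
            raise ValidationError(f"no flow curve for object {obj!r}")
        curve = curves[obj]
        grads = np.abs(curve_gradients(curve))
        n = len(curve)
        chosen = {
            curve.grid.index_of(a) for a in grp["chosen_azimuth_deg"].to_numpy(float)
        }
        complement = sorted(set(range(n)) - chosen)
        row = {"object": obj, "n_selected": len(chosen), "complete_coverage": not complement}
        if complement:
            row["front_mean_abs_gradient"] = float(grads[sorted(chosen)].mean())
            row["nonfront_mean_abs_gradient"] = float(grads[complement].mean())
        else:
            row["front_mean_abs_gradient"] = np.nan
            row["nonfront_mean_abs_gradient"] = np.nan
        rows.append(row)
    per_object = pd.DataFrame(rows)
    usable = per_object.dropna(subset=["front_mean_abs_gradient"])
    if len(usable) < 2:
        raise ValidationError("need >= 2 objects with a non-empty complement")
    stat = wilcoxon_signed_rank(
        usable["front_mean_abs_gradient"], usable["nonfront_mean_abs_gradient"]
    )
    return per_object, stat
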