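"""Segmentation and centerline quality metrics."""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
from scipy.spatial import cKDTree

from .centerline import CenterlineCurve, resample_curve
from .core import ScalarVolume

__all__ = ["dice_coefficient", "centerline_distance", "EvalReport"]


def _as_bool_array(x) -> np.ndarray:
    if isinstance(x, ScalarVolume):
        return np.asarray(x.values) > 0
    return np.asarray(x) > 0


def dice_coefficient(a, b) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) of two binary masks on one grid.

    1.0 when both masks are empty (identical), and exactly 1/0 iff the
    masks are identical/disjoint.
    """
    am, bm = _as_bool_array(a), _as_bool_array(b)
    if am.shape != bm.shape:
        raise ValueError(f"grid mismatch: {am.shape} vs {bm.shape}")
    if isinstance(a, ScalarVolume) and isinstance(b, ScalarVolume):
        if not (np.allclose(a.spacing, b.spacing) and np.allclose(a.origin, b.origin, atol=1e-6)):
            raise ValueError("masks are on different physical grids")
    na, nb = int(am.sum()), int(bm.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int(np.logical_and(am, bm).sum()) / (na + nb)


def centerline_distance(
    extracted: CenterlineCurve, truth: CenterlineCurve, step_mm: float = 0.1
) -> tuple[float, float]:
    """Symmetric (mean, max) distance in mm between two polylines.

    Both curves are densely resampled at ``step_mm`` and point-to-curve
    distances are pooled over both directions.
    """
    a = resample_curve(extracted, step_mm).vertices if len(extracted) > 1 else extracted.vertices
    b = resample_curve(truth, step_mm).vertices if len(truth) > 1 else truth.vertices
    d_ab, _ = cKDTree(b).query(a, workers=-1)
    d_ba, _ = cKDTree(a).query(b, workers=-1)
    pooled = np.concatenate([d_ab, d_ba])
    return float(pooled.mean()), float(pooled.max())


@dataclass
class EvalReport:
    """Pipeline run summary: metrics, per-stage runtimes, resolved config."""

    dice: float | None = None
    mean_centerline_distance_mm: float | None = None
    hausdorff_mm: float | None = None
    runtime_s: dict[str, float] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "dice": self.dice,
                "mean_centerline_distance_mm": self.mean_centerline_distance_mm,
                "hausdorff_mm": self.hausdorff_mm,
                "runtime_s": self.runtime_s,
                "parameters": self.parameters,
            },
            indent=2,
            default=str,
        )
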