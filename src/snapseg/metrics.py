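"""Segmentation evaluation: DSC, HD95, ASD and multi-method comparison.

Structures follow the vessel-wall reporting convention: *lumen* (class 0),
*vessel wall* (the annulus, class 1) and *outer wall* (the union of lumen and
wall — the whole region enclosed by the outer boundary).  DSC is reported for
all three; the surface distances HD95 and ASD for lumen and outer wall.
``DSCavg`` — the mean of lumen and outer-wall DSC — is the model-selection
criterion.

Boundary voxels are foreground voxels with at least one face-adjacent
non-foreground neighbour within their slice (in-plane 4-connectivity);
distances between boundary voxels are Euclidean in 3D using the physical
voxel spacing.  HD95 and ASD are the 95th percentile and the mean of the
*pooled* symmetric set of nearest-boundary distances (both directions pooled
before reduction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .volume_io import LUMEN, WALL, LabelMask


def dsc(pred_mask: np.ndarray, ref_mask: np.ndarray) -> float:
    """Dice similarity coefficient in percent; 100 when both masks are empty."""
    pred_mask = np.asarray(pred_mask, dtype=bool)
    ref_mask = np.asarray(ref_mask, dtype=bool)
    if pred_mask.shape != ref_mask.shape:
        raise ValueError(f"shape mismatch: {pred_mask.shape} vs {ref_mask.shape}")
    a, b = int(pred_mask.sum()), int(ref_mask.sum())
    if a + b == 0:
        return 100.0
    inter = int((pred_mask & ref_mask).sum())
    return 100.0 * 2.0 * inter / (a + b)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """(K, 3) integer coordinates of in-plane 4-connectivity boundary voxels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D (slices, rows, cols)")
    pad = np.pad(mask, ((0, 0), (1, 1), (1, 1)), constant_values=False)
    interior = (pad[:, :-2, 1:-1] & pad[:, 2:, 1:-1]
                & pad[:, 1:-1, :-2] & pad[:, 1:-1, 2:])
    return np.argwhere(mask & ~interior)


def surface_distance_pool(pred_mask: np.ndarray, ref_mask: np.ndarray,
                          spacing: tuple[float, float, float]) -> np.ndarray:
    """Pooled symmetric nearest-boundary distances (mm) between two masks."""
    bp = boundary_voxels(pred_mask)
    br = boundary_voxels(ref_mask)
    if len(bp) == 0 or len(br) == 0:
        raise ValueError("surface distances undefined for an empty mask")
    # physical coordinates: voxel index order is (slice, row, col)
    scale = np.array([spacing[2], spacing[0], spacing[1]])
    pp, pr = bp * scale, br * scale
    d_pred = cKDTree(pr).query(pp)[0]
    d_ref = cKDTree(pp).query(pr)[0]
    return np.concatenate([d_pred, d_ref])


def surface_distances(pred_mask: np.ndarray, ref_mask: np.ndarray,
                      spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
                      ) -> tuple[float, float]:
    """(HD95, ASD) in mm from the pooled symmetric distance set."""
    pool = surface_distance_pool(pred_mask, ref_mask, spacing)
    return float(np.percentile(pool, 95)), float(pool.mean())


@dataclass
class MetricsRecord:
    """Per-volume metric set; distances are None when a mask was empty."""

    volume_id: str
    dsc_wall: float
    dsc_lumen: float
    dsc_outer: float
    hd95_lumen: float | None
    hd95_outer: float | None
    asd_lumen: float | None
    asd_outer: float | None

    @property
    def dsc_avg(self) -> float:
        return 0.5 * (self.dsc_lumen + self.dsc_outer)

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["dsc_avg"] = self.dsc_avg
        return d


def evaluate_volume(pred_class_map: np.ndarray, ref: LabelMask,
                    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                    volume_id: str = "") -> MetricsRecord:
    """Score one predicted class map against a reference label."""
    ref_map = ref.class_map
    if pred_class_map.shape != ref_map.shape:
        raise ValueError(f"shape mismatch: {pred_class_map.shape} vs {ref_map.shape}")
    masks = {}
    for name, cls in (("lumen", LUMEN), ("wall", WALL)):
        masks[name] = (pred_class_map == cls, ref_map == cls)
    masks["outer"] = (pred_class_map != 2, ref_map != 2)  # lumen ∪ wall

    distances: dict[str, tuple[float, float] | tuple[None, None]] = {}
    for name in ("lumen", "outer"):
        p, r = masks[name]
        if p.any() and r.any():
            distances[name] = surface_distances(p, r, spacing)
        else:
            distances[name] = (None, None)  # undefined; excluded from aggregation
    return MetricsRecord(
        volume_id=volume_id,
        dsc_wall=dsc(*masks["wall"]),
        dsc_lumen=dsc(*masks["lumen"]),
        dsc_outer=dsc(*masks["outer"]),
        hd95_lumen=distances["lumen"][0],
        hd95_outer=distances["outer"][0],
        asd_lumen=distances["lumen"][1],
        asd_outer=distances["outer"][1],
    )


def aggregate_metrics(records: list[MetricsRecord]) -> pd.DataFrame:
    """Per-volume metric table; aggregate with mean/std over columns,
    missing distance entries excluded automatically by pandas."""
    return pd.DataFrame([r.as_dict() for r in records])


def compare_methods(dsc_by_method: dict[str, list[float]],
                    alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Tukey HSD comparison of per-volume DSC across methods.

    Controls the family-wise error rate at ``alpha`` via the studentized-range
    procedure; returns one row per method pair with the mean difference, the
    confidence interval and the adjusted p-value.
    """
    if len(dsc_by_method) < 2:
        raise ValueError("need at least two methods to compare")
    values, groups = [], []
    for name, scores in dsc_by_method.items():
        if len(scores) < 2:
            raise ValueError(f"method {name!r} has fewer than 2 observations")
        values.extend(float(s) for s in scores)
        groups.extend([name] * len(scores))
    res = pairwise_tukeyhsd(np.asarray(values), np.asarray(groups), alpha=alpha)
    table = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    table["p-adj"] = res.pvalues
    return table
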