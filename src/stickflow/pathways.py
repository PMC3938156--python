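"""Sort streamlines into seed-to-target pathways and compute pathway metrics.

A streamline joins a target's pathway if any of its points falls inside the
target mask (point to voxel by floor); a streamline touching several targets
goes to the one reached first along its arc length from the seed point.  The
pathway voxel set is the visitation map thresholded strictly above the
visitation threshold (default: more than 5 distinct streamlines), SC is the
pathway's streamline count, SV the summed volume of pathway voxels, and
FA/AD/RD are unweighted means over pathway voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracking import Tractogram

__all__ = [
    "PathwayMetrics",
    "sort_streamlines",
    "visitation_map",
    "pathway_metrics",
    "flag_single_subject",
]


@dataclass
class PathwayMetrics:
    pathway: str
    SC: int
    SV: float  # mm^3
    FA: float | None
    AD: float | None
    RD: float | None
    n_voxels: int
    voxel_set: np.ndarray  # (k, 3) pathway voxel indices

    def as_record(self) -> dict:
        return {
            "pathway": self.pathway,
            "SC": self.SC,
            "SV": self.SV,
            "FA": "" if self.FA is None else self.FA,
            "AD": "" if self.AD is None else self.AD,
            "RD": "" if self.RD is None else self.RD,
            "n_voxels": self.n_voxels,
        }


def _streamline_voxels(points: np.ndarray) -> np.ndarray:
    return np.floor(points).astype(int)


def sort_streamlines(tractogram: Tractogram, targets: dict) -> dict:
    """Assign each streamline to the first-reached target (or discard it).

    Returns ``{target_name: [streamline, ...], "_discarded": [...]}``; arc
    length is measured in steps away from the seed point, so a streamline
    crossing several targets joins the one its trajectory meets first.
    """
    if not targets:
        raise ValueError("no target masks given")
    names = list(targets)
    shapes = {np.asarray(m).shape for m in targets.values()}
    if len(shapes) != 1:
        raise ValueError("target masks must share a grid")
    out = {name: [] for name in names}
    out["_discarded"] = []
    for s in tractogram.streamlines:
        vox = _streamline_voxels(s.points)
        arc = np.abs(np.arange(len(vox)) - s.seed_point_index)
        best_name, best_arc = None, None
        for name in names:
            m = np.asarray(targets[name], dtype=bool)
            inside = m[tuple(vox.T)]
            if inside.any():
                first = int(arc[inside].min())
                if best_arc is None or first < best_arc:
                    best_name, best_arc = name, first
        if best_name is None:
            out["_discarded"].append(s)
        else:
            out[best_name].append(s)
    return out


def visitation_map(streamlines, grid_shape) -> np.ndarray:
    """Count distinct streamlines visiting each voxel (multiple points of one
    streamline in one voxel count once)."""
    counts = np.zeros(tuple(int(g) for g in grid_shape), dtype=int)
    for s in streamlines:
        vox = np.unique(_streamline_voxels(s.points), axis=0)
        counts[tuple(vox.T)] += 1
    return counts


def pathway_metrics(streamlines, fa_map, ad_map, rd_map, voxel_dims,
                    visitation_threshold: int = 5,
                    pathway: str = "pathway") -> PathwayMetrics:
    """Aggregate one pathway: SC, SV and mean FA/AD/RD over its voxel set.

    Pathway voxels are those with strictly more than ``visitation_threshold``
    streamline visits; an empty voxel set leaves the scalar means undefined
    (None) while SC is still reported.
    """
    fa_map = np.asarray(fa_map)
    visits = visitation_map(streamlines, fa_map.shape)
    vox = np.argwhere(visits > visitation_threshold)
    voxel_volume = float(np.prod(voxel_dims))
    sc = len(streamlines)
    if len(vox) == 0:
        return PathwayMetrics(pathway, sc, 0.0, None, None, None, 0,
                              vox)
    ix = tuple(vox.T)
    return PathwayMetrics(
        pathway=pathway,
        SC=sc,
        SV=len(vox) * voxel_volume,
        FA=float(np.mean(np.asarray(fa_map)[ix])),
        AD=float(np.mean(np.asarray(ad_map)[ix])),
        RD=float(np.mean(np.asarray(rd_map)[ix])),
        n_voxels=len(vox),
        voxel_set=vox,
    )


def flag_single_subject(value: float, reference_values,
                        criterion: str = "three_se") -> bool:
    """Flag a single subject's metric against a comparison group.

    ``three_se``: value < mean(ref) - 3 * sd(ref) / sqrt(n); ``lower_decile``:
    value < empirical 10th percentile (linear interpolation).  Both strict.
    """
    ref = np.asarray(reference_values, dtype=float)
    if len(ref) < 2:
        raise ValueError("reference group needs at least 2 values")
    if criterion == "three_se":
        thr = ref.mean() - 3.0 * ref.std(ddof=1) / np.sqrt(len(ref))
    elif criterion == "lower_decile":
        thr = float(np.percentile(ref, 10.0))
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return bool(value < thr)
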