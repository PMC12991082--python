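"""Arterial tracking for TOF angiography volumes.

The stages mirror an iterative vessel-mapping pipeline for time-of-flight
MR angiography:

1. Hessian (Frangi-form) vesselness scores tubular bright structures at a
   set of scales and is normalized to [0, 1].
2. The thresholded vessel map is cleaned of small components, thinned, and
   refined by iteratively bridging endpoint pairs whose gap is short and
   whose connecting segment is tangent-consistent at both ends.
3. Paths between junctions are reconstructed with a restricted flood fill
   over skeleton voxels; every skeleton voxel is assigned to exactly one
   path (cycles are split at their lexicographically smallest voxel).
4. Diameter along a path is twice the physical distance-to-background
   (anisotropy handled by the sampled Euclidean distance transform);
   segments are classified small/large by a subject-specific median split
   on mean diameter (ties go to small).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import frangi

from .exceptions import InvalidArgumentError, PathIntegrityError
from .morphometry import SkeletonGraph, build_skeleton_graph, skeletonize_volume

__all__ = [
    "VesselnessConfig",
    "vesselness",
    "refine_skeleton",
    "reconstruct_paths",
    "segment_diameter",
    "median_split",
    "track_volume",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class VesselnessConfig:
    scales_vox: tuple = (1.0, 2.0, 3.0)
    alpha: float = 0.5
    beta: float = 0.5
    gamma: float | None = None  # None -> half of max Frobenius norm per scale
    threshold: float = 0.5

    def __post_init__(self):
        if not self.scales_vox:
            raise InvalidArgumentError("at least one scale required")
        if any(s <= 0 for s in self.scales_vox):
            raise InvalidArgumentError("scales must be positive")
        if not (0 < self.threshold < 1):
            raise InvalidArgumentError("threshold must lie in (0, 1)")


def vesselness(volume: np.ndarray, cfg: VesselnessConfig = VesselnessConfig()) -> np.ndarray:
    """Frangi tubularity score, maximum over scales, normalized to [0, 1]."""
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise InvalidArgumentError("volume must be 3D")
    if np.ptp(volume) == 0:
        return np.zeros_like(volume)
    v = frangi(volume, sigmas=cfg.scales_vox, alpha=cfg.alpha, beta=cfg.beta,
               gamma=cfg.gamma, black_ridges=False)
    peak = v.max()
    if peak > 0:
        v = v / peak
    return v


def _endpoint_tangent(skel_set, endpoint, k: int = 5):
    """Outward unit tangent at an endpoint from a short walk along its chain."""
    path = [endpoint]
    prev, cur = None, endpoint
    for _ in range(k):
        nxt = None
        ca = np.asarray(cur)
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dz == dy == dx == 0:
                        continue
                    w = (cur[0] + dz, cur[1] + dy, cur[2] + dx)
                    if w in skel_set and w != prev and w not in path:
                        nxt = w
                        break
                if nxt:
                    break
            if nxt:
                break
        if nxt is None:
            break
        path.append(nxt)
        prev, cur = cur, nxt
    if len(path) < 2:
        return None
    t = np.asarray(endpoint, dtype=float) - np.asarray(path[-1], dtype=float)
    n = np.linalg.norm(t)
    return t / n if n > 0 else None


def _line_voxels(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = int(np.ceil(np.linalg.norm(b - a))) * 2 + 1
    pts = np.round(np.linspace(a, b, n)).astype(int)
    return {tuple(p) for p in pts}


def refine_skeleton(vessel_binary: np.ndarray, min_component_voxels: int = 100,
                    max_gap_vox: float = 8.0, max_angle_deg: float = 30.0,
                    max_iter: int = 10) -> np.ndarray:
    """Thin a binarized vessel map and iteratively close tangent-consistent gaps.

    Small connected components (< ``min_component_voxels``) are removed
    before thinning.  Endpoint pairs in *different* components are bridged
    when their distance is <= ``max_gap_vox`` and the connecting segment
    deviates < ``max_angle_deg`` from both endpoint tangents; the process
    repeats until no bridge is added.  Idempotent on intact skeletons.
    """
    binary = np.asarray(vessel_binary).astype(bool)
    if not binary.any():
        return np.zeros_like(binary)
    lab, n = ndimage.label(binary, structure=_STRUCT26)
    if n > 0:
        counts = np.bincount(lab.ravel())
        small = np.flatnonzero(counts < min_component_voxels)
        binary = binary & ~np.isin(lab, small[small > 0])
    skel = skeletonize_volume(binary)
    cos_lim = np.cos(np.deg2rad(max_angle_deg))
    for _ in range(max_iter):
        lab, n = ndimage.label(skel, structure=_STRUCT26)
        if n <= 1:
            break
        skel_set = {tuple(v) for v in np.argwhere(skel)}
        # endpoints: exactly one 26-neighbor
        endpoints = []
        for v in skel_set:
            deg = sum(1 for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                      if (dz, dy, dx) != (0, 0, 0)
                      and (v[0] + dz, v[1] + dy, v[2] + dx) in skel_set)
            if deg == 1:
                endpoints.append(v)
        merged = False
        best = None  # (dist, e1, e2)
        for i, e1 in enumerate(endpoints):
            for e2 in endpoints[i + 1:]:
                if lab[e1] == lab[e2]:
                    continue
                d = np.asarray(e2, dtype=float) - np.asarray(e1, dtype=float)
                dist = np.linalg.norm(d)
                if dist == 0 or dist > max_gap_vox:
                    continue
                t1 = _endpoint_tangent(skel_set, e1)
                t2 = _endpoint_tangent(skel_set, e2)
                if t1 is None or t2 is None:
                    continue
                u = d / dist
                if np.dot(u, t1) < cos_lim or np.dot(-u, t2) < cos_lim:
                    continue
                if best is None or dist < best[0]:
                    best = (dist, e1, e2)
        if best is not None:
            for p in _line_voxels(best[1], best[2]):
                if all(0 <= p[i] < skel.shape[i] for i in range(3)):
                    skel[p] = True
            merged = True
        if not merged:
            break
    return skel


def reconstruct_paths(skeleton: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0)) -> pd.DataFrame:
    """Restricted flood fill over skeleton voxels: ordered junction-to-node paths.

    Returns a segment table (one row per path) with arc length, chord
    length and tortuosity in physical units.  ``partition`` lists the
    voxels each path claims; their union is exactly the skeleton with no
    voxel claimed twice.  Cycles appear as flagged closed paths split at
    their lexicographically smallest voxel.
    """
    graph: SkeletonGraph = build_skeleton_graph(skeleton, voxel_size_mm)
    claimed = set()
    rows = []
    for i, b in enumerate(sorted(graph.branches, key=lambda b: (b.node_a, b.node_b))):
        part = [v for v in b.path if v not in claimed]
        claimed.update(part)
        rows.append({
            "segment_id": i,
            "path": b.path,
            "partition": part,
            "arc_length_mm": b.arc_length_um,   # units follow voxel_size_mm
            "chord_length_mm": b.chord_length_um,
            "tortuosity": b.tortuosity if not b.closed else np.nan,
            "closed": b.closed,
        })
    # leftover voxels (junction-cluster interiors, isolated voxels)
    all_vox = {tuple(v) for v in np.argwhere(np.asarray(skeleton).astype(bool))}
    for v in sorted(all_vox - claimed):
        rows.append({
            "segment_id": len(rows),
            "path": [v],
            "partition": [v],
            "arc_length_mm": 0.0,
            "chord_length_mm": 0.0,
            "tortuosity": np.nan,
            "closed": False,
        })
        claimed.add(v)
    return pd.DataFrame(rows)


def segment_diameter(path, mask: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0)) -> float:
    """Mean diameter along a path: 2 x physical distance-to-background."""
    mask = np.asarray(mask).astype(bool)
    edt = ndimage.distance_transform_edt(mask, sampling=voxel_size_mm)
    diams = []
    for v in path:
        if not mask[tuple(v)]:
            raise PathIntegrityError(f"path voxel {v} lies outside the mask")
        diams.append(2.0 * edt[tuple(v)])
    return float(np.mean(diams))


def median_split(table: pd.DataFrame, diameter_col: str = "mean_diameter_mm") -> pd.DataFrame:
    """Subject-specific median split into small (<= median) and large (>)."""
    if len(table) < 2:
        raise InvalidArgumentError("median split undefined for < 2 segments")
    med = table[diameter_col].median()
    out = table.copy()
    out["size_class"] = np.where(out[diameter_col] > med, "large", "small")
    return out


def track_volume(volume: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0),
                 cfg: VesselnessConfig = VesselnessConfig(),
                 mask: np.ndarray | None = None,
                 min_component_voxels: int = 100) -> pd.DataFrame:
    """Full tracking pipeline: vesselness -> refine -> paths -> diameter -> split.

    A precomputed binary ``mask`` may be supplied to skip the vesselness
    thresholding stage.
    """
    if mask is None:
        v = vesselness(volume, cfg)
        mask = v > cfg.threshold
    mask = np.asarray(mask).astype(bool)
    skel = refine_skeleton(mask, min_component_voxels=min_component_voxels)
    table = reconstruct_paths(skel, voxel_size_mm)
    table = table[~table["closed"] & (table["path"].map(len) > 1)].reset_index(drop=True)
    edt = ndimage.distance_transform_edt(mask, sampling=voxel_size_mm)
    diams = []
    for path in table["path"]:
        vals = [2.0 * edt[tuple(v)] for v in path if mask[tuple(v)]]
        diams.append(float(np.mean(vals)) if vals else np.nan)
    table["mean_diameter_mm"] = diams
    if len(table) >= 2:
        table = median_split(table)
    return table
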