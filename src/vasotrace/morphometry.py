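"""3D vessel morphometry: skeletonization, branch graph, tortuosity, junction density.

A binary vascular mask is thinned to a one-voxel-wide medial axis, the
skeleton is decomposed into a graph of junctions (>= 3 neighbors under
26-connectivity), endpoints (exactly 1 neighbor) and the branches joining
them, and two summary statistics are computed:

* tortuosity index: branch arc length / straight-line (chord) distance
  between the branch's end nodes, >= 1 by the triangle inequality;
* junction density: junctions in the shallowest ``n_top_slices`` z-planes
  per mm^3 of those planes.

Arc lengths honor anisotropic voxel sizes (each inter-voxel step vector is
scaled per axis before taking its norm).  Deep-learning segmentation is out
of scope here: the module consumes binary masks; :func:`mask_from_intensity`
is a plain Otsu-threshold stand-in for upstream segmentation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import filters
from skimage.morphology import skeletonize

from .exceptions import InvalidArgumentError

__all__ = [
    "SkeletonBranch",
    "SkeletonGraph",
    "MorphometrySummary",
    "skeletonize_volume",
    "mask_from_intensity",
    "build_skeleton_graph",
    "branch_tortuosity",
    "junction_density",
    "summarize",
]

_OFFSETS = np.array([o for o in itertools.product((-1, 0, 1), repeat=3)
                     if o != (0, 0, 0)])


@dataclass
class SkeletonBranch:
    path: list  # ordered voxel (z, y, x) tuples, nodes included
    node_a: tuple
    node_b: tuple
    arc_length_um: float
    chord_length_um: float
    closed: bool = False  # pure cycle anchored at a synthetic node

    @property
    def tortuosity(self) -> float:
        if self.chord_length_um <= 0:
            return np.inf
        return self.arc_length_um / self.chord_length_um


@dataclass
class SkeletonGraph:
    junctions: list  # representative voxel per junction cluster
    junction_clusters: list  # full voxel sets
    endpoints: list
    branches: list  # SkeletonBranch
    voxel_size_um: tuple
    shape: tuple

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    @property
    def n_endpoints(self) -> int:
        return len(self.endpoints)

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def branch_table(self) -> pd.DataFrame:
        rows = [(i, b.node_a, b.node_b, b.arc_length_um, b.chord_length_um,
                 b.tortuosity if not b.closed else np.nan, b.closed)
                for i, b in enumerate(self.branches)]
        return pd.DataFrame(rows, columns=[
            "branch_id", "node_a", "node_b", "arc_length_um",
            "chord_length_um", "tortuosity", "closed"])


@dataclass
class MorphometrySummary:
    mean_tortuosity: float
    n_junctions: int
    n_endpoints: int
    n_branches: int
    junction_density_per_mm3: float
    n_excluded_branches: int = 0
    per_branch_tortuosity: list = field(default_factory=list)


def skeletonize_volume(mask: np.ndarray) -> np.ndarray:
    """Medial-axis thinning of a 3D binary mask to a 1-voxel-wide skeleton."""
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise InvalidArgumentError("mask must be 3D")
    if not mask.any():
        return np.zeros_like(mask, dtype=bool)
    return skeletonize(mask.astype(bool)).astype(bool)


def mask_from_intensity(volume: np.ndarray) -> np.ndarray:
    """Otsu-threshold segmentation stand-in for upstream learned segmentation."""
    volume = np.asarray(volume, dtype=float)
    t = filters.threshold_otsu(volume)
    return volume > t


def _neighbor_map(voxels):
    """26-neighbor adjacency with redundant diagonal edges pruned.

    A diagonal edge (squared distance >= 2) is dropped when a third
    skeleton voxel sits strictly closer to both ends (an orthogonal
    two-step detour exists); otherwise right-angle corners read as
    spurious 3-neighbor junctions.
    """
    vox = set(voxels)
    nbrs = {}
    for v in vox:
        va = np.asarray(v)
        ns = []
        for o in _OFFSETS:
            w = tuple(va + o)
            if w in vox:
                ns.append(w)
        nbrs[v] = ns
    pruned = {v: list(ns) for v, ns in nbrs.items()}
    for v, ns in nbrs.items():
        va = np.asarray(v)
        for w in ns:
            d2 = int(((va - np.asarray(w)) ** 2).sum())
            if d2 < 2:
                continue
            for c in ns:
                if c == w:
                    continue
                dc_v = int(((va - np.asarray(c)) ** 2).sum())
                dc_w = int(((np.asarray(w) - np.asarray(c)) ** 2).sum())
                if c in nbrs[w] and dc_v < d2 and dc_w < d2:
                    if w in pruned[v]:
                        pruned[v].remove(w)
                    if v in pruned[w]:
                        pruned[w].remove(v)
                    break
    return pruned


def _step_um(a, b, vs):
    d = (np.asarray(b) - np.asarray(a)) * vs
    return float(np.linalg.norm(d))


def _simplify_path(path, tol: float = 1.0):
    """Douglas-Peucker simplification of a voxel path (index space).

    Collapses digital staircases (which inflate naive step-sum lengths by
    up to ~8% depending on orientation) onto their underlying straight
    segments while preserving genuine corners, whose deviation exceeds the
    sub-voxel tolerance.
    """
    pts = np.asarray(path, dtype=float)
    if len(pts) < 3:
        return pts
    keep = np.zeros(len(pts), dtype=bool)
    keep[[0, -1]] = True
    stack = [(0, len(pts) - 1)]
    while stack:
        i, j = stack.pop()
        if j <= i + 1:
            continue
        a, b = pts[i], pts[j]
        ab = b - a
        denom = np.linalg.norm(ab)
        seg = pts[i + 1:j]
        if denom == 0:
            d = np.linalg.norm(seg - a, axis=1)
        else:
            d = np.linalg.norm(np.cross(seg - a, ab / denom), axis=1)
        kmax = int(np.argmax(d))
        if d[kmax] > tol:
            k = i + 1 + kmax
            keep[k] = True
            stack.extend([(i, k), (k, j)])
    return pts[keep]


def _path_lengths(path, vs, simplify_tol: float = 1.0):
    """Arc (digital-bias-corrected) and chord length of a voxel path, in um."""
    poly = _simplify_path(path, simplify_tol) * vs
    arc = float(np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)))
    chord = _step_um(path[0], path[-1], vs)
    return arc, chord


def build_skeleton_graph(skeleton: np.ndarray, voxel_size_um=(1.0, 1.0, 1.0)) -> SkeletonGraph:
    """Decompose a thinned skeleton into junctions, endpoints and branches.

    Junction voxels (>= 3 neighbors, 26-connectivity) that touch each other
    are merged into one junction cluster; branches are traced through
    degree-2 chains between node voxels.  A pure cycle with no node is
    emitted as a closed branch anchored at its lexicographically smallest
    voxel and flagged.
    """
    skeleton = np.asarray(skeleton).astype(bool)
    vs = np.asarray(voxel_size_um, dtype=float)
    voxels = [tuple(v) for v in np.argwhere(skeleton)]
    nbrs = _neighbor_map(voxels)

    junction_vox = {v for v, ns in nbrs.items() if len(ns) >= 3}
    endpoint_vox = {v for v, ns in nbrs.items() if len(ns) == 1}

    # cluster adjacent junction voxels
    clusters = []
    cluster_of = {}
    seen = set()
    for v in sorted(junction_vox):
        if v in seen:
            continue
        stack, cl = [v], set()
        while stack:
            u = stack.pop()
            if u in cl:
                continue
            cl.add(u)
            seen.add(u)
            for w in nbrs[u]:
                if w in junction_vox and w not in cl:
                    stack.append(w)
        clusters.append(cl)
        for u in cl:
            cluster_of[u] = len(clusters) - 1
    junction_reps = [min(cl) for cl in clusters]

    node_vox = junction_vox | endpoint_vox
    branches = []
    used_half_edges = set()

    def trace(start, first):
        """Walk from node voxel `start` through `first` until the next node."""
        path = [start, first]
        prev, cur = start, first
        while cur not in node_vox:
            nxt = None
            for w in sorted(nbrs[cur]):
                if w != prev and w not in path:
                    nxt = w
                    break
            if nxt is None:  # dead end inside a chain (shouldn't happen when thinned)
                break
            path.append(nxt)
            prev, cur = cur, nxt
        return path

    for start in sorted(node_vox):
        for first in sorted(nbrs[start]):
            if (start, first) in used_half_edges:
                continue
            if start in junction_vox and first in junction_vox and \
                    cluster_of[start] == cluster_of[first]:
                continue  # internal cluster adjacency, not a branch
            path = trace(start, first)
            end = path[-1]
            used_half_edges.add((start, first))
            used_half_edges.add((end, path[-2]))
            arc, chord = _path_lengths(path, vs)
            branches.append(SkeletonBranch(
                path=path, node_a=path[0], node_b=end,
                arc_length_um=arc, chord_length_um=chord))

    # pure cycles: remaining degree-2 voxels on no traced branch
    on_branch = {v for b in branches for v in b.path}
    leftover = sorted(v for v, ns in nbrs.items()
                      if len(ns) == 2 and v not in on_branch and v not in node_vox)
    visited_cycle = set()
    for v in leftover:
        if v in visited_cycle:
            continue
        path = [v]
        prev, cur = None, v
        while True:
            nxt = None
            for w in sorted(nbrs[cur]):
                if w != prev:
                    nxt = w
                    break
            if nxt is None or nxt == v:
                break
            path.append(nxt)
            prev, cur = cur, nxt
            if len(path) > len(leftover) + 1:
                break
        visited_cycle.update(path)
        path.append(v)  # close the loop at the synthetic anchor
        arc, _ = _path_lengths(path, vs)
        branches.append(SkeletonBranch(
            path=path, node_a=v, node_b=v,
            arc_length_um=arc, chord_length_um=0.0, closed=True))

    return SkeletonGraph(
        junctions=junction_reps,
        junction_clusters=clusters,
        endpoints=sorted(endpoint_vox),
        branches=branches,
        voxel_size_um=tuple(vs),
        shape=tuple(skeleton.shape),
    )


def prune_spurs(graph: SkeletonGraph, min_length_um: float) -> SkeletonGraph:
    """Drop endpoint-terminated branches shorter than ``min_length_um``.

    Off by default in :func:`summarize`; provided for noisy skeletons whose
    thinning leaves short side whiskers.
    """
    endpoint_set = set(graph.endpoints)
    kept = [b for b in graph.branches
            if not ((b.node_a in endpoint_set or b.node_b in endpoint_set)
                    and b.arc_length_um < min_length_um)]
    dropped_eps = {b.node_a for b in graph.branches if b not in kept} | \
                  {b.node_b for b in graph.branches if b not in kept}
    return SkeletonGraph(
        junctions=graph.junctions,
        junction_clusters=graph.junction_clusters,
        endpoints=[e for e in graph.endpoints
                   if e not in dropped_eps or any(e in (b.node_a, b.node_b) for b in kept)],
        branches=kept,
        voxel_size_um=graph.voxel_size_um,
        shape=graph.shape,
    )


def branch_tortuosity(graph: SkeletonGraph, include_isolated: bool = True):
    """Per-branch tortuosity (arc/chord) and its mean over open branches.

    Closed loops (chord 0) are excluded and tallied.  Isolated
    endpoint-to-endpoint segments are included by default (they are a
    superset of the junction/junction-endpoint branches); pass
    ``include_isolated=False`` to restrict to branches touching a junction.
    Returns ``(per_branch, mean, n_excluded)``.
    """
    endpoint_set = set(graph.endpoints)
    taus, excluded = [], 0
    for b in graph.branches:
        if b.closed or b.chord_length_um <= 0:
            excluded += 1
            continue
        if not include_isolated and b.node_a in endpoint_set and b.node_b in endpoint_set:
            continue
        taus.append(b.tortuosity)
    mean = float(np.mean(taus)) if taus else np.nan
    return taus, mean, excluded


def junction_density(graph: SkeletonGraph, volume_shape, voxel_size_um,
                     n_top_slices: int = 50) -> float:
    """Junctions in the top ``n_top_slices`` z-planes per mm^3 of those planes."""
    if n_top_slices <= 0:
        raise InvalidArgumentError("n_top_slices must be positive")
    nz = volume_shape[0]
    n_top = min(n_top_slices, nz)
    count = sum(1 for j in graph.junctions if j[0] < n_top)
    vs = np.asarray(voxel_size_um, dtype=float)
    vol_mm3 = (n_top * vs[0] * volume_shape[1] * vs[1]
               * volume_shape[2] * vs[2]) * 1e-9  # um^3 -> mm^3
    return count / vol_mm3


def summarize(graph: SkeletonGraph, volume_shape=None, voxel_size_um=None,
              n_top_slices: int = 50) -> MorphometrySummary:
    """Morphometry summary: mean tortuosity, counts, junction density."""
    taus, mean, excluded = branch_tortuosity(graph) if graph.branches else ([], np.nan, 0)
    if volume_shape is None:
        volume_shape = graph.shape
    if voxel_size_um is None:
        voxel_size_um = graph.voxel_size_um
    density = junction_density(graph, volume_shape, voxel_size_um, n_top_slices)
    return MorphometrySummary(
        mean_tortuosity=mean,
        n_junctions=graph.n_junctions,
        n_endpoints=graph.n_endpoints,
        n_branches=graph.n_branches,
        junction_density_per_mm3=density,
        n_excluded_branches=excluded,
        per_branch_tortuosity=taus,
    )
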