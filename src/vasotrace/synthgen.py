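"""Synthetic data generators for every input the pipeline consumes.

Each generator is a pure function of its spec (including the seed) and
returns the simulated data together with a machine-readable ground-truth
record, so every downstream module can be tested without any acquisition
data.  The phantoms emulate:

* two-photon vascular stacks (sulforhodamine channel): tubes of prescribed
  centerline geometry and radius under a Gaussian PSF and additive noise;
* line-scan kymographs: dark RBC streaks of prescribed slope on a bright
  plasma background;
* amyloid stacks (Methoxy-X04 channel): CAA painted on vessel walls plus
  spherical parenchymal plaques;
* longitudinal cohort tables with a group x age interaction and a
  sigmoidal amyloid accumulation trajectory;
* DEG tables and cell-type marker atlases with prescribed overlap.

Noise is additive Gaussian throughout; shot noise is deliberately not
modelled because every downstream operation is threshold- or
variance-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .exceptions import InvalidSpecError

__all__ = [
    "Branch",
    "VascularPhantomSpec",
    "KymographSpec",
    "AmyloidPhantomSpec",
    "CohortSimSpec",
    "OmicsSimSpec",
    "generate_vascular_volume",
    "generate_kymograph",
    "generate_amyloid_volume",
    "simulate_cohort",
    "simulate_omics_tables",
    "sigmoid",
]

# Centerline sampling step in voxels; small enough that arc lengths are
# resolution independent for the curvatures phantoms use.
_SAMPLE_STEP_VOX = 0.5


def sigmoid(t, lower, upper, rate, inflection):
    """Four-parameter logistic y = A + (B - A) / (1 + exp(-k (t - t0)))."""
    t = np.asarray(t, dtype=float)
    return lower + (upper - lower) / (1.0 + np.exp(-rate * (t - inflection)))


# ---------------------------------------------------------------------------
# vascular phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Branch:
    """One vessel branch: control points (voxel coords, (z, y, x)) + radius."""

    control_points: tuple
    radius_vox: float

    def points(self) -> np.ndarray:
        return np.asarray(self.control_points, dtype=float)


@dataclass(frozen=True)
class VascularPhantomSpec:
    volume_shape: tuple  # (nz, ny, nx)
    branches: tuple  # sequence of Branch
    voxel_size_um: tuple = (3.0, 2.2, 2.2)  # two-photon z step 3, xy 2.2
    psf_sigma_vox: float = 0.0
    noise_sd: float = 0.0
    background_level: float = 0.0
    seed: int = 0

    def __post_init__(self):
        shape = np.asarray(self.volume_shape)
        if len(shape) != 3 or np.any(shape <= 0):
            raise InvalidSpecError("volume_shape must be a positive voxel triple")
        if np.any(np.asarray(self.voxel_size_um) <= 0):
            raise InvalidSpecError("voxel sizes must be positive")
        if not (0 <= self.background_level < 1):
            raise InvalidSpecError("background_level must lie in [0, 1)")
        if self.psf_sigma_vox < 0 or self.noise_sd < 0:
            raise InvalidSpecError("psf_sigma_vox and noise_sd must be nonnegative")
        if not self.branches:
            raise InvalidSpecError("at least one branch required")
        for b in self.branches:
            pts = b.points()
            if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
                raise InvalidSpecError("each branch needs >= 2 control points")
            if np.any(pts < 0) or np.any(pts > shape - 1):
                raise InvalidSpecError("control points must lie inside volume_shape")
            if b.radius_vox < 1:
                raise InvalidSpecError("branch radius must be >= 1 voxel")


def _sample_centerline(points: np.ndarray, step: float = _SAMPLE_STEP_VOX) -> np.ndarray:
    """Cubic-spline interpolation through control points at <= `step` voxels."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return points[:1]
    n = max(int(np.ceil(total / step)) + 1, points.shape[0])
    grid = np.linspace(0.0, total, n)
    if points.shape[0] == 2:
        # two points define a straight segment
        frac = (grid / total)[:, None]
        return points[0] + frac * (points[1] - points[0])
    spl = CubicSpline(s, points, axis=0, bc_type="natural")
    return spl(grid)


def _branch_geometry(samples: np.ndarray, voxel_size_um) -> dict:
    steps = np.diff(samples, axis=0)
    arc_vox = float(np.sum(np.linalg.norm(steps, axis=1)))
    chord_vox = float(np.linalg.norm(samples[-1] - samples[0]))
    vs = np.asarray(voxel_size_um, dtype=float)
    arc_um = float(np.sum(np.linalg.norm(steps * vs, axis=1)))
    chord_um = float(np.linalg.norm((samples[-1] - samples[0]) * vs))
    tort = arc_vox / chord_vox if chord_vox > 0 else np.inf
    return {
        "arc_length_vox": arc_vox,
        "chord_length_vox": chord_vox,
        "arc_length_um": arc_um,
        "chord_length_um": chord_um,
        "tortuosity": tort,
    }


def _rasterize_tube(shape, samples: np.ndarray, radius: float) -> np.ndarray:
    """Voxel in mask iff its center lies within `radius` of the centerline."""
    mask = np.zeros(shape, dtype=bool)
    lo = np.maximum(np.floor(samples.min(axis=0) - radius).astype(int), 0)
    hi = np.minimum(np.ceil(samples.max(axis=0) + radius).astype(int) + 1,
                    np.asarray(shape))
    grids = np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)], indexing="ij")
    coords = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    tree = cKDTree(samples)
    d, _ = tree.query(coords, k=1, distance_upper_bound=radius + 1e-9)
    inside = d <= radius
    idx = coords[inside].astype(int)
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return mask


def _truth_nodes(branches_samples: Sequence[np.ndarray]) -> dict:
    """Cluster coincident branch ends into junctions (>=3 ends) / endpoints (1)."""
    ends = []
    for bi, samples in enumerate(branches_samples):
        ends.append((bi, 0, samples[0]))
        ends.append((bi, 1, samples[-1]))
    used = [False] * len(ends)
    junctions, endpoints = [], []
    for i, (_, _, p) in enumerate(ends):
        if used[i]:
            continue
        cluster = [i]
        used[i] = True
        for j in range(i + 1, len(ends)):
            if not used[j] and np.linalg.norm(ends[j][2] - p) < 0.75:
                cluster.append(j)
                used[j] = True
        coord = np.mean([ends[k][2] for k in cluster], axis=0)
        if len(cluster) >= 3:
            junctions.append(coord.tolist())
        elif len(cluster) == 1:
            endpoints.append(coord.tolist())
        # degree-2 coincidences are pass-through points, neither kind
    return {"junctions": junctions, "endpoints": endpoints}


def generate_vascular_volume(spec: VascularPhantomSpec):
    """Render a tubular vascular phantom.

    Returns ``(intensity, mask, truth)`` where ``truth`` carries the sampled
    centerlines, per-branch arc/chord lengths and tortuosity, and the
    junction / endpoint coordinates implied by the construction.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.volume_shape)
    mask = np.zeros(shape, dtype=bool)
    branch_records = []
    all_samples = []
    for bi, b in enumerate(spec.branches):
        samples = _sample_centerline(b.points())
        all_samples.append(samples)
        mask |= _rasterize_tube(shape, samples, b.radius_vox)
        rec = _branch_geometry(samples, spec.voxel_size_um)
        rec.update(branch_index=bi, radius_vox=b.radius_vox,
                   centerline=samples.tolist())
        branch_records.append(rec)

    img = mask.astype(np.float32)
    if spec.psf_sigma_vox > 0:
        img = ndimage.gaussian_filter(img, spec.psf_sigma_vox)
    intensity = spec.background_level + (1.0 - spec.background_level) * img
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=shape)
    truth = {"branches": branch_records, **_truth_nodes(all_samples)}
    truth["n_junctions"] = len(truth["junctions"])
    truth["n_endpoints"] = len(truth["endpoints"])
    return intensity.astype(np.float32), mask, truth


# ---------------------------------------------------------------------------
# kymograph
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KymographSpec:
    duration_ms: float
    true_velocity_um_s: float
    line_rate_hz: float = 833.34  # two-photon line-scan acquisition speed
    pixel_pitch_um: float = 0.37
    n_pixels: int = 96  # spatial samples along the scanned centerline
    streak_width_px: float = 2.0  # Gaussian sigma of a streak profile
    streak_spacing_px: float = 10.0
    contrast: float = 0.8
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.line_rate_hz <= 0 or self.pixel_pitch_um <= 0:
            raise InvalidSpecError("line rate and pixel pitch must be positive")
        if self.duration_ms <= 0 or self.n_pixels < 4:
            raise InvalidSpecError("duration and field width must be positive")
        if not (0 < self.contrast <= 1):
            raise InvalidSpecError("contrast must lie in (0, 1]")
        if self.streak_width_px <= 0 or self.streak_spacing_px <= 0:
            raise InvalidSpecError("streak width and spacing must be positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be nonnegative")
        if not np.isfinite(self.true_velocity_um_s):
            raise InvalidSpecError("velocity must be finite")

    @property
    def slope_px_per_line(self) -> float:
        return self.true_velocity_um_s / (self.pixel_pitch_um * self.line_rate_hz)


def generate_kymograph(spec: KymographSpec):
    """Render a line-scan kymograph (rows = lines/time, cols = space).

    Moving RBCs are dark Gaussian streaks of slope
    ``v / (pixel_pitch * line_rate)`` px/line on a bright plasma background.
    Cells enter and exit the field; no wrap-around.
    Returns ``(image, truth)`` with the stored slope and velocity.
    """
    rng = np.random.default_rng(spec.seed)
    n_lines = int(round(spec.duration_ms / 1000.0 * spec.line_rate_hz))
    n_lines = max(n_lines, 2)
    slope = spec.slope_px_per_line
    # seed cell anchor positions at line 0, extended so streaks cover the
    # whole field over the full duration regardless of travel direction
    reach = abs(slope) * n_lines + 3 * spec.streak_width_px
    span = spec.n_pixels + 2 * reach
    # Poisson-like random cell positions (mean gap = streak_spacing_px);
    # irregular spacing mirrors real capillary flow and avoids the angular
    # aliasing a strictly periodic train would create
    n_cells = max(int(round(span / spec.streak_spacing_px)), 1)
    x0 = np.sort(rng.uniform(-reach, spec.n_pixels + reach, size=n_cells))
    lines = np.arange(n_lines)[:, None]
    cols = np.arange(spec.n_pixels)[None, :]
    img = np.ones((n_lines, spec.n_pixels), dtype=np.float64)
    centers = x0[None, :] + slope * np.arange(n_lines)[:, None]  # (lines, cells)
    sig2 = 2.0 * spec.streak_width_px ** 2
    for c in range(centers.shape[1]):
        cc = centers[:, c]
        # skip cells that never enter the field
        if cc.max() < -3 * spec.streak_width_px or cc.min() > spec.n_pixels + 3 * spec.streak_width_px:
            continue
        img -= spec.contrast * np.exp(-((cols - cc[:, None]) ** 2) / sig2)
    del lines
    np.clip(img, 0.0, None, out=img)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    truth = {
        "true_velocity_um_s": spec.true_velocity_um_s,
        "slope_px_per_line": slope,
        "n_lines": n_lines,
        "line_period_s": 1.0 / spec.line_rate_hz,
        "pixel_pitch_um": spec.pixel_pitch_um,
    }
    return img, truth


# ---------------------------------------------------------------------------
# amyloid phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmyloidPhantomSpec:
    phantom: VascularPhantomSpec
    # (branch index, covered fraction of MIP footprint in [0,1], wall intensity)
    caa_segments: tuple = ()
    # (center voxel (z,y,x), radius_vox, intensity)
    plaques: tuple = ()
    background_level: float = 0.05
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        shape = np.asarray(self.phantom.volume_shape)
        for bi, frac, _ in self.caa_segments:
            if not (0 <= frac <= 1):
                raise InvalidSpecError("covered fraction must lie in [0, 1]")
            if not (0 <= bi < len(self.phantom.branches)):
                raise InvalidSpecError("CAA branch index out of range")
        for center, radius, _ in self.plaques:
            c = np.asarray(center)
            if np.any(c < 0) or np.any(c > shape - 1):
                raise InvalidSpecError("plaque center must lie inside the volume")
            if radius <= 0:
                raise InvalidSpecError("plaque radius must be positive")


def _ball_voxels(shape, center, radius):
    lo = np.maximum(np.floor(np.asarray(center) - radius).astype(int), 0)
    hi = np.minimum(np.ceil(np.asarray(center) + radius).astype(int) + 1,
                    np.asarray(shape))
    grids = np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)], indexing="ij")
    coords = np.stack([g.ravel() for g in grids], axis=1)
    d = np.linalg.norm(coords - np.asarray(center), axis=1)
    return coords[d <= radius]


def generate_amyloid_volume(spec: AmyloidPhantomSpec):
    """Render the amyloid channel matching a vascular phantom.

    CAA is painted on the wall of the listed branches so that its MIP
    covers an exact fraction of that branch's MIP footprint (pixels are
    claimed in order of arc position, emulating a deposit growing along the
    vessel).  Plaques are rendered as solid balls.  Returns
    ``(amyloid_volume, roi_labels, truth)`` where ``roi_labels`` is the 2D
    per-branch MIP footprint label image (branch i -> label i + 1).
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.phantom.volume_shape)
    _, vessel_mask, vessel_truth = generate_vascular_volume(spec.phantom)

    # per-branch masks and MIP footprints
    branch_masks = []
    for b, rec in zip(spec.phantom.branches, vessel_truth["branches"]):
        samples = np.asarray(rec["centerline"])
        branch_masks.append(_rasterize_tube(shape, samples, b.radius_vox))
    roi_labels = np.zeros(shape[1:], dtype=np.int32)
    for bi, bm in enumerate(branch_masks):
        fp = bm.any(axis=0)
        roi_labels[fp & (roi_labels == 0)] = bi + 1

    vol = np.full(shape, spec.background_level, dtype=np.float64)
    truth = {"caa": [], "plaques": [], "warnings": []}

    for bi, frac, wall_intensity in spec.caa_segments:
        bm = branch_masks[bi]
        fp = bm.any(axis=0)
        fp_idx = np.argwhere(fp)
        n_fp = len(fp_idx)
        if n_fp == 0:
            continue
        # order footprint pixels by arc position of the nearest centerline sample
        samples = np.asarray(vessel_truth["branches"][bi]["centerline"])
        tree = cKDTree(samples[:, 1:])  # (y, x) of centerline
        _, nearest = tree.query(fp_idx.astype(float))
        order = np.argsort(nearest, kind="stable")
        n_cov = int(round(frac * n_fp))
        covered = fp_idx[order[:n_cov]]
        cov_im = np.zeros(shape[1:], dtype=bool)
        cov_im[covered[:, 0], covered[:, 1]] = True
        paint = bm & cov_im[None, :, :]
        vol[paint] = np.maximum(vol[paint], wall_intensity)
        truth["caa"].append({
            "branch_index": bi,
            "requested_fraction": frac,
            "covered_fraction": n_cov / n_fp,
            "coverage_pct": 100.0 * n_cov / n_fp,
            "n_footprint_px": n_fp,
            "n_covered_px": n_cov,
        })

    for center, radius, intensity in spec.plaques:
        coords = _ball_voxels(shape, center, radius)
        overlap = bool(vessel_mask[coords[:, 0], coords[:, 1], coords[:, 2]].any())
        if overlap:
            truth["warnings"].append(
                f"plaque at {tuple(center)} overlaps the vessel mask")
        vol[coords[:, 0], coords[:, 1], coords[:, 2]] = intensity
        truth["plaques"].append({
            "center": list(center),
            "radius_vox": radius,
            "n_voxels": int(len(coords)),
            "overlaps_vessel": overlap,
        })

    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=shape)
    truth["vessel_truth"] = vessel_truth
    return vol, roi_labels, truth


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimSpec:
    """Longitudinal two-group design (control = 0, amyloidosis model = 1).

    ``outcome`` follows the interaction model
    ``b0 + age_slope*age + group_effect*g + interaction_coef*age*g + noise``;
    ``amyloid`` follows the 4-parameter sigmoid in age for the model group
    and stays at the sigmoid's lower asymptote for controls.
    """

    n_per_cell: int = 5  # subjects per group x sex cell
    age_grid_months: tuple = (3.0, 6.0, 9.0, 12.0, 15.0, 18.0)
    intercept: float = 1.2
    age_slope: float = 0.0
    group_effect: float = 0.0
    interaction_coef: float = 0.0
    sigmoid_params: tuple = (0.0, 30.0, 0.8, 12.04)  # (A, B, k, t0 months)
    noise_sd: float = 0.05
    amyloid_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        ages = np.asarray(self.age_grid_months, dtype=float)
        if ages.size == 0:
            raise InvalidSpecError("age grid must be non-empty")
        if np.any(np.diff(ages) <= 0):
            raise InvalidSpecError("age grid must be strictly increasing")
        if self.n_per_cell <= 0:
            raise InvalidSpecError("n_per_cell must be positive")
        if self.noise_sd < 0 or self.amyloid_noise_sd < 0:
            raise InvalidSpecError("noise SDs must be nonnegative")


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Simulate a longitudinal cohort table (one row per subject x session)."""
    rng = np.random.default_rng(spec.seed)
    lower, upper, rate, t0 = spec.sigmoid_params
    rows = []
    sid = 0
    for group in (0, 1):
        for sex in ("F", "M"):
            for _ in range(spec.n_per_cell):
                sid += 1
                for age in spec.age_grid_months:
                    y = (spec.intercept + spec.age_slope * age
                         + spec.group_effect * group
                         + spec.interaction_coef * age * group)
                    if spec.noise_sd > 0:
                        y += rng.normal(0.0, spec.noise_sd)
                    if group == 1:
                        amy = sigmoid(age, lower, upper, rate, t0)
                    else:
                        amy = lower
                    if spec.amyloid_noise_sd > 0:
                        amy = amy + rng.normal(0.0, spec.amyloid_noise_sd)
                    rows.append((f"s{sid:04d}", float(age), sex, group,
                                 float(y), float(amy)))
    return pd.DataFrame(
        rows, columns=["subject", "age", "sex", "group", "outcome", "amyloid"])


# ---------------------------------------------------------------------------
# omics simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OmicsSimSpec:
    gene_universe_size: int
    marker_sets: dict = field(default_factory=dict)  # cell type -> set of gene ids
    deg_effects: dict = field(default_factory=dict)  # gene id -> (log2fc, is_null)
    n_samples_per_group: int = 6
    detection_power: float = 1.0  # P(FDR < 0.05) for a true non-null gene
    contrast: str = "AD_vs_WT"
    seed: int = 0

    def __post_init__(self):
        if self.gene_universe_size <= 0:
            raise InvalidSpecError("gene universe must be positive")
        universe = set(self.gene_ids())
        for ct, genes in self.marker_sets.items():
            if not set(genes) <= universe:
                raise InvalidSpecError(f"marker set '{ct}' has genes outside the universe")
        if not set(self.deg_effects) <= universe:
            raise InvalidSpecError("deg_effects contain genes outside the universe")
        if not (0 <= self.detection_power <= 1):
            raise InvalidSpecError("detection_power must lie in [0, 1]")

    def gene_ids(self):
        return [f"g{i:05d}" for i in range(self.gene_universe_size)]


def simulate_omics_tables(spec: OmicsSimSpec):
    """Build a DEG table plus marker-atlas tables with known overlap truth.

    True non-null genes draw FDR < 0.05 with probability ``detection_power``;
    null genes deterministically draw FDR >= 0.05.  Returns
    ``(deg_table, atlas_table, truth)``.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    lfc = rng.normal(0.0, 0.15, size=len(genes))
    fdr = rng.uniform(0.05, 1.0, size=len(genes))
    detected = set()
    index = {g: i for i, g in enumerate(genes)}
    for g, (effect, is_null) in spec.deg_effects.items():
        i = index[g]
        lfc[i] = effect
        if not is_null and rng.uniform() < spec.detection_power:
            fdr[i] = rng.uniform(1e-6, 0.0499)
            detected.add(g)
        else:
            fdr[i] = rng.uniform(0.05, 1.0)
    deg_table = pd.DataFrame({
        "gene": genes,
        "log2fc": lfc,
        "fdr": fdr,
        "contrast": spec.contrast,
    })
    atlas_rows = []
    for ct, gs in spec.marker_sets.items():
        for rank, g in enumerate(sorted(gs)):
            atlas_rows.append((ct, g, rank + 1))
    atlas_table = pd.DataFrame(atlas_rows, columns=["cell_type", "gene", "rank"])
    true_degs = {g for g, (_, is_null) in spec.deg_effects.items() if not is_null}
    truth = {
        "true_degs": sorted(true_degs),
        "detected_degs": sorted(detected),
        "overlaps": {ct: sorted(detected & set(gs))
                     for ct, gs in spec.marker_sets.items()},
        "overlap_counts": {ct: len(detected & set(gs))
                           for ct, gs in spec.marker_sets.items()},
    }
    return deg_table, atlas_table, truth
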