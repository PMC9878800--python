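"""Aorta geometry: isotropic resampling, centerline extraction, orthogonal
analysis planes, nearest-plane voxel assignment, branch exclusion, and
AAo / arch / DAo segment labelling.

All geometric quantities live in world millimetres with the voxel-center
convention (voxel ``(i, j, k)`` at ``(i*sx, j*sy, k*sz)``), so anisotropic
acquisitions are handled correctly before resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, GeometryError

# Segment label codes
EXCLUDED = 0
AAO = 1
ARCH = 2
DAO = 3
SEGMENT_NAMES = {AAO: "AAo", ARCH: "Arch", DAO: "DAo", EXCLUDED: "excluded"}


@dataclass
class Centerline:
    """Ordered centerline points at 1 mm arc-length spacing.

    ``points`` are world-mm coordinates ordered from the aortic-valve end
    toward the descending aorta; ``tangents`` are unit vectors pointing in
    the direction of travel (i.e. away from the valve), and ``arc_length``
    is the cumulative distance from the valve end.
    """

    points: np.ndarray  # (n, 3) mm
    tangents: np.ndarray  # (n, 3) unit
    arc_length: np.ndarray  # (n,) mm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.tangents = np.asarray(self.tangents, dtype=float)
        self.arc_length = np.asarray(self.arc_length, dtype=float)
        if not (len(self.points) == len(self.tangents) == len(self.arc_length)):
            raise ConfigurationError("centerline fields must have equal length")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    def reversed(self) -> "Centerline":
        """Same path traversed distal -> valve (flips every tangent)."""
        arc = self.arc_length[-1] - self.arc_length[::-1]
        return Centerline(self.points[::-1].copy(), -self.tangents[::-1], arc)


@dataclass
class PlaneSet:
    """One orthogonal analysis plane per centerline point.

    The plane normal equals the local tangent, so positive projected
    velocity is forward flow (away from the valve) and negative projected
    velocity is reverse flow (toward the valve).
    """

    origins: np.ndarray  # (n, 3) mm
    normals: np.ndarray  # (n, 3) unit
    arc_length: np.ndarray  # (n,) mm

    @property
    def n(self) -> int:
        return len(self.origins)


@dataclass
class LandmarkSet:
    """Arc-length positions (mm from the valve end) of the four manually
    placed analysis planes that delineate the aortic segments:
    sinotubular junction, proximal to the first supra-aortic branch,
    distal to the left subclavian artery, and proximal to the celiac
    artery."""

    stj_mm: float
    branch_mm: float
    subclavian_mm: float
    celiac_mm: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.stj_mm, self.branch_mm, self.subclavian_mm, self.celiac_mm)

    def validate(self, total_length_mm: float) -> None:
        vals = self.as_tuple()
        if not all(np.diff(vals) > 0):
            raise ConfigurationError(f"landmarks must be strictly increasing, got {vals}")
        if vals[0] < 0 or vals[-1] > total_length_mm:
            raise ConfigurationError(
                f"landmarks {vals} outside centerline range [0, {total_length_mm:.1f}] mm"
            )


def resample_isotropic(
    data: np.ndarray,
    spacing_mm,
    target_mm: float = 1.0,
    order: int = 1,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Resample the three spatial axes of ``data`` to isotropic resolution.

    ``data`` may carry trailing non-spatial axes (time, vector component),
    which are resampled slice-by-slice.  Interpolation order 1 (trilinear)
    is used for velocities and magnitude, order 0 (nearest) for masks.
    World coordinates are preserved: output voxel ``i`` sits at
    ``i * target_mm`` on each axis.
    """
    spacing = tuple(float(s) for s in spacing_mm)
    if np.allclose(spacing, target_mm):
        return data.copy(), (target_mm,) * 3
    old_shape = data.shape[:3]
    new_shape = tuple(int(np.floor((n - 1) * s / target_mm)) + 1 for n, s in zip(old_shape, spacing))
    grids = [np.arange(n_new) * target_mm / s for n_new, s in zip(new_shape, spacing)]
    coords = np.meshgrid(*grids, indexing="ij")
    coords = np.stack(coords, axis=0)

    trailing = data.shape[3:]
    flat = data.reshape(old_shape + (-1,))
    out = np.empty(new_shape + (flat.shape[-1],), dtype=float)
    for j in range(flat.shape[-1]):
        out[..., j] = ndimage.map_coordinates(
            np.asarray(flat[..., j], dtype=float), coords, order=order, mode="nearest"
        )
    out = out.reshape(new_shape + trailing)
    if data.dtype == bool:
        out = out > 0.5
    return out, (target_mm,) * 3


def _resample_polyline(points: np.ndarray, step_mm: float = 1.0) -> np.ndarray:
    """Resample a polyline at uniform arc-length steps (chord-length param)."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.arange(0.0, np.floor(total / step_mm) * step_mm + step_mm / 2, step_mm)
    return np.column_stack([np.interp(targets, s, points[:, d]) for d in range(3)])


def _smooth_polyline(points: np.ndarray, sigma_samples: float) -> np.ndarray:
    """Gaussian smoothing with odd (point-symmetric) end padding, which
    continues the path linearly through each endpoint instead of flattening
    it — plain boundary modes would pull the ends inward and shorten the
    recovered vessel."""
    pad = int(np.ceil(4 * sigma_samples)) + 1
    if len(points) <= pad:
        return points
    padded = np.pad(points, ((pad, pad), (0, 0)), mode="reflect", reflect_type="odd")
    smoothed = ndimage.gaussian_filter1d(padded, sigma_samples, axis=0, mode="nearest")
    return smoothed[pad:-pad]


def _tangents_from_points(points: np.ndarray) -> np.ndarray:
    t = np.gradient(points, axis=0)
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    return t / norms


def _recentre_polyline(
    points: np.ndarray,
    tangents: np.ndarray,
    mask: np.ndarray,
    spacing,
    edt: np.ndarray,
    slab_mm: float = 1.5,
    iterations: int = 2,
) -> np.ndarray:
    """Sub-voxel refinement: pull each point toward the distance-weighted
    centroid of the lumen cross-section slab perpendicular to the local
    tangent.  The axial component of each shift is removed so the
    refinement re-centres without shrinking the path."""
    from scipy.spatial import cKDTree

    vox = np.argwhere(mask)
    world = vox * np.asarray(spacing, dtype=float)
    weights = edt[mask] ** 2
    tree = cKDTree(world)
    shape = np.asarray(mask.shape)
    pts = points.copy()
    for _ in range(iterations):
        new = pts.copy()
        for i, (p, t) in enumerate(zip(pts, tangents)):
            nearest_vox = tuple(np.clip(np.round(p / spacing).astype(int), 0, shape - 1))
            r_loc = max(float(edt[nearest_vox]), 2.0)
            idx = np.asarray(tree.query_ball_point(p, r_loc + 1.0))
            if idx.size < 5:
                continue
            axial = (world[idx] - p) @ t
            sel = idx[np.abs(axial) <= slab_mm]
            if sel.size < 5:
                continue
            w = weights[sel]
            shift = (w[:, None] * (world[sel] - p)).sum(axis=0) / w.sum()
            shift -= (shift @ t) * t
            new[i] = p + shift
        pts = new
    return pts


def extract_centerline(
    mask: np.ndarray,
    spacing_mm,
    seed_valve,
    seed_distal,
    smooth_sigma_mm: float = 2.0,
    step_mm: float = 1.0,
) -> Centerline:
    """Extract the vessel centerline between two seed voxels.

    The path maximises distance to the lumen boundary: a minimum-cost
    geometric path is traced through ``1 / (d + 0.5)**2`` where ``d`` is
    the Euclidean distance transform of the mask (mm), then Gaussian
    smoothed, refined to sub-voxel accuracy by distance-weighted
    cross-section re-centring, and resampled at ``step_mm`` arc-length
    spacing.  Tangents are central differences, renormalised, and
    oriented valve -> distal.

    Raises
    ------
    GeometryError
        If a seed lies outside the mask or the two seeds are not in the
        same connected component (the case that forced scan exclusions in
        clinical practice).
    """
    from skimage.graph import MCP_Geometric

    mask = np.asarray(mask).astype(bool)
    seed_valve = tuple(int(i) for i in seed_valve)
    seed_distal = tuple(int(i) for i in seed_distal)
    for name, seed in (("valve", seed_valve), ("distal", seed_distal)):
        if not mask[seed]:
            raise GeometryError(f"{name} seed {seed} lies outside the aorta mask")
    labels, _ = ndimage.label(mask)
    if labels[seed_valve] != labels[seed_distal]:
        raise GeometryError("seeds lie in disconnected components of the mask")

    spacing = tuple(float(s) for s in spacing_mm)
    edt = ndimage.distance_transform_edt(mask, sampling=spacing)
    cost = np.where(mask, 1.0 / (edt + 0.5) ** 2, np.inf)
    mcp = MCP_Geometric(cost, sampling=spacing)
    _, _ = mcp.find_costs([seed_valve], [seed_distal])
    path = np.asarray(mcp.traceback(seed_distal), dtype=float)  # valve -> distal
    pts = path * np.asarray(spacing)

    # Smooth in samples: the raw path advances by roughly one voxel per step.
    step = float(np.median(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    sigma = smooth_sigma_mm / max(step, 1e-6)
    if sigma > 0 and len(pts) > 4:
        pts = _smooth_polyline(pts, sigma)

    pts = _resample_polyline(pts, step_mm)
    tangents = _tangents_from_points(pts)
    pts = _recentre_polyline(pts, tangents, mask, spacing, edt)
    pts = _resample_polyline(pts, step_mm)
    tangents = _tangents_from_points(pts)
    chord = pts[-1] - pts[0]
    if np.dot(tangents.sum(axis=0), chord) < 0:  # pragma: no cover - defensive
        pts, tangents = pts[::-1], -tangents[::-1]
    # nominal arc-length parameterisation: the resample targets themselves
    arc = np.arange(len(pts), dtype=float) * step_mm
    return Centerline(pts, tangents, arc)


def build_planes(centerline: Centerline) -> PlaneSet:
    """One orthogonal plane per centerline point; normal = local tangent,
    oriented forward (away from the valve).  Orientation is verified
    against the valve -> distal chord."""
    chord = centerline.points[-1] - centerline.points[0]
    if np.dot(centerline.tangents.sum(axis=0), chord) < 0:
        raise GeometryError("centerline tangents are oriented toward the valve; reverse the path")
    return PlaneSet(
        origins=centerline.points.copy(),
        normals=centerline.tangents.copy(),
        arc_length=centerline.arc_length.copy(),
    )


def assign_voxels(
    mask: np.ndarray,
    centerline: Centerline,
    spacing_mm,
    chunk: int = 65536,
) -> np.ndarray:
    """Map every mask voxel to the index of the Euclidean-nearest
    centerline point (ties -> lowest index); -1 outside the mask."""
    mask = np.asarray(mask).astype(bool)
    assignment = np.full(mask.shape, -1, dtype=np.int32)
    idx = np.argwhere(mask)
    if idx.size == 0:
        return assignment
    world = idx * np.asarray(spacing_mm, dtype=float)
    nearest = np.empty(len(world), dtype=np.int32)
    for start in range(0, len(world), chunk):
        d = cdist(world[start : start + chunk], centerline.points)
        nearest[start : start + chunk] = np.argmin(d, axis=1)  # first min = lowest index
    assignment[tuple(idx.T)] = nearest
    return assignment


def exclude_branches(mask: np.ndarray, exclusion_roi: np.ndarray | None = None) -> np.ndarray:
    """Remove a manually drawn region of exclusion (e.g. supra-aortic
    branches) from the segmentation.  Warns if the ROI removes more than
    half of the mask."""
    mask = np.asarray(mask).astype(bool)
    if exclusion_roi is None:
        return mask.copy()
    roi = np.asarray(exclusion_roi).astype(bool)
    if roi.shape != mask.shape:
        raise ConfigurationError("exclusion ROI shape does not match the mask")
    out = mask & ~roi
    removed = mask.sum() - out.sum()
    if mask.sum() and removed > 0.5 * mask.sum():
        warnings.warn(
            f"exclusion ROI removes {removed} of {int(mask.sum())} mask voxels (> 50%)",
            stacklevel=2,
        )
    return out


def boxes_to_roi(boxes, shape) -> np.ndarray:
    """Build an exclusion ROI from a list of voxel-index boxes
    ``[[x0, x1, y0, y1, z0, z1], ...]`` (half-open upper bounds)."""
    roi = np.zeros(shape, dtype=bool)
    for b in boxes:
        x0, x1, y0, y1, z0, z1 = (int(v) for v in b)
        roi[x0:x1, y0:y1, z0:z1] = True
    return roi


def label_segments(
    assignment: np.ndarray,
    centerline: Centerline,
    landmarks: LandmarkSet,
) -> np.ndarray:
    """Label each assigned voxel AAo / arch / DAo from the four landmark
    planes; voxels proximal to the sinotubular junction (LVOT) or distal
    to the celiac plane are excluded.

    Segment intervals are half-open in arc length: AAo = [STJ, branch),
    arch = [branch, subclavian), DAo = [subclavian, celiac] with the final
    celiac plane inclusive, so the three segments partition the
    non-excluded mask exactly.
    """
    landmarks.validate(centerline.total_length)
    s = centerline.arc_length
    plane_label = np.full(centerline.n, EXCLUDED, dtype=np.int8)
    stj, branch, subclavian, celiac = landmarks.as_tuple()
    plane_label[(s >= stj) & (s < branch)] = AAO
    plane_label[(s >= branch) & (s < subclavian)] = ARCH
    plane_label[(s >= subclavian) & (s <= celiac)] = DAO

    labels = np.zeros(assignment.shape, dtype=np.int8)
    inside = assignment >= 0
    labels[inside] = plane_label[assignment[inside]]
    return labels
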