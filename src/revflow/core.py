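"""Voxel-wise forward/reverse flow quantification.

The core computation: project each voxel's velocity onto the unit normal
of its nearest orthogonal analysis plane (positive = forward, away from
the valve), detect end systole as the first inflection of the mean
net-flow curve after peak systole, truncate to the common 600 ms cardiac
window, and integrate the positive and negative parts of the projected
velocity into per-voxel forward and reverse flow volumes (mL per window
per 1 mm^3 voxel) for systole, diastole and the whole cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .errors import ConfigurationError, TimingError
from .geometry import SEGMENT_NAMES, PlaneSet

log = logging.getLogger(__name__)

WINDOW_NAMES = ("systolic", "diastolic", "whole_cycle")
DIRECTIONS = ("reverse", "forward")


def project_velocities(
    values: np.ndarray,
    assignment: np.ndarray,
    planes: PlaneSet,
) -> np.ndarray:
    """Signed along-track velocity ``s_i(t) = v_i(t) . n_hat`` (mm/s).

    ``values`` has shape ``(nx, ny, nz, nt, 3)``; the result has shape
    ``(nx, ny, nz, nt)`` and is zero outside the assigned mask.  Positive
    values are forward flow (away from the valve)."""
    values = np.asarray(values)
    if assignment.shape != values.shape[:3]:
        raise ConfigurationError("assignment map does not match the velocity grid")
    inside = assignment >= 0
    normals = planes.normals[assignment[inside]]  # (m, 3)
    s = np.zeros(values.shape[:4], dtype=np.float64)
    s[inside] = np.einsum("mtc,mc->mt", values[inside].astype(np.float64), normals)
    return s


def net_flow_curve(
    along_track: np.ndarray,
    mask: np.ndarray,
    face_area_mm2: float = 1.0,
) -> np.ndarray:
    """Mean net flow over the segmentation, per frame:
    ``Q(t) = mean_i s_i(t) * a`` in mm^3/s."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ConfigurationError("cannot compute a net-flow curve over an empty mask")
    return along_track[mask].mean(axis=0) * face_area_mm2


def detect_end_systole(q: np.ndarray, smooth_width: int = 3) -> int:
    """End systole: the first inflection of the mean net-flow curve after
    peak systole.

    The curve is lightly smoothed (moving average, default width 3) to
    suppress single-frame noise.  Peak systole is the earliest global
    maximum ``k*``; end systole is the first frame ``k > k*`` where the
    centred second difference ``Q(k+1) - 2 Q(k) + Q(k-1)`` changes sign
    (concave -> convex).  If no sign change exists (e.g. strictly convex
    monotone decay), the frame of the post-peak minimum is returned with
    a logged warning.

    Raises
    ------
    TimingError
        If the curve has fewer than 5 frames or peaks at the final frame
        (the cycle cannot be split into systole and diastole).
    """
    q = np.asarray(q, dtype=float)
    n = q.size
    if n < 5:
        raise TimingError(f"net-flow curve has only {n} frames; need at least 5")
    qs = uniform_filter1d(q, smooth_width, mode="nearest") if smooth_width > 1 else q
    k_star = int(np.argmax(qs))
    if k_star >= n - 1:
        raise TimingError("net-flow curve peaks at the final frame; cannot split phases")
    d2 = qs[2:] - 2.0 * qs[1:-1] + qs[:-2]  # d2[k-1] is centred at frame k
    tol = 1e-9 * max(np.abs(d2).max(), 1.0)
    candidates = range(k_star + 1, n - 1)
    if candidates:
        first = d2[k_star]  # curvature just after the peak
        if abs(first) <= tol:
            return k_star + 1
        sign0 = np.sign(first)
        for k in range(k_star + 2, n - 1):
            if d2[k - 1] * sign0 <= tol:
                return k
    # no curvature sign change after the peak: first post-peak local minimum
    for k in range(k_star + 1, n - 1):
        if q[k] <= q[k + 1]:
            k_min = k
            break
    else:
        k_min = n - 1
    log.warning(
        "no post-peak inflection found in the net-flow curve; "
        "falling back to the post-peak minimum at frame %d",
        k_min,
    )
    return k_min


@dataclass
class CardiacWindow:
    """Frames included in the common cardiac window.

    ``n_inc`` frames (those fully contained in ``window_ms``, i.e.
    ``floor(window_ms / dt_ms)``, capped by the acquisition) are split
    into systole ``[0, k_es)`` and diastole ``[k_es, n_inc)``."""

    n_inc: int
    k_es: int
    dt_ms: float
    window_ms: float = 600.0

    def __post_init__(self) -> None:
        if not (0 < self.k_es < self.n_inc):
            raise TimingError(
                f"end-systole frame {self.k_es} must lie strictly inside [1, {self.n_inc})"
            )


def truncate_window(n_frames: int, dt_ms: float, window_ms: float = 600.0) -> int:
    """Number of frames fully contained in the common window:
    ``min(n_frames, floor(window_ms / dt_ms))``.

    Raises :class:`TimingError` if fewer than 5 frames remain (temporal
    resolution too coarse to split the cycle)."""
    if dt_ms <= 0:
        raise ConfigurationError("dt_ms must be positive")
    n_inc = int(min(n_frames, np.floor(window_ms / dt_ms)))
    if n_inc < 5:
        raise TimingError(
            f"only {n_inc} frames fit the {window_ms:.0f} ms window at dt = {dt_ms} ms"
        )
    return n_inc


@dataclass
class ReverseFlowMap:
    """Per-voxel flow volumes in mL per window per voxel.

    ``maps[(window, direction)]`` is a 3D array for window in
    {systolic, diastolic, whole_cycle} and direction in
    {reverse, forward}.  Whole-cycle maps are constructed as the
    elementwise sum of the systolic and diastolic maps, so that identity
    is exact by construction."""

    maps: dict = dc_field(default_factory=dict)
    window: CardiacWindow | None = None

    def __getitem__(self, key) -> np.ndarray:
        return self.maps[key]


def integrate_flow(
    along_track: np.ndarray,
    window: CardiacWindow,
    face_area_mm2: float = 1.0,
) -> ReverseFlowMap:
    """Integrate the negative (reverse) and positive (forward) parts of
    the along-track velocity over each cardiac window.

    Per voxel: ``R(W) = sum_{t in W} max(0, -s(t)) * a * dt`` converted
    to mL (1 mL = 1000 mm^3), and analogously for forward flow."""
    s = np.asarray(along_track, dtype=np.float64)
    dt_s = window.dt_ms / 1000.0
    scale = face_area_mm2 * dt_s / 1000.0  # mm/s * mm^2 * s -> mm^3 -> mL
    rev = np.clip(-s, 0.0, None)
    fwd = np.clip(s, 0.0, None)
    slices = {
        "systolic": slice(0, window.k_es),
        "diastolic": slice(window.k_es, window.n_inc),
    }
    maps = {}
    for wname, sl in slices.items():
        maps[(wname, "reverse")] = rev[..., sl].sum(axis=-1) * scale
        maps[(wname, "forward")] = fwd[..., sl].sum(axis=-1) * scale
    for direction in DIRECTIONS:
        maps[("whole_cycle", direction)] = (
            maps[("systolic", direction)] + maps[("diastolic", direction)]
        )
    return ReverseFlowMap(maps=maps, window=window)


def segment_means(map3d: np.ndarray, labels: np.ndarray) -> dict:
    """Arithmetic mean and SD of a per-voxel map over each labelled
    segment.  Empty segments are reported as missing (NaN), never zero."""
    out = {}
    for code, name in SEGMENT_NAMES.items():
        if name == "excluded":
            continue
        vals = map3d[labels == code]
        if vals.size == 0:
            out[name] = {"mean": np.nan, "sd": np.nan, "n": 0}
        else:
            out[name] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std()),
                "n": int(vals.size),
            }
    return out


def segment_statistics(rfmap: ReverseFlowMap, labels: np.ndarray) -> pd.DataFrame:
    """Tidy per-segment statistics for every window and flow direction."""
    rows = []
    for (wname, direction), map3d in rfmap.maps.items():
        for seg, stats in segment_means(map3d, labels).items():
            rows.append(
                {
                    "segment": seg,
                    "window": wname,
                    "direction": direction,
                    "mean_mL": stats["mean"],
                    "sd_mL": stats["sd"],
                    "n_voxels": stats["n"],
                    "k_es": rfmap.window.k_es if rfmap.window else -1,
                    "n_inc": rfmap.window.n_inc if rfmap.window else -1,
                }
            )
    return pd.DataFrame(rows).sort_values(["direction", "window", "segment"]).reset_index(
        drop=True
    )
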