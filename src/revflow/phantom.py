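"""Synthetic 4D flow aorta phantom with analytic ground truth.

The phantom emulates a curved "candy-cane" thoracic aorta: a straight
ascending segment, a semicircular arch, and a straight descending
segment, all of circular cross-section.  Lumen voxels carry an axial
velocity ``u(rho, t) = U(t) * profile(rho)`` along the local centerline
tangent, where ``U(t)`` is a raised-cosine systolic ejection waveform.
Two reverse-flow components can be injected:

* a near-wall retrograde *ring* during systolic frames (the flow-reversal
  pattern that accompanies valve-stenosis jets), subtracting a constant
  amplitude for ``rho/R >= rho0``; and
* a uniform *regurgitant* plug during diastolic frames (valve
  regurgitation), subtracting a constant amplitude across the lumen.

Acquisition artifacts (spatially linear phase offsets, Gaussian velocity
noise, venc wrapping) are injected separately so that the artifact-free
field and its analytic reverse-flow ground truth remain available.  The
ground truth is evaluated on the acquisition grid before any
interpolation; closed-form cross-section integrals of the reverse
component are exact for both plug and parabolic profiles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError
from .geometry import Centerline, LandmarkSet
from .io import FlowDataset, VelocityField4D, save_dataset

SEGMENTS = ("AAo", "Arch", "DAo")
WINDOWS = ("systolic", "diastolic", "whole_cycle")


@dataclass(frozen=True)
class ReverseRingSpec:
    """Near-wall systolic retrograde ring: subtract ``amplitude_mms`` from
    the axial velocity for ``rho/R in [inner_fraction, 1]`` during frames
    ``frame_range[0] <= t < frame_range[1]``."""

    inner_fraction: float = 0.7
    amplitude_mms: float = 150.0
    frame_range: tuple[int, int] = (1, 6)


@dataclass(frozen=True)
class RegurgitantSpec:
    """Uniform diastolic regurgitant plug: subtract ``amplitude_mms``
    across the whole lumen during ``frame_range``."""

    amplitude_mms: float = 100.0
    frame_range: tuple[int, int] = (9, 15)


@dataclass
class PhantomSpec:
    """Full parameterisation of the synthetic aorta.

    Geometry is a straight ascending segment (length ``ascending_len_mm``
    along +z), a semicircular arch of radius ``arch_radius_mm`` in the
    y-z plane, and a straight descending segment (``descending_len_mm``
    along -z), centred laterally in the grid.  The default grid and
    dimensions are scaled so that lumen, arch and a surrounding
    static-tissue shell fit a 64 x 64 x 96 volume at 1 mm isotropic
    resolution with at least a two-voxel margin.

    The default temporal resolution (40 ms) and venc (150 cm/s) sit in
    the ranges typical of prospectively gated aortic 4D flow protocols
    (TR 36-42 ms, venc 150-300 cm/s).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 96)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_frames: int = 15
    dt_ms: float = 40.0
    venc_cms: float = 150.0
    tube_radius_mm: float = 10.0
    ascending_len_mm: float = 40.0
    arch_radius_mm: float = 19.0
    descending_len_mm: float = 45.0
    peak_velocity_mms: float = 800.0
    t_end_systole_ms: float = 360.0
    profile: str = "parabolic"  # or "plug"
    reverse_ring: ReverseRingSpec = field(default_factory=ReverseRingSpec)
    regurgitant: RegurgitantSpec = field(default_factory=RegurgitantSpec)
    noise_sigma_mms: float = 0.0
    # per-component linear phase-offset coefficients (c0, cx, cy, cz):
    # offset = c0 + cx*x + cy*y + cz*z with world coordinates in mm
    eddy_coeffs: tuple[tuple[float, float, float, float], ...] = (
        (0.0, 0.0, 0.0, 0.0),
        (0.0, 0.0, 0.0, 0.0),
        (0.0, 0.0, 0.0, 0.0),
    )
    alias_enabled: bool = False
    seed: int = 0
    window_ms: float = 600.0

    def __post_init__(self) -> None:
        self.validate()

    # ---- derived geometry -------------------------------------------------
    @property
    def extent_mm(self) -> np.ndarray:
        """World extent spanned by voxel centers on each axis."""
        return (np.asarray(self.grid_shape) - 1) * np.asarray(self.spacing_mm)

    @property
    def plane_x_mm(self) -> float:
        return float(self.extent_mm[0] / 2.0)

    @property
    def arch_center_y_mm(self) -> float:
        return float(self.extent_mm[1] / 2.0)

    @property
    def z_start_mm(self) -> float:
        """Valve-end z chosen so top and bottom tube margins are equal."""
        ez = self.extent_mm[2]
        return float(
            (ez - 2 * self.ascending_len_mm - self.arch_radius_mm + self.descending_len_mm) / 2.0
        )

    @property
    def total_arc_length_mm(self) -> float:
        return self.ascending_len_mm + np.pi * self.arch_radius_mm + self.descending_len_mm

    def default_landmarks(self) -> LandmarkSet:
        """Segment-delineating planes: STJ 10 mm above the valve end,
        branch plane at the end of the ascending segment, subclavian plane
        at the end of the arch, celiac plane 8 mm before the distal end."""
        a = self.ascending_len_mm
        return LandmarkSet(
            stj_mm=10.0,
            branch_mm=a,
            subclavian_mm=a + np.pi * self.arch_radius_mm,
            celiac_mm=self.total_arc_length_mm - 8.0,
        )

    def default_seeds(self) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
        """Voxel indices nearest the valve and distal lumen end points."""
        cl = build_candycane_centerline(self)
        sp = np.asarray(self.spacing_mm)
        valve = cl.points[0] / sp
        distal = cl.points[-1] / sp
        return tuple(int(round(v)) for v in valve), tuple(int(round(v)) for v in distal)

    # ---- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.n_frames < 8:
            raise ConfigurationError("n_frames must be >= 8")
        if self.dt_ms <= 0 or self.venc_cms <= 0:
            raise ConfigurationError("dt_ms and venc_cms must be positive")
        for name in (
            "tube_radius_mm",
            "ascending_len_mm",
            "arch_radius_mm",
            "descending_len_mm",
            "peak_velocity_mms",
            "t_end_systole_ms",
            "noise_sigma_mms",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.profile not in ("plug", "parabolic"):
            raise ConfigurationError(f"unknown velocity profile {self.profile!r}")
        if not (0.0 <= self.reverse_ring.inner_fraction < 1.0):
            raise ConfigurationError("reverse_ring.inner_fraction must be in [0, 1)")
        if self.reverse_ring.amplitude_mms < 0 or self.regurgitant.amplitude_mms < 0:
            raise ConfigurationError("reverse amplitudes must be non-negative")
        for fr in (self.reverse_ring.frame_range, self.regurgitant.frame_range):
            if not (0 <= fr[0] <= fr[1] <= self.n_frames):
                raise ConfigurationError(f"frame range {fr} outside [0, {self.n_frames})")
        if len(self.eddy_coeffs) != 3 or any(len(c) != 4 for c in self.eddy_coeffs):
            raise ConfigurationError("eddy_coeffs must be three (c0, cx, cy, cz) quadruples")
        # tube must fit the grid with >= 2-voxel margin
        ex, ey, ez = self.extent_mm
        r, R = self.tube_radius_mm, self.arch_radius_mm
        margin = 2.0 * max(self.spacing_mm)
        lo_y = self.arch_center_y_mm - R - r
        hi_y = self.arch_center_y_mm + R + r
        top = self.z_start_mm + self.ascending_len_mm + R + r
        bottom = (
            min(self.z_start_mm, self.z_start_mm + self.ascending_len_mm - self.descending_len_mm)
            - r
        )
        checks = [
            self.plane_x_mm - r >= margin,
            ex - self.plane_x_mm - r >= margin,
            lo_y >= margin,
            ey - hi_y >= margin,
            bottom >= margin,
            ez - top >= margin,
        ]
        if not all(checks):
            raise ConfigurationError(
                "candy-cane geometry does not fit the grid with a 2-voxel margin"
            )

    def replace(self, **kwargs) -> "PhantomSpec":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key, sub in (("reverse_ring", ReverseRingSpec), ("regurgitant", RegurgitantSpec)):
            if key in d and isinstance(d[key], dict):
                sub_d = dict(d[key])
                if "frame_range" in sub_d:
                    sub_d["frame_range"] = tuple(sub_d["frame_range"])
                d[key] = sub(**sub_d)
        for key in ("grid_shape", "spacing_mm"):
            if key in d:
                d[key] = tuple(d[key])
        if "eddy_coeffs" in d:
            d["eddy_coeffs"] = tuple(tuple(c) for c in d["eddy_coeffs"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Analytic ground truth computed from the phantom construction
    before noise and artifacts."""

    s_true: np.ndarray  # (nx, ny, nz, nt) signed along-track velocity, mm/s
    lumen_mask: np.ndarray  # (nx, ny, nz) bool
    static_shell: np.ndarray  # (nx, ny, nz) bool, zero-velocity high-magnitude shell
    per_segment: dict  # {segment: {window: mL per voxel}}
    k_es: int  # true end-systole frame index
    n_inc: int  # frames inside the common 600 ms window


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def forward_amplitude(spec: PhantomSpec, t_ms: np.ndarray) -> np.ndarray:
    """Raised-cosine ejection: ``0.5 * peak * (1 - cos(2*pi*t/T))`` for
    ``0 <= t < T`` (T = t_end_systole_ms), zero afterwards.  The waveform
    peaks at T/2 and its first post-peak inflection lies at 3T/4."""
    t = np.asarray(t_ms, dtype=float)
    T = spec.t_end_systole_ms
    u = 0.5 * spec.peak_velocity_mms * (1.0 - np.cos(2.0 * np.pi * t / T))
    return np.where((t >= 0) & (t < T), u, 0.0)


def frame_amplitudes(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame forward U(t), ring A(t) and regurgitant B(t) amplitudes."""
    k = np.arange(spec.n_frames)
    U = forward_amplitude(spec, k * spec.dt_ms)
    A = np.where(
        (k >= spec.reverse_ring.frame_range[0]) & (k < spec.reverse_ring.frame_range[1]),
        spec.reverse_ring.amplitude_mms,
        0.0,
    )
    B = np.where(
        (k >= spec.regurgitant.frame_range[0]) & (k < spec.regurgitant.frame_range[1]),
        spec.regurgitant.amplitude_mms,
        0.0,
    )
    return U, A, B


def true_end_systole_frame(spec: PhantomSpec) -> int:
    """Frame index nearest the analytic first post-peak inflection of the
    raised-cosine ejection waveform (at 3/4 of t_end_systole_ms)."""
    return int(round(0.75 * spec.t_end_systole_ms / spec.dt_ms))


def included_frames(spec: PhantomSpec) -> int:
    return int(min(spec.n_frames, np.floor(spec.window_ms / spec.dt_ms)))


# ---------------------------------------------------------------------------
# centerline and synthesis
# ---------------------------------------------------------------------------

def build_candycane_centerline(spec: PhantomSpec) -> Centerline:
    """Analytic candy-cane centerline: points at exact 1 mm arc-length
    spacing with exact unit tangents, ordered valve -> descending end."""
    spec.validate()
    A, R, D = spec.ascending_len_mm, spec.arch_radius_mm, spec.descending_len_mm
    L = spec.total_arc_length_mm
    s = np.arange(0.0, np.floor(L) + 0.5, 1.0)
    x = np.full_like(s, spec.plane_x_mm)
    yc, z0 = spec.arch_center_y_mm, spec.z_start_mm
    zA = z0 + A

    y = np.empty_like(s)
    z = np.empty_like(s)
    ty = np.empty_like(s)
    tz = np.empty_like(s)

    asc = s <= A
    y[asc], z[asc] = yc - R, z0 + s[asc]
    ty[asc], tz[asc] = 0.0, 1.0

    arch = (s > A) & (s <= A + np.pi * R)
    theta = (s[arch] - A) / R
    y[arch] = yc - R * np.cos(theta)
    z[arch] = zA + R * np.sin(theta)
    ty[arch], tz[arch] = np.sin(theta), np.cos(theta)

    desc = s > A + np.pi * R
    d = s[desc] - A - np.pi * R
    y[desc], z[desc] = yc + R, zA - d
    ty[desc], tz[desc] = 0.0, -1.0

    points = np.column_stack([x, y, z])
    tangents = np.column_stack([np.zeros_like(s), ty, tz])
    return Centerline(points, tangents, s.copy())


def _voxel_world_coords(spec: PhantomSpec) -> np.ndarray:
    idx = np.indices(spec.grid_shape).reshape(3, -1).T
    return idx * np.asarray(spec.spacing_mm)


def _radial_geometry(spec: PhantomSpec, centerline: Centerline):
    """Per-voxel nearest centerline index, perpendicular radius (mm) and
    along-tangent offset (mm), vectorised over the whole grid."""
    world = _voxel_world_coords(spec)
    tree = cKDTree(centerline.points)
    dist, nearest = tree.query(world, workers=-1)
    rel = world - centerline.points[nearest]
    axial = np.einsum("ij,ij->i", rel, centerline.tangents[nearest])
    perp = np.sqrt(np.maximum(dist**2 - axial**2, 0.0))
    return nearest, perp, axial


def synthesize(spec: PhantomSpec):
    """Build the phantom.

    Returns ``(velocity, magnitude, mask, ground_truth)`` where
    ``velocity`` is the artifact-free :class:`VelocityField4D`,
    ``magnitude`` a 4D magnitude series (high in lumen and static shell,
    low elsewhere), ``mask`` the binary lumen segmentation, and
    ``ground_truth`` the analytic construction record.
    """
    spec.validate()
    cl = build_candycane_centerline(spec)
    nearest, perp, axial = _radial_geometry(spec, cl)
    r = spec.tube_radius_mm
    # Voxels nearest an interior point sit within ~0.5 mm axially by
    # construction; the axial bound only trims the tube ends flat instead
    # of leaving spherical caps at the valve and distal openings.
    half_step = 0.6
    axial_ok = (np.abs(axial) <= half_step) | ((nearest > 0) & (nearest < cl.n - 1))
    lumen_flat = (perp <= r) & axial_ok
    # static-tissue shell at 2-2.4 lumen radii: thick enough to anchor the
    # phase-offset fit, thin enough that background still dominates the
    # magnitude histogram
    shell_flat = (perp >= 2.0 * r) & (perp <= 2.4 * r) & axial_ok

    shape = spec.grid_shape
    lumen = lumen_flat.reshape(shape)
    shell = shell_flat.reshape(shape) & ~lumen

    U, A, B = frame_amplitudes(spec)
    x_frac = perp[lumen_flat] / r
    prof = np.ones_like(x_frac) if spec.profile == "plug" else 1.0 - x_frac**2
    in_ring = x_frac >= spec.reverse_ring.inner_fraction

    # signed along-track velocity for lumen voxels, all frames: (M, T)
    s_lumen = (
        prof[:, None] * U[None, :]
        - np.where(in_ring[:, None], A[None, :], 0.0)
        - B[None, :]
    )

    nt = spec.n_frames
    s_true = np.zeros(shape + (nt,), dtype=np.float32)
    s_true[lumen] = s_lumen.astype(np.float32)

    values = np.zeros(shape + (nt, 3), dtype=np.float32)
    tang = cl.tangents[nearest[lumen_flat]]  # (M, 3)
    values[lumen] = (s_lumen[:, :, None] * tang[:, None, :]).astype(np.float32)

    magnitude3d = np.full(shape, 0.05, dtype=np.float32)
    magnitude3d[shell] = 0.7
    magnitude3d[lumen] = 1.0
    magnitude = np.repeat(magnitude3d[..., None], nt, axis=3)

    velocity = VelocityField4D(values, spec.spacing_mm, spec.dt_ms, spec.venc_cms)
    gt = GroundTruth(
        s_true=s_true,
        lumen_mask=lumen,
        static_shell=shell,
        per_segment=analytic_reverse_flow(spec),
        k_es=true_end_systole_frame(spec),
        n_inc=included_frames(spec),
    )
    return velocity, magnitude, lumen, gt


def inject_artifacts(
    field: VelocityField4D, spec: PhantomSpec, rng: np.random.Generator | None = None
) -> VelocityField4D:
    """Add the acquisition error model: a per-component spatially linear
    phase offset everywhere (static tissue included), i.i.d. Gaussian
    velocity noise, and — if enabled — venc wrapping
    ``v -> ((v + venc) mod 2 venc) - venc``."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    values = np.asarray(field.values, dtype=np.float64).copy()
    shape = field.grid_shape
    coords = [np.arange(n) * s for n, s in zip(shape, field.spacing_mm)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    for c, (c0, cx, cy, cz) in enumerate(spec.eddy_coeffs):
        off = c0 + cx * X + cy * Y + cz * Z
        values[..., c] += off[..., None]
    if spec.noise_sigma_mms > 0:
        values += rng.normal(0.0, spec.noise_sigma_mms, size=values.shape)
    if spec.alias_enabled:
        venc = field.venc_mms
        values = np.mod(values + venc, 2.0 * venc) - venc
    return VelocityField4D(
        values.astype(np.float32), field.spacing_mm, field.dt_ms, field.venc_cms
    )


# ---------------------------------------------------------------------------
# analytic ground truth
# ---------------------------------------------------------------------------

def _interval_reverse_parabolic(U: float, C: float, y1: float, y2: float) -> float:
    """``int_{y1}^{y2} max(0, C - U*(1 - y)) dy`` with ``y = (rho/R)^2``.

    This is the cross-section reverse-flow integral over one radial
    interval for the parabolic profile (the substitution ``y = x^2``
    absorbs the ``2x dx`` area element of the unit disk)."""
    if U == 0.0:
        return max(C, 0.0) * (y2 - y1)
    # integrand g(y) = (C - U) + U*y is increasing in y; positive for y > yc
    yc = (U - C) / U
    a = max(y1, min(y2, yc))
    if a >= y2:
        return 0.0
    return (C - U) * (y2 - a) + U * (y2**2 - a**2) / 2.0


def _interval_reverse_plug(U: float, C: float, y1: float, y2: float) -> float:
    return max(C - U, 0.0) * (y2 - y1)


def disk_mean_reverse_velocity(spec: PhantomSpec, frame: int) -> float:
    """Closed-form lumen cross-section average of ``max(0, -u(rho, t))``
    (mm/s) at one frame."""
    U, A, B = frame_amplitudes(spec)
    u, a, b = float(U[frame]), float(A[frame]), float(B[frame])
    x0sq = spec.reverse_ring.inner_fraction**2
    f = _interval_reverse_plug if spec.profile == "plug" else _interval_reverse_parabolic
    return f(u, b, 0.0, x0sq) + f(u, a + b, x0sq, 1.0)


def disk_mean_forward_velocity(spec: PhantomSpec, frame: int) -> float:
    """Closed-form cross-section average of ``max(0, +u(rho, t))`` (mm/s).

    Uses ``max(0, u) = u + max(0, -u)`` and the closed-form disk mean of
    the signed velocity."""
    U, A, B = frame_amplitudes(spec)
    u, a, b = float(U[frame]), float(A[frame]), float(B[frame])
    x0sq = spec.reverse_ring.inner_fraction**2
    mean_prof = 1.0 if spec.profile == "plug" else 0.5
    signed = u * mean_prof - a * (1.0 - x0sq) - b
    return signed + disk_mean_reverse_velocity(spec, frame)


def analytic_reverse_flow(spec: PhantomSpec, face_area_mm2: float = 1.0) -> dict:
    """Expected per-voxel mean reverse flow (mL per window per voxel) for
    each segment and cardiac window.

    The reverse components are axially uniform along the tube, so every
    segment shares the same cross-section integral; values are reported
    per segment to mirror the measurement layout.  Windows use the true
    end-systole frame (systole = frames ``[0, k_es)``, diastole =
    ``[k_es, n_inc)``) and the common 600 ms truncation.
    """
    k_es = true_end_systole_frame(spec)
    n_inc = included_frames(spec)
    dt_s = spec.dt_ms / 1000.0
    m = np.array([disk_mean_reverse_velocity(spec, k) for k in range(spec.n_frames)])
    per_frame_ml = m * face_area_mm2 * dt_s / 1000.0  # mm^3 -> mL
    windows = {
        "systolic": float(per_frame_ml[:k_es].sum()),
        "diastolic": float(per_frame_ml[k_es:n_inc].sum()),
    }
    windows["whole_cycle"] = windows["systolic"] + windows["diastolic"]
    return {seg: dict(windows) for seg in SEGMENTS}


# ---------------------------------------------------------------------------
# dataset export
# ---------------------------------------------------------------------------

def generate_dataset(spec: PhantomSpec, out_dir: str | Path | None = None):
    """Synthesize, inject the configured artifacts, and (optionally) write
    the dataset to ``out_dir`` in the NIfTI + JSON sidecar layout.

    Returns ``(FlowDataset, GroundTruth)``.
    """
    clean, magnitude, mask, gt = synthesize(spec)
    degraded = inject_artifacts(clean, spec)
    seeds = spec.default_seeds()
    meta = {
        "seed": spec.seed,
        "spec": spec.to_dict(),
        "seed_valve": list(seeds[0]),
        "seed_distal": list(seeds[1]),
        "landmarks_mm": list(spec.default_landmarks().as_tuple()),
        "true_arc_length_mm": spec.total_arc_length_mm,
    }
    dataset = FlowDataset(degraded, magnitude, mask, meta)
    if out_dir is not None:
        save_dataset(out_dir, dataset)
        truth_path = Path(out_dir) / "ground_truth.json"
        truth_path.write_text(
            json.dumps(
                {
                    "per_segment": gt.per_segment,
                    "k_es": gt.k_es,
                    "n_inc": gt.n_inc,
                },
                indent=2,
            )
        )
    return dataset, gt
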