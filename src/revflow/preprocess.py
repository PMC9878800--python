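"""Phase-contrast velocity preprocessing.

Classical implementations of the standard corrections applied to 4D flow
velocity data before analysis:

* **static-tissue detection** — voxels with high time-averaged signal
  magnitude and low temporal velocity variation;
* **eddy-current / phase-offset correction** — a polynomial surface
  (order 0 or 1 in x, y, z) fit to the time-averaged velocity over static
  tissue and subtracted from every frame, per component.  Phase offsets
  from eddy currents and Maxwell terms are spatially smooth and
  temporally static, so a time-averaged linear fit is the standard model;
* **velocity antialiasing** — sequential temporal unwrapping: whenever
  the jump between consecutive frames exceeds venc, multiples of
  ``2*venc`` are added to minimise the jump.  The first frame is trusted;
* **noise masking** — voxels below a magnitude-histogram quantile are
  flagged and excluded from downstream statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .io import VelocityField4D

log = logging.getLogger(__name__)


def detect_static_tissue(
    magnitude: np.ndarray,
    field: VelocityField4D,
    mag_quantile: float = 0.6,
    std_threshold_mms: float = 20.0,
) -> np.ndarray:
    """Binary mask of static tissue: time-averaged magnitude strictly
    above the ``mag_quantile`` threshold of the volume AND temporal
    standard deviation of the velocity magnitude below
    ``std_threshold_mms``."""
    if magnitude.shape != field.values.shape[:4]:
        raise ConfigurationError("magnitude and velocity grids are not co-registered")
    mag_mean = np.asarray(magnitude, dtype=float).mean(axis=3)
    thresh = np.quantile(mag_mean, mag_quantile)
    speed = np.linalg.norm(np.asarray(field.values, dtype=float), axis=4)  # (x,y,z,t)
    pulsatility = speed.std(axis=3)
    static = (mag_mean > thresh) & (pulsatility < std_threshold_mms)
    if not static.any():
        warnings.warn(
            "static-tissue mask is empty; eddy-current correction will be skipped",
            stacklevel=2,
        )
    return static


@dataclass
class EddyFit:
    """Fitted per-component phase-offset surfaces."""

    order: int
    coeffs: np.ndarray  # (3, n_terms): [c0] or [c0, cx, cy, cz]
    n_static: int


def _design_matrix(coords: np.ndarray, order: int) -> np.ndarray:
    if order == 0:
        return np.ones((len(coords), 1))
    return np.column_stack([np.ones(len(coords)), coords])


def correct_eddy_currents(
    field: VelocityField4D,
    static_mask: np.ndarray,
    order: int = 1,
) -> tuple[VelocityField4D, EddyFit | None]:
    """Fit and subtract a spatially polynomial, temporally static velocity
    offset estimated from static tissue.

    Per component, a polynomial of the given order in world coordinates
    (x, y, z) is least-squares fit to the *time-averaged* velocity over
    static-tissue voxels and subtracted from every frame.  A
    rank-deficient order-1 fit (e.g. static tissue confined to a plane)
    falls back to order 0 with a warning.  An empty static mask leaves
    the field unchanged.
    """
    if order not in (0, 1):
        raise ConfigurationError("eddy-current correction order must be 0 or 1")
    static_mask = np.asarray(static_mask).astype(bool)
    if not static_mask.any():
        warnings.warn("empty static mask: skipping eddy-current correction", stacklevel=2)
        return field.copy(), None

    idx = np.argwhere(static_mask)
    coords = idx * np.asarray(field.spacing_mm)
    X = _design_matrix(coords, order)
    if order == 1 and np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn(
            "static tissue does not support an order-1 fit (rank deficient); "
            "falling back to order 0",
            stacklevel=2,
        )
        order = 0
        X = _design_matrix(coords, order)

    mean_vel = np.asarray(field.values, dtype=np.float64).mean(axis=3)  # (x,y,z,3)
    targets = mean_vel[static_mask]  # (n_static, 3)
    coeffs, *_ = np.linalg.lstsq(X, targets, rcond=None)  # (n_terms, 3)

    shape = field.grid_shape
    grids = [np.arange(n) * s for n, s in zip(shape, field.spacing_mm)]
    XX, YY, ZZ = np.meshgrid(*grids, indexing="ij")
    corrected = np.asarray(field.values, dtype=np.float64).copy()
    for c in range(3):
        if order == 0:
            surface = np.full(shape, coeffs[0, c])
        else:
            surface = coeffs[0, c] + coeffs[1, c] * XX + coeffs[2, c] * YY + coeffs[3, c] * ZZ
        corrected[..., c] -= surface[..., None]
    fit = EddyFit(order=order, coeffs=coeffs.T.copy(), n_static=len(idx))
    return (
        VelocityField4D(corrected, field.spacing_mm, field.dt_ms, field.venc_cms),
        fit,
    )


def unwrap_aliasing(field: VelocityField4D) -> VelocityField4D:
    """Temporal venc unwrapping, per voxel and component.

    Whenever the jump between consecutive frames exceeds venc (mm/s) the
    series is shifted by the multiple of ``2*venc`` that minimises the
    jump; the first frame is trusted.  Values may exceed venc after
    unwrapping — that is the point.  The number of voxels whose series
    changed is logged so ambiguous multi-wrap cases are visible rather
    than silently fixed.
    """
    period = 2.0 * field.venc_mms
    values = np.asarray(field.values, dtype=np.float64)
    unwrapped = np.unwrap(values, axis=3, period=period)
    changed = np.any(unwrapped != values, axis=(3, 4)).sum()
    if changed:
        log.info("venc unwrapping adjusted %d voxels", int(changed))
    return VelocityField4D(unwrapped, field.spacing_mm, field.dt_ms, field.venc_cms)


def wrap_velocities(values: np.ndarray, venc_mms: float) -> np.ndarray:
    """The acquisition-side wrap operator ``v -> ((v + venc) mod 2 venc) - venc``."""
    return np.mod(np.asarray(values, dtype=float) + venc_mms, 2.0 * venc_mms) - venc_mms


def noise_mask(magnitude: np.ndarray, quantile: float = 0.1) -> np.ndarray:
    """Voxels whose time-averaged magnitude falls strictly below the given
    quantile of the volume histogram; flagged voxels are excluded from all
    downstream statistics."""
    if not 0.0 < quantile < 1.0:
        raise ConfigurationError("noise quantile must lie in (0, 1)")
    mag_mean = np.asarray(magnitude, dtype=float).mean(axis=3)
    return mag_mean < np.quantile(mag_mean, quantile)


def preprocess_field(
    field: VelocityField4D,
    magnitude: np.ndarray,
    eddy_order: int = 1,
    mag_quantile: float = 0.6,
    std_threshold_mms: float = 20.0,
    noise_quantile: float = 0.1,
):
    """Full correction chain: unwrap -> static-tissue detection ->
    eddy-current correction -> noise mask.

    Returns ``(corrected_field, info)`` where ``info`` carries the static
    and noise masks and the eddy fit.
    """
    unwrapped = unwrap_aliasing(field)
    static = detect_static_tissue(magnitude, unwrapped, mag_quantile, std_threshold_mms)
    corrected, fit = correct_eddy_currents(unwrapped, static, order=eddy_order)
    noisy = noise_mask(magnitude, noise_quantile)
    info = {"static_mask": static, "noise_mask": noisy, "eddy_fit": fit}
    return corrected, info
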