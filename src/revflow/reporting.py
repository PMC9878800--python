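"""Visualisation and secondary quantification.

Sagittal mean-intensity-projection (MIP) reverse-flow maps, the
clinical-context total-reverse-flow estimate through a circular 2D ROI
at the mid-ascending aorta, Bland-Altman interobserver agreement, and
the report bundle writer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError


@dataclass
class MIPImage:
    """2D mean-intensity projection of a 3D per-voxel flow map.

    ``values`` holds the mean over contributing mask voxels along the
    projection axis; pixels with no contributing voxel are flagged empty
    via ``counts == 0`` (their value is NaN, never a silent zero)."""

    values: np.ndarray  # (a, b) float, NaN where empty
    counts: np.ndarray  # (a, b) int

    @property
    def empty(self) -> np.ndarray:
        return self.counts == 0


def mip_sagittal(map3d: np.ndarray, include_mask: np.ndarray, axis: int = 0) -> MIPImage:
    """Average a 3D map along the sagittal axis over included mask voxels.

    ``axis`` defaults to 0, the left-right axis of the package's
    RAS-oriented grids; for other orientations pass the axis explicitly
    (derive it from the NIfTI header with ``nibabel.aff2axcodes``)."""
    if axis not in (0, 1, 2):
        raise ConfigurationError("projection axis must be 0, 1 or 2")
    include = np.asarray(include_mask).astype(bool)
    if include.shape != np.asarray(map3d).shape:
        raise ConfigurationError("mask shape does not match the map")
    weighted = np.where(include, np.asarray(map3d, dtype=float), 0.0)
    counts = include.sum(axis=axis)
    sums = weighted.sum(axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return MIPImage(values=values, counts=counts.astype(int))


def estimate_plane_total(mean_per_voxel_ml: float, diameter_mm: float) -> float:
    """Estimated total reverse flow (mL) through a circular 2D ROI.

    Assumes every 1 mm^2 voxel in a circle of the given diameter (e.g.
    the mid-ascending aorta diameter) experiences the measured mean
    per-voxel flow; the continuous circle area pi*(d/2)^2 counts the
    voxels.  Report to 0.1 mL."""
    if diameter_mm < 0:
        raise ConfigurationError("diameter must be non-negative")
    return float(np.pi * (diameter_mm / 2.0) ** 2 * mean_per_voxel_ml)


@dataclass
class AgreementResult:
    """Bland-Altman interobserver agreement statistics.

    ``loa`` is the half-width 1.96 * SD of the paired differences;
    ``cov_percent`` is 100 * SD(differences) / grand mean of all
    measurements (NaN when the grand mean is zero)."""

    bias: float
    loa: float
    cov_percent: float
    r: float
    p_value: float
    n: int


def bland_altman(obs1, obs2) -> AgreementResult:
    """Agreement between paired repeated measurements.

    Differences ``d = obs1 - obs2``: bias = mean(d), LOA = 1.96 * SD(d)
    (sample SD, ddof=1), CoV relative to the grand mean, Pearson
    correlation of the pairs, and a paired two-sided t-test of bias = 0.
    """
    a = np.asarray(obs1, dtype=float)
    b = np.asarray(obs2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigurationError("observations must be two equal-length 1D arrays")
    if a.size < 3:
        raise ConfigurationError("Bland-Altman analysis needs at least 3 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    grand = float(np.concatenate([a, b]).mean())
    cov = 100.0 * sd / grand if grand != 0 else float("nan")
    if np.allclose(d, d[0]):
        # constant difference: correlation of identical-offset series is 1,
        # and the t-test of a zero-variance difference is degenerate
        r = 1.0 if (a.std() > 0 or np.allclose(a, b)) else float("nan")
        p = 1.0 if np.isclose(d[0], 0.0) else 0.0
    else:
        r = float(sps.pearsonr(a, b).statistic)
        p = float(sps.ttest_rel(a, b).pvalue)
    return AgreementResult(bias=bias, loa=1.96 * sd, cov_percent=cov, r=r, p_value=p, n=a.size)


def export_results(
    out_dir: str | Path,
    stats_df,
    mips: dict | None = None,
    manifest: dict | None = None,
) -> Path:
    """Write the report bundle: per-segment statistics CSV, MIP PNG
    renderings with a shared colour scale across windows, and a JSON
    manifest echoing every configuration parameter.  Output is
    deterministic for identical inputs (no timestamps)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stats_df.to_csv(out / "segment_stats.csv", index=False, float_format="%.9g")
    if manifest is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    if mips:
        finite = np.concatenate(
            [m.values[np.isfinite(m.values)].ravel() for m in mips.values()]
        )
        vmax = float(np.percentile(finite, 99)) if finite.size else 1.0
        for name, mip in mips.items():
            fig, ax = plt.subplots(figsize=(4, 5))
            shown = np.ma.masked_invalid(mip.values).T
            im = ax.imshow(shown, origin="lower", vmin=0.0, vmax=max(vmax, 1e-12), cmap="inferno")
            ax.set_title(name.replace("_", " "))
            ax.set_xlabel("anterior-posterior (mm)")
            ax.set_ylabel("inferior-superior (mm)")
            fig.colorbar(im, ax=ax, label="mL / window / voxel")
            fig.savefig(out / f"mip_{name}.png", dpi=120)
            plt.close(fig)
    return out
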