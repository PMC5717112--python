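"""Vessel segmentation from the PC-MRA and wall-point extraction.

The manual expert segmentation used in clinical workflows is replaced by a
deterministic surrogate (threshold on the time-averaged PC-MRA, largest
connected component, one morphological closing pass); externally supplied
masks in the same volume layout remain usable throughout the pipeline.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure

from .core import AortaMask, ParameterError, PCMRAVolume, SegmentationError, WallPointSet

log = logging.getLogger(__name__)


def segment_vessel(
    pcmra: PCMRAVolume,
    threshold_fraction: float = 0.2,
    keep_band: Optional[tuple[int, int]] = None,
) -> AortaMask:
    """Threshold segmentation of the time-averaged PC-MRA.

    Voxels with PC-MRA >= ``threshold_fraction`` x the volume's 99th
    percentile are kept, optionally restricted to an axial (z-index) band
    standing in for the annulus-to-brachiocephalic extent; the largest
    26-connected component is retained and closed once. Deterministic.
    """
    if not (0 < threshold_fraction < 1):
        raise ParameterError("threshold_fraction must lie in (0, 1)")
    thr = threshold_fraction * np.percentile(pcmra.data, 99)
    mask = (pcmra.data >= thr) & (pcmra.data > 0)
    if keep_band is not None:
        z0, z1 = keep_band
        band = np.zeros_like(mask)
        band[:, :, z0:z1] = True
        mask &= band
    if not mask.any():
        raise SegmentationError(
            f"empty segmentation at threshold_fraction={threshold_fraction} (abs {thr:.3g})"
        )
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    # edge-pad so the closing stays extensive at the volume faces
    padded = np.pad(mask, 1, mode="edge")
    padded = ndimage.binary_closing(padded, structure=np.ones((3, 3, 3), bool))
    mask = padded[1:-1, 1:-1, 1:-1] | mask
    if not mask.any():
        raise SegmentationError("segmentation empty after closing")
    return AortaMask(mask, pcmra.spacing)


def _smoothed_indicator(mask: AortaMask, sigma_vox: float = 1.0) -> np.ndarray:
    return ndimage.gaussian_filter(mask.data.astype(float), sigma=sigma_vox)


def _trilinear(volume: np.ndarray, points_mm: np.ndarray, spacing) -> np.ndarray:
    coords = (points_mm / np.asarray(spacing)).T
    return ndimage.map_coordinates(volume, coords, order=1, mode="nearest")


def extract_wall(
    mask: AortaMask,
    sigma_vox: float = 1.0,
    project_to_surface: bool = True,
) -> WallPointSet:
    """Derive wall points, outward normals and local radii from a mask.

    Wall voxels are inside voxels with at least one outside 6-neighbor.
    Each spawns a wall point that is projected (along its normal) onto the
    0.5-level set of the Gaussian-smoothed indicator, i.e. onto a sub-voxel
    estimate of the lumen surface. Normals are the normalized negative
    gradient of the smoothed indicator; the local radius is the maximal
    value of the Euclidean distance transform along the inward normal ray
    (the maximal inscribed distance). The mean per-point surface area comes
    from a marching-cubes triangulation of the smoothed indicator.
    """
    mask.validate()
    spacing = np.asarray(mask.spacing)
    cross = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(mask.data, structure=cross)
    wall_vox = mask.data & ~interior
    idx = np.argwhere(wall_vox)
    points = idx * spacing

    u = _smoothed_indicator(mask, sigma_vox)
    grads = np.gradient(u, *spacing)
    gvecs = np.stack([_trilinear(g, points, spacing) for g in grads], axis=1)
    gnorm = np.linalg.norm(gvecs, axis=1)
    degenerate = gnorm < 1e-9
    gnorm[degenerate] = 1.0
    normals = -gvecs / gnorm[:, None]  # u decreases outward
    normals[degenerate] = np.array([1.0, 0.0, 0.0])

    h = float(spacing.min())
    if project_to_surface:
        # secant search for u = 0.5 along the normal within +-1.5 voxels
        offsets = np.linspace(-1.5 * h, 1.5 * h, 13)
        samples = np.stack(
            [_trilinear(u, points + t * normals, spacing) for t in offsets], axis=1
        )
        best = np.argmin(np.abs(samples - 0.5), axis=1)
        t0 = offsets[best]
        # one linear refinement between the bracketing samples
        lo = np.clip(best - 1, 0, len(offsets) - 1)
        hi = np.clip(best + 1, 0, len(offsets) - 1)
        denom = samples[np.arange(len(points)), hi] - samples[np.arange(len(points)), lo]
        ok = np.abs(denom) > 1e-9
        frac = np.where(
            ok,
            (0.5 - samples[np.arange(len(points)), lo]) / np.where(ok, denom, 1.0),
            0.5,
        )
        t_ref = offsets[lo] + np.clip(frac, 0.0, 1.0) * (offsets[hi] - offsets[lo])
        crossed = np.abs(samples[np.arange(len(points)), best] - 0.5) < 0.45
        t_final = np.where(crossed, t_ref, t0)
        points = points + t_final[:, None] * normals
        degenerate |= ~crossed

    # local radius: max EDT along the inward ray
    edt = ndimage.distance_transform_edt(mask.data, sampling=mask.spacing)
    max_r = float(edt.max())
    steps = np.arange(0.0, max_r + 2 * h, h / 2)
    ray_vals = np.stack(
        [_trilinear(edt, points - s * normals, spacing) for s in steps], axis=1
    )
    radius = ray_vals.max(axis=1)
    thin = radius < 1.5 * h
    if thin.any():
        log.warning("%d wall points flagged: mask thinner than ~3 voxels", int(thin.sum()))
    flagged = degenerate | thin
    radius = np.maximum(radius, h / 2)  # keep the invariant radius > 0

    # per-point area from a marching-cubes surface of the smoothed indicator
    try:
        verts, faces, _, _ = measure.marching_cubes(u, level=0.5, spacing=tuple(spacing))
        total_area = measure.mesh_surface_area(verts, faces)
    except (ValueError, RuntimeError):
        sx, sy, sz = mask.spacing
        total_area = len(points) * float(np.cbrt(sx * sy * sz)) ** 2
    point_area = np.full(len(points), total_area / max(len(points), 1))

    return WallPointSet(
        points=points,
        normals=normals,
        radius=radius,
        point_area=point_area,
        flagged=flagged,
        spacing=mask.spacing,
    )
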