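"""Velocity pre-processing: eddy-current correction, phase unwrapping,
noise masking and PC-MRA computation.

The correction order follows standard phase-contrast practice: background
(eddy-current) phase offsets are removed first, aliased voxels are then
unwrapped, and a noise mask built from the magnitude images suppresses
air/background voxels before the PC-MRA is formed.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from scipy import ndimage

from .core import (
    GridError,
    MagnitudeSeries,
    ParameterError,
    PCMRAVolume,
    VelocityField4D,
)

log = logging.getLogger(__name__)

#: Temporal velocity sd (m/s) below which a voxel counts as static tissue.
STATIC_SD_THRESHOLD = 0.05
#: Time-averaged magnitude above which a voxel carries tissue signal at all.
STATIC_MAG_THRESHOLD = 0.02
#: Minimum number of static voxels required to fit the correction plane.
MIN_STATIC_VOXELS = 100


def _check_same_grid(field: VelocityField4D, magnitude: MagnitudeSeries):
    if field.grid_shape != magnitude.grid_shape:
        raise GridError(
            f"velocity grid {field.grid_shape} != magnitude grid {magnitude.grid_shape}"
        )


def static_tissue_mask(
    field: VelocityField4D,
    magnitude: MagnitudeSeries,
    sd_threshold: float = STATIC_SD_THRESHOLD,
    mag_threshold: float = STATIC_MAG_THRESHOLD,
) -> np.ndarray:
    """Voxels with tissue signal but no appreciable flow over the cycle."""
    mag_ok = magnitude.time_average() > mag_threshold
    sd = field.data.std(axis=0).max(axis=-1)  # worst direction
    return mag_ok & (sd < sd_threshold)


def correct_eddy_currents(
    field: VelocityField4D,
    magnitude: MagnitudeSeries,
    sd_threshold: float = STATIC_SD_THRESHOLD,
    mag_threshold: float = STATIC_MAG_THRESHOLD,
) -> VelocityField4D:
    """Remove residual eddy-current phase offsets.

    A first-order polynomial (constant + linear in x, y, z) is fitted per
    velocity direction to the static-tissue velocities of the last time
    frame (late diastole, where true flow is minimal) and subtracted from
    all frames. If fewer than ``MIN_STATIC_VOXELS`` static voxels are found
    the field is returned unchanged with a warning.
    """
    _check_same_grid(field, magnitude)
    static = static_tissue_mask(field, magnitude, sd_threshold, mag_threshold)
    n_static = int(static.sum())
    if n_static < MIN_STATIC_VOXELS:
        log.warning(
            "eddy-current correction skipped: only %d static voxels (< %d)",
            n_static,
            MIN_STATIC_VOXELS,
        )
        return field.copy()

    idx = np.argwhere(static).astype(float)
    coords = idx * np.asarray(field.spacing)  # mm
    design = np.column_stack([np.ones(len(coords)), coords])

    nx, ny, nz = field.grid_shape
    sx, sy, sz = field.spacing
    X, Y, Z = np.meshgrid(
        np.arange(nx) * sx, np.arange(ny) * sy, np.arange(nz) * sz, indexing="ij"
    )
    data = field.data.copy()
    last = field.data[-1]
    for d in range(3):
        beta, *_ = np.linalg.lstsq(design, last[..., d][static], rcond=None)
        plane = beta[0] + beta[1] * X + beta[2] * Y + beta[3] * Z
        data[..., d] -= plane[None, ...]
    return replace(field, data=data)


def unwrap_velocity(
    field: VelocityField4D, max_iter: int = 5
) -> VelocityField4D:
    """Repair phase-wrapped (aliased) velocities.

    Per direction and frame: voxels whose value differs from the median of
    their 3x3x3 neighborhood by more than venc are shifted by the nearest
    multiple of 2*venc toward that median. Iterated (wrapped clusters peel
    from the outside in) until nothing changes or ``max_iter`` passes.
    Idempotent on wrap-free fields.
    """
    if any(v <= 0 for v in field.venc):
        raise ParameterError("venc must be positive to unwrap")
    data = field.data.copy()
    for d in range(3):
        venc = field.venc[d]
        for t in range(field.frame_count):
            vol = data[t, ..., d]
            for _ in range(max_iter):
                med = ndimage.median_filter(vol, size=3, mode="reflect")
                diff = med - vol
                wrapped = np.abs(diff) > venc
                if not wrapped.any():
                    break
                shift = 2 * venc * np.round(diff / (2 * venc))
                vol = vol + np.where(wrapped, shift, 0.0)
            data[t, ..., d] = vol
    return replace(field, data=data)


def noise_mask(magnitude: MagnitudeSeries, floor_fraction: float = 0.1) -> np.ndarray:
    """Keep voxels whose time-averaged magnitude reaches ``floor_fraction``
    of the 99th-percentile time-averaged magnitude."""
    if not (0 < floor_fraction < 1):
        raise ParameterError("floor_fraction must lie in (0, 1)")
    avg = magnitude.time_average()
    ref = np.percentile(avg, 99)
    if ref <= 0:
        raise ParameterError("magnitude is constant zero; no noise mask possible")
    mask = avg >= floor_fraction * ref
    if not mask.any():
        log.warning("noise mask is empty at floor_fraction=%g", floor_fraction)
    return mask


def apply_noise_mask(field: VelocityField4D, mask: np.ndarray) -> VelocityField4D:
    """Zero velocities outside the noise mask."""
    data = field.data * mask[None, ..., None]
    return replace(field, data=data)


def compute_pcmra(field: VelocityField4D, magnitude: MagnitudeSeries) -> PCMRAVolume:
    """PC-MRA: per-frame magnitude x |v|, averaged over all time frames."""
    _check_same_grid(field, magnitude)
    if field.frame_count != magnitude.data.shape[0]:
        raise GridError(
            f"frame count mismatch: {field.frame_count} vs {magnitude.data.shape[0]}"
        )
    pcmra = (magnitude.data * field.speed()).mean(axis=0)
    return PCMRAVolume(pcmra, field.spacing)
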