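"""Core containers for 4D-flow MRI analysis.

Velocity data are stored in m/s on a regular grid with anisotropic voxel
spacing in mm; voxel centers sit at ``index * spacing`` (0-based indices).
Time-resolved arrays are indexed ``(frame, x, y, z)`` with a trailing
direction axis of length 3 for vector fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage


class Flow4DError(Exception):
    """Base class for all flow4d errors."""


class GeometryError(Flow4DError):
    """Phantom geometry inconsistent with the grid (e.g. tube not contained)."""


class ParameterError(Flow4DError):
    """Invalid parameter value."""


class GridError(Flow4DError):
    """Two volumes that must share a grid do not."""


class SegmentationError(Flow4DError):
    """Vessel segmentation produced an empty or invalid mask."""


class AtlasError(Flow4DError):
    """Shared-geometry construction failed."""


class RegistrationError(Flow4DError):
    """Mask registration failed or produced insufficient overlap."""


class StatsError(Flow4DError):
    """Voxel-wise statistics could not be computed."""


def _as_triple(x) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (3,))
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class VelocityField4D:
    """Time-resolved three-directional velocity volume.

    Parameters
    ----------
    data
        Array of shape ``(n_frames, nx, ny, nz, 3)`` in m/s.
    spacing
        Voxel spacing in mm per axis.
    frame_dt
        Temporal resolution in ms.
    venc
        Velocity-encoding limit in m/s, per direction. Measured values live
        in ``[-venc, venc)``; true speeds beyond it alias (wrap).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    frame_dt: float
    venc: tuple[float, float, float]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 5 or self.data.shape[-1] != 3:
            raise ParameterError(
                f"velocity data must have shape (t, nx, ny, nz, 3), got {self.data.shape}"
            )
        self.spacing = _as_triple(self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ParameterError("spacing must be positive")
        self.venc = _as_triple(self.venc)
        if self.frame_count < 1:
            raise ParameterError("need at least one frame")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("velocity data must be finite")

    @property
    def frame_count(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[1:4])

    def speed(self) -> np.ndarray:
        """|v| per frame, shape (t, nx, ny, nz)."""
        return np.linalg.norm(self.data, axis=-1)

    def frame(self, t: int) -> np.ndarray:
        """Single-frame velocity volume, shape (nx, ny, nz, 3)."""
        return self.data[t]

    def copy(self) -> "VelocityField4D":
        return replace(self, data=self.data.copy())


@dataclass
class MagnitudeSeries:
    """Phase-contrast magnitude images (arbitrary units), shape (t, nx, ny, nz)."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ParameterError("magnitude data must have shape (t, nx, ny, nz)")
        if np.any(self.data < 0):
            raise ParameterError("magnitude must be nonnegative")
        self.spacing = _as_triple(self.spacing)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[1:4])

    def time_average(self) -> np.ndarray:
        return self.data.mean(axis=0)


@dataclass
class PCMRAVolume:
    """Time-averaged PC-MRA volume: magnitude x |v| averaged over frames."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ParameterError("PC-MRA volume must be 3D")
        if np.any(self.data < 0):
            raise ParameterError("PC-MRA must be nonnegative")
        self.spacing = _as_triple(self.spacing)


@dataclass
class AortaMask:
    """Binary segmentation of the vessel lumen.

    Voxel centers are at ``index * spacing`` (mm). The mask is expected to be
    one 26-connected component; ``validate`` enforces that.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ParameterError("mask must be 3D")
        self.spacing = _as_triple(self.spacing)

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def validate(self) -> "AortaMask":
        if self.n_voxels == 0:
            raise SegmentationError("empty mask")
        _, n = ndimage.label(self.data, structure=np.ones((3, 3, 3), bool))
        if n != 1:
            raise SegmentationError(f"mask has {n} connected components, expected 1")
        return self

    def world_coords(self) -> np.ndarray:
        """(n, 3) array of voxel-center positions (mm) of mask voxels."""
        idx = np.argwhere(self.data)
        return idx * np.asarray(self.spacing)

    def centroid(self) -> np.ndarray:
        return self.world_coords().mean(axis=0)


@dataclass
class WallPointSet:
    """Wall points with outward unit normals and local lumen radius.

    ``points`` are positions in mm (sub-voxel, projected onto the smoothed
    mask surface); ``normals`` are outward unit vectors; ``radius`` is the
    local lumen radius in mm, used as the length of the inward sampling ray
    for wall shear stress. ``flagged`` marks degenerate points (thin mask,
    failed surface projection); flagged points are kept but excluded from
    scalar summaries downstream.
    """

    points: np.ndarray
    normals: np.ndarray
    radius: np.ndarray
    point_area: np.ndarray
    flagged: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.normals = np.atleast_2d(np.asarray(self.normals, dtype=float))
        self.radius = np.asarray(self.radius, dtype=float)
        self.point_area = np.asarray(self.point_area, dtype=float)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        n = len(self.points)
        if not (len(self.normals) == len(self.radius) == len(self.point_area) == len(self.flagged) == n):
            raise ParameterError("wall point arrays must have equal length")
        norms = np.linalg.norm(self.normals, axis=1)
        ok = np.abs(norms - 1.0) < 1e-6
        if not np.all(ok[~self.flagged]):
            raise ParameterError("non-unit normals on unflagged wall points")
        self.spacing = _as_triple(self.spacing)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def total_area(self) -> float:
        """Estimated wall surface area in mm^2."""
        return float(self.point_area.sum())


@dataclass
class Viscosity:
    """Dynamic viscosity. Stored as cP; ``pa_s`` converts to SI (1 cP = 1e-3 Pa s).

    The default 3.2 cP is the standard assumption for blood in vivo.
    """

    cp: float = 3.2

    def __post_init__(self):
        if self.cp <= 0:
            raise ParameterError("viscosity must be positive")

    @property
    def pa_s(self) -> float:
        return self.cp * 1e-3


@dataclass
class HemodynamicSummary:
    """Per-subject peak-systolic summary metrics."""

    peak_velocity: float
    mean_velocity: float
    mean_wss: float
    energy_loss: float
    peak_frame: int

    def __post_init__(self):
        if not (self.peak_velocity >= self.mean_velocity >= 0):
            raise ParameterError(
                "expected peak_velocity >= mean_velocity >= 0, got "
                f"{self.peak_velocity} / {self.mean_velocity}"
            )

    def as_dict(self) -> dict:
        return {
            "peak_velocity": self.peak_velocity,
            "mean_velocity": self.mean_velocity,
            "mean_wss": self.mean_wss,
            "energy_loss": self.energy_loss,
            "peak_frame": self.peak_frame,
        }
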