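"""Shared-geometry atlas: mask registration, cohort mapping and averaging.

All subjects of both cohorts are rigidly registered to a reference mask
(the mask of median volume) to build a shared vessel geometry; each
subject's haemodynamic maps are then carried into it by affine registration
followed by nearest-neighbour interpolation, so that per-voxel (and
per-wall-point) group statistics can be computed.

Registration maximizes the soft Dice overlap of Gaussian-smoothed masks
with a derivative-free local optimizer (Powell) from a centroid-aligned
start plus a fixed list of seeded perturbation restarts; masks are binary,
so intensity-based metrics would add nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core import AortaMask, AtlasError, ParameterError, RegistrationError, WallPointSet
from .segment import extract_wall

log = logging.getLogger(__name__)


@dataclass
class AffineTransform:
    """World-coordinate (mm) affine map x -> A (x - c) + c + t.

    ``center`` is the rotation center (fixed-mask centroid). For rigid
    transforms A is a pure rotation.
    """

    matrix: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    center: np.ndarray  # (3,)

    @classmethod
    def identity(cls, center=None) -> "AffineTransform":
        c = np.zeros(3) if center is None else np.asarray(center, float)
        return cls(np.eye(3), np.zeros(3), c)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return (points - self.center) @ self.matrix.T + self.center + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        # x' = A(x-c)+c+t  =>  x = A^-1(x'-c-t)+c
        return AffineTransform(inv, -inv @ self.translation, self.center)

    @property
    def rotation_deg(self) -> float:
        """Rotation angle (deg) of the closest pure rotation."""
        u, _, vt = np.linalg.svd(self.matrix)
        rot = u @ vt
        if np.linalg.det(rot) < 0:
            rot = -rot
        return float(np.rad2deg(np.linalg.norm(Rotation.from_matrix(rot).as_rotvec())))

    def coefficients(self) -> np.ndarray:
        """12 affine coefficients (row-major 3x3 matrix, then the net
        translation including the rotation-center contribution)."""
        net_t = self.translation + self.center - self.matrix @ self.center
        return np.concatenate([self.matrix.ravel(), net_t])


def _params_to_transform(params: np.ndarray, center: np.ndarray, mode: str) -> AffineTransform:
    angles = params[0:3]
    trans = params[3:6]
    rot = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
    if mode == "rigid":
        A = rot
    else:
        scale = np.diag(params[6:9])
        shear = np.eye(3)
        shear[0, 1], shear[0, 2], shear[1, 2] = params[9:12]
        A = rot @ scale @ shear
    return AffineTransform(A, np.asarray(trans, float), center)


def _pull_volume(
    volume: np.ndarray,
    spacing,
    transform: AffineTransform,
    out_shape,
    out_spacing,
    order: int = 1,
) -> np.ndarray:
    """Resample ``volume`` (moving) onto the fixed grid under ``transform``
    (moving -> fixed world). Pull: fixed voxel x' reads moving at T^-1 x'."""
    inv = transform.inverse()
    idx = np.indices(out_shape, dtype=float)
    pts = np.stack([idx[i] * out_spacing[i] for i in range(3)], axis=-1)
    src = inv.apply(pts.reshape(-1, 3)).reshape(pts.shape)
    coords = np.stack([src[..., i] / spacing[i] for i in range(3)])
    return ndimage.map_coordinates(volume, coords, order=order, mode="constant", cval=0.0)


def _soft_dice(a: np.ndarray, b: np.ndarray) -> float:
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * (a * b).sum() / denom)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Hard Dice overlap of two boolean volumes on one grid."""
    a = mask_a.astype(bool)
    b = mask_b.astype(bool)
    denom = a.sum() + b.sum()
    return float(2.0 * (a & b).sum() / denom) if denom else 0.0


def register_masks(
    moving: AortaMask,
    fixed: AortaMask,
    mode: str = "rigid",
    seed: int = 0,
    n_starts: int = 3,
    init: Optional[AffineTransform] = None,
    maxiter: int = 30,
) -> AffineTransform:
    """Register ``moving`` onto ``fixed`` by maximizing the overlap of the
    Gaussian-smoothed masks (normalized cross-correlation, which peaks at 1
    for perfect alignment of identical shapes).

    Returns the moving -> fixed world transform. ``mode`` is ``rigid``
    (3 rotations + 3 translations) or ``affine`` (plus scales and shears).
    The search is Powell from a centroid-aligned start (or ``init``) plus
    seeded perturbation restarts, so identical inputs give identical
    transforms; restarts are skipped once the first solution is essentially
    perfect.
    """
    if mode not in ("rigid", "affine"):
        raise ParameterError(f"unknown registration mode {mode!r}")
    fix_s = ndimage.gaussian_filter(fixed.data.astype(float), 1.0)
    mov_s = ndimage.gaussian_filter(moving.data.astype(float), 1.0)
    center = fixed.centroid()
    t0 = moving.centroid() - fixed.centroid()

    # evaluate the metric only inside a dilated bounding box of the fixed mask
    support = fix_s > 1e-3
    lo = np.maximum(np.array([a.min() for a in np.nonzero(support)]) - 3, 0)
    hi = np.minimum(np.array([a.max() for a in np.nonzero(support)]) + 4, fixed.data.shape)
    sub = tuple(slice(l, h) for l, h in zip(lo, hi))
    fix_vals = fix_s[sub].ravel()
    fix_norm = np.linalg.norm(fix_vals)
    idx = np.indices(fix_s[sub].shape, dtype=float)
    pts = np.stack(
        [(idx[i] + lo[i]) * fixed.spacing[i] for i in range(3)], axis=-1
    ).reshape(-1, 3)
    mov_spacing = np.asarray(moving.spacing)
    mov_norm = np.linalg.norm(mov_s)

    n_par = 6 if mode == "rigid" else 12
    x0 = np.zeros(n_par)
    x0[3:6] = -t0  # move the moving centroid onto the fixed one
    if mode == "affine":
        x0[6:9] = 1.0
    if init is not None:
        # seed the search with a previous (e.g. rigid) solution
        rot = Rotation.from_matrix(_closest_rotation(init.matrix)).as_euler("xyz", degrees=True)
        x0[0:3] = rot
        x0[3:6] = init.translation

    def objective(params: np.ndarray) -> float:
        tf = _params_to_transform(params, center, mode)
        src = tf.inverse().apply(pts)
        coords = (src / mov_spacing).T
        pulled = ndimage.map_coordinates(mov_s, coords, order=1, mode="constant", cval=0.0)
        denom = fix_norm * max(np.linalg.norm(pulled), 1e-12)
        return -float(fix_vals @ pulled) / denom

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(n_starts - 1):
        pert = x0.copy()
        pert[0:3] += rng.uniform(-3, 3, 3)
        pert[3:6] += rng.uniform(-2, 2, 3)
        starts.append(pert)

    best, best_val = None, np.inf
    for s in starts:
        res = optimize.minimize(
            objective, s, method="Powell", options={"maxiter": maxiter, "xtol": 1e-2, "ftol": 1e-5}
        )
        if res.fun < best_val:
            best, best_val = res.x, res.fun
        if best_val < -0.995:  # essentially perfect alignment
            break
    return _params_to_transform(best, center, mode)


def _closest_rotation(matrix: np.ndarray) -> np.ndarray:
    u, _, vt = np.linalg.svd(matrix)
    rot = u @ vt
    if np.linalg.det(rot) < 0:
        rot = -rot
    return rot


@dataclass
class SharedGeometry:
    """Reference geometry shared by all subjects of both cohorts."""

    mask: AortaMask
    wall: WallPointSet
    inclusion_fraction: float
    reference_index: int
    rigid_transforms: list  # per subject, moving -> shared world
    voxel_index: np.ndarray = dc_field(init=False)  # (n_loc, 3) shared-mask voxels

    def __post_init__(self):
        self.voxel_index = np.argwhere(self.mask.data)

    @property
    def n_voxel_locations(self) -> int:
        return len(self.voxel_index)

    @property
    def n_wall_locations(self) -> int:
        return len(self.wall)


def build_shared_geometry(
    masks: Sequence[AortaMask],
    inclusion_fraction: float = 0.6,
    seed: int = 0,
) -> SharedGeometry:
    """Build the shared vessel geometry from the pooled cohorts.

    The reference is the mask of median lumen volume (ties toward the lower
    subject index); every mask is rigidly registered to it and the shared
    mask keeps voxels covered by at least ``inclusion_fraction`` of the
    registered masks (largest connected component).
    """
    if len(masks) < 2:
        raise ParameterError("need at least two masks")
    if not (0 < inclusion_fraction <= 1):
        raise ParameterError("inclusion_fraction must lie in (0, 1]")
    volumes = np.array([m.n_voxels * m.voxel_volume for m in masks])
    order = np.argsort(volumes, kind="stable")
    ref_ix = int(order[(len(masks) - 1) // 2])
    ref = masks[ref_ix]

    coverage = np.zeros(ref.data.shape)
    transforms = []
    for i, m in enumerate(masks):
        if i == ref_ix:
            tf = AffineTransform.identity(ref.centroid())
        else:
            # one seed for every registration: results are then independent
            # of the subject order (permutation stability)
            tf = register_masks(m, ref, mode="rigid", seed=seed)
        transforms.append(tf)
        pulled = _pull_volume(m.data.astype(float), m.spacing, tf, ref.data.shape, ref.spacing)
        coverage += pulled > 0.5
    shared = coverage / len(masks) >= inclusion_fraction
    if not shared.any():
        raise AtlasError(
            f"shared mask empty at inclusion_fraction={inclusion_fraction}; lower it"
        )
    labels, n = ndimage.label(shared, structure=np.ones((3, 3, 3), bool))
    if n > 1:
        sizes = ndimage.sum_labels(shared, labels, index=np.arange(1, n + 1))
        shared = labels == (1 + int(np.argmax(sizes)))
    shared_mask = AortaMask(shared, ref.spacing)
    wall = extract_wall(shared_mask)
    return SharedGeometry(
        mask=shared_mask,
        wall=wall,
        inclusion_fraction=inclusion_fraction,
        reference_index=ref_ix,
        rigid_transforms=transforms,
    )


def map_subject(
    values: np.ndarray,
    mask: AortaMask,
    shared: SharedGeometry,
    domain: str = "voxel",
    wall: Optional[WallPointSet] = None,
    init: Optional[AffineTransform] = None,
    transform: Optional[AffineTransform] = None,
    seed: int = 0,
    max_dist_vox: float = 2.0,
    min_dice: float = 0.5,
) -> tuple[np.ndarray, AffineTransform]:
    """Carry one subject's map onto the shared geometry.

    ``domain='voxel'``: ``values`` is a volume on the subject grid; the
    result is a 1D array over ``shared.voxel_index`` locations.
    ``domain='wall'``: ``values`` is per subject wall point (requires
    ``wall``); the result is per shared wall point. Nearest-neighbour
    interpolation; shared locations farther than ``max_dist_vox`` voxels
    from any subject point become NaN (missing). Subjects whose registered
    mask overlaps the shared mask with Dice < ``min_dice`` are rejected.
    A precomputed ``transform`` (subject -> shared world) skips the affine
    registration, so one registration can serve several quantities.
    """
    if transform is not None:
        tf = transform
    else:
        tf = register_masks(mask, shared.mask, mode="affine", seed=seed, init=init, n_starts=2)
    pulled = _pull_volume(
        mask.data.astype(float), mask.spacing, tf, shared.mask.data.shape, shared.mask.spacing
    )
    d = dice(pulled > 0.5, shared.mask.data)
    if d < min_dice:
        raise RegistrationError(f"registration overlap Dice {d:.2f} < {min_dice}")

    inv = tf.inverse()
    spacing = np.asarray(mask.spacing)
    if domain == "voxel":
        pts_shared = shared.voxel_index * np.asarray(shared.mask.spacing)
        src = inv.apply(pts_shared)
        # snap to the nearest subject lumen voxel within the distance cutoff
        dist_vox, nearest = ndimage.distance_transform_edt(
            ~mask.data, return_indices=True
        )
        coords = np.round(src / spacing).astype(int)
        coords = np.clip(coords, 0, np.array(mask.data.shape) - 1)
        cx, cy, cz = coords.T
        dist = dist_vox[cx, cy, cz]
        nx, ny, nz = nearest[:, cx, cy, cz]
        out = np.asarray(values, float)[nx, ny, nz]
        out = np.where(dist <= max_dist_vox, out, np.nan)
        return out, tf
    elif domain == "wall":
        if wall is None:
            raise ParameterError("wall domain requires the subject WallPointSet")
        vals = np.asarray(values, float)
        if len(vals) != len(wall):
            raise ParameterError("values must align with the subject wall points")
        src = inv.apply(shared.wall.points)
        tree = cKDTree(wall.points)
        dist, ix = tree.query(src)
        cutoff = max_dist_vox * float(np.mean(spacing))
        out = np.where(dist <= cutoff, vals[ix], np.nan)
        return out, tf
    raise ParameterError(f"unknown domain {domain!r}")


@dataclass
class CohortMap:
    """Per-location subject values for one cohort on the shared geometry.

    ``values`` has shape (n_subjects, n_locations); NaN marks missing.
    The mean is defined only where at least two subjects contribute.
    """

    values: np.ndarray
    shared: SharedGeometry
    domain: str

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, float))
        n_loc = (
            self.shared.n_voxel_locations
            if self.domain == "voxel"
            else self.shared.n_wall_locations
        )
        if self.values.shape[1] != n_loc:
            raise ParameterError(
                f"expected {n_loc} locations for domain {self.domain}, got {self.values.shape[1]}"
            )

    @property
    def n_subjects(self) -> np.ndarray:
        return np.sum(~np.isnan(self.values), axis=0)

    @property
    def mean(self) -> np.ndarray:
        n = self.n_subjects
        with np.errstate(invalid="ignore"):
            m = np.nanmean(np.where(np.isnan(self.values), np.nan, self.values), axis=0)
        return np.where(n >= 2, m, np.nan)

    def mean_volume(self) -> np.ndarray:
        """Cohort-mean map as a volume on the shared grid (voxel domain)."""
        if self.domain != "voxel":
            raise ParameterError("mean_volume is only defined for voxel maps")
        vol = np.full(self.shared.mask.data.shape, np.nan)
        ix = self.shared.voxel_index
        vol[ix[:, 0], ix[:, 1], ix[:, 2]] = self.mean
        return vol


def cohort_average(maps: Sequence[np.ndarray], shared: SharedGeometry, domain: str = "voxel") -> CohortMap:
    """Stack per-subject shared-geometry value arrays into a CohortMap."""
    if len(maps) == 0:
        raise ParameterError("no subject maps")
    return CohortMap(np.stack([np.asarray(m, float) for m in maps]), shared, domain)


def maximum_intensity_projection(volume: np.ndarray, axis: int = 1) -> np.ndarray:
    """Per-pixel maximum along one axis (NaN-aware)."""
    vol = np.asarray(volume, float)
    if vol.ndim != 3:
        raise ParameterError("MIP expects a 3D volume")
    with np.errstate(invalid="ignore"):
        return np.nanmax(np.where(np.isnan(vol), -np.inf, vol), axis=axis)
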