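"""Ground-truthed 4D-flow phantoms.

The generator produces a tubular, ascending-aorta-like vessel on a regular
grid at the working resolution of clinical 4D-flow protocols
(2.0 x 1.7 x 2.2 mm^3, 40 ms / 18 cardiac phases by default), fills it with
an analytic axial flow profile, and optionally corrupts the measurement the
way phase-contrast MRI does: per-direction Gaussian velocity noise, a
slowly-varying eddy-current offset plane, and phase wrapping beyond venc.

For the steady parabolic (Poiseuille) profile the wall shear stress and the
viscous dissipation rate have closed forms,

    WSS = 2 mu v_max / R,          EL = 2 pi mu L v_max^2,

which every downstream numerical stage is validated against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.special import jv

from .core import (
    AortaMask,
    GeometryError,
    MagnitudeSeries,
    ParameterError,
    VelocityField4D,
    Viscosity,
    _as_triple,
)

log = logging.getLogger(__name__)

#: Magnitude-image intensity outside the vessel (static-tissue floor).
STATIC_TISSUE_MAGNITUDE = 0.05


def default_envelope(n_frames: int) -> np.ndarray:
    """Systolic temporal envelope: a half-sine over the first half of the
    cycle, zero flow in diastole, normalized to max 1."""
    n_sys = max(1, int(np.ceil(n_frames / 2)))
    env = np.zeros(n_frames)
    t = np.arange(n_sys)
    env[:n_sys] = np.sin(np.pi * (t + 1) / (n_sys + 1))
    return env / env.max()


@dataclass
class PhantomConfig:
    """Full description of one synthetic 4D-flow acquisition.

    Geometry is a straight (optionally tilted/translated) tube of radius
    ``tube_radius`` spanning the z extent of the grid unless ``tube_length``
    is given. ``profile`` selects the axial velocity law:

    - ``poiseuille``: v = v_max (1 - r^2/R^2), the analytic oracle;
    - ``eccentric_jet``: a displaced parabolic core of radius R/2 with zero
      co-flow, its axis offset by ``jet_offset`` mm (offset 0 = central jet);
    - ``womersley``: pulsatile Bessel-function tube flow, for time-resolved
      realism only.
    """

    grid_shape: tuple[int, int, int] = (80, 94, 46)
    spacing: tuple[float, float, float] = (2.0, 1.7, 2.2)
    n_frames: int = 18
    frame_dt: float = 40.0  # ms
    tube_radius: float = 10.0  # mm
    tube_length: Optional[float] = None  # mm; None = full z extent
    centerline: str = "straight"
    profile: str = "poiseuille"
    v_max: float = 1.0  # m/s
    jet_offset: float = 0.0  # mm, radial displacement of the jet axis
    temporal_envelope: Optional[Sequence[float]] = None
    venc: tuple[float, float, float] = (1.5, 1.5, 1.5)  # m/s per direction
    noise_sigma: float = 0.0  # m/s
    wrap_enabled: bool = False
    #: per-direction eddy-current offsets (c0 [m/s], cx, cy, cz [m/s per mm])
    eddy_plane_coeffs: Optional[np.ndarray] = None
    womersley_alpha: float = 13.0
    #: rigid pose jitter of the tube (used by the cohort generator)
    axis_rot_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        self.spacing = _as_triple(self.spacing)
        self.venc = _as_triple(self.venc)
        if self.tube_radius <= 0:
            raise ParameterError("tube_radius must be > 0")
        if self.tube_length is not None and self.tube_length <= 0:
            raise ParameterError("tube_length must be > 0")
        if any(s <= 0 for s in self.spacing):
            raise ParameterError("spacing must be positive")
        if self.n_frames < 1:
            raise ParameterError("need at least one frame")
        if self.profile not in ("poiseuille", "womersley", "eccentric_jet"):
            raise ParameterError(f"unknown profile {self.profile!r}")
        if self.centerline != "straight":
            raise ParameterError("only straight centerlines are supported")
        if self.profile == "eccentric_jet":
            if self.jet_offset + self.tube_radius / 2 > self.tube_radius + 1e-9:
                raise ParameterError(
                    "jet_offset + jet core radius (R/2) must not exceed R"
                )
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.wrap_enabled and any(v <= 0 for v in self.venc):
            raise ParameterError("venc must be > 0 when wrapping is enabled")

    def envelope(self) -> np.ndarray:
        if self.temporal_envelope is None:
            return default_envelope(self.n_frames)
        env = np.asarray(self.temporal_envelope, dtype=float)
        if env.shape != (self.n_frames,):
            raise ParameterError("temporal_envelope length must equal n_frames")
        if env.min() < 0 or abs(env.max() - 1.0) > 1e-9:
            raise ParameterError("temporal_envelope must lie in [0, 1] with max 1")
        return env

    @property
    def extent(self) -> np.ndarray:
        """Physical extent of the grid in mm per axis."""
        return (np.asarray(self.grid_shape) - 1) * np.asarray(self.spacing)

    def effective_length(self) -> float:
        """Tube length in mm (full z extent unless tube_length is set)."""
        return float(self.extent[2] if self.tube_length is None else self.tube_length)

    def pose(self) -> tuple[np.ndarray, np.ndarray]:
        """(axis unit vector, tube center in mm) after rigid jitter."""
        rot = Rotation.from_euler("xyz", self.axis_rot_deg, degrees=True)
        axis = rot.apply(np.array([0.0, 0.0, 1.0]))
        center = self.extent / 2 + np.asarray(self.center_offset, dtype=float)
        return axis, center


@dataclass
class PhantomTruth:
    """Analytic ground truth bundled with a phantom.

    ``wall_wss_analytic``/``el_analytic`` hold the Poiseuille closed forms
    (NaN for profiles without one); ``clean_velocity`` is the uncorrupted
    field every corruption round-trip is checked against.
    """

    mask: AortaMask
    wall_wss_analytic: float  # Pa (uniform over the wall for a straight tube)
    el_analytic: float  # mW
    v_max_true: float  # m/s
    clean_velocity: VelocityField4D

    def __post_init__(self):
        if self.mask.n_voxels == 0:
            raise GeometryError("truth mask is empty")
        if np.isfinite(self.el_analytic) and self.el_analytic < 0:
            raise ParameterError("analytic EL must be >= 0")
        if np.isfinite(self.wall_wss_analytic) and self.wall_wss_analytic < 0:
            raise ParameterError("analytic WSS must be >= 0")


def _grid_world(config: PhantomConfig) -> np.ndarray:
    nx, ny, nz = config.grid_shape
    sx, sy, sz = config.spacing
    x = np.arange(nx) * sx
    y = np.arange(ny) * sy
    z = np.arange(nz) * sz
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    return np.stack([X, Y, Z], axis=-1)


def _tube_geometry(config: PhantomConfig):
    """Radial distance, axial coordinate, in-plane offset vector and mask."""
    axis, center = config.pose()
    X = _grid_world(config) - center
    a = X @ axis  # axial coordinate relative to tube center
    radial_vec = X - a[..., None] * axis
    r = np.linalg.norm(radial_vec, axis=-1)
    L = config.effective_length()
    mask = (r <= config.tube_radius) & (np.abs(a) <= L / 2 + 1e-9)
    return r, a, radial_vec, axis, mask


def _check_contained(config: PhantomConfig, mask: np.ndarray):
    # The tube may legitimately run through the z faces (full-length tube);
    # it must never leak out of the lateral faces.
    if mask[0, :, :].any() or mask[-1, :, :].any() or mask[:, 0, :].any() or mask[:, -1, :].any():
        raise GeometryError("tube is not laterally contained in the grid")
    if not mask.any():
        raise GeometryError("tube does not intersect the grid")


def _spatial_profile(config: PhantomConfig, r, radial_vec, axis) -> np.ndarray:
    """Unit-peak axial speed profile s(x) with s in [0, 1]."""
    R = config.tube_radius
    if config.profile in ("poiseuille", "womersley"):
        s = np.clip(1.0 - (r / R) ** 2, 0.0, None)
    else:  # eccentric_jet
        # displacement direction: lab x projected into the tube cross-section
        e = np.array([1.0, 0.0, 0.0])
        e = e - (e @ axis) * axis
        e = e / np.linalg.norm(e)
        off = config.jet_offset * e
        rj = np.linalg.norm(radial_vec - off, axis=-1)
        core = R / 2
        s = np.clip(1.0 - (rj / core) ** 2, 0.0, None)
    return s


def _womersley_time_profiles(config: PhantomConfig, r_over_R: np.ndarray) -> np.ndarray:
    """Pulsatile tube-flow speed (frames, ...) from the Bessel solution.

    Single-harmonic oscillatory flow superposed on a steady parabolic
    component, normalized so the peak speed over space and time is 1.
    """
    alpha = config.womersley_alpha
    beta = alpha * np.exp(1j * 3 * np.pi / 4)  # i^{3/2} alpha
    j0_wall = jv(0, beta)
    shape = np.clip(1 - jv(0, beta * np.clip(r_over_R, 0, 1)) / j0_wall, None, None)
    t = np.arange(config.n_frames) / config.n_frames
    osc = np.real(shape[None, ...] * np.exp(2j * np.pi * t.reshape((-1,) + (1,) * r_over_R.ndim)))
    steady = 0.5 * np.clip(1 - r_over_R**2, 0.0, None)
    v = steady[None, ...] + 0.5 * osc
    peak = np.abs(v).max()
    return v / peak if peak > 0 else v


def generate_phantom(
    config: PhantomConfig, mu: Viscosity | float = 3.2
) -> tuple[VelocityField4D, MagnitudeSeries, PhantomTruth]:
    """Generate a clean phantom acquisition plus its analytic ground truth.

    ``mu`` (cP) is only used to evaluate the closed-form WSS/EL truth values;
    the velocity field itself is viscosity-free.
    """
    if not isinstance(mu, Viscosity):
        mu = Viscosity(mu)
    r, a, radial_vec, axis, mask = _tube_geometry(config)
    _check_contained(config, mask)
    env = config.envelope()

    n_frames = config.n_frames
    vel = np.zeros((n_frames,) + tuple(config.grid_shape) + (3,))
    if config.profile == "womersley":
        speed = config.v_max * _womersley_time_profiles(config, r / config.tube_radius)
        speed = speed * mask[None, ...]
        vel = speed[..., None] * axis
    else:
        s = _spatial_profile(config, r, radial_vec, axis) * mask
        for tix in range(n_frames):
            vel[tix] = (config.v_max * env[tix] * s)[..., None] * axis

    mag = np.where(mask, 1.0, STATIC_TISSUE_MAGNITUDE)
    mag = np.broadcast_to(mag, (n_frames,) + mag.shape).copy()

    field = VelocityField4D(vel, config.spacing, config.frame_dt, config.venc)
    magnitude = MagnitudeSeries(mag, config.spacing)

    if config.profile == "poiseuille":
        R_m = config.tube_radius * 1e-3
        L_m = config.effective_length() * 1e-3
        wss = 2 * mu.pa_s * config.v_max / R_m
        el = 2 * np.pi * mu.pa_s * L_m * config.v_max**2 * 1e3  # W -> mW
    else:
        wss = np.nan
        el = np.nan
    if config.v_max == 0:
        wss, el = 0.0, 0.0
    truth = PhantomTruth(
        mask=AortaMask(mask, config.spacing),
        wall_wss_analytic=wss,
        el_analytic=el,
        v_max_true=config.v_max,
        clean_velocity=field.copy(),
    )
    return field, magnitude, truth


def wrap_phase(v: np.ndarray, venc: float) -> np.ndarray:
    """Alias velocities into [-venc, venc) the way phase measurement does."""
    return v - 2 * venc * np.round(v / (2 * venc))


def corrupt_phantom(field: VelocityField4D, config: PhantomConfig) -> VelocityField4D:
    """Apply MR measurement corruption: eddy-current offset plane, Gaussian
    noise, then phase wrapping. Reproducible given ``config.seed``."""
    if config.wrap_enabled and any(v <= 0 for v in config.venc):
        raise ParameterError("venc must be > 0 when wrapping is enabled")
    rng = np.random.default_rng(config.seed)
    data = field.data.copy()

    if config.eddy_plane_coeffs is not None:
        coeffs = np.asarray(config.eddy_plane_coeffs, dtype=float)
        if coeffs.shape != (3, 4):
            raise ParameterError("eddy_plane_coeffs must have shape (3, 4)")
        X = _grid_world(config)
        for d in range(3):
            c0, cx, cy, cz = coeffs[d]
            plane = c0 + cx * X[..., 0] + cy * X[..., 1] + cz * X[..., 2]
            data[..., d] += plane[None, ...]

    if config.noise_sigma > 0:
        data += rng.normal(0.0, config.noise_sigma, size=data.shape)

    if config.wrap_enabled:
        for d in range(3):
            data[..., d] = wrap_phase(data[..., d], config.venc[d])

    return replace(field, data=data)


@dataclass
class SubjectData:
    """One synthetic subject: measured (corrupted) data plus ground truth."""

    subject_id: str
    group: str
    velocity: VelocityField4D
    magnitude: MagnitudeSeries
    truth: PhantomTruth
    config: PhantomConfig


def generate_cohorts(
    n_per_group: int,
    base: PhantomConfig,
    effect: tuple[float, float] = (4.0, 0.0),
    seed: int = 0,
    jet_offset_sd: float = 0.5,
    v_max_sd: float = 0.15,
    jitter_rot_deg: float = 5.0,
    jitter_trans_mm: float = 3.0,
) -> tuple[list[SubjectData], list[SubjectData]]:
    """Draw two cohorts differing in jet centrality and/or peak velocity.

    Group A ("stented-like") subjects draw their jet offset around
    ``base.jet_offset + effect[0]`` and v_max around ``base.v_max +
    effect[1]``; group B ("stentless-like") around the base (central)
    setting. Every subject gets a small rigid pose jitter (rotation <=
    ``jitter_rot_deg`` about a random axis, translation <=
    ``jitter_trans_mm`` per axis) so downstream registration is exercised.
    All randomness derives from ``seed``.
    """
    if n_per_group < 2:
        raise ParameterError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    d_off, d_vmax = effect

    def draw_subject(group: str, index: int) -> SubjectData:
        sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        if group == "A":
            offset_mean, vmax_mean = base.jet_offset + d_off, base.v_max + d_vmax
        else:
            offset_mean, vmax_mean = base.jet_offset, base.v_max
        jet_offset = abs(sub_rng.normal(offset_mean, jet_offset_sd))
        R = base.tube_radius
        jet_offset = min(jet_offset, R / 2)  # keep the core inside the lumen
        v_max = max(0.2, sub_rng.normal(vmax_mean, v_max_sd))

        angle = sub_rng.uniform(0, jitter_rot_deg)
        ax = sub_rng.normal(size=3)
        ax /= np.linalg.norm(ax)
        euler = Rotation.from_rotvec(np.deg2rad(angle) * ax).as_euler("xyz", degrees=True)
        trans = sub_rng.uniform(-jitter_trans_mm, jitter_trans_mm, size=3)

        cfg = replace(
            base,
            profile="eccentric_jet",
            jet_offset=jet_offset,
            v_max=v_max,
            axis_rot_deg=tuple(euler),
            center_offset=tuple(trans),
            seed=int(sub_rng.integers(0, 2**31 - 1)),
        )
        field, mag, truth = generate_phantom(cfg)
        measured = corrupt_phantom(field, cfg)
        return SubjectData(f"{group}{index:02d}", group, measured, mag, truth, cfg)

    group_a = [draw_subject("A", i) for i in range(n_per_group)]
    group_b = [draw_subject("B", i) for i in range(n_per_group)]
    return group_a, group_b
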