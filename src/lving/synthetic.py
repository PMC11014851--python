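"""Forward-simulated ground-truth scenes rendered as noisy OPD movies.

A scene prescribes a velocity field, a biomass source term and a cell-like
texture; the density field is evolved by semi-Lagrangian advection (backtrace
plus bicubic sampling — unconditionally stable, so the forward model's error
stays decoupled from the inverse pipeline's) with an explicit source update,
then rendered to OPD with additive Gaussian noise.  Every pipeline stage can
therefore be tested against exact ground truth without any real data.

The cell texture is a smooth disk profile multiplied by band-limited granular
contrast (default correlation length ~3 px): a featureless disk would defeat
correlation velocimetry and test nothing, whereas real cytoplasm carries
mass-density granularity at about this scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable
import warnings

import numpy as np
from scipy import ndimage

from .mass_imaging import Calibration, CellMask, MassFrame, PhaseFrame
from .velocimetry import PIVConfig, VelocityField

__all__ = [
    "VelocitySpec",
    "SourceSpec",
    "TextureSpec",
    "SyntheticScene",
    "GroundTruth",
    "render_movie",
    "fixed_cell_fixture",
]


# ---------------------------------------------------------------------------
# Scene specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VelocitySpec:
    """Prescribed velocity field (um/min).

    kind: 'zero' | 'uniform' (u, v) | 'rotation' (omega rad/min about
    center um) | 'shear' (u = k * y) | 'custom' (callable (x, y, t) ->
    (u, v) arrays).
    """

    kind: str = "zero"
    u: float = 0.0
    v: float = 0.0
    omega: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)
    k: float = 0.0
    fn: Callable | None = None

    def __call__(self, x: np.ndarray, y: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if self.kind == "zero":
            return np.zeros_like(x), np.zeros_like(y)
        if self.kind == "uniform":
            return np.full_like(x, self.u), np.full_like(y, self.v)
        if self.kind == "rotation":
            cx, cy = self.center
            return -self.omega * (y - cy), self.omega * (x - cx)
        if self.kind == "shear":
            return self.k * y, np.zeros_like(y)
        if self.kind == "custom":
            return self.fn(x, y, t)
        raise ValueError(f"unknown velocity kind {self.kind!r}")


@dataclass(frozen=True)
class BlobSource:
    """Localized co-moving source: a smooth cosine bump of peak ``rate``
    (pg/um^2/h) and compact support ``radius`` (um) around ``center`` (um).
    Negative rates model degradation."""

    center: tuple[float, float]
    radius: float
    rate: float


@dataclass(frozen=True)
class SourceSpec:
    """Biomass source term.

    kind: 'zero' | 'uniform_specific' (exponential growth at specific rate
    g in 1/h, sigma <- sigma * e^(g dt)) | 'blobs' (additive co-moving
    BlobSource bumps, sigma <- sigma + r dt).
    """

    kind: str = "zero"
    g: float = 0.0
    blobs: tuple[BlobSource, ...] = ()


@dataclass(frozen=True)
class TextureSpec:
    """Cell-like initial density: smooth disk plus granular contrast.

    center, radius in um; density_scale in pg/um^2 (plateau value);
    taper_width um of cosine edge roll-off; granularity_um correlation
    length of the multiplicative contrast; contrast its relative amplitude.
    """

    center: tuple[float, float]
    radius: float
    density_scale: float = 1.5
    taper_width: float = 1.0
    granularity_um: float = 0.75
    contrast: float = 0.35


@dataclass(frozen=True)
class SyntheticScene:
    """Full specification of a ground-truth movie (same seed => same bytes)."""

    shape: tuple[int, int] = (96, 96)
    pixel_size: float = 0.25
    frame_interval: float = 1.0
    n_frames: int = 31
    velocity: VelocitySpec = field(default_factory=VelocitySpec)
    source: SourceSpec = field(default_factory=SourceSpec)
    texture: TextureSpec | None = None
    noise_sigma: float = 5.0e-4  # OPD um; 0.5 nm, small vs. cellular OPD
    refractive_increment: float = 0.18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_interval <= 0 or self.n_frames < 1:
            raise ValueError("scene scales must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @property
    def calibration(self) -> Calibration:
        return Calibration(self.pixel_size, self.frame_interval, self.refractive_increment)

    def default_texture(self) -> TextureSpec:
        ny, nx = self.shape
        return TextureSpec(
            center=(nx * self.pixel_size / 2.0, ny * self.pixel_size / 2.0),
            radius=0.3 * min(nx, ny) * self.pixel_size,
        )


@dataclass
class GroundTruth:
    """Exact per-frame state of a rendered scene."""

    scene: SyntheticScene
    densities: list[np.ndarray]  # noiseless sigma per frame, pg/um^2
    source_maps: list[np.ndarray]  # r in pg/um^2/h at each frame start
    cell_mask: CellMask  # initial support of the texture

    def mass_frames(self) -> list[MassFrame]:
        cal = self.scene.calibration
        return [
            MassFrame(d, k * cal.frame_interval, cal)
            for k, d in enumerate(self.densities)
        ]

    def total_masses(self) -> np.ndarray:
        a = self.scene.calibration.pixel_area
        return np.array([d.sum() * a for d in self.densities])

    def velocity_field(self, k: int, grid_step_px: int = 8) -> VelocityField:
        """The prescribed velocity sampled on a regular node grid, as the
        pipeline's VelocityField type (all nodes valid)."""
        cal = self.scene.calibration
        ny, nx = self.scene.shape
        gx = (np.arange(grid_step_px // 2, nx, grid_step_px) + 0.5) * cal.pixel_size
        gy = (np.arange(grid_step_px // 2, ny, grid_step_px) + 0.5) * cal.pixel_size
        xx, yy = np.meshgrid(gx, gy)
        t = k * cal.frame_interval
        u, v = self.scene.velocity(xx, yy, t)
        return VelocityField(
            grid_x=gx, grid_y=gy, u=u, v=v,
            valid=np.ones(u.shape, dtype=bool), dt=cal.frame_interval,
        )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _pixel_center_grids(shape, pixel_size):
    ny, nx = shape
    x = (np.arange(nx) + 0.5) * pixel_size
    y = (np.arange(ny) + 0.5) * pixel_size
    return np.meshgrid(x, y)


def _initial_density(scene: SyntheticScene, rng: np.random.Generator) -> np.ndarray:
    tex = scene.texture or scene.default_texture()
    xx, yy = _pixel_center_grids(scene.shape, scene.pixel_size)
    r = np.hypot(xx - tex.center[0], yy - tex.center[1])
    profile = np.zeros(scene.shape)
    inner = r <= tex.radius - tex.taper_width
    ramp = (r > tex.radius - tex.taper_width) & (r < tex.radius)
    profile[inner] = 1.0
    profile[ramp] = 0.5 * (
        1.0 + np.cos(np.pi * (r[ramp] - tex.radius + tex.taper_width) / tex.taper_width)
    )
    white = rng.standard_normal(scene.shape)
    # granularity_um is the approximate feature diameter: FWHM of a
    # Gaussian-filtered white field is ~2.35 sigma, so sigma = d / 2.35
    gran_px = max(tex.granularity_um / scene.pixel_size / 2.35, 0.5)
    granular = ndimage.gaussian_filter(white, gran_px)
    granular /= max(granular.std(), 1e-12)
    density = tex.density_scale * profile * np.clip(1.0 + tex.contrast * granular, 0.0, None)
    return density


def _blob_map(blobs, centers, shape, pixel_size) -> np.ndarray:
    """Source map (pg/um^2/h) for blob bumps at the given current centers."""
    xx, yy = _pixel_center_grids(shape, pixel_size)
    out = np.zeros(shape)
    for blob, c in zip(blobs, centers):
        r = np.hypot(xx - c[0], yy - c[1])
        bump = np.where(r < blob.radius, np.cos(0.5 * np.pi * r / blob.radius) ** 2, 0.0)
        out += blob.rate * bump
    return out


def _advect_semi_lagrangian(
    density: np.ndarray, vel: VelocitySpec, t: float, dt: float, pixel_size: float
) -> np.ndarray:
    xx, yy = _pixel_center_grids(density.shape, pixel_size)
    if vel.kind == "rotation":
        # exact departure map: a single-step backtrace has an O((w dt)^2)
        # chord error that spirals mass radially and breaks conservation
        cx, cy = vel.center
        th = vel.omega * dt
        dx, dy = xx - cx, yy - cy
        dep_x = np.cos(th) * dx + np.sin(th) * dy + cx
        dep_y = -np.sin(th) * dx + np.cos(th) * dy + cy
    else:
        # midpoint backtrace (second order) for general fields
        u, v = vel(xx, yy, t)
        u2, v2 = vel(xx - 0.5 * dt * u, yy - 0.5 * dt * v, t)
        dep_x = xx - u2 * dt
        dep_y = yy - v2 * dt
    dep_i = dep_y / pixel_size - 0.5
    dep_j = dep_x / pixel_size - 0.5
    out = ndimage.map_coordinates(
        density, [dep_i, dep_j], order=3, mode="constant", cval=0.0, prefilter=True
    )
    return np.clip(out, 0.0, None)


def _fourier_translate(img: np.ndarray, dx_px: float, dy_px: float) -> np.ndarray:
    return np.real(np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(img), (dy_px, dx_px))))


def _evolve_exact_uniform(scene: SyntheticScene, density0: np.ndarray):
    """Closed-form evolution for zero/uniform velocity.

    In the co-moving frame the density obeys d(sigma)/dt = r exactly, so
    sigma(x, t) = [sigma0 * e^(g t)](xi) or [sigma0 + t * r0](xi) with
    xi = x - v t; frames are rendered by spectral translation of the
    initial state, avoiding any cumulative resampling diffusion.
    """
    dt_min = scene.frame_interval
    dt_h = dt_min / 60.0
    px = scene.pixel_size
    u, v = (scene.velocity.u, scene.velocity.v) if scene.velocity.kind == "uniform" else (0.0, 0.0)
    r0 = (
        _blob_map(scene.source.blobs, [b.center for b in scene.source.blobs], scene.shape, px)
        if scene.source.kind == "blobs"
        else None
    )
    densities, source_maps = [], []
    for k in range(scene.n_frames):
        t_min = k * dt_min
        shift_px = (u * t_min / px, v * t_min / px)
        base = _fourier_translate(density0, *shift_px)
        if scene.source.kind == "uniform_specific":
            d = base * np.exp(scene.source.g * k * dt_h)
            src = scene.source.g * d
        elif scene.source.kind == "blobs":
            r_here = _fourier_translate(r0, *shift_px)
            d = base + (k * dt_h) * r_here
            src = r_here
        else:
            d = base
            src = np.zeros(scene.shape)
        densities.append(np.clip(d, 0.0, None))
        source_maps.append(src)
    return densities, source_maps


def render_movie(scene: SyntheticScene) -> tuple[list[PhaseFrame], GroundTruth]:
    """Evolve the scene and render it as a noisy OPD movie.

    Zero/uniform velocity scenes evolve in closed form (spectral translation
    of the initial state plus the analytic source update), so their ground
    truth is exact.  General fields use semi-Lagrangian advection (backtrace
    + bicubic sampling) with the explicit source update: sigma * e^(g dt)
    for a uniform specific source, sigma + r dt for blob sources whose
    centers co-advect with the material.  OPD = sigma * alpha plus
    independent Gaussian read noise per frame, clipped at zero.

    Warns when the prescribed per-frame displacement exceeds the search
    capability of the default PIV configuration.
    """
    rng = np.random.default_rng(scene.seed)
    cal = scene.calibration
    dt_min = cal.frame_interval
    dt_h = dt_min / 60.0

    density = _initial_density(scene, rng)
    cell_mask = CellMask(density > 0.05 * (scene.texture or scene.default_texture()).density_scale)

    _cfl_guard(scene)

    if scene.velocity.kind in ("zero", "uniform"):
        densities, source_maps = _evolve_exact_uniform(scene, density)
    else:
        blob_centers = [np.array(b.center, float) for b in scene.source.blobs]
        densities = [density]
        source_maps = []
        for k in range(scene.n_frames - 1):
            t = k * dt_min
            if scene.source.kind == "uniform_specific":
                source_maps.append(scene.source.g * density)
            elif scene.source.kind == "blobs":
                source_maps.append(
                    _blob_map(scene.source.blobs, blob_centers, scene.shape, scene.pixel_size)
                )
            else:
                source_maps.append(np.zeros(scene.shape))

            density = _advect_semi_lagrangian(density, scene.velocity, t, dt_min, scene.pixel_size)
            if scene.source.kind == "uniform_specific":
                density = density * np.exp(scene.source.g * dt_h)
            elif scene.source.kind == "blobs":
                for n, c in enumerate(blob_centers):
                    u, v = scene.velocity(np.array([c[0]]), np.array([c[1]]), t)
                    blob_centers[n] = c + dt_min * np.array([u[0], v[0]])
                density = np.clip(
                    density
                    + dt_h * _blob_map(scene.source.blobs, blob_centers, scene.shape, scene.pixel_size),
                    0.0,
                    None,
                )
            densities.append(density)
        source_maps.append(np.zeros(scene.shape))  # no update follows the last frame

    frames = []
    for k, d in enumerate(densities):
        opd = d * scene.refractive_increment
        if scene.noise_sigma > 0:
            opd = opd + rng.normal(0.0, scene.noise_sigma, size=scene.shape)
        frames.append(PhaseFrame(opd=np.clip(opd, 0.0, None), timestamp=k * dt_min))
    return frames, GroundTruth(scene, densities, source_maps, cell_mask)


def _cfl_guard(scene: SyntheticScene) -> None:
    xx, yy = _pixel_center_grids(scene.shape, scene.pixel_size)
    speeds = []
    for k in range(scene.n_frames - 1):
        u, v = scene.velocity(xx, yy, k * scene.frame_interval)
        speeds.append(np.hypot(u, v).max())
    if not speeds:
        return
    disp_px = max(speeds) * scene.frame_interval / scene.pixel_size
    if disp_px > PIVConfig().search_radius:
        warnings.warn(
            f"prescribed displacement {disp_px:.1f} px/frame exceeds the default "
            f"PIV search radius ({PIVConfig().search_radius} px); velocimetry on "
            "this movie will alias",
            stacklevel=2,
        )


# ---------------------------------------------------------------------------
# Fixed-cell control fixture
# ---------------------------------------------------------------------------

def fixed_cell_fixture(
    base_frame: MassFrame,
    shifts: list[tuple[float, float]],
    noise_sigma: float,
    seed: int = 0,
) -> list[PhaseFrame]:
    """Rigid-drift movie of a frozen cell: ground-truth growth is zero.

    ``shifts`` are per-frame displacement increments in px; output frame k
    is the base frame Fourier-shifted by the cumulative shift of the first
    k increments (frame 0 is unshifted, so the movie has len(shifts) + 1
    frames), plus fresh Gaussian OPD noise.  Emulates the standard control
    of translating images of a fixed (dead) cell, where any apparent
    growth is pure pipeline error.

    Raises when the cumulative drift would push cell signal across the
    image border (the control would no longer be mass-conserving).
    """
    rng = np.random.default_rng(seed)
    cal = base_frame.calibration
    opd0 = base_frame.density * cal.refractive_increment
    cum = np.cumsum(np.asarray(shifts, float).reshape(-1, 2), axis=0)
    cum = np.vstack([[0.0, 0.0], cum])

    margin = int(np.ceil(np.abs(cum).max())) + 1
    border = np.ones(opd0.shape, dtype=bool)
    if margin < min(opd0.shape) // 2:
        border[margin:-margin, margin:-margin] = False
    if opd0[border].max() > 1e-3 * max(opd0.max(), 1e-12):
        raise ValueError("cell signal reaches the border; drift would clip the cell")

    f0 = np.fft.fft2(opd0)
    frames = []
    for k, (dx, dy) in enumerate(cum):
        shifted = np.real(np.fft.ifft2(ndimage.fourier_shift(f0, (dy, dx))))
        if noise_sigma > 0:
            shifted = shifted + rng.normal(0.0, noise_sigma, size=opd0.shape)
        frames.append(
            PhaseFrame(opd=np.clip(shifted, 0.0, None), timestamp=k * cal.frame_interval)
        )
    return frames
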