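"""Phase-to-dry-mass imaging: OPD ingestion, background correction, segmentation.

Quantitative phase imaging (QPI) measures the optical path difference (OPD)
of light through a specimen.  Because the refractive-index excess of cellular
material is proportional to its dry-mass concentration (specific refractive
increment alpha, here 0.18 um^3/pg), an OPD image divides directly into an
areal dry-mass density image sigma = OPD / alpha in pg/um^2.

Pixel grid convention (shared by every module): arrays are row-major and
0-based; the physical coordinate of the *center* of pixel (i, j) is
x = (j + 0.5) * pixel_size, y = (i + 0.5) * pixel_size, with y increasing
down rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy import ndimage
from skimage import measure

__all__ = [
    "Calibration",
    "PhaseFrame",
    "MassFrame",
    "CellMask",
    "background_correct",
    "phase_to_mass",
    "segment_cell",
    "total_mass",
    "read_opd_stack",
    "write_mass_stack",
    "read_mask",
    "pixel_centers",
]

#: Specific refractive increment of cellular dry material, um^3/pg.
DEFAULT_REFRACTIVE_INCREMENT = 0.18


class EmptySegmentationError(ValueError):
    """Raised when no pixels exceed the segmentation threshold."""


class EmptyBackgroundError(ValueError):
    """Raised when a mask leaves no background pixels to fit."""


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of an acquisition.

    Parameters
    ----------
    pixel_size : float
        Edge length of one pixel in um.
    frame_interval : float
        Time between consecutive frames in min.
    refractive_increment : float
        Specific refractive increment alpha in um^3/pg; converts OPD (um)
        to areal density (pg/um^2) as sigma = OPD / alpha.
    """

    pixel_size: float
    frame_interval: float
    refractive_increment: float = DEFAULT_REFRACTIVE_INCREMENT

    def __post_init__(self) -> None:
        for name in ("pixel_size", "frame_interval", "refractive_increment"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"Calibration.{name} must be strictly positive")

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in um^2."""
        return self.pixel_size**2


@dataclass(frozen=True)
class PhaseFrame:
    """One OPD image (um) at a timestamp (min)."""

    opd: np.ndarray
    timestamp: float

    def __post_init__(self) -> None:
        opd = np.asarray(self.opd, dtype=float)
        if opd.ndim != 2:
            raise ValueError("opd must be a 2-D array")
        if not np.all(np.isfinite(opd)):
            raise ValueError("opd must be finite")
        if self.timestamp < 0:
            raise ValueError("timestamp must be non-negative")
        object.__setattr__(self, "opd", opd)


@dataclass(frozen=True)
class MassFrame:
    """Areal dry-mass density sigma (pg/um^2) at a timestamp (min)."""

    density: np.ndarray
    timestamp: float
    calibration: Calibration

    def __post_init__(self) -> None:
        density = np.asarray(self.density, dtype=float)
        if density.ndim != 2:
            raise ValueError("density must be a 2-D array")
        object.__setattr__(self, "density", density)

    @property
    def shape(self) -> tuple[int, int]:
        return self.density.shape


@dataclass(frozen=True)
class CellMask:
    """Boolean region mask with a semantic label (cell | nucleus | cytoplasm)."""

    mask: np.ndarray
    label: str = "cell"

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("mask must be a 2-D array")
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def __and__(self, other: "CellMask") -> "CellMask":
        return CellMask(self.mask & other.mask, label=f"{self.label}&{other.label}")


def cytoplasm_mask(cell: CellMask, nucleus: CellMask) -> CellMask:
    """Cytoplasm = cell AND NOT nucleus."""
    if cell.shape != nucleus.shape:
        raise ValueError("cell and nucleus masks must share a shape")
    return CellMask(cell.mask & ~nucleus.mask, label="cytoplasm")


def pixel_centers(shape: tuple[int, int], pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Physical (x, y) coordinates of pixel centers, each shaped like the image."""
    ny, nx = shape
    x = (np.arange(nx) + 0.5) * pixel_size
    y = (np.arange(ny) + 0.5) * pixel_size
    return np.meshgrid(x, y)


# ---------------------------------------------------------------------------
# Background correction
# ---------------------------------------------------------------------------

def background_correct(frame: PhaseFrame, cell_mask: CellMask) -> PhaseFrame:
    """Remove a least-squares background plane fitted off-cell.

    A plane a*x + b*y + c is fit over the non-cell region and subtracted
    everywhere, modelling slowly varying illumination; afterwards the
    residual median over the background region is removed so the off-cell
    OPD has median ~ 0 before mass conversion.
    """
    if cell_mask.shape != frame.opd.shape:
        raise ValueError("mask shape does not match frame shape")
    bg = ~cell_mask.mask
    if not bg.any():
        raise EmptyBackgroundError("mask leaves no background pixels to fit")
    jj, ii = np.meshgrid(np.arange(frame.opd.shape[1]), np.arange(frame.opd.shape[0]))
    A = np.column_stack([jj[bg], ii[bg], np.ones(int(bg.sum()))])
    coeffs, *_ = np.linalg.lstsq(A, frame.opd[bg], rcond=None)
    plane = coeffs[0] * jj + coeffs[1] * ii + coeffs[2]
    corrected = frame.opd - plane
    corrected -= np.median(corrected[bg])
    return PhaseFrame(opd=corrected, timestamp=frame.timestamp)


# ---------------------------------------------------------------------------
# Mass conversion
# ---------------------------------------------------------------------------

def phase_to_mass(frame: PhaseFrame, cal: Calibration) -> MassFrame:
    """Convert OPD (um) to areal dry-mass density sigma = OPD / alpha (pg/um^2).

    The conversion is linear and exactly invertible: ``density * alpha``
    reproduces the OPD to machine precision.  Per-pixel mass is
    ``density * cal.pixel_area``.
    """
    density = frame.opd / cal.refractive_increment
    return MassFrame(density=density, timestamp=frame.timestamp, calibration=cal)


def mass_to_phase(frame: MassFrame) -> PhaseFrame:
    """Inverse of :func:`phase_to_mass` (OPD = sigma * alpha)."""
    return PhaseFrame(
        opd=frame.density * frame.calibration.refractive_increment,
        timestamp=frame.timestamp,
    )


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_cell(
    frame: MassFrame,
    threshold: float = 0.05,
    smooth_sigma: float = 1.0,
) -> CellMask:
    """Segment the cell as the largest connected above-threshold region.

    Gaussian pre-smoothing (``smooth_sigma`` px) suppresses shot noise, a
    fixed density threshold (pg/um^2) binarizes, the largest connected
    component is kept and its holes filled.  Deterministic given the frame
    and the threshold.
    """
    smoothed = ndimage.gaussian_filter(frame.density, sigma=smooth_sigma)
    binary = smoothed > threshold
    if not binary.any():
        raise EmptySegmentationError(
            f"no pixels above segmentation threshold {threshold} pg/um^2"
        )
    labels = measure.label(binary, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    return CellMask(mask=mask, label="cell")


def total_mass(frame: MassFrame, mask: CellMask) -> float:
    """Total dry mass in pg over the mask: sum(sigma) * pixel_area."""
    if mask.shape != frame.shape:
        raise ValueError("mask shape does not match frame shape")
    return float(frame.density[mask.mask].sum() * frame.calibration.pixel_area)


# ---------------------------------------------------------------------------
# I/O: multi-page float TIFF stacks + metadata sidecar
# ---------------------------------------------------------------------------

def read_metadata_sidecar(path: str | Path) -> Calibration:
    """Read a JSON or YAML sidecar with pixel_size_um / frame_interval_min keys."""
    path = Path(path)
    text = path.read_text()
    meta = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    missing = {"pixel_size_um", "frame_interval_min"} - set(meta)
    if missing:
        raise KeyError(
            f"metadata sidecar {path.name} is missing required key(s): {sorted(missing)}"
        )
    return Calibration(
        pixel_size=float(meta["pixel_size_um"]),
        frame_interval=float(meta["frame_interval_min"]),
        refractive_increment=float(
            meta.get("refractive_increment", DEFAULT_REFRACTIVE_INCREMENT)
        ),
    )


def read_opd_stack(
    tiff_path: str | Path, metadata_path: str | Path
) -> tuple[list[PhaseFrame], Calibration]:
    """Read a multi-page float TIFF of OPD (um), one page per timepoint."""
    cal = read_metadata_sidecar(metadata_path)
    stack = tifffile.imread(tiff_path)
    if stack.ndim == 2:
        stack = stack[None]
    frames = [
        PhaseFrame(opd=np.asarray(page, dtype=float), timestamp=k * cal.frame_interval)
        for k, page in enumerate(stack)
    ]
    return frames, cal


def write_opd_stack(path: str | Path, frames: list[PhaseFrame]) -> None:
    """Write OPD frames as a 32-bit float multi-page TIFF (deterministic bytes)."""
    data = np.stack([f.opd for f in frames]).astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")


def write_mass_stack(path: str | Path, frames: list[MassFrame]) -> None:
    """Write density frames as a 32-bit float multi-page TIFF."""
    data = np.stack([f.density for f in frames]).astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")


def read_mask(path: str | Path, label: str = "cell") -> CellMask:
    """Read a single-page TIFF/PNG mask; nonzero pixels are inside."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        from imageio.v3 import imread

        arr = imread(path)
    if arr.ndim == 3:  # drop color channels
        arr = arr[..., 0]
    return CellMask(mask=arr != 0, label=label)
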