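"""Net growth-rate estimation from Lagrangian mass series.

In the co-moving frame the mass of a tracked control volume changes only
through net biomass generation (the source term of the intracellular mass
balance), so the ordinary-least-squares slope of mass versus time over a
window is the volume's net growth rate in pg/h.  Rates are rasterized back
onto the image grid at the volumes' window-start footprints to form growth
maps, and windows slide over the movie for time-resolved series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath

from .mass_imaging import Calibration, CellMask, MassFrame, segment_cell, total_mass
from .tracking import ControlVolume, ControlVolumeTrack, seed_control_volumes, track_control_volumes
from .velocimetry import VelocityField

__all__ = [
    "GrowthEstimate",
    "GrowthMap",
    "fit_growth_rate",
    "assemble_growth_map",
    "windowed_growth",
    "ols_slope",
]


@dataclass(frozen=True)
class GrowthEstimate:
    """OLS growth rate of one control volume over one window.

    rate, rate_se : pg/h slope and its standard error.
    initial_mass : pg at the first usable frame (for specific rates).
    valid : False when fewer than 3 in-bounds frames fell in the window.
    """

    cv_id: int
    rate: float
    rate_se: float
    window: tuple[float, float]
    n_frames: int
    initial_mass: float = float("nan")
    valid: bool = True


@dataclass(frozen=True)
class GrowthMap:
    """Per-pixel net growth rate (pg/h) over one window.

    Pixels not covered by any in-bounds control volume are NaN.
    """

    raster: np.ndarray
    window: tuple[float, float]

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.raster)


def ols_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and standard error of y on t by ordinary least squares.

    Returns (slope, se); se is 0 for an exact linear fit and NaN when fewer
    than 3 points are supplied.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = len(t)
    if n < 2:
        return float("nan"), float("nan")
    tbar = t.mean()
    sxx = float(((t - tbar) ** 2).sum())
    if sxx == 0:
        return float("nan"), float("nan")
    slope = float(((t - tbar) * (y - y.mean())).sum() / sxx)
    if n < 3:
        return slope, float("nan")
    resid = y - (y.mean() + slope * (t - tbar))
    sigma2 = float((resid**2).sum()) / (n - 2)
    return slope, float(np.sqrt(sigma2 / sxx))


def fit_growth_rate(
    track: ControlVolumeTrack, window: tuple[float, float]
) -> GrowthEstimate:
    """Fit the net growth rate (pg/h) of one track within a time window (min).

    Uses only in-bounds frames with t_start <= t <= t_end; time is converted
    to hours so the slope is directly in pg/h.  Fewer than 3 usable frames
    marks the estimate invalid instead of raising.
    """
    t_start, t_end = window
    t = track.timestamps
    sel = track.in_bounds & (t >= t_start - 1e-9) & (t <= t_end + 1e-9)
    n = int(sel.sum())
    if n < 3:
        return GrowthEstimate(
            cv_id=track.cv_id, rate=float("nan"), rate_se=float("nan"),
            window=window, n_frames=n, valid=False,
        )
    t_h = t[sel] / 60.0
    mass = track.masses[sel]
    rate, se = ols_slope(t_h, mass)
    return GrowthEstimate(
        cv_id=track.cv_id, rate=rate, rate_se=se, window=window,
        n_frames=n, initial_mass=float(mass[0]),
    )


def assemble_growth_map(
    estimates: list[GrowthEstimate],
    cvs_at_window_start: list[ControlVolume],
    shape: tuple[int, int],
    cal: Calibration,
) -> GrowthMap:
    """Rasterize per-volume rates onto the pixel grid.

    Each pixel whose center lies inside a volume's window-start polygon
    carries that volume's rate; where polygons overlap, the volume with the
    nearest seed center wins.  Uncovered pixels are NaN.
    """
    by_id = {cv.id: cv for cv in cvs_at_window_start}
    raster = np.full(shape, np.nan)
    best_d2 = np.full(shape, np.inf)
    ny, nx = shape
    px = cal.pixel_size
    xs = (np.arange(nx) + 0.5) * px
    ys = (np.arange(ny) + 0.5) * px
    window = estimates[0].window if estimates else (float("nan"), float("nan"))
    for est in estimates:
        if not est.valid or est.cv_id not in by_id:
            continue
        cv = by_id[est.cv_id]
        j0 = max(int(np.floor(cv.corners[:, 0].min() / px)), 0)
        j1 = min(int(np.ceil(cv.corners[:, 0].max() / px)), nx)
        i0 = max(int(np.floor(cv.corners[:, 1].min() / px)), 0)
        i1 = min(int(np.ceil(cv.corners[:, 1].max() / px)), ny)
        if j0 >= j1 or i0 >= i1:
            continue
        xx, yy = np.meshgrid(xs[j0:j1], ys[i0:i1])
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        inside = MplPath(cv.corners).contains_points(pts).reshape(xx.shape)
        d2 = (xx - cv.seed_center[0]) ** 2 + (yy - cv.seed_center[1]) ** 2
        sub = (slice(i0, i1), slice(j0, j1))
        take = inside & (d2 < best_d2[sub])
        raster[sub][take] = est.rate
        best_d2[sub][take] = d2[take]
    return GrowthMap(raster=raster, window=window)


@dataclass(frozen=True)
class WindowResult:
    """Everything computed for one sliding window."""

    window: tuple[float, float]
    cvs: list[ControlVolume]
    tracks: list[ControlVolumeTrack]
    estimates: list[GrowthEstimate]
    map: GrowthMap
    mask: CellMask
    excluded: bool = False


def _mitosis_guard(frames: list[MassFrame], masks: list[CellMask]) -> bool:
    """True when whole-cell mass or area jumps > 20% between two frames.

    Division-like events break the Lagrangian assumption (material identity
    of the tracked volumes), so such windows are excluded with a warning.
    """
    masses = np.array([total_mass(f, m) for f, m in zip(frames, masks)])
    areas = np.array([m.mask.sum() for m in masks], dtype=float)
    for series in (masses, areas):
        prev = series[:-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            jump = np.abs(np.diff(series)) / np.where(prev > 0, prev, np.nan)
        if np.nanmax(jump, initial=0.0) > 0.20:
            return True
    return False


def windowed_growth(
    frames: list[MassFrame],
    fields: list[VelocityField],
    window_len: float = 30.0,
    window_step: float | None = None,
    cv_area: float = 0.7,
    masks: list[CellMask] | None = None,
    segmentation_threshold: float = 0.05,
    scheme: str = "euler",
    method: str = "clip",
    anchored: bool = True,
    piv_cfg=None,
) -> list[WindowResult]:
    """Sliding-window growth maps over a movie.

    At each window start the cell is (re-)segmented, control volumes are
    re-seeded on the current mask, tracked through the window, fit, and
    rasterized.  ``window_len`` and ``window_step`` are in min; windows
    overlap when step < length.  Windows containing a mitosis-like jump
    (whole-cell mass or area changing > 20% in one frame) are excluded
    with a warning.
    """
    if len(fields) != len(frames) - 1:
        raise ValueError("need exactly one velocity field per consecutive frame pair")
    times = np.array([f.timestamp for f in frames])
    duration = times[-1] - times[0]
    if window_len > duration + 1e-9:
        raise ValueError("window_len exceeds the movie duration")
    if window_step is None:
        window_step = window_len
    if window_step <= 0:
        raise ValueError("window_step must be positive")

    if masks is None:
        masks = [segment_cell(f, threshold=segmentation_threshold) for f in frames]

    results: list[WindowResult] = []
    t0 = times[0]
    while t0 + window_len <= times[-1] + 1e-9:
        window = (float(t0), float(t0 + window_len))
        sel = np.nonzero((times >= window[0] - 1e-9) & (times <= window[1] + 1e-9))[0]
        w_frames = [frames[k] for k in sel]
        w_masks = [masks[k] for k in sel]
        w_fields = [fields[k] for k in sel[:-1]]
        mask0 = w_masks[0]
        cal = w_frames[0].calibration
        if _mitosis_guard(w_frames, w_masks):
            warnings.warn(
                f"window {window}: whole-cell mass/area jump > 20% in one frame "
                "(division-like event); window excluded from growth analysis",
                stacklevel=2,
            )
            results.append(
                WindowResult(window, [], [], [],
                             GrowthMap(np.full(w_frames[0].shape, np.nan), window),
                             mask0, excluded=True)
            )
            t0 += window_step
            continue
        cvs = seed_control_volumes(mask0, cal, target_area=cv_area)
        tracks = track_control_volumes(
            w_frames, w_fields, cvs, scheme=scheme, method=method,
            anchored=anchored, piv_cfg=piv_cfg,
        )
        estimates = [fit_growth_rate(tr, window) for tr in tracks]
        gmap = assemble_growth_map(estimates, cvs, w_frames[0].shape, cal)
        results.append(WindowResult(window, cvs, tracks, estimates, gmap, mask0))
        t0 += window_step
    return results


def estimates_to_dataframe(estimates: list[GrowthEstimate]):
    """Tidy per-volume rate table (cv_id, rate_pg_per_h, rate_se, window)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "cv_id": [e.cv_id for e in estimates],
            "rate_pg_per_h": [e.rate for e in estimates],
            "rate_se": [e.rate_se for e in estimates],
            "t_start_min": [e.window[0] for e in estimates],
            "t_end_min": [e.window[1] for e in estimates],
            "n_frames": [e.n_frames for e in estimates],
            "initial_mass_pg": [e.initial_mass for e in estimates],
            "valid": [e.valid for e in estimates],
        }
    )
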