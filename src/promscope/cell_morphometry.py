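"""Cell segmentation, boundary tracking, kymographs and regional statistics.

Operates on the PWS / PIS shift images.  The PIS channel carries the
strongest boundary contrast (the focal-adhesion "ring" along the cell
periphery), so it is the default segmentation channel.  Boundaries are
extracted as sub-pixel closed contours, resampled at equal arclength so
that kymograph rows stay comparable across frames, and tracked frame to
frame along local normals.

Coordinates are 0-based pixel indices with pixel centers on integer
coordinates and row (y) increasing downward; physical positions are
index * pixel_pitch_um.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import splev, splprep
from scipy.ndimage import (binary_fill_holes, distance_transform_edt,
                           gaussian_filter, gaussian_filter1d,
                           map_coordinates)
from skimage import measure, morphology
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

DEFAULT_N_SAMPLES = 360
# contour cleaning: allowed RMS deviation of the smoothing spline from the
# marching-squares vertices, and the residual above which a vertex is
# treated as a genuine corner and pinned
_SPLINE_TOL_PX = 0.3
_CORNER_RESID_PX = 0.85
_CORNER_WEIGHT = 20.0


class NoCellError(ValueError):
    """Segmentation found no foreground."""


class DegenerateContourError(ValueError):
    """Mask too small to carry a meaningful closed contour."""


class RegionEmptyError(ValueError):
    """Edge or center region vanished after erosion by the chosen margins."""


@dataclass(frozen=True)
class CellBoundary:
    """Closed sub-pixel contour with outward unit normals.

    ``points`` is (N, 2) in (row, col) pixel coordinates, ordered
    counterclockwise in image convention and equally spaced in arclength;
    ``normals`` is (N, 2) outward unit vectors; ``arclength_px`` the
    cumulative arclength parameter of each sample.
    """

    points: np.ndarray
    normals: np.ndarray
    arclength_px: np.ndarray
    frame_index: int = 0
    pixel_pitch_um: float = 0.6

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        n = np.asarray(self.normals, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2 or p.shape != n.shape:
            raise ValueError("points and normals must be (N, 2)")
        norms = np.linalg.norm(n, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("normals must be unit length")
        object.__setattr__(self, "points", p)
        object.__setattr__(self, "normals", n)

    @property
    def perimeter_px(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.hypot(*np.diff(closed, axis=0).T).sum())

    @property
    def perimeter_um(self) -> float:
        return self.perimeter_px * self.pixel_pitch_um


@dataclass(frozen=True)
class Kymograph:
    """Boundary-arclength x time sampling of a shift image within a band."""

    matrix: np.ndarray          # (n_samples, n_frames)
    band_offset_um: float
    band_width_um: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != self.n_samples:
            raise ValueError("kymograph row count must equal n_samples")


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_cell(image: np.ndarray, smooth_sigma_px: float = 1.0,
                 closing_radius_px: int = 2) -> np.ndarray:
    """Binary cell mask: smooth, Otsu, close, keep largest component, fill.

    NaN pixels (invalid fits) are treated as background signal 0 before
    smoothing.
    """
    img = np.asarray(image, dtype=float)
    img = np.where(np.isfinite(img), img, 0.0)
    sm = gaussian_filter(img, smooth_sigma_px)
    if np.ptp(sm) == 0:
        raise NoCellError("image has no dynamic range")
    mask = sm > threshold_otsu(sm)
    if not mask.any():
        raise NoCellError("Otsu threshold produced an empty foreground")
    mask = morphology.closing(mask, morphology.disk(closing_radius_px))
    labels = measure.label(mask)
    if labels.max() == 0:
        raise NoCellError("no connected component after closing")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    return binary_fill_holes(mask)


# ---------------------------------------------------------------------------
# boundary extraction
# ---------------------------------------------------------------------------

def _clean_contour(contour: np.ndarray) -> "tuple[np.ndarray, np.ndarray]":
    """Corner-pinned periodic smoothing spline through marching-squares
    vertices.  Removes the staircase jitter of the discrete contour (which
    otherwise inflates perimeters by several percent) while following
    genuine corners: vertices whose residual exceeds a threshold are
    re-weighted and the spline re-fit.  Returns the spline tck and u."""
    c = contour
    if np.allclose(c[0], c[-1]):
        c = c[:-1]
    m = len(c)
    w = np.ones(m)
    tck = u = None
    for _ in range(3):
        tck, u = splprep([c[:, 0], c[:, 1]], w=w, s=m * _SPLINE_TOL_PX ** 2,
                         per=1)
        x, y = splev(u, tck)
        resid = np.hypot(c[:, 0] - x, c[:, 1] - y)
        pins = resid > _CORNER_RESID_PX
        if not pins.any():
            break
        w = np.where(pins | (w > 1), _CORNER_WEIGHT, 1.0)
    return tck, u


def _resample_closed(points: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    closed = np.vstack([points, points[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    si = np.linspace(0.0, total, n, endpoint=False)
    res = np.column_stack([np.interp(si, s, closed[:, 0]),
                           np.interp(si, s, closed[:, 1])])
    return res, si


def _normals_from_points(points: np.ndarray, mask: np.ndarray | None,
                         smooth_sigma: float = 1.5) -> np.ndarray:
    tx = gaussian_filter1d(points[:, 0], smooth_sigma, mode="wrap", order=1)
    ty = gaussian_filter1d(points[:, 1], smooth_sigma, mode="wrap", order=1)
    t = np.column_stack([tx, ty])
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    nrm = np.column_stack([t[:, 1], -t[:, 0]])  # tangent rotated -90 deg
    if mask is not None:
        # orient outward: probe the mask a pixel along each normal
        probe = points + nrm
        inside = map_coordinates(mask.astype(float), probe.T, order=1,
                                 mode="constant")
        if np.mean(inside) > 0.5:
            nrm = -nrm
    return nrm


def extract_boundary(mask: np.ndarray, n_samples: int = DEFAULT_N_SAMPLES,
                     frame_index: int = 0,
                     pixel_pitch_um: float = 0.6) -> CellBoundary:
    """Sub-pixel 0.5-level boundary resampled at equal arclength.

    The marching-squares contour is cleaned by a corner-pinned periodic
    smoothing spline, resampled to ``n_samples`` points, and given outward
    unit normals.  A component touching the frame edge is contoured as far
    as possible with a logged warning.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() < 9:
        raise DegenerateContourError("mask too small for a closed contour")
    if (mask[0].any() or mask[-1].any() or mask[:, 0].any()
            or mask[:, -1].any()):
        logger.warning("cell component touches the frame edge; contour "
                       "will be clipped")
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise DegenerateContourError("no iso-contour found")
    contour = max(contours, key=len)
    if len(contour) < 8:
        raise DegenerateContourError("contour too short")
    tck, _ = _clean_contour(contour)
    uu = np.linspace(0.0, 1.0, 8 * max(n_samples, len(contour)),
                     endpoint=False)
    dense = np.column_stack(splev(uu, tck))
    points, arclength = _resample_closed(dense, n_samples)
    # enforce counterclockwise orientation in (row, col) image convention
    area2 = np.sum(points[:, 1] * np.roll(points[:, 0], -1)
                   - np.roll(points[:, 1], -1) * points[:, 0])
    if area2 < 0:
        points = points[::-1].copy()
        points = np.roll(points, 1, axis=0)
        _, arclength = _resample_closed(points, n_samples)
    normals = _normals_from_points(points, mask)
    return CellBoundary(points, normals, arclength, frame_index,
                        pixel_pitch_um)


# ---------------------------------------------------------------------------
# boundary tracking
# ---------------------------------------------------------------------------

def track_boundary(prev: CellBoundary, next_mask: np.ndarray,
                   search_um: float = 10.0,
                   displacement_smooth: float = 2.0) -> CellBoundary:
    """Correspond a boundary to the next frame along local normals.

    For each arclength sample a ray is cast along its outward normal over
    ``+-search_um`` and the corresponded point placed where the ray crosses
    the next frame's cleaned sub-pixel contour (extracted with the same
    corner-pinned spline pipeline, so identical masks track with zero
    displacement), choosing the crossing nearest the previous position.
    Samples without a crossing are flagged, logged, and filled by circular
    interpolation of their neighbors' displacements, so the sample indexing
    — and therefore kymograph rows — stays coherent across frames.  The
    displacement profile is finally smoothed circularly (sigma
    ``displacement_smooth`` samples) to suppress residual pixel jitter.
    """
    field = np.asarray(next_mask).astype(float)
    search_px = search_um / prev.pixel_pitch_um
    n = len(prev.points)
    contours = measure.find_contours(field, 0.5)
    if not contours:
        raise ValueError("next mask has no contour")
    tck, _ = _clean_contour(max(contours, key=len))
    uu = np.linspace(0.0, 1.0, 16 * n, endpoint=False)
    dense = np.column_stack(splev(uu, tck))
    disp = np.full(n, np.nan)
    tangents = np.column_stack([-prev.normals[:, 1], prev.normals[:, 0]])
    for i in range(n):
        d = dense - prev.points[i]
        t = d @ prev.normals[i]
        u = d @ tangents[i]
        on_ray = (np.abs(u) < 0.75) & (np.abs(t) <= search_px)
        if not on_ray.any():
            continue
        tc = t[on_ray]
        uc = np.abs(u[on_ray])
        nearest = np.abs(tc).argmin()
        cluster = np.abs(tc - tc[nearest]) < 1.0
        disp[i] = tc[cluster][uc[cluster].argmin()]
    missing = ~np.isfinite(disp)
    if missing.all():
        raise ValueError("no normal ray crossed the next mask; masks "
                         "probably do not overlap")
    if missing.any():
        logger.warning("%d/%d boundary samples had no crossing within "
                       "%.1f um; interpolated from neighbors",
                       int(missing.sum()), n, search_um)
        idx = np.arange(n)
        good = idx[~missing]
        disp[missing] = np.interp(idx[missing], good, disp[good],
                                  period=n)
    if displacement_smooth > 0:
        disp = gaussian_filter1d(disp, displacement_smooth, mode="wrap")
    points = prev.points + disp[:, None] * prev.normals
    normals = _normals_from_points(points, field > 0.5)
    closed = np.vstack([points, points[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    arclength = np.concatenate([[0.0], np.cumsum(seg)[:-1]])
    out = CellBoundary(points, normals, arclength, prev.frame_index + 1,
                       prev.pixel_pitch_um)
    object.__setattr__(out, "displacement_px", disp)
    return out


# ---------------------------------------------------------------------------
# band kymograph
# ---------------------------------------------------------------------------

def band_kymograph(images, boundaries, band_offset_um: float,
                   band_width_um: float,
                   samples_per_um: float = 4.0) -> Kymograph:
    """Sample a shift image along inward normal segments, per frame.

    Entry (i, t) is the mean of image t over the segment of the inward
    normal ray at boundary sample i covering [offset, offset + width] um
    inside the boundary (bilinear interpolation, NaN pixels excluded).
    A zero-width band degenerates to a single-sample line profile at the
    offset curve.
    """
    frames = list(images)
    bnds = list(boundaries)
    if len(frames) != len(bnds):
        raise ValueError("one boundary per frame is required")
    n = len(bnds[0].points)
    mat = np.full((n, len(frames)), np.nan)
    for t, (img, bnd) in enumerate(zip(frames, bnds)):
        if len(bnd.points) != n:
            raise ValueError("boundaries must share the sample count")
        pitch = bnd.pixel_pitch_um
        if band_width_um > 0:
            k = max(2, int(np.ceil(band_width_um * samples_per_um)))
            offs = np.linspace(band_offset_um, band_offset_um + band_width_um,
                               k) / pitch
        else:
            offs = np.array([band_offset_um / pitch])
        data = np.asarray(img, dtype=float)
        for i in range(n):
            pts = bnd.points[i] - offs[:, None] * bnd.normals[i]
            vals = map_coordinates(np.nan_to_num(data, nan=0.0), pts.T,
                                   order=1, mode="constant", cval=np.nan)
            ok = map_coordinates(np.isfinite(data).astype(float), pts.T,
                                 order=1, mode="constant") > 0.999
            if ok.any():
                mat[i, t] = vals[ok].mean()
    return Kymograph(mat, band_offset_um, band_width_um, n)


# ---------------------------------------------------------------------------
# regional statistics and profiles
# ---------------------------------------------------------------------------

def edge_center_stats(image: np.ndarray, mask: np.ndarray | list,
                      edge_depth_um: float = 3.0,
                      center_margin_um: float = 6.0,
                      pixel_pitch_um: float = 0.6) -> pd.DataFrame:
    """Mean/SD of a shift image over the cell edge versus the cell center.

    Edge: mask pixels within ``edge_depth_um`` of the boundary.  Center:
    mask pixels farther than ``center_margin_um``.  With a list of masks
    (several cells), per-cell rows are emitted plus a pooled row weighting
    each cell equally.
    """
    masks = mask if isinstance(mask, (list, tuple)) else [mask]
    img = np.asarray(image, dtype=float)
    rows = []
    for ci, m in enumerate(masks):
        m = np.asarray(m).astype(bool)
        if not m.any():
            raise RegionEmptyError(f"cell {ci}: empty mask")
        dist_um = distance_transform_edt(m) * pixel_pitch_um
        edge = m & (dist_um <= edge_depth_um)
        center = m & (dist_um > center_margin_um)
        for name, region in (("edge", edge), ("center", center)):
            vals = img[region]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                raise RegionEmptyError(
                    f"cell {ci}: {name} region empty for edge_depth="
                    f"{edge_depth_um} um / center_margin={center_margin_um} um")
            rows.append({"cell": ci, "region": name,
                         "mean": float(vals.mean()),
                         "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                         "n_pixels": int(vals.size)})
    table = pd.DataFrame(rows)
    if len(masks) > 1:
        pooled = (table.groupby("region", sort=False)
                  .agg(mean=("mean", "mean"), sd=("mean", "std"),
                       n_pixels=("n_pixels", "sum")).reset_index())
        pooled.insert(0, "cell", "pooled")
        table = pd.concat([table, pooled], ignore_index=True)
    return table


def cross_section(image: np.ndarray, p0, p1, n_samples: int = 200,
                  pixel_pitch_um: float = 0.6) -> pd.DataFrame:
    """Bilinear line profile between two (row, col) pixel endpoints.

    Returns a table with physical position along the line (um), the pixel
    coordinates of each sample, and the interpolated value.
    """
    img = np.asarray(image, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    for p in (p0, p1):
        if not (0 <= p[0] <= img.shape[0] - 1 and 0 <= p[1] <= img.shape[1] - 1):
            raise ValueError(f"endpoint {p} outside the frame")
    frac = np.linspace(0.0, 1.0, n_samples)
    pts = p0 + frac[:, None] * (p1 - p0)
    vals = map_coordinates(img, pts.T, order=1, mode="nearest")
    pos_um = frac * np.hypot(*(p1 - p0)) * pixel_pitch_um
    return pd.DataFrame({"position_um": pos_um, "y_px": pts[:, 0],
                         "x_px": pts[:, 1], "value": vals})


def temporal_curves(shift_images_seq, masks,
                    normalize_pis: bool = True) -> pd.DataFrame:
    """In-mask mean and SD of PWS and PIS per frame.

    One row per frame with timestamps, per-channel means and SDs over valid
    masked pixels, and (optionally) a min-max normalized PIS mean column for
    cross-channel comparison on a common [0, 1] scale.  Frames with an empty
    mask are flagged rather than dropped.
    """
    from .image_pipeline import normalize_series

    rows = []
    for t, (si, m) in enumerate(zip(shift_images_seq, masks)):
        m = np.asarray(m).astype(bool) & si.valid_mask
        row = {"frame": t, "t_s": si.timestamp_s, "flagged": not m.any()}
        for name, img in (("pws", si.pws_image), ("pis", si.pis_image)):
            vals = img[m]
            vals = vals[np.isfinite(vals)]
            row[f"{name}_mean"] = float(vals.mean()) if vals.size else np.nan
            row[f"{name}_sd"] = (float(vals.std(ddof=1))
                                 if vals.size > 1 else np.nan)
        rows.append(row)
    table = pd.DataFrame(rows)
    if normalize_pis and len(table) >= 2 and table["pis_mean"].nunique() > 1:
        table["pis_mean_norm"] = normalize_series(table["pis_mean"].to_numpy())
    return table
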