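"""Assembly of PWS and PIS images from per-frame resonance maps.

Sign conventions follow the instrument's: the peak wavelength shift
PWS = PWV_frame - PWV_background is positive for a red shift (cell
attachment adds dielectric mass), and the peak intensity shift
PIS = PIV_background - PIV_frame is positive for a reduction in reflection
efficiency (focal-adhesion scattering outcouples resonant photons), so both
contrasts render attachment as bright.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class DegenerateRangeError(ValueError):
    """Min-max normalization of a constant series is undefined."""


@dataclass(frozen=True)
class HyperspectralCube:
    """One line-scan frame: reflectance over (y, x, wavelength)."""

    data: np.ndarray
    wavelengths_nm: np.ndarray
    pixel_pitch_um: float = 0.6
    timestamp_s: float = 0.0
    frame_index: int = 0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        w = np.asarray(self.wavelengths_nm, dtype=float)
        if data.ndim != 3 or data.shape[2] != w.size:
            raise ValueError("data must be (y, x, wavelength) matching the "
                             "wavelength axis")
        if w.size > 1 and not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "wavelengths_nm", w)


@dataclass(frozen=True)
class ResonanceMaps:
    """Per-pixel PWV (nm) and normalized PIV maps with a validity mask."""

    pwv_map: np.ndarray
    piv_map: np.ndarray
    valid_mask: np.ndarray
    frame_index: int = 0
    timestamp_s: float = 0.0
    pixel_pitch_um: float = 0.6
    fwhm_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        pwv = np.asarray(self.pwv_map, dtype=float)
        piv = np.asarray(self.piv_map, dtype=float)
        mask = np.asarray(self.valid_mask, dtype=bool)
        if not (pwv.shape == piv.shape == mask.shape):
            raise ValueError("maps and mask must share a shape")
        if np.any(piv[mask] < 0):
            raise ValueError("PIV must be nonnegative where valid")
        object.__setattr__(self, "pwv_map", pwv)
        object.__setattr__(self, "piv_map", piv)
        object.__setattr__(self, "valid_mask", mask)


@dataclass(frozen=True)
class ShiftImages:
    """PWS (nm, red shift positive) and PIS (intensity reduction positive)."""

    pws_image: np.ndarray
    pis_image: np.ndarray
    valid_mask: np.ndarray
    frame_index: int = 0
    timestamp_s: float = 0.0
    pixel_pitch_um: float = 0.6

    def __post_init__(self) -> None:
        if not (self.pws_image.shape == self.pis_image.shape
                == self.valid_mask.shape):
            raise ValueError("images and mask must share a shape")


def shift_images(frame: ResonanceMaps, background: ResonanceMaps) -> ShiftImages:
    """PWS = PWV_frame - PWV_bg; PIS = PIV_bg - PIV_frame; masks intersect.

    Example worked by the instrument: a pixel whose resonance moves from
    626 nm / 0.90 before attachment to 628 nm / 0.80 after yields
    PWS = +2 nm and PIS = +0.10.
    """
    if frame.pwv_map.shape != background.pwv_map.shape:
        raise ValueError("frame and background shapes differ")
    mask = frame.valid_mask & background.valid_mask
    pws = np.where(mask, frame.pwv_map - background.pwv_map, np.nan)
    pis = np.where(mask, background.piv_map - frame.piv_map, np.nan)
    return ShiftImages(pws, pis, mask, frame.frame_index, frame.timestamp_s,
                       frame.pixel_pitch_um)


def background_from_sequence(maps_sequence: Sequence[ResonanceMaps],
                             strategy: str = "first_frame",
                             cell_free_masks: Sequence[np.ndarray] | None = None
                             ) -> ResonanceMaps:
    """Per-pixel background reference from a time series.

    ``first_frame`` uses frame 0 unchanged (the pre-attachment scan).
    ``cell_free_median`` takes, per pixel, the median over frames in which
    that pixel is marked cell-free, which tolerates late-arriving cells and
    slow drifts at the cost of needing per-frame cell-free masks.
    """
    if len(maps_sequence) == 0:
        raise ValueError("empty maps sequence")
    if strategy == "first_frame":
        return maps_sequence[0]
    if strategy != "cell_free_median":
        raise ValueError("strategy must be 'first_frame' or 'cell_free_median'")
    if cell_free_masks is None or len(cell_free_masks) != len(maps_sequence):
        raise ValueError("cell_free_median needs one cell-free mask per frame")
    pwv = np.stack([m.pwv_map for m in maps_sequence])
    piv = np.stack([m.piv_map for m in maps_sequence])
    valid = np.stack([m.valid_mask for m in maps_sequence])
    free = np.stack([np.asarray(m, dtype=bool) for m in cell_free_masks]) & valid
    with np.errstate(invalid="ignore"):
        pwv_bg = np.nanmedian(np.where(free, pwv, np.nan), axis=0)
        piv_bg = np.nanmedian(np.where(free, piv, np.nan), axis=0)
    mask_bg = free.any(axis=0) & np.isfinite(pwv_bg) & np.isfinite(piv_bg)
    first = maps_sequence[0]
    return ResonanceMaps(pwv_bg, piv_bg, mask_bg, first.frame_index,
                         first.timestamp_s, first.pixel_pitch_um)


def normalize_series(values: Sequence[float], mode: str = "minmax") -> np.ndarray:
    """Normalize a per-frame series; ``minmax`` maps it onto [0, 1]."""
    v = np.asarray(values, dtype=float)
    if mode == "none":
        return v.copy()
    if mode != "minmax":
        raise ValueError("mode must be 'none' or 'minmax'")
    if v.size < 2:
        raise ValueError("minmax normalization needs at least 2 frames")
    vmin, vmax = np.nanmin(v), np.nanmax(v)
    if vmax == vmin:
        raise DegenerateRangeError("constant series: min-max range is zero")
    return (v - vmin) / (vmax - vmin)
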