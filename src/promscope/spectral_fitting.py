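"""Per-spectrum resonance extraction: PWV and PIV estimation.

Each image pixel yields one reflectance spectrum.  After normalization to a
water-background reference (peak reflectance 100% for the bare sensor in
water), the resonance is summarized by its peak wavelength value (PWV) and
normalized peak intensity value (PIV).  The default estimator is a Lorentzian
least-squares fit over a window around the discrete maximum, with a
parabolic-vertex fallback; the GMR line is near-Lorentzian over the top of
the peak, and both estimators are provided because neither is canonical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .gmr_forward import ReflectionSpectrum

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_NM = 3.0
DEFAULT_TOP_K = 7


class GridMismatchError(ValueError):
    """Raw and reference spectra are sampled on different wavelength grids."""


@dataclass(frozen=True)
class ResonanceFit:
    """Fitted resonance peak: wavelength, normalized intensity, linewidth."""

    pwv_nm: float
    piv: float
    fwhm_nm: float
    fit_method: str
    goodness: float           # residual RMS over the fit window
    valid: bool
    invalid_reason: str = ""


def normalize_spectrum(raw: ReflectionSpectrum,
                       reference: ReflectionSpectrum) -> ReflectionSpectrum:
    """Normalize to the reference peak: the water background maps to 1.0."""
    if raw.wavelengths_nm.shape != reference.wavelengths_nm.shape or \
            not np.allclose(raw.wavelengths_nm, reference.wavelengths_nm,
                            rtol=0, atol=1e-9):
        raise GridMismatchError("raw and reference wavelength grids differ")
    ref_peak = float(np.max(reference.reflectance))
    if ref_peak <= 0:
        raise ValueError("reference spectrum has nonpositive maximum")
    return ReflectionSpectrum(
        raw.wavelengths_nm, raw.reflectance / ref_peak, raw.polarization,
        metadata={**raw.metadata, "normalized_to": ref_peak})


def _lorentzian(lam, amplitude, center, fwhm, baseline):
    hw2 = (fwhm / 2.0) ** 2
    return amplitude * hw2 / ((lam - center) ** 2 + hw2) + baseline


def _parabolic_vertex(w: np.ndarray, r: np.ndarray, i_max: int, top_k: int,
                      w_lo: float, w_hi: float) -> ResonanceFit:
    half = top_k // 2
    lo = max(0, i_max - half)
    hi = min(len(w), lo + top_k)
    lo = max(0, hi - top_k)
    ww, rr = w[lo:hi], r[lo:hi]
    # center the abscissa for conditioning
    w0 = ww.mean()
    a, b, c = np.polyfit(ww - w0, rr, 2)
    if a >= 0:
        return ResonanceFit(np.nan, np.nan, np.nan, "parabolic_vertex",
                            np.nan, False, "non-concave vertex fit")
    vx = -b / (2 * a) + w0
    vy = c - b ** 2 / (4 * a)
    if not (w_lo <= vx <= w_hi):
        return ResonanceFit(np.nan, np.nan, np.nan, "parabolic_vertex",
                            np.nan, False, "vertex outside fit window")
    resid = rr - np.polyval([a, b, c], ww - w0)
    # FWHM of the parabola about its vertex (crude but monotone linewidth proxy)
    fwhm = 2.0 * np.sqrt(max(vy, 0.0) / (2.0 * -a)) if vy > 0 else np.nan
    return ResonanceFit(float(vx), float(vy), float(fwhm), "parabolic_vertex",
                        float(np.sqrt(np.mean(resid ** 2))), True)


def fit_resonance(spectrum: ReflectionSpectrum, method: str = "lorentzian",
                  window_nm: float = DEFAULT_WINDOW_NM,
                  top_k: int = DEFAULT_TOP_K) -> ResonanceFit:
    """Estimate PWV, PIV and FWHM of the dominant reflectance peak.

    The fit window spans ``+-window_nm`` around the discrete argmax (ties
    break to the lowest wavelength).  A peak on the grid boundary or a fit
    that escapes the window yields ``valid=False`` rather than raising; a
    non-convergent Lorentzian falls back to the parabolic vertex with a
    logged warning.
    """
    w = spectrum.wavelengths_nm
    r = spectrum.reflectance
    if w.size < 5:
        return ResonanceFit(np.nan, np.nan, np.nan, method, np.nan, False,
                            "fewer than 5 samples")
    i_max = int(np.argmax(r))
    if i_max in (0, w.size - 1) or np.allclose(r, r[0]):
        return ResonanceFit(np.nan, np.nan, np.nan, method, np.nan, False,
                            "peak on grid boundary or flat spectrum")
    sel = np.abs(w - w[i_max]) <= window_nm
    ww, rr = w[sel], r[sel]
    if ww.size < 5:
        return ResonanceFit(np.nan, np.nan, np.nan, method, np.nan, False,
                            "fewer than 5 samples in fit window")
    w_lo, w_hi = ww[0], ww[-1]

    if method == "parabolic_vertex":
        j = int(np.argmax(rr))
        return _parabolic_vertex(ww, rr, j, top_k, w_lo, w_hi)
    if method != "lorentzian":
        raise ValueError("method must be 'lorentzian' or 'parabolic_vertex'")

    base0 = float(rr.min())
    amp0 = float(r[i_max] - base0)
    above = rr >= base0 + amp0 / 2
    fwhm0 = max(float(ww[above][-1] - ww[above][0]), float(np.diff(ww).min()))
    p0 = (amp0, float(w[i_max]), fwhm0, base0)
    try:
        with warnings.catch_warnings():
            # noiseless spectra fit exactly; the singular covariance is fine
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(_lorentzian, ww, rr, p0=p0, maxfev=4000,
                                xtol=1e-12, ftol=1e-12)
        amp, center, fwhm, baseline = popt
        fwhm = abs(fwhm)
        if not (w_lo <= center <= w_hi) or amp <= 0 or fwhm <= 0:
            raise RuntimeError("fit escaped the window")
        resid = rr - _lorentzian(ww, *popt)
        return ResonanceFit(float(center), float(amp + baseline), float(fwhm),
                            "lorentzian", float(np.sqrt(np.mean(resid ** 2))),
                            True)
    except RuntimeError as exc:
        logger.warning("Lorentzian fit failed (%s); falling back to "
                       "parabolic vertex", exc)
        j = int(np.argmax(rr))
        fit = _parabolic_vertex(ww, rr, j, top_k, w_lo, w_hi)
        return fit


def fit_cube(cube, reference, method: str = "lorentzian",
             window_nm: float = DEFAULT_WINDOW_NM):
    """Fit every pixel of a hyperspectral cube into PWV and PIV maps.

    ``reference`` is either a single :class:`ReflectionSpectrum` (applied to
    all pixels) or a reference cube of the same shape (per-pixel water
    background).  Pixels whose fit is invalid are NaN in both maps and False
    in the validity mask.
    """
    from .image_pipeline import HyperspectralCube, ResonanceMaps

    if not isinstance(cube, HyperspectralCube):
        raise TypeError("cube must be a HyperspectralCube")
    w = cube.wavelengths_nm
    ny, nx, _ = cube.data.shape

    if isinstance(reference, HyperspectralCube):
        if not np.allclose(reference.wavelengths_nm, w, rtol=0, atol=1e-9):
            raise GridMismatchError("cube and reference grids differ")
        ref_peak = reference.data.max(axis=2)
    elif isinstance(reference, ReflectionSpectrum):
        if not np.allclose(reference.wavelengths_nm, w, rtol=0, atol=1e-9):
            raise GridMismatchError("cube and reference grids differ")
        ref_peak = np.full((ny, nx), float(reference.reflectance.max()))
    else:
        raise TypeError("reference must be a HyperspectralCube or "
                        "ReflectionSpectrum")
    if np.any(ref_peak <= 0):
        raise ValueError("reference maximum must be positive everywhere")

    pwv = np.full((ny, nx), np.nan)
    piv = np.full((ny, nx), np.nan)
    fwhm = np.full((ny, nx), np.nan)
    valid = np.zeros((ny, nx), dtype=bool)
    for iy in range(ny):
        for ix in range(nx):
            spec = ReflectionSpectrum(w, cube.data[iy, ix] / ref_peak[iy, ix])
            fit = fit_resonance(spec, method=method, window_nm=window_nm)
            if fit.valid:
                pwv[iy, ix] = fit.pwv_nm
                piv[iy, ix] = fit.piv
                fwhm[iy, ix] = fit.fwhm_nm
                valid[iy, ix] = True
    return ResonanceMaps(pwv, piv, valid,
                         frame_index=cube.frame_index,
                         timestamp_s=cube.timestamp_s,
                         pixel_pitch_um=cube.pixel_pitch_um,
                         fwhm_map=fwhm)
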