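"""Rigorous coupled-wave analysis (RCWA) of the 1D photonic-crystal biosensor.

The sensor is a replica-molded polymer grating (trapezoidal ridges) coated with
a sputtered TiO2 film, immersed in an aqueous superstrate.  Guided-mode
resonance (GMR) produces a narrow near-unity reflection peak near 626 nm whose
wavelength reports the refractive index of the medium within the evanescent
tail of the leaky mode.

The solver is a Fourier modal method for lamellar multilayer gratings at
normal incidence (planar diffraction), with the inverse-rule factorization of
Li/Lalanne for the polarization with E perpendicular to the grating lines
("TM" here), and an enhanced-transmittance-matrix recursion for numerical
stability with many staircase slabs.

Geometry model
--------------
``build_staircase`` discretizes two trapezoids (polymer ridge, TiO2 cap) into
horizontal slabs.  The sputtered TiO2 film is represented conformally: a film
of the stated slab thickness covers the groove floor, and sidewall strips of
thickness ``(tio2_duty - grating_duty) * period / 2`` flank the polymer ridge
(the lateral growth implied by the cap being wider than the ridge).  With
both duty cycles at 1 the structure degenerates to planar films and the
solver must agree with the thin-film transfer-matrix result.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import solve as lin_solve
from scipy.linalg import toeplitz

logger = logging.getLogger(__name__)

DEFAULT_HARMONICS = 12          # 2M+1 = 25 Fourier orders
DEFAULT_WAVELENGTHS = (600.0, 650.0, 0.05)   # design-study grid, nm


class GeometryError(ValueError):
    """Staircase discretization produced an impossible fill fraction."""


class SolverError(RuntimeError):
    """RCWA eigen-decomposition or boundary matching failed."""


class ResonanceLocationError(ValueError):
    """No interior reflectance peak could be located in the spectrum."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GratingStack:
    """Geometric and optical description of the photonic-crystal sensor.

    Lengths in nm, angles in degrees from the horizontal (90 deg = vertical
    sidewall), duty cycles as fractions of the period at trapezoid mid-height.
    """

    period_nm: float = 400.0
    polymer_index: float = 1.46
    grating_depth_nm: float = 120.0
    grating_duty: float = 0.416
    grating_sidewall_deg: float = 85.0
    tio2_index: float = 2.4
    tio2_thickness_nm: float = 61.0
    tio2_duty: float = 0.50
    tio2_sidewall_deg: float = 82.0
    substrate_index: float = 1.52
    staircase_layers: int = 8

    def __post_init__(self) -> None:
        if self.period_nm <= 0:
            raise ValueError("period_nm must be positive")
        for name in ("grating_duty", "tio2_duty"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("grating_sidewall_deg", "tio2_sidewall_deg"):
            v = getattr(self, name)
            if not 0.0 < v <= 90.0:
                raise ValueError(f"{name} must lie in (0, 90], got {v}")
        if self.grating_depth_nm < 0 or self.tio2_thickness_nm < 0:
            raise ValueError("thicknesses must be >= 0")
        if self.staircase_layers < 1:
            raise ValueError("staircase_layers must be >= 1")


@dataclass(frozen=True)
class Medium:
    """Superstrate (cover) medium, by default water.

    ``dispersion`` optionally maps wavelength (nm) to index as a table of
    (wavelength_nm, n) pairs; between entries the index is interpolated
    linearly.  Without a table the index is constant.
    """

    superstrate_index: float = 1.333
    dispersion: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.superstrate_index < 1.0:
            raise ValueError("superstrate index must be >= 1")

    def index_at(self, wavelength_nm: float) -> float:
        if self.dispersion is None:
            return self.superstrate_index
        tab = np.asarray(self.dispersion, dtype=float)
        return float(np.interp(wavelength_nm, tab[:, 0], tab[:, 1]))


@dataclass(frozen=True)
class ReflectionSpectrum:
    """Sampled zeroth-order reflectance versus wavelength."""

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    polarization: str = "TM"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if w.ndim != 1 or w.shape != r.shape:
            raise ValueError("wavelength and reflectance grids must match")
        if w.size > 1 and not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "reflectance", r)


@dataclass(frozen=True)
class FieldProfile:
    """Laterally averaged evanescent intensity enhancement above the sensor.

    ``z_nm`` is height above the top TiO2 surface; ``intensity_enhancement``
    is the period-averaged |E|^2 of the evanescent diffraction orders divided
    by the incident intensity.  The propagating zeroth order (incident plus
    specular standing wave) is excluded so that the profile decays to zero
    and exposes the exponential tail of the leaky mode.
    """

    z_nm: np.ndarray
    intensity_enhancement: np.ndarray
    wavelength_nm: float

    def __post_init__(self) -> None:
        z = np.asarray(self.z_nm, dtype=float)
        s = np.asarray(self.intensity_enhancement, dtype=float)
        if z.shape != s.shape:
            raise ValueError("z and intensity arrays must have equal length")
        if np.any(z < 0) or not np.all(np.diff(z) > 0):
            raise ValueError("z_nm must be nonnegative and increasing")
        if np.any(s < 0):
            raise ValueError("intensity enhancement must be >= 0")
        object.__setattr__(self, "z_nm", z)
        object.__setattr__(self, "intensity_enhancement", s)


@dataclass(frozen=True)
class LateralStrip:
    """One material strip in a periodic layer: center and width as period
    fractions (center 0 = middle of the ridge), with its refractive index."""

    center_frac: float
    width_frac: float
    index: float


@dataclass(frozen=True)
class Slab:
    """One horizontal slab of the staircase: a background medium with zero or
    more lateral strips.  ``fill`` records the primary-trapezoid fill fraction
    for this slab (the quantity the staircase interpolates)."""

    thickness_nm: float
    strips: tuple[LateralStrip, ...]
    background_index: float
    fill: float
    region: str  # "tio2_cap" | "grating"


# ---------------------------------------------------------------------------
# staircase geometry
# ---------------------------------------------------------------------------

def _trapezoid_width(duty: float, depth: float, sidewall_deg: float,
                     y_center: float, period: float) -> float:
    """Ridge width at height ``y_center`` above the trapezoid base.

    The duty cycle fixes the mid-height width; the sidewall angle tilts the
    walls symmetrically, so the width varies linearly with height.
    """
    w_mid = duty * period
    return w_mid + 2.0 * (depth / 2.0 - y_center) / math.tan(math.radians(sidewall_deg))


def trapezoid_fill_fractions(duty: float, depth_nm: float, sidewall_deg: float,
                             n_layers: int, period_nm: float) -> np.ndarray:
    """Fill fractions of the staircase slabs, top slab first."""
    yc = depth_nm * (1.0 - (np.arange(n_layers) + 0.5) / n_layers)
    w = np.array([_trapezoid_width(duty, depth_nm, sidewall_deg, y, period_nm)
                  for y in yc])
    return w / period_nm


def build_staircase(stack: GratingStack, medium: Medium | None = None) -> list[Slab]:
    """Discretize the sensor cross-section into horizontal slabs, top first.

    Polymer and TiO2 trapezoids become ``staircase_layers`` slabs each, their
    fill fractions interpolating linearly between the top and bottom widths
    implied by duty cycle and sidewall angle (total thicknesses preserved
    exactly).  The conformal TiO2 film adds a groove-floor fill and sidewall
    strips in the grating region; both vanish in the planar duty-cycle limits.

    Raises
    ------
    GeometryError
        if any slab's fill fraction falls outside [0, 1] or the coated ridge
        overfills the period.
    """
    if medium is None:
        medium = Medium()
    n2 = medium.superstrate_index
    N = stack.staircase_layers
    P = stack.period_nm
    side_nm = max(0.0, (stack.tio2_duty - stack.grating_duty)) * P / 2.0

    slabs: list[Slab] = []
    cap_fills = trapezoid_fill_fractions(
        stack.tio2_duty, stack.tio2_thickness_nm, stack.tio2_sidewall_deg, N, P)
    if np.any(cap_fills < -1e-9) or np.any(cap_fills > 1 + 1e-9):
        raise GeometryError(
            "TiO2 cap sidewall geometry drives fill fraction outside [0, 1]; "
            "check duty cycle, depth and sidewall angle")
    cap_fills = np.clip(cap_fills, 0.0, 1.0)
    if stack.tio2_thickness_nm > 0:
        for f in cap_fills:
            strips = (LateralStrip(0.0, float(f), stack.tio2_index),) \
                if f > 1e-12 else ()
            slabs.append(Slab(stack.tio2_thickness_nm / N, strips, n2, float(f),
                              "tio2_cap"))

    grat_fills = trapezoid_fill_fractions(
        stack.grating_duty, stack.grating_depth_nm, stack.grating_sidewall_deg, N, P)
    if np.any(grat_fills < -1e-9) or np.any(grat_fills > 1 + 1e-9):
        raise GeometryError(
            "polymer sidewall geometry drives fill fraction outside [0, 1]; "
            "check duty cycle, depth and sidewall angle")
    grat_fills = np.clip(grat_fills, 0.0, 1.0)
    if stack.grating_depth_nm > 0:
        yc = stack.grating_depth_nm * (1.0 - (np.arange(N) + 0.5) / N)
        for f, y in zip(grat_fills, yc):
            strips = ([LateralStrip(0.0, float(f), stack.polymer_index)]
                      if f > 1e-12 else [])
            if y < stack.tio2_thickness_nm:
                # groove floor: conformal TiO2 fills the groove at this height
                bg = stack.tio2_index
            else:
                bg = n2
                if side_nm > 0 and f > 1e-12:
                    xo = (f * P / 2.0 + side_nm / 2.0) / P
                    sw = side_nm / P
                    strips.append(LateralStrip(+xo, sw, stack.tio2_index))
                    strips.append(LateralStrip(-xo, sw, stack.tio2_index))
            total = sum(s.width_frac for s in strips)
            if total > 1.0 + 1e-12:
                raise GeometryError("coated ridge wider than one period")
            slabs.append(Slab(stack.grating_depth_nm / N, tuple(strips), bg,
                              float(f), "grating"))
    return slabs


# ---------------------------------------------------------------------------
# RCWA core
# ---------------------------------------------------------------------------

def _profile_fourier(slab: Slab, n_harm: int, inverse: bool) -> np.ndarray:
    """Fourier coefficients (orders -2M..2M) of eps(x) or 1/eps(x)."""
    h = np.arange(-2 * n_harm, 2 * n_harm + 1)
    bg = slab.background_index ** 2
    if inverse:
        bg = 1.0 / bg
    c = np.zeros(h.size, dtype=complex)
    c[h == 0] = bg
    nz = h != 0
    for s in slab.strips:
        e = s.index ** 2
        if inverse:
            e = 1.0 / e
        de = e - bg
        c[h == 0] += de * s.width_frac
        c[nz] += (de * np.sin(np.pi * h[nz] * s.width_frac) / (np.pi * h[nz])
                  * np.exp(-2j * np.pi * h[nz] * s.center_frac))
    return c

def _toeplitz_block(coeffs: np.ndarray, M: int) -> np.ndarray:
    n = 2 * M + 1
    i0 = 2 * M
    return toeplitz(coeffs[i0:i0 + n], coeffs[i0::-1][:n])


@dataclass(frozen=True)
class DiffractionResult:
    """Full zeroth-and-higher-order outcome of one RCWA solve."""

    wavelength_nm: float
    R_amplitudes: np.ndarray      # reflected amplitudes, orders -M..M
    T_amplitudes: np.ndarray      # transmitted amplitudes, orders -M..M
    efficiencies_r: np.ndarray
    efficiencies_t: np.ndarray
    kx: np.ndarray                # lateral wavevectors (1/nm)
    kz_superstrate: np.ndarray    # complex normal wavevectors in the cover
    k0: float
    n_superstrate: float
    polarization: str

    @property
    def reflectance(self) -> float:
        return float(self.efficiencies_r[len(self.efficiencies_r) // 2])

    @property
    def total_efficiency(self) -> float:
        return float(self.efficiencies_r.sum() + self.efficiencies_t.sum())


def solve_wavelength(slabs: Sequence[Slab], n_superstrate: float,
                     n_substrate: float, wavelength_nm: float, period_nm: float,
                     polarization: str = "TM",
                     harmonics: int = DEFAULT_HARMONICS) -> DiffractionResult:
    """Solve planar diffraction for one wavelength at normal incidence.

    ``polarization`` is "TM" for incident E perpendicular to the grating
    lines (the instrument's configuration; inverse-rule factorization) or
    "TE" for E parallel to the lines.
    """
    pol = polarization.upper()
    if pol not in ("TE", "TM"):
        raise ValueError("polarization must be 'TE' or 'TM'")
    M = int(harmonics)
    n = 2 * M + 1
    k0 = 2.0 * np.pi / wavelength_nm
    orders = np.arange(-M, M + 1)
    kx = orders * 2.0 * np.pi / period_nm
    Kx = np.diag(kx / k0)

    def _kz(nm: float) -> np.ndarray:
        kz = np.sqrt((k0 * nm) ** 2 - kx ** 2 + 0j)
        return np.where(kz.imag < 0, -kz, kz)

    kzI = _kz(n_superstrate)
    kzII = _kz(n_substrate)
    if pol == "TE":
        YI = np.diag(kzI / k0)
        YII = np.diag(kzII / k0)
    else:
        YI = np.diag(kzI / (k0 * n_superstrate ** 2))
        YII = np.diag(kzII / (k0 * n_substrate ** 2))

    # enhanced transmittance matrix recursion, bottom interface upward
    f = np.eye(n, dtype=complex)
    g = 1j * YII
    chain: list[tuple[np.ndarray, np.ndarray]] = []
    try:
        for slab in reversed(list(slabs)):
            E = _toeplitz_block(_profile_fourier(slab, M, inverse=False), M)
            if pol == "TE":
                A = Kx @ Kx - E
                eigval, W = np.linalg.eig(A)
                q = np.sqrt(eigval)
                q = np.where(q.real < 0, -q, q)
                V = W * q
            else:
                Einv = _toeplitz_block(_profile_fourier(slab, M, inverse=True), M)
                A = lin_solve(Einv, Kx @ lin_solve(E, Kx) - np.eye(n))
                eigval, W = np.linalg.eig(A)
                q = np.sqrt(eigval)
                q = np.where(q.real < 0, -q, q)
                V = Einv @ (W * q)
            X = np.exp(-k0 * q * slab.thickness_nm)
            ab = lin_solve(np.block([[W, W], [-V, V]]), np.vstack([f, g]))
            a, b = ab[:n], ab[n:]
            a_inv = np.linalg.inv(a)
            xbx = X[:, None] * (b @ a_inv) * X[None, :]
            f = W @ (np.eye(n) + xbx)
            g = V @ (-np.eye(n) + xbx)
            chain.append((a_inv, X))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise SolverError(
            "RCWA eigen-decomposition failed; try a different harmonic "
            f"truncation (currently 2M+1={n})") from exc

    delta = np.zeros(n, dtype=complex)
    delta[M] = 1.0
    t1 = lin_solve(1j * YI @ f + g, 2j * (YI @ delta))
    R = f @ t1 - delta
    t = t1
    for a_inv, X in reversed(chain):
        t = a_inv @ (X * t)
    T = t

    if pol == "TE":
        de_r = np.abs(R) ** 2 * (kzI.real / kzI[M].real)
        de_t = np.abs(T) ** 2 * (kzII.real / kzI[M].real)
    else:
        base = kzI[M].real / n_superstrate ** 2
        de_r = np.abs(R) ** 2 * (kzI / n_superstrate ** 2).real / base
        de_t = np.abs(T) ** 2 * (kzII / n_substrate ** 2).real / base
    if not (np.all(np.isfinite(de_r)) and np.all(np.isfinite(de_t))):
        raise SolverError(
            "non-finite diffraction efficiencies; the eigenbasis is likely "
            f"degenerate at 2M+1={n} harmonics — change the truncation order")
    return DiffractionResult(wavelength_nm, R, T, de_r, de_t, kx, kzI, k0,
                             n_superstrate, pol)


def simulate_spectrum(stack: GratingStack, medium: Medium,
                      wavelengths_nm: np.ndarray | None = None,
                      polarization: str = "TM",
                      harmonics: int = DEFAULT_HARMONICS) -> ReflectionSpectrum:
    """Zeroth-order reflectance spectrum at normal incidence.

    For lossless media the sum of all propagating diffraction efficiencies is
    1 at every wavelength; the residual is recorded in the metadata.
    """
    if wavelengths_nm is None:
        lo, hi, step = DEFAULT_WAVELENGTHS
        wavelengths_nm = np.arange(lo, hi + step / 2, step)
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    refl = np.empty_like(wavelengths_nm)
    worst = 0.0
    for i, lam in enumerate(wavelengths_nm):
        n2 = medium.index_at(lam)
        slabs = build_staircase(stack, replace(medium, superstrate_index=n2))
        res = solve_wavelength(slabs, n2, stack.substrate_index, lam,
                               stack.period_nm, polarization, harmonics)
        refl[i] = res.reflectance
        worst = max(worst, abs(res.total_efficiency - 1.0))
    return ReflectionSpectrum(
        wavelengths_nm, refl, polarization.upper(),
        metadata={"harmonics": harmonics, "max_energy_residual": worst,
                  "n_superstrate": medium.superstrate_index})


def locate_resonance(spectrum: ReflectionSpectrum, method: str = "lorentzian"):
    """Fit the dominant reflectance peak; raise if none is locatable.

    Thin wrapper over :func:`promscope.spectral_fitting.fit_resonance` that
    converts an invalid fit (flat spectrum, peak on the grid boundary) into a
    :class:`ResonanceLocationError`.
    """
    from .spectral_fitting import fit_resonance

    fit = fit_resonance(spectrum, method=method)
    if not fit.valid:
        raise ResonanceLocationError(
            f"no interior resonance peak found: {fit.invalid_reason}")
    return fit


def resonance_vs_index(stack: GratingStack, n2_values: Sequence[float],
                       wavelengths_nm: np.ndarray | None = None,
                       polarization: str = "TM",
                       harmonics: int = DEFAULT_HARMONICS):
    """Sweep the superstrate index; tabulate (n2, PWV, PIV, PWS).

    The peak-wavelength-shift column is referenced to the first index in the
    sweep, mirroring how a cell-attachment red shift is referenced to the
    cell-free background.
    """
    import pandas as pd

    n2_values = list(n2_values)
    if any(v < 1.0 for v in n2_values):
        raise ValueError("superstrate indices must be >= 1")
    rows = []
    for n2 in n2_values:
        spec = simulate_spectrum(stack, Medium(n2), wavelengths_nm,
                                 polarization, harmonics)
        fit = locate_resonance(spec)
        rows.append({"n2": n2, "pwv_nm": fit.pwv_nm, "piv": fit.piv})
    table = pd.DataFrame(rows)
    table["pws_nm"] = table["pwv_nm"] - table["pwv_nm"].iloc[0]
    return table


def field_profile(stack: GratingStack, medium: Medium, wavelength_nm: float,
                  z_max_nm: float = 1100.0, dz_nm: float = 2.0,
                  harmonics: int = DEFAULT_HARMONICS,
                  polarization: str = "TM") -> FieldProfile:
    """Evanescent near-field intensity versus height above the TiO2 surface.

    The profile is the lateral average over one period of |E|^2 carried by
    the evanescent reflected diffraction orders, normalized to the incident
    intensity.  Cross terms between distinct orders vanish under the lateral
    average, so the profile is a sum of decaying exponentials; on resonance
    it is dominated by the +-1 orders, whose decay constant is the leaky
    mode's evanescent kappa.
    """
    n2 = medium.index_at(wavelength_nm)
    slabs = build_staircase(stack, replace(medium, superstrate_index=n2))
    res = solve_wavelength(slabs, n2, stack.substrate_index, wavelength_nm,
                           stack.period_nm, polarization, harmonics)
    z = np.arange(0.0, z_max_nm + dz_nm / 2, dz_nm)
    M = len(res.R_amplitudes) // 2
    enh = np.zeros_like(z)
    for i, (amp, kzi, kxi) in enumerate(
            zip(res.R_amplitudes, res.kz_superstrate, res.kx)):
        if i == M:
            continue  # propagating specular order: not part of the bound tail
        if kzi.imag <= 0:
            continue  # higher propagating order (none for subwavelength gratings)
        if res.polarization == "TM":
            weight = (abs(kxi) ** 2 + abs(kzi) ** 2) / (res.k0 ** 2 * n2 ** 2)
        else:
            weight = 1.0
        enh += weight * abs(amp) ** 2 * np.exp(-2.0 * kzi.imag * z)
    return FieldProfile(z, enh, wavelength_nm)


def evanescent_decay_constant(profile: FieldProfile, z_min_nm: float = 50.0,
                              z_max_nm: float = 400.0) -> tuple[float, float]:
    """Fit the exponential tail; return (kappa_per_nm, r_squared).

    ``kappa`` is the field-amplitude decay constant: intensity falls as
    exp(-2 kappa z), so the returned value is half the log-intensity slope.
    The analytic expectation for first-order coupling at normal incidence is
    kappa = (2 pi / lambda) sqrt(n_eff^2 - n2^2) with n_eff = lambda / period.
    """
    mask = (profile.z_nm >= z_min_nm) & (profile.z_nm <= z_max_nm)
    z = profile.z_nm[mask]
    s = profile.intensity_enhancement[mask]
    if z.size < 3 or np.any(s <= 0):
        raise ValueError("profile tail too short or nonpositive for a log fit")
    logs = np.log(s)
    slope, intercept = np.polyfit(z, logs, 1)
    resid = logs - (slope * z + intercept)
    r2 = 1.0 - resid.var() / logs.var()
    return -slope / 2.0, float(r2)
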