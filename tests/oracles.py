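"""Independent oracles for cross-checking the solver and the models.

Everything here is implemented from closed forms or brute force, deliberately
sharing no code with the package internals.
"""

import numpy as np


def tmm_reflectance(n_films, d_films_nm, n_sup, n_sub, wavelength_nm):
    """Normal-incidence reflectance of a planar film stack via the
    characteristic-matrix method (Abeles)."""
    k0 = 2.0 * np.pi / wavelength_nm
    M = np.eye(2, dtype=complex)
    for n, d in zip(n_films, d_films_nm):
        delta = k0 * n * d
        M = M @ np.array([[np.cos(delta), 1j * np.sin(delta) / n],
                          [1j * n * np.sin(delta), np.cos(delta)]])
    B, C = M @ np.array([1.0, n_sub], dtype=complex)
    r = (n_sup * B - C) / (n_sup * B + C)
    return float(abs(r) ** 2)


def monte_carlo_sphere_overlap(radius_nm, center_height_nm, z_profile,
                               enh_profile, n_points=1_000_000, seed=1234):
    """Brute-force 3D Monte-Carlo integral of |E(z)|^2 over a sphere."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-radius_nm, radius_nm, size=(n_points, 3))
    inside = (pts ** 2).sum(axis=1) <= radius_nm ** 2
    z = pts[inside, 2] + center_height_nm
    enh = np.interp(z, z_profile, enh_profile)
    cube_volume = (2.0 * radius_nm) ** 3
    return enh.mean() * inside.mean() * cube_volume


def lorentzian(lam, amplitude, center, fwhm, baseline=0.0):
    hw2 = (fwhm / 2.0) ** 2
    return amplitude * hw2 / ((lam - center) ** 2 + hw2) + baseline
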