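# promscope

Computational toolkit for **photonic resonator outcoupler microscopy
(PROM)** — label-free, kinetic imaging of live-cell attachment and
focal-adhesion (FA) formation on a photonic-crystal (PC) biosensor.

A PC biosensor is a subwavelength grating that acts as a guided-mode
resonance (GMR) reflector: at normal incidence it reflects a narrow band
(here near λ₀ ≈ 626 nm in water) with near-unity efficiency, carried by an
evanescent field that extends only a couple hundred nanometers into the
medium. Two per-pixel observables are extracted from the resonant
reflection spectrum at each ~0.6 × 0.6 µm² pixel:

* **PWV / PWS** — peak wavelength value and its shift,
  PWS = PWV_frame − PWV_background. Attached cellular mass raises the local
  refractive index inside the evanescent tail and red-shifts the resonance
  (e.g., λ_BG ≈ 626 nm → λ_cell ≈ 628 nm).
* **PIV / PIS** — normalized peak intensity value and its shift,
  PIS = PIV_background − PIV_frame. Dense protein clusters (FAs, n ≈ 1.46)
  scatter resonantly stored photons out of the mode and lower the peak
  reflectance (e.g., 90% → 80% normalized to the bare sensor in water).
  In coupled-mode terms the peak falls as (γ_r/(γ_r+γ_s))², where γ_s is
  the scatterer-induced outcoupling rate ∝ Mie cross-section × local field.

The two images are complementary: PWS maps attached mass (high in the cell
interior), PIS maps FA clusters (a ring hugging the cell boundary).

The package provides, for users who model or analyze such instruments:

| module | contents |
| --- | --- |
| `gmr_forward` | RCWA solver for the trapezoidal, conformally coated 1D grating: spectra, resonance, evanescent field profile |
| `perturbation_model` | FA sphere on the resonator: first-order PWS, Mie scattering, coupled-mode PIS |
| `spectral_fitting` | water-reference normalization, Lorentzian / parabolic peak estimators, per-pixel cube fitting |
| `image_pipeline` | PWS/PIS assembly with fixed sign conventions, backgrounds, series normalization |
| `cell_morphometry` | segmentation, sub-pixel boundary extraction and tracking, band kymographs, edge/center statistics, cross-sections |
| `synthetic_scene` | ground-truth cell scenes rendered into noisy hyperspectral cubes |
| `io_cli` | HDF5 / ENVI / TIFF / CSV I/O, JSON config, run manifests, the `promscope` CLI |

## Worked example

```python
import numpy as np
import promscope as p

stack, water = p.GratingStack(), p.Medium()
spec = p.simulate_spectrum(stack, water, np.arange(620.0, 636.0001, 0.1))
fit = p.locate_resonance(spec)
print(f"resonance: PWV = {fit.pwv_nm:.2f} nm, PIV = {fit.piv:.3f}, "
      f"FWHM = {fit.fwhm_nm:.2f} nm")
profile = p.field_profile(stack, water, fit.pwv_nm)
kappa, r2 = p.evanescent_decay_constant(profile)
print(f"surface enhancement = {profile.intensity_enhancement[0]:.0f}x, "
      f"decay length 1/kappa = {1/kappa:.0f} nm (R^2 = {r2:.3f})")
resonator = p.resonator_from_simulation(fit, profile, stack.period_nm, water)
table = p.fa_sweep([50, 100, 250, 500], profile, resonator, water)
print(table.round(3).to_string(index=False))
```

prints

```
resonance: PWV = 627.60 nm, PIV = 1.000, FWHM = 2.35 nm
surface enhancement = 84x, decay length 1/kappa = 121 nm (R^2 = 1.000)
 radius_nm  pws_nm  pis_norm
        50   1.583     0.020
       100   6.689     0.332
       250  27.823     0.953
       500  64.427     0.997
```

The printed sensor geometry resonates at 627.6 nm in water with a 2.35 nm
linewidth; the resonant near field is enhanced 84× at the surface and
decays exponentially with a 121 nm amplitude decay length. Growing the FA
sphere from 50 to 500 nm radius strictly increases both the red shift and
the outcoupling loss (model units; trends, not absolute calibrations).

The synthetic pipeline end to end — canonical elliptical cell, noisy
rendering, per-pixel fitting, shift images, re-segmentation:

```python
scene = p.generate_scene(p.SceneParams(), seed=1)
inst = p.InstrumentModel(noise_sd=0.01, seed=1)
cube = p.render_sequence(scene, inst, seed=1)[0]
ref = p.render_reference_cube((100, 100), p.InstrumentModel(noise_sd=0.0))
maps = p.fit_cube(cube, ref)
bg = p.fit_cube(p.render_cube((np.full((100, 100), 626.0),
                               np.full((100, 100), 0.90)),
                              p.InstrumentModel(noise_sd=0.01, seed=1),
                              seed=1007), ref)
shifts = p.shift_images(maps, bg)
seg = p.segment_cell(shifts.pis_image)
print(p.edge_center_stats(shifts.pis_image, seg).round(4).to_string(index=False))
```

```
 cell region   mean     sd  n_pixels
    0   edge 0.0563 0.0293       584
    0 center 0.0001 0.0061       325
```

The FA ring shows up as a PIS edge mean of 0.056 against a center mean at
the noise floor — the boundary-concentrated outcoupling signature — while
the PWS image (not shown) has the opposite ordering, center ≈ +2 nm.

The same steps are available from the shell:

```sh
promscope --seed 1 synth --frames 10 --out run.h5
promscope fit  --cube run.h5  --out fits.h5
promscope maps --fits fits.h5 --out shifts.h5
promscope stats --shifts shifts.h5 --out stats.csv
promscope kymo  --shifts shifts.h5 --out kymo.h5
```

See `docs/methods.md` for the models, parameter choices, and limitations.

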