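# Methods

`promscope` models and analyzes photonic resonator outcoupler microscopy
(PROM): label-free imaging of live-cell attachment on a guided-mode-resonance
(GMR) photonic-crystal (PC) biosensor. This note records the models, the
parameters that matter, the numerical choices, and the limits of what the
synthetic test bed can show.

## Sensor forward model (RCWA)

The sensor is a one-dimensional replica-molded polymer grating (period
Λ = 400 nm, depth d_g = 120 nm, duty f_g = 41.6%, sidewall 85°, n₀ = 1.46)
reactively sputtered with TiO₂ (n₁ = 2.4, slab thickness d_s = 61 nm, duty
f_s = 50%, sidewall 82°) on a glass substrate (n = 1.52), immersed in water
(n₂ = 1.333). We solve normal-incidence planar diffraction with rigorous
coupled-wave analysis (a Fourier modal method): per layer, a Toeplitz
eigenproblem in 2M+1 spatial harmonics; across layers, the
enhanced-transmittance-matrix recursion, which stays stable for arbitrarily
many thin slabs. For the instrument's polarization (E perpendicular to the
grating lines, "TM" here) the inverse-rule Fourier factorization of
Li/Lalanne is used; the parallel polarization (TE) uses the Laurent rule.

**Geometry.** Both the polymer ridge and the TiO₂ cap are trapezoids,
discretized into 8 horizontal slabs each whose fill fractions interpolate
linearly between the widths implied by duty cycle and sidewall angle (the
mean fill equals the mid-height duty exactly; total thicknesses are
preserved). The sputtered film is represented *conformally*: TiO₂ of the
stated slab thickness covers the groove floors, and sidewall strips flank
the polymer ridge with thickness (f_s − f_g)·Λ/2 ≈ 16.8 nm — the lateral
film growth implied by the cap duty exceeding the ridge duty. All coating
dimensions are therefore derived from the stated fabrication parameters;
nothing is fitted. Without the conformal film the layered model has no
waveguide dense enough to resonate near 626 nm (it lands near 608–613 nm);
with it, the computed resonance sits at 627.6 nm with near-unity peak
reflectance and ≈ 2.4 nm FWHM. In the planar limits (duty 0 or 1, vertical
walls) the staircase degenerates to uniform films and the solver reproduces
closed-form transfer-matrix reflectance to 10⁻⁶; for lossless media the sum
of propagating diffraction efficiencies is 1 to 10⁻⁶ at every wavelength.

**Truncation.** Default 2M+1 = 25 harmonics. The conformal three-material
profile converges more slowly than a plain lamellar grating; at 25 harmonics
the resonance wavelength moves by < 0.08 nm when the truncation is doubled
(at 21 it moves ≈ 0.11 nm, which is why 25 is the default). A full 1001-point
design sweep takes ~15 s on one CPU.

**Near field.** The reported `FieldProfile` is the lateral average over one
period of |E|² carried by the *evanescent* reflected orders, normalized to
the incident intensity, from the top TiO₂ surface upward. The propagating
specular order (incident + reflected standing wave) is excluded so the
profile decays to zero and exposes the leaky mode's exponential tail. On
resonance the surface enhancement is ≈ 84×; the fitted amplitude decay
constant κ (intensity falls as e^(−2κz), fitted over z = 50–400 nm) matches
the analytic κ = (2π/λ)·√(n_eff² − n₂²) with n_eff = λ/Λ to better than 1%.
The corresponding 1/κ ≈ 120 nm; we report the fitted constant rather than
hard-coding a "field extent" because extent depends on an arbitrary
threshold convention.

## Focal-adhesion perturbation surrogate

A focal adhesion (FA) is a homogeneous lossless sphere (n_FA = 1.46, radius
50–500 nm) resting on the surface (center height = radius) in water. Two
observables:

* **Peak wavelength shift (PWS)** — first-order cavity perturbation:
  Δλ = λ₀ (n_FA² − n₂²) ∫_sphere |E|² dV / (2U), with the sphere integral
  evaluated by slicing into horizontal disks against the laterally averaged
  tail (cross-checked against 10⁶-point Monte-Carlo integration to < 1%),
  and U the modal-energy proxy Λ² ∫ ε|E|² dz over one Λ×Λ unit cell (one FA
  per cell). Zero at radius 0 and for an index-matched sphere; strictly
  increasing in radius.
* **Peak intensity shift (PIS)** — temporal coupled-mode theory: the
  intrinsic FWHM sets the radiative rate γ_r (= FWHM/2 in linewidth units);
  the sphere adds a loss rate γ_s = C·(λ₀²/4π)·σ_sc·⟨|E|²⟩_sphere / U, with
  σ_sc the full Mie scattering cross section in water and C a single
  calibration constant (default 1 in model units). The loss is driven by
  the enhancement averaged over the sphere volume, not the value at the
  sphere center: for spheres larger than the evanescent decay length the
  contact region dominates the scattering, and a center-point rule would
  make the loss *fall* with radius, contradicting the monotone outcoupling
  trend the model exists to capture; both rules agree in the small-sphere
  limit. Peak reflectance with the extra channel is
  PIV₀·(γ_r/(γ_r+γ_s))², so γ_s = γ_r costs exactly ¾ of the peak.

These are trend-level surrogates calibrated to reproduce the sensor's
dichotomy — a bulk index change moves the wavelength with the intensity
unchanged (< 0.2% over n₂ = 1.333…1.373, sensitivity ≈ 105 nm/RIU), while a
localized scatterer does the reverse — not to replicate any particular
full-wave number. Lateral placement relative to the grating ridge is
averaged out (an FA spans several periods). The Mie series is validated by
the lossless identity Q_ext = Q_sca (machine precision) and approaches the
Rayleigh closed form for size parameter x ≲ 0.3; note that at a = 50 nm
(x = 0.67) the dynamic-polarizability correction already puts the full Mie
result ≈ 13% below Rayleigh — a real feature of the physics, not a solver
error.

## Resonance fitting

Spectra are normalized so the bare sensor in water peaks at 100%. The
default per-pixel estimator is a four-parameter Lorentzian least-squares
fit (amplitude, center, FWHM, baseline) over a ±3 nm window around the
discrete argmax (ties break to the lowest wavelength); PWV is the fitted
center, PIV the fitted peak height. A parabola through the top 7 samples is
the fallback (and an alternative method): it is exact for symmetric peaks
and is used when the Lorentzian fit fails to converge. Peaks on the grid
boundary, flat spectra, or vertices escaping the window are flagged invalid
(NaN in the maps, False in the validity mask) rather than raised, so one
bad pixel never kills a cube. On the synthetic instrument (0.2 nm sampling,
4 nm FWHM, additive noise SD 0.01) the estimator recovers noiseless centers
to < 10⁻³ nm and has a per-pixel scatter of ≈ 0.01 nm.

## Shift images and conventions

PWS = PWV_frame − PWV_background (red shift positive);
PIS = PIV_background − PIV_frame (intensity reduction positive) — both
render attachment as bright. The default background is the first
(pre-attachment) frame; a per-pixel median over cell-free frames is
available for drifting sequences. "Normalized PIS" time series use min–max
normalization onto [0, 1] (the normalization used for such displays is
otherwise a display convention; min–max is our documented choice). Images
export as 32-bit float TIFF in physical units, never rescaled 8-bit.

## Morphometry

Segmentation (on the PIS channel by default, where the FA ring gives the
strongest boundary contrast): 1 px Gaussian smoothing → Otsu → morphological
closing (radius 2 px) → largest component → hole filling. Boundaries are
sub-pixel 0.5-level contours cleaned by a corner-pinned periodic smoothing
spline: the spline may deviate RMS 0.3 px from the marching-squares
vertices, except that vertices with residual > 0.85 px are treated as
genuine corners and re-weighted ×20. This removes the staircase jitter that
otherwise inflates perimeters by 6–8% (disk perimeters are recovered to
< 1%, square corners to < 0.5 px with < 0.5% perimeter error). Contours are
resampled to 360 equal-arclength samples, oriented counterclockwise, with
outward normals from the smoothed tangent.

Frame-to-frame tracking casts each sample's normal ray (±10 µm) against the
next frame's *cleaned* contour and takes the crossing nearest the previous
position, so identical masks track with ~0 displacement and tracking is
inverse-consistent to < 0.5 px; samples without a crossing are interpolated
circularly from neighbors and logged. Band kymographs average the image
along the inward normal over [offset, offset+width] µm (band 1 = 0–3 µm,
band 2 = 6–12 µm by default — the bands' extents are a documented choice,
as only their qualitative roles are defined by the imaging context).
Edge/center statistics use the in-mask Euclidean distance transform
(edge ≤ 3 µm from the boundary, center > 6 µm); with several cells, pooled
rows weight each cell equally. Coordinates are 0-based pixel indices with
pixel centers on integers, y down; physical positions are index × 0.6 µm.

## Synthetic scenes

The generator emulates the canonical attachment morphology: an elliptical
cell (30 × 20 µm on a 100 × 100 px frame at 0.6 µm pitch) carrying a
surface-mass map that plateaus in the interior (taper 3 µm) and an FA ring
within 2 µm of the boundary; an adhesion series grows the mask and ramps
both amplitudes linearly (area scale from 55%, amplitudes from 30%).
Calibration maps mass to a red shift (canonical interior +2 nm over the
626.0 nm background) and FA density to an intensity drop (canonical ring
0.80 against the 0.90 background) — linear surrogates anchored to the
instrument's worked example, since no biomass-to-shift calibration curve
exists; the coupled-mode model can be substituted via a hook. Rendering
uses a symmetric Lorentzian lineshape (FWHM 4 nm) on a 615–640 nm, 0.2 nm
grid with seeded additive Gaussian noise (SD 0.01); the grid must cover
every center wavelength by ±1.5×FWHM (the half-maximum span plus a full
linewidth — a stricter multiple would exclude the worked example's own
626 nm line on the default grid). All randomness flows from explicit seeds.

What the synthetic bed does **not** emulate: Fano asymmetry of real GMR
lines (the fitter would acquire a small bias), shot noise and camera gain,
stage drift and registration error, filopodia-scale substructure, and
multi-cell contact. Passing tests therefore demonstrate the correctness of
the pipeline's operations and conventions, not instrument-level accuracy on
real recordings.

## Problem sizes

Default test and analysis sizes were chosen as the smallest that exercise
each claim cleanly: RCWA design sweeps on 0.05–0.1 nm grids with 25
harmonics, 10-frame 100 × 100 × 126 synthetic cubes, 200-replicate
Monte-Carlo fitting studies, and a 10⁶-point Monte-Carlo integration
oracle.

## Known limitations

* The RCWA model is 2D (1D grating, planar incidence); conical incidence
  and 2D photonic crystals are out of scope.
* The conformal-coating representation is a layered idealization of the
  real sputtered film; the computed 627.6 nm resonance should be read as
  "near 626 nm", not as a fabrication-grade prediction.
* The outcoupling constant C is uncalibrated against full-wave scattering;
  only trends and limits are meaningful.
* The modal-energy proxy uses the superstrate tail only; energy stored in
  the grating is absorbed into C.
* `fit_cube` loops pixels through `scipy.optimize.curve_fit` (~3 s per
  100 × 100 frame); batched Gauss–Newton would be the next optimization.
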