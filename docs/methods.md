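# Methods

`fluorbind` implements the standard desk pipeline for characterizing the
binding of a small absorbing ligand to a fluorescent plasma protein (the
bundled presets emulate human serum albumin, HSA, and transferrin, TRF,
titrated with a xanthone-type ligand) from steady-state fluorescence
titrations. This note records the models, conventions, numerical choices and
known limitations.

## Experimental model

The unit of analysis is a titration: emission scans (excitation 282 nm,
emission 280–500 nm) at fixed protein concentration (10 µM) and increasing
ligand concentration (0, 4, 8, 10, 16, 24, 32, 40 µM), at one or more
temperatures (typically 298 K and 310 K). The zero-ligand scan defines F₀.

### Inner-filter correction

A ligand that absorbs at the excitation or emission wavelength attenuates
the measured signal independently of quenching. The half-path correction

    F_corr = F_obs · 10^(A_exc/2) · 10^(A_em/2)

is applied per spectrum, with A_exc and A_em read off the ligand absorption
spectrum rescaled to each titration concentration by Beer–Lambert (1 cm
path). A_em is evaluated at the *zero-ligand* emission maximum for every
spectrum in the series (configurable): pinning the wavelength keeps the
correction independent of the binding-induced peak shift that the pipeline
also measures. The plain half-path form is used; no cuvette-geometry
refinements are attempted.

### Quenching analysis

Stern–Volmer: ordinary least squares of F₀/F on ligand concentration [D];
the slope K_SV (L/mol) divided by the unquenched fluorophore lifetime τ₀
gives the bimolecular rate K_q. τ₀ defaults to 10⁻⁸ s, the conventional
tryptophan magnitude (and the value under which published K_SV/K_q pairs
for these systems are mutually consistent). Mechanism classification uses
two independent rules, both logged: K_SV falling with temperature → static,
rising → dynamic; K_q above the diffusion-controlled collision limit
(2.0×10¹⁰ L mol⁻¹ s⁻¹) → static. Agreement decides the call; conflict is
reported as indeterminate rather than resolved silently.

Binding constant and stoichiometry: OLS of lg[(F₀−F)/F] on lg[D] (base-10
throughout). The association constant is always 10^intercept and the
apparent site number the slope. Zero-concentration points are excluded
(lg undefined); points with F ≥ F₀ are dropped with a warning. Fits are
unweighted (the convention under which the reported SD/R statistics of such
titrations are defined); weighting is a possible extension.

**Reading F.** The pipeline reads each spectrum's *own* maximum-emission
intensity, not the intensity at a fixed wavelength. With a binding-induced
band shift the two differ; the per-spectrum peak is the quantity a
titration protocol records and is the reading under which the double-log
fit exactly inverts the generator's law. A fixed-wavelength reading remains
available via an argument. The peak height itself is estimated in two
stages: a parabola through the log intensity over the upper half of the
band (exact for a Gaussian band whose centre falls between grid points),
then a linear-space Gaussian least-squares refinement seeded by it — the
maximum-likelihood estimate under additive noise, which averages the whole
band instead of trusting the noise-inflated grid maximum. On clean data the
seed already minimizes the refinement, so nothing changes.

### Förster energy transfer

The overlap integral J = ∫F(λ)ε(λ)λ⁴dλ / ∫F(λ)dλ is evaluated by
trapezoidal quadrature on the intersection of the donor-emission and
acceptor-absorptivity grids, resampled (linear interpolation) to the finer
of the two steps; wavelengths are converted nm → cm inside the integrand
only, giving J in M⁻¹ cm³ — the units the prefactor of

    R₀⁶ = 8.8×10⁻²⁵ · κ² · n⁻⁴ · Φ · J   (cm⁶)

requires. Defaults: κ² = 2/3 (isotropic dynamic averaging), Φ = 0.13
(tryptophan donor), refractive index n = 1.336 (aqueous buffer). The
published critical distances for these systems are reproduced exactly only
with n = 1.36; since both values circulate in this literature, n is an
explicit parameter and the pipeline's "reproduce published constants" mode
sets 1.36, with the choice logged. Transfer efficiency E = 1 − F/F₀ is
taken by convention at the titration point closest to 1:1 protein:ligand
(configurable); distance follows from r = R₀(1/E − 1)^(1/6). Distances
below 7 nm set a "non-radiative transfer plausible" flag.

### Thermodynamics

Two-point van't Hoff: ΔH = R·ln(K₂/K₁)/(1/T₁ − 1/T₂) with R = 8.314
J mol⁻¹ K⁻¹ exactly; ΔG = −RT ln K independently at each temperature; ΔS =
(ΔH − ΔG)/T at the lower temperature. With exactly two temperatures this
construction is algebraically consistent at both (the reported Gibbs–Helmholtz
residuals are round-off; they become informative only if the fitted ΔS is
reused outside the pair). Force classification by the conventional sign
heuristics: (ΔH>0, ΔS>0) hydrophobic; (<0, <0) hydrogen bonding / van der
Waals; (<0, >0) electrostatic; (+, −) has no conventional assignment and is
reported as unclassified. No ΔCp curvature and no error propagation from
the fit covariances are attempted.

### Polarization

G = I_HV/I_HH, P = (I_VV − G·I_VH)/(I_VV + G·I_VH), r = (I_VV − G·I_VH)/
(I_VV + 2G·I_VH); r = 2P/(3 − P) holds identically and is enforced by
construction. The tight/weak binding call compares P of the free and
complexed protein by sign only (a configurable minimum-change threshold,
default 0, guards against noise).

## Synthetic data

The generator is the stand-in for raw titration spectra, with known ground
truth for every stage:

- emission: a Gaussian band (σ = 18 nm; centres 335 nm for the albumin-like
  preset, 328 nm for the transferrin-like one) whose peak height follows
  the quenching law and whose centre interpolates linearly from the free to
  the bound position (308 nm / 337 nm, i.e. a 27 nm blue shift and a 9 nm
  red shift) with the bound fraction 1 − F/F₀;
- quenching law: `power` (default), (F₀−F)/F = K[D]ⁿ — the exact form the
  double-log fit inverts, so noise-free recovery is exact by construction —
  or `mass_action`, a 1:1 complexation with depletion, to probe model
  mismatch (which underlying law real titrations obey is not knowable from
  the printed results);
- ligand absorption: Gaussian bands at 213/245/332 nm (the ligand's UV
  maxima) with widths 15/18/25 nm and peak absorptivities
  3.0×10⁴/1.2×10⁴/1.0×10⁴ M⁻¹cm⁻¹ — xanthone-like magnitudes chosen once;
  the spectrum is recorded at the top titration concentration (40 µM),
  giving a maximum absorbance near 1;
- inner filter: optional uniform attenuation 10^−(A_exc+A_em)/2 with the
  generated absorption spectrum scaled to each concentration;
- noise: additive Gaussian, σ = `noise_sd` × the unquenched peak (default
  1%), seeded; identical seeds give bit-identical datasets.

Default titration design, protein concentration, grid (250–500 nm, 1 nm —
the sampling interval is not dictated by any protocol and is configurable)
and temperatures follow the experimental design above.

What the generator does **not** emulate: Rayleigh/Raman scatter, baseline
drift, photobleaching, detector nonlinearity, non-Gaussian band shapes, and
multi-site binding beyond the apparent-n power law. Passing recovery tests
therefore demonstrates correctness of the analysis chain under the stated
model, not robustness to every instrumental artefact.

## Numerical choices

- Peak ties break to the smaller wavelength; optional boxcar smoothing
  (default off) before peak finding; shifts smaller than one grid step are
  reported as "none".
- Quadrature convergence: halving the grid step changes J by < 0.1% for
  smooth bands (tested against a 10×-refined oracle and a single-point
  analytic case).
- Interpolation is linear and never extrapolates; requests outside the
  measured span raise.
- All logarithms in the binding fit are base 10; K = 10^intercept exactly
  (no separate rounding of K).
- Validation: strictly increasing wavelength grids, non-negative
  intensities/absorbances (negative absorbance signals a blank-subtraction
  problem and raises), titrations must begin at zero ligand.

## Problem sizes

The bundled tests run the full pipeline on 8-point titrations of 251-point
spectra; the parameter-recovery study uses 100 seeded replicates with K
drawn log-uniformly over 10⁵–10⁶ L/mol and n over 0.9–1.2 at 1% noise.
The whole suite completes in a few seconds on one core.

## Known limitations

- The modified Stern–Volmer (Lehrer) accessible-fraction analysis and
  global multi-wavelength fitting are out of scope.
- The double-log intercept extrapolates far outside the sampled
  concentration decade (lg[D] ≈ −5.4…−4.4 → intercept at lg[D] = 0), so K
  inherits roughly five times the slope's standard error; at 1% noise the
  median relative error of K across the recovery study is below 10%, but
  individual replicates can be far worse. This is intrinsic to the method,
  not to the implementation.
- Synchronous-scan shift quantification operates on the scan axis of
  whatever spectra are supplied; the package models synchronous spectra as
  ordinary wavelength-indexed scans with a recorded Δλ context (15 nm
  tyrosine, 60 nm tryptophan) rather than simulating the full
  excitation-emission matrix.
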