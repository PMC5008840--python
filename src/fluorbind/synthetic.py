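"""Synthetic titration generator with known ground truth.

The generator emulates a fluorescence titration of a tryptophan-bearing
plasma protein (10 uM) with an absorbing ligand at 0-40 uM: a Gaussian
emission band quenched according to a known binding law, a ligand
absorption spectrum built from Gaussian UV bands, optional inner-filter
attenuation, and seeded additive Gaussian noise.  Every pipeline stage can
therefore be tested against exact generating parameters.

Two quenching laws are available:

* ``power`` (default) — (F0-F)/F = K [D]^n, the exact functional form the
  double-log fit inverts, so noise-free recovery of (lg K, n) is exact;
* ``mass_action`` — 1:1 complexation with ligand/protein depletion
  (quadratic root), to probe model mismatch.

What the generator does not emulate: scatter and Raman peaks,
photobleaching, detector nonlinearity, baseline drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .polarization import PolarizedIntensities
from .spectra import AbsorptionSpectrum, EmissionSpectrum, TitrationSeries

__all__ = [
    "GroundTruth",
    "PAPER_CONCENTRATIONS",
    "hsa_preset",
    "trf_preset",
    "generate_titration",
    "generate_polarized",
]

#: The titration design: ligand concentrations in mol/L (0-40 uM at 10 uM protein).
PAPER_CONCENTRATIONS = tuple(c * 1e-6 for c in (0, 4, 8, 10, 16, 24, 32, 40))

#: Ligand UV absorption bands: (center nm, sigma nm, peak epsilon M^-1 cm^-1).
_DEFAULT_ACCEPTOR_BANDS = ((213.0, 15.0, 3.0e4), (245.0, 18.0, 1.2e4), (332.0, 25.0, 1.0e4))


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters of one synthetic titration."""

    k_true: float = 6.4832e5  # L/mol
    n_true: float = 1.15  # apparent binding sites
    quench_model: str = "static"  # "static" | "dynamic" (bookkeeping for the mechanism call)
    binding_law: str = "power"  # "power" | "mass_action"
    emission_center_free: float = 335.0  # nm
    emission_center_bound: float = 308.0  # nm
    emission_sigma: float = 18.0  # nm
    acceptor_bands: tuple = _DEFAULT_ACCEPTOR_BANDS
    noise_sd: float = 0.01  # fraction of the F0 peak
    inner_filter: bool = True
    f0_peak: float = 1000.0  # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true <= 0:
            raise ValidationError("k_true must be > 0")
        if not 0 < self.n_true <= 2:
            raise ValidationError("n_true must be in (0, 2]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.binding_law not in ("power", "mass_action"):
            raise ValidationError(f"unknown binding_law {self.binding_law!r}")

    @property
    def shift_direction(self) -> str:
        if self.emission_center_bound < self.emission_center_free:
            return "blue"
        if self.emission_center_bound > self.emission_center_free:
            return "red"
        return "none"


def hsa_preset(**overrides) -> GroundTruth:
    """Albumin-like system: 335 nm emission, blue shift on binding, K ~ 6.5e5."""
    return GroundTruth(**overrides)


def trf_preset(**overrides) -> GroundTruth:
    """Transferrin-like system: 328 nm emission, red shift, K ~ 1.5e5."""
    defaults = dict(
        k_true=1.4652e5,
        n_true=1.09,
        emission_center_free=328.0,
        emission_center_bound=337.0,
    )
    defaults.update(overrides)
    return GroundTruth(**defaults)


def _gauss(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _quenched_fraction(truth: GroundTruth, d: float, protein_conc: float) -> float:
    """Return F/F0 at ligand concentration d."""
    if d == 0:
        return 1.0
    if truth.binding_law == "power":
        return 1.0 / (1.0 + truth.k_true * d**truth.n_true)
    # 1:1 mass action with depletion: K = [PL]/([P][L])
    k, p0 = truth.k_true, protein_conc
    b = p0 + d + 1.0 / k
    pl = (b - np.sqrt(b * b - 4.0 * p0 * d)) / 2.0
    return 1.0 - pl / p0


def generate_titration(
    truth: GroundTruth,
    concentrations=PAPER_CONCENTRATIONS,
    protein_concentration: float = 1e-5,
    temperature: float = 298.0,
    excitation_wavelength: float = 282.0,
    wavelength_start: float = 250.0,
    wavelength_stop: float = 500.0,
    wavelength_step: float = 1.0,
    protein_id: str = "synthetic",
) -> tuple[TitrationSeries, AbsorptionSpectrum, GroundTruth]:
    """Generate one titration, its ligand absorption spectrum and the truth.

    The emission band center interpolates linearly from the free to the
    bound position with the quenched (bound) fraction 1 - F/F0; the ligand
    absorption spectrum is recorded at the top titration concentration and
    rescales linearly (Beer-Lambert) inside the inner-filter attenuation
    10^-(A_exc + A_em)/2.  Identical seeds give bit-identical datasets.
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc[0] != 0 or np.any(np.diff(conc) <= 0):
        raise ValidationError("concentrations must start at 0 and strictly increase")
    rng = np.random.default_rng(truth.seed)
    grid = np.arange(wavelength_start, wavelength_stop + wavelength_step / 2, wavelength_step)

    # acceptor molar absorptivity and its spectrum at the reference conc
    eps = np.zeros_like(grid)
    for center, sigma, peak in truth.acceptor_bands:
        eps += peak * _gauss(grid, center, sigma)
    ref_conc = float(conc[-1]) if conc[-1] > 0 else 4e-5
    acceptor = AbsorptionSpectrum(
        wavelength=grid.copy(),
        absorbance=eps * ref_conc,
        chromophore_concentration=ref_conc,
        path_length=1.0,
        label=f"{protein_id}-ligand",
    )
    eps_exc = float(np.interp(excitation_wavelength, grid, eps))
    eps_em = float(np.interp(truth.emission_center_free, grid, eps))

    spectra = []
    noise_scale = truth.noise_sd * truth.f0_peak
    for d in conc:
        ratio = _quenched_fraction(truth, float(d), protein_concentration)
        peak_height = truth.f0_peak * ratio
        bound_frac = 1.0 - ratio
        center = (
            truth.emission_center_free
            + (truth.emission_center_bound - truth.emission_center_free) * bound_frac
        )
        intensity = peak_height * _gauss(grid, center, truth.emission_sigma)
        if truth.inner_filter:
            a_exc = eps_exc * d
            a_em = eps_em * d
            intensity = intensity * 10.0 ** (-(a_exc + a_em) / 2.0)
        if truth.noise_sd > 0:
            intensity = intensity + rng.normal(0.0, noise_scale, size=grid.size)
            intensity = np.clip(intensity, 0.0, None)
        spectra.append(
            EmissionSpectrum(
                wavelength=grid.copy(),
                intensity=intensity,
                excitation_wavelength=excitation_wavelength,
                temperature=temperature,
                quencher_concentration=float(d),
                label=f"{protein_id} [{d * 1e6:g} uM]",
            )
        )
    series = TitrationSeries(
        protein_id=protein_id,
        protein_concentration=protein_concentration,
        temperature=temperature,
        spectra=spectra,
    )
    return series, acceptor, truth


def generate_polarized(
    truth_p: float,
    g: float,
    base_intensity: float = 100.0,
    seed: int = 0,
) -> PolarizedIntensities:
    """Construct a polarized quadruple with exact target P and G factor.

    Inverts the polarization formulas: I_VV is the base intensity,
    I_VH = I_VV (1-P) / ((1+P) G), and the horizontal-excitation pair
    satisfies I_HV/I_HH = g exactly with a seeded overall level.
    """
    if not -1.0 < truth_p < 1.0:
        raise ValidationError("target P must be in (-1, 1)")
    if g <= 0 or base_intensity <= 0:
        raise ValidationError("g and base_intensity must be > 0")
    rng = np.random.default_rng(seed)
    i_vv = base_intensity
    i_vh = base_intensity * (1.0 - truth_p) / ((1.0 + truth_p) * g)
    i_hh = base_intensity * float(rng.uniform(0.5, 0.9))
    i_hv = g * i_hh
    return PolarizedIntensities(i_vv=i_vv, i_vh=i_vh, i_hv=i_hv, i_hh=i_hh)
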