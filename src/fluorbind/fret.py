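"""Förster resonance energy-transfer chain.

From the donor (protein) emission spectrum and the acceptor (ligand) molar
absorptivity, the spectral overlap integral

    J = int F(l) eps(l) l^4 dl / int F(l) dl        [M^-1 cm^3]

feeds the critical transfer distance

    R0^6 = 8.8e-25 kappa^2 n^-4 Phi J               [cm^6]

at which transfer efficiency is 50%; the measured efficiency E = 1 - F/F0
then yields the donor-acceptor distance r through
E = R0^6 / (R0^6 + r^6).  Wavelengths are converted nm -> cm inside the
quadrature only, which is what the 8.8e-25 prefactor requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .spectra import AbsorptionSpectrum, EmissionSpectrum

__all__ = [
    "EnergyTransferResult",
    "KAPPA2_ISOTROPIC",
    "REFRACTIVE_INDEX_DEFAULT",
    "QUANTUM_YIELD_DEFAULT",
    "overlap_integral",
    "forster_radius",
    "transfer_efficiency",
    "binding_distance",
    "efficiency_from_distance",
    "energy_transfer_analysis",
]

#: Isotropic dynamic-averaging dipole orientation factor.
KAPPA2_ISOTROPIC = 2.0 / 3.0
#: Refractive index of the aqueous buffer medium.
REFRACTIVE_INDEX_DEFAULT = 1.336
#: Donor (tryptophan) fluorescence quantum yield.
QUANTUM_YIELD_DEFAULT = 0.13
#: Distances below this make non-radiative transfer plausible, nm.
NONRADIATIVE_DISTANCE_NM = 7.0

_NM_TO_CM = 1e-7


@dataclass(frozen=True)
class EnergyTransferResult:
    """J, R0, E and r for one donor-acceptor system."""

    j_overlap: float  # M^-1 cm^3
    r0: float  # nm
    efficiency: float
    distance: float  # nm
    kappa2: float = KAPPA2_ISOTROPIC
    refractive_index: float = REFRACTIVE_INDEX_DEFAULT
    quantum_yield: float = QUANTUM_YIELD_DEFAULT

    @property
    def nonradiative_transfer_plausible(self) -> bool:
        return self.distance < NONRADIATIVE_DISTANCE_NM


def overlap_integral(
    donor_emission: EmissionSpectrum,
    acceptor_epsilon: AbsorptionSpectrum,
) -> float:
    """Spectral overlap integral J in M^-1 cm^3 by trapezoidal quadrature.

    The two spectra are intersected in wavelength and resampled onto the
    finer of the two grids (linear interpolation); the acceptor absorbance
    is converted to molar absorptivity via Beer-Lambert.  Because the donor
    intensity appears in numerator and denominator, J is invariant under
    rescaling F.
    """
    lo = max(donor_emission.wavelength[0], acceptor_epsilon.wavelength[0])
    hi = min(donor_emission.wavelength[-1], acceptor_epsilon.wavelength[-1])
    if lo >= hi:
        raise ValidationError("donor emission and acceptor absorption do not overlap")
    step = min(
        float(np.min(np.diff(donor_emission.wavelength))),
        float(np.min(np.diff(acceptor_epsilon.wavelength))),
    )
    n = max(int(round((hi - lo) / step)) + 1, 2)
    grid = np.linspace(lo, hi, n)
    f = np.interp(grid, donor_emission.wavelength, donor_emission.intensity)
    eps_full = acceptor_epsilon.molar_absorptivity()
    eps = np.interp(grid, acceptor_epsilon.wavelength, eps_full)
    denom = np.trapezoid(f, grid)
    if denom <= 0:
        raise ValidationError("donor emission integrates to zero over the overlap")
    lam_cm = grid * _NM_TO_CM
    numer = np.trapezoid(f * eps * lam_cm**4, grid)
    return float(numer / denom)


def forster_radius(
    j: float,
    kappa2: float = KAPPA2_ISOTROPIC,
    n_refr: float = REFRACTIVE_INDEX_DEFAULT,
    phi: float = QUANTUM_YIELD_DEFAULT,
) -> float:
    """Critical transfer distance R0 in nm from the overlap integral."""
    for name, v in (("j", j), ("kappa2", kappa2), ("n_refr", n_refr), ("phi", phi)):
        if not v > 0:
            raise ValidationError(f"{name} must be > 0, got {v}")
    r0_cm = (8.8e-25 * kappa2 * n_refr**-4 * phi * j) ** (1.0 / 6.0)
    return float(r0_cm * 1e7)  # cm -> nm


def transfer_efficiency(f: float, f0: float) -> float:
    """E = 1 - F/F0 from donor intensities with and without acceptor."""
    if not 0 < f <= f0:
        raise ValidationError(f"need 0 < F <= F0, got F={f}, F0={f0}")
    return 1.0 - f / f0


def binding_distance(efficiency: float, r0: float) -> float:
    """Donor-acceptor distance r = R0 (1/E - 1)^(1/6) in nm."""
    if not 0 < efficiency < 1:
        raise ValidationError(f"efficiency must be in (0, 1), got {efficiency}")
    if not r0 > 0:
        raise ValidationError(f"r0 must be > 0, got {r0}")
    return float(r0 * (1.0 / efficiency - 1.0) ** (1.0 / 6.0))


def efficiency_from_distance(r: float, r0: float) -> float:
    """Inverse of :func:`binding_distance`: E = R0^6 / (R0^6 + r^6)."""
    if not (r > 0 and r0 > 0):
        raise ValidationError("r and r0 must be > 0")
    return float(r0**6 / (r0**6 + r**6))


def energy_transfer_analysis(
    donor_emission: EmissionSpectrum,
    acceptor_epsilon: AbsorptionSpectrum,
    f: float,
    f0: float,
    kappa2: float = KAPPA2_ISOTROPIC,
    n_refr: float = REFRACTIVE_INDEX_DEFAULT,
    phi: float = QUANTUM_YIELD_DEFAULT,
) -> EnergyTransferResult:
    """Full FRET chain: J -> R0 -> E -> r for one system.

    ``f``/``f0`` are the donor intensities with and without acceptor,
    conventionally taken at the 1:1 protein:ligand titration point.
    """
    j = overlap_integral(donor_emission, acceptor_epsilon)
    r0 = forster_radius(j, kappa2=kappa2, n_refr=n_refr, phi=phi)
    e = transfer_efficiency(f, f0)
    r = binding_distance(e, r0)
    return EnergyTransferResult(
        j_overlap=j,
        r0=r0,
        efficiency=e,
        distance=r,
        kappa2=kappa2,
        refractive_index=n_refr,
        quantum_yield=phi,
    )
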