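import numpy as np
import pytest
from hypothesis import settings

from fluorbind import EmissionSpectrum, AbsorptionSpectrum

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

# Printed reference values used across tests: the four polarized-intensity
# rows (I_VV, I_VH, I_HV, I_HH -> G, P, r) and the double-log fit lines
# (temperature, intercept, slope) for the two protein systems.
POLARIZATION_ROWS = {
    "HSA": (95.98, 71.89, 57.54, 55.91, 1.0292, 0.1294, 0.0902),
    "HSA-complex": (58.88, 38.81, 31.16, 30.09, 1.0356, 0.1887, 0.1342),
    "TRF": (232.10, 174.70, 139.30, 132.40, 1.0521, 0.1161, 0.0805),
    "TRF-complex": (154.30, 116.80, 93.19, 89.03, 1.0467, 0.1159, 0.0803),
}

DOUBLE_LOG_LINES = {
    ("HSA", 298.0): (5.8118, 1.1517),
    ("HSA", 310.0): (5.8955, 1.1934),
    ("TRF", 298.0): (5.1659, 1.0929),
    ("TRF", 310.0): (4.0638, 0.8897),
}

STERN_VOLMER_KSV = {
    ("HSA", 298.0): 1.5962e5,
    ("HSA", 310.0): 1.2165e5,
    ("TRF", 298.0): 0.5724e5,
    ("TRF", 310.0): 0.3589e5,
}

# The titration design: ligand concentrations (mol/L) at 10 uM protein.
CONCENTRATIONS = np.array([0, 4, 8, 10, 16, 24, 32, 40], dtype=float) * 1e-6


def gaussian_emission(center=335.0, sigma=15.0, peak=1000.0, start=250.0,
                      stop=500.0, step=1.0, **meta):
    wl = np.arange(start, stop + step / 2, step)
    return EmissionSpectrum(
        wavelength=wl,
        intensity=peak * np.exp(-0.5 * ((wl - center) / sigma) ** 2),
        **meta,
    )


def gaussian_absorption(center=332.0, sigma=20.0, eps_peak=1.0e4,
                        concentration=4e-5, start=250.0, stop=500.0, step=1.0):
    wl = np.arange(start, stop + step / 2, step)
    eps = eps_peak * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    return AbsorptionSpectrum(
        wavelength=wl,
        absorbance=eps * concentration,
        chromophore_concentration=concentration,
    )


def intensities_on_double_log_line(intercept, slope, concentrations=CONCENTRATIONS,
                                   f0=1000.0):
    """Titration intensities lying exactly on lg[(F0-F)/F] = intercept + slope lg D."""
    d = np.asarray(concentrations, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(d > 0, 10.0 ** intercept * d ** slope, 0.0)
    return f0 / (1.0 + ratio)


@pytest.fixture
def emission_band():
    return gaussian_emission()


@pytest.fixture
def absorption_band():
    return gaussian_absorption()
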