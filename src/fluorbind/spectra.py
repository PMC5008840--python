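"""Domain types for fluorescence and absorption spectra, plus tabular IO.

Wavelength grids are stored in nanometres throughout the package; the only
place they are converted to centimetres is inside the FRET overlap-integral
quadrature, where the Förster prefactor demands CGS units.  Emission
intensities are arbitrary units — every downstream quantity uses ratios, so
no absolute photometric calibration is attempted.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSpectrumWarning,
    ExtrapolationError,
    FormatError,
    ValidationError,
)

__all__ = [
    "EmissionSpectrum",
    "AbsorptionSpectrum",
    "TitrationSeries",
    "read_spectrum_table",
    "write_spectrum_table",
    "read_titration_table",
    "write_titration_table",
    "interpolate_to_grid",
    "peak_position",
]

_DELIMITERS = ",\t;"


def _as_wavelength_grid(values: Sequence[float]) -> np.ndarray:
    wl = np.asarray(values, dtype=float)
    if wl.ndim != 1 or wl.size == 0:
        raise ValidationError("wavelength grid must be a non-empty 1-D array")
    if not np.all(np.isfinite(wl)):
        raise ValidationError("wavelength grid contains non-finite values")
    if np.any(np.diff(wl) <= 0):
        raise ValidationError("wavelength grid must be strictly increasing")
    return wl


@dataclass(frozen=True)
class EmissionSpectrum:
    """One fluorescence emission scan at a fixed quencher concentration.

    Parameters
    ----------
    wavelength : array-like
        Strictly increasing emission wavelengths, nm.
    intensity : array-like
        Non-negative fluorescence intensities, arbitrary units.
    excitation_wavelength : float
        Excitation wavelength, nm (282 nm for tryptophan/tyrosine work).
    temperature : float
        Sample temperature, K.
    quencher_concentration : float
        Ligand (quencher) concentration in the cuvette, mol/L.
    label : str
        Free-text identifier.
    """

    wavelength: np.ndarray
    intensity: np.ndarray
    excitation_wavelength: float = 282.0
    temperature: float = 298.0
    quencher_concentration: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        wl = _as_wavelength_grid(self.wavelength)
        inten = np.asarray(self.intensity, dtype=float)
        if inten.shape != wl.shape:
            raise ValidationError(
                f"intensity length {inten.size} != wavelength length {wl.size}"
            )
        if not np.all(np.isfinite(inten)):
            raise ValidationError("intensity contains non-finite values")
        if np.any(inten < 0):
            raise ValidationError("fluorescence intensity must be >= 0")
        if self.quencher_concentration < 0:
            raise ValidationError("quencher_concentration must be >= 0")
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0 K")
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "intensity", inten)

    def with_intensity(self, intensity: np.ndarray) -> "EmissionSpectrum":
        return replace(self, intensity=np.asarray(intensity, dtype=float))


@dataclass(frozen=True)
class AbsorptionSpectrum:
    """Absorbance of the chromophore versus wavelength.

    ``chromophore_concentration`` (mol/L) and ``path_length`` (cm) convert
    absorbance to the molar absorptivity epsilon(lambda) = A / (c * l).
    """

    wavelength: np.ndarray
    absorbance: np.ndarray
    chromophore_concentration: float = float("nan")
    path_length: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        wl = _as_wavelength_grid(self.wavelength)
        ab = np.asarray(self.absorbance, dtype=float)
        if ab.shape != wl.shape:
            raise ValidationError("absorbance and wavelength lengths differ")
        if not np.all(np.isfinite(ab)):
            raise ValidationError("absorbance contains non-finite values")
        if np.any(ab < 0):
            raise ValidationError(
                "negative absorbance — check blank subtraction"
            )
        if self.path_length <= 0:
            raise ValidationError("path_length must be > 0 cm")
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "absorbance", ab)

    def molar_absorptivity(self) -> np.ndarray:
        """epsilon(lambda) in L mol^-1 cm^-1 via Beer–Lambert."""
        c = self.chromophore_concentration
        if not np.isfinite(c) or c <= 0:
            raise ValidationError(
                "chromophore_concentration must be > 0 to derive epsilon"
            )
        return self.absorbance / (c * self.path_length)

    def absorbance_at(self, wavelength: float, concentration: float | None = None) -> float:
        """Absorbance at one wavelength, optionally rescaled (Beer–Lambert)
        to a different chromophore concentration."""
        lo, hi = self.wavelength[0], self.wavelength[-1]
        if not lo <= wavelength <= hi:
            raise ExtrapolationError(
                f"{wavelength} nm outside measured span [{lo}, {hi}] nm"
            )
        a = float(np.interp(wavelength, self.wavelength, self.absorbance))
        if concentration is not None:
            c0 = self.chromophore_concentration
            if not np.isfinite(c0) or c0 <= 0:
                raise ValidationError(
                    "chromophore_concentration needed to rescale absorbance"
                )
            a *= concentration / c0
        return a


@dataclass
class TitrationSeries:
    """Ordered emission scans at fixed protein and increasing quencher.

    The first spectrum must be the quencher-free scan: it defines F0.
    """

    protein_id: str
    protein_concentration: float
    temperature: float
    spectra: list[EmissionSpectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValidationError("titration series needs >= 1 spectrum")
        conc = np.array([s.quencher_concentration for s in self.spectra])
        if conc[0] != 0:
            raise ValidationError(
                "first spectrum must have quencher_concentration 0 (defines F0)"
            )
        if np.any(np.diff(conc) <= 0):
            raise ValidationError("quencher concentrations must strictly increase")
        exc = {s.excitation_wavelength for s in self.spectra}
        if len(exc) != 1:
            raise ValidationError("all spectra must share the excitation wavelength")
        temps = {s.temperature for s in self.spectra}
        if len(temps) != 1:
            raise ValidationError("all spectra must share the temperature")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([s.quencher_concentration for s in self.spectra])

    @property
    def reference(self) -> EmissionSpectrum:
        """The quencher-free (F0) spectrum."""
        return self.spectra[0]

    @property
    def excitation_wavelength(self) -> float:
        return self.spectra[0].excitation_wavelength

    def intensities_at(self, wavelength: float) -> np.ndarray:
        """Per-spectrum intensity read off at one emission wavelength."""
        return np.array(
            [float(np.interp(wavelength, s.wavelength, s.intensity)) for s in self.spectra]
        )


# ---------------------------------------------------------------------------
# Tabular IO


def _sniff_delimiter(text: str) -> str:
    try:
        return csv.Sniffer().sniff(text, delimiters=_DELIMITERS).delimiter
    except csv.Error:
        return ","


def _read_table(path: str | Path) -> pd.DataFrame:
    raw = Path(path).read_text()
    if not raw.strip():
        raise FormatError(f"{path}: empty file")
    sep = _sniff_delimiter(raw.splitlines()[0])
    df = pd.read_csv(io.StringIO(raw), sep=sep, float_precision="round_trip")
    if df.shape[1] < 2:
        raise FormatError(
            f"{path}: expected a wavelength column plus >= 1 value column"
        )
    return df


def _wavelength_column(df: pd.DataFrame) -> str:
    for name in df.columns:
        if str(name).strip().lower() in {"wavelength", "wavelength_nm", "lambda", "nm"}:
            return name
    # fall back to the first column
    return df.columns[0]


def read_spectrum_table(
    path: str | Path,
    kind: str = "emission",
    metadata: dict | None = None,
) -> EmissionSpectrum | AbsorptionSpectrum:
    """Read a long-format (wavelength, value) delimited text file.

    The delimiter is auto-detected among comma, tab and semicolon.  Rows are
    sorted by wavelength; duplicated wavelengths are rejected.  ``metadata``
    keys are forwarded to the spectrum constructor.
    """
    metadata = dict(metadata or {})
    df = _read_table(path)
    wl_col = _wavelength_column(df)
    value_cols = [c for c in df.columns if c != wl_col]
    df = df.sort_values(wl_col, kind="stable")
    wl = df[wl_col].to_numpy(dtype=float)
    if np.any(np.diff(wl) == 0):
        raise ValidationError(f"{path}: duplicated wavelength rows")
    values = df[value_cols[0]].to_numpy(dtype=float)
    if kind == "emission":
        return EmissionSpectrum(wavelength=wl, intensity=values, **metadata)
    if kind == "absorption":
        return AbsorptionSpectrum(wavelength=wl, absorbance=values, **metadata)
    raise ValueError(f"kind must be 'emission' or 'absorption', got {kind!r}")


def write_spectrum_table(
    spectrum: EmissionSpectrum | AbsorptionSpectrum,
    path: str | Path,
    sep: str = ",",
) -> None:
    """Write a spectrum as a long-format two-column delimited file."""
    if isinstance(spectrum, EmissionSpectrum):
        df = pd.DataFrame(
            {"wavelength": spectrum.wavelength, "intensity": spectrum.intensity}
        )
    else:
        df = pd.DataFrame(
            {"wavelength": spectrum.wavelength, "absorbance": spectrum.absorbance}
        )
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_titration_table(
    path: str | Path,
    protein_id: str = "",
    protein_concentration: float = 1e-5,
    temperature: float = 298.0,
    excitation_wavelength: float = 282.0,
) -> TitrationSeries:
    """Read a wide-format titration table.

    Layout: a wavelength column plus one intensity column per titration
    point, the quencher concentrations (mol/L) carried in the header row.
    """
    df = _read_table(path)
    wl_col = _wavelength_column(df)
    df = df.sort_values(wl_col, kind="stable")
    wl = df[wl_col].to_numpy(dtype=float)
    if np.any(np.diff(wl) == 0):
        raise ValidationError(f"{path}: duplicated wavelength rows")
    spectra = []
    for col in df.columns:
        if col == wl_col:
            continue
        try:
            conc = float(col)
        except ValueError as exc:
            raise FormatError(
                f"{path}: intensity column header {col!r} is not a concentration"
            ) from exc
        spectra.append(
            EmissionSpectrum(
                wavelength=wl,
                intensity=df[col].to_numpy(dtype=float),
                excitation_wavelength=excitation_wavelength,
                temperature=temperature,
                quencher_concentration=conc,
            )
        )
    spectra.sort(key=lambda s: s.quencher_concentration)
    return TitrationSeries(
        protein_id=protein_id,
        protein_concentration=protein_concentration,
        temperature=temperature,
        spectra=spectra,
    )


def write_titration_table(series: TitrationSeries, path: str | Path, sep: str = ",") -> None:
    """Write a titration as a wide table (concentrations in the header)."""
    wl = series.reference.wavelength
    data = {"wavelength": wl}
    for s in series.spectra:
        if not np.array_equal(s.wavelength, wl):
            raise ValidationError("all spectra must share one grid to write wide format")
        data[repr(s.quencher_concentration)] = s.intensity
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Grid utilities


def interpolate_to_grid(spectrum, grid: Sequence[float]):
    """Linearly interpolate a spectrum onto a new wavelength grid.

    The grid must lie within the spectrum's span (no extrapolation).
    Values at original grid points are preserved exactly.
    """
    grid = _as_wavelength_grid(grid)
    wl = spectrum.wavelength
    if grid[0] < wl[0] or grid[-1] > wl[-1]:
        raise ExtrapolationError(
            f"grid [{grid[0]}, {grid[-1]}] nm outside span [{wl[0]}, {wl[-1]}] nm"
        )
    if isinstance(spectrum, EmissionSpectrum):
        return replace(
            spectrum, wavelength=grid, intensity=np.interp(grid, wl, spectrum.intensity)
        )
    return replace(
        spectrum, wavelength=grid, absorbance=np.interp(grid, wl, spectrum.absorbance)
    )


def _boxcar(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return y
    kernel = np.ones(width) / width
    # reflect-pad so the ends are not biased toward zero
    pad = width // 2
    padded = np.concatenate([y[pad:0:-1], y, y[-2 : -2 - pad : -1]])
    return np.convolve(padded, kernel, mode="valid")[: y.size]


def peak_position(
    spectrum: EmissionSpectrum, smooth_window: int = 0
) -> tuple[float, float]:
    """Wavelength and intensity of the global emission maximum.

    Ties break to the smallest wavelength.  ``smooth_window`` applies an
    optional boxcar (moving-average) filter before locating the maximum,
    useful on noisy scans; the returned intensity is the unsmoothed value at
    the located wavelength.
    """
    inten = spectrum.intensity
    if np.all(inten == 0):
        warnings.warn(
            "all-zero spectrum: peak position is meaningless",
            DegenerateSpectrumWarning,
            stacklevel=2,
        )
        return float(spectrum.wavelength[0]), 0.0
    search = _boxcar(inten, smooth_window) if smooth_window and smooth_window > 1 else inten
    idx = int(np.argmax(search))  # argmax returns the first (smallest-wavelength) tie
    return float(spectrum.wavelength[idx]), float(inten[idx])
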