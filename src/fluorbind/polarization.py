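"""Fluorescence polarization and anisotropy with G-factor correction.

From the four polarized intensity channels (V/H excitation x V/H emission):

    G = I_HV / I_HH                      instrument grating factor
    P = (I_VV - G I_VH)/(I_VV + G I_VH)  degree of polarization
    r = (I_VV - G I_VH)/(I_VV + 2 G I_VH)  anisotropy

P and r report rotational mobility: a ligand that binds tightly slows the
protein's rotation, lengthening the rotational relaxation time and raising
both.  r = 2P/(3 - P) holds identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

from .errors import ValidationError

__all__ = [
    "PolarizedIntensities",
    "PolarizationResult",
    "TightnessReport",
    "polarization_analysis",
    "compare_polarization",
]


@dataclass(frozen=True)
class PolarizedIntensities:
    """The four polarizer-combination intensities (all > 0, a.u.)."""

    i_vv: float
    i_vh: float
    i_hv: float
    i_hh: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("i_vv", "i_vh", "i_hv", "i_hh"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class PolarizationResult:
    g: float
    p: float
    r: float
    label: str = ""


def polarization_analysis(intensities: PolarizedIntensities) -> PolarizationResult:
    """Compute G, P and r from one polarized-intensity quadruple."""
    g = intensities.i_hv / intensities.i_hh
    num = intensities.i_vv - g * intensities.i_vh
    p = num / (intensities.i_vv + g * intensities.i_vh)
    r = num / (intensities.i_vv + 2.0 * g * intensities.i_vh)
    return PolarizationResult(g=g, p=p, r=r, label=intensities.label)


@dataclass(frozen=True)
class TightnessReport:
    """Binding-tightness interpretation of a polarization change.

    A rise in P (and r) on complex formation means a longer rotational
    relaxation time, read as tight binding; a drop as weak binding.
    """

    delta_p: float
    delta_r: float
    call: str  # "tight" | "weak" | "no-change"


def compare_polarization(
    free: PolarizationResult,
    complexed: PolarizationResult,
    min_change: float = 0.0,
) -> TightnessReport:
    """Compare free vs ligand-complexed polarization.

    ``min_change`` sets the smallest |dP| treated as a real change
    (default 0: sign alone decides, ties report "no-change").
    """
    dp = complexed.p - free.p
    dr = complexed.r - free.r
    if abs(dp) <= min_change:
        call = "no-change"
    elif dp > 0:
        call = "tight"
    else:
        call = "weak"
    return TightnessReport(delta_p=dp, delta_r=dr, call=call)
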