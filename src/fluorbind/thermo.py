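"""Van't Hoff thermodynamics of binding and force-type classification.

From association constants at two temperatures:

    ln(K2/K1) = (dH/R) (1/T1 - 1/T2)        -> dH
    dG = -R T ln K                          -> dG at each temperature
    dS = (dH - dG)/T                        -> dS at the lower temperature

The signs of dH and dS classify the dominant interaction (Ross rules):
(+,+) hydrophobic; (-,-) hydrogen bonding / van der Waals; (-,+)
electrostatic.  (+,-) has no conventional assignment and is reported as
"unclassified".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError

__all__ = [
    "GAS_CONSTANT",
    "ThermoResult",
    "vant_hoff_enthalpy",
    "gibbs_energy",
    "entropy",
    "classify_forces",
    "thermo_analysis",
]

#: Molar gas constant, J/(mol K).
GAS_CONSTANT = 8.314

_FORCE_BY_SIGNS = {
    (True, True): "hydrophobic",
    (False, False): "hbond_vdw",
    (False, True): "electrostatic",
    (True, False): "unclassified",
}


def vant_hoff_enthalpy(k1: float, t1: float, k2: float, t2: float) -> float:
    """Binding enthalpy dH (J/mol) from K at two temperatures.

    Symmetric under exchange of the two (K, T) pairs; K constant in
    temperature gives dH = 0.
    """
    if k1 <= 0 or k2 <= 0:
        raise ValidationError("binding constants must be > 0")
    if t1 <= 0 or t2 <= 0:
        raise ValidationError("temperatures must be > 0 K")
    if t1 == t2:
        raise ValidationError("van't Hoff needs two distinct temperatures")
    return GAS_CONSTANT * math.log(k2 / k1) / (1.0 / t1 - 1.0 / t2)


def gibbs_energy(k: float, t: float) -> float:
    """dG = -R T ln K in J/mol."""
    if k <= 0:
        raise ValidationError("binding constant must be > 0")
    if t <= 0:
        raise ValidationError("temperature must be > 0 K")
    return -GAS_CONSTANT * t * math.log(k)


def entropy(delta_h: float, delta_g: float, t: float) -> float:
    """dS = (dH - dG)/T in J/(mol K)."""
    if t <= 0:
        raise ValidationError("temperature must be > 0 K")
    return (delta_h - delta_g) / t


def classify_forces(delta_h: float, delta_s: float) -> str:
    """Dominant interaction type from the signs of dH and dS."""
    if not (math.isfinite(delta_h) and math.isfinite(delta_s)):
        raise ValidationError("dH and dS must be finite")
    return _FORCE_BY_SIGNS[(delta_h > 0, delta_s > 0)]


@dataclass(frozen=True)
class ThermoResult:
    """Thermodynamic characterization of one binding system.

    ``gibbs_helmholtz_residual_by_temperature`` reports, per temperature, the gap
    between dG from -RT ln K and dG reconstructed as dH - T dS with the
    single dS fitted at the lower temperature.  With exactly two
    temperatures the construction is algebraically consistent at both, so
    the residuals are round-off; they become informative only if dS is
    reused at temperatures outside the fit pair.
    """

    delta_h: float  # J/mol
    delta_g_by_temperature: dict  # K -> J/mol
    delta_s: float  # J/(mol K)
    force_class: str
    gibbs_helmholtz_residual_by_temperature: dict  # K -> J/mol
    gas_constant: float = GAS_CONSTANT


def thermo_analysis(k_by_temperature: dict) -> ThermoResult:
    """Full van't Hoff analysis from exactly two (T -> K) entries.

    dG is computed independently at each temperature; dS at the lower
    temperature (the convention consistent with reporting a single
    temperature-independent dH and dS alongside per-temperature dG).
    """
    if len(k_by_temperature) != 2:
        raise ValidationError(
            f"two-point van't Hoff needs exactly 2 temperatures, got {len(k_by_temperature)}"
        )
    (t1, k1), (t2, k2) = sorted(k_by_temperature.items())
    dh = vant_hoff_enthalpy(k1, t1, k2, t2)
    dg = {t: gibbs_energy(k, t) for t, k in ((t1, k1), (t2, k2))}
    ds = entropy(dh, dg[t1], t1)
    residual = {t: dg[t] - (dh - t * ds) for t in (t1, t2)}
    return ThermoResult(
        delta_h=dh,
        delta_g_by_temperature=dg,
        delta_s=ds,
        force_class=classify_forces(dh, ds),
        gibbs_helmholtz_residual_by_temperature=residual,
    )
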