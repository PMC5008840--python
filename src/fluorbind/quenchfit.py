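"""Stern-Volmer quenching analysis and double-logarithmic binding fits.

Two linear regressions underpin the binding analysis:

* Stern-Volmer: F0/F = 1 + K_SV [D].  The slope K_SV (L/mol), divided by
  the unquenched fluorophore lifetime tau0 (~1e-8 s for tryptophan),
  gives the bimolecular quenching rate K_q; K_q far above the
  diffusion-controlled limit (~2e10 L mol^-1 s^-1) indicates static
  (ground-state complex) quenching, as does K_SV falling with temperature.

* Double-log: lg[(F0-F)/F] = lg K + n lg[D].  Intercept -> association
  constant K (L/mol), slope -> apparent number of binding sites n.

All logarithms here are base 10; fits are unweighted ordinary least
squares, matching how such titrations are conventionally reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import (
    AntiQuenchingWarning,
    DroppedPointWarning,
    InsufficientDataError,
    ValidationError,
)
from .preprocess import CorrectedTitration
from .spectra import TitrationSeries, _boxcar, peak_position

__all__ = [
    "SternVolmerResult",
    "DoubleLogResult",
    "MechanismCall",
    "DIFFUSION_LIMIT",
    "DEFAULT_TAU0",
    "stern_volmer_fit",
    "double_log_fit",
    "classify_mechanism",
    "quench_curve",
]

#: Maximum diffusion-controlled (scatter-collision) quenching rate, L/mol/s.
DIFFUSION_LIMIT = 2.0e10

#: Default unquenched fluorophore lifetime, seconds (tryptophan-like).
DEFAULT_TAU0 = 1e-8


def _residual_sd(x: np.ndarray, y: np.ndarray, slope: float, intercept: float) -> float:
    resid = y - (intercept + slope * x)
    dof = max(x.size - 2, 1)
    return float(np.sqrt(np.sum(resid**2) / dof))


@dataclass(frozen=True)
class SternVolmerResult:
    """Stern-Volmer fit: slope K_SV, derived rate K_q = K_SV / tau0."""

    ksv: float  # L/mol
    intercept: float  # expected ~1
    kq: float  # L/mol/s
    tau0: float  # s
    r_corr: float
    sd: float
    n_points: int
    temperature: float  # K


@dataclass(frozen=True)
class DoubleLogResult:
    """Double-log binding fit: K = 10^intercept, n_sites = slope."""

    log_k: float
    k: float  # L/mol
    n_sites: float
    sd: float
    r_corr: float
    n_points: int
    temperature: float  # K

    @property
    def fitted_equation(self) -> str:
        return f"y = {self.log_k:.4f}+{self.n_sites:.4f}x"


@dataclass(frozen=True)
class MechanismCall:
    """Quenching-mechanism verdict with the per-rule evidence trail."""

    call: str  # "static" | "dynamic" | "indeterminate"
    evidence: tuple[str, ...] = field(default_factory=tuple)


def stern_volmer_fit(
    concentrations,
    f0_over_f,
    tau0: float = DEFAULT_TAU0,
    temperature: float = 298.0,
) -> SternVolmerResult:
    """Ordinary least squares of F0/F on quencher concentration.

    Requires at least three points; the zero-concentration point (ratio 1)
    may be included.  A negative slope is physically anti-quenching and is
    reported with a warning rather than rejected.
    """
    d = np.asarray(concentrations, dtype=float)
    y = np.asarray(f0_over_f, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise ValidationError("concentrations and ratios must be matching 1-D arrays")
    if d.size < 3:
        raise InsufficientDataError(
            f"Stern-Volmer fit needs >= 3 points, got {d.size}"
        )
    if tau0 <= 0:
        raise ValidationError("tau0 must be > 0 s")
    if not (0.0 in d or np.all(y >= 1.0)):
        raise ValidationError(
            "ratios must include the zero-quencher point or all be >= 1"
        )
    fit = stats.linregress(d, y)
    if fit.slope < 0:
        warnings.warn(
            f"negative Stern-Volmer slope ({fit.slope:.3g} L/mol): intensity "
            "rises with quencher",
            AntiQuenchingWarning,
            stacklevel=2,
        )
    return SternVolmerResult(
        ksv=float(fit.slope),
        intercept=float(fit.intercept),
        kq=float(fit.slope) / tau0,
        tau0=tau0,
        r_corr=float(fit.rvalue),
        sd=_residual_sd(d, y, fit.slope, fit.intercept),
        n_points=int(d.size),
        temperature=temperature,
    )


def double_log_fit(
    concentrations,
    f0: float,
    f,
    temperature: float = 298.0,
) -> DoubleLogResult:
    """OLS of lg[(F0-F)/F] on lg[D]; K = 10^intercept, n = slope.

    Zero-concentration points are excluded (lg undefined); points with
    F >= F0 are dropped with a warning.  At least three usable points are
    required.
    """
    d = np.asarray(concentrations, dtype=float)
    f_arr = np.asarray(f, dtype=float)
    if d.shape != f_arr.shape or d.ndim != 1:
        raise ValidationError("concentrations and intensities must match in shape")
    if f0 <= 0:
        raise ValidationError("F0 must be > 0")
    usable = d > 0
    bad = usable & (f_arr >= f0)
    if np.any(bad):
        warnings.warn(
            f"dropped {int(bad.sum())} point(s) with F >= F0 from the double-log fit",
            DroppedPointWarning,
            stacklevel=2,
        )
        usable &= f_arr < f0
    usable &= f_arr > 0
    if usable.sum() < 3:
        raise InsufficientDataError(
            f"double-log fit needs >= 3 usable points, got {int(usable.sum())}"
        )
    x = np.log10(d[usable])
    y = np.log10((f0 - f_arr[usable]) / f_arr[usable])
    fit = stats.linregress(x, y)
    return DoubleLogResult(
        log_k=float(fit.intercept),
        k=float(10.0 ** fit.intercept),
        n_sites=float(fit.slope),
        sd=_residual_sd(x, y, fit.slope, fit.intercept),
        r_corr=float(fit.rvalue),
        n_points=int(usable.sum()),
        temperature=temperature,
    )


def classify_mechanism(
    results_by_temperature,
    diffusion_limit: float = DIFFUSION_LIMIT,
) -> MechanismCall:
    """Static-vs-dynamic verdict from >= 2 temperature Stern-Volmer fits.

    Two independent rules are evaluated and both logged:

    * temperature trend — K_SV falling with temperature favours static
      quenching (the ground-state complex dissociates when warmed), rising
      favours dynamic (faster diffusion);
    * rate magnitude — K_q above the diffusion-controlled limit cannot be
      collisional, favouring static.

    Agreement gives the call; conflict gives ``indeterminate``.
    """
    results = sorted(results_by_temperature, key=lambda r: r.temperature)
    if len(results) < 2:
        raise ValidationError("need Stern-Volmer results at >= 2 temperatures")
    temps = [r.temperature for r in results]
    if len(set(temps)) != len(temps):
        raise ValidationError("temperatures must be distinct")

    ksv = [r.ksv for r in results]
    votes = []
    evidence = []
    if all(b < a for a, b in zip(ksv, ksv[1:])):
        votes.append("static")
        evidence.append(
            f"K_SV decreases with temperature ({ksv[0]:.4g} -> {ksv[-1]:.4g} "
            f"L/mol over {temps[0]:g} -> {temps[-1]:g} K): static"
        )
    elif all(b > a for a, b in zip(ksv, ksv[1:])):
        votes.append("dynamic")
        evidence.append(
            f"K_SV increases with temperature ({ksv[0]:.4g} -> {ksv[-1]:.4g} "
            f"L/mol over {temps[0]:g} -> {temps[-1]:g} K): dynamic"
        )
    else:
        evidence.append("K_SV temperature trend is non-monotone: no vote")

    kq_max = max(r.kq for r in results)
    if kq_max > diffusion_limit:
        votes.append("static")
        evidence.append(
            f"K_q = {kq_max:.4g} exceeds the diffusion limit "
            f"{diffusion_limit:.4g} L/mol/s: static"
        )
    else:
        votes.append("dynamic")
        evidence.append(
            f"K_q = {kq_max:.4g} within the diffusion limit "
            f"{diffusion_limit:.4g} L/mol/s: dynamic"
        )

    if votes and all(v == "static" for v in votes):
        call = "static"
    elif votes and all(v == "dynamic" for v in votes):
        call = "dynamic"
    else:
        call = "indeterminate"
    return MechanismCall(call=call, evidence=tuple(evidence))


def _refined_peak_height(spectrum) -> float:
    """Band peak intensity with sub-grid refinement.

    Two stages.  (1) A parabola through the log intensity over the upper
    half of the band: the log of a Gaussian band is exactly quadratic, so
    the vertex reproduces the true peak height to machine precision on
    clean data even when the band centre falls between grid points.
    (2) A linear-space Gaussian least-squares refinement seeded by stage 1
    — the maximum-likelihood estimate under additive noise, which averages
    the whole band instead of trusting the (upward-biased) grid maximum.
    On clean data the seed already is the optimum, so stage 2 leaves it
    unchanged.  Falls back to the grid maximum for degenerate windows.
    """
    wl, inten = spectrum.wavelength, spectrum.intensity
    idx = int(np.argmax(inten))
    grid_max = float(inten[idx])
    smoothed = _boxcar(inten, 5)
    s_idx = int(np.argmax(smoothed))
    half = 0.5 * smoothed[s_idx]
    lo = s_idx
    while lo > 0 and smoothed[lo - 1] >= half and inten[lo - 1] > 0:
        lo -= 1
    hi = s_idx
    while hi < inten.size - 1 and smoothed[hi + 1] >= half and inten[hi + 1] > 0:
        hi += 1
    if hi - lo < 2 or np.any(inten[lo : hi + 1] <= 0):
        return grid_max
    a, b, c = np.polyfit(wl[lo : hi + 1], np.log(inten[lo : hi + 1]), 2)
    if a >= 0:
        return grid_max
    height = float(np.exp(c - b**2 / (4.0 * a)))
    center = float(-b / (2.0 * a))
    sigma = float(np.sqrt(-1.0 / (2.0 * a)))

    def gaussian(x, amp, mu, sig):
        return amp * np.exp(-0.5 * ((x - mu) / sig) ** 2)

    try:
        popt, _ = optimize.curve_fit(
            gaussian, wl, inten, p0=[height, center, sigma], maxfev=2000
        )
        if popt[0] > 0:
            return float(popt[0])
    except (RuntimeError, ValueError):
        pass
    return height


def quench_curve(
    titration: TitrationSeries | CorrectedTitration,
    wavelength: float | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Extract (concentrations, F0, F) from a titration for the fits.

    By default each spectrum contributes its own maximum-emission intensity
    (the quantity recorded in a titration protocol, and robust to the
    binding-induced peak shift), refined below the grid step by a
    log-parabolic fit around the maximum; passing ``wavelength`` instead
    reads every spectrum at that fixed position.  Inner-filter correction,
    if wanted, must be applied upstream.
    """
    series = titration.series if isinstance(titration, CorrectedTitration) else titration
    if wavelength is None:
        f = np.array([_refined_peak_height(s) for s in series.spectra])
    else:
        f = series.intensities_at(wavelength)
    return series.concentrations, float(f[0]), f
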