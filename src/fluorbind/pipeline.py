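"""End-to-end analysis pipeline and structured report.

``run_pipeline`` strings the stages together in the order a binding study
reports them — inner-filter correction, Stern-Volmer quenching + mechanism
call, double-log binding fit, FRET, van't Hoff thermodynamics, polarization,
peak shifts — with stage isolation: a failing stage is recorded and
independent downstream stages still run.  The report serializes to JSON
deterministically (no timestamps), so identical configs give byte-identical
output.

Config is a flat, human-editable mapping (YAML on disk).  Every physical
constant is a config key so "reproduce published constants" versus
best-practice defaults is an explicit, logged choice::

    protein_id: HSA
    protein_concentration: 1.0e-5     # mol/L
    titrations:                       # wide-format CSVs, one per temperature
      - {path: hsa_298.csv, temperature: 298}
      - {path: hsa_310.csv, temperature: 310}
    absorption: ligand_abs.csv        # long-format CSV
    absorption_concentration: 4.0e-5  # mol/L of the recorded spectrum
    polarization:
      free:      {i_vv: 95.98, i_vh: 71.89, i_hv: 57.54, i_hh: 55.91}
      complexed: {i_vv: 58.88, i_vh: 38.81, i_hv: 31.16, i_hh: 30.09}
    constants: {tau0: 1.0e-8, kappa2: 0.6666666666666666, n_refr: 1.336,
                phi: 0.13, diffusion_limit: 2.0e10}
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import fret as _fret
from .polarization import PolarizedIntensities, compare_polarization, polarization_analysis
from .preprocess import correct_titration, peak_shift
from .quenchfit import (
    DEFAULT_TAU0,
    DIFFUSION_LIMIT,
    classify_mechanism,
    double_log_fit,
    quench_curve,
    stern_volmer_fit,
)
from .spectra import read_spectrum_table, read_titration_table
from .thermo import thermo_analysis

__all__ = ["AnalysisReport", "run_pipeline", "load_config", "default_constants"]


def default_constants(reproduce_paper: bool = False) -> dict:
    """Physical constants used across the pipeline.

    ``reproduce_paper`` switches the refractive index from the stated 1.336
    to the 1.36 that reproduces the published critical-distance values.
    """
    return {
        "tau0": DEFAULT_TAU0,
        "kappa2": _fret.KAPPA2_ISOTROPIC,
        "n_refr": 1.36 if reproduce_paper else _fret.REFRACTIVE_INDEX_DEFAULT,
        "phi": _fret.QUANTUM_YIELD_DEFAULT,
        "diffusion_limit": DIFFUSION_LIMIT,
    }


@dataclass
class AnalysisReport:
    """Structured results of one pipeline run, serializable to JSON/TSV."""

    protein_id: str = ""
    stern_volmer: dict = field(default_factory=dict)  # temperature -> result
    mechanism: Any = None
    binding: dict = field(default_factory=dict)  # temperature -> result
    energy_transfer: Any = None
    thermodynamics: Any = None
    polarization: dict = field(default_factory=dict)
    shifts: list = field(default_factory=list)
    correction_factors: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)
    errors: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return _jsonable(dataclasses.asdict(self))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    def write_tables(self, directory: str | Path) -> list[Path]:
        """Emit TSV tables mirroring the standard report layout."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []

        def emit(name: str, rows: list[dict]) -> None:
            if not rows:
                return
            p = directory / f"{name}.tsv"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
            written.append(p)

        emit(
            "stern_volmer",
            [
                {"protein": self.protein_id, "temperature_K": t, "ksv_L_per_mol": r["ksv"],
                 "kq_L_per_mol_s": r["kq"], "intercept": r["intercept"], "r_corr": r["r_corr"],
                 "sd": r["sd"], "n_points": r["n_points"]}
                for t, r in sorted(self.stern_volmer.items())
            ],
        )
        emit(
            "binding",
            [
                {"protein": self.protein_id, "temperature_K": t,
                 "fitted_equation": f"y = {r['log_k']:.4f}+{r['n_sites']:.4f}x",
                 "sd": r["sd"], "n_points": r["n_points"], "r_corr": r["r_corr"],
                 "k_L_per_mol": r["k"], "n_sites": r["n_sites"]}
                for t, r in sorted(self.binding.items())
            ],
        )
        if self.energy_transfer:
            e = self.energy_transfer
            emit(
                "energy_transfer",
                [{"protein": self.protein_id, "J_M-1cm3": e["j_overlap"], "R0_nm": e["r0"],
                  "E": e["efficiency"], "r_nm": e["distance"]}],
            )
        if self.thermodynamics:
            t = self.thermodynamics
            rows = []
            for temp, dg in sorted(t["delta_g_by_temperature"].items()):
                rows.append(
                    {"protein": self.protein_id, "temperature_K": temp,
                     "dH_kJ_per_mol": t["delta_h"] / 1e3, "dG_kJ_per_mol": dg / 1e3,
                     "dS_J_per_mol_K": t["delta_s"], "force_class": t["force_class"]}
                )
            emit("thermodynamics", rows)
        if self.polarization:
            rows = [
                {"system": name, **vals}
                for name, vals in self.polarization.items()
                if isinstance(vals, dict) and "p" in vals
            ]
            emit("polarization", rows)
        return written


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _result_dict(result) -> dict:
    return _jsonable(dataclasses.asdict(result))


def run_pipeline(config: dict, base_dir: str | Path | None = None) -> AnalysisReport:
    """Run the full analysis described by ``config`` (see module docstring).

    Relative paths resolve against ``base_dir`` (default: CWD).  Stage
    failures are isolated: the error is recorded under ``report.errors`` and
    independent stages still run; missing prerequisites (e.g. a single
    temperature for thermodynamics) land in ``report.skipped``.
    """
    base = Path(base_dir) if base_dir else Path.cwd()
    constants = default_constants(bool(config.get("reproduce_paper", False)))
    constants.update(config.get("constants", {}))
    report = AnalysisReport(
        protein_id=str(config.get("protein_id", "")),
        provenance={"config": _jsonable(config), "constants": _jsonable(constants),
                    "version": __import__("fluorbind").__version__},
    )

    def _path(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    # --- load inputs -------------------------------------------------------
    absorption = None
    if config.get("absorption"):
        try:
            meta = {}
            if config.get("absorption_concentration") is not None:
                meta["chromophore_concentration"] = float(config["absorption_concentration"])
            absorption = read_spectrum_table(_path(config["absorption"]), kind="absorption", metadata=meta)
        except Exception as exc:  # noqa: BLE001 - stage isolation
            report.errors.append(f"absorption: {exc}")

    corrected_by_temp: dict[float, Any] = {}
    for entry in config.get("titrations", []):
        temp = float(entry["temperature"])
        try:
            series = read_titration_table(
                _path(entry["path"]),
                protein_id=str(config.get("protein_id", "")),
                protein_concentration=float(config.get("protein_concentration", 1e-5)),
                temperature=temp,
                excitation_wavelength=float(config.get("excitation_wavelength", 282.0)),
            )
            if absorption is not None:
                corr = correct_titration(series, absorption)
                corrected_by_temp[temp] = corr
                report.correction_factors[temp] = corr.correction_factors.tolist()
            else:
                corrected_by_temp[temp] = series
                report.skipped.append(
                    f"inner-filter correction at {temp} K: no absorption spectrum"
                )
        except Exception as exc:  # noqa: BLE001
            report.errors.append(f"titration {entry.get('path')}: {exc}")

    # --- quenching fits ----------------------------------------------------
    sv_results = {}
    for temp, titr in sorted(corrected_by_temp.items()):
        try:
            conc, f0, f = quench_curve(titr)
            sv = stern_volmer_fit(conc, f0 / f, tau0=constants["tau0"], temperature=temp)
            sv_results[temp] = sv
            report.stern_volmer[temp] = _result_dict(sv)
            dl = double_log_fit(conc, f0, f, temperature=temp)
            report.binding[temp] = _result_dict(dl)
        except Exception as exc:  # noqa: BLE001
            report.errors.append(f"quench fits at {temp} K: {exc}")

    if len(sv_results) >= 2:
        try:
            call = classify_mechanism(
                list(sv_results.values()), diffusion_limit=constants["diffusion_limit"]
            )
            report.mechanism = {"call": call.call, "evidence": list(call.evidence)}
        except Exception as exc:  # noqa: BLE001
            report.errors.append(f"mechanism: {exc}")
    else:
        report.skipped.append("mechanism classification: needs >= 2 temperatures")

    # --- FRET --------------------------------------------------------------
    if absorption is not None and corrected_by_temp:
        try:
            temp0 = sorted(corrected_by_temp)[0]
            titr = corrected_by_temp[temp0]
            series = titr.series if hasattr(titr, "series") else titr
            conc, f0, f = quench_curve(titr)
            # F/F0 at the titration point closest to 1:1 protein:ligand
            target = float(config.get("fret_point", series.protein_concentration))
            idx = int(np.argmin(np.abs(conc - target)))
            if idx == 0:
                idx = 1
            ana = _fret.energy_transfer_analysis(
                series.reference, absorption, f=float(f[idx]), f0=f0,
                kappa2=constants["kappa2"], n_refr=constants["n_refr"], phi=constants["phi"],
            )
            report.energy_transfer = _result_dict(ana)
            report.energy_transfer["nonradiative_transfer_plausible"] = (
                ana.nonradiative_transfer_plausible
            )
        except Exception as exc:  # noqa: BLE001
            report.errors.append(f"energy transfer: {exc}")
    elif not absorption:
        report.skipped.append("energy transfer: no absorption spectrum")

    # --- thermodynamics ----------------------------------------------------
    if len(report.binding) >= 2:
        try:
            k_by_t = {t: r["k"] for t, r in sorted(report.binding.items())[:2]}
            th = thermo_analysis(k_by_t)
            report.thermodynamics = _result_dict(th)
        except Exception as exc:  # noqa: BLE001
            report.errors.append(f"thermodynamics: {exc}")
    else:
        report.skipped.append("thermodynamics: needs binding constants at >= 2 temperatures")

    # --- peak shifts -------------------------------------------------------
    for temp, titr in sorted(corrected_by_temp.items()):
        try:
            series = titr.series if hasattr(titr, "series") else titr
            sh = peak_shift(series.reference, series.spectra[-1])
            d = _result_dict(sh)
            d["temperature"] = temp
            report.shifts.append(d)
        except Exception as exc:  # noqa: BLE001
            report.errors.append(f"peak shift at {temp} K: {exc}")

    # --- polarization ------------------------------------------------------
    pol_cfg = config.get("polarization") or {}
    pol_results = {}
    for name in ("free", "complexed"):
        if name in pol_cfg:
            try:
                res = polarization_analysis(PolarizedIntensities(label=name, **pol_cfg[name]))
                pol_results[name] = res
                report.polarization[name] = _result_dict(res)
            except Exception as exc:  # noqa: BLE001
                report.errors.append(f"polarization {name}: {exc}")
    if {"free", "complexed"} <= pol_results.keys():
        cmp_res = compare_polarization(pol_results["free"], pol_results["complexed"])
        report.polarization["comparison"] = _result_dict(cmp_res)

    return report
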