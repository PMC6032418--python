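"""Readers and writers for the package's plain-text interchange formats.

Inversion-recovery data travel as long-format CSV (one row per measured
point); isotherms and spectra as two-column CSV; a complete study as a
YAML file with one block per enzyme.  All file paths in a study config
are resolved relative to the config file itself.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .binding import BindingIsotherm
from .errors import InputError
from .pipeline import EnzymeStudy, StudyConfig
from .relaxation import InversionRecoverySeries, RelaxationPair, T1Estimate
from .spinstate import AbsorbanceSpectrum

__all__ = [
    "read_inversion_recovery_csv",
    "write_t1_estimates",
    "read_isotherm_csv",
    "read_spectrum_csv",
    "read_difference_spectrum_csv",
    "load_study_config",
    "dump_study_config",
]

_IR_COLUMNS = {"proton_label", "enzyme_state", "temperature_K", "delay_s",
               "peak_height"}


def read_inversion_recovery_csv(path: str | Path) -> list[InversionRecoverySeries]:
    """Read long-format inversion-recovery CSV into one series per
    (proton_label, enzyme_state) group."""
    df = pd.read_csv(path)
    missing = _IR_COLUMNS - set(df.columns)
    if missing:
        raise InputError(
            f"{path}: missing columns {sorted(missing)}"
        )
    series = []
    for (label, state), grp in df.groupby(
        ["proton_label", "enzyme_state"], sort=True
    ):
        temps = grp["temperature_K"].unique()
        series.append(
            InversionRecoverySeries(
                proton_label=str(label),
                delays=grp["delay_s"].to_numpy(float),
                heights=grp["peak_height"].to_numpy(float),
                enzyme_state=str(state),
                temperature=float(temps[0]),
            )
        )
    if not series:
        raise InputError(f"{path}: no data rows")
    return series


def write_t1_estimates(estimates: list[T1Estimate], path: str | Path) -> None:
    rows = [
        {
            "proton_label": e.proton_label,
            "enzyme_state": e.enzyme_state,
            "t1_s": e.t1,
            "se_s": e.se,
            "rss": e.fit_diagnostics.get("rss"),
            "n_points": e.fit_diagnostics.get("n_points"),
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_isotherm_csv(path: str | Path, enzyme_label: str = "") -> BindingIsotherm:
    df = pd.read_csv(path)
    for col in ("substrate_uM", "delta_A"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    return BindingIsotherm(
        substrate_conc=df["substrate_uM"].to_numpy(float),
        delta_A=df["delta_A"].to_numpy(float),
        enzyme_label=enzyme_label,
    )


def read_spectrum_csv(path: str | Path) -> AbsorbanceSpectrum:
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "absorbance"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    return AbsorbanceSpectrum(
        wavelengths=df["wavelength_nm"].to_numpy(float),
        absorbance=df["absorbance"].to_numpy(float),
    )


def read_difference_spectrum_csv(path: str | Path):
    from .binding import DifferenceSpectrum

    df = pd.read_csv(path)
    for col in ("wavelength_nm", "delta_absorbance"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    return DifferenceSpectrum(
        wavelengths=df["wavelength_nm"].to_numpy(float),
        delta_absorbance=df["delta_absorbance"].to_numpy(float),
    )


def _study_from_block(block: dict, base: Path) -> EnzymeStudy:
    pairs = tuple(
        RelaxationPair(
            proton_label=str(p["label"]),
            t1_ferric=float(p["t1_ferric_s"]),
            se_ferric=float(p.get("se_ferric_s", 0.0)),
            t1_ferrous_co=float(p["t1_ferrous_co_s"]),
            se_ferrous_co=float(p.get("se_ferrous_co_s", 0.0)),
        )
        for p in block.get("protons", [])
    )
    isotherm = None
    if "isotherm_csv" in block:
        isotherm = read_isotherm_csv(base / block["isotherm_csv"],
                                     enzyme_label=block["label"])
    spectrum = None
    if "spectrum_csv" in block:
        spectrum = read_spectrum_csv(base / block["spectrum_csv"])
    recovery: tuple[InversionRecoverySeries, ...] = ()
    if "inversion_recovery_csv" in block:
        recovery = tuple(
            read_inversion_recovery_csv(base / block["inversion_recovery_csv"])
        )
    return EnzymeStudy(
        enzyme_label=str(block["label"]),
        p450_conc=float(block["p450_uM"]),
        substrate_conc=float(block["substrate_uM"]),
        ks=float(block["ks_uM"]),
        f_high=float(block["f_high"]),
        f_low=float(block.get("f_low", 1.0 - float(block["f_high"]))),
        tau_c=float(block["tau_c_s"]),
        relaxation_pairs=pairs,
        isotherm=isotherm,
        spectrum=spectrum,
        recovery_series=recovery,
    )


def load_study_config(path: str | Path) -> StudyConfig:
    """Load a YAML study config; file paths resolve relative to it."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "enzymes" not in raw:
        raise InputError(f"{path}: expected a mapping with an 'enzymes' list")
    default_tau = raw.get("tau_c_s")
    blocks = []
    for block in raw["enzymes"]:
        block = dict(block)
        block.setdefault("tau_c_s", default_tau)
        if block["tau_c_s"] is None:
            raise InputError(
                f"{path}: tau_c_s missing for enzyme {block.get('label')!r}"
            )
        blocks.append(block)
    return StudyConfig(
        enzymes=tuple(_study_from_block(b, path.parent) for b in blocks)
    )


def dump_study_config(config: StudyConfig, path: str | Path) -> None:
    """Write a study config (summary parameters only) back to YAML."""
    doc = {
        "enzymes": [
            {
                "label": e.enzyme_label,
                "p450_uM": e.p450_conc,
                "substrate_uM": e.substrate_conc,
                "ks_uM": e.ks,
                "f_high": e.f_high,
                "f_low": e.f_low,
                "tau_c_s": e.tau_c,
                "protons": [
                    {
                        "label": p.proton_label,
                        "t1_ferric_s": p.t1_ferric,
                        "se_ferric_s": p.se_ferric,
                        "t1_ferrous_co_s": p.t1_ferrous_co,
                        "se_ferrous_co_s": p.se_ferrous_co,
                    }
                    for p in e.relaxation_pairs
                ],
            }
            for e in config.enzymes
        ]
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def write_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
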