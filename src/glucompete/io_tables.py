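"""Delimited-text readers/writers and the run configuration.

All tables are comma-separated UTF-8 with a header row, '#' comment
lines and dot decimals.  Concentrations in user-facing tables follow
the field's mixed convention: protein/ligand in molar, glucose in
mg/dL.  Config files are YAML; every concentration entry must carry an
explicit unit annotation ({value: ..., unit: M|mM|uM|nM|mg/dL}) and is
normalized to molar internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .calibration import GlucoseResponseCurve
from .equilibrium import mgdl_to_molar
from .titration import TitrationCurve

__all__ = [
    "TableError",
    "ConfigError",
    "read_table",
    "write_table",
    "read_titration",
    "write_titration",
    "read_glucose_response",
    "write_glucose_response",
    "read_evaluation_pairs",
    "RunConfig",
    "load_config",
]

FLOAT_FMT = "%.12g"

_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "μM": 1e-6, "nM": 1e-9}


class TableError(ValueError):
    """Schema violation in a delimited-text table."""


class ConfigError(ValueError):
    """Malformed or unit-less run configuration."""


def read_table(path, columns: Sequence[str]) -> pd.DataFrame:
    """Read a CSV with the required numeric columns.

    Rejects missing/duplicate headers and non-numeric cells, reporting
    the offending data-row index.
    """
    # pandas renames duplicate headers (r, r.1, ...); check the raw line
    with open(path, "r", encoding="utf-8") as fh:  # noqa: PTH123 - path-like only
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                names = [c.strip() for c in line.split(",")]
                if len(names) != len(set(names)):
                    raise TableError(f"duplicate header columns in {path}")
                break
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing columns {missing}")
    out = {}
    for c in columns:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy() & df[c].notna().to_numpy())[0]
        if df[c].isna().any():
            bad = np.union1d(bad, np.nonzero(df[c].isna().to_numpy())[0])
        if bad.size:
            raise TableError(
                f"{path}: non-numeric value in column '{c}' at data row(s) "
                f"{(bad + 1).tolist()}"
            )
        out[c] = vals.to_numpy(dtype=float)
    return pd.DataFrame(out)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a CSV with 12-significant-digit floats (round-trip safe)."""
    Path(path).write_text(df.to_csv(index=False, float_format=FLOAT_FMT),
                          encoding="utf-8")


def read_titration(path, ligand_total: float, G: float | None = None) -> TitrationCurve:
    """Read a titration table: protein_conc_M, r  — or raw intensities
    (protein_conc_M, I_VV, I_VH) with the instrument factor G supplied."""
    header = pd.read_csv(path, comment="#", nrows=0).columns
    if "r" in header:
        df = read_table(path, ["protein_conc_M", "r"])
        r = df["r"].to_numpy()
    elif {"I_VV", "I_VH"} <= set(header):
        if G is None:
            raise TableError("raw-intensity titration table requires G")
        df = read_table(path, ["protein_conc_M", "I_VV", "I_VH"])
        num = df["I_VV"] - G * df["I_VH"]
        den = df["I_VV"] + 2.0 * G * df["I_VH"]
        r = (num / den).to_numpy()
    else:
        raise TableError(f"{path}: need column 'r' or columns I_VV, I_VH")
    order = np.argsort(df["protein_conc_M"].to_numpy())
    return TitrationCurve(
        ligand_total=ligand_total,
        protein_concs=df["protein_conc_M"].to_numpy()[order],
        r_values=r[order],
    )


def write_titration(curve: TitrationCurve, path) -> None:
    write_table(
        pd.DataFrame(
            {"protein_conc_M": curve.protein_concs, "r": curve.r_values}
        ),
        path,
    )


def read_glucose_response(path) -> GlucoseResponseCurve:
    df = read_table(path, ["glucose_mgdl", "r"])
    order = np.argsort(df["glucose_mgdl"].to_numpy())
    return GlucoseResponseCurve(
        glucose_mgdl=df["glucose_mgdl"].to_numpy()[order],
        r_values=df["r"].to_numpy()[order],
    )


def write_glucose_response(curve: GlucoseResponseCurve, path) -> None:
    write_table(
        pd.DataFrame({"glucose_mgdl": curve.glucose_mgdl, "r": curve.r_values}),
        path,
    )


def read_evaluation_pairs(path) -> tuple[np.ndarray, np.ndarray]:
    """Read (actual, predicted) glucose pairs in mg/dL."""
    df = read_table(path, ["actual_mgdl", "predicted_mgdl"])
    return df["actual_mgdl"].to_numpy(), df["predicted_mgdl"].to_numpy()


def _to_molar(entry, key: str) -> float:
    """Normalize a {value, unit} config entry to molar."""
    if not isinstance(entry, dict) or "value" not in entry or "unit" not in entry:
        raise ConfigError(
            f"config entry '{key}' must be a mapping with 'value' and 'unit'"
        )
    unit = str(entry["unit"])
    value = float(entry["value"])
    if unit in _UNIT_TO_MOLAR:
        return value * _UNIT_TO_MOLAR[unit]
    if unit == "mg/dL":
        return mgdl_to_molar(value)
    raise ConfigError(f"config entry '{key}': unknown unit {unit!r}")


@dataclass(frozen=True)
class RunConfig:
    """Resolved run parameters, all concentrations in molar."""

    K_M: float
    K_G: float
    M0: float
    C0: float
    G_low: float
    G_high: float
    grid_C0_low: float
    grid_C0_high: float
    points_per_decade: int = 60
    threshold: float = 0.40
    correction_mode: str = "naive"
    r_noise_sd: float = 0.003
    seed: int = 0
    output_dir: str = "."
    verbosity: int = 1
    extras: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Required sections: constants (K_M, K_G), mixture (M0, C0), glucose
    (low, high in mg/dL), grid (C0_low, C0_high).  Each concentration
    must be a {value, unit} mapping; bare numbers are rejected.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        constants = raw["constants"]
        mixture = raw["mixture"]
        glucose = raw["glucose"]
        grid = raw["grid"]
    except KeyError as exc:
        raise ConfigError(f"{path}: missing section {exc}") from exc
    fit = raw.get("fit", {})
    noise = raw.get("noise", {})
    return RunConfig(
        K_M=_to_molar(constants["K_M"], "constants.K_M"),
        K_G=_to_molar(constants["K_G"], "constants.K_G"),
        M0=_to_molar(mixture["M0"], "mixture.M0"),
        C0=_to_molar(mixture["C0"], "mixture.C0"),
        G_low=_to_molar(glucose["low"], "glucose.low"),
        G_high=_to_molar(glucose["high"], "glucose.high"),
        grid_C0_low=_to_molar(grid["C0_low"], "grid.C0_low"),
        grid_C0_high=_to_molar(grid["C0_high"], "grid.C0_high"),
        points_per_decade=int(grid.get("points_per_decade", 60)),
        threshold=float(raw.get("threshold", 0.40)),
        correction_mode=str(fit.get("correction_mode", "naive")),
        r_noise_sd=float(noise.get("r_noise_sd", 0.003)),
        seed=int(noise.get("seed", 0)),
        output_dir=str(raw.get("output_dir", ".")),
        verbosity=int(raw.get("verbosity", 1)),
        extras={k: v for k, v in raw.items()
                if k not in {"constants", "mixture", "glucose", "grid", "fit",
                             "noise", "threshold", "output_dir", "verbosity"}},
    )
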