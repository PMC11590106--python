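"""Sensitivity maps and reagent-concentration optimization.

The design objective is the fraction difference Delta F: how much of the
labeled ligand is released when glucose rises from the low to the high
end of the target window (default 0 to 400 mg/dL).  Delta F is evaluated
on a grid of total ligand (M0) and total receptor (C0) concentrations;
the optimum receptor concentration and the C0 range where Delta F
exceeds a threshold (the paper-style "greater than 40%" band) are read
off each fixed-M0 row.

Delta F is stored as a fraction in [0, 1]; percent rendering happens
only at reporting boundaries.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .equilibrium import BindingConstants, fraction_difference

__all__ = [
    "DesignGrid",
    "SensitivityMap",
    "DesignSummary",
    "DesignError",
    "log_grid",
    "sensitivity_map",
    "optimal_protein_conc",
    "threshold_crossings",
    "design_summary",
    "export_map",
    "read_map",
]

#: Delta F fluctuations below this are ignored by the unimodality guard.
UNIMODAL_TOL = 1e-9
#: Grid points within this Delta F of the row maximum count as the plateau.
PLATEAU_TOL = 0.005


class DesignError(ValueError):
    """Invalid grid, lookup or non-unimodal sensitivity row."""


def _ascending_positive(name: str, values: Sequence[float], min_len: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < min_len:
        raise DesignError(f"{name} needs at least {min_len} point(s)")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DesignError(f"{name} must be finite and > 0")
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise DesignError(f"{name} must be strictly ascending")
    return arr


@dataclass(frozen=True)
class DesignGrid:
    """Concentration grid for the sensitivity map (molar, ascending)."""

    M0_values: np.ndarray
    C0_values: np.ndarray
    spacing: str = "log"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "M0_values", _ascending_positive("M0_values", self.M0_values, 1)
        )
        object.__setattr__(
            self, "C0_values", _ascending_positive("C0_values", self.C0_values, 1)
        )
        if self.spacing not in ("log", "linear"):
            raise DesignError("spacing must be 'log' or 'linear'")


def log_grid(
    low: float, high: float, points_per_decade: int = 60
) -> np.ndarray:
    """Log-spaced axis from low to high, about `points_per_decade` dense."""
    if not (0 < low < high):
        raise DesignError("need 0 < low < high")
    decades = np.log10(high / low)
    n = max(2, int(np.ceil(decades * points_per_decade)) + 1)
    return np.logspace(np.log10(low), np.log10(high), n)


@dataclass(frozen=True)
class SensitivityMap:
    """Delta F over the design grid; delta_F[i, j] pairs M0_values[i]
    with C0_values[j]."""

    grid: DesignGrid
    delta_F: np.ndarray
    G_low: float
    G_high: float
    constants: BindingConstants

    def row(self, M0: float) -> np.ndarray:
        return self.delta_F[self._row_index(M0)]

    def _row_index(self, M0: float) -> int:
        idx = np.nonzero(np.isclose(self.grid.M0_values, M0, rtol=1e-9))[0]
        if idx.size != 1:
            raise DesignError(
                f"M0 = {M0:g} M is not a grid row (no silent interpolation)"
            )
        return int(idx[0])


@dataclass(frozen=True)
class DesignSummary:
    """Per-M0 design result: best receptor concentration and the
    threshold-exceeding band."""

    M0: float
    optimal_C0: float
    max_delta_F: float
    threshold: float
    threshold_range: tuple[float, float] | None
    plateau_C0: tuple[float, ...] = field(default=())


def sensitivity_map(
    constants: BindingConstants,
    grid: DesignGrid,
    G_low: float,
    G_high: float,
) -> SensitivityMap:
    """Evaluate the fraction difference at every grid point."""
    if G_high < G_low:
        raise DesignError("G_high must be >= G_low")
    dF = np.empty((grid.M0_values.size, grid.C0_values.size))
    for i, M0 in enumerate(grid.M0_values):
        for j, C0 in enumerate(grid.C0_values):
            try:
                dF[i, j] = fraction_difference(constants, M0, C0, G_low, G_high)
            except Exception as exc:  # attach grid coordinates
                raise DesignError(
                    f"solver failed at M0={M0:g} M, C0={C0:g} M: {exc}"
                ) from exc
    return SensitivityMap(
        grid=grid, delta_F=dF, G_low=G_low, G_high=G_high, constants=constants
    )


def optimal_protein_conc(
    smap: SensitivityMap, M0: float, plateau_tol: float = PLATEAU_TOL
) -> tuple[float, float, tuple[float, ...]]:
    """Grid argmax of Delta F along the fixed-M0 row.

    The objective is flat near its maximum, so alongside the argmax
    (ties broken toward the smallest C0) all grid points within
    `plateau_tol` of the maximum are returned.

    Returns
    -------
    (optimal_C0, max_delta_F, plateau_C0s)
    """
    row = smap.row(M0)
    j = int(np.argmax(row))  # argmax returns the first (smallest C0) tie
    plateau = tuple(
        float(c) for c, v in zip(smap.grid.C0_values, row) if row[j] - v <= plateau_tol
    )
    return float(smap.grid.C0_values[j]), float(row[j]), plateau


def _check_unimodal(row: np.ndarray) -> int:
    """Return argmax; raise if the row is not rise-then-fall within tol."""
    j = int(np.argmax(row))
    diffs = np.diff(row)
    bad_rise = np.nonzero(diffs[:j] < -UNIMODAL_TOL)[0]
    bad_fall = np.nonzero(diffs[j:] > UNIMODAL_TOL)[0]
    if bad_rise.size or bad_fall.size:
        raise DesignError(
            "sensitivity row is not unimodal; decreasing before the maximum at "
            f"indices {bad_rise.tolist()}, increasing after at "
            f"{(bad_fall + j).tolist()}"
        )
    return j


def threshold_crossings(
    smap: SensitivityMap, M0: float, threshold: float
) -> tuple[float, float] | None:
    """C0 interval on which Delta F exceeds `threshold`.

    Crossings are located by linear interpolation in (log10 C0, Delta F)
    between the bracketing grid points on each flank of the (unimodal)
    maximum.  A flank that never drops below the threshold is reported at
    the grid edge.  Returns None when the row maximum does not exceed
    the threshold.
    """
    if not (0.0 < threshold < 1.0):
        raise DesignError("threshold must be in (0, 1)")
    row = smap.row(M0)
    j = _check_unimodal(row)
    if row[j] <= threshold:
        return None
    x = np.log10(smap.grid.C0_values)

    def interp(k0: int, k1: int) -> float:
        f0, f1 = row[k0], row[k1]
        t = (threshold - f0) / (f1 - f0)
        return float(10 ** (x[k0] + t * (x[k1] - x[k0])))

    low = float(smap.grid.C0_values[0])
    for k in range(j, 0, -1):
        if row[k - 1] <= threshold < row[k]:
            low = interp(k - 1, k)
            break
    high = float(smap.grid.C0_values[-1])
    for k in range(j, row.size - 1):
        if row[k + 1] <= threshold < row[k]:
            high = interp(k, k + 1)
            break
    return low, high


def design_summary(
    smap: SensitivityMap, M0: float, threshold: float = 0.40
) -> DesignSummary:
    """Optimum and threshold band for one ligand concentration row."""
    opt_C0, max_dF, plateau = optimal_protein_conc(smap, M0)
    rng = threshold_crossings(smap, M0, threshold)
    return DesignSummary(
        M0=float(M0),
        optimal_C0=opt_C0,
        max_delta_F=max_dF,
        threshold=float(threshold),
        threshold_range=rng,
        plateau_C0=plateau,
    )


def export_map(smap: SensitivityMap, destination) -> None:
    """Write the map as long-format CSV: M0_molar, C0_molar, delta_F.

    Values are printed with 12 significant digits so that
    export -> read -> export is byte-identical.
    """
    rows = []
    for i, M0 in enumerate(smap.grid.M0_values):
        for j, C0 in enumerate(smap.grid.C0_values):
            rows.append((M0, C0, smap.delta_F[i, j]))
    df = pd.DataFrame(rows, columns=["M0_molar", "C0_molar", "delta_F"])
    text = df.to_csv(index=False, float_format="%.12g")
    if isinstance(destination, (str, os.PathLike)):
        with open(destination, "w", encoding="utf-8") as fh:
            fh.write(text)
    else:
        destination.write(text)


def read_map(
    source,
    constants: BindingConstants,
    G_low: float,
    G_high: float,
    spacing: str = "log",
) -> SensitivityMap:
    """Read a long-format map CSV back into a :class:`SensitivityMap`."""
    if isinstance(source, (str, os.PathLike)):
        df = pd.read_csv(source, comment="#")
    else:
        df = pd.read_csv(io.StringIO(source.read()), comment="#")
    missing = {"M0_molar", "C0_molar", "delta_F"} - set(df.columns)
    if missing:
        raise DesignError(f"map table missing columns: {sorted(missing)}")
    M0s = np.unique(df["M0_molar"].to_numpy())
    C0s = np.unique(df["C0_molar"].to_numpy())
    grid = DesignGrid(M0_values=M0s, C0_values=C0s, spacing=spacing)
    dF = np.full((M0s.size, C0s.size), np.nan)
    mi = np.searchsorted(M0s, df["M0_molar"].to_numpy())
    ci = np.searchsorted(C0s, df["C0_molar"].to_numpy())
    dF[mi, ci] = df["delta_F"].to_numpy()
    if np.isnan(dF).any():
        raise DesignError("map table does not cover the full grid")
    return SensitivityMap(
        grid=grid, delta_F=dF, G_low=G_low, G_high=G_high, constants=constants
    )
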