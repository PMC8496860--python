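"""Strain induction tables: the data the pipeline is fitted against.

A strain table holds, per sugar condition, the mean induction level of the
GAL-induced subpopulation (ON-peak position) and of the GAL-repressed
subpopulation (OFF-peak position), normalized to the strain's maximum, plus
a validity flag for missing/poor-growth conditions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .steady_state import SugarGrid

__all__ = ["StrainTable", "TableValidationError"]

COLUMNS = ["glucose", "galactose", "on_peak", "off_peak", "valid"]


class TableValidationError(ValueError):
    pass


@dataclass
class StrainTable:
    """Per-condition ON/OFF peak positions for one strain."""

    strain_id: str
    data: pd.DataFrame
    knockouts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        df = self.data
        missing = set(COLUMNS) - set(df.columns)
        if missing:
            raise TableValidationError(f"missing columns: {sorted(missing)}")
        df = df.loc[:, COLUMNS].reset_index(drop=True)
        dup = df.duplicated(subset=["glucose", "galactose"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["glucose", "galactose"]].tolist()
            raise TableValidationError(f"duplicate condition rows: {pair}")
        ok = df["valid"].astype(bool)
        bad = ok & (df["on_peak"] < df["off_peak"])
        if bad.any():
            row = df.loc[bad.idxmax()]
            raise TableValidationError(
                f"on_peak < off_peak at glucose={row.glucose}, "
                f"galactose={row.galactose}"
            )
        self.data = df

    @property
    def n_valid(self) -> int:
        return int(self.data["valid"].astype(bool).sum())

    def align_to_grid(self, grid: SugarGrid) -> "StrainTable":
        """Match table conditions to grid levels within relative 1e-6.

        Rows with conditions not on the grid raise, naming the nearest grid
        value so ladder-rounding mistakes are easy to diagnose.
        """
        def snap(value: float, levels, axis: str) -> float:
            arr = np.asarray(levels)
            err = np.abs(arr - value) / np.maximum(np.abs(arr), 1e-30)
            k = int(np.argmin(err))
            if value == 0.0 and 0.0 in levels:
                return 0.0
            if err[k] <= 1e-6:
                return float(arr[k])
            raise TableValidationError(
                f"{axis} value {value!r} not on grid; nearest grid value "
                f"is {arr[k]!r}"
            )

        df = self.data.copy()
        df["glucose"] = [
            snap(v, grid.glucose_levels, "glucose") for v in df["glucose"]
        ]
        df["galactose"] = [
            snap(v, grid.galactose_levels, "galactose") for v in df["galactose"]
        ]
        return StrainTable(self.strain_id, df, self.knockouts)
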