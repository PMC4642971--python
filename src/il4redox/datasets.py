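"""Tabular container for per-condition, per-species time-course data.

Rows are (condition, species, time_min, mean, sem) records of
background-corrected, normalized mean fluorescence intensities — the
form in which flow-cytometry time courses enter the fitting and
ROS-inference stages, whether measured or synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ExperimentDataset"]

_COLUMNS = ["condition", "species", "time_min", "mean", "sem"]

KNOWN_CONDITIONS = {"untreated", "IL4", "IL4+DPI", "IL4+H2O2", "H2O2",
                    "IL4+CHX", "IL4+MG132"}
KNOWN_SPECIES = {"pSTAT6", "STAT6", "SOCS3", "DCFDA"}


@dataclass
class ExperimentDataset:
    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in _COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        self.table = self.table[list(self.table.columns)].copy()

    def validate_for_fitting(self) -> None:
        """Fitted points need positive SEM and positive means (denominators)."""
        t = self.table
        if (t["sem"] <= 0).any():
            raise ValueError("all fitted points require sem > 0")
        if (t["mean"] <= 0).any():
            raise ValueError("all fitted points require mean > 0")
        unknown = set(t["condition"]) - KNOWN_CONDITIONS
        if unknown:
            raise ValueError(f"unknown conditions in dataset: {sorted(unknown)}")
        unknown = set(t["species"]) - KNOWN_SPECIES
        if unknown:
            raise ValueError(f"unknown species in dataset: {sorted(unknown)}")

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())

    @property
    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())

    def slice(self, condition: str | None = None, species: str | None = None
              ) -> pd.DataFrame:
        t = self.table
        if condition is not None:
            t = t[t["condition"] == condition]
        if species is not None:
            t = t[t["species"] == species]
        return t.sort_values("time_min").reset_index(drop=True)

    def series(self, condition: str, species: str
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        s = self.slice(condition, species)
        return (s["time_min"].to_numpy(float), s["mean"].to_numpy(float),
                s["sem"].to_numpy(float))

    def subset(self, conditions=None, species=None) -> "ExperimentDataset":
        t = self.table
        if conditions is not None:
            t = t[t["condition"].isin(conditions)]
        if species is not None:
            t = t[t["species"].isin(species)]
        return ExperimentDataset(t.reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "ExperimentDataset":
        return cls(pd.read_csv(path))
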