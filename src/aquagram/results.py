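"""Aquagram result container shared by both aquagram flavors."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AquagramResult"]


@dataclass
class AquagramResult:
    """Per (group, coordinate) aquagram values with 95% confidence limits.

    ``table`` is tidy with columns ``group, coordinate, value, lcl95,
    ucl95, n`` plus ``conditioned`` and ``mode`` for temperature-based
    results.  ``value`` is a dimensionless z-score (classic) or degrees
    Celsius (temperature mode); ill-conditioned coordinates carry NaN.
    """

    table: pd.DataFrame
    mode: str  # "classic" | "temperature"
    reference_info: dict = field(default_factory=dict)

    @property
    def groups(self) -> list:
        return list(self.table["group"].unique())

    @property
    def coordinates(self) -> list[str]:
        return list(self.table["coordinate"].unique())

    def values_for(self, group) -> pd.Series:
        sub = self.table[self.table["group"] == group]
        return sub.set_index("coordinate")["value"]

    def validate(self) -> None:
        t = self.table
        ok = t["value"].isna() | (
            (t["lcl95"] <= t["value"] + 1e-12) & (t["value"] <= t["ucl95"] + 1e-12)
        )
        if not ok.all():
            bad = t[~ok].iloc[0]
            raise AssertionError(
                f"confidence limits do not bracket the value for "
                f"group {bad['group']} {bad['coordinate']}"
            )
        keys = ["group", "mode"] if "mode" in t.columns else ["group"]
        counts = t.groupby(keys)["coordinate"].count()
        if not np.all(counts == len(self.coordinates)):
            raise AssertionError("groups do not all carry one row per coordinate")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")
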