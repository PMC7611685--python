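"""Replicate-structured gel-quantification tables.

The on-disk format is a plain CSV with one row per gel lane:

    condition,axis_kind,x,replicate,pct_supercoiled,pct_relaxed,pct_linear

``x`` is the exposure (Gy for ``axis_kind=dose``, hours for ``time``) and the
three percentage columns are the band shares measured within that lane.
Percentages may sum to slightly under 100 (gel quantification slack); rows
summing above 102 are rejected with the offending row number.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import ExposureAxis

__all__ = ["GelDataset", "read_gel_table", "write_gel_table", "GEL_TABLE_COLUMNS"]

GEL_TABLE_COLUMNS = [
    "condition",
    "axis_kind",
    "x",
    "replicate",
    "pct_supercoiled",
    "pct_relaxed",
    "pct_linear",
]

#: gel quantification slack: band percentages within a lane may overshoot
#: 100 by up to this many points before the row is rejected
PCT_SUM_TOLERANCE = 2.0

_SPECIES = ("supercoiled", "relaxed", "linear")


@dataclass
class GelDataset:
    """Band-percentage measurements versus one exposure axis.

    Parameters
    ----------
    table
        DataFrame with the :data:`GEL_TABLE_COLUMNS` schema (percent scale).
    axis
        The exposure axis shared by every row.
    condition
        Free-text label (agent, activity, plasmid concentration).
    """

    table: pd.DataFrame
    axis: ExposureAxis = ExposureAxis.DOSE
    condition: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in GEL_TABLE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"gel table missing columns: {missing}")
        self.table = self.table[GEL_TABLE_COLUMNS].reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        t = self.table
        for idx, row in t.iterrows():
            rowno = int(idx) + 1
            if not np.isfinite(row["x"]) or row["x"] < 0:
                raise ValueError(f"row {rowno}: exposure x must be >= 0, got {row['x']}")
            pcts = [row[f"pct_{sp}"] for sp in _SPECIES]
            for sp, p in zip(_SPECIES, pcts):
                if not np.isfinite(p) or p < 0:
                    raise ValueError(
                        f"row {rowno}: pct_{sp} must be a number >= 0, got {p}"
                    )
            total = float(sum(pcts))
            if total > 100.0 + PCT_SUM_TOLERANCE:
                raise ValueError(
                    f"row {rowno}: band percentages sum to {total:.6g} > "
                    f"{100 + PCT_SUM_TOLERANCE}"
                )
            if int(row["replicate"]) < 1:
                raise ValueError(f"row {rowno}: replicate must be >= 1")
        kinds = set(t["axis_kind"].unique())
        if kinds - {self.axis.value}:
            raise ValueError(
                f"axis_kind column contains {sorted(kinds)} but dataset axis is "
                f"{self.axis.value!r}; mixing exposure axes is not allowed"
            )

    # ------------------------------------------------------------------ #

    @property
    def n_lanes(self) -> int:
        return len(self.table)

    @property
    def exposures(self) -> np.ndarray:
        """Distinct exposure values, sorted."""
        return np.sort(self.table["x"].unique())

    def fractions(self) -> pd.DataFrame:
        """Per-lane species fractions (percent / 100) with the exposure."""
        t = self.table
        return pd.DataFrame(
            {
                "x": t["x"].to_numpy(float),
                "supercoiled": t["pct_supercoiled"].to_numpy(float) / 100.0,
                "relaxed": t["pct_relaxed"].to_numpy(float) / 100.0,
                "linear": t["pct_linear"].to_numpy(float) / 100.0,
            }
        )

    def summarize_replicates(self) -> pd.DataFrame:
        """Per-exposure mean and sample SD (ddof=1) for each species, in percent.

        SD is 0 where only one replicate exists; the fitting layer imposes a
        weight floor so such points cannot receive infinite weight.
        """
        if self.n_lanes == 0:
            raise ValueError("empty dataset")
        t = self.table
        rows = []
        for x, grp in t.groupby("x", sort=True):
            rec: dict[str, float] = {"x": float(x), "n": len(grp)}
            for sp in _SPECIES:
                vals = grp[f"pct_{sp}"].to_numpy(float)
                rec[f"mean_{sp}"] = float(np.mean(vals))
                rec[f"sd_{sp}"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            rows.append(rec)
        return pd.DataFrame(rows)


def read_gel_table(path: str | Path | io.TextIOBase) -> GelDataset:
    """Read a gel-quantification CSV into a validated :class:`GelDataset`."""
    df = pd.read_csv(path)
    got = list(df.columns)
    if got != GEL_TABLE_COLUMNS:
        raise ValueError(
            f"malformed header: expected {GEL_TABLE_COLUMNS}, got {got}"
        )
    kinds = df["axis_kind"].unique()
    if len(kinds) != 1 or kinds[0] not in ("dose", "time"):
        raise ValueError(
            f"axis_kind must be uniformly 'dose' or 'time', got {sorted(map(str, kinds))}"
        )
    axis = ExposureAxis(kinds[0])
    condition = str(df["condition"].iloc[0]) if len(df) else ""
    return GelDataset(table=df, axis=axis, condition=condition)


def write_gel_table(data: GelDataset, path: str | Path | io.TextIOBase) -> None:
    """Write the dataset back to CSV in the fixed column order (byte-stable)."""
    data.table[GEL_TABLE_COLUMNS].to_csv(path, index=False)
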