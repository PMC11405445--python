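"""National burden aggregation: attributable cost x incidence.

Per-infection mean attributable costs (in a common currency year) are
multiplied by central / low / high national incident-case counts, then
summed into device-associated and nondevice subtotals and a grand total.
Burden counts are carried rounded to the nearest 100 cases, matching the
convention of the published incidence surveys this table layout follows;
money is kept at full precision and rounded only when printed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LEVELS = ("central", "low", "high")


def round_to_100(x: float) -> int:
    """Round to the nearest 100, ties away from zero."""
    return int(np.sign(x) * np.floor(np.abs(x) / 100.0 + 0.5) * 100)


def split_burden(total_burden: float, proportion: float) -> tuple[int, int]:
    """Split a total incidence count into device and nondevice parts.

    ``proportion`` is the device-associated share (e.g. the
    ventilator-associated fraction of all pneumonias).  Both parts are
    rounded to the nearest 100 from the *unrounded* intermediates — the
    parts are never derived from each other.
    """
    if not 0 <= proportion <= 1:
        raise ValueError(f"proportion must lie in [0, 1], got {proportion}")
    device_raw = total_burden * proportion
    return round_to_100(device_raw), round_to_100(total_burden - device_raw)


def validate_burden(burden: pd.DataFrame) -> None:
    """Check 0 <= low <= central <= high and multiples-of-100 counts."""
    for col in ("burden_central", "burden_low", "burden_high"):
        if (burden[col] < 0).any():
            raise ValueError(f"negative counts in {col}")
        if (burden[col] % 100 != 0).any():
            raise ValueError(f"{col} contains counts not rounded to the nearest 100")
    bad = burden.loc[
        ~(
            (burden["burden_low"] <= burden["burden_central"])
            & (burden["burden_central"] <= burden["burden_high"])
        )
    ]
    if len(bad):
        raise ValueError(f"burden ordering low<=central<=high violated for: {list(bad['infection'])}")


@dataclass
class NationalCostTable:
    """Per-infection and aggregate national cost estimates.

    ``per_type`` has one row per infection with the three burden columns
    and ``total_central/low/high``; ``subtotals`` and ``grand`` map each
    burden level to summed costs.
    """

    per_type: pd.DataFrame
    subtotals: dict[str, dict[str, float]]
    grand: dict[str, float]
    cost_year: int
    burden_year: int | None = None

    def __post_init__(self) -> None:
        for level in LEVELS:
            total = sum(g[level] for g in self.subtotals.values())
            if not np.isclose(total, self.grand[level], rtol=0, atol=1e-6):
                raise ValueError(f"grand total does not equal sum of subtotals at {level}")


def national_totals(
    attributable: pd.DataFrame,
    burden: pd.DataFrame,
    cost_year: int = 2017,
    burden_year: int | None = None,
) -> NationalCostTable:
    """Combine per-type attributable costs with a burden table.

    ``attributable`` needs columns ``infection``, ``cost`` and
    ``currency_year`` (all rows must share ``cost_year``); ``burden``
    needs ``infection``, ``group`` and the three burden columns.  A
    burden type with no cost estimate is an error naming the gaps; a
    zero-burden row is kept (zero cost).
    """
    years = set(attributable["currency_year"])
    if years != {cost_year}:
        raise ValueError(
            f"refusing to aggregate mixed currency years {sorted(years)} into {cost_year}$"
        )
    validate_burden(burden)
    missing = set(burden["infection"]) - set(attributable["infection"])
    if missing:
        raise ValueError(f"no attributable cost estimate for: {sorted(missing)}")
    merged = burden.merge(
        attributable[["infection", "cost"]], on="infection", how="left"
    )
    for level in LEVELS:
        merged[f"total_{level}"] = merged["cost"] * merged[f"burden_{level}"]
    subtotals = {
        group: {level: float(sub[f"total_{level}"].sum()) for level in LEVELS}
        for group, sub in merged.groupby("group")
    }
    grand = {level: float(merged[f"total_{level}"].sum()) for level in LEVELS}
    return NationalCostTable(
        per_type=merged,
        subtotals=subtotals,
        grand=grand,
        cost_year=cost_year,
        burden_year=burden_year,
    )


def shares(table: NationalCostTable, level: str = "central") -> dict:
    """Nondevice share of the grand total and within-group type shares (%)."""
    grand = table.grand[level]
    if not grand > 0:
        raise ValueError("grand total must be positive to compute shares")
    nondevice = table.subtotals.get("nondevice", {}).get(level, 0.0)
    within: dict[str, float] = {}
    for _, row in table.per_type.iterrows():
        sub = table.subtotals[row["group"]][level]
        within[row["infection"]] = (
            100.0 * row[f"total_{level}"] / sub if sub > 0 else np.nan
        )
    return {
        "nondevice_share_percent": 100.0 * nondevice / grand,
        "within_group_percent": within,
    }
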