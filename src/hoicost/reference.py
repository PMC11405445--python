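"""Bundled reference inputs.

Machine-readable transcriptions of the published LRTI artifacts — the
infection-code catalog, the stage-1 median-regression coefficients for
the 2011 (ICD-9) and 2016 (ICD-10) study years, the three-group
univariate means, and the two national burden/cost tables.  These are
*inputs* for reproduction mode and fixtures for tests; nothing here is
computed by this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cohorts import CodeCatalog, load_catalog
from .stage1 import CoefficientSet

YEAR_TO_DIALECT = {2011: "ICD9", 2016: "ICD10"}


def _data_path(name: str):
    return resources.files("hoicost.data").joinpath(name)


def load_bundled_catalog() -> CodeCatalog:
    """The shipped catalog: published LRTI codes plus synthetic toy types."""
    with resources.as_file(_data_path("catalog.yaml")) as p:
        return load_catalog(p)


def load_lrti_coefficients(year: int) -> CoefficientSet:
    """Published stage-1 coefficient set for LRTI in the given study year."""
    df = pd.read_csv(_data_path("stage1_lrti.csv"))
    sub = df.loc[df["year"] == year]
    if sub.empty:
        raise KeyError(f"no bundled coefficients for year {year}")
    est = dict(zip(sub["term"], sub["estimate"]))
    return CoefficientSet(
        estimates=est,
        infection="lrti",
        year=year,
        n_fit=0,
        se=dict(zip(sub["term"], sub["se"])),
        ci_low=dict(zip(sub["term"], sub["ci_low"])),
        ci_high=dict(zip(sub["term"], sub["ci_high"])),
    )


def load_group_means(year: int) -> pd.DataFrame:
    """Three-group univariate means for LRTI, indexed by group."""
    df = pd.read_csv(_data_path("group_means_lrti.csv"))
    sub = df.loc[df["year"] == year].set_index("group")
    if sub.empty:
        raise KeyError(f"no bundled group means for year {year}")
    return sub


def load_national_table(year: int) -> dict:
    """Reference national table split into per-type rows and printed totals.

    Returns ``{"per_type": DataFrame, "subtotals": {group: {level: $}},
    "grand": {level: $}, "burden_subtotals": ..., "cost_year": 2017}``.
    """
    name = {2011: "national_2011.csv", 2016: "national_2016.csv"}[year]
    df = pd.read_csv(_data_path(name))
    per_type = df.loc[~df["infection"].isin(["SUBTOTAL", "ALL"])].reset_index(drop=True)
    sub_rows = df.loc[df["infection"] == "SUBTOTAL"].set_index("group")
    all_row = df.loc[df["infection"] == "ALL"].iloc[0]
    levels = ("central", "low", "high")
    return {
        "per_type": per_type,
        "subtotals": {
            g: {lv: float(sub_rows.loc[g, f"total_{lv}_2017"]) for lv in levels}
            for g in sub_rows.index
        },
        "grand": {lv: float(all_row[f"total_{lv}_2017"]) for lv in levels},
        "burden_subtotals": {
            g: {lv: float(sub_rows.loc[g, f"burden_{lv}"]) for lv in levels}
            for g in sub_rows.index
        },
        "burden_grand": {lv: float(all_row[f"burden_{lv}"]) for lv in levels},
        "cost_year": 2017,
    }


def implied_inflation_factors(year: int) -> pd.Series:
    """Per-row ratio of 2017$ to year$ attributable costs in the reference
    table (a regression-free check on the single inflation factor)."""
    per_type = load_national_table(year)["per_type"]
    return per_type["cost_2017"] / per_type["cost_year"]


def reference_national_totals(year: int):
    """Reproduction mode: recompute the national table from the printed
    (rounded) per-type attributable costs and burdens."""
    from .burden import national_totals

    ref = load_national_table(year)
    per_type = ref["per_type"]
    attributable = pd.DataFrame(
        {
            "infection": per_type["infection"],
            "cost": per_type["cost_2017"],
            "currency_year": 2017,
        }
    )
    burden = per_type[
        ["infection", "group", "burden_central", "burden_low", "burden_high"]
    ]
    return national_totals(
        attributable, burden, cost_year=2017, burden_year=2011 if year == 2011 else 2015
    )
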