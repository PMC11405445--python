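"""Descriptive group comparisons and scenario arithmetic.

The univariate tables compare cost, LOS and the other model covariates
across the principal, secondary and matched no-infection groups; the
analogy rests on the secondary group being the most expensive and
longest-staying of the three, so that ordering is computed and flagged
explicitly.  Scenario helpers cover the professional-fee uplift applied
to national totals and simple cross-study ratio comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohorts import CohortTriple

SUMMARY_VARIABLES = [
    "cost",
    "los",
    "ndx",
    "npr",
    "age",
    "severity",
    "risk_mortality",
    "wage_index",
]


def _mode_dollar(values: pd.Series) -> float:
    """Mode of dollar-rounded values; ties broken by the smallest value."""
    rounded = values.round(0).astype(np.int64)
    counts = rounded.value_counts()
    top = counts.max()
    return float(min(counts.index[counts == top]))


def univariate_summary(
    triple: CohortTriple, variables: list[str] | None = None
) -> pd.DataFrame:
    """Per-group, per-variable n / mean / median / mode / min / max / SD.

    The mode is computed on whole-dollar-rounded values (meaningful for
    cost; harmless for the integer covariates).  Raises if any group is
    empty, naming it.
    """
    groups = {
        "principal": triple.principal,
        "secondary": triple.secondary,
        "no_infection": triple.controls,
    }
    for name, df in groups.items():
        if len(df) == 0:
            raise ValueError(f"group {name!r} is empty")
    variables = variables or SUMMARY_VARIABLES
    rows = []
    for gname, df in groups.items():
        for var in variables:
            if var not in df.columns:
                continue
            v = pd.to_numeric(df[var])
            rows.append(
                {
                    "group": gname,
                    "variable": var,
                    "n": len(v),
                    "mean": float(v.mean()),
                    "median": float(v.median()),
                    "mode": _mode_dollar(v),
                    "min": float(v.min()),
                    "max": float(v.max()),
                    "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def ordering_holds(summary: pd.DataFrame) -> bool:
    """True iff the secondary group's mean cost and mean LOS strictly
    exceed both the principal and no-infection groups' (the pattern the
    analogy requires)."""
    means = summary.set_index(["variable", "group"])["mean"]
    for var in ("cost", "los"):
        sec = means[(var, "secondary")]
        if not (sec > means[(var, "principal")] and sec > means[(var, "no_infection")]):
            return False
    return True


def professional_fee_uplift(total: float, rate: float = 0.15) -> float:
    """Crude uplift for physician/professional fees excluded from
    facility discharge costs: ``total x (1 + rate)``."""
    if rate < 0:
        raise ValueError("uplift rate must be >= 0")
    return total * (1.0 + rate)


def billions_3sf(amount: float) -> float:
    """Express a dollar amount in billions at three significant figures."""
    b = amount / 1e9
    if b == 0:
        return 0.0
    from math import floor, log10

    k = 2 - int(floor(log10(abs(b))))
    return round(b, k)


def compare_totals(this_total: float, other_total: float) -> dict[str, int]:
    """Ratio comparison of two study totals, to the nearest percent."""
    if not other_total > 0:
        raise ValueError("comparison total must be positive")
    ratio = this_total / other_total
    return {
        "percent_of_other": round(100.0 * ratio),
        "percent_above_other": round(100.0 * (ratio - 1.0)),
    }
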