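"""Stage 2: transfer of the analog cost model to the hospital-onset group.

The attributable cost of a hospital-onset infection is predicted for each
secondary-diagnosis record by the stage-1 linear model, with one
substitution: the record's own LOS is replaced by the *attributable LOS*,
the mean LOS of the principal-diagnosis cohort (the stay length the
infection itself would command when it is the reason for admission).
All other covariates — treatment-intensity counts, age, severity and
mortality-risk indices, facility dummies, wage index — come from the
secondary record.  The estimate for the infection type is the average of
these per-record predictions; because the model is linear this equals
the prediction at the secondary cohort's covariate means.

The mean splits exactly into a LOS component (``b_los x attributable
LOS``) and a non-LOS remainder (intercept plus all other covariate
terms), mirroring how treatment intensity and facility cost structure
contribute beyond the extra bed days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stage1 import CoefficientSet


@dataclass
class AttributableCostEstimate:
    """Mean attributable cost for one infection type and year."""

    infection: str
    mean_attributable_cost: float
    los_component: float
    other_component: float
    attributable_los: float
    n_secondary: int
    currency_year: int | None
    per_record: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_secondary < 1:
            raise ValueError("estimate requires at least one secondary record")
        if not self.attributable_los > 0:
            raise ValueError("attributable LOS must be positive")
        gap = abs(self.los_component + self.other_component - self.mean_attributable_cost)
        if gap > 0.005:  # decomposition must be exact to the cent pre-rounding
            raise ValueError(f"decomposition mismatch of ${gap:.4f}")


def attributable_cost_record(
    coeffs: CoefficientSet, attributable_los: float, record: pd.Series | dict
) -> float:
    """Stage-2 prediction for one secondary record (record LOS ignored)."""
    rec = dict(record)
    missing = [c for c in coeffs.covariates if c != "los" and c not in rec]
    if missing:
        raise KeyError(f"record missing covariates: {missing}")
    total = coeffs.estimates["intercept"]
    for cov in coeffs.covariates:
        x = attributable_los if cov == "los" else float(rec[cov])
        total += coeffs.estimates[cov] * x
    return float(total)


def predict_secondary(
    coeffs: CoefficientSet, attributable_los: float, secondary: pd.DataFrame
) -> tuple[np.ndarray, int]:
    """Vectorized per-record predictions; records with missing covariates
    are excluded and counted."""
    needed = [c for c in coeffs.covariates if c != "los"]
    ok = pd.Series(True, index=secondary.index)
    for c in needed:
        ok &= pd.to_numeric(secondary[c], errors="coerce").notna()
    usable = secondary.loc[ok]
    out = np.full(len(usable), coeffs.estimates["intercept"], dtype=float)
    for cov in coeffs.covariates:
        if cov == "los":
            out += coeffs.estimates[cov] * attributable_los
        else:
            out += coeffs.estimates[cov] * usable[cov].to_numpy(dtype=float)
    return out, int((~ok).sum())


def mean_attributable_cost(
    coeffs: CoefficientSet,
    principal: pd.DataFrame,
    secondary: pd.DataFrame,
    currency_year: int | None = None,
    keep_per_record: bool = False,
) -> AttributableCostEstimate:
    """Average stage-2 prediction over the secondary cohort.

    Attributable LOS is the principal cohort's mean LOS.  Negative
    per-record predictions are retained: the target is the mean, and
    flooring would bias it upward.
    """
    if len(principal) == 0 or len(secondary) == 0:
        raise ValueError("both cohorts must be non-empty")
    attributable_los = float(principal["los"].mean())
    preds, n_excluded = predict_secondary(coeffs, attributable_los, secondary)
    if len(preds) == 0:
        raise ValueError("no secondary records with complete covariates")
    mean = float(preds.mean())
    los_component = coeffs.estimates["los"] * attributable_los
    return AttributableCostEstimate(
        infection=coeffs.infection,
        mean_attributable_cost=mean,
        los_component=los_component,
        other_component=mean - los_component,
        attributable_los=attributable_los,
        n_secondary=len(preds),
        currency_year=currency_year if currency_year is not None else coeffs.year,
        per_record=preds if keep_per_record else None,
    )


def los_decomposition(
    coeffs: CoefficientSet, attributable_los: float, mean_cost: float | None = None
) -> dict[str, float]:
    """LOS / non-LOS split of a mean attributable cost.

    With ``mean_cost`` given (e.g. a published estimate), the non-LOS
    remainder is ``mean_cost - b_los * attributable_los``.
    """
    los_component = coeffs.estimates["los"] * attributable_los
    out = {"los_component": los_component}
    if mean_cost is not None:
        out["other_component"] = mean_cost - los_component
    return out


def wage_counterfactual(
    estimate: AttributableCostEstimate,
    coeffs: CoefficientSet,
    mean_secondary_wage: float,
    new_wage: float,
) -> AttributableCostEstimate:
    """Re-price the estimate at a different area wage index.

    By linearity, replacing every record's wage index with ``new_wage``
    shifts the mean by ``b_wage x (new_wage - mean_secondary_wage)``.
    """
    if not new_wage > 0:
        raise ValueError("new wage index must be positive")
    delta = coeffs.estimates["wage_index"] * (new_wage - mean_secondary_wage)
    return AttributableCostEstimate(
        infection=estimate.infection,
        mean_attributable_cost=estimate.mean_attributable_cost + delta,
        los_component=estimate.los_component,
        other_component=estimate.other_component + delta,
        attributable_los=estimate.attributable_los,
        n_secondary=estimate.n_secondary,
        currency_year=estimate.currency_year,
    )
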