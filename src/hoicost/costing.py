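"""Charge-to-cost conversion and currency-year inflation.

Hospital discharge datasets report billed *charges*; resource *costs* are
recovered by multiplying with a facility-level cost-to-charge ratio (CCR).
Money is moved between currency years with user-supplied multiplicative
price-index factors (the defaults are the hospital producer-price factors
implied by the bundled reference tables).  Amounts are kept at full float
precision internally; rounding to whole dollars happens only at report
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default hospital price-index factors, derived as the common ratio of the
#: paired (year$, 2017$) attributable-cost columns of the bundled national
#: reference tables.  Override via :class:`PriceIndexTable`.
DEFAULT_FACTORS: dict[tuple[int, int], float] = {
    (2011, 2017): 1.0921,
    (2016, 2017): 1.0226,
}


def charges_to_cost(total_charges: float, ccr: float) -> float:
    """Convert billed charges to estimated cost: ``charges * ccr``.

    Raises ``ValueError`` for non-positive or missing CCR and negative
    charges; record-level screening of whole tables lives in
    :func:`add_cost_column`.
    """
    if ccr is None or not np.isfinite(ccr) or ccr <= 0:
        raise ValueError(f"cost-to-charge ratio must be positive, got {ccr!r}")
    if total_charges < 0:
        raise ValueError(f"charges must be non-negative, got {total_charges!r}")
    return total_charges * ccr


def add_cost_column(
    records: pd.DataFrame,
    charges_col: str = "total_charges",
    ccr_col: str = "ccr",
    cost_col: str = "cost",
) -> tuple[pd.DataFrame, int]:
    """Attach ``cost = charges * ccr``, excluding records with unusable CCR.

    Returns the frame restricted to valid records plus the count of
    excluded rows (missing/non-positive CCR or negative charges).
    """
    ccr = pd.to_numeric(records[ccr_col], errors="coerce")
    charges = pd.to_numeric(records[charges_col], errors="coerce")
    valid = ccr.notna() & (ccr > 0) & charges.notna() & (charges >= 0)
    out = records.loc[valid].copy()
    out[cost_col] = out[charges_col] * out[ccr_col]
    return out, int((~valid).sum())


@dataclass(frozen=True)
class PriceIndexTable:
    """Multiplicative price-index factors keyed by (from_year, to_year)."""

    factors: dict[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_FACTORS)
    )
    provenance: str = "implied by bundled reference tables"

    def __post_init__(self) -> None:
        for pair, f in self.factors.items():
            if not f > 0:
                raise ValueError(f"price factor for {pair} must be > 0, got {f}")

    def factor(self, from_year: int, to_year: int) -> float:
        if from_year == to_year:
            return 1.0
        try:
            return self.factors[(from_year, to_year)]
        except KeyError:
            raise KeyError(
                f"no price-index factor for {from_year}->{to_year}; "
                "supply one via PriceIndexTable(factors=...)"
            ) from None

    def inflate(self, amount: float, from_year: int, to_year: int) -> float:
        """Express ``amount`` (from_year dollars) in to_year dollars."""
        return amount * self.factor(from_year, to_year)


def inflate(
    amount: float,
    from_year: int,
    to_year: int,
    table: PriceIndexTable | None = None,
) -> float:
    """Module-level convenience wrapper around :meth:`PriceIndexTable.inflate`."""
    return (table or PriceIndexTable()).inflate(amount, from_year, to_year)
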