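"""Scenario arithmetic: wage counterfactual, fee uplift, cross-study ratios.

Writes results/scenarios.json with the Washington-State wage-index
counterfactual for 2016 LRTI, the 15% professional-fee uplift of both
national totals, and ratio comparisons of the four-infection subtotal
against two published meta-analytic totals.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from _shared import RESULTS  # noqa: E402

from hoicost import (  # noqa: E402
    billions_3sf,
    compare_totals,
    professional_fee_uplift,
    wage_counterfactual,
)
from hoicost.reference import (  # noqa: E402
    load_group_means,
    load_lrti_coefficients,
    load_national_table,
)
from hoicost.stage2 import AttributableCostEstimate  # noqa: E402

RESULTS.mkdir(exist_ok=True)
coeffs = load_lrti_coefficients(2016)
a_los = load_group_means(2016).loc["principal", "los_mean"]
est = AttributableCostEstimate(
    infection="lrti", mean_attributable_cost=12_013.0,
    los_component=coeffs.estimates["los"] * a_los,
    other_component=12_013.0 - coeffs.estimates["los"] * a_los,
    attributable_los=a_los,
    n_secondary=int(load_group_means(2016).loc["secondary", "n"]),
    currency_year=2016,
)
adjusted = wage_counterfactual(est, coeffs, mean_secondary_wage=0.9950, new_wage=1.127)

totals = {
    year: sum(g["central"] for g in load_national_table(year)["subtotals"].values())
    for year in (2011, 2016)
}
out = {
    "wage_adjusted_lrti_2016": round(adjusted.mean_attributable_cost),
    "uplifted_totals_billion": {
        str(y): billions_3sf(professional_fee_uplift(t, 0.15)) for y, t in totals.items()
    },
    "four_infection_subtotal_vs_higher_study": compare_totals(8.7e9, 10.1e9),
    "four_infection_subtotal_vs_lower_study": compare_totals(8.7e9, 7.2e9),
}
(RESULTS / "scenarios.json").write_text(json.dumps(out, indent=2))
print(json.dumps(out, indent=2))
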