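"""Stage-2 attribution: formula, decomposition, linearity, counterfactual."""

import numpy as np
import pandas as pd
import pytest

from hoicost import (
    CoefficientSet,
    attributable_cost_record,
    mean_attributable_cost,
    wage_counterfactual,
)
from hoicost.reference import load_group_means, load_lrti_coefficients
from hoicost.stage1 import DEFAULT_COVARIATES

ZERO = {t: 0.0 for t in ["intercept"] + DEFAULT_COVARIATES}


def _record(**kw) -> dict:
    base = dict(
        ndx=0, npr=0, urban_teaching=0, small_bedsize=0, age=0,
        severity=0, risk_mortality=0, wage_index=0.0, los=999,
    )
    base.update(kw)
    return base


def test_los_only_model_reproduces_published_los_component():
    coeffs = CoefficientSet(estimates={**ZERO, "los": 1324.03})
    value = attributable_cost_record(coeffs, 3.83, _record())
    assert round(value) == 5_071


def test_all_zero_coefficients_predict_zero():
    coeffs = CoefficientSet(estimates=dict(ZERO))
    assert attributable_cost_record(coeffs, 3.83, _record(ndx=30, age=90)) == 0.0


def test_prediction_matches_hand_computed_dot_product():
    """Independent arithmetic oracle on the published 2011 coefficients."""
    coeffs = load_lrti_coefficients(2011)
    rec = _record(ndx=13, npr=2, age=54, severity=3, risk_mortality=2,
                  urban_teaching=1, small_bedsize=0, wage_index=0.99)
    # term-by-term sum, written out independently of the implementation
    expected = (
        -4180.48
        + 1324.030 * 3.83
        + 89.3800 * 13
        + 1916.808 * 2
        + 272.0654 * 1
        + (-551.727) * 0
        + 2.3119 * 54
        + 150.6755 * 3
        + 103.7112 * 2
        + 4016.947 * 0.99
    )
    assert attributable_cost_record(coeffs, 3.83, rec) == pytest.approx(expected, abs=1e-9)


def test_missing_covariate_is_reported():
    coeffs = CoefficientSet(estimates=dict(ZERO))
    with pytest.raises(KeyError, match="wage_index"):
        attributable_cost_record(coeffs, 3.0, {"ndx": 1})


def _cohorts_from_means(means_principal, means_secondary, n_sec=7):
    principal = pd.DataFrame([{**means_principal} for _ in range(5)])
    secondary = pd.DataFrame([{**means_secondary} for _ in range(n_sec)])
    return principal, secondary


def test_single_secondary_record_mean_is_that_record():
    coeffs = CoefficientSet(estimates={**ZERO, "los": 100.0, "ndx": 10.0})
    principal = pd.DataFrame([_record(los=4)])
    secondary = pd.DataFrame([_record(ndx=3, los=20)])
    est = mean_attributable_cost(coeffs, principal, secondary)
    assert est.mean_attributable_cost == pytest.approx(100.0 * 4 + 10.0 * 3)
    assert est.attributable_los == 4.0


def test_decomposition_sums_exactly(lrti_triple):
    coeffs = load_lrti_coefficients(2011)
    est = mean_attributable_cost(coeffs, lrti_triple.principal, lrti_triple.secondary)
    assert est.los_component + est.other_component == pytest.approx(
        est.mean_attributable_cost, abs=1e-9
    )
    assert est.n_secondary == len(lrti_triple.secondary)


def test_mean_prediction_equals_prediction_at_mean_covariates(lrti_triple):
    """Linearity: averaging per-record predictions == predicting at the
    secondary cohort's covariate means (1e-6 relative)."""
    coeffs = load_lrti_coefficients(2011)
    est = mean_attributable_cost(coeffs, lrti_triple.principal, lrti_triple.secondary)
    means = {c: float(lrti_triple.secondary[c].mean()) for c in DEFAULT_COVARIATES}
    at_mean = attributable_cost_record(coeffs, est.attributable_los, means)
    assert est.mean_attributable_cost == pytest.approx(at_mean, rel=1e-6)


def test_identical_cohort_means_reduce_to_stage1_fitted_value():
    coeffs = CoefficientSet(estimates={**ZERO, "intercept": 5.0, "los": 2.0, "ndx": 1.0})
    row = _record(los=6, ndx=4)
    principal, secondary = _cohorts_from_means(row, row)
    est = mean_attributable_cost(coeffs, principal, secondary)
    assert est.mean_attributable_cost == pytest.approx(5.0 + 2.0 * 6 + 1.0 * 4)


def test_reconstructed_mean_matches_published_2011_estimate():
    """At the published secondary-group covariate means, the stage-2 mean
    lands within 3% of the published $11,301 at plausible facility-dummy
    shares, and within 6% even at the extreme share vertices (the
    all-small-bedsize corner alone reaches 5.4%)."""
    coeffs = load_lrti_coefficients(2011)
    sec = load_group_means(2011).loc["secondary"]
    for urban, small in [(0, 0), (1, 0), (0, 1), (1, 1), (0.55, 0.2)]:
        rec = dict(
            ndx=sec["ndx_mean"], npr=sec["npr_mean"], age=sec["age_mean"],
            severity=sec["severity_mean"], risk_mortality=sec["risk_mortality_mean"],
            wage_index=sec["wage_index_mean"], urban_teaching=urban,
            small_bedsize=small, los=0,
        )
        value = attributable_cost_record(coeffs, 3.83, rec)
        tol = 0.03 if (urban, small) in [(0, 0), (1, 0), (0.55, 0.2)] else 0.06
        assert abs(value - 11_301) / 11_301 < tol


def test_positive_coefficient_covariates_increase_cost_monotonically():
    coeffs = load_lrti_coefficients(2011)
    base = _record(ndx=10, npr=2, age=50, severity=2, risk_mortality=2,
                   urban_teaching=0, small_bedsize=0, wage_index=1.0)
    v0 = attributable_cost_record(coeffs, 3.83, base)
    for cov in ("ndx", "npr", "age", "severity", "risk_mortality", "wage_index"):
        assert coeffs.estimates[cov] > 0 or cov in ()  # 2011: all positive
        bumped = dict(base)
        bumped[cov] += 1
        assert attributable_cost_record(coeffs, 3.83, bumped) >= v0


class TestWageCounterfactual:
    def _estimate(self):
        coeffs = load_lrti_coefficients(2016)
        est_mean = 12_013.0  # published 2016 mean, 2016$
        los_comp = coeffs.estimates["los"] * 4.24
        from hoicost.stage2 import AttributableCostEstimate

        est = AttributableCostEstimate(
            infection="lrti", mean_attributable_cost=est_mean,
            los_component=los_comp, other_component=est_mean - los_comp,
            attributable_los=4.24, n_secondary=167_961, currency_year=2016,
        )
        return est, coeffs

    def test_published_washington_state_scenario(self):
        est, coeffs = self._estimate()
        adjusted = wage_counterfactual(est, coeffs, mean_secondary_wage=0.9950, new_wage=1.127)
        assert round(adjusted.mean_attributable_cost) == 12_587

    def test_unchanged_wage_is_identity(self):
        est, coeffs = self._estimate()
        adjusted = wage_counterfactual(est, coeffs, 0.9950, 0.9950)
        assert adjusted.mean_attributable_cost == est.mean_attributable_cost

    def test_zero_wage_coefficient_is_inert(self):
        est, coeffs = self._estimate()
        coeffs = CoefficientSet(estimates={**coeffs.estimates, "wage_index": 0.0})
        adjusted = wage_counterfactual(est, coeffs, 0.9950, 2.0)
        assert adjusted.mean_attributable_cost == est.mean_attributable_cost

    def test_equals_rerunning_every_record(self, lrti_triple):
        coeffs = load_lrti_coefficients(2011)
        est = mean_attributable_cost(coeffs, lrti_triple.principal, lrti_triple.secondary)
        new_wage = 1.127
        replaced = lrti_triple.secondary.assign(wage_index=new_wage)
        direct = mean_attributable_cost(coeffs, lrti_triple.principal, replaced)
        adjusted = wage_counterfactual(
            est, coeffs, float(lrti_triple.secondary["wage_index"].mean()), new_wage
        )
        assert adjusted.mean_attributable_cost == pytest.approx(
            direct.mean_attributable_cost, rel=1e-9
        )
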