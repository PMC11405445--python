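"""Synthetic hospital-discharge data with known cost structure.

The generator emulates the statistical shape of an all-payer inpatient
discharge file (one row per hospitalization: ordered diagnosis codes,
procedure codes, LOS, charges, cost-to-charge ratio, patient and facility
covariates) so that every downstream stage — cohort construction, median
regression, attribution, burden aggregation — is testable without access
to restricted data.

Ground truth: each record's cost is ``max(floor, (b'x) * eps)`` where
``b`` is a configured coefficient vector over the nine model covariates
plus intercept, and ``eps`` is a multiplicative log-normal disturbance
with median exactly one.  Median-one noise makes the conditional median
of cost equal the linear index, so median regression on the principal
cohort recovers ``b`` — the generator's coefficients are the oracle for
stage-1 parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohorts import DX_CAPACITY

#: Procedure-code field capacity in generated files.
PR_CAPACITY = 10

#: Default clamp for degenerate (non-positive) generated costs, in dollars.
DEFAULT_COST_FLOOR = 31.0

#: Default scale (log-SD) of the multiplicative cost disturbance.  Small
#: enough that median-regression sampling error at n ~ 10^4 principal
#: records stays under 5% of even the smallest model coefficient (the
#: generator's design goal is recoverability); the log-normal shape keeps
#: the disturbance right-skewed.  Raise it to stress-test the fit.
DEFAULT_NOISE_SIGMA = 0.02

# Invented code pools; disjoint from every bundled catalog code.
_UNDERLYING_DX = [f"D{i:02d}" for i in range(1, 13)]  # principal-dx strata
_FILLER_DX = [f"F{i:03d}" for i in range(1, 81)]  # secondary-field padding
_FILLER_PR = [f"Q{i:02d}" for i in range(1, 31)]  # procedure padding

MODEL_TERMS = [
    "intercept",
    "los",
    "ndx",
    "npr",
    "urban_teaching",
    "small_bedsize",
    "age",
    "severity",
    "risk_mortality",
    "wage_index",
]


@dataclass(frozen=True)
class CovariateModel:
    """Marginal covariate distributions for one patient group.

    Counts (LOS, diagnosis and procedure codes) are shifted Poisson with
    the stated mean and hard minimum; the 1-4 APR-DRG severity and
    mortality-risk indices are ``1 + Binomial(3, (mean-1)/3)`` (exact
    mean, correct support); age and wage index are clipped normals.
    """

    los_mean: float
    ndx_mean: float
    npr_mean: float
    age_mean: float
    severity_mean: float
    risk_mean: float
    urban_teaching_share: float
    small_bedsize_share: float
    wage_mean: float
    wage_sd: float = 0.16
    age_sd: float = 20.0
    los_min: int = 1
    ndx_min: int = 1

    def shifted(self, shift: "SecondaryShift") -> "CovariateModel":
        return dataclasses.replace(
            self,
            los_mean=self.los_mean + shift.los,
            ndx_mean=self.ndx_mean + shift.ndx,
            npr_mean=self.npr_mean + shift.npr,
            age_mean=self.age_mean + shift.age,
            severity_mean=min(4.0, self.severity_mean + shift.severity),
            risk_mean=min(4.0, self.risk_mean + shift.risk),
            wage_mean=self.wage_mean + shift.wage_index,
            los_min=3,
            ndx_min=2,
        )


@dataclass(frozen=True)
class SecondaryShift:
    """Additive covariate inflation for secondary-infection records.

    Emulates the observed pattern that hospitalizations carrying an
    infection as a secondary diagnosis are longer, more heavily coded and
    sicker than principal-infection stays.  LOS and code-count shifts
    must be strictly positive so the ordering is built in.
    """

    los: float
    ndx: float
    npr: float = 0.0
    age: float = 0.0
    severity: float = 0.0
    risk: float = 0.0
    wage_index: float = 0.0

    def __post_init__(self) -> None:
        if self.los <= 0 or self.ndx <= 0:
            raise ValueError(
                "secondary shift must strictly increase LOS and diagnosis counts"
            )


@dataclass(frozen=True)
class InfectionMix:
    """Per-type probability that a record is principal / secondary infected."""

    principal: float
    secondary: float

    def __post_init__(self) -> None:
        if self.principal < 0 or self.secondary < 0:
            raise ValueError("infection-mix probabilities must be non-negative")
        if self.principal + self.secondary > 1:
            raise ValueError("infection-mix probabilities sum to more than 1")


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic discharge dataset."""

    year_dialect: str
    n_records: int
    infection_mix: dict[str, InfectionMix]
    true_coefficients: dict[str, float]
    covariates: CovariateModel
    control_covariates: CovariateModel
    secondary_shift: SecondaryShift
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    ccr_range: tuple[float, float] = (0.2, 0.65)
    cost_floor: float = DEFAULT_COST_FLOOR
    device_code_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.year_dialect not in DX_CAPACITY:
            raise ValueError(f"unknown dialect {self.year_dialect!r}")
        if self.n_records < 0:
            raise ValueError("n_records must be >= 0")
        total = sum(m.principal + m.secondary for m in self.infection_mix.values())
        if total > 1 + 1e-12:
            raise ValueError(
                f"infection-mix probabilities sum to {total:.4f} > 1 across types"
            )
        missing = [t for t in MODEL_TERMS if t not in self.true_coefficients]
        if missing:
            raise ValueError(f"true_coefficients missing terms: {missing}")
        lo, hi = self.ccr_range
        if not (0 < lo <= hi < 1):
            raise ValueError(f"ccr_range must satisfy 0 < low <= high < 1, got {self.ccr_range}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _draw_covariates(
    model: CovariateModel, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    los = model.los_min + rng.poisson(max(model.los_mean - model.los_min, 0.0), n)
    ndx = model.ndx_min + rng.poisson(max(model.ndx_mean - model.ndx_min, 0.0), n)
    npr = rng.poisson(model.npr_mean, n)
    age = np.clip(np.rint(rng.normal(model.age_mean, model.age_sd, n)), 0, 110)
    p_sev = np.clip((model.severity_mean - 1.0) / 3.0, 0.0, 1.0)
    p_risk = np.clip((model.risk_mean - 1.0) / 3.0, 0.0, 1.0)
    severity = 1 + rng.binomial(3, p_sev, n)
    risk = 1 + rng.binomial(3, p_risk, n)
    urban = (rng.random(n) < model.urban_teaching_share).astype(int)
    small = (rng.random(n) < model.small_bedsize_share).astype(int)
    wage = np.clip(rng.normal(model.wage_mean, model.wage_sd, n), 0.4, 1.6)
    return pd.DataFrame(
        {
            "los": np.minimum(los, 365).astype(int),
            "ndx": ndx.astype(int),
            "npr": npr.astype(int),
            "age": age.astype(int),
            "severity": severity,
            "risk_mortality": risk,
            "urban_teaching": urban,
            "small_bedsize": small,
            "wage_index": wage,
        }
    )


def generate(config: GeneratorConfig, catalog=None) -> pd.DataFrame:
    """Generate a discharge-record table per the configuration.

    ``catalog`` defaults to the bundled one.  Deterministic given
    ``config.seed``; ``n_records == 0`` yields an empty (but fully
    schema'd) table.  Charges are derived as ``cost / ccr`` so that the
    downstream ``charges x ccr`` conversion reproduces the generated cost
    bit-for-bit.
    """
    if catalog is None:
        from .reference import load_bundled_catalog

        catalog = load_bundled_catalog()
    dialect = config.year_dialect
    cap = DX_CAPACITY[dialect]
    rng = np.random.default_rng(config.seed)

    dx_cols = [f"DX{i}" for i in range(1, cap + 1)]
    pr_cols = [f"PR{i}" for i in range(1, PR_CAPACITY + 1)]
    all_cols = (
        ["record_id"]
        + dx_cols
        + pr_cols
        + [
            "los",
            "ndx",
            "npr",
            "age",
            "severity",
            "risk_mortality",
            "urban_teaching",
            "small_bedsize",
            "wage_index",
            "total_charges",
            "ccr",
            "cost",
        ]
    )
    n = config.n_records
    if n == 0:
        return pd.DataFrame(columns=all_cols)

    # Assign each record a role: (infection, principal|secondary) or control.
    roles = [("", "control")]
    probs = [
        max(0.0, 1.0 - sum(m.principal + m.secondary for m in config.infection_mix.values()))
    ]
    for infection, mix in config.infection_mix.items():
        roles.append((infection, "principal"))
        probs.append(mix.principal)
        roles.append((infection, "secondary"))
        probs.append(mix.secondary)
    role_idx = rng.choice(len(roles), size=n, p=np.asarray(probs) / np.sum(probs))

    secondary_model = config.covariates.shifted(config.secondary_shift)
    frames = []
    for k, (infection, role) in enumerate(roles):
        mask = role_idx == k
        m = int(mask.sum())
        if m == 0:
            continue
        model = {
            "control": config.control_covariates,
            "principal": config.covariates,
            "secondary": secondary_model,
        }[role]
        cov = _draw_covariates(model, m, rng)
        cov["ndx"] = np.minimum(cov["ndx"], cap)
        cov["npr"] = np.minimum(cov["npr"], PR_CAPACITY)
        cov.index = np.flatnonzero(mask)
        cov["_infection"] = infection
        cov["_role"] = role
        frames.append(cov)
    out = pd.concat(frames).sort_index()

    # Diagnosis-code fields: DX1 is the principal diagnosis.
    dx = np.full((n, cap), "", dtype=object)
    ndx_arr = out["ndx"].to_numpy()
    filler = rng.choice(_FILLER_DX, size=(n, cap))
    underlying = rng.choice(_UNDERLYING_DX, size=n)
    for i in range(n):
        k = ndx_arr[i]
        dx[i, :k] = filler[i, :k]
        infection, role = out["_infection"].iat[i], out["_role"].iat[i]
        if role == "principal":
            codes = sorted(catalog.codes_for(infection, dialect))
            dx[i, 0] = codes[rng.integers(len(codes))]
        else:
            dx[i, 0] = underlying[i]
            if role == "secondary":
                codes = sorted(catalog.codes_for(infection, dialect))
                pos = int(rng.integers(1, k))  # k >= 2 for secondary records
                dx[i, pos] = codes[rng.integers(len(codes))]

    # Procedure-code fields, with device placeholders for UTI / pneumonia.
    pr = np.full((n, PR_CAPACITY), "", dtype=object)
    npr_arr = out["npr"].to_numpy().copy()
    pr_filler = rng.choice(_FILLER_PR, size=(n, PR_CAPACITY))
    device_draw = rng.random(n) < config.device_code_prob
    for i in range(n):
        infection, role = out["_infection"].iat[i], out["_role"].iat[i]
        device = None
        if role != "control" and device_draw[i]:
            if infection == "uti" and catalog.catheter_procedure_codes:
                device = sorted(catalog.catheter_procedure_codes)[0]
            elif infection == "pneumonia" and catalog.ventilation_procedure_codes:
                device = sorted(catalog.ventilation_procedure_codes)[0]
        if device is not None and npr_arr[i] == 0:
            npr_arr[i] = 1
        k = npr_arr[i]
        pr[i, :k] = pr_filler[i, :k]
        if device is not None:
            pr[i, k - 1] = device
    out["npr"] = npr_arr

    # Cost from the ground-truth linear model with median-one noise.
    b = config.true_coefficients
    index = (
        b["intercept"]
        + b["los"] * out["los"]
        + b["ndx"] * out["ndx"]
        + b["npr"] * out["npr"]
        + b["urban_teaching"] * out["urban_teaching"]
        + b["small_bedsize"] * out["small_bedsize"]
        + b["age"] * out["age"]
        + b["severity"] * out["severity"]
        + b["risk_mortality"] * out["risk_mortality"]
        + b["wage_index"] * out["wage_index"]
    ).to_numpy()
    eps = rng.lognormal(mean=0.0, sigma=config.noise_sigma, size=n)
    cost = np.maximum(index * eps, config.cost_floor)
    ccr = rng.uniform(config.ccr_range[0], config.ccr_range[1], size=n)
    charges = cost / ccr

    table = pd.DataFrame({"record_id": np.arange(n)})
    for j, c in enumerate(dx_cols):
        table[c] = dx[:, j]
    for j, c in enumerate(pr_cols):
        table[c] = pr[:, j]
    for c in [
        "los",
        "ndx",
        "npr",
        "age",
        "severity",
        "risk_mortality",
        "urban_teaching",
        "small_bedsize",
        "wage_index",
    ]:
        table[c] = out[c].to_numpy()
    table["total_charges"] = charges
    table["ccr"] = ccr
    # Derived cost column equals charges * ccr bit-for-bit, so the
    # conversion done downstream reproduces it exactly.
    table["cost"] = charges * ccr
    return table


def make_lrti_fixture(year_dialect: str, n_records: int = 10_000, seed: int = 0) -> GeneratorConfig:
    """Generator configuration whose LRTI cohorts mimic the reference study.

    The ground-truth coefficients are the published stage-1 estimates for
    the dialect's study year (ICD9 -> 2011, ICD10 -> 2016), and the
    covariate models target the published principal / secondary /
    no-infection group means, so generated data exercise the pipeline at
    realistic covariate scales and support parameter-recovery tests.
    """
    from .reference import load_group_means, load_lrti_coefficients

    if year_dialect not in DX_CAPACITY:
        raise ValueError(f"unknown dialect {year_dialect!r}")
    year = 2011 if year_dialect == "ICD9" else 2016
    coeffs = load_lrti_coefficients(year)
    means = load_group_means(year)
    prin = means.loc["principal"]
    sec = means.loc["secondary"]
    ctrl = means.loc["no_infection"]

    base = CovariateModel(
        los_mean=prin["los_mean"],
        ndx_mean=prin["ndx_mean"],
        npr_mean=prin["npr_mean"],
        age_mean=prin["age_mean"],
        severity_mean=prin["severity_mean"],
        risk_mean=prin["risk_mortality_mean"],
        urban_teaching_share=0.55,
        small_bedsize_share=0.20,
        wage_mean=prin["wage_index_mean"],
    )
    shift = SecondaryShift(
        los=sec["los_mean"] - prin["los_mean"],
        ndx=sec["ndx_mean"] - prin["ndx_mean"],
        npr=sec["npr_mean"] - prin["npr_mean"],
        age=sec["age_mean"] - prin["age_mean"],
        severity=sec["severity_mean"] - prin["severity_mean"],
        risk=sec["risk_mortality_mean"] - prin["risk_mortality_mean"],
        wage_index=sec["wage_index_mean"] - prin["wage_index_mean"],
    )
    control = CovariateModel(
        los_mean=ctrl["los_mean"],
        ndx_mean=ctrl["ndx_mean"],
        npr_mean=ctrl["npr_mean"],
        age_mean=ctrl["age_mean"],
        severity_mean=ctrl["severity_mean"],
        risk_mean=ctrl["risk_mortality_mean"],
        urban_teaching_share=0.55,
        small_bedsize_share=0.20,
        wage_mean=ctrl["wage_index_mean"],
    )
    mix = {
        "lrti": InfectionMix(principal=0.25, secondary=0.20),
        "uti": InfectionMix(principal=0.02, secondary=0.02),
        "pneumonia": InfectionMix(principal=0.02, secondary=0.02),
        "bsi": InfectionMix(principal=0.01, secondary=0.01),
    }
    return GeneratorConfig(
        year_dialect=year_dialect,
        n_records=n_records,
        infection_mix=mix,
        true_coefficients=dict(coeffs.estimates),
        covariates=base,
        control_covariates=control,
        secondary_shift=shift,
        seed=seed,
    )


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write a record table as CSV with round-trip-exact float columns."""
    records.to_csv(path, index=False, float_format="%.17g")


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a record CSV written by :func:`write_records`."""
    df = pd.read_csv(
        path, keep_default_na=False, na_values=[], float_precision="round_trip"
    )
    for c in df.columns:
        if c.startswith(("DX", "PR")):
            df[c] = df[c].astype(str).replace("nan", "")
    return df


def config_to_yaml(config: GeneratorConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["ccr_range"] = list(config.ccr_range)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def config_from_yaml(path: str | Path) -> GeneratorConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["infection_mix"] = {
        k: InfectionMix(**v) for k, v in d["infection_mix"].items()
    }
    d["covariates"] = CovariateModel(**d["covariates"])
    d["control_covariates"] = CovariateModel(**d["control_covariates"])
    d["secondary_shift"] = SecondaryShift(**d["secondary_shift"])
    d["ccr_range"] = tuple(d["ccr_range"])
    return GeneratorConfig(**d)
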