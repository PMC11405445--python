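"""Stage 1: median (L1) regression of per-record cost on model covariates.

The cost model for the principal-diagnosis (community-onset analog)
cohort is fitted at the 0.5 quantile: coefficients minimize
``sum_i |cost_i - (b0 + sum_k b_k x_ik)|``.  The problem is solved
exactly as a linear program (split positive/negative residuals, HiGHS
solver), so the reported objective is the global L1 minimum; with tied
or degenerate data any L1-minimizing vertex is a valid answer and
comparisons should be made on the objective, not the coefficients.

Uncertainty is quantified by nonparametric case-resampling bootstrap
with percentile confidence intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

#: The nine cost-model covariates (plus intercept, added implicitly):
#: resource use (LOS, diagnosis and procedure counts, age, APR-DRG
#: severity and mortality-risk indices, entered as continuous) and
#: facility cost structure (urban-teaching flag, small-bedsize flag,
#: CMS area wage index).
DEFAULT_COVARIATES = [
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

#: Covariates that are reference-coded dummies; their dropped reference
#: level is reported as a structural zero row in table output.
DUMMY_COVARIATES = ("urban_teaching", "small_bedsize")


@dataclass
class CoefficientSet:
    """Fitted (or transcribed) stage-1 coefficients for one model.

    ``estimates`` maps ``intercept`` and each covariate to its
    coefficient; ``se``/``ci_low``/``ci_high`` are optional per-term
    uncertainty maps.
    """

    estimates: dict[str, float]
    infection: str = ""
    year: int | None = None
    n_fit: int = 0
    objective: float | None = None
    se: dict[str, float] | None = None
    ci_low: dict[str, float] | None = None
    ci_high: dict[str, float] | None = None
    nonunique_hint: bool = False
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))

    def __post_init__(self) -> None:
        for term, v in self.estimates.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite coefficient for {term!r}")
        if self.ci_low and self.ci_high:
            for term in self.estimates:
                lo = self.ci_low.get(term)
                hi = self.ci_high.get(term)
                if lo is not None and hi is not None and not (lo <= hi):
                    raise ValueError(f"CI bounds for {term!r} do not bracket")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Linear predictor at the covariate rows of ``X``."""
        out = np.full(len(X), self.estimates["intercept"], dtype=float)
        for term in self.covariates:
            out += self.estimates[term] * X[term].to_numpy(dtype=float)
        return out

    def to_frame(self, reference_rows: bool = False) -> pd.DataFrame:
        """Tabular form; optionally append structural-zero rows for the
        dropped reference level of each dummy covariate."""
        rows = []
        for term in ["intercept"] + list(self.covariates):
            rows.append(
                {
                    "term": term,
                    "estimate": self.estimates[term],
                    "se": (self.se or {}).get(term, np.nan),
                    "ci_low": (self.ci_low or {}).get(term, np.nan),
                    "ci_high": (self.ci_high or {}).get(term, np.nan),
                }
            )
            if reference_rows and term in DUMMY_COVARIATES:
                rows.append(
                    {"term": term + "_ref", "estimate": 0.0, "se": 0.0,
                     "ci_low": 0.0, "ci_high": 0.0}
                )
        return pd.DataFrame(rows)

    def write_json(self, path: str | Path) -> None:
        payload = {
            "infection": self.infection,
            "year": self.year,
            "n_fit": self.n_fit,
            "objective": self.objective,
            "covariates": self.covariates,
            "estimates": self.estimates,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def read_json(cls, path: str | Path) -> "CoefficientSet":
        d = json.loads(Path(path).read_text())
        return cls(
            estimates=d["estimates"],
            infection=d.get("infection", ""),
            year=d.get("year"),
            n_fit=d.get("n_fit", 0),
            objective=d.get("objective"),
            se=d.get("se"),
            ci_low=d.get("ci_low"),
            ci_high=d.get("ci_high"),
            covariates=d.get("covariates", list(DEFAULT_COVARIATES)),
        )


def _design(records: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    X = np.column_stack(
        [np.ones(len(records))]
        + [records[c].to_numpy(dtype=float) for c in covariates]
    )
    return X


def _check_rank(X: np.ndarray, covariates: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Identify offending columns by greedy removal.
        names = ["intercept"] + list(covariates)
        bad = []
        keep: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def l1_objective(
    records: pd.DataFrame,
    estimates: dict[str, float],
    covariates: list[str] = DEFAULT_COVARIATES,
    cost_col: str = "cost",
) -> float:
    """Sum of absolute residuals of a coefficient set on a cohort."""
    X = _design(records, list(covariates))
    beta = np.array([estimates["intercept"]] + [estimates[c] for c in covariates])
    return float(np.abs(records[cost_col].to_numpy(dtype=float) - X @ beta).sum())


def fit_median_regression(
    records: pd.DataFrame,
    covariates: list[str] | None = None,
    cost_col: str = "cost",
    infection: str = "",
    year: int | None = None,
) -> CoefficientSet:
    """Exact L1 fit of cost on the covariates via linear programming.

    minimize  1'u + 1'v   s.t.  X b + u - v = y,  u, v >= 0, b free.

    Raises on an empty cohort, a rank-deficient design (naming the
    collinear columns), or fewer rows than parameters.
    """
    covariates = list(DEFAULT_COVARIATES if covariates is None else covariates)
    if len(records) == 0:
        raise ValueError("cannot fit on an empty cohort")
    y = records[cost_col].to_numpy(dtype=float)
    X = _design(records, covariates)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"{n} records but {p} parameters; underdetermined fit")
    _check_rank(X, covariates)

    A_eq = sparse.hstack(
        [sparse.csc_matrix(X), sparse.eye(n, format="csc"), -sparse.eye(n, format="csc")],
        format="csc",
    )
    c = np.concatenate([np.zeros(p), np.ones(2 * n)])
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"L1 linear program failed: {res.message}")
    beta = res.x[:p]
    resid = y - X @ beta
    # A non-degenerate L1 vertex interpolates exactly p points; more
    # near-zero residuals hint at ties / multiple optima.
    scale = max(1.0, float(np.abs(y).max()))
    n_zero = int((np.abs(resid) <= 1e-9 * scale).sum())
    estimates = {"intercept": float(beta[0])}
    estimates.update({cov: float(b) for cov, b in zip(covariates, beta[1:])})
    return CoefficientSet(
        estimates=estimates,
        infection=infection,
        year=year,
        n_fit=n,
        objective=float(np.abs(resid).sum()),
        nonunique_hint=n_zero > p,
        covariates=covariates,
    )


def bootstrap_se(
    records: pd.DataFrame,
    covariates: list[str] | None = None,
    B: int = 500,
    seed: int = 0,
    cost_col: str = "cost",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Case-resampling bootstrap SEs and percentile CIs for the L1 fit.

    Returns a frame indexed by term with ``se``, ``ci_low``, ``ci_high``.
    Deterministic given ``seed``.
    """
    if B < 2:
        raise ValueError("bootstrap needs B >= 2 replicates")
    covariates = list(DEFAULT_COVARIATES if covariates is None else covariates)
    rng = np.random.default_rng(seed)
    n = len(records)
    terms = ["intercept"] + covariates
    draws = np.empty((B, len(terms)))
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        fit = fit_median_regression(
            records.iloc[idx], covariates=covariates, cost_col=cost_col
        )
        draws[b] = [fit.estimates[t] for t in terms]
    se = draws.std(axis=0, ddof=1)
    lo = np.quantile(draws, alpha / 2, axis=0)
    hi = np.quantile(draws, 1 - alpha / 2, axis=0)
    return pd.DataFrame({"se": se, "ci_low": lo, "ci_high": hi}, index=terms)


def fit_with_bootstrap(
    records: pd.DataFrame,
    covariates: list[str] | None = None,
    B: int = 500,
    seed: int = 0,
    cost_col: str = "cost",
    infection: str = "",
    year: int | None = None,
) -> CoefficientSet:
    """Point fit plus bootstrap uncertainty in one CoefficientSet."""
    fit = fit_median_regression(
        records, covariates=covariates, cost_col=cost_col, infection=infection, year=year
    )
    boot = bootstrap_se(records, covariates=fit.covariates, B=B, seed=seed, cost_col=cost_col)
    fit.se = boot["se"].to_dict()
    fit.ci_low = boot["ci_low"].to_dict()
    fit.ci_high = boot["ci_high"].to_dict()
    return fit
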