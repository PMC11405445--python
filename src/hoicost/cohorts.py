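"""Cohort construction from discharge records.

A discharge record is one hospitalization: an ordered diagnosis-code list
(first entry = principal diagnosis, the chief reason for the stay),
procedure codes, length of stay, charges, and patient/facility covariates.
For each infection type, records are classified as

* ``principal`` — a catalog code is the first-listed diagnosis (the
  community-onset analog whose cost parameterizes the attribution model);
* ``secondary`` — a catalog code appears in a non-first diagnosis field,
  the first code is not in the catalog, and the stay lasted at least
  three days (the hospital-onset proxy group);
* ``none`` — otherwise.

A 5:1 no-infection comparison group is drawn by exact stratification on
the principal diagnosis codes of the secondary group, restricted to
records carrying no infection code of any type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: Number of diagnosis-code fields per coding dialect (1 principal +
#: 24 secondary for ICD-9 files, 1 + 29 for ICD-10 files).
DX_CAPACITY = {"ICD9": 25, "ICD10": 30}

SECONDARY_MIN_LOS = 3  # days; stays shorter than this cannot be hospital-onset proxies

COVARIATE_COLUMNS = [
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


def dx_columns(records: pd.DataFrame) -> list[str]:
    """Ordered DX1..DXk columns present in a record table."""
    cols = [c for c in records.columns if c.startswith("DX")]
    return sorted(cols, key=lambda c: int(c[2:]))


def pr_columns(records: pd.DataFrame) -> list[str]:
    cols = [c for c in records.columns if c.startswith("PR")]
    return sorted(cols, key=lambda c: int(c[2:]))


def validate_schema(records: pd.DataFrame, dialect: str) -> None:
    """Check the DX layout matches the dialect's field capacity.

    Extra diagnosis columns beyond the dialect's capacity are an error
    (they indicate a file from the wrong dialect/layout).
    """
    if dialect not in DX_CAPACITY:
        raise ValueError(f"unknown dialect {dialect!r}; expected ICD9 or ICD10")
    n = len(dx_columns(records))
    cap = DX_CAPACITY[dialect]
    if n > cap:
        raise ValueError(
            f"{n} diagnosis columns but {dialect} files carry at most {cap}"
        )
    if n == 0:
        raise ValueError("no DX columns found; malformed record table")


@dataclass(frozen=True)
class CodeCatalog:
    """Diagnosis-code sets per infection type and dialect, plus device rules.

    ``diagnosis_codes[infection][dialect]`` is a frozenset of code strings.
    ``groups[infection]`` labels the type device/procedure-associated
    (traditional surveillance) or nondevice.
    """

    diagnosis_codes: dict[str, dict[str, frozenset[str]]]
    groups: dict[str, str] = field(default_factory=dict)
    catheter_procedure_codes: frozenset[str] = frozenset()
    ventilation_procedure_codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for infection, by_dialect in self.diagnosis_codes.items():
            for dialect, codes in by_dialect.items():
                if not codes:
                    raise ValueError(
                        f"empty {dialect} code set for infection {infection!r}"
                    )
        for dialect in ("ICD9", "ICD10"):
            seen: dict[str, str] = {}
            for infection, by_dialect in self.diagnosis_codes.items():
                for code in by_dialect.get(dialect, ()):
                    if code in seen:
                        raise ValueError(
                            f"code {code} appears under both {seen[code]!r} "
                            f"and {infection!r} ({dialect})"
                        )
                    seen[code] = infection

    @property
    def infections(self) -> list[str]:
        return list(self.diagnosis_codes)

    def codes_for(self, infection: str, dialect: str) -> frozenset[str]:
        try:
            by_dialect = self.diagnosis_codes[infection]
        except KeyError:
            raise KeyError(f"infection type {infection!r} not in catalog") from None
        if dialect not in by_dialect:
            raise ValueError(
                f"catalog has no {dialect} codes for {infection!r} (dialect mismatch?)"
            )
        return by_dialect[dialect]

    def all_codes(self, dialect: str) -> frozenset[str]:
        """Union of every infection type's codes — used to screen controls."""
        out: set[str] = set()
        for by_dialect in self.diagnosis_codes.values():
            out |= by_dialect.get(dialect, frozenset())
        return frozenset(out)


def load_catalog(path: str | Path) -> CodeCatalog:
    """Read a catalog from YAML: infection -> {icd9: [...], icd10: [...], group}."""
    raw = yaml.safe_load(Path(path).read_text())
    devices = raw.pop("devices", {})
    dx: dict[str, dict[str, frozenset[str]]] = {}
    groups: dict[str, str] = {}
    for infection, entry in raw.items():
        dx[infection] = {}
        for key, dialect in (("icd9", "ICD9"), ("icd10", "ICD10")):
            if key in entry:
                dx[infection][dialect] = frozenset(str(c) for c in entry[key])
        groups[infection] = entry.get("group", "nondevice")
    return CodeCatalog(
        diagnosis_codes=dx,
        groups=groups,
        catheter_procedure_codes=frozenset(
            devices.get("catheter_procedure_codes", ())
        ),
        ventilation_procedure_codes=frozenset(
            devices.get("ventilation_procedure_codes", ())
        ),
    )


def classify(
    diagnosis_codes: list[str],
    los: int,
    catalog: CodeCatalog,
    infection: str,
    dialect: str,
) -> str:
    """Classify one record for one infection type.

    Returns ``"principal"``, ``"secondary"``, or ``"none"``.  A record whose
    first code is in the catalog is principal even if later catalog codes
    are present (no within-type double counting).
    """
    codes = [c for c in diagnosis_codes if c]
    if not codes:
        raise ValueError("record has an empty diagnosis-code list (malformed)")
    catalog_codes = catalog.codes_for(infection, dialect)
    if codes[0] in catalog_codes:
        return "principal"
    if los >= SECONDARY_MIN_LOS and any(c in catalog_codes for c in codes[1:]):
        return "secondary"
    return "none"


def classify_frame(
    records: pd.DataFrame, catalog: CodeCatalog, infection: str, dialect: str
) -> pd.Series:
    """Vectorized :func:`classify` over a record table (one label per row)."""
    validate_schema(records, dialect)
    cols = dx_columns(records)
    catalog_codes = catalog.codes_for(infection, dialect)
    dx = records[cols]
    if dx[cols[0]].isna().any() or (dx[cols[0]].astype(str) == "").any():
        raise ValueError("records with empty first diagnosis field (malformed)")
    principal = dx[cols[0]].isin(catalog_codes)
    any_later = pd.Series(False, index=records.index)
    for c in cols[1:]:
        any_later |= dx[c].isin(catalog_codes)
    secondary = ~principal & any_later & (records["los"] >= SECONDARY_MIN_LOS)
    labels = pd.Series("none", index=records.index, dtype=object)
    labels[secondary] = "secondary"
    labels[principal] = "principal"
    return labels


def device_associate(
    diagnosis_codes: list[str],
    procedure_codes: list[str],
    catalog: CodeCatalog,
    dialect: str,
    uti_type: str = "uti",
    pneumonia_type: str = "pneumonia",
) -> dict[str, bool]:
    """Device-association flags for one record.

    ``cauti`` requires a urinary-tract-infection diagnosis code anywhere in
    the record *and* a catheter-insertion procedure code; ``vap`` requires a
    pneumonia code and a mechanical-ventilation procedure code.  Bloodstream
    infections are never split by device (a single combined type covers
    primary and central-line-associated bloodstream infections).
    """
    dx = {c for c in diagnosis_codes if c}
    pr = {c for c in procedure_codes if c}
    flags = {"cauti": False, "vap": False}
    if uti_type in catalog.diagnosis_codes:
        uti_codes = catalog.codes_for(uti_type, dialect)
        flags["cauti"] = bool(dx & uti_codes) and bool(
            pr & catalog.catheter_procedure_codes
        )
    if pneumonia_type in catalog.diagnosis_codes:
        pn_codes = catalog.codes_for(pneumonia_type, dialect)
        flags["vap"] = bool(dx & pn_codes) and bool(
            pr & catalog.ventilation_procedure_codes
        )
    return flags


@dataclass
class CohortTriple:
    """Principal, secondary, and matched no-infection groups for one type."""

    infection: str
    dialect: str
    principal: pd.DataFrame
    secondary: pd.DataFrame
    controls: pd.DataFrame
    match_ratio: int = 5
    match_report: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        overlap = set(self.principal["record_id"]) & set(self.secondary["record_id"])
        if overlap:
            raise ValueError(f"records in both principal and secondary: {overlap}")
        if len(self.secondary) and (self.secondary["los"] < SECONDARY_MIN_LOS).any():
            raise ValueError("secondary cohort contains stays shorter than 3 days")
        if len(self.controls) > self.match_ratio * len(self.secondary):
            raise ValueError("more controls than match_ratio allows")


def build_matched_controls(
    secondary: pd.DataFrame,
    pool: pd.DataFrame,
    catalog: CodeCatalog,
    dialect: str,
    ratio: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a ratio:1 no-infection group matched on principal diagnosis.

    For each principal-diagnosis-code stratum of the secondary group, up to
    ``ratio x stratum size`` pool records with that principal code and zero
    infection codes (any type, any field) are sampled without replacement.
    Returns ``(controls, report)``; the report lists requested and achieved
    counts per stratum (shortfalls are reported, never back-filled).
    """
    if ratio < 1:
        raise ValueError("match ratio must be >= 1")
    report_rows = []
    if secondary.empty or pool.empty:
        report = pd.DataFrame(
            columns=["principal_dx", "n_secondary", "requested", "achieved"]
        )
        return pool.iloc[0:0].copy(), report

    overlap = set(secondary["record_id"]) & set(pool["record_id"])
    if overlap:
        raise ValueError("candidate pool overlaps the secondary cohort")

    cols = dx_columns(pool)
    infection_codes = catalog.all_codes(dialect)
    has_infection = pd.Series(False, index=pool.index)
    for c in cols:
        has_infection |= pool[c].isin(infection_codes)
    eligible = pool.loc[~has_infection]

    first_col_sec = dx_columns(secondary)[0]
    strata = secondary[first_col_sec].value_counts()
    rng = np.random.default_rng(seed)
    taken = []
    for code in sorted(strata.index):
        n_sec = int(strata[code])
        want = ratio * n_sec
        candidates = eligible.loc[eligible[cols[0]] == code]
        k = min(want, len(candidates))
        if k:
            idx = rng.choice(candidates.index.to_numpy(), size=k, replace=False)
            taken.append(eligible.loc[np.sort(idx)])
        report_rows.append(
            {"principal_dx": code, "n_secondary": n_sec, "requested": want, "achieved": k}
        )
    controls = (
        pd.concat(taken) if taken else eligible.iloc[0:0].copy()
    )
    report = pd.DataFrame(report_rows)
    return controls, report


def build_cohorts(
    records: pd.DataFrame,
    catalog: CodeCatalog,
    infection: str,
    dialect: str,
    ratio: int = 5,
    seed: int = 0,
) -> CohortTriple:
    """Classify a record table and assemble the full cohort triple."""
    labels = classify_frame(records, catalog, infection, dialect)
    principal = records.loc[labels == "principal"].copy()
    secondary = records.loc[labels == "secondary"].copy()
    pool = records.loc[labels == "none"].copy()
    controls, report = build_matched_controls(
        secondary, pool, catalog, dialect, ratio=ratio, seed=seed
    )
    return CohortTriple(
        infection=infection,
        dialect=dialect,
        principal=principal,
        secondary=secondary,
        controls=controls,
        match_ratio=ratio,
        match_report=report,
    )
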