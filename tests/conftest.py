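import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hoicost import build_cohorts, generate, make_lrti_fixture
from hoicost.reference import load_bundled_catalog

settings.register_profile("fixed", derandomize=True, deadline=None)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def catalog():
    return load_bundled_catalog()


@pytest.fixture(scope="session")
def fixture_cfg():
    # 2e4 records -> ~5e3 principal-LRTI, ~4e3 secondary-LRTI
    return make_lrti_fixture("ICD9", n_records=20_000, seed=7)


@pytest.fixture(scope="session")
def records(fixture_cfg, catalog):
    return generate(fixture_cfg, catalog)


@pytest.fixture(scope="session")
def lrti_triple(records, catalog):
    return build_cohorts(records, catalog, "lrti", "ICD9", ratio=5, seed=3)


def make_records(rows, n_dx=25, n_pr=5):
    """Build a small record table from dicts with 'dx' / 'pr' code lists."""
    out = []
    for i, row in enumerate(rows):
        dx = list(row.get("dx", []))
        pr = list(row.get("pr", []))
        rec = {
            "record_id": row.get("record_id", i),
            "los": row.get("los", 4),
            "ndx": len(dx),
            "npr": len(pr),
            "age": row.get("age", 50),
            "severity": row.get("severity", 2),
            "risk_mortality": row.get("risk_mortality", 2),
            "urban_teaching": row.get("urban_teaching", 0),
            "small_bedsize": row.get("small_bedsize", 0),
            "wage_index": row.get("wage_index", 1.0),
            "total_charges": row.get("total_charges", 10_000.0),
            "ccr": row.get("ccr", 0.5),
        }
        for j in range(n_dx):
            rec[f"DX{j + 1}"] = dx[j] if j < len(dx) else ""
        for j in range(n_pr):
            rec[f"PR{j + 1}"] = pr[j] if j < len(pr) else ""
        rec["cost"] = row.get("cost", rec["total_charges"] * rec["ccr"])
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture
def tiny_records():
    return make_records
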