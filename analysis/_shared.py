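"""Shared defaults for the numbered analysis drivers.

Each driver regenerates what it needs deterministically (fixed seeds),
caching the synthetic discharge files under scratch/ and writing its
tables under results/.
"""

from pathlib import Path

from hoicost import build_cohorts, generate, make_lrti_fixture
from hoicost.reference import load_bundled_catalog
from hoicost.synthetic import read_records, write_records

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

N_RECORDS = 20_000
SEED = 11
DIALECTS = {"ICD9": 2011, "ICD10": 2016}

CATALOG = load_bundled_catalog()


def records_for(dialect: str):
    """Synthetic discharge records for a dialect, cached on disk."""
    SCRATCH.mkdir(exist_ok=True)
    path = SCRATCH / f"records_{dialect.lower()}.csv"
    if path.exists():
        return read_records(path)
    cfg = make_lrti_fixture(dialect, n_records=N_RECORDS, seed=SEED)
    df = generate(cfg, CATALOG)
    write_records(df, path)
    return df


def lrti_cohorts(dialect: str):
    return build_cohorts(records_for(dialect), CATALOG, "lrti", dialect, ratio=5, seed=SEED)
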