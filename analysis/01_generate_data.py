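"""Generate the synthetic discharge datasets used by the later drivers.

Writes one 20,000-record file per coding dialect (ICD-9 ~ 2011 layout,
ICD-10 ~ 2016 layout) under scratch/ and prints the infection-role
composition implied by the fixture mix.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from _shared import CATALOG, DIALECTS, records_for  # noqa: E402

from hoicost import classify_frame  # noqa: E402

for dialect, year in DIALECTS.items():
    df = records_for(dialect)
    labels = classify_frame(df, CATALOG, "lrti", dialect)
    counts = labels.value_counts().to_dict()
    print(
        f"{dialect} ({year}): {len(df)} records — "
        f"{counts.get('principal', 0)} principal-LRTI, "
        f"{counts.get('secondary', 0)} secondary-LRTI, "
        f"{counts.get('none', 0)} other"
    )
print("Records cached under scratch/.")
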