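#!/usr/bin/env python
"""Quality-control filtering of the simulated cohort.

Applies the duplicate-fatigue concordance filter (agreement within 40 mm
after orientation) and reports the filtering ledger: raw records, records
with complete item sets, and QC-passing records, by expedition arm.
"""

import json
from pathlib import Path

from amsnet.pipeline import filtering_ledger
from amsnet.records import qc_filter, read_records

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    df = read_records(RESULTS / "cohort.csv")
    ledger = filtering_ledger(df)
    (RESULTS / "qc_ledger.json").write_text(json.dumps(ledger, indent=2))

    passed = df[qc_filter(df)]
    passed.to_csv(RESULTS / "qc_passed.csv", index=False, float_format="%.1f")

    print(json.dumps(ledger, indent=2))
    print(f"\n{ledger['qc_passed']['excluded']} questionnaires "
          f"({ledger['qc_passed']['excluded_pct']}%) excluded by the 40 mm "
          "agreement threshold")
    print(f"wrote {RESULTS / 'qc_passed.csv'}")


if __name__ == "__main__":
    main()
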