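#!/usr/bin/env python
"""Stage 3 — cohort filters and prevalence report.

Applies control exclusion (gene pairs called in any cancer-free control are
removed from all tumors) and the recurrence rule (>= 1 junction-crossing read
in >= 3 distinct patients, pooled across subtypes), then writes the
per-subtype prevalence table under results/.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
CALLS = ROOT / "results" / "calls"
COHORT = ROOT / "results" / "cohort"

from neofusion import (  # noqa: E402
    CohortCallSet,
    SampleMeta,
    exclude_control_fusions,
    prevalence_report,
    recurrence_filter,
)
from neofusion.cohort import retained_pairs  # noqa: E402
from neofusion.serialize import read_calls  # noqa: E402


def main(seed: int = 42) -> None:  # noqa: ARG001 - filters are deterministic
    meta_df = pd.read_csv(COHORT / "samples.tsv", sep="\t")
    metas = {
        r.sample_id: SampleMeta(r.sample_id, r.group, bool(r.is_case))
        for r in meta_df.itertuples(index=False)
    }
    calls, _ = read_calls(CALLS)
    for sid in metas:
        calls.setdefault(sid, [])
    callset = CohortCallSet(calls, metas)
    detected = sorted(retained_pairs(callset))
    callset = exclude_control_fusions(callset)
    after_controls = sorted(retained_pairs(callset))
    callset = recurrence_filter(callset, 3)
    retained = sorted(retained_pairs(callset))
    report = prevalence_report(callset)
    report.to_csv(ROOT / "results" / "prevalence.tsv", sep="\t", index=False)
    print(f"detected pairs:        {detected}")
    print(f"after control filter:  {after_controls}")
    print(f"after recurrence (3):  {retained}")
    print(report.to_string(index=False))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 42)
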