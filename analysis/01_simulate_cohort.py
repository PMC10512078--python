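#!/usr/bin/env python
"""Stage 1 — simulate the study-shaped cohort.

Builds the toy reference (six plus-strand genes on one contig), plants a
read-through fusion expressed in all six tumor samples plus a decoy fusion
expressed in one cancer-free control and three tumors, and simulates 2x76 bp
paired-end reads (2000 pairs/sample, substitution error 0.001).  Writes the
reference, annotation, sample sheet and a per-sample truth summary under
results/cohort/ (reads and full truth tables are regenerated
deterministically from the seed by later stages).
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "cohort"

from neofusion.pipeline import build_cohort, validate_config  # noqa: E402


def main(seed: int = 42) -> None:
    cfg = validate_config({"seed": seed})
    reference, samples, truth = build_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    reference.write_fasta(OUT / "reference.fa")
    reference.write_gtf(OUT / "genes.gtf")
    pd.DataFrame(
        [
            {"sample_id": s.meta.sample_id, "group": s.meta.group, "is_case": s.meta.is_case}
            for s in samples
        ]
    ).to_csv(OUT / "samples.tsv", sep="\t", index=False)
    rows = []
    for s in samples:
        counts = s.truth.origin.value_counts()
        rows.append(
            {
                "sample_id": s.meta.sample_id,
                "n_pairs": len(s.pairs),
                "junction_crossing": int(counts.get("fusion_junction_crossing", 0)),
                "spanning": int(counts.get("fusion_spanning", 0)),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "truth_summary.tsv", sep="\t", index=False)
    primary = truth["primary"]
    print(f"cohort: {len(samples)} samples ({sum(r['n_pairs'] for r in rows)} pairs total)")
    print(f"planted fusion: {primary.five_gene}[exon 1-{primary.five_last_exon}] -> "
          f"{primary.three_gene}[exon {primary.three_first_exon}-]")
    if truth["decoy"]:
        d = truth["decoy"]
        print(f"decoy fusion (in control C01): {d.five_gene}|{d.three_gene}")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 42)
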