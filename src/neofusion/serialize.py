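"""Flat-file round-tripping of per-sample calls and split reads.

Keeps the CLI stages and the analysis drivers decoupled: `detect` writes
these tables, `filter` and `consensus` read them back.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .alignment import Alignment, SplitAlignment
from .detection import FusionCandidate

CANDIDATE_COLUMNS = [
    "sample_id", "gene_5p", "gene_3p", "breakpoint_5p", "breakpoint_3p",
    "bp5_transcript", "bp3_transcript", "junction_crossing_reads", "spanning_pairs",
]


def candidates_to_frame(calls: dict[str, list[FusionCandidate]]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": c.sample_id,
            "gene_5p": c.five_gene,
            "gene_3p": c.three_gene,
            "breakpoint_5p": c.breakpoint_5p,
            "breakpoint_3p": c.breakpoint_3p,
            "bp5_transcript": c.bp5_transcript,
            "bp3_transcript": c.bp3_transcript,
            "junction_crossing_reads": c.junction_crossing_reads,
            "spanning_pairs": c.spanning_pairs,
        }
        for sid in sorted(calls)
        for c in calls[sid]
    ]
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def frame_to_candidates(df: pd.DataFrame) -> dict[str, list[FusionCandidate]]:
    calls: dict[str, list[FusionCandidate]] = {}
    for row in df.itertuples(index=False):
        calls.setdefault(row.sample_id, []).append(
            FusionCandidate(
                sample_id=row.sample_id,
                five_gene=row.gene_5p,
                three_gene=row.gene_3p,
                breakpoint_5p=int(row.breakpoint_5p),
                breakpoint_3p=int(row.breakpoint_3p),
                bp5_transcript=int(row.bp5_transcript),
                bp3_transcript=int(row.bp3_transcript),
                junction_crossing_reads=int(row.junction_crossing_reads),
                spanning_pairs=int(row.spanning_pairs),
            )
        )
    return calls


def splits_to_frame(calls: dict[str, list[FusionCandidate]]) -> pd.DataFrame:
    rows = []
    for sid in sorted(calls):
        for c in calls[sid]:
            for sp in c.split_reads:
                rows.append(
                    {
                        "sample_id": sid,
                        "read_id": sp.read_id,
                        "gene_5p": sp.left.target,
                        "gene_3p": sp.right.target,
                        "left_start": sp.left.target_start,
                        "right_start": sp.right.target_start,
                        "junction_offset_in_read": sp.junction_offset_in_read,
                        "seq_forward": sp.seq_forward,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "read_id", "gene_5p", "gene_3p", "left_start",
            "right_start", "junction_offset_in_read", "seq_forward",
        ],
    )


def frame_to_splits(df: pd.DataFrame) -> list[SplitAlignment]:
    out = []
    for row in df.itertuples(index=False):
        L = len(row.seq_forward)
        s = int(row.junction_offset_in_read)
        left = Alignment(
            row.read_id, row.gene_5p, int(row.left_start), int(row.left_start) + s,
            0, s, "+", 0, 0, 0,
        )
        right = Alignment(
            row.read_id, row.gene_3p, int(row.right_start), int(row.right_start) + (L - s),
            s, L, "+", 0, 0, 0,
        )
        out.append(SplitAlignment(row.read_id, left, right, s, row.seq_forward))
    return out


def write_calls(calls: dict[str, list[FusionCandidate]], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    candidates_to_frame(calls).to_csv(out / "candidates.tsv", sep="\t", index=False)
    splits_to_frame(calls).to_csv(out / "splits.tsv", sep="\t", index=False)


def read_calls(out_dir: str | Path) -> tuple[dict[str, list[FusionCandidate]], pd.DataFrame]:
    out = Path(out_dir)
    calls = frame_to_candidates(pd.read_csv(out / "candidates.tsv", sep="\t"))
    splits = pd.read_csv(out / "splits.tsv", sep="\t")
    return calls, splits
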