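"""Cohort-level fusion filtering and prevalence reporting.

Three per-gene-pair predicates refine the per-sample calls:

* control exclusion — any pair seen in a cancer-free control is removed from
  every case; pairs seen only in adjacent-normal tissue are retained (the
  false-negative filter's rationale: adjacent normals may harbour
  pre-malignant clones, cancer-free tissue may not);
* recurrence — a retained pair needs at least one junction-crossing read in a
  minimum number of distinct case samples, pooled across subtypes;
* external recurrence — optionally, a retained pair must also appear in an
  independent dataset's evidence table.

All three are pure per-pair predicates, so they commute and are invariant to
sample relabelling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from .detection import FusionCandidate
from .synthetic import SampleMeta

CASE_GROUPS = ("TNBC", "HER2+", "HR+")


@dataclass
class CohortCallSet:
    calls: dict[str, list[FusionCandidate]]
    meta: dict[str, SampleMeta]
    external_evidence: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        missing = set(self.calls) - set(self.meta)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    def pairs_in(self, sample_id: str) -> set[tuple[str, str]]:
        return {c.gene_pair for c in self.calls.get(sample_id, [])}

    def _subset(self, keep: set[tuple[str, str]], case_only: bool = True) -> "CohortCallSet":
        calls = {}
        for sid, cands in self.calls.items():
            if case_only and self.meta[sid].is_case:
                calls[sid] = [c for c in cands if c.gene_pair in keep]
            else:
                calls[sid] = list(cands)
        return replace(self, calls=calls)


def exclude_control_fusions(callset: CohortCallSet) -> CohortCallSet:
    """Remove from all case samples any gene pair called in a cancer-free
    control.  Pairs found only in adjacent-normal samples are retained."""
    controls = [s for s, m in callset.meta.items() if m.group == "cancer_free_control"]
    if not controls:
        warnings.warn("no cancer-free control samples; control exclusion is a no-op")
        return callset
    control_pairs: set[tuple[str, str]] = set()
    for sid in controls:
        control_pairs |= callset.pairs_in(sid)
    case_pairs = _case_pairs(callset)
    return callset._subset(case_pairs - control_pairs)


def recurrence_filter(callset: CohortCallSet, min_patients: int = 3) -> CohortCallSet:
    """Retain gene pairs with >= 1 junction-crossing read in at least
    ``min_patients`` distinct case samples (pooled across subtypes)."""
    support: dict[tuple[str, str], set[str]] = {}
    for sid, cands in callset.calls.items():
        if not callset.meta[sid].is_case:
            continue
        for c in cands:
            if c.junction_crossing_reads >= 1:
                support.setdefault(c.gene_pair, set()).add(sid)
    keep = {pair for pair, sids in support.items() if len(sids) >= min_patients}
    return callset._subset(keep)


def external_recurrence_filter(callset: CohortCallSet, enabled: bool = True) -> CohortCallSet:
    """Retain only gene pairs present in the external evidence table.

    With ``enabled=False`` (or when no table was loaded and the caller turns
    the check off) the callset passes through unchanged.
    """
    if not enabled:
        return callset
    return callset._subset(_case_pairs(callset) & set(callset.external_evidence))


def _case_pairs(callset: CohortCallSet) -> set[tuple[str, str]]:
    out: set[tuple[str, str]] = set()
    for sid, m in callset.meta.items():
        if m.is_case:
            out |= callset.pairs_in(sid)
    return out


def retained_pairs(callset: CohortCallSet) -> set[tuple[str, str]]:
    return _case_pairs(callset)


def prevalence_report(callset: CohortCallSet, round_integer: bool = True) -> pd.DataFrame:
    """Per gene pair and subtype: positive-sample count and the mean number of
    junction-crossing reads over positive samples (rounded half-up to mirror
    the integer presentation of cohort summaries; ``round_integer=False``
    keeps full precision).  Rows are sorted by total positive samples."""
    rows = []
    pairs = sorted(_case_pairs(callset))
    for pair in pairs:
        row: dict[str, object] = {"gene_5p": pair[0], "gene_3p": pair[1]}
        total = 0
        for group in CASE_GROUPS:
            counts = [
                c.junction_crossing_reads
                for sid, cands in callset.calls.items()
                if callset.meta[sid].group == group
                for c in cands
                if c.gene_pair == pair and c.junction_crossing_reads >= 1
            ]
            positive = len(counts)
            avg = sum(counts) / positive if positive else 0.0
            if round_integer:
                avg = math.floor(avg + 0.5)
            row[f"{group}_positive"] = positive
            row[f"{group}_avg_junction_reads"] = avg
            total += positive
        row["total_positive"] = total
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["total_positive", "gene_5p", "gene_3p"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return df


def load_external_evidence(path) -> set[tuple[str, str]]:
    """Read an independent dataset's fusion table (TSV with gene_5p/gene_3p)."""
    df = pd.read_csv(path, sep="\t")
    return set(zip(df["gene_5p"], df["gene_3p"]))
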