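"""MHC class I binding promiscuity ranking.

The binding predictor is an interface, not a dependency: any tool producing
(peptide, HLA allele, IC50 nM) rows can feed this module.  Promiscuity is the
number of distinct alleles a peptide binds strictly below an IC50 threshold
(the conventional binder threshold being 500 nM); peptides are ranked by
promiscuity at 500 nM.  An optional lower bound can drop ultra-strong binders
(<50 nM), which have been reported not to initiate immune responses; it is off
by default.

The printed binding table for the NSFP1-LRRC37A2 study peptides ships as a
package fixture (``data/study_binding_table.tsv``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .util import NeofusionError, ParameterError

_ALLELE_RE = re.compile(r"^(?:HLA-?)?([ABC])\*?(\d{2}):?(\d{2,})$", re.IGNORECASE)
ALLELE_PATTERN = re.compile(r"^HLA-[ABC]\*\d{2}:\d{2,}$")


class AlleleParseError(NeofusionError):
    pass


def normalize_allele(raw: str) -> str:
    """Normalize an HLA class I allele name to ``HLA-X*NN:NN`` form."""
    m = _ALLELE_RE.match(str(raw).strip())
    if not m:
        raise AlleleParseError(f"malformed HLA class I allele: {raw!r}")
    locus, group, protein = m.groups()
    return f"HLA-{locus.upper()}*{group}:{protein}"


@dataclass(frozen=True)
class BindingRecord:
    peptide: str
    allele: str
    ic50_nm: float

    def __post_init__(self) -> None:
        if self.ic50_nm <= 0:
            raise ParameterError("IC50 must be positive")
        if not ALLELE_PATTERN.match(self.allele):
            raise ParameterError(f"allele not normalized: {self.allele!r}")


@dataclass(frozen=True)
class PromiscuityProfile:
    peptide: str
    counts: dict[int, int]  # threshold (nM) -> distinct alleles strictly below
    best_allele: str | None
    best_ic50: float | None

    def count(self, threshold: int) -> int:
        return self.counts[threshold]


def load_binding_table(source) -> pd.DataFrame:
    """Load a peptide/allele/IC50 TSV into a normalized binding table.

    Alleles are normalized; duplicated (peptide, allele) rows are an error.
    Accepts a path or an already-parsed DataFrame.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    for needed in ("peptide", "allele"):
        if needed not in cols:
            raise ParameterError(f"binding table lacks a {needed!r} column")
    ic50_col = next((cols[c] for c in ("ic50_nm", "ic50", "ic50nm") if c in cols), None)
    if ic50_col is None:
        raise ParameterError("binding table lacks an IC50 column")
    out = pd.DataFrame(
        {
            "peptide": df[cols["peptide"]].astype(str).str.strip().str.upper(),
            "allele": df[cols["allele"]].astype(str),
            "ic50_nm": pd.to_numeric(df[ic50_col]),
        }
    )
    if "source" in cols:
        out["source"] = df[cols["source"]].values
    normalized = []
    for i, raw in enumerate(out["allele"]):
        try:
            normalized.append(normalize_allele(raw))
        except AlleleParseError as exc:
            raise AlleleParseError(f"row {i + 1}: {exc}") from None
    out["allele"] = normalized
    if (out["ic50_nm"] <= 0).any():
        bad = int(np.argmax(out["ic50_nm"].values <= 0)) + 1
        raise ParameterError(f"row {bad}: IC50 must be positive")
    dup = out.duplicated(subset=["peptide", "allele"])
    if dup.any():
        first = out[dup].iloc[0]
        raise ParameterError(
            f"duplicated (peptide, allele) row: {first.peptide}/{first.allele}"
        )
    return out


def study_binding_table() -> pd.DataFrame:
    """The packaged study binding table (per-peptide allele/IC50 rows)."""
    with resources.as_file(
        resources.files("neofusion").joinpath("data/study_binding_table.tsv")
    ) as p:
        return load_binding_table(Path(p))


def promiscuity_profile(
    records: pd.DataFrame, peptide: str, thresholds: tuple[int, ...] = (50, 500, 1000)
) -> PromiscuityProfile:
    """Distinct-allele counts strictly below each IC50 threshold for one
    peptide.  Unknown peptides yield an all-zero profile."""
    sub = records[records["peptide"] == peptide]
    counts = {
        t: int(sub.loc[sub["ic50_nm"] < t, "allele"].nunique()) for t in sorted(thresholds)
    }
    if sub.empty:
        return PromiscuityProfile(peptide, counts, None, None)
    best = sub.sort_values(["ic50_nm", "allele"]).iloc[0]
    return PromiscuityProfile(peptide, counts, best.allele, float(best.ic50_nm))


def allele_union(records: pd.DataFrame, peptides, threshold: int = 500) -> set[str]:
    """Union of distinct alleles bound (IC50 < threshold) by any of the
    given peptides."""
    peptides = set(peptides)
    sub = records[records["peptide"].isin(peptides) & (records["ic50_nm"] < threshold)]
    return set(sub["allele"])


def min_ic50_by_allele(records: pd.DataFrame, allele: str) -> tuple[str, float]:
    """The strongest-binding peptide for an allele; ties go to the
    lexicographically smallest peptide."""
    sub = records[records["allele"] == normalize_allele(allele)]
    if sub.empty:
        raise KeyError(f"no records for allele {allele}")
    best = sub.sort_values(["ic50_nm", "peptide"]).iloc[0]
    return str(best.peptide), float(best.ic50_nm)


def rank_and_distribution(
    records: pd.DataFrame,
    thresholds: tuple[int, ...] = (50, 500, 1000),
    rank_threshold: int = 500,
    lower_bound_nm: float | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Rank peptides by promiscuity and histogram the promiscuity values.

    Ranking: promiscuity at ``rank_threshold`` descending, ties by best IC50
    ascending then peptide.  ``lower_bound_nm`` optionally ignores records
    below that IC50 (ultra-strong binders) before counting.  The histogram is
    indexed by integer promiscuity with peptide counts as values.
    """
    working = records if lower_bound_nm is None else records[records["ic50_nm"] >= lower_bound_nm]
    rows = []
    for pep in sorted(working["peptide"].unique()):
        prof = promiscuity_profile(working, pep, thresholds)
        row = {"peptide": pep, "best_allele": prof.best_allele, "best_ic50": prof.best_ic50}
        for t in sorted(thresholds):
            row[f"n_alleles_lt_{t}"] = prof.count(t)
        rows.append(row)
    ranked = pd.DataFrame(rows)
    key = f"n_alleles_lt_{rank_threshold}"
    ranked = ranked.sort_values(
        [key, "best_ic50", "peptide"], ascending=[False, True, True]
    ).reset_index(drop=True)
    hist = ranked[key].value_counts().sort_index()
    hist.name = "n_peptides"
    return ranked, hist
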