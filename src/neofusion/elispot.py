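"""ELISpot positivity calling and comparison statistics.

Replicate spot counts (SFU per 10^6 cells) are background-subtracted by the
mean of the unstimulated negative-control wells.  A condition is called
positive when its adjusted mean reaches the 20-SFC threshold *and* a
Mann-Whitney U test against the reference (positive-control) wells reaches
significance — no multiple-testing correction, matching common ELISpot
practice.  The test is two-sided by default (sidedness is flag-switchable;
assay reports rarely state it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .util import ParameterError


@dataclass
class ElispotPlate:
    """Per-condition replicate SFU counts with named control conditions."""

    conditions: dict[str, list[float]]
    negative_control_label: str = "NC"
    positive_control_label: str = "CMV"

    def __post_init__(self) -> None:
        for label in (self.negative_control_label, self.positive_control_label):
            if label not in self.conditions or not self.conditions[label]:
                raise ParameterError(f"control condition {label!r} missing or empty")
        for cond, reps in self.conditions.items():
            if any(v < 0 for v in reps):
                raise ParameterError(f"negative spot count in condition {cond!r}")


@dataclass
class ElispotCall:
    condition: str
    adjusted_mean: float
    positive: bool
    p_value: float
    fold_vs_positive: float | None
    warning: str | None = field(default=None)


def background_subtract(plate: ElispotPlate) -> dict[str, list[float]]:
    """Subtract the negative-control mean from every replicate (including the
    positive control).  Values may go negative; they are clamped only for
    fold-change display."""
    nc = plate.conditions[plate.negative_control_label]
    nc_mean = float(np.mean(nc))
    return {cond: [v - nc_mean for v in reps] for cond, reps in plate.conditions.items()}


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U statistic (for x) and p value.

    Exact enumeration p for small untied samples; mid-rank normal
    approximation with tie correction otherwise.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    if not x or not y:
        raise ParameterError("both groups need at least one value")
    has_ties = len(set(x + y)) < len(x) + len(y)
    method = "asymptotic" if has_ties or len(x) + len(y) > 12 else "exact"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    p = float(min(res.pvalue, 1.0))
    return float(res.statistic), p


def fold_vs_reference(adjusted_condition_mean: float, adjusted_reference_mean: float) -> float | None:
    """Ratio of background-adjusted means, with negatives clamped to zero.
    A zero reference mean makes the ratio undefined (None)."""
    cond = max(adjusted_condition_mean, 0.0)
    ref = max(adjusted_reference_mean, 0.0)
    if ref == 0.0:
        return None
    return cond / ref


def call_positive(
    plate: ElispotPlate,
    threshold: float = 20.0,
    alpha: float = 0.05,
    alternative: str = "two-sided",
) -> list[ElispotCall]:
    """Positivity calls for every non-control condition.

    positive <=> adjusted mean >= threshold and Mann-Whitney p <= alpha versus
    the positive-control wells.  Conditions with fewer than one replicate in
    either group skip the test with a warning.
    """
    adjusted = background_subtract(plate)
    ref = adjusted[plate.positive_control_label]
    ref_mean = float(np.mean(ref))
    calls = []
    for cond in plate.conditions:
        if cond in (plate.negative_control_label, plate.positive_control_label):
            continue
        reps = adjusted[cond]
        mean = float(np.mean(reps))
        note = None
        if not reps or not ref:
            p = float("nan")
            note = "test skipped: missing replicates"
            warnings.warn(f"{cond}: {note}")
            positive = False
        else:
            _, p = mann_whitney(reps, ref, alternative=alternative)
            positive = mean >= threshold and p <= alpha
        calls.append(
            ElispotCall(
                condition=cond,
                adjusted_mean=mean,
                positive=positive,
                p_value=p,
                fold_vs_positive=fold_vs_reference(mean, ref_mean),
                warning=note,
            )
        )
    return calls


def load_plate(
    path, negative_control_label: str = "NC", positive_control_label: str = "CMV"
) -> ElispotPlate:
    """Read a plate TSV with columns condition / replicate / sfu_per_million."""
    df = pd.read_csv(path, sep="\t")
    conds: dict[str, list[float]] = {}
    for cond, grp in df.groupby("condition", sort=False):
        conds[str(cond)] = [float(v) for v in grp["sfu_per_million"]]
    return ElispotPlate(conds, negative_control_label, positive_control_label)


def calls_to_frame(calls: list[ElispotCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "condition": c.condition,
                "adjusted_mean": c.adjusted_mean,
                "p_value": c.p_value,
                "fold_vs_positive": c.fold_vs_positive,
                "positive": c.positive,
            }
            for c in calls
        ]
    )


def simulate_plate(
    peptides: list[str],
    responder: str,
    seed: int = 0,
    n_replicates: int = 4,
    background_mean: float = 12.0,
    positive_mean: float = 60.0,
    responder_fold: float = 2.0,
    replicate_cv: float = 0.10,
) -> ElispotPlate:
    """A synthetic demonstration plate: background wells, a positive-control
    pool, and one responding peptide at ``responder_fold`` times the positive
    control above background.  Stand-in for real plate counts, which assay
    readouts rarely publish per replicate.  Replicate noise defaults to a 10%
    CV, the commonly quoted intra-assay variability of ELISpot counts."""
    rng = np.random.default_rng(seed)

    def wells(mean: float) -> list[float]:
        return [
            float(max(0, rng.normal(mean, mean * replicate_cv))) for _ in range(n_replicates)
        ]

    conds: dict[str, list[float]] = {"NC": wells(background_mean)}
    conds["CMV"] = wells(background_mean + positive_mean)
    for pep in peptides:
        bump = positive_mean * responder_fold if pep == responder else rng.uniform(0, 6)
        conds[pep] = wells(background_mean + bump)
    return ElispotPlate(conds, "NC", "CMV")
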