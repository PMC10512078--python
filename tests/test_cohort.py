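"""Cohort filters are pure per-gene-pair predicates: cancer-free controls
exclude, adjacent normals do not, recurrence pools case samples across
subtypes, and the filters commute.  A brute-force predicate oracle re-derives
the retained set on random callsets."""

import itertools

import numpy as np
import pytest

from neofusion import (
    CohortCallSet,
    FusionCandidate,
    SampleMeta,
    exclude_control_fusions,
    external_recurrence_filter,
    prevalence_report,
    recurrence_filter,
)
from neofusion.cohort import retained_pairs


def cand(sid, g5, g3, jc=5, sp=3):
    return FusionCandidate(sid, g5, g3, 0, 0, 0, 0, jc, sp)


def meta(sid, group):
    return SampleMeta(sid, group, group in ("TNBC", "HER2+", "HR+"))


def make_callset(calls, groups):
    metas = {sid: meta(sid, groups[sid]) for sid in groups}
    full = {sid: calls.get(sid, []) for sid in groups}
    return CohortCallSet(full, metas)


@pytest.fixture
def basic_groups():
    return {
        "T1": "TNBC", "T2": "TNBC", "H1": "HER2+", "R1": "HR+",
        "A1": "adjacent_normal", "C1": "cancer_free_control",
    }


def test_control_pair_removed_everywhere(basic_groups):
    cs = make_callset(
        {
            "T1": [cand("T1", "A", "B")],
            "T2": [cand("T2", "A", "B")],
            "H1": [cand("H1", "A", "B")],
            "C1": [cand("C1", "A", "B")],
        },
        basic_groups,
    )
    out = exclude_control_fusions(cs)
    assert retained_pairs(out) == set()


def test_adjacent_normal_pair_retained(basic_groups):
    cs = make_callset(
        {
            "T1": [cand("T1", "A", "B")],
            "T2": [cand("T2", "A", "B")],
            "H1": [cand("H1", "A", "B")],
            "A1": [cand("A1", "A", "B")],
        },
        basic_groups,
    )
    out = exclude_control_fusions(cs)
    assert retained_pairs(out) == {("A", "B")}


def test_empty_callset_passes_through(basic_groups):
    cs = make_callset({}, basic_groups)
    assert retained_pairs(exclude_control_fusions(cs)) == set()


def test_missing_controls_warns_and_passes_through():
    groups = {"T1": "TNBC"}
    cs = make_callset({"T1": [cand("T1", "A", "B")]}, groups)
    with pytest.warns(UserWarning):
        out = exclude_control_fusions(cs)
    assert retained_pairs(out) == {("A", "B")}


def test_recurrence_boundary(basic_groups):
    three = make_callset(
        {s: [cand(s, "A", "B", jc=1)] for s in ("T1", "T2", "H1")}, basic_groups
    )
    assert retained_pairs(recurrence_filter(three, 3)) == {("A", "B")}
    two = make_callset({s: [cand(s, "A", "B", jc=1)] for s in ("T1", "T2")}, basic_groups)
    assert retained_pairs(recurrence_filter(two, 3)) == set()


def test_zero_junction_read_calls_do_not_count(basic_groups):
    cs = make_callset(
        {s: [cand(s, "A", "B", jc=0)] for s in ("T1", "T2", "H1")}, basic_groups
    )
    assert retained_pairs(recurrence_filter(cs, 3)) == set()


def test_recurrence_monotone_in_min_patients():
    groups = {f"S{i}": ["TNBC", "HER2+", "HR+"][i % 3] for i in range(9)}
    groups["C1"] = "cancer_free_control"
    rng = np.random.default_rng(0)
    calls = {
        f"S{i}": [cand(f"S{i}", "A", "B")] if rng.random() < 0.8 else [] for i in range(9)
    }
    cs = make_callset(calls, groups)
    sizes = [len(retained_pairs(recurrence_filter(cs, mp))) for mp in range(1, 6)]
    assert sizes == sorted(sizes, reverse=True)


def test_external_recurrence_filter(basic_groups):
    cs = make_callset(
        {"T1": [cand("T1", "A", "B"), cand("T1", "C", "D")]}, basic_groups
    )
    cs.external_evidence = {("A", "B")}
    assert retained_pairs(external_recurrence_filter(cs)) == {("A", "B")}
    assert retained_pairs(external_recurrence_filter(cs, enabled=False)) == {
        ("A", "B"),
        ("C", "D"),
    }


def test_filters_commute(basic_groups):
    cs = make_callset(
        {
            "T1": [cand("T1", "A", "B"), cand("T1", "C", "D")],
            "T2": [cand("T2", "A", "B")],
            "H1": [cand("H1", "A", "B")],
            "C1": [cand("C1", "C", "D")],
        },
        basic_groups,
    )
    ab = retained_pairs(recurrence_filter(exclude_control_fusions(cs), 3))
    ba = retained_pairs(exclude_control_fusions(recurrence_filter(cs, 3)))
    assert ab == ba == {("A", "B")}


def test_filters_invariant_under_sample_relabeling(basic_groups):
    calls = {
        "T1": [cand("T1", "A", "B")],
        "T2": [cand("T2", "A", "B")],
        "H1": [cand("H1", "A", "B"), cand("H1", "C", "D")],
        "C1": [cand("C1", "C", "D")],
    }
    cs = make_callset(calls, basic_groups)
    relabel = {"T1": "T2", "T2": "T1", "H1": "H1", "R1": "R1", "A1": "A1", "C1": "C1"}
    calls2 = {
        relabel[s]: [cand(relabel[s], c.five_gene, c.three_gene) for c in cs.calls[s]]
        for s in calls
    }
    cs2 = make_callset(calls2, basic_groups)
    pipeline = lambda c: retained_pairs(recurrence_filter(exclude_control_fusions(c), 3))
    assert pipeline(cs) == pipeline(cs2)


def test_retained_set_matches_brute_force_predicate_oracle():
    rng = np.random.default_rng(11)
    pairs = [("A", "B"), ("C", "D"), ("E", "F"), ("G", "H")]
    groups = {f"S{i}": ["TNBC", "HER2+", "HR+"][i % 3] for i in range(8)}
    groups.update({"A1": "adjacent_normal", "C1": "cancer_free_control", "C2": "cancer_free_control"})
    for trial in range(20):
        calls = {}
        present = {}
        for sid in groups:
            mine = [p for p in pairs if rng.random() < 0.35]
            present[sid] = set(mine)
            calls[sid] = [cand(sid, *p, jc=int(rng.integers(1, 9))) for p in mine]
        cs = make_callset(calls, groups)
        got = retained_pairs(recurrence_filter(exclude_control_fusions(cs), 3))
        expected = set()
        for p in pairs:
            in_control = any(p in present[s] for s in ("C1", "C2"))
            case_support = sum(
                1 for s, g in groups.items()
                if g in ("TNBC", "HER2+", "HR+") and p in present[s]
            )
            if not in_control and case_support >= 3:
                expected.add(p)
        assert got == expected, f"trial {trial}"


def test_prevalence_report_arithmetic():
    groups = {f"T{i}": "TNBC" for i in range(5)}
    groups.update({"C1": "cancer_free_control"})
    calls = {"T0": [cand("T0", "A", "B", jc=10)], "T1": [cand("T1", "A", "B", jc=20)]}
    cs = make_callset(calls, groups)
    df = prevalence_report(cs)
    row = df.iloc[0]
    assert row["TNBC_positive"] == 2
    assert row["TNBC_avg_junction_reads"] == 15
    assert row["HR+_positive"] == 0 and row["HR+_avg_junction_reads"] == 0
    full = prevalence_report(cs, round_integer=False)
    assert full.iloc[0]["TNBC_avg_junction_reads"] == pytest.approx(15.0)


def test_prevalence_rounds_half_up():
    groups = {"T0": "TNBC", "T1": "TNBC", "C1": "cancer_free_control"}
    calls = {"T0": [cand("T0", "A", "B", jc=1)], "T1": [cand("T1", "A", "B", jc=2)]}
    df = prevalence_report(make_callset(calls, groups))
    assert df.iloc[0]["TNBC_avg_junction_reads"] == 2  # mean 1.5 rounds up
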