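"""Mapper semantics: the cost model (mismatch 2, indel 3), the similarity
gate, pair classification, and split mapping of junction-crossing reads, all
checked against exhaustive oracles on small instances."""

import numpy as np
import pytest

from neofusion import (
    AlignConfig,
    PlantedFusion,
    TranscriptomeIndex,
    align_read,
    build_fusion_cdna_truth,
    classify_pair,
    split_map,
)
from neofusion.util import revcomp


def _exhaustive_best_cost(read, target, mismatch=2, gap=3):
    """Full semi-global DP over the whole target, both strands: the
    independent oracle for the minimum alignment cost of the entire read."""
    best = None
    for s in (read, revcomp(read)):
        n, m = len(s), len(target)
        prev = [0] * (m + 1)
        for i in range(1, n + 1):
            cur = [prev[0] + gap] + [0] * m
            for j in range(1, m + 1):
                cur[j] = min(
                    prev[j - 1] + (0 if target[j - 1] == s[i - 1] else mismatch),
                    prev[j] + gap,
                    cur[j - 1] + gap,
                )
            prev = cur
        cost = min(prev)
        best = cost if best is None else min(best, cost)
    return best


@pytest.fixture(scope="module")
def small_index():
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), 1000))
    return TranscriptomeIndex({"T1": seq}, k=16, split_k=12), seq


def test_exact_unique_read_maps_once(small_index):
    index, seq = small_index
    read = seq[100:176]
    hits = align_read(read, index)
    assert len(hits) == 1
    h = hits[0]
    assert (h.target_start, h.target_end, h.mismatches, h.score, h.strand) == (100, 176, 0, 0, "+")
    assert h.read_end - h.read_start == 76


def test_single_substitution_costs_two(small_index):
    index, seq = small_index
    read = list(seq[300:376])
    read[40] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[40]]
    hits = align_read("".join(read), index)
    assert hits[0].mismatches == 1
    assert hits[0].score == 2


def test_reverse_complement_reads_found(small_index):
    index, seq = small_index
    hits = align_read(revcomp(seq[500:576]), index)
    assert hits and hits[0].strand == "-" and hits[0].target_start == 500


def test_unalignable_read_returns_empty(small_index):
    index, _ = small_index
    rng = np.random.default_rng(1)
    assert align_read("".join(rng.choice(list("ACGT"), 76)), index) == []


def test_best_cost_matches_exhaustive_dp_oracle(small_index):
    index, seq = small_index
    rng = np.random.default_rng(7)
    for _ in range(30):
        start = int(rng.integers(0, len(seq) - 76))
        read = list(seq[start : start + 76])
        kind = rng.integers(0, 4)
        for _ in range(int(kind) if kind < 3 else 0):  # 0-2 substitutions
            i = int(rng.integers(0, len(read)))
            read[i] = "ACGT"[int(rng.integers(0, 4))]
        if kind == 3:  # one small indel
            i = int(rng.integers(20, 56))
            if rng.random() < 0.5:
                del read[i]
            else:
                read.insert(i, "ACGT"[int(rng.integers(0, 4))])
        read = "".join(read)
        if rng.random() < 0.5:
            read = revcomp(read)
        hits = align_read(read, index)
        oracle = _exhaustive_best_cost(read, seq)
        if hits:
            assert hits[0].score == oracle
        else:
            # rejected only by the similarity gate, never by a missed placement
            assert oracle > 2 * int(0.2 * len(read))


def test_max_hits_caps_repetitive_placements():
    unit = "ACGTTGCAAGGTCCATAGGC"  # 20-mer repeated: one read, many diagonals
    seq = unit * 60
    index = TranscriptomeIndex({"R": seq}, k=16, split_k=12)
    hits = align_read(seq[:76], index, AlignConfig(max_hits=10))
    assert len(hits) == 10
    assert hits == sorted(hits, key=lambda h: (h.score, h.target, h.target_start, h.strand))


def test_pair_classification(toy_reference, index, tumor_sample, fusion_truth):
    by_origin = {}
    truth_src = dict(zip(tumor_sample.truth.pair_id, tumor_sample.truth.origin))
    for p in tumor_sample.pairs:
        by_origin.setdefault(truth_src[p.pair_id], []).append(p)
    wt = by_origin["wildtype"][0]
    k = classify_pair(align_read(wt.mate1_seq, index), align_read(wt.mate2_seq, index))
    assert k == "concordant"
    # spanning fusion pair: mates in two genes
    span = by_origin["fusion_spanning"][0]
    k = classify_pair(align_read(span.mate1_seq, index), align_read(span.mate2_seq, index))
    assert k == "discordant_two_genes"
    # scrambled mate 2
    rng = np.random.default_rng(0)
    scrambled = "".join(rng.choice(list("ACGT"), 76))
    assert classify_pair(align_read(wt.mate1_seq, index), align_read(scrambled, index)) == "half_mapped"
    assert classify_pair([], []) == "unmapped"


def test_split_maps_error_free_junction_read_at_true_offset(toy_reference, index, fusion_truth):
    j = fusion_truth.junction_offset_nt
    read = fusion_truth.cdna[j - 30 : j + 46]
    sp = split_map(read, index)
    assert sp is not None
    assert sp.junction_offset_in_read == 30
    assert (sp.left.target, sp.right.target) == ("GENE2", "GENE3")
    assert sp.bp5_transcript == j  # fusion coords == 5' transcript coords left of the junction
    # breakpoints sit exactly on annotated exon boundaries
    g5 = toy_reference.genes["GENE2"]
    g3 = toy_reference.genes["GENE3"]
    assert sp.bp5_transcript in g5.exon_end_offsets()
    assert sp.bp3_transcript in g3.exon_start_offsets()


def test_split_reported_on_forward_sense_for_reverse_reads(index, fusion_truth):
    j = fusion_truth.junction_offset_nt
    read = revcomp(fusion_truth.cdna[j - 40 : j + 36])
    sp = split_map(read, index)
    assert sp is not None
    assert sp.left.target == "GENE2" and sp.right.target == "GENE3"
    assert sp.junction_offset_in_read == 40
    assert sp.seq_forward == revcomp(read)


def test_read_inside_one_exon_is_not_split(index, toy_reference):
    t = toy_reference.transcript("GENE2")
    assert split_map(t[10:86], index) is None


def test_overhang_below_min_unaligned_is_not_split(index, fusion_truth):
    j = fusion_truth.junction_offset_nt
    read = fusion_truth.cdna[j - 68 : j + 8]  # only 8 nt past the junction
    sp = split_map(read, index)
    assert sp is None


def test_split_consistency_and_arm_lengths(index, fusion_truth):
    j = fusion_truth.junction_offset_nt
    rng = np.random.default_rng(5)
    cfg = AlignConfig()
    for _ in range(20):
        off = int(rng.integers(16, 61))
        read = fusion_truth.cdna[j - off : j - off + 76]
        sp = split_map(read, index, cfg)
        if sp is None:
            continue
        assert sp.left.read_end == sp.right.read_start == sp.junction_offset_in_read
        assert sp.left.read_start == 0 and sp.right.read_end == len(read)
        assert sp.junction_offset_in_read >= cfg.min_unaligned
        assert len(read) - sp.junction_offset_in_read >= cfg.min_unaligned
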