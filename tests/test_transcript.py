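"""Consensus junction building (majority vote, motif extraction), exon
boundary assignment with the 10-nt tolerance, fusion cDNA assembly, and
in-silico PCR conventions."""

import numpy as np
import pytest

from neofusion import (
    GeneModel,
    PlantedFusion,
    Reference,
    SampleMeta,
    align_sample,
    assemble_fusion_cdna,
    build_consensus_junction,
    build_fusion_cdna_truth,
    detect_fusions,
    in_silico_pcr,
    map_exon_boundaries,
    simulate_sample,
)
from neofusion.transcript import ClusterConflictError, FusionJunction, UnannotatedBreakpointError
from neofusion.util import ParameterError, revcomp


@pytest.fixture(scope="module")
def junction_cluster(toy_reference, index, tumor_sample):
    sa = align_sample(tumor_sample.pairs, index)
    cands = detect_fusions(sa, toy_reference)
    return cands[0].split_reads


def test_error_free_consensus_equals_planted_sequence(junction_cluster, fusion_truth):
    j = build_consensus_junction(junction_cluster)
    truth = fusion_truth.cdna
    jt = fusion_truth.junction_offset_nt
    window = truth[jt - j.junction_offset : jt + (len(j.consensus_seq) - j.junction_offset)]
    assert j.consensus_seq == window
    assert j.five_motif == truth[jt - 6 : jt]
    assert j.three_motif == truth[jt : jt + 6]
    assert j.n_supporting_reads == len(junction_cluster)


def test_single_read_consensus_is_that_read(junction_cluster):
    one = [junction_cluster[0]]
    j = build_consensus_junction(one)
    assert j.consensus_seq == one[0].seq_forward
    assert j.junction_offset == one[0].junction_offset_in_read


def test_consensus_with_sequencing_errors_matches_truth(
    toy_reference, index, planted_fusion, fusion_truth
):
    for seed in range(3):
        s = simulate_sample(
            toy_reference, [planted_fusion], SampleMeta(f"E{seed}", "TNBC", True),
            1500, error_rate=0.001, seed=seed,
        )
        sa = align_sample(s.pairs, index)
        cands = detect_fusions(sa, toy_reference)
        j = build_consensus_junction(cands[0].split_reads)
        jt = fusion_truth.junction_offset_nt
        # compare only well-covered columns around the junction
        assert j.five_motif == fusion_truth.cdna[jt - 6 : jt]
        assert j.three_motif == fusion_truth.cdna[jt : jt + 6]
        core = j.consensus_seq[j.junction_offset - 30 : j.junction_offset + 30]
        assert core == fusion_truth.cdna[jt - 30 : jt + 30]


def test_conflicting_breakpoints_raise(junction_cluster):
    import dataclasses

    a = junction_cluster[0]
    shifted_left = dataclasses.replace(
        a.left, target_start=a.left.target_start + 20, target_end=a.left.target_end + 20
    )
    b = dataclasses.replace(a, left=shifted_left)
    with pytest.raises(ClusterConflictError):
        build_consensus_junction([a, b])


def test_motif_invariant_for_constructed_junctions():
    seq = "ACGTACGTGGGTTTCCCAAA"
    j = FusionJunction(seq, 10, "A", "B", 100, 50, 3)
    assert j.five_motif == seq[4:10]
    assert j.three_motif == seq[10:16]
    assert len(j.five_motif) == len(j.three_motif) == 6


def test_exon_boundaries_assigned_exactly(junction_cluster, toy_reference):
    j = build_consensus_junction(junction_cluster)
    j = map_exon_boundaries(j, toy_reference)
    assert j.five_boundary == ("GENE2", 1, 0)
    assert j.three_boundary == ("GENE3", 2, 0)


def test_boundary_within_tolerance_reported_with_distance(junction_cluster, toy_reference):
    j = build_consensus_junction(junction_cluster)
    j.bp5_transcript += 3
    j = map_exon_boundaries(j, toy_reference)
    assert j.five_boundary[2] == 3


def test_boundary_beyond_tolerance_raises(junction_cluster, toy_reference):
    j = build_consensus_junction(junction_cluster)
    j.bp5_transcript += 11
    with pytest.raises(UnannotatedBreakpointError):
        map_exon_boundaries(j, toy_reference)


def _two_gene_reference():
    rng = np.random.default_rng(9)
    contig = "".join(rng.choice(list("ACGT"), 1200))
    gA = GeneModel("A", "chrT", "+", ((0, 100), (150, 270)))
    gB = GeneModel("B", "chrT", "+", ((400, 480), (600, 690)))
    return Reference({"chrT": contig}, {"A": gA, "B": gB})


def test_assembly_arithmetic_on_constructed_exons():
    ref = _two_gene_reference()
    ft = assemble_fusion_cdna(ref, ("A", 2), ("B", 2))
    assert ft.length_nt == 100 + 120 + 90
    assert ft.junction_offset_nt == 220
    full = assemble_fusion_cdna(ref, ("A", 2), ("B", 1))
    assert full.cdna == ref.transcript("A") + ref.transcript("B")


def test_assembly_agrees_with_truth_builder(toy_reference):
    for e5, e3 in [(1, 2), (2, 1), (1, 1)]:
        fus = PlantedFusion("GENE2", e5, "GENE3", e3, 0.0)
        truth = build_fusion_cdna_truth(toy_reference, fus)
        asm = assemble_fusion_cdna(toy_reference, ("GENE2", e5), ("GENE3", e3))
        assert asm.cdna == truth.cdna
        assert asm.junction_offset_nt == truth.junction_offset_nt


def test_pcr_product_length_is_outer_to_outer():
    rng = np.random.default_rng(3)
    fwd = "GCCTGCAAGTGACGAGAG"
    rev = "CGGTCCAACTGTATGCTTTC"
    middle = "".join(rng.choice(list("ACGT"), 100 - len(fwd) - len(rev)))
    template = (
        "".join(rng.choice(list("ACGT"), 50)) + fwd + middle + revcomp(rev)
        + "".join(rng.choice(list("ACGT"), 50))
    )
    assert in_silico_pcr(template, fwd, rev) == [100]


def test_pcr_requires_both_primers_and_orientation():
    rng = np.random.default_rng(4)
    fwd = "GCCTGCAAGTGACGAGAG"
    rev = "CGGTCCAACTGTATGCTTTC"
    bare = "".join(rng.choice(list("ACGT"), 200))
    assert in_silico_pcr(bare + fwd + bare, fwd, rev) == []
    # reverse site upstream of forward site -> wrong orientation, no product
    template = revcomp(rev) + "".join(rng.choice(list("ACGT"), 40)) + fwd
    assert in_silico_pcr(template, fwd, rev) == []
    with pytest.raises(ParameterError):
        in_silico_pcr(bare, "ACGTACGT", rev)


def test_pcr_invariant_to_flanking_sequence():
    rng = np.random.default_rng(5)
    fwd = "GCCTGCAAGTGACGAGAG"
    rev = "CGGTCCAACTGTATGCTTTC"
    core = fwd + "".join(rng.choice(list("ACGT"), 83)) + revcomp(rev)
    for flank_seed in range(3):
        r2 = np.random.default_rng(flank_seed)
        template = (
            "".join(r2.choice(list("ACGT"), 30)) + core + "".join(r2.choice(list("ACGT"), 60))
        )
        assert in_silico_pcr(template, fwd, rev) == [len(core)]


def test_pcr_reports_multiple_products():
    fwd = "GCCTGCAAGTGACGAGAG"
    rev = "CGGTCCAACTGTATGCTTTC"
    spacer = "ATGCATGCATGCATGCATGC"
    template = fwd + spacer + revcomp(rev) + spacer + revcomp(rev)
    products = in_silico_pcr(template, fwd, rev)
    assert len(products) == 2
    assert products[0] < products[1]
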