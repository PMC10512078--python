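"""The simulated cohort must have the structure the caller assumes: exact
determinism, consistent annotation, truth labels that partition the pairs, and
error-free reads that are literal substrings of their source transcripts."""

import io

import numpy as np
import pytest

from neofusion import (
    GeneModel,
    PlantedFusion,
    Reference,
    SampleMeta,
    build_fusion_cdna_truth,
    generate_reference,
    simulate_sample,
)
from neofusion.util import ParameterError, revcomp


def _toy_gene(gid, start, exon_lens, gap=5):
    exons, cur = [], start
    for ln in exon_lens:
        exons.append((cur, cur + ln))
        cur += ln + gap
    return GeneModel(gid, "chrT", "+", tuple(exons))


def test_reference_is_deterministic_and_adjacent_same_strand():
    a = generate_reference(7, n_genes=2)
    b = generate_reference(7, n_genes=2)
    assert a.contigs == b.contigs
    fa, fb = io.StringIO(), io.StringIO()
    for ref, buf in ((a, fa), (b, fb)):
        for name in sorted(ref.contigs):
            buf.write(f">{name}\n{ref.contigs[name]}\n")
    assert fa.getvalue() == fb.getvalue()
    assert {g.strand for g in a.genes.values()} == {"+"}
    assert len(a.genes) == 2


def test_every_exon_lies_within_contig_bounds():
    ref = generate_reference(3, n_genes=5)
    for gene in ref.genes.values():
        contig = ref.contigs[gene.chrom]
        for s, e in gene.exons:
            assert 0 <= s < e <= len(contig)
    spans = sorted(g.span for g in ref.genes.values())
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2, "genes overlap"


def test_invalid_generator_ranges_rejected():
    with pytest.raises(ParameterError):
        generate_reference(1, n_genes=1)
    with pytest.raises(ParameterError):
        generate_reference(1, exon_len_range=(200, 100))


def test_fusion_cdna_arithmetic_on_constructed_genes():
    gA = _toy_gene("A", 0, [10, 10, 10])
    gB = _toy_gene("B", 100, [10, 10, 10])
    contig = "".join(np.random.default_rng(0).choice(list("ACGT"), 200))
    ref = Reference({"chrT": contig}, {"A": gA, "B": gB})
    ft = build_fusion_cdna_truth(ref, PlantedFusion("A", 2, "B", 2, 0.0))
    assert ft.length_nt == 40
    assert ft.junction_offset_nt == 20
    full = build_fusion_cdna_truth(ref, PlantedFusion("A", 3, "B", 1, 0.0))
    assert full.cdna == ref.transcript("A") + ref.transcript("B")


def test_fusion_cdna_matches_per_exon_concatenation_oracle():
    for seed in range(20):
        ref = generate_reference(seed, n_genes=3)
        g5, g3 = ref.genes["GENE1"], ref.genes["GENE2"]
        rng = np.random.default_rng(seed)
        e5 = int(rng.integers(1, g5.n_exons + 1))
        e3 = int(rng.integers(1, g3.n_exons + 1))
        ft = build_fusion_cdna_truth(ref, PlantedFusion("GENE1", e5, "GENE2", e3, 0.0))
        contig = ref.contigs[g5.chrom]
        oracle = "".join(contig[s:e] for s, e in g5.exons[:e5]) + "".join(
            contig[s:e] for s, e in g3.exons[e3 - 1 :]
        )
        assert ft.cdna == oracle


def test_antisense_fusion_rejected():
    gA = _toy_gene("A", 0, [30])
    gB = GeneModel("B", "chrT", "-", ((100, 130),))
    ref = Reference({"chrT": "A" * 200}, {"A": gA, "B": gB})
    with pytest.raises(ParameterError, match="orientation"):
        build_fusion_cdna_truth(ref, PlantedFusion("A", 1, "B", 1, 0.0))


def test_simulation_truth_partitions_pairs(tumor_sample):
    truth = tumor_sample.truth
    assert len(truth) == 2000
    assert set(truth.origin) <= {"wildtype", "fusion_spanning", "fusion_junction_crossing"}
    assert len(tumor_sample.pairs) == 2000


def test_zero_weight_yields_no_fusion_pairs(toy_reference):
    meta = SampleMeta("S09", "HR+", True)
    s = simulate_sample(
        toy_reference,
        [PlantedFusion("GENE2", 1, "GENE3", 2, 0.0)],
        meta, 300, error_rate=0.0, seed=5,
    )
    assert (s.truth.origin == "wildtype").all()


def test_error_free_reads_are_transcript_substrings(toy_reference, planted_fusion, fusion_truth):
    meta = SampleMeta("S02", "HER2+", True)
    s = simulate_sample(toy_reference, [planted_fusion], meta, 300, error_rate=0.0, seed=3)
    sources = list(toy_reference.transcriptome().values()) + [fusion_truth.cdna]
    for p in s.pairs:
        assert any(p.mate1_seq in t for t in sources)
        assert any(revcomp(p.mate2_seq) in t for t in sources)


def test_junction_crossing_reads_contain_junction_12mer(toy_reference):
    fus = PlantedFusion("GENE2", 1, "GENE3", 2, 1.0)
    ft = build_fusion_cdna_truth(toy_reference, fus)
    j = ft.junction_offset_nt
    kmer = ft.cdna[j - 6 : j + 6]
    meta = SampleMeta("S03", "TNBC", True)
    s = simulate_sample(toy_reference, [fus], meta, 500, error_rate=0.0, seed=11)
    crossing = [p for p in s.pairs if p.truth_origin == "fusion_junction_crossing"]
    assert crossing
    for p in crossing:
        assert kmer in p.mate1_seq or kmer in revcomp(p.mate2_seq)


def test_fusion_fraction_within_binomial_noise(toy_reference):
    fus = PlantedFusion("GENE2", 1, "GENE3", 2, 0.5)
    meta = SampleMeta("S04", "HR+", True)
    s = simulate_sample(toy_reference, [fus], meta, 2000, error_rate=0.0, seed=8)
    frac = (s.truth.source == "GENE2|GENE3").mean()
    sd = (0.5 * 0.5 / 2000) ** 0.5
    assert abs(frac - 0.5) < 3 * sd


def test_simulation_deterministic_per_seed(toy_reference, planted_fusion):
    meta = SampleMeta("S05", "TNBC", True)
    a = simulate_sample(toy_reference, [planted_fusion], meta, 200, seed=13)
    b = simulate_sample(toy_reference, [planted_fusion], meta, 200, seed=13)
    assert [p.mate1_seq for p in a.pairs] == [p.mate1_seq for p in b.pairs]
    assert a.truth.equals(b.truth)


def test_control_meta_cannot_be_case():
    with pytest.raises(ParameterError):
        SampleMeta("C01", "cancer_free_control", True)
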