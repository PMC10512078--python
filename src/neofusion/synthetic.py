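"""Synthetic cohort generator.

Emulates the statistical structure the fusion-discovery analysis assumes:
a toy reference with adjacent same-strand genes, a planted read-through
fusion joining the end of an upstream gene's exon to the start of a
downstream gene's exon, and paired-end read sets (2x76 bp by default, per-base
substitution error 0.001) drawn from the spliced wild-type transcripts and the
fusion cDNA.  Every simulated pair carries a truth label so recall/false-
positive properties of the caller can be measured exactly.

Only same-strand, 5'->3' colinear gene pairs are simulated — the geometry of a
transcriptional read-through followed by intergenic cis-splicing.  Antisense
fusions raise an error.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genes import GeneModel, Reference
from .transcript import FusionTranscript
from .util import ParameterError, revcomp

BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

GROUPS = ("TNBC", "HER2+", "HR+", "adjacent_normal", "cancer_free_control")


@dataclass(frozen=True)
class SampleMeta:
    """Cohort membership of one sample."""

    sample_id: str
    group: str
    is_case: bool

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ParameterError(f"unknown group {self.group!r}")
        if self.group == "cancer_free_control" and self.is_case:
            raise ParameterError("cancer_free_control samples cannot be cases")


@dataclass(frozen=True)
class PlantedFusion:
    """A read-through fusion: 5' gene exons 1..five_last_exon joined to
    3' gene exons three_first_exon..n, expressed at ``expression_weight``
    (fraction of fragments drawn from the fusion cDNA)."""

    five_gene: str
    five_last_exon: int
    three_gene: str
    three_first_exon: int
    expression_weight: float

    def __post_init__(self) -> None:
        if self.five_gene == self.three_gene:
            raise ParameterError("fusion partners must be distinct genes")
        if not 0.0 <= self.expression_weight <= 1.0:
            raise ParameterError("expression_weight must lie in [0, 1]")


@dataclass(frozen=True)
class ReadPair:
    pair_id: str
    mate1_seq: str
    mate2_seq: str
    sample_id: str
    truth_origin: str  # wildtype | fusion_spanning | fusion_junction_crossing


@dataclass
class SimulatedSample:
    meta: SampleMeta
    pairs: list[ReadPair]
    truth: pd.DataFrame


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def _coding_spliced(rng: np.random.Generator, gene: GeneModel) -> str:
    """A spliced sequence with an ATG..stop frame-0 CDS and an in-frame ATG
    planted shortly after each internal exon start (so downstream-gene
    truncation ORFs exist in fusions)."""
    total = gene.transcript_length
    n_codons = total // 3
    codons = ["ATG"] + [
        _SENSE_CODONS[rng.integers(0, len(_SENSE_CODONS))] for _ in range(n_codons - 2)
    ] + ["TAA"]
    for start in gene.exon_start_offsets()[1:]:
        ci = start // 3 + 4
        if 0 < ci < n_codons - 2:
            codons[ci] = "ATG"
    tail = _random_seq(rng, total - 3 * n_codons)
    return "".join(codons) + tail


def generate_reference(
    seed: int,
    n_genes: int = 6,
    exon_count_range: tuple[int, int] = (2, 4),
    exon_len_range: tuple[int, int] = (120, 200),
    intron_len_range: tuple[int, int] = (60, 120),
    intergenic_range: tuple[int, int] = (150, 300),
    coding: bool = True,
    chrom: str = "chrS",
) -> Reference:
    """Generate a deterministic toy reference: ``n_genes`` plus-strand genes
    laid out left to right on one contig, so every consecutive pair is an
    adjacent same-strand pair able to host a read-through fusion."""
    for name, (lo, hi) in {
        "exon_count_range": exon_count_range,
        "exon_len_range": exon_len_range,
        "intron_len_range": intron_len_range,
        "intergenic_range": intergenic_range,
    }.items():
        if lo <= 0 or hi < lo:
            raise ParameterError(f"invalid {name}: ({lo}, {hi})")
    if n_genes < 2:
        raise ParameterError("n_genes must be >= 2")

    rng = np.random.default_rng(seed)
    genes: dict[str, GeneModel] = {}
    pieces: list[str] = []
    cursor = 0

    def pad(n: int) -> None:
        nonlocal cursor
        pieces.append(_random_seq(rng, n))
        cursor += n

    pad(100)
    for gi in range(n_genes):
        gid = f"GENE{gi + 1}"
        n_ex = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
        exons = []
        for ei in range(n_ex):
            ln = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
            exons.append((cursor, cursor + ln))
            pieces.append("")  # placeholder, filled after splicing below
            cursor += ln
            if ei < n_ex - 1:
                pad(int(rng.integers(intron_len_range[0], intron_len_range[1] + 1)))
        gene = GeneModel(gid, chrom, "+", tuple(exons))
        spliced = _coding_spliced(rng, gene) if coding else _random_seq(rng, gene.transcript_length)
        # distribute the spliced sequence back into the exon placeholders
        off = 0
        ph = [i for i, p in enumerate(pieces) if p == ""]
        for idx, (s, e) in zip(ph, exons):
            pieces[idx] = spliced[off : off + (e - s)]
            off += e - s
        genes[gid] = gene
        if gi < n_genes - 1:
            pad(int(rng.integers(intergenic_range[0], intergenic_range[1] + 1)))
    pad(100)
    return Reference(contigs={chrom: "".join(pieces)}, genes=genes)


def build_fusion_cdna_truth(reference: Reference, fusion: PlantedFusion) -> FusionTranscript:
    """Ground-truth fusion cDNA: spliced 5'-gene exons 1..five_last_exon
    followed by spliced 3'-gene exons three_first_exon..n."""
    g5 = reference.genes[fusion.five_gene]
    g3 = reference.genes[fusion.three_gene]
    if g5.strand != g3.strand:
        raise ParameterError(
            "unsupported orientation: read-through fusions require same-strand genes"
        )
    if not 1 <= fusion.five_last_exon <= g5.n_exons:
        raise ParameterError(f"five_last_exon out of range for {g5.gene_id}")
    if not 1 <= fusion.three_first_exon <= g3.n_exons:
        raise ParameterError(f"three_first_exon out of range for {g3.gene_id}")
    t5 = reference.transcript(g5.gene_id)
    t3 = reference.transcript(g3.gene_id)
    off5 = g5.exon_end_offsets()[fusion.five_last_exon - 1]
    off3 = g3.exon_start_offsets()[fusion.three_first_exon - 1]
    cdna = t5[:off5] + t3[off3:]
    return FusionTranscript(
        cdna=cdna,
        segments=(
            (g5.gene_id, (1, fusion.five_last_exon)),
            (g3.gene_id, (fusion.three_first_exon, g3.n_exons)),
        ),
        junction_offset_nt=off5,
    )


def simulate_sample(
    reference: Reference,
    fusions: list[PlantedFusion],
    meta: SampleMeta,
    n_pairs: int,
    read_len: int = 76,
    fragment_mean: float = 180.0,
    fragment_sd: float = 25.0,
    error_rate: float = 0.001,
    seed: int = 0,
    junction_anchor: int = 6,
) -> SimulatedSample:
    """Simulate one sample's paired-end reads with truth labels.

    Fragments come from the spliced wild-type transcripts (uniformly across
    genes) or, with probability ``expression_weight``, from a fusion cDNA.
    Fragment lengths follow a truncated normal, resampled until they fit
    ``read_len <= len <= transcript length``.  Mate 2 is reverse-complemented.
    A fusion fragment is labelled ``fusion_junction_crossing`` when a mate's
    footprint covers at least ``junction_anchor`` bases on each side of the
    junction, ``fusion_spanning`` when the mates bracket the junction without
    crossing it, and ``wildtype`` otherwise (one-sided fragments carry no
    fusion signal).
    """
    if n_pairs <= 0:
        raise ParameterError("n_pairs must be positive")
    if not 0.0 <= error_rate < 0.5:
        raise ParameterError("error_rate must lie in [0, 0.5)")
    if fragment_mean <= read_len:
        raise ParameterError("fragment_mean must exceed read_len")
    if not reference.genes:
        raise ParameterError("empty transcript set")

    total_w = sum(f.expression_weight for f in fusions)
    if total_w > 1.0:
        raise ParameterError("fusion expression weights sum above 1")

    rng = np.random.default_rng(seed)
    wt_ids = sorted(reference.genes)
    sources: list[tuple[str, str, int | None]] = []  # (label, seq, junction)
    weights: list[float] = []
    for f in fusions:
        ft = build_fusion_cdna_truth(reference, f)
        sources.append((f"{f.five_gene}|{f.three_gene}", ft.cdna, ft.junction_offset_nt))
        weights.append(f.expression_weight)
    wt_share = (1.0 - total_w) / len(wt_ids)
    for gid in wt_ids:
        sources.append((gid, reference.transcript(gid), None))
        weights.append(wt_share)

    probs = np.asarray(weights)
    probs = probs / probs.sum()
    choices = rng.choice(len(sources), size=n_pairs, p=probs)

    pairs: list[ReadPair] = []
    rows = []
    for i in range(n_pairs):
        label, seq, junction = sources[choices[i]]
        tlen = len(seq)
        if tlen < read_len:
            raise ParameterError(f"transcript {label} shorter than read length")
        while True:
            fl = int(round(rng.normal(fragment_mean, fragment_sd)))
            if read_len <= fl <= tlen:
                break
        start = int(rng.integers(0, tlen - fl + 1))
        frag = seq[start : start + fl]
        m1 = frag[:read_len]
        m2 = revcomp(frag[-read_len:])
        if error_rate > 0:
            m1 = _mutate(rng, m1, error_rate)
            m2 = _mutate(rng, m2, error_rate)
        origin = "wildtype"
        if junction is not None:
            spans = [(start, start + read_len), (start + fl - read_len, start + fl)]
            if any(s <= junction - junction_anchor and e >= junction + junction_anchor for s, e in spans):
                origin = "fusion_junction_crossing"
            elif start < junction < start + fl:
                origin = "fusion_spanning"
        pid = f"{meta.sample_id}:{i:06d}"
        pairs.append(ReadPair(pid, m1, m2, meta.sample_id, origin))
        rows.append((pid, meta.sample_id, origin, label, start, fl))
    truth = pd.DataFrame(
        rows, columns=["pair_id", "sample_id", "origin", "source", "frag_start", "frag_len"]
    )
    return SimulatedSample(meta=meta, pairs=pairs, truth=truth)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        alt = [b for b in "ACGT" if b != out[i]]
        out[i] = alt[rng.integers(0, 3)]
    return "".join(out)


def write_sample(sample: SimulatedSample, out_dir: str | Path) -> None:
    """Write gzipped FASTQ mates and the truth TSV for one sample."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = sample.meta.sample_id
    for mate in (1, 2):
        with gzip.open(out / f"{sid}_R{mate}.fastq.gz", "wt") as fh:
            for p in sample.pairs:
                seq = p.mate1_seq if mate == 1 else p.mate2_seq
                fh.write(f"@{p.pair_id}/{mate}\n{seq}\n+\n{'I' * len(seq)}\n")
    sample.truth.to_csv(out / f"{sid}_truth.tsv", sep="\t", index=False)


def read_sample(meta: SampleMeta, cohort_dir: str | Path) -> SimulatedSample:
    """Load a sample written by :func:`write_sample`."""
    out = Path(cohort_dir)
    sid = meta.sample_id
    mates: dict[int, list[tuple[str, str]]] = {}
    for mate in (1, 2):
        recs = []
        with gzip.open(out / f"{sid}_R{mate}.fastq.gz", "rt") as fh:
            lines = fh.read().splitlines()
        for j in range(0, len(lines), 4):
            recs.append((lines[j][1:].rsplit("/", 1)[0], lines[j + 1]))
        mates[mate] = recs
    truth = pd.read_csv(out / f"{sid}_truth.tsv", sep="\t")
    origin = dict(zip(truth.pair_id, truth.origin))
    pairs = [
        ReadPair(pid, s1, s2, sid, origin.get(pid, "wildtype"))
        for (pid, s1), (_, s2) in zip(mates[1], mates[2])
    ]
    return SimulatedSample(meta=meta, pairs=pairs, truth=truth)
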