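"""Fusion transcript assembly: consensus junction, exon boundaries, cDNA, PCR.

The consensus junction is compiled from the stack of junction-crossing split
reads, anchored at the split point, by per-column majority vote.  Exon
boundaries are assigned by distance from the transcript-space breakpoints to
annotated exon edges, the fusion cDNA is assembled exon-by-exon from the
genome, and an in-silico PCR checks primer pairs against the assembled cDNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genes import Reference
from .util import NeofusionError, ParameterError, revcomp


class ClusterConflictError(NeofusionError):
    """Split reads supporting mutually inconsistent breakpoints."""


class UnannotatedBreakpointError(NeofusionError):
    """No exon boundary within tolerance of a breakpoint."""


@dataclass
class FusionTranscript:
    """An assembled fusion cDNA with its segment composition."""

    cdna: str
    segments: tuple[tuple[str, tuple[int, int]], ...]
    junction_offset_nt: int

    @property
    def length_nt(self) -> int:
        return len(self.cdna)


@dataclass
class FusionJunction:
    """Consensus sequence around a fusion junction.

    ``junction_offset`` indexes the first 3'-gene base of ``consensus_seq``;
    the terminal hexamers on either side are the breakpoint motifs.
    """

    consensus_seq: str
    junction_offset: int
    five_gene: str
    three_gene: str
    bp5_transcript: int
    bp3_transcript: int
    n_supporting_reads: int
    five_boundary: tuple[str, int, int] | None = None  # (gene, exon, distance)
    three_boundary: tuple[str, int, int] | None = None
    five_motif: str = field(init=False)
    three_motif: str = field(init=False)

    def __post_init__(self) -> None:
        o = self.junction_offset
        self.five_motif = self.consensus_seq[max(0, o - 6) : o]
        self.three_motif = self.consensus_seq[o : o + 6]
        if self.n_supporting_reads < 1:
            raise ParameterError("a junction needs at least one supporting read")


_BASE_ORDER = "ACGT"  # majority-vote ties resolved alphabetically


def build_consensus_junction(split_reads, cluster_window: int = 5) -> FusionJunction:
    """Majority-vote consensus over junction-anchored split reads.

    Every split read contributes its forward-sense sequence aligned so that
    its split point sits at a common column.  Columns with no coverage are
    trimmed.  Reads must support one breakpoint cluster (both transcript-space
    breakpoints within ``cluster_window``), otherwise a
    :class:`ClusterConflictError` is raised.
    """
    splits = list(split_reads)
    if not splits:
        raise ParameterError("at least one split read is required")
    bp5s = [s.bp5_transcript for s in splits]
    bp3s = [s.bp3_transcript for s in splits]
    if max(bp5s) - min(bp5s) > cluster_window or max(bp3s) - min(bp3s) > cluster_window:
        raise ClusterConflictError(
            f"split reads support conflicting breakpoints: 5' {sorted(set(bp5s))}, "
            f"3' {sorted(set(bp3s))}"
        )
    counts: dict[int, dict[str, int]] = {}
    for s in splits:
        for i, base in enumerate(s.seq_forward):
            rel = i - s.junction_offset_in_read
            counts.setdefault(rel, {}).setdefault(base, 0)
            counts[rel][base] += 1
    rels = sorted(counts)
    consensus = []
    for rel in rels:
        col = counts[rel]
        best = max(col.values())
        top = [b for b, n in col.items() if n == best]
        consensus.append(min(top, key=_BASE_ORDER.index))
    offset = rels.index(0)
    first = splits[0]
    return FusionJunction(
        consensus_seq="".join(consensus),
        junction_offset=offset,
        five_gene=first.left.target,
        three_gene=first.right.target,
        bp5_transcript=int(round(sum(bp5s) / len(bp5s))),
        bp3_transcript=int(round(sum(bp3s) / len(bp3s))),
        n_supporting_reads=len(splits),
    )


def map_exon_boundaries(
    junction: FusionJunction, reference: Reference, max_distance: int = 10
) -> FusionJunction:
    """Assign exon numbers and distances-to-boundary to a junction.

    The 5' breakpoint is matched to the nearest annotated exon *end* of the 5'
    gene, the 3' breakpoint to the nearest exon *start* of the 3' gene, both
    in transcript coordinates.  Breakpoints farther than ``max_distance`` from
    any boundary raise :class:`UnannotatedBreakpointError`.
    """
    g5 = reference.genes[junction.five_gene]
    g3 = reference.genes[junction.three_gene]
    ends = g5.exon_end_offsets()
    d5, e5 = min((abs(junction.bp5_transcript - b), i + 1) for i, b in enumerate(ends))
    starts = g3.exon_start_offsets()
    d3, e3 = min((abs(junction.bp3_transcript - b), i + 1) for i, b in enumerate(starts))
    if d5 > max_distance or d3 > max_distance:
        raise UnannotatedBreakpointError(
            f"breakpoint beyond {max_distance} nt of any exon boundary "
            f"(5' distance {d5}, 3' distance {d3})"
        )
    junction.five_boundary = (junction.five_gene, e5, d5)
    junction.three_boundary = (junction.three_gene, e3, d3)
    return junction


def assemble_fusion_cdna(
    reference: Reference,
    five_boundary: tuple[str, int],
    three_boundary: tuple[str, int],
) -> FusionTranscript:
    """Assemble the fusion cDNA from genomic exon sequences.

    ``five_boundary`` = (5' gene, last retained exon number); ``three_boundary``
    = (3' gene, first retained exon number).  Exons are spliced on the coding
    strand of each gene; the junction offset marks the first 3'-gene base.
    """
    gid5, e5 = five_boundary
    gid3, e3 = three_boundary
    g5 = reference.genes[gid5]
    g3 = reference.genes[gid3]
    if g5.strand != g3.strand:
        raise ParameterError(
            "unsupported orientation: read-through fusions require same-strand genes"
        )
    if not 1 <= e5 <= g5.n_exons or not 1 <= e3 <= g3.n_exons:
        raise ParameterError("boundary exon number out of range")

    def splice_range(gene, lo, hi):
        contig = reference.contigs[gene.chrom]
        parts = [contig[s:e] for s, e in gene.exons[lo - 1 : hi]]
        if gene.strand == "-":
            parts = [revcomp(p) for p in parts]
        return "".join(parts)

    left = splice_range(g5, 1, e5)
    right = splice_range(g3, e3, g3.n_exons)
    return FusionTranscript(
        cdna=left + right,
        segments=((gid5, (1, e5)), (gid3, (e3, g3.n_exons))),
        junction_offset_nt=len(left),
    )


def in_silico_pcr(cdna: str, forward_primer: str, reverse_primer: str) -> list[int]:
    """Amplicon lengths for a primer pair on a template.

    The forward primer must match the template as-is; the reverse primer as
    its reverse complement, downstream of the forward site.  Product length is
    counted inclusively from the forward primer's 5' end to the reverse
    primer's 5' end.  An empty list means no product.
    """
    fwd = forward_primer.upper()
    rev = reverse_primer.upper()
    if len(fwd) < 15 or len(rev) < 15:
        raise ParameterError("primers must be at least 15 nt")
    rc = revcomp(rev)

    def occurrences(needle: str) -> list[int]:
        out, i = [], cdna.find(needle)
        while i != -1:
            out.append(i)
            i = cdna.find(needle, i + 1)
        return out

    products = []
    for i in occurrences(fwd):
        for j in occurrences(rc):
            if j >= i:
                products.append(j + len(rev) - i)
    return sorted(products)
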