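"""Per-sample fusion calling from alignment evidence.

A candidate gene pair needs both kinds of evidence: at least one discordant
read pair linking the two genes near the breakpoints, and at least one
junction-crossing read split-mapped onto both genes with breakpoints close to
annotated exon boundaries (the false-positive filter).  Genes linked to more
than the promiscuity threshold of distinct partners — the signature of
repeat/pseudogene mis-mapping — are removed with all their candidates.
A refinement pass re-counts junction-crossing reads by mapping previously
unusable reads against a window around each candidate junction.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

from .alignment import SampleAlignment, SplitAlignment
from .genes import Reference
from .util import ConsistencyError, ParameterError, revcomp


@dataclass(frozen=True)
class DetectConfig:
    max_exon_boundary_distance: int = 10
    max_broken_pair_distance: int = 1000
    gene_promiscuity_threshold: int = 7
    min_junction_reads_fp_filter: int = 1
    breakpoint_cluster_window: int = 5
    refine_window: int = 150
    min_unaligned: int = 15
    similarity_fraction: float = 0.8

    def __post_init__(self) -> None:
        if min(
            self.max_exon_boundary_distance,
            self.max_broken_pair_distance,
            self.gene_promiscuity_threshold,
            self.min_junction_reads_fp_filter,
        ) < 0:
            raise ParameterError("detection thresholds must be non-negative")


@dataclass
class FusionCandidate:
    """A putative fusion between an ordered (5', 3') gene pair in one sample."""

    sample_id: str
    five_gene: str
    three_gene: str
    breakpoint_5p: int  # genomic, half-open end of the 5' segment
    breakpoint_3p: int  # genomic, start of the 3' segment
    bp5_transcript: int
    bp3_transcript: int
    junction_crossing_reads: int
    spanning_pairs: int
    split_reads: list[SplitAlignment] = field(default_factory=list)

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.five_gene, self.three_gene)


def _cluster_breakpoints(
    splits: list[SplitAlignment], window: int
) -> list[tuple[tuple[int, int], list[SplitAlignment]]]:
    """Greedy modal clustering of split-read breakpoints within ``window`` nt."""
    remaining = list(splits)
    clusters = []
    while remaining:
        modal, _ = Counter((s.bp5_transcript, s.bp3_transcript) for s in remaining).most_common(1)[0]
        near = [
            s
            for s in remaining
            if abs(s.bp5_transcript - modal[0]) <= window
            and abs(s.bp3_transcript - modal[1]) <= window
        ]
        remaining = [s for s in remaining if s not in near]
        clusters.append((modal, near))
    return clusters


def detect_fusions(
    sample: SampleAlignment,
    reference: Reference,
    cfg: DetectConfig = DetectConfig(),
) -> list[FusionCandidate]:
    """Call fusion candidates for one sample.

    Emits a candidate for an ordered gene pair iff a discordant pair links the
    genes within ``max_broken_pair_distance`` of the breakpoints and at least
    ``min_junction_reads_fp_filter`` split reads support a breakpoint cluster
    whose both breakpoints lie within ``max_exon_boundary_distance`` of an
    annotated exon boundary.
    """
    genes = reference.genes
    for sp in sample.splits:
        for g in (sp.left.target, sp.right.target):
            if g not in genes:
                raise ConsistencyError(f"alignment references unannotated gene {g}")

    # discordant pairs per ordered gene pair: 5' gene = plus-strand mate's gene
    discordant: dict[tuple[str, str], list] = defaultdict(list)
    for pid, klass in sample.pair_class.items():
        if klass != "discordant_two_genes":
            continue
        h1, h2 = sample.mate_hits[pid]
        a, b = h1[0], h2[0]
        fwd, rev = (a, b) if a.strand == "+" else (b, a)
        if fwd.strand != "+" or rev.strand != "-":
            continue
        discordant[(fwd.target, rev.target)].append((pid, fwd, rev))

    # gene promiscuity over the discordant linkage graph
    partners: dict[str, set[str]] = defaultdict(set)
    for g5, g3 in discordant:
        partners[g5].add(g3)
        partners[g3].add(g5)
    promiscuous = {g for g, ps in partners.items() if len(ps) > cfg.gene_promiscuity_threshold}

    by_pair: dict[tuple[str, str], list[SplitAlignment]] = defaultdict(list)
    for sp in sample.splits:
        by_pair[(sp.left.target, sp.right.target)].append(sp)

    candidates: list[FusionCandidate] = []
    for pair in sorted(set(discordant) | set(by_pair)):
        g5, g3 = pair
        if g5 in promiscuous or g3 in promiscuous:
            continue
        clusters = _cluster_breakpoints(by_pair.get(pair, []), cfg.breakpoint_cluster_window)
        for (bp5, bp3), cluster in clusters:
            if len({s.read_id for s in cluster}) < cfg.min_junction_reads_fp_filter:
                continue
            ends5 = genes[g5].exon_end_offsets()
            starts3 = genes[g3].exon_start_offsets()
            d5 = min(abs(bp5 - b) for b in ends5)
            d3 = min(abs(bp3 - b) for b in starts3)
            if d5 > cfg.max_exon_boundary_distance or d3 > cfg.max_exon_boundary_distance:
                continue
            support = [
                (pid, fwd, rev)
                for pid, fwd, rev in discordant.get(pair, [])
                if fwd.target_end <= bp5 + cfg.max_exon_boundary_distance
                and bp5 - fwd.target_start <= cfg.max_broken_pair_distance
                and rev.target_start >= bp3 - cfg.max_exon_boundary_distance
                and rev.target_end - bp3 <= cfg.max_broken_pair_distance
            ]
            if not support:
                continue
            candidates.append(
                FusionCandidate(
                    sample_id=sample.sample_id,
                    five_gene=g5,
                    three_gene=g3,
                    breakpoint_5p=genes[g5].transcript_to_genomic(bp5),
                    breakpoint_3p=genes[g3].transcript_to_genomic(bp3),
                    bp5_transcript=bp5,
                    bp3_transcript=bp3,
                    junction_crossing_reads=len({s.read_id for s in cluster}),
                    spanning_pairs=len({pid for pid, _, _ in support}),
                    split_reads=cluster,
                )
            )
    candidates.sort(key=lambda c: (c.five_gene, c.three_gene, c.bp5_transcript))
    return candidates


def fusion_reference_window(
    candidate: FusionCandidate, reference: Reference, half_window: int = 150
) -> tuple[str, int]:
    """The fusion reference: up to ``half_window`` nt either side of the
    junction on the candidate's fusion cDNA.  Returns (sequence, junction
    offset within the window)."""
    t5 = reference.transcript(candidate.five_gene)
    t3 = reference.transcript(candidate.three_gene)
    left = t5[max(0, candidate.bp5_transcript - half_window) : candidate.bp5_transcript]
    right = t3[candidate.bp3_transcript : candidate.bp3_transcript + half_window]
    return left + right, len(left)


def refine_fusion_counts(
    candidates: list[FusionCandidate],
    unplaced: list[tuple[str, str]],
    reference: Reference,
    cfg: DetectConfig = DetectConfig(),
) -> list[FusionCandidate]:
    """Re-count junction-crossing reads against each candidate's fusion
    reference.

    Previously unusable reads (no full-length alignment, no split) that place
    across the junction with at least ``min_unaligned`` nt on each side and
    overall identity above the similarity fraction increment the count.
    Counts never decrease.
    """
    refined = []
    for cand in candidates:
        window, joff = fusion_reference_window(cand, reference, cfg.refine_window)
        already = {s.read_id for s in cand.split_reads}
        rescued: set[str] = set()
        for rid, seq in unplaced:
            if rid in already:
                continue
            L = len(seq)
            best = None
            for variant in (seq, revcomp(seq)):
                for off in range(0, len(window) - L + 1):
                    mm = sum(a != b for a, b in zip(variant, window[off : off + L]))
                    if (L - mm) / L < cfg.similarity_fraction:
                        continue
                    if off + cfg.min_unaligned <= joff <= off + L - cfg.min_unaligned:
                        if best is None or mm < best:
                            best = mm
            if best is not None:
                rescued.add(rid)
        refined.append(
            replace(cand, junction_crossing_reads=cand.junction_crossing_reads + len(rescued))
        )
    return refined
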