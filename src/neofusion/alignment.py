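"""Desk-scale read mapping against the spliced transcriptome.

The mapper reproduces the *semantics* of the study's fusion-calling
configuration — mismatch cost 2, insertion cost 3, deletion cost 3, length
fraction 0.8, similarity fraction 0.8, at most 10 hits per read, minimum
unaligned (split-arm) length 15 — with a plain exact-seed + extension engine
adequate for toy references.  Reads are simulated from spliced transcripts, so
the alignment target is the transcriptome (one transcript per gene); transcript
coordinates are lifted to the genome through the exon models where needed.

Identity is counted as matches / aligned columns (a dialect choice for how the
similarity fraction treats indels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genes import Reference
from .util import ParameterError, revcomp


@dataclass(frozen=True)
class AlignConfig:
    mismatch_cost: int = 2
    insertion_cost: int = 3
    deletion_cost: int = 3
    length_fraction: float = 0.8
    similarity_fraction: float = 0.8
    max_hits: int = 10
    min_unaligned: int = 15
    seed_k: int = 16
    split_seed_k: int = 12
    band: int = 5

    def __post_init__(self) -> None:
        if min(self.mismatch_cost, self.insertion_cost, self.deletion_cost) <= 0:
            raise ParameterError("alignment costs must be positive")
        for f in (self.length_fraction, self.similarity_fraction):
            if not 0.0 < f <= 1.0:
                raise ParameterError("fractions must lie in (0, 1]")
        if self.max_hits < 1:
            raise ParameterError("max_hits must be >= 1")


@dataclass(frozen=True)
class Alignment:
    read_id: str
    target: str
    target_start: int
    target_end: int
    read_start: int
    read_end: int
    strand: str
    mismatches: int
    indels: int
    score: int


@dataclass(frozen=True)
class SplitAlignment:
    """A read split across two genes; ``seq_forward`` is the read in the
    fusion transcript's 5'->3' sense, split at ``junction_offset_in_read``."""

    read_id: str
    left: Alignment
    right: Alignment
    junction_offset_in_read: int
    seq_forward: str

    @property
    def bp5_transcript(self) -> int:
        return self.left.target_end

    @property
    def bp3_transcript(self) -> int:
        return self.right.target_start


class TranscriptomeIndex:
    """Exact k-mer seed index over a set of transcripts."""

    def __init__(self, transcripts: dict[str, str], k: int = 16, split_k: int = 12):
        self.transcripts = transcripts
        self.k = k
        self.split_k = split_k
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        self._split_seeds: dict[str, list[tuple[str, int]]] = {}
        for tid, seq in transcripts.items():
            for i in range(len(seq) - k + 1):
                self._seeds.setdefault(seq[i : i + k], []).append((tid, i))
            if split_k != k:
                for i in range(len(seq) - split_k + 1):
                    self._split_seeds.setdefault(seq[i : i + split_k], []).append((tid, i))
        if split_k == k:
            self._split_seeds = self._seeds

    @classmethod
    def from_reference(cls, reference: Reference, cfg: AlignConfig) -> "TranscriptomeIndex":
        return cls(reference.transcriptome(), k=cfg.seed_k, split_k=cfg.split_seed_k)

    def seeds(self, kmer: str) -> list[tuple[str, int]]:
        return self._seeds.get(kmer, [])

    def split_seeds(self, kmer: str) -> list[tuple[str, int]]:
        return self._split_seeds.get(kmer, [])


def _banded_dp(read: str, window: str, cfg: AlignConfig) -> tuple[int, int, int, int, int] | None:
    """Semi-global DP with traceback: whole read vs a reference window with
    free ends on the window.  Returns (cost, mismatches, indels, t_start,
    t_end) or None for degenerate inputs."""
    n, m = len(read), len(window)
    if n == 0 or m == 0:
        return None
    INF = 10 ** 9
    D = [[0] * (m + 1) for _ in range(n + 1)]
    P = [[0] * (m + 1) for _ in range(n + 1)]  # 0=start, 1=diag, 2=up(ins), 3=left(del)
    for i in range(1, n + 1):
        D[i][0] = D[i - 1][0] + cfg.insertion_cost
        P[i][0] = 2
    for i in range(1, n + 1):
        ri = read[i - 1]
        row, prow = D[i], D[i - 1]
        for j in range(1, m + 1):
            sub = prow[j - 1] + (0 if window[j - 1] == ri else cfg.mismatch_cost)
            ins = prow[j] + cfg.insertion_cost
            dele = row[j - 1] + cfg.deletion_cost
            best = min(sub, ins, dele)
            row[j] = best
            P[i][j] = 1 if best == sub else (2 if best == ins else 3)
    j_end = min(range(m + 1), key=lambda j: (D[n][j], j))
    cost = D[n][j_end]
    if cost >= INF:
        return None
    mm = ind = 0
    i, j = n, j_end
    while i > 0:
        move = P[i][j]
        if move == 1:
            if window[j - 1] != read[i - 1]:
                mm += 1
            i, j = i - 1, j - 1
        elif move == 2:
            ind += 1
            i -= 1
        else:
            ind += 1
            j -= 1
    return cost, mm, ind, j, j_end


def _ungapped(read: str, target: str, diag: int) -> int | None:
    """Mismatch count of the read placed at ``diag`` with no gaps."""
    if diag < 0 or diag + len(read) > len(target):
        return None
    seg = target[diag : diag + len(read)]
    if seg == read:
        return 0
    return sum(a != b for a, b in zip(read, seg))


def align_read(
    read_seq: str,
    index: TranscriptomeIndex,
    cfg: AlignConfig = AlignConfig(),
    read_id: str = "read",
) -> list[Alignment]:
    """All qualifying full-read alignments, best (lowest cost) first.

    The whole read is aligned (coverage 1.0 >= length fraction); placements
    below the similarity fraction are rejected.  Ties are broken by target
    then position.  At most ``max_hits`` alignments are returned.
    """
    if not read_seq:
        raise ParameterError("empty read")
    L = len(read_seq)
    k = cfg.seed_k
    found: dict[tuple[str, int, str], Alignment] = {}
    for strand in ("+", "-"):
        s = read_seq if strand == "+" else revcomp(read_seq)
        if L < k:
            continue
        offsets = list(range(0, L - k + 1, k))
        if offsets[-1] != L - k:
            offsets.append(L - k)
        tried: set[tuple[str, int]] = set()
        for off in offsets:
            for tid, pos in index.seeds(s[off : off + k]):
                diag = pos - off
                if (tid, diag) in tried:
                    continue
                tried.add((tid, diag))
                target = index.transcripts[tid]
                mm = _ungapped(s, target, diag)
                aln = None
                if mm is not None and (L - mm) / L >= cfg.similarity_fraction:
                    aln = Alignment(
                        read_id, tid, diag, diag + L, 0, L, strand, mm, 0, cfg.mismatch_cost * mm
                    )
                elif mm is not None or diag < 0 or diag + L > len(target):
                    w0 = max(0, diag - cfg.band)
                    w1 = min(len(target), diag + L + cfg.band)
                    res = _banded_dp(s, target[w0:w1], cfg)
                    if res is not None:
                        cost, dmm, dind, t0, t1 = res
                        cols = max(t1 - t0, L)
                        if (cols - dmm - dind) / cols >= cfg.similarity_fraction and (
                            t1 - t0
                        ) >= cfg.length_fraction * L:
                            aln = Alignment(
                                read_id, tid, w0 + t0, w0 + t1, 0, L, strand, dmm, dind, cost
                            )
                if aln is not None:
                    key = (aln.target, aln.target_start, aln.strand)
                    old = found.get(key)
                    if old is None or aln.score < old.score:
                        found[key] = aln
    hits = sorted(found.values(), key=lambda a: (a.score, a.target, a.target_start, a.strand))
    return hits[: cfg.max_hits]


def classify_pair(
    mate1_hits: list[Alignment],
    mate2_hits: list[Alignment],
    max_pair_distance: int = 1000,
) -> str:
    """Classify a read pair from its mates' hit lists.

    concordant: best mates on the same gene, opposite strands, within
    ``max_pair_distance``.  discordant_two_genes: best mates inside two
    different genes.  half_mapped: exactly one mate has hits.  unmapped:
    neither mate has hits (also the catch-all for same-gene pairs in an
    improper orientation, which are unusable as fusion evidence).
    """
    if not mate1_hits and not mate2_hits:
        return "unmapped"
    if bool(mate1_hits) != bool(mate2_hits):
        return "half_mapped"
    a, b = mate1_hits[0], mate2_hits[0]
    if a.target != b.target:
        return "discordant_two_genes"
    span = max(a.target_end, b.target_end) - min(a.target_start, b.target_start)
    proper = a.strand != b.strand and span <= max_pair_distance
    if proper:
        fwd, rev = (a, b) if a.strand == "+" else (b, a)
        proper = fwd.target_start <= rev.target_end
    return "concordant" if proper else "unmapped"


def _match_prefix_counts(seq: str, target: str, diag: int) -> list[int]:
    """cum[i] = matches of seq[:i] placed at diag; -inf-like for out of bounds."""
    L = len(seq)
    cum = [0] * (L + 1)
    for i in range(L):
        j = diag + i
        ok = 0 <= j < len(target) and target[j] == seq[i]
        cum[i + 1] = cum[i] + (1 if ok else 0)
    return cum


def split_map(
    read_seq: str,
    index: TranscriptomeIndex,
    cfg: AlignConfig = AlignConfig(),
    read_id: str = "read",
) -> SplitAlignment | None:
    """Split a read across two genes, if a valid split exists.

    Anchor seeds near both read ends propose (gene, diagonal) placements; for
    every pair of placements on two different genes, all split points with at
    least ``min_unaligned`` nucleotides on each arm are scored by total
    matches, and the best split (ties: leftmost) is kept.  Both the read and
    its reverse complement are tried; the returned segments are expressed on
    the fusion-forward sense, so ``left`` always names the 5' gene.
    """
    L = len(read_seq)
    k = cfg.split_seed_k
    if L < 2 * cfg.min_unaligned or L < k:
        return None
    best = None  # (neg_matches, strand_order, split, left_cand, right_cand, seq)
    for strand in ("+", "-"):
        s = read_seq if strand == "+" else revcomp(read_seq)
        left_cands: set[tuple[str, int]] = set()
        right_cands: set[tuple[str, int]] = set()
        for off in (0, 4, 8):
            if off + k <= L:
                for tid, pos in index.split_seeds(s[off : off + k]):
                    left_cands.add((tid, pos - off))
        for off in (L - k, L - k - 4, L - k - 8):
            if off >= 0:
                for tid, pos in index.split_seeds(s[off : off + k]):
                    right_cands.add((tid, pos - off))
        for ltid, ldiag in left_cands:
            lcum = None
            for rtid, rdiag in right_cands:
                if ltid == rtid:
                    continue
                if lcum is None:
                    lcum = _match_prefix_counts(s, index.transcripts[ltid], ldiag)
                rcum = _match_prefix_counts(s, index.transcripts[rtid], rdiag)
                for split in range(cfg.min_unaligned, L - cfg.min_unaligned + 1):
                    lm = lcum[split]
                    rm = rcum[L] - rcum[split]
                    if lm < cfg.similarity_fraction * split:
                        continue
                    if rm < cfg.similarity_fraction * (L - split):
                        continue
                    cand = (-(lm + rm), split, ltid, ldiag, rtid, rdiag, s, strand)
                    # deterministic: best total matches, then leftmost split,
                    # then lexicographic placement (independent of set order)
                    if best is None or cand[:6] < best[:6]:
                        best = cand
    if best is None:
        return None
    neg, split, ltid, ldiag, rtid, rdiag, s, strand = best
    lm = _match_prefix_counts(s, index.transcripts[ltid], ldiag)
    rm = _match_prefix_counts(s, index.transcripts[rtid], rdiag)
    left = Alignment(
        read_id, ltid, ldiag, ldiag + split, 0, split, "+",
        split - lm[split], 0, cfg.mismatch_cost * (split - lm[split]),
    )
    rmatches = rm[L] - rm[split]
    right = Alignment(
        read_id, rtid, rdiag + split, rdiag + L, split, L, "+",
        (L - split) - rmatches, 0, cfg.mismatch_cost * ((L - split) - rmatches),
    )
    return SplitAlignment(read_id, left, right, split, s)


@dataclass
class SampleAlignment:
    """Per-sample alignment evidence consumed by fusion detection."""

    sample_id: str
    pair_class: dict[str, str]
    mate_hits: dict[str, tuple[list[Alignment], list[Alignment]]]
    splits: list[SplitAlignment]
    unplaced: list[tuple[str, str]] = field(default_factory=list)  # (read_id, seq)
    n_pairs: int = 0


def align_sample(pairs, index: TranscriptomeIndex, cfg: AlignConfig = AlignConfig()) -> SampleAlignment:
    """Map every pair of a simulated sample and collect fusion evidence.

    Reads that fail whole-read alignment are offered to the split mapper;
    reads failing both are kept as unplaced for the refinement re-count.
    """
    sample_id = pairs[0].sample_id if pairs else ""
    pair_class: dict[str, str] = {}
    mate_hits = {}
    splits: list[SplitAlignment] = []
    unplaced: list[tuple[str, str]] = []
    for p in pairs:
        h1 = align_read(p.mate1_seq, index, cfg, read_id=p.pair_id + "/1")
        h2 = align_read(p.mate2_seq, index, cfg, read_id=p.pair_id + "/2")
        mate_hits[p.pair_id] = (h1, h2)
        pair_class[p.pair_id] = classify_pair(h1, h2)
        for mate, hits, seq in ((1, h1, p.mate1_seq), (2, h2, p.mate2_seq)):
            if hits:
                continue
            rid = f"{p.pair_id}/{mate}"
            sp = split_map(seq, index, cfg, read_id=rid)
            if sp is not None:
                splits.append(sp)
            else:
                unplaced.append((rid, seq))
    return SampleAlignment(
        sample_id=sample_id,
        pair_class=pair_class,
        mate_hits=mate_hits,
        splits=splits,
        unplaced=unplaced,
        n_pairs=len(pairs),
    )
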