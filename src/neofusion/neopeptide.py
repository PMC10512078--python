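"""ORF discovery on fusion cDNAs and junction neopeptide enumeration.

A fusion transcript typically encodes two truncation products: the 5' gene's
protein ending in a novel C-terminal run (premature termination after the
junction) and a 3'-gene product beginning with a novel N-terminal run.  The
novel residues are determined by comparing each fusion ORF against the two
wild-type proteins — a maximal terminal run absent from the wild-type
continuation — and the neopeptides are all k-mers whose window overlaps at
least one novel residue.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .util import NeofusionError, ParameterError


class ClassificationError(NeofusionError):
    """A fusion ORF matching neither wild-type terminus (or matching in full)."""


@dataclass(frozen=True)
class OpenReadingFrame:
    frame: int
    nt_start: int
    nt_end: int  # half-open, includes the stop codon
    protein: str

    @property
    def length_aa(self) -> int:
        return len(self.protein)


@dataclass(frozen=True)
class NeopeptideRegion:
    """Junction-proximal amino-acid context with its novelty mask.

    ``novel_mask[i]`` marks fusion-derived residues; they form one contiguous
    terminal run (C-terminal for a 5'-gene truncation, N-terminal for a
    3'-gene truncation).  ``junction_aa_index`` is the context index of the
    first novel residue (five_truncation) or one past the last (three_truncation).
    """

    context: str
    novel_mask: tuple[bool, ...]
    source: str  # five_truncation | three_truncation
    junction_aa_index: int

    def __post_init__(self) -> None:
        if len(self.context) != len(self.novel_mask):
            raise ParameterError("mask length must equal context length")
        if not any(self.novel_mask):
            raise ParameterError("a neopeptide region needs >= 1 novel residue")
        if self.source not in {"five_truncation", "three_truncation"}:
            raise ParameterError(f"unknown source {self.source!r}")

    @property
    def novel_run_length(self) -> int:
        return sum(self.novel_mask)


@dataclass(frozen=True)
class Neopeptide:
    seq: str
    k: int
    start_in_region: int
    source: str


def find_orfs(cdna: str, min_len_aa: int, include_reverse: bool = False) -> list[OpenReadingFrame]:
    """All ATG->stop open reading frames of at least ``min_len_aa`` residues.

    The three forward frames are scanned (the fusion orientation is known);
    reverse frames only behind the flag.  Within a frame, each stop closes the
    longest ORF opened by the first ATG since the previous stop (the outermost
    start, as ORF finders report).  Proteins exclude the stop.
    """
    seq = cdna.upper()
    orfs: list[OpenReadingFrame] = []

    def scan(s: str, frame: int, strand: int) -> None:
        start = None
        for i in range(frame, len(s) - 2, 3):
            codon = s[i : i + 3]
            if codon in ("TAA", "TAG", "TGA"):
                if start is not None:
                    aa = (i - start) // 3
                    if aa >= min_len_aa:
                        prot = str(Seq(s[start:i]).translate())
                        orfs.append(OpenReadingFrame(frame * strand, start, i + 3, prot))
                    start = None
            elif codon == "ATG" and start is None:
                start = i

    for f in range(3):
        scan(seq, f, 1)
    if include_reverse:
        from .util import revcomp

        for f in range(3):
            scan(revcomp(seq), f, -1)
    orfs.sort(key=lambda o: (-o.length_aa, o.nt_start))
    return orfs


def _lcp(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def delineate_novel_region(
    fusion_orf: OpenReadingFrame | str,
    wildtype_5p_protein: str,
    wildtype_3p_protein: str,
    k: int = 8,
) -> NeopeptideRegion:
    """Locate the fusion-derived residues of a truncation ORF.

    The ORF is classified as a 5'-gene truncation when it shares a longer
    N-terminal prefix with the 5' wild-type protein than C-terminal suffix
    with the 3' wild-type protein (and vice versa).  The novel run is the
    maximal terminal stretch absent from the wild-type continuation; the
    context adds k-1 flanking wild-type residues so that every k-mer touching
    a novel residue is representable.
    """
    protein = fusion_orf.protein if isinstance(fusion_orf, OpenReadingFrame) else fusion_orf
    prefix = _lcp(protein, wildtype_5p_protein)
    suffix = _lcp(protein[::-1], wildtype_3p_protein[::-1])
    if prefix == 0 and suffix == 0:
        raise ClassificationError("ORF shares no terminus with either wild-type protein")
    if prefix >= len(protein) or suffix >= len(protein):
        raise ClassificationError("ORF is identical to a wild-type protein; no novel residues")
    if prefix >= suffix:
        novel = len(protein) - prefix
        ctx_len = min(len(protein), novel + k - 1)
        context = protein[-ctx_len:]
        mask = tuple(i >= ctx_len - novel for i in range(ctx_len))
        return NeopeptideRegion(context, mask, "five_truncation", ctx_len - novel)
    novel = len(protein) - suffix
    ctx_len = min(len(protein), novel + k - 1)
    context = protein[:ctx_len]
    mask = tuple(i < novel for i in range(ctx_len))
    return NeopeptideRegion(context, mask, "three_truncation", novel)


def enumerate_neopeptides(region: NeopeptideRegion, k: int = 8) -> list[Neopeptide]:
    """All distinct k-mers of the region whose window overlaps at least one
    novel residue, in order of start; duplicate sequences keep the first."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    L = len(region.context)
    out: list[Neopeptide] = []
    seen: set[str] = set()
    for start in range(0, L - k + 1):
        if not any(region.novel_mask[start : start + k]):
            continue
        pep = region.context[start : start + k]
        if pep in seen:
            continue
        seen.add(pep)
        out.append(Neopeptide(pep, k, start, region.source))
    return out
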