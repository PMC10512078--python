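"""Gene models, spliced transcripts and annotation I/O.

A :class:`GeneModel` is a minimal single-transcript gene: an ordered list of
exon intervals on a contig, numbered 1..n in transcription order.  All
internal coordinates are 0-based half-open; GTF is written/read 1-based
inclusive per the standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .util import ParameterError, revcomp


@dataclass(frozen=True)
class GeneModel:
    """A gene with exons ordered 1..n in transcription order."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ParameterError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ParameterError(f"{self.gene_id}: at least one exon required")
        for s, e in self.exons:
            if e <= s:
                raise ParameterError(f"{self.gene_id}: empty exon interval ({s},{e})")
        # transcription order: genomic ascending for +, descending for -
        ordered = sorted(self.exons, reverse=(self.strand == "-"))
        if tuple(ordered) != tuple(self.exons):
            raise ParameterError(f"{self.gene_id}: exons not in transcription order")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ParameterError(f"{self.gene_id}: overlapping exons")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_lengths(self) -> list[int]:
        return [e - s for s, e in self.exons]

    @property
    def transcript_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    def splice(self, contig_seq: str) -> str:
        """The mature (intron-free) transcript on the coding strand."""
        parts = [contig_seq[s:e] for s, e in self.exons]
        if self.strand == "-":
            return "".join(revcomp(p) for p in parts)
        return "".join(parts)

    def exon_end_offsets(self) -> list[int]:
        """Transcript offset of the end of exon i (1-based exon i -> entry i-1)."""
        out, c = [], 0
        for ln in self.exon_lengths:
            c += ln
            out.append(c)
        return out

    def exon_start_offsets(self) -> list[int]:
        """Transcript offset of the start of exon i."""
        ends = self.exon_end_offsets()
        return [0] + ends[:-1]

    def transcript_to_genomic(self, pos: int) -> int:
        """Map a transcript coordinate to a genomic coordinate.

        For a position equal to the transcript length, the coordinate one
        past the last exonic base is returned (useful for half-open ends).
        """
        if pos < 0 or pos > self.transcript_length:
            raise ParameterError(f"transcript position {pos} out of range")
        c = 0
        for (s, e), ln in zip(self.exons, self.exon_lengths):
            if pos < c + ln:
                off = pos - c
                return s + off if self.strand == "+" else e - 1 - off
            c += ln
        last_s, last_e = self.exons[-1]
        return last_e if self.strand == "+" else last_s - 1


@dataclass
class Reference:
    """A reference bundle: contig sequences plus gene models."""

    contigs: dict[str, str]
    genes: dict[str, GeneModel]
    _transcripts: dict[str, str] = field(default_factory=dict, repr=False)

    def transcript(self, gene_id: str) -> str:
        if gene_id not in self._transcripts:
            g = self.genes[gene_id]
            self._transcripts[gene_id] = g.splice(self.contigs[g.chrom])
        return self._transcripts[gene_id]

    def transcriptome(self) -> dict[str, str]:
        return {gid: self.transcript(gid) for gid in self.genes}

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in sorted(self.contigs.items())
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    def write_gtf(self, path: str | Path) -> None:
        lines = []
        for gid in sorted(self.genes):
            g = self.genes[gid]
            attrs = f'gene_id "{gid}"; transcript_id "{gid}.t1";'
            gs, ge = g.span
            lines.append(
                f"{g.chrom}\tneofusion\ttranscript\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\t{attrs}"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                lines.append(
                    f"{g.chrom}\tneofusion\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f'{attrs} exon_number "{i}";'
                )
        Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gtf(path: str | Path) -> dict[str, GeneModel]:
    """Parse exon features of a GTF back into gene models.

    Uses gffutils when available (the standard parser); falls back to a
    line parser for the minimal dialect written by :meth:`Reference.write_gtf`.
    """
    by_gene: dict[str, dict] = {}
    try:
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
        for feat in db.features_of_type("exon"):
            gid = feat.attributes["gene_id"][0]
            info = by_gene.setdefault(gid, {"chrom": feat.seqid, "strand": feat.strand, "exons": []})
            info["exons"].append((feat.start - 1, feat.end))
    except Exception:
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            attrs = dict(
                (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                for kv in f[8].strip().strip(";").split(";")
                if kv.strip()
            )
            gid = attrs["gene_id"]
            info = by_gene.setdefault(gid, {"chrom": f[0], "strand": f[6], "exons": []})
            info["exons"].append((int(f[3]) - 1, int(f[4])))
    genes = {}
    for gid, info in by_gene.items():
        exons = sorted(info["exons"], reverse=(info["strand"] == "-"))
        genes[gid] = GeneModel(gid, info["chrom"], info["strand"], tuple(exons))
    return genes
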