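#!/usr/bin/env python
"""Stage 4 — consensus junction, fusion cDNA, in-silico PCR and neopeptides.

Pools the junction-crossing split reads of the retained fusion, builds the
per-column majority-vote consensus with its breakpoint hexamers, assigns exon
boundaries, assembles the fusion cDNA, designs a junction-flanking primer
pair and verifies the expected amplicon appears on the fusion but not on the
wild-type transcripts, then enumerates junction-overlapping 8-mer neopeptides
from the truncation ORFs.  Writes junction/cDNA FASTA+TSV and peptides.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
CALLS = ROOT / "results" / "calls"
OUT = ROOT / "results"

from neofusion import (  # noqa: E402
    assemble_fusion_cdna,
    build_consensus_junction,
    delineate_novel_region,
    enumerate_neopeptides,
    find_orfs,
    in_silico_pcr,
    map_exon_boundaries,
)
from neofusion.genes import Reference, read_fasta, read_gtf  # noqa: E402
from neofusion.neopeptide import ClassificationError  # noqa: E402
from neofusion.serialize import frame_to_splits  # noqa: E402
from neofusion.util import revcomp  # noqa: E402


def main(seed: int = 42) -> None:  # noqa: ARG001 - consensus is deterministic
    reference = Reference(
        contigs=read_fasta(ROOT / "results" / "cohort" / "reference.fa"),
        genes=read_gtf(ROOT / "results" / "cohort" / "genes.gtf"),
    )
    prevalence = pd.read_csv(OUT / "prevalence.tsv", sep="\t")
    g5, g3 = prevalence.iloc[0].gene_5p, prevalence.iloc[0].gene_3p
    splits_df = pd.read_csv(CALLS / "splits.tsv", sep="\t")
    sub = splits_df[(splits_df.gene_5p == g5) & (splits_df.gene_3p == g3)]
    junction = build_consensus_junction(frame_to_splits(sub))
    junction = map_exon_boundaries(junction, reference)
    print(
        f"{g5}|{g3}: consensus from {junction.n_supporting_reads} junction reads, "
        f"boundaries exon {junction.five_boundary[1]} | exon {junction.three_boundary[1]} "
        f"(distances {junction.five_boundary[2]}, {junction.three_boundary[2]}), "
        f"motifs {junction.five_motif}-3' | 5'-{junction.three_motif}"
    )
    (OUT / "junction.fasta").write_text(
        f">consensus_junction {g5}|{g3}\n{junction.consensus_seq}\n"
    )

    fusion_tx = assemble_fusion_cdna(
        reference, junction.five_boundary[:2], junction.three_boundary[:2]
    )
    (OUT / "fusion_cdna.fasta").write_text(f">fusion_cdna {g5}|{g3}\n{fusion_tx.cdna}\n")
    print(f"fusion cDNA: {fusion_tx.length_nt} nt, junction at {fusion_tx.junction_offset_nt}")

    # junction-flanking PCR assay: product only on the fusion template
    j = fusion_tx.junction_offset_nt
    fwd = fusion_tx.cdna[j - 60 : j - 42]
    rev = revcomp(fusion_tx.cdna[j + 42 : j + 60])
    product = in_silico_pcr(fusion_tx.cdna, fwd, rev)
    wt_products = [
        p
        for gid in (g5, g3)
        for p in in_silico_pcr(reference.transcript(gid), fwd, rev)
    ]
    print(f"in-silico PCR: fusion product {product} bp, wild-type products {wt_products}")

    wt5 = find_orfs(reference.transcript(g5), 10)[0].protein
    wt3 = find_orfs(reference.transcript(g3), 10)[0].protein
    rows = []
    for orf in find_orfs(fusion_tx.cdna, 30)[:4]:
        try:
            region = delineate_novel_region(orf, wt5, wt3, 8)
        except ClassificationError:
            continue
        for pep in enumerate_neopeptides(region, 8):
            rows.append(
                {"peptide": pep.seq, "source": pep.source, "start_in_region": pep.start_in_region}
            )
    peptides = pd.DataFrame(rows).drop_duplicates(subset=["peptide", "source"])
    peptides.to_csv(OUT / "peptides.tsv", sep="\t", index=False)
    by_src = peptides.groupby("source").size().to_dict() if len(peptides) else {}
    print(f"neopeptides: {len(peptides)} junction-overlapping 8-mers {by_src}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 42)
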