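"""End-to-end orchestration: simulate -> align -> detect -> filter ->
consensus -> peptides -> rank (-> elispot), with one structured config, a
global seed and reproducible artifacts.

Defaults reproduce the study's printed analysis parameters: alignment costs
(2, 3, 3) with 0.8 fractions and 10 hits; detection thresholds (unaligned 15,
exon-boundary distance 10, broken-pair distance 1000, gene promiscuity 7);
8-mer peptides; IC50 thresholds 50/500/1000 nM; ELISpot 20 SFC and alpha 0.05.
Rerunning with an identical config and seed is byte-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import elispot as elispot_mod
from .alignment import AlignConfig, SampleAlignment, TranscriptomeIndex, align_sample
from .detection import DetectConfig, detect_fusions, refine_fusion_counts
from .genes import Reference
from .mhc import load_binding_table, rank_and_distribution, study_binding_table
from .neopeptide import ClassificationError, delineate_novel_region, enumerate_neopeptides, find_orfs
from .synthetic import (
    PlantedFusion,
    SampleMeta,
    SimulatedSample,
    generate_reference,
    simulate_sample,
    write_sample,
)
from .transcript import assemble_fusion_cdna, build_consensus_junction, map_exon_boundaries
from .util import NeofusionError


class ConfigError(NeofusionError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


DEFAULT_CONFIG: dict = {
    "seed": 42,
    "simulate": {
        "n_genes": 6,
        "exon_count_range": [2, 4],
        "exon_len_range": [120, 200],
        "intron_len_range": [60, 120],
        "n_pairs": 2000,
        "read_len": 76,
        "fragment_mean": 180.0,
        "fragment_sd": 25.0,
        "error_rate": 0.001,
        "n_cases": 6,
        "n_controls": 2,
        "fusion_weight": 0.08,
        "decoy_in_control": True,
        "write_reads": False,
    },
    "align": {
        "mismatch_cost": 2,
        "insertion_cost": 3,
        "deletion_cost": 3,
        "length_fraction": 0.8,
        "similarity_fraction": 0.8,
        "max_hits": 10,
        "min_unaligned": 15,
        "seed_k": 16,
    },
    "detect": {
        "max_exon_boundary_distance": 10,
        "max_broken_pair_distance": 1000,
        "gene_promiscuity_threshold": 7,
        "min_junction_reads_fp_filter": 1,
        "breakpoint_cluster_window": 5,
        "refine_window": 150,
    },
    "filter": {
        "min_patients": 3,
        "use_external": False,
        "external_evidence": None,
    },
    "peptides": {
        "k": 8,
        "min_orf_len_aa": 30,
    },
    "rank": {
        "thresholds": [50, 500, 1000],
        "primary_threshold": 500,
        "lower_bound_nm": None,
        "binding_table": "study",
    },
    "elispot": {
        "threshold_sfc": 20.0,
        "alpha": 0.05,
        "plate": None,
        "alternative": "two-sided",
    },
}

# keys whose value may be null / replaced by a path string
_NULLABLE = {
    "filter.external_evidence",
    "rank.lower_bound_nm",
    "rank.binding_table",
    "elispot.plate",
}


def _check(node, default, prefix: str, errors: list[str], out) -> None:
    for key, value in node.items():
        path = f"{prefix}{key}"
        if key not in default:
            errors.append(f"{path}: unknown key")
            continue
        dval = default[key]
        if isinstance(dval, dict):
            if not isinstance(value, dict):
                errors.append(f"{path}: expected a mapping of settings")
                continue
            _check(value, dval, path + ".", errors, out[key])
            continue
        if path in _NULLABLE:
            out[key] = value
            continue
        if isinstance(dval, bool):
            if not isinstance(value, bool):
                errors.append(f"{path}: expected a boolean, got {type(value).__name__}")
                continue
        elif isinstance(dval, (int, float)):
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                errors.append(f"{path}: expected a number, got {type(value).__name__}")
                continue
        elif isinstance(dval, list):
            if not isinstance(value, list):
                errors.append(f"{path}: expected a list, got {type(value).__name__}")
                continue
        elif isinstance(dval, str) and not isinstance(value, str):
            errors.append(f"{path}: expected a string, got {type(value).__name__}")
            continue
        out[key] = value


def validate_config(config: dict | None) -> dict:
    """Merge a (possibly partial) config over the defaults.

    Unknown keys are rejected and type errors reported, all at once."""
    merged = copy.deepcopy(DEFAULT_CONFIG)
    errors: list[str] = []
    _check(config or {}, DEFAULT_CONFIG, "", errors, merged)
    sim = merged["simulate"]
    if not errors:
        if not 0.0 <= sim["error_rate"] < 0.5:
            errors.append("simulate.error_rate: must lie in [0, 0.5)")
        if sim["n_pairs"] <= 0:
            errors.append("simulate.n_pairs: must be positive")
        if not 0.0 <= sim["fusion_weight"] <= 0.5:
            errors.append("simulate.fusion_weight: must lie in [0, 0.5]")
        if merged["filter"]["min_patients"] < 1:
            errors.append("filter.min_patients: must be >= 1")
    if errors:
        raise ConfigError(errors)
    return merged


def load_config(path) -> dict:
    raw = yaml.safe_load(Path(path).read_text()) if path else {}
    return validate_config(raw or {})


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _child_seed(seed: int, idx: int) -> int:
    return (seed * 100003 + 7919 * idx + 1) % (2 ** 31 - 1)


def build_cohort(config: dict) -> tuple[Reference, list[SimulatedSample], dict]:
    """Simulate the default study-shaped cohort: cases across three subtypes
    carrying a planted read-through fusion, cancer-free controls, and (by
    default) a decoy fusion planted in a control plus some cases so the
    control-exclusion filter has work to do."""
    sim = config["simulate"]
    seed = config["seed"]
    reference = generate_reference(
        seed,
        n_genes=sim["n_genes"],
        exon_count_range=tuple(sim["exon_count_range"]),
        exon_len_range=tuple(sim["exon_len_range"]),
        intron_len_range=tuple(sim["intron_len_range"]),
    )
    gids = sorted(reference.genes)
    g2, g3 = reference.genes[gids[1]], reference.genes[gids[2]]
    primary = PlantedFusion(
        five_gene=gids[1],
        five_last_exon=max(1, g2.n_exons - 1),
        three_gene=gids[2],
        three_first_exon=min(2, reference.genes[gids[2]].n_exons),
        expression_weight=sim["fusion_weight"],
    )
    decoy = None
    if sim["decoy_in_control"] and len(gids) >= 5:
        g4 = reference.genes[gids[3]]
        decoy = PlantedFusion(
            five_gene=gids[3],
            five_last_exon=max(1, g4.n_exons - 1),
            three_gene=gids[4],
            three_first_exon=min(2, reference.genes[gids[4]].n_exons),
            expression_weight=sim["fusion_weight"],
        )

    groups = ["TNBC", "HER2+", "HR+"]
    samples: list[SimulatedSample] = []
    idx = 0
    for ci in range(sim["n_cases"]):
        meta = SampleMeta(f"S{ci + 1:02d}", groups[ci % 3], True)
        fusions = [primary]
        if decoy is not None and ci < 3:
            fusions = [primary, decoy]
        samples.append(
            simulate_sample(
                reference, fusions, meta, sim["n_pairs"],
                read_len=sim["read_len"], fragment_mean=sim["fragment_mean"],
                fragment_sd=sim["fragment_sd"], error_rate=sim["error_rate"],
                seed=_child_seed(seed, idx),
            )
        )
        idx += 1
    for ki in range(sim["n_controls"]):
        meta = SampleMeta(f"C{ki + 1:02d}", "cancer_free_control", False)
        fusions = [decoy] if (decoy is not None and ki == 0) else []
        samples.append(
            simulate_sample(
                reference, fusions, meta, sim["n_pairs"],
                read_len=sim["read_len"], fragment_mean=sim["fragment_mean"],
                fragment_sd=sim["fragment_sd"], error_rate=sim["error_rate"],
                seed=_child_seed(seed, idx),
            )
        )
        idx += 1
    truth = {"primary": primary, "decoy": decoy}
    return reference, samples, truth


def align_and_detect(
    reference: Reference, samples: list[SimulatedSample], config: dict
) -> tuple[dict, dict[str, SampleAlignment], list[str]]:
    acfg = AlignConfig(**config["align"])
    dcfg = DetectConfig(
        **config["detect"],
        min_unaligned=config["align"]["min_unaligned"],
        similarity_fraction=config["align"]["similarity_fraction"],
    )
    index = TranscriptomeIndex.from_reference(reference, acfg)
    calls: dict[str, list] = {}
    alns: dict[str, SampleAlignment] = {}
    log: list[str] = []
    for s in samples:
        sa = align_sample(s.pairs, index, acfg)
        cands = refine_fusion_counts(
            detect_fusions(sa, reference, dcfg), sa.unplaced, reference, dcfg
        )
        calls[s.meta.sample_id] = cands
        alns[s.meta.sample_id] = sa
        n_disc = sum(1 for v in sa.pair_class.values() if v == "discordant_two_genes")
        log.append(
            f"{s.meta.sample_id}: pairs={sa.n_pairs} discordant={n_disc} "
            f"split_reads={len(sa.splits)} unplaced={len(sa.unplaced)} "
            f"candidates={len(cands)}"
        )
    return calls, alns, log


def run_all(config: dict | None = None, out_dir: str | Path = "results/run") -> dict:
    """Execute every stage on the synthetic cohort and write the report
    bundle.  Returns the machine-readable summary."""
    cfg = validate_config(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config_hash={config_hash(cfg)}", f"seed={cfg['seed']}"]

    reference, samples, truth = build_cohort(cfg)
    reference.write_fasta(out / "reference.fa")
    reference.write_gtf(out / "genes.gtf")
    meta_rows = [
        {"sample_id": s.meta.sample_id, "group": s.meta.group, "is_case": s.meta.is_case}
        for s in samples
    ]
    pd.DataFrame(meta_rows).to_csv(out / "samples.tsv", sep="\t", index=False)
    if cfg["simulate"]["write_reads"]:
        for s in samples:
            write_sample(s, out / "reads")
    log.append(f"simulated {len(samples)} samples, {cfg['simulate']['n_pairs']} pairs each")

    calls, alns, stage_log = align_and_detect(reference, samples, cfg)
    log.extend(stage_log)

    callset = cohort_mod.CohortCallSet(
        calls=calls, meta={s.meta.sample_id: s.meta for s in samples}
    )
    before = sorted(cohort_mod.retained_pairs(callset))
    callset = cohort_mod.exclude_control_fusions(callset)
    after_controls = sorted(cohort_mod.retained_pairs(callset))
    callset = cohort_mod.recurrence_filter(callset, cfg["filter"]["min_patients"])
    if cfg["filter"]["use_external"]:
        ev = cfg["filter"]["external_evidence"]
        callset.external_evidence = cohort_mod.load_external_evidence(ev) if ev else set()
        callset = cohort_mod.external_recurrence_filter(callset)
    retained = sorted(cohort_mod.retained_pairs(callset))
    log.append(
        f"gene pairs: detected={before} after_control_exclusion={after_controls} "
        f"retained={retained}"
    )
    report = cohort_mod.prevalence_report(callset)
    report.to_csv(out / "prevalence.tsv", sep="\t", index=False)

    summary: dict = {
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "n_samples": len(samples),
        "planted_fusion": truth["primary"].five_gene + "|" + truth["primary"].three_gene,
        "pairs_detected": ["|".join(p) for p in before],
        "pairs_retained": ["|".join(p) for p in retained],
        "n_retained_fusions": len(retained),
    }

    if retained:
        top = max(
            retained,
            key=lambda p: sum(
                c.junction_crossing_reads
                for cands in calls.values()
                for c in cands
                if c.gene_pair == p
            ),
        )
        pool = [
            sp
            for sid, cands in calls.items()
            if callset.meta[sid].is_case
            for c in cands
            if c.gene_pair == top
            for sp in c.split_reads
        ]
        junction = build_consensus_junction(pool, cfg["detect"]["breakpoint_cluster_window"])
        junction = map_exon_boundaries(
            junction, reference, cfg["detect"]["max_exon_boundary_distance"]
        )
        fusion_tx = assemble_fusion_cdna(
            reference, junction.five_boundary[:2], junction.three_boundary[:2]
        )
        (out / "junction.fasta").write_text(
            f">consensus_junction {top[0]}|{top[1]}\n{junction.consensus_seq}\n"
        )
        (out / "fusion_cdna.fasta").write_text(
            f">fusion_cdna {top[0]}|{top[1]}\n{fusion_tx.cdna}\n"
        )
        pd.DataFrame(
            [
                {
                    "gene_5p": top[0],
                    "gene_3p": top[1],
                    "five_exon": junction.five_boundary[1],
                    "five_boundary_distance": junction.five_boundary[2],
                    "three_exon": junction.three_boundary[1],
                    "three_boundary_distance": junction.three_boundary[2],
                    "five_motif": junction.five_motif,
                    "three_motif": junction.three_motif,
                    "n_supporting_reads": junction.n_supporting_reads,
                }
            ]
        ).to_csv(out / "junction.tsv", sep="\t", index=False)
        summary["top_fusion"] = {
            "gene_pair": f"{top[0]}|{top[1]}",
            "five_exon": junction.five_boundary[1],
            "three_exon": junction.three_boundary[1],
            "five_motif": junction.five_motif,
            "three_motif": junction.three_motif,
            "n_supporting_reads": junction.n_supporting_reads,
            "cdna_length_nt": fusion_tx.length_nt,
        }

        # neopeptides from the assembled fusion cDNA
        k = cfg["peptides"]["k"]
        min_aa = cfg["peptides"]["min_orf_len_aa"]
        wt5 = find_orfs(reference.transcript(top[0]), 10)
        wt3 = find_orfs(reference.transcript(top[1]), 10)
        pep_rows = []
        if wt5 and wt3:
            for orf in find_orfs(fusion_tx.cdna, min_aa)[:4]:
                try:
                    region = delineate_novel_region(orf, wt5[0].protein, wt3[0].protein, k)
                except ClassificationError:
                    continue
                for pep in enumerate_neopeptides(region, k):
                    pep_rows.append(
                        {
                            "peptide": pep.seq,
                            "source": pep.source,
                            "start_in_region": pep.start_in_region,
                            "novel_overlap": sum(
                                region.novel_mask[pep.start_in_region : pep.start_in_region + k]
                            ),
                        }
                    )
        peptides = pd.DataFrame(pep_rows).drop_duplicates(subset=["peptide", "source"])
        peptides.to_csv(out / "peptides.tsv", sep="\t", index=False)
        summary["n_neopeptides"] = int(len(peptides))
        log.append(f"neopeptides: {len(peptides)} distinct {k}-mers from {top[0]}|{top[1]}")

    table_src = cfg["rank"]["binding_table"]
    if table_src:
        table = study_binding_table() if table_src == "study" else load_binding_table(table_src)
        ranked, hist = rank_and_distribution(
            table,
            thresholds=tuple(cfg["rank"]["thresholds"]),
            rank_threshold=cfg["rank"]["primary_threshold"],
            lower_bound_nm=cfg["rank"]["lower_bound_nm"],
        )
        ranked.to_csv(out / "ranking.tsv", sep="\t", index=False)
        hist.to_frame().to_csv(out / "promiscuity_histogram.tsv", sep="\t")
        summary["top_ranked_peptide"] = str(ranked.iloc[0].peptide)
        log.append(f"ranked {len(ranked)} peptides; top {ranked.iloc[0].peptide}")

    if cfg["elispot"]["plate"]:
        plate = elispot_mod.load_plate(cfg["elispot"]["plate"])
        ecalls = elispot_mod.call_positive(
            plate,
            threshold=cfg["elispot"]["threshold_sfc"],
            alpha=cfg["elispot"]["alpha"],
            alternative=cfg["elispot"]["alternative"],
        )
        elispot_mod.calls_to_frame(ecalls).to_csv(out / "elispot.tsv", sep="\t", index=False)
        summary["elispot_positive"] = [c.condition for c in ecalls if c.positive]

    (out / "run.log").write_text("\n".join(log) + "\n")
    summary_text = json.dumps(summary, indent=2, sort_keys=True)
    (out / "summary.json").write_text(summary_text + "\n")
    summary["summary_hash"] = hashlib.sha256(summary_text.encode()).hexdigest()[:16]
    return summary
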