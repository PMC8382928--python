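"""End-to-end orchestration: simulate -> filter -> scan -> FineMAV -> report.

A single seed in the configuration fans out deterministically to per-stage
child seeds (numpy SeedSequence spawning keyed on stage index), so any stage
can be re-run independently and the whole pipeline is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from wgdadapt import convergence as conv
from wgdadapt import finemav as fm
from wgdadapt import poolseq, scan
from wgdadapt.simulate import (
    SimulationConfig,
    _tile_genes,
    simulate_pool_reads,
    simulate_quartet_afs,
    simulate_substitutions,
    write_synthetic_inputs,
)

log = logging.getLogger("wgdadapt")

_STAGE = {"afs": 0, "reads": 1, "subs": 2, "perm": 3}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic child seed for a named stage, below 2**31."""
    ss = np.random.SeedSequence([seed, _STAGE[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Pipeline configuration: either a simulation config or input paths."""

    simulation: SimulationConfig | None = None
    vcf: str | None = None
    gff: str | None = None
    sample_map: str | None = None
    window_bp: int = 1000
    min_snps: int = 20
    min_snps_per_gene: int = 5
    top_frac: float = 0.01
    exclusion_order: str = "before"
    min_dp: int = 10
    max_dp: int | None = None
    depth_scope: str = "replicate"
    finemav_exponent: float = 3.5
    finemav_top_frac: float = 0.01
    substitution_fraction: float = 0.05
    min_confidence: int = 400
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = self.vcf is not None
        if self.simulation is not None and has_paths:
            raise ValueError("give either a simulation config or input paths, not both")
        if self.simulation is None and not has_paths:
            raise ValueError("give a simulation config or input paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        config = cls(
            simulation=SimulationConfig(**sim) if sim is not None else None, **raw
        )
        return config


def read_gff_genes(path) -> pd.DataFrame:
    """Gene spans from a GFF3 file (0-based half-open internally)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}")
            rows.append((gene_id, f[0], int(f[3]) - 1, int(f[4])))
    return pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end"])


def sweep_recovery(
    rank_table: pd.DataFrame, truth: pd.DataFrame, window_bp: int = 1000
) -> dict[str, float]:
    """Compare candidate windows against implanted-sweep truth.

    A sweep is recovered if any candidate window contains at least one of its
    SNPs.  Reports the ploidy-sweep recovery rate, the lineage-sweep false
    recovery rate, and the count of candidate windows containing SNPs of a
    sweep private to one population (exclusion violations).
    """
    cand = rank_table[rank_table["candidate"]]
    cand_keys = set(zip(cand["scaffold"], cand["start"]))
    sweeps = truth[truth["class"] != "neutral"]
    recovered: dict[str, bool] = {}
    for locus, grp in sweeps.groupby("locus_id"):
        keys = set(
            zip(grp["scaffold"], (grp["pos"] // window_bp) * window_bp)
        )
        recovered[locus] = bool(keys & cand_keys)
    ploidy = [l for l in recovered if l.startswith("ploidy")]
    lineage = [l for l in recovered if l.startswith("lineage")]
    return {
        "n_ploidy_sweeps": len(ploidy),
        "n_lineage_sweeps": len(lineage),
        "ploidy_recovery": float(np.mean([recovered[l] for l in ploidy])) if ploidy else float("nan"),
        "lineage_false_recovery": float(np.mean([recovered[l] for l in lineage])) if lineage else 0.0,
        "exclusion_violations": int(sum(recovered[l] for l in lineage)),
        "n_candidates": int(len(cand)),
    }


def run_scan_pipeline(config: RunConfig, out_dir: str | None = None) -> dict:
    """Simulate or load pool-seq data, filter, scan, score, and report.

    Returns a report dict with the filtered AF table, per-window rank-sum
    table, candidate windows and genes, gene-level scan, FineMAV outliers,
    Table-1-style contrast statistics for all six pairs, and (when ground
    truth is available) sweep-recovery metrics.  When ``out_dir`` is given all
    intermediates are persisted as TSV.
    """
    truth = None
    subs = None
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        log.info("simulating quartet AFs: %d SNPs", sim.n_snps)
        true_afs, truth = simulate_quartet_afs(sim)
        reads = simulate_pool_reads(true_afs, sim, seed=stage_seed(config.seed, "reads"))
        genes = _tile_genes(sim)
        subs = simulate_substitutions(
            truth,
            sim,
            fraction=config.substitution_fraction,
            seed=stage_seed(config.seed, "subs"),
            genes=genes,
        )
        ploidy = sim.ploidy
    else:
        sample_map = poolseq.read_sample_map(config.sample_map)
        reads, skipped = poolseq.read_pool_vcf(config.vcf, sample_map)
        log.info("VCF read: %d SNPs, skipped %s", reads.n_snps, skipped)
        genes = read_gff_genes(config.gff) if config.gff else pd.DataFrame(
            columns=["gene_id", "scaffold", "start", "end"]
        )
        ploidy = reads.ploidy

    n_input = reads.n_snps
    reads, depth_log = poolseq.filter_sites(
        reads, min_dp=config.min_dp, max_dp=config.max_dp, scope=config.depth_scope
    )
    table, af_log = poolseq.population_afs(reads)
    log.info(
        "sites: %d input -> %d depth-filtered -> %d analyzed",
        n_input,
        reads.n_snps,
        table.n_snps,
    )

    design = scan.QuartetDesign.from_ploidy(ploidy)
    windows = {
        name: scan.window_fst(table, pair, config.window_bp, config.min_snps)
        for name, pair in design.contrasts.items()
    }
    rank_table = scan.quartet_rank_sum(
        windows, top_frac=config.top_frac, exclusion_order=config.exclusion_order
    )
    cand_windows = rank_table[rank_table["candidate"]]
    cand_genes = scan.annotate_candidates(cand_windows, genes) if len(genes) else []
    gene_table = (
        scan.gene_level_scan(
            table,
            genes,
            design,
            min_snps_per_gene=config.min_snps_per_gene,
            top_frac=config.top_frac,
            exclusion_order=config.exclusion_order,
        )
        if len(genes)
        else None
    )
    stats = {
        name: scan.genome_stats(table, pair) for name, pair in design.contrasts.items()
    }
    genic_r, genic_n = scan.genic_fraction_check(windows["p1"], genes) if len(genes) else (float("nan"), 0)

    finemav_table = None
    if subs is not None and len(subs):
        finemav_table = fm.top_fraction(
            fm.score_table(subs, exponent=config.finemav_exponent),
            frac=config.finemav_top_frac,
        )

    report = {
        "design": design,
        "af_table": table,
        "genes": genes,
        "windows": windows,
        "rank_table": rank_table,
        "candidate_windows": cand_windows,
        "candidate_genes": cand_genes,
        "gene_table": gene_table,
        "contrast_stats": stats,
        "genic_fraction_r": genic_r,
        "genic_fraction_n": genic_n,
        "finemav": finemav_table,
        "filter_log": {
            "input_snps": int(n_input),
            "depth_removed": int(len(depth_log)),
            "zero_depth_removed": int(len(af_log)),
            "analyzed_snps": int(table.n_snps),
        },
        "truth": truth,
    }
    if truth is not None:
        truth_kept = truth.merge(table.sites[["scaffold", "pos"]], on=["scaffold", "pos"])
        report["recovery"] = sweep_recovery(rank_table, truth_kept, config.window_bp)

    if out_dir is not None:
        _persist(report, config, out_dir)
    return report


def _persist(report: dict, config: RunConfig, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    report["af_table"].write_tsv(os.path.join(out_dir, "allele_frequencies.tsv"))
    report["rank_table"].to_csv(os.path.join(out_dir, "windows.tsv"), sep="\t", index=False)
    cand = report["candidate_windows"]
    cand[["scaffold", "start", "end"]].to_csv(
        os.path.join(out_dir, "candidate_windows.bed"), sep="\t", index=False, header=False
    )
    pd.Series(report["candidate_genes"], name="gene_id").to_csv(
        os.path.join(out_dir, "candidate_genes.tsv"), sep="\t", index=False
    )
    if report["gene_table"] is not None:
        report["gene_table"].to_csv(os.path.join(out_dir, "gene_scan.tsv"), sep="\t", index=False)
    if report["finemav"] is not None:
        report["finemav"].to_csv(os.path.join(out_dir, "finemav.tsv"), sep="\t", index=False)
    stats = pd.DataFrame(
        {name: dataclasses.asdict(s) for name, s in report["contrast_stats"].items()}
    ).T
    stats.index.name = "contrast"
    stats.to_csv(os.path.join(out_dir, "contrast_stats.tsv"), sep="\t")
    summary = {
        "filter_log": report["filter_log"],
        "genic_fraction_r": report["genic_fraction_r"],
        "n_candidate_windows": int(len(cand)),
        "n_candidate_genes": len(report["candidate_genes"]),
        "seed": config.seed,
    }
    if "recovery" in report:
        summary["recovery"] = report["recovery"]
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


def run_convergence_pipeline(
    candidates_a: list[str],
    candidates_b: list[str],
    universe: list[str],
    term_genes: dict[str, set[str]] | None = None,
    dag=None,
    edges: pd.DataFrame | None = None,
    min_node_size: int = 150,
    elim_cutoff: float = 0.01,
    alpha: float = 0.05,
    min_confidence: int = 400,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Ortholog overlap, GO elim enrichment in both species, sharing, and network tests.

    Empty candidate lists skip the affected tests with explicit notes.
    """
    report: dict = {"notes": []}
    if not candidates_a or not candidates_b:
        report["notes"].append("empty candidate list: all tests skipped")
        return report

    n_overlap, p_overlap = conv.overlap_test(
        set(candidates_a), set(candidates_b), set(universe)
    )
    report["ortholog_overlap"] = {"n": n_overlap, "p": p_overlap}

    if term_genes is not None and dag is not None:
        res_a = conv.go_enrichment_elim(
            set(candidates_a), set(universe), term_genes, dag, min_node_size, elim_cutoff
        )
        res_b = conv.go_enrichment_elim(
            set(candidates_b), set(universe), term_genes, dag, min_node_size, elim_cutoff
        )
        tested = set(res_a["term"]) | set(res_b["term"])
        shared, p_shared = conv.shared_enrichment(res_a, res_b, tested, alpha=alpha)
        report["go"] = {
            "results_a": res_a,
            "results_b": res_b,
            "shared_terms": shared,
            "p_sharing": p_shared,
        }
    else:
        report["notes"].append("no GO annotations: enrichment skipped")

    if edges is not None:
        report["network"] = conv.interaction_overlap_perm(
            candidates_a,
            candidates_b,
            edges,
            universe,
            min_confidence=min_confidence,
            n_perm=n_perm,
            seed=stage_seed(seed, "perm"),
        )
    else:
        report["notes"].append("no interaction edges: permutation test skipped")
    return report
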