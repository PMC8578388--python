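"""End-to-end orchestration: discovery, characterization, demo.

``run_discovery`` composes the two evidence streams (assembly
comparison in both directions, WGS coverage asymmetry) and intersects
them into the final ppRE/ppERV sets with Venn counts.
``run_characterization`` adds subfamily enrichment, clustering, the
activity rule, closest-gene assignment and the shuffled-control
expression comparison. ``run_demo`` does all of it on a freshly forged
synthetic world and reports recovery against the truth manifest.

Every stochastic stage draws from its own seed derived from the run
seed, so stages are independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly_compare, coverage_calls, repeat_stats, synthforge
from .core import frame_to_elements
from .io import write_bed, write_json, write_world

logger = logging.getLogger(__name__)

__all__ = ["PipelineParams", "DiscoveryResult", "run_discovery",
           "run_characterization", "run_demo"]


@dataclass
class PipelineParams:
    """All thresholds of the pipeline, with their standard defaults."""

    min_match_len: int = 20
    max_gap: int = 50
    min_cluster_len: int = 200
    require_both_flanks: bool = True
    min_reads: int = 10
    cluster_max_gap: int = 20
    min_rpkm: float = 1.0
    min_len: int = 50
    ratio_threshold: float = 7.0
    p_threshold: float = 0.001
    fc_threshold: float = 4.0
    fdr_threshold: float = 0.001
    n_shuffles: int = 50
    n_resamples: int = 1000

    def validate(self) -> None:
        for name in ("min_match_len", "max_gap", "min_cluster_len", "min_reads",
                     "cluster_max_gap", "min_rpkm", "min_len", "fc_threshold",
                     "n_shuffles", "n_resamples"):
            if getattr(self, name) <= 0 and name not in ("max_gap",):
                raise ValueError(f"{name} must be positive")


@dataclass
class DiscoveryResult:
    assembly_calls: dict[str, list]
    coverage_calls: list
    final_calls: list
    final_ervs: list
    venn: dict[str, dict[str, int]]
    report: dict


def _pct(part: float, whole: float) -> float:
    return round(100.0 * part / whole, 2) if whole else 0.0


def run_discovery(world: synthforge.World, params: PipelineParams | None = None) -> DiscoveryResult:
    """Both evidence streams plus their intersection on one world."""
    params = params or PipelineParams()
    params.validate()
    repeats = {
        "A": frame_to_elements(world.annotation_A),
        "B": frame_to_elements(world.annotation_B),
    }
    asm_calls = {}
    for strain, (ref, query) in (
        ("A", (world.genome_A, world.genome_B)),
        ("B", (world.genome_B, world.genome_A)),
    ):
        asm_calls[strain] = assembly_compare.call_direction(
            ref, query, repeats[strain],
            min_match_len=params.min_match_len, max_gap=params.max_gap,
            min_cluster_len=params.min_cluster_len,
            require_both_flanks=params.require_both_flanks,
        )
        logger.info("assembly stream %s: %d candidate elements", strain, len(asm_calls[strain]))
    if world.coverage is None:
        raise ValueError("world has no coverage table")
    cov_calls = coverage_calls.classify_by_coverage(world.coverage, min_reads=params.min_reads)
    final, venn = coverage_calls.intersect_methods(asm_calls, cov_calls)
    ervs = coverage_calls.subset_ervs(final)
    report = {"strains": {}}
    for strain in ("A", "B"):
        f = [c for c in final if c.private_to == strain]
        e = [c for c in ervs if c.private_to == strain]
        report["strains"][strain] = {
            "assembly_candidates": len(asm_calls.get(strain, [])),
            "coverage_candidates": sum(1 for c in cov_calls if c.private_to == strain),
            "venn": venn.get(strain, {"assembly_only": 0, "coverage_only": 0, "both": 0}),
            "final_ppres": len(f),
            "final_ppervs": len(e),
            "pperv_pct_of_ppres": _pct(len(e), len(f)),
        }
    return DiscoveryResult(
        assembly_calls=asm_calls, coverage_calls=cov_calls,
        final_calls=final, final_ervs=ervs, venn=venn, report=report,
    )


def recovery_vs_truth(result: DiscoveryResult, manifest: pd.DataFrame) -> dict:
    """Compare final calls against the planted truth, per strain."""
    out = {}
    for strain in ("A", "B"):
        truth = set(manifest.loc[manifest["strain"] == strain, "element_id"])
        called = {c.element.element_id for c in result.final_calls if c.private_to == strain}
        out[strain] = {
            "planted": len(truth),
            "recovered": len(truth & called),
            "false_positives": len(called - truth),
            "recovery_pct": _pct(len(truth & called), len(truth)),
        }
    total_truth = sum(v["planted"] for v in out.values())
    total_rec = sum(v["recovered"] for v in out.values())
    out["overall"] = {
        "planted": total_truth,
        "recovered": total_rec,
        "false_positives": sum(v["false_positives"] for v in out.values() if "false_positives" in v),
        "recovery_pct": _pct(total_rec, total_truth),
    }
    return out


def run_characterization(
    world: synthforge.World,
    discovery: DiscoveryResult,
    params: PipelineParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Enrichment, clustering, activity and expression analyses of final calls."""
    params = params or PipelineParams()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    report: dict = {"strains": {}}
    for strain in ("A", "B"):
        annot = world.annotation_A if strain == "A" else world.annotation_B
        genome_repeats = frame_to_elements(annot)
        ppres = [c for c in discovery.final_calls if c.private_to == strain]
        ppervs = [c for c in discovery.final_ervs if c.private_to == strain]
        entry: dict = {"n_ppres": len(ppres), "n_ppervs": len(ppervs)}

        enr = repeat_stats.subfamily_enrichment(
            ppervs, genome_repeats,
            ratio_threshold=params.ratio_threshold, p_threshold=params.p_threshold,
        ) if ppervs else []
        entry["enrichment"] = [asdict(e) for e in enr]
        entry["flagged_subfamilies"] = [e.subfamily for e in enr if e.flagged]

        clusters, solos = repeat_stats.cluster_elements(
            ppres, cluster_max_gap=params.cluster_max_gap
        ) if ppres else ([], [])
        clustered_ids = {m.element.element_id for cl in clusters for m in cl.members}
        erv_ids = {c.element.element_id for c in ppervs}
        n_clustered_erv = len(erv_ids & clustered_ids)
        entry["n_clusters"] = len(clusters)
        entry["n_solo_ppres"] = len(solos)
        entry["pperv_clustered_pct"] = _pct(n_clustered_erv, len(erv_ids))
        entry["pperv_solo_pct"] = _pct(len(erv_ids) - n_clustered_erv, len(erv_ids))

        if ppervs and world.signal is not None:
            activity = repeat_stats.call_active(
                ppervs, world.signal, min_rpkm=params.min_rpkm, min_len=params.min_len
            )
            active_ids = {a.element.element_id for a in activity if a.active}
        else:
            activity, active_ids = [], set()
        entry["n_active_ppervs"] = len(active_ids)
        entry["n_active_in_clusters"] = len(active_ids & clustered_ids)
        entry["n_active_solo"] = len(active_ids - clustered_ids)

        expr_summary = None
        if active_ids and world.expression is not None:
            active_calls = [c for c in ppervs if c.element.element_id in active_ids]
            active_clusters = [
                cl for cl in clusters
                if any(m.element.element_id in active_ids for m in cl.members)
            ]
            solo_active = [
                c for c in active_calls if c.element.element_id not in clustered_ids
            ]
            targets: list = active_clusters + solo_active
            assignment = repeat_stats.assign_closest_gene(
                targets, world.expression, tss_column=f"tss_{strain}"
            )
            genes = sorted(set(assignment.values()))
            entry["n_assigned_genes"] = len(genes)
            if len(genes) >= 2:
                cmp = repeat_stats.compare_closest_gene_expression(
                    genes, world.expression, carrier=strain,
                    n_shuffles=params.n_shuffles, rng=rng,
                )
                expr_summary = {
                    "mean_log2_carrier": round(cmp.mean_carrier, 4),
                    "mean_log2_other": round(cmp.mean_other, 4),
                    "mean_log2_control": round(cmp.mean_control, 4),
                    "p_carrier_vs_other": cmp.p_carrier_vs_other,
                    "p_carrier_vs_control": cmp.p_carrier_vs_control,
                }
        entry["expression"] = expr_summary
        report["strains"][strain] = entry
    return report


def run_demo(
    seed: int = 0,
    outdir: str | Path | None = None,
    config: synthforge.SimConfig | None = None,
    params: PipelineParams | None = None,
) -> dict:
    """Forge a synthetic world, run the whole pipeline, report everything."""
    config = config or synthforge.SimConfig(rng_seed=seed)
    config.rng_seed = seed
    params = params or PipelineParams()
    world = synthforge.forge_world(config)
    discovery = run_discovery(world, params)
    recovery = recovery_vs_truth(discovery, world.manifest)
    characterization = run_characterization(
        world, discovery, params, rng=np.random.default_rng([5, seed])
    )
    report = {
        "seed": seed,
        "config": asdict(config),
        "params": asdict(params),
        "discovery": discovery.report,
        "recovery": recovery,
        "characterization": characterization,
    }
    if outdir is not None:
        outdir = Path(outdir)
        write_world(world, outdir)
        for strain in ("A", "B"):
            calls = [c for c in discovery.final_calls if c.private_to == strain]
            write_bed(
                [(c.element.chrom, c.element.start, c.element.end,
                  c.element.element_id, 0, c.element.strand) for c in calls],
                outdir / f"final_ppres_{strain}.bed",
            )
        write_json(report, outdir / "report.json")
    return report
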