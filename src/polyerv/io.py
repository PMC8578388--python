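"""Readers and writers for the pipeline's on-disk formats.

Assemblies travel as FASTA; annotations, tables and call sets as
TSV/BED with headers; reports and Venn counts as JSON; run
configuration as YAML. Writers and readers round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(intervals: list[tuple], path: str | Path) -> None:
    """Write (chrom, start, end[, name[, score[, strand]]]) tuples as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    try:
        import numpy as np

        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_yaml(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path: str | Path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def read_gene_list(path: str | Path) -> set[str]:
    """One gene id per line; blank lines ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_world(world, outdir: str | Path) -> Path:
    """Persist a synthetic world (genomes, tables, truth, config) to a directory."""
    import dataclasses

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(world.genome_A, out / "genome_A.fa")
    write_fasta(world.genome_B, out / "genome_B.fa")
    write_table(world.annotation_A, out / "annotation_A.tsv")
    write_table(world.annotation_B, out / "annotation_B.tsv")
    write_table(world.manifest, out / "truth_manifest.tsv")
    if world.genes is not None:
        write_table(world.genes, out / "genes.tsv")
    if world.coverage is not None:
        write_table(world.coverage, out / "coverage.tsv")
    if world.signal is not None:
        write_table(world.signal, out / "element_signal.tsv")
    if world.expression is not None:
        write_table(world.expression, out / "expression.tsv")
    write_yaml(dataclasses.asdict(world.config), out / "config.yaml")
    return out


def read_world(worlddir: str | Path):
    """Load a world directory written by :func:`write_world`."""
    from .synthforge import SimConfig, World

    d = Path(worlddir)
    cfg_raw = read_yaml(d / "config.yaml")
    cfg_raw["active_rpkm_range"] = tuple(cfg_raw["active_rpkm_range"])
    config = SimConfig(**cfg_raw)

    def opt(name):
        p = d / name
        return read_table(p) if p.exists() else None

    manifest = read_table(d / "truth_manifest.tsv")
    manifest["nearest_gene_id"] = manifest["nearest_gene_id"].fillna("")
    return World(
        config=config,
        genome_A=read_fasta(d / "genome_A.fa"),
        genome_B=read_fasta(d / "genome_B.fa"),
        annotation_A=read_table(d / "annotation_A.tsv"),
        annotation_B=read_table(d / "annotation_B.tsv"),
        manifest=manifest,
        genes=opt("genes.tsv"),
        coverage=opt("coverage.tsv"),
        signal=opt("element_signal.tsv"),
        expression=opt("expression.tsv"),
    )
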