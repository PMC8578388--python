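"""Synthetic two-genome worlds with planted polymorphic repeat insertions.

The generator emulates the situation of two inbred mouse strains that
share a common genomic backbone but differ by full-length repeat
insertions: shared insertions sit at homologous loci in both
assemblies, private insertions exist in exactly one. Downstream assay
tables — per-element WGS read counts, H3K27ac element signal, and
per-gene expression — are simulated on top, together with a truth
manifest used by recovery tests.

Design choices worth knowing:

* The backbone is i.i.d. uniform nucleotides, so 20-mers are unique
  with overwhelming probability and anchor matching is unambiguous.
* Each inserted element is an independently diverged copy of its
  subfamily consensus (default 10% substitution divergence). Copies of
  the same subfamily at different loci therefore share no long exact
  matches, exactly as diverged genomic repeats do; only the homologous
  shared copies are identical between the two assemblies.
* Insertion boundaries are adjusted so the first/last inserted base
  differs from the displaced backbone base; exact matches then
  terminate precisely at the annotated element boundary.
* Coverage is emitted as a per-element unique-read count table (the
  downstream calling rule operates on such counts); read-level
  simulation is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    ANNOTATION_COLUMNS,
    ERV_CLASS,
    ERV_FAMILIES,
    interval_tss_distance,
    reverse_complement,
)

__all__ = [
    "RepeatConsensus",
    "SimConfig",
    "World",
    "default_repeat_library",
    "synthesize_genome_pair",
    "make_gene_models",
    "simulate_wgs_coverage",
    "simulate_chip_and_expression",
    "forge_world",
]

_BASES = "ACGT"

# stage constants for deriving independent RNG streams from one seed
_STAGE_GENOME = 1
_STAGE_GENES = 2
_STAGE_WGS = 3
_STAGE_CHIP = 4

MANIFEST_COLUMNS = [
    "element_id", "strain", "subfamily", "family", "class", "strand",
    "is_erv", "chrom", "site_pos", "start_A", "end_A", "start_B", "end_B",
    "clustered", "is_active", "nearest_gene_id",
]


@dataclass(frozen=True)
class RepeatConsensus:
    """A repeat subfamily consensus, the template for inserted copies."""

    subfamily: str
    family: str
    class_: str
    sequence: str
    insertion_weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set(_BASES):
            raise ValueError(f"{self.subfamily}: sequence must be non-empty over ACGT")

    @property
    def is_erv(self) -> bool:
        return self.class_ == ERV_CLASS and self.family in ERV_FAMILIES


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def default_repeat_library() -> list[RepeatConsensus]:
    """A deterministic library of mouse-like repeat subfamilies.

    Subfamily names follow RepeatMasker conventions; the retrotransposition-
    active ERVK subfamilies (IAP, ETn, GLN) carry higher insertion weights,
    matching the observation that young ERVK elements dominate recent,
    strain-segregating insertions.
    """
    specs = [
        # subfamily, family, class, length, insertion weight
        ("IAPEz-int", "ERVK", "LTR", 1800, 6.0),
        ("IAPLTR1_Mm", "ERVK", "LTR", 340, 5.0),
        ("ETnERV-int", "ERVK", "LTR", 1500, 5.0),
        ("MMERGLN-int", "ERVK", "LTR", 1600, 3.0),
        ("MMERGLN_LTR", "ERVK", "LTR", 380, 3.0),
        ("RLTR4_MM", "ERV1", "LTR", 330, 3.0),
        ("RLTR13D6", "ERVK", "LTR", 400, 1.0),
        ("MERVL-int", "ERVL", "LTR", 1200, 1.0),
        ("MT2_Mm", "ERVL", "LTR", 480, 1.0),
        ("ORR1B1", "ERVL-MaLR", "LTR", 350, 1.0),
        ("B1_Mus1", "Alu", "SINE", 150, 2.0),
        ("B2_Mm1a", "B2", "SINE", 190, 2.0),
        ("L1Md_T", "L1", "LINE", 900, 1.5),
        ("MIRb", "MIR", "SINE", 180, 0.5),
    ]
    library = []
    for idx, (sub, fam, cls, length, weight) in enumerate(specs):
        rng = np.random.default_rng([7_102_433, idx])
        library.append(
            RepeatConsensus(sub, fam, cls, _random_sequence(rng, length), weight)
        )
    return library


@dataclass
class SimConfig:
    """Parameters of the synthetic world.

    The defaults define the standard study conditions used throughout
    the test suite: a 5 Mb backbone over two chromosomes carrying 40
    shared and 25 + 15 strain-private insertions, 30x mean per-element
    WGS depth with no mismapping, and a +2 log2 fold-change expression
    effect on genes nearest to active private ERVs.
    """

    backbone_length: int = 5_000_000
    n_chromosomes: int = 2
    n_shared_insertions: int = 40
    n_private_A: int = 25
    n_private_B: int = 15
    erv_fraction: float = 0.7
    wgs_depth: float = 30.0
    mismap_rate: float = 0.0
    active_fraction: float = 0.5
    active_rpkm_range: tuple[float, float] = (2.0, 5.0)
    expression_effect_log2fc: float = 2.0
    n_genes: int = 400
    rng_seed: int = 0
    # artifact knobs below: divergence of each inserted copy from its
    # consensus, spacing constraints, clustered-run planting, expression noise
    divergence: float = 0.10
    min_insert_spacing: int = 1000
    end_margin: int = 5000
    clustered_run_fraction: float = 0.3
    expr_noise_sd: float = 0.3
    baseline_log2_fpkm: float = 3.0
    inactive_rpkm_max: float = 0.5
    gene_min_dist_to_insertion: int = 500

    def validate(self) -> None:
        counts = [
            self.backbone_length, self.n_chromosomes, self.n_shared_insertions,
            self.n_private_A, self.n_private_B, self.n_genes,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        for name in ("erv_fraction", "mismap_rate", "active_fraction",
                     "divergence", "clustered_run_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.active_rpkm_range
        if lo > hi:
            raise ValueError("active_rpkm_range must be (low, high) with low <= high")


@dataclass
class World:
    """Everything the pipeline needs, bundled: genomes, tables, truth."""

    config: SimConfig
    genome_A: dict[str, str]
    genome_B: dict[str, str]
    annotation_A: pd.DataFrame
    annotation_B: pd.DataFrame
    manifest: pd.DataFrame
    genes: pd.DataFrame | None = None
    coverage: pd.DataFrame | None = None
    signal: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None


def _spaced_positions(
    rng: np.random.Generator, k: int, length: int, margin: int, spacing: int
) -> list[int]:
    """k sorted positions in [margin, length - margin] with pairwise gaps >= spacing."""
    if k == 0:
        return []
    usable = length - 2 * margin - (k - 1) * spacing
    if usable < k:
        raise ValueError(
            f"insertion overflow: cannot place {k} insertions with spacing "
            f"{spacing} on a {length} bp chromosome"
        )
    raw = np.sort(rng.integers(0, usable, size=k))
    return [int(margin + raw[i] + i * spacing) for i in range(k)]


def _mutate_copy(rng: np.random.Generator, consensus: str, divergence: float) -> str:
    seq = np.frombuffer(consensus.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(seq.size) < divergence)
    for i in hit:
        choices = [b for b in b"ACGT" if b != seq[i]]
        seq[i] = choices[rng.integers(0, 3)]
    return seq.tobytes().decode()


def _force_boundary(seq: str, first_forbidden: str, last_forbidden: str) -> str:
    """Make the copy's first/last base differ from the displaced backbone base."""
    s = list(seq)
    if s[0] == first_forbidden:
        s[0] = _BASES[(_BASES.index(s[0]) + 1) % 4]
    if s[-1] == last_forbidden:
        s[-1] = _BASES[(_BASES.index(s[-1]) + 1) % 4]
    return "".join(s)


def _pick_consensus(
    rng: np.random.Generator, library: list[RepeatConsensus],
    erv_fraction: float, weighted: bool,
) -> RepeatConsensus:
    ervs = [c for c in library if c.is_erv]
    others = [c for c in library if not c.is_erv]
    pool = ervs if (ervs and (not others or rng.random() < erv_fraction)) else others
    if weighted:
        w = np.array([c.insertion_weight for c in pool])
        return pool[rng.choice(len(pool), p=w / w.sum())]
    return pool[rng.integers(0, len(pool))]


def synthesize_genome_pair(
    config: SimConfig, library: list[RepeatConsensus]
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Build two assemblies sharing a backbone, plus annotations and truth.

    Returns ``(genome_A, genome_B, annotation_A, annotation_B, manifest)``.
    Annotations are BED-like tables with 0-based half-open coordinates in
    their own assembly. A fraction of private insertions is planted as
    clustered runs of 2-4 elements separated by < 20 bp spacers to
    exercise downstream cluster logic.
    """
    config.validate()
    if not library:
        raise ValueError("empty repeat library")
    rng = np.random.default_rng([_STAGE_GENOME, config.rng_seed])

    per_chrom = config.backbone_length // config.n_chromosomes
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    backbones = {c: _random_sequence(rng, per_chrom) for c in chroms}

    # -- plan site units: shared units carry one element, private units may
    #    carry a clustered run of 2-4 elements
    def private_units(n: int, prefix: str) -> list[list[str]]:
        ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
        n_clustered = int(round(config.clustered_run_fraction * n))
        units: list[list[str]] = []
        i = 0
        while n_clustered - i >= 2:
            size = min(int(rng.integers(2, 5)), n_clustered - i)
            if n_clustered - i - size == 1:  # avoid a stranded single
                size = size - 1 if size > 2 else size + 1
            units.append(ids[i : i + size])
            i += size
        units.extend([x] for x in ids[i:])
        return units

    units: list[tuple[str, list[str]]] = []  # (strain, element ids)
    units += [("shared", [f"s{i + 1:04d}"]) for i in range(config.n_shared_insertions)]
    units += [("A", u) for u in private_units(config.n_private_A, "a")]
    units += [("B", u) for u in private_units(config.n_private_B, "b")]
    units = [units[i] for i in rng.permutation(len(units))]

    # -- allocate units to chromosomes proportionally, then draw spaced sites
    n_units = len(units)
    alloc = [n_units // config.n_chromosomes] * config.n_chromosomes
    for i in range(n_units % config.n_chromosomes):
        alloc[i] += 1
    site_plan: list[tuple[str, int, str, list[str]]] = []  # chrom, pos, strain, ids
    ui = 0
    for chrom, k in zip(chroms, alloc):
        positions = _spaced_positions(
            rng, k, per_chrom, config.end_margin, config.min_insert_spacing
        )
        for pos in positions:
            strain, ids = units[ui]
            site_plan.append((chrom, pos, strain, ids))
            ui += 1
    site_plan.sort(key=lambda t: (t[0], t[1]))

    # -- realize element copies per unit
    consensus_by_id: dict[str, RepeatConsensus] = {}
    seq_by_id: dict[str, str] = {}
    strand_by_id: dict[str, str] = {}
    spacers: dict[str, list[str]] = {}
    for chrom, pos, strain, ids in site_plan:
        for eid in ids:
            cons = _pick_consensus(
                rng, library, config.erv_fraction, weighted=(strain != "shared")
            )
            copy = _mutate_copy(rng, cons.sequence, config.divergence)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                copy = reverse_complement(copy)
            consensus_by_id[eid] = cons
            seq_by_id[eid] = copy
            strand_by_id[eid] = strand
        spacers["|".join(ids)] = [
            _random_sequence(rng, int(rng.integers(5, 20))) for _ in range(len(ids) - 1)
        ]

    # boundary adjustment so exact matches stop at the annotated edges
    for chrom, pos, strain, ids in site_plan:
        bb = backbones[chrom]
        first, last = ids[0], ids[-1]
        seq_by_id[first] = _force_boundary(seq_by_id[first], bb[pos], "")
        seq_by_id[last] = _force_boundary(seq_by_id[last], "", bb[pos - 1])

    # -- compose genomes and annotations
    genomes: dict[str, dict[str, str]] = {"A": {}, "B": {}}
    annot_rows: dict[str, list] = {"A": [], "B": []}
    coords: dict[str, dict[str, tuple[int, int]]] = {"A": {}, "B": {}}
    for strain_key in ("A", "B"):
        for chrom in chroms:
            bb = backbones[chrom]
            parts: list[str] = []
            cursor = 0  # backbone position consumed so far
            length_so_far = 0
            for c2, pos, strain, ids in site_plan:
                if c2 != chrom:
                    continue
                present = strain == "shared" or strain == strain_key
                if not present:
                    continue
                parts.append(bb[cursor:pos])
                length_so_far += pos - cursor
                cursor = pos
                sp = spacers["|".join(ids)]
                for i, eid in enumerate(ids):
                    seq = seq_by_id[eid]
                    start = length_so_far
                    end = start + len(seq)
                    parts.append(seq)
                    length_so_far = end
                    coords[strain_key][eid] = (start, end)
                    cons = consensus_by_id[eid]
                    annot_rows[strain_key].append(
                        (chrom, start, end, eid, cons.subfamily,
                         strand_by_id[eid], cons.family, cons.class_)
                    )
                    if i < len(sp):
                        parts.append(sp[i])
                        length_so_far += len(sp[i])
            parts.append(bb[cursor:])
            genomes[strain_key][chrom] = "".join(parts)

    annot_A = pd.DataFrame(annot_rows["A"], columns=ANNOTATION_COLUMNS)
    annot_B = pd.DataFrame(annot_rows["B"], columns=ANNOTATION_COLUMNS)

    man_rows = []
    for chrom, pos, strain, ids in site_plan:
        for eid in ids:
            cons = consensus_by_id[eid]
            ca = coords["A"].get(eid, (-1, -1))
            cb = coords["B"].get(eid, (-1, -1))
            man_rows.append(
                (eid, strain, cons.subfamily, cons.family, cons.class_,
                 strand_by_id[eid], cons.is_erv, chrom, pos,
                 ca[0], ca[1], cb[0], cb[1], len(ids) > 1, False, "")
            )
    manifest = pd.DataFrame(man_rows, columns=MANIFEST_COLUMNS)
    return genomes["A"], genomes["B"], annot_A, annot_B, manifest


def make_gene_models(manifest: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Place TSSs on the backbone away from insertion sites.

    Returns a table with the TSS position mapped into each assembly's
    coordinates (insertions upstream of a TSS shift it rightward).
    """
    if config.n_genes <= 0:
        raise ValueError("n_genes must be positive")
    rng = np.random.default_rng([_STAGE_GENES, config.rng_seed])
    per_chrom = config.backbone_length // config.n_chromosomes
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    sites = {
        c: np.sort(manifest.loc[manifest["chrom"] == c, "site_pos"].to_numpy())
        for c in chroms
    }
    # cumulative inserted length per assembly, keyed by site
    shift: dict[str, dict[str, np.ndarray]] = {}
    for strain_key, (s_col, e_col) in (("A", ("start_A", "end_A")), ("B", ("start_B", "end_B"))):
        shift[strain_key] = {}
        for c in chroms:
            sub = manifest[(manifest["chrom"] == c) & (manifest[s_col] >= 0)]
            lens = (sub[e_col] - sub[s_col]).groupby(sub["site_pos"]).sum()
            pos = np.sort(sub["site_pos"].unique())
            # total spacer length inside clustered runs also shifts coordinates
            run_extra = []
            for p in pos:
                rows = sub[sub["site_pos"] == p].sort_values(s_col)
                span = int(rows[e_col].max() - rows[s_col].min())
                run_extra.append(span - int(lens[p]))
            cum = np.cumsum(lens.loc[pos].to_numpy() + np.array(run_extra, dtype=int))
            shift[strain_key][c] = np.stack([pos, cum]) if len(pos) else np.zeros((2, 0), int)

    rows = []
    gi = 0
    n_per = [config.n_genes // len(chroms)] * len(chroms)
    for i in range(config.n_genes % len(chroms)):
        n_per[i] += 1
    for c, k in zip(chroms, n_per):
        placed = 0
        attempts = 0
        while placed < k:
            attempts += 1
            if attempts > 100 * k:
                raise RuntimeError("could not place genes away from insertions")
            tss = int(rng.integers(config.end_margin, per_chrom - config.end_margin))
            if sites[c].size and np.min(np.abs(sites[c] - tss)) < config.gene_min_dist_to_insertion:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            mapped = {}
            for strain_key in ("A", "B"):
                pos, cum = shift[strain_key][c]
                j = np.searchsorted(pos, tss, side="right")
                mapped[strain_key] = tss + (int(cum[j - 1]) if j > 0 else 0)
            gi += 1
            rows.append((f"g{gi:05d}", c, tss, mapped["A"], mapped["B"], strand))
            placed += 1
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "tss_backbone", "tss_A", "tss_B", "strand"]
    )
    return genes.sort_values(["chrom", "tss_backbone"], ignore_index=True)


def simulate_wgs_coverage(
    manifest: pd.DataFrame,
    annotation_A: pd.DataFrame,
    annotation_B: pd.DataFrame,
    config: SimConfig,
) -> pd.DataFrame:
    """Per-element unique-read counts for both WGS libraries on both assemblies.

    Elements present in a strain draw Poisson(``wgs_depth``) counts from
    that strain's library. Elements absent from a strain receive zero
    reads with probability ``1 - mismap_rate``, otherwise a count drawn
    from Poisson(``mismap_rate * wgs_depth``) — a crude stand-in for
    multi-mapping leakage.
    """
    if config.wgs_depth <= 0:
        raise ValueError("wgs_depth must be positive")
    rng = np.random.default_rng([_STAGE_WGS, config.rng_seed])
    strain_of = dict(zip(manifest["element_id"], manifest["strain"]))
    rows = []
    for asm, annot in (("A", annotation_A), ("B", annotation_B)):
        for r in annot.to_dict("records"):
            strain = strain_of.get(r["element_id"])
            if strain is None:
                raise ValueError(f"annotation element {r['element_id']} missing from manifest")
            counts = {}
            for lib in ("A", "B"):
                present = strain in ("shared", lib)
                if present:
                    counts[lib] = int(rng.poisson(config.wgs_depth))
                elif config.mismap_rate > 0 and rng.random() < config.mismap_rate:
                    counts[lib] = int(rng.poisson(config.mismap_rate * config.wgs_depth))
                else:
                    counts[lib] = 0
            rows.append(
                (asm, r["element_id"], r["chrom"], r["start"], r["end"],
                 r["subfamily"], r["family"], r["class"], counts["A"], counts["B"])
            )
    return pd.DataFrame(
        rows,
        columns=["assembly", "element_id", "chrom", "start", "end", "subfamily",
                 "family", "class", "count_A", "count_B"],
    )


def simulate_chip_and_expression(
    manifest: pd.DataFrame,
    annotations: dict[str, pd.DataFrame],
    gene_models: pd.DataFrame,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """H3K27ac element signal and per-gene expression for both strains.

    A fraction ``active_fraction`` of private ERV insertions is flagged
    active in its carrier strain and assigned element RPKM drawn
    uniformly from ``active_rpkm_range``; every other element draws RPKM
    below 1. Gene expression is log-normal around a common baseline;
    the gene nearest to an active private element gains
    ``expression_effect_log2fc`` log2 units in the carrier strain only.
    Updates ``manifest`` in place (``is_active``, ``nearest_gene_id``).
    """
    config.validate()
    if gene_models.empty:
        raise ValueError("gene model table is empty")
    rng = np.random.default_rng([_STAGE_CHIP, config.rng_seed])

    priv = manifest[(manifest["strain"].isin(["A", "B"])) & (manifest["is_erv"])]
    n_active = int(round(config.active_fraction * len(priv)))
    active_ids: set[str] = set()
    if n_active > 0:
        chosen = rng.choice(len(priv), size=n_active, replace=False)
        active_ids = set(priv.iloc[np.sort(chosen)]["element_id"])
    manifest["is_active"] = manifest["element_id"].isin(active_ids)

    lo, hi = config.active_rpkm_range
    sig_rows = []
    for asm, annot in annotations.items():
        strain_of = dict(zip(manifest["element_id"], manifest["strain"]))
        for r in annot.itertuples(index=False):
            carrier = strain_of[r.element_id]
            if r.element_id in active_ids and carrier == asm:
                rpkm = float(rng.uniform(lo, hi))
            else:
                rpkm = float(rng.uniform(0.0, config.inactive_rpkm_max))
            sig_rows.append((asm, r.element_id, rpkm))
    signal = pd.DataFrame(sig_rows, columns=["assembly", "element_id", "rpkm"])

    # nearest expressed gene per private element, in carrier coordinates
    genes_sorted = gene_models.sort_values(["chrom", "tss_backbone"])
    nearest = {}
    for row in manifest.itertuples(index=False):
        if row.strain not in ("A", "B"):
            continue
        s_col = f"tss_{row.strain}"
        start = row.start_A if row.strain == "A" else row.start_B
        end = row.end_A if row.strain == "A" else row.end_B
        cand = genes_sorted[genes_sorted["chrom"] == row.chrom]
        if cand.empty:
            continue
        dists = cand[s_col].map(lambda t: interval_tss_distance(start, end, int(t)))
        best = min(zip(dists, cand["gene_id"]))
        nearest[row.element_id] = best[1]
    manifest["nearest_gene_id"] = manifest["element_id"].map(nearest).fillna("")

    boosted: dict[str, set[str]] = {"A": set(), "B": set()}
    for row in manifest.itertuples(index=False):
        if row.is_active and row.strain in ("A", "B") and row.nearest_gene_id:
            boosted[row.strain].add(row.nearest_gene_id)

    base = config.baseline_log2_fpkm + rng.normal(0.0, 1.0, size=len(gene_models))
    noise_A = rng.normal(0.0, config.expr_noise_sd, size=len(gene_models))
    noise_B = rng.normal(0.0, config.expr_noise_sd, size=len(gene_models))
    log_A = base + noise_A
    log_B = base + noise_B
    ids = gene_models["gene_id"].to_numpy()
    log_A = log_A + np.isin(ids, list(boosted["A"])) * config.expression_effect_log2fc
    log_B = log_B + np.isin(ids, list(boosted["B"])) * config.expression_effect_log2fc
    expression = gene_models.copy()
    expression["fpkm_A"] = np.maximum(np.exp2(log_A) - 1.0, 0.0)
    expression["fpkm_B"] = np.maximum(np.exp2(log_B) - 1.0, 0.0)
    return signal, expression


def forge_world(config: SimConfig | None = None,
                library: list[RepeatConsensus] | None = None) -> World:
    """Generate the complete synthetic world for one configuration."""
    config = config if config is not None else SimConfig()
    library = library if library is not None else default_repeat_library()
    gA, gB, annA, annB, manifest = synthesize_genome_pair(config, library)
    genes = make_gene_models(manifest, config)
    coverage = simulate_wgs_coverage(manifest, annA, annB, config)
    signal, expression = simulate_chip_and_expression(
        manifest, {"A": annA, "B": annB}, genes, config
    )
    return World(
        config=config, genome_A=gA, genome_B=gB,
        annotation_A=annA, annotation_B=annB, manifest=manifest,
        genes=genes, coverage=coverage, signal=signal, expression=expression,
    )
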