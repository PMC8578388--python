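"""Characterization of final ppERV calls.

Covers subfamily enrichment against the genome-wide ERV background,
single-linkage clustering of calls into runs, the activity rule
(element H3K27ac RPKM > 1 and length > 50 bp), closest-gene assignment
by TSS distance, and the shuffled-control expression comparison between
the carrier strain and the other strain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import PpreCall, RepeatElement, interval_tss_distance

__all__ = [
    "SubfamilyEnrichment",
    "PpreCluster",
    "ActivityCall",
    "hypergeom_two_tailed",
    "hypergeom_upper_tail",
    "subfamily_enrichment",
    "cluster_elements",
    "call_active",
    "assign_closest_gene",
    "compare_closest_gene_expression",
]

logger = logging.getLogger(__name__)


@dataclass
class SubfamilyEnrichment:
    """Observed vs expected ppERV count for one subfamily.

    ``expected = (n / N) * X`` where n = subfamily elements genome-wide,
    N = all ERV elements genome-wide, X = total ppERVs called.
    """

    subfamily: str
    n: int
    N: int
    X: int
    observed: int
    expected: float
    ratio: float
    p: float
    flagged: bool


@dataclass
class PpreCluster:
    """A run of >= 2 calls with inter-element gaps below the threshold."""

    members: list[PpreCall]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster needs at least two members")

    @property
    def chrom(self) -> str:
        return self.members[0].element.chrom

    @property
    def start(self) -> int:
        return min(m.element.start for m in self.members)

    @property
    def end(self) -> int:
        return max(m.element.end for m in self.members)

    @property
    def private_to(self) -> str:
        return self.members[0].private_to

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ActivityCall:
    element: RepeatElement
    h3k27ac_rpkm: float
    active: bool = field(init=False)
    _min_rpkm: float = 1.0
    _min_len: int = 50

    def __post_init__(self) -> None:
        self.active = (
            self.h3k27ac_rpkm > self._min_rpkm and self.element.length > self._min_len
        )


def hypergeom_two_tailed(N: int, n: int, X: int, k: int) -> float:
    """Two-tailed hypergeometric probability by the minimum-likelihood rule.

    Population ``N`` with ``n`` successes, ``X`` draws, ``k`` observed:
    the p-value sums PMF(j) over every j in the support whose PMF does
    not exceed PMF(k) (with a small relative tolerance against floating
    point ties). This is the standard exact two-sided construction.
    """
    if X > N or n > N or k > min(n, X) or k < max(0, n + X - N):
        raise ValueError(f"inconsistent hypergeometric parameters N={N} n={n} X={X} k={k}")
    support = np.arange(max(0, n + X - N), min(n, X) + 1)
    pmf = stats.hypergeom.pmf(support, N, n, X)
    pk = float(stats.hypergeom.pmf(k, N, n, X))
    return float(min(1.0, pmf[pmf <= pk * (1 + 1e-9)].sum()))


def hypergeom_upper_tail(N: int, n: int, X: int, k: int) -> float:
    """One-sided enrichment probability P(K >= k)."""
    return float(stats.hypergeom.sf(k - 1, N, n, X))


def subfamily_enrichment(
    ppervs: list[PpreCall],
    genome_repeats: list[RepeatElement],
    ratio_threshold: float = 7.0,
    p_threshold: float = 0.001,
    two_tailed: bool = True,
) -> list[SubfamilyEnrichment]:
    """Per-subfamily enrichment of ppERVs against the genome-wide ERV set.

    Only subfamilies present in the genome-wide ERV annotation are
    reported. No multiple-testing adjustment is applied; a subfamily is
    flagged when its observed/expected ratio exceeds ``ratio_threshold``
    and its p-value is below ``p_threshold``.
    """
    erv_bg = [e for e in genome_repeats if e.is_erv()]
    N = len(erv_bg)
    X = len(ppervs)
    if X > N:
        raise ValueError("more ppERVs than genome-wide ERV elements")
    bg_counts: dict[str, int] = {}
    for e in erv_bg:
        bg_counts[e.subfamily] = bg_counts.get(e.subfamily, 0) + 1
    obs_counts: dict[str, int] = {}
    for c in ppervs:
        sub = c.element.subfamily
        if sub not in bg_counts:
            raise ValueError(f"ppERV subfamily {sub} absent from genome-wide annotation")
        obs_counts[sub] = obs_counts.get(sub, 0) + 1
    results = []
    for sub in sorted(bg_counts):
        n = bg_counts[sub]
        k = obs_counts.get(sub, 0)
        expected = (n / N) * X if N else 0.0
        ratio = k / expected if expected > 0 else float("nan")
        if two_tailed:
            p = hypergeom_two_tailed(N, n, X, k)
        else:
            p = hypergeom_upper_tail(N, n, X, k)
        results.append(
            SubfamilyEnrichment(
                subfamily=sub, n=n, N=N, X=X, observed=k, expected=expected,
                ratio=ratio, p=p,
                flagged=bool(ratio > ratio_threshold and p < p_threshold),
            )
        )
    return results


def cluster_elements(
    ppres: list[PpreCall], cluster_max_gap: int = 20
) -> tuple[list[PpreCluster], list[PpreCall]]:
    """Partition calls into clusters (runs of >= 2) and solo calls.

    Single-linkage on genomic order within one chromosome and strain:
    consecutive calls join when ``next.start - prev.end`` is strictly
    below ``cluster_max_gap``. Touching elements (gap 0) join;
    overlapping elements (negative gap) join with a logged warning.
    """
    groups: dict[tuple[str, str], list[PpreCall]] = {}
    for c in ppres:
        groups.setdefault((c.private_to, c.element.chrom), []).append(c)
    clusters: list[PpreCluster] = []
    solos: list[PpreCall] = []
    for key in sorted(groups):
        calls = sorted(groups[key], key=lambda c: (c.element.start, c.element.end))
        run = [calls[0]]
        for prev, nxt in zip(calls, calls[1:]):
            gap = nxt.element.start - prev.element.end
            if gap < 0:
                logger.warning(
                    "overlapping elements %s and %s (gap %d); joining cluster",
                    prev.element.element_id, nxt.element.element_id, gap,
                )
            if gap < cluster_max_gap:
                run.append(nxt)
            else:
                if len(run) >= 2:
                    clusters.append(PpreCluster(run))
                else:
                    solos.append(run[0])
                run = [nxt]
        if len(run) >= 2:
            clusters.append(PpreCluster(run))
        else:
            solos.append(run[0])
    return clusters, solos


def call_active(
    ppervs: list[PpreCall],
    signal: pd.DataFrame,
    min_rpkm: float = 1.0,
    min_len: int = 50,
) -> list[ActivityCall]:
    """Apply the activity rule: RPKM strictly above 1 and length strictly above 50 bp.

    ``signal`` must provide one RPKM per called element, measured in the
    carrier strain's ChIP library. Rows are matched by element id (and
    by assembly/strain when the table carries an ``assembly`` column).
    """
    calls = []
    if "assembly" in signal.columns:
        keyed = {(r["assembly"], r["element_id"]): float(r["rpkm"])
                 for r in signal.to_dict("records")}
        lookup = lambda c: keyed.get((c.private_to, c.element.element_id))
    else:
        keyed = dict(zip(signal["element_id"], signal["rpkm"].astype(float)))
        lookup = lambda c: keyed.get(c.element.element_id)
    for c in ppervs:
        rpkm = lookup(c)
        if rpkm is None:
            raise ValueError(f"no signal row for element {c.element.element_id}")
        calls.append(
            ActivityCall(element=c.element, h3k27ac_rpkm=rpkm,
                         _min_rpkm=min_rpkm, _min_len=min_len)
        )
    return calls


def assign_closest_gene(
    elements: list[PpreCall | PpreCluster],
    genes: pd.DataFrame,
    tss_column: str = "tss_A",
    fpkm_columns: tuple[str, str] = ("fpkm_A", "fpkm_B"),
) -> dict[str, str]:
    """Map each element (or cluster span) to the expressed gene with the nearest TSS.

    Only genes with FPKM > 0 in at least one sample compete. Distance is
    zero when the TSS lies inside the element interval; ties break to
    the lexicographically smaller gene id. Elements on chromosomes with
    no expressed gene are left unassigned (and logged).
    """
    expressed = genes
    present = [c for c in fpkm_columns if c in genes.columns]
    if present:
        expressed = genes[(genes[present] > 0).any(axis=1)]
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for r in expressed.to_dict("records"):
        by_chrom.setdefault(str(r["chrom"]), []).append((int(r[tss_column]), str(r["gene_id"])))
    assignment: dict[str, str] = {}
    for el in elements:
        if isinstance(el, PpreCluster):
            key = f"cluster:{el.chrom}:{el.start}-{el.end}"
            chrom, start, end = el.chrom, el.start, el.end
        else:
            key = el.element.element_id
            chrom, start, end = el.element.chrom, el.element.start, el.element.end
        cands = by_chrom.get(chrom)
        if not cands:
            logger.warning("no expressed gene on %s; %s unassigned", chrom, key)
            continue
        best = min((interval_tss_distance(start, end, tss), gid) for tss, gid in cands)
        assignment[key] = best[1]
    return assignment


@dataclass
class ExpressionComparison:
    """Paired comparison of assigned genes' expression across strains."""

    gene_ids: list[str]
    carrier_log2: np.ndarray
    other_log2: np.ndarray
    control_log2: np.ndarray  # per-position mean over shuffles, carrier strain
    p_carrier_vs_other: float
    p_carrier_vs_control: float
    n_shuffles: int

    @property
    def mean_carrier(self) -> float:
        return float(self.carrier_log2.mean())

    @property
    def mean_other(self) -> float:
        return float(self.other_log2.mean())

    @property
    def mean_control(self) -> float:
        return float(self.control_log2.mean())


def _one_tailed_paired_t(x: np.ndarray, y: np.ndarray) -> float:
    """P(mean(x) > mean(y)) via one-tailed paired t-test; 0.5 when all ties."""
    diff = x - y
    if np.allclose(diff.std(ddof=1), 0.0):
        return 0.5 if np.allclose(diff.mean(), 0.0) else (0.0 if diff.mean() > 0 else 1.0)
    res = stats.ttest_rel(x, y, alternative="greater")
    return float(res.pvalue)


def compare_closest_gene_expression(
    assigned_genes: list[str],
    expression: pd.DataFrame,
    carrier: str = "A",
    n_shuffles: int = 50,
    rng: np.random.Generator | int | None = None,
) -> ExpressionComparison:
    """Compare assigned genes' expression in the carrier strain vs the other
    strain and vs a size-matched shuffled control.

    Expression is compared on the log2(FPKM + 1) scale. The control is
    the per-position average of ``n_shuffles`` random size-matched draws
    from the expressed-gene universe (FPKM > 0 in at least one sample).
    One-tailed paired t-tests ask whether carrier-strain expression
    exceeds the other strain's / the control's.
    """
    if len(assigned_genes) < 2:
        raise ValueError("need at least two assigned genes")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    other = "B" if carrier == "A" else "A"
    expressed = expression[(expression[["fpkm_A", "fpkm_B"]] > 0).any(axis=1)]
    universe = expressed["gene_id"].tolist()
    if len(universe) < len(assigned_genes):
        raise ValueError("expressed-gene universe smaller than the assigned gene set")
    log2 = {
        s: dict(zip(expressed["gene_id"], np.log2(expressed[f"fpkm_{s}"] + 1.0)))
        for s in ("A", "B")
    }
    missing = [g for g in assigned_genes if g not in log2[carrier]]
    if missing:
        raise ValueError(f"assigned genes not in expressed universe: {missing[:5]}")
    carrier_vals = np.array([log2[carrier][g] for g in assigned_genes])
    other_vals = np.array([log2[other][g] for g in assigned_genes])
    draws = np.empty((n_shuffles, len(assigned_genes)))
    carrier_col = np.array([log2[carrier][g] for g in universe])
    for i in range(n_shuffles):
        idx = rng.choice(len(universe), size=len(assigned_genes), replace=False)
        draws[i] = carrier_col[idx]
    control = draws.mean(axis=0)
    return ExpressionComparison(
        gene_ids=list(assigned_genes),
        carrier_log2=carrier_vals,
        other_log2=other_vals,
        control_log2=control,
        p_carrier_vs_other=_one_tailed_paired_t(carrier_vals, other_vals),
        p_carrier_vs_control=_one_tailed_paired_t(carrier_vals, control),
        n_shuffles=n_shuffles,
    )
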