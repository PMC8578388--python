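"""ChIP track normalization and Poisson differential peaks.

RPKM is computed per fixed-width genomic bin (default 100 bp) and per
annotated element; input (control) RPKM is subtracted bin-wise without
clipping. Differential peaks between two samples are assessed on
depth-normalized counts over the merged peak universe with an
upper-tail Poisson test and Benjamini-Hochberg FDR control; a peak is
differential when its pseudocounted fold change exceeds the threshold
and its FDR falls below the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BinnedTrack",
    "MergedPeak",
    "binned_rpkm",
    "input_subtract",
    "element_rpkm",
    "merge_peaks",
    "poisson_differential",
]


@dataclass
class BinnedTrack:
    """Tiled fixed-width bins over one or more chromosomes.

    ``values`` holds RPKM (or input-subtracted RPKM, which may be
    negative) keyed by (chrom, bin_start).
    """

    bin_size: int
    values: dict[tuple[str, int], float]
    total_reads: int

    def value(self, chrom: str, bin_start: int) -> float:
        return self.values.get((chrom, bin_start), 0.0)


@dataclass
class MergedPeak:
    chrom: str
    start: int
    end: int
    raw_a: float
    raw_b: float
    norm_a: float
    norm_b: float
    fold_change: float
    direction: str  # which sample is higher, "A" or "B"
    p: float
    q: float
    differential: bool


def binned_rpkm(
    counts: dict[tuple[str, int], int] | pd.DataFrame,
    total_reads: int,
    bin_size: int = 100,
) -> BinnedTrack:
    """Depth- and length-normalize per-bin read counts to RPKM.

    ``RPKM = count / ((bin_size / 1e3) * (total_reads / 1e6))``.
    Accepts either a mapping (chrom, bin_start) -> count or a DataFrame
    with columns chrom, bin_start, count.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if isinstance(counts, pd.DataFrame):
        items = [((str(r["chrom"]), int(r["bin_start"])), float(r["count"]))
                 for r in counts.to_dict("records")]
    else:
        items = [(k, float(v)) for k, v in counts.items()]
    denom = (bin_size / 1e3) * (total_reads / 1e6)
    values = {}
    for (chrom, start), count in items:
        if start % bin_size:
            raise ValueError(f"bin start {start} is not a multiple of {bin_size}")
        values[(chrom, start)] = count / denom
    return BinnedTrack(bin_size=bin_size, values=values, total_reads=total_reads)


def input_subtract(ip: BinnedTrack, control: BinnedTrack) -> BinnedTrack:
    """Per-bin IP minus input; negative values are retained, not clipped."""
    if ip.bin_size != control.bin_size:
        raise ValueError("binning mismatch between IP and input tracks")
    keys = set(ip.values) | set(control.values)
    values = {k: ip.value(*k) - control.value(*k) for k in keys}
    return BinnedTrack(bin_size=ip.bin_size, values=values, total_reads=ip.total_reads)


def element_rpkm(
    elements: pd.DataFrame,
    counts: dict[str, int],
    total_reads: int,
) -> pd.DataFrame:
    """Per-element RPKM from read counts over annotated intervals.

    ``elements`` is a BED-like table (chrom, start, end, element_id, ...);
    ``counts`` maps element_id -> read count.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    rows = []
    for r in elements.to_dict("records"):
        length = int(r["end"]) - int(r["start"])
        if length <= 0:
            raise ValueError(f"zero-length element {r['element_id']}")
        count = counts.get(str(r["element_id"]), 0)
        rpkm = count / ((length / 1e3) * (total_reads / 1e6))
        rows.append((r["element_id"], r["chrom"], r["start"], r["end"], count, rpkm))
    return pd.DataFrame(
        rows, columns=["element_id", "chrom", "start", "end", "count", "rpkm"]
    )


def merge_peaks(
    peaks_a: list[tuple[str, int, int]],
    peaks_b: list[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    """Union of two peak sets with overlapping or bookended intervals merged."""
    merged: list[list] = []
    for chrom, start, end in sorted(peaks_a + peaks_b):
        if merged and chrom == merged[-1][0] and start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
        else:
            merged.append([chrom, start, end])
    return [tuple(m) for m in merged]


def poisson_differential(
    merged: list[tuple[str, int, int]],
    counts_a: list[int] | np.ndarray,
    counts_b: list[int] | np.ndarray,
    total_a: int,
    total_b: int,
    fc_threshold: float = 4.0,
    fdr_threshold: float = 0.001,
    pseudocount: float = 1.0,
) -> list[MergedPeak]:
    """Differential assessment of merged peaks on depth-normalized counts.

    Counts are scaled to reads per million. Per peak the larger
    normalized count x = max(normA, normB) is tested against a Poisson
    null centred on the pooled mean,
    lam = (normA + normB) / 2 + pseudocount, via the upper tail
    P(X >= round(x) | lam); centring on the pooled mean keeps the test
    conservative under a null of equal rates, which an asymmetric null
    (rate taken from the smaller sample alone) is not. The fold change
    is (max + pseudocount) / (min + pseudocount). FDR is
    Benjamini-Hochberg across all merged peaks; a peak is differential
    when fold change strictly exceeds ``fc_threshold`` and q is
    strictly below ``fdr_threshold``.
    """
    if not merged:
        raise ValueError("empty merged peak list")
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if counts_a.shape != (len(merged),) or counts_b.shape != (len(merged),):
        raise ValueError("one count per merged peak per sample required")
    norm_a = counts_a * 1e6 / total_a
    norm_b = counts_b * 1e6 / total_b
    hi = np.maximum(norm_a, norm_b)
    lo = np.minimum(norm_a, norm_b)
    lam = (norm_a + norm_b) / 2.0 + pseudocount
    fc = (hi + pseudocount) / (lo + pseudocount)
    p = stats.poisson.sf(np.round(hi) - 1, lam)
    q = multipletests(p, method="fdr_bh")[1]
    out = []
    for i, (chrom, start, end) in enumerate(merged):
        out.append(
            MergedPeak(
                chrom=chrom, start=start, end=end,
                raw_a=float(counts_a[i]), raw_b=float(counts_b[i]),
                norm_a=float(norm_a[i]), norm_b=float(norm_b[i]),
                fold_change=float(fc[i]),
                direction="A" if norm_a[i] >= norm_b[i] else "B",
                p=float(p[i]), q=float(q[i]),
                differential=bool(fc[i] > fc_threshold and q[i] < fdr_threshold),
            )
        )
    return out


def peaks_to_frame(peaks: list[MergedPeak]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.chrom, p.start, p.end, p.norm_a, p.norm_b, p.fold_change,
             p.direction, p.p, p.q, p.differential)
            for p in peaks
        ],
        columns=["chrom", "start", "end", "normA", "normB", "fc", "direction",
                 "p", "q", "differential"],
    )
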