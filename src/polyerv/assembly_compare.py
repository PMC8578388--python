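"""Assembly-comparison evidence stream for polymorphic repeat discovery.

Two assemblies of the same species are compared with a nucmer-style
anchor strategy: all maximal exact matches above a minimum length are
found on both strands, chained into collinear clusters, and the
reference intervals left uncovered by any retained cluster ("gaps") are
intersected with the repeat annotation. A repeat fully contained in a
gap is a candidate private insertion of the reference strain.

The anchor parameters mirror common practice for closely related
assemblies: minimum match length 20 bp, maximum within-cluster gap
50 bp, minimum summed cluster length 200 bp.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .core import (
    RepeatElement,
    encode_sequence,
    reverse_complement,
)

__all__ = [
    "AnchorMatch",
    "AnchorCluster",
    "GapInterval",
    "find_exact_matches",
    "chain_matches",
    "extract_gaps",
    "call_assembly_ppres",
    "call_direction",
]

_EXT_CHUNK = 8192


@dataclass(frozen=True)
class AnchorMatch:
    """A maximal exact match between reference and query.

    Query coordinates are always on the forward strand of the query;
    ``strand == "-"`` means the match is against the reverse complement.
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    query_chrom: str
    query_start: int
    query_end: int
    strand: str

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start

    def __post_init__(self) -> None:
        if (self.ref_end - self.ref_start) != (self.query_end - self.query_start):
            raise ValueError("ref and query intervals of a match must have equal length")


@dataclass
class AnchorCluster:
    """A collinear chain of anchor matches on a single strand."""

    members: list[AnchorMatch]
    matched_bp: int = field(init=False)

    def __post_init__(self) -> None:
        self.matched_bp = sum(m.length for m in self.members)

    @property
    def ref_chrom(self) -> str:
        return self.members[0].ref_chrom

    @property
    def query_chrom(self) -> str:
        return self.members[0].query_chrom

    @property
    def strand(self) -> str:
        return self.members[0].strand

    @property
    def ref_start(self) -> int:
        return min(m.ref_start for m in self.members)

    @property
    def ref_end(self) -> int:
        return max(m.ref_end for m in self.members)

    @property
    def query_start(self) -> int:
        return min(m.query_start for m in self.members)

    @property
    def query_end(self) -> int:
        return max(m.query_end for m in self.members)


@dataclass(frozen=True)
class GapInterval:
    """A reference interval uncovered by any retained anchor cluster."""

    chrom: str
    start: int
    end: int
    flanked_both_sides: bool

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("gap end must exceed start")


def _kmer_hashes(code: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact 2-bit packed k-mer codes and a mask of windows free of N."""
    n = code.size
    h = np.zeros(n - k + 1, dtype=np.uint64)
    for t in range(k):
        h = (h << np.uint64(2)) | (code[t : n - k + 1 + t].astype(np.uint64) & np.uint64(3))
    is_n = np.concatenate(([0], np.cumsum(code == 255)))
    valid = (is_n[k:] - is_n[:-k]) == 0
    return h, valid


def _extend_right(rcode: np.ndarray, qcode: np.ndarray, i: int, j: int, k: int) -> int:
    """Length of the exact match starting at (i, j), known to cover >= k bp."""
    lim = min(rcode.size - i, qcode.size - j)
    t = k
    while t < lim:
        e = min(t + _EXT_CHUNK, lim)
        a = rcode[i + t : i + e]
        b = qcode[j + t : j + e]
        bad = np.flatnonzero((a != b) | (a == 255))
        if bad.size:
            return t + int(bad[0])
        t = e
    return lim


def _mems_encoded(rcode: np.ndarray, qcode: np.ndarray, k: int) -> list[tuple[int, int, int]]:
    """All maximal exact matches of length >= k as (ref_pos, query_pos, length)."""
    if rcode.size < k or qcode.size < k:
        return []
    rh, rvalid = _kmer_hashes(rcode, k)
    qh, qvalid = _kmer_hashes(qcode, k)
    rpos = np.flatnonzero(rvalid)
    qpos = np.flatnonzero(qvalid)
    if rpos.size == 0 or qpos.size == 0:
        return []
    order = np.argsort(rh[rpos], kind="stable")
    rhv = rh[rpos][order]
    rpos_sorted = rpos[order]
    lo = np.searchsorted(rhv, qh[qpos], side="left")
    hi = np.searchsorted(rhv, qh[qpos], side="right")
    counts = hi - lo
    hit = counts > 0
    if not hit.any():
        return []
    qpos, lo, counts = qpos[hit], lo[hit], counts[hit]
    total = int(counts.sum())
    # expand [lo, lo+count) ranges into a flat index vector
    offsets = np.repeat(np.cumsum(counts) - counts, counts)
    flat = np.repeat(lo, counts) + (np.arange(total) - offsets)
    ri = rpos_sorted[flat]
    qi = np.repeat(qpos, counts)
    # keep only left-maximal seeds: boundary, mismatch, or N just before
    interior = (ri > 0) & (qi > 0)
    start = ~interior
    prev_r = rcode[ri[interior] - 1]
    prev_q = qcode[qi[interior] - 1]
    start[interior] = (prev_r != prev_q) | (prev_r == 255)
    ri, qi = ri[start], qi[start]
    out = []
    for i, j in zip(ri.tolist(), qi.tolist()):
        out.append((i, j, _extend_right(rcode, qcode, i, j, k)))
    return out


def find_exact_matches(
    ref: dict[str, str],
    query: dict[str, str],
    min_match_len: int = 20,
) -> list[AnchorMatch]:
    """All maximal exact matches >= ``min_match_len`` between two assemblies.

    Both the forward strand and the reverse complement of the query are
    scanned; N never matches anything, including another N. Matches are
    maximal in the brute-force sense: not extendable by one base on
    either side.
    """
    if not ref or not query:
        raise ValueError("both assemblies must be non-empty")
    if not (1 <= min_match_len <= 32):
        raise ValueError("min_match_len must be in [1, 32] for 2-bit packed seeding")
    rcodes = {c: encode_sequence(s) for c, s in ref.items()}
    matches: list[AnchorMatch] = []
    for qchrom, qseq in query.items():
        fwd = encode_sequence(qseq)
        rev = encode_sequence(reverse_complement(qseq))
        m = len(qseq)
        for rchrom, rcode in rcodes.items():
            for i, j, length in _mems_encoded(rcode, fwd, min_match_len):
                matches.append(
                    AnchorMatch(rchrom, i, i + length, qchrom, j, j + length, "+")
                )
            for i, j, length in _mems_encoded(rcode, rev, min_match_len):
                matches.append(
                    AnchorMatch(
                        rchrom, i, i + length, qchrom, m - (j + length), m - j, "-"
                    )
                )
    matches.sort(key=lambda a: (a.ref_chrom, a.ref_start, a.query_chrom, a.query_start, a.strand))
    return matches


def _query_gap(prev: AnchorMatch, nxt: AnchorMatch, strand: str) -> int:
    if strand == "+":
        return nxt.query_start - prev.query_end
    return prev.query_start - nxt.query_end


def chain_matches(
    matches: list[AnchorMatch],
    max_gap: int = 50,
    min_cluster_len: int = 200,
) -> list[AnchorCluster]:
    """Chain collinear matches of one (ref chrom, query chrom, strand) group.

    Greedy longest-first seeding with monotone extension in both
    directions: a neighbour joins the chain when it is collinear and the
    gap on both the reference and the query is within ``max_gap``
    (negative gaps, i.e. overlaps, do not chain). Chains whose summed
    match length falls below ``min_cluster_len`` are discarded.
    """
    if not matches:
        return []
    key = (matches[0].ref_chrom, matches[0].query_chrom, matches[0].strand)
    if any((m.ref_chrom, m.query_chrom, m.strand) != key for m in matches):
        raise ValueError("chain_matches expects matches from one chromosome pair and strand")
    strand = key[2]
    ms = sorted(matches, key=lambda m: (m.ref_start, m.ref_end))
    n = len(ms)
    seed_order = sorted(range(n), key=lambda i: (-ms[i].length, ms[i].ref_start))
    # candidate windows: forward joins need ref_start in [cur_end, cur_end+gap],
    # backward joins need ref_end in [cur_start-gap, cur_start]
    starts = [m.ref_start for m in ms]
    by_end = sorted(range(n), key=lambda i: (ms[i].ref_end, ms[i].ref_start))
    ends = [ms[i].ref_end for i in by_end]
    used = [False] * n
    clusters: list[AnchorCluster] = []

    def grow(idx: int, forward: bool) -> int | None:
        cur = ms[idx]
        if forward:
            lo = bisect.bisect_left(starts, cur.ref_end)
            hi = bisect.bisect_right(starts, cur.ref_end + max_gap)
            for j in range(lo, hi):
                if used[j]:
                    continue
                if 0 <= _query_gap(cur, ms[j], strand) <= max_gap:
                    return j
        else:
            lo = bisect.bisect_left(ends, cur.ref_start - max_gap)
            hi = bisect.bisect_right(ends, cur.ref_start)
            # nearest on the reference first
            for pos in range(hi - 1, lo - 1, -1):
                j = by_end[pos]
                if used[j]:
                    continue
                if 0 <= _query_gap(ms[j], cur, strand) <= max_gap:
                    return j
        return None

    for seed in seed_order:
        if used[seed]:
            continue
        used[seed] = True
        chain = [seed]
        cur = seed
        while (nxt := grow(cur, True)) is not None:
            used[nxt] = True
            chain.append(nxt)
            cur = nxt
        cur = seed
        while (prv := grow(cur, False)) is not None:
            used[prv] = True
            chain.insert(0, prv)
            cur = prv
        cluster = AnchorCluster([ms[i] for i in chain])
        if cluster.matched_bp >= min_cluster_len:
            clusters.append(cluster)
    clusters.sort(key=lambda c: (c.ref_chrom, c.ref_start))
    return clusters


def chain_all(
    matches: list[AnchorMatch],
    max_gap: int = 50,
    min_cluster_len: int = 200,
) -> list[AnchorCluster]:
    """Group matches by (ref chrom, query chrom, strand) and chain each group."""
    groups: dict[tuple[str, str, str], list[AnchorMatch]] = {}
    for m in matches:
        groups.setdefault((m.ref_chrom, m.query_chrom, m.strand), []).append(m)
    clusters: list[AnchorCluster] = []
    for group in groups.values():
        clusters.extend(chain_matches(group, max_gap=max_gap, min_cluster_len=min_cluster_len))
    clusters.sort(key=lambda c: (c.ref_chrom, c.ref_start))
    return clusters


def extract_gaps(clusters: list[AnchorCluster], ref: dict[str, str]) -> list[GapInterval]:
    """Maximal reference intervals uncovered by any retained cluster span.

    A gap that touches a chromosome end lacks an anchoring cluster on
    that side and is reported with ``flanked_both_sides=False``.
    """
    gaps: list[GapInterval] = []
    for chrom, seq in ref.items():
        n = len(seq)
        spans = sorted(
            (c.ref_start, c.ref_end) for c in clusters if c.ref_chrom == chrom
        )
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        prev = 0
        for s, e in merged:
            if s > prev:
                gaps.append(GapInterval(chrom, prev, s, flanked_both_sides=prev > 0))
            prev = max(prev, e)
        if prev < n:
            gaps.append(GapInterval(chrom, prev, n, flanked_both_sides=False))
    gaps.sort(key=lambda g: (g.chrom, g.start))
    return gaps


def call_assembly_ppres(
    gaps: list[GapInterval],
    repeats: list[RepeatElement],
    require_both_flanks: bool = True,
) -> list[RepeatElement]:
    """Repeats fully contained in an alignment gap (candidate private insertions).

    Containment is strict: ``repeat.start >= gap.start`` and
    ``repeat.end <= gap.end``. With ``require_both_flanks`` (default),
    gaps touching a chromosome end are ignored because they mostly
    reflect assembly incompleteness rather than insertions.
    """
    usable: dict[str, list[GapInterval]] = {}
    for g in gaps:
        if require_both_flanks and not g.flanked_both_sides:
            continue
        usable.setdefault(g.chrom, []).append(g)
    for glist in usable.values():
        glist.sort(key=lambda g: g.start)
    called = []
    for rep in repeats:
        glist = usable.get(rep.chrom)
        if not glist:
            continue
        starts = [g.start for g in glist]
        idx = bisect.bisect_right(starts, rep.start) - 1
        if idx >= 0 and rep.end <= glist[idx].end:
            called.append(rep)
    return called


def call_direction(
    ref: dict[str, str],
    query: dict[str, str],
    ref_repeats: list[RepeatElement],
    min_match_len: int = 20,
    max_gap: int = 50,
    min_cluster_len: int = 200,
    require_both_flanks: bool = True,
) -> list[RepeatElement]:
    """Full assembly-comparison stream for one direction (ref-private calls)."""
    matches = find_exact_matches(ref, query, min_match_len=min_match_len)
    clusters = chain_all(matches, max_gap=max_gap, min_cluster_len=min_cluster_len)
    gaps = extract_gaps(clusters, ref)
    return call_assembly_ppres(gaps, ref_repeats, require_both_flanks=require_both_flanks)
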