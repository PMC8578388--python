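# Methods

This note documents the models, parameter choices and numerical
conventions behind `polyerv`, and what the synthetic-data tests do and
do not demonstrate.

## Coordinates and identity

All intervals are 0-based, half-open (BED convention). An element's
identity is its annotation row id; the two evidence streams operate on
the same repeat annotation per assembly, so intersection is exact id
matching. Fragmented annotations (e.g. the LTR and internal segments
of one provirus) are counted as separate elements, as annotation rows.

## Assembly-comparison stream

**Maximal exact matches.** `find_exact_matches` returns every exact
match ≥ `min_match_len` (default 20 bp) between reference and query
that cannot be extended by one base on either side, on the forward
strand and against the reverse complement of the query. The
implementation seeds with exact 2-bit-packed k-mers (k =
`min_match_len`, hence k ≤ 32), keeps only left-maximal seeds, and
extends each once; the output set is defined by — and tested against —
a brute-force all-diagonals oracle. Runs of N terminate matches: an
ambiguous base matches nothing, including another N. This is
conservative where assemblies are incomplete.

**Chaining.** Matches are chained per (reference chromosome, query
chromosome, strand): greedy longest-first seeding, then monotone
extension in both directions, joining the nearest match whose gap on
*both* genomes is within `max_gap` (default 50 bp; overlapping matches
do not chain). Chains with summed match length < `min_cluster_len`
(default 200 bp) are discarded. Ties in seeding order break to the
leftmost reference coordinate, making the output deterministic.

**Gaps and containment.** Per reference chromosome, gaps are the
maximal intervals not covered by any retained cluster span. A repeat
is called when it is fully contained in a gap (`repeat.start ≥
gap.start` and `repeat.end ≤ gap.end`). Containment is interpreted as
repeat-within-gap: the opposite reading would call almost nothing,
because insertions produce gaps at least as large as the inserted
element. Gaps touching a chromosome end lack an anchoring cluster on
one side and are excluded by default (`require_both_flanks=True`),
since terminal gaps mostly reflect assembly truncation rather than
insertions.

## Coverage stream and intersection

The coverage rule is literal and strict: `count > 10` in exactly one
library and `count == 0` in the other. A count of 10 does not call;
a single stray read on the other side vetoes the element. An element
annotated in assembly S can only be called private to strain S.
Final calls require both streams; per-strain Venn counts
(assembly-only / coverage-only / both) are reported. The ERV subset
keeps class "LTR" with family in {ERV1, ERVK, ERVL, ERVL-MaLR}
(configurable).

## Statistics

**Subfamily enrichment.** With N genome-wide ERV elements, n of them
in a subfamily, X called ppERVs and k observed in the subfamily:
expected = (n/N)·X and ratio = k/expected. The two-tailed p sums the
hypergeometric PMF over all support points whose PMF does not exceed
PMF(k) (minimum-likelihood two-sided construction; a relative
tolerance of 1e-9 guards against floating-point ties). A one-sided
upper tail is also exposed. Flagging uses ratio > `ratio_threshold`
(default 7, configurable — analyses of less complete assemblies may
warrant 10) and p < 0.001, with no multiple-testing adjustment. The
p-values are exact scipy hypergeometric sums and are tested against
integer-arithmetic enumeration over the full grid N ≤ 30.

**Clustering.** Single-linkage on genomic order within one chromosome
and strain: consecutive calls join when `next.start − prev.end` < 20
(strict). Touching elements (gap 0) join; overlapping annotations join
with a logged warning.

**Activity.** Active ⇔ RPKM > 1 and length > 50 bp, both strict, so
the boundary values (RPKM exactly 1, length exactly 50) are inactive.

**Closest genes.** Distance between a half-open interval and a TSS is
`max(start − tss, tss − (end − 1), 0)`; ties break to the
lexicographically smaller gene id. Only genes with FPKM > 0 in at
least one sample compete, and the same filter defines the shuffle
universe. The shuffled control is the per-position mean of 50 random
size-matched draws of carrier-strain expression. Comparisons are
one-tailed paired t-tests (carrier > other / carrier > control) on
log2(FPKM+1); an all-zero difference vector returns p = 0.5.

**Differential peaks.** Counts over merged peaks (overlapping or
bookended intervals union-merged) are scaled to reads per million.
The larger normalized count x = max(a, b) is tested against
λ = (a + b)/2 + 1 via the Poisson upper tail P(X ≥ round(x) | λ); the
pooled-mean λ keeps the test conservative under a null of equal rates
(measured type-I fraction at p < 0.05: 0.0001–0.011 across means
5–100), whereas centring on the smaller count alone is strongly
anticonservative (0.11–0.22). Fold change is (max+1)/(min+1); FDR is
Benjamini–Hochberg; differential ⇔ fold change > 4 and FDR < 0.001,
both strict. The pseudocount is exposed. Input-subtracted binned RPKM
retains negative values — no clipping.

**Bootstrap overlap.** Draws are subsets of size |A| taken uniformly
without replacement from the universe (genes in B are not excluded);
`p = (#{null ≥ observed} + 1)/(n_resamples + 1)`, never zero. The add-one
estimator makes p slightly super-uniform in proportion to the tie mass
of the discrete overlap distribution; calibration tests therefore use
set sizes large enough that the overlap sd (≈ 14 at universe 8,000
and sets of 1,600) keeps the largest atom near 0.02.

## Synthetic worlds

The generator builds the situation the pipeline is designed for: two
assemblies sharing a backbone, differing only by full-element
insertions. Defaults define the standard study conditions: 5 Mb of
backbone over 2 chromosomes, 40 shared + 25/15 private insertions,
mean per-element WGS depth 30 with mismap rate 0, half of private ERVs
active with RPKM in (2, 5), +2 log2 expression effect on nearest
genes, 400 genes. Design features that matter:

* The backbone is i.i.d. uniform ACGT, so 20-mers are unique with
  overwhelming probability on ≤ 10 Mb and anchoring is unambiguous.
* Every inserted copy diverges from its subfamily consensus by 10%
  random substitutions. Homologous shared copies are byte-identical
  between assemblies (one mutated copy planted at the homologous
  locus), but two different copies of one subfamily share only ~81%
  pairwise identity and essentially never a ≥ 20 bp exact match —
  mirroring real diverged repeats, and preventing repeat–repeat
  anchors from masking private-insertion gaps.
* The first/last base of each inserted run is forced to differ from
  the backbone base it displaces, so maximal exact matches terminate
  exactly at annotated element boundaries and the containment rule is
  exercised at its exact intent. Real annotations are less crisp;
  recovery on real data will be bounded by annotation accuracy, which
  the simulation deliberately does not model.
* Private subfamilies are drawn with weights favouring young ERVK
  subfamilies (IAP, ETn, GLN), shared insertions uniformly — giving
  the enrichment analysis a realistic signal direction.
* A configurable fraction (default 0.3) of private elements is planted
  as clustered runs of 2–4 elements with 5–19 bp spacers, exercising
  the <20 bp cluster rule.
* Coverage is a per-element count table (Poisson around the depth when
  present; zero when absent, except with probability `mismap_rate` a
  Poisson(mismap_rate × depth) leak), not simulated reads: the calling
  rule consumes per-element unique-read counts, and read simulation
  plus alignment is out of scope. Expression is log-normal around a
  common baseline with 0.3 sd per-strain noise.

What passing tests show: the discovery logic is exact on clean,
fully-annotated insertions, the statistics match their definitions,
and effect propagation (insertion → chromatin → nearest gene) is
detected at the planted effect size. What they do not show: robustness
to annotation boundary error, assembly gaps/N-runs at insertion sites,
segmental duplications, partial or truncated insertions, or diploid
heterozygosity — all absent from the generator by design.

## Determinism and problem sizes

Every stochastic stage derives its own `numpy` Generator from the run
seed plus a stage constant, so reruns are byte-identical and stages
are independently reproducible. Test and acceptance problem sizes —
the 5 Mb world, the N ≤ 30 hypergeometric grid, Poisson tails to
λ = 50/x = 200, 150–200 bootstrap calibration replicates, 100 power
replicates — were chosen so the full suite completes in a few minutes
on one CPU while keeping every check statistically meaningful.
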