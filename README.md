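# polyerv

Discovery and characterization of **potential polymorphic repetitive
elements (ppREs)** — transposable-element insertions present in one
mouse strain's genome and absent from another's — with a focus on
**polymorphic endogenous retroviruses (ppERVs)** and their
cis-regulatory impact.

Laboratory mouse strains differ by thousands of recent
transposable-element integrations, dominated by young ERVK families
(IAP, ETn/MusD, GLN). A strain-private ERV can deposit active-enhancer
chromatin (H3K27ac) near a gene and shift its expression relative to
the strain that lacks the insertion. This package implements the full
computational chain for finding and characterizing such elements from
two genome assemblies and strain-matched functional genomics data, and
ships a synthetic-data generator so that every stage is testable
against a planted ground truth without any external downloads.

## Method

ppREs are called from two independent evidence streams and intersected:

1. **Assembly comparison** — all maximal exact matches ≥ 20 bp between
   the two assemblies (both strands; N matches nothing) are chained
   into collinear anchor clusters (intra-cluster gap ≤ 50 bp on both
   genomes, summed match length ≥ 200 bp). The reference intervals not
   covered by any retained cluster are alignment *gaps*; a repeat
   annotation **fully contained** in a gap flanked by clusters on both
   sides is a candidate insertion private to the reference strain.
2. **WGS coverage asymmetry** — a per-element table of unique-read
   counts from each strain's whole-genome sequencing library; an
   element with **> 10 reads in one library and exactly 0 in the
   other** is a candidate private to the covered strain.

The final ppRE set is the per-strain intersection of the two streams
(reported with Venn counts). Downstream characterization:

* **Subfamily enrichment**: for each subfamily with `n` of the
  genome's `N` ERV elements and `k` of the `X` called ppERVs,
  `expected = (n/N)·X`, ratio `k/expected`, and a two-tailed
  hypergeometric p (minimum-likelihood construction, no
  multiple-testing adjustment).
* **Clustering**: runs of ≥ 2 calls with inter-element gaps < 20 bp
  are ppRE clusters; the remainder are solo elements.
* **Activity**: a ppERV with element-level H3K27ac RPKM > 1 and
  length > 50 bp is *active*.
* **Closest genes**: each active element or cluster is assigned the
  expressed gene with the nearest TSS; assigned genes' log2(FPKM+1)
  in the carrier strain is compared to the other strain and to a
  50-shuffle size-matched control with one-tailed paired t-tests.
* **Differential ChIP peaks**: merged peaks are tested on
  depth-normalized counts with an upper-tail Poisson test
  (λ = pooled mean + 1 pseudocount), BH FDR; differential means fold
  change > 4 and FDR < 0.001. Binned RPKM and input-subtracted tracks
  are also provided.
* **Gene-set overlap**: a non-parametric bootstrap (1,000 size-matched
  random draws from the expressed universe) tests whether two
  dysregulated-gene lists overlap more than chance,
  `p = (r+1)/(n+1)`.

## Worked example

The `analysis/` scripts run the whole study on a synthetic world:
a 5 Mb two-chromosome backbone carrying 40 shared, 25 A-private and
15 B-private insertions (30× WGS depth, no mismapping), with part of
the private insertions planted as clustered runs:

```bash
python analysis/01_forge_world.py --seed 0
python analysis/02_discover_ppres.py
python analysis/03_characterize_ppervs.py
python analysis/04_differential_peaks.py
python analysis/05_overlap_bootstrap.py
```

Output of steps 02–03 at seed 0:

```
strain A: assembly 25, coverage 25, final 25 ppREs (17 ppERVs, 68.0%)
  recovery 100.0% of 25 planted, 0 false positives
strain B: assembly 15, coverage 15, final 15 ppREs (12 ppERVs, 80.0%)
  recovery 100.0% of 15 planted, 0 false positives
strain A: 17 ppERVs (23.53% clustered, 76.47% solo); 10 active (3 in clusters, 7 solo)
  closest genes: log2(FPKM+1) 5.00 in carrier vs 2.89 in the other strain (control 2.97);
  one-tailed paired t p = 1.12e-08
```

Both evidence streams recover every planted private element with no
false calls, and the genes nearest the active private ERVs show the
planted ~2 log2-unit expression advantage in the carrier strain while
the shuffled control sits at baseline. The same pipeline is available
as a CLI (`polyerv forge|discover|characterize|diffpeaks|overlap-test|demo`)
and as library functions (`polyerv.run_discovery`,
`polyerv.run_characterization`, `polyerv.run_demo`).

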