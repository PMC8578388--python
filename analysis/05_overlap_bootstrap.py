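#!/usr/bin/env python
"""Bootstrap overlap between dysregulated-gene sets and strain-biased genes.

From the world's expression table, genes with higher expression in one
strain (|log2 difference| > 1) play the role of strain-biased sets; a
synthetic 'knockout' DEG list is built to share half its genes with
the strain-B-biased set. The bootstrap test (1,000 size-matched random
draws from the expressed universe) quantifies whether the concordant
overlaps exceed chance while the discordant pairings stay at the null.
Output: results/overlap/overlap_results.json.
"""

import argparse
from pathlib import Path

import numpy as np

from polyerv import io
from polyerv.setstats import overlap_with_direction

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    rng = np.random.default_rng([37, args.seed])

    world = io.read_world(RESULTS / "world")
    expr = world.expression
    expressed = expr[(expr[["fpkm_A", "fpkm_B"]] > 0).any(axis=1)]
    diff = np.log2(expressed["fpkm_A"] + 1) - np.log2(expressed["fpkm_B"] + 1)
    universe = set(expressed["gene_id"])
    high_a = set(expressed.loc[diff > 1, "gene_id"])
    high_b = set(expressed.loc[diff < -1, "gene_id"])
    rest = sorted(universe - high_a - high_b)

    # synthetic KO response: up-set takes half its genes from the B-biased set
    n_up = max(10, len(high_b))
    up = set(rng.choice(sorted(high_b), size=len(high_b) // 2, replace=False))
    up |= set(rng.choice(rest, size=n_up - len(up), replace=False))
    n_down = max(10, len(high_a))
    down = set(rng.choice(sorted(high_a), size=len(high_a) // 2, replace=False))
    down |= set(rng.choice(sorted(set(rest) - up), size=n_down - len(down),
                           replace=False))

    results = overlap_with_direction(universe, up, down, high_a, high_b,
                                     n_resamples=1000, rng=rng)
    out = RESULTS / "overlap"
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        name: {"universe": r.universe_size, "size_a": r.size_a, "size_b": r.size_b,
               "observed": r.observed, "null_mean": r.null_mean,
               "expected": r.expected, "p": r.p}
        for name, r in results.items()
    }
    io.write_json(payload, out / "overlap_results.json")

    print(f"universe: {len(universe)} expressed genes; "
          f"higher-in-A {len(high_a)}, higher-in-B {len(high_b)}; "
          f"up {len(up)}, down {len(down)}")
    for name, r in results.items():
        print(f"  {name}: observed {r.observed} (null mean {r.null_mean:.1f}, "
              f"expected {r.expected:.1f}), one-tailed p = {r.p:.4g}")


if __name__ == "__main__":
    main()
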