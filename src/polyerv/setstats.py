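"""Non-parametric bootstrap overlap test for gene sets.

Measures whether two differentially-expressed-gene lists share more
genes than expected by chance: size-matched random gene lists are drawn
from the expressed-gene universe and the overlap with the query set is
recorded, giving a null distribution for the observed overlap. The
one-tailed p uses the add-one convention (r + 1) / (n + 1), so it is
never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GeneSetOverlapResult", "bootstrap_overlap", "overlap_with_direction"]


@dataclass
class GeneSetOverlapResult:
    universe_size: int
    size_a: int
    size_b: int
    observed: int
    null_overlaps: np.ndarray
    p: float

    @property
    def null_mean(self) -> float:
        return float(self.null_overlaps.mean())

    @property
    def expected(self) -> float:
        """Analytic null mean |A||B| / |universe|."""
        return self.size_a * self.size_b / self.universe_size


def bootstrap_overlap(
    universe: set[str] | list[str],
    set_a: set[str],
    set_b: set[str],
    n_resamples: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> GeneSetOverlapResult:
    """Bootstrap test of the overlap between two gene sets.

    Draws ``n_resamples`` random subsets of size ``|set_a|`` from the
    universe (without replacement within each draw), records their
    overlap with ``set_b``, and returns
    ``p = (#{null >= observed} + 1) / (n_resamples + 1)``.
    """
    universe_list = sorted(set(universe))
    set_a, set_b = set(set_a), set(set_b)
    if not set_a <= set(universe_list) or not set_b <= set(universe_list):
        raise ValueError("both gene sets must be contained in the universe")
    if not universe_list:
        raise ValueError("empty universe")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_univ = len(universe_list)
    size_a = len(set_a)
    observed = len(set_a & set_b)
    mask_b = np.array([g in set_b for g in universe_list])
    if size_a == 0:
        null = np.zeros(n_resamples, dtype=int)
    else:
        # random keys per draw; the size_a smallest index a uniform subset
        keys = rng.random((n_resamples, n_univ))
        draws = np.argpartition(keys, size_a - 1, axis=1)[:, :size_a]
        null = mask_b[draws].sum(axis=1)
    p = (int(np.sum(null >= observed)) + 1) / (n_resamples + 1)
    return GeneSetOverlapResult(
        universe_size=n_univ, size_a=size_a, size_b=len(set_b),
        observed=observed, null_overlaps=null, p=p,
    )


def overlap_with_direction(
    universe: set[str] | list[str],
    deg_up: set[str],
    deg_down: set[str],
    strain_high_a: set[str],
    strain_high_b: set[str],
    n_resamples: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> dict[str, GeneSetOverlapResult]:
    """Concordant and discordant overlap tests for directional DEG sets.

    With strain A as the perturbed background, the concordant pairings
    are up-regulated genes vs genes higher in strain B, and
    down-regulated genes vs genes higher in strain A; the two swapped
    pairings are the discordant controls.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pairings = {
        "up_vs_high_other": (deg_up, strain_high_b),
        "down_vs_high_own": (deg_down, strain_high_a),
        "up_vs_high_own": (deg_up, strain_high_a),
        "down_vs_high_other": (deg_down, strain_high_b),
    }
    return {
        name: bootstrap_overlap(universe, a, b, n_resamples=n_resamples, rng=rng)
        for name, (a, b) in pairings.items()
    }
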