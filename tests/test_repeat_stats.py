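"""Subfamily enrichment, clustering, activity rule, closest genes, expression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polyerv import repeat_stats as rs
from polyerv.core import PpreCall, RepeatElement

from tests.oracles import hypergeom_two_tailed_exact, hypergeom_upper_exact


def _element(eid, start=0, end=500, subfamily="IAPEz-int", family="ERVK",
             class_="LTR", chrom="chr1"):
    return RepeatElement(chrom, start, end, eid, subfamily, family, class_)


def _call(eid, strain="A", **kw):
    return PpreCall(element=_element(eid, **kw), private_to=strain,
                    evidence_assembly=True, evidence_coverage=True, final=True)


class TestHypergeomTwoTailed:
    def test_matches_pmf_summation_oracle_spot_checks(self):
        for (N, n, X, k) in [(100, 10, 20, 8), (100, 10, 20, 2), (50, 25, 10, 9),
                             (40, 5, 30, 1), (25, 12, 12, 12)]:
            assert rs.hypergeom_two_tailed(N, n, X, k) == pytest.approx(
                hypergeom_two_tailed_exact(N, n, X, k), rel=1e-9, abs=1e-12
            )

    def test_upper_tail_matches_oracle(self):
        assert rs.hypergeom_upper_tail(100, 10, 20, 8) == pytest.approx(
            hypergeom_upper_exact(100, 10, 20, 8), rel=1e-9
        )

    def test_degenerate_single_subfamily(self):
        # all ERVs one subfamily: every draw is a success
        assert rs.hypergeom_two_tailed(100, 100, 20, 20) == pytest.approx(1.0)

    def test_inconsistent_parameters_rejected(self):
        with pytest.raises(ValueError):
            rs.hypergeom_two_tailed(10, 5, 20, 3)  # X > N
        with pytest.raises(ValueError):
            rs.hypergeom_two_tailed(100, 5, 20, 8)  # k > n


def _genome(counts):
    """counts: {subfamily: n}; all ERVK/LTR, laid out on chr1."""
    elements = []
    pos = 0
    for sub, n in counts.items():
        for i in range(n):
            elements.append(_element(f"{sub}_{i}", pos, pos + 500, subfamily=sub))
            pos += 1000
    return elements


class TestSubfamilyEnrichment:
    def test_expected_and_ratio_arithmetic(self):
        genome = _genome({"IAP": 10, "other": 90})
        ppervs = [_call(f"IAP_{i}", subfamily="IAP") for i in range(2)]
        ppervs += [_call(f"other_{i}", subfamily="other") for i in range(18)]
        res = {e.subfamily: e for e in rs.subfamily_enrichment(ppervs, genome)}
        assert res["IAP"].expected == pytest.approx(2.0)  # (10/100)*20
        assert res["IAP"].ratio == pytest.approx(1.0)

    def test_observed_and_expected_sum_to_X_over_partition(self):
        genome = _genome({"a": 7, "b": 13, "c": 30})
        ppervs = [_call(f"a_{i}", subfamily="a") for i in range(5)]
        ppervs += [_call(f"c_{i}", subfamily="c") for i in range(6)]
        res = rs.subfamily_enrichment(ppervs, genome)
        assert sum(e.observed for e in res) == len(ppervs)
        assert sum(e.expected for e in res) == pytest.approx(len(ppervs), abs=1e-9)

    def test_p_matches_oracle(self):
        genome = _genome({"IAP": 10, "other": 90})
        ppervs = [_call(f"IAP_{i}", subfamily="IAP") for i in range(8)]
        ppervs += [_call(f"other_{i}", subfamily="other") for i in range(12)]
        res = {e.subfamily: e for e in rs.subfamily_enrichment(ppervs, genome)}
        assert res["IAP"].p == pytest.approx(
            hypergeom_two_tailed_exact(100, 10, 20, 8), rel=1e-9
        )

    def test_flagging_requires_ratio_and_p(self):
        genome = _genome({"IAP": 10, "other": 990})
        ppervs = [_call(f"IAP_{i}", subfamily="IAP") for i in range(9)]
        ppervs += [_call(f"other_{i}", subfamily="other") for i in range(11)]
        res = {e.subfamily: e for e in rs.subfamily_enrichment(
            ppervs, genome, ratio_threshold=7.0, p_threshold=0.001)}
        iap = res["IAP"]
        assert iap.ratio > 7.0 and iap.p < 0.001 and iap.flagged
        assert not res["other"].flagged

    def test_unknown_subfamily_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            rs.subfamily_enrichment([_call("x", subfamily="nope")],
                                    _genome({"IAP": 5}))


class TestClusterElements:
    def test_gap_19_joins(self):
        calls = [_call("e1", start=100, end=200), _call("e2", start=219, end=300)]
        clusters, solos = rs.cluster_elements(calls)
        assert len(clusters) == 1 and clusters[0].size == 2 and solos == []

    def test_gap_20_stays_solo(self):
        calls = [_call("e1", start=100, end=200), _call("e2", start=220, end=300)]
        clusters, solos = rs.cluster_elements(calls)
        assert clusters == [] and len(solos) == 2

    def test_chained_gaps_build_one_cluster(self):
        calls = [_call("e1", start=0, end=100), _call("e2", start=110, end=200),
                 _call("e3", start=215, end=300)]
        clusters, _ = rs.cluster_elements(calls)
        assert len(clusters) == 1 and clusters[0].size == 3

    def test_strains_and_chromosomes_do_not_mix(self):
        calls = [_call("e1", start=0, end=100, strain="A"),
                 _call("e2", start=105, end=200, strain="B")]
        clusters, solos = rs.cluster_elements(calls)
        assert clusters == [] and len(solos) == 2

    @given(st.lists(st.tuples(st.integers(0, 3000), st.integers(1, 300)),
                    min_size=1, max_size=25))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_partition_covers_every_call_once(self, raw):
        calls = [_call(f"e{i}", start=s, end=s + ln)
                 for i, (s, ln) in enumerate(raw)]
        clusters, solos = rs.cluster_elements(calls)
        seen = [m.element.element_id for cl in clusters for m in cl.members]
        seen += [c.element.element_id for c in solos]
        assert sorted(seen) == sorted(c.element.element_id for c in calls)
        assert all(cl.size >= 2 for cl in clusters)


class TestCallActive:
    def _signal(self, rpkm):
        return pd.DataFrame({"element_id": ["e1"], "rpkm": [rpkm]})

    @pytest.mark.parametrize(
        "rpkm, length, active",
        [
            (1.5, 100, True),
            (1.0, 100, False),   # strict on RPKM
            (5.0, 50, False),    # strict on length
            (1.0 + 1e-9, 51, True),
        ],
    )
    def test_strict_thresholds(self, rpkm, length, active):
        call = _call("e1", start=0, end=length)
        [res] = rs.call_active([call], self._signal(rpkm))
        assert res.active is active

    def test_missing_signal_row_raises(self):
        with pytest.raises(ValueError, match="no signal"):
            rs.call_active([_call("e1")], pd.DataFrame({"element_id": [],
                                                        "rpkm": []}))

    def test_monotone_in_rpkm_and_length(self):
        base = rs.call_active([_call("e1", start=0, end=80)], self._signal(1.2))[0]
        more_rpkm = rs.call_active([_call("e1", start=0, end=80)], self._signal(2.4))[0]
        longer = rs.call_active([_call("e1", start=0, end=160)], self._signal(1.2))[0]
        assert base.active
        assert more_rpkm.active and longer.active


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss_A", "fpkm_A",
                                       "fpkm_B"])


class TestAssignClosestGene:
    def test_nearest_by_distance(self):
        genes = _genes([("g1", "chr1", 900, 5.0, 5.0), ("g2", "chr1", 1500, 5.0, 5.0)])
        out = rs.assign_closest_gene([_call("e1", start=1000, end=1100)], genes)
        assert out == {"e1": "g1"}

    def test_tss_inside_element_wins_at_distance_zero(self):
        genes = _genes([("g1", "chr1", 900, 5.0, 5.0), ("g2", "chr1", 1050, 5.0, 5.0)])
        out = rs.assign_closest_gene([_call("e1", start=1000, end=1100)], genes)
        assert out == {"e1": "g2"}

    def test_tie_breaks_to_smaller_gene_id(self):
        genes = _genes([("g2", "chr1", 900, 5.0, 5.0), ("g1", "chr1", 1199, 5.0, 5.0)])
        # distances: g2 -> 100, g1 -> 100 (element [1000,1100) half-open)
        out = rs.assign_closest_gene([_call("e1", start=1000, end=1100)], genes)
        assert out == {"e1": "g1"}

    def test_unexpressed_genes_do_not_compete(self):
        genes = _genes([("g1", "chr1", 990, 0.0, 0.0), ("g2", "chr1", 1500, 5.0, 0.0)])
        out = rs.assign_closest_gene([_call("e1", start=1000, end=1100)], genes)
        assert out == {"e1": "g2"}

    def test_cluster_span_used_for_distance(self):
        cluster = rs.PpreCluster([_call("e1", start=1000, end=1100),
                                  _call("e2", start=1110, end=1300)])
        genes = _genes([("g1", "chr1", 1310, 5.0, 5.0), ("g2", "chr1", 960, 5.0, 5.0)])
        out = rs.assign_closest_gene([cluster], genes)
        assert list(out.values()) == ["g1"]  # 10 vs 40

    def test_no_expressed_gene_on_chromosome_leaves_unassigned(self):
        genes = _genes([("g1", "chr2", 900, 5.0, 5.0)])
        out = rs.assign_closest_gene([_call("e1", start=1000, end=1100)], genes)
        assert out == {}


def _expression(n=40, seed=5, effect=0.0):
    rng = np.random.default_rng(seed)
    base = rng.normal(3, 1, n)
    fa = np.exp2(base + effect) - 1
    fb = np.exp2(base) - 1
    return pd.DataFrame({
        "gene_id": [f"g{i:03d}" for i in range(n)],
        "chrom": "chr1", "tss_A": np.arange(n) * 1000,
        "fpkm_A": np.clip(fa, 0, None), "fpkm_B": np.clip(fb, 0, None),
    })


class TestCompareClosestGeneExpression:
    def test_identical_strain_columns_give_half_p(self):
        expr = _expression(effect=0.0)
        genes = expr["gene_id"].tolist()[:10]
        res = rs.compare_closest_gene_expression(genes, expr, rng=1)
        assert res.p_carrier_vs_other == pytest.approx(0.5)

    def test_positive_effect_detected(self):
        expr = _expression(effect=2.0)
        genes = expr["gene_id"].tolist()[:20]
        res = rs.compare_closest_gene_expression(genes, expr, rng=1)
        assert res.p_carrier_vs_other < 1e-6
        assert res.mean_carrier > res.mean_other

    def test_shuffled_control_is_deterministic_given_seed(self):
        expr = _expression(effect=1.0)
        genes = expr["gene_id"].tolist()[:10]
        r1 = rs.compare_closest_gene_expression(genes, expr, rng=7)
        r2 = rs.compare_closest_gene_expression(genes, expr, rng=7)
        np.testing.assert_array_equal(r1.control_log2, r2.control_log2)
        assert r1.p_carrier_vs_control == r2.p_carrier_vs_control

    def test_universe_smaller_than_set_rejected(self):
        expr = _expression(n=5)
        with pytest.raises(ValueError):
            rs.compare_closest_gene_expression(
                [f"g{i:03d}" for i in range(5)] + ["missing"], expr
            )

    def test_needs_two_genes(self):
        with pytest.raises(ValueError):
            rs.compare_closest_gene_expression(["g000"], _expression())
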