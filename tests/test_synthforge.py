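"""Synthetic world generator: identity, conservation, determinism, assays."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from polyerv import synthforge
from polyerv.synthforge import SimConfig, default_repeat_library


def _cfg(**kw):
    base = dict(
        backbone_length=200_000, n_chromosomes=1, n_shared_insertions=3,
        n_private_A=0, n_private_B=0, n_genes=50, rng_seed=11,
        clustered_run_fraction=0.0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestSynthesizeGenomePair:
    def test_no_private_insertions_forces_identical_genomes(self):
        gA, gB, annA, annB, _ = synthforge.synthesize_genome_pair(
            _cfg(), default_repeat_library()
        )
        assert gA == gB
        pdt.assert_frame_equal(annA, annB)

    def test_private_insertions_conserve_length(self):
        cfg = _cfg(n_shared_insertions=0, n_private_A=5)
        gA, gB, annA, _, manifest = synthforge.synthesize_genome_pair(
            cfg, default_repeat_library()
        )
        inserted = int((manifest["end_A"] - manifest["start_A"]).sum())
        assert len(gA["chr1"]) == len(gB["chr1"]) + inserted

    def test_seed_determinism(self):
        lib = default_repeat_library()
        cfg = _cfg(n_private_A=4, n_private_B=2, clustered_run_fraction=0.5)
        out1 = synthforge.synthesize_genome_pair(cfg, lib)
        out2 = synthforge.synthesize_genome_pair(_cfg(
            n_private_A=4, n_private_B=2, clustered_run_fraction=0.5), lib)
        assert out1[0] == out2[0] and out1[1] == out2[1]
        pdt.assert_frame_equal(out1[2], out2[2])
        pdt.assert_frame_equal(out1[4], out2[4])

    def test_manifest_annotation_consistency(self, small_world):
        for strain, annot in (("A", small_world.annotation_A),
                              ("B", small_world.annotation_B)):
            man = small_world.manifest
            present = man[man[f"start_{strain}"] >= 0]
            assert set(present["element_id"]) == set(annot["element_id"])
            merged = annot.merge(present, on="element_id", suffixes=("", "_m"))
            assert (merged["start"] == merged[f"start_{strain}"]).all()
            assert (merged["end"] == merged[f"end_{strain}"]).all()

    def test_private_rows_have_coordinates_in_exactly_one_genome(self, small_world):
        man = small_world.manifest
        priv = man[man["strain"] != "shared"]
        in_a = priv["start_A"] >= 0
        in_b = priv["start_B"] >= 0
        assert (in_a ^ in_b).all()
        shared = man[man["strain"] == "shared"]
        assert ((shared["start_A"] >= 0) & (shared["start_B"] >= 0)).all()

    def test_annotated_sequences_match_genome_slices(self, small_world):
        annot = small_world.annotation_A.head(10)
        for r in annot.to_dict("records"):
            seq = small_world.genome_A[r["chrom"]][r["start"]:r["end"]]
            assert len(seq) == r["end"] - r["start"]
            assert set(seq) <= set("ACGT")

    def test_insertion_overflow_raises(self):
        cfg = _cfg(backbone_length=20_000, n_shared_insertions=50)
        with pytest.raises(ValueError, match="overflow"):
            synthforge.synthesize_genome_pair(cfg, default_repeat_library())

    def test_empty_library_raises(self):
        with pytest.raises(ValueError, match="library"):
            synthforge.synthesize_genome_pair(_cfg(), [])

    def test_clustered_runs_have_small_gaps(self):
        cfg = _cfg(backbone_length=500_000, n_private_A=12,
                   clustered_run_fraction=1.0)
        *_, annA, _, manifest = synthforge.synthesize_genome_pair(
            cfg, default_repeat_library()
        )
        clustered = manifest[manifest["clustered"]]
        assert len(clustered) == 12
        for site, rows in clustered.groupby("site_pos"):
            assert 2 <= len(rows) <= 4
            srt = rows.sort_values("start_A")
            gaps = srt["start_A"].to_numpy()[1:] - srt["end_A"].to_numpy()[:-1]
            assert ((gaps >= 5) & (gaps < 20)).all()


class TestSimulateWgsCoverage:
    def test_absent_elements_get_zero_reads_without_mismapping(self, small_world):
        cov = small_world.coverage
        man = small_world.manifest
        a_priv = set(man.loc[man["strain"] == "A", "element_id"])
        b_priv = set(man.loc[man["strain"] == "B", "element_id"])
        assert (cov.loc[cov["element_id"].isin(a_priv), "count_B"] == 0).all()
        assert (cov.loc[cov["element_id"].isin(b_priv), "count_A"] == 0).all()

    def test_present_element_counts_match_poisson_mean(self):
        cfg = _cfg(backbone_length=1_500_000, n_shared_insertions=500,
                   min_insert_spacing=500, wgs_depth=30.0)
        lib = default_repeat_library()
        gA, gB, annA, annB, man = synthforge.synthesize_genome_pair(cfg, lib)
        cov = synthforge.simulate_wgs_coverage(man, annA, annB, cfg)
        counts = np.concatenate([cov["count_A"].to_numpy(), cov["count_B"].to_numpy()])
        se = np.sqrt(30.0 / counts.size)
        assert abs(counts.mean() - 30.0) < 3 * se

    def test_mismap_rate_produces_leakage(self):
        cfg = _cfg(n_shared_insertions=0, n_private_A=60,
                   backbone_length=1_000_000, mismap_rate=0.5, wgs_depth=30.0)
        lib = default_repeat_library()
        gA, gB, annA, annB, man = synthforge.synthesize_genome_pair(cfg, lib)
        cov = synthforge.simulate_wgs_coverage(man, annA, annB, cfg)
        assert (cov["count_B"] > 0).any()

    def test_same_seed_same_table(self, small_world):
        again = synthforge.simulate_wgs_coverage(
            small_world.manifest, small_world.annotation_A,
            small_world.annotation_B, small_world.config,
        )
        pdt.assert_frame_equal(again, small_world.coverage)


class TestSimulateChipAndExpression:
    def _world_tables(self, **kw):
        cfg = _cfg(backbone_length=800_000, n_shared_insertions=5,
                   n_private_A=10, n_private_B=5, erv_fraction=1.0,
                   n_genes=500, **kw)
        lib = default_repeat_library()
        gA, gB, annA, annB, man = synthforge.synthesize_genome_pair(cfg, lib)
        genes = synthforge.make_gene_models(man, cfg)
        sig, expr = synthforge.simulate_chip_and_expression(
            man, {"A": annA, "B": annB}, genes, cfg
        )
        return cfg, man, sig, expr

    def test_zero_active_fraction_leaves_all_rpkm_below_one(self):
        _, man, sig, _ = self._world_tables(active_fraction=0.0)
        assert (sig["rpkm"] < 1.0).all()
        assert not man["is_active"].any()

    def test_active_elements_pass_activity_threshold(self):
        _, man, sig, _ = self._world_tables(active_fraction=1.0,
                                            active_rpkm_range=(2.0, 5.0))
        active = man.loc[man["is_active"], "element_id"]
        assert len(active) > 0
        for strain in ("A", "B"):
            ids = man.loc[man["is_active"] & (man["strain"] == strain), "element_id"]
            sub = sig[(sig["assembly"] == strain) & sig["element_id"].isin(ids)]
            assert (sub["rpkm"] > 1.0).all()

    def test_null_effect_gives_zero_mean_strain_difference(self):
        _, _, _, expr = self._world_tables(expression_effect_log2fc=0.0)
        diff = np.log2(expr["fpkm_A"] + 1) - np.log2(expr["fpkm_B"] + 1)
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se

    def test_effect_boosts_nearest_genes_in_carrier_only(self):
        _, man, _, expr = self._world_tables(active_fraction=1.0,
                                             expression_effect_log2fc=2.0)
        boosted = man.loc[man["is_active"] & (man["strain"] == "A"),
                          "nearest_gene_id"]
        sub = expr[expr["gene_id"].isin(boosted)]
        diff = np.log2(sub["fpkm_A"] + 1) - np.log2(sub["fpkm_B"] + 1)
        assert diff.mean() > 1.0  # effect of +2 minus noise

    def test_gene_tss_away_from_insertions_and_mapped_consistently(self, small_world):
        genes = small_world.genes
        man = small_world.manifest
        for c in genes["chrom"].unique():
            sites = man.loc[man["chrom"] == c, "site_pos"].to_numpy()
            tss = genes.loc[genes["chrom"] == c, "tss_backbone"].to_numpy()
            assert np.min(np.abs(tss[:, None] - sites[None, :])) >= 500
        assert (genes["tss_A"] >= genes["tss_backbone"]).all()
        assert (genes["tss_B"] >= genes["tss_backbone"]).all()
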