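"""Gene counting, z standardization, Fisher combination, FDR, score overlay."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from admixscan import enrichment_scan as es
from admixscan.ancestry_io import UNASSIGNED, GeneModel, ScoreTrack

from conftest import (
    brute_force_counts,
    build_panel,
    chi2_even_df_sf,
    random_toy_genes,
    random_toy_panel,
)


class TestGeneCounting:
    def test_switch_inside_gene_drops_haplotype(self, palette3):
        # gene [40, 60): all-AFR; all-EUR; AFR->EUR switch at the midpoint
        panel = build_panel(
            palette3,
            [([], [0]), ([], [1]), ([50], [0, 1]), ([], [UNASSIGNED])],
            (0, 100),
        )
        gene = GeneModel("chr1", 40, 60, "G")
        counts = es.assign_gene_ancestries(panel, gene)
        assert counts.h_tot == 2
        assert counts.h_anc == (1, 1, 0)

    def test_unassigned_haplotype_excluded(self, palette3):
        panel = build_panel(palette3, [([], [UNASSIGNED]), ([], [2])], (0, 100))
        counts = es.assign_gene_ancestries(panel, GeneModel("chr1", 10, 90, "G"))
        assert counts.h_tot == 1 and counts.h_anc == (0, 0, 1)

    def test_single_ancestry_panel_counts_all(self, palette3):
        panel = build_panel(palette3, [([], [0])] * 6, (0, 100))
        for gene in (GeneModel("chr1", 0, 100, "A"), GeneModel("chr1", 33, 34, "B")):
            assert es.assign_gene_ancestries(panel, gene).h_tot == 6

    def test_gene_outside_span_rejected(self, palette3):
        panel = build_panel(palette3, [([], [0])] * 2, (0, 100))
        with pytest.raises(ValueError, match="outside"):
            es.assign_gene_ancestries(panel, GeneModel("chr1", 50, 150, "G"))

    def test_matches_per_base_enumeration_oracle(self, palette3):
        rng = np.random.default_rng(42)
        for _ in range(25):
            panel = random_toy_panel(rng, palette3)
            for gene in random_toy_genes(rng):
                counts = es.assign_gene_ancestries(panel, gene)
                h_anc, h_tot = brute_force_counts(panel, gene)
                assert counts.h_anc == h_anc
                assert counts.h_tot == h_tot


def _neutral_panel(palette, seed=0, n=60):
    from admixscan import synthetic_data as sd

    cfg = sd.CohortConfig(
        populations=(sd.PopulationSpec("P", (0.3, 0.5, 0.2), n),),
        palette=palette, chrom_length_bp=50_000_000, gene_count=40, seed=seed,
    )
    return sd.generate_panel(cfg, "P"), sd.generate_genes(cfg)


class TestScan:
    def test_z_is_exact_standardization(self, palette3):
        panel, genes = _neutral_panel(palette3)
        table = es.scan(panel, genes)
        d = table.data
        for anc in palette3.labels:
            sub = d[(d.ancestry == anc) & d.f_anc.notna()]
            expected = (sub.f_anc - table.mu_anc[anc]) / table.sigma_anc[anc]
            assert np.allclose(sub.z_anc, expected, rtol=0, atol=0)

    def test_z_normalized_over_retained_universe(self, palette3):
        panel, genes = _neutral_panel(palette3, seed=3)
        table = es.scan(panel, genes)
        d = table.data
        for anc in palette3.labels:
            sub = d[(d.ancestry == anc) & d.retained]
            assert abs(sub.z_anc.mean()) < 1e-9
            assert abs(sub.z_anc.std(ddof=1) - 1.0) < 1e-9

    def test_fractions_sum_to_one(self, palette3):
        panel, genes = _neutral_panel(palette3, seed=4)
        d = es.scan(panel, genes).data
        sums = d[d.h_tot > 0].groupby("gene").f_anc.sum()
        assert np.allclose(sums, 1.0)

    def test_degenerate_ancestry_flagged_not_fatal(self, palette3):
        from admixscan import synthetic_data as sd

        cfg = sd.CohortConfig(
            populations=(sd.PopulationSpec("P", (0.5, 0.5, 0.0), 40),),
            palette=palette3, chrom_length_bp=50_000_000, gene_count=20, seed=1,
        )
        table = es.scan(sd.generate_panel(cfg, "P"), sd.generate_genes(cfg))
        assert "NAT" in table.undefined_ancestries
        nat = table.data[table.data.ancestry == "NAT"]
        assert nat.z_anc.isna().all()

    def test_identical_genes_get_identical_rows(self, palette3):
        panel, genes = _neutral_panel(palette3, seed=5)
        twin = [GeneModel(g.chrom, g.start_bp, g.end_bp, f"{g.name}b") for g in genes]
        table = es.scan(panel, [*genes, *twin])
        d = table.data.set_index(["gene", "ancestry"])
        for g, t in zip(genes, twin):
            for anc in palette3.labels:
                assert d.loc[(g.name, anc), "z_anc"] == d.loc[(t.name, anc), "z_anc"]


class TestUniverse:
    def test_gene_failing_in_one_population_excluded(self, palette3):
        panel, genes = _neutral_panel(palette3, seed=6)
        t1 = es.scan(panel, genes)
        t2 = es.scan(panel, genes)
        # force one gene to fail the filter in exactly one population
        fail = t1.retained_genes[0]
        t2.data.loc[t2.data.gene == fail, "retained"] = False
        universe = es.finalize_gene_universe([t1, t2])
        assert fail not in universe
        assert set(universe) == set(t1.retained_genes) - {fail}

    def test_disjoint_gene_lists_rejected(self, palette3):
        panel, genes = _neutral_panel(palette3, seed=7)
        t1 = es.scan(panel, genes[: len(genes) // 2])
        t2 = es.scan(panel, genes[len(genes) // 2:])
        with pytest.raises(ValueError, match="differ"):
            es.finalize_gene_universe([t1, t2])


class TestFisherCombine:
    def test_boundary_all_ones(self):
        F = -2 * np.log(np.ones(4)).sum()
        assert F == 0.0
        assert stats.chi2.sf(F, 8) == 1.0

    def test_quadruple_p05_matches_closed_form(self):
        F = -2 * 4 * np.log(0.05)
        assert F == pytest.approx(23.9659, abs=1e-4)
        assert chi2_even_df_sf(F, 4) == pytest.approx(2.32e-3, rel=5e-3)
        assert stats.chi2.sf(F, 8) == pytest.approx(chi2_even_df_sf(F, 4), rel=1e-12)

    def test_single_population_identity(self, palette3):
        # chi2 with 2 df has survival exp(-x/2), so p_chi2 == P exactly
        panel, genes = _neutral_panel(palette3, seed=8)
        table = es.scan(panel, genes)
        universe = table.retained_genes
        combined = es.fisher_combine([table], universe, "enrich")
        obs = combined.data.set_index(["gene", "ancestry"])
        src = table.data.set_index(["gene", "ancestry"])
        for idx in obs.index:
            assert obs.loc[idx, "p_chi2"] == pytest.approx(
                src.loc[idx, "p_enrich"], rel=1e-12
            )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        p=st.lists(st.floats(1e-10, 1.0), min_size=4, max_size=4),
        i=st.integers(0, 3),
        factor=st.floats(0.1, 0.999),
    )
    def test_monotone_in_each_p(self, p, i, factor):
        F_base = -2 * np.log(p).sum()
        smaller = list(p)
        smaller[i] *= factor
        assert -2 * np.log(smaller).sum() > F_base

    def test_zero_p_rejected(self, palette3):
        panel, genes = _neutral_panel(palette3, seed=9)
        table = es.scan(panel, genes)
        table.data.loc[0, "p_enrich"] = 0.0
        gene0 = table.data.loc[0, "gene"]
        if gene0 not in table.retained_genes:
            table.data.loc[table.data.gene == gene0, "retained"] = True
        with pytest.raises(ValueError, match="0"):
            es.fisher_combine([table, table], table.retained_genes, "enrich")


class TestBHFDR:
    def test_step_up_hand_example(self):
        q, rej = es.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert rej.all()
        assert q[-1] == pytest.approx(0.04)

    def test_all_ones(self):
        q, rej = es.bh_fdr([1.0, 1.0, 1.0])
        assert (q == 1.0).all() and not rej.any()

    def test_single_p_identity(self):
        q, rej = es.bh_fdr([0.04])
        assert q[0] == pytest.approx(0.04) and rej[0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            es.bh_fdr([])

    def test_q_monotone_in_sorted_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        q, _ = es.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestOverlay:
    def test_single_point_above_threshold(self):
        track = ScoreTrack(np.array([150]), np.array([3.1]))
        out = es.overlay_scores([GeneModel("chr1", 100, 200, "G")], track)
        assert out.max_abs_score[0] == 3.1 and out.above_threshold[0]

    def test_all_below_threshold(self):
        track = ScoreTrack(np.array([10, 20]), np.array([1.0, -2.0]))
        out = es.overlay_scores([GeneModel("chr1", 0, 30, "G")], track)
        assert not out.above_threshold[0]

    def test_absolute_value_rule_with_flank(self):
        track = ScoreTrack(np.array([90, 210]), np.array([2.0, -2.6]))
        out = es.overlay_scores(
            [GeneModel("chr1", 100, 200, "G")], track, flank_bp=50
        )
        assert out.max_abs_score[0] == 2.6 and out.above_threshold[0]

    def test_no_points_gives_nan_and_false(self):
        track = ScoreTrack(np.array([500]), np.array([9.0]))
        out = es.overlay_scores([GeneModel("chr1", 0, 100, "G")], track)
        assert np.isnan(out.max_abs_score[0]) and not out.above_threshold[0]
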