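"""Multinomial and Wright-Fisher null ensembles, empirical p, power."""

import dataclasses

import numpy as np
import pytest

from admixscan import enrichment_scan as es
from admixscan import null_simulation as ns
from admixscan.ancestry_io import AncestryPalette, GeneModel


THETA = {"A": np.array([0.3, 0.5, 0.2]), "B": np.array([0.25, 0.45, 0.30])}


def _h_tot(G=50, value=200):
    return {pop: np.full(G, value) for pop in THETA}


class TestGenewiseNull:
    def test_deterministic_under_seed(self):
        e1 = ns.genewise_null(_h_tot(), THETA, R=3, seed=9)
        e2 = ns.genewise_null(_h_tot(), THETA, R=3, seed=9)
        np.testing.assert_array_equal(e1.values, e2.values)

    def test_degenerate_theta_flagged_nan(self):
        theta = {"A": np.array([1.0, 0.0, 0.0])}
        ens = ns.genewise_null({"A": np.full(10, 100)}, theta, R=2, seed=0)
        assert np.isnan(ens.values).all()

    def test_fraction_moments_match_binomial_oracle(self):
        # f_AFR over genes: mean theta_0, SD sqrt(theta_0(1-theta_0)/h_tot)
        theta = {"A": np.array([0.3, 0.5, 0.2])}
        h_tot = {"A": np.full(200, 200)}
        rng = np.random.default_rng(1)
        draws = rng.multinomial(200, theta["A"], size=(100, 200))
        f = draws[..., 0] / 200
        exp_sd = np.sqrt(0.3 * 0.7 / 200)
        assert abs(f.mean() - 0.3) < 3 * exp_sd / np.sqrt(f.size)
        assert abs(f.std() - exp_sd) < 3 * exp_sd / np.sqrt(f.size)

    def test_values_nonnegative(self):
        ens = ns.genewise_null(_h_tot(G=20), THETA, R=5, seed=2)
        finite = ens.values[np.isfinite(ens.values)]
        assert (finite >= 0).all()


class TestEmpiricalP:
    def _ens(self, values, mode="per_gene"):
        return ns.NullEnsemble(np.asarray(values, float).reshape(1, -1, 1), mode)

    def test_extreme_observation_pool_19999(self):
        rng = np.random.default_rng(0)
        ens = ns.NullEnsemble(rng.random((1, 19_999, 1)), "per_gene")
        assert ns.empirical_p(2.0, ens) == pytest.approx(1 / 20_000)

    def test_observation_below_all_nulls(self):
        ens = self._ens([1.0, 2.0, 3.0])
        assert ns.empirical_p(0.0, ens) == 1.0

    def test_tie_counts_as_greater_equal(self):
        ens = self._ens([5.0])
        assert ns.empirical_p(5.0, ens) == 1.0

    def test_never_returns_zero_and_bounds_hold(self):
        rng = np.random.default_rng(3)
        ens = ns.NullEnsemble(rng.random((4, 25, 2)), "per_gene")
        obs = rng.random(100) * 3
        p = ns.empirical_p(obs, ens)
        assert (p > 0).all() and (p <= 1).all()
        assert p.min() >= 1 / (ens.pool().size + 1)

    def test_max_statistic_pool_is_per_replicate_maximum(self):
        vals = np.arange(24, dtype=float).reshape(2, 4, 3)
        ens = ns.NullEnsemble(vals, "max_statistic")
        assert sorted(ens.pool()) == [11.0, 23.0]

    def test_mode_mismatch_rejected(self):
        ens = self._ens([1.0], mode="per_gene")
        with pytest.raises(ValueError, match="mode"):
            ns.empirical_p(1.0, ens, mode="max_statistic")


class TestPower:
    def test_null_case_power_near_alpha(self):
        df = ns.power_analysis(
            0.3, {"A": THETA["A"]}, n_grid=[100], R=400, alpha=0.05, seed=4
        )
        p_hat = df.power[0]
        # binomial 99% interval around alpha at R = 400
        half = 2.58 * np.sqrt(0.05 * 0.95 / 400)
        assert abs(p_hat - 0.05) < half + 1e-9

    def test_extreme_separation_gives_full_power(self):
        df = ns.power_analysis(
            1.0, THETA, n_grid=[10_000], R=100, alpha=0.05, seed=5
        )
        assert df.power[0] == 1.0

    def test_regression_strong_signal_power(self):
        # planted 0.45 vs 0.25 background, 4 populations, n = 100 diploids
        theta = {f"P{i}": np.array([0.25, 0.75 - 0.05 * i, 0.05 * i])
                 for i in range(4)}
        df = ns.power_analysis(
            0.45, theta, n_grid=[100], R=50, alpha=1e-4, seed=1
        )
        assert df.power[0] >= 0.9

    def test_power_nondecreasing_in_n(self):
        df = ns.power_analysis(
            0.35, THETA, n_grid=[10, 100, 1000], R=200, alpha=0.01, seed=6
        )
        assert df.power.is_monotonic_increasing or \
            (np.diff(df.power) > -0.1).all()  # Monte-Carlo slack


class TestWrightFisher:
    @pytest.fixture
    def wf_cfg(self, palette3):
        return ns.WFConfig(
            N=30, generations=5, theta=(0.3, 0.5, 0.2), palette=palette3,
            morgans=1.0, chrom_length_bp=100_000_000, seed=0,
        )

    def test_founders_single_ancestry_with_largest_remainder(self, palette3):
        cfg = ns.WFConfig(
            N=10, generations=0, theta=(0.34, 0.33, 0.33), palette=palette3,
        )
        panel = ns.wright_fisher_sim(cfg)
        comp = np.zeros(3, dtype=int)
        for tracts in panel.haplotypes:
            assert len(tracts) == 1
            comp[tracts[0].ancestry] += 1
        np.testing.assert_array_equal(
            comp // 2, ns.largest_remainder_counts(10, (0.34, 0.33, 0.33))
        )

    def test_largest_remainder_sums_to_n(self):
        for n in (3, 10, 97):
            counts = ns.largest_remainder_counts(n, (0.251, 0.25, 0.499))
            assert counts.sum() == n and (counts >= 0).all()

    def test_output_tiles_chromosome_exactly(self, wf_cfg):
        panel = ns.wright_fisher_sim(wf_cfg)
        panel.validate()  # raises on any gap/overlap
        for tracts in panel.haplotypes:
            assert tracts[0].start_bp == 0
            assert tracts[-1].end_bp == wf_cfg.chrom_length_bp

    def test_meiosis_crossover_count_matches_map_length(self, palette3):
        rng = np.random.default_rng(8)
        L = 2.0
        hap_a = (np.empty(0), np.array([0]))
        hap_b = (np.empty(0), np.array([1]))
        switches = [
            len(ns.meiosis(rng, hap_a, hap_b, L)[0]) for _ in range(2000)
        ]
        # every crossover is a junction between distinct-ancestry founders
        mean = np.mean(switches)
        se = np.sqrt(L / 2000)
        assert abs(mean - L) < 3 * se

    def test_sample_size_exceeding_n_rejected(self, palette3):
        with pytest.raises(ValueError, match="sample size"):
            ns.WFConfig(N=5, generations=1, theta=(0.5, 0.3, 0.2),
                        palette=palette3, sample_size=6)

    def test_neutral_drift_variance_increases_with_g(self, palette3):
        # variance of the population ancestry-0 fraction grows with time
        def rep_var(g, reps=40):
            fracs = []
            for r in range(reps):
                cfg = ns.WFConfig(N=40, generations=g, theta=(0.5, 0.3, 0.2),
                                  palette=palette3, seed=100 + r)
                panel = ns.wright_fisher_sim(cfg)
                tot = anc0 = 0
                for tracts in panel.haplotypes:
                    for t in tracts:
                        tot += t.length_bp
                        anc0 += t.length_bp * (t.ancestry == 0)
                fracs.append(anc0 / tot)
            return np.mean(fracs), np.var(fracs)

        m1, v1 = rep_var(1)
        m10, v10 = rep_var(10)
        assert v10 > v1
        # neutrality: expectation stays at the founding fraction
        assert abs(m10 - 0.5) < 4 * np.sqrt(v10 / 40)

    def test_minimum_population_size_runs(self, palette3):
        cfg = ns.WFConfig(N=2, generations=3, theta=(0.5, 0.5, 0.0),
                          palette=palette3, seed=1)
        panel = ns.wright_fisher_sim(cfg)
        assert panel.n_haplotypes == 4


class TestChromosomeNull:
    def test_reproducible_and_valid(self, palette3):
        cfgs = {
            "A": ns.WFConfig(N=25, generations=3, theta=(0.3, 0.5, 0.2),
                             palette=palette3, chrom_length_bp=50_000_000),
            "B": ns.WFConfig(N=25, generations=3, theta=(0.25, 0.45, 0.30),
                             palette=palette3, chrom_length_bp=50_000_000),
        }
        genes = [GeneModel("chr1", i * 5_000_000 + 100_000,
                           i * 5_000_000 + 150_000, f"G{i}") for i in range(10)]
        e1 = ns.chromosome_null(cfgs, genes, R=2, seed=3)
        e2 = ns.chromosome_null(cfgs, genes, R=2, seed=3)
        np.testing.assert_array_equal(e1.values, e2.values)
        finite = e1.values[np.isfinite(e1.values)]
        assert finite.size > 0 and (finite >= 0).all()
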