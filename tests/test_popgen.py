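"""Allele frequencies, MAF correlation, F_st estimators, tier selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pygmyscan as pg
from pygmyscan.errors import ConfigurationError, ValidationError
from pygmyscan.popgen import nei_gst_from_frequencies

from conftest import make_matrix
from oracles import wc_components_brute


def _hw_matrix(p1, p2, n_per_pop):
    """Deterministic Hardy-Weinberg-proportioned genotypes for two pops."""
    def genotypes(p, n):
        counts = np.round(np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n)
        counts[2] = n - counts[0] - counts[1]
        return np.repeat([0, 1, 2], counts.astype(int))

    row = np.concatenate([genotypes(p1, n_per_pop), genotypes(p2, n_per_pop)])
    samples = [f"s{i}" for i in range(2 * n_per_pop)]
    manifest = pg.PopulationManifest(
        pd.DataFrame(
            {"population": ["p1"] * n_per_pop + ["p2"] * n_per_pop},
            index=pd.Index(samples, name="sample_id"),
        )
    )
    return make_matrix([row], samples), manifest


class TestAlleleFrequencies:
    def test_direct_count(self, two_pop_manifest):
        gm = make_matrix([[0, 1, 2, 2]], ["s1", "s2", "s3", "s4"])
        single = pg.PopulationManifest(
            two_pop_manifest.table.assign(population="p1")
        )
        freqs = pg.allele_frequencies(gm, single)
        assert freqs.freq.loc[0, "p1"] == pytest.approx(0.625)
        assert freqs.maf.loc[0, "p1"] == pytest.approx(0.375)

    def test_all_missing_flagged_undefined(self, two_pop_manifest):
        gm = make_matrix([[-1, -1, 0, 1]], ["s1", "s2", "s3", "s4"])
        freqs = pg.allele_frequencies(gm, two_pop_manifest)
        assert np.isnan(freqs.freq.loc[0, "p1"])
        assert not freqs.defined().loc[0, "p1"]
        assert freqs.defined().loc[0, "p2"]

    def test_matches_simulator_truth(self, small_cohort):
        freqs = pg.allele_frequencies(small_cohort.genotypes,
                                      small_cohort.manifest)
        emp = freqs.freq["baka"].to_numpy()
        truth = small_cohort.truth["freq_baka"].to_numpy()
        # binomial error at n = 30: bound at ~4 standard errors
        assert np.nanmax(np.abs(emp - truth)) < 4 * np.sqrt(0.25 / 60)


class TestMafCorrelation:
    def test_self_correlation(self):
        a = np.linspace(0.05, 0.95, 50)
        res = pg.maf_correlation(a, a)
        assert res.r_squared == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-30)
        assert res.df == 48

    def test_negation_about_half(self):
        a = np.linspace(0.1, 0.9, 40)
        res = pg.maf_correlation(a, 1.0 - a)
        assert res.r_squared == pytest.approx(1.0)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0.1, 0.9, 200)
        b = np.clip(a + rng.normal(0, 0.1, 200), 0, 1)
        res = pg.maf_correlation(a, b)
        assert res.ci_low <= res.r_squared <= res.ci_high
        assert res.n_snps == 200 and res.df == 198

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pg.maf_correlation(np.full(10, 0.5), np.linspace(0, 1, 10))

    def test_monte_carlo_recovery_of_generating_correlation(self):
        """r^2 estimates average to the generating 0.9^2 over 200 seeds."""
        target = 0.9
        cov = np.array([[1.0, target], [target, 1.0]]) * 0.01
        estimates = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            xy = rng.multivariate_normal([0.5, 0.5], cov, size=100)
            estimates.append(pg.maf_correlation(xy[:, 0], xy[:, 1]).r_squared)
        assert np.mean(estimates) == pytest.approx(target**2, abs=0.05)


class TestWeirCockerham:
    def test_oracle_equivalence_on_random_tables(self):
        """Vectorized components match the brute-force equations to 1e-12."""
        rng = np.random.default_rng(0)
        for _ in range(500):
            n = rng.integers(2, 30, size=2)
            gts = [rng.integers(0, 3, size=ni) for ni in n]
            a_o, b_o, c_o = wc_components_brute(gts)
            p = np.array([[g.mean() / 2 for g in gts]])
            h = np.array([[(g == 1).mean() for g in gts]])
            a, b, c = pg.weir_cockerham_components(
                np.array([n], dtype=float), p, h
            )
            assert abs(a[0] - a_o) < 1e-12
            assert abs(b[0] - b_o) < 1e-12
            assert abs(c[0] - c_o) < 1e-12

    def test_fixed_difference_is_one(self, two_pop_manifest):
        gm = make_matrix([[2, 2, 0, 0]], ["s1", "s2", "s3", "s4"])
        fst = pg.fst_scan(gm, two_pop_manifest)
        assert fst.table.loc[0, "fst"] == pytest.approx(1.0)

    def test_monomorphic_site_flagged_undefined(self, two_pop_manifest):
        gm = make_matrix([[0, 0, 0, 0], [2, 0, 0, 2]],
                         ["s1", "s2", "s3", "s4"])
        fst = pg.fst_scan(gm, two_pop_manifest)
        assert not fst.table.loc[0, "defined"]
        assert np.isnan(fst.table.loc[0, "fst"])
        assert fst.table.loc[1, "defined"]


class TestNeiGst:
    def test_hand_computed_case(self):
        """p = 0.9 vs 0.1: Ht = 0.5, Hs = 0.18, G_st = 0.64."""
        gm, manifest = _hw_matrix(0.9, 0.1, 100)
        fst = pg.fst_scan(gm, manifest, estimator="nei_gst")
        assert fst.table.loc[0, "fst"] == pytest.approx(0.64)
        assert fst.table.loc[0, "ht"] == pytest.approx(0.5)
        assert fst.table.loc[0, "hs"] == pytest.approx(0.18)

    def test_identical_frequencies_give_zero(self):
        gm, manifest = _hw_matrix(0.3, 0.3, 50)
        fst = pg.fst_scan(gm, manifest, estimator="nei_gst")
        assert fst.table.loc[0, "fst"] == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(0.05, 0.5),
        st.floats(0.01, 0.24),
        st.floats(0.25, 0.49),
    )
    def test_monotone_in_frequency_separation(self, center, d_small, d_large):
        """G_st grows with |p1 - p2| around a fixed center frequency."""
        small = nei_gst_from_frequencies(
            np.array([[center, min(center + 2 * d_small, 1.0)]])
        )[2][0]
        large = nei_gst_from_frequencies(
            np.array([[center, min(center + 2 * d_large, 1.0)]])
        )[2][0]
        assert large >= small - 1e-12

    def test_unknown_estimator_rejected(self, two_pop_manifest):
        gm = make_matrix([[0, 1, 1, 2]], ["s1", "s2", "s3", "s4"])
        with pytest.raises(ConfigurationError):
            pg.fst_scan(gm, two_pop_manifest, estimator="hudson")


class TestAggregateFst:
    def test_single_site_mean_equals_weighted(self, two_pop_manifest):
        gm = make_matrix([[2, 2, 0, 0]], ["s1", "s2", "s3", "s4"])
        agg = pg.aggregate_fst(pg.fst_scan(gm, two_pop_manifest))
        assert agg.mean_fst == pytest.approx(agg.weighted_fst)

    def test_component_arithmetic(self):
        """Sites with a = (1, 0), b+c = (0, 1): mean 0.5, weighted 0.5."""
        table = pg.FstTable(
            pd.DataFrame(
                {
                    "a": [1.0, 0.0],
                    "b": [0.0, 1.0],
                    "c": [0.0, 0.0],
                    "fst": [1.0, 0.0],
                    "defined": [True, True],
                }
            ),
            "weir_cockerham",
        )
        agg = pg.aggregate_fst(table)
        assert agg.mean_fst == pytest.approx(0.5)
        assert agg.weighted_fst == pytest.approx(0.5)

    def test_mean_bounded_by_site_extremes(self, small_cohort):
        fst = pg.fst_scan(small_cohort.genotypes, small_cohort.manifest)
        agg = pg.aggregate_fst(fst)
        per_site = fst.defined_fst()
        assert per_site.min() <= agg.mean_fst <= per_site.max()

    def test_no_defined_sites_raises(self, two_pop_manifest):
        gm = make_matrix([[0, 0, 0, 0]], ["s1", "s2", "s3", "s4"])
        with pytest.raises(ValidationError):
            pg.aggregate_fst(pg.fst_scan(gm, two_pop_manifest))


class TestSelectTiers:
    def _table(self, values):
        return pg.FstTable(
            pd.DataFrame({"fst": values, "defined": np.isfinite(values)}),
            "weir_cockerham",
        )

    def test_threshold_strictly_greater(self):
        tiers = pg.select_tiers(self._table(np.array([0.1, 0.35, 0.8, 0.30])),
                                thresholds=[0.30], top_quantiles=[])
        assert tiers[0].n_selected == 2

    def test_all_zero_gives_empty_tier(self):
        tiers = pg.select_tiers(self._table(np.zeros(5)),
                                thresholds=[0.30], top_quantiles=[])
        assert tiers[0].n_selected == 0

    def test_top_quantile_order_statistics(self):
        rng = np.random.default_rng(7)
        values = rng.beta(0.5, 5.0, size=10_000)
        tiers = pg.select_tiers(self._table(values), thresholds=[],
                                top_quantiles=[0.001])
        tier = tiers[0]
        assert tier.n_selected == 10
        assert tier.overflow == 0
        assert np.all(values[tier.indices] >= tier.realized_threshold)

    def test_boundary_ties_included_with_overflow(self):
        values = np.array([0.9] * 3 + [0.1] * 997)
        tiers = pg.select_tiers(self._table(values), thresholds=[],
                                top_quantiles=[0.001])
        assert tiers[0].n_selected == 3
        assert tiers[0].overflow == 2

    def test_quantile_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            pg.select_tiers(self._table(np.array([0.5])), thresholds=[],
                            top_quantiles=[1.5])


def test_manhattan_table_cumulative_positions(small_cohort):
    fst = pg.fst_scan(small_cohort.genotypes, small_cohort.manifest)
    mt = pg.manhattan_table(fst)
    assert (np.diff(mt["cumulative_pos"]) > 0).all()  # single chromosome
    assert len(mt) == small_cohort.genotypes.n_variants
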