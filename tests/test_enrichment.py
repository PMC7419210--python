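"""Permutation-enrichment engine: placements, nulls, and the statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dupliconevo import (
    GenomeLandscape,
    GenomicInterval,
    PermutationConfig,
    RegionSet,
    RepeatAnnotation,
    bonferroni,
    empirical_p_z,
    ks_gc_test,
    null_distribution,
    observed_feature,
    p_value_se,
    permute_regions,
    run_enrichment,
)
from dupliconevo.enrichment import NullDistribution, results_table


def make_null(values):
    v = np.asarray(values, dtype=float)
    return NullDistribution("SINE", v, np.array([]), float(v.mean()), float(v.std()))


class TestEmpiricalPZ:
    def test_observed_at_mean_gives_half(self):
        null = make_null([1.0, 2.0, 3.0])
        assert empirical_p_z(2.0, null) == pytest.approx(0.5)

    def test_1p96_sigma(self):
        # upper-tail area beyond mean + 1.96 sd of a standard normal
        null = make_null([0.0, 2.0])  # mean 1, sd 1
        assert empirical_p_z(1.0 + 1.96, null) == pytest.approx(0.0250, abs=1e-4)

    def test_5_sigma(self):
        null = make_null([0.0, 2.0])
        assert empirical_p_z(6.0, null) == pytest.approx(2.87e-7, rel=0.01)

    def test_degenerate_null_errors(self):
        with pytest.raises(ValueError):
            empirical_p_z(1.0, make_null([2.0, 2.0, 2.0]))

    def test_depletion_direction(self):
        null = make_null([0.0, 2.0])
        assert empirical_p_z(0.0, null, depletion=True) == pytest.approx(
            stats.norm.cdf(-1.0)
        )


class TestKS:
    def test_identical_samples(self):
        d, p = ks_gc_test([0.3, 0.4, 0.5], [0.3, 0.4, 0.5])
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = ks_gc_test([0.0, 0.0], [1.0, 1.0])
        assert d == 1.0

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            ks_gc_test([], [1.0])

    @given(
        st.lists(st.floats(0, 1, width=32), min_size=2, max_size=30),
        st.lists(st.floats(0, 1, width=32), min_size=2, max_size=30),
    )
    @settings(derandomize=True, max_examples=50)
    def test_statistic_matches_exhaustive_cdf_gap(self, a, b):
        d, _ = ks_gc_test(a, b)
        pts = sorted(set(a) | set(b))
        gap = max(
            abs(sum(x <= t for x in a) / len(a) - sum(x <= t for x in b) / len(b))
            for t in pts
        )
        assert d == pytest.approx(gap, abs=1e-12)


class TestBonferroniAndSE:
    def test_cap_and_arithmetic(self):
        assert bonferroni(0.5, 9) == 1.0
        assert bonferroni(0.004, 9) == pytest.approx(0.036)
        assert bonferroni(0.0, 9) == 0.0

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bonferroni(1.5)

    @pytest.mark.parametrize(
        "p, n, printed, sig_figs",
        [
            # donor and pre-integration rows of the published summary table
            (1.6e-5, 63, 0.0005, 1),
            (3.7e-8, 63, 2.4e-5, 2),
            (0.2, 63, 0.05, 1),
            (0.09, 13, 0.08, 1),
            (0.0077, 13, 0.024, 2),
            (0.024, 13, 0.04, 1),
        ],
    )
    def test_se_reproduces_published_values_at_printed_precision(
        self, p, n, printed, sig_figs
    ):
        se = p_value_se(p, n)
        decimals = sig_figs - 1 - int(math.floor(math.log10(abs(printed))))
        assert round(se, decimals) == pytest.approx(printed)

    def test_se_edge_cases(self):
        assert p_value_se(0.0, 63) == 0.0
        with pytest.raises(ValueError):
            p_value_se(0.5, 0)


class TestPermutePlacements:
    def test_forced_placement(self):
        regions = RegionSet([GenomicInterval("c", 0, 100)])
        allowed = RegionSet([GenomicInterval("c", 400, 500)])
        out = permute_regions(regions, allowed, np.random.default_rng(0))
        assert (out[0].start, out[0].end) == (400, 500)

    def test_region_longer_than_every_segment_errors(self):
        regions = RegionSet([GenomicInterval("c", 0, 100, name="big")])
        allowed = RegionSet(
            [GenomicInterval("c", 0, 99), GenomicInterval("c", 200, 250)]
        )
        with pytest.raises(ValueError, match="big"):
            permute_regions(regions, allowed, np.random.default_rng(0))

    def test_length_preserved_and_inside_allowed(self):
        rng = np.random.default_rng(1)
        regions = RegionSet([GenomicInterval("c", 0, 37), GenomicInterval("c", 0, 11)])
        allowed = RegionSet(
            [GenomicInterval("c", 100, 300), GenomicInterval("c", 500, 560)]
        )
        for _ in range(50):
            out = permute_regions(regions, allowed, rng)
            assert out.lengths() == [37, 11]
            for iv in out:
                assert (100 <= iv.start and iv.end <= 300) or (
                    500 <= iv.start and iv.end <= 560
                )

    def test_start_distribution_uniform(self):
        # 1 bp region over a 50 bp allowed space: chi-square goodness of fit
        regions = RegionSet([GenomicInterval("c", 0, 1)])
        allowed = RegionSet([GenomicInterval("c", 0, 50)])
        rng = np.random.default_rng(7)
        counts = np.zeros(50)
        n = 5000
        for _ in range(n):
            counts[permute_regions(regions, allowed, rng)[0].start] += 1
        chi2 = float(((counts - n / 50) ** 2 / (n / 50)).sum())
        assert stats.chi2.sf(chi2, df=49) > 0.001


class TestNullDistribution:
    def test_determinism(self, toy_landscape):
        regions = RegionSet(
            [GenomicInterval("chr1", 300_000, 310_000) for _ in range(5)]
        )
        cfg = PermutationConfig(n_permutations=50, seed=11)
        a = null_distribution(regions, toy_landscape, "SINE", cfg)
        b = null_distribution(regions, toy_landscape, "SINE", cfg)
        assert np.array_equal(a.per_permutation_values, b.per_permutation_values)

    def test_homogeneous_landscape_E_near_one(self):
        # uniform SINE density: observed ~ null mean
        rng = np.random.default_rng(3)
        size = 2_000_000
        repeats = [
            RepeatAnnotation(GenomicInterval("c", int(s), int(s) + 300), "SINE", "Alu")
            for s in rng.integers(0, size - 300, size=700)
        ]
        land = GenomeLandscape(
            chrom_sizes={"c": size},
            repeats=repeats,
            gc_track={"c": np.full(size // 1000, 0.4)},
            gc_window=1000,
        )
        # the observed count of a single region draw fluctuates by several
        # percent itself, so test the limit on E averaged over region draws
        Es = []
        for k in range(8):
            regions = RegionSet(
                [
                    GenomicInterval("c", int(s), int(s) + 20_000)
                    for s in rng.integers(0, size - 20_000, size=40)
                ]
            )
            obs, _ = observed_feature(regions, land, "SINE")
            null = null_distribution(
                regions, land, "SINE", PermutationConfig(n_permutations=250, seed=5 + k)
            )
            Es.append(obs / null.mean)
        assert np.mean(Es) == pytest.approx(1.0, abs=0.05)

    def test_z_p_agrees_with_monte_carlo_rank_p(self, toy_landscape):
        regions = RegionSet(
            [GenomicInterval("chr1", int(s), int(s) + 15_000) for s in
             np.random.default_rng(9).integers(0, 900_000, size=12)]
        )
        obs, _ = observed_feature(regions, toy_landscape, "SINE")
        null = null_distribution(
            regions, toy_landscape, "SINE", PermutationConfig(n_permutations=1500, seed=13)
        )
        p_z = empirical_p_z(obs, null)
        rank = (np.sum(null.per_permutation_values >= obs) + 1) / (1500 + 1)
        if p_z > 1e-3:
            assert p_z / 3 < rank < p_z * 3


class TestRunEnrichment:
    def test_grid_size_and_correction_factor(self, toy_landscape):
        rng = np.random.default_rng(17)
        sets = {}
        for name in ("donors", "acceptors", "preint"):
            sets[name] = RegionSet(
                [
                    GenomicInterval("chr1", int(s), int(s) + 8000)
                    for s in rng.integers(0, 900_000, size=6)
                ],
                role=name,
            )
        res = run_enrichment(
            toy_landscape, sets, PermutationConfig(n_permutations=60, seed=23)
        )
        assert len(res) == 9
        for r in res:
            assert r.p_corrected == pytest.approx(min(1.0, r.p_raw * 9))
            assert r.SE == pytest.approx(p_value_se(r.p_raw, r.n_regions))

    def test_single_set_single_feature_correction_one(self, toy_landscape):
        regions = RegionSet([GenomicInterval("chr1", 400_000, 420_000)])
        res = run_enrichment(
            toy_landscape,
            {"donors": regions},
            PermutationConfig(n_permutations=60, seed=2, features=("SINE",)),
        )
        assert len(res) == 1
        assert res[0].p_corrected == pytest.approx(min(1.0, res[0].p_raw))

    def test_serialized_output_deterministic(self, toy_landscape):
        regions = {
            "donors": RegionSet([GenomicInterval("chr1", 400_000, 420_000),
                                 GenomicInterval("chr2", 100_000, 130_000)])
        }
        cfg = PermutationConfig(n_permutations=80, seed=31)
        t1 = results_table(run_enrichment(toy_landscape, regions, cfg)).to_csv(sep="\t")
        t2 = results_table(run_enrichment(toy_landscape, regions, cfg)).to_csv(sep="\t")
        assert t1 == t2

    def test_gc_observed_value(self):
        land = GenomeLandscape(chrom_sizes={"c": 8}, sequence={"c": "GCGCATAT"})
        regions = RegionSet([GenomicInterval("c", 0, 4)])
        obs, vals = observed_feature(regions, land, "GC")
        assert obs == 1.0 and vals[0] == 1.0
        obs2, _ = observed_feature(RegionSet([GenomicInterval("c", 4, 8)]), land, "GC")
        assert obs2 == 0.0
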