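import math

import numpy as np
import pytest

from radmiss import (
    MISSING,
    GenotypeMatrix,
    SimConfig,
    fis_from_het,
    locus_components,
    multilocus_from_matrix,
    multilocus_stats,
    pairwise_one_vs_rest,
    per_location_stats,
    per_locus_stats,
    simulate_snp_panel,
    stat_histogram,
    wc_theta,
)

from conftest import make_random_matrix
from oracle import matrix_to_pops, naive_locus_stats


def _hwe_matrix(p, n, seed, n_loci=1, pops=1):
    rng = np.random.default_rng(seed)
    calls = (rng.random((n * pops, n_loci, 2)) < p).astype(np.int16)
    return GenotypeMatrix(
        individual_ids=[f"i{k}" for k in range(n * pops)],
        populations=[f"p{k // n}" for k in range(n * pops)],
        locus_ids=[f"L{j}" for j in range(n_loci)],
        calls=calls,
    )


class TestPerLocusStats:
    def test_hand_example(self, hand_matrix):
        s = per_locus_stats(hand_matrix)[0]
        assert s.ho == pytest.approx(0.25)
        assert s.hs == pytest.approx(0.25)
        assert s.ht == pytest.approx(0.5)
        assert s.fst == pytest.approx(0.5)
        assert s.fis == pytest.approx(0.0)
        assert s.n_typed_per_pop == {"p1": 2, "p2": 2}

    def test_hand_example_agrees_with_naive_oracle(self, hand_matrix):
        got = per_locus_stats(hand_matrix)[0]
        want = naive_locus_stats(matrix_to_pops(hand_matrix)[0])
        for key in ("ho", "hs", "ht", "fst", "fis"):
            assert getattr(got, key) == pytest.approx(want[key])

    @pytest.mark.parametrize("seed", [101, 102, 103])
    @pytest.mark.parametrize("max_allele", [1, 3])
    def test_random_panels_match_naive_oracle(self, seed, max_allele):
        gm = make_random_matrix(
            seed, n_per_pop=4, n_pops=4, n_loci=15,
            missing_rate=0.35, max_allele=max_allele,
        )
        per_locus = matrix_to_pops(gm)
        stats = per_locus_stats(gm)
        for s, locus in zip(stats, per_locus):
            want = naive_locus_stats(locus)
            for key in ("ho", "hs", "ht", "fst", "fis"):
                g, w = getattr(s, key), want[key]
                assert (math.isnan(g) and math.isnan(w)) or g == pytest.approx(w)

    def test_identical_population_tables_give_near_zero_fst(self):
        rng = np.random.default_rng(5)
        block = rng.integers(0, 2, size=(50, 10, 2)).astype(np.int16)
        gm = GenotypeMatrix(
            individual_ids=[f"i{k}" for k in range(100)],
            populations=["a"] * 50 + ["b"] * 50,
            locus_ids=[f"L{j}" for j in range(10)],
            calls=np.concatenate([block, block]),
        )
        ml = multilocus_from_matrix(gm)
        assert abs(ml.fst) < 0.02
        # fis identical whether aggregated per locus or multilocus
        per = per_locus_stats(gm)
        assert ml.fis == pytest.approx(
            1 - np.mean([s.ho for s in per]) / np.mean([s.hs for s in per])
        )

    def test_all_homozygous_polymorphic_pops_give_fis_one(self):
        # within-pop polymorphism carried entirely by homozygotes
        gm = GenotypeMatrix(
            individual_ids=["a", "b", "c", "d"],
            populations=["p1", "p1", "p2", "p2"],
            locus_ids=["L"],
            calls=np.array([[[0, 0]], [[1, 1]], [[0, 0]], [[1, 1]]]),
        )
        s = per_locus_stats(gm)[0]
        assert s.ho == 0.0
        assert s.hs > 0
        assert s.fis == pytest.approx(1.0)

    def test_fixed_difference_gives_fst_one(self):
        gm = GenotypeMatrix(
            individual_ids=["a", "b", "c", "d"],
            populations=["p1", "p1", "p2", "p2"],
            locus_ids=["L"],
            calls=np.array([[[0, 0]], [[0, 0]], [[1, 1]], [[1, 1]]]),
        )
        s = per_locus_stats(gm)[0]
        assert s.ho == 0.0
        assert s.fst == pytest.approx(1.0)
        assert not s.fis_defined  # no within-pop diversity

    def test_locus_typed_in_one_population_has_undefined_fst(self):
        calls = np.array([[[0, 1]], [[0, 0]], [[-1, -1]], [[-1, -1]]])
        gm = GenotypeMatrix(
            individual_ids=["a", "b", "c", "d"],
            populations=["p1", "p1", "p2", "p2"],
            locus_ids=["L"],
            calls=calls,
        )
        s = per_locus_stats(gm)[0]
        assert not s.fst_defined
        assert s.fis_defined  # hs from p1 alone is fine


class TestMultilocus:
    def test_single_locus_identity(self, hand_matrix):
        s = per_locus_stats(hand_matrix)
        ml = multilocus_stats(s)
        assert (ml.fst, ml.fis) == (pytest.approx(s[0].fst), pytest.approx(s[0].fis))

    def test_ratio_of_averages_not_average_of_ratios(self):
        # (hs, ht) = (0.2, 0.4) and (0.4, 0.4) -> fst = (0.4-0.3)/0.4 = 0.25
        from radmiss.popstats import LocusStats

        loci = [
            LocusStats("a", {}, 0.2, 0.2, 0.4, 0.5, 0.0),
            LocusStats("b", {}, 0.4, 0.4, 0.4, 0.0, 0.0),
        ]
        ml = multilocus_stats(loci)
        assert ml.fst == pytest.approx(0.25)
        assert ml.n_loci_used == 2

    @pytest.mark.parametrize("seed", [111, 112])
    def test_aggregation_matches_naive_recomputation(self, seed):
        gm = make_random_matrix(seed, n_pops=3, n_loci=20, missing_rate=0.3)
        naive = [naive_locus_stats(loc) for loc in matrix_to_pops(gm)]
        used = [d for d in naive if not math.isnan(d["ht"])]
        ht = np.mean([d["ht"] for d in used])
        hs = np.mean([d["hs"] for d in used])
        ho = np.mean([d["ho"] for d in used])
        ml = multilocus_from_matrix(gm)
        assert ml.fst == pytest.approx((ht - hs) / ht)
        assert ml.fis == pytest.approx(1 - ho / hs)
        assert ml.n_loci_used == len(used)

    def test_all_loci_undefined_is_an_error(self):
        calls = np.full((4, 2, 2), MISSING, dtype=np.int16)
        gm = GenotypeMatrix(
            individual_ids=["a", "b", "c", "d"],
            populations=["p1", "p1", "p2", "p2"],
            locus_ids=["L1", "L2"],
            calls=calls,
        )
        with pytest.raises(ValueError, match="no usable loci"):
            multilocus_from_matrix(gm)


class TestWcTheta:
    def test_no_differentiation_is_near_zero(self):
        gm = _hwe_matrix(0.4, n=50, seed=8, n_loci=30, pops=2)
        assert abs(wc_theta(gm).overall) < 0.05

    def test_fixed_difference_is_one(self):
        calls = np.concatenate(
            [np.zeros((10, 1, 2), np.int16), np.ones((10, 1, 2), np.int16)]
        )
        gm = GenotypeMatrix(
            individual_ids=[f"i{k}" for k in range(20)],
            populations=["a"] * 10 + ["b"] * 10,
            locus_ids=["L"],
            calls=calls,
        )
        res = wc_theta(gm)
        assert res.per_locus[0] == pytest.approx(1.0)
        assert res.overall == pytest.approx(1.0)

    def test_recovers_generating_f(self):
        gm, _ = simulate_snp_panel(SimConfig(n_loci=5000, target_fst=0.1, seed=11))
        assert wc_theta(gm).overall == pytest.approx(0.1, abs=0.01)


class TestPairwise:
    def test_two_population_matrix_is_plain_multilocus(self, hand_matrix):
        assert pairwise_one_vs_rest(hand_matrix, "p1") == pytest.approx(
            multilocus_from_matrix(hand_matrix).fst
        )

    def test_three_pop_matches_explicit_relabeling(self):
        gm = make_random_matrix(77, n_pops=3, n_loci=25, missing_rate=0.2)
        got = pairwise_one_vs_rest(gm, "pop1")
        relabeled = GenotypeMatrix(
            individual_ids=gm.individual_ids,
            populations=[
                "focal" if p == "pop1" else "other" for p in gm.populations
            ],
            locus_ids=gm.locus_ids,
            calls=gm.calls,
        )
        assert got == pytest.approx(multilocus_from_matrix(relabeled).fst)

    def test_unknown_focal_population(self):
        with pytest.raises(ValueError, match="unknown population"):
            pairwise_one_vs_rest(make_random_matrix(1), "nope")


class TestFisFromHet:
    def test_definition_and_sign_flip(self):
        assert fis_from_het(0.4, 0.5) == pytest.approx((0.5 - 0.4) / 0.5)
        assert fis_from_het(0.5, 0.4) == pytest.approx(-0.25)
        assert fis_from_het(0.3, 0.3) == 0.0

    def test_zero_expected_het_is_undefined(self):
        assert math.isnan(fis_from_het(0.0, 0.0))


class TestPerLocation:
    def test_all_heterozygotes(self):
        calls = np.tile(np.array([0, 1], np.int16), (4, 3, 1))
        gm = GenotypeMatrix(
            individual_ids=list("abcd"),
            populations=["p"] * 4,
            locus_ids=["L1", "L2", "L3"],
            calls=calls,
        )
        assert per_location_stats(gm)["p"].ho == 1.0

    def test_hwe_population_has_near_zero_fis(self):
        gm = _hwe_matrix(0.5, n=500, seed=13, n_loci=20)
        assert abs(per_location_stats(gm)["p0"].fis) < 0.05

    def test_swapped_tables_swap_results(self):
        gm = make_random_matrix(88, n_pops=2, n_loci=10, missing_rate=0.2)
        half = gm.n_individuals // 2
        swapped = GenotypeMatrix(
            individual_ids=gm.individual_ids,
            populations=gm.populations,
            locus_ids=gm.locus_ids,
            calls=np.concatenate([gm.calls[half:], gm.calls[:half]]),
        )
        a = per_location_stats(gm)
        b = per_location_stats(swapped)
        assert a["pop0"].ho == pytest.approx(b["pop1"].ho)
        assert a["pop1"].fis == pytest.approx(b["pop0"].fis) or (
            math.isnan(a["pop1"].fis) and math.isnan(b["pop0"].fis)
        )

    def test_fis_equals_ratio_of_mean_heterozygosities(self):
        gm = make_random_matrix(91, n_per_pop=6, n_pops=2, missing_rate=0.2)
        for ls in per_location_stats(gm).values():
            assert ls.fis == fis_from_het(ls.ho_paired, ls.he)


class TestHistogram:
    def test_bin_arithmetic(self):
        h = stat_histogram([0.0, 0.5, 1.0], bin_width=0.5)
        assert h.bin_lo == pytest.approx([0.0, 0.5, 1.0])
        assert h.counts.tolist() == [1, 1, 1]

    def test_all_undefined(self):
        h = stat_histogram([math.nan] * 4, bin_width=0.1)
        assert h.counts.size == 0
        assert h.n_undefined == 4

    def test_extreme_tally_is_strictly_above_threshold(self):
        h = stat_histogram([0.975, 0.976, 0.99, 0.2])
        assert h.extreme_count == 2


class TestInvariances:
    def test_permutation_invariance(self):
        gm = make_random_matrix(121, n_pops=3, n_loci=18, missing_rate=0.3)
        rng = np.random.default_rng(0)
        perm = np.concatenate(
            [rng.permutation(ix) for ix in gm.pop_indices().values()]
        )
        shuffled = gm.subset_individuals(perm).subset_loci(
            rng.permutation(gm.n_loci)
        )
        a, b = multilocus_from_matrix(gm), multilocus_from_matrix(shuffled)
        assert a.fst == pytest.approx(b.fst)
        assert a.fis == pytest.approx(b.fis)
        assert a.ho_bar == pytest.approx(b.ho_bar)

    def test_deleting_fully_missing_individual_changes_nothing(self):
        gm = make_random_matrix(131, n_pops=2, n_loci=12, missing_rate=0.2)
        calls = gm.calls.copy()
        calls[3] = MISSING
        with_row = GenotypeMatrix(
            individual_ids=gm.individual_ids,
            populations=gm.populations,
            locus_ids=gm.locus_ids,
            calls=calls,
        )
        without = with_row.subset_individuals(
            [i for i in range(gm.n_individuals) if i != 3]
        )
        a, b = multilocus_from_matrix(with_row), multilocus_from_matrix(without)
        assert a.fst == pytest.approx(b.fst)
        assert a.fis == pytest.approx(b.fis)
        ta, tb = wc_theta(with_row), wc_theta(without)
        assert ta.overall == pytest.approx(tb.overall)

    def test_estimators_agree_on_clean_panels(self):
        # no missing data: Nei-Chesser fst and WC theta both near the
        # generating F on a study-shaped panel
        for seed in (201, 202):
            gm, _ = simulate_snp_panel(
                SimConfig(n_loci=5000, target_fst=0.1, seed=seed)
            )
            nei = multilocus_from_matrix(gm).fst
            th = wc_theta(gm).overall
            assert nei == pytest.approx(0.1, abs=0.015)
            assert th == pytest.approx(0.1, abs=0.015)
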