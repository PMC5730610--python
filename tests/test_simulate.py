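import numpy as np
import pytest

from radmiss import (
    MISSING,
    SimConfig,
    apply_allelic_dropout,
    apply_individual_missingness,
    apply_mcar,
    multilocus_from_matrix,
    simulate_snp_panel,
    simulate_ssr_panel,
)


class TestSnpPanel:
    def test_regeneration_is_byte_identical(self):
        cfg = SimConfig(n_loci=120, target_fst=0.15, seed=5)
        a, ta = simulate_snp_panel(cfg)
        b, tb = simulate_snp_panel(cfg)
        assert a.equals(b)
        assert np.array_equal(ta.deme_freqs, tb.deme_freqs)

    def test_no_differentiation_limit(self):
        gm, truth = simulate_snp_panel(SimConfig(n_loci=5000, target_fst=0.0, seed=2))
        assert np.allclose(truth.deme_freqs[0], truth.deme_freqs[-1])
        assert abs(multilocus_from_matrix(gm).fst) < 0.01

    def test_study_shape_defaults(self):
        gm, _ = simulate_snp_panel(SimConfig(n_loci=10, seed=1))
        assert gm.n_individuals == 96
        assert len(gm.pop_labels) == 12
        assert all(len(ix) == 8 for ix in gm.pop_indices().values())
        assert gm.tags is not None and len(set(gm.tags)) == 10

    def test_truth_frequencies_match_genotype_frequencies(self):
        # one deme, large n: allele-1 count within 3 sigma of binomial
        cfg = SimConfig(n_pops=1, n_per_pop=500, n_loci=30, target_fst=0.0, seed=9)
        gm, truth = simulate_snp_panel(cfg)
        p = truth.deme_freqs[0, :, 1]
        count = (gm.calls == 1).sum(axis=(0, 2))
        n_copies = 2 * 500
        sigma = np.sqrt(n_copies * p * (1 - p))
        assert (np.abs(count - n_copies * p) < 3.5 * sigma).all()

    def test_degenerate_f_rejected(self):
        with pytest.raises(ValueError, match="target_fst"):
            SimConfig(target_fst=1.0)


class TestSsrPanel:
    def test_two_alleles_behave_like_snps(self):
        cfg = SimConfig(
            marker_type="ssr", n_alleles=2, n_loci=2000, target_fst=0.1, seed=3
        )
        gm, _ = simulate_ssr_panel(cfg)
        assert gm.n_alleles() == 2
        assert multilocus_from_matrix(gm).fst == pytest.approx(0.1, abs=0.03)

    def test_wide_envelope_at_few_loci(self):
        fsts = []
        for seed in range(20):
            cfg = SimConfig(
                marker_type="ssr", n_loci=8, n_alleles=10, target_fst=0.12, seed=seed
            )
            gm, _ = simulate_ssr_panel(cfg)
            fsts.append(multilocus_from_matrix(gm).fst)
        assert min(fsts) >= 0.05 and max(fsts) <= 0.20

    def test_heterozygosity_grows_with_allele_count(self):
        means = []
        for n_alleles in (2, 5, 10):
            hs = []
            for seed in range(3):
                cfg = SimConfig(
                    marker_type="ssr", n_loci=40, n_alleles=n_alleles,
                    target_fst=0.05, seed=seed,
                )
                gm, _ = simulate_ssr_panel(cfg)
                hs.append(multilocus_from_matrix(gm).hs_bar)
            means.append(np.mean(hs))
        assert means[0] < means[1] < means[2]


class TestMcar:
    def test_rate_zero_is_identity(self):
        gm, _ = simulate_snp_panel(SimConfig(n_loci=50, seed=1))
        assert apply_mcar(gm, 0.0, seed=4).equals(gm)

    def test_rate_one_is_all_missing(self):
        gm, _ = simulate_snp_panel(SimConfig(n_loci=20, seed=1))
        assert not apply_mcar(gm, 1.0, seed=4).typed.any()

    def test_realized_rate_within_binomial_error(self):
        gm, _ = simulate_snp_panel(SimConfig(n_loci=200, seed=6))  # 19,200 cells
        out = apply_mcar(gm, 0.3, seed=6)
        n_cells = gm.n_individuals * gm.n_loci
        realized = (~out.typed).sum() / n_cells
        sigma = np.sqrt(0.3 * 0.7 / n_cells)
        assert abs(realized - 0.3) < 3 * sigma


class TestIndividualMissingness:
    def test_uniform_zero_rates_identity(self):
        gm, _ = simulate_snp_panel(SimConfig(n_loci=30, seed=2))
        out = apply_individual_missingness(gm, [0.0] * 96, seed=1)
        assert out.equals(gm)

    def test_rate_one_wipes_the_row(self):
        gm, _ = simulate_snp_panel(SimConfig(n_loci=30, seed=2))
        rates = np.zeros(96)
        rates[5] = 1.0
        out = apply_individual_missingness(gm, rates, seed=1)
        assert not out.typed[5].any()
        assert out.typed[0].all() == gm.typed[0].all()

    def test_per_population_rates_ordered_as_configured(self):
        gm, _ = simulate_snp_panel(SimConfig(n_loci=400, seed=3))
        rates = np.repeat(np.linspace(0.1, 0.7, 12), 8)
        out = apply_individual_missingness(gm, rates, seed=3)
        from radmiss import missingness_summary

        pop_rates = list(missingness_summary(out).per_population_rate.values())
        assert (np.diff(pop_rates) > 0).all()

    def test_unknown_individual_in_mapping(self):
        gm, _ = simulate_snp_panel(SimConfig(n_loci=5, seed=1))
        with pytest.raises(ValueError, match="no rate"):
            apply_individual_missingness(gm, {"nobody": 0.5}, seed=1)


class TestAllelicDropout:
    def test_zero_null_fraction_is_identity(self):
        gm, truth = simulate_snp_panel(SimConfig(n_loci=100, seed=4))
        out, t2 = apply_allelic_dropout(gm, truth, q_law=(0.0, 0.0), seed=4)
        assert out.equals(gm)
        assert t2.miscalled.sum() == 0

    def test_full_dropout_silences_the_linked_lineage(self):
        gm, truth = simulate_snp_panel(SimConfig(n_loci=100, seed=4))
        out, t2 = apply_allelic_dropout(gm, truth, q_law=(1.0, 1.0), seed=4)
        linked = t2.dropout_linked_allele
        # no surviving call carries its locus's null-linked allele
        carries = out.typed & (out.calls == linked[None, :, None]).any(axis=2)
        assert not carries.any()
        # every individual that carried the linked allele lost data
        had = gm.typed & (gm.calls == linked[None, :, None]).any(axis=2)
        changed = (out.calls != gm.calls).any(axis=2)
        assert (changed | ~gm.typed)[had].all()

    def test_miscalls_are_het_to_homozygote(self):
        gm, truth = simulate_snp_panel(SimConfig(n_loci=200, seed=8))
        out, t2 = apply_allelic_dropout(gm, truth, q_law=(0.2, 0.8), seed=8)
        mis = t2.miscalled
        assert mis.any()
        # miscalled cells were heterozygous and are now typed homozygotes
        assert (gm.calls[mis][:, 0] != gm.calls[mis][:, 1]).all()
        assert (out.calls[mis][:, 0] == out.calls[mis][:, 1]).all()
        assert (out.calls[mis] != MISSING).all()

    def test_invalid_q_law_support(self):
        gm, truth = simulate_snp_panel(SimConfig(n_loci=5, seed=1))
        with pytest.raises(ValueError, match="q_law"):
            apply_allelic_dropout(gm, truth, q_law=(0.5, 1.5), seed=1)

    def test_callable_q_law_and_determinism(self):
        gm, truth = simulate_snp_panel(SimConfig(n_loci=60, seed=10))
        law = lambda rng, size: rng.beta(2, 2, size=size)
        a, _ = apply_allelic_dropout(gm, truth, q_law=law, seed=10)
        b, _ = apply_allelic_dropout(gm, truth, q_law=law, seed=10)
        c, _ = apply_allelic_dropout(gm, truth, q_law=law, seed=11)
        assert a.equals(b)
        assert not a.equals(c)
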