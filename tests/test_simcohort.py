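"""Generative-model checks for the synthetic cohort simulator: Balding-
Nichols frequency moments, HWE in founders, Mendelian transmission, sex-
chromosome semantics, platform error injection and swap planting."""

import numpy as np
import pytest

from arrayqc import simcohort
from arrayqc.genio import MISSING
from arrayqc.simcohort import AncestralComponent, ValidationError


class TestSimulateFrequencies:
    def test_fst_limit_zero_variance(self):
        """As Fst -> 0 every component frequency collapses onto the shared
        ancestral frequency, so two components' draws nearly coincide."""
        comps = [AncestralComponent("a", 1e-6), AncestralComponent("b", 1e-6)]
        out = simcohort.simulate_frequencies(2000, comps, seed=3)
        assert np.max(np.abs(out[0].allele_freqs - out[1].allele_freqs)) < 0.01

    def test_balding_nichols_moments(self):
        """Unconditional moments vs the closed form: with p ~ U[0.05, 0.95],
        E[f] = 0.5 and Var(f) = Var(p) + F E[p(1-p)]
        = 0.9^2/12 + F (0.25 - 0.9^2/12)."""
        fst = 0.2
        out = simcohort.simulate_frequencies(40000, [AncestralComponent("a", fst)], seed=5)
        f = out[0].allele_freqs
        var_p = 0.9**2 / 12
        expect_var = var_p + fst * (0.25 - var_p)
        assert np.mean(f) == pytest.approx(0.5, abs=0.01)
        assert np.var(f) == pytest.approx(expect_var, rel=0.10)

    def test_determinism_and_validation(self):
        comps = [AncestralComponent("a", 0.1)]
        a = simcohort.simulate_frequencies(100, comps, seed=9)
        b = simcohort.simulate_frequencies(100, comps, seed=9)
        assert np.array_equal(a[0].allele_freqs, b[0].allele_freqs)
        with pytest.raises(ValidationError):
            simcohort.simulate_frequencies(0, comps, seed=9)
        with pytest.raises(ValidationError):
            AncestralComponent("bad", 1.5)


class TestFounders:
    def test_heterozygosity_matches_hwe(self, components_small, small_manifest):
        """A pure-component population's mean autosomal heterozygosity equals
        the HWE closed form mean(2 f (1-f)) within Monte-Carlo error."""
        k = len(components_small)
        pure = [
            simcohort.ReferencePopulation(
                "pure0", np.eye(k)[0], 0.0, 0.0, "r0"
            )
        ]
        cohort = simcohort.simulate_individuals(
            components_small, pure, n_per_pop=60, seed=13, manifest=small_manifest
        )
        auto = cohort.truth.subset_markers(small_manifest.autosomal_ids())
        f = components_small[0].allele_freqs
        expect = np.mean(2 * f * (1 - f))
        n_calls = auto.calls.size
        got = float((auto.calls == 1).mean())
        sd = np.sqrt(expect * (1 - expect) / n_calls)
        assert abs(got - expect) < 3 * sd + 1e-4

    def test_founder_genotypes_match_binomial_hwe(self, small_cohort, small_manifest):
        """Founder genotype frequencies at each marker are Binomial(2, mean
        dosage/2) within Monte-Carlo tolerance (aggregated chi-square-like
        check over markers of one population)."""
        ids = [s for s in small_cohort.sample_ids if s.startswith("Yoruba")]
        auto = small_cohort.truth.subset_samples(ids).subset_markers(
            small_manifest.autosomal_ids()
        )
        g = auto.calls
        p_hat = g.mean(axis=0) / 2
        informative = (p_hat > 0.2) & (p_hat < 0.8)
        obs_het = (g == 1).mean(axis=0)[informative]
        exp_het = (2 * p_hat * (1 - p_hat))[informative]
        # mean deviation over many markers shrinks as 1/sqrt(n_markers)
        assert np.mean(obs_het - exp_het) == pytest.approx(0.0, abs=0.05)

    def test_empty_cohort_and_sex_semantics(self, components_small, small_manifest):
        pops = simcohort.default_populations(components_small)
        empty = simcohort.simulate_individuals(
            components_small, pops, n_per_pop=0, seed=1, manifest=small_manifest
        )
        assert empty.truth.n_samples == 0
        cohort = simcohort.simulate_individuals(
            components_small, pops[:1], n_per_pop=6, seed=2, manifest=small_manifest
        )
        x = cohort.truth.subset_markers(small_manifest.ids_in_category("X"))
        y = cohort.truth.subset_markers(small_manifest.ids_in_category("Y"))
        for s in cohort.sample_ids:
            if cohort.truth_sex[s] == "male":
                assert not np.any(x.row(s) == 1)  # hemizygous: no true hets
                assert np.all(y.row(s) != MISSING)
            else:
                assert np.all(y.row(s) == MISSING)

    def test_simplex_conservation(self, small_cohort):
        for q in small_cohort.truth_admixture.values():
            assert np.all(q >= 0)
            assert q.sum() == pytest.approx(1.0, abs=1e-9)

    def test_k_mismatch_rejected(self, components_small, small_manifest):
        bad_pop = simcohort.ReferencePopulation("bad", np.array([0.5, 0.5]), 0, 0, "r")
        with pytest.raises(ValidationError):
            simcohort.simulate_individuals(
                components_small, [bad_pop], n_per_pop=1, seed=1, manifest=small_manifest
            )


class TestFamilies:
    @pytest.fixture()
    def trio_cohort(self, components_small, small_manifest):
        pops = simcohort.default_populations(components_small)
        cohort = simcohort.simulate_individuals(
            components_small, pops[:1], n_per_pop=4, seed=41, manifest=small_manifest
        )
        return cohort

    def test_mendelian_from_homozygous_parents(self, trio_cohort, small_manifest):
        """Parents both 0 at a marker always transmit 0; forced het x het
        parents yield children 0/1/2 near the exact Mendelian 1/4,1/2,1/4."""
        cohort = trio_cohort
        father, mother = "Yakut_0000", "Yakut_0001"
        auto_ids = small_manifest.autosomal_ids()
        cols = [cohort.truth.marker_ids.index(m) for m in auto_ids]
        fi = cohort.truth.sample_index(father)
        mi = cohort.truth.sample_index(mother)
        cohort.truth.calls[fi, cols] = 1  # force het x het everywhere autosomal
        cohort.truth.calls[mi, cols] = 1
        simcohort.add_family(cohort, father, mother, n_children=6, seed=42)
        kids = [c for c, f, m in cohort.pedigree]
        g = np.concatenate([cohort.truth.row(c)[cols] for c in kids])
        freq = np.array([(g == v).mean() for v in (0, 1, 2)])
        sd = np.sqrt(np.array([0.25 * 0.75, 0.25, 0.25 * 0.75]) / g.size)
        assert np.all(np.abs(freq - [0.25, 0.5, 0.25]) < 4 * sd)

    def test_parent_offspring_never_opposite_homozygous(self, small_cohort, small_manifest):
        """Error-free Mendelian transmission forbids opposite homozygotes in
        any parent-child pair (IBS >= 1 at every autosomal marker)."""
        auto = small_cohort.truth.subset_markers(small_manifest.autosomal_ids())
        for child, father, mother in small_cohort.pedigree:
            for parent in (father, mother):
                d = np.abs(
                    auto.row(child).astype(int) - auto.row(parent).astype(int)
                )
                assert np.max(d) <= 1

    def test_maternal_mt_and_sex_chromosomes(self, small_cohort, small_manifest):
        mt = small_cohort.truth.subset_markers(
            small_manifest.ids_in_category("mitochondrial")
        )
        y = small_cohort.truth.subset_markers(small_manifest.ids_in_category("Y"))
        for child, father, mother in small_cohort.pedigree:
            assert np.array_equal(mt.row(child), mt.row(mother))
            assert small_cohort.truth_haplogroup[child] == small_cohort.truth_haplogroup[mother]
            if small_cohort.truth_sex[child] == "male":
                assert np.array_equal(y.row(child), y.row(father))
            else:
                assert np.all(y.row(child) == MISSING)

    def test_family_validation(self, trio_cohort):
        with pytest.raises(ValidationError):
            simcohort.add_family(trio_cohort, "Yakut_0000", "Yakut_0000", 1, seed=1)
        with pytest.raises(ValidationError):
            simcohort.add_family(trio_cohort, "nobody", "Yakut_0001", 1, seed=1)
        with pytest.raises(ValidationError):  # father must be male
            simcohort.add_family(trio_cohort, "Yakut_0001", "Yakut_0003", 1, seed=1)


class TestPlatforms:
    def test_zero_error_platform_is_truth(self, small_cohort):
        cohort = small_cohort
        simcohort.genotype_on_platform(cohort, "clean", 0.0, 0.0, seed=5)
        assert np.array_equal(cohort.genotypes_by_platform["clean"].calls, cohort.truth.calls)

    def test_error_rate_half_flips_half(self, components_small, small_manifest):
        pops = simcohort.default_populations(components_small)
        cohort = simcohort.simulate_individuals(
            components_small, pops[:2], n_per_pop=20, seed=51, manifest=small_manifest
        )
        simcohort.genotype_on_platform(cohort, "noisy", error_rate=0.5, missing_rate=0.0, seed=52)
        plat = cohort.genotypes_by_platform["noisy"]
        obs = (cohort.truth.calls != MISSING)
        diff = (plat.calls != cohort.truth.calls) & obs
        rate = diff.sum() / obs.sum()
        n = obs.sum()
        assert abs(rate - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_all_missing_platform(self, small_cohort):
        cohort = small_cohort
        simcohort.genotype_on_platform(cohort, "void", 0.0, 1.0, seed=6)
        assert np.all(cohort.genotypes_by_platform["void"].calls == MISSING)

    def test_platform_determinism(self, small_cohort):
        a = simcohort.genotype_on_platform(small_cohort, "d1", 0.01, 0.01, seed=77)
        b = simcohort.genotype_on_platform(small_cohort, "d2", 0.01, 0.01, seed=77)
        assert np.array_equal(
            a.genotypes_by_platform["d1"].calls, b.genotypes_by_platform["d2"].calls
        )


class TestSwaps:
    def test_swap_is_involution(self, small_cohort):
        cohort = small_cohort
        before = cohort.genotypes_by_platform["alpha"].calls.copy()
        a, b = cohort.sample_ids[0], cohort.sample_ids[5]
        simcohort.plant_swap(cohort, "alpha", a, b)
        assert cohort.planted_swaps == [("alpha", a, b)]
        assert not np.array_equal(cohort.genotypes_by_platform["alpha"].calls, before)
        simcohort.plant_swap(cohort, "alpha", a, b)
        assert np.array_equal(cohort.genotypes_by_platform["alpha"].calls, before)
        assert cohort.planted_swaps == []

    def test_self_swap_rejected(self, small_cohort):
        with pytest.raises(ValidationError):
            simcohort.plant_swap(small_cohort, "alpha", "Yakut_0000", "Yakut_0000")
        with pytest.raises(ValidationError):
            simcohort.plant_swap(small_cohort, "nope", "Yakut_0000", "Yakut_0001")
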