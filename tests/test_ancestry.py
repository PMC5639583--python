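"""Supervised admixture EM (parameter recovery, likelihood monotonicity,
grid-search oracles), geographic placement, and convex decomposition."""

import numpy as np
import pytest

from arrayqc import ancestry, simcohort
from arrayqc.ancestry import (
    AdmixtureVector,
    ReferencePanel,
    admixture_subset_stability,
    gps_place,
    loo_accuracy,
    project_admixture,
    readmix_decompose,
    readmix_residual,
)
from arrayqc.simcohort import ReferencePopulation, ValidationError


@pytest.fixture(scope="module")
def panel9():
    comps = simcohort.simulate_frequencies(
        2000, simcohort.default_components(fst=0.15), seed=101
    )
    pops = simcohort.default_populations(comps)
    return ReferencePanel.from_components(comps, pops)


def _genotypes_for(q, freqs, rng):
    p = np.asarray(q) @ freqs
    return rng.binomial(2, p).astype(float)


def grid_search_1simplex(g, f, n_grid=2001):
    """Exhaustive likelihood maximization over a K=2 simplex grid."""
    best_q, best_ll = None, -np.inf
    for t in np.linspace(0, 1, n_grid):
        q = np.array([t, 1 - t])
        pa = np.clip(q @ f, 1e-12, 1 - 1e-12)
        ll = np.sum(g * np.log(pa) + (2 - g) * np.log1p(-pa))
        if ll > best_ll:
            best_ll, best_q = ll, q
    return best_q


class TestProjectAdmixture:
    def test_pure_component_recovery(self, panel9, rng):
        """An individual genotyped from a single component projects >= 0.95
        onto it (2000 AIMs, Fst 0.15)."""
        k = len(panel9.components)
        for j in (0, 4, 8):
            g = _genotypes_for(np.eye(k)[j], panel9.component_freqs, rng)
            q = project_admixture(g, panel9).proportions
            assert q[j] >= 0.95

    def test_even_mixture_matches_grid_oracle(self, rng):
        """A 50/50 two-component mix recovers (0.5, 0.5) within 0.05 and
        agrees with an exhaustive 1-simplex grid search."""
        comps = simcohort.simulate_frequencies(
            2000, simcohort.default_components(k=2, fst=0.15), seed=103
        )
        pops = simcohort.default_populations(comps)
        panel = ReferencePanel.from_components(comps, pops)
        g = _genotypes_for([0.5, 0.5], panel.component_freqs, rng)
        q = project_admixture(g, panel).proportions
        oracle = grid_search_1simplex(g, panel.component_freqs)
        assert q == pytest.approx([0.5, 0.5], abs=0.05)
        assert q == pytest.approx(oracle, abs=2e-3)

    def test_single_component_panel(self, rng):
        comps = simcohort.simulate_frequencies(
            300, [simcohort.AncestralComponent("only", 0.1)], seed=104
        )
        panel = ReferencePanel.from_components(
            comps, [ReferencePopulation("p", np.array([1.0]), 0, 0, "r")]
        )
        g = _genotypes_for([1.0], panel.component_freqs, rng)
        q = project_admixture(g, panel)
        assert q.proportions.tolist() == [1.0]
        assert np.isfinite(q.loglik)

    def test_too_few_markers_undetermined(self, panel9):
        g = np.full(2000, -1.0)
        g[:50] = 1.0
        q = project_admixture(g, panel9)
        assert np.isnan(q.proportions).all()
        assert q.n_markers_used == 50

    def test_em_loglik_monotone(self, panel9, rng):
        """EM never decreases the log-likelihood, from random starts."""
        for _ in range(10):
            q0 = rng.dirichlet(np.ones(9))
            g = _genotypes_for(rng.dirichlet(np.ones(9)), panel9.component_freqs, rng)
            trace = ancestry.em_loglik_trace(g, panel9, n_iter=40, q0=q0)
            assert np.all(np.diff(trace) >= -1e-8)

    def test_missing_markers_skipped(self, panel9, rng):
        g = _genotypes_for(np.eye(9)[1], panel9.component_freqs, rng)
        g[::3] = -1
        q = project_admixture(g, panel9)
        assert q.n_markers_used == int((g >= 0).sum())
        assert q.proportions[1] >= 0.9


class TestSubsetStability:
    def test_full_subset_is_identical(self, panel9, rng):
        g = _genotypes_for(np.eye(9)[0], panel9.component_freqs, rng)
        with pytest.raises(ValidationError):
            admixture_subset_stability(g, panel9, subset_size=2000)

    def test_large_subsets_converge_to_full(self, panel9, rng):
        """Near-full subsets reproduce the full-panel vector closely; small
        subsets scatter more (projection noise scales with 1/sqrt(markers))."""
        g = _genotypes_for(np.eye(9)[2], panel9.component_freqs, rng)
        near_full = admixture_subset_stability(g, panel9, subset_size=1900, n_repeats=5, seed=5)
        small = admixture_subset_stability(g, panel9, subset_size=300, n_repeats=5, seed=5)
        assert near_full <= 0.05
        assert near_full < small

    def test_deterministic_given_seed(self, panel9, rng):
        g = _genotypes_for(np.eye(9)[4], panel9.component_freqs, rng)
        w1 = admixture_subset_stability(g, panel9, subset_size=500, n_repeats=3, seed=9)
        w2 = admixture_subset_stability(g, panel9, subset_size=500, n_repeats=3, seed=9)
        assert w1 == w2


class TestGpsPlace:
    def test_zero_distance_returns_exact_coords(self, panel9):
        pop = panel9.populations[3]
        q = AdmixtureVector(list(panel9.components), pop.mean_admixture.copy(), 0.0, 2000)
        lat, lon, nearest = gps_place(q, panel9)
        assert (lat, lon, nearest) == (pop.latitude, pop.longitude, pop.name)

    def test_equidistant_pair_spherical_midpoint(self):
        """Equidistant between two references at the same latitude: the
        prediction is the great-circle midpoint (closed-form oracle)."""
        mu_a, mu_b = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        pops = [
            ReferencePopulation("A", mu_a, 40.0, 10.0, "r"),
            ReferencePopulation("B", mu_b, 40.0, 50.0, "r"),
        ]
        panel = ReferencePanel(["c1", "c2"], np.full((2, 150), 0.5), [f"m{i}" for i in range(150)], pops)
        q = AdmixtureVector(["c1", "c2"], np.array([0.5, 0.5]), 0.0, 150)
        lat, lon, _ = gps_place(q, panel, n_neighbors=2)

        def unit(la, lo):
            la, lo = np.radians([la, lo])
            return np.array([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)])

        v = unit(40, 10) + unit(40, 50)
        v /= np.linalg.norm(v)
        assert lat == pytest.approx(np.degrees(np.arcsin(v[2])), abs=1e-9)
        assert lon == pytest.approx(30.0, abs=1e-9)
        assert lat > 40.0  # great-circle midpoint bulges poleward

    def test_rotation_consistency(self, panel9):
        """Shifting every panel longitude by delta shifts predictions by
        delta (mod 360)."""
        q = AdmixtureVector(
            list(panel9.components),
            0.6 * panel9.populations[1].mean_admixture + 0.4 * panel9.populations[7].mean_admixture,
            0.0,
            2000,
        )
        lat0, lon0, _ = gps_place(q, panel9)
        delta = 73.0
        shifted = ReferencePanel(
            list(panel9.components),
            panel9.component_freqs,
            list(panel9.marker_ids),
            [
                ReferencePopulation(
                    p.name, p.mean_admixture, p.latitude,
                    ((p.longitude + delta + 180) % 360) - 180, p.region
                )
                for p in panel9.populations
            ],
        )
        lat1, lon1, _ = gps_place(q, shifted)
        assert lat1 == pytest.approx(lat0, abs=1e-9)
        assert (lon1 - lon0) % 360 == pytest.approx(delta, abs=1e-9)

    def test_empty_panel_rejected(self, panel9):
        empty = ReferencePanel(list(panel9.components), panel9.component_freqs, list(panel9.marker_ids), [])
        q = AdmixtureVector(list(panel9.components), np.full(9, 1 / 9), 0.0, 2000)
        with pytest.raises(ValidationError):
            gps_place(q, empty)


class TestLooAccuracy:
    def test_well_separated_populations_recovered(self, panel9, rng):
        """With 9 well-separated populations, leave-one-out placement
        recovers the truth population for nearly every sample."""
        samples, truth = {}, {}
        for pop in panel9.populations:
            for i in range(6):
                sid = f"{pop.name}_{i}"
                samples[sid] = _genotypes_for(pop.mean_admixture, panel9.component_freqs, rng)
                truth[sid] = pop.name
        acc = loo_accuracy(samples, truth, panel9, level="population")
        assert acc["accuracy"].mean() >= 0.95

    def test_single_population_panel_rejected(self, panel9):
        solo = ReferencePanel(
            list(panel9.components), panel9.component_freqs, list(panel9.marker_ids),
            panel9.populations[:1],
        )
        with pytest.raises(ValidationError):
            loo_accuracy({}, {}, solo)


class TestReadmix:
    def test_exact_population_gets_weight_one(self, panel9):
        pop = panel9.populations[5]
        q = AdmixtureVector(list(panel9.components), pop.mean_admixture.copy(), 0.0, 2000)
        w = readmix_decompose(q, panel9)
        assert w == {pop.name: 1.0}

    def test_even_mix_matches_grid_oracle(self, panel9):
        """q = 0.5 mu_A + 0.5 mu_B decomposes to (0.5, 0.5) and matches an
        exhaustive two-population simplex grid search within 1e-4."""
        a, b = panel9.populations[0], panel9.populations[8]
        q_vec = 0.5 * a.mean_admixture + 0.5 * b.mean_admixture
        q = AdmixtureVector(list(panel9.components), q_vec, 0.0, 2000)
        w = readmix_decompose(q, panel9)
        assert set(w) == {a.name, b.name}
        assert w[a.name] == pytest.approx(0.5, abs=1e-6)
        # independent oracle: grid over weight on population A among (A, B)
        ts = np.linspace(0, 1, 100001)
        residuals = [
            np.linalg.norm(q_vec - (t * a.mean_admixture + (1 - t) * b.mean_admixture))
            for t in ts
        ]
        assert w[a.name] == pytest.approx(ts[int(np.argmin(residuals))], abs=1e-4)

    def test_residual_never_worse_than_best_single(self, panel9, rng):
        for _ in range(5):
            q_vec = rng.dirichlet(np.ones(9))
            q = AdmixtureVector(list(panel9.components), q_vec, 0.0, 2000)
            w = readmix_decompose(q, panel9, prune_threshold=0.0)
            multi = readmix_residual(w, q, panel9)
            best_single = min(
                np.linalg.norm(q_vec - p.mean_admixture) for p in panel9.populations
            )
            assert multi <= best_single + 1e-9

    def test_unmixed_cohort_single_assignment(self, panel9, rng):
        """Samples simulated from one population average ~1 assignment."""
        pop = panel9.populations[6]
        counts = []
        for _ in range(10):
            g = _genotypes_for(pop.mean_admixture, panel9.component_freqs, rng)
            q = project_admixture(g, panel9)
            w = readmix_decompose(q, panel9, prune_threshold=0.05)
            counts.append(len(w))
            assert max(w, key=w.get) == pop.name
        assert np.mean(counts) <= 1.5
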