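"""Synthetic-data generator: deme model, trails, families, space, phenotypes."""

import numpy as np
import pandas as pd
import pytest
from conftest import make_genotypes

import popembed as pe
from popembed.genotype_io import MISSING
from popembed.synthdata import (
    THREE_GENERATION_PEDIGREE,
    draw_deme_frequencies,
    estimate_fst,
    genotypes_from_freqs,
    simulate_admixed,
    simulate_demes,
    simulate_family,
    simulate_phenotypes,
    simulate_spatial,
)


class TestSimulateDemes:
    def test_shape_and_labels(self):
        G, table = simulate_demes(pe.DemeConfig(n_pops=3, n_per_pop=10, L=50, seed=0))
        assert G.calls.shape == (30, 50)
        assert np.array_equal(table["pop_label"], np.repeat([0, 1, 2], 10))
        assert set(np.unique(G.calls)) <= {0, 1, 2}

    def test_seed_reproducibility_bit_identical(self):
        a, _ = simulate_demes(pe.DemeConfig(n_pops=2, n_per_pop=15, L=100, seed=9))
        b, _ = simulate_demes(pe.DemeConfig(n_pops=2, n_per_pop=15, L=100, seed=9))
        assert np.array_equal(a.calls, b.calls)

    def test_f_of_one_rejected(self):
        with pytest.raises(ValueError):
            pe.DemeConfig(fst=1.0)

    @pytest.mark.parametrize("F", [0.0, 0.01, 0.05, 0.1])
    def test_realized_fst_matches_configured(self, F):
        """Hudson F_ST over 5,000 variants lands within +-0.01 of F (the
        Balding-Nichols F targets exactly this estimand)."""
        G, table = simulate_demes(
            pe.DemeConfig(n_pops=2, fst=F, n_per_pop=100, L=5000, seed=17)
        )
        fhat = estimate_fst(G, table["pop_label"].to_numpy())
        assert fhat == pytest.approx(F, abs=0.01)


class TestSimulateAdmixed:
    def test_theta_boundaries_reproduce_parental_distributions(self):
        ones = np.ones(30)
        zeros = np.zeros(30)
        G = simulate_admixed(ones, zeros, np.array([1.0, 0.0]), seed=0)
        assert np.array_equal(G.calls[0], np.full(30, 2))  # pure A, p_a = 1
        assert np.array_equal(G.calls[1], np.zeros(30))  # pure B, p_b = 0

    def test_mean_allele_count_tracks_mixture(self):
        rng = np.random.default_rng(5)
        pa = rng.uniform(0.1, 0.9, 3000)
        pb = rng.uniform(0.1, 0.9, 3000)
        theta = 0.3
        G = simulate_admixed(pa, pb, np.full(200, theta), seed=5)
        expected = 2 * (theta * pa + (1 - theta) * pb)
        assert np.mean(G.calls.mean(axis=0) - expected) == pytest.approx(0, abs=0.01)

    def test_errors(self):
        with pytest.raises(ValueError):
            simulate_admixed(np.ones(5), np.ones(4), np.array([0.5]))
        with pytest.raises(ValueError):
            simulate_admixed(np.ones(5), np.ones(5), np.array([1.5]))


class TestSimulateFamily:
    def test_forced_transmission_at_fixed_frequencies(self):
        for p, expected in [(0.0, 0), (1.0, 2)]:
            G, ped = simulate_family(np.full(40, p), pe.FamilyConfig(), seed=1)
            offspring = G.calls[(ped["role"] == "offspring").to_numpy()]
            assert (offspring == expected).all()

    def test_no_mendelian_violations(self):
        rng = np.random.default_rng(11)
        freqs = rng.uniform(0.05, 0.95, 2000)
        G, ped = simulate_family(
            freqs, pe.FamilyConfig(founders=4, offspring_per_mating=3), seed=11
        )
        idx = {s: i for i, s in enumerate(ped["sample_id"])}
        for _, row in ped[ped["role"] == "offspring"].iterrows():
            child = G.calls[idx[row["sample_id"]]]
            for parent in (row["parent1"], row["parent2"]):
                pg = G.calls[idx[parent]]
                assert not ((child == 0) & (pg == 2)).any()
                assert not ((child == 2) & (pg == 0)).any()

    def test_parent_offspring_correlation_near_half(self):
        """Centering by the population frequency, parent-child genotype
        correlation across 5,000 variants is ~0.5 (kinship expectation)."""
        freqs = np.random.default_rng(1300).uniform(0.05, 0.95, 5000)
        G, ped = simulate_family(
            freqs, pe.FamilyConfig(founders=2, offspring_per_mating=1), seed=13
        )
        centred = (G.calls - 2 * freqs) / np.sqrt(2 * freqs * (1 - freqs))
        r = np.corrcoef(centred[0], centred[2])[0, 1]  # parent F0 vs child
        assert r == pytest.approx(0.5, abs=0.05)

    def test_three_generation_pedigree_roles(self):
        G, ped = simulate_family(
            np.full(10, 0.5), seed=2, pedigree=THREE_GENERATION_PEDIGREE
        )
        assert list(ped["sample_id"]) == [p[0] for p in THREE_GENERATION_PEDIGREE]
        assert (ped["role"] == "founder").sum() == 3

    def test_malformed_pedigrees_rejected(self):
        freqs = np.full(10, 0.5)
        with pytest.raises(ValueError):
            simulate_family(freqs, pedigree=(("a", None, None), ("b", "a", None)))
        with pytest.raises(ValueError):
            simulate_family(freqs, pedigree=(("a", "ghost", "ghost2"),))
        with pytest.raises(ValueError):
            simulate_family(freqs, pedigree=(("a", None, None), ("a", None, None)))
        with pytest.raises(ValueError):
            pe.FamilyConfig(founders=3)


class TestSimulateSpatial:
    def test_sample_count_and_coordinates(self):
        cfg = pe.SpatialConfig(grid=3, n_per_cell=4)
        G, table = simulate_spatial(cfg, L=30, seed=0)
        assert G.n_samples == 9 * 4
        assert len(table) == 36
        assert table["northing_km"].nunique() == 3

    def test_infinite_smoothness_gives_homogeneous_cells(self):
        """As correlation length -> inf all cells share one frequency surface,
        so between-cell differentiation vanishes."""
        cfg = pe.SpatialConfig(grid=2, smoothness=1e6, n_per_cell=40)
        G, table = simulate_spatial(cfg, L=2000, seed=3)
        cells = table["cell"].to_numpy()
        sub = np.isin(cells, [0, 3])
        fst = estimate_fst(G.calls[sub], cells[sub])
        assert abs(fst) <= 0.01

    def test_adjacent_cells_more_similar_than_opposite_corners(self):
        cfg = pe.SpatialConfig(grid=4, smoothness=1.5, n_per_cell=8)
        G, table = simulate_spatial(cfg, L=400, seed=4)
        cells = table["cell"].to_numpy()

        def sharing(c1, c2):
            A, B = G.calls[cells == c1], G.calls[cells == c2]
            diffs = np.abs(A[:, None, :] - B[None, :, :]).mean()
            return 1.0 - diffs / 2.0

        grid = cfg.grid
        adjacent = np.mean([sharing(c, c + 1) for c in (0, 5, 10)])
        corners = np.mean([sharing(0, grid * grid - 1), sharing(grid - 1, grid * grid - grid)])
        assert adjacent > corners

    def test_config_validation(self):
        with pytest.raises(ValueError):
            pe.SpatialConfig(grid=1)


class TestSimulatePhenotypes:
    def _table(self, n_per_group=50):
        return pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(2 * n_per_group)],
                "pop_label": np.repeat(["a", "b"], n_per_group),
            }
        )

    def test_near_zero_noise_recovers_group_means(self):
        cfg = pe.PhenoConfig(group_means={"a": 1.0, "b": 3.0}, noise_sd=1e-12, seed=0)
        out = simulate_phenotypes(self._table(), cfg)
        for g, mu in [("a", 1.0), ("b", 3.0)]:
            assert np.allclose(out.loc[out.pop_label == g, "phenotype"], mu, atol=1e-9)

    def test_unknown_group_rejected(self):
        cfg = pe.PhenoConfig(group_means={"a": 0.0}, seed=0)
        with pytest.raises(ValueError):
            simulate_phenotypes(self._table(), cfg)

    def test_age_effect_removed_by_residualization(self):
        cfg = pe.PhenoConfig(
            group_means={"a": 0.0, "b": 0.0},
            covariate_effects=(0.5, 0.0, 0.0, 0.0),
            noise_sd=0.1,
            seed=1,
        )
        out = simulate_phenotypes(self._table(200), cfg)
        resid = pe.ols_residualize(
            out["phenotype"].to_numpy(), out["age"].to_numpy()[:, None]
        )
        assert abs(np.corrcoef(resid, out["age"])[0, 1]) < 1e-10

    def test_reproducible(self):
        cfg = pe.PhenoConfig(group_means={"a": 0, "b": 1}, seed=5)
        a = simulate_phenotypes(self._table(), cfg)["phenotype"]
        b = simulate_phenotypes(self._table(), cfg)["phenotype"]
        assert np.array_equal(a, b)


class TestEstimateFst:
    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(21)
        freqs = rng.uniform(0.2, 0.8, 4000)
        calls = genotypes_from_freqs(freqs, 200, rng)
        labels = np.repeat([0, 1], 100)
        assert estimate_fst(calls, labels) == pytest.approx(0.0, abs=0.01)

    def test_fixed_difference_is_one(self):
        calls = np.vstack([np.full((10, 50), 2), np.zeros((10, 50), dtype=int)])
        assert estimate_fst(calls, np.repeat([0, 1], 10)) == pytest.approx(1.0)

    def test_matches_per_variant_hand_computation(self):
        """Three hand-set variants, ratio of averages computed longhand."""
        pop1 = np.array([[0, 1, 2], [1, 1, 2], [0, 2, 2], [1, 0, 2]])
        pop2 = np.array([[2, 0, 0], [2, 1, 0], [1, 0, 0], [2, 1, 0]])
        calls = np.vstack([pop1, pop2])
        labels = np.repeat([0, 1], 4)
        nums, dens = [], []
        for j in range(3):
            p1 = pop1[:, j].sum() / 8.0
            p2 = pop2[:, j].sum() / 8.0
            n1 = n2 = 8
            nums.append((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1))
            dens.append(p1 * (1 - p2) + p2 * (1 - p1))
        expected = np.mean(nums) / np.mean(dens)
        assert estimate_fst(calls, labels) == pytest.approx(expected, abs=1e-12)

    def test_errors(self):
        calls = np.zeros((4, 5), dtype=int)
        with pytest.raises(ValueError):
            estimate_fst(calls, np.array([0, 1, 2, 2]))
        with pytest.raises(ValueError):
            estimate_fst(calls, np.array([0, 1, 1, 1]))

    def test_missing_calls_ignored(self):
        rng = np.random.default_rng(23)
        G, table = simulate_demes(pe.DemeConfig(n_pops=2, fst=0.05, n_per_pop=80, L=3000, seed=23))
        calls = G.calls.copy().astype(np.int8)
        full = estimate_fst(calls, table["pop_label"].to_numpy())
        calls[rng.random(calls.shape) < 0.02] = MISSING
        sparse = estimate_fst(make_genotypes(calls), table["pop_label"].to_numpy())
        assert sparse == pytest.approx(full, abs=0.01)
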