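"""Synthetic flora generator: determinism, structure, geography, extinctions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from floradiv.diversity import Assemblage, fric
from floradiv.gower import gower_matrix, make_embeddable
from floradiv.ordination import pcoa
from floradiv.synthdata import (ExtinctionScenario, SyntheticFlora,
                                SyntheticFloraConfig, apply_extinction,
                                default_trait_dictionary, simulate_geography,
                                simulate_trait_matrix, template_dictionary)
from floradiv.traits import (drop_invariant_traits, impute_genus_means,
                             standardize_and_transform, summarize_missingness)

from .conftest import MASTER_SEED


SMALL = dict(n_na_angiosperms=20, n_eu_angiosperms=12, n_na_gymnosperms=5,
             n_eu_gymnosperms=4, n_shared_gymnosperms=1)


def embed(matrix):
    sub, _ = drop_invariant_traits(matrix)
    return pcoa(make_embeddable(gower_matrix(standardize_and_transform(sub))))


class TestTraitGenerator:
    def test_default_dictionary_has_study_composition(self):
        counts = pd.Series([t.data_type for t in default_trait_dictionary()]).value_counts()
        assert counts.to_dict() == {"ordinal": 9, "continuous": 7, "nominal": 4,
                                    "binary": 4, "multichoice": 2}
        assert len(default_trait_dictionary()) == 26

    def test_template_dictionary_counts(self):
        d = template_dictionary(3, 2, 1, 2, 1)
        assert len(d) == 9

    def test_zero_missing_rate_gives_complete_matrix(self):
        m = simulate_trait_matrix(SyntheticFloraConfig(seed=1, missing_rate=0.0, **SMALL))
        assert summarize_missingness(m)["fraction_missing"] == 0.0

    def test_missing_fraction_within_binomial_interval(self):
        m = simulate_trait_matrix(SyntheticFloraConfig(seed=MASTER_SEED))
        n_cells = m.shape[0] * m.shape[1]
        lo, hi = stats.binom.interval(0.99, n_cells, 0.14)
        assert lo <= m.missing_mask().to_numpy().sum() <= hi

    def test_same_seed_is_bit_reproducible(self):
        a = simulate_trait_matrix(SyntheticFloraConfig(seed=7, **SMALL))
        b = simulate_trait_matrix(SyntheticFloraConfig(seed=7, **SMALL))
        assert a.cells.equals(b.cells)
        assert a.species_meta.equals(b.species_meta)
        c = simulate_trait_matrix(SyntheticFloraConfig(seed=8, **SMALL))
        assert not a.cells.equals(c.cells)

    def test_generated_matrix_passes_validators(self):
        m = simulate_trait_matrix(SyntheticFloraConfig(seed=2, **SMALL))
        m.validate()  # must not raise
        gower_matrix(standardize_and_transform(drop_invariant_traits(m)[0]))

    def test_species_pool_counts_and_shared_species(self):
        m = simulate_trait_matrix(SyntheticFloraConfig(seed=3))
        meta = m.species_meta
        assert len(meta) == 221
        gym = meta[meta["clade"] == "gymnosperm"]
        assert len(gym.index[gym["continent"].isin(["NA", "both"])]) == 29
        assert len(gym.index[gym["continent"].isin(["EU", "both"])]) == 11

    def test_gymnosperm_invariant_traits_are_the_designed_four(self):
        m = simulate_trait_matrix(SyntheticFloraConfig(seed=4))
        mi = impute_genus_means(m)
        sub, dropped = drop_invariant_traits(mi.subset_clade("gymnosperm"))
        assert sorted(dropped) == ["l.composition", "n.fix", "porosity", "tracheids"]
        assert sub.shape[1] == 22
        ang, dropped_ang = drop_invariant_traits(mi.subset_clade("angiosperm"))
        assert dropped_ang == [] and ang.shape[1] == 26

    def test_genus_mean_imputation_reaches_target_missingness(self):
        m = simulate_trait_matrix(SyntheticFloraConfig(seed=MASTER_SEED))
        after = summarize_missingness(impute_genus_means(m))["fraction_missing"]
        assert after == pytest.approx(0.06, abs=0.015)

    def test_genus_clustered_missingness_mode(self):
        m = simulate_trait_matrix(SyntheticFloraConfig(
            seed=5, missing_pattern="genus", **SMALL))
        frac = summarize_missingness(m)["fraction_missing"]
        assert 0.05 < frac < 0.30


class TestGeography:
    def test_same_seed_identical_rasters(self):
        cfg = SyntheticFloraConfig(seed=9, **SMALL)
        r1, c1, e1, m1 = simulate_geography(cfg)
        r2, c2, e2, m2 = simulate_geography(cfg)
        assert np.array_equal(c1, c2) and np.array_equal(e1, e2) and np.array_equal(m1, m2)
        assert all(r1[s].equals(r2[s]) for s in r1)

    def test_first_two_climate_axes_dominate(self):
        from floradiv.geospatial import climate_pca_regions
        cfg = SyntheticFloraConfig(seed=10, **SMALL)
        flora = SyntheticFlora(cfg)
        _, climate, _, mask = flora.geography()
        rm = climate_pca_regions(climate, cfg.grid, mask, k=4)
        assert rm.method["first2_variance"] >= 0.80

    def test_range_cell_counts_match_analytic_expectation(self):
        cfg = SyntheticFloraConfig(seed=MASTER_SEED, climate_trait_corr=0.0)
        flora = SyntheticFlora(cfg)
        ranges, _, _, _ = flora.geography()
        from floradiv.geospatial import rasterize_range
        counts = [rasterize_range(g, cfg.grid).sum() for g in ranges.values()]
        # analytic oracle: E[cells] = E[min(w, W)] * E[min(h, H)] / res^2 for
        # single-rectangle ranges; shared species have two rectangles
        rng = np.random.default_rng(0)
        draws = np.exp(rng.normal(np.log(cfg.range_width_mean), cfg.range_width_sd,
                                  size=200_000))
        cont_w = (cfg.grid.east - cfg.grid.west) / 2
        cont_h = cfg.grid.north - cfg.grid.south
        e_w = np.minimum(draws, cont_w).mean()
        e_h = np.minimum(draws, cont_h).mean()
        n_shared = (flora.species_meta["continent"] == "both").sum()
        n_single = len(flora.species_meta) - n_shared
        expected = (e_w * e_h / cfg.grid.resolution ** 2) * (
            (n_single + 2 * n_shared) / (n_single + n_shared))
        assert np.mean(counts) == pytest.approx(expected, rel=0.10)

    def test_elevation_crosses_cutoff_and_mask_is_band(self):
        cfg = SyntheticFloraConfig(seed=11, **SMALL)
        _, _, elev, mask = simulate_geography(cfg)
        assert (elev > 1000).any() and (elev <= 1000).any()
        rows_in = mask.any(axis=1)
        assert rows_in.sum() < cfg.grid.nrow  # band excludes extreme latitudes


class TestExtinction:
    def _complete_pool(self, seed=MASTER_SEED, n=30):
        cfg = SyntheticFloraConfig(seed=seed, missing_rate=0.0,
                                   n_na_angiosperms=n, n_eu_angiosperms=n,
                                   n_na_gymnosperms=2, n_eu_gymnosperms=2,
                                   n_shared_gymnosperms=0)
        return SyntheticFlora(cfg).trait_matrix().subset_clade("angiosperm")

    def test_zero_fraction_is_identity(self):
        m = self._complete_pool()
        out = apply_extinction(m, ExtinctionScenario("random", 0.0, seed=1))
        assert out.cells.equals(m.cells)

    def test_directed_removal_shrinks_trait_range_and_fric(self):
        m = self._complete_pool()
        out = apply_extinction(m, ExtinctionScenario("directed", 1 / 3, trait="height"))
        vals = pd.to_numeric(m.cells["height"], errors="coerce")
        surv = pd.to_numeric(out.cells["height"], errors="coerce")
        assert surv.max() < vals.max()
        assert surv.min() == vals.min()
        p = embed(m)
        full, _ = fric(Assemblage(id="f", members=tuple(m.species)), p, axes=2)
        less, _ = fric(Assemblage(id="l", members=tuple(out.species)), p, axes=2)
        assert less < full

    def test_direction_low_removes_bottom_tail(self):
        m = self._complete_pool()
        out = apply_extinction(m, ExtinctionScenario("directed", 1 / 3,
                                                     trait="height", direction="low"))
        vals = pd.to_numeric(m.cells["height"], errors="coerce")
        surv = pd.to_numeric(out.cells["height"], errors="coerce")
        assert surv.min() > vals.min() and surv.max() == vals.max()

    def test_random_is_seeded_and_keeps_fraction(self):
        m = self._complete_pool()
        a = apply_extinction(m, ExtinctionScenario("random", 0.5, seed=42))
        b = apply_extinction(m, ExtinctionScenario("random", 0.5, seed=42))
        assert a.species == b.species
        assert len(a.species) == len(m.species) - round(0.5 * len(m.species))

    def test_directed_exceeds_random_fric_loss_in_expectation(self):
        """Paired simulation: trait-directed loss trims the hull more."""
        wins = 0
        n_rep = 60
        for rep in range(n_rep):
            m = self._complete_pool(seed=50_000 + rep, n=20)
            p = embed(m)
            full, _ = fric(Assemblage(id="f", members=tuple(m.species)), p, axes=2)
            d = apply_extinction(m, ExtinctionScenario("directed", 1 / 3, trait="height"))
            r = apply_extinction(m, ExtinctionScenario("random", 1 / 3, seed=rep))
            fd_, _ = fric(Assemblage(id="d", members=tuple(d.species)), p, axes=2)
            fr_, _ = fric(Assemblage(id="r", members=tuple(r.species)), p, axes=2)
            wins += (full - fd_) > (full - fr_)
        assert wins >= 0.8 * n_rep

    def test_infeasible_scenarios_rejected(self):
        m = self._complete_pool(n=3)
        with pytest.raises(ValueError, match="fewer than 3"):
            apply_extinction(m, ExtinctionScenario("random", 0.9, seed=0))
        with pytest.raises(ValueError):
            ExtinctionScenario("directed", 0.5)  # no directing trait
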