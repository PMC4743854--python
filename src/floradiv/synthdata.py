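"""Synthetic floras: traits, ranges, climate, elevation, and extinctions.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised without compiled trait databases or
digitised range maps:

* a 26-trait dictionary of tree functional traits (7 continuous, 4 binary,
  9 ordinal, 4 nominal, 2 multichoice) with realistic names, units and
  levels;
* genus-structured species pools of two clades (angiosperms, gymnosperms) on
  two continents (``EU``, ``NA``), with an optional species shared between
  both (continent ``both``);
* trait values driven by a small number of latent strategy axes (two by
  default — an acquisitive-conservative axis and an overstorey-understorey
  axis) through per-trait loadings, thresholded into levels for categorical
  traits; four categorical traits are held constant within gymnosperms so
  the clade-wise invariant-trait filter has work to do;
* missing cells completely at random at a configurable rate (default 14%);
* contiguous rectangular toy ranges on a lon/lat grid, smooth climate layers
  built from two latent gradients (so a PCA concentrates variance on two
  axes), a smooth elevation surface crossing 1000 m, and a temperate
  latitude-band mask;
* random and trait-directed extinction scenarios acting on the species pool.

All outputs are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import box
from shapely.ops import unary_union

from .geospatial import GridSpec
from .traits import (MISSING, PROV_AGGREGATED, PROV_MISSING, TraitDefinition,
                     TraitMatrix)

__all__ = [
    "SyntheticFloraConfig",
    "ExtinctionScenario",
    "SyntheticFlora",
    "default_trait_dictionary",
    "template_dictionary",
    "simulate_trait_matrix",
    "simulate_geography",
    "apply_extinction",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# trait dictionaries
# ---------------------------------------------------------------------------

def default_trait_dictionary() -> list[TraitDefinition]:
    """The 26-trait tree functional trait dictionary used by default.

    Seven continuous traits (with declared variance-stabilising transforms),
    four binary, nine ordinal, four nominal and two multichoice traits
    covering leaf, whole-plant, wood/root and regeneration characteristics.
    """
    C, O, N, B, M = "continuous", "ordinal", "nominal", "binary", "multichoice"
    return [
        # leaf traits
        TraitDefinition("l.area", C, unit="mm^2", transform="log"),
        TraitDefinition("l.arrange", N, levels=("alternate", "whorled", "opposite",
                                                "spirally", "short.shoot", "other")),
        TraitDefinition("leaf.cn", C, unit="mg*g^-1"),
        TraitDefinition("l.composition", B),            # 0 simple, 1 composite
        TraitDefinition("leaf.mar", O, levels=(0, 1, 2, 3)),
        TraitDefinition("l.type", N, levels=("evgr.needle", "evgr.scale", "evgr.broad",
                                             "decid.broad", "decid.needle")),
        TraitDefinition("sla", C, unit="cm^2*g^-1", transform="sqrt"),
        # plant-level traits
        TraitDefinition("fire.res", B),
        TraitDefinition("growth.form", N, levels=("tree", "shrub", "tree.shrub")),
        TraitDefinition("growth.rate", O, levels=(1, 2, 3)),
        TraitDefinition("life.span", C, unit="a", transform="log"),
        TraitDefinition("height", C, unit="m", transform="sqrt"),
        TraitDefinition("n.fix", B),
        TraitDefinition("allelo", O, levels=(0, 1)),
        TraitDefinition("resp.dist", O, levels=(0, 1)),
        TraitDefinition("resp.fire", O, levels=(0, 1, 2, 3)),
        TraitDefinition("tox", O, levels=(0, 1, 2, 3)),
        # root and wood traits
        TraitDefinition("tracheids", B),
        TraitDefinition("bark.surf", O, levels=(1, 2, 3, 4, 5)),
        TraitDefinition("porosity", M, levels=("ring", "semi.ring", "diffuse")),
        TraitDefinition("root.habit", N, levels=("tap", "shallow", "variable")),
        TraitDefinition("wood.dens", C, unit="kg*m^-3"),
        # reproduction traits
        TraitDefinition("dispersal", M, levels=("animal", "wind", "gravity", "water")),
        TraitDefinition("seed.mass", C, unit="mg", transform="log"),
        TraitDefinition("seed.spread", O, levels=(1, 2, 3)),
        TraitDefinition("veg.spread", O, levels=(1, 2, 3)),
    ]


#: Categorical traits held constant within gymnosperms by the generator
#: (wood porosity, leaf compoundness, tracheid presence, nitrogen fixation).
GYMNOSPERM_CONSTANT = {
    "porosity": frozenset({"diffuse"}),
    "l.composition": 0,
    "tracheids": 1,
    "n.fix": 0,
}


def template_dictionary(n_continuous: int = 7, n_binary: int = 4, n_ordinal: int = 9,
                        n_nominal: int = 4, n_multichoice: int = 2
                        ) -> list[TraitDefinition]:
    """Generic unnamed dictionary with the given count per data type."""
    out: list[TraitDefinition] = []
    for i in range(n_continuous):
        out.append(TraitDefinition(f"cont{i + 1}", "continuous", unit="1",
                                   transform=("none", "log", "sqrt")[i % 3]))
    for i in range(n_binary):
        out.append(TraitDefinition(f"bin{i + 1}", "binary"))
    for i in range(n_ordinal):
        out.append(TraitDefinition(f"ord{i + 1}", "ordinal", levels=tuple(range(4))))
    for i in range(n_nominal):
        out.append(TraitDefinition(f"nom{i + 1}", "nominal", levels=("a", "b", "c")))
    for i in range(n_multichoice):
        out.append(TraitDefinition(f"mc{i + 1}", "multichoice", levels=("u", "v", "w", "x")))
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticFloraConfig:
    """Study-shaped defaults for the synthetic flora.

    Species counts mirror the two-continent tree floras the pipeline is built
    for: 126 North American and 56 European angiosperms, 28 and 10
    gymnosperms plus one gymnosperm shared between the continents, so the
    per-continent gymnosperm subsets count 29 and 11 species.  The missing
    rate is 14%; genus structure (mean genus size ~4 species with a small
    fraction of monotypic genera) is such that genus-mean imputation of
    quantitative traits brings missingness down to about 6%.
    """

    n_na_angiosperms: int = 126
    n_eu_angiosperms: int = 56
    n_na_gymnosperms: int = 28
    n_eu_gymnosperms: int = 10
    n_shared_gymnosperms: int = 1
    n_shared_angiosperms: int = 0

    mean_genus_size: float = 4.0
    singleton_genus_fraction: float = 0.08

    dictionary: tuple[TraitDefinition, ...] | None = None  # default: 26 named traits
    n_latent: int = 2
    genus_signal: float = 0.6        # sd share of the genus effect on latent axes
    trait_noise: float = 0.5         # per-trait noise sd around the latent projection
    clade_offset: float = 1.5        # gymnosperm shift on the last latent axis
    continent_shift: float = 0.0     # EU-vs-NA mean shift on latent axis 1 (null: 0)
    continent_dispersion_ratio: float = 1.0  # EU latent spread / NA latent spread
    missing_rate: float = 0.14
    missing_pattern: str = "mcar"    # or "genus" for genus-clustered gaps

    # geography
    grid: GridSpec = GridSpec(west=0.0, south=40.0, east=12.0, north=52.0,
                              resolution=0.25)
    range_width_mean: float = 3.0    # degrees, lognormal median of range extent
    range_width_sd: float = 0.4      # lognormal sigma of range extent
    climate_noise: float = 0.3       # layer noise sd around the two gradients
    n_climate_layers: int = 19
    elevation_peak: float = 1600.0   # m, ridge maximum (cutoff at 1000 m bites)
    temperate_band: float = 0.8      # central latitude fraction kept temperate
    climate_trait_corr: float = 0.5  # pull of latent axis 1 on range latitude

    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing rate must be in [0, 1)")
        for name in ("n_na_angiosperms", "n_eu_angiosperms",
                     "n_na_gymnosperms", "n_eu_gymnosperms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.missing_pattern not in ("mcar", "genus"):
            raise ValueError("missing_pattern must be 'mcar' or 'genus'")

    def trait_dictionary(self) -> list[TraitDefinition]:
        d = list(self.dictionary) if self.dictionary else default_trait_dictionary()
        for t in d:
            if t.data_type in ("ordinal", "nominal", "multichoice") and len(t.levels) < 2:
                raise ValueError(f"trait {t.name!r}: fewer than 2 levels is infeasible")
        return d


@dataclass(frozen=True)
class ExtinctionScenario:
    """Random or trait-directed loss of a fraction of the species pool."""

    mode: str                       # "random" | "directed"
    fraction: float
    trait: str | None = None        # directing trait (directed mode)
    direction: str = "high"         # remove "high" or "low" quantile tail
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in ("random", "directed"):
            raise ValueError("mode must be 'random' or 'directed'")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must be in [0, 1]")
        if self.mode == "directed" and not self.trait:
            raise ValueError("directed extinction needs a directing trait")
        if self.direction not in ("high", "low"):
            raise ValueError("direction must be 'high' or 'low'")


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

class SyntheticFlora:
    """Deterministic generator of one synthetic flora from a config.

    Species identities, genus assignments and latent strategy scores are
    fixed by the config seed, so the trait matrix and the geography built
    from the same config are mutually consistent (ranges can track latent
    axis 1 via ``climate_trait_corr``).
    """

    def __init__(self, config: SyntheticFloraConfig):
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        (self._seed_pools, self._seed_traits,
         self._seed_missing, self._seed_geo) = ss.spawn(4)
        self.dictionary = config.trait_dictionary()
        self.species_meta = self._build_pools()
        self.latent = self._draw_latents()

    # -- species pools ---------------------------------------------------
    def _build_pools(self) -> pd.DataFrame:
        cfg = self.config
        rng = np.random.default_rng(self._seed_pools)
        rows = []
        specs = [
            ("angiosperm", "NA", cfg.n_na_angiosperms),
            ("angiosperm", "EU", cfg.n_eu_angiosperms),
            ("angiosperm", "both", cfg.n_shared_angiosperms),
            ("gymnosperm", "NA", cfg.n_na_gymnosperms),
            ("gymnosperm", "EU", cfg.n_eu_gymnosperms),
            ("gymnosperm", "both", cfg.n_shared_gymnosperms),
        ]
        counters = {"angiosperm": 0, "gymnosperm": 0}
        for clade, continent, n in specs:
            for _ in range(n):
                counters[clade] += 1
                rows.append({"species": f"{clade[:3]}_{counters[clade]:03d}",
                             "clade": clade, "continent": continent})
        meta = pd.DataFrame(rows).set_index("species")
        meta["genus"] = ""
        for clade in ("angiosperm", "gymnosperm"):
            idx = list(meta.index[meta["clade"] == clade])
            rng.shuffle(idx)
            n = len(idx)
            n_single = int(round(cfg.singleton_genus_fraction * n))
            n_multi_genera = max(1, int(np.ceil((n - n_single) / cfg.mean_genus_size)))
            genus_names = [f"{clade[:1].upper()}gen{i + 1}" for i in range(n_single + n_multi_genera)]
            for i, sp in enumerate(idx[:n_single]):
                meta.at[sp, "genus"] = genus_names[i]
            for j, sp in enumerate(idx[n_single:]):
                meta.at[sp, "genus"] = genus_names[n_single + j % n_multi_genera]
        return meta

    # -- latent strategy axes --------------------------------------------
    def _draw_latents(self) -> pd.DataFrame:
        cfg = self.config
        rng = np.random.default_rng(self._seed_traits)
        n = len(self.species_meta)
        L = cfg.n_latent
        tau = cfg.genus_signal
        genus_codes, genus_idx = pd.factorize(self.species_meta["genus"])
        genus_eff = rng.normal(0.0, tau, size=(len(genus_idx), L))
        indiv = rng.normal(0.0, np.sqrt(max(1.0 - tau ** 2, 1e-9)), size=(n, L))
        z = genus_eff[genus_codes] + indiv
        is_eu = (self.species_meta["continent"] == "EU").to_numpy()
        is_gym = (self.species_meta["clade"] == "gymnosperm").to_numpy()
        if cfg.continent_dispersion_ratio != 1.0:
            z[is_eu] *= cfg.continent_dispersion_ratio
        z[is_eu, 0] += cfg.continent_shift
        z[is_gym, L - 1] += cfg.clade_offset
        return pd.DataFrame(z, index=self.species_meta.index,
                            columns=[f"latent{i + 1}" for i in range(L)])

    # -- trait matrix -----------------------------------------------------
    def trait_matrix(self) -> TraitMatrix:
        cfg = self.config
        rng = np.random.default_rng(self._seed_traits.spawn(1)[0])
        z = self.latent.to_numpy()
        n, L = z.shape
        sigma = cfg.trait_noise
        marg_sd = np.sqrt(1.0 + sigma ** 2)   # sd of w.z + noise with unit loading

        cells = pd.DataFrame(MISSING, index=self.species_meta.index,
                             columns=[t.name for t in self.dictionary], dtype=object)
        is_gym = (self.species_meta["clade"] == "gymnosperm").to_numpy()

        def latent_score() -> np.ndarray:
            w = rng.normal(size=L)
            w /= np.linalg.norm(w)
            return z @ w + rng.normal(0.0, sigma, size=n)

        for tdef in self.dictionary:
            if tdef.data_type == "continuous":
                s = latent_score() / marg_sd
                if tdef.transform == "log":
                    vals = np.exp(3.0 + 1.2 * s)
                elif tdef.transform == "sqrt":
                    vals = (4.0 + s) ** 2
                else:
                    vals = 100.0 + 25.0 * s
                cells[tdef.name] = [float(v) for v in vals]
            elif tdef.data_type == "binary":
                s = latent_score()
                cells[tdef.name] = [int(v) for v in (s > np.median(s))]
            elif tdef.data_type == "ordinal":
                # empirical-quantile cuts keep level occupancy balanced in the pool
                s = latent_score()
                k = len(tdef.levels)
                cuts = np.quantile(s, np.arange(1, k) / k)
                idx = np.searchsorted(cuts, s)
                cells[tdef.name] = [float(tdef.levels[i]) for i in idx]
            elif tdef.data_type == "nominal":
                scores = np.column_stack([latent_score() for _ in tdef.levels])
                idx = scores.argmax(axis=1)
                cells[tdef.name] = [tdef.levels[i] for i in idx]
            else:  # multichoice
                scores = np.column_stack([latent_score() for _ in tdef.levels])
                thresh = marg_sd * stats.norm.ppf(0.6)    # ~40% inclusion per level
                memb = scores > thresh
                out = []
                for i in range(n):
                    levels = [lv for lv, m in zip(tdef.levels, memb[i]) if m]
                    if not levels:
                        levels = [tdef.levels[scores[i].argmax()]]
                    out.append(frozenset(levels))
                cells[tdef.name] = out
            if is_gym.any() and tdef.name in GYMNOSPERM_CONSTANT:
                const = GYMNOSPERM_CONSTANT[tdef.name]
                col = cells[tdef.name].copy()
                col[is_gym] = [const] * int(is_gym.sum())
                cells[tdef.name] = col

        # missingness
        rng_m = np.random.default_rng(self._seed_missing)
        if cfg.missing_rate > 0:
            if cfg.missing_pattern == "mcar":
                mask = rng_m.random(cells.shape) < cfg.missing_rate
            else:  # genus-clustered: whole genus more or less gappy
                genus_codes, genus_idx = pd.factorize(self.species_meta["genus"])
                genus_rate = rng_m.beta(2.0, 2.0 / cfg.missing_rate - 2.0,
                                        size=len(genus_idx))
                mask = rng_m.random(cells.shape) < genus_rate[genus_codes][:, None]
            cells = cells.mask(pd.DataFrame(mask, index=cells.index,
                                            columns=cells.columns), MISSING)

        self._ensure_within_clade_variation(cells, rng_m)
        prov = pd.DataFrame(np.where(cells.isna(), PROV_MISSING, PROV_AGGREGATED),
                            index=cells.index, columns=cells.columns)
        return TraitMatrix(self.species_meta, self.dictionary, cells, prov)

    def _ensure_within_clade_variation(self, cells: pd.DataFrame,
                                       rng: np.random.Generator) -> None:
        """Guarantee every non-designated trait varies within each clade.

        The study structure the generator emulates has exactly four traits
        constant within gymnosperms and none within angiosperms; thresholding
        a shifted clade into few levels can accidentally produce more.  Where
        a categorical trait's observed values are constant within a clade,
        two observed species are deterministically reassigned to a
        neighbouring level (or, for multichoice, given one extra level).
        """
        from .traits import is_missing
        for clade in ("angiosperm", "gymnosperm"):
            rows = self.species_meta.index[self.species_meta["clade"] == clade]
            if len(rows) < 3:
                continue
            for tdef in self.dictionary:
                if clade == "gymnosperm" and tdef.name in GYMNOSPERM_CONSTANT:
                    continue
                if tdef.data_type == "continuous":
                    continue
                col = cells.loc[rows, tdef.name]
                observed = col[~col.isna()]
                if tdef.data_type == "multichoice":
                    distinct = {frozenset(v) for v in observed}
                else:
                    distinct = set(observed)
                if len(distinct) > 1 or observed.empty:
                    continue
                targets = rng.choice(observed.index, size=min(2, len(observed)),
                                     replace=False)
                current = observed.iloc[0]
                if tdef.data_type == "multichoice":
                    missing_levels = [lv for lv in tdef.levels if lv not in current]
                    if missing_levels:
                        new = frozenset(current) | {missing_levels[0]}
                    else:  # constant at the full level set: drop the last level
                        ordered = sorted(current, key=list(tdef.levels).index)
                        new = frozenset(ordered[:-1])
                elif tdef.data_type == "nominal":
                    new = next(lv for lv in tdef.levels if lv != current)
                else:  # binary / ordinal
                    lv_vals = ([0, 1] if tdef.data_type == "binary"
                               else [float(l) for l in tdef.levels])
                    new = next(lv for lv in lv_vals if lv != current)
                for sp in targets:
                    cells.at[sp, tdef.name] = new

    # -- geography ---------------------------------------------------------
    def continent_bounds(self) -> dict[str, tuple[float, float, float, float]]:
        g = self.config.grid
        mid = g.west + (g.east - g.west) / 2.0
        return {"EU": (g.west, g.south, mid, g.north),
                "NA": (mid, g.south, g.east, g.north)}

    def continent_raster(self) -> np.ndarray:
        g = self.config.grid
        lon, _ = g.cell_centers()
        mid = g.west + (g.east - g.west) / 2.0
        return np.where(lon < mid, "EU", "NA")

    def geography(self):
        """(ranges, climate stack, elevation, temperate mask) on the config grid.

        Ranges are per-species rectangles inside the species' continent (one
        rectangle per continent for shared species), with log-normal extents
        and centre latitudes optionally pulled along latent axis 1
        (``climate_trait_corr``).  Climate layers mix a north-south and an
        east-west gradient with layer noise; elevation is a smooth two-ridge
        surface; the temperate mask keeps a central latitude band.
        """
        cfg = self.config
        g = cfg.grid
        rng = np.random.default_rng(self._seed_geo)
        lon, lat = g.cell_centers()

        # climate: two latent gradients + correlated noise; the second gradient
        # (oceanic-continental) runs within each continent so climate regions
        # straddle both continents like the real temperate zone
        g1 = (lat - lat.mean()) / lat.std()
        mid = g.west + (g.east - g.west) / 2.0
        east_west = np.where(lon < mid, (lon - g.west) / (mid - g.west),
                             (lon - mid) / (g.east - mid))
        g2 = (east_west - east_west.mean()) / east_west.std()
        layers = np.empty((cfg.n_climate_layers,) + g.shape)
        for i in range(cfg.n_climate_layers):
            a, b = rng.normal(size=2)
            norm = np.hypot(a, b)
            a, b = a / norm, b / norm
            layers[i] = a * g1 + b * g2 + rng.normal(0.0, cfg.climate_noise, size=g.shape)

        # elevation: one ridge per continent crossing the 1000 m cutoff
        elev = np.full(g.shape, 150.0)
        for west, south, east, north in self.continent_bounds().values():
            cx = west + 0.7 * (east - west)
            cy = south + 0.45 * (north - south)
            r2 = ((lon - cx) ** 2 + (lat - cy) ** 2) / ((east - west) * 0.18) ** 2
            elev = elev + cfg.elevation_peak * np.exp(-r2)

        # temperate mask: central latitude band
        half = cfg.temperate_band / 2.0
        mid_lat = (g.north + g.south) / 2.0
        span = g.north - g.south
        mask = np.abs(lat - mid_lat) <= half * span

        # ranges
        bounds = self.continent_bounds()
        lat_pull = cfg.climate_trait_corr
        z1 = self.latent["latent1"]
        z1_rank = z1.rank(pct=True)
        ranges: dict[str, object] = {}
        for sp, row in self.species_meta.iterrows():
            conts = ["EU", "NA"] if row["continent"] == "both" else [row["continent"]]
            parts = []
            for cont in conts:
                west, south, east, north = bounds[cont]
                w = min(np.exp(rng.normal(np.log(cfg.range_width_mean), cfg.range_width_sd)),
                        east - west)
                h = min(np.exp(rng.normal(np.log(cfg.range_width_mean), cfg.range_width_sd)),
                        north - south)
                cx = rng.uniform(west + w / 2, east - w / 2) if east - west > w else (west + east) / 2
                lat_target = south + h / 2 + float(z1_rank[sp]) * (north - south - h)
                cy_rand = rng.uniform(south + h / 2, north - h / 2) if north - south > h else (south + north) / 2
                cy = lat_pull * lat_target + (1 - lat_pull) * cy_rand
                parts.append(box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2))
            ranges[sp] = unary_union(parts) if len(parts) > 1 else parts[0]
        return ranges, layers, elev, mask


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def simulate_trait_matrix(config: SyntheticFloraConfig) -> TraitMatrix:
    """Genus-structured latent-factor trait matrix; see :class:`SyntheticFlora`."""
    return SyntheticFlora(config).trait_matrix()


def simulate_geography(config: SyntheticFloraConfig):
    """Toy ranges, 19 climate layers, elevation, and temperate mask."""
    return SyntheticFlora(config).geography()


def apply_extinction(matrix: TraitMatrix, scenario: ExtinctionScenario) -> TraitMatrix:
    """Remove species from the pool under a random or directed scenario.

    Random mode keeps a uniform sample of ``1 - fraction`` of the pool.
    Directed mode removes the species beyond the ``1 - fraction`` (or below
    the ``fraction``, for direction ``low``) quantile of the directing
    quantitative trait — the environmental-filter analogue that trims the
    fringe of the trait cloud.  Species missing the directing trait are
    retained (they cannot be ranked).
    """
    species = list(matrix.species_meta.index)
    n = len(species)
    n_remove = int(round(scenario.fraction * n))
    if scenario.mode == "random":
        rng = np.random.default_rng(scenario.seed)
        doomed = set(rng.choice(species, size=n_remove, replace=False)) if n_remove else set()
    else:
        vals = pd.to_numeric(matrix.cells[scenario.trait], errors="coerce").dropna()
        if vals.empty:
            raise ValueError(f"directing trait {scenario.trait!r} missing for all species")
        ordered = vals.sort_values(ascending=(scenario.direction == "low"))
        doomed = set(ordered.index[:n_remove])
    survivors = [s for s in species if s not in doomed]
    if len(survivors) < 3:
        raise ValueError("extinction scenario leaves fewer than 3 species")
    return matrix.subset_species(survivors)
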