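"""End-to-end orchestration of the two-continent functional diversity study.

For each clade (angiosperms, gymnosperms) the pipeline:

1. subsets the trait matrix, drops traits invariant within the clade,
   imputes genus means, applies declared transforms and standardises;
2. computes the Gower dissimilarity (square-root embedded by default) and
   its principal-coordinate representation;
3. summarises FDis/FRic for the continental pools and the climatic
   sub-regions, and the per-grid-cell richness-versus-FDis profile;
4. runs the dispersion-homogeneity permutation test and perMANOVA between
   continents, pooled and within each region, into a compact results table;
5. fits trait vectors for biplots and per-continent kernel densities of
   trait-space occupation.

Species present on both continents (continent label ``both``) are included
in each continent's group; for the permutation tests this is realised by
duplicating their dissimilarity rows under per-continent aliases so group
labels stay a partition.

All randomness is derived from one seed; a run manifest (seed, config hash,
library versions) is written alongside the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .diversity import Assemblage, default_fric_axes, fd_profile, profile_frame
from .geospatial import (OccurrenceGrid, RegionMask, apply_elevation_mask,
                         build_cooccurrence, climate_pca_regions, gridcell_fd,
                         rasterize_range)
from .gower import DissimilarityMatrix, check_embeddable, gower_matrix, make_embeddable
from .inference import PermutationScheme, dispersion_test, permanova, results_table
from .ordination import fit_trait_vectors, kde2d, pcoa
from .synthdata import SyntheticFlora, SyntheticFloraConfig
from .traits import (TraitMatrix, drop_invariant_traits, impute_genus_means,
                     read_trait_table, standardize_and_transform,
                     summarize_missingness)

log = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_analysis", "clade_preparation", "continent_groups"]


@dataclass(frozen=True)
class AnalysisConfig:
    """What to analyse and how.

    Either ``synthetic`` or the explicit input paths must be provided.
    ``scales`` selects which summaries are produced; clade analyses always
    run independently of each other.
    """

    synthetic: SyntheticFloraConfig | None = None
    trait_table: str | None = None
    trait_dictionary: str | None = None

    clades: tuple[str, ...] = ("angiosperm", "gymnosperm")
    scales: tuple[str, ...] = ("pooled", "region", "grid")
    n_perm: int = 999
    seed: int = 0
    gower_sqrt: bool = True
    bias_adjust: bool = True
    fric_axes: int | None = None
    elevation_cutoff: float = 1000.0
    region_k: int = 4
    region_split_rule: str = "quadrant"
    min_region_group: int = 2      # smallest continent group testable per region
    outdir: str | None = None
    make_figures: bool = False

    def __post_init__(self):
        if not self.scales:
            raise ValueError("select at least one scale")
        unknown = set(self.scales) - {"pooled", "region", "grid"}
        if unknown:
            raise ValueError(f"unknown scales {sorted(unknown)}")
        if self.synthetic is None and not (self.trait_table and self.trait_dictionary):
            raise ValueError("provide a synthetic config or trait table + dictionary paths")

    def content_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            return repr(obj)
        payload = json.dumps(enc(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def clade_preparation(matrix: TraitMatrix, clade: str, gower_sqrt: bool = True):
    """Clade subset -> impute -> drop invariants -> standardise -> Gower -> PCoA.

    Returns (prepared matrix, dropped trait names, dissimilarity, ordination).
    """
    sub = matrix.subset_clade(clade)
    sub = impute_genus_means(sub)
    sub, dropped = drop_invariant_traits(sub)
    std = standardize_and_transform(sub)
    d_raw = gower_matrix(std)
    d = make_embeddable(d_raw) if gower_sqrt else check_embeddable(d_raw)
    return std, dropped, d, pcoa(d)


def continent_groups(matrix: TraitMatrix) -> dict[str, list[str]]:
    """Per-continent member lists; ``both`` species appear in each."""
    return {c: matrix.continent_members(c) for c in ("EU", "NA")}


def _aliased_test_inputs(d: DissimilarityMatrix, groups: dict[str, list[str]]):
    """Duplicate shared species per continent so group labels partition.

    Returns a DissimilarityMatrix over alias labels and the matching label
    series; returns None when any group is smaller than 2.
    """
    idx, labels, glab = [], [], []
    pos = {l: i for i, l in enumerate(d.labels)}
    seen: dict[str, int] = {}
    for cont, members in groups.items():
        members = [m for m in members if m in pos]
        if len(members) < 2:
            return None
        for m in members:
            seen[m] = seen.get(m, 0) + 1
            idx.append(pos[m])
            labels.append(m if seen[m] == 1 else f"{m}@{cont}")
            glab.append(cont)
    sub = DissimilarityMatrix(labels, d.values[np.ix_(idx, idx)],
                              sqrt_transformed=d.sqrt_transformed)
    return sub, pd.Series(glab, index=labels)


def _run_tests(d: DissimilarityMatrix, groups: dict[str, list[str]],
               scheme: PermutationScheme, bias_adjust: bool):
    prepared = _aliased_test_inputs(d, groups)
    if prepared is None:
        return None
    sub, glab = prepared
    disp = dispersion_test(sub, glab, scheme=scheme, bias_adjust=bias_adjust)
    perm = permanova(sub, glab, scheme=scheme)
    return disp, perm


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------

def run_analysis(config: AnalysisConfig) -> dict:
    """Execute the configured analysis; return (and optionally write) a bundle.

    The bundle maps each clade to its prepared inputs and results and carries
    a ``table2`` frame with one dispersion row and one perMANOVA row per
    clade x {pooled, region 1..k}, the grid-scale profile, trait-vector fits,
    KDE surfaces, and a manifest.
    """
    rng_root = np.random.SeedSequence(config.seed)
    seeds = {name: s for name, s in zip(
        ("tests", "vectors", "regions"), rng_root.spawn(3))}

    # ---- inputs --------------------------------------------------------
    flora = None
    if config.synthetic is not None:
        flora = SyntheticFlora(config.synthetic)
        matrix = flora.trait_matrix()
    else:
        matrix = read_trait_table(config.trait_table, config.trait_dictionary)

    missing_before = summarize_missingness(matrix)["fraction_missing"]

    spatial = None
    if {"region", "grid"} & set(config.scales):
        if flora is None:
            log.warning("region/grid scales need synthetic geography; skipping them")
        else:
            ranges, climate, elevation, temperate = flora.geography()
            grid = flora.config.grid
            kept = apply_elevation_mask(grid, elevation, cutoff=config.elevation_cutoff)
            kept &= temperate
            regions = climate_pca_regions(
                climate, grid, temperate & kept, k=config.region_k,
                split_rule=config.region_split_rule,
                seed=int(seeds["regions"].generate_state(1)[0] % (2 ** 31)))
            rasterized = {sp: rasterize_range(geom, grid) for sp, geom in ranges.items()}
            occ = build_cooccurrence(rasterized, grid, kept, elevation=elevation,
                                     continent=flora.continent_raster(), regions=regions)
            spatial = {"occurrence": occ, "regions": regions,
                       "climate_variance_first2": regions.method["first2_variance"]}

    results: dict = {"clades": {}, "missing_before": missing_before,
                     "spatial": spatial}
    table_rows = []

    for clade in config.clades:
        std, dropped, d, p = clade_preparation(matrix, clade, config.gower_sqrt)
        groups = continent_groups(std)
        clade_res: dict = {
            "matrix": std, "dropped_traits": dropped, "dissimilarity": d,
            "pcoa": p, "n_traits_used": std.shape[1],
            "missing_after_imputation": summarize_missingness(std)["fraction_missing"],
            "groups": {k: len(v) for k, v in groups.items()},
        }

        scheme = PermutationScheme(
            n_perm=config.n_perm,
            seed=int(seeds["tests"].generate_state(1)[0] % (2 ** 31)))

        # pooled-scale tests and FD
        if "pooled" in config.scales:
            tests = _run_tests(d, groups, scheme, config.bias_adjust)
            if tests:
                disp, perm = tests
                clade_res["dispersion_pooled"] = disp
                clade_res["permanova_pooled"] = perm
                table_rows.append({
                    "class": clade, "region": "pooled", "df": disp.df_between,
                    "F": disp.F, "p_dispersion": disp.p_value,
                    "pseudo_F": perm.pseudo_F, "p_permanova": perm.p_value})
            pool = Assemblage(id=f"{clade}:pool", members=tuple(std.species))
            assembl = [Assemblage(id=f"{clade}:{c}", members=tuple(m))
                       for c, m in groups.items()]
            axes = config.fric_axes or default_fric_axes(
                min(a.richness for a in assembl), p.n_real_axes)
            clade_res["fd_pooled"] = fd_profile(assembl + [pool], p, axes=axes,
                                                reference_pool=pool)

        # regional scale
        if spatial is not None and "region" in config.scales:
            occ: OccurrenceGrid = spatial["occurrence"]
            clade_species = [s for s in occ.presence.columns if s in d.labels]
            region_ids = sorted(set(occ.cell_meta["region"]) - {0})
            clade_res["regions"] = {}
            for rid in region_ids:
                cells = occ.cell_meta.index[occ.cell_meta["region"] == rid]
                present = occ.presence.loc[cells, clade_species].any(axis=0)
                members = list(present.index[present])
                rgroups = {c: [m for m in groups[c] if m in members]
                           for c in ("EU", "NA")}
                if min(len(v) for v in rgroups.values()) < config.min_region_group:
                    log.info("region %s: group too small for %s, skipped", rid, clade)
                    continue
                reg_members = sorted(set(rgroups["EU"]) | set(rgroups["NA"]))
                d_reg = d.submatrix(reg_members)
                tests = _run_tests(d_reg, rgroups, scheme, config.bias_adjust)
                if tests is None:
                    continue
                disp, perm = tests
                clade_res["regions"][rid] = {"dispersion": disp, "permanova": perm}
                table_rows.append({
                    "class": clade, "region": f"region{rid}", "df": disp.df_between,
                    "F": disp.F, "p_dispersion": disp.p_value,
                    "pseudo_F": perm.pseudo_F, "p_permanova": perm.p_value})

        # grid scale
        if spatial is not None and "grid" in config.scales:
            occ = spatial["occurrence"]
            clade_species = [s for s in occ.presence.columns if s in d.labels]
            clade_res["grid_profile"] = gridcell_fd(occ, p, species=clade_species)

        # interpretation layers
        vec_seed = int(seeds["vectors"].generate_state(1)[0] % (2 ** 31))
        clade_res["trait_vectors"] = fit_trait_vectors(
            p, std, axes=2, n_perm=config.n_perm, seed=vec_seed)
        if p.n_real_axes >= 2:
            memberships = {c: groups[c] for c in ("EU", "NA")}
            clade_res["kde"] = kde2d(p, memberships)
        results["clades"][clade] = clade_res

    results["table2"] = results_table(table_rows)
    results["manifest"] = {
        "seed": config.seed, "config_hash": config.content_hash(),
        "floradiv_version": __version__,
        "numpy_version": np.__version__, "pandas_version": pd.__version__,
    }

    if config.outdir:
        _write_bundle(results, config)
    return results


# ---------------------------------------------------------------------------
# output writing
# ---------------------------------------------------------------------------

def _write_bundle(results: dict, config: AnalysisConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results["table2"].to_csv(out / "table2.tsv", sep="\t", index=False)
    for clade, res in results["clades"].items():
        if "fd_pooled" in res:
            profile_frame(res["fd_pooled"]).to_csv(out / f"fd_{clade}.tsv", sep="\t")
        if "grid_profile" in res:
            res["grid_profile"].to_csv(out / f"grid_profile_{clade}.tsv", sep="\t")
        p = res["pcoa"]
        coords = pd.DataFrame(p.coordinates, index=p.labels,
                              columns=[f"axis{i + 1}" for i in range(p.n_real_axes)])
        coords.to_csv(out / f"pcoa_{clade}.tsv", sep="\t")
        vec = pd.DataFrame(
            [{"trait": f.trait, "p_value": f.p_value, "n": f.n,
              **{f"axis{i + 1}": l for i, l in enumerate(f.loadings)}}
             for f in res["trait_vectors"]])
        vec.to_csv(out / f"trait_vectors_{clade}.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(results["manifest"], indent=2))
    if config.make_figures:
        _write_figures(results, out)


def _write_figures(results: dict, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for clade, res in results["clades"].items():
        p = res["pcoa"]
        if p.n_real_axes < 2:
            continue
        groups = res["matrix"].species_meta["continent"]
        fig, ax = plt.subplots(figsize=(6, 5))
        for cont, color in (("EU", "tab:blue"), ("NA", "tab:orange"), ("both", "tab:green")):
            sel = (groups == cont).to_numpy()
            if sel.any():
                ax.scatter(p.coordinates[sel, 0], p.coordinates[sel, 1],
                           s=14, label=cont, color=color, alpha=0.8)
        for f in res["trait_vectors"]:
            ax.annotate(f.trait, xy=(0, 0),
                        xytext=(f.loadings[0], f.loadings[1] if len(f.loadings) > 1 else 0.0),
                        arrowprops=dict(arrowstyle="<-", color="grey", lw=0.8),
                        fontsize=7)
        ax.set_xlabel(f"PCoA 1 ({res['pcoa'].variance_explained[0]:.0%})")
        ax.set_ylabel(f"PCoA 2 ({res['pcoa'].variance_explained[1]:.0%})")
        ax.legend()
        ax.set_title(f"{clade}: trait space")
        fig.tight_layout()
        fig.savefig(out / f"biplot_{clade}.png", dpi=150)
        plt.close(fig)

        if "kde" in res and res["kde"]:
            fig, axes_ = plt.subplots(1, len(res["kde"]), figsize=(5 * len(res["kde"]), 4),
                                      squeeze=False)
            for axp, surf in zip(axes_[0], res["kde"]):
                axp.contourf(surf.x, surf.y, surf.density, levels=12, cmap="viridis")
                axp.set_title(f"{clade} {surf.group} (n={surf.n})")
            fig.tight_layout()
            fig.savefig(out / f"kde_{clade}.png", dpi=150)
            plt.close(fig)

        if "grid_profile" in res and len(res["grid_profile"]):
            gp = res["grid_profile"]
            fig, ax = plt.subplots(figsize=(6, 4))
            for cont, color in (("EU", "tab:blue"), ("NA", "tab:orange")):
                sel = gp["continent"] == cont
                ax.scatter(gp.loc[sel, "richness"], gp.loc[sel, "fdis"],
                           s=6, alpha=0.4, label=cont, color=color)
            ax.set_xlabel("grid-cell species richness")
            ax.set_ylabel("grid-cell FDis")
            ax.legend()
            fig.tight_layout()
            fig.savefig(out / f"richness_fdis_{clade}.png", dpi=150)
            plt.close(fig)
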