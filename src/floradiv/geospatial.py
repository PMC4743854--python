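"""Grid-cell assemblages from range maps, masks, and climate regions.

Rasters are plain numpy arrays tied to a :class:`GridSpec` — a geographic
(WGS84) lon/lat lattice with cell-center registration, half-open cell
intervals [west, east) x [south, north), and 0-based row-major indexing from
the north-west corner.  Range geometries (shapely polygons) are rasterised by
the center-in-polygon rule; cells above an elevation cutoff are excluded;
climatically similar regions are delineated by a PCA of bioclimatic layers
pooled over both continents, split into quadrants of the first two component
scores; and per-cell functional dispersion is computed for the resulting
assemblages.

Plain-text raster I/O uses the ESRI ASCII grid format.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry
from sklearn.decomposition import PCA

from .diversity import Assemblage, fdis
from .ordination import PCoAResult

__all__ = [
    "GridSpec",
    "OccurrenceGrid",
    "RegionMask",
    "rasterize_range",
    "apply_elevation_mask",
    "climate_pca_regions",
    "build_cooccurrence",
    "gridcell_fd",
    "read_ascii_grid",
    "write_ascii_grid",
]

log = logging.getLogger(__name__)

#: Default grid resolution: 5 arc minutes, in degrees.
FIVE_ARCMIN = 5.0 / 60.0


@dataclass(frozen=True)
class GridSpec:
    """A geographic lon/lat grid: bounds, resolution, center registration."""

    west: float
    south: float
    east: float
    north: float
    resolution: float = FIVE_ARCMIN
    crs: str = "WGS84"

    def __post_init__(self):
        if self.east <= self.west or self.north <= self.south:
            raise ValueError("grid bounds are empty")
        for span in (self.east - self.west, self.north - self.south):
            k = span / self.resolution
            if abs(k - round(k)) > 1e-9:
                raise ValueError("grid bounds must align to resolution multiples")

    @property
    def ncol(self) -> int:
        return int(round((self.east - self.west) / self.resolution))

    @property
    def nrow(self) -> int:
        return int(round((self.north - self.south) / self.resolution))

    @property
    def shape(self) -> tuple[int, int]:
        return self.nrow, self.ncol

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (nrow, ncol); row 0 at the north edge."""
        lon = self.west + (np.arange(self.ncol) + 0.5) * self.resolution
        lat = self.north - (np.arange(self.nrow) + 0.5) * self.resolution
        return np.meshgrid(lon, lat)

    def cell_id(self, row: int, col: int) -> int:
        return row * self.ncol + col


@dataclass
class RegionMask:
    """Per-cell region label in {1..k} (0 outside), with method metadata."""

    grid: GridSpec
    labels: np.ndarray                    # int array, 0 = no region
    method: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.labels.shape != self.grid.shape:
            raise ValueError("region labels do not match grid shape")


@dataclass
class OccurrenceGrid:
    """Presence of species on kept grid cells, with cell metadata.

    ``presence`` is a boolean DataFrame (kept cell id x species);
    ``cell_meta`` is indexed by cell id with lon, lat, elevation, continent
    and region columns.
    """

    grid: GridSpec
    presence: pd.DataFrame
    cell_meta: pd.DataFrame

    def richness(self, species: Sequence[str] | None = None) -> pd.Series:
        sub = self.presence if species is None else self.presence[list(species)]
        return sub.sum(axis=1)

    def species_cells(self, species: str) -> pd.Index:
        return self.presence.index[self.presence[species]]


# ---------------------------------------------------------------------------
# rasterisation and masking
# ---------------------------------------------------------------------------

def rasterize_range(geometry: BaseGeometry | np.ndarray, grid: GridSpec) -> np.ndarray:
    """Boolean presence raster: cell true iff its center lies in the range.

    Accepts a shapely geometry or an already-rasterised boolean array of the
    grid's shape (passed through after validation).  An empty geometry yields
    an all-false raster with a warning.
    """
    if isinstance(geometry, np.ndarray):
        if geometry.shape != grid.shape:
            raise ValueError("presence raster shape does not match grid")
        return geometry.astype(bool)
    if not geometry.is_valid:
        raise ValueError("invalid range geometry")
    if geometry.is_empty:
        warnings.warn("empty range geometry rasterises to no cells", stacklevel=2)
        return np.zeros(grid.shape, dtype=bool)
    lon, lat = grid.cell_centers()
    out = shapely.contains_xy(geometry, lon.ravel(), lat.ravel()).reshape(grid.shape)
    if not out.any() and geometry.area == 0:
        warnings.warn("degenerate (zero-area) geometry missed all cell centers",
                      stacklevel=2)
    return out


def apply_elevation_mask(grid: GridSpec, elevation: np.ndarray,
                         cutoff: float = 1000.0) -> np.ndarray:
    """Kept-flag per cell: elevation <= cutoff (cells exactly at it are kept).

    Cells with missing (NaN) elevation are dropped, with a log entry of the
    count.
    """
    if elevation.shape != grid.shape:
        raise ValueError("elevation raster shape does not match grid")
    missing = np.isnan(elevation)
    if missing.any():
        log.info("dropping %d cells with missing elevation", int(missing.sum()))
    return (~missing) & (elevation <= cutoff)


# ---------------------------------------------------------------------------
# climate regions
# ---------------------------------------------------------------------------

def climate_pca_regions(climate: np.ndarray, grid: GridSpec,
                        temperate_mask: np.ndarray, k: int = 4,
                        split_rule: str = "quadrant",
                        seed: int | None = None) -> RegionMask:
    """Delineate climatically similar regions from a PCA of climate layers.

    The cell x layer matrix (cells inside ``temperate_mask``, both continents
    pooled) is standardised and PCA-fitted; cells are assigned to regions
    from their first-two-component scores.  The default ``quadrant`` rule
    labels the four sign-quadrants of (PC1, PC2) about the pooled score
    medians (requires k=4); ``kmeans`` clusters the score pairs into k groups
    with a fixed seed.  Regions exist only inside the mask.
    """
    if climate.ndim != 3 or climate.shape[1:] != grid.shape:
        raise ValueError("climate stack must be (n_layers, nrow, ncol) on the grid")
    if temperate_mask.shape != grid.shape:
        raise ValueError("temperate mask shape does not match grid")
    cells = np.flatnonzero(temperate_mask.ravel())
    if cells.size == 0:
        raise ValueError("temperate mask is empty")
    x = climate.reshape(climate.shape[0], -1).T[cells]          # cells x layers
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    xz = (x - x.mean(axis=0)) / sd
    n_comp = min(xz.shape[0], xz.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(xz)[:, :2]

    labels_flat = np.zeros(grid.nrow * grid.ncol, dtype=int)
    if split_rule == "quadrant":
        if k != 4:
            raise ValueError("quadrant split rule defines exactly 4 regions")
        med = np.median(scores, axis=0)
        quad = (scores[:, 0] >= med[0]).astype(int) * 2 + (scores[:, 1] >= med[1]).astype(int)
        labels_flat[cells] = quad + 1
    elif split_rule == "kmeans":
        from sklearn.cluster import KMeans
        if k > len(np.unique(scores.round(12), axis=0)):
            raise ValueError("k exceeds distinct climate score patterns")
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels_flat[cells] = km.fit_predict(scores) + 1
    else:
        raise ValueError(f"unknown split rule {split_rule!r}")

    return RegionMask(
        grid=grid, labels=labels_flat.reshape(grid.shape),
        method={
            "split_rule": split_rule, "k": k,
            "variance_explained": pca.explained_variance_ratio_.tolist(),
            "first2_variance": float(pca.explained_variance_ratio_[:2].sum()),
            "loadings_pc1": pca.components_[0].tolist(),
            "loadings_pc2": pca.components_[1].tolist() if n_comp > 1 else [],
        })


# ---------------------------------------------------------------------------
# co-occurrence assembly
# ---------------------------------------------------------------------------

def build_cooccurrence(rasterized: Mapping[str, np.ndarray], grid: GridSpec,
                       kept: np.ndarray,
                       elevation: np.ndarray | None = None,
                       continent: np.ndarray | None = None,
                       regions: RegionMask | None = None) -> OccurrenceGrid:
    """Assemble the cell x species presence matrix on kept cells.

    ``rasterized`` maps species name to a boolean presence raster;
    ``kept`` is the boolean keep-flag raster (e.g. elevation and land masks
    combined).  Species with no kept cell stay in the matrix as all-false
    columns, with a log entry.  Optional elevation / continent-label /
    region rasters populate the cell metadata.
    """
    if kept.shape != grid.shape:
        raise ValueError("kept mask shape does not match grid")
    cell_ids = np.flatnonzero(kept.ravel())
    data = {}
    for sp, ras in rasterized.items():
        if ras.shape != grid.shape:
            raise ValueError(f"species {sp!r}: raster shape does not match grid")
        data[sp] = ras.ravel()[cell_ids]
        if not data[sp].any():
            log.info("species %s has no kept cells", sp)
    presence = pd.DataFrame(data, index=cell_ids).astype(bool)

    lon, lat = grid.cell_centers()
    meta = pd.DataFrame(index=cell_ids)
    meta["row"], meta["col"] = np.divmod(cell_ids, grid.ncol)
    meta["lon"] = lon.ravel()[cell_ids]
    meta["lat"] = lat.ravel()[cell_ids]
    meta["elevation"] = elevation.ravel()[cell_ids] if elevation is not None else np.nan
    meta["continent"] = (np.asarray(continent).ravel()[cell_ids]
                         if continent is not None else "")
    meta["region"] = regions.labels.ravel()[cell_ids] if regions is not None else 0
    return OccurrenceGrid(grid=grid, presence=presence, cell_meta=meta)


def gridcell_fd(occ: OccurrenceGrid, p: PCoAResult,
                species: Sequence[str] | None = None,
                min_richness: int = 2) -> pd.DataFrame:
    """Per-cell FDis of resident species (optionally clade-filtered).

    Returns a frame indexed by cell id with richness, fdis, continent and
    region — the grid-scale richness-versus-dispersion profile.  Cells below
    ``min_richness`` are skipped (count logged).
    """
    cols = [s for s in (species if species is not None else occ.presence.columns)
            if s in p.labels]
    sub = occ.presence[cols]
    rich = sub.sum(axis=1)
    skipped = int((rich < min_richness).sum())
    if skipped:
        log.info("skipping %d cells below richness %d", skipped, min_richness)
    rows = []
    arr = sub.to_numpy()
    colnames = np.array(cols)
    for i, cid in enumerate(sub.index):
        if rich.iloc[i] < min_richness:
            continue
        members = tuple(colnames[arr[i]])
        a = Assemblage(id=str(cid), members=members)
        rows.append({
            "cell": cid, "richness": len(members), "fdis": fdis(a, p),
            "continent": occ.cell_meta.at[cid, "continent"],
            "region": occ.cell_meta.at[cid, "region"],
        })
    return pd.DataFrame(rows, columns=["cell", "richness", "fdis", "continent", "region"]
                        ).set_index("cell")


# ---------------------------------------------------------------------------
# plain-text raster I/O (ESRI ASCII grid)
# ---------------------------------------------------------------------------

def write_ascii_grid(values: np.ndarray, grid: GridSpec, path: str | Path,
                     nodata: float = -9999.0) -> None:
    """Write a raster as an ESRI ASCII grid (row 0 = north edge)."""
    if values.shape != grid.shape:
        raise ValueError("raster shape does not match grid")
    vals = np.where(np.isnan(values.astype(float)), nodata, values)
    header = (f"ncols {grid.ncol}\nnrows {grid.nrow}\n"
              f"xllcorner {grid.west}\nyllcorner {grid.south}\n"
              f"cellsize {grid.resolution}\nNODATA_value {nodata}\n")
    body = "\n".join(" ".join(f"{v:.10g}" for v in row) for row in vals)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    lines = Path(path).read_text().splitlines()
    hdr = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
        key, val = lines[i].split()
        hdr[key.lower()] = float(val)
        i += 1
    res = hdr["cellsize"]
    ncol, nrow = int(hdr["ncols"]), int(hdr["nrows"])
    grid = GridSpec(west=hdr["xllcorner"], south=hdr["yllcorner"],
                    east=hdr["xllcorner"] + ncol * res,
                    north=hdr["yllcorner"] + nrow * res, resolution=res)
    vals = np.loadtxt(lines[i:], dtype=float).reshape(nrow, ncol)
    nodata = hdr.get("nodata_value")
    if nodata is not None:
        vals = np.where(vals == nodata, np.nan, vals)
    return vals, grid
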