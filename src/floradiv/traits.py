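"""Mixed-type functional trait matrices: ingestion, aggregation, imputation, filtering.

A trait matrix holds one row per species and one column per trait, where each
trait is declared by a :class:`TraitDefinition` as continuous, binary, ordinal,
nominal, or multichoice (a set of nominal levels, e.g. a dispersal syndrome of
``{animal, wind}``).  Raw observations (:class:`TraitRecord`) are aggregated to
species level — continuous traits by their median (robust against outliers),
ordinal traits by the mean of their level scores, categorical traits by their
mode — and gaps in continuous/ordinal traits may then be filled with genus
means.  Every cell carries a provenance flag (raw / aggregated / imputed).

Missing cells are marked with :data:`MISSING` (``pandas.NA``), a sentinel that
is distinct from every valid level code and number.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MISSING",
    "DATA_TYPES",
    "TraitDefinition",
    "TraitRecord",
    "TraitMatrix",
    "TraitValidationError",
    "aggregate_records",
    "impute_genus_means",
    "drop_invariant_traits",
    "standardize_and_transform",
    "summarize_missingness",
    "read_trait_table",
    "write_trait_table",
    "read_trait_dictionary",
    "write_trait_dictionary",
]

#: Sentinel for missing cells; distinct from any valid level code or number.
MISSING = pd.NA

DATA_TYPES = ("continuous", "binary", "ordinal", "nominal", "multichoice")
TRANSFORMS = ("none", "log", "sqrt")

#: Provenance codes for matrix cells.
PROV_RAW = "raw"
PROV_AGGREGATED = "aggregated"
PROV_IMPUTED = "imputed"
PROV_MISSING = "missing"

#: Delimiter for multichoice level sets in flat-file encodings.
MULTICHOICE_SEP = "|"


class TraitValidationError(ValueError):
    """A trait value violates its declaration; names the offending species/trait."""


def is_missing(value) -> bool:
    """True for the missing sentinel (also accepts None / float NaN)."""
    if value is MISSING or value is None:
        return True
    if isinstance(value, float):
        return np.isnan(value)
    return False


@dataclass(frozen=True)
class TraitDefinition:
    """Declaration of one trait: its data type, unit, levels, and transform.

    ``levels`` is the ordered tuple of allowed level codes for ordinal
    (integers, totally ordered), nominal and multichoice traits; empty for
    continuous and binary.  ``transform`` declares the variance-stabilising
    transform (log or sqrt) applied to continuous traits before
    standardisation.
    """

    name: str
    data_type: str
    unit: str = ""
    levels: tuple = ()
    transform: str = "none"

    def __post_init__(self):
        if self.data_type not in DATA_TYPES:
            raise ValueError(f"unknown data_type {self.data_type!r} for trait {self.name!r}")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r} for trait {self.name!r}")
        object.__setattr__(self, "levels", tuple(self.levels))
        if self.data_type == "ordinal":
            if len(self.levels) < 2 or list(self.levels) != sorted(self.levels):
                raise ValueError(f"ordinal trait {self.name!r} needs >=2 totally ordered levels")
        if self.data_type in ("nominal", "multichoice") and len(self.levels) < 2:
            raise ValueError(f"{self.data_type} trait {self.name!r} needs >=2 levels")

    @property
    def quantitative(self) -> bool:
        """Continuous and ordinal traits are treated as quantitative scores."""
        return self.data_type in ("continuous", "ordinal")

    def validate(self, value, species: str = "?") -> None:
        """Raise :class:`TraitValidationError` if *value* violates this declaration."""
        if is_missing(value):
            return
        tag = f"species {species!r}, trait {self.name!r}"
        if self.data_type == "continuous":
            if not isinstance(value, (int, float, np.integer, np.floating)) or isinstance(value, bool):
                raise TraitValidationError(f"{tag}: expected a number, got {value!r}")
        elif self.data_type == "binary":
            if value not in (0, 1):
                raise TraitValidationError(f"{tag}: binary value must be 0 or 1, got {value!r}")
        elif self.data_type == "ordinal":
            # aggregated scores may fall between levels; raw levels must be declared
            if not isinstance(value, (int, float, np.integer, np.floating)) or isinstance(value, bool):
                raise TraitValidationError(f"{tag}: expected an ordinal score, got {value!r}")
            if not (min(self.levels) <= float(value) <= max(self.levels)):
                raise TraitValidationError(
                    f"{tag}: ordinal score {value!r} outside level range {self.levels}"
                )
        elif self.data_type == "nominal":
            if value not in self.levels:
                raise TraitValidationError(f"{tag}: level {value!r} not in {self.levels}")
        elif self.data_type == "multichoice":
            if not isinstance(value, (set, frozenset)):
                raise TraitValidationError(f"{tag}: expected a level set, got {value!r}")
            if not value:
                raise TraitValidationError(f"{tag}: multichoice level set is empty")
            bad = set(value) - set(self.levels)
            if bad:
                raise TraitValidationError(f"{tag}: unknown levels {sorted(bad)}")


@dataclass(frozen=True)
class TraitRecord:
    """One raw observation of one trait for one species."""

    species: str
    trait: str
    value: object
    source: str = ""


class TraitMatrix:
    """Species x trait values with missingness, genus/clade/continent labels.

    Parameters
    ----------
    species_meta:
        DataFrame indexed by species name with columns ``genus``, ``clade``
        (``angiosperm`` or ``gymnosperm``) and ``continent`` (``EU``, ``NA``
        or ``both`` for species present on both continents).
    traits:
        Sequence of :class:`TraitDefinition`, one per matrix column.
    cells:
        DataFrame (species x trait, object dtype) with :data:`MISSING` gaps.
    provenance:
        DataFrame of the same shape with per-cell provenance codes.
    """

    def __init__(self, species_meta: pd.DataFrame, traits: Sequence[TraitDefinition],
                 cells: pd.DataFrame, provenance: pd.DataFrame | None = None):
        traits = tuple(traits)
        names = [t.name for t in traits]
        if len(set(names)) != len(names):
            raise ValueError("duplicate trait names")
        missing_meta = {"genus", "clade", "continent"} - set(species_meta.columns)
        if missing_meta:
            raise ValueError(f"species metadata lacks columns {sorted(missing_meta)}")
        if species_meta[["genus", "clade", "continent"]].isna().any().any():
            raise ValueError("genus/clade/continent labels must be non-missing")
        bad_clade = set(species_meta["clade"]) - {"angiosperm", "gymnosperm"}
        if bad_clade:
            raise ValueError(f"unknown clade labels {sorted(bad_clade)}")
        cells = cells.reindex(index=species_meta.index, columns=names).astype(object)
        if provenance is None:
            provenance = pd.DataFrame(
                np.where(cells.isna(), PROV_MISSING, PROV_RAW),
                index=cells.index, columns=cells.columns,
            )
        provenance = provenance.reindex(index=cells.index, columns=cells.columns)
        self.species_meta = species_meta
        self.traits = traits
        self.cells = cells
        self.provenance = provenance
        self._by_name = {t.name: t for t in traits}

    # -- basic accessors -------------------------------------------------
    @property
    def species(self) -> list[str]:
        return list(self.species_meta.index)

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]

    def trait(self, name: str) -> TraitDefinition:
        return self._by_name[name]

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    def missing_mask(self) -> pd.DataFrame:
        return self.cells.isna()

    def copy(self) -> "TraitMatrix":
        return TraitMatrix(self.species_meta.copy(), self.traits,
                           self.cells.copy(), self.provenance.copy())

    def subset_species(self, species: Iterable[str]) -> "TraitMatrix":
        species = list(species)
        unknown = set(species) - set(self.species_meta.index)
        if unknown:
            raise KeyError(f"unknown species {sorted(unknown)}")
        return TraitMatrix(self.species_meta.loc[species], self.traits,
                           self.cells.loc[species], self.provenance.loc[species])

    def subset_clade(self, clade: str) -> "TraitMatrix":
        keep = self.species_meta.index[self.species_meta["clade"] == clade]
        return self.subset_species(keep)

    def continent_members(self, continent: str) -> list[str]:
        """Species of a continent; species labelled ``both`` belong to each."""
        m = self.species_meta["continent"]
        return list(self.species_meta.index[(m == continent) | (m == "both")])

    def drop_traits(self, names: Iterable[str]) -> "TraitMatrix":
        names = set(names)
        kept = [t for t in self.traits if t.name not in names]
        cols = [t.name for t in kept]
        return TraitMatrix(self.species_meta, kept, self.cells[cols], self.provenance[cols])

    def validate(self) -> None:
        """Check every cell against its trait declaration."""
        for tdef in self.traits:
            col = self.cells[tdef.name]
            for sp, val in col.items():
                tdef.validate(val, species=sp)

    def __repr__(self):
        n_sp, n_tr = self.shape
        miss = summarize_missingness(self)["fraction_missing"]
        return f"<TraitMatrix {n_sp} species x {n_tr} traits, {miss:.1%} missing>"


# ---------------------------------------------------------------------------
# aggregation of raw records
# ---------------------------------------------------------------------------

def _aggregate_values(tdef: TraitDefinition, values: list):
    """Aggregate one species' observations of one trait to a single cell value."""
    if tdef.data_type == "continuous":
        return float(np.median([float(v) for v in values]))
    if tdef.data_type == "ordinal":
        return float(np.mean([float(v) for v in values]))
    if tdef.data_type == "multichoice":
        counts = Counter(frozenset(v) for v in values)
        top = max(counts.values())
        # mode tie-break: prefer the set whose sorted level tuple comes first
        # in the declared level order
        order = {lv: i for i, lv in enumerate(tdef.levels)}
        cands = [s for s, c in counts.items() if c == top]
        return min(cands, key=lambda s: sorted(order[lv] for lv in s))
    # binary / nominal: mode, ties broken by declared level order (binary: 0 first)
    counts = Counter(values)
    top = max(counts.values())
    cands = [v for v, c in counts.items() if c == top]
    if tdef.data_type == "binary":
        return min(cands)
    order = {lv: i for i, lv in enumerate(tdef.levels)}
    return min(cands, key=lambda v: order[v])


def aggregate_records(records: Iterable[TraitRecord],
                      dictionary: Sequence[TraitDefinition],
                      species_meta: pd.DataFrame) -> TraitMatrix:
    """Aggregate raw trait observations to a species-level matrix.

    Continuous traits are aggregated by their median, ordinal traits by the
    arithmetic mean of their level scores, and binary/nominal/multichoice
    traits by their mode (ties resolved toward the earliest declared level).
    Species x trait combinations with no observation are marked missing.

    Parameters
    ----------
    records:
        Raw observations; each must name a trait present in *dictionary* and a
        species present in *species_meta*, and its value must conform to the
        trait declaration.
    dictionary:
        The trait declarations defining matrix columns.
    species_meta:
        Species metadata frame (index = species) defining matrix rows.
    """
    by_name = {t.name: t for t in dictionary}
    buckets: dict[tuple[str, str], list] = defaultdict(list)
    for rec in records:
        if rec.trait not in by_name:
            raise TraitValidationError(
                f"species {rec.species!r}, trait {rec.trait!r}: trait not in dictionary")
        if rec.species not in species_meta.index:
            raise TraitValidationError(f"species {rec.species!r}: not in species metadata")
        tdef = by_name[rec.trait]
        value = rec.value
        if tdef.data_type == "multichoice" and isinstance(value, (set, frozenset)):
            value = frozenset(value)
        tdef.validate(value, species=rec.species)
        if is_missing(value):
            continue
        buckets[(rec.species, rec.trait)].append(value)

    names = [t.name for t in dictionary]
    cells = pd.DataFrame(MISSING, index=species_meta.index, columns=names, dtype=object)
    prov = pd.DataFrame(PROV_MISSING, index=species_meta.index, columns=names)
    for (sp, tr), values in buckets.items():
        cells.at[sp, tr] = _aggregate_values(by_name[tr], values)
        prov.at[sp, tr] = PROV_AGGREGATED
    return TraitMatrix(species_meta, dictionary, cells, prov)


# ---------------------------------------------------------------------------
# genus-mean imputation
# ---------------------------------------------------------------------------

def impute_genus_means(matrix: TraitMatrix) -> TraitMatrix:
    """Fill gaps in continuous and ordinal traits with genus mean values.

    A missing quantitative cell is replaced by the mean of the non-missing
    values of congeneric species when at least one exists; categorical traits
    and cells without a genus donor are left untouched.  Returns a new matrix;
    the input is not modified.
    """
    out = matrix.copy()
    genus = matrix.species_meta["genus"]
    for tdef in matrix.traits:
        if not tdef.quantitative:
            continue
        col = matrix.cells[tdef.name]
        vals = pd.to_numeric(col, errors="coerce")
        genus_means = vals.groupby(genus).mean()
        for sp in matrix.species_meta.index[col.isna()]:
            m = genus_means.get(genus[sp])
            if m is not None and not np.isnan(m):
                out.cells.at[sp, tdef.name] = float(m)
                out.provenance.at[sp, tdef.name] = PROV_IMPUTED
    return out


# ---------------------------------------------------------------------------
# invariant-trait filtering
# ---------------------------------------------------------------------------

def drop_invariant_traits(matrix: TraitMatrix,
                          subset: Iterable[str] | None = None,
                          ) -> tuple[TraitMatrix, list[str]]:
    """Remove traits that do not vary across a species subset.

    A trait is invariant when all its non-missing values over *subset* are
    identical (multichoice: identical level sets).  Traits with no observed
    values at all are also dropped.  Analysing a clade with such traits would
    contribute zero information and break standardisation, so the matrix for
    each analysis group is filtered first.

    Returns the filtered matrix (restricted to *subset* if given) and the
    list of dropped trait names.
    """
    sub = matrix if subset is None else matrix.subset_species(subset)
    if sub.shape[0] == 0:
        raise ValueError("empty species subset")
    dropped = []
    for tdef in sub.traits:
        observed = [v for v in sub.cells[tdef.name] if not is_missing(v)]
        if tdef.data_type == "multichoice":
            distinct = {frozenset(v) for v in observed}
        else:
            distinct = set(observed)
        if len(distinct) <= 1:
            dropped.append(tdef.name)
    if len(dropped) == len(sub.traits):
        raise ValueError("all traits invariant over the subset; analysis is degenerate")
    return sub.drop_traits(dropped), dropped


# ---------------------------------------------------------------------------
# transform + standardisation
# ---------------------------------------------------------------------------

def standardize_and_transform(matrix: TraitMatrix) -> TraitMatrix:
    """Apply declared transforms and z-score quantitative traits.

    Continuous traits are log- or sqrt-transformed where their declaration
    says so (log requires strictly positive values), then continuous and
    ordinal traits are centred and scaled to zero mean and unit standard
    deviation (ddof=1) over their non-missing entries.  Categorical traits are
    passed through unchanged.
    """
    out = matrix.copy()
    for tdef in matrix.traits:
        if not tdef.quantitative:
            continue
        col = pd.to_numeric(matrix.cells[tdef.name], errors="coerce").astype(float)
        obs = col.dropna()
        if tdef.data_type == "continuous" and tdef.transform != "none":
            if tdef.transform == "log":
                if (obs <= 0).any():
                    raise ValueError(f"trait {tdef.name!r}: log transform needs positive values")
                col = np.log(col)
            elif tdef.transform == "sqrt":
                if (obs < 0).any():
                    raise ValueError(f"trait {tdef.name!r}: sqrt transform needs non-negative values")
                col = np.sqrt(col)
            obs = col.dropna()
        sd = obs.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(
                f"trait {tdef.name!r} has zero variance after transform; "
                "drop invariant traits first")
        z = (col - obs.mean()) / sd
        for sp in matrix.species_meta.index:
            if not np.isnan(z[sp]):
                out.cells.at[sp, tdef.name] = float(z[sp])
    return out


# ---------------------------------------------------------------------------
# missingness summary
# ---------------------------------------------------------------------------

def summarize_missingness(matrix: TraitMatrix) -> dict:
    """Fraction of missing cells, overall and per trait / per species."""
    mask = matrix.missing_mask()
    n_sp, n_tr = mask.shape
    total = n_sp * n_tr
    return {
        "fraction_missing": float(mask.to_numpy().sum()) / total if total else 0.0,
        "per_trait": mask.mean(axis=0).to_dict(),
        "per_species": mask.mean(axis=1).to_dict(),
    }


# ---------------------------------------------------------------------------
# flat-file I/O
# ---------------------------------------------------------------------------

def write_trait_dictionary(traits: Sequence[TraitDefinition], path: str | Path) -> None:
    """Write a trait dictionary as YAML (or JSON when path ends in .json)."""
    payload = [
        {"name": t.name, "data_type": t.data_type, "unit": t.unit,
         "levels": list(t.levels), "transform": t.transform}
        for t in traits
    ]
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def read_trait_dictionary(path: str | Path) -> list[TraitDefinition]:
    path = Path(path)
    raw = json.loads(path.read_text()) if path.suffix == ".json" else yaml.safe_load(path.read_text())
    return [
        TraitDefinition(name=d["name"], data_type=d["data_type"], unit=d.get("unit", ""),
                        levels=tuple(d.get("levels") or ()), transform=d.get("transform", "none"))
        for d in raw
    ]


def write_trait_table(matrix: TraitMatrix, table_path: str | Path,
                      dict_path: str | Path | None = None, sep: str = ",") -> None:
    """Write the matrix as CSV/TSV with a sidecar trait dictionary.

    Multichoice level sets are encoded as ``|``-separated level codes in one
    field; metadata columns (genus, clade, continent) precede trait columns.
    """
    flat = matrix.cells.copy()
    for t in matrix.traits:
        if t.data_type == "multichoice":
            flat[t.name] = [
                MISSING if is_missing(v) else MULTICHOICE_SEP.join(
                    sorted(v, key=list(t.levels).index))
                for v in flat[t.name]
            ]
    out = pd.concat([matrix.species_meta[["genus", "clade", "continent"]], flat], axis=1)
    out.to_csv(table_path, sep=sep, index_label="species")
    if dict_path is not None:
        write_trait_dictionary(matrix.traits, dict_path)


def read_trait_table(table_path: str | Path, dict_path: str | Path,
                     sep: str = ",") -> TraitMatrix:
    """Read a trait CSV/TSV and its sidecar dictionary back into a matrix."""
    traits = read_trait_dictionary(dict_path)
    # keep_default_na=False: the continent code "NA" is a value, not a gap
    df = pd.read_csv(table_path, sep=sep, index_col="species",
                     keep_default_na=False, na_values=[""])
    meta = df[["genus", "clade", "continent"]]
    cells = df[[t.name for t in traits]].astype(object)
    for t in traits:
        col = cells[t.name]
        if t.data_type == "multichoice":
            cells[t.name] = [
                MISSING if is_missing(v) else frozenset(str(v).split(MULTICHOICE_SEP))
                for v in col
            ]
        elif t.data_type == "nominal":
            cells[t.name] = [MISSING if is_missing(v) else str(v) for v in col]
        elif t.data_type == "binary":
            cells[t.name] = [MISSING if is_missing(v) else int(v) for v in col]
        else:
            cells[t.name] = [MISSING if is_missing(v) else float(v) for v in col]
    mat = TraitMatrix(meta, traits, cells)
    mat.validate()
    return mat
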