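"""Gower dissimilarity for mixed trait types with missing-data weighting.

The coefficient is a weighted mean of per-trait dissimilarities,

    d(a, b) = sum_k w_k * delta_k(a, b) / sum_k w_k,

where the weight w_k is 1 when both species have trait k observed and 0
otherwise (pairwise deletion with renormalisation).  Per-trait contributions:

* continuous / ordinal (standardised scores): |a - b| / range_k, with range_k
  the observed value range over the full analysis set;
* binary and nominal: 0 on agreement, 1 on mismatch (symmetric treatment —
  shared absence counts as agreement, since the binary traits encode states);
* multichoice: Jaccard dissimilarity 1 - |A∩B| / |A∪B| of the level sets.

With complete data the resulting similarity matrix is positive semi-definite,
so the element-wise square root of the dissimilarities embeds in Euclidean
space; missing-data weighting can break this, which :func:`make_embeddable`
detects via the smallest eigenvalue of the doubly centred matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .traits import TraitDefinition, TraitMatrix, is_missing

__all__ = [
    "DissimilarityMatrix",
    "NoSharedTraitsError",
    "gower_pair",
    "gower_matrix",
    "make_embeddable",
    "read_dissimilarity",
    "write_dissimilarity",
]


class NoSharedTraitsError(ValueError):
    """A species pair shares no observed trait, so their Gower weight sum is 0."""


@dataclass
class DissimilarityMatrix:
    """Symmetric species x species dissimilarities with a zero diagonal.

    ``euclidean_embeddable`` and ``min_eigenvalue`` are populated by
    :func:`make_embeddable` (or :func:`check_embeddable`); ``sqrt_transformed``
    records whether the classical square-root embedding device has been
    applied.
    """

    labels: list[str]
    values: np.ndarray
    euclidean_embeddable: bool | None = None
    min_eigenvalue: float | None = None
    weight_normalized: bool = True
    sqrt_transformed: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count does not match matrix size")
        if np.isnan(v).any():
            raise ValueError("dissimilarity matrix contains missing entries")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("dissimilarities must be non-negative")
        self.values = np.clip((v + v.T) / 2.0, 0.0, None)

    def __len__(self):
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def submatrix(self, labels: Sequence[str]) -> "DissimilarityMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DissimilarityMatrix(
            list(labels), self.values[np.ix_(idx, idx)],
            euclidean_embeddable=None, min_eigenvalue=None,
            weight_normalized=self.weight_normalized,
            sqrt_transformed=self.sqrt_transformed)


# ---------------------------------------------------------------------------
# per-trait dissimilarity pieces
# ---------------------------------------------------------------------------

def _quant_range(matrix: TraitMatrix, trait: str) -> float:
    vals = pd.to_numeric(matrix.cells[trait], errors="coerce").dropna()
    if vals.empty:
        return 0.0
    return float(vals.max() - vals.min())


def _is_constant(matrix: TraitMatrix, trait: TraitDefinition) -> bool:
    """True when a trait's non-missing values are all identical.

    Constant traits carry no information; excluding them from the weighted
    mean (weight 0, the classical zero-range rule extended to categorical
    types) makes the coefficient invariant to their presence.
    """
    observed = [v for v in matrix.cells[trait.name] if not is_missing(v)]
    if trait.data_type == "multichoice":
        return len({frozenset(v) for v in observed}) <= 1
    return len(set(observed)) <= 1


def _pair_terms(tdef: TraitDefinition, a, b, rng: float) -> tuple[float, float]:
    """Return (weight, delta) for one trait of one species pair."""
    if is_missing(a) or is_missing(b):
        return 0.0, 0.0
    if tdef.quantitative:
        if rng <= 0:
            return 0.0, 0.0
        return 1.0, abs(float(a) - float(b)) / rng
    if tdef.data_type == "multichoice":
        sa, sb = frozenset(a), frozenset(b)
        union = sa | sb
        if not union:
            return 1.0, 0.0
        return 1.0, 1.0 - len(sa & sb) / len(union)
    return 1.0, 0.0 if a == b else 1.0


def gower_pair(matrix: TraitMatrix, species_a: str, species_b: str,
               ranges: Mapping[str, float] | None = None) -> float:
    """Gower dissimilarity in [0, 1] between two species of a matrix.

    ``ranges`` fixes the quantitative value ranges; by default they are taken
    over the full matrix, which is the analysis set.  Raises
    :class:`NoSharedTraitsError` when the pair shares no observed trait.
    """
    if ranges is None:
        ranges = {t.name: _quant_range(matrix, t.name) for t in matrix.traits if t.quantitative}
    wsum = dsum = 0.0
    row_a, row_b = matrix.cells.loc[species_a], matrix.cells.loc[species_b]
    for tdef in matrix.traits:
        if _is_constant(matrix, tdef):
            continue
        w, d = _pair_terms(tdef, row_a[tdef.name], row_b[tdef.name],
                           ranges.get(tdef.name, 0.0))
        wsum += w
        dsum += w * d
    if wsum == 0:
        raise NoSharedTraitsError(
            f"species pair ({species_a!r}, {species_b!r}) shares no observed trait")
    return min(dsum / wsum, 1.0)


# ---------------------------------------------------------------------------
# full matrix (vectorised per trait)
# ---------------------------------------------------------------------------

def gower_matrix(matrix: TraitMatrix) -> DissimilarityMatrix:
    """All-pairs Gower dissimilarity of a trait matrix.

    Quantitative ranges are computed once over the full matrix so that every
    pair is normalised identically.  Requires at least two species; raises
    :class:`NoSharedTraitsError` naming the first offending pair if any two
    species share no observed trait.
    """
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("need at least two species")
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for tdef in matrix.traits:
        if _is_constant(matrix, tdef):
            continue
        col = matrix.cells[tdef.name]
        if tdef.quantitative:
            v = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            present = ~np.isnan(v)
            rng = _quant_range(matrix, tdef.name)
            vv = np.where(present, v, 0.0)
            delta = np.abs(vv[:, None] - vv[None, :]) / rng if rng > 0 else np.zeros((n, n))
        elif tdef.data_type == "multichoice":
            sets = [None if is_missing(x) else frozenset(x) for x in col]
            present = np.array([s is not None for s in sets])
            delta = np.zeros((n, n))
            idx = np.flatnonzero(present)
            for ii, i in enumerate(idx):
                for j in idx[ii + 1:]:
                    si, sj = sets[i], sets[j]
                    union = si | sj
                    d = 1.0 - len(si & sj) / len(union) if union else 0.0
                    delta[i, j] = delta[j, i] = d
        else:
            codes = np.array([None if is_missing(x) else x for x in col], dtype=object)
            present = np.array([x is not None for x in codes])
            eq = codes[:, None] == codes[None, :]
            delta = np.where(eq, 0.0, 1.0)
        w = (present[:, None] & present[None, :]).astype(float)
        num += w * delta
        den += w
    if (den == 0).any():
        i, j = np.argwhere(den == 0)[0]
        raise NoSharedTraitsError(
            f"species pair ({matrix.species[i]!r}, {matrix.species[j]!r}) "
            "shares no observed trait")
    d = num / den
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DissimilarityMatrix(matrix.species, d)


# ---------------------------------------------------------------------------
# Euclidean embeddability
# ---------------------------------------------------------------------------

def _min_centered_eigenvalue(d: np.ndarray) -> float:
    """Smallest eigenvalue of the doubly centred -1/2 D^2 Gower matrix."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    b = (b + b.T) / 2.0
    return float(np.linalg.eigvalsh(b)[0])


def check_embeddable(d: DissimilarityMatrix, tol: float = 1e-8) -> DissimilarityMatrix:
    """Evaluate Euclidean embeddability in place and return the matrix."""
    lam = _min_centered_eigenvalue(d.values)
    d.min_eigenvalue = lam
    d.euclidean_embeddable = lam >= -tol
    return d


def make_embeddable(d: DissimilarityMatrix, tol: float = 1e-8) -> DissimilarityMatrix:
    """Square-root transform toward a Euclidean-embeddable dissimilarity.

    Taking the element-wise square root of Gower dissimilarities is the
    classical embedding device: with complete data the Gower similarity
    matrix is positive semi-definite and sqrt(d) is then Euclidean.  The
    returned matrix re-evaluates embeddability from the smallest eigenvalue
    of its doubly centred form, which missing-data weighting may leave
    negative.
    """
    out = DissimilarityMatrix(
        list(d.labels), np.sqrt(d.values),
        weight_normalized=d.weight_normalized, sqrt_transformed=True)
    return check_embeddable(out, tol=tol)


# ---------------------------------------------------------------------------
# I/O: square CSV with header labels
# ---------------------------------------------------------------------------

def write_dissimilarity(d: DissimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(d.values, index=d.labels, columns=d.labels).to_csv(path)


def read_dissimilarity(path: str | Path) -> DissimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    return DissimilarityMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))
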