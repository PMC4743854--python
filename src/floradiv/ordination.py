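"""Principal coordinates analysis, trait-vector biplot fitting, and 2-D KDE.

Classical metric scaling of a dissimilarity matrix D: the doubly centred
matrix B = -1/2 J D^2 J (J the centering matrix) is eigendecomposed, positive
eigenvalues yield real coordinate axes scaled by sqrt(lambda), negative
eigenvalues — which arise when D is not Euclidean-embeddable — are kept as
"imaginary" axes scaled by sqrt(|lambda|) so that downstream statistics
(functional dispersion, dispersion tests) can apply the standard correction
of subtracting imaginary squared distances.

Trait vectors for biplots are Pearson correlations of (dummy-coded) trait
values with the leading axis scores, with permutation p-values; trait-space
occupation per group is summarised by a Gaussian kernel density on the first
two axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .gower import DissimilarityMatrix
from .traits import TraitMatrix, is_missing

__all__ = [
    "PCoAResult",
    "TraitVectorFit",
    "KDESurface",
    "pcoa",
    "fit_trait_vectors",
    "kde2d",
    "dummy_code_traits",
]

log = logging.getLogger(__name__)


@dataclass
class PCoAResult:
    """Species scores from classical scaling.

    ``coordinates`` holds scores on real (positive-eigenvalue) axes, columns
    ordered by descending eigenvalue; ``imaginary_coordinates`` holds scores
    on negative-eigenvalue axes ordered by descending |eigenvalue|.
    ``variance_explained`` is each real axis's share of the positive
    eigenvalue sum.
    """

    labels: list[str]
    coordinates: np.ndarray
    imaginary_coordinates: np.ndarray
    eigenvalues: np.ndarray          # descending, real axes then zeros dropped, negatives last
    imaginary_eigenvalues: np.ndarray
    variance_explained: np.ndarray

    @property
    def n_real_axes(self) -> int:
        return self.coordinates.shape[1]

    def axis_scores(self, axis: int) -> pd.Series:
        return pd.Series(self.coordinates[:, axis], index=self.labels)

    def subset(self, labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Real and imaginary score rows for a species subset (original axes)."""
        idx = [self.labels.index(l) for l in labels]
        return self.coordinates[idx], self.imaginary_coordinates[idx]


def pcoa(d: DissimilarityMatrix, tol: float | None = None,
         correction: str = "none") -> PCoAResult:
    """Classical scaling (principal coordinates analysis) of a dissimilarity.

    Parameters
    ----------
    d:
        Symmetric dissimilarity matrix with n >= 3 species.
    tol:
        Eigenvalue magnitudes at or below this are treated as zero.  Defaults
        to ``n * eps * lambda_max``.
    correction:
        ``"none"`` (default), or ``"lingoes"`` / ``"cailliez"`` to make a
        non-Euclidean input embeddable by adding a constant to squared
        (Lingoes) or raw (Cailliez) off-diagonal dissimilarities.
    """
    v = np.asarray(d.values, dtype=float)
    n = v.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 species")
    if not np.allclose(v, v.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")

    if correction not in ("none", "lingoes", "cailliez"):
        raise ValueError(f"unknown correction {correction!r}")
    if correction != "none":
        v = _corrected_dissimilarity(v, correction)

    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (v ** 2) @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = linalg.eigh(b)          # ascending
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    lam_max = max(eigval.max(), 0.0)
    if tol is None:
        tol = n * np.finfo(float).eps * max(lam_max, 1.0)

    pos = eigval > tol
    neg = eigval < -tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    neg_idx = np.argsort(eigval[neg])        # most negative first
    imag = eigvec[:, neg][:, neg_idx] * np.sqrt(-eigval[neg][neg_idx])
    pos_sum = eigval[pos].sum()
    var_exp = eigval[pos] / pos_sum if pos_sum > 0 else np.zeros(pos.sum())
    return PCoAResult(
        labels=list(d.labels),
        coordinates=coords,
        imaginary_coordinates=imag,
        eigenvalues=eigval[pos],
        imaginary_eigenvalues=eigval[neg][neg_idx],
        variance_explained=var_exp,
    )


def _corrected_dissimilarity(v: np.ndarray, method: str) -> np.ndarray:
    """Lingoes / Cailliez constants turning a non-Euclidean D Euclidean."""
    n = v.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (v ** 2) @ j
    if method == "lingoes":
        lam_min = float(np.linalg.eigvalsh((b + b.T) / 2.0)[0])
        if lam_min >= 0:
            return v
        c = -lam_min
        out = np.sqrt(v ** 2 + 2 * c)
        np.fill_diagonal(out, 0.0)
        return out
    # Cailliez: smallest constant c so that d + c is Euclidean, from the
    # 2n x 2n companion eigenproblem
    b2 = -0.5 * j @ v @ j
    zero = np.zeros((n, n))
    eye = np.eye(n)
    block = np.block([[zero, 2.0 * b], [-eye, -4.0 * b2]])
    c = float(np.max(np.real(np.linalg.eigvals(block))))
    if c <= 0:
        return v
    out = v + c
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# trait-vector fitting (biplot arrows)
# ---------------------------------------------------------------------------

@dataclass
class TraitVectorFit:
    """Correlation of one (dummy-coded) trait vector with the leading axes."""

    trait: str
    loadings: np.ndarray     # Pearson r per axis, each in [-1, 1]
    p_value: float
    n: int                   # species with the trait observed


def dummy_code_traits(matrix: TraitMatrix) -> pd.DataFrame:
    """Numeric design frame for correlation: scores and 0/1 level dummies.

    Continuous and ordinal traits contribute their (possibly standardised)
    scores under their own name; binary traits contribute their 0/1 value;
    each nominal level becomes an indicator column ``trait=level``; each
    multichoice level becomes a membership indicator.  Missing cells become
    NaN in every derived column.
    """
    cols: dict[str, np.ndarray] = {}
    for tdef in matrix.traits:
        col = matrix.cells[tdef.name]
        if tdef.quantitative or tdef.data_type == "binary":
            cols[tdef.name] = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
        elif tdef.data_type == "nominal":
            for lv in tdef.levels:
                cols[f"{tdef.name}={lv}"] = np.array(
                    [np.nan if is_missing(v) else float(v == lv) for v in col])
        else:  # multichoice
            for lv in tdef.levels:
                cols[f"{tdef.name}={lv}"] = np.array(
                    [np.nan if is_missing(v) else float(lv in v) for v in col])
    return pd.DataFrame(cols, index=matrix.species_meta.index)


def fit_trait_vectors(p: PCoAResult, matrix: TraitMatrix, axes: int = 2,
                      n_perm: int = 999, min_loading: float = 0.25,
                      alpha: float = 0.001, seed: int | None = None,
                      ) -> list[TraitVectorFit]:
    """Correlate trait vectors with leading PCoA axes, permutation-tested.

    Each quantitative trait and each dummy-coded categorical level is Pearson-
    correlated with the first *axes* score vectors over the species where it
    is observed.  The permutation p-value uses the maximum |r| across axes as
    the statistic, shuffling the trait values.  Returned fits are filtered to
    ``p < alpha`` and ``max |loading| >= min_loading``; constant vectors are
    skipped with a log entry.
    """
    if list(p.labels) != list(matrix.species_meta.index):
        raise ValueError("PCoA species do not match trait matrix species")
    axes = min(axes, p.n_real_axes)
    scores = p.coordinates[:, :axes]
    design = dummy_code_traits(matrix)
    rng = np.random.default_rng(seed)
    fits: list[TraitVectorFit] = []
    for name in design.columns:
        y = design[name].to_numpy()
        ok = ~np.isnan(y)
        n = int(ok.sum())
        if n < 3 or np.std(y[ok]) == 0:
            log.info("trait vector %s skipped (constant or n<3)", name)
            continue
        yc = y[ok] - y[ok].mean()
        yc /= np.linalg.norm(yc)
        xs = scores[ok]
        xc = xs - xs.mean(axis=0)
        norms = np.linalg.norm(xc, axis=0)
        norms[norms == 0] = np.inf
        r_obs = (yc @ xc) / norms
        stat_obs = np.abs(r_obs).max()
        # permutation: shuffle the trait vector, recompute max |r|
        perms = np.empty((n_perm, n))
        for k in range(n_perm):
            perms[k] = rng.permutation(yc)
        r_perm = (perms @ xc) / norms
        stat_perm = np.abs(r_perm).max(axis=1)
        pval = (np.count_nonzero(stat_perm >= stat_obs - 1e-12) + 1) / (n_perm + 1)
        if pval <= alpha and stat_obs >= min_loading:
            fits.append(TraitVectorFit(trait=name, loadings=r_obs, p_value=pval, n=n))
    return fits


# ---------------------------------------------------------------------------
# 2-D kernel density of trait-space occupation
# ---------------------------------------------------------------------------

@dataclass
class KDESurface:
    """Gaussian kernel density of one group on the first two PCoA axes."""

    group: str
    x: np.ndarray            # lattice coordinates, axis 1
    y: np.ndarray            # lattice coordinates, axis 2
    density: np.ndarray      # shape (len(y), len(x)), non-negative
    bandwidth: np.ndarray    # 2x2 kernel covariance matrix
    n: int

    def integral(self) -> float:
        """Trapezoid integral of the density over the lattice (should be ~1)."""
        return float(np.trapezoid(np.trapezoid(self.density, self.x, axis=1), self.y))

    def mode(self) -> tuple[float, float]:
        iy, ix = np.unravel_index(np.argmax(self.density), self.density.shape)
        return float(self.x[ix]), float(self.y[iy])


def kde2d(p: PCoAResult, group_labels, gridsize: int = 128,
          pad_bandwidths: float = 3.0) -> list[KDESurface]:
    """Per-group 2-D Gaussian KDE on the first two PCoA axes.

    ``group_labels`` is either a per-species label mapping / Series, or a
    mapping of group name to a list of member species (memberships may then
    overlap, e.g. a species present on both continents).  All groups are
    evaluated on one shared lattice covering every species score plus a
    margin of ``pad_bandwidths`` marginal bandwidths, so that surfaces are
    directly comparable.  Groups with fewer than 3 species are skipped with
    a log entry.  Bandwidths use Silverman's multivariate rule on the full
    sample covariance (oriented kernels).
    """
    if p.n_real_axes < 2:
        raise ValueError("need at least two real PCoA axes for a 2-D density")
    pts = p.coordinates[:, :2]
    if isinstance(group_labels, Mapping) and group_labels and all(
            isinstance(v, (list, tuple, set, pd.Index, np.ndarray))
            for v in group_labels.values()):
        membership = {str(g): list(m) for g, m in group_labels.items()}
    else:
        groups = pd.Series(group_labels).reindex(p.labels)
        membership = {str(g): list(groups.index[groups == g])
                      for g in pd.unique(groups.dropna())}
    pos = {l: i for i, l in enumerate(p.labels)}
    surfaces: list[KDESurface] = []
    kdes = []
    max_bw = np.zeros(2)
    for g, members in membership.items():
        sel = np.array([pos[m] for m in members], dtype=int)
        if sel.size < 3:
            log.info("KDE group %s skipped (n=%d < 3)", g, int(sel.size))
            continue
        data = pts[sel].T
        kde = stats.gaussian_kde(data, bw_method="silverman")
        kdes.append((str(g), kde, int(sel.size)))
        max_bw = np.maximum(max_bw, np.sqrt(np.diag(kde.covariance)))
    if not kdes:
        return []
    lo = pts.min(axis=0) - pad_bandwidths * max_bw
    hi = pts.max(axis=0) + pad_bandwidths * max_bw
    x = np.linspace(lo[0], hi[0], gridsize)
    y = np.linspace(lo[1], hi[1], gridsize)
    xx, yy = np.meshgrid(x, y)
    grid = np.vstack([xx.ravel(), yy.ravel()])
    for g, kde, n in kdes:
        dens = kde(grid).reshape(yy.shape)
        surfaces.append(KDESurface(group=g, x=x, y=y, density=dens,
                                   bandwidth=kde.covariance.copy(), n=n))
    return surfaces
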