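"""Permutation tests on dissimilarity matrices for group differences.

Two complementary tests compare species groups (here: continents) in trait
space:

* **Homogeneity of multivariate dispersions** (a multivariate Levene
  analogue): each species' distance to its own group centroid is computed
  directly from the dissimilarities via Gower's identity

      dist_i^2 = (1/n_g) sum_{j in g} d_ij^2  -  (1/n_g^2) sum_{j<k in g} d_jk^2,

  which equals the distance in the principal-coordinate embedding including
  the negative-eigenvalue correction (squared distances may come out
  negative for non-Euclidean input and are floored at zero).  Distances are
  optionally bias-adjusted by sqrt(n_g / (n_g - 1)) for small groups, an
  observed F is taken from a one-way ANOVA on the distances, and group
  labels of the distances are permuted for inference.

* **perMANOVA** on centroid location: sums of squared dissimilarities are
  partitioned as SS_total = (1/N) sum_{i<j} d_ij^2 and
  SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2, giving
  pseudo-F = (SS_between/(g-1)) / (SS_within/(N-g)); raw group labels are
  permuted and the SS terms recomputed per permutation.

Both use the add-one permutation p-value (count of permuted statistics >=
observed, plus one, over n_perm + 1), so p is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gower import DissimilarityMatrix

__all__ = [
    "PermutationScheme",
    "DispersionTestResult",
    "PermanovaResult",
    "dispersion_test",
    "permanova",
    "centroid_distances",
]


@dataclass(frozen=True)
class PermutationScheme:
    """How permutations are drawn: count, seed, and the permuted unit."""

    n_perm: int = 999
    seed: int | None = None
    unit: str = "labels"

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.unit not in ("labels", "residuals"):
            raise ValueError("permutation unit must be 'labels' or 'residuals'")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class DispersionTestResult:
    group_distances: pd.Series        # per species, distance to own-group centroid
    group_means: pd.Series            # mean distance per group
    F: float
    permutation_F: np.ndarray
    p_value: float
    n_perm: int
    bias_adjusted: bool
    df_between: int
    df_within: int


@dataclass
class PermanovaResult:
    pseudo_F: float
    df_between: int
    df_within: int
    SS_between: float
    SS_within: float
    SS_total: float
    permutation_F: np.ndarray
    p_value: float
    n_perm: int


def _group_arrays(d: DissimilarityMatrix, groups) -> tuple[np.ndarray, np.ndarray, list]:
    g = pd.Series(groups)
    if set(g.index) >= set(d.labels):
        g = g.reindex(d.labels)
    elif len(g) == len(d.labels):
        g = pd.Series(np.asarray(groups), index=d.labels)
    if g.isna().any():
        raise ValueError("every species needs a group label")
    levels = list(pd.unique(g))
    codes = g.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
    return g.to_numpy(), codes, levels


def centroid_distances(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Distance of each point to its group centroid, from squared dissimilarities."""
    n = d2.shape[0]
    dist2 = np.empty(n)
    for gi in range(n_groups):
        idx = np.flatnonzero(codes == gi)
        ng = idx.size
        sub = d2[np.ix_(idx, idx)]
        mean_to_others = sub.sum(axis=1) / ng
        within_mean = sub.sum() / (2 * ng * ng)  # (1/ng^2) * sum_{j<k} d2
        dist2[idx] = mean_to_others - within_mean
    return np.sqrt(np.maximum(0.0, dist2))


def _anova_f(x: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """One-way ANOVA F statistic of x across groups."""
    n = x.size
    grand = x.mean()
    ss_between = ss_within = 0.0
    for gi in range(n_groups):
        xg = x[codes == gi]
        m = xg.mean()
        ss_between += xg.size * (m - grand) ** 2
        ss_within += ((xg - m) ** 2).sum()
    df_b, df_w = n_groups - 1, n - n_groups
    if ss_within <= 0:
        return 0.0 if ss_between <= 0 else np.inf
    return (ss_between / df_b) / (ss_within / df_w)


def dispersion_test(d: DissimilarityMatrix, groups, scheme: PermutationScheme | None = None,
                    bias_adjust: bool = True) -> DispersionTestResult:
    """Permutation test for homogeneity of multivariate group dispersions.

    Tests whether groups differ in their spread around their own centroids —
    the species-level analogue of a functional-dispersion difference.  Small
    groups' centroid distances are inflated by sqrt(n_g/(n_g-1)) when
    ``bias_adjust`` is on, correcting the downward bias of distances to an
    estimated centroid.  Group labels of the (fixed) distances are permuted.
    """
    scheme = scheme or PermutationScheme()
    labels_arr, codes, levels = _group_arrays(d, groups)
    n_groups = len(levels)
    if n_groups < 2:
        raise ValueError("need at least two groups")
    counts = np.bincount(codes, minlength=n_groups)
    if (counts < 2).any():
        small = [levels[i] for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"groups of size < 2 not testable: {small}")

    d2 = d.values ** 2
    dist = centroid_distances(d2, codes, n_groups)
    if bias_adjust:
        dist = dist * np.sqrt(counts[codes] / (counts[codes] - 1.0))
    f_obs = _anova_f(dist, codes, n_groups)

    rng = scheme.rng()
    perm_f = np.empty(scheme.n_perm)
    for k in range(scheme.n_perm):
        perm_f[k] = _anova_f(dist, rng.permutation(codes), n_groups)
    p = (np.count_nonzero(perm_f >= f_obs - 1e-12) + 1) / (scheme.n_perm + 1)

    means = pd.Series(
        {lv: float(dist[codes == i].mean()) for i, lv in enumerate(levels)})
    return DispersionTestResult(
        group_distances=pd.Series(dist, index=d.labels),
        group_means=means, F=float(f_obs), permutation_F=perm_f,
        p_value=float(p), n_perm=scheme.n_perm, bias_adjusted=bias_adjust,
        df_between=n_groups - 1, df_within=len(d.labels) - n_groups)


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int,
                  ss_total: float) -> tuple[float, float]:
    ss_within = 0.0
    for gi in range(n_groups):
        idx = np.flatnonzero(codes == gi)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss_total - ss_within, ss_within


def permanova(d: DissimilarityMatrix, groups,
              scheme: PermutationScheme | None = None) -> PermanovaResult:
    """One-way perMANOVA (pseudo-F on partitioned squared dissimilarities).

    Tests whether group centroids differ in location in the space implied by
    the dissimilarities; inference permutes the raw group labels.  With
    univariate data and Euclidean distance the pseudo-F equals the classical
    one-way ANOVA F.
    """
    scheme = scheme or PermutationScheme()
    _, codes, levels = _group_arrays(d, groups)
    n_groups = len(levels)
    n = len(d.labels)
    if n_groups < 2:
        raise ValueError("need at least two groups")
    if n <= n_groups:
        raise ValueError("need more observations than groups")

    d2 = d.values ** 2
    ss_total = d2.sum() / (2.0 * n)
    ss_between, ss_within = _permanova_ss(d2, codes, n_groups, ss_total)
    if ss_within < -1e-8:
        raise ValueError("negative within-group sum of squares: invalid dissimilarity")
    ss_within = max(ss_within, 0.0)
    df_b, df_w = n_groups - 1, n - n_groups
    f_obs = (ss_between / df_b) / (ss_within / df_w) if ss_within > 0 else np.inf

    rng = scheme.rng()
    perm_f = np.empty(scheme.n_perm)
    for k in range(scheme.n_perm):
        pc = rng.permutation(codes)
        ssb, ssw = _permanova_ss(d2, pc, n_groups, ss_total)
        perm_f[k] = (ssb / df_b) / (ssw / df_w) if ssw > 0 else np.inf
    p = (np.count_nonzero(perm_f >= f_obs - 1e-12) + 1) / (scheme.n_perm + 1)

    return PermanovaResult(
        pseudo_F=float(f_obs), df_between=df_b, df_within=df_w,
        SS_between=float(ss_between), SS_within=float(ss_within),
        SS_total=float(ss_total), permutation_F=perm_f, p_value=float(p),
        n_perm=scheme.n_perm)


def results_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Assemble a two-test summary table (class, region, df, F, p, pseudo-F, p)."""
    return pd.DataFrame(rows, columns=[
        "class", "region", "df", "F", "p_dispersion", "pseudo_F", "p_permanova"])
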