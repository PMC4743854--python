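"""Functional diversity indices of assemblages in PCoA trait space.

FDis (functional dispersion) is the mean distance of an assemblage's species
to their centroid.  Distances are computed in the principal-coordinate
embedding with the standard correction for negative eigenvalues: the squared
distance on imaginary axes is subtracted from the squared distance on real
axes (floored at zero), so the index stays defined for non-Euclidean
dissimilarities and reduces to the plain Euclidean computation for complete
embeddable data.

FRic (functional richness) is the convex-hull volume of the assemblage in a
reduced trait space spanned by the first few real axes; it is undefined when
the assemblage has no more species than axes, and degenerate (coplanar)
point sets report zero volume with a flag.  FRic may also be reported as a
fraction of a reference pool's hull volume to make groups of different total
extent comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .ordination import PCoAResult

__all__ = ["Assemblage", "FDSummary", "fdis", "fric", "fd_profile", "FRIC_UNDEFINED"]

#: Marker for an undefined FRic (richness <= axes).
FRIC_UNDEFINED = None


@dataclass(frozen=True)
class Assemblage:
    """A species set at some scale: continental pool, region, or grid cell."""

    id: str
    members: tuple[str, ...]

    def __post_init__(self):
        if len(self.members) == 0:
            raise ValueError(f"assemblage {self.id!r} is empty")
        object.__setattr__(self, "members", tuple(self.members))

    @property
    def richness(self) -> int:
        return len(self.members)


@dataclass
class FDSummary:
    """FDis / FRic of one assemblage."""

    id: str
    richness: int
    fdis: float
    fric: float | None          # None when undefined (richness <= axes)
    fric_fraction: float | None  # fric / reference-pool hull volume
    fric_axes: int
    degenerate_hull: bool = False
    note: str = ""


def _member_scores(assemblage: Assemblage, p: PCoAResult) -> tuple[np.ndarray, np.ndarray]:
    missing = [m for m in assemblage.members if m not in p.labels]
    if missing:
        raise KeyError(f"assemblage {assemblage.id!r}: species absent from ordination: {missing}")
    return p.subset(assemblage.members)


def fdis(assemblage: Assemblage, p: PCoAResult) -> float:
    """Mean distance of members to their centroid, imaginary-axis corrected.

    For each member i with real scores x_i and imaginary scores u_i,

        dist_i = sqrt(max(0, ||x_i - x_bar||^2 - ||u_i - u_bar||^2))

    and FDis is the unweighted mean of dist_i.  A singleton assemblage has
    FDis 0.
    """
    real, imag = _member_scores(assemblage, p)
    if real.shape[0] == 1:
        return 0.0
    dr2 = ((real - real.mean(axis=0)) ** 2).sum(axis=1)
    di2 = ((imag - imag.mean(axis=0)) ** 2).sum(axis=1) if imag.size else 0.0
    return float(np.sqrt(np.maximum(0.0, dr2 - di2)).mean())


def fric(assemblage: Assemblage, p: PCoAResult, axes: int = 2,
         degeneracy_tol: float = 1e-12) -> tuple[float | None, bool]:
    """Convex-hull volume of members on the first *axes* real axes.

    Returns ``(volume, degenerate)``; volume is :data:`FRIC_UNDEFINED` when
    richness <= axes (a hull cannot enclose volume), and 0.0 with
    ``degenerate=True`` when the points are (numerically) affinely dependent,
    e.g. collinear in two dimensions.
    """
    if axes < 2:
        raise ValueError("FRic needs at least 2 axes")
    if axes > p.n_real_axes:
        raise ValueError(f"requested {axes} axes but only {p.n_real_axes} real axes exist")
    real, _ = _member_scores(assemblage, p)
    if assemblage.richness <= axes:
        return FRIC_UNDEFINED, False
    pts = real[:, :axes]
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0, True
    vol = float(hull.volume)
    if vol <= degeneracy_tol:
        return 0.0, True
    return vol, False


def default_fric_axes(min_richness: int, n_real_axes: int, cap: int = 6) -> int:
    """Axis count keeping hulls defined for the smallest assemblage compared."""
    return max(2, min(min_richness - 1, n_real_axes, cap))


def fd_profile(assemblages: Sequence[Assemblage], p: PCoAResult,
               axes: int | None = None,
               reference_pool: Assemblage | None = None) -> list[FDSummary]:
    """FDis/FRic summary per assemblage, on a common axis count.

    ``axes`` defaults to :func:`default_fric_axes` over the assemblage set so
    hull volumes are commensurable.  When ``reference_pool`` is given (e.g.
    the pooled two-continent flora), each FRic is also reported as a fraction
    of the pool's hull volume.  Per-assemblage failures are recorded in the
    summary's ``note`` rather than raised.
    """
    if not assemblages:
        return []
    if axes is None:
        min_rich = min(a.richness for a in assemblages)
        axes = default_fric_axes(min_rich, p.n_real_axes)
    pool_vol = None
    if reference_pool is not None:
        pool_vol, pool_degen = fric(reference_pool, p, axes=axes)
        if not pool_vol:
            pool_vol = None
    out: list[FDSummary] = []
    for a in assemblages:
        try:
            f = fdis(a, p)
            v, degen = fric(a, p, axes=axes)
        except KeyError as exc:
            out.append(FDSummary(id=a.id, richness=a.richness, fdis=float("nan"),
                                 fric=None, fric_fraction=None, fric_axes=axes,
                                 note=str(exc)))
            continue
        frac = (v / pool_vol) if (v is not None and pool_vol) else None
        out.append(FDSummary(id=a.id, richness=a.richness, fdis=f, fric=v,
                             fric_fraction=frac, fric_axes=axes,
                             degenerate_hull=degen))
    return out


def profile_frame(summaries: Iterable[FDSummary]) -> pd.DataFrame:
    """Tabular view of FD summaries, for TSV export keyed by assemblage id."""
    return pd.DataFrame(
        [{"id": s.id, "richness": s.richness, "fdis": s.fdis, "fric": s.fric,
          "fric_fraction": s.fric_fraction, "fric_axes": s.fric_axes,
          "degenerate_hull": s.degenerate_hull, "note": s.note}
         for s in summaries]
    ).set_index("id")
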