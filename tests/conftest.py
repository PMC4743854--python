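"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest

from floradiv.gower import DissimilarityMatrix
from floradiv.traits import MISSING, TraitDefinition, TraitMatrix, is_missing

MASTER_SEED = 20160205  # fixed project-wide test seed


# ---------------------------------------------------------------------------
# small hand-built mixed-type matrix
# ---------------------------------------------------------------------------

def small_dictionary():
    return [
        TraitDefinition("height", "continuous", unit="m"),
        TraitDefinition("seed.mass", "continuous", unit="mg", transform="log"),
        TraitDefinition("growth.rate", "ordinal", levels=(1, 2, 3)),
        TraitDefinition("n.fix", "binary"),
        TraitDefinition("form", "nominal", levels=("tree", "shrub", "both")),
        TraitDefinition("dispersal", "multichoice", levels=("animal", "wind", "gravity", "water")),
    ]


def make_matrix(cells_rows, genera=None, clades=None, continents=None, traits=None):
    """Build a TraitMatrix from a list of per-species dicts."""
    traits = traits or small_dictionary()
    species = [f"sp{i + 1}" for i in range(len(cells_rows))]
    meta = pd.DataFrame({
        "genus": genera or ["G1"] * len(species),
        "clade": clades or ["angiosperm"] * len(species),
        "continent": continents or ["EU"] * len(species),
    }, index=species)
    cells = pd.DataFrame(
        [{t.name: row.get(t.name, MISSING) for t in traits} for row in cells_rows],
        index=species, dtype=object)
    return TraitMatrix(meta, traits, cells)


@pytest.fixture
def toy_matrix():
    """Five species, all six data-type behaviours, a few gaps."""
    return make_matrix([
        {"height": 10.0, "seed.mass": 5.0, "growth.rate": 1.0, "n.fix": 0,
         "form": "tree", "dispersal": frozenset({"animal", "wind"})},
        {"height": 20.0, "seed.mass": 50.0, "growth.rate": 2.0, "n.fix": 1,
         "form": "shrub", "dispersal": frozenset({"wind"})},
        {"height": 30.0, "growth.rate": 3.0, "n.fix": 0,
         "form": "tree", "dispersal": frozenset({"gravity", "wind"})},
        {"height": 15.0, "seed.mass": 500.0, "n.fix": 1,
         "form": "both", "dispersal": frozenset({"animal"})},
        {"seed.mass": 20.0, "growth.rate": 2.0, "n.fix": 0,
         "form": "shrub", "dispersal": frozenset({"water", "animal"})},
    ], genera=["Qu", "Qu", "Qu", "Pi", "Pi"])


# ---------------------------------------------------------------------------
# dissimilarity helpers
# ---------------------------------------------------------------------------

def euclidean_dm(points, labels=None):
    pts = np.asarray(points, dtype=float)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    labels = labels or [f"s{i}" for i in range(len(pts))]
    return DissimilarityMatrix(list(labels), d)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def gower_pair_oracle(matrix, a, b):
    """Straight transcription of the weighted-mean Gower definition."""
    ranges = {}
    for t in matrix.traits:
        if t.quantitative:
            vals = [float(v) for v in matrix.cells[t.name] if not is_missing(v)]
            ranges[t.name] = max(vals) - min(vals) if vals else 0.0
    num = den = 0.0
    for t in matrix.traits:
        va, vb = matrix.cells.at[a, t.name], matrix.cells.at[b, t.name]
        if is_missing(va) or is_missing(vb):
            continue
        if t.quantitative:
            if ranges[t.name] <= 0:   # zero-range trait: excluded (Gower's rule)
                continue
            delta = abs(float(va) - float(vb)) / ranges[t.name]
        elif t.data_type == "multichoice":
            sa, sb = set(va), set(vb)
            delta = 1.0 - len(sa & sb) / len(sa | sb) if (sa | sb) else 0.0
        else:
            delta = 0.0 if va == vb else 1.0
        num += delta
        den += 1.0
    if den == 0:
        raise ValueError("no shared traits")
    return num / den


def gower_matrix_oracle(matrix):
    n = matrix.shape[0]
    out = np.zeros((n, n))
    sp = matrix.species
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = gower_pair_oracle(matrix, sp[i], sp[j])
    return out


def anova_f_oracle(values, groups):
    """Textbook one-way ANOVA F."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    grand = values.mean()
    ssb = sum((values[groups == g].mean() - grand) ** 2 * (groups == g).sum()
              for g in levels)
    ssw = sum(((values[groups == g] - values[groups == g].mean()) ** 2).sum()
              for g in levels)
    dfb, dfw = len(levels) - 1, len(values) - len(levels)
    return (ssb / dfb) / (ssw / dfw)


def permanova_f_oracle(d, groups):
    """Pseudo-F from explicit double loops over the distance matrix."""
    d = np.asarray(d, dtype=float)
    groups = np.asarray(groups)
    n = len(groups)
    levels = pd.unique(groups)
    ss_t = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in levels:
        idx = np.flatnonzero(groups == g)
        ss_w += sum(d[i, j] ** 2 for ii, i in enumerate(idx) for j in idx[ii + 1:]) / len(idx)
    ss_a = ss_t - ss_w
    return (ss_a / (len(levels) - 1)) / (ss_w / (n - len(levels)))


def hull_area_oracle(points):
    """2-D convex hull area via Andrew's monotone chain + shoelace."""
    pts = sorted(map(tuple, np.asarray(points, dtype=float)))
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    area = 0.0
    for i in range(len(hull)):
        x1, y1 = hull[i]
        x2, y2 = hull[(i + 1) % len(hull)]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0
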