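"""Cross-species comparative statistics for organ trait tables.

Implements the non-phylogenetic statistical toolkit used to compare
flower and leaf hydraulic traits: paired t-tests across species,
one-way ANOVA with Fisher's protected LSD post hoc and a compact letter
display, ordinary least squares and standardized major axis (SMA)
regression for trait-trait scaling, PCA on centered and scaled traits,
and the overlap of convex hulls in PC space as a measure of how much of
the multivariate trait space two organ types share.

SMA (a symmetric line fit appropriate when both variables carry error)
has slope sign(r)·sd(y)/sd(x); its significance test is the test of the
Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ComputationError, InputError

__all__ = [
    "TraitTable",
    "PairedT",
    "AnovaLSD",
    "OLSFit",
    "SMAFit",
    "PCAResult",
    "HullOverlap",
    "paired_t",
    "anova_lsd",
    "ols",
    "sma",
    "pca",
    "hull_overlap",
]


class TraitTable:
    """Species × organ trait matrix (one row per species-organ pair).

    Wraps a wide :class:`pandas.DataFrame` indexed by ``(species, organ)``
    with one column per trait.  Missing values are explicit NaN (e.g.
    stomatal traits of astomatous petals).  Standard errors, when known,
    live in a parallel frame ``se``.
    """

    def __init__(self, wide: pd.DataFrame, se: pd.DataFrame | None = None):
        if not isinstance(wide.index, pd.MultiIndex) or wide.index.names != ["species", "organ"]:
            raise InputError("TraitTable expects a (species, organ) MultiIndex")
        self.wide = wide.sort_index()
        self.se = se.sort_index() if se is not None else None

    # -- construction --------------------------------------------------
    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "TraitTable":
        """Build from long format: columns species, organ, trait, mean[, se, n]."""
        required = {"species", "organ", "trait", "mean"}
        if not required.issubset(df.columns):
            raise InputError(f"long trait table needs columns {sorted(required)}")
        wide = df.pivot_table(index=["species", "organ"], columns="trait", values="mean")
        wide.columns.name = None
        se = None
        if "se" in df.columns:
            se = df.pivot_table(index=["species", "organ"], columns="trait", values="se")
            se.columns.name = None
        return cls(wide, se)

    @classmethod
    def from_csv(cls, path) -> "TraitTable":
        df = pd.read_csv(path)
        if {"species", "organ", "trait", "mean"}.issubset(df.columns):
            return cls.from_long(df)
        return cls(df.set_index(["species", "organ"]))

    def to_csv(self, path) -> None:
        self.wide.reset_index().to_csv(path, index=False)

    # -- accessors -----------------------------------------------------
    @property
    def traits(self) -> list:
        return list(self.wide.columns)

    @property
    def species(self) -> list:
        return sorted(self.wide.index.get_level_values("species").unique())

    @property
    def organs(self) -> list:
        return sorted(self.wide.index.get_level_values("organ").unique())

    def organ_values(self, trait: str, organ: str) -> pd.Series:
        """Species-indexed values of one trait for one organ."""
        sub = self.wide.xs(organ, level="organ")
        if trait not in sub.columns:
            raise InputError(f"unknown trait {trait!r}")
        return sub[trait]

    def organ_pairs(self, trait: str) -> pd.DataFrame:
        """Complete flower/leaf pairs for one trait, indexed by species."""
        organs = self.organs
        cols = {org: self.organ_values(trait, org) for org in organs}
        return pd.DataFrame(cols).dropna()

    def organ_means(self) -> pd.DataFrame:
        """Mean ± SE of every trait per organ (across species)."""
        rows = []
        for organ in self.organs:
            sub = self.wide.xs(organ, level="organ")
            for trait in self.traits:
                vals = sub[trait].dropna()
                rows.append({
                    "organ": organ, "trait": trait, "n": len(vals),
                    "mean": vals.mean() if len(vals) else float("nan"),
                    "se": vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else float("nan"),
                })
        return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# paired t-test


@dataclass(frozen=True)
class PairedT:
    t: float
    p: float
    n: int
    df: int
    mean_diff: float

    def summary(self) -> str:
        return f"paired t = {self.t:.3f}, p = {self.p:.4g} (n = {self.n} pairs, df = {self.df})"


def _paired_t_from_diffs(diffs: np.ndarray) -> PairedT:
    n = len(diffs)
    if n < 2:
        raise InputError("paired t-test needs at least 2 complete pairs")
    if np.all(diffs == 0):
        # no difference anywhere: t = 0 with p = 1 by continuity
        return PairedT(t=0.0, p=1.0, n=n, df=n - 1, mean_diff=0.0)
    sd = float(np.std(diffs, ddof=1))
    if sd == 0:
        raise ComputationError("zero-variance nonzero differences: t undefined")
    t = float(np.mean(diffs) / (sd / math.sqrt(n)))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return PairedT(t=t, p=float(p), n=n, df=n - 1, mean_diff=float(np.mean(diffs)))


def paired_t(table: TraitTable, trait: str, organ_a: str = "flower", organ_b: str = "leaf") -> PairedT:
    """Paired t-test of organ_a − organ_b differences across species."""
    pairs = table.organ_pairs(trait)
    for org in (organ_a, organ_b):
        if org not in pairs.columns:
            raise InputError(f"organ {org!r} absent for trait {trait!r}")
    diffs = (pairs[organ_a] - pairs[organ_b]).to_numpy(float)
    return _paired_t_from_diffs(diffs)


# ----------------------------------------------------------------------
# one-way ANOVA with LSD letters


@dataclass(frozen=True)
class AnovaLSD:
    f: float
    p: float
    df_between: int
    df_within: int
    mse: float
    means: dict
    letters: dict
    pairwise_p: pd.DataFrame
    protected: bool

    def summary(self) -> str:
        lines = [
            f"one-way ANOVA: F({self.df_between}, {self.df_within}) = {self.f:.3f}, p = {self.p:.4g}",
            "group means and LSD letters:",
        ]
        for g in sorted(self.means, key=lambda k: -self.means[k]):
            lines.append(f"  {g:>12s}  {self.means[g]:10.4g}  {self.letters[g]}")
        return "\n".join(lines)


def _compact_letters(order: Sequence[str], significant: set) -> dict:
    """Insert-and-absorb compact letter display.

    ``order`` lists groups by descending mean; ``significant`` holds
    frozensets {a, b} of significantly different pairs.  Groups sharing a
    letter are not significantly different.
    """
    sets = [set(order)]
    for pair in significant:
        a, b = tuple(pair)
        new_sets = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb duplicates and subsets
        sets = []
        for s in new_sets:
            if any(s < t or (s == t) for t in sets):
                continue
            sets = [t for t in sets if not t < s] + [s]
        sets = [s for s in sets if s]
    # order letter sets by the rank of their best (highest-mean) member
    rank = {g: i for i, g in enumerate(order)}
    sets.sort(key=lambda s: min(rank[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for i, s in enumerate(sets):
        for g in s:
            letters[g] += alphabet[i % len(alphabet)]
    return {g: "".join(sorted(letters[g])) for g in order}


def anova_lsd(groups: Mapping[str, Sequence[float]], alpha: float = 0.05, protected: bool = True) -> AnovaLSD:
    """One-way ANOVA with Fisher's LSD post hoc and letter display.

    Pairwise LSD t-tests use the pooled within-group mean square on
    N − k degrees of freedom.  With ``protected=True`` (default) the
    post hoc is only run when the omnibus ANOVA is significant at
    ``alpha``; otherwise all groups share one letter.
    """
    names = list(groups)
    data = {g: np.asarray(groups[g], float) for g in names}
    if len(names) < 2:
        raise InputError("ANOVA needs at least 2 groups")
    for g, v in data.items():
        if len(v) < 2:
            raise InputError(f"group {g!r} has fewer than 2 values")
    f, p = stats.f_oneway(*data.values())
    k = len(names)
    n_total = sum(len(v) for v in data.values())
    df_within = n_total - k
    mse = sum((len(v) - 1) * np.var(v, ddof=1) for v in data.values()) / df_within
    means = {g: float(np.mean(v)) for g, v in data.items()}

    pw = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    significant = set()
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            se = math.sqrt(mse * (1.0 / len(data[a]) + 1.0 / len(data[b])))
            if se == 0:
                pij = 1.0 if means[a] == means[b] else 0.0
            else:
                t = abs(means[a] - means[b]) / se
                pij = 2.0 * stats.t.sf(t, df_within)
            pw.loc[a, b] = pw.loc[b, a] = pij
            if pij < alpha:
                significant.add(frozenset((a, b)))
    if protected and not (p < alpha):
        significant = set()
    order = sorted(names, key=lambda g: -means[g])
    letters = _compact_letters(order, significant)
    return AnovaLSD(
        f=float(f), p=float(p), df_between=k - 1, df_within=df_within, mse=float(mse),
        means=means, letters=letters, pairwise_p=pw, protected=protected,
    )


# ----------------------------------------------------------------------
# OLS and SMA regression


@dataclass(frozen=True)
class OLSFit:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int

    def summary(self) -> str:
        return (
            f"OLS: y = {self.slope:.4f} x + {self.intercept:.4f}; "
            f"r2 = {self.r2:.4f}, p = {self.p:.4g}, n = {self.n}"
        )


@dataclass(frozen=True)
class SMAFit:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int

    def summary(self) -> str:
        return (
            f"SMA: y = {self.slope:.4f} x + {self.intercept:.4f}; "
            f"r2 = {self.r2:.4f}, p = {self.p:.4g}, n = {self.n}"
        )


def _complete_xy(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise InputError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise InputError("need at least 3 complete pairs")
    return x, y


def ols(x, y) -> OLSFit:
    """Ordinary least squares of y on x with two-sided slope test."""
    x, y = _complete_xy(x, y)
    if np.var(x) == 0:
        raise InputError("zero variance in x")
    res = stats.linregress(x, y)
    return OLSFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue**2), p=float(res.pvalue), n=len(x),
    )


def sma(x, y) -> SMAFit:
    """Standardized major axis fit: slope = sign(r)·sd(y)/sd(x).

    The intercept makes the line pass through the bivariate mean, and
    the p-value is that of the Pearson correlation (the SMA slope cannot
    be tested against zero, so association itself is tested).  Swapping
    x and y inverts the slope exactly.
    """
    x, y = _complete_xy(x, y)
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    if sx == 0 or sy == 0:
        raise InputError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    sign = -1.0 if r < 0 else 1.0
    slope = sign * sy / sx
    intercept = float(np.mean(y) - slope * np.mean(x))
    return SMAFit(slope=float(slope), intercept=intercept, r2=float(r**2), p=float(p), n=len(x))


# ----------------------------------------------------------------------
# PCA


@dataclass(frozen=True)
class PCAResult:
    loadings: pd.DataFrame        # trait x PC, orthonormal columns
    scores: pd.DataFrame          # (species, organ) x PC
    explained: np.ndarray         # variance fractions, sums to 1
    dropped: list = field(default_factory=list)

    def summary(self) -> str:
        parts = ", ".join(
            f"PC{i + 1} {frac * 100:.1f}%" for i, frac in enumerate(self.explained[:4])
        )
        out = f"PCA: {parts} (of {len(self.explained)} components)"
        if self.dropped:
            out += f"; dropped {len(self.dropped)} incomplete rows"
        return out


def pca(table: TraitTable | pd.DataFrame, traits: Sequence[str] | None = None, scale: bool = True) -> PCAResult:
    """PCA of the trait matrix on centered (and by default scaled) data.

    Rows with missing values in the selected traits are dropped and
    recorded in ``dropped``.  Component signs are fixed so the trait
    with the largest absolute loading on each PC loads positively.
    Variance fractions always sum to 1 (all components are retained).
    """
    from sklearn.decomposition import PCA as _SKPCA

    wide = table.wide if isinstance(table, TraitTable) else table
    traits = list(traits) if traits is not None else list(wide.columns)
    missing_cols = [t for t in traits if t not in wide.columns]
    if missing_cols:
        raise InputError(f"unknown traits: {missing_cols}")
    sub = wide[traits]
    complete = sub.dropna()
    dropped = [idx for idx in sub.index if idx not in complete.index]
    X = complete.to_numpy(float)
    if X.shape[0] < 3:
        raise InputError("need at least 3 complete rows for PCA")
    sd = X.std(axis=0, ddof=1)
    const = [traits[i] for i in range(len(traits)) if sd[i] == 0]
    if const:
        raise InputError(f"constant trait column(s): {const}")
    Z = X - X.mean(axis=0)
    if scale:
        Z = Z / sd
    model = _SKPCA(n_components=None, svd_solver="full")
    scores = model.fit_transform(Z)
    components = model.components_          # n_pc x n_traits
    # sign convention: the dominant trait on each PC loads positively
    for i in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] *= -1.0
            scores[:, i] *= -1.0
    pcs = [f"PC{i + 1}" for i in range(components.shape[0])]
    return PCAResult(
        loadings=pd.DataFrame(components.T, index=traits, columns=pcs),
        scores=pd.DataFrame(scores, index=complete.index, columns=pcs),
        explained=model.explained_variance_ratio_.copy(),
        dropped=dropped,
    )


# ----------------------------------------------------------------------
# convex hull overlap in PC space


@dataclass(frozen=True)
class HullOverlap:
    iou: float
    intersection_area: float
    union_area: float
    hull_areas: dict
    degenerate: list

    def summary(self) -> str:
        out = f"hull overlap (IoU) = {self.iou:.4f}"
        if self.degenerate:
            out += f"; degenerate (zero-area) groups: {self.degenerate}"
        return out


def hull_overlap(points, labels) -> HullOverlap:
    """Intersection-over-union of 2-D convex hulls of two groups.

    ``points`` is (n, 2) (e.g. PC1-PC2 scores) and ``labels`` assigns each
    row to one of exactly two groups.  Collinear groups yield a zero-area
    hull, are flagged, and contribute zero overlap.
    """
    from shapely.geometry import MultiPoint

    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InputError("points must be an (n, 2) array")
    labels = np.asarray(labels)
    names = sorted(set(labels.tolist()))
    if len(names) != 2:
        raise InputError("hull overlap is defined for exactly 2 groups")
    hulls, areas, degenerate = {}, {}, []
    for g in names:
        sub = pts[labels == g]
        if sub.shape[0] < 3:
            raise InputError(f"group {g!r} needs at least 3 points")
        hull = MultiPoint([tuple(p) for p in sub]).convex_hull
        hulls[g] = hull
        areas[g] = float(hull.area)
        if hull.area == 0:
            degenerate.append(g)
    a, b = (hulls[g] for g in names)
    inter = a.intersection(b).area
    union = a.union(b).area
    if union == 0:
        iou = 1.0 if a.equals(b) else 0.0
    else:
        iou = inter / union
    return HullOverlap(
        iou=float(iou), intersection_area=float(inter), union_area=float(union),
        hull_areas=areas, degenerate=degenerate,
    )
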