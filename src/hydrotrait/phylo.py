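"""Phylogenetic independent contrasts (PIC) and contrast correlations.

Under Brownian-motion trait evolution on a rooted tree with branch
lengths, the standardized differences at each internal node,

    contrast = (x_i − x_j) / sqrt(v_i + v_j),

are independent and identically distributed, where x_i, x_j are the
(estimated) trait values of the two daughter lineages and v_i, v_j their
effective branch lengths.  Felsenstein's pruning recursion estimates the
ancestral value at each node as the variance-weighted mean of its
daughters and inflates the node's own branch length by v_i·v_j/(v_i+v_j)
to account for estimation uncertainty.  A bifurcating tree with n tips
yields n − 1 contrasts.

Contrast-contrast association is tested with regression through the
origin (the sign of each contrast is arbitrary, so the fitted line must
pass through zero); the slope t-test uses (#contrasts − 1) degrees of
freedom, i.e. n_tips − 2 on a bifurcating tree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import stats

from .exceptions import ComputationError, InputError, NewickError

__all__ = ["Phylogeny", "ContrastSet", "PicCorrelation", "parse_newick", "pic", "pic_correlation"]


class Phylogeny:
    """A rooted, branch-length-bearing tree aligned to species codes.

    Thin wrapper over a :class:`dendropy.Tree`.  Tip labels must be
    unique; every branch needs a length.  Polytomies are accepted but
    resolved arbitrarily into bifurcations with zero-length branches
    (with a warning), so that the contrast count is always n_tips − 1.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self.polytomies_resolved = False
        self._validate_and_resolve()

    # -- construction --------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickError(f"malformed newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- validation ----------------------------------------------------
    def _validate_and_resolve(self):
        tree = self._tree
        tips = tree.leaf_nodes()
        if len(tips) < 2:
            raise NewickError("tree needs at least 2 tips")
        labels = [t.taxon.label if t.taxon else None for t in tips]
        if any(lab is None for lab in labels):
            raise NewickError("every tip must be labeled")
        if len(set(labels)) != len(labels):
            raise NewickError("tip labels must be unique")
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                if node.edge.length is None:
                    node.edge.length = 0.0
                continue
            if node.edge.length is None:
                name = node.taxon.label if node.taxon else "an internal node"
                raise NewickError(f"missing branch length on the edge above {name}")
            if node.edge.length < 0:
                raise NewickError("branch lengths must be nonnegative")
        if any(len(n.child_nodes()) > 2 for n in tree.preorder_internal_node_iter()):
            warnings.warn(
                "tree contains polytomies; resolving arbitrarily with zero-length branches",
                stacklevel=3,
            )
            tree.resolve_polytomies()
            for node in tree.preorder_node_iter():
                if node.edge.length is None:
                    node.edge.length = 0.0
            self.polytomies_resolved = True

    # -- accessors -----------------------------------------------------
    @property
    def tip_labels(self) -> list:
        return [t.taxon.label for t in self._tree.leaf_nodes()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    def vcv(self):
        """Brownian-motion covariance: C_ij = shared root-to-MRCA path length.

        Returns ``(labels, C)`` with rows/columns ordered as ``labels``.
        """
        tree = self._tree
        depth = {}
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            depth[node] = (depth[parent] if parent else 0.0) + (node.edge.length or 0.0)
        leaves = tree.leaf_nodes()
        labels = [t.taxon.label for t in leaves]
        n = len(leaves)
        pdm = tree.phylogenetic_distance_matrix()
        C = np.zeros((n, n))
        for i in range(n):
            C[i, i] = depth[leaves[i]]
            for j in range(i + 1, n):
                dij = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
                C[i, j] = C[j, i] = 0.5 * (depth[leaves[i]] + depth[leaves[j]] - dij)
        return labels, C

    def depth(self) -> float:
        """Maximum root-to-tip distance."""
        _, C = self.vcv()
        return float(np.max(np.diag(C)))


def parse_newick(text: str) -> Phylogeny:
    """Parse a newick string into a :class:`Phylogeny`."""
    return Phylogeny.from_newick(text)


@dataclass(frozen=True)
class ContrastSet:
    """Standardized contrasts, one per internal node (postorder)."""

    contrasts: np.ndarray
    node_tips: list          # frozenset of descendant tip labels per node
    ancestral_states: np.ndarray

    def __len__(self):
        return len(self.contrasts)


def pic(phylogeny: Phylogeny, traits: Mapping[str, float]) -> ContrastSet:
    """Felsenstein's phylogenetic independent contrasts for one trait.

    ``traits`` maps every tip label to a finite value.  Returns n − 1
    standardized contrasts for a bifurcating n-tip tree; a tree with
    resolved polytomies contributes zero-length branches, which is the
    conventional arbitrary-resolution treatment.
    """
    labels = phylogeny.tip_labels
    missing = [lab for lab in labels if lab not in traits or not math.isfinite(float(traits[lab]))]
    if missing:
        raise InputError(f"missing or non-finite trait values for tips: {sorted(missing)}")

    contrasts = []
    node_tips = []
    ancestral = []

    def visit(node):
        if node.is_leaf():
            return float(traits[node.taxon.label]), float(node.edge.length or 0.0), frozenset([node.taxon.label])
        children = node.child_nodes()
        assert len(children) == 2, "tree must be bifurcating after resolution"
        x1, v1, t1 = visit(children[0])
        x2, v2, t2 = visit(children[1])
        vsum = v1 + v2
        if vsum <= 0:
            if x1 == x2:
                c = 0.0
            else:
                raise ComputationError(
                    "zero total branch length at a node with differing child values"
                )
        else:
            c = (x1 - x2) / math.sqrt(vsum)
        contrasts.append(c)
        node_tips.append(t1 | t2)
        xa = x1 if vsum <= 0 else (x1 * v2 + x2 * v1) / vsum
        ancestral.append(xa)
        va = (node.edge.length or 0.0) + (0.0 if vsum <= 0 else v1 * v2 / vsum)
        return xa, va, t1 | t2

    visit(phylogeny.tree.seed_node)
    return ContrastSet(
        contrasts=np.asarray(contrasts, float),
        node_tips=node_tips,
        ancestral_states=np.asarray(ancestral, float),
    )


@dataclass(frozen=True)
class PicCorrelation:
    """Through-origin regression of one contrast set on another."""

    slope: float
    r2: float
    p: float
    n_contrasts: int
    df: int
    through_origin: bool
    intercept: float = 0.0

    def summary(self) -> str:
        kind = "through origin" if self.through_origin else "with intercept"
        return (
            "PIC correlation ({})\n"
            "slope = {:.4f}, r2 = {:.4f}, p = {:.4g} "
            "({} contrasts, {} df)".format(kind, self.slope, self.r2, self.p, self.n_contrasts, self.df)
        )


def pic_correlation(
    phylogeny: Phylogeny,
    trait_x: Mapping[str, float],
    trait_y: Mapping[str, float],
    through_origin: bool = True,
) -> PicCorrelation:
    """Test for correlated evolution of two traits via their contrasts.

    The default through-origin model is the field standard: contrast
    signs depend on an arbitrary child ordering, and only a zero-intercept
    fit is invariant to flipping them.  A with-intercept mode is provided
    for sensitivity analysis.
    """
    cx = pic(phylogeny, trait_x).contrasts
    cy = pic(phylogeny, trait_y).contrasts
    m = len(cx)
    if m < 3:
        raise ComputationError("fewer than 3 contrasts: correlation statistics undefined")
    if through_origin:
        sxx = float(np.sum(cx * cx))
        syy = float(np.sum(cy * cy))
        if sxx == 0 or syy == 0:
            raise ComputationError("zero contrast variance; correlation undefined")
        sxy = float(np.sum(cx * cy))
        slope = sxy / sxx
        resid = cy - slope * cx
        sse = float(np.sum(resid**2))
        r2 = 1.0 - sse / syy
        df = m - 1
        if sse <= 1e-15 * syy:
            p = 0.0
        else:
            se = math.sqrt(sse / df / sxx)
            t = slope / se
            p = 2.0 * stats.t.sf(abs(t), df)
        return PicCorrelation(slope=slope, r2=r2, p=p, n_contrasts=m, df=df, through_origin=True)
    res = stats.linregress(cx, cy)
    return PicCorrelation(
        slope=float(res.slope), r2=float(res.rvalue**2), p=float(res.pvalue),
        n_contrasts=m, df=m - 2, through_origin=False, intercept=float(res.intercept),
    )
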