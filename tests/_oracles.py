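"""Independent brute-force oracles used to validate the implementation.

The GLS contrast oracle below never touches hydrotrait's pruning code:
it rebuilds each subtree's Brownian-motion covariance matrix from shared
path lengths and estimates ancestral values by generalized least squares
(matrix inversion), which is algebraically equivalent to — but
computationally disjoint from — Felsenstein's recursion.
"""

import dendropy
import numpy as np


def _subtree_gls(node, traits):
    """GLS estimate (xhat, var) of the trait value at ``node``.

    Uses the covariance matrix C of the node's descendant tips, with
    C_ij = path length from ``node`` to the MRCA of tips i and j, and
    xhat = (1'C^-1 x)/(1'C^-1 1), var = 1/(1'C^-1 1).
    """
    if node.is_leaf():
        return float(traits[node.taxon.label]), 0.0
    leaves = node.leaf_nodes()
    # depth of every descendant from `node`
    depth = {node: 0.0}
    stack = [node]
    while stack:
        nd = stack.pop()
        for ch in nd.child_nodes():
            depth[ch] = depth[nd] + ch.edge.length
            stack.append(ch)
    # ancestor chains within the subtree
    chains = {}
    for leaf in leaves:
        chain = []
        nd = leaf
        while nd is not node:
            chain.append(nd)
            nd = nd.parent_node
        chain.append(node)
        chains[leaf] = chain
    n = len(leaves)
    C = np.zeros((n, n))
    for i, li in enumerate(leaves):
        C[i, i] = depth[li]
        for j in range(i + 1, n):
            lj = leaves[j]
            common = [nd for nd in chains[li] if nd in chains[lj]]
            mrca = min(common, key=lambda nd: -depth[nd])  # deepest shared node
            C[i, j] = C[j, i] = depth[mrca]
    x = np.array([traits[leaf.taxon.label] for leaf in leaves], float)
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    denom = ones @ Cinv @ ones
    return float((ones @ Cinv @ x) / denom), float(1.0 / denom)


def gls_contrasts(newick: str, traits: dict) -> dict:
    """Standardized contrasts keyed by frozenset of descendant tip labels."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    out = {}
    for node in tree.postorder_internal_node_iter():
        ch = node.child_nodes()
        assert len(ch) == 2
        xa, ua = _subtree_gls(ch[0], traits)
        xb, ub = _subtree_gls(ch[1], traits)
        va = ch[0].edge.length + ua
        vb = ch[1].edge.length + ub
        tips = frozenset(l.taxon.label for l in node.leaf_nodes())
        out[tips] = (xa - xb) / np.sqrt(va + vb)
    return out
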