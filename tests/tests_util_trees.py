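"""Shared test helpers: path-length metrics on trees."""

import numpy as np


def tree_metric(tree):
    """Additive leaf-to-leaf distance matrix of a PhyloTree, with leaf labels."""
    chains = []
    for v in range(tree.n_nodes):
        chain = {}
        x, dist = v, 0.0
        while x >= 0:
            chain[x] = dist
            dist += tree.blen[x]
            x = int(tree.parent[x])
        chains.append(chain)
    leaves = [v for v in range(tree.n_nodes) if tree.labels[v] is not None]
    labels = [tree.labels[v] for v in leaves]
    n = len(leaves)
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            va, vb = leaves[a], leaves[b]
            shared = set(chains[va]) & set(chains[vb])
            D[a, b] = D[b, a] = min(chains[va][c] + chains[vb][c] for c in shared)
    return D, labels
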