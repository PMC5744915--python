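"""Independently coded oracles used by the acceptance suite.

These deliberately avoid the package's own code paths: explicit matrix
inverses and Python loops instead of the solver/statistic implementations
they are checking.
"""

import numpy as np

from opershape.phylo import ancestral_scp


def blomberg_k_direct(tree, y):
    """Univariate Blomberg K from its direct formula (explicit inverse)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    C = tree.vcv()
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    a = float(ones @ Cinv @ y) / float(ones @ Cinv @ ones)
    mse0 = float((y - a) @ (y - a)) / (n - 1)
    mse = float((y - a) @ Cinv @ (y - a)) / (n - 1)
    expected_ratio = (np.trace(C) - n / float(ones @ Cinv @ ones)) / (n - 1)
    return (mse0 / mse) / expected_ratio


def c_metrics_enumeration(tree, scores, tip_a, tip_b):
    """C1-C4 for one focal pair by explicit enumeration of cross-lineage
    state pairs and per-edge state changes."""
    tips = np.array([scores[t] for t in tree.tip_labels], dtype=float)
    anc = ancestral_scp(tree, tips)
    states = np.zeros((tree.n_nodes, 2))
    states[tree.tip_indices] = tips
    states[anc.node_indices] = anc.values

    ia, ib = tree.tip_index(tip_a), tree.tip_index(tip_b)
    m = tree.mrca(ia, ib)

    def lineage(tip):
        path = [tip]
        while path[-1] != m:
            path.append(int(tree.parent[path[-1]]))
        return path

    lin_a, lin_b = lineage(ia), lineage(ib)
    dtip = float(np.linalg.norm(states[ia] - states[ib]))
    dmax = max(
        float(np.linalg.norm(states[u] - states[v]))
        for u in lin_a
        for v in lin_b
    )
    c1 = 1.0 - dtip / dmax
    c2 = dmax - dtip
    lineage_evol = sum(
        float(np.linalg.norm(states[n] - states[int(tree.parent[n])]))
        for n in lin_a[:-1] + lin_b[:-1]
    )
    clade_evol = sum(
        float(np.linalg.norm(states[n] - states[int(tree.parent[n])]))
        for n in tree.subtree_nodes(m)
        if n != m
    )
    return c1, c2, c2 / lineage_evol, c2 / clade_evol
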