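"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive (enumeration, matrix exponentials,
path walking) and shares no code with the package internals it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm


def rate_matrix(q01: float, q10: float) -> np.ndarray:
    return np.array([[-q01, q01], [q10, -q10]])


def pmat_expm(q01: float, q10: float, t: float) -> np.ndarray:
    """Transition matrix by scipy's matrix exponential."""
    return expm(rate_matrix(q01, q10) * t)


def _node_info(tree):
    """(nodes, parent index, branch length, tip state slot) in postorder."""
    nodes = tree.postorder()
    index = {id(n): i for i, n in enumerate(nodes)}
    parent = [index[id(n.parent)] if n.parent is not None else -1 for n in nodes]
    brlen = [n.length if n.length is not None else 0.0 for n in nodes]
    return nodes, index, parent, brlen


def enum_likelihood(tree, states: dict, q01: float, q10: float, pi=(0.5, 0.5)):
    """Likelihood by summing over every assignment of unobserved node states.

    *states* maps tip labels to 0/1/None; None (and all internal nodes) are
    enumerated.  Exponential in tree size: use only on tiny trees.
    """
    nodes, index, parent, brlen = _node_info(tree)
    P = [pmat_expm(q01, q10, brlen[i]) for i in range(len(nodes))]
    free = [
        i
        for i, n in enumerate(nodes)
        if (not n.is_leaf) or states[n.label] is None
    ]
    fixed = {
        i: states[n.label]
        for i, n in enumerate(nodes)
        if n.is_leaf and states[n.label] is not None
    }
    total = 0.0
    for combo in itertools.product((0, 1), repeat=len(free)):
        assign = dict(fixed)
        assign.update(dict(zip(free, combo)))
        prob = pi[assign[len(nodes) - 1]]
        for i in range(len(nodes) - 1):
            prob *= P[i][assign[parent[i]], assign[i]]
        total += prob
    return total


def enum_marginals(tree, states: dict, q01: float, q10: float, pi=(0.5, 0.5)):
    """Exact per-node posterior P(state 1 | tips) by full enumeration."""
    nodes, index, parent, brlen = _node_info(tree)
    P = [pmat_expm(q01, q10, brlen[i]) for i in range(len(nodes))]
    free = [
        i
        for i, n in enumerate(nodes)
        if (not n.is_leaf) or states[n.label] is None
    ]
    fixed = {
        i: states[n.label]
        for i, n in enumerate(nodes)
        if n.is_leaf and states[n.label] is not None
    }
    weight1 = np.zeros(len(nodes))
    total = 0.0
    for combo in itertools.product((0, 1), repeat=len(free)):
        assign = dict(fixed)
        assign.update(dict(zip(free, combo)))
        prob = pi[assign[len(nodes) - 1]]
        for i in range(len(nodes) - 1):
            prob *= P[i][assign[parent[i]], assign[i]]
        total += prob
        for i in range(len(nodes)):
            if assign[i] == 1:
                weight1[i] += prob
    return weight1 / total


def tip_path_lengths(tree) -> dict:
    """{frozenset({a, b}): path length} over all tip pairs, by root walks."""
    paths = {}
    for tip in tree.tips():
        chain = []
        node = tip
        dist = 0.0
        while node is not None:
            chain.append((id(node), dist))
            dist += node.length or 0.0
            node = node.parent
        paths[tip.label] = dict(chain)
    out = {}
    labels = list(paths)
    for a, b in itertools.combinations(labels, 2):
        pa, pb = paths[a], paths[b]
        best = min(pa[k] + pb[k] for k in pa.keys() & pb.keys())
        out[frozenset((a, b))] = best
    return out


def bruteforce_mrca(tree, taxa):
    """MRCA by intersecting full ancestor sets, deepest common ancestor."""
    ancestor_sets = []
    for label in taxa:
        tip = next(n for n in tree.tips() if n.label == label)
        anc = set()
        node = tip
        while node is not None:
            anc.add(id(node))
            node = node.parent
        ancestor_sets.append(anc)
    common = set.intersection(*ancestor_sets)

    def depth(node):
        d = 0
        while node.parent is not None:
            d += 1
            node = node.parent
        return d

    candidates = [n for n in tree.postorder() if id(n) in common]
    return max(candidates, key=depth)


def bruteforce_single_copy_size(og) -> int:
    """Maximum distinct-taxon count over all single-copy candidate clades.

    Same-taxon tips forming a monophyletic group are first collapsed by a
    cherry-merge fixpoint; then every node's induced clade is scored,
    requiring at most one tip per taxon.
    """
    tree = og.copy()
    # fixpoint: merge any internal node whose clade is a single taxon
    changed = True
    while changed:
        changed = False
        for node in tree.postorder():
            if node.is_leaf:
                continue
            tips = node.clade_tips()
            taxa = {t.label.split("|", 1)[0] for t in tips}
            if len(taxa) == 1 and len(tips) > 1:
                node.children = []
                node.label = tips[0].label
                changed = True
                break
        if changed:
            tree = type(tree)(tree.root)
    best = 0
    for node in tree.postorder():
        labels = [t.label for t in node.clade_tips()]
        taxa = [l.split("|", 1)[0] for l in labels]
        if len(set(taxa)) == len(taxa):
            best = max(best, len(taxa))
    return best


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration."""
    from math import comb

    n = a + b + c + d
    row1 = a + b
    col1 = a + c

    def pmf(x):
        return comb(col1, x) * comb(n - col1, row1 - x) / comb(n, row1)

    p_obs = pmf(a)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))
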