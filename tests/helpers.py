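"""Independent test oracles shared across test modules.

Everything here is deliberately implemented by routes different from the
package: additive distances are read off a randomly grown tree by explicit
path summation, and Fisher p-values are enumerated with exact rational
arithmetic.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

from mitoarray.phylogeny import TreeNode


def random_additive_tree(rng: np.random.Generator, n: int):
    """Grow a random unrooted binary tree with positive branch lengths by
    splitting a uniformly chosen edge for each new leaf."""
    ids = [f"t{i}" for i in range(n)]
    root = TreeNode(
        children=[
            TreeNode(ids[0], float(rng.uniform(0.1, 1.0))),
            TreeNode(ids[1], float(rng.uniform(0.1, 1.0))),
            TreeNode(ids[2], float(rng.uniform(0.1, 1.0))),
        ]
    )
    edges = list(root.children)
    parents = {id(c): root for c in root.children}
    for k in range(3, n):
        target = edges[int(rng.integers(0, len(edges)))]
        par = parents[id(target)]
        newleaf = TreeNode(ids[k], float(rng.uniform(0.1, 1.0)))
        upper = float(target.length) * float(rng.uniform(0.2, 0.8))
        inner = TreeNode(length=upper, children=[newleaf, target])
        target.length = target.length - upper + float(rng.uniform(0.05, 0.5))
        par.children[par.children.index(target)] = inner
        parents[id(inner)] = par
        parents[id(target)] = inner
        parents[id(newleaf)] = inner
        edges.extend([newleaf, inner])
    return root, ids


def tree_path_distances(root: TreeNode, ids: list[str]) -> np.ndarray:
    """Leaf-to-leaf distances by summing branch lengths over the unique
    paths (the definition of tree additivity)."""
    paths: dict[str, dict[int, float]] = {}

    def walk(node: TreeNode, acc: list[tuple[int, float]]):
        if node.is_leaf():
            paths[node.name] = dict(acc)
        for c in node.children:
            walk(c, acc + [(id(c), c.length)])

    walk(root, [])
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = paths[ids[i]], paths[ids[j]]
            d = sum(l for e, l in pi.items() if e not in pj)
            d += sum(l for e, l in pj.items() if e not in pi)
            D[i, j] = D[j, i] = d
    return D


def fisher_exact_fraction(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exhaustive enumeration in exact arithmetic."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    denom = comb(n, col1)

    def pmf(x: int) -> Fraction:
        return Fraction(comb(row1, x) * comb(n - row1, col1 - x), denom)

    p_obs = pmf(a)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs)
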