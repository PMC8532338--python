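"""Pairwise distances, neighbor joining and site-resampling bootstrap.

The distance models are the standard closed forms on aligned SNP columns:
p-distance (mismatch proportion), Kimura two-parameter
``d = -1/2 ln((1-2P-Q) sqrt(1-2Q))`` with P/Q the transition/transversion
proportions, and Tamura–Nei 1993 with empirical base frequencies.  Missing
bases (``N``) are excluded pairwise by default.  Saturated pairs (a log
argument at or below zero) raise :class:`SaturationError` naming the pair
rather than returning NaN.

Neighbor joining is the Saitou–Nei agglomeration with deterministic
tie-breaking (lowest (row, column) pair in the current working order, newly
joined nodes appended at the end), so reruns are byte-identical.  On an
additive (tree-metric) input it recovers the generating topology and branch
lengths exactly.

Bootstrap support for each internal bipartition of the tree built from the
full matrix is the percentage of column-resampled replicate trees containing
that bipartition.  Internal edges of length <= 1e-12 are collapsed before
bipartitions are read off: a zero-length edge carries no signal, so an
all-monomorphic matrix yields no supported clades at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np

from .seqio import SiteMatrix

__all__ = [
    "BootstrapConfig",
    "DistanceMatrix",
    "SaturationError",
    "SupportedTree",
    "TreeNode",
    "bootstrap_tree",
    "neighbor_joining",
    "pairwise_distance",
    "read_newick",
    "robinson_foulds",
    "write_newick",
]

logger = logging.getLogger(__name__)

Model = Literal["p", "k2p", "tn93"]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
# purines A(0),G(2); pyrimidines C(1),T(3)
_ZERO_EDGE = 1e-12


class SaturationError(ValueError):
    """A distance model's log argument left its domain for some pair."""


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix must be finite")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.values[i, j])


def encode_matrix(matrix: SiteMatrix) -> np.ndarray:
    """(n_samples, n_sites) uint8 encoding with A=0 C=1 G=2 T=3 N=4."""
    table = np.full(256, 255, dtype=np.uint8)
    for b, c in _CODE.items():
        table[ord(b)] = c
    enc = np.vstack(
        [table[np.frombuffer(row.encode("ascii"), dtype=np.uint8)] for row in matrix.rows]
    )
    if np.any(enc == 255):
        raise ValueError("site matrix contains characters outside A/C/G/T/N")
    return enc


def _pair_counts(enc: np.ndarray) -> dict[str, np.ndarray]:
    """Pairwise co-occurrence counts via indicator matrix products.

    Returns n x n arrays: comparable-site counts L, mismatches nd,
    A<->G transitions P1n, C<->T transitions P2n, transversions Qn, and the
    per-pair base-count totals ``base[b]`` (summed over both rows of the
    pair, for TN93 frequency estimates).
    """
    ind = [(enc == b).astype(np.float64) for b in range(4)]
    C = {}
    for b in range(4):
        for c in range(4):
            C[(b, c)] = ind[b] @ ind[c].T
    L = sum(C[(b, c)] for b in range(4) for c in range(4))
    match = sum(C[(b, b)] for b in range(4))
    p1 = C[(0, 2)] + C[(2, 0)]
    p2 = C[(1, 3)] + C[(3, 1)]
    nd = L - match
    qn = nd - p1 - p2
    valid = sum(ind)  # 1 where base is not N
    base = {}
    for b in range(4):
        base[b] = ind[b] @ valid.T + valid @ ind[b].T
    return {"L": L, "nd": nd, "P1": p1, "P2": p2, "Q": qn, "base": base}


def _first_bad_pair(mask: np.ndarray, ids: Sequence[str]) -> tuple[str, str]:
    i, j = np.argwhere(mask)[0]
    return ids[i], ids[j]


def distances_from_encoded(
    enc: np.ndarray, ids: Sequence[str], model: Model = "k2p"
) -> np.ndarray:
    n = enc.shape[0]
    cnt = _pair_counts(enc)
    L, nd = cnt["L"], cnt["nd"]
    off = ~np.eye(n, dtype=bool)
    if np.any((L == 0) & off):
        a, b = _first_bad_pair((L == 0) & off, ids)
        raise ValueError(f"zero comparable sites between {a!r} and {b!r}")
    Lsafe = np.where(L == 0, 1.0, L)
    if model == "p":
        d = nd / Lsafe
    elif model == "k2p":
        P = cnt["P1"] / Lsafe + cnt["P2"] / Lsafe
        Q = cnt["Q"] / Lsafe
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        bad = ((w1 <= 0) | (w2 <= 0)) & off
        if np.any(bad):
            a, b = _first_bad_pair(bad, ids)
            raise SaturationError(f"K2P distance undefined (saturated) for {a!r}/{b!r}")
        d = -0.5 * np.log(np.where(off, w1, 1.0)) - 0.25 * np.log(
            np.where(off, w2, 1.0)
        )
    elif model == "tn93":
        d = _tn93(cnt, off, ids, Lsafe)
    else:
        raise ValueError(f"unknown distance model {model!r}")
    d = np.where(off, d, 0.0)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def _tn93(cnt, off, ids, Lsafe) -> np.ndarray:
    P1 = cnt["P1"] / Lsafe
    P2 = cnt["P2"] / Lsafe
    Q = cnt["Q"] / Lsafe
    tot = sum(cnt["base"][b] for b in range(4))
    tot = np.where(tot == 0, 1.0, tot)
    gA = cnt["base"][0] / tot
    gC = cnt["base"][1] / tot
    gG = cnt["base"][2] / tot
    gT = cnt["base"][3] / tot
    gR = gA + gG
    gY = gC + gT
    with np.errstate(divide="ignore", invalid="ignore"):
        k1 = 2.0 * gA * gG / np.where(gR == 0, 1.0, gR)
        k2 = 2.0 * gC * gT / np.where(gY == 0, 1.0, gY)
        k3 = 2.0 * (
            gR * gY
            - gA * gG * gY / np.where(gR == 0, 1.0, gR)
            - gC * gT * gR / np.where(gY == 0, 1.0, gY)
        )
        w1 = 1.0 - P1 / np.where(k1 == 0, 1.0, k1) - Q / np.where(gR == 0, 1.0, 2.0 * gR)
        w2 = 1.0 - P2 / np.where(k2 == 0, 1.0, k2) - Q / np.where(gY == 0, 1.0, 2.0 * gY)
        den3 = 2.0 * gR * gY
        w3 = 1.0 - Q / np.where(den3 == 0, 1.0, den3)
    # degenerate compositions: a term with no corresponding changes drops out
    deg1 = (k1 == 0) & (P1 > 0)
    deg2 = (k2 == 0) & (P2 > 0)
    deg3 = (den3 == 0) & (Q > 0)
    bad = ((w1 <= 0) | (w2 <= 0) | (w3 <= 0) | deg1 | deg2 | deg3) & off
    if np.any(bad):
        a, b = _first_bad_pair(bad, ids)
        raise SaturationError(f"TN93 distance undefined (saturated) for {a!r}/{b!r}")
    t1 = np.where(k1 > 0, -k1 * np.log(np.where(w1 > 0, w1, 1.0)), 0.0)
    t2 = np.where(k2 > 0, -k2 * np.log(np.where(w2 > 0, w2, 1.0)), 0.0)
    t3 = np.where(den3 > 0, -k3 * np.log(np.where(w3 > 0, w3, 1.0)), 0.0)
    return t1 + t2 + t3


def pairwise_distance(
    matrix: SiteMatrix, model: Model = "k2p", missing: str = "pairwise"
) -> DistanceMatrix:
    """Distance matrix under p/K2P/TN93 with pairwise deletion of ``N``.

    ``missing='complete'`` drops every column containing any ``N`` before
    computing distances.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if matrix.n_sites < 1:
        raise ValueError("need at least 1 site")
    enc = encode_matrix(matrix)
    if missing == "complete":
        enc = enc[:, ~np.any(enc == 4, axis=0)]
        if enc.shape[1] == 0:
            raise ValueError("no complete columns left after complete deletion")
    elif missing != "pairwise":
        raise ValueError(f"unknown missing-data mode {missing!r}")
    d = distances_from_encoded(enc, matrix.ids, model)
    return DistanceMatrix(matrix.ids, d)


# -- trees ---------------------------------------------------------------


class TreeNode:
    """A rooted view of an (unrooted) tree; the NJ root is a trifurcation."""

    __slots__ = ("name", "length", "children")

    def __init__(
        self,
        name: str | None = None,
        length: float = 0.0,
        children: list["TreeNode"] | None = None,
    ):
        self.name = name
        self.length = length
        self.children = children if children is not None else []

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def postorder(self) -> Iterator["TreeNode"]:
        for c in self.children:
            yield from c.postorder()
        yield self


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; returns the unrooted tree rooted at the
    final three-way join."""
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    D = dm.values.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # first minimum in row-major order: lowest (i, j)
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        new = TreeNode(children=[child_i, child_j])
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D2[: m - 2, m - 2] = dnew[keep]
        D2[m - 2, : m - 2] = dnew[keep]
        D2[m - 2, m - 2] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
    # final three-way join with closed-form lengths
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    nodes[0].length = 0.5 * (d01 + d02 - d12)
    nodes[1].length = 0.5 * (d01 + d12 - d02)
    nodes[2].length = 0.5 * (d02 + d12 - d01)
    return TreeNode(children=nodes)


def _canonical(side: frozenset[str], all_leaves: frozenset[str]) -> frozenset[str]:
    anchor = min(all_leaves)
    return all_leaves - side if anchor in side else side


def internal_bipartitions(
    root: TreeNode, collapse_zero: bool = True
) -> dict[frozenset[str], TreeNode]:
    """Canonical internal bipartitions (side not containing the anchor leaf).

    With ``collapse_zero`` (the default), internal edges of length <= 1e-12
    are skipped — they carry no signal and are treated as polytomies.
    """
    all_leaves = root.leaf_names()
    n = len(all_leaves)
    out: dict[frozenset[str], TreeNode] = {}
    leafsets: dict[int, frozenset[str]] = {}
    for node in root.postorder():
        if node.is_leaf():
            leafsets[id(node)] = frozenset([node.name])
            continue
        ls = frozenset().union(*(leafsets[id(c)] for c in node.children))
        leafsets[id(node)] = ls
        if node is root:
            continue
        if 2 <= len(ls) <= n - 2:
            if collapse_zero and node.length <= _ZERO_EDGE:
                continue
            out[_canonical(ls, all_leaves)] = node
    return out


def robinson_foulds(a: TreeNode, b: TreeNode) -> int:
    """Unweighted RF distance: symmetric difference of internal bipartitions
    (zero-length edges are *not* collapsed here)."""
    if a.leaf_names() != b.leaf_names():
        raise ValueError("trees must share a leaf set")
    ba = set(internal_bipartitions(a, collapse_zero=False))
    bb = set(internal_bipartitions(b, collapse_zero=False))
    return len(ba ^ bb)


@dataclass(frozen=True)
class BootstrapConfig:
    replicates: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class SupportedTree:
    """An NJ topology plus bootstrap support per internal bipartition.

    ``supports`` maps the canonical side of each non-collapsed internal edge
    to a percentage in [0, 100].  Trivial (single-leaf) splits are present in
    every resampled replicate by construction and are treated as 100.
    """

    root: TreeNode
    supports: dict[frozenset[str], float]

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def sides(self) -> Iterator[tuple[frozenset[str], float]]:
        """Every candidate branch = one side of any edge, with its support.

        Yields both sides of every non-collapsed edge; trivial splits get
        support 100.
        """
        all_leaves = self.leaf_names()
        for side, _node in internal_bipartitions(self.root).items():
            sup = self.supports.get(side, 0.0)
            yield side, sup
            yield all_leaves - side, sup
        for name in sorted(all_leaves):
            yield frozenset([name]), 100.0
            yield all_leaves - {name}, 100.0


def bootstrap_tree(
    matrix: SiteMatrix,
    model: Model = "k2p",
    config: BootstrapConfig = BootstrapConfig(),
    missing: str = "pairwise",
) -> SupportedTree:
    """NJ tree from the full matrix plus column-resampling bootstrap supports.

    Replicate ``r`` draws its columns from an RNG stream seeded by
    ``(seed, r)`` so runs are reproducible and independent of execution
    order.  Replicates on which the distance model is undefined (saturated)
    are redrawn from a fresh stream, with a log note.
    """
    dm = pairwise_distance(matrix, model=model, missing=missing)
    root = neighbor_joining(dm)
    orig = internal_bipartitions(root)
    counts = {side: 0 for side in orig}
    enc = encode_matrix(matrix)
    if missing == "complete":
        enc = enc[:, ~np.any(enc == 4, axis=0)]
    n_cols = enc.shape[1]
    for r in range(config.replicates):
        for attempt in range(100):
            rng = np.random.default_rng([config.seed, r, attempt])
            idx = rng.integers(0, n_cols, size=n_cols)
            try:
                d = distances_from_encoded(enc[:, idx], matrix.ids, model)
            except (SaturationError, ValueError) as exc:
                logger.warning("bootstrap replicate %d redrawn: %s", r, exc)
                continue
            rep_root = neighbor_joining(DistanceMatrix(matrix.ids, d))
            rep_biparts = set(internal_bipartitions(rep_root))
            for side in counts:
                if side in rep_biparts:
                    counts[side] += 1
            break
        else:
            raise SaturationError(
                f"bootstrap replicate {r} failed 100 redraw attempts"
            )
    supports = {
        side: 100.0 * c / config.replicates for side, c in counts.items()
    }
    return SupportedTree(root=root, supports=supports)


# -- newick --------------------------------------------------------------


def to_newick(tree: SupportedTree | TreeNode) -> str:
    """Serialize with supports as internal node labels; negative branch
    lengths are floored at zero on output."""
    if isinstance(tree, SupportedTree):
        root = tree.root
        all_leaves = tree.leaf_names()
        supports = tree.supports
    else:
        root, all_leaves, supports = tree, tree.leaf_names(), {}

    leafsets: dict[int, frozenset[str]] = {}
    for node in root.postorder():
        if node.is_leaf():
            leafsets[id(node)] = frozenset([node.name])
        else:
            leafsets[id(node)] = frozenset().union(
                *(leafsets[id(c)] for c in node.children)
            )

    def fmt_len(x: float) -> str:
        return repr(max(0.0, float(x)))

    def render(node: TreeNode, is_root: bool) -> str:
        if node.is_leaf():
            return f"{node.name}:{fmt_len(node.length)}"
        inner = ",".join(render(c, False) for c in node.children)
        if is_root:
            return f"({inner});"
        label = ""
        key = _canonical(leafsets[id(node)], all_leaves)
        if key in supports:
            label = f"{supports[key]:g}"
        return f"({inner}){label}:{fmt_len(node.length)}"

    return render(root, True)


def write_newick(tree: SupportedTree | TreeNode, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n", encoding="utf-8")


def read_newick(source: str | Path, is_string: bool = False) -> SupportedTree:
    """Parse a newick tree (supports stored as internal node labels)."""
    import dendropy

    text = str(source) if is_string else Path(source).read_text(encoding="utf-8")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            return TreeNode(
                name=dnode.taxon.label.replace(" ", "_"),
                length=dnode.edge.length or 0.0,
            )
        node = TreeNode(
            name=dnode.label,
            length=dnode.edge.length or 0.0,
            children=[convert(c) for c in dnode.child_nodes()],
        )
        return node

    root = convert(dtree.seed_node)
    all_leaves = root.leaf_names()
    supports: dict[frozenset[str], float] = {}
    leafsets: dict[int, frozenset[str]] = {}
    for node in root.postorder():
        if node.is_leaf():
            leafsets[id(node)] = frozenset([node.name])
            continue
        ls = frozenset().union(*(leafsets[id(c)] for c in node.children))
        leafsets[id(node)] = ls
        if node is root or not node.name:
            continue
        try:
            sup = float(node.name)
        except ValueError:
            continue
        if 2 <= len(ls) <= len(all_leaves) - 2:
            supports[_canonical(ls, all_leaves)] = sup
        node.name = None
    return SupportedTree(root=root, supports=supports)
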