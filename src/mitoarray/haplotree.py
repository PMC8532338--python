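"""Haplogroup nomenclature and PhyloTree-style haplogroup phylogenies.

A haplogroup label is an alternating letter/digit string ("L0b1a", "H", "M");
its *level* is simply its character count (L0 = 2, L0d = 3, L0d1 = 4).  A
:class:`HaplogroupTree` is a rooted tree of labels in which every branch
carries the clade-defining substitutions (1-based reference position plus
derived base) accumulated on that branch.  Version 1 assumes an
infinite-sites history: each position mutates on at most one branch and
never reverts, so the defining mutations of a haplogroup are exactly the
union of the mutations on its root path.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple

__all__ = [
    "DefiningMutation",
    "HaplogroupTree",
    "level",
    "load_haplotree",
    "path_mutations",
    "prefix_compatible",
    "truncate_label",
    "write_haplotree",
]

_BASES = frozenset("ACGT")
# letters and digits alternating in groups, starting with a letter
_LABEL_RE = re.compile(r"^[A-Za-z]+(?:[0-9]+[A-Za-z]+)*[0-9]*$")


class DefiningMutation(NamedTuple):
    """A clade-defining substitution: 1-based position and derived base."""

    position: int
    derived_base: str


def validate_label(label: str) -> str:
    if not label or not _LABEL_RE.match(label):
        raise ValueError(f"malformed haplogroup label: {label!r}")
    return label


def level(label: str) -> int:
    """Nomenclature depth of a label = its character count ('L0d1' -> 4)."""
    return len(label)


def truncate_label(label: str, lvl: int) -> str:
    """Truncate a label to at most ``lvl`` characters ('L0b1a', 3 -> 'L0b')."""
    if lvl < 1:
        raise ValueError(f"level must be >= 1, got {lvl}")
    return label[:lvl]


def prefix_compatible(a: str, b: str) -> bool:
    """True iff one label is a prefix of the other.

    This is the resolution-blind notion of agreement between two haplogroup
    calls: assigning "L0" where the truth is "L0a2a" is compatible, while
    "L1" versus "L2a" is not.
    """
    return a.startswith(b) or b.startswith(a)


@dataclass(frozen=True)
class HaplogroupTree:
    """Rooted haplogroup phylogeny with per-branch defining mutations.

    ``parent`` maps every label to its parent label (``None`` for the root);
    ``branch_mutations`` maps every label to the mutations on the branch
    leading *into* it (empty for the root).
    """

    root: str
    parent: Mapping[str, str | None]
    branch_mutations: Mapping[str, tuple[DefiningMutation, ...]]
    _children: Mapping[str, tuple[str, ...]] = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self._children is None:
            kids: dict[str, list[str]] = {lab: [] for lab in self.parent}
            for lab, par in self.parent.items():
                if par is not None:
                    kids[par].append(lab)
            object.__setattr__(
                self, "_children", {k: tuple(sorted(v)) for k, v in kids.items()}
            )

    @staticmethod
    def from_nodes(
        nodes: Iterable[tuple[str, str | None, Iterable[DefiningMutation]]],
    ) -> "HaplogroupTree":
        """Build and validate a tree from (label, parent, mutations) rows."""
        parent: dict[str, str | None] = {}
        muts: dict[str, tuple[DefiningMutation, ...]] = {}
        for label, par, mm in nodes:
            validate_label(label)
            if label in parent:
                raise ValueError(f"duplicate haplogroup label: {label!r}")
            parent[label] = par
            muts[label] = tuple(mm)
        roots = [lab for lab, par in parent.items() if par is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        root = roots[0]
        for lab, par in parent.items():
            if par is not None and par not in parent:
                raise ValueError(f"unknown parent {par!r} for haplogroup {lab!r}")
        # reachability from root doubles as the cycle check
        children: dict[str, list[str]] = {lab: [] for lab in parent}
        for lab, par in parent.items():
            if par is not None:
                children[par].append(lab)
        seen: set[str] = set()
        stack = [root]
        while stack:
            node = stack.pop()
            seen.add(node)
            stack.extend(children[node])
        if len(seen) != len(parent):
            orphans = sorted(set(parent) - seen)
            raise ValueError(f"cycle or disconnected nodes: {orphans}")
        # infinite-sites: a position appears on at most one branch
        pos_owner: dict[int, str] = {}
        for lab, mm in muts.items():
            for m in mm:
                if m.position < 1:
                    raise ValueError(f"position must be >= 1: {m} on {lab!r}")
                if m.derived_base not in _BASES:
                    raise ValueError(f"bad derived base in {m} on {lab!r}")
                if m.position in pos_owner:
                    raise ValueError(
                        f"position {m.position} reused on branches "
                        f"{pos_owner[m.position]!r} and {lab!r}"
                    )
                pos_owner[m.position] = lab
        tree = HaplogroupTree(
            root=root,
            parent=dict(parent),
            branch_mutations=muts,
            _children={lab: tuple(sorted(kids)) for lab, kids in children.items()},
        )
        return tree

    # -- queries ---------------------------------------------------------

    def __contains__(self, label: str) -> bool:
        return label in self.parent

    def __len__(self) -> int:
        return len(self.parent)

    def labels(self) -> Iterator[str]:
        return iter(self.parent)

    def children(self, label: str) -> tuple[str, ...]:
        return self._children[label]

    def terminals(self) -> list[str]:
        """Labels without children, in sorted order."""
        return sorted(lab for lab in self.parent if not self._children[lab])

    def path_mutations(self, label: str) -> frozenset[DefiningMutation]:
        """All defining mutations on the root -> ``label`` path."""
        if label not in self.parent:
            raise KeyError(f"unknown haplogroup {label!r}")
        out: set[DefiningMutation] = set()
        node: str | None = label
        while node is not None:
            out.update(self.branch_mutations[node])
            node = self.parent[node]
        return frozenset(out)

    def defining_positions(self) -> frozenset[int]:
        """Every position used by any branch of the tree."""
        return frozenset(
            m.position for mm in self.branch_mutations.values() for m in mm
        )

    def max_position(self) -> int:
        pos = self.defining_positions()
        return max(pos) if pos else 0


def path_mutations(tree: HaplogroupTree, label: str) -> frozenset[DefiningMutation]:
    return tree.path_mutations(label)


# -- TSV round trip ------------------------------------------------------
# UTF-8 TSV, header "haplogroup<TAB>parent<TAB>mutations", mutations are
# comma-separated "POS:BASE" tokens with 1-based POS.

_HEADER = "haplogroup\tparent\tmutations"


def _parse_mutation(token: str) -> DefiningMutation:
    parts = token.split(":")
    if len(parts) != 2 or not parts[0].isdigit() or parts[1] not in _BASES:
        raise ValueError(f"malformed mutation token: {token!r}")
    return DefiningMutation(int(parts[0]), parts[1])


def load_haplotree(path: str | Path) -> HaplogroupTree:
    """Read a haplogroup tree from its tab-delimited table format."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ValueError(f"empty haplogroup tree file: {path}")
    if lines[0].strip() == _HEADER:
        lines = lines[1:]
    rows = []
    for ln in lines:
        fields = ln.rstrip("\n").split("\t")
        if len(fields) not in (2, 3):
            raise ValueError(f"expected 2-3 tab-separated fields: {ln!r}")
        label = fields[0].strip()
        par = fields[1].strip() or None
        mut_field = fields[2].strip() if len(fields) == 3 else ""
        mm = [_parse_mutation(t.strip()) for t in mut_field.split(",") if t.strip()]
        rows.append((label, par, mm))
    return HaplogroupTree.from_nodes(rows)


def write_haplotree(tree: HaplogroupTree, path: str | Path) -> None:
    """Write a tree in the format read by :func:`load_haplotree`."""
    out = [_HEADER]
    # root first, then breadth-first for readability
    queue = [tree.root]
    while queue:
        lab = queue.pop(0)
        par = tree.parent[lab] or ""
        mm = ",".join(f"{m.position}:{m.derived_base}" for m in tree.branch_mutations[lab])
        out.append(f"{lab}\t{par}\t{mm}")
        queue.extend(tree.children(lab))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")
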