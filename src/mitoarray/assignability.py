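"""The clade-based "assignable haplogroup" criterion and its aggregates.

A haplogroup is *assignable* in a bootstrapped tree when all, or all but
``max_missing``, of the leaves belonging to its subhaplogroups cluster
together under one branch whose bootstrap support reaches ``min_support``,
with at most ``max_intruders`` leaves on that branch that do not belong.
Because an unrooted NJ tree has no branches in the rendered-tree sense, a
"branch" here is one side of an edge (a bipartition side); both sides of
every edge are candidates.  A candidate side must contain at least two
members of the subhaplogroup leaf set — a single stray leaf is not a
cluster — which also means single-leaf sides never qualify on their own.

Percentages mirror the benchmark design: the full-genome tree is the gold
standard, so the denominator at each level is the set of haplogroups
assignable there, and an array scores the fraction of those it preserves.
Haplogroups represented by fewer than two leaves are excluded and reported
separately (monophyly of one sequence is vacuous).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from . import stats as _stats
from .haplotree import truncate_label
from .phylogeny import SupportedTree

__all__ = [
    "AssignabilityCriterion",
    "AssignabilityReport",
    "Witness",
    "assignability_percentages",
    "compare_arrays_fisher",
    "is_assignable",
    "subhaplogroup_leaves",
]

FULL_TREE_NAME = "full"


@dataclass(frozen=True)
class AssignabilityCriterion:
    min_support: float = 50.0
    max_missing: int = 1
    max_intruders: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.min_support <= 100:
            raise ValueError("min_support must be in [0, 100]")
        if self.max_missing < 0 or self.max_intruders < 0:
            raise ValueError("max_missing and max_intruders must be >= 0")


class Witness(NamedTuple):
    """The best branch supporting an assignability call."""

    side: frozenset[str]
    support: float
    missing: int
    intruders: int


def subhaplogroup_leaves(
    labels: Mapping[str, str], target: str
) -> frozenset[str]:
    """Leaves whose true haplogroup has ``target`` as a prefix."""
    return frozenset(
        leaf for leaf, lab in labels.items() if lab is not None and lab.startswith(target)
    )


def is_assignable(
    tree: SupportedTree,
    labels: Mapping[str, str],
    target: str,
    crit: AssignabilityCriterion = AssignabilityCriterion(),
) -> tuple[bool, Witness | None]:
    """Apply the clade criterion to one haplogroup on one tree.

    Returns the verdict and, when assignable, the best witness branch
    (highest support, then fewest intruders).
    """
    leaves = tree.leaf_names()
    unknown = set(labels) - set(leaves)
    if unknown:
        raise ValueError(f"labels refer to unknown leaves: {sorted(unknown)[:5]}")
    S = subhaplogroup_leaves(labels, target)
    if len(S) < 2:
        raise ValueError(
            f"haplogroup {target!r} has {len(S)} labeled leaves; "
            "the clade criterion needs at least 2"
        )
    best: Witness | None = None
    for side, support in tree.sides():
        if support < crit.min_support:
            continue
        clustered = len(S & side)
        if clustered < 2:  # a cluster needs at least two members
            continue
        missing = len(S) - clustered
        intruders = len(side - S)
        if missing <= crit.max_missing and intruders <= crit.max_intruders:
            w = Witness(side, support, missing, intruders)
            if best is None or (w.support, -w.intruders) > (best.support, -best.intruders):
                best = w
    return best is not None, best


class ReportRow(NamedTuple):
    array: str
    level: int
    haplogroup: str
    n_leaves: int
    assignable: bool
    support: float | None


@dataclass
class AssignabilityReport:
    """Per-haplogroup verdicts plus the aggregate percentages.

    ``aggregates`` maps (array, level) -> percentage of gold-standard
    assignable haplogroups preserved by the array (or of all eligible
    haplogroups when ``denominator='all'``); ``per_major`` pools levels
    within each major haplogroup.  ``excluded`` lists (level, haplogroup)
    pairs with fewer than two leaves.
    """

    criterion: AssignabilityCriterion
    levels: tuple[int, ...]
    denominator: str
    african_only: bool
    rows: list[ReportRow] = field(default_factory=list)
    aggregates: dict[tuple[str, int], float] = field(default_factory=dict)
    counts: dict[tuple[str, int], tuple[int, int]] = field(default_factory=dict)
    per_major: dict[tuple[str, str], float] = field(default_factory=dict)
    excluded: list[tuple[int, str]] = field(default_factory=list)

    def assignable_set(self, array: str, level: int) -> frozenset[str]:
        return frozenset(
            r.haplogroup
            for r in self.rows
            if r.array == array and r.level == level and r.assignable
        )


def _eligible_groups(
    labels: Mapping[str, str], level: int, african_only: bool
) -> dict[str, frozenset[str]]:
    groups: dict[str, frozenset[str]] = {}
    for lab in set(labels.values()):
        if lab is None:
            continue
        if african_only and not lab.startswith("L"):
            continue
        groups.setdefault(truncate_label(lab, level), None)
    return {g: subhaplogroup_leaves(labels, g) for g in sorted(groups)}


def assignability_percentages(
    full_tree: SupportedTree,
    array_trees: Mapping[str, SupportedTree],
    labels: Mapping[str, str],
    levels: Sequence[int] = (2, 3, 4),
    crit: AssignabilityCriterion = AssignabilityCriterion(),
    african_only: bool = True,
    denominator: str = "gold",
) -> AssignabilityReport:
    """Score every array tree against the full-genome gold standard.

    For each nomenclature level, the haplogroups under test are the truncated
    true labels (African only by default, i.e. starting with "L"); those
    with fewer than two leaves are excluded.  ``denominator='gold'``
    conditions on haplogroups assignable in the full tree;
    ``denominator='all'`` uses every eligible haplogroup.
    """
    if denominator not in ("gold", "all"):
        raise ValueError("denominator must be 'gold' or 'all'")
    full_leaves = full_tree.leaf_names()
    for name, t in array_trees.items():
        if t.leaf_names() != full_leaves:
            raise ValueError(f"array tree {name!r} leaf set differs from full tree")
    report = AssignabilityReport(
        criterion=crit,
        levels=tuple(levels),
        denominator=denominator,
        african_only=african_only,
    )
    all_trees = {FULL_TREE_NAME: full_tree, **array_trees}
    gold: dict[int, set[str]] = {}
    eligible: dict[int, list[tuple[str, int]]] = {}
    for lvl in levels:
        groups = _eligible_groups(labels, lvl, african_only)
        elig = []
        for g, S in groups.items():
            if len(S) < 2:
                report.excluded.append((lvl, g))
                continue
            elig.append((g, len(S)))
        eligible[lvl] = elig
        gold[lvl] = set()
        for name, t in all_trees.items():
            for g, nleaves in elig:
                ok, wit = is_assignable(t, labels, g, crit)
                report.rows.append(
                    ReportRow(name, lvl, g, nleaves, ok, wit.support if wit else None)
                )
                if name == FULL_TREE_NAME and ok:
                    gold[lvl].add(g)
    for name in all_trees:
        for lvl in levels:
            if denominator == "gold":
                den_set = gold[lvl]
            else:
                den_set = {g for g, _ in eligible[lvl]}
            num = len(den_set & report.assignable_set(name, lvl))
            den = len(den_set)
            report.counts[(name, lvl)] = (num, den)
            report.aggregates[(name, lvl)] = 100.0 * num / den if den else 0.0
    # per-major pooling across levels (Fig. 2-style): one pooled percentage
    # per (array, major haplogroup)
    majors = sorted(
        {truncate_label(g, 2) for lvl in levels for g, _ in eligible[lvl]}
    )
    for name in all_trees:
        for major in majors:
            num = den = 0
            for lvl in levels:
                if denominator == "gold":
                    den_set = {g for g in gold[lvl] if g.startswith(major[:2])}
                else:
                    den_set = {
                        g for g, _ in eligible[lvl] if g.startswith(major[:2])
                    }
                den += len(den_set)
                num += len(den_set & report.assignable_set(name, lvl))
            if den:
                report.per_major[(name, major)] = 100.0 * num / den
    return report


def compare_arrays_fisher(
    report: AssignabilityReport, array_a: str, array_b: str, level: int
) -> tuple[float, float]:
    """Fisher's exact test on (assignable, not) x (array A, array B)."""
    try:
        num_a, den_a = report.counts[(array_a, level)]
        num_b, den_b = report.counts[(array_b, level)]
    except KeyError as exc:
        raise ValueError(f"no counts for {exc} in report") from exc
    if den_a == 0 or den_b == 0:
        raise ValueError("zero denominator: no eligible haplogroups at this level")
    table = _stats.ContingencyTable2x2(num_a, den_a - num_a, num_b, den_b - num_b)
    return _stats.fishers_exact_2x2(table)
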