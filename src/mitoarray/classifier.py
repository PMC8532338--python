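"""Coverage-aware rule-based haplogroup assignment with a Kulczynski rank.

For a sample typed at a set of covered positions, each candidate haplogroup
``h`` has an expected mutation set E(h) — the defining mutations on its
root path — and the sample has an observed variant set O (non-reference
bases at covered positions).  The match quality is the Kulczynski measure

    rank(h) = 1/2 ( |O ∩ E| / |E|  +  |O ∩ E| / |O| ),    0/0 := 1,

the measure behind HaploGrep2's published "overall rank"; reports label the
score "Kulczynski rank (HaploGrep2-analog)".  The assigned haplogroup is
the argmax, ties broken toward the deeper (longer) label, then
lexicographically.

By default E(h) is the *full* path mutation set, so defining mutations the
array does not cover count against the expected term: this is what drives
array ranks below full-genome ranks (a sample typed on a sparse array can
recover only the covered share of its haplogroup's defining sites).  Set
``restrict_expected=True`` to drop uncovered expected sites from both
numerator and denominator instead, mimicking a range-aware caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .haplotree import DefiningMutation, HaplogroupTree, prefix_compatible, truncate_label
from .seqio import ReferenceSequence, SiteMatrix

__all__ = [
    "ClassificationResult",
    "ObservedVariants",
    "classify",
    "cohort_ranks",
    "kulczynski_rank",
    "observed_variants",
    "percent_correct",
]


@dataclass(frozen=True)
class ObservedVariants:
    """A sample's non-reference calls restricted to its covered positions."""

    sample_id: str
    variants: frozenset[DefiningMutation]
    covered: frozenset[int]

    def __post_init__(self) -> None:
        for v in self.variants:
            if v.position not in self.covered:
                raise ValueError(
                    f"variant at uncovered position {v.position} in {self.sample_id!r}"
                )
            if v.derived_base not in "ACGT":
                raise ValueError(f"bad variant base {v.derived_base!r}")


@dataclass(frozen=True)
class ClassificationResult:
    sample_id: str
    assigned: str
    rank: float
    n_expected_found: int
    n_expected: int
    n_observed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.rank <= 1.0:
            raise ValueError("rank must lie in [0, 1]")
        if self.n_expected_found > min(self.n_expected, self.n_observed):
            raise ValueError("found count exceeds expected or observed count")


def kulczynski_rank(found: int, expected: int, observed: int) -> float:
    """½(found/expected + found/observed) with 0/0 := 1 for either term."""
    if found < 0 or expected < 0 or observed < 0:
        raise ValueError("counts must be nonnegative")
    if found > expected or found > observed:
        raise ValueError("found cannot exceed expected or observed")
    t1 = 1.0 if expected == 0 else found / expected
    t2 = 1.0 if observed == 0 else found / observed
    return 0.5 * (t1 + t2)


def observed_variants(
    matrix: SiteMatrix, reference: ReferenceSequence
) -> list[ObservedVariants]:
    """Derive each sample's observed variant set from a (masked) site
    matrix; ``N`` calls are neither variants nor reference matches but the
    position still counts as covered by the assay."""
    covered = frozenset(matrix.positions)
    out = []
    for sid, row in zip(matrix.ids, matrix.rows):
        var = frozenset(
            DefiningMutation(pos, b)
            for pos, b in zip(matrix.positions, row)
            if b != "N" and b != reference.base_at(pos)
        )
        out.append(ObservedVariants(sid, var, covered))
    return out


def classify(
    sample: ObservedVariants,
    tree: HaplogroupTree,
    restrict_expected: bool = False,
) -> ClassificationResult:
    """Assign the haplogroup maximizing the Kulczynski rank."""
    if len(tree) == 0:
        raise ValueError("empty haplogroup tree")
    n_obs = len(sample.variants)
    best: tuple[float, int, str] | None = None
    best_counts: tuple[int, int] | None = None
    for h in tree.labels():
        expected = tree.path_mutations(h)
        if restrict_expected:
            expected = frozenset(m for m in expected if m.position in sample.covered)
        found = len(sample.variants & expected)
        rank = kulczynski_rank(found, len(expected), n_obs)
        key = (rank, len(h), _neg_lex(h))
        if best is None or key > best:
            best = key
            best_h = h
            best_counts = (found, len(expected))
    return ClassificationResult(
        sample_id=sample.sample_id,
        assigned=best_h,
        rank=best[0],
        n_expected_found=best_counts[0],
        n_expected=best_counts[1],
        n_observed=n_obs,
    )


def _neg_lex(label: str) -> tuple[int, ...]:
    # lexicographically *smallest* label should win the final tie-break,
    # inside a max() comparison
    return tuple(-ord(c) for c in label)


def major_haplogroup(label: str) -> str:
    """L-prefixed labels pool at two characters (L0..L6); others at one."""
    return label[:2] if label.startswith("L") else label[:1]


def cohort_ranks(
    results: Sequence[ClassificationResult],
    truth_labels: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Mean Kulczynski rank overall and per major haplogroup.

    Grouping uses the truth labels when given (Fig.-3-style summaries group
    by the sample's actual haplogroup), otherwise the assigned labels.
    """
    if not results:
        raise ValueError("no classification results")
    groups: dict[str, list[float]] = {}
    for res in results:
        lab = truth_labels[res.sample_id] if truth_labels else res.assigned
        groups.setdefault(major_haplogroup(lab), []).append(res.rank)
    out = {"overall": sum(r.rank for r in results) / len(results)}
    for major, ranks in sorted(groups.items()):
        out[major] = sum(ranks) / len(ranks)
    return out


def percent_correct(
    results: Sequence[ClassificationResult],
    truth_labels: Mapping[str, str],
    african_only: bool = False,
    mode: str = "prefix",
    at_level: int = 4,
) -> float:
    """Percentage of samples whose call agrees with the truth.

    ``mode='prefix'`` (default) counts a call as correct when it is
    prefix-compatible with the truth — resolution is ignored, so "L0"
    against "L0a2a" is correct.  ``mode='exact'`` requires equality after
    truncating both labels to ``at_level`` characters.
    """
    picked = []
    for res in results:
        if res.sample_id not in truth_labels:
            raise ValueError(f"missing truth label for {res.sample_id!r}")
        truth = truth_labels[res.sample_id]
        if african_only and not truth.startswith("L"):
            continue
        picked.append((res.assigned, truth))
    if not picked:
        raise ValueError("no samples to score")
    if mode == "prefix":
        good = sum(prefix_compatible(a, t) for a, t in picked)
    elif mode == "exact":
        good = sum(
            truncate_label(a, at_level) == truncate_label(t, at_level)
            for a, t in picked
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return 100.0 * good / len(picked)
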