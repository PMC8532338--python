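"""Synthetic haplogroup phylogenies, sequence cohorts and array manifests.

The generator emulates the benchmark's study design: a rooted macro-
haplogroup-L tree whose African majors (L0, L1, L2, L3 by default) branch
into nested subhaplogroups named by the alternating letter/digit
nomenclature down to five-character terminals, with the non-African majors
M, N and R nested under the deepest L3 lineage.  Every branch carries at
least one clade-defining substitution (Poisson-distributed count), placed
under an infinite-sites model: no position is ever used twice, so the truth
is unambiguous for oracle tests.  Cohorts take one sequence per terminal
African haplogroup and two per non-African major; each sequence is the
reference with its haplogroup's path mutations applied plus Poisson-
distributed private mutations at positions unused anywhere else —
phylogenetically uninformative noise by construction.

Array manifests contain a tunable fraction of the tree's defining positions
plus a count of uninformative background positions, which is exactly the
axis the benchmark studies: how much clade-defining content an array
carries, as opposed to how many mtDNA positions it types.

All generators are pure functions of (config, seed); distinct stages draw
from independent named RNG streams so outputs are bit-reproducible.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .haplotree import DefiningMutation, HaplogroupTree
from .seqio import AlignedSequenceSet, ArrayManifest, ReferenceSequence, Sample

__all__ = [
    "ManifestSpec",
    "SimulationConfig",
    "simulate_dataset",
    "simulate_haplotree",
    "simulate_manifest",
]

_BASES = np.array(list("ACGT"))
# stream tags keep the tree / reference / private-mutation draws independent
_TREE_STREAM, _SEQ_STREAM, _MANIFEST_STREAM = 101, 202, 303


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome_length: int = 16_569
    levels: int = 5
    children_per_node: int | tuple[int, int] = (2, 3)
    n_african_majors: int = 4
    mutations_per_branch: float = 3.0
    private_mutations_per_sample: float = 2.0
    n_per_terminal_african: int = 1
    n_per_major_non_african: int = 2

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2 (root plus majors)")
        if not 1 <= self.n_african_majors <= 7:
            raise ValueError("n_african_majors must be in 1..7 (L0..L6)")
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")

    def children_range(self) -> tuple[int, int]:
        c = self.children_per_node
        return (c, c) if isinstance(c, int) else tuple(c)


@dataclass(frozen=True)
class ManifestSpec:
    name: str
    defining_fraction: float = 1.0
    n_background: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.defining_fraction <= 1.0:
            raise ValueError("defining_fraction must be in [0, 1]")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")


def _child_labels(parent: str, k: int) -> list[str]:
    """Extend a label by one nomenclature character per child.

    Labels alternate letter/digit groups, so a label ending in a digit gets
    letter children (L0 -> L0a, L0b) and vice versa (L0a -> L0a1, L0a2).
    """
    if parent[-1].isdigit():
        symbols = string.ascii_lowercase
    else:
        symbols = string.digits[1:] + string.digits[0]  # 1..9 then 0
    if k > len(symbols):
        raise ValueError(f"cannot create {k} children for {parent!r}")
    return [parent + symbols[i] for i in range(k)]


def simulate_haplotree(cfg: SimulationConfig) -> HaplogroupTree:
    """Generate a haplogroup tree with clade-defining mutations.

    Root "L"; African majors L0..L(n-1) subdivide down to ``cfg.levels``
    characters; non-African majors M, N, R hang off the deepest L3 (or last
    African major) lineage.  Every branch draws max(1, Poisson(mu))
    defining mutations at globally unique positions.
    """
    rng = np.random.default_rng([cfg.seed, _TREE_STREAM])
    nodes: list[tuple[str, str | None]] = [("L", None)]
    lo, hi = cfg.children_range()

    def expand(label: str) -> None:
        if len(label) >= cfg.levels:
            return
        k = int(rng.integers(lo, hi + 1))
        for child in _child_labels(label, k):
            nodes.append((child, label))
            expand(child)

    majors = [f"L{i}" for i in range(cfg.n_african_majors)]
    for major in majors:
        nodes.append((major, "L"))
        expand(major)
    # attach M, N, R under the deepest lineage of the last African major
    attach_major = majors[-1]
    deepest = max(
        (lab for lab, _ in nodes if lab.startswith(attach_major)),
        key=lambda lab: (len(lab), [-ord(c) for c in lab]),
    )
    for non_african in ("M", "N", "R"):
        nodes.append((non_african, deepest))

    n_branches = len(nodes) - 1
    counts = {lab: max(1, int(rng.poisson(cfg.mutations_per_branch)))
              for lab, par in nodes if par is not None}
    total = sum(counts.values())
    if total > cfg.genome_length:
        raise ValueError(
            f"infeasible mutation budget: {total} mutations exceed "
            f"genome length {cfg.genome_length} ({n_branches} branches)"
        )
    positions = rng.choice(cfg.genome_length, size=total, replace=False) + 1
    bases = rng.integers(0, 4, size=total)
    out = []
    cursor = 0
    for lab, par in nodes:
        if par is None:
            out.append((lab, par, []))
            continue
        k = counts[lab]
        muts = [
            DefiningMutation(int(positions[cursor + i]), str(_BASES[bases[cursor + i]]))
            for i in range(k)
        ]
        cursor += k
        out.append((lab, par, muts))
    return HaplogroupTree.from_nodes(out)


def _terminal_african(tree: HaplogroupTree) -> list[str]:
    """African haplogroups with no African children.

    The non-African majors (M, N, R) nest inside the deepest African
    lineage, so that lineage still counts as a terminal African haplogroup
    and still contributes a sample.
    """
    return sorted(
        lab
        for lab in tree.labels()
        if lab.startswith("L")
        and len(lab) > 1
        and not any(c.startswith("L") for c in tree.children(lab))
    )


def simulate_dataset(
    tree: HaplogroupTree, cfg: SimulationConfig
) -> AlignedSequenceSet:
    """Generate a cohort of reference-length sequences along the tree.

    One sample per terminal African haplogroup and ``n_per_major_non_african``
    per non-African major (M, N, R).  Each sample is the reference with its
    haplogroup's path mutations applied, plus private mutations at positions
    unused by any branch or any other sample (strict infinite sites).  The
    derived base of every defining mutation differs from the reference by
    construction: the reference is resampled at defining positions when a
    collision occurs.
    """
    rng = np.random.default_rng([cfg.seed, _SEQ_STREAM])
    n = cfg.genome_length
    if tree.max_position() > n:
        raise ValueError("tree uses positions beyond the configured genome length")
    ref = rng.integers(0, 4, size=n)
    defining = {}
    for lab in tree.labels():
        for m in tree.branch_mutations[lab]:
            defining[m.position] = m.derived_base
    for pos, base in defining.items():
        code = int(np.where(_BASES == base)[0][0])
        if ref[pos - 1] == code:
            # reference must carry the ancestral state: pick another base
            alternatives = [b for b in range(4) if b != code]
            ref[pos - 1] = alternatives[int(rng.integers(0, 3))]
    ref_str = "".join(_BASES[ref])
    reference = ReferenceSequence("reference", ref_str)

    cohort: list[tuple[str, str]] = []  # (sample_id, haplogroup)
    for i, term in enumerate(_terminal_african(tree)):
        for k in range(cfg.n_per_terminal_african):
            cohort.append((f"{term}_{k}", term))
    for major in ("M", "N", "R"):
        if major in tree:
            for k in range(cfg.n_per_major_non_african):
                cohort.append((f"{major}_{k}", major))

    used = set(defining)
    free = np.array([p for p in range(1, n + 1) if p not in used])
    rng.shuffle(free)
    free_cursor = 0
    samples = []
    for sid, hap in cohort:
        seq = ref.copy()
        for m in tree.path_mutations(hap):
            seq[m.position - 1] = int(np.where(_BASES == m.derived_base)[0][0])
        n_priv = int(rng.poisson(cfg.private_mutations_per_sample))
        if free_cursor + n_priv > len(free):
            raise ValueError("position exhaustion: genome too short for private mutations")
        for _ in range(n_priv):
            pos = int(free[free_cursor])
            free_cursor += 1
            current = int(seq[pos - 1])
            alternatives = [b for b in range(4) if b != current]
            seq[pos - 1] = alternatives[int(rng.integers(0, 3))]
        samples.append(Sample(sid, "".join(_BASES[seq]), hap))
    return AlignedSequenceSet(reference, tuple(samples))


def simulate_manifest(
    tree: HaplogroupTree,
    spec: ManifestSpec,
    genome_length: int,
) -> ArrayManifest:
    """Build an array manifest with a chosen share of defining positions.

    Includes ceil(defining_fraction x D) defining positions sampled without
    replacement (D = all clade-defining positions of the tree) plus
    ``n_background`` non-defining positions.
    """
    rng = np.random.default_rng([spec.seed, _MANIFEST_STREAM])
    defining = np.array(sorted(tree.defining_positions()))
    if len(defining) and defining[-1] > genome_length:
        raise ValueError("tree uses positions beyond the given genome length")
    n_def = int(np.ceil(spec.defining_fraction * len(defining)))
    chosen = rng.choice(defining, size=n_def, replace=False) if n_def else np.array([], int)
    non_def = np.setdiff1d(np.arange(1, genome_length + 1), defining)
    if spec.n_background > len(non_def):
        raise ValueError(
            f"requested {spec.n_background} background positions but only "
            f"{len(non_def)} non-defining positions exist"
        )
    background = (
        rng.choice(non_def, size=spec.n_background, replace=False)
        if spec.n_background
        else np.array([], int)
    )
    positions = tuple(int(p) for p in np.concatenate([chosen, background]))
    return ArrayManifest(spec.name, positions)
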