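"""End-to-end benchmark: simulate (or load) -> mask -> trees -> scores.

``run_benchmark`` executes the whole comparison for a list of array
manifests against the full-genome gold standard and returns a
:class:`BenchmarkReport` whose tables mirror the four summary views of the
analysis: per-array assignability percentages by nomenclature level, pooled
per-major-haplogroup percentages, mean Kulczynski ranks, percent-correct
classification, the pairwise Fisher-exact p-value matrix at the deepest
level, and the SNP-count-versus-performance correlations with their
Fisher-z comparison.  Every report embeds the seed, criterion, and model
choices, plus the deviations-from-reference-tooling notice (distance model,
rank analog, denominator mode), so any number is reproducible from the JSON
alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .assignability import (
    FULL_TREE_NAME,
    AssignabilityCriterion,
    AssignabilityReport,
    assignability_percentages,
    compare_arrays_fisher,
)
from .classifier import classify, cohort_ranks, observed_variants, percent_correct
from .haplotree import HaplogroupTree
from .phylogeny import BootstrapConfig, bootstrap_tree
from .seqio import (
    AlignedSequenceSet,
    ArrayManifest,
    SiteMatrix,
    mask_to_array,
    read_fasta,
    read_manifest,
)
from .simulate import (
    ManifestSpec,
    SimulationConfig,
    simulate_dataset,
    simulate_haplotree,
    simulate_manifest,
)

__all__ = ["BenchmarkReport", "RunConfig", "render_tables", "run_benchmark"]

logger = logging.getLogger(__name__)

_DEVIATIONS = (
    "distance model is p/K2P/TN93, not MEGA Maximum Composite Likelihood",
    "haplogroup caller is the transparent Kulczynski rank (HaploGrep2-analog)",
    "assignability denominators condition on the full-genome gold standard",
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one benchmark run.

    Synthetic mode generates everything from ``sim`` and ``manifest_specs``;
    fasta mode reads an aligned cohort (labels in headers), a haplogroup
    tree TSV and manifest files.
    """

    mode: str = "synthetic"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    manifest_specs: tuple[ManifestSpec, ...] = ()
    fasta_path: str | None = None
    haplotree_path: str | None = None
    manifest_paths: tuple[str, ...] = ()
    bootstrap_replicates: int = 500
    model: str = "k2p"
    criterion: AssignabilityCriterion = field(default_factory=AssignabilityCriterion)
    levels: tuple[int, ...] = (2, 3, 4)
    african_only: bool = True
    denominator: str = "gold"
    restrict_expected: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "fasta"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "fasta":
            for p in (self.fasta_path, self.haplotree_path, *self.manifest_paths):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input file missing: {p}")


@dataclass
class BenchmarkReport:
    seed: int
    config: dict
    assignability: AssignabilityReport
    mean_ranks: dict[str, dict[str, float]]
    percent_correct: dict[str, float]
    fisher_pairwise: dict[str, dict[str, float]]
    correlations: dict
    manifest_sizes: dict[str, int]
    provenance: dict

    def aggregate_table(self) -> "pd.DataFrame":
        import pandas as pd

        rows = [
            {"array": a, "level": lvl, "percent_assignable": pct,
             "n_assignable": self.assignability.counts[(a, lvl)][0],
             "n_denominator": self.assignability.counts[(a, lvl)][1]}
            for (a, lvl), pct in sorted(self.assignability.aggregates.items())
        ]
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        rep = self.assignability
        return {
            "seed": self.seed,
            "config": self.config,
            "assignability": {
                "criterion": asdict(rep.criterion),
                "levels": list(rep.levels),
                "denominator": rep.denominator,
                "african_only": rep.african_only,
                "aggregates": {
                    f"{a}|{lvl}": pct for (a, lvl), pct in sorted(rep.aggregates.items())
                },
                "counts": {
                    f"{a}|{lvl}": list(c) for (a, lvl), c in sorted(rep.counts.items())
                },
                "per_major": {
                    f"{a}|{m}": pct for (a, m), pct in sorted(rep.per_major.items())
                },
                "excluded": [list(x) for x in sorted(rep.excluded)],
                "rows": [list(r) for r in rep.rows],
            },
            "mean_ranks": self.mean_ranks,
            "percent_correct": self.percent_correct,
            "fisher_pairwise": self.fisher_pairwise,
            "correlations": self.correlations,
            "manifest_sizes": self.manifest_sizes,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), sort_keys=True, indent=1)


def _build_inputs(
    cfg: RunConfig,
) -> tuple[HaplogroupTree, AlignedSequenceSet, list[ArrayManifest]]:
    if cfg.mode == "synthetic":
        tree = simulate_haplotree(cfg.sim)
        aset = simulate_dataset(tree, cfg.sim)
        manifests = [
            simulate_manifest(tree, spec, cfg.sim.genome_length)
            for spec in cfg.manifest_specs
        ]
    else:
        from .haplotree import load_haplotree

        tree = load_haplotree(cfg.haplotree_path)
        aset = read_fasta(cfg.fasta_path)
        manifests = [read_manifest(p) for p in cfg.manifest_paths]
    if not manifests:
        raise ValueError("at least one array manifest is required")
    if not aset.samples:
        raise ValueError("empty cohort: no samples to benchmark")
    return tree, aset, manifests


def run_benchmark(cfg: RunConfig, seed: int | None = None) -> BenchmarkReport:
    """Execute all stages; identical (cfg, seed) gives identical reports."""
    seed = cfg.sim.seed if seed is None else seed
    for note in _DEVIATIONS:
        logger.info("deviation: %s", note)
    tree, aset, manifests = _build_inputs(cfg)
    labels = {s.id: s.label for s in aset.samples}
    if any(v is None for v in labels.values()):
        raise ValueError("every sample needs a true haplogroup label")

    full_matrix = SiteMatrix.from_sequences(aset)
    full_tree = bootstrap_tree(
        full_matrix,
        model=cfg.model,
        config=BootstrapConfig(cfg.bootstrap_replicates, seed=_derive(seed, 0)),
    )
    array_trees = {}
    masked: dict[str, SiteMatrix] = {}
    for i, manifest in enumerate(manifests, start=1):
        masked[manifest.name] = mask_to_array(aset, manifest)
        array_trees[manifest.name] = bootstrap_tree(
            masked[manifest.name],
            model=cfg.model,
            config=BootstrapConfig(cfg.bootstrap_replicates, seed=_derive(seed, i)),
        )

    report = assignability_percentages(
        full_tree,
        array_trees,
        labels,
        levels=cfg.levels,
        crit=cfg.criterion,
        african_only=cfg.african_only,
        denominator=cfg.denominator,
    )

    mean_ranks: dict[str, dict[str, float]] = {}
    pct_correct: dict[str, float] = {}
    for name, matrix in [(FULL_TREE_NAME, full_matrix), *masked.items()]:
        obs = observed_variants(matrix, aset.reference)
        results = [classify(o, tree, restrict_expected=cfg.restrict_expected) for o in obs]
        mean_ranks[name] = cohort_ranks(results, truth_labels=labels)
        pct_correct[name] = percent_correct(
            results, labels, african_only=cfg.african_only
        )

    deepest = max(cfg.levels)
    fisher: dict[str, dict[str, float]] = {}
    names = [m.name for m in manifests]
    for a in names:
        fisher[a] = {}
        for b in names:
            if a == b:
                continue
            try:
                _, p = compare_arrays_fisher(report, a, b, deepest)
            except ValueError:
                p = float("nan")
            fisher[a][b] = p

    sizes = {m.name: len(m) for m in manifests}
    correlations = _correlation_block(report, sizes, cfg.levels)

    return BenchmarkReport(
        seed=seed,
        config=_config_dict(cfg),
        assignability=report,
        mean_ranks=mean_ranks,
        percent_correct=pct_correct,
        fisher_pairwise=fisher,
        correlations=correlations,
        manifest_sizes=sizes,
        provenance={
            "package": "mitoarray",
            "version": __version__,
            "seed": seed,
            "n_samples": len(aset.samples),
            "model": cfg.model,
            "denominator": cfg.denominator,
            "deviations": list(_DEVIATIONS),
        },
    )


def _derive(seed: int, k: int) -> int:
    # distinct bootstrap streams per tree, stable across runs
    return (seed * 1000 + k) % (2**31 - 1)


def _config_dict(cfg: RunConfig) -> dict:
    d = {
        "mode": cfg.mode,
        "bootstrap_replicates": cfg.bootstrap_replicates,
        "model": cfg.model,
        "criterion": asdict(cfg.criterion),
        "levels": list(cfg.levels),
        "african_only": cfg.african_only,
        "denominator": cfg.denominator,
        "restrict_expected": cfg.restrict_expected,
    }
    if cfg.mode == "synthetic":
        d["sim"] = asdict(cfg.sim)
        d["manifest_specs"] = [asdict(s) for s in cfg.manifest_specs]
    else:
        d["fasta_path"] = cfg.fasta_path
        d["haplotree_path"] = cfg.haplotree_path
        d["manifest_paths"] = list(cfg.manifest_paths)
    return d


def _correlation_block(
    report: AssignabilityReport, sizes: Mapping[str, int], levels: Sequence[int]
) -> dict:
    """Pearson r between manifest size and percent assignable, per level,
    plus the Fisher-1925 z comparison between the two deepest levels."""
    from . import stats as _stats

    out: dict = {"per_level": {}}
    usable: dict[int, _stats.CorrelationResult] = {}
    names = sorted(sizes)
    x = [sizes[n] for n in names]
    for lvl in levels:
        y = [report.aggregates.get((n, lvl), float("nan")) for n in names]
        try:
            res = _stats.pearson_r(x, y)
        except ValueError as exc:
            out["per_level"][str(lvl)] = {"error": str(exc)}
            continue
        usable[lvl] = res
        out["per_level"][str(lvl)] = {"r": res.r, "n": res.n, "p": res.p}
    lvls = sorted(usable)
    if len(lvls) >= 2:
        l1, l2 = lvls[-2], lvls[-1]
        z, p = _stats.fisher1925_z(
            usable[l1].r, usable[l1].n, usable[l2].r, usable[l2].n
        )
        out["comparison"] = {
            "levels": [l1, l2],
            "fisher_z": z,
            "p": p,
        }
    return out


def render_tables(report: BenchmarkReport, out_dir: str | Path) -> list[Path]:
    """Write the report as a TSV set plus one JSON; returns written paths."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: "pd.DataFrame", name: str) -> None:
        p = out_dir / name
        df.to_csv(p, sep="\t", index=False)
        written.append(p)

    rep = report.assignability
    save(
        pd.DataFrame(
            [r._asdict() for r in rep.rows],
        ),
        "assignability_rows.tsv",
    )
    save(report.aggregate_table(), "assignability_aggregates.tsv")
    save(
        pd.DataFrame(
            [
                {"array": a, "major": m, "percent_assignable": pct}
                for (a, m), pct in sorted(rep.per_major.items())
            ]
        ),
        "assignability_per_major.tsv",
    )
    save(
        pd.DataFrame(
            [
                {"array": a, "group": g, "mean_rank": v}
                for a, d in sorted(report.mean_ranks.items())
                for g, v in sorted(d.items())
            ]
        ),
        "mean_ranks.tsv",
    )
    save(
        pd.DataFrame(
            [
                {"array": a, "percent_correct": v}
                for a, v in sorted(report.percent_correct.items())
            ]
        ),
        "percent_correct.tsv",
    )
    save(
        pd.DataFrame(
            [
                {"array_a": a, "array_b": b, "p": p}
                for a, d in sorted(report.fisher_pairwise.items())
                for b, p in sorted(d.items())
            ]
        ),
        "fisher_pairwise.tsv",
    )
    json_path = out_dir / "report.json"
    json_path.write_text(report.to_json(), encoding="utf-8")
    written.append(json_path)
    return written


def plot_report(report: BenchmarkReport, out_dir: str | Path) -> list[Path]:
    """Optional bar-chart renderings of the four summary tables."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    df = report.aggregate_table()
    fig, ax = plt.subplots(figsize=(8, 4))
    for lvl, sub in df.groupby("level"):
        ax.bar(
            [f"{a}\nL{lvl}" for a in sub["array"]],
            sub["percent_assignable"],
            label=f"level {lvl}",
        )
    ax.set_ylabel("% assignable (vs full genome)")
    ax.legend()
    p = out_dir / "assignability.png"
    fig.tight_layout()
    fig.savefig(p)
    plt.close(fig)
    written.append(p)
    return written
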