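"""Sequence, manifest and variant-table I/O on rCRS-style coordinates.

All coordinates are 1-based and closed, on a reference mitochondrial genome
(16,569 bp for the real rCRS).  Samples are assumed pre-aligned to the
reference coordinate system; the only alignment post-processing implemented
is the reference-gap rule: alignment columns that insert a gap *into the
reference* are deleted outright so that reference numbering is preserved.

Only single-base substitutions are modeled.  IUPAC ambiguity codes are
mapped to ``N`` (missing) with a warning; gaps in sample sequences at kept
columns likewise become ``N``.  ``N`` never contributes an ALT allele and is
emitted as a ``.`` genotype in VCF output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlignedSequenceSet",
    "ArrayManifest",
    "ReferenceSequence",
    "Sample",
    "SiteMatrix",
    "filter_vcf_positions",
    "mask_to_array",
    "panel_missing_count",
    "read_fasta",
    "read_manifest",
    "read_vcf",
    "sites_to_vcf",
    "strip_reference_gaps",
    "write_fasta",
]

_VALID = frozenset("ACGTN")
_AMBIGUOUS = frozenset("RYSWKMBDHV")


def _normalize_bases(bases: str, context: str) -> str:
    up = bases.upper().replace("U", "T")
    if any(c in _AMBIGUOUS for c in up):
        warnings.warn(
            f"{context}: IUPAC ambiguity codes mapped to N", stacklevel=3
        )
        up = "".join("N" if c in _AMBIGUOUS else c for c in up)
    bad = set(up) - _VALID
    if bad:
        raise ValueError(
            f"{context}: invalid characters {sorted(bad)} "
            "(gapped input must go through strip_reference_gaps first)"
        )
    return up


@dataclass(frozen=True)
class ReferenceSequence:
    """A reference genome: id plus bases over A/C/G/T/N."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("reference sequence must be nonempty")

    def __len__(self) -> int:
        return len(self.bases)

    def base_at(self, position: int) -> str:
        """Base at a 1-based position."""
        return self.bases[position - 1]


@dataclass(frozen=True)
class Sample:
    id: str
    bases: str
    label: str | None = None


@dataclass(frozen=True)
class AlignedSequenceSet:
    """Reference plus same-length samples with optional true haplogroup labels."""

    reference: ReferenceSequence
    samples: tuple[Sample, ...]

    def __post_init__(self) -> None:
        n = len(self.reference)
        ids = set()
        for s in self.samples:
            if len(s.bases) != n:
                raise ValueError(
                    f"sample {s.id!r} length {len(s.bases)} != reference length {n}"
                )
            if s.id in ids:
                raise ValueError(f"duplicate sample id {s.id!r}")
            ids.add(s.id)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.samples)

    def labels(self) -> dict[str, str | None]:
        return {s.id: s.label for s in self.samples}


@dataclass(frozen=True)
class ArrayManifest:
    """A named, deduplicated, sorted set of 1-based array positions."""

    name: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = tuple(sorted(set(self.positions)))
        if pos and pos[0] < 1:
            raise ValueError(f"manifest {self.name!r}: positions must be >= 1")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.positions)

    def position_set(self) -> frozenset[int]:
        return frozenset(self.positions)


@dataclass(frozen=True)
class SiteMatrix:
    """Per-sample bases at a sorted list of 1-based positions.

    Columns are always stored in ascending position order, whatever order
    they were supplied in — downstream statistics (bootstrap supports in
    particular) therefore cannot depend on input column order.
    """

    positions: tuple[int, ...]
    ids: tuple[str, ...]
    rows: tuple[str, ...]
    labels: tuple[str | None, ...] = None

    def __post_init__(self) -> None:
        if self.labels is None:
            object.__setattr__(self, "labels", tuple(None for _ in self.ids))
        if len(self.rows) != len(self.ids) or len(self.labels) != len(self.ids):
            raise ValueError("ids, rows and labels must have equal length")
        k = len(self.positions)
        for sid, row in zip(self.ids, self.rows):
            if len(row) != k:
                raise ValueError(f"row {sid!r} has {len(row)} columns, expected {k}")
        order = sorted(range(k), key=lambda i: self.positions[i])
        pos_sorted = tuple(self.positions[i] for i in order)
        if len(set(pos_sorted)) != k:
            raise ValueError("duplicate positions in site matrix")
        if pos_sorted != tuple(self.positions):
            object.__setattr__(self, "positions", pos_sorted)
            object.__setattr__(
                self, "rows", tuple("".join(r[i] for i in order) for r in self.rows)
            )

    @property
    def n_samples(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def label_map(self) -> dict[str, str | None]:
        return dict(zip(self.ids, self.labels))

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    @staticmethod
    def from_sequences(aset: AlignedSequenceSet) -> "SiteMatrix":
        """The identity mask: every reference position becomes a column."""
        n = len(aset.reference)
        return SiteMatrix(
            positions=tuple(range(1, n + 1)),
            ids=aset.sample_ids,
            rows=tuple(s.bases for s in aset.samples),
            labels=tuple(s.label for s in aset.samples),
        )


# -- FASTA ---------------------------------------------------------------


def _split_header(header: str) -> tuple[str, str | None]:
    if "|" in header:
        sid, lab = header.split("|", 1)
        return sid, (lab or None)
    return header, None


def read_fasta(
    path: str | Path, reference: ReferenceSequence | None = None
) -> AlignedSequenceSet:
    """Read an aligned FASTA; the first record is the reference unless one
    is supplied separately.  A ``>id|label`` header carries the sample's
    true haplogroup."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty FASTA file: {path}")
    samples: list[Sample] = []
    if reference is None:
        ref_rec = records[0]
        rid, _ = _split_header(ref_rec.id)
        reference = ReferenceSequence(rid, _normalize_bases(str(ref_rec.seq), rid))
        records = records[1:]
    for rec in records:
        sid, lab = _split_header(rec.id)
        samples.append(Sample(sid, _normalize_bases(str(rec.seq), sid), lab))
    return AlignedSequenceSet(reference, tuple(samples))


def write_fasta(aset: AlignedSequenceSet, path: str | Path) -> None:
    recs = [SeqRecord(Seq(aset.reference.bases), id=aset.reference.id, description="")]
    for s in aset.samples:
        header = f"{s.id}|{s.label}" if s.label else s.id
        recs.append(SeqRecord(Seq(s.bases), id=header, description=""))
    SeqIO.write(recs, str(path), "fasta")


def strip_reference_gaps(
    aligned_reference: str,
    aligned_samples: Iterable[tuple[str, str, str | None]],
    reference_id: str = "reference",
) -> AlignedSequenceSet:
    """Delete every alignment column where the reference holds a gap.

    This is the rule used to keep reference nucleotide numbering intact
    after multiple alignment: insertions relative to the reference are
    discarded.  Sample gaps at surviving columns are recorded as missing
    (``N``).
    """
    samples = list(aligned_samples)
    n = len(aligned_reference)
    for sid, bases, _ in samples:
        if len(bases) != n:
            raise ValueError(f"aligned sample {sid!r} length != reference length")
    keep = [i for i, c in enumerate(aligned_reference) if c != "-"]
    ref = "".join(aligned_reference[i] for i in keep)
    out = []
    for sid, bases, lab in samples:
        kept = "".join(bases[i] for i in keep).replace("-", "N")
        out.append(Sample(sid, _normalize_bases(kept, sid), lab))
    return AlignedSequenceSet(
        ReferenceSequence(reference_id, _normalize_bases(ref, reference_id)),
        tuple(out),
    )


# -- manifests -----------------------------------------------------------


def read_manifest(path: str | Path, name: str | None = None) -> ArrayManifest:
    """Read a manifest: one integer position per line, or a TSV with a
    ``position`` column.  Duplicates are tolerated and removed."""
    lines = [
        ln for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()
    ]
    if not lines:
        raise ValueError(f"empty manifest file: {path}")
    first = [f.strip() for f in lines[0].split("\t")]
    digit_cols = [i for i, f in enumerate(first) if f.lstrip("-").isdigit()]
    if digit_cols:
        col = digit_cols[0]
    else:
        # header row: find the position column
        lowered = [f.lower() for f in first]
        for cand in ("position", "pos"):
            if cand in lowered:
                col = lowered.index(cand)
                break
        else:
            raise ValueError(f"no 'position' column in manifest header: {lines[0]!r}")
        lines = lines[1:]
    positions = []
    for ln in lines:
        token = ln.split("\t")[col].strip()
        if not token.isdigit():
            raise ValueError(f"non-integer position token: {token!r}")
        positions.append(int(token))
    return ArrayManifest(name or Path(path).stem, tuple(positions))


def write_manifest(manifest: ArrayManifest, path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(str(p) for p in manifest.positions) + "\n", encoding="utf-8"
    )


def mask_to_array(aset: AlignedSequenceSet, manifest: ArrayManifest) -> SiteMatrix:
    """Extract the bases at the manifest's positions for every sample."""
    n = len(aset.reference)
    if manifest.positions and manifest.positions[-1] > n:
        raise ValueError(
            f"manifest {manifest.name!r} position {manifest.positions[-1]} "
            f"exceeds reference length {n}"
        )
    idx = [p - 1 for p in manifest.positions]
    return SiteMatrix(
        positions=manifest.positions,
        ids=aset.sample_ids,
        rows=tuple("".join(s.bases[i] for i in idx) for s in aset.samples),
        labels=tuple(s.label for s in aset.samples),
    )


def panel_missing_count(manifest: ArrayManifest, panel: ArrayManifest) -> int:
    """How many positions of a software panel (e.g. Hi-MC's 54 SNPs) are
    absent from an array manifest."""
    return len(panel.position_set() - manifest.position_set())


# -- minimal haploid VCF -------------------------------------------------
# Writes the snp-sites convention: one row per polymorphic column, REF from
# the reference, ALT alleles in first-observation order, haploid GT with
# "." for missing; columns where every sample equals the reference are
# omitted entirely.


def sites_to_vcf(
    matrix: SiteMatrix, reference: ReferenceSequence, path: str | Path
) -> int:
    """Write a haploid VCFv4.2 for the matrix; returns the row count."""
    if matrix.n_sites == 0 or matrix.n_samples == 0:
        raise ValueError("cannot write VCF for an empty site matrix")
    lines = [
        "##fileformat=VCFv4.2",
        "##source=mitoarray",
        f"##contig=<ID={reference.id},length={len(reference)}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.ids),
    ]
    n_rows = 0
    for j, pos in enumerate(matrix.positions):
        ref_base = reference.base_at(pos)
        col = matrix.column(j)
        alts: list[str] = []
        for c in col:
            if c not in ("N", ref_base) and c not in alts:
                alts.append(c)
        if not alts:
            continue  # monomorphic-reference column: omitted (snp-sites behavior)
        allele_index = {ref_base: "0", **{a: str(k + 1) for k, a in enumerate(alts)}}
        gts = "\t".join("." if c == "N" else allele_index[c] for c in col)
        lines.append(
            f"{reference.id}\t{pos}\t.\t{ref_base}\t{','.join(alts)}\t.\t.\t.\tGT\t{gts}"
        )
        n_rows += 1
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return n_rows


def read_vcf(path: str | Path) -> SiteMatrix:
    """Read a haploid VCF written by :func:`sites_to_vcf` back into a
    :class:`SiteMatrix` (polymorphic columns only, labels unknown)."""
    ids: tuple[str, ...] | None = None
    positions: list[int] = []
    cols: list[str] = []
    for ln in Path(path).read_text(encoding="utf-8").splitlines():
        if not ln.strip():
            continue
        if ln.startswith("##"):
            continue
        fields = ln.rstrip("\n").split("\t")
        if ln.startswith("#CHROM"):
            if len(fields) < 10:
                raise ValueError("VCF has no sample columns")
            ids = tuple(fields[9:])
            continue
        if ids is None:
            raise ValueError("VCF data row before #CHROM header")
        if len(fields) != 9 + len(ids):
            raise ValueError(f"malformed VCF row: {ln!r}")
        pos, ref, alt = int(fields[1]), fields[3], fields[4]
        alleles = [ref] + (alt.split(",") if alt != "." else [])
        column = []
        for gt in fields[9:]:
            if gt == ".":
                column.append("N")
            else:
                k = int(gt)
                if k >= len(alleles):
                    raise ValueError(f"genotype {gt} out of allele range at POS {pos}")
                column.append(alleles[k])
        positions.append(pos)
        cols.append("".join(column))
    if ids is None:
        raise ValueError(f"no #CHROM header in {path}")
    rows = tuple("".join(col[i] for col in cols) for i in range(len(ids)))
    return SiteMatrix(positions=tuple(positions), ids=ids, rows=rows)


def filter_vcf_positions(
    vcf_path: str | Path, manifest: ArrayManifest, out_path: str | Path
) -> int:
    """Keep only VCF rows whose POS is on the manifest (headers preserved);
    returns the surviving row count."""
    wanted = manifest.position_set()
    out: list[str] = []
    kept = 0
    for ln in Path(vcf_path).read_text(encoding="utf-8").splitlines():
        if ln.startswith("#"):
            out.append(ln)
            continue
        if not ln.strip():
            continue
        fields = ln.split("\t", 2)
        if len(fields) < 3 or not fields[1].isdigit():
            raise ValueError(f"malformed VCF row: {ln!r}")
        if int(fields[1]) in wanted:
            out.append(ln)
            kept += 1
    Path(out_path).write_text("\n".join(out) + "\n", encoding="utf-8")
    return kept
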