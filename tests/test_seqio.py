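import numpy as np
import pytest

from mitoarray.seqio import (
    AlignedSequenceSet,
    ArrayManifest,
    ReferenceSequence,
    Sample,
    SiteMatrix,
    filter_vcf_positions,
    mask_to_array,
    panel_missing_count,
    read_fasta,
    read_manifest,
    read_vcf,
    sites_to_vcf,
    strip_reference_gaps,
    write_fasta,
)


def _aset(ref="ACGTACGTAC", samples=(("s1", "ACGTACGTAG", "L0a"),)):
    return AlignedSequenceSet(
        ReferenceSequence("ref", ref),
        tuple(Sample(*s) for s in samples),
    )


class TestFasta:
    def test_two_records_one_sample(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">ref\nACGTACGTAC\n>s1|L0a\nACGTACGTAG\n")
        aset = read_fasta(p)
        assert aset.reference.id == "ref"
        assert len(aset.samples) == 1
        assert aset.samples[0].label == "L0a"

    def test_length_mismatch_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">ref\nACGTACGTAC\n>s1\nACGTACGTA\n")
        with pytest.raises(ValueError, match="length"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_fasta(p)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">ref\nACGT\n>s1\nACGA\n>s1\nACGC\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(p)

    def test_ambiguity_codes_become_missing(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">ref\nACGT\n>s1\nACRT\n")
        with pytest.warns(UserWarning, match="IUPAC"):
            aset = read_fasta(p)
        assert aset.samples[0].bases == "ACNT"

    def test_roundtrip_simulated_cohort(self, tmp_path, sim_dataset):
        p = tmp_path / "cohort.fasta"
        write_fasta(sim_dataset, p)
        back = read_fasta(p)
        assert back.reference.bases == sim_dataset.reference.bases
        assert back.samples == sim_dataset.samples


class TestStripReferenceGaps:
    def test_single_insertion_column_dropped(self):
        out = strip_reference_gaps("AC-GT", [("s", "ACTGT", None)])
        assert out.reference.bases == "ACGT"
        assert out.samples[0].bases == "ACGT"

    def test_gapless_identity(self):
        out = strip_reference_gaps("ACGT", [("s", "AGGT", None)])
        assert out.reference.bases == "ACGT"
        assert out.samples[0].bases == "AGGT"

    def test_sample_gap_becomes_missing(self):
        out = strip_reference_gaps("ACGT", [("s", "A-GT", None)])
        assert out.samples[0].bases == "ANGT"

    def test_positional_bookkeeping_random(self):
        # dropping reference-gap columns must keep every ungapped reference
        # base, in order, and shorten by exactly the gap count
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for _ in range(25):
            n = int(rng.integers(10, 60))
            ref = list(rng.choice(bases, size=n))
            gap_idx = rng.choice(n, size=int(rng.integers(0, n // 3 + 1)), replace=False)
            for i in gap_idx:
                ref[i] = "-"
            ref_str = "".join(ref)
            sample = "".join(rng.choice(bases, size=n))
            out = strip_reference_gaps(ref_str, [("s", sample, None)])
            assert len(out.reference) == n - len(gap_idx)
            assert out.reference.bases == ref_str.replace("-", "")
            assert out.samples[0].bases == "".join(
                c for c, r in zip(sample, ref_str) if r != "-"
            )


class TestManifest:
    def test_dedup_and_sort(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("263\n73\n263\n")
        m = read_manifest(p)
        assert m.positions == (73, 263)
        assert len(m) == 2

    def test_tsv_with_position_column(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("rsid\tposition\nrs1\t73\nrs2\t263\n")
        assert read_manifest(p).positions == (73, 263)

    def test_non_integer_rejected(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("73\nxx\n")
        with pytest.raises(ValueError, match="non-integer"):
            read_manifest(p)


class TestMask:
    def test_first_position_column(self):
        aset = _aset()
        m = mask_to_array(aset, ArrayManifest("m", (1,)))
        assert m.rows == ("A",)
        assert m.positions == (1,)

    def test_identity_mask(self):
        aset = _aset()
        m = mask_to_array(aset, ArrayManifest("m", tuple(range(1, 11))))
        assert m.rows[0] == aset.samples[0].bases

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            mask_to_array(_aset(), ArrayManifest("m", (11,)))

    def test_per_cell_oracle_random(self, sim_dataset):
        rng = np.random.default_rng(3)
        n = len(sim_dataset.reference)
        pos = tuple(sorted(rng.choice(n, size=40, replace=False) + 1))
        m = mask_to_array(sim_dataset, ArrayManifest("m", pos))
        for i, s in enumerate(sim_dataset.samples):
            for j, p in enumerate(m.positions):
                assert m.rows[i][j] == s.bases[p - 1]

    def test_union_restriction_consistency(self, sim_dataset):
        m1 = ArrayManifest("a", (5, 10, 20))
        m2 = ArrayManifest("b", (3, 10, 40))
        union = ArrayManifest("u", m1.positions + m2.positions)
        mu = mask_to_array(sim_dataset, union)
        ma = mask_to_array(sim_dataset, m1)
        keep = [j for j, p in enumerate(mu.positions) if p in m1.position_set()]
        for row_u, row_a in zip(mu.rows, ma.rows):
            assert "".join(row_u[j] for j in keep) == row_a


class TestVcf:
    def test_single_variant_row_matches_expected(self, tmp_path):
        ref = ReferenceSequence("chrM", "A" * 100)
        m = SiteMatrix(positions=(73,), ids=("s1", "s2"), rows=("A", "G"))
        out = tmp_path / "x.vcf"
        n = sites_to_vcf(m, ref, out)
        assert n == 1
        data = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert data == ["chrM\t73\t.\tA\tG\t.\t.\t.\tGT\t0\t1"]

    def test_monomorphic_reference_omitted(self, tmp_path):
        ref = ReferenceSequence("chrM", "ACGT")
        m = SiteMatrix(positions=(1, 2), ids=("s1", "s2"), rows=("AC", "AC"))
        n = sites_to_vcf(m, ref, tmp_path / "x.vcf")
        assert n == 0

    def test_missing_becomes_dot_and_never_alt(self, tmp_path):
        ref = ReferenceSequence("chrM", "AAAA")
        m = SiteMatrix(positions=(2,), ids=("s1", "s2", "s3"), rows=("N", "T", "A"))
        out = tmp_path / "x.vcf"
        sites_to_vcf(m, ref, out)
        row = [l for l in out.read_text().splitlines() if not l.startswith("#")][0]
        fields = row.split("\t")
        assert fields[4] == "T"  # N excluded from ALT
        assert fields[9:] == [".", "1", "0"]

    def test_roundtrip_recovers_polymorphic_columns(self, tmp_path, sim_dataset):
        m = mask_to_array(
            sim_dataset, ArrayManifest("m", tuple(range(1, 201)))
        )
        out = tmp_path / "r.vcf"
        sites_to_vcf(m, sim_dataset.reference, out)
        back = read_vcf(out)
        assert back.ids == m.ids
        poly = [
            j
            for j, p in enumerate(m.positions)
            if any(
                c not in ("N", sim_dataset.reference.base_at(p)) for c in m.column(j)
            )
        ]
        assert back.positions == tuple(m.positions[j] for j in poly)
        for i in range(m.n_samples):
            assert back.rows[i] == "".join(m.rows[i][j] for j in poly)

    def test_output_parses_with_pysam(self, tmp_path, sim_dataset):
        pysam = pytest.importorskip("pysam")
        m = mask_to_array(sim_dataset, ArrayManifest("m", tuple(range(1, 101))))
        out = tmp_path / "p.vcf"
        n = sites_to_vcf(m, sim_dataset.reference, out)
        with pysam.VariantFile(str(out)) as vf:
            recs = list(vf)
        assert len(recs) == n
        for rec in recs:
            assert rec.alts  # never an empty ALT list
            assert rec.ref == sim_dataset.reference.base_at(rec.pos)


class TestFilterVcf:
    @pytest.fixture()
    def vcf(self, tmp_path, sim_dataset):
        m = mask_to_array(sim_dataset, ArrayManifest("m", tuple(range(1, 301))))
        p = tmp_path / "all.vcf"
        sites_to_vcf(m, sim_dataset.reference, p)
        return p

    def test_disjoint_manifest_keeps_nothing(self, vcf, tmp_path):
        out = tmp_path / "f.vcf"
        kept = filter_vcf_positions(vcf, ArrayManifest("m", (1900, 1999)), out)
        assert kept == 0
        assert all(l.startswith("#") for l in out.read_text().splitlines())

    def test_superset_manifest_keeps_identical_rows(self, vcf, tmp_path):
        out = tmp_path / "f.vcf"
        filter_vcf_positions(vcf, ArrayManifest("m", tuple(range(1, 301))), out)
        orig = [l for l in vcf.read_text().splitlines() if not l.startswith("#")]
        kept = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert kept == orig

    def test_intersection_count_oracle(self, vcf, tmp_path):
        rng = np.random.default_rng(9)
        vcf_pos = {
            int(l.split("\t")[1])
            for l in vcf.read_text().splitlines()
            if not l.startswith("#")
        }
        for _ in range(5):
            pos = tuple(rng.choice(300, size=60, replace=False) + 1)
            manifest = ArrayManifest("m", pos)
            kept = filter_vcf_positions(vcf, manifest, tmp_path / "f.vcf")
            assert kept == len(vcf_pos & manifest.position_set())


class TestPanelOverlap:
    def test_contained_panel_has_nothing_missing(self):
        m = ArrayManifest("m", tuple(range(1, 100)))
        panel = ArrayManifest("p", (3, 5, 7))
        assert panel_missing_count(m, panel) == 0

    def test_fifty_four_snp_panel_with_single_overlap(self):
        # a 54-position software panel of which the array carries exactly one
        panel = ArrayManifest("panel", tuple(range(100, 154)))
        manifest = ArrayManifest("m", (100, 1000, 2000))
        assert len(panel) == 54
        assert panel_missing_count(manifest, panel) == 53

    def test_random_sets_match_bruteforce_and_partition(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = ArrayManifest("m", tuple(rng.integers(1, 200, size=50)))
            p = ArrayManifest("p", tuple(rng.integers(1, 200, size=30)))
            brute = sum(1 for x in p.positions if x not in m.position_set())
            missing = panel_missing_count(m, p)
            assert missing == brute
            assert missing + len(p.position_set() & m.position_set()) == len(p)
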