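import math

import numpy as np
import pytest

from helpers import random_additive_tree, tree_path_distances
from mitoarray.phylogeny import (
    BootstrapConfig,
    DistanceMatrix,
    SaturationError,
    SupportedTree,
    TreeNode,
    bootstrap_tree,
    internal_bipartitions,
    neighbor_joining,
    pairwise_distance,
    read_newick,
    robinson_foulds,
    to_newick,
    write_newick,
)
from mitoarray.seqio import SiteMatrix


def _matrix(*rows, ids=None):
    ids = ids or tuple(f"s{i}" for i in range(len(rows)))
    return SiteMatrix(
        positions=tuple(range(1, len(rows[0]) + 1)), ids=tuple(ids), rows=tuple(rows)
    )


class TestDistances:
    def test_p_distance_direct_count(self):
        dm = pairwise_distance(_matrix("AAAA", "AATT"), model="p")
        assert dm.values[0, 1] == pytest.approx(0.5)

    def test_k2p_closed_form(self):
        # one A<->G transition in ten sites: P=0.1, Q=0 -> -0.5 ln(0.8)
        dm = pairwise_distance(_matrix("A" * 10, "G" + "A" * 9), model="k2p")
        assert dm.values[0, 1] == pytest.approx(-0.5 * math.log(0.8), abs=1e-9)
        assert dm.values[0, 1] == pytest.approx(0.111572, abs=1e-6)

    @pytest.mark.parametrize("model", ["p", "k2p", "tn93"])
    def test_identical_rows_are_zero(self, model):
        dm = pairwise_distance(_matrix("ACGTACGT", "ACGTACGT", "ACGTACGT"), model=model)
        assert np.allclose(dm.values, 0.0)

    @pytest.mark.parametrize("model", ["p", "k2p", "tn93"])
    def test_symmetry_and_zero_diagonal_random(self, model):
        # mtDNA-like low divergence: a few percent of sites mutated per row
        rng = np.random.default_rng(11)
        base = rng.choice(list("ACGT"), size=200)
        rows = []
        for _ in range(6):
            row = base.copy()
            for i in rng.choice(200, size=8, replace=False):
                row[i] = rng.choice([b for b in "ACGT" if b != row[i]])
            rows.append("".join(row))
        dm = pairwise_distance(_matrix(*rows), model=model)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)

    def test_pairwise_deletion_ignores_missing_columns(self):
        # column 1 has an N for s0: only 3 columns compared for that pair
        dm = pairwise_distance(_matrix("NAAA", "TATA"), model="p")
        assert dm.values[0, 1] == pytest.approx(1 / 3)

    def test_complete_deletion_mode(self):
        dm = pairwise_distance(_matrix("NAAA", "TATA", "AATA"), missing="complete", model="p")
        # first column dropped for everyone
        assert dm.values[1, 2] == pytest.approx(0.0)

    def test_zero_comparable_sites_error(self):
        with pytest.raises(ValueError, match="zero comparable"):
            pairwise_distance(_matrix("NNAA", "AANN"), model="p")

    def test_k2p_saturation_names_pair(self):
        with pytest.raises(SaturationError, match="s0.*s1"):
            pairwise_distance(_matrix("A" * 10, "G" * 10), model="k2p")

    def test_tn93_reduces_to_k2p_on_balanced_composition(self):
        # columns engineered so pooled base frequencies are exactly uniform
        # and both transition types are equally frequent
        pairs = (
            ["AG", "CT"] * 2          # transitions, balanced
            + ["AC", "CA", "GT", "TG"]  # transversions, balanced
            + ["AA", "CC", "GG", "TT"] * 3  # matches, balanced
        )
        r1 = "".join(p[0] for p in pairs)
        r2 = "".join(p[1] for p in pairs)
        d_tn = pairwise_distance(_matrix(r1, r2), model="tn93").values[0, 1]
        d_k2 = pairwise_distance(_matrix(r1, r2), model="k2p").values[0, 1]
        assert d_tn == pytest.approx(d_k2, abs=1e-9)


class TestNeighborJoining:
    def test_spec_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2),(C:3,D:4)) with internal edge 1
        ids = ("A", "B", "C", "D")
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = neighbor_joining(DistanceMatrix(ids, D))
        sides = set(internal_bipartitions(tree, collapse_zero=False))
        assert frozenset({"C", "D"}) in sides or frozenset({"A", "B"}) in sides
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(("a", "b", "c"), D))
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths["a"] == pytest.approx(0.5 * (2 + 3 - 5))
        assert lengths["b"] == pytest.approx(0.5 * (2 + 5 - 3))
        assert lengths["c"] == pytest.approx(0.5 * (3 + 5 - 2))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(DistanceMatrix(("a", "b"), np.zeros((2, 2))))

    @pytest.mark.parametrize("seed", range(20))
    def test_random_additive_recovery(self, seed):
        rng = np.random.default_rng(seed)
        root, ids = random_additive_tree(rng, 12)
        D = tree_path_distances(root, ids)
        nj = neighbor_joining(DistanceMatrix(tuple(ids), D))
        assert robinson_foulds(root, nj) == 0
        assert np.allclose(tree_path_distances(nj, ids), D, atol=1e-9)

    def test_unrooted_binary_edge_count(self):
        rng = np.random.default_rng(7)
        root, ids = random_additive_tree(rng, 15)
        nj = neighbor_joining(DistanceMatrix(tuple(ids), tree_path_distances(root, ids)))
        n_edges = sum(1 for node in nj.postorder() if node is not nj)
        assert n_edges == 2 * len(ids) - 3

    def test_matches_scikit_bio_topology(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(19)
        root, ids = random_additive_tree(rng, 10)
        D = tree_path_distances(root, ids)
        ours = neighbor_joining(DistanceMatrix(tuple(ids), D))
        theirs = skbio_nj(skbio.DistanceMatrix(D, ids=list(ids)))
        ours_sides = set(internal_bipartitions(ours, collapse_zero=False))
        anchor_all = frozenset(ids)
        theirs_sides = set()
        for node in theirs.non_tips():
            names = frozenset(t.name for t in node.tips())
            if 2 <= len(names) <= len(ids) - 2:
                side = names if min(anchor_all) not in names else anchor_all - names
                theirs_sides.add(side)
        assert ours_sides == theirs_sides


class TestBootstrap:
    def test_unanimous_signal_gives_full_support(self):
        rows = ["A" * 50 + "C" * 450, "A" * 50 + "C" * 450,
                "G" * 50 + "C" * 450, "G" * 50 + "C" * 450]
        st = bootstrap_tree(_matrix(*rows), config=BootstrapConfig(100, seed=4))
        central = frozenset({"s2", "s3"})
        assert st.supports[central] == 100.0

    def test_single_replicate_granularity(self, sim_dataset):
        from mitoarray.seqio import ArrayManifest, mask_to_array

        m = mask_to_array(sim_dataset, ArrayManifest("m", tuple(range(1, 120))))
        st = bootstrap_tree(m, config=BootstrapConfig(1, seed=2))
        assert set(st.supports.values()) <= {0.0, 100.0}

    def test_seeded_determinism(self, sim_dataset, full_manifest):
        from mitoarray.seqio import mask_to_array

        m = mask_to_array(sim_dataset, full_manifest)
        a = bootstrap_tree(m, config=BootstrapConfig(60, seed=5))
        b = bootstrap_tree(m, config=BootstrapConfig(60, seed=5))
        assert a.supports == b.supports
        assert to_newick(a) == to_newick(b)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(21)
        pos = tuple(range(1, 81))
        rows = tuple("".join(rng.choice(list("ACGT"), size=80)) for _ in range(6))
        m1 = SiteMatrix(positions=pos, ids=tuple("abcdef"), rows=rows)
        perm = rng.permutation(80)
        m2 = SiteMatrix(
            positions=tuple(pos[i] for i in perm),
            ids=tuple("abcdef"),
            rows=tuple("".join(r[i] for i in perm) for r in rows),
        )
        s1 = bootstrap_tree(m1, model="p", config=BootstrapConfig(40, seed=8))
        s2 = bootstrap_tree(m2, model="p", config=BootstrapConfig(40, seed=8))
        assert s1.supports == s2.supports

    def test_different_seeds_agree_within_sampling_noise(self):
        rng = np.random.default_rng(13)
        # two 4-leaf clusters separated by 6 of 200 columns: support well
        # inside (0, 100), so seed-to-seed spread is binomial
        base = "".join(rng.choice(list("ACGT"), size=200))
        flip = {"A": "G", "G": "A", "C": "T", "T": "C"}
        other = base[:6].translate(str.maketrans(flip)) + base[6:]
        rows = [base, base, other, other]
        m = _matrix(*rows)
        s1 = bootstrap_tree(m, config=BootstrapConfig(200, seed=1))
        s2 = bootstrap_tree(m, config=BootstrapConfig(200, seed=2))
        central = frozenset({"s2", "s3"})
        p = s1.supports[central] / 100
        ci = 2.58 * math.sqrt(max(p * (1 - p), 0.01) / 200) * 100
        assert abs(s1.supports[central] - s2.supports[central]) <= 2 * ci + 1

    def test_monomorphic_matrix_has_no_internal_bipartitions(self):
        st = bootstrap_tree(
            _matrix("AAAA", "AAAA", "AAAA", "AAAA", "AAAA"),
            model="p",
            config=BootstrapConfig(5, seed=3),
        )
        assert st.supports == {}


class TestNewick:
    def test_four_leaf_tree_has_internal_label(self):
        rows = ["A" * 5 + "C" * 50, "A" * 5 + "C" * 50,
                "G" * 5 + "C" * 50, "G" * 5 + "C" * 50]
        st = bootstrap_tree(_matrix(*rows), config=BootstrapConfig(10, seed=1))
        text = to_newick(st)
        assert ")100:" in text

    def test_roundtrip_preserves_everything(self, tmp_path):
        rng = np.random.default_rng(17)
        for seed in range(5):
            root, ids = random_additive_tree(np.random.default_rng(seed), 8)
            D = tree_path_distances(root, ids)
            st = SupportedTree(
                root=neighbor_joining(DistanceMatrix(tuple(ids), D)),
                supports={},
            )
            st = SupportedTree(
                root=st.root,
                supports={
                    side: float(rng.integers(0, 101))
                    for side in internal_bipartitions(st.root)
                },
            )
            p = tmp_path / f"t{seed}.nwk"
            write_newick(st, p)
            back = read_newick(p)
            assert back.supports == st.supports
            assert robinson_foulds(back.root, st.root) == 0
            assert np.allclose(
                tree_path_distances(back.root, ids),
                tree_path_distances(st.root, ids),
                atol=1e-9,
            )

    def test_unbalanced_parentheses_rejected(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((a:1,b:1):1,(c:1,d:1;")
        with pytest.raises(ValueError, match="malformed newick"):
            read_newick(p)

    def test_negative_lengths_floored_on_write(self):
        t = TreeNode(
            children=[
                TreeNode("a", -0.5),
                TreeNode("b", 1.0),
                TreeNode("c", 2.0),
            ]
        )
        assert "a:0.0" in to_newick(t)
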