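import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

from p25scan import (
    DistanceMatrix, ProteinSeq, neighbor_joining, p_distance,
)
from p25scan.seqio import newick_string


def random_additive_matrix(rng, n_leaves):
    """Distances from a random binary tree with positive branch lengths."""
    nodes = [(f"t{i}",) for i in range(n_leaves)]
    lengths = {}
    children = {}
    while len(nodes) > 1:
        a = nodes.pop(int(rng.integers(len(nodes))))
        b = nodes.pop(int(rng.integers(len(nodes))))
        parent = a + b
        children[parent] = (a, b)
        lengths[a] = float(rng.uniform(0.05, 1.0))
        lengths[b] = float(rng.uniform(0.05, 1.0))
        nodes.append(parent)
    root = nodes[0]

    def leaf_depths(node, acc):
        if node in children:
            out = {}
            for ch in children[node]:
                for leaf, d in leaf_depths(ch, acc + lengths[ch]).items():
                    out[leaf] = d
            return out
        return {node[0]: acc}

    def paths(node):
        if node not in children:
            return {node[0]: 0.0}
        a, b = children[node]
        da = {k: v + lengths[a] for k, v in paths(a).items()}
        db = {k: v + lengths[b] for k, v in paths(b).items()}
        da.update(db)
        return da

    taxa = sorted(leaf_depths(root, 0.0))
    n = len(taxa)
    d = np.zeros((n, n))

    def fill(node):
        if node not in children:
            return
        a, b = children[node]
        pa, pb = paths(a), paths(b)
        for la, va in pa.items():
            for lb, vb in pb.items():
                i, j = taxa.index(la), taxa.index(lb)
                d[i, j] = d[j, i] = va + lengths[a] + vb + lengths[b]
        fill(a)
        fill(b)

    fill(root)
    return DistanceMatrix(taxa, d)


def topology_signature(tree_root, taxa):
    """Set of leaf bipartitions induced by internal edges."""
    full = frozenset(taxa)
    parts = set()
    for node in tree_root.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        parts.add(min(side, full - side, key=sorted))
    return parts


class TestPDistance:
    def test_identical_rows_zero(self):
        dm = p_distance([ProteinSeq("a", "MKLV"), ProteinSeq("b", "MKLV")])
        assert dm.d[0, 1] == 0.0

    def test_simple_count(self):
        dm = p_distance([ProteinSeq("a", "AAAA"), ProteinSeq("b", "AAAT")])
        assert dm.d[0, 1] == 0.25

    def test_pairwise_deletion_skips_gapped_columns(self):
        dm = p_distance([ProteinSeq("a", "MK-V"), ProteinSeq("b", "MALV")])
        assert dm.d[0, 1] == pytest.approx(1 / 3)

    def test_zero_comparable_columns_rejected(self):
        with pytest.raises(ValueError):
            p_distance([ProteinSeq("a", "M--"), ProteinSeq("b", "-KV")])

    def test_matches_column_counting_oracle(self, rng):
        letters = list("ACDEFG-")
        for _ in range(20):
            rows = ["".join(rng.choice(letters, size=30)) for _ in range(4)]
            # ensure comparability
            rows = [("M" + r[1:]) for r in rows]
            msa = [ProteinSeq(f"t{i}", r) for i, r in enumerate(rows)]
            dm = p_distance(msa)
            for i in range(4):
                for j in range(i + 1, 4):
                    comp = [(a, b) for a, b in zip(rows[i], rows[j])
                            if a != "-" and b != "-"]
                    expected = sum(a != b for a, b in comp) / len(comp)
                    assert dm.d[i, j] == pytest.approx(expected)


class TestNeighborJoining:
    def test_three_taxa_three_point_formulas(self):
        d = np.array([[0.0, 0.3, 0.5],
                      [0.3, 0.0, 0.6],
                      [0.5, 0.6, 0.0]])
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        la = tree.root.find("a").length
        lb = tree.root.find("b").length
        lc = tree.root.find("c").length
        assert la == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lb == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lc == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_four_taxon_additive_exact(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) — four-point condition by hand
        d = np.array([
            [0.0, 3.0, 5.0, 6.0],
            [3.0, 0.0, 6.0, 7.0],
            [5.0, 6.0, 0.0, 7.0],
            [6.0, 7.0, 7.0, 0.0],
        ])
        dm = DistanceMatrix(["a", "b", "c", "d"], d)
        tree = neighbor_joining(dm)
        for i, ti in enumerate(dm.taxa):
            for j in range(i + 1, 4):
                assert tree.tip_distance(ti, dm.taxa[j]) == \
                    pytest.approx(d[i, j], abs=1e-9)
        sig = topology_signature(tree.root, dm.taxa)
        assert frozenset({"a", "b"}) in sig or frozenset({"c", "d"}) in sig

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(
                DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
            )

    def test_additive_recovery_random_trees(self, rng):
        for _ in range(30):
            dm = random_additive_matrix(rng, 8)
            tree = neighbor_joining(dm)
            assert set(t.name for t in tree.root.tips()) == set(dm.taxa)
            for i, ti in enumerate(dm.taxa):
                for j in range(i + 1, len(dm.taxa)):
                    assert tree.tip_distance(ti, dm.taxa[j]) == \
                        pytest.approx(dm.d[i, j], abs=1e-9)

    def test_topology_matches_skbio_nj(self, rng):
        for _ in range(10):
            dm = random_additive_matrix(rng, 7)
            ours = neighbor_joining(dm)
            theirs = skbio_nj(SkbioDM(dm.d, ids=dm.taxa))
            ours_sig = topology_signature(ours.root, dm.taxa)
            theirs_sig = topology_signature(theirs.root(), dm.taxa)
            assert ours_sig == theirs_sig

    def test_negative_estimates_clamped_and_flagged(self):
        # strongly non-additive distances force a negative NJ estimate
        d = np.array([
            [0.00, 0.64, 0.28, 0.05],
            [0.64, 0.00, 0.03, 0.82],
            [0.28, 0.03, 0.00, 0.91],
            [0.05, 0.82, 0.91, 0.00],
        ])
        tree = neighbor_joining(DistanceMatrix(list("abcd"), d))
        lengths = [n.length for n in tree.root.traverse()
                   if n.length is not None]
        assert all(l >= 0 for l in lengths)
        assert tree.negative_branches_clamped

    def test_newick_export(self):
        d = np.array([[0.0, 0.2, 0.4],
                      [0.2, 0.0, 0.4],
                      [0.4, 0.4, 0.0]])
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        text = newick_string(tree)
        assert text.endswith(";")
        assert all(t in text for t in "abc")


class TestMatrixValidation:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.1, 1.0], [1.0, 0.0]]))
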