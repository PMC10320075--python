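"""p-distances, neighbor joining and Newick output."""

import io
import itertools

import numpy as np
import pytest
from Bio import Phylo

from sh2num.phylo import (
    DistanceMatrix,
    neighbor_joining,
    pdistance_matrix,
    write_newick,
    write_phylip_matrix,
)
from sh2num.profile_numbering import Alignment


def tree_path_lengths(newick: str) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths parsed back from Newick (independent of NJ)."""
    tree = Phylo.read(io.StringIO(newick), "newick")
    leaves = tree.get_terminals()
    out = {}
    for a, b in itertools.combinations(leaves, 2):
        key = tuple(sorted((a.name, b.name)))
        out[key] = tree.distance(a, b)
    return out


def additive_matrix_from_quartet(
    a: float, b: float, c: float, d: float, internal: float
) -> DistanceMatrix:
    """Distances on the quartet tree ((A:a,B:b):internal,(C:c,D:d))."""
    vals = np.array([
        [0, a + b, a + internal + c, a + internal + d],
        [a + b, 0, b + internal + c, b + internal + d],
        [a + internal + c, b + internal + c, 0, c + d],
        [a + internal + d, b + internal + d, c + d, 0],
    ], dtype=float)
    return DistanceMatrix(("A", "B", "C", "D"), vals)


class TestPDistance:
    def test_identical_records_zero(self):
        aln = Alignment((("a", "ACDEF"), ("b", "ACDEF")))
        assert pdistance_matrix(aln).values[0, 1] == 0.0

    def test_half_different(self):
        aln = Alignment((("a", "AAAAAAAAAA"), ("b", "AAAAACCCCC")))
        assert pdistance_matrix(aln).values[0, 1] == pytest.approx(0.5)

    def test_pairwise_deletion(self):
        # 4 comparable columns, 1 differing
        aln = Alignment((("a", "AC-EF"), ("b", "AC-EW")))
        assert pdistance_matrix(aln).values[0, 1] == pytest.approx(0.25)

    def test_no_comparable_columns_errors(self):
        aln = Alignment((("a", "AA--"), ("b", "--AA")))
        with pytest.raises(ValueError, match="comparable"):
            pdistance_matrix(aln)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(13)
        alphabet = list("ACDEFG-")
        rows = ["".join(rng.choice(alphabet, size=40)) for _ in range(8)]
        aln = Alignment(tuple((f"r{i}", s) for i, s in enumerate(rows)))
        dm = pdistance_matrix(aln)
        for i in range(8):
            for j in range(8):
                comp = [
                    (x, y) for x, y in zip(rows[i], rows[j])
                    if x != "-" and y != "-"
                ]
                expected = (
                    sum(1 for x, y in comp if x != y) / len(comp) if comp else 0.0
                )
                if i == j:
                    expected = 0.0
                assert dm.values[i, j] == pytest.approx(expected)

    def test_symmetry_and_zero_diagonal(self, family, family_annotations):
        from sh2num.profile_numbering import numbered_subalignment
        numbering, _ = family_annotations
        dm = pdistance_matrix(numbered_subalignment(family.alignment, numbering))
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)
        assert ((dm.values >= 0) & (dm.values <= 1)).all()


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(("A", "B", "C"), np.array([
            [0.0, 0.3, 0.5],
            [0.3, 0.0, 0.6],
            [0.5, 0.6, 0.0],
        ]))
        newick = write_newick(neighbor_joining(d))
        paths = tree_path_lengths(newick)
        assert paths[("A", "B")] == pytest.approx(0.3, abs=1e-9)
        assert paths[("A", "C")] == pytest.approx(0.5, abs=1e-9)
        assert paths[("B", "C")] == pytest.approx(0.6, abs=1e-9)

    def test_additive_quartet_recovered_exactly(self):
        dm = additive_matrix_from_quartet(0.1, 0.25, 0.05, 0.3, internal=0.2)
        tree = neighbor_joining(dm)
        paths = tree_path_lengths(write_newick(tree))
        for (x, y), expected in {
            ("A", "B"): 0.35, ("C", "D"): 0.35,
            ("A", "C"): 0.35, ("A", "D"): 0.60,
            ("B", "C"): 0.50, ("B", "D"): 0.75,
        }.items():
            assert paths[tuple(sorted((x, y)))] == pytest.approx(expected, abs=1e-9)
        # topology: A,B are sisters (their path avoids the internal branch)
        t = Phylo.read(io.StringIO(write_newick(tree)), "newick")
        ab = t.common_ancestor(["A", "B"])
        assert {l.name for l in ab.get_terminals()} == {"A", "B"}

    def test_additive_five_taxon_path_lengths(self):
        # caterpillar tree ((((A:1,B:2):1,C:3):1,D:4):1,E:5) as distances
        names = ("A", "B", "C", "D", "E")
        leaf = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0, "E": 5.0}
        depth = {"A": 3, "B": 3, "C": 2, "D": 1, "E": 0}  # internal edges above each leaf
        vals = np.zeros((5, 5))
        for i, x in enumerate(names):
            for j, y in enumerate(names):
                if i != j:
                    shared = min(depth[x], depth[y])
                    vals[i, j] = leaf[x] + leaf[y] + (depth[x] - shared) + (depth[y] - shared)
        dm = DistanceMatrix(names, vals)
        paths = tree_path_lengths(write_newick(neighbor_joining(dm)))
        for i, x in enumerate(names):
            for j in range(i + 1, 5):
                y = names[j]
                assert paths[(x, y)] == pytest.approx(vals[i, j], abs=1e-9)

    def test_ultrametric_sister_groupings(self):
        # ((A,B) at height 1, (C,D) at height 2) joined at height 4; E at height 4
        names = ("A", "B", "C", "D", "E")
        vals = np.array([
            [0, 2, 8, 8, 8],
            [2, 0, 8, 8, 8],
            [8, 8, 0, 4, 8],
            [8, 8, 4, 0, 8],
            [8, 8, 8, 8, 0],
        ], dtype=float)
        t = neighbor_joining(DistanceMatrix(names, vals))
        tree = Phylo.read(io.StringIO(write_newick(t)), "newick")
        # unrooted check: the bipartitions {A,B} and {C,D} must both be splits
        all_names = set(names)
        splits = set()
        for clade in tree.find_clades():
            terms = frozenset(l.name for l in clade.get_terminals())
            splits.add(terms)
            splits.add(frozenset(all_names - terms))
        assert frozenset({"A", "B"}) in splits
        assert frozenset({"C", "D"}) in splits

    def test_agrees_with_scikit_bio(self):
        """Independent implementation oracle on a random (noisy) matrix."""
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(23)
        n = 7
        base = rng.uniform(0.1, 0.9, size=(n, n))
        vals = (base + base.T) / 2
        np.fill_diagonal(vals, 0.0)
        labels = tuple(f"t{i}" for i in range(n))
        ours = neighbor_joining(DistanceMatrix(labels, vals))
        theirs = skbio_nj(skbio.DistanceMatrix(vals, labels))
        ours_paths = tree_path_lengths(write_newick(ours))
        for (x, y), v in ours_paths.items():
            assert theirs.find(x).distance(theirs.find(y)) == pytest.approx(v, abs=1e-6)

    def test_leaf_and_branch_counts(self, family, family_annotations):
        from sh2num.profile_numbering import numbered_subalignment
        numbering, _ = family_annotations
        dm = pdistance_matrix(numbered_subalignment(family.alignment, numbering))
        tree = neighbor_joining(dm)
        n = len(dm)
        assert len(tree.get_terminals()) == n
        n_branches = sum(1 for _ in tree.find_clades()) - 1  # root has no branch
        assert n_branches == 2 * n - 3

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("A", "B", "C"), np.array([
                [0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0],
            ]))

    def test_negative_branch_lengths_clamped(self):
        vals = np.array([
            [0.0, 0.1, 0.4, 0.4],
            [0.1, 0.0, 0.4, 0.45],
            [0.4, 0.4, 0.0, 0.05],
            [0.4, 0.45, 0.05, 0.0],
        ])
        tree = neighbor_joining(DistanceMatrix(("A", "B", "C", "D"), vals))
        for clade in tree.find_clades():
            if clade.branch_length is not None:
                assert clade.branch_length >= 0.0


class TestNewick:
    def test_three_leaf_single_nesting(self):
        d = DistanceMatrix(("A", "B", "C"), np.array([
            [0.0, 0.2, 0.4], [0.2, 0.0, 0.4], [0.4, 0.4, 0.0],
        ]))
        newick = write_newick(neighbor_joining(d))
        assert newick.count("(") == 1
        assert newick.endswith(";\n")

    def test_roundtrip_topology_and_lengths(self):
        rng = np.random.default_rng(31)
        for trial in range(5):
            n = int(rng.integers(4, 9))
            base = rng.uniform(0.05, 1.0, size=(n, n))
            vals = (base + base.T) / 2
            np.fill_diagonal(vals, 0.0)
            labels = tuple(f"leaf{i}" for i in range(n))
            tree = neighbor_joining(DistanceMatrix(labels, vals))
            nw = write_newick(tree)
            parsed = Phylo.read(io.StringIO(nw), "newick")
            assert {l.name for l in parsed.get_terminals()} == set(labels)
            assert tree_path_lengths(nw) == pytest.approx(
                tree_path_lengths(write_newick(parsed)), abs=1e-9
            )

    def test_labels_with_spaces_quoted(self):
        from Bio.Phylo.BaseTree import Clade
        clade = Clade(clades=[
            Clade(name="GRB2 SH2", branch_length=0.1),
            Clade(name="SRC-C", branch_length=0.2),
            Clade(name="plain", branch_length=0.3),
        ])
        nw = write_newick(clade)
        assert "'GRB2 SH2'" in nw
        assert "'SRC-C'" not in nw  # hyphens need no quoting

    def test_lengths_at_six_decimals(self):
        from Bio.Phylo.BaseTree import Clade
        clade = Clade(clades=[
            Clade(name="a", branch_length=0.1234567), Clade(name="b", branch_length=1.0),
        ])
        assert ":0.123457" in write_newick(clade)


class TestPhylipMatrix:
    def test_square_matrix_output(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 0.5], [0.5, 0.0]]))
        text = write_phylip_matrix(dm)
        lines = text.strip().splitlines()
        assert lines[0] == "2"
        assert lines[1].split("\t") == ["A", "0.000000", "0.500000"]
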