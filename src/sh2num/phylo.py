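"""Distance-based phylogeny over the numbered-position sub-alignment.

Restricting the family MSA to columns that carry a generic number yields a
gap-sparse alignment of structurally equivalent positions, a natural input
for distance-based tree building across SH2-domain-containing proteins.
Distances are p-distances (proportion of differing residues over mutually
ungapped columns, i.e. pairwise deletion); the tree is built by
neighbor joining (Saitou & Nei), which is exact on additive matrices.
Ties in the joining criterion break deterministically by label order, and
negative branch lengths are clamped to zero.  C-terminal domains of
dual-SH2 proteins are conventionally labelled with a "-C" suffix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from Bio.Phylo.BaseTree import Clade, Tree

from .profile_numbering import GAP, Alignment

__all__ = [
    "DistanceMatrix",
    "pdistance_matrix",
    "neighbor_joining",
    "write_newick",
    "write_phylip_matrix",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.labels)


def pdistance_matrix(aln: Alignment) -> DistanceMatrix:
    """Pairwise p-distances over mutually non-gap columns (pairwise deletion)."""
    if len(aln.records) < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    ids = aln.ids
    seqs = [s for _, s in aln.records]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = 0
            diffs = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a != GAP and b != GAP:
                    comparable += 1
                    if a != b:
                        diffs += 1
            if comparable == 0:
                raise ValueError(
                    f"records {ids[i]!r} and {ids[j]!r} share no comparable columns"
                )
            d[i, j] = d[j, i] = diffs / comparable
    return DistanceMatrix(tuple(ids), d)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Neighbor joining (Saitou-Nei agglomeration) on a distance matrix.

    Exact on additive matrices.  Deterministic: among tied joining pairs the
    one with the lexicographically smallest label pair is taken; negative
    branch lengths are clamped to zero.  Returns an unrooted tree
    (trifurcating root).
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.values.astype(float).copy()
    nodes: list[Clade] = [Clade(name=lab) for lab in dm.labels]
    # sort key per node: smallest leaf label under it, for tie-breaking
    keys: list[str] = list(dm.labels)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] <= qmin + 1e-12:
                    pair_key = tuple(sorted((keys[i], keys[j])))
                    if best is None or pair_key < best[0]:
                        best = (pair_key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length = li
        child_j.branch_length = lj
        new = Clade(clades=[child_i, child_j])
        new_key = min(keys[i], keys[j])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])

        keep = [k for k in range(m) if k not in (i, j)]
        d_next = np.zeros((len(keep) + 1, len(keep) + 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = d_next[:-1, -1] = new_d[keep]
        d = d_next
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [new_key]

    # three remaining nodes: closed-form terminal branch lengths
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    a.branch_length = max(la, 0.0)
    b.branch_length = max(lb, 0.0)
    c.branch_length = max(lc, 0.0)
    order = sorted(range(3), key=lambda k: keys[k])
    root = Clade(clades=[nodes[k] for k in order])
    return Tree(root=root, rooted=False)


_PLAIN_LABEL = re.compile(r"^[A-Za-z0-9_.\-|/]+$")


def _quote_label(label: str) -> str:
    if _PLAIN_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _newick_clade(clade: Clade) -> str:
    if clade.clades:
        inner = ",".join(_newick_clade(c) for c in clade.clades)
        text = f"({inner})"
        if clade.name:
            text += _quote_label(clade.name)
    else:
        text = _quote_label(clade.name or "")
    if clade.branch_length is not None:
        text += f":{clade.branch_length:.6f}"
    return text


def write_newick(tree: Tree | Clade) -> str:
    """Newick text with branch lengths at 6 decimals; odd labels are quoted."""
    root = tree.root if isinstance(tree, Tree) else tree
    return _newick_clade(root) + ";\n"


def write_phylip_matrix(dm: DistanceMatrix) -> str:
    """Square PHYLIP-style tab-separated distance matrix."""
    lines = [str(len(dm))]
    for lab, row in zip(dm.labels, dm.values):
        lines.append("\t".join([lab] + [f"{v:.6f}" for v in row]))
    return "\n".join(lines) + "\n"
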