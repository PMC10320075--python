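"""Derive generic numbering from a multiple sequence alignment.

Given a curated MSA of SH2 domain sequences and a per-column segmentation
(which columns belong to which secondary-structure segment), this module
scores column conservation, picks each segment's most conserved column as
the x50 anchor, numbers the remaining segment columns sequentially, and
propagates the column numbers to every member sequence — and, by pairwise
alignment, to new sequences not in the MSA.

Conservation is the modal non-gap residue frequency among non-gap entries:
simple, auditable and sufficient to locate invariant anchor columns.
Segmentation is an input (curated, or from structure annotations); secondary
structure is never predicted here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .scheme import (
    ANCHOR_INDEX,
    DomainAnnotation,
    GenericNumber,
    SchemeError,
    parse_generic_number,
)

__all__ = [
    "Alignment",
    "ColumnSegmentation",
    "ColumnNumbering",
    "column_conservation",
    "select_anchor_column",
    "number_segment_columns",
    "number_alignment",
    "propagate",
    "number_new_sequence",
    "numbered_subalignment",
]

GAP = "-"


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment: (id, aligned sequence) records."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
        ids = [i for i, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in alignment")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    def sequence(self, rec_id: str) -> str:
        for i, s in self.records:
            if i == rec_id:
                return s
        raise KeyError(rec_id)

    def column(self, j: int) -> str:
        if not 0 <= j < self.length:
            raise IndexError(f"column {j} out of range 0..{self.length - 1}")
        return "".join(s[j] for _, s in self.records)

    @classmethod
    def from_fasta(cls, handle_or_text) -> "Alignment":
        if isinstance(handle_or_text, str):
            handle_or_text = io.StringIO(handle_or_text)
        recs = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(handle_or_text, "fasta")]
        return cls(tuple(recs))

    def to_fasta(self) -> str:
        return "".join(f">{i}\n{s}\n" for i, s in self.records)


@dataclass(frozen=True)
class ColumnSegmentation:
    """Per-column segment label (or None for loop / unnumbered columns)."""

    labels: tuple[Optional[str], ...]

    def __post_init__(self) -> None:
        # each segment's columns must form one contiguous block
        seen_done: set[str] = set()
        current: Optional[str] = None
        for lab in self.labels:
            if lab != current:
                if lab is not None:
                    if lab in seen_done:
                        raise ValueError(f"segment {lab!r} occupies non-contiguous columns")
                    seen_done.add(lab)
                current = lab

    def blocks(self) -> list[tuple[str, range]]:
        """Ordered (segment, column range) blocks of labelled columns."""
        out: list[tuple[str, range]] = []
        start = None
        current: Optional[str] = None
        for j, lab in enumerate(list(self.labels) + [None]):
            if lab != current:
                if current is not None:
                    out.append((current, range(start, j)))
                current, start = lab, j
        return out

    @classmethod
    def from_tsv(cls, text: str, length: int) -> "ColumnSegmentation":
        """Read a two-column (column_index, segment_label) table; 0-based columns."""
        labels: list[Optional[str]] = [None] * length
        for ln, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"segmentation line {ln}: expected 2 fields, got {len(parts)}")
            j, lab = int(parts[0]), parts[1]
            if not 0 <= j < length:
                raise ValueError(f"segmentation line {ln}: column {j} out of range")
            labels[j] = lab
        return cls(tuple(labels))


@dataclass(frozen=True)
class ColumnNumbering:
    """Map from alignment column index to :class:`GenericNumber`."""

    mapping: Mapping[int, GenericNumber] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.mapping)

    def columns(self) -> list[int]:
        return sorted(self.mapping)

    def merged(self, other: "ColumnNumbering") -> "ColumnNumbering":
        m = dict(self.mapping)
        m.update(other.mapping)
        return ColumnNumbering(m)


def column_conservation(aln: Alignment, column: int) -> float:
    """Modal non-gap residue frequency among non-gap entries of one column.

    Returns 0.0 for an all-gap column.
    """
    col = aln.column(column)
    residues = [c for c in col if c != GAP]
    if not residues:
        return 0.0
    counts: dict[str, int] = {}
    for c in residues:
        counts[c] = counts.get(c, 0) + 1
    return max(counts.values()) / len(residues)


def select_anchor_column(
    aln: Alignment, seg_cols: Sequence[int], max_gap_fraction: float = 0.5
) -> int:
    """The most conserved column of a segment block: its x50 anchor.

    Ties break to the leftmost column.  Columns where more than half the
    records are gapped are ineligible, unless every column is.
    """
    cols = list(seg_cols)
    if not cols:
        raise ValueError("empty segment column range")
    n = len(aln.records)
    eligible = [
        j for j in cols
        if sum(1 for c in aln.column(j) if c == GAP) / n <= max_gap_fraction
    ]
    if not eligible:
        eligible = cols
    best = eligible[0]
    best_score = column_conservation(aln, best)
    for j in eligible[1:]:
        s = column_conservation(aln, j)
        if s > best_score:
            best, best_score = j, s
    return best


def number_segment_columns(
    seg_cols: Sequence[int], anchor: int, seg: str
) -> ColumnNumbering:
    """Number a segment's columns sequentially around its anchor (index 50).

    The bBbC turn is special-cased: its two columns are fixed x49/x50
    regardless of conservation, so the ``anchor`` argument is ignored there.
    """
    cols = list(seg_cols)
    if seg == "bBbC":
        if len(cols) != 2:
            raise SchemeError(f"the bBbC turn spans exactly 2 columns, got {len(cols)}")
        return ColumnNumbering({
            cols[0]: GenericNumber("bBbC", 49),
            cols[1]: GenericNumber("bBbC", 50),
        })
    if anchor not in cols:
        raise ValueError(f"anchor column {anchor} not in segment columns")
    a = cols.index(anchor)
    return ColumnNumbering({
        j: GenericNumber(seg, ANCHOR_INDEX + (k - a)) for k, j in enumerate(cols)
    })


def number_alignment(aln: Alignment, segm: ColumnSegmentation) -> ColumnNumbering:
    """Anchor and number every labelled segment block of the alignment."""
    if len(segm.labels) != aln.length:
        raise ValueError(
            f"segmentation covers {len(segm.labels)} columns, alignment has {aln.length}"
        )
    numbering = ColumnNumbering({})
    for seg, cols in segm.blocks():
        anchor = cols[0] if seg == "bBbC" else select_anchor_column(aln, cols)
        numbering = numbering.merged(number_segment_columns(cols, anchor, seg))
    return numbering


def propagate(
    aln: Alignment, segm: ColumnSegmentation, numbering: ColumnNumbering | None = None
) -> tuple[ColumnNumbering, dict[str, DomainAnnotation]]:
    """Propagate column numbers to every alignment record.

    Each non-gap residue in a numbered column receives that column's generic
    number; a record gapped at a numbered column simply lacks that number.
    Residue numbers are 1-based positions in the record's ungapped sequence.
    Segments without internal gaps in a record are marked contiguous in its
    annotation.
    """
    if numbering is None:
        numbering = number_alignment(aln, segm)
    if len(segm.labels) != aln.length:
        raise ValueError("segmentation inconsistent with alignment length")
    for j in numbering.mapping:
        if segm.labels[j] is None:
            raise ValueError(f"numbered column {j} has no segment label")

    annotations: dict[str, DomainAnnotation] = {}
    for rec_id, seq in aln.records:
        resnum = 0
        col_to_res: dict[int, int] = {}
        for j, c in enumerate(seq):
            if c != GAP:
                resnum += 1
                col_to_res[j] = resnum
        position_map: dict[GenericNumber, int] = {}
        for j, gn in numbering.mapping.items():
            if j in col_to_res:
                position_map[gn] = col_to_res[j]
        contiguous: set[str] = set()
        for seg, cols in segm.blocks():
            if all(seq[j] != GAP for j in cols):
                contiguous.add(seg)
        annotations[rec_id] = DomainAnnotation(
            protein_id=rec_id,
            layout="common",
            position_map=position_map,
            contiguous_segments=frozenset(contiguous),
            sequence=seq.replace(GAP, ""),
            seq_start=1,
        )
    return numbering, annotations


def _make_aligner(
    matrix: str = "BLOSUM62", gap_open: float = 11.0, gap_extend: float = 1.0
) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    # global with free end gaps
    aligner.end_gap_score = 0.0
    aligner.mode = "global"
    return aligner


def _pairwise_identity_and_map(aligner: PairwiseAligner, a: str, b: str):
    """Align a to b; return (identity over aligned pairs, dict a_pos -> b_pos, 0-based)."""
    alignment = aligner.align(a, b)[0]
    pos_map: dict[int, int] = {}
    matches = 0
    aligned_pairs = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for k in range(a1 - a0):
            ia, ib = a0 + k, b0 + k
            pos_map[ia] = ib
            aligned_pairs += 1
            if a[ia] == b[ib]:
                matches += 1
    identity = matches / aligned_pairs if aligned_pairs else 0.0
    return identity, pos_map


def number_new_sequence(
    seq: str,
    aln: Alignment,
    segm: ColumnSegmentation,
    numbering: ColumnNumbering | None = None,
    min_identity: float = 0.25,
    min_length: int = 60,
    max_length: int = 160,
    seq_start: int = 1,
    protein_id: str = "query",
) -> DomainAnnotation:
    """Number a sequence not in the MSA by pairwise alignment to its closest record.

    The query is globally aligned (substitution-matrix scored, affine gaps,
    free end gaps) to the most similar alignment member; column numbers are
    transferred through the pairwise alignment.  Refused when the best
    identity falls below ``min_identity``.
    """
    seq = seq.upper().replace(GAP, "")
    if not min_length <= len(seq) <= max_length:
        raise ValueError(
            f"sequence length {len(seq)} outside the plausible SH2 range "
            f"{min_length}..{max_length}"
        )
    numbering, annotations = propagate(aln, segm, numbering)
    aligner = _make_aligner()

    best_id: Optional[str] = None
    best_identity = -1.0
    best_map: dict[int, int] = {}
    for rec_id, aligned_seq in aln.records:
        template = aligned_seq.replace(GAP, "")
        identity, pos_map = _pairwise_identity_and_map(aligner, seq, template)
        if identity > best_identity:
            best_id, best_identity, best_map = rec_id, identity, pos_map
    if best_identity < min_identity:
        raise ValueError(
            f"best pairwise identity {best_identity:.2f} (to {best_id}) is below "
            f"the floor {min_identity:.2f}; refusing to transfer numbering"
        )

    template_ann = annotations[best_id]
    template_res_to_gn = {res: gn for gn, res in template_ann.position_map.items()}
    inverse = {tpos: qpos for qpos, tpos in best_map.items()}
    position_map: dict[GenericNumber, int] = {}
    for res, gn in template_res_to_gn.items():
        tpos0 = res - 1
        if tpos0 in inverse:
            position_map[gn] = inverse[tpos0] + seq_start

    # a segment is contiguous for the query if its transferred positions are
    # consecutive in both index and residue number
    by_seg: dict[str, list[tuple[int, int]]] = {}
    for gn, res in position_map.items():
        by_seg.setdefault(gn.segment, []).append((gn.index, res))
    contiguous = set()
    for seg, pairs in by_seg.items():
        pairs.sort()
        if all(
            (i2 - i1) == (r2 - r1) == 1
            for (i1, r1), (i2, r2) in zip(pairs, pairs[1:])
        ):
            contiguous.add(seg)

    return DomainAnnotation(
        protein_id=protein_id,
        position_map=position_map,
        contiguous_segments=frozenset(contiguous),
        sequence=seq,
        seq_start=seq_start,
    )


def numbered_subalignment(aln: Alignment, numbering: ColumnNumbering) -> Alignment:
    """Restrict the alignment to numbered columns (order preserved)."""
    if not numbering.mapping:
        raise ValueError("empty column numbering")
    cols = numbering.columns()
    return Alignment(tuple(
        (rec_id, "".join(seq[j] for j in cols)) for rec_id, seq in aln.records
    ))
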