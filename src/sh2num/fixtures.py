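"""Synthetic SH2-like families and idealized structures with known ground truth.

Everything here is generated, seeded and pure: calling a generator twice
with the same arguments reproduces the output bit-exactly.  The synthetic
families emulate the features of the real family that the numbering
machinery relies on — one invariant anchor column per secondary-structure
segment, point substitutions elsewhere, and indels confined to loops — not
realistic evolution.  The module also bundles the published STAT5B and
SHP2-N anchor annotations so the scheme is usable offline out of the box.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional

import numpy as np
from Bio.Data.IUPACData import protein_letters_1to3

from .profile_numbering import (
    Alignment,
    ColumnNumbering,
    ColumnSegmentation,
    number_segment_columns,
)
from .scheme import DomainAnnotation, GenericNumber
from .structure_io import Atom, DomainStructure, StructureModel

__all__ = [
    "SyntheticFamily",
    "BundledAnchors",
    "make_synthetic_family",
    "make_synthetic_domain_structure",
    "make_synthetic_domain",
    "random_rigid_transform",
    "bundled_anchors",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# (segment label or None for loop, block length, anchor offset within block)
_TEMPLATE_LAYOUT: tuple[tuple[Optional[str], int, Optional[int]], ...] = (
    (None, 3, None),
    ("bA", 5, 2),
    (None, 4, None),
    ("aA", 10, 4),
    (None, 3, None),
    ("bB", 7, 4),      # indices 46..52, anchor the 5th column
    ("bBbC", 2, None),  # fixed x49/x50
    ("bC", 6, 3),
    (None, 3, None),
    ("bD", 6, 3),      # indices 47..52
    (None, 2, None),
    ("bE", 4, 1),
    (None, 3, None),
    ("bF", 4, 1),
    (None, 4, None),
    ("aB", 10, 4),
    (None, 3, None),
)


@dataclass(frozen=True)
class SyntheticFamily:
    """A generated alignment with its full ground truth."""

    alignment: Alignment
    segmentation: ColumnSegmentation
    true_numbering: ColumnNumbering
    true_annotations: Mapping[str, DomainAnnotation]
    anchor_columns: Mapping[str, int]
    template: str
    seed: int


def _template_structure() -> tuple[list[Optional[str]], dict[str, int], ColumnNumbering]:
    """Column labels, anchor column per segment, and the true numbering."""
    labels: list[Optional[str]] = []
    anchors: dict[str, int] = {}
    numbering = ColumnNumbering({})
    col = 0
    for seg, length, anchor_off in _TEMPLATE_LAYOUT:
        cols = list(range(col, col + length))
        if seg is not None:
            anchor = cols[anchor_off] if anchor_off is not None else cols[0]
            anchors[seg] = anchor
            numbering = numbering.merged(number_segment_columns(cols, anchor, seg))
        labels.extend([seg] * length)
        col += length
    return labels, anchors, numbering


def make_synthetic_family(
    n_records: int = 20,
    mutation_rate: float = 0.1,
    seed: int = 0,
    gap_probability: float = 0.3,
) -> SyntheticFamily:
    """Generate a family of SH2-like aligned sequences with known numbering.

    A random template follows the common segment layout.  One column per
    numbered segment is invariant (the planted anchor); every other column
    mutates i.i.d. at ``mutation_rate`` per record.  To keep the planted
    anchor the unique conservation maximum of its segment — i.e. to make the
    ground truth identifiable — any non-anchor numbered column that drew no
    substitution at all receives one forced substitution in one record.
    Indels are planted only in loop columns, honouring the rationale that
    loops are too variable for position-wise comparison.
    """
    if n_records < 2:
        raise ValueError("need at least 2 records")
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels, anchors, numbering = _template_structure()
    n_cols = len(labels)
    anchor_cols = set(anchors.values())
    # both bBbC columns are fixed constants, treat them as anchors too
    bbbc_cols = {j for j, lab in enumerate(labels) if lab == "bBbC"}
    protected = anchor_cols | bbbc_cols

    template = "".join(rng.choice(list(AMINO_ACIDS)) for _ in range(n_cols))

    rows: list[list[str]] = []
    for _ in range(n_records):
        row = list(template)
        if mutation_rate > 0:
            for j in range(n_cols):
                if j in protected:
                    continue
                if rng.random() < mutation_rate:
                    choices = [a for a in AMINO_ACIDS if a != template[j]]
                    row[j] = choices[rng.integers(len(choices))]
        rows.append(row)

    if mutation_rate > 0:
        # identifiability pass: every non-anchor numbered column differs from
        # the template in at least one record
        for j in range(n_cols):
            if labels[j] is None or j in protected:
                continue
            if all(rows[r][j] == template[j] for r in range(n_records)):
                r = int(rng.integers(n_records))
                choices = [a for a in AMINO_ACIDS if a != template[j]]
                rows[r][j] = choices[rng.integers(len(choices))]

        # indels confined to loops
        loop_blocks = []
        col = 0
        for seg, length, _ in _TEMPLATE_LAYOUT:
            if seg is None and length >= 2:
                loop_blocks.append(list(range(col, col + length)))
            col += length
        for r in range(n_records):
            if rng.random() < gap_probability:
                block = loop_blocks[rng.integers(len(loop_blocks))]
                width = int(rng.integers(1, min(2, len(block) - 1) + 1))
                start = int(rng.integers(len(block) - width + 1))
                for j in block[start:start + width]:
                    rows[r][j] = "-"

    records = tuple(
        (f"rec{r:02d}", "".join(row)) for r, row in enumerate(rows)
    )
    alignment = Alignment(records)
    segmentation = ColumnSegmentation(tuple(labels))

    annotations: dict[str, DomainAnnotation] = {}
    for rec_id, seq in records:
        pos = 0
        position_map: dict[GenericNumber, int] = {}
        for j, c in enumerate(seq):
            if c == "-":
                continue
            pos += 1
            if j in numbering.mapping:
                position_map[numbering.mapping[j]] = pos
        contiguous = set()
        col = 0
        for seg, length, _ in _TEMPLATE_LAYOUT:
            if seg is not None and "-" not in seq[col:col + length]:
                contiguous.add(seg)
            col += length
        annotations[rec_id] = DomainAnnotation(
            protein_id=rec_id,
            layout="common",
            position_map=position_map,
            contiguous_segments=frozenset(contiguous),
            sequence=seq.replace("-", ""),
            seq_start=1,
        )

    return SyntheticFamily(
        alignment=alignment,
        segmentation=segmentation,
        true_numbering=numbering,
        true_annotations=annotations,
        anchor_columns=anchors,
        template=template,
        seed=seed,
    )


def random_rigid_transform(seed: int) -> tuple[np.ndarray, np.ndarray]:
    """A seeded proper rotation (det +1) and translation, for oracle tests."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=10.0, size=3)
    return Q, t


def make_synthetic_domain_structure(
    ann: DomainAnnotation,
    transform: Optional[tuple[np.ndarray, np.ndarray]] = None,
    seed: int = 0,
    jitter: float = 0.05,
    chain: str = "A",
) -> StructureModel:
    """Idealized backbone coordinates (N, CA, C) for every numbered residue.

    CA atoms follow a gentle helical curve (3.8 A rise), so the point set is
    never collinear; seeded jitter of at most ``jitter`` Angstrom is added to
    every coordinate.  The applied rigid transform, if any, is recorded in
    the model metadata so oracle tests can check its recovery.
    """
    rng = np.random.default_rng(seed)
    residues = sorted(set(ann.full_position_map().values()))
    if not residues:
        raise ValueError("annotation maps no positions")
    atoms: list[Atom] = []
    R, t = (np.eye(3), np.zeros(3)) if transform is None else transform
    for k, res in enumerate(residues):
        ca = np.array([3.8 * k, 4.7 * np.sin(0.6 * k), 4.7 * np.cos(0.6 * k)])
        coords = {
            "N": ca + np.array([-1.2, 0.5, 0.3]),
            "CA": ca,
            "C": ca + np.array([1.2, 0.5, -0.3]),
        }
        letter = ann.residue_letter(res) or "A"
        resname = protein_letters_1to3.get(letter, "Ala").upper()
        for name in ("N", "CA", "C"):
            xyz = coords[name] + rng.uniform(-jitter, jitter, size=3)
            xyz = R @ xyz + t
            atoms.append(Atom(
                chain=chain, residue_number=res, insertion_code="",
                residue_name=resname, atom_name=name, alt_loc="",
                occupancy=1.0, coordinates=tuple(float(v) for v in xyz),
            ))
    metadata = {
        "entry_id": ann.protein_id[:4].upper() or "SYNT",
        "applied_rotation": R,
        "applied_translation": t,
        "synthetic": True,
    }
    return StructureModel(atoms=atoms, metadata=metadata)


def make_synthetic_domain(
    ann: DomainAnnotation,
    transform: Optional[tuple[np.ndarray, np.ndarray]] = None,
    seed: int = 0,
    name: Optional[str] = None,
) -> DomainStructure:
    """A :class:`DomainStructure` wrapping an idealized synthetic model."""
    model = make_synthetic_domain_structure(ann, transform=transform, seed=seed)
    return DomainStructure(
        name=name or f"{ann.protein_id}_{ann.domain_slot}",
        chain="A",
        domain_slot=ann.domain_slot,
        atoms=model.atoms,
        annotation=ann,
    )


@dataclass(frozen=True)
class BundledAnchors:
    """The published anchor annotations shipped with the package."""

    stat5b: DomainAnnotation
    shp2_n: DomainAnnotation
    flvr_exceptions: tuple[str, ...]


@lru_cache(maxsize=1)
def bundled_anchors() -> BundledAnchors:
    """Anchor maps for STAT5B (full pY-pocket set) and SHP2 N-SH2 (bE strand)."""
    raw = json.loads(
        resources.files("sh2num").joinpath("data/anchors.json").read_text()
    )
    return BundledAnchors(
        stat5b=DomainAnnotation.from_dict(raw["STAT5B"]),
        shp2_n=DomainAnnotation.from_dict(raw["SHP2"]),
        flvr_exceptions=tuple(raw["flvr_exceptions"]),
    )
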