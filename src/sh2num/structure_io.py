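"""PDB-format parsing, wild-type renumbering, domain trimming and splitting.

Experimental SH2 structures come with author residue numbering that rarely
matches the wild-type (UniProt) sequence, often carry extra tags, fusion
partners or flanking domains, and may hold the same domain in several chains
or two SH2 domains in one chain.  This module implements the preprocessing
pipeline that turns such files into analysis-ready single-domain structures:
parse, renumber to the wild-type sequence (recording point mutations on the
way), trim everything outside the domain, and split multi-domain /
multi-chain entries.

Only the fixed-column PDB dialect is handled (ATOM/HETATM records); parsing
applies a deterministic alternate-location policy (highest occupancy, ties
to altloc "A") and retains insertion-coded residues as distinct residues
until renumbering eliminates them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.PDBData import protein_letters_3to1_extended

from .scheme import DomainAnnotation

__all__ = [
    "PDBFormatError",
    "RenumberError",
    "Atom",
    "StructureModel",
    "DomainStructure",
    "Mutation",
    "read_structure",
    "chain_sequence",
    "renumber_to_wildtype",
    "extract_domains",
    "write_structure",
]

WATER_NAMES = {"HOH", "WAT", "DOD"}


class PDBFormatError(ValueError):
    """Raised for unparseable PDB content."""


class RenumberError(ValueError):
    """Raised when a chain cannot be mapped onto the wild-type sequence."""


@dataclass(frozen=True)
class Atom:
    chain: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    alt_loc: str
    occupancy: float
    coordinates: tuple[float, float, float]
    hetero: bool = False

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_number, self.insertion_code)


@dataclass
class StructureModel:
    """Parsed atomic coordinates plus minimal metadata."""

    atoms: list[Atom]
    metadata: dict = field(default_factory=dict)

    def chains(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain not in seen:
                seen.append(a.chain)
        return seen

    def residues(self, chain: Optional[str] = None) -> list[tuple[str, int, str]]:
        """Residue keys in file order (first-atom order)."""
        seen: list[tuple[str, int, str]] = []
        seen_set = set()
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            if a.residue_key not in seen_set:
                seen.append(a.residue_key)
                seen_set.add(a.residue_key)
        return seen

    def coordinates(self) -> np.ndarray:
        return np.array([a.coordinates for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class Mutation:
    """A point difference from the wild type: ``(wild-type residue, position, observed)``."""

    wild_type: str
    position: int
    observed: str

    def __str__(self) -> str:
        return f"{self.wild_type}{self.position}{self.observed}"


@dataclass
class DomainStructure:
    """A renumbered, trimmed single-SH2-domain structure."""

    name: str  # entry id + chain (+ slot)
    chain: str
    domain_slot: str
    atoms: list[Atom]
    annotation: Optional[DomainAnnotation] = None
    mutations: list[Mutation] = field(default_factory=list)

    def residues(self) -> list[tuple[str, int, str]]:
        return StructureModel(self.atoms).residues()

    def residue_numbers(self) -> list[int]:
        return [r[1] for r in self.residues()]

    def backbone_coordinates(
        self, residue_number: int, atom_names: Sequence[str] = ("N", "CA", "C")
    ) -> Optional[np.ndarray]:
        found = {}
        for a in self.atoms:
            if a.residue_number == residue_number and a.atom_name in atom_names:
                found[a.atom_name] = a.coordinates
        if set(found) != set(atom_names):
            return None
        return np.array([found[n] for n in atom_names], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "DomainStructure":
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new_atoms = [
            replace(a, coordinates=tuple(np.round(R @ np.array(a.coordinates) + t, 6)))
            for a in self.atoms
        ]
        return DomainStructure(
            name=self.name, chain=self.chain, domain_slot=self.domain_slot,
            atoms=new_atoms, annotation=self.annotation, mutations=list(self.mutations),
        )


def _parse_atom_line(line: str, lineno: int) -> Atom:
    try:
        name = line[12:16].strip()
        alt = line[16].strip() if len(line) > 16 else ""
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resseq = int(line[22:26])
        icode = line[26].strip() if len(line) > 26 else ""
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occ = float(occ_field) if occ_field else 1.0
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    if not all(np.isfinite(v) for v in (x, y, z)):
        raise PDBFormatError(f"non-finite coordinates at line {lineno}")
    return Atom(
        chain=chain, residue_number=resseq, insertion_code=icode,
        residue_name=resname, atom_name=name, alt_loc=alt, occupancy=occ,
        coordinates=(x, y, z), hetero=line.startswith("HETATM"),
    )


def read_structure(
    text: str, keep_hetero: bool = False, keep_waters: bool = False
) -> StructureModel:
    """Parse fixed-column PDB content into a :class:`StructureModel`.

    Alternate locations collapse to the highest-occupancy conformer (ties go
    to altloc "A"); insertion-coded residues are kept as distinct residues;
    waters and heteroatoms are dropped unless requested.
    """
    atoms: list[Atom] = []
    metadata: dict = {}
    n_atom_records = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "HEADER" and len(line) >= 66:
            metadata["entry_id"] = line[62:66].strip()
        elif rec == "EXPDTA":
            metadata["method"] = line[10:].strip()
        elif rec in ("ATOM", "HETATM"):
            if rec == "ATOM":
                n_atom_records += 1
            atom = _parse_atom_line(line, lineno)
            if atom.residue_name in WATER_NAMES and not keep_waters:
                continue
            if atom.hetero and not keep_hetero and atom.residue_name not in WATER_NAMES:
                # modified residues (e.g. MSE) are part of the chain: keep them
                if atom.residue_name not in protein_letters_3to1_extended:
                    continue
            atoms.append(atom)
    if n_atom_records == 0:
        raise PDBFormatError("no ATOM records found")

    # altloc policy: per (residue, atom name) keep highest occupancy, tie -> "A"
    def altloc_rank(a: Atom) -> tuple[float, int]:
        return (a.occupancy, 1 if a.alt_loc in ("", "A") else 0)

    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.residue_key, a.atom_name)
        if key not in best:
            best[key] = a
            order.append(key)
        elif altloc_rank(a) > altloc_rank(best[key]):
            best[key] = a
    return StructureModel(atoms=[best[k] for k in order], metadata=metadata)


def chain_sequence(
    model: StructureModel, chain: str
) -> tuple[str, list[tuple[str, int, str]]]:
    """One-letter sequence of a chain plus the parallel residue-key list.

    Modified residues map to their parent amino acid (MSE -> M); unknown
    residue names become ``X``.
    """
    residues = model.residues(chain)
    if not residues:
        raise KeyError(f"chain {chain!r} not present (chains: {model.chains()})")
    name_of: dict[tuple, str] = {}
    for a in model.atoms:
        name_of.setdefault(a.residue_key, a.residue_name)
    seq = "".join(
        protein_letters_3to1_extended.get(name_of[r], "X") for r in residues
    )
    return seq, residues


def _wt_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.end_gap_score = 0.0
    aligner.mode = "global"
    return aligner


def renumber_to_wildtype(
    model: StructureModel,
    chain: str,
    wt: str,
    wt_offset: int = 1,
    min_identity: float = 0.9,
) -> tuple[StructureModel, list[Mutation]]:
    """Renumber a chain onto the wild-type sequence; record point mutations.

    The chain sequence is globally aligned (free end gaps) to ``wt``;
    aligned residues take the number ``wt position + wt_offset - 1``.
    Structure residues with no wild-type counterpart (tags, insertions) are
    removed, as are this chain's heteroatoms outside the alignment; other
    chains pass through untouched.  Insertion codes are eliminated by
    renumbering.  Fails if the best identity is below ``min_identity``.
    """
    wt = wt.upper()
    seq, residues = chain_sequence(model, chain)
    aligner = _wt_aligner()
    alignment = aligner.align(seq, wt)[0]
    matches = 0
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for k in range(a1 - a0):
            pairs.append((a0 + k, b0 + k))
            if seq[a0 + k] == wt[b0 + k]:
                matches += 1
    identity = matches / len(pairs) if pairs else 0.0
    if identity < min_identity:
        raise RenumberError(
            f"chain {chain!r} matches the wild type at identity {identity:.3f}, "
            f"below the floor {min_identity:.2f}"
        )

    new_number: dict[tuple, int] = {}
    mutations: list[Mutation] = []
    for spos, wpos in pairs:
        res_key = residues[spos]
        number = wpos + wt_offset
        new_number[res_key] = number
        if seq[spos] != wt[wpos]:
            mutations.append(Mutation(wt[wpos], number, seq[spos]))

    new_atoms: list[Atom] = []
    for a in model.atoms:
        if a.chain != chain:
            new_atoms.append(a)
            continue
        if a.residue_key not in new_number:
            continue  # unaligned residue: trimmed
        new_atoms.append(replace(
            a, residue_number=new_number[a.residue_key], insertion_code=""
        ))
    return StructureModel(atoms=new_atoms, metadata=dict(model.metadata)), mutations


def extract_domains(
    model: StructureModel,
    boundaries: Iterable[tuple[str, str, int, int]],
    mutations: Optional[Sequence[Mutation]] = None,
) -> list[DomainStructure]:
    """Split a renumbered model into single-domain structures.

    ``boundaries`` rows are ``(chain, domain_slot, start, end)`` with the
    span inclusive in wild-type numbering.  Entries holding two SH2 domains
    in one chain, or the same domain in several chains, yield one
    :class:`DomainStructure` each.
    """
    entry = model.metadata.get("entry_id", "model")
    out: list[DomainStructure] = []
    for chain, slot, start, end in boundaries:
        selected = [
            a for a in model.atoms
            if a.chain == chain and start <= a.residue_number <= end
        ]
        if not selected:
            raise ValueError(
                f"boundary ({chain}, {slot}, {start}, {end}) selects no residues"
            )
        dom_muts = [
            m for m in (mutations or []) if start <= m.position <= end
        ]
        out.append(DomainStructure(
            name=f"{entry}_{chain}_{slot}",
            chain=chain,
            domain_slot=slot,
            atoms=selected,
            mutations=dom_muts,
        ))
    return out


def _format_atom_name(name: str) -> str:
    # names of up to 3 characters start in column 14 (0-based 13)
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_structure(ds: DomainStructure | StructureModel) -> str:
    """Serialise to fixed-width PDB text; round-trips exactly at 3 decimals."""
    atoms = ds.atoms
    lines: list[str] = []
    for serial, a in enumerate(atoms, start=1):
        record = "HETATM" if a.hetero else "ATOM  "
        lines.append(
            f"{record}{serial:5d} {_format_atom_name(a.atom_name)}{a.alt_loc or ' ':1s}"
            f"{a.residue_name:>3s} {a.chain:1s}{a.residue_number:4d}{a.insertion_code or ' ':1s}"
            f"   {a.coordinates[0]:8.3f}{a.coordinates[1]:8.3f}{a.coordinates[2]:8.3f}"
            f"{a.occupancy:6.2f}{0.0:6.2f}          {a.atom_name[0]:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def domain_fasta(ds: DomainStructure) -> str:
    """FASTA of the domain's observed sequence (renumbered residue order)."""
    model = StructureModel(ds.atoms)
    seq, _ = chain_sequence(model, ds.chain)
    return f">{ds.name}\n{seq}\n"
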