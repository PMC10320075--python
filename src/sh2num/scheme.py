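"""Generic residue numbering scheme for SH2 domains.

SH2 domains share an alpha-beta-beta-beta-alpha fold whose secondary-structure
segments (three helices aA, aB', aB and six strands bA..bF, plus the short
bBbC turn) are structurally conserved across the family.  Each segment's most
conserved alignment position is the ``x50`` anchor and its neighbours within
the segment are numbered sequentially, so a label like ``bBx50`` (the
invariant phosphotyrosine-anchoring arginine on strand bB) addresses the
equivalent residue in any SH2 domain regardless of its author numbering.
Loops between segments are deliberately left unnumbered: they are flexible
and their residues do not occupy equivalent positions in space.

This module defines the label grammar (:class:`GenericNumber`), the segment
layouts (:class:`SchemeDefinition`) and the per-protein realisation of the
scheme (:class:`DomainAnnotation`), together with resolution of generic
positions to wild-type residue numbers and back.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Iterator, Mapping, Optional

__all__ = [
    "SchemeError",
    "GenericNumberParseError",
    "ResolutionError",
    "GenericNumber",
    "SegmentDef",
    "SchemeDefinition",
    "DomainAnnotation",
    "Finding",
    "parse_generic_number",
    "format_generic_number",
    "resolve_position",
    "assign_position",
    "sheinerman_set",
    "segment_layout",
    "validate_annotation",
    "default_scheme",
    "SEGMENT_NAMES",
    "HELIX_NAMES",
    "STRAND_NAMES",
    "TURN_NAMES",
]


class SchemeError(ValueError):
    """Base class for numbering-scheme errors."""


class GenericNumberParseError(SchemeError):
    """A generic-number label could not be parsed."""


class ResolutionError(SchemeError):
    """A generic position could not be mapped to a residue number (or back)."""


HELIX_NAMES = ("aA", "aB'", "aB")
STRAND_NAMES = ("bA", "bB", "bC", "bD", "bE", "bF")
TURN_NAMES = ("bBbC",)
SEGMENT_NAMES = STRAND_NAMES[:2] + TURN_NAMES + STRAND_NAMES[2:] + HELIX_NAMES

# ASCII-friendly spellings accepted on input for the STAT-specific aB' helix.
_SEGMENT_ALIASES = {
    "aBp": "aB'",
    "aB′": "aB'",  # prime
    "aB’": "aB'",  # right single quote
}

ANCHOR_INDEX = 50


@dataclass(frozen=True, order=True)
class GenericNumber:
    """A generic residue position: a segment label plus a positive index.

    ``GenericNumber("bB", 50)`` is the x50 anchor of strand bB — the
    (almost) invariant arginine of the FLVR motif in most SH2 domains.
    """

    segment: str
    index: int

    def __post_init__(self) -> None:
        if self.segment not in SEGMENT_NAMES:
            raise GenericNumberParseError(
                f"unknown segment {self.segment!r}; expected one of {', '.join(SEGMENT_NAMES)}"
            )
        if not isinstance(self.index, int) or self.index < 1:
            raise GenericNumberParseError(f"index must be a positive integer, got {self.index!r}")

    def __str__(self) -> str:
        return format_generic_number(self)


def parse_generic_number(label: str) -> GenericNumber:
    """Parse a label such as ``bBx50`` or ``bBbCx49`` into a :class:`GenericNumber`.

    The canonical separator is ``x``; ``.`` is accepted as an input alias
    (``bE.48``), as is the ASCII spelling ``aBp`` for the aB' helix.
    """
    if not label or not isinstance(label, str):
        raise GenericNumberParseError("empty generic-number label")
    text = label.strip()
    for alias, canonical in _SEGMENT_ALIASES.items():
        if text.startswith(alias):
            text = canonical + text[len(alias):]
            break
    # longest-first so bBbC is matched before bB
    for seg in sorted(SEGMENT_NAMES, key=len, reverse=True):
        if text.startswith(seg):
            rest = text[len(seg):]
            m = re.fullmatch(r"[x.](\d+)", rest)
            if m is None:
                raise GenericNumberParseError(
                    f"malformed generic number {label!r}: expected '<segment>x<index>', "
                    f"offending token {rest!r}"
                )
            index = int(m.group(1))
            if index < 1:
                raise GenericNumberParseError(f"non-positive index in {label!r}")
            return GenericNumber(seg, index)
    raise GenericNumberParseError(
        f"malformed generic number {label!r}: unknown segment token"
    )


def format_generic_number(gn: GenericNumber) -> str:
    """Canonical text form, ``<segment>x<index>`` (e.g. ``bDx50``, ``aB'x50``)."""
    return f"{gn.segment}x{gn.index}"


@dataclass(frozen=True)
class SegmentDef:
    """One secondary-structure segment of the domain layout."""

    name: str
    kind: str  # helix | strand | turn
    order_rank: int

    def __post_init__(self) -> None:
        if self.kind not in ("helix", "strand", "turn"):
            raise SchemeError(f"bad segment kind {self.kind!r}")
        if self.kind == "helix" and not self.name.startswith("a"):
            raise SchemeError(f"helix names start with 'a': {self.name!r}")
        if self.kind == "strand" and not re.fullmatch(r"b[A-Z]", self.name):
            raise SchemeError(f"strand names are 'b' + one letter: {self.name!r}")
        if self.kind == "turn" and self.name != "bBbC":
            raise SchemeError(f"the only numbered turn is bBbC, got {self.name!r}")


@dataclass(frozen=True)
class SchemeDefinition:
    """The full scheme: segment layouts, index spans, key position sets.

    Two layouts exist: the *common* one (strand bD followed by the short
    strands bE and bF, then helix aB) and the *STAT* one, where bE/bF are
    absent and the STAT-exclusive aB' helix sits between bD and aB.
    Per-segment index spans are data, not constants, because anchors need not
    sit at the centre of a segment (e.g. the SHP2 bE strand begins at x48).
    """

    segments_common: tuple[SegmentDef, ...]
    segments_stat: tuple[SegmentDef, ...]
    index_spans: Mapping[str, tuple[int, int]]
    sheinerman_positions: tuple[GenericNumber, ...]
    flvr_exception_proteins: tuple[str, ...]
    anchor_index: int = ANCHOR_INDEX

    def __post_init__(self) -> None:
        names = {s.name for s in self.segments_common} | {s.name for s in self.segments_stat}
        helices = {n for n in names if n.startswith("a")}
        strands = {n for n in names if re.fullmatch(r"b[A-Z]", n)}
        if len(helices) != 3 or len(strands) != 6:
            raise SchemeError(
                f"scheme must define 3 helices and 6 strands, got {sorted(helices)} / {sorted(strands)}"
            )
        stat_names = {s.name for s in self.segments_stat}
        if {"bE", "bF"} & stat_names or "aB'" not in stat_names:
            raise SchemeError("STAT layout must lack bE/bF and contain aB'")
        common_names = {s.name for s in self.segments_common}
        if "aB'" in common_names:
            raise SchemeError("common layout must not contain aB'")
        if len(self.sheinerman_positions) != 8:
            raise SchemeError("the phosphotyrosine-pocket (Sheinerman) set has exactly 8 positions")


def _layout_from_json(entries: list[dict]) -> tuple[SegmentDef, ...]:
    return tuple(
        SegmentDef(name=e["name"], kind=e["kind"], order_rank=i)
        for i, e in enumerate(entries)
    )


@lru_cache(maxsize=1)
def default_scheme() -> SchemeDefinition:
    """Load the packaged scheme resource (versioned JSON)."""
    raw = json.loads(
        resources.files("sh2num").joinpath("data/scheme.json").read_text()
    )
    return SchemeDefinition(
        segments_common=_layout_from_json(raw["layouts"]["common"]),
        segments_stat=_layout_from_json(raw["layouts"]["STAT"]),
        index_spans={k: (v[0], v[1]) for k, v in raw["index_spans"].items()},
        sheinerman_positions=tuple(parse_generic_number(s) for s in raw["sheinerman_positions"]),
        flvr_exception_proteins=tuple(raw["flvr_exception_proteins"]),
        anchor_index=int(raw["anchor_index"]),
    )


def sheinerman_set(scheme: SchemeDefinition | None = None) -> list[GenericNumber]:
    """The eight pY-pocket positions chiefly responsible for phosphotyrosine anchoring."""
    scheme = scheme or default_scheme()
    return list(scheme.sheinerman_positions)


def segment_layout(scheme: SchemeDefinition | None, variant: str) -> list[SegmentDef]:
    """Ordered numbered segments of the ``common`` or ``STAT`` layout."""
    scheme = scheme or default_scheme()
    if variant == "common":
        return list(scheme.segments_common)
    if variant == "STAT":
        return list(scheme.segments_stat)
    raise SchemeError(f"unknown layout variant {variant!r} (expected 'common' or 'STAT')")


@dataclass(frozen=True)
class DomainAnnotation:
    """Mapping between generic positions and wild-type residue numbers for one domain.

    Positions may be given explicitly (``position_map``) or through an anchor
    plus an inclusive index span per segment; for segments declared
    *contiguous* the map obeys ``residue(x) - residue(y) == x - y``, so a
    single anchor determines the whole segment.  Residue numbering is 1-based
    wild-type numbering.
    """

    protein_id: str
    domain_slot: str = "N"  # N or C
    layout: str = "common"
    position_map: Mapping[GenericNumber, int] = field(default_factory=dict)
    anchors: Mapping[str, tuple[int, int]] = field(default_factory=dict)  # seg -> (index, residue)
    segment_spans: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    contiguous_segments: frozenset[str] = frozenset()
    sequence: Optional[str] = None
    seq_start: int = 1  # wild-type residue number of sequence[0]

    def __post_init__(self) -> None:
        if self.domain_slot not in ("N", "C"):
            raise SchemeError(f"domain_slot must be 'N' or 'C', got {self.domain_slot!r}")
        if self.layout not in ("common", "STAT"):
            raise SchemeError(f"layout must be 'common' or 'STAT', got {self.layout!r}")
        object.__setattr__(self, "contiguous_segments", frozenset(self.contiguous_segments))

    # -- derived views ----------------------------------------------------

    def segments(self) -> set[str]:
        segs = {gn.segment for gn in self.position_map}
        segs.update(self.anchors)
        return segs

    def segment_index_span(self, seg: str) -> tuple[int, int]:
        if seg in self.segment_spans:
            return self.segment_spans[seg]
        idx = [gn.index for gn in self.position_map if gn.segment == seg]
        if not idx:
            raise ResolutionError(f"segment {seg!r} not annotated for {self.protein_id}")
        return min(idx), max(idx)

    def iter_positions(self) -> Iterator[tuple[GenericNumber, int]]:
        """All (generic position, residue number) pairs, anchored spans expanded."""
        seen: dict[GenericNumber, int] = dict(self.position_map)
        for seg, (a_idx, a_res) in self.anchors.items():
            lo, hi = self.segment_index_span(seg)
            for i in range(lo, hi + 1):
                gn = GenericNumber(seg, i)
                seen.setdefault(gn, a_res + (i - a_idx))
        yield from sorted(seen.items(), key=lambda kv: kv[1])

    def full_position_map(self) -> dict[GenericNumber, int]:
        return dict(self.iter_positions())

    def residue_range(self) -> tuple[int, int]:
        numbers = [r for _, r in self.iter_positions()]
        if self.sequence is not None:
            numbers += [self.seq_start, self.seq_start + len(self.sequence) - 1]
        if not numbers:
            raise ResolutionError(f"annotation for {self.protein_id} is empty")
        return min(numbers), max(numbers)

    def residue_letter(self, residue: int) -> Optional[str]:
        if self.sequence is None:
            return None
        i = residue - self.seq_start
        if 0 <= i < len(self.sequence):
            return self.sequence[i]
        return None

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "protein_id": self.protein_id,
            "domain_slot": self.domain_slot,
            "layout": self.layout,
            "position_map": {str(gn): r for gn, r in self.position_map.items()},
            "anchors": {s: list(v) for s, v in self.anchors.items()},
            "segment_spans": {s: list(v) for s, v in self.segment_spans.items()},
            "contiguous_segments": sorted(self.contiguous_segments),
            "sequence": self.sequence,
            "seq_start": self.seq_start,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DomainAnnotation":
        return cls(
            protein_id=d["protein_id"],
            domain_slot=d.get("domain_slot", "N"),
            layout=d.get("layout", "common"),
            position_map={
                parse_generic_number(k): int(v)
                for k, v in d.get("position_map", {}).items()
            },
            anchors={s: (int(v[0]), int(v[1])) for s, v in d.get("anchors", {}).items()},
            segment_spans={s: (int(v[0]), int(v[1])) for s, v in d.get("segment_spans", {}).items()},
            contiguous_segments=frozenset(d.get("contiguous_segments", ())),
            sequence=d.get("sequence"),
            seq_start=int(d.get("seq_start", 1)),
        )

    def with_sequence(self, sequence: str, seq_start: int = 1) -> "DomainAnnotation":
        return replace(self, sequence=sequence, seq_start=seq_start)


def resolve_position(ann: DomainAnnotation, gn: GenericNumber | str) -> int:
    """Wild-type residue number of a generic position in one domain.

    Explicit map entries win; otherwise, for a contiguous segment with an
    anchor, the residue is ``anchor_residue + (index - anchor_index)`` —
    generic indices and residue numbers increment together within a segment.
    """
    if isinstance(gn, str):
        gn = parse_generic_number(gn)
    if gn in ann.position_map:
        return ann.position_map[gn]
    seg = gn.segment
    if seg not in ann.segments():
        raise ResolutionError(
            f"segment {seg!r} is not annotated for {ann.protein_id} ({ann.domain_slot})"
        )
    lo, hi = ann.segment_index_span(seg)
    if not lo <= gn.index <= hi:
        raise ResolutionError(
            f"{gn} outside the declared span {seg}x{lo}..{seg}x{hi} for {ann.protein_id}"
        )
    if seg in ann.anchors and seg in ann.contiguous_segments:
        a_idx, a_res = ann.anchors[seg]
        return a_res + (gn.index - a_idx)
    raise ResolutionError(
        f"{gn} not explicitly mapped and segment {seg!r} is not contiguous for {ann.protein_id}"
    )


def assign_position(ann: DomainAnnotation, residue: int) -> Optional[GenericNumber]:
    """Generic position of a wild-type residue number, or ``None`` for loop residues.

    Left inverse of :func:`resolve_position` on numbered positions.  Residues
    between segments (loops, which the scheme deliberately does not number)
    yield ``None``; residues outside the domain's range raise.
    """
    inverse: dict[int, GenericNumber] = {}
    for gn, res in ann.iter_positions():
        if res in inverse:
            raise SchemeError(
                f"residue {res} mapped to both {inverse[res]} and {gn} in {ann.protein_id}"
            )
        inverse[res] = gn
    if residue in inverse:
        return inverse[residue]
    lo, hi = ann.residue_range()
    if lo <= residue <= hi:
        return None
    raise ResolutionError(
        f"residue {residue} outside the {ann.protein_id} domain range {lo}..{hi}"
    )


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``level`` is ``error`` or ``warning``."""

    level: str
    code: str
    message: str


def validate_annotation(
    ann: DomainAnnotation, scheme: SchemeDefinition | None = None
) -> list[Finding]:
    """Consistency checks on an annotation; returns findings, raises nothing.

    Errors: overlapping segment residue ranges, non-monotone numbering, a
    residue number under two generic positions.  Warning: a non-arginine at
    bBx50 (the FLVR-motif arginine), suppressed for the known exception
    proteins (RIN2, TYK2, SH2D5) where an aromatic residue replaces it.
    """
    scheme = scheme or default_scheme()
    findings: list[Finding] = []
    positions = list(ann.iter_positions())

    by_segment: dict[str, list[tuple[int, int]]] = {}
    for gn, res in positions:
        by_segment.setdefault(gn.segment, []).append((gn.index, res))

    seen_res: dict[int, GenericNumber] = {}
    for gn, res in positions:
        if res in seen_res:
            findings.append(Finding(
                "error", "duplicate-residue",
                f"residue {res} carries both {seen_res[res]} and {gn}",
            ))
        else:
            seen_res[res] = gn

    ranges: dict[str, tuple[int, int]] = {}
    for seg, pairs in by_segment.items():
        pairs.sort()
        for (i1, r1), (i2, r2) in zip(pairs, pairs[1:]):
            if r2 <= r1:
                findings.append(Finding(
                    "error", "non-monotone",
                    f"{seg}: residue numbers do not increase with index "
                    f"({seg}x{i1}->{r1}, {seg}x{i2}->{r2})",
                ))
        ranges[seg] = (min(r for _, r in pairs), max(r for _, r in pairs))

    segs = sorted(ranges, key=lambda s: ranges[s])
    for s1, s2 in zip(segs, segs[1:]):
        if ranges[s2][0] <= ranges[s1][1]:
            findings.append(Finding(
                "error", "overlap",
                f"segments {s1} ({ranges[s1][0]}..{ranges[s1][1]}) and "
                f"{s2} ({ranges[s2][0]}..{ranges[s2][1]}) overlap",
            ))

    if ann.sequence is not None:
        try:
            res = resolve_position(ann, GenericNumber("bB", scheme.anchor_index))
        except ResolutionError:
            res = None
        if res is not None:
            letter = ann.residue_letter(res)
            if (
                letter is not None
                and letter != "R"
                and ann.protein_id not in scheme.flvr_exception_proteins
            ):
                findings.append(Finding(
                    "warning", "flvr",
                    f"residue at bBx50 is {letter}, not the FLVR-motif arginine "
                    f"(known exceptions: {', '.join(scheme.flvr_exception_proteins)})",
                ))
    return findings
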