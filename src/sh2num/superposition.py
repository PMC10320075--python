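"""Rigid superposition of SH2 domains on the core beta-sheet.

Across the family, the most reliable frame for overlaying SH2 domains is the
central antiparallel beta-sheet formed by strands bB, bC and bD: loops and
helix termini vary, the sheet does not.  Superposition therefore pairs
backbone atoms (N, CA, C) of the generic positions shared by two domains
within those three strands, and solves the least-squares rigid-body problem
with the Kabsch algorithm (SVD of the covariance, reflection corrected).

No outlier-rejection cycles are performed: plain least squares keeps the
result deterministic and exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scheme import GenericNumber, resolve_position, ResolutionError
from .structure_io import DomainStructure

__all__ = [
    "SuperpositionError",
    "SuperpositionResult",
    "CORE_SHEET_SEGMENTS",
    "BACKBONE_ATOMS",
    "core_sheet_pairs",
    "kabsch",
    "superpose_all",
    "export_session_script",
]

CORE_SHEET_SEGMENTS = ("bB", "bC", "bD")
BACKBONE_ATOMS = ("N", "CA", "C")
MIN_PAIRED_ATOMS = 9  # three positions' worth of backbone


class SuperpositionError(ValueError):
    """Raised for unusable atom pairings or degenerate coordinate sets."""


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform (x -> R x + t) of a mobile domain onto a reference."""

    rotation: np.ndarray      # 3x3 proper orthonormal
    translation: np.ndarray   # Angstrom
    rmsd: float               # Angstrom over the paired atoms
    n_atoms: int
    paired_positions: tuple[GenericNumber, ...] = ()

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def core_sheet_pairs(
    mobile: DomainStructure, reference: DomainStructure
) -> tuple[np.ndarray, np.ndarray, list[GenericNumber]]:
    """Paired backbone coordinates over shared core-sheet generic positions.

    For every generic position within bB/bC/bD present in both annotations,
    the backbone N, CA, C atoms present in both structures are collected in
    matching order.  Returns (mobile coords, reference coords, positions).
    """
    if mobile.annotation is None or reference.annotation is None:
        raise SuperpositionError("both domains must carry annotations")

    def core_positions(ds: DomainStructure) -> dict[GenericNumber, int]:
        out = {}
        for gn, res in ds.annotation.iter_positions():
            if gn.segment in CORE_SHEET_SEGMENTS:
                out[gn] = res
        return out

    mob_pos = core_positions(mobile)
    ref_pos = core_positions(reference)
    shared = sorted(set(mob_pos) & set(ref_pos))

    P: list[np.ndarray] = []
    Q: list[np.ndarray] = []
    paired: list[GenericNumber] = []
    for gn in shared:
        bm = mobile.backbone_coordinates(mob_pos[gn], BACKBONE_ATOMS)
        br = reference.backbone_coordinates(ref_pos[gn], BACKBONE_ATOMS)
        if bm is None or br is None:
            continue
        P.append(bm)
        Q.append(br)
        paired.append(gn)
    if not P or 3 * len(paired) < MIN_PAIRED_ATOMS:
        raise SuperpositionError(
            f"only {3 * len(paired)} paired backbone atoms in the core sheet; "
            f"at least {MIN_PAIRED_ATOMS} required"
        )
    return np.vstack(P), np.vstack(Q), paired


def kabsch(
    P: np.ndarray, Q: np.ndarray, paired_positions: tuple[GenericNumber, ...] = ()
) -> SuperpositionResult:
    """Least-squares rigid superposition of P onto Q (Kabsch, proper rotation).

    Solves min over rotations R and translations t of ||R P + t - Q||; a
    reflection in the SVD solution is corrected by flipping the smallest
    singular direction, so det(R) = +1 always.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise SuperpositionError(f"coordinate sets must both be n x 3, got {P.shape} / {Q.shape}")
    if len(P) < 3:
        raise SuperpositionError("at least 3 atom pairs are required")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    Pc = P - pc
    Qc = Q - qc
    sv = np.linalg.svd(Pc, compute_uv=False)
    if sv[1] < 1e-8 * max(1.0, sv[0]):
        raise SuperpositionError("degenerate (collinear) coordinates")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
    return SuperpositionResult(
        rotation=R, translation=t, rmsd=rmsd, n_atoms=len(P),
        paired_positions=tuple(paired_positions),
    )


def superpose_all(
    domains: list[DomainStructure], reference: DomainStructure
) -> list[tuple[DomainStructure, SuperpositionResult | None, str | None]]:
    """Superpose each domain onto the reference frame via the core beta-sheet.

    Returns, in input order, ``(transformed domain, result, error)`` triples;
    a per-domain failure is reported in ``error`` (result None, domain
    untransformed) without aborting the batch.
    """
    out = []
    for dom in domains:
        try:
            P, Q, paired = core_sheet_pairs(dom, reference)
            res = kabsch(P, Q, tuple(paired))
            out.append((dom.transformed(res.rotation, res.translation), res, None))
        except (SuperpositionError, ResolutionError) as exc:
            out.append((dom, None, str(exc)))
    return out


def export_session_script(
    domains: list[DomainStructure],
    highlight: list[GenericNumber] = (),
    file_suffix: str = ".pdb",
) -> str:
    """Emit a molecular-graphics session script for already-superposed domains.

    The script loads each structure, saves each highlighted generic position
    as a named selection (``gn_<label>``, label with ``'`` spelled ``p``)
    across all domains where it resolves, and shows those selections as
    sticks.  Positions resolvable in no domain produce a warning comment.
    """
    lines = [
        "# session script: superposed SH2 domains with highlighted generic positions",
    ]
    for dom in domains:
        lines.append(f"load {dom.name}{file_suffix}, {dom.name}")
    for gn in highlight:
        clauses = []
        for dom in domains:
            if dom.annotation is None:
                continue
            try:
                res = resolve_position(dom.annotation, gn)
            except ResolutionError:
                continue
            if res in dom.residue_numbers():
                clauses.append(f"({dom.name} and resi {res})")
        sel_name = "gn_" + str(gn).replace("'", "p")
        if not clauses:
            lines.append(f"# warning: {gn} resolves in no loaded domain")
            continue
        lines.append(f"select {sel_name}, {' or '.join(clauses)}")
        lines.append(f"show sticks, {sel_name}")
    return "\n".join(lines) + "\n"
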