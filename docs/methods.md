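# Methods

## The numbering model

Each SH2 secondary-structure segment (helices aA, aB′, aB; strands bA–bF;
the bBbC turn) is assigned generic indices around a single anchor: the most
conserved alignment column of the segment is index 50, and columns either
side are numbered sequentially (49, 48, … left; 51, 52, … right). Two
assumptions follow. First, within a segment, generic indices and wild-type
residue numbers increment together — segments are treated as indel-free
blocks, which is what "conserved secondary structural characteristic" means
operationally here. Second, loops are not comparable position-by-position
across proteins, so they receive no numbers at all; the bDbE "blocking
loop" of SHP2 is addressed as a loop name, not as numbered positions.

The bBbC turn is the one exception to anchoring by conservation: it has
exactly two numbered positions, fixed as x49/x50, because both belong to the
eight-residue phosphotyrosine-pocket (Sheinerman) set rather than being
selected by a conservation maximum.

Conservation of a column is the modal non-gap residue frequency among
non-gap entries. This is the simplest score that identifies invariant
columns and is directly auditable; no entropy weighting or substitution
similarity is used. Anchor selection breaks ties to the leftmost column and
excludes columns with more than 50% gaps (unless every column of the segment
is gap-majority). Per-segment index spans are data carried by the scheme
resource, not constants, because anchors need not sit at a segment's centre
(the SHP2 bE strand begins at x48).

## Annotations and resolution

A `DomainAnnotation` realises the scheme for one protein domain either as an
explicit position→residue map or as per-segment anchors with inclusive index
spans. For segments declared *contiguous*, resolution is arithmetic:
`residue = anchor_residue + (index − anchor_index)`, with the span as a hard
bound. `assign_position` is the left inverse on numbered positions and
returns `None` for loop/terminal residues inside the domain range.
Validation reports overlapping segment ranges, non-monotone numbering and
duplicate residues as errors, and a non-arginine at bBx50 as a warning —
suppressed for RIN2, TYK2 and SH2D5, the human domains known to carry an
aromatic residue in place of the FLVR-motif arginine.

The bundled annotations contain exactly the published facts: the STAT5B
pY-pocket map (anchors aAx43=600, bBx50=618, bBbCx49=621, bDx50=642, with
spans wide enough to cover all eight published positions) and the SHP2 N-SH2
bE anchor (x48 = Tyr62). No unpublished segment bounds are invented; other
proteins must be numbered from a user-supplied alignment.

## Numbering from alignments

Propagation is column-based: every non-gap residue in a numbered column
inherits that column's generic number, and a record gapped at a numbered
column simply lacks that number — no per-record re-anchoring. New sequences
are numbered by global pairwise alignment (BLOSUM62, gap open 11, extend 1,
free end gaps) to the most similar alignment member, transferring numbers
through aligned pairs; transfer is refused below 25% identity. Sequence
lengths outside 60–160 residues are rejected as implausible for a single
SH2 domain (all thresholds configurable). Segmentation (which columns belong
to which segment) is always an input — curated or structure-derived;
secondary-structure prediction is out of scope.

## Structure preprocessing

Only the fixed-column PDB dialect is parsed. Policies: alternate locations
collapse to the highest-occupancy conformer with ties going to altloc "A";
insertion-coded residues stay distinct until renumbering, which eliminates
insertion codes; waters and non-polymer heteroatoms are dropped by default
(modified residues with a standard parent, e.g. MSE, are kept and translate
to the parent letter). Renumbering aligns the observed chain sequence to the
wild-type sequence globally with free end gaps and requires ≥ 90% identity;
aligned positions that differ are recorded as mutations (e.g. `N642H`),
and unaligned structure residues (tags, fusions) are trimmed. Domain
boundaries for splitting are explicit inputs; automated SH2 detection is
deliberately not attempted.

## Superposition

The superposition frame is the core β-sheet: all generic positions within
bB, bC and bD shared by mobile and reference, using backbone N, CA and C
atoms present in both (carbonyl O is excluded — it is frequently absent or
variable at strand edges). At least nine paired atoms (three positions) are
required. The transform is plain Kabsch least squares: SVD of the centred
covariance with the reflection corrected so det(R) = +1; no outlier-
rejection cycles, keeping results deterministic and exactly reproducible.
Degenerate (collinear) point sets are rejected by a singular-value check at
1e-8 relative tolerance. Batch superposition collects per-domain failures
without aborting. The session exporter emits plain-text commands (`load`,
`select gn_<label>`, `show sticks`) with the prime in aB′ spelled `p` in
selection names.

## Phylogeny

Distances over the numbered-position sub-alignment are p-distances with
pairwise deletion (proportion of differing residues over mutually non-gap
columns); no substitution model is imposed. Trees are built by neighbor
joining with deterministic tie-breaking (ties in the Q criterion at 1e-12
resolve to the lexicographically smallest label pair) and negative branch
lengths clamped to zero; the result is an unrooted tree with a trifurcating
root. Newick output carries branch lengths at six decimals and quotes
labels containing spaces or other non-word characters. NJ is exact on
additive matrices, which the tests exploit as an oracle; an independent
implementation (scikit-bio) serves as a cross-check on non-additive input.

## Synthetic data

`make_synthetic_family` emulates exactly the features the numbering
machinery relies on: a random template over the common layout (segment
lengths: bA 5, aA 10, bB 7, bBbC 2, bC 6, bD 6, bE 4, bF 4, aB 10,
with loops of 2–4 columns; bB and bD lengths follow the published STAT5B
arithmetic), one invariant anchor column per numbered segment, i.i.d.
substitutions elsewhere at the requested rate (default 0.1 over 20 records,
the conditions used throughout the tests), and indels confined to loop
columns. After the i.i.d. pass, any non-anchor numbered column that drew no
substitution receives one forced substitution, making the planted anchor the
*unique* conservation maximum — without this, a short segment at rate 0.1
has an appreciable chance of a second invariant column, leaving the ground
truth ill-defined. The generators are pure functions of their arguments
including the seed.

What the fixtures do **not** emulate: realistic evolutionary covariation
(no substitution-model sampling), segment-length variation across records,
gaps inside segments, or real side-chain geometry — synthetic structures are
idealized N/CA/C backbones on a smooth curve with ≤ 0.05 Å seeded jitter.
Passing tests therefore demonstrate correctness of the numbering, mapping,
superposition and tree machinery under the scheme's own assumptions, not
robustness to heavily diverged or misaligned real families.

## Numerical choices and limitations

- Identity floors: 0.9 for wild-type renumbering, 0.25 for numbering
  transfer; both configurable per call.
- Kabsch degeneracy threshold 1e-8 (relative); NJ tie tolerance 1e-12;
  Newick precision 6 decimals; PDB coordinates 3 decimals.
- Label grammar: `<segment>x<index>`; `.` accepted as separator alias and
  `aBp` as ASCII alias for aB′ on input; canonical output uses `x` and `'`.
- Legacy labels (αA2, βB5) are not inferred; mmCIF is not supported; no
  bootstrap values or likelihood trees; no rendering or web components.
- Problem sizes in the test suite (20-record families, ~80-column
  alignments, single-domain structures of ~50–60 residues) are chosen as the
  smallest sizes at which every behaviour under test is exercised
  non-trivially.
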