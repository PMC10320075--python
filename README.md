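# sh2num

Generic residue numbering and structural comparison for SH2 domains.

SH2 domains are ~100-residue phosphotyrosine-reader modules with a conserved
αβββα fold: a central antiparallel β-sheet (strands bB–bD) sandwiched between
two helices, dividing the binding surface into the phosphotyrosine (pY) and
specificity (pY+3) pockets. Comparing equivalent residues across the 120
human SH2 domains is awkward in author numbering; `sh2num` implements a
generic numbering scheme in the spirit of Ballesteros–Weinstein numbers for
GPCRs: each secondary-structure segment's most conserved alignment column is
its **x50 anchor**, neighbours within the segment are numbered sequentially
(`bBx50`, `bDx52`, …), and loops are deliberately left unnumbered because
their residues do not occupy equivalent positions in space. The scheme knows
two layouts: the common one (bA aA bB bBbC bC bD bE bF aB) and the STAT
variant, which lacks bE/bF and instead carries the STAT-exclusive aB′ helix.

On top of the scheme the package provides:

- **profile numbering** — conservation scoring, anchor selection and number
  propagation from a multiple sequence alignment, including transfer to new
  sequences by pairwise alignment (BLOSUM62, affine gaps, free end gaps);
- **structure preprocessing** — fixed-column PDB parsing, renumbering onto
  the wild-type sequence (recording point mutations such as the oncogenic
  STAT5B N642H), trimming to the domain, splitting dual-domain and
  multi-chain entries;
- **superposition** — Kabsch least-squares rigid superposition on backbone
  N/CA/C atoms of the core β-sheet (bB, bC, bD), plus export of `.pml`-style
  session scripts with the eight pY-pocket (Sheinerman) residues saved as
  named selections and shown as sticks;
- **phylogeny** — p-distances over the numbered-position sub-alignment and a
  neighbor-joining tree written as Newick;
- **fixtures** — seeded generators for SH2-like synthetic families and
  idealized domain structures with full ground truth, and the bundled
  published anchor maps for STAT5B and the SHP2 N-SH2 domain.

## Worked example

Resolve published pocket positions for STAT5B (anchors: bBx50 = Arg618,
bDx50 = Asn642, aAx43 = Lys600, bBbCx49 = Asp621):

```sh
$ sh2num resolve --protein STAT5B bDx50
642
$ sh2num resolve --protein STAT5B bBx52
620
$ sh2num resolve --protein SHP2 bEx48
62
```

`620` is Ser620 of STAT5B: within a segment, generic indices and wild-type
residue numbers increment together, so bBx52 = 618 + (52 − 50). `62` is
Tyr62 of SHP2, the first position of the bE strand that follows the
autoregulatory "blocking loop" (bDbE loop).

The same from Python, including the inverse mapping:

```python
>>> from sh2num import bundled_anchors, resolve_position, assign_position
>>> stat5b = bundled_anchors().stat5b
>>> resolve_position(stat5b, "bDx52")
644
>>> str(assign_position(stat5b, 642))   # the N642H hotspot sits on strand bD
'bDx50'
```

A complete offline workflow on synthetic data — generate a family, number
it, superpose the idealized structures onto a reference and build a tree:

```sh
sh2num fixtures --n-records 10 --seed 1 --outdir fam --structures
sh2num number --alignment fam/family.fasta --segmentation fam/segmentation.tsv \
              --out-subalignment fam/sub.fasta --out-annotations fam/ann.json
sh2num superpose --reference fam/rec00.pdb --annotations fam/annotations.json \
                 --outdir sup fam/rec01.pdb fam/rec02.pdb
sh2num tree --alignment fam/sub.fasta > fam/tree.nwk
sh2num session --annotations fam/annotations.json --highlight sheinerman \
               sup/rec01.pdb sup/rec02.pdb > session.pml
```

`superpose` reports, per structure, the RMSD over the paired core-sheet
backbone atoms (0.000 Å here, since same-seed fixtures differ only by a
rigid transform) and writes the transformed PDB files.

## Scheme resource schema

The scheme ships as `src/sh2num/data/scheme.json`:
`anchor_index` (50), `layouts.common` / `layouts.STAT` (ordered
`{name, kind}` segment lists), `index_spans` (inclusive generic-index range
per segment), `sheinerman_positions` (the eight pY-pocket labels) and
`flvr_exception_proteins` (RIN2, TYK2, SH2D5 — the domains where an aromatic
residue replaces the FLVR arginine at bBx50). Published per-protein anchors
live in `data/anchors.json` with the same `DomainAnnotation` JSON layout the
CLI uses for sidecar files.

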