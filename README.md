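# gpcralign

Reduced-alphabet profiling and per-helix alignment of ligand–GPCR binding
sites, for ranking drug-repurposing candidates.

## The problem

G protein-coupled receptors (GPCRs) share a barrel of seven transmembrane
α-helices (TM1–TM7) with the orthosteric ligand pocket in its upper,
extracellular third. Because the fold and the pocket location are conserved
while sequences are not, a drug bound to one GPCR can often be *repurposed*
for another whose pocket presents a similar physico-chemical surface.
`gpcralign` quantifies that similarity directly from ligand–receptor complex
structures (PDB/mmCIF).

## The method

For one complex the tool:

1. finds the **binding site**: receptor residues with any heavy atom within
   4 Å of any ligand atom (boundary inclusive);
2. encodes every helix residue as an integer from a reduced
   physico-chemical alphabet —
   **8DP**: hydrophobic 0, hydrophilic 1, negative 2, positive 3, with +4
   for binding-site residues (symbols 0–7);
   **10DP**: aliphatic 0, aromatic 1, hydrophilic 2, negative 3, positive 4,
   with +5 for binding-site residues (symbols 0–9), so π-stacking contacts
   are distinguished;
3. splits the digit string into **seven per-helix 1D arrays** using a helix
   annotation (user file, or backbone-dihedral detection).

Two complexes are compared by locally aligning each helix against its
counterpart (TMk vs TMk, Smith–Waterman-style dynamic programming with a
linear non-positive GAP penalty) under a substitution matrix reduced from
BLOSUM62 or a GPCR-transmembrane-style matrix to the group alphabet
(arithmetic-mean aggregation by default), or under identity/custom scoring.
With T the sum of the seven target-vs-reference helix scores and R the
reference's self-alignment total, the **normalized score** is

    N = T / R

N equals 1 for self-comparison; in an all-vs-all screen, pairs with
N ≥ 0.5 are reported as repurposing candidates.

## Worked example

Everything below runs offline on synthetic complexes with known ground
truth:

```bash
gpcralign make-fixture --seed 42 --pocket "3:8,3:9,6:10,7:12" --out demo
gpcralign profile demo.pdb --scheme 10DP
```

```
# complex demo  ligand LIG  scheme 10DP
TM1 421441410400020202200031
TM2 204204004414122032004041
TM3 122300005801100043104023
...
# binding-site residues:
#   TM3 A:LEU67 -> 5
#   TM3 A:ASP68 -> 8
#   TM6 A:LYS156 -> 9
#   TM7 A:ASN187 -> 7
```

Each line is one helix's digit string; digits ≥ 5 (10DP) mark binding-site
residues, e.g. `ASP68 -> 8` is a negatively charged residue (3) in contact
with the ligand (+5). Aligning against a second complex whose pocket is a
subset of this one:

```bash
gpcralign make-fixture --seed 42 --pocket "3:8,3:9,6:10" --out sub
gpcralign align sub.pdb demo.pdb --scheme 10DP --matrix blosum62
```

```
total T = 5.97222
reference self-score R = 7.34722
normalized N = T/R = 0.81
```

N = 0.81 ≥ 0.5: the smaller pocket is recognized as chemically compatible
with the reference pocket, so the reference's ligand is a repurposing
candidate for it. An unrelated random pocket scores N = 0.02 under the same
settings. `gpcralign screen manifest.tsv --scheme 8DP --out results/` runs
the all-vs-all version and writes the directed N matrix, the hit list and
run metadata; `gpcralign matrices` prints the reduced score tables;
`gpcralign calibrate` grid-searches the scoring conventions (alignment
scope, matrix aggregation, flag policy) against externally printed scores.

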