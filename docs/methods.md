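# Methods

This note records the model behind `gpcralign`, the choices made where the
procedure is genuinely open, and what the synthetic-fixture tests do and do
not demonstrate.

## Binding-site definition

A receptor residue belongs to the binding site when at least one of its
atoms lies within `cutoff` Å (default 4.0) of at least one ligand atom.
The test is plain Euclidean distance, **boundary inclusive** (d ≤ cutoff):
"within 4 Å" is ambiguous at the boundary, so the inclusive reading is
fixed here and covered by tests at 3.90/4.10 Å. By default only heavy atoms
enter the test on both sides (`heavy_atoms_only`): most crystal structures
carry no hydrogens, and including modeled ones would make the site depend
on the modeling protocol rather than the structure. Hydrogens are parsed
and retained, flagged, for users who want them (`heavy_atoms_only=False`).

Waters, monatomic ions and common crystallization additives (HOH, NA, CL,
SO4, GOL, OLC, CLR, ...) are never treated as the ligand; the exclusion
list is user-extensible. Ligand auto-detection requires exactly one
remaining hetero component with ≥ 6 heavy atoms, otherwise it errors and
lists the candidates. Fusion domains (BRIL, T4 lysozyme) are the user's job
to excise via `residue_range`; a warning fires when the receptor exceeds
450 residues, the typical GPCR-plus-fusion signature. Alternate locations
are resolved per residue to the highest-occupancy conformer, ties broken
alphabetically; insertion codes are preserved in residue keys; MSE and a
short list of common modified residues are remapped to their parents at
parse time.

## Helix topology

Profiles are split into exactly seven arrays (TM1–TM7); the amphipathic
helix 8 of some receptors is never profiled. A user annotation file
(`TM<k> <chain> <start> <end>`, inclusive ranges) is always authoritative.
Without one, a dihedral-window detector is used: residue i is called
helical when every defined φ/ψ among residues i−1…i+1 falls inside
φ ∈ (−100°, −30°), ψ ∈ (−80°, −5°); dihedrals across a chain break (C–N
distance > 2 Å) are undefined and ignored; maximal helical runs of at
least `min_len` (default 8) residues are kept and the seven longest, in
sequence order, form the annotation. The windows are part of the contract
and were chosen to accept ideal α-helical geometry (−57°, −47°) with broad
margins while rejecting extended conformations. This detector is adequate
for idealized bundles and clean structures; strongly kinked real helices
may fragment, which is why user annotations override it. The annotation
source ("user"/"detected") is recorded in run metadata.

## Profiling alphabets

The residue→group assignment is configurable because reasonable chemists
disagree about the edge cases. Defaults:

| group (8DP digit / 10DP digit) | residues |
|---|---|
| hydrophobic 0 → aliphatic 0 | G A V L I P M C |
| hydrophobic 0 → aromatic 1 | F W Y |
| hydrophilic 1 / 2 | S T N Q |
| negative 2 / 3 | D E |
| positive 3 / 4 | K R H |

H sits with the positives (protonatable at physiological pH), Y with the
aromatics (its ring dominates its contact behaviour), C and G with the
aliphatics for want of a better bin. The 10DP map refines the 8DP map
*only* by splitting hydrophobic into aliphatic/aromatic — a property the
tests enforce, since the two schemes are meant to differ only in how π–π
contacts are weighted. Binding-site residues add the flag offset (4 or 5),
doubling the alphabet. Any assignment can be overridden by a key-value
config file without touching code.

## Substitution scoring

A 20×20 residue matrix is reduced to group level by aggregating over all
ordered residue pairs across two groups. The default aggregator is the
unweighted arithmetic mean — the simplest reduction that preserves symmetry
exactly and needs no extra assumptions; median and min are available
behind a config knob because the original reduction convention for this
kind of profiling is not fixed by the method's definition. No rounding is
applied anywhere; normalized scores are displayed to 2 decimals.

Flag interaction (`flag_policy`): flagged-vs-flagged and
unflagged-vs-unflagged pairs always score the group value; for mixed pairs,
`penalize` (default) adds the MISS penalty to the group value, `miss_only`
scores MISS alone, `ignore` makes flags invisible. MISS and GAP must be
non-positive (default −2 for both, matching the published screening
settings).

BLOSUM62 comes from Biopython's canonical tables and is spot-checked in
tests against hand-copied published entries. The `gpcrtm` mode stands for a
class-A-transmembrane substitution matrix; the published matrix is not
redistributed here, so the mode is backed by a **synthetic stand-in**
(BLOSUM62 with +1 on hydrophobic–hydrophobic pairs, mimicking the stronger
hydrophobic conservation inside the bilayer; see
`_gpcrtm_synthetic.py`). Results under `gpcrtm` are therefore *not* the
published matrix's scores; users holding the published table should load it
via the custom residue-matrix file, which is reduced identically.

## Alignment and normalization

Corresponding helices are aligned with the standard local
(Smith–Waterman-style) dynamic program with linear gap penalty; a global
(Needleman–Wunsch-style) variant exists for gap-sensitivity analysis.
Traceback is made bit-stable: the maximal cell with smallest row then
column index wins, and moves prefer diagonal over up over left. Helices
align only to their counterparts, never cross-helix. T is the sum of the
seven helix scores, R the reference self-alignment total, N = T/R. R ≤ 0
(possible under adversarial scoring conventions, e.g. `min` aggregation
with an all-hydrophobic pocket) raises an explicit error instead of
yielding NaN.

**Scope.** Either the full helix strings are aligned (`helix`) or only the
flagged binding-site positions of each helix (`pocket`). The default is
`pocket`: the normalization is meaningful precisely because R then scales
with pocket size, i.e. with the volume the ligand occupies, which is the
stated purpose of normalizing at all. Both modes are first-class, and the
calibration harness (`gpcralign.calibrate`) exists to decide such
conventions empirically against externally printed score tables: it
grid-searches scope × aggregation × flag-policy uniformly across pairs and
ranks the conventions by maximum absolute error.

## Screening

All ordered pairs get N = T/R; the matrix is directed (the denominator
changes with the reference role). The diagonal is exactly 1. Hits are pairs
with N ≥ threshold (default 0.5) and distinct ids, sorted by descending N
with ties broken by target then reference id. Self-scores and profiles are
computed once per complex (k self-alignments for k complexes). Hits are
split into same-receptor and cross-receptor lists by manifest labels; the
cross-receptor fraction is the repurposing yield of a screen.

## Synthetic fixtures

The generator emulates the geometric facts the pipeline relies on and
nothing more: seven ideal α-helices (φ = −57°, ψ = −47°, standard backbone
internal coordinates, ~1.5 Å rise/residue) built by natural-extension
placement, axes on a 20 Å circle, alternating direction; backbone + Cβ
only; a "ligand" of carbon atoms placed at `contact_distance` (default
3.5 Å) radially out from each planned pocket residue's Cβ and verified by a
brute-force scan to be ≥ `spacer_distance` (default 6 Å) from every other
residue. Planned pocket residues cannot be glycine (no Cβ to place the
contact against); random sequences substitute alanine there, which changes
no group in either scheme. Generation is byte-deterministic per spec.

Ground truth (helix ranges, pocket keys, per-scheme digit strings) is
derived from the plan with independent literal lookup tables, never by
running the pipeline, so fixtures act as end-to-end oracles. Pair
generators produce known relations: identical (N = 1), within-group residue
shuffles (identical digit strings, N = 1 — the dimensionality-reduction
premise), and contiguous pocket subsets (N equal to the pocket-size ratio
under identity scoring, pocket scope).

What fixtures do **not** show: performance on real structures — no loops,
kinks, rotamers, missing atoms, alternate conformations beyond the
dedicated parser tests, or chemically realistic ligands. Passing the
fixture suite demonstrates the pipeline's internal correctness and the
contracts above, not agreement with any published screen; the latter is
exactly what the calibration harness plus real PDB inputs are for.

## Problem sizes

The test suite and the acceptance script run on deliberately small
problems: 200 random string pairs of length ≤ 7 against the exhaustive
alignment oracle, 50 (tests) / 10 (script) random fixtures for
self-normalization across the four scoring modes, 10 fixtures for
binding-site recovery, and a five-complex screen. These sizes give exact,
enumerable expectations while keeping the whole suite around fifteen
seconds.

## Known limitations

- The dihedral helix detector is not a DSSP replacement; annotate real
  structures explicitly.
- Group assignments at pH 7 are table lookups; no protonation-state
  calculation is performed.
- The `gpcrtm` mode uses the synthetic stand-in described above.
- Linear (not affine) gap penalties, matching a single user-set GAP value.
- No structure superposition, generic residue numbering, docking, or
  statistical significance estimates for alignment scores.
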