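"""SYNTHETIC stand-in for the GPCRtm residue substitution matrix.

The published GPCRtm matrix (a log-odds matrix estimated from class A GPCR
transmembrane sequences) is not redistributed here.  This module constructs a
synthetic surrogate with the same qualitative character - stronger reward for
conserving hydrophobic residues, as expected inside a lipid bilayer - by
taking BLOSUM62 and adding +1 to every hydrophobic-hydrophobic pair.

Anyone holding the published matrix should pass it through the custom-matrix
loader (``load_custom_matrix`` / ``--matrix-file``) instead; results with
this stand-in are *not* the published GPCRtm scores.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_HYDROPHOBIC = set("GAVLIPMCFWY")
_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def gpcrtm_synthetic() -> dict[tuple[str, str], float]:
    """20x20 symmetric residue matrix: BLOSUM62 with hydrophobic pairs +1."""
    blosum = substitution_matrices.load("BLOSUM62")
    table: dict[tuple[str, str], float] = {}
    for a in _RESIDUES:
        for b in _RESIDUES:
            bonus = 1.0 if a in _HYDROPHOBIC and b in _HYDROPHOBIC else 0.0
            table[(a, b)] = float(blosum[a, b]) + bonus
    return table
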