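"""Assigning receptor residues to the seven transmembrane helices.

Profiles are aligned helix-by-helix, so every residue must be attributed to
one of TM1..TM7 (or to none: loops and termini are excluded from profiling).
Helix bounds come either from a user annotation file - always authoritative -
or from a simple backbone-dihedral detector that suffices for idealized
geometry and annotation-free inputs.

Annotation file format (TSV/whitespace, ``#`` comments)::

    TM1 A 30 60
    TM2 A 67 96
    ...
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._geometry import dihedral
from .errors import ParseError, ValidationError
from .structio import LigandComplex, ResidueKey

#: phi/psi windows (degrees) for calling a residue alpha-helical
PHI_WINDOW = (-100.0, -30.0)
PSI_WINDOW = (-80.0, -5.0)

#: a C(i)-N(i+1) distance above this breaks backbone continuity
PEPTIDE_BOND_MAX = 2.0

N_HELICES = 7
MIN_SEGMENT_LEN = 4


@dataclass(frozen=True)
class HelixAnnotation:
    """Seven inclusive (chain, start, end) residue ranges, TM1..TM7 in order."""

    segments: tuple[tuple[str, int, int], ...]
    source: str  # "user" | "detected"

    def __post_init__(self) -> None:
        if len(self.segments) != N_HELICES:
            raise ValidationError(
                f"expected {N_HELICES} segments, got {len(self.segments)}"
            )
        prev_end = None
        for chain, start, end in self.segments:
            if end < start:
                raise ValidationError(f"segment {chain} {start}-{end} reversed")
            if end - start + 1 < MIN_SEGMENT_LEN:
                raise ValidationError(
                    f"segment {chain} {start}-{end} shorter than {MIN_SEGMENT_LEN}"
                )
            if prev_end is not None and start <= prev_end:
                raise ValidationError(
                    f"segments overlap or are out of order at {chain} {start}-{end}"
                )
            prev_end = end


def helix_of(annotation: HelixAnnotation, residue_key: ResidueKey) -> int | None:
    """1-based helix index containing ``residue_key``, or None for loop and
    terminal residues.  Segment bounds are inclusive."""
    chain_id, res_seq, _icode = residue_key
    for idx, (chain, start, end) in enumerate(annotation.segments, start=1):
        if chain == chain_id and start <= res_seq <= end:
            return idx
    return None


def load_annotation(path: str | Path, cx: LigandComplex) -> HelixAnnotation:
    """Read a 7-line helix-range file and check it against the complex."""
    segments: list[tuple[str, int, int]] = []
    seen: list[str] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ParseError(f"{path}:{lineno}: expected 'TM<k> chain start end'")
        label, chain, start_s, end_s = parts
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer range") from exc
        seen.append(label)
        segments.append((chain, start, end))
    if len(segments) != N_HELICES:
        raise ValidationError(
            f"{path}: expected {N_HELICES} segments, got {len(segments)}"
        )
    segments.sort(key=lambda seg: seg[1])
    annotation = HelixAnnotation(segments=tuple(segments), source="user")
    known = {(r.chain_id, r.res_seq) for r in cx.receptor}
    for chain, start, end in segments:
        if (chain, start) not in known or (chain, end) not in known:
            raise ValidationError(
                f"{path}: range {chain} {start}-{end} does not resolve to "
                "receptor residues"
            )
    return annotation


def _backbone(res) -> dict[str, np.ndarray] | None:
    coords = {}
    for atom in res.atoms:
        if atom.name in ("N", "CA", "C") and atom.name not in coords:
            coords[atom.name] = np.asarray(atom.coords, dtype=float)
    return coords if len(coords) == 3 else None


def detect_helices(cx: LigandComplex, min_len: int = 8) -> HelixAnnotation:
    """Detect the seven TM helices from backbone dihedrals.

    A residue is called helical when every defined phi/psi among residues
    i-1..i+1 falls inside the alpha-helix windows; dihedrals spanning a chain
    break (C-N distance > 2 A) are treated as undefined.  Maximal helical
    runs that do not cross a break are kept when >= ``min_len`` residues; the
    seven longest runs, in sequence order, form the annotation.
    """
    residues = cx.receptor
    backbones = [_backbone(r) for r in residues]
    n = len(residues)
    if sum(b is not None for b in backbones) < 0.9 * n:
        raise ValidationError(
            "backbone N/CA/C missing for more than 10% of residues"
        )

    def bonded(i: int) -> bool:
        """Peptide bond intact between residues i and i+1."""
        a, b = backbones[i], backbones[i + 1]
        if a is None or b is None:
            return False
        return float(np.linalg.norm(b["N"] - a["C"])) <= PEPTIDE_BOND_MAX

    phi = [None] * n
    psi = [None] * n
    for i in range(n):
        b = backbones[i]
        if b is None:
            continue
        if i > 0 and bonded(i - 1):
            prev = backbones[i - 1]
            phi[i] = dihedral(prev["C"], b["N"], b["CA"], b["C"])
        if i < n - 1 and bonded(i):
            nxt = backbones[i + 1]
            psi[i] = dihedral(b["N"], b["CA"], b["C"], nxt["N"])

    def in_window(value, window) -> bool:
        return value is None or window[0] < value < window[1]

    helical = []
    for i in range(n):
        window_idx = [j for j in (i - 1, i, i + 1) if 0 <= j < n]
        ok = backbones[i] is not None and all(
            in_window(phi[j], PHI_WINDOW) and in_window(psi[j], PSI_WINDOW)
            for j in window_idx
        )
        helical.append(ok)

    runs: list[tuple[int, int]] = []  # index ranges, inclusive
    start = None
    for i in range(n):
        if helical[i] and start is None:
            start = i
        broken = i == n - 1 or not bonded(i)
        if start is not None and (not helical[i] or broken):
            end = i if helical[i] else i - 1
            if end - start + 1 >= min_len:
                runs.append((start, end))
            start = None

    if len(runs) < N_HELICES:
        raise ValidationError(
            f"fewer than {N_HELICES} helices detected ({len(runs)} runs of "
            f"length >= {min_len})"
        )
    runs = sorted(sorted(runs, key=lambda r: r[0] - r[1])[:N_HELICES])
    segments = tuple(
        (residues[a].chain_id, residues[a].res_seq, residues[b].res_seq)
        for a, b in runs
    )
    return HelixAnnotation(segments=segments, source="detected")
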