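"""Per-helix local alignment of profile strings and normalized scoring.

Corresponding helices (TMk against TMk, never cross-helix) are aligned with
the classic local dynamic program - edit-style recursion with substitution
scores and a linear, non-positive gap penalty:

    H(i,j) = max(0, H(i-1,j-1) + s(a_i, b_j), H(i-1,j) + gap, H(i,j-1) + gap)

The pair score is the table maximum; traceback starts at the maximal cell
(ties: smallest row, then smallest column) and prefers diagonal over up over
left, so outputs are bit-stable.  Seven helix scores sum to the total T; the
reference's self-alignment total R normalizes it:

    N = T / R

N is 1 for self-comparison and, with the 0.5 threshold used in screening,
ranks candidate ligand swaps between receptors.

Two alignment scopes exist: ``helix`` aligns full helix strings, ``pocket``
aligns only the flagged binding-site positions of each helix (the default;
the N denominator then reflects pocket size, i.e. ligand volume).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DegenerateReferenceError, ValidationError
from .matrices import SubstitutionModel
from .profiler import ComplexProfile, HelixProfile, restrict_to_pocket

SCOPES = ("helix", "pocket")


@dataclass(frozen=True)
class HelixAlignment:
    """Result of aligning one helix pair."""

    helix_index: int
    score: float
    aligned_a: str  # digit string with '-' gaps
    aligned_b: str
    a_start: int  # 0-based, half-open offsets into the inputs
    a_end: int
    b_start: int
    b_end: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValidationError("aligned strings differ in length")


@dataclass(frozen=True)
class AlignmentSummary:
    """Seven helix alignments plus total, reference self-total and N = T/R."""

    target_id: str
    reference_id: str
    per_helix: tuple[HelixAlignment, ...]
    total: float  # T
    reference_self: float  # R
    normalized: float  # N = T / R
    scope: str

    def render(self) -> str:
        lines = [
            f"# target {self.target_id}  reference {self.reference_id}  "
            f"scope {self.scope}"
        ]
        for h in self.per_helix:
            lines.append(
                f"TM{h.helix_index} score {h.score:g}\n"
                f"  target    {h.aligned_a or '-'}\n"
                f"  reference {h.aligned_b or '-'}"
            )
        lines.append(f"total T = {self.total:g}")
        lines.append(f"reference self-score R = {self.reference_self:g}")
        lines.append(f"normalized N = T/R = {self.normalized:.2f}")
        return "\n".join(lines) + "\n"


def _check_symbols(profile: HelixProfile, model: SubstitutionModel) -> None:
    for s in profile.symbols:
        if not 0 <= s < model.alphabet_size:
            raise ValidationError(
                f"symbol {s} outside model alphabet (size {model.alphabet_size})"
            )


def align_helix(
    a: HelixProfile,
    b: HelixProfile,
    model: SubstitutionModel,
    mode: str = "local",
) -> HelixAlignment:
    """Align two same-index helix strings; ``mode`` is ``local``
    (Smith-Waterman style, the default) or ``global`` (Needleman-Wunsch
    style, for gap-sensitivity checks)."""
    if a.helix_index != b.helix_index:
        raise ValidationError(
            f"cannot align TM{a.helix_index} against TM{b.helix_index}"
        )
    _check_symbols(a, model)
    _check_symbols(b, model)
    if mode not in ("local", "global"):
        raise ValidationError(f"unknown alignment mode {mode!r}")
    gap = model.params.gap
    sa, sb = a.symbols, b.symbols
    m, n = len(sa), len(sb)
    local = mode == "local"

    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    if not local:
        for i in range(1, m + 1):
            H[i][0] = i * gap
        for j in range(1, n + 1):
            H[0][j] = j * gap
    best, best_i, best_j = 0.0, 0, 0
    for i in range(1, m + 1):
        row = H[i]
        prev = H[i - 1]
        for j in range(1, n + 1):
            score = max(
                prev[j - 1] + model.score(sa[i - 1], sb[j - 1]),
                prev[j] + gap,
                row[j - 1] + gap,
            )
            if local:
                score = max(score, 0.0)
            row[j] = score
            if local and score > best:
                best, best_i, best_j = score, i, j

    if not local:
        best, best_i, best_j = H[m][n], m, n
    if local and best == 0.0:
        return HelixAlignment(a.helix_index, 0.0, "", "", 0, 0, 0, 0)

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = best_i, best_j
    while (i > 0 or j > 0) if not local else H[i][j] > 0:
        h = H[i][j]
        if (
            i > 0
            and j > 0
            and h == H[i - 1][j - 1] + model.score(sa[i - 1], sb[j - 1])
        ):
            out_a.append(str(sa[i - 1]))
            out_b.append(str(sb[j - 1]))
            i, j = i - 1, j - 1
        elif i > 0 and h == H[i - 1][j] + gap:
            out_a.append(str(sa[i - 1]))
            out_b.append("-")
            i -= 1
        elif j > 0 and h == H[i][j - 1] + gap:
            out_a.append("-")
            out_b.append(str(sb[j - 1]))
            j -= 1
        else:  # pragma: no cover - defensive; DP construction precludes this
            raise AssertionError("traceback inconsistency")
    return HelixAlignment(
        helix_index=a.helix_index,
        score=float(best),
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        a_start=i,
        a_end=best_i,
        b_start=j,
        b_end=best_j,
    )


def rescore_alignment(alignment: HelixAlignment, model: SubstitutionModel) -> float:
    """Sum of substitution and gap terms along the traceback; must equal the
    DP score for local alignments."""
    total = 0.0
    for ca, cb in zip(alignment.aligned_a, alignment.aligned_b):
        if ca == "-" or cb == "-":
            total += model.params.gap
        else:
            total += model.score(int(ca), int(cb))
    return total


def _scoped(profile: ComplexProfile, scope: str) -> ComplexProfile:
    if scope not in SCOPES:
        raise ValidationError(f"unknown scope {scope!r}; use one of {SCOPES}")
    return restrict_to_pocket(profile) if scope == "pocket" else profile


def self_score(
    profile: ComplexProfile, model: SubstitutionModel, scope: str = "pocket",
    mode: str = "local",
) -> float:
    """Total self-alignment score R of a complex profile."""
    scoped = _scoped(profile, scope)
    return sum(align_helix(h, h, model, mode=mode).score for h in scoped.helices)


def align_complexes(
    target: ComplexProfile,
    reference: ComplexProfile,
    model: SubstitutionModel,
    scope: str = "pocket",
    mode: str = "local",
    reference_self: float | None = None,
) -> AlignmentSummary:
    """Align all seven helix pairs and normalize by the reference self-score.

    ``reference_self`` lets callers (the screen) reuse a cached R.
    """
    if target.scheme_name != reference.scheme_name:
        raise ValidationError(
            f"scheme mismatch: {target.scheme_name} vs {reference.scheme_name}"
        )
    t_scoped = _scoped(target, scope)
    r_scoped = _scoped(reference, scope)
    per_helix = tuple(
        align_helix(ht, hr, model, mode=mode)
        for ht, hr in zip(t_scoped.helices, r_scoped.helices)
    )
    total = sum(h.score for h in per_helix)
    if reference_self is None:
        reference_self = self_score(reference, model, scope=scope, mode=mode)
    if reference_self <= 0:
        raise DegenerateReferenceError(
            f"reference {reference.source_id} has self-alignment score "
            f"{reference_self}; N = T/R is undefined"
        )
    return AlignmentSummary(
        target_id=target.source_id,
        reference_id=reference.source_id,
        per_helix=per_helix,
        total=float(total),
        reference_self=float(reference_self),
        normalized=float(total / reference_self),
        scope=scope,
    )


def score_pair_bidirectional(
    p1: ComplexProfile,
    p2: ComplexProfile,
    model: SubstitutionModel,
    scope: str = "pocket",
    mode: str = "local",
) -> tuple[float, float]:
    """Normalized scores with each complex taking the target role in turn.

    The two values generally differ (different self-score denominators) even
    though the raw total T is shared under a symmetric model.
    """
    n1 = align_complexes(p1, p2, model, scope=scope, mode=mode).normalized
    n2 = align_complexes(p2, p1, model, scope=scope, mode=mode).normalized
    return (n1, n2)
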