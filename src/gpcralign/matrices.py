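"""Substitution scoring over the flagged profile alphabets.

A 20x20 residue substitution matrix (BLOSUM62, the GPCRtm surrogate, or a
user-supplied file) is *reduced* to the scheme's group level by aggregating
the scores of all residue pairs across two groups (arithmetic mean by
default), then *expanded* to the doubled, flag-aware alphabet.  How a flagged
symbol scores against an unflagged one is controlled by ``flag_policy``:

* ``penalize`` (default) - group score plus the MISS penalty;
* ``miss_only``          - the MISS penalty alone;
* ``ignore``             - the group score, flags invisible.

MISS and GAP are user-set penalties and must be non-positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from ._gpcrtm_synthetic import gpcrtm_synthetic
from .errors import ParseError, ValidationError
from .profiler import STANDARD_RESIDUES, ProfileScheme

MODES = ("blosum62", "gpcrtm", "identity", "custom")
FLAG_POLICIES = ("penalize", "miss_only", "ignore")
AGGREGATIONS = ("mean", "median", "min")


@dataclass(frozen=True)
class ScoringParams:
    """User-facing scoring knobs (mirrors the alignment form of the GUI-era
    tool: matrix choice, MISS, GAP, plus reduction/flag policies)."""

    mode: str = "blosum62"
    miss: float = -2.0
    gap: float = -2.0
    flag_policy: str = "penalize"
    match: float = 1.0  # identity mode only
    aggregation: str = "mean"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"unknown scoring mode {self.mode!r}")
        if self.miss > 0 or self.gap > 0:
            raise ValidationError(
                f"MISS and GAP must be non-positive (got miss={self.miss}, "
                f"gap={self.gap})"
            )
        if self.flag_policy not in FLAG_POLICIES:
            raise ValidationError(f"unknown flag_policy {self.flag_policy!r}")
        if self.aggregation not in AGGREGATIONS:
            raise ValidationError(f"unknown aggregation {self.aggregation!r}")
        if self.mode == "identity" and self.match <= 0:
            raise ValidationError(f"identity match must be > 0, got {self.match}")


@dataclass(frozen=True)
class SubstitutionModel:
    """Symmetric score table over the full flagged alphabet (8x8 or 10x10)."""

    scheme_name: str
    table: np.ndarray
    params: ScoringParams

    def __post_init__(self) -> None:
        t = self.table
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValidationError("substitution table must be square")
        if not np.all(np.isfinite(t)):
            raise ValidationError("substitution table has non-finite entries")
        if not np.allclose(t, t.T):
            raise ValidationError("substitution table must be symmetric")

    @property
    def alphabet_size(self) -> int:
        return self.table.shape[0]

    def score(self, x: int, y: int) -> float:
        if not (0 <= x < self.alphabet_size and 0 <= y < self.alphabet_size):
            raise ValidationError(
                f"symbol pair ({x},{y}) outside alphabet of size {self.alphabet_size}"
            )
        return float(self.table[x, y])


def _lookup(full, a: str, b: str) -> float:
    """Score of a residue pair from a Bio.Align Array or a dict keyed by
    (a, b) tuples."""
    try:
        return float(full[a, b])
    except (KeyError, IndexError, TypeError):
        pass
    try:
        return float(full[(a, b)])
    except KeyError:
        raise ValidationError(f"residue pair ({a},{b}) missing from matrix")


def residue_matrix(mode: str):
    """The built-in 20x20 residue matrix behind a named mode."""
    if mode == "blosum62":
        return substitution_matrices.load("BLOSUM62")
    if mode == "gpcrtm":
        return gpcrtm_synthetic()
    raise ValidationError(f"mode {mode!r} has no built-in residue matrix")


def reduce_matrix(
    full, scheme: ProfileScheme, aggregation: str = "mean"
) -> np.ndarray:
    """Aggregate a 20x20 residue matrix to group level.

    Entry (g, h) aggregates ``full[a, b]`` over all ordered residue pairs
    with a in group g and b in group h; the default arithmetic mean keeps
    the result exactly symmetric, with no rounding.
    """
    if aggregation not in AGGREGATIONS:
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    agg = {"mean": np.mean, "median": np.median, "min": np.min}[aggregation]
    n = scheme.n_groups
    out = np.zeros((n, n), dtype=float)
    for g in range(n):
        for h in range(n):
            values = [
                _lookup(full, a, b)
                for a in scheme.members(g)
                for b in scheme.members(h)
            ]
            out[g, h] = float(agg(values))
    return out


def expand_to_flagged(
    group_matrix: np.ndarray, params: ScoringParams, scheme: ProfileScheme
) -> SubstitutionModel:
    """Lift a group-level matrix onto the doubled flag-aware alphabet."""
    n = scheme.n_groups
    group_matrix = np.asarray(group_matrix, dtype=float)
    if group_matrix.shape != (n, n):
        raise ValidationError(
            f"group matrix shape {group_matrix.shape} does not match "
            f"{n} groups of scheme {scheme.name}"
        )
    size = 2 * n
    table = np.zeros((size, size), dtype=float)
    for x in range(size):
        for y in range(size):
            gx, fx = x % n, x >= n
            gy, fy = y % n, y >= n
            base = group_matrix[gx, gy]
            if fx == fy or params.flag_policy == "ignore":
                table[x, y] = base
            elif params.flag_policy == "penalize":
                table[x, y] = base + params.miss
            else:  # miss_only
                table[x, y] = params.miss
    return SubstitutionModel(scheme_name=scheme.name, table=table, params=params)


def identity_model(params: ScoringParams, scheme: ProfileScheme) -> SubstitutionModel:
    """Match/miss scoring over the flagged alphabet: s(x,x) = match,
    s(x,y != x) = miss."""
    if params.mode != "identity":
        raise ValidationError("identity_model requires params.mode == 'identity'")
    size = scheme.alphabet_size
    table = np.full((size, size), params.miss, dtype=float)
    np.fill_diagonal(table, params.match)
    return SubstitutionModel(scheme_name=scheme.name, table=table, params=params)


def load_custom_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a whitespace-separated labeled square matrix (PAM/BLOSUM layout,
    ``#`` comments).  Returns (labels, matrix); asymmetry beyond 1e-9 is an
    error naming the offending cell."""
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.split("#", 1)[0].strip()
    ]
    if not lines:
        raise ParseError(f"{path}: empty matrix file")
    labels = lines[0].split("#", 1)[0].split()
    n = len(labels)
    rows = []
    row_labels = []
    for ln in lines[1:]:
        parts = ln.split("#", 1)[0].split()
        if not parts:
            continue
        row_labels.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric entry in row {parts[0]!r}") from exc
    if len(rows) != n or any(len(r) != n for r in rows):
        raise ParseError(
            f"{path}: expected a {n}x{n} matrix for labels {labels}, got "
            f"{len(rows)} rows of lengths {[len(r) for r in rows]}"
        )
    if row_labels != labels:
        raise ParseError(f"{path}: row labels {row_labels} != column labels {labels}")
    matrix = np.array(rows, dtype=float)
    bad = np.argwhere(np.abs(matrix - matrix.T) > 1e-9)
    if bad.size:
        i, j = bad[0]
        raise ParseError(
            f"{path}: asymmetric entries at ({labels[i]},{labels[j]}): "
            f"{matrix[i, j]} vs {matrix[j, i]}"
        )
    return labels, matrix


def build_model(
    scheme: ProfileScheme,
    params: ScoringParams,
    custom_path: str | Path | None = None,
) -> SubstitutionModel:
    """One-stop construction of the substitution model for a scheme/params
    combination, dispatching on ``params.mode``."""
    if params.mode == "identity":
        return identity_model(params, scheme)
    if params.mode == "custom":
        if custom_path is None:
            raise ValidationError("custom mode requires a matrix file")
        labels, matrix = load_custom_matrix(custom_path)
        if len(labels) == scheme.n_groups:
            if list(labels) != list(scheme.group_names):
                raise ValidationError(
                    f"custom matrix labels {labels} do not match scheme groups "
                    f"{list(scheme.group_names)}"
                )
            return expand_to_flagged(matrix, params, scheme)
        if len(labels) == scheme.alphabet_size:
            return SubstitutionModel(
                scheme_name=scheme.name, table=matrix, params=params
            )
        if sorted(labels) == sorted(STANDARD_RESIDUES):
            full = {
                (a, b): matrix[labels.index(a), labels.index(b)]
                for a in labels
                for b in labels
            }
            group = reduce_matrix(full, scheme, params.aggregation)
            return expand_to_flagged(group, params, scheme)
        raise ValidationError(
            f"custom matrix labels {labels} match neither the scheme groups, "
            "the flagged alphabet, nor the 20 standard residues"
        )
    full = residue_matrix(params.mode)
    group = reduce_matrix(full, scheme, params.aggregation)
    return expand_to_flagged(group, params, scheme)
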