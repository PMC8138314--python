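"""Calibration harness: grid-search the exposed scoring conventions against
externally printed normalized scores.

Several conventions of the profiling pipeline are open choices rather than
fixed by the method's definition: the alignment scope (full helices vs
pocket-only strings), how a residue matrix is aggregated to group level, and
how flagged symbols score against unflagged ones.  Given pairs of complexes
with known (printed) normalized scores, :func:`calibrate` evaluates every
combination of those knobs uniformly across all pairs and reports them
ranked, so the convention best matching a published table can be identified
and then pinned in configuration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import math

from .aligner import SCOPES, score_pair_bidirectional
from .errors import DegenerateReferenceError
from .matrices import AGGREGATIONS, FLAG_POLICIES, ScoringParams, build_model
from .profiler import get_scheme
from .screen import ScreenConfig, ScreenEntry, _profile_entry


@dataclass(frozen=True)
class CalibrationPair:
    """Two complexes, the scheme/matrix to use, and the printed target
    values (target-as-first, first-as-reference orientation first)."""

    first: ScreenEntry
    second: ScreenEntry
    scheme: str
    matrix_mode: str  # "blosum62" | "gpcrtm"
    printed: tuple[float, ...]  # (N first-as-target, [N second-as-target])


@dataclass
class CalibrationResult:
    scope: str
    aggregation: str
    flag_policy: str
    computed: list[tuple[float, ...]]
    errors: list[float]  # |computed - printed| per printed value

    @property
    def max_error(self) -> float:
        return max(self.errors)

    @property
    def mean_error(self) -> float:
        return sum(self.errors) / len(self.errors)

    def within(self, tolerance: float) -> bool:
        return self.max_error <= tolerance


def calibrate(
    pairs: list[CalibrationPair],
    miss: float = -2.0,
    gap: float = -2.0,
    cutoff: float = 4.0,
    scopes: tuple[str, ...] = SCOPES,
    aggregations: tuple[str, ...] = AGGREGATIONS,
    flag_policies: tuple[str, ...] = FLAG_POLICIES,
) -> list[CalibrationResult]:
    """Evaluate every (scope, aggregation, flag_policy) combination on all
    pairs; results are sorted by max |error| then mean |error|."""
    # profiles depend on scheme and cutoff only - cache across the grid
    profile_cache: dict[tuple[str, str], object] = {}

    def profile(entry: ScreenEntry, scheme: str):
        key = (entry.id, scheme)
        if key not in profile_cache:
            config = ScreenConfig(scheme=scheme, cutoff=cutoff)
            profile_cache[key] = _profile_entry(entry, config)
        return profile_cache[key]

    results = []
    for scope, aggregation, flag_policy in itertools.product(
        scopes, aggregations, flag_policies
    ):
        computed = []
        errors = []
        for pair in pairs:
            params = ScoringParams(
                mode=pair.matrix_mode,
                miss=miss,
                gap=gap,
                flag_policy=flag_policy,
                aggregation=aggregation,
            )
            model = build_model(get_scheme(pair.scheme), params)
            try:
                n_pair = score_pair_bidirectional(
                    profile(pair.first, pair.scheme),
                    profile(pair.second, pair.scheme),
                    model,
                    scope=scope,
                )
            except DegenerateReferenceError:
                # e.g. "min" aggregation can make all self-scores non-positive;
                # such a convention cannot have produced the printed values
                computed.append(())
                errors.extend([math.inf] * len(pair.printed))
                continue
            values = n_pair[: len(pair.printed)]
            computed.append(values)
            errors.extend(
                abs(v - printed) for v, printed in zip(values, pair.printed)
            )
        results.append(
            CalibrationResult(
                scope=scope,
                aggregation=aggregation,
                flag_policy=flag_policy,
                computed=computed,
                errors=errors,
            )
        )
    results.sort(key=lambda r: (r.max_error, r.mean_error))
    return results


def render_report(results: list[CalibrationResult], tolerance: float = 0.05) -> str:
    lines = ["scope\taggregation\tflag_policy\tmax_err\tmean_err\twithin_tol"]
    for r in results:
        lines.append(
            f"{r.scope}\t{r.aggregation}\t{r.flag_policy}\t"
            f"{r.max_error:.4f}\t{r.mean_error:.4f}\t{r.within(tolerance)}"
        )
    return "\n".join(lines) + "\n"
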