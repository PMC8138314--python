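"""Local alignment DP against an independent oracle, plus score invariants."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from gpcralign.aligner import (
    align_complexes,
    align_helix,
    rescore_alignment,
    score_pair_bidirectional,
)
from gpcralign.errors import DegenerateReferenceError, ValidationError
from gpcralign.matrices import ScoringParams, SubstitutionModel, identity_model
from gpcralign.profiler import ComplexProfile, HelixProfile, get_scheme


def hp(symbols, index=1, scheme="8DP"):
    return HelixProfile(
        helix_index=index,
        symbols=tuple(symbols),
        residue_keys=tuple(("A", i + 1, "") for i in range(len(symbols))),
        scheme_name=scheme,
    )


def random_model(rng, size, gap):
    base = rng.integers(-3, 4, size=(size, size)).astype(float)
    table = (base + base.T) / 2.0
    np.fill_diagonal(table, rng.integers(1, 5, size=size))
    params = ScoringParams(mode="identity", match=1.0, miss=-1.0, gap=gap)
    return SubstitutionModel(scheme_name="8DP", table=table, params=params)


def oracle_local_score(a, b, model):
    """Independent local-alignment oracle: maximum, over all substring pairs,
    of the globally optimal gapped alignment score computed by memoized
    recursion on suffixes (empty alignment = 0 included)."""
    gap = model.params.gap

    @lru_cache(maxsize=None)
    def global_score(x, y):
        if not x and not y:
            return 0.0
        options = []
        if x and y:
            options.append(global_score(x[:-1], y[:-1]) + model.score(x[-1], y[-1]))
        if x:
            options.append(global_score(x[:-1], y) + gap)
        if y:
            options.append(global_score(x, y[:-1]) + gap)
        return max(options)

    best = 0.0
    for i1 in range(len(a) + 1):
        for i2 in range(i1, len(a) + 1):
            for j1 in range(len(b) + 1):
                for j2 in range(j1, len(b) + 1):
                    best = max(best, global_score(a[i1:i2], b[j1:j2]))
    return best


def identity_8dp(miss=-2.0, gap=-2.0, match=1.0):
    return identity_model(
        ScoringParams(mode="identity", match=match, miss=miss, gap=gap),
        get_scheme("8DP"),
    )


def test_single_symbol_self_alignment():
    model = identity_8dp()
    result = align_helix(hp([3]), hp([3]), model)
    assert result.score == 1.0
    assert (result.aligned_a, result.aligned_b) == ("3", "3")


def test_perfect_self_match_scores_length():
    model = identity_8dp()
    result = align_helix(hp([6, 0, 3, 7]), hp([6, 0, 3, 7]), model)
    assert result.score == 4.0
    assert result.aligned_a == "6037"


def test_all_mismatch_gives_empty_alignment():
    model = identity_8dp()
    result = align_helix(hp([0, 0, 0]), hp([1, 1, 1]), model)
    assert result.score == 0.0
    assert result.aligned_a == "" and result.aligned_b == ""


def test_dp_matches_bruteforce_oracle_on_random_pairs():
    rng = np.random.default_rng(42)
    for trial in range(200):
        size = int(rng.choice([4, 8, 10]))
        gap = float(rng.choice([-1.0, -2.0, -3.0]))
        model = random_model(rng, size, gap)
        la, lb = int(rng.integers(0, 8)), int(rng.integers(1, 8))
        a = tuple(int(s) for s in rng.integers(0, size, la))
        b = tuple(int(s) for s in rng.integers(0, size, lb))
        result = align_helix(hp(a), hp(b), model)
        expected = oracle_local_score(a, b, model)
        assert result.score == pytest.approx(expected), (trial, a, b)
        # traceback re-scoring reproduces the DP score exactly
        assert rescore_alignment(result, model) == pytest.approx(result.score)


def test_score_symmetry_under_input_swap():
    rng = np.random.default_rng(7)
    model = random_model(rng, 8, -2.0)
    for _ in range(50):
        a = tuple(int(s) for s in rng.integers(0, 8, rng.integers(1, 10)))
        b = tuple(int(s) for s in rng.integers(0, 8, rng.integers(1, 10)))
        assert align_helix(hp(a), hp(b), model).score == align_helix(
            hp(b), hp(a), model
        ).score


def test_gap_monotonicity():
    rng = np.random.default_rng(13)
    for _ in range(30):
        a = tuple(int(s) for s in rng.integers(0, 8, rng.integers(2, 12)))
        b = tuple(int(s) for s in rng.integers(0, 8, rng.integers(2, 12)))
        scores = [
            align_helix(hp(a), hp(b), identity_8dp(gap=g)).score
            for g in (-1.0, -2.0, -4.0)
        ]
        assert scores[0] >= scores[1] >= scores[2]


def test_local_score_bounds_global_score():
    rng = np.random.default_rng(99)
    model = random_model(rng, 8, -2.0)
    for _ in range(30):
        a = tuple(int(s) for s in rng.integers(0, 8, rng.integers(1, 9)))
        b = tuple(int(s) for s in rng.integers(0, 8, rng.integers(1, 9)))
        local = align_helix(hp(a), hp(b), model).score
        global_ = align_helix(hp(a), hp(b), model, mode="global").score
        assert local >= global_
        assert local >= 0.0


def test_cross_helix_alignment_rejected():
    model = identity_8dp()
    with pytest.raises(ValidationError, match="TM1 against TM2"):
        align_helix(hp([1]), hp([1], index=2), model)


def complex_profile(helix_symbols, source="cx", scheme="8DP", pocket=()):
    helices = tuple(
        hp(symbols, index=i + 1, scheme=scheme)
        for i, symbols in enumerate(helix_symbols)
    )
    return ComplexProfile(
        source_id=source,
        ligand_code="LIG",
        helices=helices,
        pocket_keys=frozenset(pocket),
        scheme_name=scheme,
    )


def test_self_alignment_normalizes_to_one():
    profile = complex_profile([[4, 0, 3], [1, 5], [2], [0, 0], [6], [7, 1], [3]])
    summary = align_complexes(profile, profile, identity_8dp(), scope="helix")
    assert summary.normalized == 1.0
    assert summary.total == summary.reference_self


def test_empty_pocket_self_alignment_helix_scope():
    profile = complex_profile([[0, 1, 2, 3]] * 7)  # nothing flagged
    summary = align_complexes(profile, profile, identity_8dp(), scope="helix")
    assert summary.normalized == 1.0


def test_empty_pocket_pocket_scope_is_degenerate():
    profile = complex_profile([[0, 1, 2, 3]] * 7)
    with pytest.raises(DegenerateReferenceError):
        align_complexes(profile, profile, identity_8dp(), scope="pocket")


def test_substring_helices_closed_form():
    """Target helices that are substrings of the reference helices score
    match * len(target) per helix, so N = total target length ratio."""
    rng = np.random.default_rng(5)
    ref_helices = [
        [int(s) for s in rng.integers(0, 4, 10)] for _ in range(7)
    ]
    target_helices = [symbols[2:7] for symbols in ref_helices]
    reference = complex_profile(ref_helices, source="ref")
    target = complex_profile(target_helices, source="tgt")
    summary = align_complexes(target, reference, identity_8dp(), scope="helix")
    assert summary.total == sum(len(h) for h in target_helices)
    assert summary.normalized == pytest.approx(
        sum(map(len, target_helices)) / sum(map(len, ref_helices))
    )


def test_bidirectional_shares_t_but_not_n():
    rng = np.random.default_rng(21)
    p1 = complex_profile(
        [[int(s) for s in rng.integers(0, 8, 8)] for _ in range(7)], source="p1"
    )
    p2 = complex_profile(
        [[int(s) for s in rng.integers(0, 8, 12)] for _ in range(7)], source="p2"
    )
    model = identity_8dp()
    s12 = align_complexes(p1, p2, model, scope="helix")
    s21 = align_complexes(p2, p1, model, scope="helix")
    assert s12.total == pytest.approx(s21.total)  # symmetric model
    n1, n2 = score_pair_bidirectional(p1, p2, model, scope="helix")
    assert (n1, n2) == (
        pytest.approx(s12.normalized),
        pytest.approx(s21.normalized),
    )


def test_identical_complexes_bidirectional_unity():
    profile = complex_profile([[4, 0, 3, 2]] * 7)
    assert score_pair_bidirectional(
        profile, profile, identity_8dp(), scope="helix"
    ) == (1.0, 1.0)
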