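"""All-vs-all screening: matrix invariants, hits, caching, manifest parsing."""

from __future__ import annotations

import numpy as np
import pytest

import gpcralign.screen as screen_mod
from gpcralign.errors import ParseError, ValidationError
from gpcralign.matrices import ScoringParams
from gpcralign.screen import (
    ScreenConfig,
    ScreenEntry,
    partition_hits,
    read_manifest,
    run_screen,
    write_screen_outputs,
)
from gpcralign.synth import FixtureSpec, make_complex

from conftest import POCKET_PLAN

IDENTITY = ScoringParams(mode="identity", match=1.0)


def write_spec(tmp_path, spec, name):
    pdb_text, truth = make_complex(spec)
    path = tmp_path / f"{name}.pdb"
    path.write_text(pdb_text)
    return str(path), truth


@pytest.fixture
def identical_trio(tmp_path):
    spec = FixtureSpec(pocket_plan=POCKET_PLAN, seed=9)
    path, _ = write_spec(tmp_path, spec, "same")
    return [
        ScreenEntry(id=f"c{i}", path=path, ligand_code="LIG", receptor_label="R")
        for i in range(3)
    ]


def test_identical_complexes_all_unity(identical_trio):
    config = ScreenConfig(scheme="8DP", scoring=IDENTITY)
    table = run_screen(identical_trio, config)[0]
    assert np.allclose(table.n_matrix, 1.0)
    assert len(table.hits) == 6  # all ordered off-diagonal pairs
    assert all(n == 1.0 for _, _, n in table.hits)


def test_disjoint_pocket_groups_score_zero(tmp_path):
    base = dict(helix_length=16, seed=2)
    # all pocket residues hydrophobic in one complex, positive in the other;
    # under identity scoring every cross-pocket pair is a miss
    seq_hydro = ("L" * 16,) * 7
    seq_pos = ("K" * 16,) * 7
    plan = ((1, 6), (1, 7), (4, 8))
    path_a, _ = write_spec(
        tmp_path, FixtureSpec(sequences=seq_hydro, pocket_plan=plan, **base), "hyd"
    )
    path_b, _ = write_spec(
        tmp_path, FixtureSpec(sequences=seq_pos, pocket_plan=plan, **base), "pos"
    )
    entries = [
        ScreenEntry(id="hyd", path=path_a, receptor_label="A"),
        ScreenEntry(id="pos", path=path_b, receptor_label="B"),
    ]
    table = run_screen(entries, ScreenConfig(scheme="8DP", scoring=IDENTITY))[0]
    assert table.n_matrix[0, 1] == 0.0 and table.n_matrix[1, 0] == 0.0
    assert table.hits == []


def test_threshold_above_one_empties_hits(identical_trio):
    config = ScreenConfig(scheme="8DP", scoring=IDENTITY, threshold=1.1)
    table = run_screen(identical_trio, config)[0]
    assert table.hits == []


def test_diagonal_exactly_one_and_threshold_monotone(identical_trio):
    low = run_screen(identical_trio, ScreenConfig(scoring=IDENTITY, threshold=0.2))[0]
    high = run_screen(identical_trio, ScreenConfig(scoring=IDENTITY, threshold=0.9))[0]
    assert np.all(np.diag(low.n_matrix) == 1.0)
    assert set(high.hits) <= set(low.hits)


def test_self_alignments_computed_once_per_complex(identical_trio, monkeypatch):
    calls = []
    original = screen_mod.self_score

    def counting(profile, model, scope="pocket", mode="local"):
        calls.append(profile.source_id)
        return original(profile, model, scope=scope, mode=mode)

    monkeypatch.setattr(screen_mod, "self_score", counting)
    run_screen(identical_trio, ScreenConfig(scoring=IDENTITY))
    assert sorted(calls) == ["c0", "c1", "c2"]  # k, not k^2


def test_failed_complexes_are_skipped(identical_trio, tmp_path):
    bogus = tmp_path / "missing.pdb"
    entries = identical_trio + [ScreenEntry(id="bad", path=str(bogus))]
    table = run_screen(entries, ScreenConfig(scoring=IDENTITY))[0]
    assert table.skipped == ["bad"]
    assert table.ids == ["c0", "c1", "c2"]
    with pytest.raises(ValidationError, match=">= 2 usable"):
        run_screen(entries[:1], ScreenConfig(scoring=IDENTITY))


def test_partition_hits_by_receptor_label(identical_trio):
    table = run_screen(identical_trio, ScreenConfig(scoring=IDENTITY))[0]
    same, cross, fraction = partition_hits(table)
    assert cross == [] and fraction == 0.0
    labels = {"c0": "A", "c1": "A", "c2": "B"}
    same, cross, fraction = partition_hits(table, labels)
    cross_pairs = {(t, r) for t, r, _ in cross}
    assert cross_pairs == {("c0", "c2"), ("c1", "c2"), ("c2", "c0"), ("c2", "c1")}
    assert fraction == pytest.approx(4 / 6)
    with pytest.raises(ValidationError, match="missing receptor labels"):
        partition_hits(table, {"c0": "A"})


def test_hits_sorted_by_score_then_ids(tmp_path):
    spec = FixtureSpec(pocket_plan=((3, 6), (3, 7), (3, 8), (3, 9)), seed=6)
    from gpcralign.synth import make_pair

    (pdb_a, _), (pdb_b, _), _ = make_pair(spec, "pocket_subset")
    pa = tmp_path / "a.pdb"
    pa.write_text(pdb_a)
    pb = tmp_path / "b.pdb"
    pb.write_text(pdb_b)
    entries = [
        ScreenEntry(id="full", path=str(pa)),
        ScreenEntry(id="half", path=str(pb)),
    ]
    table = run_screen(entries, ScreenConfig(scoring=IDENTITY, threshold=0.4))[0]
    assert [h[:2] for h in table.hits] == [("full", "half"), ("half", "full")]
    assert table.hits[0][2] == 1.0 and table.hits[1][2] == pytest.approx(0.5)


def test_manifest_parsing_and_outputs(identical_trio, tmp_path):
    manifest = tmp_path / "manifest.tsv"
    rows = [
        f"{e.id}\t{e.path}\tLIG\tR\t-" for e in identical_trio
    ]
    manifest.write_text("# id path ligand label annotation\n" + "\n".join(rows) + "\n")
    entries = read_manifest(manifest)
    assert [e.id for e in entries] == ["c0", "c1", "c2"]
    assert entries[0].annotation_path is None

    bad = tmp_path / "bad.tsv"
    bad.write_text("onlyonefield\n")
    with pytest.raises(ParseError, match="bad.tsv:1"):
        read_manifest(bad)

    table = run_screen(entries, ScreenConfig(scoring=IDENTITY))[0]
    out = tmp_path / "out"
    write_screen_outputs(table, out)
    matrix_lines = (out / "n_matrix.tsv").read_text().splitlines()
    assert matrix_lines[0].split("\t")[1:] == ["c0", "c1", "c2"]
    assert (out / "hits.tsv").exists() and (out / "run_metadata.json").exists()
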