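"""Shared fixtures: synthetic complexes written to disk, plus a raw PDB-line
helper for hand-built edge-case structures."""

from __future__ import annotations

import pytest

from gpcralign import structio, topology
from gpcralign.synth import FixtureSpec, make_complex

#: default pocket plan: two contacts on TM1, one on TM4, one on TM7
POCKET_PLAN = ((1, 4), (1, 8), (4, 10), (7, 12))


@pytest.fixture
def default_spec() -> FixtureSpec:
    return FixtureSpec(pocket_plan=POCKET_PLAN, seed=11)


@pytest.fixture
def write_fixture(tmp_path):
    """Factory writing a FixtureSpec to a PDB file; returns (path, truth)."""

    def _write(spec: FixtureSpec, name: str = "fix"):
        pdb_text, truth = make_complex(spec)
        path = tmp_path / f"{name}.pdb"
        path.write_text(pdb_text)
        return path, truth

    return _write


@pytest.fixture
def loaded(write_fixture, default_spec):
    """(complex, detected annotation, truth) for the default fixture."""
    path, truth = write_fixture(default_spec)
    cx = structio.load_complex(path)
    annotation = topology.detect_helices(cx)
    return cx, annotation, truth


def pdb_line(
    serial: int,
    name: str,
    res_name: str,
    chain: str,
    res_seq: int,
    x: float,
    y: float,
    z: float,
    occupancy: float = 1.0,
    alt_loc: str = " ",
    element: str = "C",
    het: bool = False,
    icode: str = " ",
) -> str:
    """One fixed-column ATOM/HETATM record."""
    record = "HETATM" if het else "ATOM  "
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record}{serial:5d} {name_field}{alt_loc}{res_name:>3s} {chain}"
        f"{res_seq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}"
        f"{20.0:6.2f}          {element:>2s}"
    )
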