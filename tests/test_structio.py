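"""Structure parsing, ligand selection and binding-site detection."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from gpcralign import structio
from gpcralign.errors import AmbiguousLigandError, ValidationError
from gpcralign.structio import BindingSiteSpec, find_binding_site, load_complex
from gpcralign.synth import FixtureSpec, make_complex

from conftest import POCKET_PLAN, pdb_line


def brute_force_site(cx, spec):
    """Independent O(N*M) double-loop binding-site scan."""
    ligand = [
        np.asarray(a.coords)
        for a in cx.ligand_atoms
        if not (spec.heavy_atoms_only and a.is_hydrogen)
    ]
    keys = []
    for res in cx.receptor:
        hit = False
        for atom in res.atoms:
            if spec.heavy_atoms_only and atom.is_hydrogen:
                continue
            for lig in ligand:
                if np.linalg.norm(np.asarray(atom.coords) - lig) <= spec.cutoff:
                    hit = True
        if hit:
            keys.append(res.key)
    return keys


def test_roundtrip_of_generated_fixture(write_fixture, default_spec, tmp_path):
    path, truth = write_fixture(default_spec)
    cx = load_complex(path)
    assert len(cx.receptor) == sum(default_spec.lengths())
    assert cx.ligand_code == "LIG"
    out = tmp_path / "rt.pdb"
    structio.write_complex(cx, out)
    cx2 = load_complex(out)
    assert [r.key for r in cx2.receptor] == [r.key for r in cx.receptor]
    for a, b in zip(cx.receptor, cx2.receptor):
        assert np.allclose(a.heavy_coords(), b.heavy_coords(), atol=1.5e-3)


def test_altloc_highest_occupancy_wins(tmp_path):
    lines = [
        pdb_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, element="N"),
        pdb_line(2, "CA", "ALA", "A", 1, 1.5, 0.0, 0.0),
        pdb_line(3, "CB", "ALA", "A", 1, 2.0, 1.0, 0.0, occupancy=0.6, alt_loc="A"),
        pdb_line(4, "CB", "ALA", "A", 1, 9.0, 9.0, 9.0, occupancy=0.4, alt_loc="B"),
    ]
    lines += [
        pdb_line(10 + i, f"C{i}", "LIG", "B", 90, 20.0 + i, 0.0, 0.0, het=True)
        for i in range(1, 7)
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    cx = load_complex(path)
    cb = [a for a in cx.receptor[0].atoms if a.name == "CB"]
    assert len(cb) == 1
    assert cb[0].coords == pytest.approx((2.0, 1.0, 0.0))
    assert cb[0].alt_loc == "A"


def test_altloc_tie_breaks_alphabetically(tmp_path):
    lines = [
        pdb_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0),
        pdb_line(2, "O", "HOH", "A", 2, 5.0, 0.0, 0.0, occupancy=0.5, alt_loc="B", element="O"),
    ]
    lines = [
        pdb_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
        pdb_line(2, "CB", "ALA", "A", 1, 1.0, 0.0, 0.0, occupancy=0.5, alt_loc="B"),
        pdb_line(3, "CB", "ALA", "A", 1, 2.0, 0.0, 0.0, occupancy=0.5, alt_loc="A"),
    ] + [
        pdb_line(10 + i, f"C{i}", "LIG", "B", 90, 20.0 + i, 0.0, 0.0, het=True)
        for i in range(1, 7)
    ]
    path = tmp_path / "tie.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    cx = load_complex(path)
    cb = [a for a in cx.receptor[0].atoms if a.name == "CB"]
    assert cb[0].coords == pytest.approx((2.0, 0.0, 0.0))  # conformer A


def test_mse_remapped_to_met(tmp_path):
    lines = [
        pdb_line(1, "CA", "MSE", "A", 1, 0.0, 0.0, 0.0, het=True),
        pdb_line(2, "CA", "ALA", "A", 2, 3.8, 0.0, 0.0),
    ] + [
        pdb_line(10 + i, f"C{i}", "LIG", "B", 90, 20.0 + i, 0.0, 0.0, het=True)
        for i in range(1, 7)
    ]
    path = tmp_path / "mse.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    cx = load_complex(path)
    assert cx.receptor[0].res_name == "MET"
    assert cx.receptor[0].one_letter == "M"


def test_ligand_autodetect_skips_small_decoy(write_fixture, default_spec, tmp_path):
    path, _ = write_fixture(default_spec)
    text = path.read_text().replace("END", "").rstrip()
    decoy = "\n".join(
        pdb_line(9000 + i, f"C{i}", "XYZ", "D", 95, 100.0 + i, 100.0, 100.0, het=True)
        for i in range(1, 4)  # 3 atoms: below the >=6 heavy-atom bar
    )
    path2 = tmp_path / "decoy.pdb"
    path2.write_text(text + "\n" + decoy + "\nEND\n")
    cx = load_complex(path2)
    assert cx.ligand_code == "LIG"


def test_ligand_autodetect_ambiguous_lists_candidates(write_fixture, default_spec, tmp_path):
    path, _ = write_fixture(default_spec)
    text = path.read_text().replace("END", "").rstrip()
    decoy = "\n".join(
        pdb_line(9000 + i, f"C{i}", "XYZ", "D", 95, 100.0 + i, 100.0, 100.0, het=True)
        for i in range(1, 8)  # 7 atoms: a genuine competitor
    )
    path2 = tmp_path / "two_ligands.pdb"
    path2.write_text(text + "\n" + decoy + "\nEND\n")
    with pytest.raises(AmbiguousLigandError) as err:
        load_complex(path2)
    assert sorted(err.value.candidates) == ["LIG", "XYZ"]
    assert load_complex(path2, ligand_code="LIG").ligand_code == "LIG"


@pytest.mark.parametrize(
    "contact,included", [(3.90, True), (4.10, False)], ids=["3.90A", "4.10A"]
)
def test_cutoff_boundary_inclusive(write_fixture, contact, included):
    spec = FixtureSpec(pocket_plan=((3, 10),), contact_distance=contact, seed=5)
    path, truth = write_fixture(spec, name=f"b{contact}")
    cx = load_complex(path)
    site = find_binding_site(cx, BindingSiteSpec(cutoff=4.0))
    key = truth.pocket_keys[0]
    assert (key in site) == included


def test_designated_pocket_recovered_exactly(write_fixture):
    spec = FixtureSpec(pocket_plan=((1, 4), (1, 8), (2, 4), (2, 8)), seed=7)
    path, truth = write_fixture(spec, name="pocket")
    cx = load_complex(path)
    site = find_binding_site(cx, BindingSiteSpec(cutoff=4.0))
    assert tuple(site) == truth.pocket_keys


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_spatial_index_equals_brute_force(write_fixture, seed):
    spec = FixtureSpec(pocket_plan=POCKET_PLAN, seed=seed)
    path, _ = write_fixture(spec, name=f"bf{seed}")
    cx = load_complex(path)
    for cutoff in (3.0, 4.0, 5.5):
        spec_bs = BindingSiteSpec(cutoff=cutoff)
        assert find_binding_site(cx, spec_bs) == brute_force_site(cx, spec_bs)


def test_site_invariant_under_rigid_motion(loaded):
    cx, _, _ = loaded
    rng = np.random.default_rng(3)
    # random proper rotation via QR
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    shift = rng.normal(scale=50.0, size=3)

    def move(atom):
        return dataclasses.replace(
            atom, coords=tuple(q @ np.asarray(atom.coords) + shift)
        )

    moved = structio.LigandComplex(
        source_id=cx.source_id,
        receptor=[
            dataclasses.replace(r, atoms=tuple(move(a) for a in r.atoms))
            for r in cx.receptor
        ],
        ligand_code=cx.ligand_code,
        ligand_atoms=[move(a) for a in cx.ligand_atoms],
    )
    spec = BindingSiteSpec(cutoff=4.0)
    assert find_binding_site(moved, spec) == find_binding_site(cx, spec)


def test_cutoff_monotonicity(loaded):
    cx, _, _ = loaded
    sites = [
        set(find_binding_site(cx, BindingSiteSpec(cutoff=c))) for c in (3.0, 4.0, 5.0)
    ]
    assert sites[0] <= sites[1] <= sites[2]


def test_residue_range_excises_and_empty_range_errors(write_fixture, default_spec):
    path, truth = write_fixture(default_spec)
    tm1 = truth.helix_ranges[0]
    cx = load_complex(path, residue_range=(tm1[1], tm1[2]))
    assert len(cx.receptor) == tm1[2] - tm1[1] + 1
    with pytest.raises(ValidationError):
        load_complex(path, residue_range=(90000, 90010))
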