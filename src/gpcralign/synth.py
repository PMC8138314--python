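"""Synthetic ligand-receptor complex fixtures with known ground truth.

The generator builds an idealized seven-helix bundle - each helix an ideal
alpha-helix (phi = -57, psi = -47, 1.5 A rise per residue) constructed from
standard internal coordinates, axes placed on a circle and alternating in
direction - and a multi-atom "ligand" whose atoms sit at a chosen contact
distance from designated pocket residues and far (>= spacer distance) from
every other residue.  Backbone plus C-beta only: binding-site detection is
distance-based, so C-beta proxies suffice; no rotamer or chemical realism is
attempted.

Alongside the PDB text, :func:`make_complex` returns a :class:`FixtureTruth`
whose helix ranges, pocket keys and per-scheme digit strings are derived
directly from the plan with independent literal lookup tables - never by
running the profiling pipeline - so fixtures double as end-to-end oracles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from ._geometry import place_atom
from .errors import FixtureGeometryError, ValidationError

# one-letter -> three-letter, generator-local on purpose
_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# independent digit oracles: literal residue -> group digit tables, written
# out by hand so truth strings never depend on the profiler module
_DIGIT_8DP = {
    "G": 0, "A": 0, "V": 0, "L": 0, "I": 0, "P": 0, "M": 0, "C": 0,
    "F": 0, "W": 0, "Y": 0,
    "S": 1, "T": 1, "N": 1, "Q": 1,
    "D": 2, "E": 2,
    "K": 3, "R": 3, "H": 3,
}
_DIGIT_10DP = {
    "G": 0, "A": 0, "V": 0, "L": 0, "I": 0, "P": 0, "M": 0, "C": 0,
    "F": 1, "W": 1, "Y": 1,
    "S": 2, "T": 2, "N": 2, "Q": 2,
    "D": 3, "E": 3,
    "K": 4, "R": 4, "H": 4,
}
_FLAG_OFFSET = {"8DP": 4, "10DP": 5}

#: residue swaps that stay inside one 10DP group (hence inside 8DP too)
GROUP_PRESERVING_SWAPS = {
    "D": "E", "E": "D", "F": "W", "W": "F", "K": "R", "R": "K",
    "S": "T", "T": "S", "N": "Q", "Q": "N", "L": "I", "I": "L",
    "V": "A", "A": "V",
}

_SEQ_GAP = 5  # res_seq numbering gap between consecutive helices


@dataclass(frozen=True)
class FixtureSpec:
    """Plan for one synthetic complex."""

    n_helices: int = 7
    helix_length: int = 24
    helix_lengths: tuple[int, ...] | None = None  # overrides helix_length
    sequences: tuple[str, ...] | None = None  # per-helix; random if None
    pocket_plan: tuple[tuple[int, int], ...] = ()  # (helix 1-based, 0-based pos)
    contact_distance: float = 3.5
    spacer_distance: float = 6.0
    bundle_radius: float = 20.0
    seed: int = 0
    chain_id: str = "A"
    ligand_code: str = "LIG"
    geometry: str = "helix"  # "helix" | "strand"

    def lengths(self) -> tuple[int, ...]:
        if self.helix_lengths is not None:
            if len(self.helix_lengths) != self.n_helices:
                raise ValidationError("helix_lengths does not match n_helices")
            return self.helix_lengths
        return (self.helix_length,) * self.n_helices

    def __post_init__(self) -> None:
        if not self.contact_distance < self.spacer_distance:
            raise ValidationError("contact_distance must be < spacer_distance")
        lengths = self.lengths()
        for helix, pos in self.pocket_plan:
            if not 1 <= helix <= self.n_helices:
                raise ValidationError(f"pocket plan helix {helix} out of range")
            if not 0 <= pos < lengths[helix - 1]:
                raise ValidationError(
                    f"pocket position {pos} outside helix {helix} "
                    f"(length {lengths[helix - 1]})"
                )


@dataclass(frozen=True)
class FixtureTruth:
    """Ground truth for one fixture, derivable from the plan alone."""

    helix_ranges: tuple[tuple[str, int, int], ...]
    pocket_keys: tuple[tuple[str, int, str], ...]
    sequences: tuple[str, ...]
    digit_strings: dict[str, tuple[str, ...]]  # scheme -> per-helix strings

    def to_json(self) -> str:
        return json.dumps(
            {
                "helix_ranges": [list(r) for r in self.helix_ranges],
                "pocket_keys": [list(k) for k in self.pocket_keys],
                "sequences": list(self.sequences),
                "digit_strings": {
                    k: list(v) for k, v in self.digit_strings.items()
                },
            },
            indent=2,
        )


# ideal backbone internal coordinates (angstroms / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O, _A_N_CA_CB = (
    111.2, 116.2, 121.7, 120.8, 110.4,
)
_T_CB = -122.6  # C-N-CA-CB improper, L-configuration
HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -120.0, 120.0


def _build_segment(sequence: str, phi: float, psi: float) -> list[dict[str, np.ndarray]]:
    """Backbone + CB coordinates for one segment from internal coordinates."""
    n_res = len(sequence)
    residues: list[dict[str, np.ndarray]] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - _A_N_CA_C)
    c = ca + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i, code in enumerate(sequence):
        atoms = {"N": n, "CA": ca, "C": c}
        if code != "G":
            atoms["CB"] = place_atom(c, n, ca, _B_CA_CB, _A_N_CA_CB, _T_CB)
        residues.append(atoms)
        if i < n_res - 1:
            n_next = place_atom(n, ca, c, _B_C_N, _A_CA_C_N, psi)
            atoms["O"] = place_atom(n, ca, c, _B_C_O, _A_CA_C_O, psi + 180.0)
            ca_next = place_atom(ca, c, n_next, _B_N_CA, _A_C_N_CA, 180.0)
            c_next = place_atom(c, n_next, ca_next, _B_CA_C, _A_N_CA_C, phi)
            n, ca, c = n_next, ca_next, c_next
        else:
            atoms["O"] = place_atom(n, ca, c, _B_C_O, _A_CA_C_O, psi + 180.0)
    return residues


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Proper rotation mapping unit vector `axis` onto +z."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    c = float(np.dot(axis, z))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _place_segment(
    residues: list[dict[str, np.ndarray]], angle: float, radius: float, flip: bool
) -> list[dict[str, np.ndarray]]:
    """Align the segment axis with z, optionally flip it, and translate its
    axis onto the bundle circle."""
    cas = np.array([r["CA"] for r in residues])
    center = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - center)
    axis = vt[0]
    if np.dot(cas[-1] - cas[0], axis) < 0:
        axis = -axis
    rot = _rotation_to_z(axis / np.linalg.norm(axis))
    if flip:
        rot = np.diag([1.0, -1.0, -1.0]) @ rot
    shift = np.array([radius * math.cos(angle), radius * math.sin(angle), 0.0])
    out = []
    for r in residues:
        out.append({k: rot @ (v - center) + shift for k, v in r.items()})
    return out


def _random_sequences(spec: FixtureSpec) -> tuple[str, ...]:
    rng = np.random.default_rng(spec.seed)
    codes = np.array(list(_ONE_TO_THREE))
    return tuple(
        "".join(rng.choice(codes, size=length)) for length in spec.lengths()
    )


def _helix_starts(spec: FixtureSpec) -> list[int]:
    starts, pos = [], 1
    for length in spec.lengths():
        starts.append(pos)
        pos += length + _SEQ_GAP
    return starts


def _resolved_sequences(spec: FixtureSpec) -> tuple[str, ...]:
    """Sequences actually generated: planned pocket residues need a C-beta
    for ligand placement, so random glycines there become alanine (same
    group in both schemes); explicit glycine pocket plans are rejected."""
    pocket_positions = set(spec.pocket_plan)
    if spec.sequences is None:
        return tuple(
            "".join(
                "A" if code == "G" and (h, i) in pocket_positions else code
                for i, code in enumerate(seq)
            )
            for h, seq in enumerate(_random_sequences(spec), start=1)
        )
    for helix, pos in spec.pocket_plan:
        if spec.sequences[helix - 1][pos] == "G":
            raise ValidationError(
                f"glycine at pocket position (helix {helix}, pos {pos}) "
                "has no C-beta to place the ligand contact against"
            )
    return spec.sequences


def make_complex(spec: FixtureSpec) -> tuple[str, FixtureTruth]:
    """Generate one fixture: PDB text plus its ground truth.

    Deterministic for a given spec (same bytes on repeated calls).  Raises
    :class:`FixtureGeometryError` when the pocket plan cannot satisfy the
    contact/spacer distances, verified post hoc by a brute-force scan.
    """
    sequences = _resolved_sequences(spec)
    if len(sequences) != spec.n_helices:
        raise ValidationError("sequences count does not match n_helices")
    for seq, length in zip(sequences, spec.lengths()):
        if len(seq) != length:
            raise ValidationError("sequence length does not match helix length")
        bad = set(seq) - set(_ONE_TO_THREE)
        if bad:
            raise ValidationError(f"unknown residue codes {sorted(bad)}")

    phi, psi = (
        (HELIX_PHI, HELIX_PSI) if spec.geometry == "helix" else (STRAND_PHI, STRAND_PSI)
    )
    placed: list[list[dict[str, np.ndarray]]] = []
    for h, seq in enumerate(sequences):
        segment = _build_segment(seq, phi, psi)
        angle = 2.0 * math.pi * h / max(spec.n_helices, 1)
        placed.append(
            _place_segment(segment, angle, spec.bundle_radius, flip=h % 2 == 1)
        )

    starts = _helix_starts(spec)
    pocket_set = set(spec.pocket_plan)

    # ligand: one contact atom per pocket residue + fillers near the bundle axis
    ligand_atoms: list[np.ndarray] = []
    for helix, pos in sorted(pocket_set):
        atoms = placed[helix - 1][pos]
        angle = 2.0 * math.pi * (helix - 1) / max(spec.n_helices, 1)
        axis_xy = spec.bundle_radius * np.array([math.cos(angle), math.sin(angle)])
        origin = atoms.get("CB", atoms["CA"])
        # radially outward from this helix's own axis, so the contact atom
        # clears the i+/-3, i+/-4 turns of the same helix
        direction = origin - np.array([axis_xy[0], axis_xy[1], origin[2]])
        direction = direction / np.linalg.norm(direction)
        ligand_atoms.append(origin + spec.contact_distance * direction)
    n_fill = max(6 - len(ligand_atoms), 2)
    for k in range(n_fill):
        ligand_atoms.append(np.array([0.0, 0.0, 1.5 * k]))

    # brute-force feasibility check against the plan
    lig = np.array(ligand_atoms)
    for h, residues in enumerate(placed, start=1):
        for pos, atoms in enumerate(residues):
            coords = np.array(list(atoms.values()))
            dmin = float(
                np.min(np.linalg.norm(coords[:, None, :] - lig[None, :, :], axis=2))
            )
            if (h, pos) in pocket_set:
                if dmin > spec.contact_distance + 1e-6:
                    raise FixtureGeometryError(
                        f"pocket residue helix {h} pos {pos} at {dmin:.2f} A "
                        f"> contact {spec.contact_distance}"
                    )
            elif dmin < spec.spacer_distance - 1e-6:
                raise FixtureGeometryError(
                    f"non-pocket residue helix {h} pos {pos} at {dmin:.2f} A "
                    f"< spacer {spec.spacer_distance}"
                )

    # --- emit PDB via gemmi --------------------------------------------------
    structure = gemmi.Structure()
    structure.name = "synthetic"
    model = gemmi.Model(1)
    chain = gemmi.Chain(spec.chain_id)
    for h, (residues, seq) in enumerate(zip(placed, sequences), start=1):
        for pos, (atoms, code) in enumerate(zip(residues, seq)):
            res = gemmi.Residue()
            res.name = _ONE_TO_THREE[code]
            res.seqid = gemmi.SeqId(starts[h - 1] + pos, " ")
            res.het_flag = "A"
            for atom_name in ("N", "CA", "C", "O", "CB"):
                if atom_name not in atoms:
                    continue
                a = gemmi.Atom()
                a.name = atom_name
                a.element = gemmi.Element(atom_name[0])
                a.pos = gemmi.Position(*np.round(atoms[atom_name], 3))
                a.occ = 1.0
                res.add_atom(a)
            chain.add_residue(res)
    model.add_chain(chain)
    lig_chain = gemmi.Chain("L")
    res = gemmi.Residue()
    res.name = spec.ligand_code
    res.seqid = gemmi.SeqId(901, " ")
    res.het_flag = "H"
    for k, pos_vec in enumerate(ligand_atoms, start=1):
        a = gemmi.Atom()
        a.name = f"C{k}"
        a.element = gemmi.Element("C")
        a.pos = gemmi.Position(*np.round(pos_vec, 3))
        a.occ = 1.0
        res.add_atom(a)
    lig_chain.add_residue(res)
    model.add_chain(lig_chain)
    structure.add_model(model)
    structure.setup_entities()
    pdb_text = structure.make_pdb_string()

    # --- independent ground truth -------------------------------------------
    ranges = tuple(
        (spec.chain_id, starts[h], starts[h] + spec.lengths()[h] - 1)
        for h in range(spec.n_helices)
    )
    pocket_keys = tuple(
        (spec.chain_id, starts[helix - 1] + pos, "")
        for helix, pos in sorted(pocket_set)
    )
    digit_strings: dict[str, tuple[str, ...]] = {}
    for scheme, table in (("8DP", _DIGIT_8DP), ("10DP", _DIGIT_10DP)):
        per_helix = []
        for h, seq in enumerate(sequences, start=1):
            digits = [
                table[code] + (_FLAG_OFFSET[scheme] if (h, i) in pocket_set else 0)
                for i, code in enumerate(seq)
            ]
            per_helix.append("".join(str(d) for d in digits))
        digit_strings[scheme] = tuple(per_helix)
    truth = FixtureTruth(
        helix_ranges=ranges,
        pocket_keys=pocket_keys,
        sequences=tuple(sequences),
        digit_strings=digit_strings,
    )
    return pdb_text, truth


def make_pair(
    spec_a: FixtureSpec, relation: str = "identical"
) -> tuple[tuple[str, FixtureTruth], tuple[str, FixtureTruth], dict]:
    """Generate a fixture pair with a known normalized-score relation.

    relation:
        ``identical``      - same complex twice; N = 1 both ways.
        ``pocket_subset``  - second complex keeps the first half of each
            helix's (contiguous) pocket run; under identity scoring and
            pocket scope, N(target=subset) = pocket-size ratio.
        ``group_shuffled`` - residues swapped within their 10DP group;
            digit strings identical, N = 1 both ways.
    """
    if relation == "identical":
        fix = make_complex(spec_a)
        return fix, fix, {"relation": relation, "expected_n": (1.0, 1.0)}

    if relation == "pocket_subset":
        by_helix: dict[int, list[int]] = {}
        for helix, pos in sorted(spec_a.pocket_plan):
            by_helix.setdefault(helix, []).append(pos)
        subset: list[tuple[int, int]] = []
        for helix, positions in by_helix.items():
            if positions != list(range(positions[0], positions[0] + len(positions))):
                raise ValidationError(
                    "pocket_subset requires a contiguous pocket run per helix"
                )
            keep = max(1, len(positions) // 2)
            subset.extend((helix, p) for p in positions[:keep])
        spec_b = replace(spec_a, pocket_plan=tuple(subset))
        ratio = len(subset) / len(spec_a.pocket_plan)
        return (
            make_complex(spec_a),
            make_complex(spec_b),
            {"relation": relation, "expected_n_subset_as_target": ratio},
        )

    if relation == "group_shuffled":
        sequences = _resolved_sequences(spec_a)
        shuffled = tuple(
            "".join(GROUP_PRESERVING_SWAPS.get(c, c) for c in seq)
            for seq in sequences
        )
        spec_b = replace(spec_a, sequences=shuffled)
        spec_a_fixed = replace(spec_a, sequences=tuple(sequences))
        return (
            make_complex(spec_a_fixed),
            make_complex(spec_b),
            {"relation": relation, "expected_n": (1.0, 1.0)},
        )

    raise ValidationError(f"unknown pair relation {relation!r}")
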