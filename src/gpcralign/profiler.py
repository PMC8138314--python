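"""Reduced-alphabet residue profiling.

Each residue is mapped to a small physico-chemical group and encoded as an
integer symbol; symbols of binding-site residues are shifted by a constant
offset so one digit string carries both chemistry and contact information.

Two schemes are provided:

* ``8DP`` - 4 groups: hydrophobic 0, hydrophilic 1, negatively charged 2,
  positively charged 3; binding-site residues add 4 (symbols 4..7).
* ``10DP`` - 5 groups: the hydrophobic group is split into aliphatic 0 and
  aromatic 1 (so pi-stacking contacts are distinguished), then hydrophilic 2,
  negative 3, positive 4; binding-site residues add 5 (symbols 5..9).

The exact group membership is configurable; the defaults below place H with
the positives (protonatable), Y with the aromatics, and C/G with the
aliphatics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ParseError, ValidationError
from .structio import LigandComplex, ResidueKey
from .topology import HelixAnnotation, helix_of

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

_8DP_GROUPS = {
    "hydrophobic": "GAVLIPMCFWY",
    "hydrophilic": "STNQ",
    "negative": "DE",
    "positive": "KRH",
}
_10DP_GROUPS = {
    "aliphatic": "GAVLIPMC",
    "aromatic": "FWY",
    "hydrophilic": "STNQ",
    "negative": "DE",
    "positive": "KRH",
}


@dataclass(frozen=True)
class ProfileScheme:
    """A reduced residue alphabet with a binding-site flag offset."""

    name: str
    group_names: tuple[str, ...]
    groups: dict[str, int]  # 1-letter residue code -> group index

    def __post_init__(self) -> None:
        missing = sorted(set(STANDARD_RESIDUES) - set(self.groups))
        if missing:
            raise ValidationError(f"scheme {self.name}: unmapped residues {missing}")
        indices = set(self.groups.values())
        if indices != set(range(len(self.group_names))):
            raise ValidationError(f"scheme {self.name}: group indices not dense")

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    @property
    def flag_offset(self) -> int:
        return self.n_groups

    @property
    def alphabet_size(self) -> int:
        return 2 * self.n_groups

    def members(self, group_index: int) -> tuple[str, ...]:
        return tuple(
            sorted(code for code, g in self.groups.items() if g == group_index)
        )


def _make_scheme(name: str, group_map: dict[str, str]) -> ProfileScheme:
    groups = {
        code: idx for idx, members in enumerate(group_map.values()) for code in members
    }
    return ProfileScheme(name=name, group_names=tuple(group_map), groups=groups)


SCHEMES: dict[str, ProfileScheme] = {
    "8DP": _make_scheme("8DP", _8DP_GROUPS),
    "10DP": _make_scheme("10DP", _10DP_GROUPS),
}


def get_scheme(name: str) -> ProfileScheme:
    try:
        return SCHEMES[name.upper()]
    except KeyError:
        raise ValidationError(f"unknown scheme {name!r}; use one of {sorted(SCHEMES)}")


def scheme_from_config(name: str, path: str | Path) -> ProfileScheme:
    """Build a scheme from a key-value file mapping residue codes to group
    names, e.g. ``H = hydrophilic`` (one pair per line, ``#`` comments).
    Unlisted residues keep the built-in assignment of scheme ``name``."""
    base = get_scheme(name)
    groups = dict(base.groups)
    by_name = {g: i for i, g in enumerate(base.group_names)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = [p.strip() for p in line.replace("=", " ").split()]
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected '<code> = <group>'")
        code, group = parts[0].upper(), parts[1].lower()
        if group not in by_name:
            raise ParseError(
                f"{path}:{lineno}: unknown group {group!r}; "
                f"valid: {list(by_name)}"
            )
        groups[code] = by_name[group]
    return ProfileScheme(name=base.name, group_names=base.group_names, groups=groups)


def classify_residue(res_code: str, scheme: ProfileScheme, is_binding: bool) -> int:
    """Integer symbol for one residue: group index, plus the scheme's flag
    offset when the residue is part of the binding site."""
    try:
        group = scheme.groups[res_code.upper()]
    except KeyError:
        raise ValidationError(
            f"residue code {res_code!r} has no group in scheme {scheme.name}"
        )
    return group + (scheme.flag_offset if is_binding else 0)


@dataclass(frozen=True)
class HelixProfile:
    """One helix's digit string with a parallel residue back-map."""

    helix_index: int
    symbols: tuple[int, ...]
    residue_keys: tuple[ResidueKey, ...]
    scheme_name: str

    def __post_init__(self) -> None:
        if len(self.symbols) != len(self.residue_keys):
            raise ValidationError("symbols and residue_keys length mismatch")

    def digits(self) -> str:
        return "".join(str(s) for s in self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class ComplexProfile:
    """Seven per-helix digit strings for one ligand-receptor complex."""

    source_id: str
    ligand_code: str
    helices: tuple[HelixProfile, ...]
    pocket_keys: frozenset[ResidueKey]
    scheme_name: str

    def __post_init__(self) -> None:
        if len(self.helices) != 7:
            raise ValidationError(f"expected 7 helices, got {len(self.helices)}")

    def flagged_count(self) -> int:
        scheme = get_scheme(self.scheme_name)
        return sum(
            1 for h in self.helices for s in h.symbols if s >= scheme.flag_offset
        )


def build_profile(
    cx: LigandComplex,
    annotation: HelixAnnotation,
    pocket: list[ResidueKey],
    scheme: ProfileScheme,
) -> ComplexProfile:
    """Encode the receptor into seven per-helix digit strings.

    Residues outside every helix are dropped; pocket residues that fall in a
    loop are recorded but cannot be profiled (a warning is emitted).
    """
    pocket_set = set(pocket)
    unknown = pocket_set - {r.key for r in cx.receptor}
    if unknown:
        raise ValidationError(f"pocket keys not in receptor: {sorted(unknown)}")

    per_helix: dict[int, list[tuple[int, ResidueKey]]] = {k: [] for k in range(1, 8)}
    placed: set[ResidueKey] = set()
    for res in cx.receptor:
        helix = helix_of(annotation, res.key)
        if helix is None:
            continue
        code = res.one_letter
        if code is None:
            raise ValidationError(
                f"{cx.source_id}: residue {res.res_name} {res.key} has no "
                "1-letter code; add it to the scheme config"
            )
        symbol = classify_residue(code, scheme, res.key in pocket_set)
        per_helix[helix].append((symbol, res.key))
        placed.add(res.key)

    dropped = pocket_set - placed
    if dropped:
        warnings.warn(
            f"{cx.source_id}: {len(dropped)} binding-site residues fall outside "
            f"all helices and are not profiled: {sorted(dropped)}",
            stacklevel=2,
        )
    helices = []
    for k in range(1, 8):
        entries = per_helix[k]
        if not entries:
            raise ValidationError(f"{cx.source_id}: helix TM{k} has no residues")
        helices.append(
            HelixProfile(
                helix_index=k,
                symbols=tuple(s for s, _ in entries),
                residue_keys=tuple(key for _, key in entries),
                scheme_name=scheme.name,
            )
        )
    return ComplexProfile(
        source_id=cx.source_id,
        ligand_code=cx.ligand_code,
        helices=tuple(helices),
        pocket_keys=frozenset(pocket_set),
        scheme_name=scheme.name,
    )


def restrict_to_pocket(profile: ComplexProfile) -> ComplexProfile:
    """Profile containing only the flagged (binding-site) positions of each
    helix - the pocket alignment scope."""
    scheme = get_scheme(profile.scheme_name)
    helices = []
    for h in profile.helices:
        pairs = [
            (s, k) for s, k in zip(h.symbols, h.residue_keys) if s >= scheme.flag_offset
        ]
        helices.append(
            HelixProfile(
                helix_index=h.helix_index,
                symbols=tuple(s for s, _ in pairs),
                residue_keys=tuple(k for _, k in pairs),
                scheme_name=h.scheme_name,
            )
        )
    return ComplexProfile(
        source_id=profile.source_id,
        ligand_code=profile.ligand_code,
        helices=tuple(helices),
        pocket_keys=profile.pocket_keys,
        scheme_name=profile.scheme_name,
    )


def unflag(profile: ComplexProfile) -> ComplexProfile:
    """Remove binding-site flags (equivalent to an empty pocket)."""
    scheme = get_scheme(profile.scheme_name)
    helices = tuple(
        HelixProfile(
            helix_index=h.helix_index,
            symbols=tuple(
                s - scheme.flag_offset if s >= scheme.flag_offset else s
                for s in h.symbols
            ),
            residue_keys=h.residue_keys,
            scheme_name=h.scheme_name,
        )
        for h in profile.helices
    )
    return ComplexProfile(
        source_id=profile.source_id,
        ligand_code=profile.ligand_code,
        helices=helices,
        pocket_keys=frozenset(),
        scheme_name=profile.scheme_name,
    )


def render_profile(profile: ComplexProfile, cx: LigandComplex | None = None) -> str:
    """Human-readable text table: one digit line per helix plus a legend of
    the flagged (binding-site) positions.  ``parse_profile`` round-trips the
    digit strings."""
    scheme = get_scheme(profile.scheme_name)
    lines = [
        f"# complex {profile.source_id}  ligand {profile.ligand_code}  "
        f"scheme {profile.scheme_name}"
    ]
    for h in profile.helices:
        lines.append(f"TM{h.helix_index} {h.digits() or '-'}")
    flagged = [
        (h.helix_index, key, s)
        for h in profile.helices
        for s, key in zip(h.symbols, h.residue_keys)
        if s >= scheme.flag_offset
    ]
    if not flagged:
        lines.append("# no binding-site residues")
    else:
        lines.append("# binding-site residues:")
        names = {}
        if cx is not None:
            names = {r.key: r.res_name for r in cx.receptor}
        for helix, key, symbol in flagged:
            chain, seq, icode = key
            label = f"{names.get(key, '')}{seq}{icode}".strip()
            lines.append(f"#   TM{helix} {chain}:{label} -> {symbol}")
    return "\n".join(lines) + "\n"


def parse_profile(text: str) -> dict[int, tuple[int, ...]]:
    """Digit strings per helix index from a rendered profile table."""
    out: dict[int, tuple[int, ...]] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line.startswith("TM"):
            continue
        label, _, digits = line.partition(" ")
        digits = digits.strip()
        out[int(label[2:])] = (
            tuple() if digits == "-" else tuple(int(c) for c in digits)
        )
    return out


def profile_to_json(profile: ComplexProfile) -> str:
    """Machine-readable JSON export of a profile."""
    doc = {
        "source_id": profile.source_id,
        "ligand_code": profile.ligand_code,
        "scheme": profile.scheme_name,
        "helices": [
            {
                "index": h.helix_index,
                "digits": h.digits(),
                "residue_keys": [list(k) for k in h.residue_keys],
            }
            for h in profile.helices
        ],
        "pocket": sorted(list(k) for k in profile.pocket_keys),
    }
    return json.dumps(doc, indent=2)
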