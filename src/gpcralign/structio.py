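"""Reading ligand-receptor complex structures and locating binding-site residues.

A *complex* here is one receptor chain (a seven-transmembrane receptor in the
intended use, but nothing below depends on that) plus one small-molecule
ligand taken from the structure's hetero components.  Parsing of PDB and mmCIF
files is delegated to :mod:`gemmi`; this module reduces a structure to the
minimal record types the profiling pipeline needs and implements the
distance-cutoff definition of the binding site: a receptor residue belongs to
the site when at least one of its (by default heavy) atoms lies within
``cutoff`` angstroms of any ligand atom, boundary inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .errors import AmbiguousLigandError, ParseError, ValidationError

#: residue key: (chain_id, res_seq, insertion_code)
ResidueKey = tuple[str, int, str]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: common chemically modified residues remapped to their parent at parse time
MODIFIED_PARENTS = {
    "MSE": "MET", "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
    "HYP": "PRO", "MLY": "LYS", "M3L": "LYS", "KCX": "LYS", "PCA": "GLU",
    "CME": "CYS", "OCS": "CYS",
}

#: waters, monatomic ions and common crystallization/cryo additives that are
#: never treated as the ligand (user-extensible via `exclude_components`)
EXCLUDED_COMPONENTS = frozenset({
    "HOH", "WAT", "DOD", "NA", "K", "CL", "BR", "IOD", "F", "MG", "CA", "ZN",
    "MN", "FE", "FE2", "CO", "NI", "CU", "CD", "HG", "SO4", "PO4", "NO3",
    "ACT", "FMT", "GOL", "EDO", "PEG", "PGE", "P6G", "1PE", "DMS", "TRS",
    "MES", "EPE", "BME", "MPD", "OLA", "OLB", "OLC", "CLR", "CHS", "PLM",
    "MYR", "BNG", "LMT", "LDA", "UNX", "UNL",
})

#: receptor chains longer than this usually carry a fusion domain (BRIL, T4
#: lysozyme, ...) that the user should excise with `residue_range`
FUSION_WARN_LENGTH = 450


@dataclass(frozen=True)
class AtomRecord:
    """One atom: label, element, Cartesian coordinates in angstroms."""

    name: str
    element: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    is_hetero: bool = False
    alt_loc: str = ""

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass(frozen=True)
class ResidueRecord:
    """One receptor residue with author numbering and its atoms."""

    chain_id: str
    res_seq: int
    insertion_code: str
    res_name: str
    atoms: tuple[AtomRecord, ...]

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.res_seq, self.insertion_code)

    @property
    def one_letter(self) -> str | None:
        return THREE_TO_ONE.get(self.res_name)

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if not a.is_hydrogen], dtype=float)


@dataclass
class LigandComplex:
    """A parsed receptor chain plus one ligand component."""

    source_id: str
    receptor: list[ResidueRecord]
    ligand_code: str
    ligand_atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        if not self.receptor:
            raise ValidationError(f"{self.source_id}: receptor is empty")
        if not self.ligand_atoms:
            raise ValidationError(f"{self.source_id}: ligand has no atoms")
        keys = [r.key for r in self.receptor]
        if len(set(keys)) != len(keys):
            raise ValidationError(f"{self.source_id}: duplicate residue keys")

    def residue(self, key: ResidueKey) -> ResidueRecord:
        for r in self.receptor:
            if r.key == key:
                return r
        raise KeyError(key)

    def sequence(self) -> str:
        return "".join(r.one_letter or "X" for r in self.receptor)


@dataclass(frozen=True)
class BindingSiteSpec:
    """Parameters of the distance-cutoff binding-site definition."""

    cutoff: float = 4.0
    heavy_atoms_only: bool = True
    exclude_waters_ions: bool = True

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValidationError(f"cutoff must be positive, got {self.cutoff}")


def _altloc(atom: gemmi.Atom) -> str:
    # gemmi encodes "no altloc" as the NUL character
    return atom.altloc if atom.altloc not in ("\x00", " ", "") else ""


def _pick_altloc(residue: gemmi.Residue) -> str:
    """Choose the conformer to keep: highest occupancy, ties broken
    alphabetically.  Returns '' when the residue has no alternate locations."""
    occ: dict[str, float] = {}
    for atom in residue:
        loc = _altloc(atom)
        if loc:
            occ.setdefault(loc, 0.0)
            occ[loc] = max(occ[loc], atom.occ)
    if not occ:
        return ""
    return min(occ, key=lambda a: (-occ[a], a))


def _convert_atoms(residue: gemmi.Residue, is_hetero: bool) -> tuple[AtomRecord, ...]:
    chosen = _pick_altloc(residue)
    out = []
    for atom in residue:
        if _altloc(atom) and _altloc(atom) != chosen:
            continue
        element = atom.element.name if atom.element else ""
        out.append(
            AtomRecord(
                name=atom.name,
                element=element,
                coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                occupancy=atom.occ,
                is_hetero=is_hetero,
                alt_loc=_altloc(atom),
            )
        )
    return tuple(out)


def _is_amino_acid(name: str) -> bool:
    return name in THREE_TO_ONE or name in MODIFIED_PARENTS


def _heavy_count(residue: gemmi.Residue) -> int:
    return sum(1 for a in residue if a.element.name not in ("H", "D"))


def load_complex(
    path: str | Path,
    ligand_code: str | None = None,
    chain_id: str | None = None,
    residue_range: tuple[int, int] | None = None,
    exclude_components: frozenset[str] = EXCLUDED_COMPONENTS,
    min_ligand_heavy_atoms: int = 6,
) -> LigandComplex:
    """Parse one structure file into a :class:`LigandComplex`.

    Parameters
    ----------
    path:
        PDB or mmCIF file.  Only the first MODEL is used.
    ligand_code:
        Three-letter chemical component id of the ligand.  When omitted the
        ligand is auto-detected: exactly one non-excluded hetero component
        with at least ``min_ligand_heavy_atoms`` heavy atoms must exist.
    chain_id:
        Receptor chain.  When omitted the chain with the most amino-acid
        residues is selected.
    residue_range:
        Inclusive ``(first, last)`` author res_seq interval; used to excise
        fusion domains from the receptor.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise ParseError(f"{path}: structure contains no models")
    model = structure[0]

    # --- receptor chain selection -------------------------------------------
    def aa_count(chain: gemmi.Chain) -> int:
        return sum(1 for r in chain if _is_amino_acid(r.name))

    if chain_id is None:
        candidates = [(aa_count(c), c.name) for c in model]
        candidates.sort(key=lambda t: (-t[0], t[1]))
        if not candidates or candidates[0][0] == 0:
            raise ParseError(f"{path}: no chain with amino-acid residues")
        chain_id = candidates[0][1]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ParseError(f"{path}: chain {chain_id!r} not found")

    receptor: list[ResidueRecord] = []
    for residue in chain:
        if not _is_amino_acid(residue.name):
            continue
        num = residue.seqid.num
        if residue_range is not None and not residue_range[0] <= num <= residue_range[1]:
            continue
        name = MODIFIED_PARENTS.get(residue.name, residue.name)
        icode = residue.seqid.icode.strip()
        receptor.append(
            ResidueRecord(
                chain_id=chain_id,
                res_seq=num,
                insertion_code=icode,
                res_name=name,
                atoms=_convert_atoms(residue, is_hetero=False),
            )
        )
    if not receptor:
        raise ValidationError(f"{path}: empty receptor after chain/range selection")
    if len(receptor) > FUSION_WARN_LENGTH:
        warnings.warn(
            f"{path}: receptor has {len(receptor)} residues (> {FUSION_WARN_LENGTH}); "
            "a fusion domain may be present - consider residue_range",
            stacklevel=2,
        )

    # --- ligand selection ----------------------------------------------------
    het: list[tuple[str, gemmi.Residue]] = []
    for c in model:
        for residue in c:
            if _is_amino_acid(residue.name) or residue.name in exclude_components:
                continue
            if residue.het_flag != "H" and c.name == chain_id:
                continue  # polymer residue of the receptor chain
            het.append((residue.name, residue))

    if ligand_code is not None:
        matching = [r for name, r in het if name == ligand_code]
        if not matching:
            raise ValidationError(f"{path}: no hetero component {ligand_code!r} found")
    else:
        big = [(name, r) for name, r in het if _heavy_count(r) >= min_ligand_heavy_atoms]
        names = sorted({name for name, _ in big})
        if len(names) != 1:
            raise AmbiguousLigandError(
                f"{path}: ligand auto-detection found {len(names)} candidates "
                f"{names}; pass ligand_code explicitly",
                candidates=names,
            )
        ligand_code = names[0]
        matching = [r for name, r in big if name == ligand_code]

    if len(matching) > 1:
        # several copies of the same component: keep the one closest to the
        # receptor centroid
        centroid = np.mean(
            [a.coords for r in receptor for a in r.atoms if not a.is_hydrogen], axis=0
        )

        def dist(residue: gemmi.Residue) -> float:
            pts = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in residue])
            return float(np.min(np.linalg.norm(pts - centroid, axis=1)))

        matching.sort(key=dist)
    ligand_atoms = list(_convert_atoms(matching[0], is_hetero=True))

    return LigandComplex(
        source_id=path.stem,
        receptor=receptor,
        ligand_code=ligand_code,
        ligand_atoms=ligand_atoms,
    )


def _ligand_coords(cx: LigandComplex, heavy_only: bool) -> np.ndarray:
    pts = [a.coords for a in cx.ligand_atoms if not (heavy_only and a.is_hydrogen)]
    return np.array(pts, dtype=float)


def minimum_distances(cx: LigandComplex, spec: BindingSiteSpec) -> dict[ResidueKey, float]:
    """Per-residue minimum atom-atom distance to the ligand (same atom filter
    as :func:`find_binding_site`)."""
    ligand = _ligand_coords(cx, spec.heavy_atoms_only)
    if ligand.size == 0:
        raise ValidationError("ligand has no atoms after the hydrogen filter")
    tree = cKDTree(ligand)
    out: dict[ResidueKey, float] = {}
    for res in cx.receptor:
        pts = [
            a.coords for a in res.atoms if not (spec.heavy_atoms_only and a.is_hydrogen)
        ]
        if not pts:
            continue
        d, _ = tree.query(np.asarray(pts, dtype=float))
        out[res.key] = float(np.min(d))
    return out


def find_binding_site(cx: LigandComplex, spec: BindingSiteSpec) -> list[ResidueKey]:
    """Receptor residues with >= 1 atom within ``spec.cutoff`` of the ligand.

    The distance test is Euclidean and boundary inclusive (d <= cutoff); the
    returned keys follow receptor sequence order.
    """
    dists = minimum_distances(cx, spec)
    return [res.key for res in cx.receptor if dists.get(res.key, np.inf) <= spec.cutoff]


def write_pocket_report(cx: LigandComplex, spec: BindingSiteSpec, path: str | Path) -> None:
    """Write a TSV of binding-site residues and their minimum ligand distance."""
    dists = minimum_distances(cx, spec)
    site = set(find_binding_site(cx, spec))
    with open(path, "w") as fh:
        fh.write("chain\tres_seq\ticode\tres_name\tmin_distance_A\n")
        for res in cx.receptor:
            if res.key in site:
                fh.write(
                    f"{res.chain_id}\t{res.res_seq}\t{res.insertion_code}\t"
                    f"{res.res_name}\t{dists[res.key]:.3f}\n"
                )


def write_complex(cx: LigandComplex, path: str | Path) -> None:
    """Write the complex back out as a PDB file (receptor ATOM records plus
    the ligand as HETATM records, coordinates at PDB precision)."""
    structure = gemmi.Structure()
    structure.name = cx.source_id
    model = gemmi.Model(1)
    chain = gemmi.Chain(cx.receptor[0].chain_id)

    def make_residue(name: str, num: int, icode: str, het: bool) -> gemmi.Residue:
        res = gemmi.Residue()
        res.name = name
        res.seqid = gemmi.SeqId(num, icode or " ")
        res.het_flag = "H" if het else "A"
        return res

    for rec in cx.receptor:
        res = make_residue(rec.res_name, rec.res_seq, rec.insertion_code, het=False)
        for atom in rec.atoms:
            a = gemmi.Atom()
            a.name = atom.name
            a.element = gemmi.Element(atom.element)
            a.pos = gemmi.Position(*atom.coords)
            a.occ = atom.occupancy
            res.add_atom(a)
        chain.add_residue(res)
    model.add_chain(chain)

    lig_chain_id = "Z" if cx.receptor[0].chain_id != "Z" else "Y"
    lig_chain = gemmi.Chain(lig_chain_id)
    res = make_residue(cx.ligand_code, 9001, "", het=True)
    for atom in cx.ligand_atoms:
        a = gemmi.Atom()
        a.name = atom.name
        a.element = gemmi.Element(atom.element)
        a.pos = gemmi.Position(*atom.coords)
        a.occ = atom.occupancy
        res.add_atom(a)
    lig_chain.add_residue(res)
    model.add_chain(lig_chain)

    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))
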