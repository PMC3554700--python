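"""Molecular structures as ordered atom lists, with PDB I/O (via gemmi),
van der Waals radius assignment and a small atom-selection language.

The clash analysis works on heavy atoms of crystal or docked structures, which
usually lack hydrogens; the STD-NMR module instead requires explicit hydrogens.
Radii default to the Bondi set (C 1.70 Å, N 1.55, O 1.52, S 1.80, H 1.20 Å);
the 4π·1.70² = 36.3 Å² surface of a carbon sphere is the normalization anchor
used by the clash score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

#: Bondi (1964) van der Waals radii, Å
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

#: surface area of one carbon-sized sphere, the clash-score normalization (Å²)
CARBON_SURFACE_AREA = 4.0 * math.pi * BONDI_RADII["C"] ** 2


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    chain: str
    residue_number: int
    coords: np.ndarray
    vdw_radius: float | None = None
    occupancy: float = 1.0
    #: free-form role tags, e.g. segment="branch", node_id=2
    tags: dict = field(default_factory=dict)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy(), tags=dict(self.tags))


class StructureModel:
    """An ordered list of atoms plus provenance metadata."""

    def __init__(self, atoms: list[Atom] | None = None, metadata: dict | None = None):
        self.atoms: list[Atom] = atoms or []
        self.metadata: dict = metadata or {}

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self.atoms])

    def set_positions(self, pos: np.ndarray) -> None:
        for atom, xyz in zip(self.atoms, np.asarray(pos, float)):
            atom.coords = xyz.copy()

    def copy(self) -> "StructureModel":
        return StructureModel([a.copy() for a in self.atoms], dict(self.metadata))

    def renumber(self) -> None:
        for i, atom in enumerate(self.atoms, start=1):
            atom.serial = i

    # -- queries ------------------------------------------------------------

    def heavy(self) -> "StructureModel":
        return StructureModel([a for a in self.atoms if not a.is_hydrogen], dict(self.metadata))

    def residues(self) -> list[tuple[tuple[str, int, str], list[Atom]]]:
        """Atoms grouped by (chain, residue number, residue name), file order."""
        groups: list[tuple[tuple[str, int, str], list[Atom]]] = []
        for atom in self.atoms:
            key = (atom.chain, atom.residue_number, atom.residue_name)
            if groups and groups[-1][0] == key:
                groups[-1][1].append(atom)
            else:
                groups.append((key, [atom]))
        return groups

    def find_atom(self, name: str, residue_number: int | None = None) -> Atom:
        for atom in self.atoms:
            if atom.name == name and (
                residue_number is None or atom.residue_number == residue_number
            ):
                return atom
        raise KeyError(f"atom {name!r} (residue {residue_number}) not found")


class SelectionError(ValueError):
    pass


def select_atoms(model: StructureModel, expression: str) -> StructureModel:
    """Select a subset of atoms, preserving order.

    The expression is a whitespace-joined conjunction of clauses:

    ``chain A``, ``resname HOH,TFD``, ``resnum 5`` or ``resnum 5-20``,
    ``name C1,O5``, ``element C``, ``heavy``, ``hydrogen``, ``all``,
    and any clause may be prefixed with ``not``.
    """
    tokens = expression.split()
    if not tokens:
        raise SelectionError("empty selection expression")
    predicates = []
    i = 0
    while i < len(tokens):
        negate = False
        if tokens[i] == "not":
            negate = True
            i += 1
            if i >= len(tokens):
                raise SelectionError("dangling 'not'")
        word = tokens[i]
        if word == "and":
            i += 1
            continue
        if word in ("heavy", "hydrogen", "all"):
            pred = {
                "heavy": lambda a: not a.is_hydrogen,
                "hydrogen": lambda a: a.is_hydrogen,
                "all": lambda a: True,
            }[word]
            i += 1
        elif word in ("chain", "resname", "resnum", "name", "element"):
            if i + 1 >= len(tokens):
                raise SelectionError(f"selection keyword {word!r} needs a value")
            value = tokens[i + 1]
            pred = _field_predicate(word, value)
            i += 2
        else:
            raise SelectionError(f"unknown selection token {word!r}")
        predicates.append((lambda a, p=pred: not p(a)) if negate else pred)
    atoms = [a for a in model.atoms if all(p(a) for p in predicates)]
    return StructureModel(atoms, dict(model.metadata))


def _field_predicate(key: str, value: str):
    if key == "resnum":
        if "-" in value.lstrip("-")[:]:
            try:
                lo, hi = value.split("-", 1)
                lo_i, hi_i = int(lo), int(hi)
            except ValueError as exc:
                raise SelectionError(f"bad resnum range {value!r}") from exc
            return lambda a: lo_i <= a.residue_number <= hi_i
        try:
            num = int(value)
        except ValueError as exc:
            raise SelectionError(f"bad resnum {value!r}") from exc
        return lambda a: a.residue_number == num
    values = {v.upper() for v in value.split(",")}
    getter = {
        "chain": lambda a: a.chain.upper(),
        "resname": lambda a: a.residue_name.upper(),
        "name": lambda a: a.name.upper(),
        "element": lambda a: a.element.upper(),
    }[key]
    return lambda a: getter(a) in values


# ---------------------------------------------------------------------------
# radii


def assign_vdw_radii(
    model: StructureModel, table: dict[str, float] | None = None
) -> StructureModel:
    """Attach a van der Waals radius to every atom (in place; returns model).

    Unknown elements raise rather than silently defaulting.  Idempotent.
    """
    table = {k.upper(): v for k, v in (table or BONDI_RADII).items()}
    for atom in model.atoms:
        key = atom.element.upper()
        if key not in table:
            raise KeyError(
                f"no van der Waals radius for element {atom.element!r} "
                f"(atom {atom.serial} {atom.name})"
            )
        atom.vdw_radius = table[key]
    return model


# ---------------------------------------------------------------------------
# PDB I/O


def read_pdb(path) -> StructureModel:
    """Read ATOM/HETATM records from a PDB file.

    Alternate locations are resolved by keeping the highest-occupancy
    conformer.  Waters are retained (drop them with
    ``select_atoms(model, "not resname HOH")``).
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, OSError, ValueError) as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    models = list(st)
    if not models:
        raise IOError(f"no models in PDB file {path}")
    model = _convert_gemmi_model(models[0], title=st.name)
    if not model.atoms:
        raise IOError(f"no atoms in PDB file {path}")
    return model


def read_pdb_models(path) -> list[StructureModel]:
    """Read every MODEL of a multi-model PDB file."""
    st = gemmi.read_pdb(str(path))
    out = [_convert_gemmi_model(m, title=st.name) for m in st]
    if not out or not any(len(m) for m in out):
        raise IOError(f"no atoms in PDB file {path}")
    return out


def _convert_gemmi_model(gmodel, title: str = "") -> StructureModel:
    atoms: list[Atom] = []
    serial = 0
    for chain in gmodel:
        for residue in chain:
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for gatom in residue:
                if gatom.name not in best:
                    order.append(gatom.name)
                    best[gatom.name] = gatom
                elif gatom.occ > best[gatom.name].occ:
                    best[gatom.name] = gatom
            for name in order:
                gatom = best[name]
                serial += 1
                atoms.append(
                    Atom(
                        serial=serial,
                        name=gatom.name,
                        element=gatom.element.name,
                        residue_name=residue.name,
                        chain=chain.name,
                        residue_number=residue.seqid.num,
                        coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                        occupancy=gatom.occ,
                    )
                )
    return StructureModel(atoms, {"title": title})


def _to_gemmi_structure(models: list[StructureModel], name: str = "glycograft") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    for i, model in enumerate(models, start=1):
        gmodel = gemmi.Model(i)
        for (chain_name, resnum, resname), res_atoms in model.residues():
            chain = None
            for existing in gmodel:
                if existing.name == chain_name:
                    chain = existing
                    break
            if chain is None:
                gmodel.add_chain(gemmi.Chain(chain_name or "A"))
                chain = gmodel[-1]
            residue = gemmi.Residue()
            residue.name = resname
            residue.seqid = gemmi.SeqId(resnum, " ")
            residue.het_flag = "H"
            for atom in res_atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(*atom.coords)
                gatom.occ = atom.occupancy
                residue.add_atom(gatom)
            chain.add_residue(residue)
        st.add_model(gmodel)
    return st


def write_pdb(model: StructureModel | list[StructureModel], path, remarks: list[str] | None = None) -> None:
    """Write one model, or a list of models as a multi-MODEL PDB file."""
    models = model if isinstance(model, list) else [model]
    st = _to_gemmi_structure(models)
    st.setup_entities()
    doc = st.make_pdb_string()
    if remarks:
        header = "".join(f"REMARK 250 {r}\n" for r in remarks)
        doc = header + doc
    with open(path, "w") as fh:
        fh.write(doc)
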