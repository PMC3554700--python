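"""Idealized monosaccharide residue templates.

Each template is a pyranose ring in an idealized chair (ring bond lengths
≈1.53 Å), with every exocyclic group placed axially or equatorially according
to the residue's stereochemistry, hydrogens included.  D-aldohexoses are built
in the 4C1 chair; L-fucose is obtained by mirroring a 6-deoxy-galactose
template (giving the 1C4 chair of an L-sugar); the ulosonic acids Neu5Ac,
Neu5Gc and KDN carry their anomeric center at C2 with a carboxyl group and a
three-carbon glycerol tail.

Templates use PDB-style atom names (C1..C6, O2..O6, H1..., N2/C7/O7/C8 for the
2-acetamido group, C1/O1A/O1B/N5/C10/O10/C11 for sialic acids) so grafting can
establish atom-name correspondence with carbohydrate residues in deposited or
docked structures.
"""

from __future__ import annotations

import functools

import numpy as np

from ._geometry import place_atom
from .structure import Atom, StructureModel

#: IUPAC residue code -> PDB residue code used in output files
PDB_RESIDUE_CODES = {
    "Gal": "GAL",
    "Glc": "GLC",
    "Man": "MAN",
    "GalNAc": "NGA",
    "GlcNAc": "NAG",
    "ManNAc": "BM3",
    "Fuc": "FUC",
    "Xyl": "XYL",
    "GlcA": "GCU",
    "IdoA": "IDS",
    "Neu5Ac": "SIA",
    "Neu5Gc": "NGC",
    "KDN": "KDN",
}

# bond lengths (Å) and angles (deg) for idealized placement
CC = 1.53
CO = 1.43
CH = 1.09
OH = 0.96
CN = 1.45
TET = 109.47

_RING_RADIUS = 1.45
_RING_PUCKER = 0.25


class TemplateError(KeyError):
    pass


def _ring_coordinates() -> np.ndarray:
    """Six ring vertices of an ideal chair, alternating above/below the plane."""
    coords = []
    for i in range(6):
        theta = np.radians(60.0 * i)
        z = _RING_PUCKER * (1 if i % 2 == 0 else -1)
        coords.append([_RING_RADIUS * np.cos(theta), _RING_RADIUS * np.sin(theta), z])
    return np.array(coords)


def _exocyclic_directions(ring: np.ndarray, i: int) -> tuple[np.ndarray, np.ndarray]:
    """(axial, equatorial) unit vectors at ring vertex i."""
    c = ring[i]
    e1 = ring[(i - 1) % 6] - c
    e2 = ring[(i + 1) % 6] - c
    e1 /= np.linalg.norm(e1)
    e2 /= np.linalg.norm(e2)
    bisector = -(e1 + e2)
    bisector /= np.linalg.norm(bisector)
    normal = np.cross(e1, e2)
    normal /= np.linalg.norm(normal)
    half = np.radians(TET / 2.0)
    d1 = bisector * np.cos(half) + normal * np.sin(half)
    d2 = bisector * np.cos(half) - normal * np.sin(half)
    # axial is the direction more nearly parallel to the ring axis (z)
    if abs(d1[2]) >= abs(d2[2]):
        return d1, d2
    return d2, d1


class _TemplateBuilder:
    def __init__(self, residue_name: str):
        self.residue_name = residue_name
        self.atoms: list[Atom] = []
        self._index: dict[str, int] = {}

    def add(self, name: str, element: str, coords) -> None:
        self._index[name] = len(self.atoms)
        self.atoms.append(
            Atom(
                serial=len(self.atoms) + 1,
                name=name,
                element=element,
                residue_name=PDB_RESIDUE_CODES.get(self.residue_name, "UNK"),
                chain="X",
                residue_number=1,
                coords=np.asarray(coords, float),
            )
        )

    def pos(self, name: str) -> np.ndarray:
        return self.atoms[self._index[name]].coords

    def place(self, name, element, ref_a, ref_b, ref_c, bond, ang, dih) -> None:
        self.add(
            name,
            element,
            place_atom(self.pos(ref_a), self.pos(ref_b), self.pos(ref_c), bond, ang, dih),
        )

    def hydroxyl(self, carbon: str, direction: np.ndarray, pos: int, prev_ref: str) -> None:
        oname, hname = f"O{pos}", f"HO{pos}"
        self.add(oname, "O", self.pos(carbon) + direction * CO)
        self.place(hname, "H", prev_ref, carbon, oname, OH, 107.0, 180.0)

    def model(self) -> StructureModel:
        return StructureModel([a.copy() for a in self.atoms], {"template": self.residue_name})


#: oxygen/nitrogen orientation at C2/C3/C4 per residue ("ax" or "eq"); C6 group is
#: always equatorial in the 4C1 D-chair; O1 orientation follows the anomer.
_ALDOSE_STEREO = {
    "Glc": {"2": "eq", "3": "eq", "4": "eq"},
    "Gal": {"2": "eq", "3": "eq", "4": "ax"},
    "Man": {"2": "ax", "3": "eq", "4": "eq"},
    "GlcNAc": {"2": "eq", "3": "eq", "4": "eq"},
    "GalNAc": {"2": "eq", "3": "eq", "4": "ax"},
    "Fuc6d": {"2": "eq", "3": "eq", "4": "ax"},  # 6-deoxy-Gal skeleton, mirrored to L
    "Xyl": {"2": "eq", "3": "eq", "4": "eq"},
}

_ACETAMIDO = {"GlcNAc", "GalNAc", "ManNAc"}


def _build_aldose(residue: str, anomer: str) -> StructureModel:
    skeleton = "Fuc6d" if residue == "Fuc" else residue
    stereo = _ALDOSE_STEREO.get(skeleton, _ALDOSE_STEREO["Glc"])
    ring = _ring_coordinates()
    names = ["O5", "C1", "C2", "C3", "C4", "C5"]
    b = _TemplateBuilder(residue)
    for name, xyz in zip(names, ring):
        b.add(name, name[0], xyz)

    # C1: anomeric.  α-D: O1 axial; β-D: O1 equatorial.
    ax, eq = _exocyclic_directions(ring, 1)
    o1_dir, h1_dir = (ax, eq) if anomer == "α" else (eq, ax)
    b.add("O1", "O", ring[1] + o1_dir * CO)
    b.add("H1", "H", ring[1] + h1_dir * CH)
    b.place("HO1", "H", "C2", "C1", "O1", OH, 107.0, 180.0)

    # C2, C3, C4 hydroxyls (or 2-acetamido); ring index of Cn is n
    for pos in (2, 3, 4):
        ax, eq = _exocyclic_directions(ring, pos)
        o_dir, h_dir = (ax, eq) if stereo[str(pos)] == "ax" else (eq, ax)
        carbon = f"C{pos}"
        b.add(f"H{pos}", "H", ring[pos] + h_dir * CH)
        if pos == 2 and residue in _ACETAMIDO:
            b.add("N2", "N", ring[2] + o_dir * CN)
            b.place("C7", "C", "C1", "C2", "N2", 1.33, 122.0, -120.0)
            b.place("HN2", "H", "C1", "C2", "N2", 1.01, 118.0, 60.0)
            b.place("O7", "O", "C2", "N2", "C7", 1.23, 123.0, 0.0)
            b.place("C8", "C", "C2", "N2", "C7", 1.50, 116.0, 180.0)
            for k, dih in zip((1, 2, 3), (60.0, 180.0, -60.0)):
                b.place(f"H8{k}", "H", "N2", "C7", "C8", CH, TET, dih)
        else:
            b.hydroxyl(carbon, o_dir, pos, f"C{pos - 1}")

    # C5 substituents: H5 axial, C6 (or methyl for 6-deoxy) equatorial
    ax, eq = _exocyclic_directions(ring, 5)
    b.add("H5", "H", ring[5] + ax * CH)
    b.add("C6", "C", ring[5] + eq * CC)
    if residue == "Fuc":
        for k, dih in zip((1, 2, 3), (60.0, 180.0, -60.0)):
            b.place(f"H6{k}", "H", "O5", "C5", "C6", CH, TET, dih)
    elif residue == "Xyl":
        raise TemplateError("Xyl has no C6; use a dedicated pentose template")
    else:
        # default ω (O6-C6-C5-O5) = -60°; rotamer assignment overrides at build time
        b.place("O6", "O", "O5", "C5", "C6", CO, TET, -60.0)
        b.place("H61", "H", "O5", "C5", "C6", CH, TET, 60.0)
        b.place("H62", "H", "O5", "C5", "C6", CH, TET, 180.0)
        b.place("HO6", "H", "C5", "C6", "O6", OH, 107.0, 180.0)

    model = b.model()
    if residue == "Fuc":
        # mirror the D-skeleton to obtain the L-sugar (α-L-fucose 1C4 chair)
        for atom in model.atoms:
            atom.coords = atom.coords * np.array([-1.0, 1.0, 1.0])
    return model


def _build_ulosonic(residue: str, anomer: str) -> StructureModel:
    """Neu5Ac / Neu5Gc / KDN: ring O6-C2-C3-C4-C5-C6, anomeric C2."""
    ring = _ring_coordinates()
    names = ["O6", "C2", "C3", "C4", "C5", "C6"]
    b = _TemplateBuilder(residue)
    for name, xyz in zip(names, ring):
        b.add(name, name[0], xyz)

    # C2: glycosidic O2 axial for α (carboxyl equatorial); swapped for β
    ax, eq = _exocyclic_directions(ring, 1)
    o2_dir, c1_dir = (ax, eq) if anomer == "α" else (eq, ax)
    b.add("O2", "O", ring[1] + o2_dir * CO)
    b.add("C1", "C", ring[1] + c1_dir * CC)
    b.place("HO2", "H", "C3", "C2", "O2", OH, 107.0, 180.0)
    b.place("O1A", "O", "O6", "C2", "C1", 1.25, 118.0, 0.0)
    b.place("O1B", "O", "O6", "C2", "C1", 1.25, 118.0, 180.0)

    # C3: deoxy position, two hydrogens
    ax, eq = _exocyclic_directions(ring, 2)
    b.add("H31", "H", ring[2] + ax * CH)
    b.add("H32", "H", ring[2] + eq * CH)

    # C4: equatorial hydroxyl
    ax, eq = _exocyclic_directions(ring, 3)
    b.add("H4", "H", ring[3] + ax * CH)
    b.hydroxyl("C4", eq, 4, "C3")

    # C5: N-acetyl (Neu5Ac/Neu5Gc) or hydroxyl (KDN), equatorial
    ax, eq = _exocyclic_directions(ring, 4)
    b.add("H5", "H", ring[4] + ax * CH)
    if residue == "KDN":
        b.hydroxyl("C5", eq, 5, "C4")
    else:
        b.add("N5", "N", ring[4] + eq * CN)
        b.place("C10", "C", "C4", "C5", "N5", 1.33, 122.0, -120.0)
        b.place("HN5", "H", "C4", "C5", "N5", 1.01, 118.0, 60.0)
        b.place("O10", "O", "C5", "N5", "C10", 1.23, 123.0, 0.0)
        b.place("C11", "C", "C5", "N5", "C10", 1.50, 116.0, 180.0)
        for k, dih in zip((1, 2, 3), (60.0, 180.0, -60.0)):
            b.place(f"H1{k}A", "H", "N5", "C10", "C11", CH, TET, dih)
        if residue == "Neu5Gc":
            # glycolyl: hydroxyl on the methyl carbon
            b.place("O11", "O", "N5", "C10", "C11", CO, TET, 60.0)

    # C6: H axial, glycerol tail C7-C8-C9 equatorial, extended
    ax, eq = _exocyclic_directions(ring, 5)
    b.add("H6", "H", ring[5] + ax * CH)
    b.add("C7", "C", ring[5] + eq * CC)
    b.place("O7", "O", "O6", "C6", "C7", CO, TET, 60.0)
    b.place("H7", "H", "O6", "C6", "C7", CH, TET, -60.0)
    b.place("HO7", "H", "C6", "C7", "O7", OH, 107.0, 180.0)
    b.place("C8", "C", "O6", "C6", "C7", CC, TET, 180.0)
    b.place("O8", "O", "C6", "C7", "C8", CO, TET, 60.0)
    b.place("H8", "H", "C6", "C7", "C8", CH, TET, -60.0)
    b.place("HO8", "H", "C7", "C8", "O8", OH, 107.0, 180.0)
    b.place("C9", "C", "C6", "C7", "C8", CC, TET, 180.0)
    b.place("O9", "O", "C7", "C8", "C9", CO, TET, 180.0)
    b.place("H91", "H", "C7", "C8", "C9", CH, TET, 60.0)
    b.place("H92", "H", "C7", "C8", "C9", CH, TET, -60.0)
    b.place("HO9", "H", "C8", "C9", "O9", OH, 107.0, 180.0)
    return b.model()


_ULOSONIC = {"Neu5Ac", "Neu5Gc", "KDN"}


@functools.lru_cache(maxsize=None)
def get_template(residue: str, anomer: str) -> StructureModel:
    """Template for ``residue`` with the given anomeric configuration (α or β).

    Returned models are cached; callers receive a fresh copy.
    """
    if anomer not in ("α", "β"):
        raise TemplateError(f"anomer must be α or β, got {anomer!r}")
    if residue in _ULOSONIC:
        return _build_ulosonic(residue, anomer)
    if residue in _ALDOSE_STEREO or residue in _ACETAMIDO or residue == "Fuc":
        return _build_aldose(residue, anomer)
    raise TemplateError(f"no template for residue {residue!r}")


def template_copy(residue: str, anomer: str) -> StructureModel:
    return get_template(residue, anomer).copy()


def anomeric_atoms(residue: str) -> dict[str, str]:
    """Names of the anomeric-center atoms used when forming a glycosidic bond.

    ``phi_ref`` is the fourth atom of the φ dihedral: the anomeric hydrogen for
    aldoses (φ = H1-C1-O-Cx) and the carboxyl carbon for the sialic-type acids
    (φ = C1-C2-O-Cx).
    """
    if residue in _ULOSONIC:
        return {"C": "C2", "O": "O2", "HO": "HO2", "phi_ref": "C1"}
    return {"C": "C1", "O": "O1", "HO": "HO1", "phi_ref": "H1"}


def ring_atom_names(residue: str) -> list[str]:
    """Ring heavy atoms used for determinant superposition."""
    if residue in _ULOSONIC:
        return ["O6", "C2", "C3", "C4", "C5", "C6"]
    return ["O5", "C1", "C2", "C3", "C4", "C5"]


def attachment_atoms(residue: str, position: int) -> dict[str, str]:
    """Parent-side atom names for a linkage at ``position``.

    ``O`` is the oxygen that becomes glycosidic, ``C`` the ring (or exocyclic)
    carbon bearing it, ``psi_ref`` the fourth atom of the ψ dihedral and ``HO``
    the hydroxyl proton removed on linkage formation.
    """
    if residue in _ULOSONIC:
        valid = {4: "C3", 8: "C7", 9: "C8"}
        if position not in valid:
            raise TemplateError(f"{residue} cannot accept a linkage at position {position}")
        return {
            "O": f"O{position}",
            "C": f"C{position}",
            "psi_ref": f"H{position}" if position != 9 else "H91",
            "HO": f"HO{position}",
        }
    if position == 6:
        if residue == "Fuc":
            raise TemplateError("Fuc is 6-deoxy; no 6-linkage possible")
        return {"O": "O6", "C": "C6", "psi_ref": "C5", "HO": "HO6"}
    if position in (2, 3, 4):
        return {"O": f"O{position}", "C": f"C{position}", "psi_ref": f"H{position}", "HO": f"HO{position}"}
    raise TemplateError(f"{residue} cannot accept a linkage at position {position}")
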