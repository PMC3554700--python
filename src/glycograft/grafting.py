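"""Graft library-glycan branches onto a bound minimal determinant.

The library glycan is built in full from templates, its determinant ring heavy
atoms are least-squares superposed (Kabsch) onto the bound determinant in the
complex, and everything that is *not* the determinant core — extra residues,
substituents such as sulfate, and the aglycon — is carried along by the same
rigid transform and spliced into the complex.  The experimentally validated
bound pose always wins: protein and determinant coordinates are bitwise
unchanged in the grafted model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .builder import build_glycan_3d, LinkageGeometry
from .glycans import (
    ALPHA,
    UNDEFINED,
    GlycanTree,
    MotifMatch,
    RotamerAssignment,
    enumerate_rotamer_assignments,
    find_motif,
)
from .structure import Atom, StructureModel, select_atoms
from .templates import PDB_RESIDUE_CODES, ring_atom_names


class GraftError(ValueError):
    pass


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray):
    """Optimal rigid superposition of paired point sets (Kabsch, via SVD).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation ≈ target``; the rotation is proper
    (det = +1).  Requires n ≥ 3 non-degenerate points.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GraftError("mobile and target must be matched (n, 3) arrays")
    if len(P) < 3:
        raise GraftError("superposition needs at least 3 paired atoms")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1.0):
        raise GraftError("degenerate (rank-deficient) point configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


@dataclass
class GraftedModel:
    """A complex with grafted branch atoms and provenance."""

    protein: StructureModel
    determinant: StructureModel
    branch: StructureModel
    glycan_id: str
    rotamer_label: str
    alignment_rmsd: float

    def combined(self) -> StructureModel:
        model = StructureModel(
            [a.copy() for a in self.protein.atoms]
            + [a.copy() for a in self.determinant.atoms]
            + [a.copy() for a in self.branch.atoms],
            {
                "glycan": self.glycan_id,
                "rotamer": self.rotamer_label,
                "rmsd": self.alignment_rmsd,
            },
        )
        model.renumber()
        return model


#: reverse map: PDB residue code -> IUPAC residue code
_IUPAC_FROM_PDB = {v: k for k, v in PDB_RESIDUE_CODES.items()}


def _bound_ring_coordinates(determinant: StructureModel, motif: GlycanTree):
    """Ring heavy atoms of the bound determinant, residue by residue, in the
    motif's pre-order residue order (root first)."""
    residues = determinant.residues()
    motif_nodes = motif.nodes()
    if len(residues) != len(motif_nodes):
        raise GraftError(
            f"bound determinant has {len(residues)} residues; motif has {len(motif_nodes)}"
        )
    # map motif residues onto bound residues by residue code; the bound
    # determinant's file order must correspond to the motif pre-order (root
    # first) or its reverse — both are accepted.
    orders = [residues, residues[::-1]]
    for order in orders:
        names_ok = all(
            _IUPAC_FROM_PDB.get(key[2], key[2]) == node.residue_name
            for key, node in zip([k for k, _ in order], motif_nodes)
        )
        if names_ok:
            coords, atoms = [], []
            for (key, res_atoms), node in zip(order, motif_nodes):
                lookup = {a.name: a for a in res_atoms}
                for name in ring_atom_names(node.residue_name):
                    if name not in lookup:
                        raise GraftError(
                            f"bound determinant residue {key} lacks ring atom {name}"
                        )
                    atoms.append(lookup[name])
                    coords.append(lookup[name].coords)
            return np.array(coords)
    raise GraftError(
        "cannot establish residue correspondence between bound determinant "
        f"({[k[2] for k, _ in residues]}) and motif"
    )


def _substitute_alpha_root(tree: GlycanTree) -> GlycanTree:
    if tree.root.anomeric_config == UNDEFINED:
        tree.root.anomeric_config = ALPHA
    return tree


def graft(
    complex_model: StructureModel,
    determinant_selection: str,
    glycan: GlycanTree,
    assignment: RotamerAssignment,
    motif: GlycanTree | None = None,
    geometry: LinkageGeometry | None = None,
    rmsd_gate: float = 0.8,
    aglycon: str = "methyl",
    match_index: int = 0,
) -> GraftedModel:
    """Graft one rotamer of ``glycan`` onto the bound determinant.

    ``determinant_selection`` picks the bound ligand out of the complex;
    ``motif`` defaults to the TF disaccharide with an α root.  Glycans whose
    determinant occurs internally keep their reducing-end chain as one more
    branch.  A methyl aglycon is supplied when the glycan has none, matching
    the methyl-glycoside convention of the screen.
    """
    import copy

    from .glycans import tf_motif

    motif = motif or tf_motif()
    work = copy.deepcopy(glycan)
    _substitute_alpha_root(work)
    if work.aglycon is None:
        work.aglycon = aglycon
    matches = find_motif(work, motif)
    if not matches:
        raise GraftError(f"glycan {work.source_id or to_text(work)!r} does not contain the determinant")
    match = matches[min(match_index, len(matches) - 1)]

    determinant = select_atoms(complex_model, determinant_selection)
    if not determinant.atoms:
        raise GraftError(f"determinant selection {determinant_selection!r} selects no atoms")
    det_serials = {a.serial for a in determinant.atoms}
    protein = StructureModel(
        [a for a in complex_model.atoms if a.serial not in det_serials],
        dict(complex_model.metadata),
    )

    built = build_glycan_3d(work, assignment, geometry)
    target = _bound_ring_coordinates(determinant, motif)

    node_index = {id(n): i for i, n in enumerate(work.nodes())}
    det_ids = {node_index[id(n)] for n in match.matched_nodes}
    # ring atoms must be gathered in the same residue order as the target;
    # match.matched_nodes is in motif pre-order already
    mobile_atoms = []
    for n in match.matched_nodes:
        nid = node_index[id(n)]
        for name in ring_atom_names(n.residue_name):
            mobile_atoms.append(
                next(
                    a
                    for a in built.atoms
                    if a.tags.get("node_id") == nid and a.name == name
                )
            )
    mobile = np.array([a.coords for a in mobile_atoms])
    R, t, rmsd = kabsch_superpose(mobile, target)
    if rmsd > rmsd_gate:
        raise GraftError(
            f"determinant alignment RMSD {rmsd:.3f} Å exceeds gate {rmsd_gate} Å"
        )

    branch_atoms = []
    for a in built.atoms:
        nid = a.tags.get("node_id")
        is_core = nid in det_ids and a.tags.get("segment") not in ("aglycon", "substituent")
        if not is_core:
            b = a.copy()
            b.coords = R @ a.coords + t
            if b.tags.get("segment") not in ("aglycon", "substituent"):
                b.tags["segment"] = "branch"
            branch_atoms.append(b)
    for a in protein.atoms:
        a.tags.setdefault("segment", "protein")
    for a in determinant.atoms:
        a.tags["segment"] = "determinant"
    branch = StructureModel(branch_atoms)
    return GraftedModel(
        protein=protein,
        determinant=determinant,
        branch=branch,
        glycan_id=work.source_id,
        rotamer_label=assignment.label,
        alignment_rmsd=rmsd,
    )


def graft_all_rotamers(
    complex_model: StructureModel,
    determinant_selection: str,
    glycan: GlycanTree,
    motif: GlycanTree | None = None,
    geometry: LinkageGeometry | None = None,
    rmsd_gate: float = 0.8,
) -> list[GraftedModel]:
    """One grafted model per rotamer assignment, in enumeration order."""
    import copy

    work = copy.deepcopy(glycan)
    _substitute_alpha_root(work)
    return [
        graft(
            complex_model,
            determinant_selection,
            work,
            assignment,
            motif=motif,
            geometry=geometry,
            rmsd_gate=rmsd_gate,
        )
        for assignment in enumerate_rotamer_assignments(work)
    ]


def to_text(tree: GlycanTree) -> str:
    from .glycans import to_iupac_condensed

    return to_iupac_condensed(tree)
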