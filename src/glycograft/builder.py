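"""Assemble idealized 3D glycan models from residue templates.

Each residue of a :class:`~glycograft.glycans.GlycanTree` is instantiated from
its chair template and joined to its parent through a glycosidic bond of
idealized geometry (C–O 1.43 Å, 117° at the bridging oxygen).  Torsions follow
per-linkage-class defaults — for the TF β1-3 linkage φ(H1-C1-O3-C3) = 61.5°
and ψ(C1-O3-C3-H3) = 6.2°, the energy-minimized solution conformation — while
flexible torsions (ω of 1-6/2-6 linkages, φ of 2-3 linkages) are set from a
:class:`~glycograft.glycans.RotamerAssignment`.  The ω dihedral is measured in
the O(glycosidic)-C6-C5-O5 frame.

No energy minimization is performed: the discrete rotamer set *is* the
conformational model, which the downstream steric screen depends on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _geometry as geo
from .glycans import (
    ALPHA,
    BETA,
    UNDEFINED,
    GlycanTree,
    MonosaccharideNode,
    RotamerAssignment,
    classify_flexible_linkages,
)
from .structure import Atom, StructureModel
from .templates import (
    anomeric_atoms,
    attachment_atoms,
    ring_atom_names,
    template_copy,
)


class BuildError(ValueError):
    pass


@dataclass
class LinkageGeometry:
    """Glycosidic bond geometry and per-class default torsions.

    ``defaults`` maps ``(anomer, "c-p")`` — or ``("*", "c-p")`` or
    ``(anomer, "*")`` as fallbacks — to (φ, ψ) in degrees.  φ is measured
    H1-C1-O-Cx for aldoses and C1-C2-O-Cx for sialic-type residues; ψ is
    C1-O-Cx-Hx (heavy-atom reference C5 for 6-linkages).
    """

    bond_length: float = 1.43
    bond_angle: float = 117.0
    defaults: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: {
            (BETA, "1-3"): (61.5, 6.2),
            (BETA, "1-6"): (60.0, 180.0),
            (ALPHA, "1-6"): (-60.0, 180.0),
            ("*", "2-6"): (-60.0, 180.0),
            ("*", "2-3"): (-60.0, 0.0),
            (ALPHA, "*"): (-60.0, 0.0),
            (BETA, "*"): (60.0, 0.0),
        }
    )

    def torsions_for(self, anomer: str, linkage: tuple[int, int]) -> tuple[float, float]:
        key = f"{linkage[0]}-{linkage[1]}"
        for probe in ((anomer, key), ("*", key), (anomer, "*")):
            if probe in self.defaults:
                return self.defaults[probe]
        raise BuildError(f"no default torsions for linkage {key} ({anomer})")


DEFAULT_GEOMETRY = LinkageGeometry()


def _node_anomer(node: MonosaccharideNode, tree: GlycanTree) -> str:
    if node.anomeric_config == UNDEFINED:
        raise BuildError(
            f"{node.residue_name} has undefined anomeric configuration; "
            "substitute α or β before building"
        )
    return node.anomeric_config


def _atoms_of_node(model: StructureModel, node_id: int) -> list[Atom]:
    return [a for a in model.atoms if a.tags.get("node_id") == node_id]


def _atom_of_node(model: StructureModel, node_id: int, name: str) -> Atom:
    for a in model.atoms:
        if a.tags.get("node_id") == node_id and a.name == name:
            return a
    raise BuildError(f"atom {name!r} of residue {node_id} not found")


def build_glycan_3d(
    tree: GlycanTree,
    assignment: RotamerAssignment | None = None,
    geometry: LinkageGeometry | None = None,
) -> StructureModel:
    """Build one 3D conformer of ``tree`` under a rotamer assignment.

    The assignment must cover every flexible linkage; a rigid glycan may pass
    ``assignment=None``.  A methyl aglycon (and, as a modeling stand-in, any
    named spacer) is realized as an O-methyl group on the anomeric oxygen.
    Atoms are tagged with ``node_id`` (pre-order residue index) so callers can
    separate determinant and branch atoms after grafting.
    """
    geometry = geometry or DEFAULT_GEOMETRY
    flexible = classify_flexible_linkages(tree)
    if flexible and assignment is None:
        raise BuildError("glycan has flexible linkages; a rotamer assignment is required")
    nodes = tree.nodes()
    node_ids = {id(n): i for i, n in enumerate(nodes)}
    if assignment is not None:
        for f in flexible:
            if assignment.value_for(node_ids[id(f.child)]) is None:
                raise BuildError(f"rotamer assignment missing flexible linkage {f.label}")
    model = StructureModel(metadata={"glycan": tree.source_id, "rotamer": getattr(assignment, "label", "rigid")})

    _place_residue(model, tree, tree.root, node_ids, parent=None, assignment=assignment, geometry=geometry)
    if tree.aglycon is not None:
        _add_methyl_aglycon(model, tree, node_ids)
    _check_sanity(model)
    # keep each residue's atoms contiguous (aglycon and substituent atoms are
    # appended late); stable sort preserves within-residue order
    model.atoms.sort(key=lambda a: a.tags.get("node_id", 0))
    model.renumber()
    return model


def _place_residue(model, tree, node, node_ids, parent, assignment, geometry):
    nid = node_ids[id(node)]
    template = template_copy(node.residue_name, _node_anomer(node, tree))
    for atom in template.atoms:
        atom.tags["node_id"] = nid
        atom.residue_number = nid + 1
        atom.tags["residue"] = node.residue_name
    if parent is None:
        model.atoms.extend(template.atoms)
    else:
        _attach_child(model, tree, node, parent, node_ids, template, assignment, geometry)
    for pos, grp in node.substituents:
        if grp == "S":
            _add_sulfate(model, node, nid, pos)
    for child in node.children:
        _place_residue(model, tree, child, node_ids, node, assignment, geometry)


def _attach_child(model, tree, child, parent, node_ids, template, assignment, geometry):
    c, p = child.link_to_parent
    pid = node_ids[id(parent)]
    cid = node_ids[id(child)]
    pinfo = attachment_atoms(parent.residue_name, p)
    aninfo = anomeric_atoms(child.residue_name)
    anomer = _node_anomer(child, tree)

    ox = _atom_of_node(model, pid, pinfo["O"])
    cx = _atom_of_node(model, pid, pinfo["C"])
    psi_ref = _atom_of_node(model, pid, pinfo["psi_ref"])

    phi, psi = geometry.torsions_for(anomer, (c, p))
    if assignment is not None and c == 2 and p == 3:
        override = assignment.value_for(cid)
        if override is not None:
            phi = override

    # place the child's anomeric carbon, then rigidly map the template onto it
    can_target = geo.place_atom(
        psi_ref.coords, cx.coords, ox.coords, geometry.bond_length, geometry.bond_angle, psi
    )
    can_tmpl = template.atoms[[a.name for a in template.atoms].index(aninfo["C"])]
    oan_tmpl = next(a for a in template.atoms if a.name == aninfo["O"])
    R = geo.align_vector_rotation(oan_tmpl.coords - can_tmpl.coords, ox.coords - can_target)
    shift = can_tmpl.coords.copy()
    for atom in template.atoms:
        atom.coords = (atom.coords - shift) @ R.T + can_target

    # twist about the new C(anomeric)-O bond to set φ
    phi_ref = next(a for a in template.atoms if a.name == aninfo["phi_ref"])
    current = geo.dihedral(phi_ref.coords, can_target, ox.coords, cx.coords)
    axis = ox.coords - can_target
    movable = [a for a in template.atoms if a.name != aninfo["C"]]
    _rotate_to_target(
        movable,
        lambda: geo.dihedral(phi_ref.coords, can_target, ox.coords, cx.coords),
        can_target,
        axis,
        phi - current,
        phi,
    )

    # drop the child's anomeric hydroxyl (replaced by the glycosidic bond) and
    # the parent's hydroxyl proton at the linkage position
    template.atoms = [a for a in template.atoms if a.name not in (aninfo["O"], aninfo["HO"])]
    model.atoms = [
        a
        for a in model.atoms
        if not (a.tags.get("node_id") == pid and a.name == pinfo["HO"])
    ]
    model.atoms.extend(template.atoms)

    # ω rotamer for 6-linkages: rotate O6 + its hydrogens + the child subtree
    if p == 6:
        omega = assignment.value_for(cid) if assignment is not None else None
        if omega is not None:
            _set_omega(model, pid, cid, omega)


def _set_omega(model, parent_id, child_id, omega):
    o6 = _atom_of_node(model, parent_id, "O6")
    c6 = _atom_of_node(model, parent_id, "C6")
    c5 = _atom_of_node(model, parent_id, "C5")
    o5 = _atom_of_node(model, parent_id, "O5")
    # called right after the child template is spliced in, before any of the
    # child's own descendants exist: the rigid group is O6 + its hydrogens +
    # the child's atoms
    moving = [o6] + [
        a
        for a in model.atoms
        if (a.tags.get("node_id") == parent_id and a.name in ("H61", "H62"))
        or a.tags.get("node_id") == child_id
    ]
    current = geo.dihedral(o6.coords, c6.coords, c5.coords, o5.coords)
    _rotate_to_target(
        moving,
        lambda: geo.dihedral(o6.coords, c6.coords, c5.coords, o5.coords),
        c6.coords,
        c5.coords - c6.coords,
        omega - current,
        omega,
    )


def _rotate_to_target(atoms, measure, origin, axis, delta, target):
    """Rotate ``atoms`` about the axis by ``delta``; retry with the opposite
    sense if the measured dihedral moved the wrong way."""
    for attempt_delta in (delta, -2.0 * delta):
        pts = np.array([a.coords for a in atoms])
        rotated = geo.rotate_about_bond(pts, origin, axis, attempt_delta)
        for a, xyz in zip(atoms, rotated):
            a.coords = xyz
        err = (measure() - target + 180.0) % 360.0 - 180.0
        if abs(err) < 1e-6:
            return
    raise BuildError(f"torsion rotation failed to reach {target}°")


def _add_methyl_aglycon(model, tree, node_ids):
    root = tree.root
    nid = node_ids[id(root)]
    aninfo = anomeric_atoms(root.residue_name)
    can = _atom_of_node(model, nid, aninfo["C"])
    oan = _atom_of_node(model, nid, aninfo["O"])
    phi_ref = _atom_of_node(model, nid, aninfo["phi_ref"])
    # exo-anomeric orientation of the O-methyl (gauche to the anomeric H);
    # anti would park the methyl in the 1,3-diaxial pocket under the ring
    cm_pos = geo.place_atom(phi_ref.coords, can.coords, oan.coords, 1.43, 114.0, 60.0)
    model.atoms = [
        a for a in model.atoms if not (a.tags.get("node_id") == nid and a.name == aninfo["HO"])
    ]
    _append_atom(model, "CM", "C", cm_pos, can, segment="aglycon")
    for k, dih in zip((1, 2, 3), (60.0, 180.0, -60.0)):
        hpos = geo.place_atom(can.coords, oan.coords, cm_pos, 1.09, 109.47, dih)
        _append_atom(model, f"HM{k}", "H", hpos, can, segment="aglycon")


def _add_sulfate(model, node, nid, pos):
    try:
        o = _atom_of_node(model, nid, f"O{pos}")
        c = _atom_of_node(model, nid, f"C{pos}")
    except BuildError as exc:
        raise BuildError(f"cannot sulfate position {pos} of {node.residue_name}") from exc
    ref = _atom_of_node(model, nid, "C1" if pos != 1 else "C2")
    s_pos = geo.place_atom(ref.coords, c.coords, o.coords, 1.58, 118.0, 180.0)
    model.atoms = [
        a for a in model.atoms if not (a.tags.get("node_id") == nid and a.name == f"HO{pos}")
    ]
    _append_atom(model, f"S{pos}", "S", s_pos, o, segment="substituent")
    for k, dih in zip(("A", "B", "C"), (60.0, 180.0, -60.0)):
        opos = geo.place_atom(c.coords, o.coords, s_pos, 1.45, 109.47, dih)
        _append_atom(model, f"O{pos}{k}", "O", opos, o, segment="substituent")


def _append_atom(model, name, element, coords, like: Atom, segment: str):
    atom = Atom(
        serial=len(model.atoms) + 1,
        name=name,
        element=element,
        residue_name=like.residue_name,
        chain=like.chain,
        residue_number=like.residue_number,
        coords=np.asarray(coords, float),
        tags={"node_id": like.tags.get("node_id"), "segment": segment},
    )
    model.atoms.append(atom)


def _check_sanity(model):
    heavy = [a for a in model.atoms if not a.is_hydrogen]
    pos = np.array([a.coords for a in heavy])
    if len(pos) < 2:
        return
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < 1.0:
        import warnings

        warnings.warn(
            f"intra-model heavy-atom distance {d.min():.2f} Å < 1.0 Å "
            "(ring collision in this rotamer)",
            stacklevel=2,
        )


# ---------------------------------------------------------------------------
# torsion measurement and editing on arbitrary models


def measure_torsion(model: StructureModel, atoms: tuple) -> float:
    """Dihedral over four atoms given as indices or (name, residue_number) pairs."""
    refs = [_resolve_atom(model, a) for a in atoms]
    if len({id(a) for a in refs}) != 4:
        raise ValueError("four distinct atoms required")
    return geo.dihedral(*(a.coords for a in refs))


def set_glycosidic_torsion(model: StructureModel, atoms: tuple, value: float) -> StructureModel:
    """Set the dihedral a-b-c-d to ``value`` by rotating the subtree bonded
    through ``b`` (the distal side) about the b–c bond.  Edits in place."""
    a, b, c, d = (_resolve_atom(model, x) for x in atoms)
    moving = _component_through(model, b, c)
    current = geo.dihedral(a.coords, b.coords, c.coords, d.coords)
    _rotate_to_target(
        [x for x in moving if x is not b],
        lambda: geo.dihedral(a.coords, b.coords, c.coords, d.coords),
        b.coords,
        c.coords - b.coords,
        value - current,
        value,
    )
    return model


def _resolve_atom(model: StructureModel, ref) -> Atom:
    if isinstance(ref, Atom):
        return ref
    if isinstance(ref, int):
        return model.atoms[ref]
    name, resnum = ref
    return model.find_atom(name, resnum)


def _component_through(model: StructureModel, b: Atom, c: Atom) -> list[Atom]:
    """Atoms connected to ``b`` when the b–c bond is severed (b excluded)."""
    pos = model.positions
    n = len(model.atoms)
    is_h = np.array([a.is_hydrogen for a in model.atoms])
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    cutoff = np.where(is_h[:, None] | is_h[None, :], 1.25, 1.85)
    bonded = (d < cutoff) & ~np.eye(n, dtype=bool)
    bi = model.atoms.index(b)
    ci = model.atoms.index(c)
    bonded[bi, ci] = bonded[ci, bi] = False
    seen = {bi}
    stack = [bi]
    while stack:
        i = stack.pop()
        for j in np.nonzero(bonded[i])[0]:
            if j not in seen:
                seen.add(int(j))
                stack.append(int(j))
    if ci in seen:
        raise ValueError("bond b-c lies on a ring; torsion rotation is ill-defined")
    return [model.atoms[i] for i in sorted(seen - {bi})]


def determinant_ring_atoms(model: StructureModel, tree: GlycanTree, nodes) -> list[Atom]:
    """Ring heavy atoms of the given tree nodes, in a deterministic order."""
    ids = {i for i, n in enumerate(tree.nodes()) if n in nodes}
    out = []
    for nid in sorted(ids):
        node = tree.nodes()[nid]
        for name in ring_atom_names(node.residue_name):
            out.append(_atom_of_node(model, nid, name))
    return out
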