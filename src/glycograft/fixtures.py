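"""Self-contained synthetic test inputs.

Real inputs to a grafting screen are a crystal (or docked) antibody–glycan
complex and a database-derived glycan list; neither is needed to exercise the
machinery.  This module builds:

* toy binding pockets — a hemispherical shell of carbon pseudo-atoms around a
  built determinant, with a cleared cone ("the opening") in a controlled
  direction, so that which branch directions clash is known by construction;
* toy glycan libraries — seeded random IUPAC-condensed sequences with an exact
  planted fraction containing a motif;
* the 23-sequence TF-glycan array catalog list and the six extended binder
  groups used for open-direction tests;
* synthetic STD scenarios — a hydrogenated pocket plus rotated ligand poses
  and a pseudo-experimental intensity table derived from one of them.

Everything is reproducible bit-for-bit from (spec, seed).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import _geometry as geo
from .builder import build_glycan_3d
from .glycans import (
    ALPHA,
    GlycanTree,
    MonosaccharideNode,
    RotamerAssignment,
    enumerate_rotamer_assignments,
    find_motif,
    parse_iupac_condensed,
    tf_motif,
    to_iupac_condensed,
)
from .structure import Atom, StructureModel

# ---------------------------------------------------------------------------
# array-catalog sequence lists

#: the 23 TF-containing glycans of the v4.0 array screen, by catalog row.
#: Rows 17-20 have an undefined reducing anomer on the array (α is substituted
#: at screening time); rows 19-23 carry the determinant internally.
TABLE3_SEQUENCES: list[str] = [
    "Galβ1-3GalNAcα",
    "Neu5Acβ2-6(Galβ1-3)GalNAcα",
    "Neu5Acα2-6(Galβ1-3)GalNAcα",
    "Galβ1-4GlcNAcβ1-6(Galβ1-3)GalNAcα",
    "GlcNAcβ1-6(Galβ1-3)GalNAcα",
    "Neu5Acα2-3Galβ1-4(Fucα1-3)GlcNAcβ1-6(Galβ1-3)GalNAcα",
    "Neu5Acα2-3Galβ1-4GlcNAcβ1-6(Galβ1-3)GalNAcα",
    "(3S)Galβ1-3GalNAcα",
    "Fucα1-2Galβ1-3GalNAcα",
    "GlcNAcβ1-2Galβ1-3GalNAcα",
    "GlcNAcβ1-3Galβ1-3GalNAcα",
    "6S(Neu5Acα2-3Galβ1-3)GalNAcα",
    "Neu5Acα2-3Galβ1-3GalNAcα",
    "Neu5Acα2-6(Neu5Acα2-3Galβ1-3)GalNAcα",
    "KDNα2-3Galβ1-3GalNAcα",
    "Neu5Acα2-3Galβ1-4GlcNAcβ1-6(Neu5Acα2-3Galβ1-3)GalNAcα",
    "Neu5Acα2-3Galβ1-4(Fucα1-3)GlcNAcβ1-6(Neu5Acα2-3Galβ1-3)GalNAc",
    "GlcNAcα1-4Galβ1-3GalNAc",
    "Galβ1-3GalNAcα1-3(Fucα1-2)Galβ1-4GlcNAc",
    "Galβ1-3GalNAcα1-3(Fucα1-2)Galβ1-4Glc",
    "Fucα1-2Galβ1-3GalNAcα1-3(Fucα1-2)Galβ1-4GlcNAcβ",
    "Fucα1-2Galβ1-3GalNAcα1-3(Fucα1-2)Galβ1-4Glcβ",
    "GalNAcα1-3(Fucα1-2)Galβ1-3GalNAcα1-3(Fucα1-2)Galβ1-4GlcNAcβ",
]

#: catalog rows whose reducing anomeric configuration is undefined on the array
TABLE3_UNDEFINED_ANOMER = (17, 18, 19, 20)

#: extended core-2 binder groups (6-branch elaborations of the determinant),
#: polylactosamine repeats expanded at one repeat unit
BINDER_GROUP_SEQUENCES: list[str] = [
    "Galβ1-4GlcNAcβ1-3Galβ1-4GlcNAcβ1-6(Galβ1-3)GalNAc",
    "Neu5Acα2-3Galβ1-4(Fucα1-3)GlcNAcβ1-6(Galβ1-3)GalNAc",
    "Galβ1-4(Fucα1-3)GlcNAcβ1-6(Galβ1-3)GalNAc",
    "Fucα1-2Galβ1-4(Fucα1-3)GlcNAcβ1-6(Galβ1-3)GalNAc",
    "Galβ1-3GlcNAcβ1-3Galβ1-4GlcNAcβ1-6(Galβ1-3)GalNAc",
    "Fucα1-2Galβ1-4GlcNAcβ1-6(Galβ1-3)GalNAc",
]


def make_table3_list() -> list[str]:
    """The 23 array-catalog sequences as ``"<row>\\t<sequence>"`` lines."""
    return [f"{i + 1}\t{seq}" for i, seq in enumerate(TABLE3_SEQUENCES)]


def make_binder_group_list() -> list[str]:
    return [f"B{i + 1}\t{seq}" for i, seq in enumerate(BINDER_GROUP_SEQUENCES)]


# ---------------------------------------------------------------------------
# toy pocket


@dataclass
class ToyPocketSpec:
    """Geometry of a synthetic binding pocket.

    A hemispherical-to-spherical shell of carbon pseudo-atoms (Bondi radius) is
    placed around the determinant, with every shell atom inside the opening
    cone removed.  Carbon-only walls keep expected overlap areas closed-form.
    """

    shell_radius: float = 8.6
    opening_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    opening_half_angle: float = 60.0
    spacing: float = 1.8
    seed: int = 0
    jitter: float = 0.05
    hydrogens: bool = False


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_toy_pocket(
    spec: ToyPocketSpec,
    determinant: GlycanTree | str = "Galβ1-3GalNAcα",
    assignment: RotamerAssignment | None = None,
) -> StructureModel:
    """Build ``determinant`` at the origin inside a carbon shell.

    The determinant (chain X) is centered on its heavy-atom centroid; shell
    pseudo-atoms (chain W, residue SHL) cover the sphere of ``shell_radius``
    except for the opening cone.  With ``spec.hydrogens`` each wall atom gets
    an inward-pointing proton so the pocket can serve STD predictions.
    """
    if not 10.0 < spec.opening_half_angle < 170.0:
        raise ValueError("opening half-angle must be in (10°, 170°)")
    if isinstance(determinant, str):
        determinant = parse_iupac_condensed(determinant)
    ligand = build_glycan_3d(determinant, assignment)
    heavy = ligand.heavy()
    center = heavy.positions.mean(axis=0)
    for atom in ligand.atoms:
        atom.coords = atom.coords - center
    extent = float(np.max(np.linalg.norm(ligand.heavy().positions, axis=1)))
    if spec.shell_radius <= extent + 2.0:
        raise ValueError(
            f"shell radius {spec.shell_radius} Å too small for determinant "
            f"extent {extent:.1f} Å (need > extent + 2)"
        )

    # enough points for a mean nearest-neighbour distance ≈ spacing
    n = max(8, int(round(4.0 * np.pi * spec.shell_radius**2 / (0.87 * spec.spacing**2))))
    directions = _fibonacci_sphere(n)
    opening = np.asarray(spec.opening_direction, float)
    opening /= np.linalg.norm(opening)
    cos_cut = np.cos(np.radians(spec.opening_half_angle))
    keep = directions @ opening < cos_cut
    rng = np.random.default_rng(spec.seed)
    points = directions[keep] * spec.shell_radius
    points = points + rng.normal(0.0, spec.jitter, points.shape)

    atoms = [a.copy() for a in ligand.atoms]
    serial = len(atoms)
    for i, xyz in enumerate(points):
        serial += 1
        atoms.append(
            Atom(
                serial=serial,
                name="C",
                element="C",
                residue_name="SHL",
                chain="W",
                residue_number=i + 1,
                coords=xyz.copy(),
                tags={"segment": "wall"},
            )
        )
        if spec.hydrogens:
            serial += 1
            inward = -xyz / np.linalg.norm(xyz)
            atoms.append(
                Atom(
                    serial=serial,
                    name="H",
                    element="H",
                    residue_name="SHL",
                    chain="W",
                    residue_number=i + 1,
                    coords=xyz + 1.09 * inward,
                    tags={"segment": "wall"},
                )
            )
    model = StructureModel(atoms, {"fixture": "toy_pocket", "extent": extent})
    model.renumber()
    return model


def make_contoured_pocket(
    determinant: GlycanTree | str,
    channels: list[tuple[np.ndarray, float]],
    gap: float = 4.0,
    spacing: float = 1.7,
    seed: int = 0,
    jitter: float = 0.04,
    hydrogens: bool = False,
    n_directions: int = 8000,
) -> StructureModel:
    """A canyon-style pocket: carbon wall at fixed clearance from the
    determinant surface, with carved escape channels.

    Wall pseudo-atoms are placed along rays from the determinant centroid at
    the smallest distance where the ray is ``gap`` Å from every determinant
    heavy atom, so the wall hugs the ligand the way a combining-site surface
    does; rays within any ``(direction, half_angle)`` channel cone are left
    open.  Points are thinned to ``spacing`` deterministically.
    """
    if isinstance(determinant, str):
        determinant = parse_iupac_condensed(determinant)
    ligand = build_glycan_3d(determinant)
    center = ligand.heavy().positions.mean(axis=0)
    for atom in ligand.atoms:
        atom.coords = atom.coords - center
    A = ligand.heavy().positions

    dirs = _fibonacci_sphere(n_directions)
    mask = np.ones(len(dirs), dtype=bool)
    for direction, half in channels:
        u = np.asarray(direction, float)
        u = u / np.linalg.norm(u)
        mask &= dirs @ u < np.cos(np.radians(half))
    dirs = dirs[mask]

    # smallest t with |t·u − a| ≥ gap for every determinant atom a
    proj = dirs @ A.T  # (n, m)
    disc = proj**2 - (A**2).sum(axis=1)[None, :] + gap * gap
    t_exit = np.where(disc > 0, proj + np.sqrt(np.clip(disc, 0.0, None)), 0.0)
    t_star = np.maximum(t_exit.max(axis=1), gap)
    candidates = dirs * t_star[:, None]

    kept: list[np.ndarray] = []
    min_sq = (0.95 * spacing) ** 2
    for point in candidates:
        if all(((point - q) ** 2).sum() >= min_sq for q in kept):
            kept.append(point)
    rng = np.random.default_rng(seed)
    points = np.array(kept) + rng.normal(0.0, jitter, (len(kept), 3))

    atoms = [a.copy() for a in ligand.atoms]
    for i, xyz in enumerate(points):
        atoms.append(
            Atom(
                serial=0,
                name="C",
                element="C",
                residue_name="SHL",
                chain="W",
                residue_number=i + 1,
                coords=xyz.copy(),
                tags={"segment": "wall"},
            )
        )
        if hydrogens:
            inward = -xyz / np.linalg.norm(xyz)
            atoms.append(
                Atom(
                    serial=0,
                    name="H",
                    element="H",
                    residue_name="SHL",
                    chain="W",
                    residue_number=i + 1,
                    coords=xyz + 1.09 * inward,
                    tags={"segment": "wall"},
                )
            )
    model = StructureModel(atoms, {"fixture": "contoured_pocket"})
    model.renumber()
    return model


def determinant_exit_vectors(tree: GlycanTree | str = "Galβ1-3GalNAcα"):
    """Unit vectors (from the heavy-atom centroid) of the determinant's
    anomeric-oxygen exit and root O6 exit — the two directions tolerated by
    the combining site."""
    if isinstance(tree, str):
        tree = parse_iupac_condensed(tree)
    ligand = build_glycan_3d(tree)
    center = ligand.heavy().positions.mean(axis=0)

    def _pos(name, resnum):
        return ligand.find_atom(name, resnum).coords - center

    o6_exit = _pos("O6", 1) + 1.8 * _unit(_pos("O6", 1) - _pos("C6", 1))
    o1_exit = _pos("O1", 1) + 1.8 * _unit(_pos("O1", 1) - _pos("C1", 1))
    return _unit(o1_exit), _unit(o6_exit)


def make_specificity_pocket(
    seed: int = 0,
    hydrogens: bool = False,
    aglycon_half_angle: float = 30.0,
    branch_half_angle: float = 62.0,
    gap: float = 3.8,
) -> tuple[StructureModel, str]:
    """A pocket engineered to reproduce the array specificity pattern.

    Two escape channels are carved into a determinant-hugging wall: one around
    the α-anomeric exit (for the methyl aglycon) and a wide one around the
    GalNAc O6 exit (for core-2-style 6-branches, whose ω rotamers fan out
    around that axis).  Everything else — 2-/3-position extensions of the Gal
    residue, a β-oriented aglycon — runs into the wall by construction.

    Returns (complex model, determinant selection expression).
    """
    d_aglycon, d_o6 = determinant_exit_vectors()
    pocket = make_contoured_pocket(
        "Galβ1-3GalNAcα",
        channels=[(d_aglycon, aglycon_half_angle), (d_o6, branch_half_angle)],
        gap=gap,
        seed=seed,
        hydrogens=hydrogens,
    )
    return pocket, "chain X"


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# toy glycan library

_LIBRARY_EXTENSIONS = [
    ("Gal", "β", 1),
    ("GlcNAc", "β", 1),
    ("GalNAc", "α", 1),
    ("Fuc", "α", 1),
    ("Neu5Ac", "α", 2),
]
_LIBRARY_ROOTS = ["GlcNAc", "Glc", "Man", "GalNAc"]


def make_toy_glycan_library(
    n: int,
    motif: GlycanTree | None = None,
    fraction_with_motif: float = 0.25,
    seed: int = 0,
    max_extra_residues: int = 3,
) -> list[str]:
    """Seeded random IUPAC-condensed sequences with an exact planted motif count.

    Exactly ``round(n * fraction_with_motif)`` sequences contain the motif as a
    subtree (the motif itself, randomly extended); the remainder are random
    decoys verified motif-free.  The list is shuffled deterministically.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= fraction_with_motif <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    motif = motif or tf_motif(ALPHA)
    rng = np.random.default_rng(seed)
    n_with = int(round(n * fraction_with_motif))
    sequences: list[str] = []
    for _ in range(n_with):
        tree = copy.deepcopy(motif)
        if tree.root.anomeric_config not in (ALPHA, "β"):
            tree.root.anomeric_config = ALPHA
        _extend_randomly(tree, rng, int(rng.integers(0, max_extra_residues + 1)))
        sequences.append(to_iupac_condensed(tree))
    while len(sequences) < n:
        root_name = _LIBRARY_ROOTS[int(rng.integers(len(_LIBRARY_ROOTS)))]
        tree = parse_iupac_condensed(root_name + ALPHA)
        _extend_randomly(tree, rng, int(rng.integers(0, max_extra_residues + 1)))
        if find_motif(tree, motif) or find_motif(tree, tf_motif("?")):
            continue  # decoys must be motif-free
        sequences.append(to_iupac_condensed(tree))
    order = rng.permutation(n)
    return [sequences[i] for i in order]


def _extend_randomly(tree: GlycanTree, rng, n_extra: int) -> None:
    from .glycans import RESIDUES

    for _ in range(n_extra):
        nodes = tree.nodes()
        candidates = []
        for node in nodes:
            taken = {p for p, _ in node.substituents} | {
                c.link_to_parent[1] for c in node.children
            }
            for p in RESIDUES[node.residue_name][1]:
                if p not in taken:
                    candidates.append((node, p))
        if not candidates:
            return
        node, pos = candidates[int(rng.integers(len(candidates)))]
        options = [
            (res, ano, apos)
            for res, ano, apos in _LIBRARY_EXTENSIONS
            if not (apos == 2 and pos not in (3, 6))
        ]
        res, ano, apos = options[int(rng.integers(len(options)))]
        child = MonosaccharideNode(res, ano, link_to_parent=(apos, pos))
        node.children.append(child)


# ---------------------------------------------------------------------------
# STD scenario


def make_std_scenario(
    seed: int = 0, n_poses: int = 4
) -> tuple[list[tuple[str, StructureModel]], dict[str, float], str, dict[str, list[str]]]:
    """Hydrogenated pocket + rotated ligand poses + pseudo-experimental table.

    Pose 1 is the reference orientation; the experimental table is its
    predicted profile with small seeded multiplicative noise, so pose 1 is the
    ground-truth best match.  The other poses are the same ligand rotated
    inside the pocket.  Returns (poses, experimental table, ligand selection,
    methyl grouping).
    """
    from .std import predict_std

    pocket, selection = make_specificity_pocket(seed=seed, hydrogens=True)
    rng = np.random.default_rng(seed + 1)
    poses: list[tuple[str, StructureModel]] = []
    axes = _fibonacci_sphere(max(n_poses, 4))
    for k in range(n_poses):
        model = pocket.copy()
        if k > 0:
            ligand_atoms = [a for a in model.atoms if a.chain == "X"]
            pivot = np.mean([a.coords for a in ligand_atoms if not a.is_hydrogen], axis=0)
            R = geo.rotation_about_axis(axes[k], 60.0 + 40.0 * k)
            for a in ligand_atoms:
                a.coords = (a.coords - pivot) @ R.T + pivot
        poses.append((f"pose{k + 1}", model))

    methyl_groups = {"NAc-Me": ["H81", "H82", "H83"]}
    reference = predict_std(poses[0][1], selection, methyl_groups)
    experimental = {
        label: max(norm * float(1.0 + rng.normal(0.0, 0.03)), 0.0)
        for label, _, norm in reference.entries
    }
    return poses, experimental, selection, methyl_groups
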