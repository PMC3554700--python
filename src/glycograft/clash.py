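"""Van der Waals surface-overlap clash scoring and binder classification.

The steric cost of a grafted branch is the total area of the branch atoms'
van der Waals surfaces buried inside protein atoms (and vice versa), summed
over all overlapping branch–protein pairs and expressed in units of one
carbon sphere's surface (4π·1.70² = 36.3 Å²).  A glycan is a putative binder
when at least one rotamer scores strictly below the threshold (default 1.0,
one occluded carbon's worth of surface).  Pairs involving the retained bound
determinant are excluded: the validated pose necessarily contacts the protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .glycans import (
    ALPHA,
    UNDEFINED,
    GlycanParseError,
    GlycanTree,
    find_motif,
    parse_iupac_condensed,
    tf_motif,
    to_iupac_condensed,
)
from .grafting import GraftedModel, GraftError, graft_all_rotamers
from .structure import CARBON_SURFACE_AREA, StructureModel, assign_vdw_radii


def sphere_overlap_area(r1: float, r2: float, d: float) -> float:
    """Buried van der Waals *surface* area of two overlapping spheres (Å²).

    The sum of the two spherical caps each sphere buries inside the other:
    ``A = 2π r1 h1 + 2π r2 h2`` with ``h_i = r_i − (d² + r_i² − r_j²)/(2d)``.
    Zero for separated or tangent spheres (d ≥ r1+r2); when one sphere is
    engulfed (d + r_min ≤ r_max) the full surface of the smaller sphere,
    4π·r_min², is returned.
    """
    if r1 <= 0 or r2 <= 0 or d < 0:
        raise ValueError("radii must be positive and distance non-negative")
    if d >= r1 + r2:
        return 0.0
    rmin, rmax = min(r1, r2), max(r1, r2)
    if d + rmin <= rmax:
        return 4.0 * math.pi * rmin**2
    h1 = r1 - (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    h2 = r2 - (d * d + r2 * r2 - r1 * r1) / (2.0 * d)
    return 2.0 * math.pi * (r1 * h1 + r2 * h2)


@dataclass
class ClashReport:
    """Overlap bookkeeping for one grafted rotamer."""

    pair_overlaps: list[tuple[int, int, float]]  # (branch serial, protein serial, Å²)
    total_area: float
    clash_score: float
    rotamer_label: str
    binder: bool
    threshold: float = 1.0
    #: branch vs bound-determinant overlap (not part of the score); flagged
    #: when itself above threshold
    intra_overlap_score: float = 0.0

    @property
    def intra_flag(self) -> bool:
        return self.intra_overlap_score >= self.threshold


def _pairwise_overlap(
    atoms_a, atoms_b, min_distance: float = 0.0
) -> tuple[list[tuple[int, int, float]], float]:
    if not atoms_a or not atoms_b:
        return [], 0.0
    ra = np.array([a.vdw_radius for a in atoms_a])
    rb = np.array([b.vdw_radius for b in atoms_b])
    if np.any(ra == None) or np.any(rb == None):  # noqa: E711
        raise ValueError("assign van der Waals radii before clash scoring")
    pa = np.array([a.coords for a in atoms_a])
    pb = np.array([b.coords for b in atoms_b])
    tree_a = cKDTree(pa)
    tree_b = cKDTree(pb)
    max_cut = float(ra.max() + rb.max())
    pairs = tree_a.query_ball_tree(tree_b, r=max_cut)
    overlaps = []
    total = 0.0
    for i, js in enumerate(pairs):
        for j in js:
            d = float(np.linalg.norm(pa[i] - pb[j]))
            if min_distance <= d < ra[i] + rb[j]:
                area = sphere_overlap_area(float(ra[i]), float(rb[j]), d)
                overlaps.append((atoms_a[i].serial, atoms_b[j].serial, area))
                total += area
    return overlaps, total


def clash_score(
    model: GraftedModel,
    threshold: float = 1.0,
    normalization: float = CARBON_SURFACE_AREA,
    include_hydrogens: bool = False,
) -> ClashReport:
    """Score one grafted rotamer against the protein surface.

    Heavy atoms only by default (crystal and docked inputs usually lack
    hydrogens, and the carbon-surface normalization is a heavy-atom anchor).
    """
    branch = model.branch if include_hydrogens else model.branch.heavy()
    protein = model.protein if include_hydrogens else model.protein.heavy()
    determinant = model.determinant if include_hydrogens else model.determinant.heavy()
    for part in (branch, protein, determinant):
        if any(a.vdw_radius is None for a in part.atoms):
            assign_vdw_radii(part)
    overlaps, total = _pairwise_overlap(branch.atoms, protein.atoms)
    # branch-vs-determinant diagnostic: pairs closer than 2.5 Å are the
    # glycosidic bond and its geminal neighbours, not steric strain
    _, intra_total = _pairwise_overlap(
        branch.atoms, determinant.atoms, min_distance=2.5
    )
    score = total / normalization
    return ClashReport(
        pair_overlaps=overlaps,
        total_area=total,
        clash_score=score,
        rotamer_label=model.rotamer_label,
        binder=score < threshold,
        threshold=threshold,
        intra_overlap_score=intra_total / normalization,
    )


@dataclass
class GlycanVerdict:
    """Screening result for one glycan: best rotamer wins."""

    glycan_id: str
    sequence: str
    n_rotamers: int
    best_score: float | None
    best_rotamer: str | None
    binder: bool
    per_rotamer: list[ClashReport] = field(default_factory=list)
    skipped_reason: str | None = None
    error: str | None = None


def classify_glycan(
    complex_model: StructureModel,
    determinant_selection: str,
    glycan: GlycanTree,
    threshold: float = 1.0,
    motif: GlycanTree | None = None,
    rmsd_gate: float = 0.8,
    normalization: float = CARBON_SURFACE_AREA,
) -> GlycanVerdict:
    """Score every rotamer of one glycan; binder iff min score < threshold.

    A single score per glycan is reported — the minimum over rotamers —
    because binding requires only one sterically viable conformer.
    """
    grafted = graft_all_rotamers(
        complex_model, determinant_selection, glycan, motif=motif, rmsd_gate=rmsd_gate
    )
    reports = [clash_score(g, threshold, normalization) for g in grafted]
    best = min(reports, key=lambda r: r.clash_score)
    return GlycanVerdict(
        glycan_id=glycan.source_id,
        sequence=to_iupac_condensed(glycan),
        n_rotamers=len(reports),
        best_score=best.clash_score,
        best_rotamer=best.rotamer_label,
        binder=best.clash_score < threshold,
        per_rotamer=reports,
    )


def screen_library(
    complex_model: StructureModel,
    determinant_selection: str,
    glycans: list[GlycanTree | str],
    threshold: float = 1.0,
    motif: GlycanTree | None = None,
    rmsd_gate: float = 0.8,
    normalization: float = CARBON_SURFACE_AREA,
) -> list[GlycanVerdict]:
    """Screen a glycan list; per-entry failures are recorded, not fatal.

    Entries may be :class:`GlycanTree` objects or raw IUPAC-condensed strings
    (optionally ``"id<TAB>sequence"``).  Motif-free entries are reported with a
    skip reason; glycans with an undefined reducing anomer are screened with α
    substituted, following the methyl-α-glycoside convention of the screen.
    """
    motif = motif or tf_motif()
    results: list[GlycanVerdict] = []
    for i, entry in enumerate(glycans):
        gid, tree, err = _coerce_entry(entry, i)
        if err is not None:
            results.append(
                GlycanVerdict(gid, str(entry), 0, None, None, False, error=err)
            )
            continue
        probe = _alpha_substituted(tree)
        if not find_motif(probe, motif):
            results.append(
                GlycanVerdict(
                    tree.source_id,
                    to_iupac_condensed(tree),
                    0,
                    None,
                    None,
                    False,
                    skipped_reason="determinant absent",
                )
            )
            continue
        try:
            results.append(
                classify_glycan(
                    complex_model,
                    determinant_selection,
                    tree,
                    threshold=threshold,
                    motif=motif,
                    rmsd_gate=rmsd_gate,
                    normalization=normalization,
                )
            )
        except (GraftError, ValueError) as exc:
            results.append(
                GlycanVerdict(
                    tree.source_id,
                    to_iupac_condensed(tree),
                    0,
                    None,
                    None,
                    False,
                    error=str(exc),
                )
            )
    return results


def _coerce_entry(entry, index: int):
    if isinstance(entry, GlycanTree):
        return entry.source_id or str(index + 1), entry, None
    text = str(entry).strip()
    gid = str(index + 1)
    if "\t" in text:
        gid, text = text.split("\t", 1)
        gid, text = gid.strip(), text.strip()
    try:
        tree = parse_iupac_condensed(text, source_id=gid)
    except GlycanParseError as exc:
        return gid, None, str(exc)
    return gid, tree, None


def _alpha_substituted(tree: GlycanTree) -> GlycanTree:
    import copy

    if tree.root.anomeric_config == UNDEFINED:
        tree = copy.deepcopy(tree)
        tree.root.anomeric_config = ALPHA
    return tree


def screening_table(results: list[GlycanVerdict]) -> "pandas.DataFrame":  # noqa: F821
    """Tabulate screening results (columns fixed: id, sequence, n_rotamers,
    min_clash_score, binder, intra_flag, skipped/error note)."""
    import pandas as pd

    rows = []
    for r in results:
        note = r.skipped_reason or r.error or ""
        intra = any(rep.intra_flag for rep in r.per_rotamer)
        rows.append(
            {
                "id": r.glycan_id,
                "sequence": r.sequence,
                "n_rotamers": r.n_rotamers,
                "min_clash_score": float("nan") if r.best_score is None else round(r.best_score, 3),
                "binder": r.binder,
                "intra_flag": intra,
                "note": note,
            }
        )
    return pd.DataFrame(rows, columns=["id", "sequence", "n_rotamers", "min_clash_score", "binder", "intra_flag", "note"])
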