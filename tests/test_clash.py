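"""Sphere-overlap arithmetic, clash scoring and binder classification."""

import math

import numpy as np
import pytest

from glycograft.clash import (
    ClashReport,
    classify_glycan,
    clash_score,
    screen_library,
    sphere_overlap_area,
)
from glycograft.grafting import GraftedModel
from glycograft.structure import Atom, StructureModel, CARBON_SURFACE_AREA
from glycograft.glycans import BETA, parse_iupac_condensed, tf_motif


def _mc_overlap(r1, r2, d, n=200_000, seed=0):
    """Monte-Carlo buried-surface oracle: sample each sphere's surface and
    count points inside the other sphere."""
    rng = np.random.default_rng(seed)
    centers = (np.zeros(3), np.array([0.0, 0.0, d]))
    total, var = 0.0, 0.0
    for (r, c), (r_o, c_o) in ((( r1, centers[0]), (r2, centers[1])),
                               ((r2, centers[1]), (r1, centers[0]))):
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        inside = np.linalg.norm(c + r * v - c_o, axis=1) < r_o
        p = inside.mean()
        area = 4.0 * math.pi * r * r
        total += area * p
        var += (area * math.sqrt(max(p * (1 - p), 0.0) / n)) ** 2
    return total, math.sqrt(var)


class TestSphereOverlap:
    def test_tangent_spheres_zero(self):
        assert sphere_overlap_area(1.70, 1.70, 3.40) == 0.0

    def test_equal_radii_at_d_equals_r(self):
        # closed form: h = r/2 per cap, total area 2πr² — half a sphere,
        # i.e. clash contribution 0.5 carbon equivalents at r = 1.70
        area = sphere_overlap_area(1.70, 1.70, 1.70)
        assert area == pytest.approx(2.0 * math.pi * 1.70**2, rel=1e-12)
        assert area / CARBON_SURFACE_AREA == pytest.approx(0.5, rel=1e-12)

    def test_engulfed_returns_smaller_sphere_surface(self):
        assert sphere_overlap_area(1.0, 3.0, 0.5) == pytest.approx(4 * math.pi)
        assert sphere_overlap_area(1.7, 1.7, 0.0) == pytest.approx(4 * math.pi * 1.7**2)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            r1, r2 = rng.uniform(0.8, 2.2, 2)
            d = rng.uniform(0.0, r1 + r2 + 0.5)
            assert sphere_overlap_area(r1, r2, d) == pytest.approx(
                sphere_overlap_area(r2, r1, d)
            )

    def test_monotone_decreasing_and_continuous(self):
        r1, r2 = 1.70, 1.52
        lo, hi = abs(r1 - r2), r1 + r2
        ds = np.linspace(lo + 1e-6, hi - 1e-6, 200)
        areas = [sphere_overlap_area(r1, r2, d) for d in ds]
        assert all(a > b for a, b in zip(areas, areas[1:]))
        # continuity at both boundary radii
        assert sphere_overlap_area(r1, r2, hi - 1e-9) == pytest.approx(0.0, abs=1e-5)
        assert sphere_overlap_area(r1, r2, lo + 1e-9) == pytest.approx(
            4 * math.pi * min(r1, r2) ** 2, abs=1e-5
        )

    def test_negative_inputs_raise(self):
        with pytest.raises(ValueError):
            sphere_overlap_area(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            sphere_overlap_area(1.0, 1.0, -0.1)

    def test_against_monte_carlo_oracle(self):
        rng = np.random.default_rng(7)
        for k in range(40):
            r1, r2 = rng.uniform(1.1, 2.0, 2)
            d = rng.uniform(0.2, 0.99 * (r1 + r2))
            analytic = sphere_overlap_area(r1, r2, d)
            mc, sigma = _mc_overlap(r1, r2, d, seed=k)
            assert abs(analytic - mc) <= max(3.0 * sigma, 1e-9)


def _atom(serial, xyz, element="C", name=None):
    return Atom(
        serial=serial,
        name=name or element,
        element=element,
        residue_name="X",
        chain="A",
        residue_number=serial,
        coords=np.array(xyz, float),
        vdw_radius={"C": 1.70, "O": 1.52}[element],
    )


def _toy_grafted(branch_atoms, protein_atoms, determinant_atoms=()):
    return GraftedModel(
        protein=StructureModel(list(protein_atoms)),
        determinant=StructureModel(list(determinant_atoms)),
        branch=StructureModel(list(branch_atoms)),
        glycan_id="toy",
        rotamer_label="rigid",
        alignment_rmsd=0.0,
    )


class TestClashScore:
    def test_distant_branch_scores_zero(self):
        g = _toy_grafted([_atom(1, (10, 0, 0))], [_atom(2, (0, 0, 0))])
        report = clash_score(g)
        assert report.clash_score == 0.0
        assert report.binder

    def test_single_carbon_pair_half_occlusion(self):
        g = _toy_grafted([_atom(1, (1.70, 0, 0))], [_atom(2, (0, 0, 0))])
        report = clash_score(g)
        assert report.clash_score == pytest.approx(0.5, rel=1e-9)
        assert report.total_area == pytest.approx(2 * math.pi * 1.70**2)
        assert len(report.pair_overlaps) == 1

    def test_determinant_pairs_excluded(self):
        det = _atom(3, (1.0, 0, 0))
        g = _toy_grafted([_atom(1, (10, 0, 0))], [_atom(2, (0, 0, 0))], [det])
        assert clash_score(g).clash_score == 0.0

    def test_intra_overlap_flagged_not_scored(self):
        # six determinant atoms in nonbonded contact (2.6 Å) with the branch:
        # diagnostic exceeds 1.0 but the protein-facing score stays 0
        dets = [
            _atom(10 + k, 2.6 * np.array(v))
            for k, v in enumerate(
                [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
            )
        ]
        g = _toy_grafted([_atom(1, (0, 0, 0))], [_atom(2, (20, 0, 0))], dets)
        report = clash_score(g)
        assert report.clash_score == 0.0
        assert report.intra_overlap_score > 1.0
        assert report.intra_flag

    def test_bonded_branch_contact_not_intra_flagged(self):
        # the glycosidic-bond contact itself (1.43 Å) is excluded
        det = _atom(3, (1.43, 0, 0), element="O")
        g = _toy_grafted([_atom(1, (0, 0, 0))], [_atom(2, (20, 0, 0))], [det])
        report = clash_score(g)
        assert report.intra_overlap_score == 0.0
        assert not report.intra_flag

    def test_threshold_strictness_at_exactly_one(self):
        report = ClashReport([], CARBON_SURFACE_AREA, 1.0, "rigid", binder=1.0 < 1.0)
        assert not report.binder  # score exactly 1.0 is a non-binder


class TestClassify:
    def test_tf_itself_is_binder(self, specificity_pocket):
        pocket, sel = specificity_pocket
        v = classify_glycan(pocket, sel, parse_iupac_condensed("Galβ1-3GalNAcα"))
        assert v.binder and v.best_score < 1.0

    def test_min_rule_over_rotamers(self, specificity_pocket):
        # one open and at least one blocked omega rotamer: glycan-level score
        # is the minimum, so the glycan is a binder
        pocket, sel = specificity_pocket
        v = classify_glycan(
            pocket, sel, parse_iupac_condensed("GlcNAcβ1-6(Galβ1-3)GalNAcα")
        )
        scores = sorted(r.clash_score for r in v.per_rotamer)
        assert v.best_score == pytest.approx(scores[0])
        assert v.binder
        assert scores[-1] > 1.0  # the wall blocks at least one rotamer

    def test_beta_aglycon_excluded(self, specificity_pocket):
        pocket, sel = specificity_pocket
        v = classify_glycan(
            pocket, sel, parse_iupac_condensed("Galβ1-3GalNAcβ"), motif=tf_motif(BETA)
        )
        assert not v.binder

    def test_verdict_flips_with_threshold(self, specificity_pocket):
        pocket, sel = specificity_pocket
        tree = parse_iupac_condensed("Galβ1-3GalNAcβ")
        strict = classify_glycan(pocket, sel, tree, motif=tf_motif(BETA), threshold=1.0)
        loose = classify_glycan(
            pocket, sel, tree, motif=tf_motif(BETA), threshold=strict.best_score + 0.01
        )
        assert not strict.binder and loose.binder


class TestScreen:
    def test_catalog_screen_all_rows_scored(self, specificity_pocket):
        pocket, sel = specificity_pocket
        from glycograft.fixtures import make_table3_list

        rows = screen_library(pocket, sel, make_table3_list())
        assert len(rows) == 23
        assert all(r.skipped_reason is None and r.error is None for r in rows)
        assert all(r.best_score is not None for r in rows)

    def test_motif_free_entry_skipped_with_reason(self, specificity_pocket):
        pocket, sel = specificity_pocket
        rows = screen_library(pocket, sel, ["Galβ1-4GlcNAcβ"])
        assert rows[0].skipped_reason == "determinant absent"
        assert not rows[0].binder

    def test_unparseable_entry_recorded_not_fatal(self, specificity_pocket):
        pocket, sel = specificity_pocket
        rows = screen_library(pocket, sel, ["Qux1-3GalNAcα", "Galβ1-3GalNAcα"])
        assert rows[0].error is not None
        assert rows[1].binder

    def test_empty_list(self, specificity_pocket):
        pocket, sel = specificity_pocket
        assert screen_library(pocket, sel, []) == []

    def test_undefined_root_screened_as_alpha(self, specificity_pocket):
        pocket, sel = specificity_pocket
        rows = screen_library(pocket, sel, ["Galβ1-3GalNAc"])
        assert rows[0].best_score is not None
        assert rows[0].binder
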