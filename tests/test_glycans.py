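"""Glycan notation parsing, serialization, motif location and rotamer counts."""

import pytest
from hypothesis import given, settings, strategies as st

from glycograft.glycans import (
    ALPHA,
    BETA,
    UNDEFINED,
    GlycanParseError,
    GlycanTree,
    MonosaccharideNode,
    RESIDUES,
    classify_flexible_linkages,
    enumerate_rotamer_assignments,
    expand_ambiguous_linkages,
    find_motif,
    parse_iupac_condensed,
    tf_motif,
    to_iupac_condensed,
    trees_isomorphic,
)
from glycograft.fixtures import TABLE3_SEQUENCES


class TestParsing:
    def test_tf_disaccharide(self):
        t = parse_iupac_condensed("Galβ1-3GalNAcα")
        assert t.root.residue_name == "GalNAc"
        assert t.root.anomeric_config == ALPHA
        (gal,) = t.root.children
        assert gal.residue_name == "Gal"
        assert gal.anomeric_config == BETA
        assert gal.link_to_parent == (1, 3)

    def test_branched_disialyl(self):
        t = parse_iupac_condensed("Neu5Acα2-6(Neu5Acα2-3Galβ1-3)GalNAcα")
        assert t.root.residue_name == "GalNAc"
        by_pos = {c.link_to_parent[1]: c for c in t.root.children}
        assert by_pos[6].residue_name == "Neu5Ac"
        assert by_pos[3].residue_name == "Gal"
        (neu,) = by_pos[3].children
        assert neu.residue_name == "Neu5Ac"
        assert neu.link_to_parent == (2, 3)

    def test_undefined_reducing_anomer_preserved(self):
        t = parse_iupac_condensed("Galβ1-3GalNAc")
        assert t.root.anomeric_config == UNDEFINED

    def test_sulfate_prefix_forms(self):
        t = parse_iupac_condensed("(3S)Galβ1-3GalNAcα")
        assert t.root.children[0].substituents == [(3, "S")]
        t2 = parse_iupac_condensed("6S(Neu5Acα2-3Galβ1-3)GalNAcα")
        assert t2.root.substituents == [(6, "S")]

    def test_aglycon_suffixes(self):
        assert parse_iupac_condensed("Galβ1-3GalNAcα-OMe").aglycon == "methyl"
        assert parse_iupac_condensed("Galβ1-3GalNAcα-Sp8").aglycon == "Sp8"

    @pytest.mark.parametrize(
        "bad",
        [
            "",
            "Galβ1-3(GalNAcα",  # unbalanced
            "Qux1-3GalNAcα",  # unknown residue
            "Galβ1=3GalNAcα",  # malformed linkage
            "Neu5Acα1-3Galβ",  # sialic acid must link through position 2
            "Galβ1-3(Fucα1-3)GalNAcα",  # position occupied twice
        ],
    )
    def test_malformed_inputs_raise(self, bad):
        with pytest.raises(GlycanParseError):
            parse_iupac_condensed(bad)

    def test_ambiguous_linkage_rejected_then_expanded(self):
        with pytest.raises(GlycanParseError, match="ambiguous"):
            parse_iupac_condensed("Neu5Acα2-3/6Galβ1-3GalNAcα")
        variants = expand_ambiguous_linkages("Neu5Acα2-3/6Galβ1-3GalNAcα")
        assert variants == [
            "Neu5Acα2-3Galβ1-3GalNAcα",
            "Neu5Acα2-6Galβ1-3GalNAcα",
        ]
        for v in variants:
            parse_iupac_condensed(v)


class TestSerialization:
    def test_single_residue(self):
        assert to_iupac_condensed(parse_iupac_condensed("Galβ")) == "Galβ"

    def test_branch_style_matches_catalog(self):
        seq = "Galβ1-4GlcNAcβ1-6(Galβ1-3)GalNAcα"
        assert to_iupac_condensed(parse_iupac_condensed(seq)) == seq

    @pytest.mark.parametrize("seq", TABLE3_SEQUENCES)
    def test_round_trip_catalog(self, seq):
        t = parse_iupac_condensed(seq)
        assert trees_isomorphic(t, parse_iupac_condensed(to_iupac_condensed(t)))


# -- random tree machinery for property tests --------------------------------

_EXTENSIONS = [("Gal", BETA, 1), ("GlcNAc", BETA, 1), ("Fuc", ALPHA, 1),
               ("GalNAc", ALPHA, 1), ("Neu5Ac", ALPHA, 2)]


def _random_tree(rnd, n_nodes):
    root = MonosaccharideNode("GalNAc", ALPHA)
    tree = GlycanTree(root)
    while len(tree) < n_nodes:
        nodes = tree.nodes()
        node = nodes[rnd.randrange(len(nodes))]
        taken = {c.link_to_parent[1] for c in node.children}
        free = [p for p in RESIDUES[node.residue_name][1] if p not in taken]
        if not free:
            continue
        pos = free[rnd.randrange(len(free))]
        options = [e for e in _EXTENSIONS if not (e[2] == 2 and pos not in (3, 6))]
        res, ano, apos = options[rnd.randrange(len(options))]
        node.children.append(MonosaccharideNode(res, ano, link_to_parent=(apos, pos)))
    return tree


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 10**6), st.integers(1, 8))
def test_round_trip_random_trees(seed, n_nodes):
    import random

    tree = _random_tree(random.Random(seed), n_nodes)
    text = to_iupac_condensed(tree)
    assert trees_isomorphic(tree, parse_iupac_condensed(text))


def _nx_motif_count(tree, motif):
    """Independent oracle: count motif embeddings via networkx monomorphism."""
    import networkx as nx
    from networkx.algorithms.isomorphism import DiGraphMatcher

    def to_graph(t):
        g = nx.DiGraph()
        for i, node in enumerate(t.nodes()):
            g.add_node(id(node), res=node.residue_name, ano=node.anomeric_config)
        for node in t.nodes():
            for child in node.children:
                g.add_edge(id(node), id(child), link=child.link_to_parent)
        return g

    G, M = to_graph(tree), to_graph(motif)
    matcher = DiGraphMatcher(
        G,
        M,
        node_match=lambda a, b: a["res"] == b["res"]
        and (b["ano"] == UNDEFINED or a["ano"] == b["ano"]),
        edge_match=lambda a, b: a["link"] == b["link"],
    )
    return sum(1 for _ in matcher.subgraph_monomorphisms_iter())


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10**6), st.integers(2, 8))
def test_motif_matching_against_monomorphism_oracle(seed, n_nodes):
    import random

    tree = _random_tree(random.Random(seed), n_nodes)
    motif = parse_iupac_condensed("Galβ1-3GalNAcα")
    assert len(find_motif(tree, motif)) == _nx_motif_count(tree, motif)


class TestMotif:
    def test_exact_match_no_branches(self):
        matches = find_motif(parse_iupac_condensed("Galβ1-3GalNAcα"), tf_motif())
        assert len(matches) == 1
        assert matches[0].branch_attachments == []
        assert matches[0].anchored_at_root

    def test_extra_branch_reported(self):
        matches = find_motif(
            parse_iupac_condensed("Neu5Acα2-3Galβ1-3GalNAcα"), tf_motif()
        )
        assert len(matches) == 1
        (det, pos, desc) = matches[0].branch_attachments[0]
        assert det.residue_name == "Gal" and pos == 3
        assert "Neu5Ac" in desc

    def test_determinant_absent(self):
        assert find_motif(parse_iupac_condensed("Galβ1-4GlcNAcβ"), tf_motif()) == []

    def test_anomer_mismatch_blocks_match(self):
        assert find_motif(parse_iupac_condensed("Galβ1-3GalNAcβ"), tf_motif(ALPHA)) == []

    def test_internal_determinant_reports_reducing_chain(self):
        t = parse_iupac_condensed("Galβ1-3GalNAcα1-3(Fucα1-2)Galβ1-4GlcNAc")
        matches = find_motif(t, tf_motif(ALPHA))
        assert len(matches) == 1
        assert not matches[0].anchored_at_root
        anomeric = [b for b in matches[0].branch_attachments if b[1] == 1]
        assert len(anomeric) == 1

    def test_all_catalog_sequences_contain_determinant(self):
        motif = tf_motif(UNDEFINED)
        hits = [
            len(find_motif(parse_iupac_condensed(seq), motif)) >= 1
            for seq in TABLE3_SEQUENCES
        ]
        assert hits.count(True) == 23


class TestRotamers:
    def test_rigid_glycan_single_assignment(self):
        t = parse_iupac_condensed("Galβ1-3GalNAcα")
        assert classify_flexible_linkages(t) == []
        assert len(enumerate_rotamer_assignments(t)) == 1

    def test_omega_and_phi_classes(self):
        t = parse_iupac_condensed("Neu5Acα2-6(Neu5Acα2-3Galβ1-3)GalNAcα")
        classes = sorted(f.torsion_class for f in classify_flexible_linkages(t))
        assert classes == ["omega", "phi23"]
        assert len(enumerate_rotamer_assignments(t)) == 6

    @pytest.mark.parametrize("row,expected", [(4, 3), (17, 12)])
    def test_catalog_rotamer_counts(self, row, expected):
        t = parse_iupac_condensed(TABLE3_SEQUENCES[row - 1])
        assert len(enumerate_rotamer_assignments(t)) == expected

    @pytest.mark.parametrize("seq", TABLE3_SEQUENCES)
    def test_cardinality_law(self, seq):
        t = parse_iupac_condensed(seq)
        flex = classify_flexible_linkages(t)
        k = sum(1 for f in flex if f.torsion_class == "omega")
        m = sum(1 for f in flex if f.torsion_class == "phi23")
        assignments = enumerate_rotamer_assignments(t)
        assert len(assignments) == 3**k * 2**m
        # assignments are distinct and complete
        labels = {a.label for a in assignments}
        assert len(labels) == len(assignments)
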