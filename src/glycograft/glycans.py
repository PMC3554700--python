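"""Glycan sequences as rooted trees.

A glycan in IUPAC-condensed notation, e.g. ``Galβ1-4GlcNAcβ1-6(Galβ1-3)GalNAcα``,
is represented as a tree rooted at the reducing-end residue (the rightmost token).
Every non-root residue records how it is linked to its parent: its own anomeric
position (1 for aldoses, 2 for the ulosonic acids Neu5Ac/Neu5Gc/KDN) and the ring
position it occupies on the parent.

The module also owns motif location (finding a minimal binding determinant such as
the Thomsen-Friedenreich disaccharide Galβ1-3GalNAcα inside a larger glycan) and
the discrete-rotamer bookkeeping used for conformer library generation: ω angles of
1-6/2-6 linkages populate three stable rotamers (+60°, −60°, 180°) and φ angles of
2-3 (sialic-type) linkages populate two (−60°, 180°); everything else is treated as
rigid at its class default.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

ALPHA = "α"
BETA = "β"
UNDEFINED = "?"

#: residue code -> (anomeric position, positions a child or substituent may occupy)
RESIDUES: dict[str, tuple[int, tuple[int, ...]]] = {
    "Gal": (1, (2, 3, 4, 6)),
    "Glc": (1, (2, 3, 4, 6)),
    "Man": (1, (2, 3, 4, 6)),
    "GalNAc": (1, (3, 4, 6)),
    "GlcNAc": (1, (3, 4, 6)),
    "ManNAc": (1, (3, 4, 6)),
    "Fuc": (1, (2, 3, 4)),
    "Xyl": (1, (2, 3, 4)),
    "GlcA": (1, (2, 3, 4)),
    "IdoA": (1, (2, 3, 4)),
    "Neu5Ac": (2, (4, 8, 9)),
    "Neu5Gc": (2, (4, 8, 9)),
    "KDN": (2, (4, 8, 9)),
}

_RESIDUE_RE = "|".join(sorted(RESIDUES, key=len, reverse=True))
_ROOT_RE = re.compile(rf"(?P<res>{_RESIDUE_RE})(?P<ano>[αβab?])?$")
_LINKAGE_RE = re.compile(r"(?P<c>\d)-(?P<p>\d)$")
_SUBSTITUENT_RE = re.compile(r"^(?P<pos>\d)(?P<grp>S|P)$")
_AGLYCON_RE = re.compile(r"-(?P<agl>OMe|Me|Sp\w+)$")

_ANOMER_MAP = {"α": ALPHA, "a": ALPHA, "β": BETA, "b": BETA, "?": UNDEFINED}


class GlycanParseError(ValueError):
    """Raised for malformed IUPAC-condensed input; names the offending span."""


@dataclass
class MonosaccharideNode:
    """One pyranose residue in a glycan tree."""

    residue_name: str
    anomeric_config: str = UNDEFINED  # ALPHA, BETA or UNDEFINED
    substituents: list[tuple[int, str]] = field(default_factory=list)
    #: (child anomeric position, position on parent); None for the root
    link_to_parent: tuple[int, int] | None = None
    children: list["MonosaccharideNode"] = field(default_factory=list)

    @property
    def anomeric_position(self) -> int:
        return RESIDUES[self.residue_name][0]

    def walk(self):
        """Pre-order traversal."""
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class GlycanTree:
    """A rooted glycan: the root is the reducing-end residue."""

    root: MonosaccharideNode
    aglycon: str | None = None  # None, "methyl", or a spacer label such as "Sp8"
    source_id: str = ""

    def walk(self):
        yield from self.root.walk()

    def nodes(self) -> list[MonosaccharideNode]:
        return list(self.walk())

    def __len__(self) -> int:
        return sum(1 for _ in self.walk())

    def parent_of(self, node: MonosaccharideNode) -> MonosaccharideNode | None:
        for candidate in self.walk():
            if node in candidate.children:
                return candidate
        return None


# ---------------------------------------------------------------------------
# parsing


def parse_iupac_condensed(text: str, source_id: str = "") -> GlycanTree:
    """Parse one IUPAC-condensed glycan sequence into a :class:`GlycanTree`.

    The rightmost residue becomes the tree root.  Anomeric configurations left
    unstated (e.g. a reducing terminus written ``GalNAc``) are preserved as
    undefined.  Sulfation is accepted both as a parenthesized prefix ``(3S)``
    and as a bare ``6S`` token, and is normalized to a positional substituent.
    Ambiguous linkages such as ``2-3/6`` are rejected here; expand them first
    with :func:`expand_ambiguous_linkages`.
    """
    s = text.strip()
    if not s:
        raise GlycanParseError("empty glycan sequence")
    if s.count("(") != s.count(")"):
        raise GlycanParseError(f"unbalanced parentheses in {text!r}")
    aglycon = None
    m = _AGLYCON_RE.search(s)
    if m:
        label = m.group("agl")
        aglycon = "methyl" if label in ("OMe", "Me") else label
        s = s[: m.start()]
    root = _parse_subtree(s, text)
    return GlycanTree(root=root, aglycon=aglycon, source_id=source_id)


def _parse_subtree(s: str, full: str) -> MonosaccharideNode:
    """Parse a span whose rightmost token is ``Residue[anomer]``."""
    m = _ROOT_RE.search(s)
    if m is None:
        raise GlycanParseError(f"unknown residue code at end of {s!r} (in {full!r})")
    node = MonosaccharideNode(
        residue_name=m.group("res"),
        anomeric_config=_ANOMER_MAP[m.group("ano")] if m.group("ano") else UNDEFINED,
    )
    prefix = s[: m.start()]
    branches: list[str] = []
    while prefix:
        if prefix.endswith(")"):
            group, prefix = _split_paren_group(prefix, full)
            sub = _SUBSTITUENT_RE.match(group)
            if sub:
                _add_substituent(node, int(sub.group("pos")), sub.group("grp"), full)
            else:
                branches.append(group)
        else:
            sub = _SUBSTITUENT_RE.match(prefix)
            if sub:
                _add_substituent(node, int(sub.group("pos")), sub.group("grp"), full)
                prefix = ""
            else:
                branches.append(prefix)
                prefix = ""
    # branches were collected right-to-left; restore written order
    for branch in reversed(branches):
        _attach_branch(node, branch, full)
    return node


def _split_paren_group(prefix: str, full: str) -> tuple[str, str]:
    depth = 0
    for i in range(len(prefix) - 1, -1, -1):
        if prefix[i] == ")":
            depth += 1
        elif prefix[i] == "(":
            depth -= 1
            if depth == 0:
                return prefix[i + 1 : -1], prefix[:i]
    raise GlycanParseError(f"unbalanced parentheses near {prefix!r} (in {full!r})")


def _add_substituent(node: MonosaccharideNode, pos: int, group: str, full: str) -> None:
    _check_position_free(node, pos, full)
    node.substituents.append((pos, group))


def _attach_branch(parent: MonosaccharideNode, branch: str, full: str) -> None:
    if "/" in branch:
        raise GlycanParseError(
            f"ambiguous linkage in {branch!r}; expand with expand_ambiguous_linkages()"
        )
    m = _LINKAGE_RE.search(branch)
    if m is None:
        raise GlycanParseError(f"missing or malformed linkage token in {branch!r} (in {full!r})")
    child = _parse_subtree(branch[: m.start()], full)
    c, p = int(m.group("c")), int(m.group("p"))
    if c != child.anomeric_position:
        raise GlycanParseError(
            f"{child.residue_name} links through position {child.anomeric_position}, "
            f"not {c} (in {full!r})"
        )
    if p not in RESIDUES[parent.residue_name][1]:
        raise GlycanParseError(
            f"position {p} is not a valid attachment site on {parent.residue_name} "
            f"(in {full!r})"
        )
    _check_position_free(parent, p, full)
    child.link_to_parent = (c, p)
    parent.children.append(child)


def _check_position_free(node: MonosaccharideNode, pos: int, full: str) -> None:
    taken = {p for p, _ in node.substituents} | {
        c.link_to_parent[1] for c in node.children
    }
    if pos in taken:
        raise GlycanParseError(
            f"position {pos} on {node.residue_name} occupied twice (in {full!r})"
        )


def expand_ambiguous_linkages(text: str) -> list[str]:
    """Expand ``c-p1/p2`` linkage alternatives into explicit sequences.

    ``"Neu5Acα2-3/6Gal"`` becomes ``["Neu5Acα2-3Gal", "Neu5Acα2-6Gal"]``; the
    Cartesian product is taken when several ambiguous linkages occur.  Sequences
    with no ambiguity are returned as a one-element list.
    """
    m = re.search(r"(\d)-(\d(?:/\d)+)", text)
    if m is None:
        return [text]
    out: list[str] = []
    for p in m.group(2).split("/"):
        variant = text[: m.start()] + f"{m.group(1)}-{p}" + text[m.end() :]
        out.extend(expand_ambiguous_linkages(variant))
    return out


# ---------------------------------------------------------------------------
# serialization


def to_iupac_condensed(tree: GlycanTree) -> str:
    """Canonical IUPAC-condensed serialization.

    Branches on a residue are ordered by parent position; the highest-position
    branch is written unparenthesized (leftmost) and the remainder parenthesized,
    matching the customary array-catalog style, e.g.
    ``Galβ1-4GlcNAcβ1-6(Galβ1-3)GalNAcα``.
    """
    s = _serialize_node(tree.root)
    if tree.aglycon == "methyl":
        s += "-OMe"
    elif tree.aglycon:
        s += f"-{tree.aglycon}"
    return s


def _serialize_node(node: MonosaccharideNode) -> str:
    children = sorted(node.children, key=lambda c: c.link_to_parent[1])
    parts: list[str] = []
    if children:
        last = children[-1]
        parts.append(_serialize_child(last))
        for child in children[:-1]:
            parts.append(f"({_serialize_child(child)})")
    for pos, grp in sorted(node.substituents):
        parts.append(f"({pos}{grp})")
    anomer = "" if node.anomeric_config == UNDEFINED else node.anomeric_config
    parts.append(node.residue_name + anomer)
    return "".join(parts)


def _serialize_child(child: MonosaccharideNode) -> str:
    c, p = child.link_to_parent
    return f"{_serialize_node(child)}{c}-{p}"


def trees_isomorphic(a: GlycanTree | MonosaccharideNode, b: GlycanTree | MonosaccharideNode) -> bool:
    """Structural equality ignoring branch listing order."""
    na = a.root if isinstance(a, GlycanTree) else a
    nb = b.root if isinstance(b, GlycanTree) else b
    if isinstance(a, GlycanTree) and isinstance(b, GlycanTree) and a.aglycon != b.aglycon:
        return False
    return _nodes_isomorphic(na, nb)


def _nodes_isomorphic(a: MonosaccharideNode, b: MonosaccharideNode) -> bool:
    if (
        a.residue_name != b.residue_name
        or a.anomeric_config != b.anomeric_config
        or a.link_to_parent != b.link_to_parent
        or sorted(a.substituents) != sorted(b.substituents)
        or len(a.children) != len(b.children)
    ):
        return False
    ka = sorted(a.children, key=lambda c: c.link_to_parent[1])
    kb = sorted(b.children, key=lambda c: c.link_to_parent[1])
    return all(_nodes_isomorphic(x, y) for x, y in zip(ka, kb))


# ---------------------------------------------------------------------------
# motif location


@dataclass
class MotifMatch:
    """One occurrence of a determinant motif inside a glycan.

    ``branch_attachments`` lists everything hanging off the determinant that is
    not part of the motif itself: extra child subtrees, substituents such as
    sulfate, and — when the determinant root is linked onward toward the
    reducing end — the parent-side chain, reported at the anomeric position.
    """

    matched_nodes: list[MonosaccharideNode]
    branch_attachments: list[tuple[MonosaccharideNode, int, str]]
    anchored_at_root: bool = True


def find_motif(tree: GlycanTree, motif: GlycanTree) -> list[MotifMatch]:
    """Locate every occurrence of ``motif`` in ``tree``.

    A match requires residue names, anomeric configurations and linkage
    positions to be identical; an undefined anomer in the motif acts as a
    wildcard.  When the motif root residue occurs internally (linked onward
    through its anomeric carbon), the reducing-end side of the glycan is
    reported as a branch attachment at the anomeric position.
    """
    matches: list[MotifMatch] = []
    for node in tree.walk():
        mapped: list[tuple[MonosaccharideNode, MonosaccharideNode]] = []
        if _match_at(node, motif.root, mapped, is_anchor=True):
            matched = [t for t, _ in mapped]
            attachments = _collect_attachments(tree, node, matched)
            matches.append(
                MotifMatch(matched, attachments, anchored_at_root=node is tree.root)
            )
    return matches


def _match_at(
    tnode: MonosaccharideNode,
    mnode: MonosaccharideNode,
    mapped: list,
    is_anchor: bool,
) -> bool:
    if tnode.residue_name != mnode.residue_name:
        return False
    if mnode.anomeric_config != UNDEFINED and tnode.anomeric_config != mnode.anomeric_config:
        return False
    if not is_anchor and tnode.link_to_parent != mnode.link_to_parent:
        return False
    checkpoint = len(mapped)
    mapped.append((tnode, mnode))
    for mchild in mnode.children:
        c, p = mchild.link_to_parent
        tchild = next(
            (t for t in tnode.children if t.link_to_parent == (c, p)), None
        )
        if tchild is None or not _match_at(tchild, mchild, mapped, is_anchor=False):
            del mapped[checkpoint:]
            return False
    return True


def _collect_attachments(tree, anchor, matched):
    attachments = []
    for det in matched:
        for pos, grp in det.substituents:
            attachments.append((det, pos, f"substituent {pos}{grp}"))
        for child in det.children:
            if child not in matched:
                c, p = child.link_to_parent
                attachments.append((det, p, f"{_serialize_node(child)}{c}-{p}"))
    if anchor is not tree.root:
        attachments.append(
            (anchor, anchor.anomeric_position, "reducing-end chain at anomeric position")
        )
    return attachments


def tf_motif(anomeric: str = ALPHA) -> GlycanTree:
    """The Thomsen-Friedenreich determinant Galβ1-3GalNAc with the given root anomer."""
    anomer = "" if anomeric == UNDEFINED else anomeric
    return parse_iupac_condensed(f"Galβ1-3GalNAc{anomer}")


# ---------------------------------------------------------------------------
# flexible linkages and rotamer enumeration

OMEGA_ROTAMERS = (60.0, -60.0, 180.0)
PHI23_ROTAMERS = (-60.0, 180.0)


@dataclass(frozen=True)
class FlexibleLinkage:
    """A flexible glycosidic linkage, identified by its child node."""

    child: MonosaccharideNode
    torsion_class: str  # "omega" or "phi23"

    @property
    def label(self) -> str:
        c, p = self.child.link_to_parent
        name = "ω" if self.torsion_class == "omega" else "φ"
        return f"{name}({self.child.residue_name}{c}-{p})"


def classify_flexible_linkages(tree: GlycanTree) -> list[FlexibleLinkage]:
    """Tag each linkage that populates more than one stable rotamer.

    1-6 and 2-6 linkages are ω-flexible (three rotamers); 2-3 linkages are
    φ-flexible (two rotamers); everything else is rigid.
    """
    out: list[FlexibleLinkage] = []
    for node in tree.walk():
        if node.link_to_parent is None:
            continue
        c, p = node.link_to_parent
        if p == 6:
            out.append(FlexibleLinkage(node, "omega"))
        elif c == 2 and p == 3:
            out.append(FlexibleLinkage(node, "phi23"))
    return out


@dataclass
class RotamerAssignment:
    """One discrete torsion choice per flexible linkage, defining a conformer.

    Torsions are keyed by the child node's pre-order index, which is stable
    under tree copies (structure-preserving), unlike object identity.
    """

    torsions: dict[int, tuple[str, float]]  # pre-order index -> (class, degrees)
    label: str

    def value_for(self, node_index: int) -> float | None:
        entry = self.torsions.get(node_index)
        return entry[1] if entry else None


def enumerate_rotamer_assignments(tree: GlycanTree) -> list[RotamerAssignment]:
    """All rotamer combinations: 3^(#ω) × 2^(#φ2-3), in deterministic order.

    Flexible linkages are taken in pre-order; the last-listed linkage varies
    fastest.  A rigid glycan yields the single empty assignment.
    """
    flexible = classify_flexible_linkages(tree)
    index = {id(n): i for i, n in enumerate(tree.walk())}
    value_sets = [
        OMEGA_ROTAMERS if f.torsion_class == "omega" else PHI23_ROTAMERS
        for f in flexible
    ]
    assignments = []
    for combo in itertools.product(*value_sets):
        torsions = {
            index[id(f.child)]: (f.torsion_class, v) for f, v in zip(flexible, combo)
        }
        label = "|".join(
            f"{f.label}:{v:+.0f}" for f, v in zip(flexible, combo)
        ) or "rigid"
        assignments.append(RotamerAssignment(torsions, label))
    return assignments
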