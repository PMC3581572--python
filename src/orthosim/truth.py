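"""True ortholog extraction and reduction of predictions to pairwise form.

Within a gene family, the relation between two extant genes is decided by
the event label of their lowest common ancestor in the gene tree:
speciation -> ortholog, duplication -> paralog, transfer -> xenolog.  Only
orthologs enter the truth set; xenologs (pairs related through a lateral
transfer) are deliberately excluded, so a method that reports a transferred
gene as ortholog of the replaced copy's relatives is counted wrong.

Any method output -- pair lists, ortholog group files, or event-labelled
gene trees -- reduces to a set of unordered cross-species gene pairs, the
common denominator used for scoring.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Sequence, TextIO

from .evolver import GeneTree, GeneTreeNode

__all__ = [
    "PairClass",
    "OrthologPairSet",
    "classify_pair",
    "true_ortholog_pairs",
    "groups_to_pairs",
    "labelled_tree_to_pairs",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "read_groups",
    "parse_nhx_gene_tree",
]


class PairClass(Enum):
    ORTHOLOG = "ortholog"
    PARALOG = "paralog"
    XENOLOG = "xenolog"


_EVENT_TO_CLASS = {
    "speciation": PairClass.ORTHOLOG,
    "duplication": PairClass.PARALOG,
    "transfer": PairClass.XENOLOG,
}


def _species_of(qualified: str) -> str:
    if "|" not in qualified:
        raise ValueError(f"gene id {qualified!r} carries no species tag")
    return qualified.split("|", 1)[0]


class OrthologPairSet:
    """Set of unordered cross-species gene pairs (``species|gene`` ids)."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = (), source: str = ""):
        self.source = source
        self._pairs: set[tuple[str, str]] = set()
        for a, b in pairs:
            self.add(a, b)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-pair {a!r}")
        if _species_of(a) == _species_of(b):
            raise ValueError(f"pair {a!r}/{b!r} joins two genes of one species")
        self._pairs.add(self._key(a, b))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self._key(*pair) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self):
        return iter(self._pairs)

    def __eq__(self, other) -> bool:
        return isinstance(other, OrthologPairSet) and self._pairs == other._pairs

    def intersection(self, other: "OrthologPairSet") -> "OrthologPairSet":
        out = OrthologPairSet(source=f"{self.source}&{other.source}")
        out._pairs = self._pairs & other._pairs
        return out

    def difference(self, other: "OrthologPairSet") -> "OrthologPairSet":
        out = OrthologPairSet(source=f"{self.source}-{other.source}")
        out._pairs = self._pairs - other._pairs
        return out

    def union(self, other: "OrthologPairSet") -> "OrthologPairSet":
        out = OrthologPairSet(source=f"{self.source}|{other.source}")
        out._pairs = self._pairs | other._pairs
        return out

    def sorted_pairs(self) -> list[tuple[str, str]]:
        return sorted(self._pairs)


# --------------------------------------------------------------------------
# classification and truth extraction


def classify_pair(tree: GeneTree, x: GeneTreeNode, y: GeneTreeNode) -> PairClass:
    """Relation of two extant leaves: the event label of their LCA."""
    if x is y:
        raise ValueError("a gene is not paired with itself")
    ancestors_x = []
    node = x
    while node is not None:
        ancestors_x.append(node)
        node = node.parent
    seen = {id(n) for n in ancestors_x}
    node = y
    while node is not None:
        if id(node) in seen:
            lca = node
            break
        node = node.parent
    else:
        raise ValueError("leaves do not share a tree")
    if lca.parent is None and lca.event not in _EVENT_TO_CLASS:
        # a pruned root that kept a non-event label is treated as speciation
        # only if labelled so; otherwise it is an error
        raise ValueError(f"unlabelled LCA node (event={lca.event!r})")
    try:
        return _EVENT_TO_CLASS[lca.event]
    except KeyError:
        raise ValueError(f"unlabelled internal node (event={lca.event!r})") from None


def _pairs_from_labelled_root(root: GeneTreeNode, source: str) -> OrthologPairSet:
    """Union over speciation nodes of the cross products of the leaf sets of
    distinct children, keeping cross-species pairs only."""
    out = OrthologPairSet(source=source)
    leafsets: dict[int, list[tuple[str, str]]] = {}
    for node in reversed(list(root.preorder())):
        if node.is_leaf:
            if node.species is None or node.gene_id is None:
                raise ValueError("leaf without (species, gene) identity")
            leafsets[id(node)] = [(node.species, f"{node.species}|{node.gene_id}")]
            continue
        if node.event not in _EVENT_TO_CLASS:
            raise ValueError(f"unlabelled internal node (event={node.event!r})")
        kids = [leafsets.pop(id(c)) for c in node.children]
        if node.event == "speciation":
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    for sp_a, a in kids[i]:
                        for sp_b, b in kids[j]:
                            if sp_a != sp_b:
                                out.add(a, b)
        leafsets[id(node)] = [g for k in kids for g in k]
    return out


def true_ortholog_pairs(trees: Iterable[GeneTree]) -> OrthologPairSet:
    """Truth set of a simulation: all extant cross-species pairs whose gene
    tree LCA is a speciation node, over all families."""
    out = OrthologPairSet(source="truth")
    for tree in trees:
        if tree is None:
            continue
        fam = _pairs_from_labelled_root(tree.root, source="truth")
        out._pairs |= fam._pairs
    return out


def labelled_tree_to_pairs(tree: GeneTree) -> OrthologPairSet:
    """Pairwise orthologs implied by an externally produced labelled tree;
    identical semantics to :func:`true_ortholog_pairs` for one family."""
    return _pairs_from_labelled_root(tree.root, source="labelled-tree")


def groups_to_pairs(groups: Iterable[Sequence[str]]) -> OrthologPairSet:
    """All cross-species member pairs of each ortholog group, unioned.

    Member ids must be species-qualified (``species|gene``); same-species
    pairs within a group are excluded.
    """
    out = OrthologPairSet(source="groups")
    for group in groups:
        members = list(dict.fromkeys(group))  # de-duplicate, keep order
        for m in members:
            _species_of(m)  # raises on malformed ids
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if _species_of(members[i]) != _species_of(members[j]):
                    out.add(members[i], members[j])
    return out


# --------------------------------------------------------------------------
# readers / writers


def write_pairs_tsv(pairs: OrthologPairSet, handle: TextIO) -> None:
    """Canonical sorted pair TSV: species1 gene1 species2 gene2."""
    for a, b in pairs.sorted_pairs():
        sp_a, g_a = a.split("|", 1)
        sp_b, g_b = b.split("|", 1)
        handle.write(f"{sp_a}\t{g_a}\t{sp_b}\t{g_b}\n")


def read_pairs_tsv(handle: TextIO, source: str = "pairs") -> OrthologPairSet:
    """Read a pair TSV; accepts 2 columns (qualified ids) or >= 4 columns
    (species, gene, species, gene, [extras])."""
    out = OrthologPairSet(source=source)
    for lineno, line in enumerate(handle, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) >= 4:
            a = f"{fields[0]}|{fields[1]}"
            b = f"{fields[2]}|{fields[3]}"
        elif len(fields) == 2:
            a, b = fields
        else:
            raise ValueError(f"line {lineno}: expected 2 or >=4 columns")
        out.add(a, b)
    return out


def read_groups(handle: TextIO) -> list[list[str]]:
    """Parse ortholog group files.

    Supports the OrthoMCL-like layout ``groupid: sp|gene sp|gene ...`` and a
    plain one-group-per-line fallback (whitespace-separated qualified ids).
    """
    groups: list[list[str]] = []
    for lineno, line in enumerate(handle, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" in line.split()[0]:
            line = line.split(":", 1)[1]
        members = line.split()
        for m in members:
            if "|" not in m:
                raise ValueError(
                    f"line {lineno}: member {m!r} carries no species tag"
                )
        if members:
            groups.append(members)
    return groups


_NHX_EVENTS = {"S": "speciation", "D": "duplication", "T": "transfer"}


def parse_nhx_gene_tree(text: str, family: str = "external") -> GeneTree:
    """Parse an annotated Newick gene tree into a labelled :class:`GeneTree`.

    Understands NHX tags ``[&&NHX:Ev=S|D|T]`` and the ``D=Y``/``D=N``
    duplication dialect.  Leaf labels must be ``species|gene`` (the pipe may
    be written as ``|`` or ``_``-free; quoted labels are not supported).
    An internal node without a recognised annotation is an error.
    """
    import re

    import dendropy

    dtree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
        extract_comment_metadata=False,
    )

    def event_of(dnode) -> str | None:
        for comment in dnode.comments or []:
            m = re.search(r"Ev=([SDT])", comment)
            if m:
                return _NHX_EVENTS[m.group(1)]
            m = re.search(r"\bD=([YN])", comment)
            if m:
                return "duplication" if m.group(1) == "Y" else "speciation"
        return None

    def convert(dnode) -> GeneTreeNode:
        length = float(dnode.edge.length or 0.0)
        if not dnode.child_nodes():
            label = dnode.taxon.label if dnode.taxon else None
            if not label or "|" not in label:
                raise ValueError(
                    f"leaf label {label!r} is not species|gene qualified"
                )
            species, gene = label.split("|", 1)
            return GeneTreeNode(
                event="leaf", length=length, species=species, gene_id=gene
            )
        ev = event_of(dnode)
        if ev is None:
            raise ValueError("internal node without speciation/duplication/"
                             "transfer annotation")
        node = GeneTreeNode(event=ev, length=length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return GeneTree(convert(dtree.seed_node), family)


def write_nhx_gene_tree(tree: GeneTree) -> str:
    """Serialize a labelled gene tree with ``[&&NHX:Ev=...]`` node tags."""
    codes = {v: k for k, v in _NHX_EVENTS.items()}

    def render(node: GeneTreeNode) -> str:
        if node.is_leaf:
            return f"{node.species}|{node.gene_id}:{node.length:.17g}"
        inner = ",".join(render(c) for c in node.children)
        tag = f"[&&NHX:Ev={codes[node.event]}]" if node.event in codes else ""
        return f"({inner}):{node.length:.17g}{tag}"

    return render(tree.root) + ";"
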