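"""Species trees with branch lengths in PAM units.

Trees are rooted, with every branch length interpreted directly as an
evolutionary distance in PAM units (1 PAM = 1 expected substitution per 100
sites).  The module reads and writes a plain Newick dialect (unquoted labels,
decimal branch lengths, optional root length), computes summary statistics
(heights, total length, mean pairwise leaf distance) and generates random
birth-death-shaped surrogate trees rescaled to match a target statistic.

Surrogate trees stand in for empirically sampled species phylogenies: a
benchmark regime is characterised here by its leaf count plus either its
total tree length or its mean root-to-leaf height, and the generator rescales
a random topology so the requested statistic is matched exactly while all
leaf pairs stay at least ``min_pair_distance`` PAM apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import count
from typing import Iterator, Optional

import dendropy
import numpy as np

__all__ = [
    "TreeNode",
    "SpeciesTree",
    "TreeStats",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "tree_stats",
    "surrogate_tree",
]


class NewickParseError(ValueError):
    """Raised for malformed Newick input; carries the character offset."""

    def __init__(self, message: str, offset: Optional[int] = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)


@dataclass
class TreeNode:
    """A node of a rooted tree; ``length`` is the PAM length of the branch
    leading into the node (0.0 for a root without a stem)."""

    name: Optional[str] = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["TreeNode"]:
        out: list[TreeNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.preorder() if n.is_leaf]


class SpeciesTree:
    """Rooted species tree with PAM branch lengths and unique leaf labels."""

    def __init__(self, root: TreeNode):
        self.root = root
        labels = [leaf.name for leaf in root.leaves()]
        if any(lab is None for lab in labels):
            raise ValueError("every leaf must carry a species label")
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")
        for node in root.preorder():
            if node.length < 0:
                raise ValueError(f"negative branch length on node {node.name!r}")
        # name internal nodes so event logs can reference their branches
        taken = set(labels)
        counter = count(1)
        for node in root.preorder():
            if node.name is None:
                name = f"n{next(counter)}"
                while name in taken:
                    name = f"n{next(counter)}"
                node.name = name
                taken.add(name)

    @property
    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def depths(self) -> dict[int, float]:
        """Map id(node) -> summed PAM distance from (above) the root,
        including the root's own stem length."""
        out: dict[int, float] = {}
        for node in self.root.preorder():
            parent_depth = out[id(node.parent)] if node.parent is not None else 0.0
            out[id(node)] = parent_depth + node.length
        return out

    def leaf_depths(self) -> dict[str, float]:
        d = self.depths()
        return {leaf.name: d[id(leaf)] for leaf in self.leaves}

    def pairwise_leaf_distances(self) -> np.ndarray:
        """Condensed matrix of path distances between leaves (order of
        :attr:`leaves`)."""
        leaves = self.leaves
        idx = {id(leaf): i for i, leaf in enumerate(leaves)}
        n = len(leaves)
        dist = np.zeros((n, n))
        # Accumulate leaf-to-ancestor distances bottom-up; for each internal
        # node combine the leaf sets of its children.
        below: dict[int, dict[int, float]] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                below[id(node)] = {idx[id(node)]: 0.0}
            else:
                merged: dict[int, float] = {}
                kids = [
                    {i: d + child.length for i, d in below.pop(id(child)).items()}
                    for child in node.children
                ]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for i, di in kids[a].items():
                            for j, dj in kids[b].items():
                                dist[i, j] = dist[j, i] = di + dj
                for k in kids:
                    merged.update(k)
                below[id(node)] = merged
        return dist

    def validate_for_simulation(self, min_pair_distance: float = 1.0) -> None:
        """Check the sampling constraint that every leaf pair is separated by
        at least ``min_pair_distance`` PAM."""
        if self.n_leaves < 2:
            raise ValueError("simulation requires at least 2 species")
        dist = self.pairwise_leaf_distances()
        iu = np.triu_indices(self.n_leaves, k=1)
        dmin = dist[iu].min()
        if dmin < min_pair_distance:
            raise ValueError(
                f"leaf pairs must be >= {min_pair_distance} PAM apart; "
                f"minimum observed is {dmin:.4f}"
            )

    def copy(self) -> "SpeciesTree":
        def clone(node: TreeNode) -> TreeNode:
            c = TreeNode(name=node.name, length=node.length)
            for child in node.children:
                c.add_child(clone(child))
            return c

        return SpeciesTree(clone(self.root))


@dataclass(frozen=True)
class TreeStats:
    """Summary statistics of a species tree, all in PAM units."""

    n_leaves: int
    total_length: float
    min_height: float
    max_height: float
    mean_height: float
    mean_pairwise_distance: float

    def as_row(self) -> dict[str, float]:
        return {
            "n_leaves": self.n_leaves,
            "total_length": self.total_length,
            "min_height": self.min_height,
            "max_height": self.max_height,
            "mean_height": self.mean_height,
            "mean_pairwise_distance": self.mean_pairwise_distance,
        }


def parse_newick(text: str) -> SpeciesTree:
    """Parse a Newick string with branch lengths into a :class:`SpeciesTree`.

    Every non-root edge must carry an explicit branch length; a missing
    length is an error rather than silently treated as zero.
    """
    text = text.strip()
    if not text:
        raise NewickParseError("empty Newick input", 0)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        offset = None
        # dendropy DataError exposes line_num/col_num; recover an offset
        col = getattr(exc, "col_num", None)
        line = getattr(exc, "line_num", None)
        if col is not None:
            offset = col - 1
            if line is not None and line > 1:
                lines = text.splitlines(keepends=True)
                offset += sum(len(l) for l in lines[: line - 1])
        raise NewickParseError(f"malformed Newick: {exc}", offset) from exc

    def convert(dnode, is_root: bool) -> TreeNode:
        if dnode.edge.length is None:
            if not is_root:
                label = dnode.taxon.label if dnode.taxon else "<internal>"
                raise NewickParseError(
                    f"missing branch length on node {label!r}"
                )
            length = 0.0
        else:
            length = float(dnode.edge.length)
        name = dnode.taxon.label if dnode.taxon is not None else None
        node = TreeNode(name=name, length=length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild, False))
        return node

    return SpeciesTree(convert(dtree.seed_node, True))


def write_newick(tree: SpeciesTree, include_root_length: bool = True) -> str:
    """Serialize to Newick; round-trips through :func:`parse_newick`."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.length:.17g}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}):{node.length:.17g}"

    root = tree.root
    inner = ",".join(render(c) for c in root.children) if root.children else (root.name or "")
    if root.children:
        s = f"({inner})"
    else:
        s = root.name or ""
    if include_root_length:
        s += f":{root.length:.17g}"
    return s + ";"


def tree_stats(tree: SpeciesTree) -> TreeStats:
    """Compute :class:`TreeStats`; requires at least two leaves (pairwise
    distances are undefined otherwise)."""
    if tree.n_leaves < 2:
        raise ValueError("tree statistics require at least 2 leaves")
    heights = np.array(list(tree.leaf_depths().values()))
    total = sum(n.length for n in tree.root.preorder())
    dist = tree.pairwise_leaf_distances()
    iu = np.triu_indices(tree.n_leaves, k=1)
    return TreeStats(
        n_leaves=tree.n_leaves,
        total_length=float(total),
        min_height=float(heights.min()),
        max_height=float(heights.max()),
        mean_height=float(heights.mean()),
        mean_pairwise_distance=float(dist[iu].mean()),
    )


def _birth_death_topology(
    n_leaves: int, rng: np.random.Generator, rate_jitter_sd: float = 0.25
) -> SpeciesTree:
    """Pure-birth (Yule) tree shape with a final holding time so tips have
    positive length, then mild lognormal rate multipliers per branch so the
    tree is not exactly ultrametric (real species trees are not)."""
    root = TreeNode()
    tips: list[TreeNode] = [root.add_child(TreeNode()), root.add_child(TreeNode())]
    elapsed = 0.0
    birth_times: dict[int, float] = {id(t): 0.0 for t in tips}
    while True:
        elapsed += rng.exponential(1.0 / len(tips))
        if len(tips) == n_leaves:
            break
        i = int(rng.integers(0, len(tips)))
        parent = tips.pop(i)
        parent.length = elapsed - birth_times.pop(id(parent))
        for _ in range(2):
            child = parent.add_child(TreeNode())
            birth_times[id(child)] = elapsed
            tips.append(child)
    for i, tip in enumerate(tips, 1):
        tip.length = elapsed - birth_times[id(tip)]
        tip.name = f"S{i:02d}"
    if rate_jitter_sd > 0:
        for node in root.preorder():
            if node.parent is not None:
                node.length *= float(rng.lognormal(0.0, rate_jitter_sd))
    return SpeciesTree(root)


def surrogate_tree(
    n_leaves: int,
    target: TreeStats,
    rng: np.random.Generator,
    match: str = "total_length",
    min_pair_distance: float = 1.0,
    max_tries: int = 200,
) -> tuple[SpeciesTree, TreeStats]:
    """Generate a random birth-death-shaped tree rescaled so that one target
    statistic is matched exactly.

    Parameters
    ----------
    n_leaves:
        Number of extant species (>= 2).
    target:
        Target statistics; only the field selected by ``match`` is enforced
        exactly.  The achieved statistics are returned alongside the tree.
    match:
        ``"total_length"`` (default) rescales so the summed branch lengths
        equal ``target.total_length``; ``"mean_height"`` rescales so the mean
        root-to-leaf PAM depth equals ``target.mean_height``.
    min_pair_distance:
        Rejection constraint: every leaf pair must be at least this many PAM
        apart (rescale-and-reject loop).

    Returns
    -------
    (tree, achieved_stats)
    """
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    if match not in ("total_length", "mean_height"):
        raise ValueError(f"unknown match criterion {match!r}")
    target_value = getattr(target, match)
    if target_value <= 0:
        raise ValueError(f"target {match} must be positive")

    best_violation = np.inf
    for _ in range(max_tries):
        if n_leaves == 2:
            root = TreeNode()
            root.add_child(TreeNode(name="S01", length=0.5))
            root.add_child(TreeNode(name="S02", length=0.5))
            tree = SpeciesTree(root)
        else:
            tree = _birth_death_topology(n_leaves, rng)
        stats = tree_stats(tree)
        scale = target_value / getattr(stats, match)
        for node in tree.root.preorder():
            node.length *= scale
        achieved = tree_stats(tree)
        dist = tree.pairwise_leaf_distances()
        iu = np.triu_indices(n_leaves, k=1)
        dmin = float(dist[iu].min())
        if dmin >= min_pair_distance:
            return tree, achieved
        best_violation = min(best_violation, min_pair_distance - dmin)
    raise RuntimeError(
        f"could not satisfy the >= {min_pair_distance} PAM pair-distance "
        f"constraint in {max_tries} attempts (best attempt fell short by "
        f"{best_violation:.4f} PAM); the target may be too short for "
        f"{n_leaves} leaves"
    )
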