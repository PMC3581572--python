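"""Genome evolution simulator: gene families along a species tree.

Each root gene founds a family that evolves down the species tree.  Three
gene-level event types act as independent Poisson processes with per-gene,
per-PAM rates:

* duplication -- one gene is copied in place; both copies continue on the
  same species branch, and the gene tree gains a duplication node;
* loss -- the gene lineage terminates;
* lateral gene transfer (LGT), modelled as orthologous replacement -- the
  gene is copied into a contemporaneous recipient species branch where it
  *replaces* that species' existing copy of the same family (the replaced
  lineage terminates); the gene tree gains a transfer node whose children
  are the donor continuation and the transferred lineage.

Because lineages interact through transfers, each family is simulated on a
global clock: depth from the root (in PAM) orders all events across the
whole species tree via a priority queue.

Sequence-level evolution runs along the resulting (pruned) gene tree:
insertions and deletions occur as a per-site Poisson process with the length
of the current sequence modulating the total rate (Gillespie sampling of
event times), indel lengths are Zipf distributed, insertion content is drawn
from the stationary distribution, and substitutions are applied site-wise
over the full branch length.  Every insertion allocates fresh columns in a
per-family master column order, so the true multiple alignment of the extant
family members is known exactly and is emitted alongside the sequences.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, asdict
from typing import Iterator, Optional

import numpy as np

from .phylo import SpeciesTree, TreeNode
from .substitution import (
    SubstitutionModel,
    evolve_indices,
    indices_to_seq,
    sample_stationary,
    seq_to_indices,
    wag_model,
)

__all__ = [
    "ScenarioConfig",
    "GeneTreeNode",
    "GeneTree",
    "Gene",
    "SimulatedDataset",
    "AlignmentTrack",
    "TrackedSequence",
    "sample_root_genome",
    "sample_indel_length",
    "evolve_gene_branch",
    "simulate_family",
    "simulate_dataset",
    "gamma_params_from_mean_sd",
]


# --------------------------------------------------------------------------
# configuration


def gamma_params_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """(shape, scale) of a gamma distribution with the given mean and sd."""
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return shape, scale


@dataclass
class ScenarioConfig:
    """All simulation parameters for one scenario cell.

    Rates are per PAM unit: ``dup_rate``/``loss_rate``/``lgt_rate`` per gene,
    ``ins_rate``/``del_rate`` per site.  Sequence lengths at the root are
    gamma distributed (``length_shape``, ``length_scale`` in residues),
    redrawn until at least ``min_length``.  Indel lengths follow a Zipf law
    with exponent ``zipf_exponent`` truncated at ``max_indel_len``.
    ``artefact_mu``/``artefact_sd`` parametrise the downstream ambiguity
    masking (proportion of sequence length); zero means no masking.
    """

    n_root_families: int = 1000
    length_shape: float = 2.8366
    length_scale: float = 112.8125
    min_length: int = 50
    dup_rate: float = 0.0
    loss_rate: float = 0.0
    lgt_rate: float = 0.0
    ins_rate: float = 0.000125
    del_rate: float = 0.000125
    zipf_exponent: float = 1.821
    max_indel_len: int = 50
    artefact_mu: float = 0.0
    artefact_sd: float = 0.0
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dup_rate", "loss_rate", "lgt_rate", "ins_rate", "del_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.artefact_mu <= 1.0):
            raise ValueError("artefact_mu must lie in [0, 1]")
        if self.artefact_sd < 0:
            raise ValueError("artefact_sd must be >= 0")
        if self.length_shape <= 0 or self.length_scale <= 0:
            raise ValueError("gamma length parameters must be positive")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.zipf_exponent <= 1.0:
            raise ValueError("zipf_exponent must exceed 1")
        if self.max_indel_len < 1:
            raise ValueError("max_indel_len must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(**d)


# --------------------------------------------------------------------------
# gene trees


@dataclass
class GeneTreeNode:
    """Node of an event-labelled gene tree.

    ``event`` is one of ``"root"``, ``"speciation"``, ``"duplication"``,
    ``"transfer"`` or ``"leaf"``.  ``species`` names the species-tree branch
    the node sits on (for leaves: the species of the extant gene).  Depths
    are summed PAM from the gene-tree root; ``length`` is the PAM branch into
    the node.
    """

    event: str
    depth: float = 0.0
    length: float = 0.0
    species: Optional[str] = None
    gene_id: Optional[str] = None
    n_dup: int = 0
    n_transfer: int = 0
    children: list["GeneTreeNode"] = field(default_factory=list)
    parent: Optional["GeneTreeNode"] = None

    def add_child(self, child: "GeneTreeNode") -> "GeneTreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return self.event == "leaf"

    def preorder(self) -> Iterator["GeneTreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


class GeneTree:
    """Event-labelled gene tree of one family (extant lineages only)."""

    def __init__(self, root: GeneTreeNode, family: str):
        self.root = root
        self.family = family

    def leaves(self) -> list[GeneTreeNode]:
        return [n for n in self.root.preorder() if n.is_leaf]

    def internal_nodes(self) -> list[GeneTreeNode]:
        return [n for n in self.root.preorder() if not n.is_leaf]


# --------------------------------------------------------------------------
# dataset containers


@dataclass
class Gene:
    species: str
    gene_id: str
    family: str
    sequence: str
    n_dup: int = 0
    n_transfer: int = 0
    degenerate: bool = False

    @property
    def qualified_id(self) -> str:
        return f"{self.species}|{self.gene_id}"


@dataclass
class EventRecord:
    event: str
    family: str
    species_branch: str
    depth: float
    detail: str = ""


@dataclass
class SimulatedDataset:
    """Everything one simulation replicate knows with certainty."""

    genomes: dict[str, list[Gene]]
    gene_trees: dict[str, GeneTree]
    true_msas: dict[str, tuple[list[str], list[str]]]  # family -> (row ids, rows)
    event_log: list[EventRecord]
    config: Optional[ScenarioConfig] = None

    def all_genes(self) -> Iterator[Gene]:
        for species in sorted(self.genomes):
            yield from self.genomes[species]

    def n_genes(self) -> int:
        return sum(len(g) for g in self.genomes.values())


# --------------------------------------------------------------------------
# root genome and indel lengths


def sample_root_genome(
    cfg: ScenarioConfig, model: SubstitutionModel, rng: np.random.Generator
) -> list[str]:
    """Ancestral gene set: stationary sequences with gamma-distributed
    integer lengths, redrawn until >= cfg.min_length."""
    seqs = []
    for _ in range(cfg.n_root_families):
        while True:
            length = int(round(rng.gamma(cfg.length_shape, cfg.length_scale)))
            if length >= cfg.min_length:
                break
        seqs.append(sample_stationary(length, model, rng))
    return seqs


_zipf_cache: dict[tuple[float, int], np.ndarray] = {}


def _zipf_cdf(c: float, l_max: int) -> np.ndarray:
    key = (c, l_max)
    cdf = _zipf_cache.get(key)
    if cdf is None:
        pmf = np.arange(1, l_max + 1, dtype=float) ** (-c)
        pmf /= pmf.sum()
        cdf = np.cumsum(pmf)
        _zipf_cache[key] = cdf
    return cdf


def sample_indel_length(c: float, l_max: int, rng: np.random.Generator) -> int:
    """Truncated Zipf draw: P(l) proportional to l^(-c) on {1..l_max}."""
    if c <= 1.0:
        raise ValueError("zipf exponent must exceed 1")
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    cdf = _zipf_cdf(c, l_max)
    return int(np.searchsorted(cdf, rng.random()) + 1)


# --------------------------------------------------------------------------
# alignment tracking


_HEAD = -1
_TAIL = -2


class AlignmentTrack:
    """Master column order of one family's true alignment.

    Columns are integer ids in a doubly linked list; insertions splice new
    ids next to their anchor column so that every lineage's column list stays
    a subsequence of the master order.
    """

    def __init__(self, n_initial: int):
        self._next: dict[int, int] = {}
        self._prev: dict[int, int] = {}
        prev = _HEAD
        for col in range(n_initial):
            self._next[prev] = col
            self._prev[col] = prev
            prev = col
        self._next[prev] = _TAIL
        self._prev[_TAIL] = prev
        self._counter = n_initial

    def insert_run(self, anchor: Optional[int], before: Optional[int], k: int) -> list[int]:
        """Allocate ``k`` fresh columns after ``anchor`` (or immediately
        before ``before`` when inserting at the start of a lineage)."""
        if anchor is None:
            anchor = self._prev[before] if before is not None else self._prev[_TAIL]
        new = list(range(self._counter, self._counter + k))
        self._counter += k
        nxt = self._next[anchor]
        prev = anchor
        for col in new:
            self._next[prev] = col
            self._prev[col] = prev
            prev = col
        self._next[prev] = nxt
        self._prev[nxt] = prev
        return new

    def column_order(self) -> list[int]:
        out = []
        col = self._next[_HEAD]
        while col != _TAIL:
            out.append(col)
            col = self._next[col]
        return out


@dataclass
class TrackedSequence:
    """A sequence plus the master-alignment columns its residues occupy."""

    residues: np.ndarray  # int8 codes into the amino-acid alphabet
    columns: list[int]
    track: AlignmentTrack
    degenerate: bool = False

    @classmethod
    def from_string(cls, seq: str, track: Optional[AlignmentTrack] = None) -> "TrackedSequence":
        if track is None:
            track = AlignmentTrack(len(seq))
            cols = list(range(len(seq)))
        else:
            cols = track.insert_run(None, None, len(seq))
        return cls(seq_to_indices(seq), cols, track)

    def to_string(self) -> str:
        return indices_to_seq(self.residues)

    def copy(self) -> "TrackedSequence":
        return TrackedSequence(
            self.residues.copy(), list(self.columns), self.track, self.degenerate
        )


def evolve_gene_branch(
    ts: TrackedSequence,
    b: float,
    cfg: ScenarioConfig,
    model: SubstitutionModel,
    rng: np.random.Generator,
) -> TrackedSequence:
    """Evolve a tracked sequence along a branch of ``b`` PAM.

    Indel events are placed first by a Gillespie walk whose total rate is
    ``(ins_rate + del_rate) * current_length`` per PAM (the event count is
    Poisson conditional on the length trajectory); substitutions are then
    applied site-wise over the full branch length.  Deletions are truncated
    at the sequence end.  A sequence that shrinks below one residue is kept
    but flagged degenerate.
    """
    if b < 0:
        raise ValueError("branch length must be >= 0")
    out = ts.copy()
    total_indel = cfg.ins_rate + cfg.del_rate
    if total_indel > 0 and b > 0:
        residues = list(out.residues)
        cols = out.columns
        t = 0.0
        while True:
            L = len(residues)
            if L == 0:
                out.degenerate = True
                break
            rate = total_indel * L
            t += rng.exponential(1.0 / rate)
            if t >= b:
                break
            length = sample_indel_length(cfg.zipf_exponent, cfg.max_indel_len, rng)
            if rng.random() < cfg.ins_rate / total_indel:
                pos = int(rng.integers(0, L + 1))
                anchor = cols[pos - 1] if pos > 0 else None
                before = cols[0] if pos == 0 else None
                new_cols = out.track.insert_run(anchor, before, length)
                new_res = rng.choice(20, size=length, p=model.pi)
                residues[pos:pos] = list(new_res)
                cols[pos:pos] = new_cols
            else:
                start = int(rng.integers(0, L))
                length = min(length, L - start)
                del residues[start : start + length]
                del cols[start : start + length]
        out.residues = np.array(residues, dtype=np.int8)
    if len(out.residues) == 0:
        out.degenerate = True
        return out
    out.residues = evolve_indices(out.residues, b, model, rng)
    return out


# --------------------------------------------------------------------------
# genealogy simulation (topology + events on the global depth clock)


@dataclass
class _Lineage:
    lid: int
    species_node: TreeNode  # the species-tree node whose incoming edge hosts it
    attach: GeneTreeNode  # gene-tree node this lineage descends from
    start_depth: float
    n_dup: int
    n_transfer: int
    alive: bool = True


def _species_edges(tree: SpeciesTree) -> tuple[dict[int, float], list[TreeNode]]:
    depths = tree.depths()
    nodes = [n for n in tree.root.preorder()]
    return depths, nodes


def simulate_genealogy(
    species_tree: SpeciesTree,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    family: str,
) -> tuple[Optional[GeneTree], list[EventRecord]]:
    """Simulate the event-labelled gene tree of one family.

    Returns the pruned gene tree (``None`` if the family went extinct) and
    the family's event log.  Leaf nodes carry per-lineage duplication and
    transfer counters accumulated on the *unpruned* root-to-leaf path, so
    the duplication/LGT background of a dataset can be measured exactly as
    the paper-style proportion of extant genes with such an event in their
    history.
    """
    depths = species_tree.depths()
    total_rate = cfg.dup_rate + cfg.loss_rate + cfg.lgt_rate
    events: list[EventRecord] = []

    root_gnode = GeneTreeNode(event="root", depth=0.0, species=None)
    lineages: dict[int, _Lineage] = {}
    heap: list[tuple[float, int, int]] = []  # (depth, tiebreak, lid)
    counter = 0
    leaf_counter = 0

    def schedule(lin: _Lineage) -> None:
        nonlocal counter
        edge_end = depths[id(lin.species_node)]
        if total_rate > 0:
            wait = rng.exponential(1.0 / total_rate)
        else:
            wait = math.inf
        when = min(lin.start_depth + wait, edge_end)
        # store the pending depth on the lineage so stale heap entries can
        # be recognised after a transfer kills a lineage
        heapq.heappush(heap, (when, counter, lin.lid))
        counter += 1

    def new_lineage(species_node: TreeNode, attach: GeneTreeNode, start: float,
                    n_dup: int, n_transfer: int) -> _Lineage:
        nonlocal counter
        lin = _Lineage(counter, species_node, attach, start, n_dup, n_transfer)
        counter += 1
        lineages[lin.lid] = lin
        schedule(lin)
        return lin

    new_lineage(species_tree.root, root_gnode, 0.0, 0, 0)

    while heap:
        depth, _, lid = heapq.heappop(heap)
        lin = lineages.get(lid)
        if lin is None or not lin.alive:
            continue
        edge_end = depths[id(lin.species_node)]
        if depth >= edge_end - 1e-15 or depth >= edge_end:
            # reached the species node at the bottom of the edge
            node_depth = edge_end
            sp = lin.species_node
            if sp.is_leaf:
                leaf_counter += 1
                leaf = GeneTreeNode(
                    event="leaf",
                    depth=node_depth,
                    length=node_depth - lin.attach.depth,
                    species=sp.name,
                    gene_id=f"{family}.{leaf_counter:03d}",
                    n_dup=lin.n_dup,
                    n_transfer=lin.n_transfer,
                )
                lin.attach.add_child(leaf)
                lin.alive = False
                del lineages[lid]
            else:
                snode = GeneTreeNode(
                    event="speciation",
                    depth=node_depth,
                    length=node_depth - lin.attach.depth,
                    species=sp.name,
                )
                lin.attach.add_child(snode)
                lin.alive = False
                del lineages[lid]
                for child in sp.children:
                    new_lineage(child, snode, node_depth, lin.n_dup, lin.n_transfer)
            continue

        # gene-level event at this depth
        u = rng.random() * total_rate
        branch_name = lin.species_node.name
        if u < cfg.dup_rate:
            dnode = GeneTreeNode(
                event="duplication",
                depth=depth,
                length=depth - lin.attach.depth,
                species=branch_name,
            )
            lin.attach.add_child(dnode)
            lin.alive = False
            del lineages[lid]
            # the continuing copy keeps its history; only the new copy
            # "arose by duplication"
            new_lineage(lin.species_node, dnode, depth, lin.n_dup, lin.n_transfer)
            new_lineage(lin.species_node, dnode, depth, lin.n_dup + 1, lin.n_transfer)
            events.append(EventRecord("duplication", family, branch_name, depth))
        elif u < cfg.dup_rate + cfg.loss_rate:
            lin.alive = False
            del lineages[lid]
            events.append(EventRecord("loss", family, branch_name, depth))
        else:
            # lateral transfer by orthologous replacement
            eligible = [
                l
                for l in lineages.values()
                if l.alive
                and l.lid != lid
                and l.species_node is not lin.species_node
                and l.start_depth <= depth <= depths[id(l.species_node)]
            ]
            # group by recipient species edge; pick the edge uniformly, then
            # a resident gene copy uniformly within it
            by_edge: dict[str, list[_Lineage]] = {}
            for l in eligible:
                by_edge.setdefault(l.species_node.name, []).append(l)
            if not by_edge:
                events.append(
                    EventRecord("transfer_skipped", family, branch_name, depth,
                                "no eligible recipient lineage")
                )
                schedule_from = depth
                lin.start_depth = schedule_from
                schedule(lin)
                continue
            edge_ids = sorted(by_edge)
            recipients = by_edge[edge_ids[int(rng.integers(0, len(edge_ids)))]]
            victim = recipients[int(rng.integers(0, len(recipients)))]
            victim.alive = False
            del lineages[victim.lid]
            recipient_branch = victim.species_node.name
            events.append(
                EventRecord(
                    "transfer", family, branch_name, depth,
                    f"recipient={recipient_branch}",
                )
            )
            events.append(
                EventRecord(
                    "replaced", family, recipient_branch, depth,
                    f"donor={branch_name}",
                )
            )
            tnode = GeneTreeNode(
                event="transfer",
                depth=depth,
                length=depth - lin.attach.depth,
                species=branch_name,
            )
            lin.attach.add_child(tnode)
            lin.alive = False
            del lineages[lid]
            # donor continuation keeps its history; the copy in the
            # recipient species "originated from an LGT event"
            new_lineage(lin.species_node, tnode, depth, lin.n_dup, lin.n_transfer)
            new_lineage(victim.species_node, tnode, depth, lin.n_dup, lin.n_transfer + 1)

    pruned = _prune(root_gnode)
    if pruned is None:
        return None, events
    return GeneTree(pruned, family), events


def _prune(root: GeneTreeNode) -> Optional[GeneTreeNode]:
    """Drop subtrees without extant leaves and suppress unary nodes,
    merging branch lengths."""

    def rec(node: GeneTreeNode) -> Optional[GeneTreeNode]:
        if node.is_leaf:
            return node
        kept = []
        for child in node.children:
            sub = rec(child)
            if sub is not None:
                kept.append(sub)
        if not kept:
            return None
        if len(kept) == 1:
            only = kept[0]
            only.length += node.length
            only.parent = node.parent
            return only
        node.children = []
        for child in kept:
            node.add_child(child)
        return node

    out = rec(root)
    if out is not None:
        out.parent = None
    return out


# --------------------------------------------------------------------------
# full family / dataset simulation


def simulate_family(
    species_tree: SpeciesTree,
    cfg: ScenarioConfig,
    model: SubstitutionModel,
    family_root_seq: str,
    rng: np.random.Generator,
    family: str = "F0000",
    evolve_sequences: bool = True,
) -> tuple[Optional[GeneTree], Optional[tuple[list[str], list[str]]], list[Gene], list[EventRecord]]:
    """Simulate one family end to end.

    Returns (gene tree, true MSA, extant genes, events); the tree is ``None``
    when the family is lost everywhere.  With ``evolve_sequences=False`` only
    the genealogy is produced (sequences empty) -- used for event-rate
    calibration where sequence content is irrelevant.
    """
    tree, events = simulate_genealogy(species_tree, cfg, rng, family)
    if tree is None:
        return None, None, [], events

    genes: list[Gene] = []
    if not evolve_sequences:
        for leaf in tree.leaves():
            genes.append(
                Gene(leaf.species, leaf.gene_id, family, "",
                     n_dup=leaf.n_dup, n_transfer=leaf.n_transfer)
            )
        return tree, None, genes, events

    track = AlignmentTrack(len(family_root_seq))
    root_ts = TrackedSequence(
        seq_to_indices(family_root_seq), list(range(len(family_root_seq))), track
    )
    leaf_states: dict[int, TrackedSequence] = {}

    # iterative DFS carrying the tracked sequence down the pruned gene tree
    stack: list[tuple[GeneTreeNode, TrackedSequence]] = [(tree.root, root_ts)]
    while stack:
        node, state = stack.pop()
        if node is not tree.root:
            state = evolve_gene_branch(state, node.length, cfg, model, rng)
        if node.is_leaf:
            leaf_states[id(node)] = state
        else:
            for child in reversed(node.children):
                stack.append((child, state))

    row_ids: list[str] = []
    col_maps: list[dict[int, str]] = []
    for leaf in tree.leaves():
        state = leaf_states[id(leaf)]
        seq = state.to_string()
        genes.append(
            Gene(leaf.species, leaf.gene_id, family, seq,
                 n_dup=leaf.n_dup, n_transfer=leaf.n_transfer,
                 degenerate=state.degenerate)
        )
        if state.degenerate:
            events.append(
                EventRecord("degenerate", family, leaf.species, leaf.depth,
                            f"gene={leaf.gene_id}")
            )
        row_ids.append(f"{leaf.species}|{leaf.gene_id}")
        col_maps.append(dict(zip(state.columns, seq)))

    order = [
        col for col in track.column_order() if any(col in m for m in col_maps)
    ]
    rows = [
        "".join(m.get(col, "-") for col in order) for m in col_maps
    ]
    return tree, (row_ids, rows), genes, events


def simulate_dataset(
    species_tree: SpeciesTree,
    cfg: ScenarioConfig,
    rng: Optional[np.random.Generator] = None,
    model: Optional[SubstitutionModel] = None,
    evolve_sequences: bool = True,
) -> SimulatedDataset:
    """Simulate all root families of one replicate.

    Fully reproducible: with ``rng=None`` a generator is seeded from
    ``cfg.seed``; the scenario runner derives one generator per replicate.
    """
    species_tree.validate_for_simulation()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if model is None:
        model = wag_model()

    root_seqs = (
        sample_root_genome(cfg, model, rng)
        if evolve_sequences
        else [""] * cfg.n_root_families
    )
    genomes: dict[str, list[Gene]] = {leaf.name: [] for leaf in species_tree.leaves}
    gene_trees: dict[str, GeneTree] = {}
    true_msas: dict[str, tuple[list[str], list[str]]] = {}
    event_log: list[EventRecord] = []
    width = max(4, len(str(cfg.n_root_families - 1)))
    for i, root_seq in enumerate(root_seqs):
        family = f"F{i:0{width}d}"
        tree, msa, genes, events = simulate_family(
            species_tree, cfg, model, root_seq, rng, family,
            evolve_sequences=evolve_sequences,
        )
        event_log.extend(events)
        if tree is None:
            continue
        gene_trees[family] = tree
        if msa is not None:
            true_msas[family] = msa
        for gene in genes:
            genomes[gene.species].append(gene)
    return SimulatedDataset(genomes, gene_trees, true_msas, event_log, cfg)
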