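"""Synthetic-data generators with known ground truth.

simulate_family evolves a gene family along a species tree under a
linear birth-death process (per-copy duplication rate lambda, loss rate
mu, single ancestral copy by default) and logs every true event against
its species branch, so reconciliation inferences can be scored for both
count and placement.  scramble perturbs a gene tree by random NNIs and
marks the touched edges with low support - the test harness for the
constrained rearrangement search.  evolve_sequences runs Jukes-Cantor
sites along the tree; simulate_mm draws noisy Michaelis-Menten rate
data in triplicate.

All generators take a seed and derive per-component substreams from it
deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kinetics import RateSeries, michaelis_menten
from .rearrangement import SyntenyTable, nni_edges, nni_neighbors
from .trees import GeneTree, SpeciesTree, Tree, TreeNode

__all__ = [
    "SimParams",
    "SimResult",
    "simulate_family",
    "scramble",
    "evolve_sequences",
    "emit_synteny",
    "simulate_mm",
]


@dataclass(frozen=True)
class SimParams:
    """Birth-death gene-family parameters.

    Rates are events per gene copy per unit branch length; the family
    starts from ``root_copies`` ancestral copies at the species root.
    """

    dup_rate: float = 0.1
    loss_rate: float = 0.05
    seed: int = 0
    root_copies: int = 1

    def __post_init__(self):
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.root_copies < 1:
            raise ValueError("root_copies must be >= 1")


@dataclass
class SimResult:
    """Simulation output: surviving-copy gene tree plus the true event log.

    ``events`` rows: type (duplication|loss), species_branch (child-node
    id of the branch the event occurred on), time (offset from the top of
    that branch).  ``gene_order`` is the left-to-right gene order along
    each species' single scaffold (tandem copies adjacent).
    """

    gene_tree: Optional[GeneTree]
    events: pd.DataFrame
    extinct: bool
    gene_order: dict[str, list[str]]

    @property
    def n_true_events(self) -> int:
        return len(self.events)


class _Lineage:
    __slots__ = ("node",)

    def __init__(self, node: TreeNode):
        self.node = node


def simulate_family(
    s: SpeciesTree, params: SimParams, resample_extinct: bool = False
) -> SimResult:
    """Evolve one gene family along *s* under the birth-death process.

    Each extant copy waits an Exp(lambda+mu) time; the event is a
    duplication with probability lambda/(lambda+mu), else a loss.  At a
    species split every surviving copy enters both child branches.
    Extinct families (no survivors) are returned with ``extinct=True``
    unless ``resample_extinct`` asks for redraws (bounded at 1000).
    """
    for node in s.tree.postorder():
        if not node.is_root and (node.length is None or node.length <= 0):
            raise ValueError("simulate_family requires positive branch lengths")
    rng = np.random.default_rng(params.seed)
    for attempt in range(1000):
        result = _simulate_once(s, params, rng)
        if not result.extinct or not resample_extinct:
            return result
    raise RuntimeError("1000 consecutive extinct families; raise the rates?")


def _simulate_once(s: SpeciesTree, params: SimParams, rng) -> SimResult:
    lam, mu = params.dup_rate, params.loss_rate
    total = lam + mu
    events: list[dict] = []
    gene_order: dict[str, list[str]] = {}
    leaf_nodes: list[TreeNode] = []

    def evolve_branch(snode: TreeNode, order: list[TreeNode]) -> list[TreeNode]:
        """Evolve the ordered copy population along the branch above snode;
        returns the surviving ordered population at the bottom."""
        branch_id = s.node_id(snode)
        length = snode.length
        t = 0.0
        pop = list(order)
        while pop:
            if total == 0:
                break
            wait = rng.exponential(1.0 / (total * len(pop)))
            if t + wait > length:
                break
            t += wait
            idx = rng.integers(len(pop))
            victim = pop[idx]
            if rng.random() < (lam / total if total else 0.0):
                events.append(
                    {"type": "duplication", "species_branch": branch_id, "time": t}
                )
                left, right = TreeNode(), TreeNode()
                victim.dup = True
                victim.add_child(left)
                victim.add_child(right)
                pop[idx] = left
                pop.insert(idx + 1, right)  # tandem: new copy adjacent
            else:
                events.append(
                    {"type": "loss", "species_branch": branch_id, "time": t}
                )
                victim.species = "__extinct__"
                pop.pop(idx)
        return pop

    def descend(snode: TreeNode, incoming: list[TreeNode]) -> None:
        if snode.is_leaf:
            order = []
            for copy in incoming:
                copy.species = snode.label
                leaf_nodes.append(copy)
                order.append(copy)
            gene_order[snode.label] = order  # gene ids assigned after pruning
            return
        for child in snode.children:
            pop = [TreeNode() for _ in incoming]
            for parent_copy, new in zip(incoming, pop):
                parent_copy.add_child(new)
            survivors = evolve_branch(child, pop)
            descend(child, survivors)

    root_copies = [TreeNode() for _ in range(params.root_copies)]
    if params.root_copies == 1:
        virtual_root = root_copies[0]
    else:
        virtual_root = TreeNode()
        for c in root_copies:
            virtual_root.dup = True
            virtual_root.add_child(c)
    descend(s.tree.root, root_copies)

    events_df = pd.DataFrame(events, columns=["type", "species_branch", "time"])
    # prune lineages with no surviving descendants, suppress unary nodes
    surviving = set()
    for leaf in leaf_nodes:
        cur = leaf
        while cur is not None:
            surviving.add(id(cur))
            cur = cur.parent
    if id(virtual_root) not in surviving:
        return SimResult(None, events_df, True, {})

    def prune(node: TreeNode) -> Optional[TreeNode]:
        if id(node) not in surviving:
            return None
        kids = [prune(c) for c in node.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            out = TreeNode(label=node.label)
            out.species = node.species
            return out
        if len(kids) == 1:
            return kids[0]
        out = TreeNode()
        out.dup = node.dup
        for k in kids:
            out.add_child(k)
        return out

    # name surviving leaves by per-species scaffold order
    counters: dict[str, int] = {}
    names: dict[int, str] = {}
    for sp, order in gene_order.items():
        kept = [c for c in order if id(c) in surviving]
        ids = []
        for copy in kept:
            k = counters.get(sp, 0)
            counters[sp] = k + 1
            gid = f"{sp}_g{k}"
            names[id(copy)] = gid
            ids.append(gid)
        gene_order[sp] = ids
    for leaf in leaf_nodes:
        if id(leaf) in surviving:
            leaf.label = names[id(leaf)]
    gene_order = {sp: ids for sp, ids in gene_order.items() if ids}

    pruned = prune(virtual_root)
    for node in pruned.postorder():
        if not node.is_leaf:
            node.support = 100.0
    tree = Tree(pruned)
    if len(tree.leaves()) == 0:
        return SimResult(None, events_df, True, {})
    return SimResult(GeneTree(tree), events_df, False, gene_order)


def emit_synteny(r: SimResult) -> SyntenyTable:
    """One scaffold per species; ranks follow the simulated gene order
    (a duplication inserted its new copy adjacent to the parent copy)."""
    loci = {}
    for sp, order in r.gene_order.items():
        for rank, gid in enumerate(order):
            loci[gid] = (sp, f"{sp}_sc0", rank)
    return SyntenyTable(loci)


def scramble(
    g: GeneTree, k: int, seed: int = 0
) -> tuple[GeneTree, list[tuple]]:
    """Apply *k* random NNIs; touched edges get support 30, others 100.

    Returns the perturbed tree and the applied (edge key, neighbor index)
    moves.  Errors if the tree has no internal NNI edge and k > 0.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if not g.tree.is_binary():
        raise ValueError("scramble requires a binary tree")
    rng = np.random.default_rng(seed)
    current = g.copy()
    for node in current.tree.internal_nodes(include_root=False):
        node.support = 100.0
    moves = []
    for _ in range(k):
        edges = nni_edges(current.tree)
        if not edges:
            raise ValueError("tree has no internal edges to scramble")
        edge = edges[rng.integers(len(edges))]
        which = int(rng.integers(2))
        current = nni_neighbors(current, edge)[which]
        moves.append((edge, which))
    for node in current.tree.internal_nodes(include_root=False):
        node.support = 30.0 if node.rearranged else 100.0
    return current, moves


_BASES = np.array(list("ACGT"))


def evolve_sequences(
    tree: Tree, length: int = 1000, rate: float = 1.0, seed: int = 0
) -> dict[str, str]:
    """Jukes-Cantor sequence evolution along *tree*.

    Along a branch of length t the per-site substitution probability is
    p = 3/4 (1 - exp(-4 rate t / 3)); conditional on substitution the new
    base is uniform over the other three.  Returns leaf label -> sequence.
    """
    rng = np.random.default_rng(seed)
    seqs: dict[int, np.ndarray] = {}
    root_seq = rng.integers(4, size=length)
    seqs[id(tree.root)] = root_seq
    for node in tree.preorder():
        if node.is_root:
            continue
        t = node.length if node.length is not None else 0.0
        p = 0.75 * (1.0 - np.exp(-4.0 * rate * t / 3.0))
        parent_seq = seqs[id(node.parent)]
        child = parent_seq.copy()
        hit = rng.random(length) < p
        n_hit = int(hit.sum())
        if n_hit:
            # uniform over the three other bases
            child[hit] = (parent_seq[hit] + rng.integers(1, 4, size=n_hit)) % 4
        seqs[id(node)] = child
    return {
        leaf.label: "".join(_BASES[seqs[id(leaf)]])
        for leaf in tree.leaves()
    }


def simulate_mm(
    km: float,
    vmax: float,
    grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    replicates: int = 3,
    substrate: str = "synthetic",
) -> RateSeries:
    """Noisy Michaelis-Menten rate data, truncated at zero, in replicate."""
    if km <= 0 or vmax <= 0:
        raise ValueError("Km and Vmax must be positive")
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("concentration grid must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for conc in grid:
        v_true = michaelis_menten(conc, vmax, km)
        for rep in range(replicates):
            v = v_true + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append(
                {
                    "substrate_uM": conc,
                    "rate_uM_per_min": max(v, 0.0),
                    "replicate": rep,
                }
            )
    return RateSeries(substrate, pd.DataFrame(rows))
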