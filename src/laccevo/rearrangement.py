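"""Synteny-aware most-parsimonious local rearrangement of a gene tree.

Low-support branches of the gene tree are open to nearest-neighbor
interchanges (NNI); the search minimizes a lexicographic objective:
first the duplication+loss reconciliation cost, then a genomic-proximity
(synteny) score that pulls tandem gene copies toward topological
adjacency.  Well-supported branches are frozen, mirroring a manually
topologically-constrained re-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .reconciliation import reconcile
from .trees import GeneTree, SpeciesTree, Tree, TreeNode, write_newick

__all__ = [
    "SyntenyTable",
    "RearrangementConfig",
    "editable_edges",
    "nni_edges",
    "nni_neighbors",
    "synteny_score",
    "objective",
    "search",
]

# An NNI edge is identified by the descendant leaf-label set of its child
# end; the unrooted edge across a binary root is the special key "ROOT".
EdgeKey = Union[frozenset, str]
ROOT_EDGE: EdgeKey = "ROOT"


@dataclass
class SyntenyTable:
    """Gene id -> (species, scaffold, 0-based rank along the scaffold)."""

    loci: dict[str, tuple[str, str, int]]

    def __post_init__(self):
        seen = {}
        for gene, (sp, scaf, rank) in self.loci.items():
            if rank < 0:
                raise ValueError(f"negative rank for {gene}")
            key = (sp, scaf, rank)
            if key in seen:
                raise ValueError(
                    f"genes {seen[key]} and {gene} share locus {key}"
                )
            seen[key] = gene

    @classmethod
    def from_tsv(cls, path) -> "SyntenyTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"gene_id", "species", "scaffold", "rank"}
        if not required.issubset(df.columns):
            raise ValueError(f"synteny TSV must have columns {sorted(required)}")
        return cls(
            {
                r.gene_id: (r.species, str(r.scaffold), int(r.rank))
                for r in df.itertuples()
            }
        )

    def to_tsv(self, path) -> None:
        rows = [
            {"gene_id": g, "species": sp, "scaffold": scaf, "rank": rank}
            for g, (sp, scaf, rank) in sorted(self.loci.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def __len__(self):
        return len(self.loci)


@dataclass
class RearrangementConfig:
    """Knobs of the constrained NNI search.

    support_threshold : percent; edges with support strictly below it (or
        with no support at all) may be rearranged.  Default 70, the
        conventional bootstrap-confidence cutoff.
    mode : "greedy" (deterministic hill climb) or "exhaustive" (breadth-
        first enumeration of editable-edge NNI sequences up to
        ``exhaustive_depth``; small trees only).
    """

    support_threshold: float = 70.0
    mode: str = "greedy"
    max_passes: int = 50
    exhaustive_depth: int = 4

    def __post_init__(self):
        if not 0.0 <= self.support_threshold <= 100.0:
            raise ValueError("support_threshold must be in [0, 100]")
        if self.mode not in ("greedy", "exhaustive"):
            raise ValueError(f"unknown mode {self.mode!r}")


def nni_edges(tree: Tree) -> list[EdgeKey]:
    """All unrooted-internal edges of a binary rooted tree, in deterministic order.

    Edges (u, v) with u below the root are keyed by v's clade; the edge
    across a binary root whose two children are both internal contributes
    the single key ``ROOT_EDGE``.
    """
    clades = tree.clades()
    keys: list[EdgeKey] = []
    for node in tree.postorder():
        if node.is_leaf or node.is_root:
            continue
        if node.parent.is_root:
            continue
        keys.append(clades[id(node)])
    root = tree.root
    if len(root.children) == 2 and all(not c.is_leaf for c in root.children):
        keys.append(ROOT_EDGE)
    return sorted(keys, key=_edge_sort_key)


def _edge_sort_key(key: EdgeKey):
    if key == ROOT_EDGE:
        return (1, ())
    return (0, tuple(sorted(key)))


def _edge_support(tree: Tree, key: EdgeKey) -> Optional[float]:
    if key == ROOT_EDGE:
        for c in tree.root.children:
            if c.support is not None:
                return c.support
        return None
    node = _find_by_clade(tree, key)
    return node.support


def _find_by_clade(tree: Tree, clade: frozenset) -> TreeNode:
    clades = tree.clades()
    for node in tree.postorder():
        if clades[id(node)] == clade and not node.is_leaf and not node.is_root:
            return node
    raise KeyError(f"no internal edge with clade {sorted(clade)[:3]}...")


def editable_edges(g: GeneTree, cfg: RearrangementConfig) -> list[EdgeKey]:
    """NNI edges whose support is absent or below the threshold."""
    out = []
    for key in nni_edges(g.tree):
        sup = _edge_support(g.tree, key)
        if sup is None or sup < cfg.support_threshold:
            out.append(key)
    return out


def _swap(a: TreeNode, b: TreeNode) -> None:
    pa, pb = a.parent, b.parent
    ia, ib = pa.children.index(a), pb.children.index(b)
    pa.children[ia], pb.children[ib] = b, a
    a.parent, b.parent = pb, pa


def nni_neighbors(g: GeneTree, edge: EdgeKey) -> list[GeneTree]:
    """The two standard NNI rearrangements across an internal edge.

    Supports on unaffected edges are preserved; the rearranged edge keeps
    its (now provisional) support and is flagged ``rearranged``.
    """
    out = []
    for which in (0, 1):
        tree = g.tree.copy()
        if edge == ROOT_EDGE:
            root = tree.root
            if len(root.children) != 2 or any(c.is_leaf for c in root.children):
                raise ValueError("root edge is not an internal binary edge")
            c1, c2 = root.children
            if len(c1.children) != 2 or len(c2.children) != 2:
                raise ValueError("NNI requires binary edge endpoints")
            x = c1.children[0]
            w = c2.children[which]
            _swap(x, w)
            c1.rearranged = c2.rearranged = True
        else:
            v = _find_by_clade(tree, edge)
            u = v.parent
            if len(u.children) != 2 or len(v.children) != 2:
                raise ValueError("NNI requires binary edge endpoints")
            sibling = next(c for c in u.children if c is not v)
            _swap(sibling, v.children[which])
            v.rearranged = True
        tree.canonicalize()
        out.append(GeneTree(tree))
    return out


def synteny_score(g: GeneTree, syn: Optional[SyntenyTable]) -> float:
    """Genomic-proximity penalty: lower is better.

    Sum over unordered pairs of same-species, same-scaffold genes of
    nodal_distance(i, j) / (1 + |rank_i - rank_j|): chromosomal neighbours
    that sit far apart on the tree cost the most.  Genes without locus
    information contribute nothing.
    """
    if syn is None or not syn.loci:
        return 0.0
    present = {l.label for l in g.leaves()}
    by_scaffold: dict[tuple[str, str], list[tuple[str, int]]] = {}
    for gene, (sp, scaf, rank) in syn.loci.items():
        if gene in present:
            by_scaffold.setdefault((sp, scaf), []).append((gene, rank))
    total = 0.0
    for genes in by_scaffold.values():
        genes.sort()
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                gi, ri = genes[i]
                gj, rj = genes[j]
                total += g.tree.nodal_distance(gi, gj) / (1 + abs(ri - rj))
    return total


def objective(
    g: GeneTree, s: SpeciesTree, syn: Optional[SyntenyTable] = None
) -> tuple[int, float]:
    """Lexicographic objective: (duplications + losses, synteny score)."""
    r = reconcile(g, s)
    return (r.cost, synteny_score(g, syn))


def _edge_label(key: EdgeKey) -> str:
    if key == ROOT_EDGE:
        return "ROOT"
    return min(key) + f"|{len(key)}"


def _serialize_edge(key: EdgeKey) -> str:
    if key == ROOT_EDGE:
        return "ROOT"
    return ";".join(sorted(key))


def _deserialize_edge(text: str) -> EdgeKey:
    if text == "ROOT":
        return ROOT_EDGE
    return frozenset(text.split(";"))


def replay_moves(g: GeneTree, log: pd.DataFrame) -> GeneTree:
    """Re-apply a greedy move log to its input tree."""
    current = g
    for row in log.itertuples():
        edge = _deserialize_edge(row.edge_key)
        current = nni_neighbors(current, edge)[int(row.neighbor)]
    return current


def search(
    g: GeneTree,
    s: SpeciesTree,
    syn: Optional[SyntenyTable] = None,
    cfg: Optional[RearrangementConfig] = None,
) -> tuple[GeneTree, pd.DataFrame]:
    """Constrained NNI search minimizing (D+L, synteny score).

    Greedy mode applies the best strictly-improving move per pass until a
    local optimum (deterministic: ties broken by edge enumeration order).
    Exhaustive mode enumerates all trees reachable by editable-edge NNI
    sequences up to ``cfg.exhaustive_depth`` and returns the global best.
    The returned objective never exceeds the input's.
    """
    cfg = cfg or RearrangementConfig()
    if not g.tree.is_binary():
        raise ValueError("search requires a binary gene tree")
    log_rows: list[dict] = []
    if cfg.mode == "greedy":
        current = g
        cur_obj = objective(current, s, syn)
        for pass_no in range(1, cfg.max_passes + 1):
            best = None  # (obj, edge order index, neighbor index, tree)
            for ei, edge in enumerate(editable_edges(current, cfg)):
                for ni, nb in enumerate(nni_neighbors(current, edge)):
                    obj = objective(nb, s, syn)
                    cand = (obj, ei, ni, nb, edge)
                    if best is None or cand[:3] < best[:3]:
                        best = cand
            if best is None or best[0] >= cur_obj:
                break
            obj, _, ni, nb, edge = best
            log_rows.append(
                {
                    "pass": pass_no,
                    "edge": _edge_label(edge),
                    "edge_key": _serialize_edge(edge),
                    "neighbor": ni,
                    "cost_before": cur_obj[0],
                    "synteny_before": cur_obj[1],
                    "cost_after": obj[0],
                    "synteny_after": obj[1],
                }
            )
            current, cur_obj = nb, obj
        best_tree, best_obj = current, cur_obj
    else:  # exhaustive
        start_obj = objective(g, s, syn)
        visited = {write_newick(g.tree): (g, start_obj, 0)}
        frontier = [g]
        depth = 0
        while frontier and depth < cfg.exhaustive_depth:
            depth += 1
            nxt = []
            for tree in frontier:
                for edge in editable_edges(tree, cfg):
                    for nb in nni_neighbors(tree, edge):
                        key = write_newick(nb.tree)
                        if key in visited:
                            continue
                        visited[key] = (nb, objective(nb, s, syn), depth)
                        nxt.append(nb)
            frontier = nxt
        best_key = min(visited, key=lambda k: (visited[k][1], visited[k][2], k))
        best_tree, best_obj, best_depth = visited[best_key]
        if best_depth > 0:
            log_rows.append(
                {
                    "pass": best_depth,
                    "edge": "exhaustive",
                    "edge_key": "",
                    "neighbor": -1,
                    "cost_before": start_obj[0],
                    "synteny_before": start_obj[1],
                    "cost_after": best_obj[0],
                    "synteny_after": best_obj[1],
                }
            )
    log = pd.DataFrame(
        log_rows,
        columns=[
            "pass",
            "edge",
            "edge_key",
            "neighbor",
            "cost_before",
            "synteny_before",
            "cost_after",
            "synteny_after",
        ],
    )
    return best_tree, log
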