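"""Most-parsimonious duplication/loss reconciliation via LCA mapping.

Each gene-tree node is mapped onto the species tree by the standard LCA
(last-common-ancestor) map; internal nodes whose mapped species node
coincides with a child's image are duplications, the rest speciations.
Losses are read off every gene-tree edge from the species-tree path
between the images of its endpoints and placed on the off-path species
branches.  The LCA map minimizes the total duplication + loss count, so
the result is the (unique) most parsimonious reconciliation.

Convention: losses implied above the gene-tree root (between the species
root and the image of the gene root) are not counted by default - the
family is assumed to start as a single ancestral copy at its own root.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .trees import GeneTree, SpeciesTree, TreeNode, write_newick

__all__ = [
    "ReconciliationResult",
    "lca_map",
    "classify_nodes",
    "losses_on_edge",
    "reconcile",
    "events_by_species_branch",
]

SPECIATION = "speciation"
DUPLICATION = "duplication"


def _gene_node_id(node: TreeNode) -> str:
    if node.is_leaf:
        return node.label
    leaves = sorted(node.leaf_labels())
    return f"{leaves[0]}|{len(leaves)}"


def lca_map(g: GeneTree, s: SpeciesTree) -> dict[int, TreeNode]:
    """LCA map M: gene node -> species node, keyed by ``id(gene node)``.

    ``M(leaf)`` is the species-tree leaf of the gene's species;
    ``M(v) = mrca_S({M(c) : c child of v})`` for internal ``v``.
    """
    sleaf = {n.label: n for n in s.tree.leaves()}
    # species-node depth + parent climb for pairwise mrca
    depth: dict[int, int] = {}
    for node in s.tree.preorder():
        depth[id(node)] = 0 if node.is_root else depth[id(node.parent)] + 1

    def smrca(a: TreeNode, b: TreeNode) -> TreeNode:
        while a is not b:
            if depth[id(a)] >= depth[id(b)]:
                a = a.parent
            else:
                b = b.parent
        return a

    M: dict[int, TreeNode] = {}
    for node in g.tree.postorder():
        if node.is_leaf:
            sp = node.species
            if sp not in sleaf:
                raise ValueError(
                    f"gene {node.label!r} maps to unknown species {sp!r}"
                )
            M[id(node)] = sleaf[sp]
        else:
            img = M[id(node.children[0])]
            for c in node.children[1:]:
                img = smrca(img, M[id(c)])
            M[id(node)] = img
    return M


def classify_nodes(g: GeneTree, M: dict[int, TreeNode]) -> dict[int, str]:
    """Speciation/duplication classification of internal gene nodes.

    A node is a duplication iff its image equals the image of at least one
    of its children (equivalently, the children's species sets intersect).
    Soft polytomies whose children have pairwise disjoint species sets are
    treated as simultaneous speciations; otherwise an error instructs the
    user to resolve the polytomy first.
    """
    cls: dict[int, str] = {}
    species_below: dict[int, frozenset[str]] = {}
    for node in g.tree.postorder():
        if node.is_leaf:
            species_below[id(node)] = frozenset([node.species])
            continue
        sets = [species_below[id(c)] for c in node.children]
        species_below[id(node)] = frozenset().union(*sets)
        if len(node.children) > 2:
            if sum(len(x) for x in sets) != len(species_below[id(node)]):
                raise ValueError(
                    f"polytomy at {_gene_node_id(node)} has overlapping child "
                    "species sets; resolve it to binary before reconciling"
                )
            cls[id(node)] = SPECIATION  # simultaneous speciations
            continue
        dup = any(M[id(c)] is M[id(node)] for c in node.children)
        cls[id(node)] = DUPLICATION if dup else SPECIATION
    return cls


def _species_path_down(top: TreeNode, bottom: TreeNode) -> list[TreeNode]:
    """Species nodes from *top* down to *bottom* inclusive; errors if not nested."""
    path = [bottom]
    cur = bottom
    while cur is not top:
        cur = cur.parent
        if cur is None:
            raise ValueError(
                "inconsistent mapping: child image is not a descendant of "
                "the parent image"
            )
        path.append(cur)
    return list(reversed(path))


def losses_on_edge(
    g_parent: TreeNode,
    g_child: TreeNode,
    M: dict[int, TreeNode],
    classification: dict[int, str],
) -> list[TreeNode]:
    """Species branches (child-node ends) on which the edge implies a loss.

    Let d be the number of species-tree edges between the images of the
    endpoints.  The edge implies d losses if the parent is a duplication,
    d - 1 if a speciation (never below 0).  Walking the image path top-down,
    each loss sits on the off-path child branch of a species node on the
    path: at every strictly-intermediate node, plus at the parent's image
    itself in the duplication case.
    """
    if g_child.parent is not g_parent:
        raise ValueError("g_parent is not the parent of g_child")
    top, bottom = M[id(g_parent)], M[id(g_child)]
    path = _species_path_down(top, bottom)  # top .. bottom
    d = len(path) - 1
    parent_dup = classification.get(id(g_parent)) == DUPLICATION
    if d == 0:
        return []
    start = 0 if parent_dup else 1
    out: list[TreeNode] = []
    for i in range(start, d):  # species nodes path[i] strictly above bottom
        on_path_child = path[i + 1]
        for child in path[i].children:
            if child is not on_path_child:
                out.append(child)
    return out


@dataclass
class ReconciliationResult:
    """Everything the LCA reconciliation of one gene family infers."""

    gene_tree: GeneTree
    species_tree: SpeciesTree
    mapping: dict[int, TreeNode]
    classification: dict[int, str]
    duplications: list[tuple[TreeNode, TreeNode]]  # (gene node, species node)
    losses: list[tuple[TreeNode, tuple[TreeNode, TreeNode]]]  # (sp branch, gene edge)
    count_root_losses: bool = False

    @property
    def D(self) -> int:
        return len(self.duplications)

    @property
    def L(self) -> int:
        return len(self.losses)

    @property
    def cost(self) -> int:
        return self.D + self.L

    def gene_node_id(self, node: TreeNode) -> str:
        return _gene_node_id(node)

    def annotated_newick(self) -> str:
        """NHX Newick with D=Y/N flags and S=<species> leaf tags."""
        tree = self.gene_tree.tree.copy()
        # rebuild classification on the copy by clade identity
        by_clade = {
            frozenset(n.leaf_labels()): self.classification[id(n)]
            for n in self.gene_tree.tree.internal_nodes()
        }
        for node in tree.internal_nodes():
            node.dup = by_clade[frozenset(node.leaf_labels())] == DUPLICATION
        return write_newick(tree, nhx=True)

    def summary(self) -> str:
        return f"reconciliation: D={self.D} duplications, L={self.L} losses"


def reconcile(g: GeneTree, s: SpeciesTree, count_root_losses: bool = False) -> ReconciliationResult:
    """Most parsimonious duplication/loss reconciliation of *g* against *s*.

    With ``count_root_losses=True`` losses implied between the species root
    and the gene root's image are also counted (off-path branches along
    that path), departing from the single-ancestral-copy convention.
    """
    g.validate_against(s)
    M = lca_map(g, s)
    cls = classify_nodes(g, M)
    duplications: list[tuple[TreeNode, TreeNode]] = []
    losses: list[tuple[TreeNode, tuple[TreeNode, TreeNode]]] = []
    for node in g.tree.postorder():
        if node.is_leaf:
            continue
        if cls[id(node)] == DUPLICATION:
            duplications.append((node, M[id(node)]))
        for child in node.children:
            for branch in losses_on_edge(node, child, M, cls):
                losses.append((branch, (node, child)))
    if count_root_losses:
        root_img = M[id(g.tree.root)]
        path = _species_path_down(s.tree.root, root_img)
        for i in range(len(path) - 1):
            for child in path[i].children:
                if child is not path[i + 1]:
                    losses.append((child, (g.tree.root, g.tree.root)))
    return ReconciliationResult(
        gene_tree=g,
        species_tree=s,
        mapping=M,
        classification=cls,
        duplications=duplications,
        losses=losses,
        count_root_losses=count_root_losses,
    )


def events_by_species_branch(r: ReconciliationResult) -> pd.DataFrame:
    """Per-species-branch event table (the reconciliation timeline).

    One row per species branch (identified by its child-node id) carrying
    at least one event; duplications are attributed to the branch
    subtending the duplication's mapped species node.  Column sums equal
    the reconciliation's (D, L) exactly.
    """
    s = r.species_tree
    rows: dict[str, dict] = {}

    def row(branch_id: str) -> dict:
        return rows.setdefault(
            branch_id,
            {"branch": branch_id, "n_duplications": 0, "n_losses": 0, "gene_edges": []},
        )

    for gnode, snode in r.duplications:
        rec = row(s.node_id(snode))
        rec["n_duplications"] += 1
        rec["gene_edges"].append(_gene_node_id(gnode))
    for branch, (gp, gc) in r.losses:
        rec = row(s.node_id(branch))
        rec["n_losses"] += 1
        rec["gene_edges"].append(f"{_gene_node_id(gp)}->{_gene_node_id(gc)}")
    out = pd.DataFrame(
        sorted(rows.values(), key=lambda x: x["branch"]),
        columns=["branch", "n_duplications", "n_losses", "gene_edges"],
    )
    out["gene_edges"] = out["gene_edges"].map(lambda v: ";".join(v))
    return out.set_index("branch")
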