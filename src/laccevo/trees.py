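"""Rooted-tree data model, Newick/NHX I/O and basic tree utilities.

Trees are rooted; children are kept in a canonical order (sorted by the
lexicographically smallest descendant leaf label) so that writing is
byte-stable and structural equality is well defined.  Bootstrap supports
live on internal edges only, expressed in percent (0-100).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Optional, Sequence

import numpy as np

logger = logging.getLogger("laccevo")

__all__ = [
    "TreeNode",
    "Tree",
    "SpeciesTree",
    "GeneTree",
    "GeneLeaf",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "annotate_support",
    "nj_tree",
    "jc69_distance",
    "jc_distance_matrix",
    "nj_tree_from_fasta",
]


class NewickParseError(ValueError):
    """Malformed Newick input; the message names the character offset."""


class TreeNode:
    """A node of a rooted tree.

    Attributes
    ----------
    label : str or None
        Leaf label, or an internal-node name (clade label).
    length : float or None
        Branch length of the edge above this node (>= 0).
    support : float or None
        Bootstrap support in percent on the edge above this node;
        meaningful only for internal, non-root nodes.
    species, scaffold, rank
        Gene-leaf payload: the species the gene belongs to and its
        (scaffold, 0-based rank) genomic locus, when known.
    dup : bool or None
        Duplication flag set by reconciliation (NHX ``D=Y/N``).
    rearranged : bool
        True if the edge above this node was altered by an NNI move.
    """

    __slots__ = (
        "label",
        "length",
        "support",
        "children",
        "parent",
        "species",
        "scaffold",
        "rank",
        "dup",
        "rearranged",
    )

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
    ):
        self.label = label
        self.length = length
        self.support = support
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        self.species: Optional[str] = None
        self.scaffold: Optional[str] = None
        self.rank: Optional[int] = None
        self.dup: Optional[bool] = None
        self.rearranged = False

    # -- structure ---------------------------------------------------------

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def postorder(self) -> Iterator["TreeNode"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.leaves())

    def copy(self) -> "TreeNode":
        new = TreeNode(self.label, self.length, self.support)
        new.species, new.scaffold, new.rank = self.species, self.scaffold, self.rank
        new.dup, new.rearranged = self.dup, self.rearranged
        for c in self.children:
            new.add_child(c.copy())
        return new

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<TreeNode {self.label or '·'} ({len(self.children)} children)>"


@dataclass(frozen=True)
class GeneLeaf:
    """A gene-tree leaf: gene id, its species, and an optional genomic locus."""

    gene_id: str
    species: str
    scaffold: Optional[str] = None
    rank: Optional[int] = None

    def __post_init__(self):
        if self.rank is not None and self.rank < 0:
            raise ValueError(f"rank must be >= 0, got {self.rank} for {self.gene_id}")


class Tree:
    """A rooted tree with unique leaf labels and canonical child ordering."""

    def __init__(self, root: TreeNode, canonicalize: bool = True):
        self.root = root
        labels = [n.label for n in root.leaves()]
        if any(l is None for l in labels):
            raise ValueError("every leaf must carry a label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        for n in root.postorder():
            if n.length is not None and n.length < 0:
                raise ValueError(f"negative branch length on {n.label!r}")
        if canonicalize:
            self.canonicalize()

    # -- canonical form ----------------------------------------------------

    def canonicalize(self) -> "Tree":
        """Sort children everywhere by smallest descendant leaf label."""
        def rec(node: TreeNode) -> str:
            if node.is_leaf:
                return node.label
            mins = [rec(c) for c in node.children]
            order = sorted(range(len(mins)), key=lambda i: mins[i])
            node.children = [node.children[i] for i in order]
            return mins[order[0]]

        rec(self.root)
        return self

    def copy(self) -> "Tree":
        return Tree(self.root.copy(), canonicalize=False)

    # -- queries -----------------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_labels(self) -> frozenset[str]:
        return self.root.leaf_labels()

    def leaf(self, label: str) -> TreeNode:
        for n in self.leaves():
            if n.label == label:
                return n
        raise KeyError(f"unknown leaf label: {label!r}")

    def internal_nodes(self, include_root: bool = True) -> list[TreeNode]:
        return [
            n
            for n in self.postorder()
            if not n.is_leaf and (include_root or not n.is_root)
        ]

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def depths(self) -> dict[int, int]:
        """Edge-count depth of every node keyed by ``id(node)``."""
        d = {id(self.root): 0}
        for n in self.preorder():
            if not n.is_root:
                d[id(n)] = d[id(n.parent)] + 1
        return d

    def mrca(self, labels: Iterable[str]) -> TreeNode:
        """Lowest node whose descendant leaves include all *labels*."""
        want = set(labels)
        if not want:
            raise ValueError("mrca of an empty set is undefined")
        by_label = {n.label: n for n in self.leaves()}
        missing = want - by_label.keys()
        if missing:
            raise KeyError(f"unknown leaf label(s): {sorted(missing)}")
        nodes = [by_label[l] for l in want]
        anc = nodes[0]
        ancestors = []
        while anc is not None:
            ancestors.append(anc)
            anc = anc.parent
        index = {id(a): i for i, a in enumerate(ancestors)}
        best = 0
        for node in nodes[1:]:
            cur = node
            while id(cur) not in index:
                cur = cur.parent
            best = max(best, index[id(cur)])
        return ancestors[best]

    def nodal_distance(self, a: str, b: str) -> int:
        """Number of edges on the path between leaves *a* and *b*."""
        if a == b:
            self.leaf(a)
            return 0
        na, nb = self.leaf(a), self.leaf(b)
        depth = self.depths()
        m = self.mrca([a, b])
        return depth[id(na)] + depth[id(nb)] - 2 * depth[id(m)]

    def clades(self) -> dict[int, frozenset[str]]:
        """Descendant leaf-label set of every node keyed by ``id(node)``."""
        out: dict[int, frozenset[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                out[id(n)] = frozenset([n.label])
            else:
                s: frozenset[str] = frozenset()
                for c in n.children:
                    s |= out[id(c)]
                out[id(n)] = s
        return out

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Unrooted non-trivial splits of the leaf set."""
        all_leaves = self.leaf_labels()
        clades = self.clades()
        splits = set()
        for n in self.postorder():
            if n.is_leaf or n.is_root:
                continue
            side = clades[id(n)]
            other = all_leaves - side
            if len(side) >= 2 and len(other) >= 2:
                splits.add(frozenset({side, other}))
        return splits

    # -- equality / output -------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, Tree):
            return NotImplemented
        return write_newick(self) == write_newick(other)

    def __hash__(self):
        return hash(write_newick(self))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree with {len(self.leaves())} leaves>"


# ---------------------------------------------------------------------------
# Newick parsing


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


def parse_newick(text: str, support_from_labels: bool = True) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Internal node labels that parse as numbers are interpreted as bootstrap
    supports (RAxML convention); values in [0, 1] are scaled by 100 with a
    logged warning.  ``[&&NHX:...]`` comments are honoured for the ``S``
    (species) and ``D`` (duplication) tags; other comments are ignored.
    """
    s = text.strip()
    if not s:
        raise NewickParseError("empty Newick string at position 0")
    pos = 0
    n = len(s)

    def err(msg: str, i: int):
        raise NewickParseError(f"{msg} at position {i}")

    def skip_comment(i: int, node: TreeNode) -> int:
        # s[i] == '['
        j = s.find("]", i)
        if j == -1:
            err("unterminated comment '['", i)
        body = s[i + 1 : j]
        if body.startswith("&&NHX"):
            for part in body[5:].split(":"):
                if not part:
                    continue
                key, _, val = part.partition("=")
                if key == "S":
                    node.species = val
                elif key == "D":
                    node.dup = val.upper() in ("Y", "T", "1")
        return j + 1

    def read_label(i: int) -> tuple[str, int]:
        if i < n and s[i] == "'":
            j = i + 1
            out = []
            while True:
                if j >= n:
                    err("unbalanced quote", i)
                if s[j] == "'":
                    if j + 1 < n and s[j + 1] == "'":  # escaped quote
                        out.append("'")
                        j += 2
                        continue
                    return "".join(out), j + 1
                out.append(s[j])
                j += 1
        j = i
        while j < n and s[j] not in ",():;[":
            j += 1
        return s[i:j].strip(), j

    def parse_node(i: int) -> tuple[TreeNode, int]:
        node = TreeNode()
        if i < n and s[i] == "(":
            i += 1
            while True:
                child, i = parse_node(i)
                node.add_child(child)
                if i >= n:
                    err("unbalanced parentheses", i)
                if s[i] == ",":
                    i += 1
                    continue
                if s[i] == ")":
                    i += 1
                    break
                err(f"unexpected character {s[i]!r}", i)
        label, i = read_label(i)
        if label:
            node.label = label
        while i < n and s[i] == "[":
            i = skip_comment(i, node)
        if i < n and s[i] == ":":
            j = i + 1
            while j < n and s[j] not in ",();[":
                j += 1
            token = s[i + 1 : j].strip()
            if not _is_number(token):
                err(f"bad branch length {token!r}", i + 1)
            node.length = float(token)
            i = j
        while i < n and s[i] == "[":
            i = skip_comment(i, node)
        return node, i

    root, pos = parse_node(pos)
    if pos >= n or s[pos] != ";":
        err("expected ';'", pos)
    if s[pos + 1 :].strip():
        err("trailing characters after ';'", pos + 1)

    if support_from_labels:
        scaled = False
        for node in root.postorder():
            if node.is_leaf or node.is_root:
                continue
            if node.label is not None and _is_number(node.label):
                v = float(node.label)
                if 0.0 <= v <= 1.0:
                    v *= 100.0
                    scaled = True
                node.support = v
                node.label = None
        if root.label is not None and _is_number(root.label):
            root.label = None  # support is undefined on the root
        if scaled:
            logger.warning("supports in [0,1] auto-scaled to percent (x100)")
    return Tree(root)


def _fmt_num(x: float) -> str:
    out = format(x, ".10g")
    return out


def _quote_if_needed(label: str) -> str:
    if any(c in label for c in ",():;[] '\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree, nhx: bool = False) -> str:
    """Serialize deterministically (canonical child order).

    Supports are emitted as internal-node labels.  With ``nhx=True``,
    gene-leaf species and duplication flags are written as
    ``[&&NHX:S=<species>:D=Y|N]`` comments.
    """

    def minleaf(node: TreeNode) -> str:
        while not node.is_leaf:
            node = min(node.children, key=minleaf)
        return node.label

    def rec(node: TreeNode) -> str:
        if node.is_leaf:
            out = _quote_if_needed(node.label)
        else:
            kids = sorted(node.children, key=minleaf)
            out = "(" + ",".join(rec(c) for c in kids) + ")"
            if node.support is not None and not node.is_root:
                out += _fmt_num(node.support)
            elif node.label:
                out += _quote_if_needed(node.label)
        tags = []
        if nhx:
            if node.species is not None:
                tags.append(f"S={node.species}")
            if node.dup is not None:
                tags.append("D=" + ("Y" if node.dup else "N"))
        if tags:
            out += "[&&NHX:" + ":".join(tags) + "]"
        if node.length is not None:
            out += ":" + _fmt_num(node.length)
        return out

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# Species and gene trees


class SpeciesTree:
    """A rooted species tree plus a registry of named, monophyletic clades."""

    def __init__(self, tree: Tree, clades: Optional[dict[str, Iterable[str]]] = None):
        self.tree = tree
        self.clades: dict[str, frozenset[str]] = {}
        for name, members in (clades or {}).items():
            self.register_clade(name, members)

    def register_clade(self, name: str, members: Iterable[str]) -> None:
        members = frozenset(members)
        node = self.tree.mrca(members)
        if node.leaf_labels() != members:
            raise ValueError(
                f"clade {name!r} is not monophyletic: MRCA spans "
                f"{sorted(node.leaf_labels() - members)} extra leaves"
            )
        self.clades[name] = members

    def clade_mrca(self, name: str) -> TreeNode:
        if name not in self.clades:
            raise KeyError(f"unknown clade: {name!r}")
        return self.tree.mrca(self.clades[name])

    def node_id(self, node: TreeNode) -> str:
        """Stable identifier for a species-tree node (= its subtending branch)."""
        if node.is_leaf:
            return node.label
        if node.label:
            return node.label
        leaves = sorted(node.leaf_labels())
        return f"{leaves[0]}|{len(leaves)}"

    def leaf_labels(self) -> frozenset[str]:
        return self.tree.leaf_labels()

    def __repr__(self) -> str:  # pragma: no cover
        return f"<SpeciesTree {len(self.tree.leaves())} taxa, {len(self.clades)} clades>"


class GeneTree:
    """A rooted gene tree whose leaves carry (gene id, species, optional locus)."""

    def __init__(
        self,
        tree: Tree,
        species_map: Optional[dict[str, str]] = None,
        species_tree: Optional[SpeciesTree] = None,
    ):
        self.tree = tree
        if species_map:
            for leaf in tree.leaves():
                if leaf.label in species_map:
                    leaf.species = species_map[leaf.label]
        missing = [l.label for l in tree.leaves() if l.species is None]
        if missing:
            raise ValueError(f"gene leaves without species assignment: {missing[:5]}")
        if species_tree is not None:
            self.validate_against(species_tree)

    def validate_against(self, species_tree: SpeciesTree) -> None:
        known = species_tree.leaf_labels()
        bad = sorted({l.species for l in self.tree.leaves()} - known)
        if bad:
            raise ValueError(f"gene-leaf species not in species tree: {bad}")

    def leaves(self) -> list[TreeNode]:
        return self.tree.leaves()

    def gene_leaf(self, node: TreeNode) -> GeneLeaf:
        return GeneLeaf(node.label, node.species, node.scaffold, node.rank)

    def species_of(self) -> dict[str, str]:
        return {l.label: l.species for l in self.leaves()}

    def copy(self) -> "GeneTree":
        return GeneTree(self.tree.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"<GeneTree {len(self.leaves())} genes>"


# ---------------------------------------------------------------------------
# Bootstrap support transfer


def annotate_support(target: Tree, replicates: Sequence[Tree]) -> Tree:
    """Set each internal-edge support of *target* from bipartition frequency.

    support = 100 x (fraction of replicates containing the edge's split),
    rounded to one decimal.  All trees must share the same leaf set.
    """
    if not replicates:
        raise ValueError("at least one replicate tree is required")
    want = target.leaf_labels()
    for i, rep in enumerate(replicates):
        have = rep.leaf_labels()
        if have != want:
            diff = sorted(want.symmetric_difference(have))
            raise ValueError(f"replicate {i} leaf-set mismatch: {diff}")
    counts: dict[frozenset[frozenset[str]], int] = {}
    for rep in replicates:
        for split in rep.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    out = target.copy()
    clades = out.clades()
    nrep = len(replicates)
    for node in out.postorder():
        if node.is_leaf or node.is_root:
            continue
        side = clades[id(node)]
        other = want - side
        if len(side) < 2 or len(other) < 2:
            continue  # trivial split: support undefined, leave as-is
        split = frozenset({side, other})
        node.support = round(100.0 * counts.get(split, 0) / nrep, 1)
    return out


# ---------------------------------------------------------------------------
# Distance-based tree building (synthetic-test plumbing)


def jc69_distance(a: str, b: str) -> float:
    """Jukes-Cantor corrected distance with pairwise deletion of non-ACGT sites."""
    valid = set("ACGT")
    pairs = [
        (x, y)
        for x, y in zip(a.upper(), b.upper())
        if x in valid and y in valid
    ]
    if not pairs:
        return 0.0
    p = sum(x != y for x, y in pairs) / len(pairs)
    if p >= 0.75:
        return 5.0  # saturated; cap
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def jc_distance_matrix(records: dict[str, str]) -> tuple[list[str], np.ndarray]:
    labels = sorted(records)
    k = len(labels)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = jc69_distance(records[labels[i]], records[labels[j]])
    return labels, d


def nj_tree(dist: np.ndarray, labels: Sequence[str]) -> Tree:
    """Neighbor-joining topology (scikit-bio), midpoint-rooted.

    Negative NJ branch-length estimates are clamped to zero.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.shape[0] != dist.shape[1] or dist.shape[0] != len(labels):
        raise ValueError("distance matrix shape does not match labels")
    if np.isnan(dist).any() or np.isinf(dist).any():
        raise ValueError("distance matrix contains NaN/inf entries")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(dist), 0.0):
        raise ValueError("distance matrix diagonal must be zero")
    from skbio import DistanceMatrix
    from skbio.tree import nj as _skbio_nj

    dm = DistanceMatrix(dist, ids=list(labels))
    sk = _skbio_nj(dm)
    sk = sk.root_at_midpoint()
    import io as _io

    buf = _io.StringIO()
    sk.write(buf, format="newick")
    tree = parse_newick(buf.getvalue().strip(), support_from_labels=False)
    for node in tree.postorder():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return Tree(tree.root)


def root_with_outgroup(tree: Tree, outgroup: Iterable[str]) -> Tree:
    """Re-root so the outgroup leaves form one child of a binary root.

    The outgroup must be one side of an (unrooted) split of the tree.
    Unrooted bipartitions are preserved; supports travel with the node
    below their edge.
    """
    t = tree.copy()
    want = frozenset(outgroup)
    missing = want - t.leaf_labels()
    if missing:
        raise KeyError(f"unknown leaf label(s): {sorted(missing)}")
    clades = t.clades()
    target = None
    for n in t.root.postorder():
        if not n.is_root and clades[id(n)] in (want, t.leaf_labels() - want):
            target = n
            break
    if target is None:
        raise ValueError("outgroup is not one side of a split of this tree")
    if target.parent.is_root and len(t.root.children) == 2:
        return Tree(t.root)
    # invert parent pointers from target's parent up to the old root
    path = []
    cur = target.parent
    while cur is not None:
        path.append(cur)
        cur = cur.parent
    old_lengths = [n.length for n in path]
    target.parent.children.remove(target)
    for i in range(len(path) - 1):
        path[i + 1].children.remove(path[i])
    for i in range(len(path) - 1):
        path[i].add_child(path[i + 1])
        path[i + 1].length = old_lengths[i]
        path[i + 1].parent = path[i]
    path[0].parent = None

    def suppress_unary(node: TreeNode) -> None:
        for child in list(node.children):
            suppress_unary(child)
        if len(node.children) == 1 and node.parent is not None:
            child = node.children[0]
            if child.length is not None and node.length is not None:
                child.length += node.length
            idx = node.parent.children.index(node)
            node.parent.children[idx] = child
            child.parent = node.parent

    new_root = TreeNode()
    new_root.add_child(target)
    new_root.add_child(path[0])
    path[0].length = 0.0
    suppress_unary(new_root)
    return Tree(new_root)


def nj_tree_from_fasta(path) -> Tree:
    """Build an NJ tree from a FASTA alignment via JC69 distances."""
    from Bio import SeqIO

    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if len(records) < 3:
        raise ValueError("need at least 3 sequences")
    labels, d = jc_distance_matrix(records)
    return nj_tree(d, labels)
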