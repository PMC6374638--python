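"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: the
reconciliation oracle is a dynamic program over *all* admissible gene-to-
species node mappings (not the LCA shortcut), and the alignment oracle is
a plain quadratic-space Needleman-Wunsch scoring recursion.
"""

from __future__ import annotations

import numpy as np

from laccevo.trees import GeneTree, SpeciesTree, Tree, TreeNode


def min_dl_cost(g: GeneTree, s: SpeciesTree) -> int:
    """Minimum duplication+loss cost over all mappings M with
    M(gene leaf) fixed and M(node) an ancestor-or-self of every child image.

    Event accounting per mapping: a binary node is a speciation iff its
    children's images fall into *different* child subtrees of its own
    image; an edge whose endpoints' images are d species-edges apart
    implies d losses below a duplication and d-1 below a speciation.
    Losses above the gene root are not counted.
    """
    snodes = list(s.tree.postorder())
    sindex = {id(n): i for i, n in enumerate(snodes)}
    depth = {}
    for n in s.tree.preorder():
        depth[id(n)] = 0 if n.is_root else depth[id(n.parent)] + 1
    # descendants-or-self per species node, and "which child subtree" lookup
    desc: dict[int, set[int]] = {}
    via_child: dict[int, dict[int, int]] = {}  # s -> (descendant -> child index)
    for n in s.tree.postorder():
        mine = {sindex[id(n)]}
        via: dict[int, int] = {}
        for ci, c in enumerate(n.children):
            for dd in desc[id(c)]:
                mine.add(dd)
                via[dd] = ci
        desc[id(n)] = mine
        via_child[id(n)] = via

    sleaf_index = {n.label: sindex[id(n)] for n in s.tree.leaves()}
    INF = float("inf")
    cost: dict[int, list[float]] = {}

    for gnode in g.tree.postorder():
        row = [INF] * len(snodes)
        if gnode.is_leaf:
            row[sleaf_index[gnode.species]] = 0.0
        else:
            assert len(gnode.children) == 2, "oracle handles binary trees"
            ca, cb = gnode.children
            ra, rb = cost[id(ca)], cost[id(cb)]
            for si, snode in enumerate(snodes):
                via = via_child[id(snode)]
                best = INF
                for sa in desc[id(snode)]:
                    if ra[sa] == INF:
                        continue
                    for sb in desc[id(snode)]:
                        if rb[sb] == INF:
                            continue
                        dup = not (
                            sa in via
                            and sb in via
                            and via[sa] != via[sb]
                        )
                        da = depth[id(snodes[sa])] - depth[id(snode)]
                        db = depth[id(snodes[sb])] - depth[id(snode)]
                        if dup:
                            ev = 1 + da + db
                        else:
                            ev = max(da - 1, 0) + max(db - 1, 0)
                        tot = ra[sa] + rb[sb] + ev
                        if tot < best:
                            best = tot
                row[si] = best
        cost[id(gnode)] = row
    return int(min(cost[id(g.tree.root)]))


def enumerate_topologies(labels: list[str]):
    """All rooted binary tree topologies over *labels* ((2n-3)!! of them),
    as nested tuples."""
    if len(labels) == 1:
        yield labels[0]
        return

    def insert_everywhere(top, leaf):
        # insert at the root
        yield (top, leaf)
        if isinstance(top, tuple):
            a, b = top
            for sub in insert_everywhere(a, leaf):
                yield (sub, b)
            for sub in insert_everywhere(b, leaf):
                yield (a, sub)

    def rec(tops, remaining):
        if not remaining:
            yield from tops
            return
        leaf, rest = remaining[0], remaining[1:]
        out = []
        for top in tops:
            out.extend(insert_everywhere(top, leaf))
        yield from rec(out, rest)

    yield from rec([(labels[0], labels[1])], labels[2:])


def tuples_to_gene_tree(top, species_of: dict[str, str]) -> GeneTree:
    def build(t) -> TreeNode:
        if isinstance(t, str):
            n = TreeNode(label=t)
            n.species = species_of[t]
            return n
        node = TreeNode()
        node.add_child(build(t[0]))
        node.add_child(build(t[1]))
        return node

    return GeneTree(Tree(build(top)))


def random_topology(rng, labels: list[str]):
    """One uniformly random rooted binary topology by random insertion."""
    top = (labels[0], labels[1])

    def edges(t, path=()):
        yield path
        if isinstance(t, tuple):
            yield from edges(t[0], path + (0,))
            yield from edges(t[1], path + (1,))

    def insert(t, path, leaf):
        if not path:
            return (t, leaf)
        a, b = t
        if path[0] == 0:
            return (insert(a, path[1:], leaf), b)
        return (a, insert(b, path[1:], leaf))

    for leaf in labels[2:]:
        sites = list(edges(top))
        top = insert(top, sites[rng.integers(len(sites))], leaf)
    return top


def nw_score(a: str, b: str, match=1, mismatch=-1, gap=-2) -> float:
    """Quadratic-space global-alignment score (independent DP)."""
    n, m = len(a), len(b)
    prev = np.array([gap * j for j in range(m + 1)], dtype=float)
    for i in range(1, n + 1):
        cur = np.empty(m + 1)
        cur[0] = gap * i
        for j in range(1, m + 1):
            sub = prev[j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            cur[j] = max(sub, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return float(prev[m])
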