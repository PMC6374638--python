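"""Orthology-group delineation and sequence-based group assignment.

Orthology groups (OGs) are the maximal gene subtrees hanging off the
chain of *stem duplications* of a focal species clade - duplication
nodes that map to the clade's MRCA while all their descendant genes lie
inside the clade ("the gene duplicated before the clade started to
proliferate").  For a pectinate chain of k stem duplications this yields
k+1 groups, which partition the focal genes.

External sequences are assigned to OGs by reciprocal best-hit exact
global alignment (Needleman-Wunsch), a transparent stand-in for a
reciprocal BLAST ranking: assignment requires reciprocity, minimum
identity and coverage, and a strictly positive margin over the best hit
in any other group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .reconciliation import DUPLICATION, ReconciliationResult
from .trees import GeneTree, SpeciesTree, TreeNode

__all__ = [
    "OrthologyGroup",
    "OGAssignment",
    "stem_duplications",
    "delineate_ogs",
    "global_align",
    "percent_identity",
    "same_species",
    "assign_og",
    "assign_by_grafting",
]

_DNA = set("ACGTUN-")


@dataclass
class OrthologyGroup:
    name: str
    node: TreeNode  # defining gene-tree node
    members: tuple[str, ...]  # gene ids
    species: frozenset[str]

    def __len__(self):
        return len(self.members)


@dataclass
class OGAssignment:
    query: str
    og: Optional[str]
    best_ref: Optional[str]
    score: float
    identity: float
    coverage: float
    margin: float
    status: str  # assigned | ambiguous | unclassified
    reason: str = ""


def stem_duplications(
    r: ReconciliationResult, s: SpeciesTree, focal: str
) -> list[TreeNode]:
    """Duplication nodes on the stem of the *focal* clade.

    A stem duplication maps to the focal clade's MRCA and every gene leaf
    below it belongs to a focal species.
    """
    mrca = s.clade_mrca(focal)
    members = s.clades[focal]
    out = []
    for gnode, snode in r.duplications:
        if snode is not mrca:
            continue
        if all(l.species in members for l in gnode.leaves()):
            out.append(gnode)
    return out


def delineate_ogs(
    g: GeneTree,
    r: ReconciliationResult,
    s: SpeciesTree,
    focal: str,
    names: Optional[Sequence[str]] = None,
) -> list[OrthologyGroup]:
    """Partition the focal clade's gene leaves into orthology groups.

    The stem-duplication chain is contracted; every maximal subtree whose
    root is not itself a stem duplication becomes one group.  Groups are
    returned in canonical tree order and named OG1..OGk unless *names*
    are supplied.
    """
    members = s.clades[focal]
    stems = {id(n) for n in stem_duplications(r, s, focal)}

    def all_focal(node: TreeNode) -> bool:
        return all(l.species in members for l in node.leaves())

    roots: list[TreeNode] = []

    def descend(node: TreeNode) -> None:
        if id(node) in stems:
            for c in node.children:
                descend(c)
        else:
            roots.append(node)

    def find_tops(node: TreeNode) -> None:
        if all_focal(node):
            descend(node)
        elif not node.is_leaf:
            for c in node.children:
                find_tops(c)

    find_tops(g.tree.root)
    if names is not None and len(names) != len(roots):
        raise ValueError(
            f"{len(roots)} orthology groups found but {len(names)} names given"
        )
    out = []
    for i, node in enumerate(roots):
        leaves = node.leaves()
        out.append(
            OrthologyGroup(
                name=names[i] if names is not None else f"OG{i + 1}",
                node=node,
                members=tuple(sorted(l.label for l in leaves)),
                species=frozenset(l.species for l in leaves),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Pairwise alignment


def _alphabet(seq: str) -> str:
    up = set(seq.upper())
    if up <= _DNA:
        return "dna"
    return "protein"


def _aligner(kind: str):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if kind == "dna":
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
    else:
        from Bio.Align import substitution_matrices

        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
    return aligner


def global_align(a: str, b: str) -> tuple[float, float, float]:
    """Optimal global alignment -> (score, identity %, coverage %).

    Nucleotide scoring is match +1 / mismatch -1 / gap -2; protein scoring
    is BLOSUM62 with gap open -11 / extend -1.  Identity is computed over
    aligned columns excluding terminal gaps; coverage is the fraction of
    the shorter sequence aligned against a residue of the other.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ka, kb = _alphabet(a), _alphabet(b)
    if ka != kb:
        raise ValueError(f"alphabet mix: {ka} vs {kb}")
    aligner = _aligner(ka)
    a, b = a.upper(), b.upper()
    aln = aligner.align(a, b)[0]
    ra, rb = str(aln[0]), str(aln[1])
    # window between the first and last column where both rows have residues
    first = last = None
    for i, (x, y) in enumerate(zip(ra, rb)):
        if x != "-" and y != "-":
            if first is None:
                first = i
            last = i
    if first is None:
        return (float(aln.score), 0.0, 0.0)
    matches = cols = both = 0
    for i in range(first, last + 1):
        x, y = ra[i], rb[i]
        cols += 1
        if x != "-" and y != "-":
            both += 1
            if x == y:
                matches += 1
    identity = 100.0 * matches / cols
    coverage = 100.0 * both / min(len(a), len(b))
    return (float(aln.score), identity, coverage)


def percent_identity(a: str, b: str) -> float:
    """Global-alignment percent identity (terminal gaps excluded)."""
    return global_align(a, b)[1]


def same_species(a: str, b: str, threshold: float = 95.0) -> bool:
    """ITS-style species identity rule: identity >= 95% means same species."""
    return percent_identity(a, b) >= threshold


# ---------------------------------------------------------------------------
# Reciprocal best-hit assignment


def assign_og(
    query_id: str,
    query: str,
    refs: Sequence[tuple[str, str, str]],
    min_identity: float = 70.0,
    min_coverage: float = 50.0,
) -> OGAssignment:
    """Assign *query* to an orthology group by reciprocal best hit.

    *refs* is a sequence of (ref id, sequence, OG name).  The best-scoring
    reference is found; the assignment holds only if (1) re-aligning that
    reference against the other references plus the query ranks the query
    or a same-OG member first (reciprocity), (2) identity and coverage
    meet the thresholds, and (3) the best hit in any other OG scores
    strictly lower.  Score ties across groups yield status "ambiguous".
    """
    if not refs:
        raise ValueError("reference set must be non-empty")
    hits = []
    for rid, rseq, og in refs:
        score, ident, cov = global_align(query, rseq)
        hits.append((score, ident, cov, rid, og))
    # deterministic: ties broken by reference id
    hits.sort(key=lambda h: (-h[0], h[3]))
    best_score, best_ident, best_cov, best_rid, best_og = hits[0]
    other = [h for h in hits if h[4] != best_og]
    best_other_score = other[0][0] if other else float("-inf")
    margin = best_score - best_other_score

    def fail(status, reason):
        return OGAssignment(
            query=query_id,
            og=None,
            best_ref=best_rid,
            score=best_score,
            identity=best_ident,
            coverage=best_cov,
            margin=margin,
            status=status,
            reason=reason,
        )

    if other and other[0][0] == best_score:
        return fail("ambiguous", "equal best score in more than one group")
    if best_ident < min_identity:
        return fail("unclassified", f"identity {best_ident:.1f} < {min_identity}")
    if best_cov < min_coverage:
        return fail("unclassified", f"coverage {best_cov:.1f} < {min_coverage}")
    # reciprocity: best hit of the best reference among refs+query must be
    # the query itself or a member of its own group
    best_ref_seq = next(s for rid, s, _ in refs if rid == best_rid)
    recip = [(global_align(best_ref_seq, query)[0], query_id, best_og)]
    for rid, rseq, og in refs:
        if rid == best_rid:
            continue
        recip.append((global_align(best_ref_seq, rseq)[0], rid, og))
    recip.sort(key=lambda h: (-h[0], h[1]))
    if recip and recip[0][2] != best_og and recip[0][1] != query_id:
        return fail("unclassified", f"reciprocity failed via {recip[0][1]}")
    return OGAssignment(
        query=query_id,
        og=best_og,
        best_ref=best_rid,
        score=best_score,
        identity=best_ident,
        coverage=best_cov,
        margin=margin,
        status="assigned",
    )


def assign_by_grafting(
    query_id: str,
    query: str,
    g: GeneTree,
    leaf_seqs: dict[str, str],
    r: ReconciliationResult,
    s: SpeciesTree,
    focal: str,
) -> Optional[str]:
    """Secondary, tree-based assignment route.

    The query is grafted as the sister of its best-scoring gene-tree leaf
    (inheriting that leaf's species), the grafted tree is re-reconciled
    and groups re-delineated; the returned name is that of the group now
    containing the query (auto OG1..OGk numbering, in tree order), or
    None if the query lands outside the focal clade's groups.
    """
    scored = sorted(
        (
            (-global_align(query, leaf_seqs[leaf.label])[0], leaf.label)
            for leaf in g.leaves()
            if leaf.label in leaf_seqs
        ),
    )
    if not scored:
        raise ValueError("no gene-tree leaf has a sequence to align against")
    best_label = scored[0][1]
    grafted = g.copy()
    host = grafted.tree.leaf(best_label)
    parent = host.parent
    joint = TreeNode(length=host.length)
    new_leaf = TreeNode(label=query_id, length=0.0)
    new_leaf.species = host.species
    if parent is None:  # single-leaf tree
        joint.add_child(host)
        joint.add_child(new_leaf)
        grafted.tree.root = joint
    else:
        idx = parent.children.index(host)
        parent.children[idx] = joint
        joint.parent = parent
        host.length = 0.0
        joint.add_child(host)
        joint.add_child(new_leaf)
    grafted.tree.canonicalize()
    from .reconciliation import reconcile as _reconcile

    r2 = _reconcile(grafted, s)
    for og in delineate_ogs(grafted, r2, s, focal):
        if query_id in og.members:
            return og.name
    return None
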