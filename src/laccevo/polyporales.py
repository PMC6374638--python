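"""The 28-taxon Polyporales species tree and the laccase gene-family
event script, encoded as executable data.

The species sample covers the four main Polyporales clades: the core
polyporoid clade (CorePol, 16 Trametes-like species subdivided into the
species groups Sp1-Sp5), the Antrodia clade (2 brown-rot species), the
Phlebioid clade (6 species, 4 of which form the Phanerochaetaceae
subclade) and the residual polyporoid clade (ResPol, 4 species).

The gene-family script states, per orthology group, the duplications
and losses that shaped the laccase family: a single ancestral copy, six
stem duplications on the CorePol stem yielding the serial groups
A, BE, C, D, F, G, H, plus a handful of within-group events and a
single loss of the ancestral Phlebioid-family gene in the
Phanerochaetaceae ancestor.  Executing the script yields a gene tree
whose reconciliation must reproduce the script's events exactly - the
package's master round-trip property.

Internals the published narrative does not constrain (Sp4, Sp5, ResPol
and Phanerochaetaceae in-group arrangements; Phlebioid vs ResPol order
on the backbone) are arbitrary choices flagged below.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .rearrangement import SyntenyTable
from .trees import GeneTree, SpeciesTree, Tree, TreeNode, parse_newick

__all__ = [
    "SPECIES",
    "CLADES",
    "build_species_tree",
    "build_gene_tree",
    "fixture_synteny",
    "expected_event_table",
    "OG_NAMES",
]

# -- species sample ---------------------------------------------------------

SP1 = ("T_villosa", "T_versicolor", "T_ochracea", "T_sp_AH28_2")
SP2 = ("T_gibbosa", "L_betulinus")
SP3 = ("T_ljubarskyi", "T_cingulata", "T_hirsuta")
SP4 = ("P_sanguineus", "P_coccineus", "P_cinnabarinus", "P_puniceus")
SP5 = ("P_arcularius", "P_brumalis", "L_tigrinus")
ANTRODIA = ("F_pinicola", "W_cocos")
PHANEROCHAETACEAE = ("Pc_carnosa", "Pc_chrysosporium", "Pp_gigantea", "B_adusta")
PHLEBIOID = ("Ph_brevispora", "Ph_chrysocreas") + PHANEROCHAETACEAE
RESPOL = ("A_faginea", "A_pallasii", "S_murashkinskyi", "C_unicolor")
COREPOL = SP1 + SP2 + SP3 + SP4 + SP5

SPECIES = COREPOL + ANTRODIA + PHLEBIOID + RESPOL

CLADES: dict[str, frozenset] = {
    "CorePol": frozenset(COREPOL),
    "Antrodia": frozenset(ANTRODIA),
    "Phlebioid": frozenset(PHLEBIOID),
    "Phanerochaetaceae": frozenset(PHANEROCHAETACEAE),
    "ResPol": frozenset(RESPOL),
    "Sp1": frozenset(SP1),
    "Sp2": frozenset(SP2),
    "Sp3": frozenset(SP3),
    "Sp4": frozenset(SP4),
    "Sp5": frozenset(SP5),
}

# Topology notes:
#   - Antrodia sister to CorePol (an alternative gene placement "demanded one
#     extra gene loss in the common ancestor of CorePol and Antrodia", so that
#     ancestor exists on the tree).
#   - Sp3 internal: T. hirsuta basal to (T. ljubarskyi, T. cingulata) - forced
#     by the OG C loss in the (ljubarskyi, cingulata) ancestor with hirsuta
#     retaining its copy.
#   - Sp1 internal: AH28-2 basal to (villosa,(versicolor,ochracea)) - forced
#     by the OG D duplication in the ancestor of the three fungi of Sp1
#     "without Trametes sp. AH28-2".
#   - ARBITRARY (unconstrained by the event narrative): Sp4, Sp5,
#     Phanerochaetaceae and ResPol in-group arrangements; Phlebioid placed
#     basal on the backbone.
_SPECIES_NEWICK = (
    "("
    "((Ph_brevispora:1,Ph_chrysocreas:1)Phlebia:1,"
    "((Pc_carnosa:1,Pc_chrysosporium:1)Phanerochaete:1,"
    "(Pp_gigantea:1,B_adusta:1)PgigBadu:1)Phanerochaetaceae:1)Phlebioid:1,"
    "(((A_faginea:1,A_pallasii:1)Antrodiella:1,"
    "(S_murashkinskyi:1,C_unicolor:1)SmurCuni:1)ResPol:1,"
    "((F_pinicola:1,W_cocos:1)Antrodia:1,"
    "((((("
    "T_sp_AH28_2:1,(T_villosa:1,(T_versicolor:1,T_ochracea:1)TverToch:1)Sp1trio:1"
    ")Sp1:1,"
    "(T_gibbosa:1,L_betulinus:1)Sp2:1)Sp1Sp2:1,"
    "(T_hirsuta:1,(T_ljubarskyi:1,T_cingulata:1)TljuTcin:1)Sp3:1)Sp123:1,"
    "((P_sanguineus:1,P_coccineus:1)PsanPcoc:1,"
    "(P_cinnabarinus:1,P_puniceus:1)PcinPpun:1)Sp4:1)Sp1234:1,"
    "(L_tigrinus:1,(P_arcularius:1,P_brumalis:1)ParcPbru:1)Sp5:1)CorePol:1"
    ")AntCore:1)ResAntCore:1)Polyporales;"
)

OUTGROUP_SPECIES = "P_lycii"


def build_species_tree(include_outgroup: bool = False) -> SpeciesTree:
    """The 28-taxon Polyporales species tree with registered clades.

    With ``include_outgroup=True`` the Russulales outgroup species
    (P. lycii) is attached basal to the Polyporales.
    """
    newick = _SPECIES_NEWICK
    if include_outgroup:
        body = newick[:-1]  # strip ';'
        newick = f"({OUTGROUP_SPECIES}:1,{body}:1)Root;"
    tree = parse_newick(newick)
    return SpeciesTree(tree, CLADES)


# -- gene-family event script ----------------------------------------------


@dataclass(frozen=True)
class Loss:
    clade: frozenset


@dataclass(frozen=True)
class Dup:
    clade: frozenset
    copies: tuple  # of (copy label, tuple of nested events)


def _fs(*names: str) -> frozenset:
    return frozenset(names)


OG_NAMES = ("A", "BE", "C", "D", "F", "G", "H")

# Per-OG events after the stem duplications ("after the clade started to
# proliferate"); the copy labels give the gene ids their published names
# (e.g. the BE duplication in the Sp3 ancestor supplies the lacB/lacE pair).
_OG_SCRIPTS: dict[str, tuple] = {
    "A": (),  # neither gene losses nor duplications
    "BE": (Dup(_fs(*SP3), (("B", ()), ("E", ()))),),
    "C": (  # three parallel early gene losses
        Loss(frozenset(SP1) | frozenset(SP2)),
        Loss(_fs("T_ljubarskyi", "T_cingulata")),
        Loss(_fs(*SP4)),
    ),
    "D": (
        Loss(_fs("T_ljubarskyi")),
        Dup(  # duplication in the Sp1 trio ancestor; the new copy lost in T. villosa
            _fs("T_villosa", "T_versicolor", "T_ochracea"),
            (("D", ()), ("D2", (Loss(_fs("T_villosa")),))),
        ),
        Dup(  # two subsequent duplications in the Sp5 ancestor
            _fs(*SP5),
            (("D", ()), ("D2", ()), ("D3", ())),
        ),
    ),
    "F": (Loss(_fs("P_puniceus")),),
    "G": (Loss(_fs(*SP4)),),
    "H": (Loss(_fs("T_hirsuta")), Loss(_fs("T_gibbosa"))),
}

# Six stem duplications on the CorePol stem produce the serial chain
# A, BE, C, D, F, G, H; a single loss removes the Phlebioid-family gene in
# the Phanerochaetaceae ancestor.
_BASE_EVENTS = (
    Dup(
        frozenset(COREPOL),
        tuple((og, _OG_SCRIPTS[og]) for og in OG_NAMES),
    ),
    Loss(frozenset(PHANEROCHAETACEAE)),
)

_CHAIN_EDGE_LENGTH = 0.1  # nominal length of stem-duplication chain edges


def _grow(snode: TreeNode, sclades: dict, events: tuple, label: str) -> Optional[TreeNode]:
    clade = sclades[id(snode)]
    for e in events:
        if isinstance(e, Loss) and e.clade == clade:
            return None
    dups = [e for e in events if isinstance(e, Dup) and e.clade == clade]
    if dups:
        d = dups[0]
        rest = tuple(e for e in events if e is not d)
        copies = []
        for copy_label, extra in d.copies:
            sub = _grow(snode, sclades, rest + tuple(extra), copy_label)
            if sub is not None:
                copies.append(sub)
        if not copies:
            return None
        # right-nested pectinate chain of duplication nodes
        node = copies[-1]
        for sub in reversed(copies[:-1]):
            chain = TreeNode(length=_CHAIN_EDGE_LENGTH)
            chain.dup = True
            chain.add_child(sub)
            chain.add_child(node)
            node = chain
        node.length = snode.length
        return node
    if snode.is_leaf:
        leaf = TreeNode(label=f"{snode.label}_lac{label}", length=snode.length)
        leaf.species = snode.label
        return leaf
    kids = [_grow(c, sclades, events, label) for c in snode.children]
    kids = [k for k in kids if k is not None]
    if not kids:
        return None
    if len(kids) == 1:
        only = kids[0]
        if only.length is not None and snode.length is not None:
            only.length = only.length + snode.length
        return only
    node = TreeNode(length=snode.length)
    for k in kids:
        node.add_child(k)
    return node


def build_gene_tree(
    species_tree: Optional[SpeciesTree] = None, include_outgroup: bool = False
) -> GeneTree:
    """Forward-execute the event script into the fixture laccase gene tree.

    A single ancestral copy enters the species root; every scripted
    duplication and loss is applied; supports are set to 100 everywhere.
    With ``include_outgroup=True`` three P. lycii genes are attached basal
    (requires the outgroup-bearing species tree).
    """
    s = species_tree or build_species_tree(include_outgroup=include_outgroup)
    if include_outgroup and OUTGROUP_SPECIES not in s.leaf_labels():
        raise ValueError("outgroup gene tree needs the outgroup species tree")
    sclades = s.tree.clades()
    start = s.tree.root
    if include_outgroup:
        # descend past the root to the Polyporales MRCA
        start = next(
            c for c in s.tree.root.children if OUTGROUP_SPECIES not in sclades[id(c)]
        )
    root = _grow(start, sclades, _BASE_EVENTS, "1")
    if include_outgroup:
        og_leaf = next(l for l in s.tree.leaves() if l.label == OUTGROUP_SPECIES)
        chain = None
        for i in (3, 2, 1):
            leaf = TreeNode(label=f"{OUTGROUP_SPECIES}_lac{i}", length=1.0)
            leaf.species = OUTGROUP_SPECIES
            if chain is None:
                chain = leaf
            else:
                node = TreeNode(length=_CHAIN_EDGE_LENGTH)
                node.dup = True
                node.add_child(leaf)
                node.add_child(chain)
                chain = node
        top = TreeNode(length=1.0)
        top.add_child(chain)
        top.add_child(root)
        root = top
    for node in root.postorder():
        if not node.is_leaf and node.parent is not None:
            node.support = 100.0
    tree = Tree(root)
    return GeneTree(tree, species_tree=s)


def _og_of_gene(gene_id: str) -> str:
    label = gene_id.rsplit("_lac", 1)[1]
    if label in ("B", "E"):
        return "BE"
    if label.startswith("D"):
        return "D"
    if label.isdigit():
        return "FAM"  # single-copy non-CorePol family
    return label


def fixture_synteny(gene_tree: Optional[GeneTree] = None) -> SyntenyTable:
    """Synteny table for the fixture: one scaffold per (species, OG);
    tandem within-OG copies occupy adjacent ranks."""
    g = gene_tree or build_gene_tree()
    loci: dict[str, tuple[str, str, int]] = {}
    counters: dict[tuple[str, str], int] = {}
    for leaf in sorted(g.leaves(), key=lambda l: l.label):
        og = _og_of_gene(leaf.label)
        key = (leaf.species, og)
        rank = counters.get(key, 0)
        counters[key] = rank + 1
        loci[leaf.label] = (leaf.species, f"{leaf.species}_sc{og}", rank)
    return SyntenyTable(loci)


def expected_event_table() -> pd.DataFrame:
    """The scripted events by species branch: the round-trip ground truth."""
    rows = [
        ("CorePol", 6, 0),
        ("Sp3", 1, 0),
        ("Sp1trio", 1, 0),
        ("Sp5", 2, 0),
        ("Sp1Sp2", 0, 1),
        ("TljuTcin", 0, 1),
        ("Sp4", 0, 2),
        ("T_ljubarskyi", 0, 1),
        ("T_villosa", 0, 1),
        ("P_puniceus", 0, 1),
        ("T_hirsuta", 0, 1),
        ("T_gibbosa", 0, 1),
        ("Phanerochaetaceae", 0, 1),
    ]
    df = pd.DataFrame(rows, columns=["branch", "n_duplications", "n_losses"])
    return df.sort_values("branch").set_index("branch")


# Published per-OG member counts implied by the event script.
OG_SIZES = {"A": 16, "BE": 19, "C": 4, "D": 23, "F": 15, "G": 12, "H": 14}
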