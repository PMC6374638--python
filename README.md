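# laccevo

Gene-tree/species-tree reconciliation tooling for the evolution of the
fungal laccase (*sensu stricto*, CAZy AA1_1) multigene family in the
wood-rotting order Polyporales, plus the Michaelis–Menten kinetics used
to compare laccase isozymes.

It is aimed at molecular evolution researchers who want to re-run or
extend a duplication/loss analysis of a gene family across a clade of
fungi: mapping a gene tree onto a species tree, timing duplications and
losses on species branches, tidying weakly supported branches with
genomic-synteny information, and carving the family into orthology
groups that biochemical observations can be hung on.

## What it computes

**Most parsimonious reconciliation.** Every gene-tree node *g* is mapped
to the species tree by the LCA map
*M(g) = mrca_S{M(c) : c child of g}*; *g* is a duplication iff
*M(g) = M(c)* for some child, else a speciation. An edge (*g*, *c*)
whose images are *d* species-edges apart implies *d* losses below a
duplication and *d − 1* below a speciation, each placed on the off-path
species branch. The LCA map minimizes the total count *D + L*, so the
result is the unique most parsimonious duplication/loss scenario
(`laccevo.reconciliation`).

**Synteny-aware rearrangement.** Branches with bootstrap support below a
threshold (default 70%) are open to nearest-neighbor interchanges; the
search minimizes the lexicographic objective
(*D + L*, Σ_pairs nodal_distance / (1 + Δrank)), the second term pulling
tandem gene copies toward topological adjacency (`laccevo.rearrangement`).

**Orthology groups.** Duplication nodes that map to a focal clade's MRCA
with all descendants inside the clade ("stem duplications") are
contracted; the hanging subtrees are the orthology groups. External
sequences are assigned to groups by reciprocal best-hit global alignment
(`laccevo.orthology`).

**The Polyporales fixture.** `laccevo.polyporales` encodes the 28-taxon
Polyporales species tree (clades CorePol with species groups Sp1–Sp5,
Antrodia, Phlebioid with the Phanerochaetaceae subclade, ResPol) and the
laccase event script — one ancestral gene, six duplications on the
CorePol stem yielding the serial orthology groups A, BE, C, D, F, G, H,
a handful of within-group events, and the loss of the ancestral gene in
the Phanerochaetaceae — as executable data.

**Synthetic data and kinetics.** `laccevo.simulate` provides birth-death
gene-family simulation with a true event log, NNI scrambling with
support marking, Jukes–Cantor sequence evolution and noisy
Michaelis–Menten rate data. `laccevo.kinetics` converts absorbance
slopes to rates (Beer–Lambert), fits *v = V_max·S/(K_M + S)* by
nonlinear least squares, and classes substrate specificity.

## Worked example

```python
from laccevo.polyporales import build_species_tree, build_gene_tree
from laccevo.reconciliation import reconcile, events_by_species_branch

s = build_species_tree()
g = build_gene_tree(s)
r = reconcile(g, s)
print(r.summary())
print(events_by_species_branch(r)[["n_duplications", "n_losses"]])
```

prints

```
reconciliation: D=10 duplications, L=10 losses
                   n_duplications  n_losses
branch
CorePol                         6         0
P_puniceus                      0         1
Phanerochaetaceae               0         1
Sp1Sp2                          0         1
Sp1trio                         1         0
Sp3                             1         0
Sp4                             0         2
Sp5                             2         0
T_gibbosa                       0         1
T_hirsuta                       0         1
T_ljubarskyi                    0         1
T_villosa                       0         1
TljuTcin                        0         1
```

— the six duplications on the CorePol stem branch are the origin of
orthology groups A–H; the two Sp4 losses are the parallel losses of the
C- and G-group genes in the *Pycnoporus* ancestor; the single
Phanerochaetaceae loss explains why those four genomes carry no
laccase. *T. hirsuta* ends up with exactly 7 gene leaves (lacA–lacG,
with lacH lost).

The same pipeline is available from a shell:

```sh
laccevo fixture --outdir demo
laccevo reconcile --gene-tree demo/gene_tree.nwk --species-tree demo/species_tree.nwk --outdir demo
laccevo classify  --gene-tree demo/gene_tree.nwk --species-tree demo/species_tree.nwk --outdir demo
laccevo kinetics --km 37 --substrate ABTS --outdir demo
```

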