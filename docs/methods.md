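# Methods

## Reconciliation model

The package implements duplication/loss parsimony for a rooted binary
gene tree *G* against a rooted species tree *S*. The LCA map sends each
gene leaf to its species and each internal node to the species-tree MRCA
of its children's images. Classification: a node is a **duplication**
iff its image equals a child's image (equivalently, its children's
species sets intersect); otherwise a **speciation**. Losses are read
edge-wise: with *d* the number of species edges between the images of an
edge's endpoints, the edge implies *d* losses when the parent is a
duplication and *d − 1* when a speciation (floored at zero). Walking the
image path top-down, each loss is placed on the off-path child branch of
a species node on the path — every strictly intermediate node, plus the
parent's image itself in the duplication case. The LCA map minimizes
*D + L* over all admissible mappings; the test suite checks this against
a brute-force dynamic program that scores *every* mapping on thousands
of enumerated topologies.

Conventions worth knowing:

- **No losses above the gene root.** The family is modelled as starting
  from a single ancestral copy at its own root, so species branches
  between the species root and the root image carry no loss. The
  `count_root_losses=True` switch restores the alternative convention.
- **Duplication timing.** A duplication is attributed to the species
  node it maps to, read as "on or within the branch subtending that
  node". Stem duplications of a clade — image at the clade MRCA, all
  descendant genes inside the clade — are the "duplicated before the
  clade started to proliferate" events that define orthology groups.
- **Polytomies** are accepted as soft only when their children's species
  sets are pairwise disjoint (simultaneous speciations); otherwise the
  user is asked to resolve them, since the NNI machinery needs binary
  trees anyway.

## Rearrangement search

The search treats the gene tree's unrooted internal edges as NNI sites.
An edge is *editable* when its bootstrap support is absent or below
`support_threshold` (default 70%, the conventional confidence cutoff;
the published procedure constrained "low supported" branches without
quantifying them). The objective is lexicographic: first the
reconciliation cost *D + L*, then the synteny score

    Σ over same-species, same-scaffold gene pairs of
        nodal_distance(i, j) / (1 + |rank_i − rank_j|),

an invented concrete form of the qualitative rule that chromosomally
adjacent copies should sit close on the tree: a tandem pair (Δrank = 1)
placed as sisters contributes 2/2 = 1, the minimum possible. Greedy mode
applies the single best strictly-improving move per pass (ties broken by
deterministic edge order; no sideways moves, so termination is
guaranteed) and its move log replays exactly to the output. Exhaustive
mode enumerates all editable-edge NNI sequences to a configured depth
(default 4) with duplicate-topology pruning — intended for small trees
or few editable edges. Edges altered by a move keep their
(sub-threshold) support and stay editable; frozen bipartitions are never
broken.

## Orthology groups and sequence assignment

Groups are the maximal subtrees left after contracting the focal clade's
stem-duplication chain: *k* pectinate stem duplications give *k + 1*
groups that partition the focal genes; non-pectinate chains (possible on
simulated data) are handled by the same contraction rule. Query
sequences are assigned by reciprocal best hit under exact global
alignment — Needleman–Wunsch with +1/−1/−2 (gap) for nucleotides and
BLOSUM62 with −11/−1 gaps for proteins — rather than a heuristic local
search: the classification depends only on the best-hit ranking.
Identity is computed over aligned columns excluding terminal gaps;
coverage is the aligned fraction of the shorter sequence. Assignment
requires reciprocity, identity ≥ 70%, coverage ≥ 50% and a strictly
positive margin over the best other-group hit; the thresholds are
package defaults, not claims about any published protocol, and are
logged in every report. A secondary, tree-based route grafts the query
as sister of its best-scoring leaf and re-delineates. The 95% identity
rule in `same_species` mirrors standard ITS barcoding practice.

## The Polyporales fixture

The fixture module encodes the 28-taxon species tree and the laccase
event script as data. Topology choices forced by the event narrative:
*T. hirsuta* basal within Sp3 (the C-group loss hits the
*T. ljubarskyi* + *T. cingulata* ancestor while *T. hirsuta* keeps its
copy); *Trametes* sp. AH28-2 basal within Sp1 (the D-group duplication
affects the other three Sp1 fungi); Sp1 and Sp2 sisters (a shared
C-group loss); Antrodia sister to CorePol (an alternative gene placement
is described as costing one extra loss in their common ancestor).
In-group arrangements of Sp4, Sp5, ResPol and Phanerochaetaceae, and the
basal position of the Phlebioid clade, are unconstrained by the
narrative and chosen arbitrarily (flagged in the source). Branch lengths
are nominal (1.0 per species branch, 0.1 per stem-chain edge) — the
reconciliation is length-free; the lengths only scale synthetic sequence
divergence. Executing the script and reconciling the result must
reproduce the script exactly (duplication and loss counts *and* branch
placements); this round trip is the package's master acceptance
property, and it also pins down the loss-counting conventions above,
which the narrative never states explicitly.

## Synthetic data

`simulate_family` runs a linear birth–death process along the species
tree: each extant copy waits Exp(λ + μ), the event is a duplication with
probability λ/(λ + μ), and every copy enters both children at a
speciation. Defaults λ = 0.1, μ = 0.05 per copy per unit length give the
sparse-event regime the fixtures inhabit. Every true event is logged
against its species branch, so inference can be scored for placement,
not just totals; extinct families are reported, not silently resampled
(resampling is an explicit flag). Expected copy number after time *t* is
e^{(λ−μ)t}, which the calibration test checks at 2000 replicates within
three standard errors; parsimony cost never exceeds the true event count
(duplications on fully-extinct lineages and compensating dup/loss pairs
are invisible to parsimony), with equality >90% of the time when
rate·depth ≤ 0.1. Gene order is tracked along lineages with new copies
inserted adjacent to their parent, so the emitted synteny table realizes
the tandem-duplication convention. Sequence evolution is Jukes–Cantor
with the exact per-branch transition matrix. What the generators do
*not* emulate: rate heterogeneity across sites or lineages, codon
structure, gene conversion, horizontal transfer, and alignment error —
passing tests therefore validate the algorithms under the stated model,
not robustness to real-data noise sources outside it.

## Kinetics

Absorbance slopes convert to product rates via Beer–Lambert
(rate = slope/(ε·path)·10⁶ µM/min; 1 cm path assumed unless configured).
The Michaelis–Menten fit averages replicates per concentration, weights
by replicate count, initializes V_max at 1.2·max(v) and K_M at the
concentration nearest half-maximal rate, and uses bounded
Levenberg–Marquardt (trust-region) least squares; standard errors come
from the local linearization. On noiseless data generated anywhere
within half the minimum to twice the maximum of the assay grid the fit
recovers the generating K_M to better than 0.1%; under 5%-of-V_max
Gaussian noise the 500-seed median |K_M| bias stays within 5%. The
++/+/±/− substrate-specificity classes use relative-rate cutoffs of
25/5/1% of the reference substrate — an invented, scale-invariant
operationalization of a symbol scale whose original cutoffs are unknown;
they are configurable and stamped into reports.

## Problem sizes and numerical choices

The test suite runs everything at desk scale: exhaustive reconciliation
oracles cover all rooted topologies through 6 gene leaves (945 per
species assignment) with seeded random samples at 7–8 leaves;
scramble/recovery uses up to 3 NNIs on the 111-leaf fixture with
exhaustive depth equal to the scramble count; simulator calibration uses
2000 replicates on an 8-taxon depth-5 tree. Supports are rounded to one
decimal; children are kept in canonical (lexicographic-by-smallest-leaf)
order so all outputs are byte-stable; Newick supports in [0, 1] are
auto-scaled to percent with a logged warning; NJ's occasional negative
branch-length estimates are clamped to zero after midpoint rooting.
Seeds: every stochastic component takes one integer seed and derives its
substreams deterministically.

## Known limitations

Reconciliation is duplication/loss only — no transfers, no probabilistic
(rate-aware) reconciliation, and the species tree must be binary where
events are inferred. The rearrangement search is NNI-local; a tree whose
distortion needs an SPR move will stall in a local optimum. The fixture
reconstructs topologies only up to what the published narrative
constrains. BLAST-style E-values are not computed; assignment confidence
is expressed through identity, coverage and margin instead.
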