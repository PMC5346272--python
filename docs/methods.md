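# Methods

This note records the models and procedures implemented in `orthoedit`,
the choices made where the design was genuinely open, and what the test
suite does and does not establish.

## Model

A gene family Γ carries a total map s: Γ → Σ to a species set. The
relation graph R = (Γ, E_R) encodes orthology (edges) and paralogy
(non-edges); same-species pairs are forced non-edges. A weight
w: pairs → R⁺ ∪ {∞} is total over all C(n,2) pairs — it prices both
edge removals and non-edge insertions — with w ≡ ∞ on same-species
pairs. Unlisted pairs default to weight 1.0, which makes the unweighted
problems the zero-configuration case. Zero weights are allowed; optima
are then not necessarily unique. Infinity is `math.inf` in the public
contract; only inside cut computations is it substituted by
(sum of finite weights) + 1, a value provably exceeding any finite cut,
because Stoer–Wagner needs finite arithmetic. All deterministic
orderings (children of cotree nodes, P4 witnesses, subset enumeration)
use lexicographic order of the opaque string identifiers, so repeated
runs are bit-identical.

DS-trees are rooted binary trees over Γ with internal labels
Dup/Spec. The Fitch rule reads relations off a tree: {x, y} is an edge
iff ev(lca(x, y)) = Spec. Ancestorship in the species tree is
*inclusive* — a node is its own ancestor — so a speciation node whose
children map to the same species-tree node is inconsistent.

## Recognition and cotrees

Satisfiability ⇔ P4-freeness is decided by the complement-connectivity
dichotomy rather than quartic enumeration: recursively, a vertex set
whose induced subgraph is disconnected becomes a parallel (Dup) node
over its components; one whose complement is disconnected becomes a
series (Spec) node over the co-components; a singleton is a leaf; if
neither holds on some set of ≥ 2 vertices the graph is not a cograph and
a witness P4 is extracted. Quadruple enumeration survives in the oracle
module as the independent cross-check. The canonical cotree is
multifurcating; DS-trees are produced by binarizing each multifurcation
into a left-leaning chain whose internal nodes inherit the parent's
event (children ordered by smallest contained gene). This is
relation-preserving: the lca of leaves in different children of the
original node stays at a node with the same label, so
`relations_from_dstree(build_dstree(R)) == R`. The trees themselves are
not unique — only the induced relations are.

P4 witnesses are canonical: 4-subsets are scanned in lexicographic
order of their sorted identifiers and the path is oriented with the
smaller endpoint first.

## Consistency

Tree-level: a binary DS-tree passes iff every Spec node maps its two
children, under the LCA mapping, to incomparable species-tree nodes; the
first violating node in post-order is reported for debuggability.

Graph-level: the criterion is *pairwise incomparability of the children
mappings at every Spec node of the canonical cotree*. With a binary
species tree a multifurcating Spec node admits a consistent binarization
iff its children's mappings are pairwise incomparable: partition the
children by the child clade of S containing their mapping and recurse;
conversely any binarization of two comparable children meets at some
Spec node that violates Definition-style consistency. This procedure is
not proved here; it is validated empirically against an oracle that
enumerates *every* binary DS-tree on the leaf set (all topologies × all
labelings), keeps those realizing the graph, and tests each — exact for
≤ 5 genes. An unsatisfiable graph raises rather than returning False:
"not a cograph" and "no consistent realization" are different answers.

## Greedy editors

`mincut_cograph_editing` implements the min-cut recursion. On vertex set
Z: C = global min cut of R[Z] under edge weights; Ĉ = global min cut of
the complement under non-edge weights. The cheaper cut is applied
(crossing edges removed for C → Dup node; crossing non-edges inserted
for Ĉ → Spec node) and both sides are recursed. Properties relied on:

* every pair crosses at most one cut, so E⁺ ∩ E⁻ = ∅ and each pair is
  edited once;
* the applied cut's weight never exceeds the optimum of the
  sub-instance, giving β(R) ≤ n·σ_R by induction;
* same-species pairs are never inserted: their infinite weight means a
  complement cut crossing one is chosen only if every bipartition does,
  and R[Z] (whose edges are finite) is preferred on ties.

Open choices, fixed as follows: ties between C and Ĉ go to C (the Dup
cut) in both editors; inside the cut computation vertices are inserted
in lexicographic order, so Stoer–Wagner's result is deterministic, and
among equal-weight cuts the first encountered is kept. If the
positive-weight subgraph is disconnected, the component containing the
smallest vertex is split off at zero cost without running Stoer–Wagner
(which assumes connectivity); zero-weight crossing edges are still
removed — the partition must genuinely disconnect the side.

Deletion-only mode never considers complement cuts and stops the
recursion early on any Z whose induced subgraph is already P4-free,
emitting its cotree directly; recursing to singletons would only remove
more edges. The mode exists because the deletion-only problem is defined
purely by its objective; early stopping preserves feasibility (E⁺ = ∅)
and can only improve the solution.

`mincut_cograph_editing_cons` replaces Ĉ by the species cut C_S(Z): the
bipartition of Z by the root of the species tree restricted to Σ(Z) —
the only complement cut a consistent speciation can make. When Z spans a
single species no speciation is possible and only the R-cut is
considered; R[Z] is then edgeless (forced paralogy) and splits for free.
Every Spec node of the output therefore respects S by construction.

The double-star family (two adjacent centers with (n−2)/2 pendant
leaves each; odd n puts the extra leaf on the left center) realizes the
tightness of the factor-n analysis: the optimum removes the single
center–center edge, while a minimum cut may peel pendant leaves one at a
time. Under the pinned tie-breaks the implementation pays 3 on the n = 8
instance (the analysis allows up to n − 3 = 5); the value is frozen in a
regression test.

## Exact oracles

`brute_force_edit(_cons)` enumerates edit subsets over the editable
pairs (all non-same-species pairs; current edges only in deletion-only
mode), by increasing cardinality and then lexicographically, so the
reported argmin is the smallest optimal edit in that order. Pruning is
sound and result-preserving: the incumbent starts at the
remove-every-edge solution (always feasible — the edgeless graph is a
cograph and vacuously consistent), any subset whose weight reaches the
incumbent is skipped, and a whole cardinality level k is skipped once
the sum of the k cheapest weights does. Guards default to n ≤ 7
(plain), n ≤ 6 (consistent), n ≤ 12 (cuts), 5 genes (tree
enumeration); the guard is a parameter because the n = 8 double star
with unit weights terminates after cardinality 1 and is exact.
Feasibility inside the plain oracle uses bitset 4-subset enumeration,
independent of the recognition recursion it is used to check.

## The multicut gadget

For a Minimum Multi-Cut instance (H, X) the gadget doubles each vertex
(primary and shadow copy, each with a fresh species), ties the copies by
a spine edge of weight q′ = q|E_H| + z, connects terminal pairs by a
direct primary–primary edge (weight q = |V_H|⁵ + 1 if an H-edge, else
1), non-terminal pairs by both primary–shadow cross edges (q/2 each if
an H-edge, else 1), and prices all non-edges at q′ so insertions never
pay. z = 2(C(|V_H|,2) − |E_H|) bounds the weight-1 edges. The two
constructive translations are implemented: components of H minus a
multicut lift to a partition of the gadget whose crossing edges form a
P4-free deletion of weight ≤ q|E′_H| + z; conversely, from any editing
within weight qW + z (W ≤ |E_H|) the multicut is read off the removed
weight-q edges and removed *pairs* of weight-q/2 edges — the pair must
be complete, otherwise the |E′_H| ≤ W accounting fails. Both directions
are verified exhaustively for |V_H| ≤ 4 (all edge sets × terminal sets ×
valid multicuts) and on seeded samples at |V_H| = 5. The asymptotic
inapproximability argument built on the gadget is theory, not code.

## Synthetic data

Generators are pure functions of their arguments; the seed fully
determines the output. Random species trees use uniform sequential
joins; genes cover every species when counts allow, the rest assigned
uniformly. Random cographs are relations of a random DS-tree whose
labels are Dup/Spec with probability 1/2 except that any node whose two
child clades share a species is forced to Dup — otherwise the forced
paralogy invariant would break. Perturbed cographs flip k distinct
non-forced pairs, so the unit-weight optimum is at most k (the flip set
ships with the instance). Weighted instances use unit weights or i.i.d.
exponential(1) / uniform(0,2) draws; no generative model for
biologically realistic confidence weights is claimed — real pipelines
would derive weights from similarity scores or bootstrap support, with
correlations these samplers do not emulate. Test instances are small by
design (the oracles are exponential); passing tests certify the
algorithms' contracts on the regime where exact ground truth is
computable, not performance or accuracy on genome-scale families.

## Problem sizes used in the checks

The verification suite runs 300 editing instances (n ≤ 7, unit and
exponential weights, random graphs and perturbed cographs) and 150
consistent-editing instances (n ≤ 6, ≤ 4 species) against the exact
oracles; 500 graphs (n ≤ 8) for recognition equivalence and the
connectivity dichotomy; 500 random DS-trees (n ≤ 10) for the relation
round trip; 200 weighted graphs (n ≤ 10) for min-cut equivalence; 200
graphs for the half-agreement bound; the full exhaustive gadget sweep at
|V_H| ≤ 4 plus 10 sampled instances at |V_H| = 5; and 100 satisfiable
instances (≤ 5 genes, ≤ 4 species) for the consistency-decision
cross-check. These sizes give exhaustive or near-exhaustive coverage of
the regimes where the oracles are exact.

## Known limitations

* Multifurcating or unrooted species trees are not supported.
* Relations must be full: every pair is orthology or paralogy; partial
  relation sets are out of scope.
* The editors are approximations; no exact solver beyond the exponential
  oracles (e.g. an ILP) is provided.
* The polynomial-time approximation schemes for the maximization
  variants are not implemented; only their guaranteed half-agreement
  baseline is, with witnessing DS-trees.
* `simulate --family multicut` defaults to ⌊n/2⌋ terminal pairs — an
  arbitrary but fixed density choice.
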