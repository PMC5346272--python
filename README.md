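# orthoedit

Correction of weighted orthology/paralogy relation graphs.

## The problem

Pairwise orthology predictions for a gene family Γ (from clustering,
synteny, or reciprocal-best-hit style pipelines) form a **relation
graph** *R*: vertices are genes, an edge {x, y} asserts that x and y are
orthologs (they diverged at a speciation), and a missing edge asserts
paralogy (divergence at a duplication). Two genes from the same genome
are necessarily paralogs, so same-species pairs are forced non-edges.

Such predicted relations are often impossible as stated:

* **Satisfiability.** A relation graph is realized by some gene tree
  with Dup/Spec-labelled internal nodes (a *DS-tree*, read through the
  Fitch rule: x, y orthologous iff their lca is a speciation) exactly
  when it is **P4-free** — a cograph. A single induced path on four
  vertices rules out every possible history.
* **Consistency.** Even a satisfiable graph may contradict the known
  species tree *S*: a DS-tree is *S*-consistent when every speciation
  node maps its two children, under the LCA mapping s<sub>G</sub>, to
  incomparable nodes of *S*; a graph is *S*-consistent when some
  realizing DS-tree is.

`orthoedit` corrects a graph by inserting and removing edges of minimum
total weight, where a weight w({x, y}) expresses the confidence in each
predicted relation (same-species pairs get weight ∞):

* **MinWES** — minimum-weight editing to satisfiability;
* **MinWEC** — minimum-weight editing to *S*-consistency;
* **MinWRS** — the deletion-only variant;
* **MaxES / MaxEC** — the maximization view: keep as many relations as
  possible; the *agreement* of a solution R′ with R is
  |E<sub>R</sub> ∩ E<sub>R′</sub>| + |non-edges in common|.

These problems are NP-hard, and the weighted minimization variants admit
no constant-factor approximation under the unique games conjecture (the
package ships the multicut gadget behind that reduction as an
adversarial instance generator). What *is* achievable is a factor-*n*
guarantee:

## The algorithm

A graph is a cograph iff every induced subgraph on ≥ 2 vertices is
disconnected or has a disconnected complement. **MinCut-Cograph-Editing**
exploits this greedily: on the current vertex set *Z* it computes a
minimum-weight cut of R[Z] (removing the crossing edges yields a
duplication node) and a minimum-weight cut of the complement (inserting
the crossing non-edges yields a speciation node), applies the cheaper
one, and recurses on both sides. Each pair is edited at most once, the
output is always P4-free together with a realizing DS-tree, and the
total weight β(R) satisfies **β(R) ≤ n·σ<sub>R</sub>** where
σ<sub>R</sub> is the optimum. The bound is tight up to n−3 on a
double-star family.

For consistency, a speciation on gene set *Z* must split it exactly as
the root of *S* restricted to the species of *Z* — the species cut
C<sub>S</sub>(Z). **MinCut-Cograph-Editing-Cons** forces the complement
cut to be C<sub>S</sub>(Z), making the output tree *S*-consistent by
construction, again within a factor *n* of the consistent optimum.

For the maximization variants the package evaluates the guaranteed
baseline: the edgeless graph and the complete multipartite graph (by
species) jointly agree with R on every pair, so the better of the two
reaches at least ⌈C(n,2)/2⌉ agreement.

Exhaustive exact solvers (edit-subset enumeration, bipartition
enumeration, all-DS-trees enumeration) are included as oracles; every
algorithmic claim above is verified against them in the test suite.

## File formats

* **Genes TSV** — `gene_id <TAB> species_id`, one gene per row.
* **Relations TSV** — `gene_a <TAB> gene_b <TAB> orth|para <TAB> weight`,
  pairs written smaller-gene-first; unlisted pairs default to
  `para 1.0`; the literal `inf` denotes infinite weight; `#` starts a
  comment. Same-species pairs are forced to `para inf`.
* **Species tree** — rooted binary Newick, leaf labels = species ids.
* **DS-tree** — Newick with internal node labels `S` (speciation) and
  `D` (duplication), e.g. `(a1,b1)S;`.
* **Multicut TSV** — rows `vertex v`, `edge u v`, `terminal u v`.

## Worked example

Simulate a satisfiable graph on 8 genes over 4 species, flip 3 relations,
then correct it towards species-tree consistency:

```
$ orthoedit simulate --family perturbed-cograph --n 8 --n-species 4 --k 3 \
      --seed 42 --out-prefix fam
$ orthoedit check-sat --genes fam.genes.tsv --relations fam.relations.tsv
not satisfiable: induced P4 on g03 - g01 - g02 - g08
$ orthoedit edit --genes fam.genes.tsv --relations fam.relations.tsv \
      --consistent --species-tree fam.stree.nwk \
      --out-edits fam.edits.tsv --out-tree fam.tree.nwk
cost	4
inserted	0
removed	4
```

`check-sat` exits 1 and names four genes whose induced path certifies
that no gene tree can display these relations. The editor removes four
orthology assertions (total weight 4, listed in `fam.edits.tsv`) and
writes the reconciling gene tree

```
((((((g01,g02)S,g03)D,g08)D,g05)D,g07)D,(g04,g06)S)D;
```

whose speciation (`S`) nodes all respect the simulated species tree
`(s03,((s01,s02),s04));`. The exact optimum for comparison:
`orthoedit oracle` mirrors `edit` on small inputs.

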