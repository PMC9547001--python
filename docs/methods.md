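# Methods

This note documents the models, rules and numerical choices behind
`metnet`, and what the synthetic-data generator does and does not
emulate.

## Input model

An SBML file is reduced to the information graph construction needs:
species (id, name, compartment), reactions (reactant/product membership
with stoichiometries, reversibility flag) and gene–protein–reaction
(GPR) boolean rules. Flux bounds and objectives are read only far
enough to warn when absent; they play no role in any graph. Two GPR
encodings are supported — the SBML `fbc` package's
`geneProductAssociation` and legacy `GENE_ASSOCIATION` strings in
reaction notes — with `fbc` preferred under auto-detection, since newer
genome-scale models use `fbc` while older patient-derived model files
predate it. A species listed on both sides of a reaction is kept on
both sides (this is why parsing goes through python-libsbml rather than
a constraint-based-modelling layer, which would net the coefficients to
zero and silently delete the species from the reaction).

GPR rules are parsed with `and` binding tighter than `or`, parentheses
overriding both, and same-operator nesting flattened. Conversion to
disjunctive normal form yields the reaction's alternative enzyme
complexes; since GPRs are monotone (no negation), the deduplicated,
absorption-reduced DNF equals the set of minimal gene sets satisfying
the rule, which is what the truth-table oracle in the test suite
checks.

## Graph construction rules

*Metabolites-based.* For each reaction, every (reactant, product) pair
becomes a directed edge after recurrent species are removed from both
sides; a species on both sides yields no self-loop. With
`double_reversible` enabled, reversible reactions also emit the
mirrored pairs; the default is off, matching the directed tissue
networks' convention of using the written direction. Edges carry the
reaction id and the flat gene list of its GPR. Weighting by a sample's
expression uses mean-per-reaction-then-sum-per-pair; the mean is over
*all* genes of the reaction's GPR regardless of AND/OR structure,
because the aggregation is defined per reaction, not per complex.
Genes absent from the expression table are dropped from the mean's
denominator by default (`missing_policy="skip"`; `"zero"` counts them
as 0). Reactions without a GPR contribute weight 0 but keep their
edges: topology is model-determined, only weights are
sample-determined, which is what makes all samples of one model share
one structure.

*Enzymes-based.* Nodes are the DNF complexes of every reaction with a
GPR (AND-conjunct → one node labelled `gene1_AND_gene2…`, sorted;
OR-alternatives → separate nodes). Complex c1 → c2 when some reaction
catalysed by c1 produces a non-recurrent species that some reaction
catalysed by c2 consumes; self-loops (c1 = c2) are removed. Reactions
without GPRs contribute no nodes and therefore break paths through
them — an accepted information loss of this projection.

*Reactions-based.* R1 → R2 (R1 ≠ R2) when R1 produces a non-recurrent
species R2 consumes.

Recurrent matching is compartment-free and case-insensitive: a species
matches the list through its display name or its id with the `M_`/`m_`
prefix and compartment suffix stripped, since models duplicate currency
metabolites across compartments while currency lists are
compartment-free. The built-in list covers the classic currency set
(H2O, H+, ATP/ADP/AMP and the other NTP families, CO2, NH3, O2,
phosphate species, NAD(P)(H), FAD(H2), CoA, sulfate); it is a
deliberate superset of the canonical examples and fully replaceable by
a user file. An edge pair is suppressed only when the recurrent species
is one of its endpoints — the non-recurrent pairs of the same reaction
survive.

Only membership matters: stoichiometry magnitudes are parsed and
ignored throughout.

## Eigenvector-centrality simplification

Centrality is computed on the weight-symmetrised undirected projection
(weight of {u, v} = sum of the two directed weights): on directed
graphs that are not strongly connected the principal eigenvector is
ill-posed, whereas the symmetrised non-negative adjacency has a
well-defined Perron vector on its dominant component. Power iteration
runs on A + I — the identity shift leaves eigenvectors unchanged but
breaks the ±λ oscillation that plain iteration exhibits on bipartite
graphs (stars, chains) — with a uniform start vector, an
infinity-norm convergence test at tolerance 1e-10, and at most 1000
iterations; failure to converge is an error, never a silent partial
result. Scores are max-normalised so the top node scores exactly 1;
ranking ties break lexicographically so results are deterministic.
Selection is top-k by rank (the published simplified datasets are
described by node counts, not score thresholds) followed by isolate
removal, so the retained count may fall below k.

## Transition matrices and the network distance

Row i of the transition matrix is node i's out-edge weight distribution
(uniform over out-neighbours when unweighted). Rows are indexed by the
walker's current node — the reading under which "row i holds the local
connectivity of node i" is literally true, and the one the row-averaged
distance requires. Dangling rows (no out-edge, zero out-weight, or a
node of the shared ordering absent from this graph) default to a unit
mass on the node itself, preserving row locality; a uniform fallback is
available. The Jensen–Shannon distance uses base-2 logarithms so
d_JS ∈ [0, 1] and hence ℳ ∈ [0, 1]; 0·log 0 := 0. Input distributions
must sum to 1 within 1e-6; rows sum to 1 within 1e-9 by construction.
Because each row is normalised, both 𝒯 and ℳ are invariant under any
global positive rescaling of edge weights.

ℳ is defined for graphs sharing one node set (the per-sample graphs of
a single model). For collections with differing node sets the Gram
matrix can be built on the sorted union ordering with absent nodes as
dangling rows — an extension beyond the distance's home setting,
provided for convenience and off by default in nothing: it is simply
what `gram_matrix` does when node sets differ.

## Classification protocol

Features are rows of the Gram matrix (distance vectors) or externally
computed embedding vectors. Per fold, min–max normalisation is fitted
on training rows only; the classifier is a linear-kernel SVM with
C = 1 (exposed as configuration; the choice is conventional, not
tuned) and class weights inversely proportional to class frequency,
wrapped one-vs-rest for more than two classes. Cross-validation is
stratified 10-fold, repeated 10 times with per-repeat seeds
`seed + r` (recorded in the report); each repeat's metrics come from
its pooled out-of-fold predictions, and the report gives mean ± sd
across repeats. The hold-out protocol restricts features to
distances-to-training-graphs, so a test sample's representation never
depends on other held-out samples (the suite asserts that perturbing
test–test distances changes nothing). Metrics: accuracy and
macro-averaged precision/recall/F1 as percentages, and the
multi-class (Gorodkin) Matthews correlation coefficient, which reduces
to the classic binary formula for two classes; an MCC on a
single-class truth is reported as 0 with a warning.

## Synthetic data: what it does and does not show

`make_model` draws a random toy model: the first reactions form a
chain over the shuffled non-recurrent species (guaranteeing a weakly
connected metabolite graph), the rest draw random reactant/product
sets; currency species named after real recurrent metabolites join
either side with probability 0.5; GPRs are random AND/OR trees over an
Ensembl-style gene pool; a configurable fraction of reactions is
reversible. Defaults (20 species, 30 reactions, 15 genes, ≤ 4 genes
per GPR, 25% reversible, 15% currency species) give graphs of ~17
nodes and ~50 edges — large enough to exercise every rule, small
enough that 200 models compare against brute-force oracles in seconds.

`make_population` layers class structure on expression: per-gene
baselines are lognormal(μ = 1, σ = 0.5) (a fixed, documented choice
emulating the scale of log-FPKM values), each class adds an additive
shift δ (`weight_shift`, default 1.0) on its own disjoint signature-gene
subset, and Gaussian noise (sd 0.3) is added per sample, clipped at 0.
With δ ≈ 3.3 noise-sd the end-to-end pipeline separates two classes of
50 samples essentially perfectly, and with δ = 0 it sits at chance —
a signal-recovery and null calibration, not a claim about real cohorts.

What passing these tests shows: the construction rules, weighting
arithmetic, distance properties and protocol plumbing are correct.
What they cannot show: behaviour on genome-scale inputs (thousands of
nodes, compartment structure, isoform-level GPRs), real expression
covariance between genes, or batch effects — the generator draws genes
independently and emulates none of those.

## Problem sizes and determinism

Default verification sizes: 200 random models for the construction
oracle, 300 random GPR trees with exhaustive 2^n truth tables, 1000
random distribution triples for the metric properties, and a
2 × 50-sample cohort for end-to-end runs — all chosen so the whole
suite completes in well under a minute of compute while still covering
the parameter grid. All randomness flows from explicit integer seeds
(numpy `default_rng`); SBML and GraphML writers are byte-deterministic
(sorted element order, fixed key ids, UTF-8, LF), so equal seeds give
equal files.

## Known limitations

- Enzyme- and reaction-graph edges record connectivity only, not
  multiplicity (parallel shared metabolites collapse to one edge).
- Eigenvector centrality on a graph whose weights are all zero (every
  incident reaction GPR-less) is undefined and raised as an error.
- The DNF conversion is exponential in GPR depth in the worst case;
  genome-scale GPRs are shallow, but pathological inputs are not
  guarded against.
- `evaluate_embeddings` accepts externally produced vectors only; no
  embedding method is implemented here.
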