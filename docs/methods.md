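# Methods

## Ontology handling

The Cell Ontology (or any OBO document) is parsed into a directed acyclic
graph whose edges point from the more specific term to the more general one
(child → parent), following both `is_a` and `part_of` relationships; all
other relationship types are ignored.  Terms are restricted by accession
namespace (default `CL` and `UBERON`; the synthetic ontology uses `SIM`),
obsolete terms are dropped, and edges crossing out of the kept namespaces
are removed.  Parsing is delegated to `obonet`; acyclicity and a light
stanza pre-check (which names the offending line) are validated here.

**Descriptor matching.** A term matches a free-text descriptor when its
name or any synonym occurs as a whole-word token run after lowercasing and
punctuation stripping.  Deliberately, longer matches do not suppress shorter
ones — a descriptor mentioning "T cell" also matches "cell" — because
reduction to the most specific terms is a separate, well-defined step:
`filter_specific` removes every hit that is an ancestor of another hit,
leaving an antichain.  This two-stage design keeps matching simple and puts
all the ordering logic in one place, where it is property-tested
exhaustively against a reachability oracle.

**Graded type similarity.** Retrieval evaluation needs a similarity in
[0, 1] between cell types, high for a term and its parent, positive whenever
any ancestry is shared.  We use the Jaccard index of inclusive ancestor sets

    sim(a, b) = |anc⁺(a) ∩ anc⁺(b)| / |anc⁺(a) ∪ anc⁺(b)|,  anc⁺(t) = {t} ∪ ancestors(t).

It is 1 exactly on identical terms, symmetric, and decays with shrinking
ancestor overlap (2/3 for a child and its parent under one further root;
1/5 for two leaves sharing only the root of a three-level tree).  The
similarity function is an argument everywhere it is consumed, so an
alternative graded measure can be plugged in without touching the
evaluation code.

## Expression data model

Matrices are genes × cells with explicit units (`counts`, `rpkm`,
`log-rpkm`).  RPKM = 10⁹·c/(N·L) with c the read count, N the cell's total
mapped reads and L the gene length in bp.  Cells with alignment rate below
0.40 are discarded (boundary inclusive: rate ≥ 0.40 is kept).  Labels are
made "high-confidence" in two ordered passes: terms mapped by fewer than 75
cells are removed from every cell's term set, then only cells left with
exactly one term are kept.

**Train/query split.** For every cell type observed in at least two
studies, one whole study of that type (chosen uniformly under the seed) is
held out as the query set; single-study types stay entirely in training.
No (type, study) pair ever appears on both sides, so retrieval scores are
never inflated by study-specific effects.

**Preprocessing.** Three deterministic steps compose in any order: `log1p`,
per-cell L2 normalization, and per-gene standardization with statistics
fitted on training cells only (variance floored at 1e-8) and reapplied
unchanged to queries.  Query matrices are aligned to the model's gene list
by zero-filling absent genes and dropping extras, with a logged count.

**Batch correction (`StudyCenterer`).** Data integrated across many labs
carries per-study gene fingerprints that can dominate the biology: on the
default synthetic conditions a classifier trained on uncentered inputs
memorizes study signatures and scores *below* chance on held-out studies
(so does L2-regularized logistic regression — the problem is the
representation, not the model class).  The pipeline therefore removes each
gene's per-study mean.  Means are fitted on the training database; a query
cell is centered by its own study's *training-side* mean, so only database
statistics flow to the query.  A query study absent from the database falls
back to its own mean when it has at least 20 cells (else the global mean) —
a documented approximation that slightly biases small, type-pure query
batches.

## Neural embedding models

A multilayer perceptron maps genes to a low-dimensional last hidden layer
(the embedding).  Activations: tanh by default (bounded embeddings, adequate
for shallow networks), sigmoid/relu/linear available.  Initialization is
Glorot-uniform under an explicit seed; optimization is minibatch SGD with
momentum (defaults: rate 0.05, momentum 0.9, batch 32, up to 100 epochs).
All gradients are derived by hand and verified against central differences
in the test suite, at the loss level and through the network.

* **Classifier mode** — softmax cross-entropy over single-term labels,
  unweighted despite class imbalance.
* **Siamese mode** — contrastive loss with margin m = 1 on the Euclidean
  distance between twin embeddings; pairs are resampled every epoch,
  balanced 50/50 same/different, uniformly within the eligible classes.
* **Triplet mode** — max(0, d_ap − d_an + α) on squared distances with
  α = 0.2 (the FaceNet convention); anchors require a class with ≥2
  members.  The fraction of triplets with positive loss ("active
  triplets") is tracked per epoch and can drive weight selection.

A held-out validation fraction (default 10%) is scored every epoch; the
returned weights are those of the epoch minimizing validation loss (or the
active-triplet fraction, when configured), with early stopping after 10
epochs without improvement.  Divergence (non-finite loss or weights) raises
an error naming the epoch.

**Prior-knowledge connectivity.** A sparse first layer can encode gene
sets: one unit per set, connected only to member genes (binary masks zero
the forbidden weights after every update, so masked positions are exactly
zero at all times), optionally alongside a fully connected side branch.
The GO-hierarchy builder assigns each term a layer by its maximum distance
to a root, wires genes to their deepest annotated terms and terms to their
parents, adds one catch-all unit per layer (for unannotated genes and
level-skipping edges), and finishes with a dense layer at the requested
embedding dimension.

**Unsupervised pretraining** is greedy layer-wise autoencoding: each hidden
layer is trained as the encoder of a one-layer autoencoder (linear decoder,
MSE, full-batch gradient descent) on the activations of the layers before
it.  Full-batch updates keep the procedure deterministic and its loss
near-monotone, which the tests assert.

## Retrieval and evaluation

The exact backend is a brute-force scan with stable-sort tie-breaking by
database insertion order.  The approximate backend is an inverted-file
(IVF) index: k-means partitions (√n by default) with multi-probe search.
Rather than fixing a probe budget, `fit()` runs a held self-test — recall
of the approximate 100-NN against an exact scan on sampled database points
— and doubles the probe count until mean recall reaches 0.92.  Clustered
embeddings (the intended workload) get small budgets; pathological
unclustered data degrades toward a full scan instead of violating the
≥ 0.9 recall contract.

Classification takes the modal label among the k = 100 nearest neighbors;
ties break by smaller summed distance, then lexicographic term id.
Similarity vectors use s = 1/(1+D) per neighbor, summed per type and
normalized to 1.

**MAFP.** For one query with graded relevances r_i = sim(query type, type
at rank i) over the full database ranking,

    AFP = Σ_i [ r_i · (Σ_{j≤i} r_j) / i ] / Σ_i r_i,

which reduces exactly to textbook average precision for binary relevance
(property-tested against an independent AP implementation).  MAFP per type
is the mean AFP of that type's queries; the overall score weights types by
their query-cell counts.  Ranking depth is the full training database;
classification uses k = 100.

The PCA baseline fits components on training cells only and projects
queries with the training loadings.  The random baseline is i.i.d. standard
normal coordinates per cell — a chance floor.  (A random *projection* of
the data is not a floor: it approximately preserves geometry.)

## DE meta-analysis

Per cell type and study, the target cells are tested against the study's
other cells, excluding cells whose type is an ontology ancestor or
descendant of the target (so sibling types are distinguished rather than
"brain vs everything"; pruning is switchable).  The default engine is a
two-sided Wilcoxon rank-sum test on log1p values with the mean log
difference as effect; any function with the same signature, or an external
results table, plugs in.  Studies lacking 10 target or 10 background cells
are skipped with a logged reason.

Across studies, each gene's p-values are pooled with Fisher's statistic
−2Σln p (χ² with 2k d.f.) and BH-adjusted.  Significance additionally
requires *support*: per-study p < 0.05 with a consistent direction in a
majority of the studies testing the gene (a single-study gene passes on
that study alone).  The support rule is what excludes single-study batch
artifacts — Fisher's method alone would happily promote one extreme
p-value — and direction consistency is enforced among supporting studies
only, so noise-level signs in uninformative studies cannot veto a true
marker.  Note that Fisher combination sharpens significance only for
informative p-values (combined p ≤ p holds below p ≈ 0.285 for two
studies); the tests assert monotonicity in that regime.

## Synthetic data

The generator emulates the assumed data model and nothing more: counts are
negative binomial (var = μ + 0.5·μ²) around log-normal gene base means;
each type's 20 marker genes are scaled by 2² = 4 in that type; every
(study, gene) pair carries a 2^N(0, 0.5) batch factor; library sizes vary
log-uniformly over [0.5, 2]; and technical dropout is Bernoulli with a
*mean-dependent* probability — logistic in log mean expression (width 0.7
ln-units), with the midpoint calibrated by bisection so the marginal
dropout rate equals the configured 0.3.  Mean dependence matters: real
capture failure concentrates on weakly expressed transcripts, and modeling
dropout as a constant rate across all genes buries the type structure
below the random-matrix detection limit at these sample sizes, which no
analysis method could recover.  Optional batch-artifact genes are
up-shifted in one randomly chosen study across all types, giving the DE
meta-analysis planted negatives.

Default conditions: 8 leaf types under 2 lineage branches (depth-3 toy
ontology with names and synonyms), 3 studies, 100 cells per (type, study),
2000 genes.  Descriptors embed the type name or a synonym among filler
tokens; 25% also mention an ancestor term, exercising the specificity
filter.  Truth tables (type map, marker map, artifact genes/study) are
returned alongside the data.

What the generator does *not* emulate: UMI counting, gene length variation
(all synthetic genes share a nominal 1 kb), correlated gene programs,
continuous differentiation trajectories, doublets, or ambient RNA.  Passing
the recovery tests therefore shows the pipeline's logic is sound under the
stated generative family, not that these accuracy numbers transfer to any
particular real dataset.

## Problem sizes and numerical choices

The packaged experiments run the full default conditions (2400 cells ×
2000 genes; training 2000→256→64 for up to 40 epochs at rate 0.01) in
well under a minute per seed on one CPU; the DE recovery experiment adds a
few seconds.  Tolerances: losses match direct evaluation to 1e-6 and
gradients to 1e-4; binary-similarity AFP matches the AP oracle to 1e-9;
standardization floors gene variance at 1e-8; Fisher p-values clip inputs
at 1e-300.  Ties in nearest-neighbor ranking break by database insertion
order (stable sort); classification ties by summed distance then term id.
All randomness — simulation, splits, initialization, sampling — runs off
explicit integer seeds, and the end-to-end command-line pipeline is
bit-reproducible (model containers are written without HDF5 timestamps).

## Known limitations

* The command-line `train` path uses log1p + standardization without study
  centering; the batch-robust path is the library `pipeline` module.  A
  persisted model container stores weights and gene list but not the
  preprocessing statistics, which must be managed by the caller.
* The GO-hierarchy layer assignment (maximum root distance) collapses terms
  of equal depth into one layer regardless of subgraph, and level-skipping
  edges route through catch-all units rather than direct connections.
* The graded similarity and the flexible-precision formula are reasonable,
  property-constrained choices, exposed as plug-in points rather than fixed
  truths; conclusions that depend on their exact shape should be checked
  under alternatives.
* `de_single_study` assumes within-study label quality; it does not model
  per-cell error as count-based engines do.  Such engines can be attached
  through the engine interface but are not reimplemented here.
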