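# scretrieve

Retrieval-based cell-type annotation for single-cell RNA-seq, built around
four pieces that usually live in separate tools:

1. **Ontology-driven labeling** — free-text sample descriptors are matched
   against Cell Ontology term names and synonyms, and the hit set is reduced
   to its most specific terms (an antichain in the ontology DAG), so a
   sample described as "primary T lymphocyte, spleen" is labeled `T cell`
   rather than the uselessly general `cell`.
2. **Supervised neural embeddings** — a cell's expression profile
   (genes as input units) is mapped through a small multilayer perceptron
   whose last hidden layer is taken as a reduced-dimension representation.
   Three training modes are provided: a softmax classifier over cell types,
   siamese twins with the contrastive loss

   L(D, Y) = Y · D²/2 + (1−Y) · max(0, m−D)²/2,

   where D is the Euclidean distance between twin embeddings and Y indicates
   a same-type pair, and triplet networks with
   L = max(0, d(a,p) − d(a,n) + α) on squared distances.  Architectures can
   be dense or carry a sparse first layer wired from prior-knowledge gene
   sets (GMT), or mirror a GO-style hierarchy.
3. **Nearest-neighbor retrieval** — query cells are embedded and matched
   against a database of labeled embeddings; the modal label among the 100
   nearest neighbors is the predicted type, and per-type similarity vectors
   s = 1/(1+D), accumulated and normalized to sum to 1, summarize each query.
   Retrieval quality is scored by **MAFP** (mean average flexible precision):
   average precision generalized to graded relevances r_i ∈ [0,1] taken from
   ontology similarity, so retrieving a parent or sibling type earns partial
   credit.
4. **Cross-study DE meta-analysis** — cell-type marker genes are found by
   running differential expression *within* each study (rank-sum on log
   expression by default; any engine producing per-gene p-values and
   directions plugs in) and combining across studies with Fisher's method,
   Benjamini–Hochberg FDR, and a majority-support rule that discards genes
   driven by a single study — the signature of a batch artifact rather than
   biology.

Training and evaluation are *study-held-out*: for every cell type present in
more than one study, one entire study is moved to the query set, so reported
accuracy cannot come from lab-specific batch effects.  A synthetic-data
module generates multi-study count data (negative binomial, type-specific
markers, per-study batch factors, mean-dependent dropout) with full truth
tables, so the whole pipeline is testable without any downloads.

## Worked example

```python
from scretrieve import pipeline

res = pipeline.retrieval_experiment(seed=1)
print(f"MAFP neural embedding : {res.mafp_embedding:.3f}")
print(f"MAFP PCA-64 baseline  : {res.mafp_pca:.3f}")
print(f"MAFP random baseline  : {res.mafp_random:.3f}")
print(f"100-NN query accuracy : {res.knn_accuracy:.3f}")
```

prints

```
MAFP neural embedding : 0.651
MAFP PCA-64 baseline  : 0.469
MAFP random baseline  : 0.414
100-NN query accuracy : 0.941
```

This simulates 8 cell types × 3 studies × 100 cells over 2000 genes (20
markers per type at 4-fold effect, study batch factors, 30% dropout), infers
labels from the generated free-text descriptors through the toy ontology,
holds out one study per type as the query set, trains a dense
classifier embedding (2000→256→64, tanh) on batch-centered log-RPKM, and
ranks the full 1600-cell training database for each of the 800 query cells.
The supervised embedding clearly out-ranks unsupervised PCA at the same
dimension, which in turn beats chance-level random coordinates; 94% of
held-out-study cells get the right type from a 100-NN majority vote.

The same stages are available from the shell:

```bash
scretrieve simulate --out data/ --seed 1
scretrieve label --metadata data/metadata.tsv --obo data/ontology.obo --out labels.tsv
scretrieve train --expr data/counts.tsv --metadata data/metadata.tsv \
    --labels labels.tsv --out model/ --seed 1
scretrieve embed --model model/model.h5 --expr data/counts.tsv --out emb.tsv
scretrieve query --db-embeddings emb.tsv --db-labels labels.tsv \
    --query-embeddings emb.tsv --out query/ --k 100
scretrieve de --expr data/counts.tsv --metadata data/metadata.tsv \
    --labels labels.tsv --obo data/ontology.obo --out de/
```

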