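"""End-to-end experiment orchestration.

Two study designs are packaged here so the command-line tool, the test
suite and the reproduction script all exercise one code path:

* :func:`retrieval_experiment` — simulate a multi-study dataset, infer
  labels from free-text descriptors through the ontology, apply the quality
  and confidence filters, hold out one study per multi-study cell type,
  train a dense classifier embedding on batch-centered inputs, and evaluate
  retrieval MAFP for the neural embedding, a PCA baseline at the same
  dimension, and a random-coordinate floor.
* :func:`de_experiment` — simulate data with planted markers and planted
  single-study batch-artifact genes, run the per-study DE + meta-analysis,
  and score marker recovery and artifact rejection against the truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dataset, de_meta, models, ontology, retrieval, synthetic

__all__ = ["RetrievalExperimentResult", "DEExperimentResult",
           "retrieval_experiment", "de_experiment", "infer_labels"]

GENE_LENGTH_BP = 1000.0  # synthetic genes share a nominal length


def infer_labels(
    records: list[dataset.CellRecord], dag: ontology.OntologyDAG
) -> list[dataset.CellRecord]:
    """Replace each record's terms with ones inferred from its descriptor."""
    out = []
    for c in records:
        hits = ontology.match_terms(c.descriptor, dag)
        specific = ontology.filter_specific(hits, dag)
        out.append(dataset.CellRecord(c.cell_id, c.study_id, c.descriptor,
                                      c.align_rate, c.total_reads, specific))
    return out


@dataclass
class RetrievalExperimentResult:
    mafp_embedding: float
    mafp_pca: float
    mafp_random: float
    knn_accuracy: float
    weighted_mafp_report: retrieval.EvalReport
    n_train: int
    n_query: int
    best_epoch: int
    history: models.TrainingHistory = field(repr=False)


def retrieval_experiment(
    config: synthetic.SimConfig | None = None,
    seed: int = 0,
    embedding_dim: int = 64,
    hidden: int = 256,
    epochs: int = 40,
    learning_rate: float = 0.01,
    min_cells_per_term: int = 75,
    knn_k: int = retrieval.DEFAULT_K,
) -> RetrievalExperimentResult:
    """Full retrieval-testing pipeline on synthetic data.

    The embedding model is a dense classifier with hidden sizes
    ``[hidden, embedding_dim]``; the PCA baseline uses the same dimension.
    Inputs to both are log1p RPKM, per-study centered against the training
    database (standardization is added for the network).  MAFP is computed
    over the full training database with ontology-graded relevance; the
    100-NN majority-vote accuracy of the query cells is reported alongside.
    """
    if config is None:
        config = synthetic.SimConfig(seed=seed)
    dag = synthetic.make_toy_ontology(config.n_types, config.depth, config.seed)
    expr, records, truth = synthetic.simulate_cells(config, dag)

    # label inference from descriptors, then the confidence filters
    records = infer_labels(records, dag)
    records = dataset.filter_alignment_rate(records)
    records = dataset.select_high_confidence(records, min_cells_per_term)
    plan = dataset.split_train_query(records, seed=seed)

    term = {c.cell_id: c.single_term for c in records}
    study = {c.cell_id: c.study_id for c in records}
    y_train = [term[c] for c in plan.train_ids]
    y_query = [term[c] for c in plan.query_ids]
    st_train = [study[c] for c in plan.train_ids]
    st_query = [study[c] for c in plan.query_ids]

    rpkm = dataset.rpkm_normalize(expr, {g: GENE_LENGTH_BP for g in expr.genes})
    train_rpkm = rpkm.subset_cells(plan.train_ids)
    query_rpkm = rpkm.subset_cells(plan.query_ids)

    sim = lambda a, b: ontology.type_similarity(a, b, dag)  # noqa: E731

    # PCA baseline input: log1p, study-centered
    pre_pca = dataset.Preprocessor(("log1p",)).fit(train_rpkm)
    cent_pca = dataset.StudyCenterer().fit(
        pre_pca.transform(train_rpkm).values.T, st_train
    )
    Xp_tr = cent_pca.transform(pre_pca.transform(train_rpkm).values.T, st_train)
    Xp_q = cent_pca.transform(pre_pca.transform(query_rpkm).values.T, st_query)
    pca_tr, pca_q = retrieval.pca_baseline(Xp_tr, Xp_q, embedding_dim, seed=seed)
    mafp_pca = retrieval.evaluate_retrieval(pca_tr, y_train, pca_q, y_query, sim).weighted_average

    # neural embedding input: log1p + standardize, study-centered
    pre_nn = dataset.Preprocessor(("log1p", "standardize")).fit(train_rpkm)
    cent_nn = dataset.StudyCenterer().fit(pre_nn.transform(train_rpkm).values.T, st_train)
    Xn_tr = cent_nn.transform(pre_nn.transform(train_rpkm).values.T, st_train)
    Xn_q = cent_nn.transform(pre_nn.transform(query_rpkm).values.T, st_query)

    classes = sorted(set(y_train))
    model = models.build_dense(expr.genes, [hidden, embedding_dim], classes=classes, seed=seed)
    tc = models.TrainingConfig(epochs=epochs, learning_rate=learning_rate, seed=seed)
    model, history = models.train(model, Xn_tr, y_train, tc)
    emb_tr = models.embed(model, Xn_tr)
    emb_q = models.embed(model, Xn_q)
    report = retrieval.evaluate_retrieval(emb_tr, y_train, emb_q, y_query, sim)

    # random-coordinate floor at the same dimension
    rng = np.random.default_rng(seed)
    mafp_rand = retrieval.evaluate_retrieval(
        rng.normal(size=(len(y_train), embedding_dim)), y_train,
        rng.normal(size=(len(y_query), embedding_dim)), y_query, sim,
    ).weighted_average

    # 100-NN majority-vote classification of query cells
    index = retrieval.build_index(emb_tr, y_train)
    correct = 0
    for qi in range(len(y_query)):
        nn = retrieval.knn_query(index, emb_q[qi], k=min(knn_k, len(y_train)))
        correct += retrieval.classify_cell(nn, y_train) == y_query[qi]

    return RetrievalExperimentResult(
        mafp_embedding=report.weighted_average,
        mafp_pca=mafp_pca,
        mafp_random=mafp_rand,
        knn_accuracy=correct / len(y_query),
        weighted_mafp_report=report,
        n_train=len(y_train),
        n_query=len(y_query),
        best_epoch=history.best_epoch,
        history=history,
    )


@dataclass
class DEExperimentResult:
    marker_recall: float
    artifact_rejection: float
    n_markers: int
    n_artifacts: int
    per_type: dict[str, de_meta.CellTypeDEList] = field(repr=False)


def de_experiment(
    config: synthetic.SimConfig | None = None,
    seed: int = 0,
    fdr_threshold: float = de_meta.FDR_THRESHOLD_DEFAULT,
) -> DEExperimentResult:
    """Planted-truth DE recovery on synthetic data.

    Recall = fraction of planted (type, marker) pairs found significant and
    up-regulated in that type's combined list; rejection = fraction of
    planted single-study batch-artifact genes absent from every type's
    significant list.
    """
    if config is None:
        config = synthetic.SimConfig(seed=seed, n_batch_artifact_genes=40)
    dag = synthetic.make_toy_ontology(config.n_types, config.depth, config.seed)
    expr, records, truth = synthetic.simulate_cells(config, dag)
    results = de_meta.de_all_types(expr, records, ontology=dag, fdr_threshold=fdr_threshold)

    found = 0
    total = 0
    for t, marker_genes in truth["markers"].items():
        sig_up = set()
        if t in results:
            tab = results[t].table
            sig_up = set(tab[(tab["significant"]) & (tab["direction"] > 0)]["gene"])
        for g in marker_genes:
            total += 1
            found += g in sig_up
    all_sig = set()
    for lst in results.values():
        all_sig |= set(lst.table[lst.table["significant"]]["gene"])
    artifacts = truth["artifact_genes"]
    rejected = sum(g not in all_sig for g in artifacts)
    return DEExperimentResult(
        marker_recall=found / total if total else float("nan"),
        artifact_rejection=rejected / len(artifacts) if artifacts else float("nan"),
        n_markers=total,
        n_artifacts=len(artifacts),
        per_type=results,
    )
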