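"""Synthetic multi-study scRNA-seq data with known ground truth.

The generator emulates the data model the rest of the package assumes: a
toy cell-type ontology (a rooted tree with named, synonym-bearing leaves),
negative-binomial counts with type-specific marker genes, multiplicative
per-study (lab/batch) factors, Bernoulli dropout zeros and variable library
sizes.  Dropout is mean-dependent, as in real scRNA-seq: the probability of
a technical zero falls logistically with a gene's expected expression, and
the logistic midpoint is calibrated so the marginal technical-dropout rate
equals the configured value.  Free-text descriptors embed the type name or
a synonym amid filler tokens so the label-inference path is exercised end
to end.  Every draw runs off the config seed and truth tables (marker map,
type map, planted batch artifacts) are first-class outputs for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dataset import CellRecord, ExpressionMatrix
from .ontology import OntoTerm, OntologyDAG

__all__ = ["SimConfig", "make_toy_ontology", "simulate_cells", "make_descriptors"]

_LEAF_WORDS = [
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta",
    "iota", "kappa", "lambda", "omicron", "sigma", "tau", "upsilon", "omega",
]
_BRANCH_WORDS = ["myeloid", "lymphoid", "stromal", "neural", "epithelial", "endothelial"]
_FILLER = ["primary", "sorted", "single", "sample", "replicate", "passage", "fresh", "adult"]


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults describe a moderately hard multi-study setting: 8 leaf cell
    types profiled by 3 studies each, 100 cells per (type, study), 2000
    genes with 20 markers per type at a log2 effect of 2 (4-fold), study
    batch factors with s.d. 0.5 on the natural-log scale, and 30% dropout.
    """

    n_types: int = 8
    depth: int = 3
    studies_per_type: int = 3
    cells_per_type_study: int = 100
    n_genes: int = 2000
    markers_per_type: int = 20
    marker_effect: float = 2.0  # log2 fold change in the marker's own type
    batch_sd: float = 0.5       # s.d. of per-(study, gene) factor, log2 scale
    dropout: float = 0.3        # marginal technical-dropout probability
    dropout_shape: float = 0.7  # logistic width of the mean-dependence (ln units)
    dispersion: float = 0.5     # NB: var = mu + dispersion * mu^2
    library_size_range: tuple[float, float] = (0.5, 2.0)
    ancestor_mention_fraction: float = 0.25
    n_batch_artifact_genes: int = 0
    batch_artifact_effect: float = 2.0  # log2, applied in one study only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1 or self.n_genes < 1 or self.cells_per_type_study < 1:
            raise ValueError("counts must be positive")
        if self.depth < 2:
            raise ValueError("ontology depth must be >= 2")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout rate must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ValueError("library size range must be positive and ordered")
        if self.n_types * self.markers_per_type + self.n_batch_artifact_genes > self.n_genes:
            raise ValueError("not enough genes for the requested markers/artifacts")


def make_toy_ontology(n_types: int = 8, depth: int = 3, seed: int = 0) -> OntologyDAG:
    """A rooted tree-like DAG with named leaf cell types and synonyms.

    depth 2 puts the leaves directly under the root "cell"; depth >= 3 adds
    intermediate lineage terms so graded similarity distinguishes sibling
    leaves from cross-lineage ones.  Deterministic for a given shape (the
    seed is accepted for interface symmetry).
    """
    if depth < 2:
        raise ValueError("depth must be >= 2")
    if n_types > len(_LEAF_WORDS):
        raise ValueError(f"at most {len(_LEAF_WORDS)} leaf types supported")
    terms = [OntoTerm("SIM:0000000", "cell", namespace="SIM")]
    edges: list[tuple[str, str]] = []

    # chain of intermediate levels between root and the branch layer
    parent_of_branches = "SIM:0000000"
    for lvl in range(depth - 3):
        tid = f"SIM:00000{90 + lvl:02d}"
        terms.append(OntoTerm(tid, f"level {lvl + 1} cell", namespace="SIM"))
        edges.append((tid, parent_of_branches))
        parent_of_branches = tid

    if depth == 2:
        branch_ids = [parent_of_branches]
    else:
        n_branches = min(len(_BRANCH_WORDS), max(2, int(np.ceil(n_types / 4))))
        branch_ids = []
        for b in range(n_branches):
            tid = f"SIM:00001{b:02d}"
            terms.append(OntoTerm(tid, f"{_BRANCH_WORDS[b]} cell", namespace="SIM"))
            edges.append((tid, parent_of_branches))
            branch_ids.append(tid)

    for i in range(n_types):
        word = _LEAF_WORDS[i]
        tid = f"SIM:00100{i:02d}" if i < 10 else f"SIM:0010{i:03d}"
        terms.append(
            OntoTerm(
                tid,
                f"{word} cell",
                synonyms=(f"{word} type cell", f"{word}cyte"),
                namespace="SIM",
            )
        )
        edges.append((tid, branch_ids[i % len(branch_ids)]))
    return OntologyDAG(terms, edges, namespaces_kept={"SIM"})


def _leaf_terms(ontology: OntologyDAG) -> list[str]:
    return sorted(ontology.leaves())


def make_descriptors(
    cell_types: Mapping[str, str],
    ontology: OntologyDAG,
    ancestor_fraction: float = 0.0,
    seed: int = 0,
) -> dict[str, str]:
    """Free-text descriptors per cell id embedding the true type name.

    Each descriptor mentions the type's name or one of its synonyms among
    filler tokens; a configurable fraction additionally mentions an ancestor
    term's name, which exercises the most-specific-term filter.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for cell_id in cell_types:
        term_id = cell_types[cell_id]
        if term_id not in ontology:
            raise KeyError(f"type {term_id!r} is not in the ontology")
        term = ontology.terms[term_id]
        phrases = [term.name, *term.synonyms]
        phrase = phrases[int(rng.integers(len(phrases)))]
        tokens = [
            _FILLER[int(rng.integers(len(_FILLER)))],
            phrase + ",",
            _FILLER[int(rng.integers(len(_FILLER)))],
            str(int(rng.integers(1, 9))),
        ]
        if rng.random() < ancestor_fraction:
            ancestors = sorted(ontology.ancestors(term_id))
            if ancestors:
                anc = ontology.terms[ancestors[int(rng.integers(len(ancestors)))]]
                tokens.append(f"({anc.name})")
        out[cell_id] = " ".join(tokens)
    return out


def _dropout_midpoint(log_means: np.ndarray, rate: float, shape: float) -> float:
    """Logistic midpoint such that the mean dropout probability equals ``rate``.

    Solved by bisection on the monotone map midpoint -> mean probability.
    """
    if rate <= 0:
        return -np.inf
    lo, hi = log_means.min() - 20.0, log_means.max() + 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        p = float(np.mean(1.0 / (1.0 + np.exp((log_means - mid) / shape))))
        if p < rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cells(
    config: SimConfig, ontology: OntologyDAG | None = None
) -> tuple[ExpressionMatrix, list[CellRecord], dict]:
    """Draw a multi-study count matrix with known markers and batch structure.

    Counts are negative binomial around gene base means; a type's marker
    genes are scaled by 2^marker_effect in that type; every (study, gene)
    pair carries a multiplicative 2^N(0, batch_sd) batch factor; optional
    planted batch-artifact genes are up-shifted in a single study across all
    types; mean-dependent Bernoulli dropout zeroes entries, hitting weakly
    expressed genes hardest.  Returns the counts, per-cell records
    (descriptor, QC stats, true term) and a truth dict with the marker map,
    the type map and the artifact genes/study.
    """
    if ontology is None:
        ontology = make_toy_ontology(config.n_types, config.depth, config.seed)
    rng = np.random.default_rng(config.seed)
    leaves = _leaf_terms(ontology)
    if len(leaves) < config.n_types:
        raise ValueError("ontology has fewer leaves than requested types")
    types = leaves[: config.n_types]
    studies = [f"study{j + 1:02d}" for j in range(config.studies_per_type)]
    genes = [f"g{i:05d}" for i in range(config.n_genes)]

    base = rng.lognormal(mean=1.0, sigma=1.0, size=config.n_genes)
    marker_map: dict[str, list[str]] = {}
    cursor = 0
    effect = np.ones((len(types), config.n_genes))
    for ti, t in enumerate(types):
        idx = np.arange(cursor, cursor + config.markers_per_type)
        marker_map[t] = [genes[i] for i in idx]
        effect[ti, idx] = 2.0 ** config.marker_effect
        cursor += config.markers_per_type
    artifact_idx = np.arange(cursor, cursor + config.n_batch_artifact_genes)
    artifact_genes = [genes[i] for i in artifact_idx]
    artifact_study = studies[int(rng.integers(len(studies)))] if len(artifact_idx) else None

    batch = 2.0 ** rng.normal(0.0, config.batch_sd, size=(len(studies), config.n_genes))
    if len(artifact_idx):
        si = studies.index(artifact_study)
        batch[si, artifact_idx] *= 2.0 ** config.batch_artifact_effect

    # calibrate the dropout curve on the grid of (type, study, gene) means
    all_means = np.log(
        np.einsum("g,tg,sg->tsg", base, effect, batch).reshape(-1)
    )
    mid = _dropout_midpoint(all_means, config.dropout, config.dropout_shape)

    lo, hi = config.library_size_range
    n_cells = len(types) * len(studies) * config.cells_per_type_study
    counts = np.empty((config.n_genes, n_cells))
    cell_ids: list[str] = []
    cell_study: list[str] = []
    type_map: dict[str, str] = {}
    col = 0
    size = 1.0 / config.dispersion  # NB shape parameter
    for si, study in enumerate(studies):
        for ti, t in enumerate(types):
            mu_gene = base * effect[ti] * batch[si]
            p_drop = (
                1.0 / (1.0 + np.exp((np.log(mu_gene) - mid) / config.dropout_shape))
                if config.dropout > 0
                else np.zeros(config.n_genes)
            )
            for k in range(config.cells_per_type_study):
                cid = f"{study}_t{ti}_c{k:03d}"
                lib = np.exp(rng.uniform(np.log(lo), np.log(hi)))
                mu = mu_gene * lib
                p = size / (size + mu)
                draw = rng.negative_binomial(size, p).astype(float)
                if config.dropout > 0:
                    draw *= rng.random(config.n_genes) >= p_drop
                counts[:, col] = draw
                cell_ids.append(cid)
                cell_study.append(study)
                type_map[cid] = t
                col += 1

    expr = ExpressionMatrix(counts, genes, cell_ids, unit="counts")
    descriptors = make_descriptors(
        type_map, ontology, config.ancestor_mention_fraction, seed=config.seed + 1
    )
    total_reads = counts.sum(axis=0)
    align_rates = rng.uniform(0.55, 0.98, size=n_cells)
    records = [
        CellRecord(
            cell_id=cid,
            study_id=cell_study[i],
            descriptor=descriptors[cid],
            align_rate=float(align_rates[i]),
            total_reads=int(total_reads[i]),
            specific_terms={type_map[cid]},
        )
        for i, cid in enumerate(cell_ids)
    ]
    truth = {
        "markers": marker_map,
        "types": type_map,
        "artifact_genes": artifact_genes,
        "artifact_study": artifact_study,
        "studies": studies,
        "type_order": types,
    }
    return expr, records, truth
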