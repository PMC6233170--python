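"""Expression-matrix I/O, RPKM normalization, quality/label filters and the
batch-effect-aware train/query split.

Conventions: matrices are genes x cells; gene symbols are matched
case-sensitively after whitespace trimming; expression units are tracked
explicitly and changed only by the operations that transform them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "CellRecord",
    "SplitPlan",
    "DatasetError",
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "rpkm_normalize",
    "filter_alignment_rate",
    "select_high_confidence",
    "split_train_query",
    "Preprocessor",
    "StudyCenterer",
    "align_to_genes",
]

ALIGNMENT_RATE_DEFAULT = 0.40
MIN_CELLS_PER_TERM_DEFAULT = 75
VARIANCE_FLOOR = 1e-8

METADATA_COLUMNS = ("cell_id", "study_id", "descriptor", "align_rate", "total_reads")


class DatasetError(ValueError):
    """Raised for malformed expression or metadata inputs."""


@dataclass
class ExpressionMatrix:
    """Genes x cells expression values with aligned name vectors."""

    values: np.ndarray
    genes: list[str]
    cells: list[str]
    unit: str = "counts"  # counts | rpkm | log-rpkm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.genes = [str(g).strip() for g in self.genes]
        self.cells = [str(c).strip() for c in self.cells]
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise DatasetError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise DatasetError(f"duplicate gene names: {dupes[:5]}")
        if len(set(self.cells)) != len(self.cells):
            raise DatasetError("duplicate cell ids")
        if self.values.size and np.nanmin(self.values) < 0:
            raise DatasetError("negative expression values")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {c: i for i, c in enumerate(self.cells)}
        idx = [pos[c] for c in cell_ids]
        return ExpressionMatrix(self.values[:, idx], list(self.genes), list(cell_ids), self.unit)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)


@dataclass
class CellRecord:
    """Per-cell metadata: provenance, descriptor, QC stats and ontology terms."""

    cell_id: str
    study_id: str
    descriptor: str = ""
    align_rate: float = 1.0
    total_reads: int = 0
    specific_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.study_id:
            raise DatasetError(f"cell {self.cell_id!r} has an empty study id")
        if not 0.0 <= self.align_rate <= 1.0:
            raise DatasetError(f"cell {self.cell_id!r} alignment rate {self.align_rate} outside [0, 1]")

    @property
    def single_term(self) -> str:
        if len(self.specific_terms) != 1:
            raise DatasetError(f"cell {self.cell_id!r} does not have exactly one term")
        return next(iter(self.specific_terms))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_expression(expr: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a matrix as TSV (genes as rows) or Matrix Market triplet.

    The mtx format stores only nonzeros and is accompanied by ``<path>.rows``
    and ``<path>.cols`` name files.
    """
    path = Path(path)
    if format == "tsv":
        df = expr.to_frame()
        # %.17g round-trips float64 exactly
        df.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(expr.values))
        Path(f"{path}.rows").write_text("\n".join(expr.genes) + ("\n" if expr.genes else ""))
        Path(f"{path}.cols").write_text("\n".join(expr.cells) + ("\n" if expr.cells else ""))
    else:
        raise DatasetError(f"unknown expression format {format!r}")


def read_expression(path: str | Path, format: str = "tsv", unit: str = "counts") -> ExpressionMatrix:
    """Read an expression matrix written by :func:`write_expression`."""
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        genes = [str(g) for g in df.index]
        if len(set(genes)) != len(genes):
            raise DatasetError(f"duplicate gene names in {path}")
        return ExpressionMatrix(df.to_numpy(dtype=float), genes, [str(c) for c in df.columns], unit)
    if format == "mtx":
        values = scipy.io.mmread(str(path)).toarray().astype(float)
        genes = [l for l in Path(f"{path}.rows").read_text().splitlines() if l]
        cells = [l for l in Path(f"{path}.cols").read_text().splitlines() if l]
        if values.shape != (len(genes), len(cells)):
            raise DatasetError(
                f"mtx shape {values.shape} does not match name files "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
        return ExpressionMatrix(values, genes, cells, unit)
    raise DatasetError(f"unknown expression format {format!r}")


def write_metadata(cells: Iterable[CellRecord], path: str | Path) -> None:
    rows = [
        {
            "cell_id": c.cell_id,
            "study_id": c.study_id,
            "descriptor": c.descriptor,
            "align_rate": c.align_rate,
            "total_reads": c.total_reads,
        }
        for c in cells
    ]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> list[CellRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "study_id": str, "descriptor": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"metadata file {path} is missing columns: {missing}")
    return [
        CellRecord(
            cell_id=row.cell_id,
            study_id=row.study_id,
            descriptor="" if pd.isna(row.descriptor) else str(row.descriptor),
            align_rate=float(row.align_rate),
            total_reads=int(row.total_reads),
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Normalization and filters
# ---------------------------------------------------------------------------

def rpkm_normalize(
    counts: ExpressionMatrix,
    gene_lengths: Mapping[str, float],
    totals: Mapping[str, float] | None = None,
) -> ExpressionMatrix:
    """Reads-per-kilobase-per-million normalization.

    RPKM = 1e9 * c / (N * L) with c the read count, N the cell's total mapped
    reads and L the gene length in bp.  When ``totals`` is omitted, per-cell
    totals are the matrix column sums.
    """
    if counts.unit != "counts":
        raise DatasetError(f"rpkm_normalize expects counts, got unit {counts.unit!r}")
    lengths = np.empty(counts.n_genes)
    for i, g in enumerate(counts.genes):
        if g not in gene_lengths:
            raise DatasetError(f"no gene length for {g!r}")
        lengths[i] = float(gene_lengths[g])
    if np.any(lengths <= 0):
        raise DatasetError("gene lengths must be positive")
    if totals is None:
        n = counts.values.sum(axis=0)
    else:
        n = np.empty(counts.n_cells)
        for j, c in enumerate(counts.cells):
            if c not in totals:
                raise DatasetError(f"no total mapped reads for cell {c!r}")
            n[j] = float(totals[c])
    if np.any(n <= 0):
        bad = [counts.cells[j] for j in np.flatnonzero(n <= 0)]
        raise DatasetError(f"non-positive total mapped reads for cells {bad[:5]}")
    values = 1e9 * counts.values / (n[None, :] * lengths[:, None])
    return ExpressionMatrix(values, list(counts.genes), list(counts.cells), unit="rpkm")


def filter_alignment_rate(
    cells: Sequence[CellRecord], threshold: float = ALIGNMENT_RATE_DEFAULT
) -> list[CellRecord]:
    """Keep cells whose alignment rate is at or above the cutoff (default 40%)."""
    if not 0.0 <= threshold <= 1.0:
        raise DatasetError(f"threshold {threshold} outside [0, 1]")
    return [c for c in cells if c.align_rate >= threshold]


def select_high_confidence(
    cells: Sequence[CellRecord], min_cells_per_term: int = MIN_CELLS_PER_TERM_DEFAULT
) -> list[CellRecord]:
    """Keep cells with a single well-supported ontology term.

    Two passes, in order: (1) terms mapped by fewer than ``min_cells_per_term``
    cells are removed from every cell's term set; (2) only cells left with
    exactly one term are kept.  This trades coverage for label confidence.
    """
    counts: dict[str, int] = {}
    for c in cells:
        for t in c.specific_terms:
            counts[t] = counts.get(t, 0) + 1
    keep_terms = {t for t, n in counts.items() if n >= min_cells_per_term}
    out: list[CellRecord] = []
    for c in cells:
        remaining = c.specific_terms & keep_terms
        if len(remaining) == 1:
            out.append(replace(c, specific_terms=set(remaining)))
    return out


# ---------------------------------------------------------------------------
# Train/query split
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Study-held-out train/query partition."""

    train_ids: list[str]
    query_ids: list[str]
    held_out_study: dict[str, str]  # cell type -> held-out study

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.query_ids):
            raise DatasetError("train and query cell sets overlap")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "train_ids": self.train_ids,
                "query_ids": self.query_ids,
                "held_out_study": self.held_out_study,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SplitPlan":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(s).read_text()
        d = json.loads(text)
        return cls(d["train_ids"], d["query_ids"], d["held_out_study"])


def split_train_query(cells: Sequence[CellRecord], seed: int = 0) -> SplitPlan:
    """Hold out one whole study per multi-study cell type as the query set.

    Query cells never share a (cell type, study) pair with training cells, so
    retrieval evaluation is never inflated by study-specific batch effects.
    Cell types present in a single study stay entirely in training.  The
    held-out study per type is chosen uniformly at random under ``seed``.
    """
    rng = np.random.default_rng(seed)
    by_type: dict[str, dict[str, list[str]]] = {}
    for c in cells:
        t = c.single_term
        by_type.setdefault(t, {}).setdefault(c.study_id, []).append(c.cell_id)
    held_out: dict[str, str] = {}
    query: list[str] = []
    train: list[str] = []
    for t in sorted(by_type):
        studies = sorted(by_type[t])
        if len(studies) >= 2:
            chosen = studies[int(rng.integers(len(studies)))]
            held_out[t] = chosen
        else:
            chosen = None
        for s in studies:
            (query if s == chosen else train).extend(by_type[t][s])
    return SplitPlan(train, query, held_out)


# ---------------------------------------------------------------------------
# Model-input preprocessing
# ---------------------------------------------------------------------------

class Preprocessor:
    """Deterministic input transform fitted on training cells only.

    ``steps`` is an ordered subset of {"log1p", "per-cell-unit-norm",
    "standardize"}.  Standardization statistics come from the training matrix
    and are reapplied unchanged to query cells; zero-variance genes are floored
    at ``VARIANCE_FLOOR`` to keep the transform finite.
    """

    KNOWN_STEPS = ("log1p", "per-cell-unit-norm", "standardize")

    def __init__(self, steps: Sequence[str] = ("log1p", "standardize")) -> None:
        unknown = [s for s in steps if s not in self.KNOWN_STEPS]
        if unknown:
            raise DatasetError(f"unknown preprocessing steps: {unknown}")
        self.steps = tuple(steps)
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    def fit(self, train: ExpressionMatrix) -> "Preprocessor":
        values = train.values
        for step in self.steps:
            if step == "log1p":
                values = np.log1p(values)
            elif step == "per-cell-unit-norm":
                values = self._unit_norm(values)
            elif step == "standardize":
                self.mean_ = values.mean(axis=1)
                self.std_ = np.sqrt(np.maximum(values.var(axis=1), VARIANCE_FLOOR))
                values = (values - self.mean_[:, None]) / self.std_[:, None]
        return self

    def transform(self, expr: ExpressionMatrix) -> ExpressionMatrix:
        values = expr.values
        unit = expr.unit
        for step in self.steps:
            if step == "log1p":
                values = np.log1p(values)
                unit = "log-rpkm" if expr.unit == "rpkm" else unit
            elif step == "per-cell-unit-norm":
                values = self._unit_norm(values)
            elif step == "standardize":
                if self.mean_ is None or self.std_ is None:
                    raise DatasetError("Preprocessor.transform called before fit")
                values = (values - self.mean_[:, None]) / self.std_[:, None]
        out = ExpressionMatrix.__new__(ExpressionMatrix)
        out.values = np.asarray(values, dtype=float)
        out.genes = list(expr.genes)
        out.cells = list(expr.cells)
        out.unit = unit
        return out

    def fit_transform(self, train: ExpressionMatrix) -> ExpressionMatrix:
        return self.fit(train).transform(train)

    @staticmethod
    def _unit_norm(values: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(values, axis=0)
        return values / np.where(norms == 0, 1.0, norms)[None, :]


class StudyCenterer:
    """Per-study gene centering against training-database statistics.

    Integrating cells from many labs leaves each study with a gene-wise
    expression fingerprint that dwarfs the biological signal; a model trained
    on such data learns the lab, not the cell type.  This step removes each
    gene's per-study mean.  Means are fitted on the training matrix and, at
    query time, a cell is centered by its own study's *training-side* mean —
    i.e. only database statistics flow to the query.  A query from a study
    absent from the database falls back to that query group's own mean when
    it has at least ``min_fallback_cells`` cells, else to the global training
    mean (logged either way).
    """

    def __init__(self, min_fallback_cells: int = 20) -> None:
        self.min_fallback_cells = min_fallback_cells
        self.study_means_: dict[str, np.ndarray] | None = None
        self.global_mean_: np.ndarray | None = None

    def fit(self, X: np.ndarray, studies: Sequence[str]) -> "StudyCenterer":
        """``X`` is cells x genes (post-preprocessing); one study id per row."""
        X = np.asarray(X, dtype=float)
        studies = np.asarray([str(s) for s in studies])
        if len(studies) != X.shape[0]:
            raise DatasetError("one study id per cell is required")
        self.study_means_ = {
            s: X[studies == s].mean(axis=0) for s in np.unique(studies)
        }
        self.global_mean_ = X.mean(axis=0)
        return self

    def transform(self, X: np.ndarray, studies: Sequence[str]) -> np.ndarray:
        if self.study_means_ is None:
            raise DatasetError("StudyCenterer.transform called before fit")
        X = np.asarray(X, dtype=float)
        studies = np.asarray([str(s) for s in studies])
        out = np.empty_like(X)
        for s in np.unique(studies):
            mask = studies == s
            if s in self.study_means_:
                center = self.study_means_[s]
            elif int(mask.sum()) >= self.min_fallback_cells:
                center = X[mask].mean(axis=0)
                logger.info("study %r not in the database; centering on its own %d cells",
                            s, int(mask.sum()))
            else:
                center = self.global_mean_
                logger.info("study %r not in the database and too small; using global mean", s)
            out[mask] = X[mask] - center
        return out

    def fit_transform(self, X: np.ndarray, studies: Sequence[str]) -> np.ndarray:
        return self.fit(X, studies).transform(X, studies)


def align_to_genes(expr: ExpressionMatrix, genes: Sequence[str]) -> ExpressionMatrix:
    """Reindex a matrix onto a model's gene list.

    Genes absent from ``expr`` are filled with zeros; extra genes are dropped.
    Both adjustments are logged so silent feature mismatches are visible.
    """
    genes = [str(g).strip() for g in genes]
    pos = {g: i for i, g in enumerate(expr.genes)}
    missing = [g for g in genes if g not in pos]
    extra = len(expr.genes) - (len(genes) - len(missing))
    if missing or extra:
        logger.info(
            "aligning matrix to %d genes: %d filled with zeros, %d dropped",
            len(genes), len(missing), extra,
        )
    values = np.zeros((len(genes), expr.n_cells))
    for i, g in enumerate(genes):
        if g in pos:
            values[i] = expr.values[pos[g]]
    return ExpressionMatrix(values, genes, list(expr.cells), expr.unit)
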