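"""Cell-type differential expression with cross-study meta-analysis.

For every cell type, DE is run separately within each study that contains
that type (target cells vs the study's other cells, optionally excluding
cells whose type is an ontology ancestor or descendant of the target, so
that closely related types are distinguished rather than "brain vs
everything").  Per-study results are then combined: Fisher's method pools
the p-values, Benjamini-Hochberg controls the FDR over the combined list,
and a gene is called significant only when a majority of the studies in
which it was tested individually support it (per-study p below a support
threshold) with a consistent effect direction.  The majority-support rule is
what makes the final lists robust to single-study batch artifacts: a gene
that moves in only one lab's data cannot be called for the cell type, no
matter how small that one p-value is.

The per-study engine is pluggable; the built-in default is a Wilcoxon
rank-sum test on log1p expression with a log fold change for the direction.
External engines (e.g. SCDE or limma-voom run elsewhere) plug in as result
tables with the same per-gene fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataset import CellRecord, ExpressionMatrix
from .ontology import OntologyDAG

logger = logging.getLogger(__name__)

__all__ = [
    "StudyDEResult",
    "CellTypeDEList",
    "DEError",
    "ranksum_engine",
    "de_single_study",
    "combine_study_results",
    "de_all_types",
    "fisher_statistic",
]

MIN_CELLS_DEFAULT = 10
FDR_THRESHOLD_DEFAULT = 0.05
SUPPORT_P_DEFAULT = 0.05


class DEError(ValueError):
    pass


@dataclass
class StudyDEResult:
    """Per-gene DE statistics from one (cell type, study) experiment."""

    cell_type: str
    study_id: str
    genes: list[str]
    pvalues: np.ndarray
    directions: np.ndarray  # sign of the effect (+1 / -1 / 0)
    effect_sizes: np.ndarray  # log fold change

    def __post_init__(self) -> None:
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        self.directions = np.asarray(self.directions, dtype=int)
        self.effect_sizes = np.asarray(self.effect_sizes, dtype=float)
        n = len(self.genes)
        if not (len(self.pvalues) == len(self.directions) == len(self.effect_sizes) == n):
            raise DEError("per-gene arrays must match the gene list")
        if self.pvalues.size and (self.pvalues.min() < 0 or self.pvalues.max() > 1):
            raise DEError("p-values outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "pvalue": self.pvalues,
                "direction": self.directions,
                "log_fc": self.effect_sizes,
            }
        )


@dataclass
class CellTypeDEList:
    """Combined DE call list for one cell type."""

    cell_type: str
    table: pd.DataFrame  # gene, combined_p, q, n_studies, n_support, direction, significant
    fdr_threshold: float
    studies_used: list[str] = field(default_factory=list)

    @property
    def significant_genes(self) -> list[str]:
        sig = self.table[self.table["significant"]]
        return list(sig.sort_values(["q", "combined_p", "gene"])["gene"])

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Engines
# ---------------------------------------------------------------------------

def ranksum_engine(
    target: np.ndarray, background: np.ndarray, genes: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Wilcoxon rank-sum (Mann-Whitney) test per gene on log1p values.

    Returns (p-values, directions, log fold changes); direction is the sign
    of the mean log1p difference (target minus background).
    """
    lt = np.log1p(np.asarray(target, dtype=float))
    lb = np.log1p(np.asarray(background, dtype=float))
    res = stats.mannwhitneyu(lt, lb, axis=1, alternative="two-sided")
    logfc = lt.mean(axis=1) - lb.mean(axis=1)
    return np.asarray(res.pvalue, dtype=float), np.sign(logfc).astype(int), logfc


Engine = Callable[[np.ndarray, np.ndarray, Sequence[str]], tuple[np.ndarray, np.ndarray, np.ndarray]]


def _related_types(target: str, ontology: OntologyDAG | None) -> set[str]:
    if ontology is None or target not in ontology:
        return {target}
    return {target} | ontology.ancestors(target) | ontology.descendants(target)


def de_single_study(
    expr: ExpressionMatrix,
    cells: Sequence[CellRecord],
    target_type: str,
    ontology: OntologyDAG | None = None,
    engine: Engine = ranksum_engine,
    min_cells: int = MIN_CELLS_DEFAULT,
    prune_related: bool = True,
) -> StudyDEResult:
    """One DE experiment: target-type cells vs background within one study.

    ``cells`` must all come from the same study.  The background is the
    study's remaining cells, minus (when ``prune_related``) cells whose type
    is an ontology ancestor or descendant of the target.
    """
    studies = {c.study_id for c in cells}
    if len(studies) != 1:
        raise DEError(f"de_single_study expects cells from one study, got {sorted(studies)}")
    study = studies.pop()
    related = _related_types(target_type, ontology) if prune_related else {target_type}

    target_ids = [c.cell_id for c in cells if c.single_term == target_type]
    background_ids = [c.cell_id for c in cells if c.single_term not in related]
    if len(target_ids) < min_cells or len(background_ids) < min_cells:
        raise DEError(
            f"study {study!r}: {len(target_ids)} target / {len(background_ids)} "
            f"background cells, below the minimum of {min_cells}"
        )
    tgt = expr.subset_cells(target_ids)
    bg = expr.subset_cells(background_ids)
    p, direction, effect = engine(tgt.values, bg.values, expr.genes)
    return StudyDEResult(target_type, study, list(expr.genes), p, direction, effect)


# ---------------------------------------------------------------------------
# Combination
# ---------------------------------------------------------------------------

def fisher_statistic(pvalues: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's combined statistic -2 sum(ln p), its d.f., and combined p."""
    p = np.clip(np.asarray(pvalues, dtype=float), 1e-300, 1.0)
    stat = float(-2.0 * np.sum(np.log(p)))
    df = 2 * len(p)
    return stat, df, float(stats.chi2.sf(stat, df))


def combine_study_results(
    results: Sequence[StudyDEResult],
    fdr_threshold: float = FDR_THRESHOLD_DEFAULT,
    support_p: float = SUPPORT_P_DEFAULT,
    min_support: int | None = None,
) -> CellTypeDEList:
    """Fisher-combine per-study DE results for one cell type.

    Per gene, p-values from the studies where it was tested are pooled with
    Fisher's method and the combined list is BH-adjusted.  A "supporting"
    study is one with per-study p < ``support_p``; significance additionally
    requires at least ``min_support`` supporting studies (default: a majority
    of the studies testing the gene; a gene tested in a single study passes
    on that study alone) with all supporting studies agreeing in direction.
    """
    if not results:
        raise DEError("no per-study results to combine")
    types = {r.cell_type for r in results}
    if len(types) != 1:
        raise DEError(f"results mix cell types: {sorted(types)}")
    cell_type = types.pop()

    per_gene: dict[str, list[tuple[float, int]]] = {}
    for r in results:
        for g, p, d in zip(r.genes, r.pvalues, r.directions):
            per_gene.setdefault(g, []).append((float(p), int(d)))

    rows = []
    for g in sorted(per_gene):
        entries = per_gene[g]
        ps = [p for p, _ in entries]
        stat, df, comb_p = fisher_statistic(ps)
        supporting = [(p, d) for p, d in entries if p < support_p and d != 0]
        support_dirs = {d for _, d in supporting}
        consistent = len(support_dirs) <= 1
        direction = support_dirs.pop() if len(support_dirs) == 1 else 0
        rows.append(
            {
                "gene": g,
                "combined_p": comb_p,
                "fisher_stat": stat,
                "df": df,
                "n_studies": len(entries),
                "n_support": len(supporting),
                "direction": direction,
                "consistent": consistent,
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["combined_p"], method="fdr_bh")[1]
    if min_support is None:
        required = (table["n_studies"] // 2 + 1).to_numpy()
    else:
        required = np.full(len(table), min_support)
    table["significant"] = (
        (table["q"] < fdr_threshold)
        & table["consistent"]
        & (table["n_support"].to_numpy() >= required)
    )
    table = table[
        ["gene", "combined_p", "q", "fisher_stat", "df", "n_studies", "n_support",
         "direction", "significant"]
    ]
    return CellTypeDEList(
        cell_type, table, fdr_threshold, studies_used=sorted({r.study_id for r in results})
    )


def de_all_types(
    expr: ExpressionMatrix,
    cells: Sequence[CellRecord],
    ontology: OntologyDAG | None = None,
    engine: Engine = ranksum_engine,
    fdr_threshold: float = FDR_THRESHOLD_DEFAULT,
    min_cells: int = MIN_CELLS_DEFAULT,
    support_p: float = SUPPORT_P_DEFAULT,
    prune_related: bool = True,
) -> dict[str, CellTypeDEList]:
    """Run the per-study/combine strategy for every eligible cell type.

    Studies that lack enough target or background cells for a type are
    skipped with a logged reason; types with no usable study are absent from
    the output.
    """
    by_study: dict[str, list[CellRecord]] = {}
    for c in cells:
        by_study.setdefault(c.study_id, []).append(c)
    all_types = sorted({c.single_term for c in cells})

    out: dict[str, CellTypeDEList] = {}
    for t in all_types:
        results: list[StudyDEResult] = []
        for study in sorted(by_study):
            try:
                results.append(
                    de_single_study(
                        expr.subset_cells([c.cell_id for c in by_study[study]]),
                        by_study[study],
                        t,
                        ontology=ontology,
                        engine=engine,
                        min_cells=min_cells,
                        prune_related=prune_related,
                    )
                )
            except DEError as exc:
                logger.info("type %s: skipping study %s (%s)", t, study, exc)
        if results:
            combined = combine_study_results(
                results, fdr_threshold=fdr_threshold, support_p=support_p
            )
            logger.info(
                "type %s: combined %d studies (%s)",
                t, len(results), ",".join(combined.studies_used),
            )
            out[t] = combined
    return out
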