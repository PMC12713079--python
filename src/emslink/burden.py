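"""Gene-level collapsing of per-site mutations.

Collapsing ultra-rare sites into genes is the move that makes association
feasible in an EMS population: a site carried by a handful of lines has a
minor-allele frequency near 0.01, but the fraction of lines with *any*
mutation in a given gene is several-fold higher (around 2-3% in a
wheat-scale library), enough for a burden-style test.

Three gene x line matrices are maintained:

* ``counts``   -- raw mutation counts (non-negative integers);
* ``weighted`` -- impact-weighted burden, the per-line sum of a numeric
  effect weight over the line's mutations in the gene;
* ``binary``   -- 0/1 presence, used by the enrichment pathway and the
  epistasis scan.

The impact weights are a modelling choice, not an annotation output; the
defaults below (HIGH 1.0, MODERATE 0.66, LOW 0.33, MODIFIER 0.1) order the
classes by expected functional consequence and are fully configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_IMPACT_WEIGHTS = {"HIGH": 1.0, "MODERATE": 0.66, "LOW": 0.33, "MODIFIER": 0.1}


@dataclass
class GeneBurdenMatrix:
    """Gene x line burden matrices plus the weights that produced them.

    ``impact_counts`` keeps one count matrix per impact class so the
    weighted burden can be recomputed exactly under any weight map.
    """

    counts: pd.DataFrame
    weighted: pd.DataFrame
    binary: pd.DataFrame
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_IMPACT_WEIGHTS))
    impact_counts: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def lines(self) -> pd.Index:
        return self.counts.columns


def aggregate_by_gene(
    table: pd.DataFrame,
    gene_ids: list[str] | pd.Index,
    line_ids: list[str] | pd.Index | None = None,
    weights: dict[str, float] | None = None,
) -> GeneBurdenMatrix:
    """Collapse a mutation table into gene x line burden matrices.

    ``gene_ids`` fixes the row universe (genes with no mutations keep
    all-zero rows); ``line_ids`` fixes the columns and defaults to the
    distinct lines in the table -- pass the full population explicitly so
    mutation-free lines are represented.  Records with no gene assignment
    are dropped and counted in the log.
    """
    gene_index = pd.Index(gene_ids, name="gene_id")
    if gene_index.has_duplicates:
        raise ValueError("duplicate gene ids in catalogue")
    if line_ids is None:
        line_ids = sorted(table["line_id"].unique())
    line_index = pd.Index(line_ids, name="line_id")
    weights = dict(DEFAULT_IMPACT_WEIGHTS) if weights is None else dict(weights)
    _check_weights(weights)

    assigned = table.dropna(subset=["gene_id"])
    n_dropped = len(table) - len(assigned)
    if n_dropped:
        logger.info("aggregate_by_gene: %d records without gene assignment dropped",
                    n_dropped)
    unknown = set(assigned["gene_id"]) - set(gene_index)
    if unknown:
        raise ValueError(f"records reference genes outside the catalogue: "
                         f"{sorted(unknown)[:5]}...")

    impact_counts = {}
    for impact in DEFAULT_IMPACT_WEIGHTS:
        sub = assigned[assigned["impact"] == impact]
        impact_counts[impact] = (
            sub.groupby(["gene_id", "line_id"], observed=True).size()
            .unstack(fill_value=0)
            .reindex(index=gene_index, columns=line_index, fill_value=0)
            .astype(np.int64)
        )
    counts = sum(impact_counts.values())
    weighted = sum(weights[c] * m for c, m in impact_counts.items()).astype(float)
    binary = (counts > 0).astype(np.int8)
    return GeneBurdenMatrix(counts=counts, weighted=weighted, binary=binary,
                            weights=weights, impact_counts=impact_counts)


def _check_weights(weights: dict[str, float]) -> None:
    missing = set(DEFAULT_IMPACT_WEIGHTS) - set(weights)
    if missing:
        raise ValueError(f"weights missing impact classes: {sorted(missing)}")
    if any(v < 0 for v in weights.values()):
        raise ValueError("impact weights must be non-negative")


def gene_mutation_frequency(matrix: GeneBurdenMatrix) -> pd.Series:
    """Per-gene fraction of lines carrying at least one mutation."""
    n_lines = matrix.binary.shape[1]
    if n_lines < 1:
        raise ValueError("burden matrix has no lines")
    return matrix.binary.sum(axis=1) / n_lines


def weighted_burden(matrix: GeneBurdenMatrix,
                    weights: dict[str, float]) -> pd.DataFrame:
    """Recompute the weighted burden matrix under new impact weights."""
    _check_weights(weights)
    return sum(weights[c] * m for c, m in matrix.impact_counts.items()).astype(float)
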