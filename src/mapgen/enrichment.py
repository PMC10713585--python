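"""Organ and cell-type enrichment of a gene set by 2x2 chi-square tests.

For each annotation context (an organ or a cell type) a 2x2 contingency
table is built over the annotated background — membership in the query
gene set crossed with membership in the context — and tested with the
Pearson chi-square test of independence (no continuity correction).
P-values are adjusted across all contexts of the same kind with the
Benjamini-Hochberg step-up procedure and reported as q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class AnnotationTable:
    """(gene, context, kind) annotation rows and the annotated background."""

    table: pd.DataFrame  # columns: gene, context, kind
    background: frozenset[str]

    def __post_init__(self) -> None:
        required = {"gene", "context", "kind"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"annotation table needs columns {sorted(required)}")
        if self.table.duplicated(["gene", "context", "kind"]).any():
            raise ValueError("duplicate (gene, context) annotation rows")
        unknown = set(self.table["kind"]) - {"organ", "cell_type"}
        if unknown:
            raise ValueError(f"unknown context kinds: {sorted(unknown)}")

    @classmethod
    def from_frame(
        cls, table: pd.DataFrame, background: set[str] | None = None
    ) -> "AnnotationTable":
        if background is None:
            background = set(table["gene"])
        return cls(table.reset_index(drop=True), frozenset(background))

    def contexts(self, kind: str) -> list[str]:
        return sorted(self.table.loc[self.table["kind"] == kind, "context"].unique())

    def genes_in(self, context: str, kind: str) -> set[str]:
        mask = (self.table["context"] == context) & (self.table["kind"] == kind)
        return set(self.table.loc[mask, "gene"])


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) for one 2x2 table.

    Degenerate tables with a zero margin are defined as no evidence:
    statistic 0, p-value 1.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p)


def enrich(
    genes: set[str],
    annotation: AnnotationTable,
    kind: str,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Test a gene set for enrichment in every context of one kind.

    Returns one row per context with the 2x2 counts (a: set-and-context,
    b: set-only, c: context-only, d: neither), the chi-square statistic,
    p, BH q, -log10(q), an odds ratio for direction, and a significance
    flag at ``q_threshold``. Rows are sorted by ascending (q, p),
    ties broken lexicographically by context.
    """
    if not genes:
        raise ValueError("empty gene set")
    background = annotation.background
    outside = genes - background
    if outside:
        logger.warning(
            "%d query genes outside the annotated background were dropped",
            len(outside),
        )
    feature = genes & background
    if not feature:
        raise ValueError("no query genes in the annotated background")

    rows = []
    for context in annotation.contexts(kind):
        annotated = annotation.genes_in(context, kind) & background
        a = len(feature & annotated)
        b = len(feature) - a
        c = len(annotated) - a
        d = len(background) - a - b - c
        stat, p = chi2_2x2(a, b, c, d)
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * d) / (b * c) if b * c else np.inf if a * d else np.nan
        rows.append(
            {"context": context, "a": a, "b": b, "c": c, "d": d,
             "chi2": stat, "p": p, "odds_ratio": odds}
        )
    result = pd.DataFrame(rows)
    _, qvals, _, _ = multipletests(result["p"], method="fdr_bh")
    result["q"] = qvals
    result["neg_log10_q"] = -np.log10(np.maximum(result["q"], 1e-300))
    result["significant"] = result["q"] < q_threshold
    result = result.sort_values(
        ["q", "p", "context"], kind="mergesort", ignore_index=True
    )
    return result
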