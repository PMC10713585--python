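"""Core data containers shared across pipeline stages.

The pipeline passes three kinds of objects between stages: disease
records (multi-modal gene-set "documents" for the topic model), count
matrices (bulk or single-cell, with column metadata), and curated
ligand-receptor pairs. They are deliberately thin wrappers over plain
Python/pandas structures so every stage can be tested in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The three disease-omics modalities: altered expression, biomarker,
#: genetic variation.
MODALITIES = ("Ae", "Bm", "Gv")


@dataclass
class DiseaseRecord:
    """One disease with up to three modality gene sets.

    Parameters
    ----------
    disease_id
        Stable identifier, unique within a corpus.
    name
        Human-readable disease name; used by name-based exclusion
        filters (e.g. dropping obviously fibrosis-related diseases).
    modality_genes
        Mapping of modality (``"Ae"``, ``"Bm"``, ``"Gv"``) to the set of
        associated gene symbols. A modality may be absent.
    """

    disease_id: str
    name: str
    modality_genes: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.modality_genes:
            raise ValueError(f"{self.disease_id}: at least one modality required")
        for mod, genes in self.modality_genes.items():
            if mod not in MODALITIES:
                raise ValueError(f"unknown modality {mod!r}")
            if any(not isinstance(g, str) or not g for g in genes):
                raise ValueError(f"{self.disease_id}/{mod}: empty gene symbol")

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(m for m in MODALITIES if m in self.modality_genes)

    def drop_modality(self, modality: str) -> "DiseaseRecord":
        """Return a copy with one modality removed (for held-out evaluation)."""
        kept = {m: set(g) for m, g in self.modality_genes.items() if m != modality}
        return DiseaseRecord(self.disease_id, self.name, kept)


@dataclass
class CountMatrix:
    """Genes-by-columns integer count matrix with column metadata.

    ``counts`` rows are genes, columns are samples (bulk) or cells
    (single-cell). ``meta`` is indexed by the same column labels and
    carries ``group`` for bulk data and ``cell_type``, ``organ``,
    ``percent_mito``, ``n_genes_detected`` for single-cell data.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.shape[1] != len(self.meta):
            raise ValueError("metadata rows must match count columns")
        if not self.counts.columns.equals(self.meta.index):
            raise ValueError("metadata index must equal count column labels")
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("counts must be non-negative")
        if values.size and not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cols(self) -> int:
        return self.counts.shape[1]

    def subset_cols(self, cols) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, cols], self.meta.loc[cols])


@dataclass(frozen=True)
class LRPair:
    """A curated ligand-receptor pair; either side may be a multi-subunit complex."""

    ligand_subunits: tuple[str, ...]
    receptor_subunits: tuple[str, ...]
    evidence: str = ""

    def __post_init__(self) -> None:
        if not self.ligand_subunits or not self.receptor_subunits:
            raise ValueError("subunit lists must be non-empty")

    @property
    def ligand_label(self) -> str:
        return "/".join(self.ligand_subunits)

    @property
    def receptor_label(self) -> str:
        return "/".join(self.receptor_subunits)

    @property
    def key(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        return (self.ligand_subunits, self.receptor_subunits)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.ligand_label}-{self.receptor_label}"
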