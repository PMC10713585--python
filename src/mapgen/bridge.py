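"""Ligand-receptor bridging of differentially expressed genes.

Given the DE genes of the primary organ and a curated ligand-receptor
database, identify (i) DE genes that encode ligands, with their
receptors, and (ii) DE genes that encode receptors, with their ligands.
A multi-subunit complex counts as hit by the DE list when ANY subunit
is a DE gene; cross-organ localization later requires ALL subunits of
the partner side to be expressed in the partner organ.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import LRPair

DEGENE_IS_LIGAND = "degene_is_ligand"
DEGENE_IS_RECEPTOR = "degene_is_receptor"


@dataclass
class BridgeResult:
    """Pairs whose DE-gene side intersects the DE list."""

    direction: str
    pairs: list[LRPair]
    degene_side_genes: set[str]
    partner_side_genes: set[str]


@dataclass
class CrossOrganPair:
    """A pair whose partner side is expressed in the partner organ.

    ``partner_cell_types`` maps each partner-side subunit to the
    (cell_type, frac_expressing, mean_log_cp10k) of its maximal-
    expression cell type among those passing the expression floor.
    """

    pair: LRPair
    direction: str
    partner_cell_types: dict[str, tuple[str, float, float]]


def _clean(degenes) -> set[str]:
    return {g.strip() for g in degenes if isinstance(g, str) and g.strip()}


def _bridge(degenes: set[str], db: list[LRPair], direction: str) -> BridgeResult:
    degenes = _clean(degenes)
    side = (
        (lambda p: p.ligand_subunits)
        if direction == DEGENE_IS_LIGAND
        else (lambda p: p.receptor_subunits)
    )
    partner = (
        (lambda p: p.receptor_subunits)
        if direction == DEGENE_IS_LIGAND
        else (lambda p: p.ligand_subunits)
    )
    matched: dict = {}
    for pair in db:
        if degenes.intersection(side(pair)):
            matched.setdefault(pair.key, pair)
    pairs = sorted(matched.values(), key=lambda p: (p.ligand_label, p.receptor_label))
    return BridgeResult(
        direction=direction,
        pairs=pairs,
        degene_side_genes={g for p in pairs for g in side(p) if g in degenes},
        partner_side_genes={g for p in pairs for g in partner(p)},
    )


def identify_ligands(degenes, db: list[LRPair]) -> BridgeResult:
    """Pairs whose ligand side contains a DE gene (DE gene is the ligand)."""
    if not db:
        raise ValueError("empty ligand-receptor database")
    return _bridge(set(degenes), db, DEGENE_IS_LIGAND)


def identify_receptors(degenes, db: list[LRPair]) -> BridgeResult:
    """Pairs whose receptor side contains a DE gene (DE gene is the receptor)."""
    if not db:
        raise ValueError("empty ligand-receptor database")
    return _bridge(set(degenes), db, DEGENE_IS_RECEPTOR)


def cross_organ_candidates(
    bridge: BridgeResult,
    partner_summaries: pd.DataFrame,
    target_organ: str,
    min_frac: float = 0.2,
) -> list[CrossOrganPair]:
    """Keep pairs whose partner side is expressed in the target organ.

    Every partner-side subunit must reach ``frac_expressing >=
    min_frac`` in at least one cell type of ``target_organ``; the
    maximal-expression cell type (by mean log CP10K) is recorded per
    subunit.
    """
    if "organ" not in partner_summaries.columns:
        raise ValueError("summaries must carry an 'organ' column")
    organ_rows = partner_summaries[partner_summaries["organ"] == target_organ]
    if organ_rows.empty:
        raise ValueError(f"no summaries for organ {target_organ!r}")

    kept: list[CrossOrganPair] = []
    for pair in bridge.pairs:
        partner_subunits = (
            pair.receptor_subunits
            if bridge.direction == DEGENE_IS_LIGAND
            else pair.ligand_subunits
        )
        evidence: dict[str, tuple[str, float, float]] = {}
        for subunit in partner_subunits:
            rows = organ_rows[
                (organ_rows["gene"] == subunit)
                & (organ_rows["frac_expressing"] >= min_frac)
            ]
            if rows.empty:
                break
            best = rows.loc[rows["mean_log_cp10k"].idxmax()]
            evidence[subunit] = (
                str(best["cell_type"]),
                float(best["frac_expressing"]),
                float(best["mean_log_cp10k"]),
            )
        else:
            kept.append(CrossOrganPair(pair, bridge.direction, evidence))
    return kept


def bridge_table(result: BridgeResult) -> pd.DataFrame:
    """TSV-ready (ligand, receptor, evidence) rows for a bridge result."""
    return pd.DataFrame(
        [
            {
                "ligand": p.ligand_label,
                "receptor": p.receptor_label,
                "evidence": p.evidence,
            }
            for p in result.pairs
        ]
    )
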