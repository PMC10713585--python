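"""Readers and writers for the plain-text interchange formats.

Formats: GMT-like disease gene sets (one line per disease/modality),
Matrix Market counts with TSV row/column metadata, the ligand-receptor
TSV, the gene annotation TSV, and the KEGG-id-to-symbol map TSV.
"""

from __future__ import annotations

import pathlib

import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CountMatrix, DiseaseRecord, LRPair

PathLike = str | pathlib.Path


# ---------------------------------------------------------------------------
# GMT-like disease gene sets: disease_id <TAB> name <TAB> modality <TAB> genes...
# ---------------------------------------------------------------------------

def write_gmt(corpus: list[DiseaseRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for rec in corpus:
            for mod in rec.modalities:
                genes = "\t".join(sorted(rec.modality_genes[mod]))
                fh.write(f"{rec.disease_id}\t{rec.name}\t{mod}\t{genes}\n")


def read_gmt(path: PathLike) -> list[DiseaseRecord]:
    sets: dict[str, tuple[str, dict[str, set[str]]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            did, name, mod = fields[0], fields[1], fields[2]
            if did not in sets:
                sets[did] = (name, {})
                order.append(did)
            sets[did][1].setdefault(mod, set()).update(g for g in fields[3:] if g)
    return [DiseaseRecord(did, sets[did][0], sets[did][1]) for did in order]


# ---------------------------------------------------------------------------
# Count matrices: Matrix Market + TSV metadata
# ---------------------------------------------------------------------------

def write_counts(cm: CountMatrix, prefix: PathLike) -> None:
    """Write ``<prefix>.mtx``, ``<prefix>.genes.tsv``, ``<prefix>.meta.tsv``."""
    prefix = pathlib.Path(prefix)
    sparse = scipy.sparse.csr_matrix(cm.counts.to_numpy())
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), sparse)
    cm.counts.index.to_series().to_csv(
        prefix.with_suffix(".genes.tsv"), sep="\t", index=False, header=["gene"]
    )
    cm.meta.to_csv(prefix.with_suffix(".meta.tsv"), sep="\t", index_label="column")


def read_counts(prefix: PathLike) -> CountMatrix:
    prefix = pathlib.Path(prefix)
    matrix = scipy.io.mmread(str(prefix.with_suffix(".mtx")))
    genes = pd.read_csv(prefix.with_suffix(".genes.tsv"), sep="\t")["gene"]
    meta = pd.read_csv(prefix.with_suffix(".meta.tsv"), sep="\t", index_col="column")
    dense = pd.DataFrame(
        matrix.toarray().astype(int), index=genes.to_list(), columns=meta.index
    )
    return CountMatrix(dense, meta)


# ---------------------------------------------------------------------------
# Ligand-receptor table: ligand_subunits <TAB> receptor_subunits <TAB> evidence
# (subunits semicolon-joined)
# ---------------------------------------------------------------------------

def write_lr_table(pairs: list[LRPair], path: PathLike) -> None:
    rows = [
        {
            "ligand_subunits": ";".join(p.ligand_subunits),
            "receptor_subunits": ";".join(p.receptor_subunits),
            "evidence": p.evidence,
        }
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_lr_table(path: PathLike) -> list[LRPair]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    pairs = []
    for row in df.itertuples(index=False):
        pairs.append(
            LRPair(
                tuple(s.strip() for s in row.ligand_subunits.split(";") if s.strip()),
                tuple(s.strip() for s in row.receptor_subunits.split(";") if s.strip()),
                row.evidence,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Annotation table and symbol map
# ---------------------------------------------------------------------------

def write_annotation(df: pd.DataFrame, path: PathLike) -> None:
    df.loc[:, ["gene", "context", "kind"]].to_csv(path, sep="\t", index=False)


def read_annotation(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_symbol_map(mapping: dict[str, str], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("kegg_id\tsymbol\n")
        for kegg_id in sorted(mapping):
            fh.write(f"{kegg_id}\t{mapping[kegg_id]}\n")


def read_symbol_map(path: PathLike) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["kegg_id"], df["symbol"]))
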