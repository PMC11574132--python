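"""TSV/GMT readers and writers.

Canonical table dialect is TSV, UTF-8, '.' decimal. Expression tables:
first column ``gene_id``, optional second column ``length_bp``, then one
column per sample. Gene identifiers are opaque case-sensitive strings.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .containers import ExpressionMatrix, validate_design
from .signatures import GeneSet

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


def read_expression(path: str | Path, scale: str = "counts") -> ExpressionMatrix:
    """Read a gene x sample expression TSV; attaches lengths when present."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path}: {exc}") from exc
    if df.columns[0] != "gene_id":
        raise ParseError(f"{path}: first column must be gene_id, got {df.columns[0]!r}")
    df = df.set_index("gene_id")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene_id {dups[:5]}")
    lengths = None
    if "length_bp" in df.columns:
        lengths = df.pop("length_bp").astype(float)
    bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        raise ParseError(f"{path}: non-numeric values in columns {list(bad)}")
    return ExpressionMatrix(values=df.astype(float), scale=scale, lengths_bp=lengths)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    out = m.values.copy()
    if m.lengths_bp is not None:
        out.insert(0, "length_bp", m.lengths_bp)
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_design(df, require_replicates=False)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    # keep_default_na=False: the class label "null" is data, not missingness
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str, "class": str},
                       keep_default_na=False, float_precision="round_trip")


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_contrast(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str},
                     float_precision="round_trip").set_index("gene_id")
    for col in ("log2fc", "p", "fdr"):
        if col not in df.columns:
            raise ParseError(f"{path}: contrast table missing column {col!r}")
    return df


def write_contrast(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (name TAB description TAB member...)."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, source = fields[0], fields[1]
            members = [f for f in fields[2:] if f]
            if len(members) != len(set(members)):
                logger.warning("%s:%d: duplicate members in set %r deduplicated", path, lineno, name)
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets.append(GeneSet(name=name, members=set(members), source=source))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.source or "na", *sorted(s.members)]) + "\n")


def read_ortholog_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (source gene id -> target gene id), functional mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: ortholog map needs two columns")
    src, dst = df.columns[:2]
    if df[src].duplicated().any():
        dups = df.loc[df[src].duplicated(), src].tolist()
        raise ParseError(f"{path}: source ids map to multiple targets: {dups[:5]}")
    return dict(zip(df[src], df[dst]))
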