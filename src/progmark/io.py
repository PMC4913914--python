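"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as TSV (gene id in the first column, sample ids
in the header), sample sheets and Ct tables as CSV, gene sets as standard
GMT (term, description, tab-separated genes).  All round trips are
lossless at full float precision, and malformed input fails with the
offending line number rather than silently coercing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

__all__ = [
    "read_matrix", "write_matrix",
    "read_sample_sheet", "write_sample_sheet",
    "read_ct_table", "write_ct_table",
    "read_gmt", "write_gmt",
    "read_gene_list", "write_gene_list",
    "read_series_matrix",
]

logger = logging.getLogger(__name__)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV.

    The first column holds gene ids, the header row sample ids.
    Duplicate ids, ragged rows and non-numeric cells are errors reported
    with their line number.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_fields = len(header)
        sample_ids = header[1:]
        if len(set(sample_ids)) != len(sample_ids):
            dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise ValueError(f"{path}: duplicate sample ids {dupes}")
        genes: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_fields:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_fields} fields, got {len(fields)}"
                )
            gene = fields[0]
            if gene in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene!r}")
            seen.add(gene)
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            genes.append(gene)
    return pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"),
                        columns=sample_ids)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.17g")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    if "sample_id" not in sheet.columns:
        raise ValueError(f"{path}: sample sheet lacks a 'sample_id' column")
    if sheet["sample_id"].duplicated().any():
        dupes = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"sample_id", "gene_id", "replicate", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: Ct table lacks columns {sorted(missing)}")
    bad = table[(table["ct"] <= 0) | (table["ct"] > 45)]
    if len(bad):
        raise ValueError(
            f"{path}: Ct values outside (0, 45] for rows {bad.index[:5].tolist()}"
        )
    return table


def write_ct_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_gmt(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a GMT gene-set file.

    Each line is ``term<TAB>description<TAB>gene1<TAB>gene2...``.  Term
    order is preserved (dicts iterate in insertion order); duplicate genes
    within a term are de-duplicated with a warning.  Returns the term ->
    gene-set map and the term -> description map.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 fields, got {len(fields)}"
                )
            term, desc, genes = fields[0], fields[1], fields[2:]
            if len(set(genes)) != len(genes):
                logger.warning("%s:%d: duplicate genes in term %s de-duplicated",
                               path, lineno, term)
            sets[term] = set(genes)
            descriptions[term] = desc
    return sets, descriptions


def write_gmt(
    sets: dict[str, set[str]], path: str | Path,
    descriptions: dict[str, str] | None = None,
) -> None:
    with Path(path).open("w") as fh:
        for term, genes in sets.items():
            desc = (descriptions or {}).get(term, "")
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines ignored."""
    with Path(path).open() as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_series_matrix(path: str | Path) -> pd.DataFrame:
    """Read the expression block of a GEO series-matrix text file.

    Parses the tab-delimited table between ``!series_matrix_table_begin``
    and ``!series_matrix_table_end``; the first column (probe/gene id)
    becomes the index.  Metadata lines are ignored.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines)
                     if l.startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines)
                   if l.startswith("!series_matrix_table_end"))
    except StopIteration:
        raise ValueError(f"{path}: no series-matrix table delimiters found") from None
    block = lines[start + 1:end]
    header = [f.strip('"') for f in block[0].split("\t")]
    rows = []
    index = []
    for line in block[1:]:
        fields = [f.strip('"') for f in line.split("\t")]
        index.append(fields[0])
        rows.append([float(v) for v in fields[1:]])
    return pd.DataFrame(rows, index=pd.Index(index, name="gene_id"),
                        columns=header[1:])
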