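"""Readers and writers for the project's on-disk formats.

Conventions: all genome coordinates are 0-based half-open (BED style);
all matrices are written cells-as-rows. Expression matrices travel as
Matrix Market triplets with gene/cell sidecar lists or as one dense TSV;
gene annotation as a BED-like TSV plus a cytoband-like arm table.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .matrix import CNAMatrix, ExpressionMatrix


class FormatError(ValueError):
    """A file does not follow the declared format."""


# ---------------------------------------------------------------- expression

def write_expression_mtx(m: ExpressionMatrix, out_dir: str | Path) -> None:
    """Write a cells x genes matrix as matrix.mtx + cells.tsv + genes.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "matrix.mtx", sparse.csr_matrix(m.values))
    pd.Series(m.cell_ids).to_csv(out / "cells.tsv", sep="\t", index=False, header=False)
    pd.Series(m.gene_ids).to_csv(out / "genes.tsv", sep="\t", index=False, header=False)
    (out / "space.txt").write_text(m.space + "\n")


def _validate_mtx(path: Path) -> None:
    """Check that the triplet body length matches the declared nnz."""
    header = None
    n_entries = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            if header is None:
                parts = line.split()
                if len(parts) != 3:
                    raise FormatError(f"malformed MTX size line: {line!r}")
                header = tuple(int(p) for p in parts)
            else:
                n_entries += 1
    if header is None:
        raise FormatError("MTX file has no size line")
    if n_entries != header[2]:
        raise FormatError(
            f"MTX declares {header[2]} entries but contains {n_entries}"
        )


def read_expression_mtx(in_dir: str | Path) -> ExpressionMatrix:
    in_dir = Path(in_dir)
    _validate_mtx(in_dir / "matrix.mtx")
    values = np.asarray(spio.mmread(in_dir / "matrix.mtx").todense(), dtype=np.float64)
    cells = pd.read_csv(in_dir / "cells.tsv", sep="\t", header=None)[0].astype(str).tolist()
    genes = pd.read_csv(in_dir / "genes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    space_file = in_dir / "space.txt"
    space = space_file.read_text().strip() if space_file.exists() else "raw"
    if values.shape != (len(cells), len(genes)):
        raise FormatError(
            f"matrix is {values.shape} but sidecars list "
            f"{len(cells)} cells and {len(genes)} genes"
        )
    return ExpressionMatrix(values=values, cell_ids=cells, gene_ids=genes, space=space)


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    """Dense TSV: first column cell_id, remaining columns one per gene."""
    df = pd.DataFrame(m.values, index=pd.Index(m.cell_ids, name="cell_id"), columns=m.gene_ids)
    df.to_csv(path, sep="\t")


def read_expression_tsv(path: str | Path, space: str = "raw") -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise FormatError(f"duplicate gene ids in {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise FormatError(f"non-numeric entries in {path}: {exc}") from exc
    return ExpressionMatrix(
        values=values,
        cell_ids=df.index.astype(str).tolist(),
        gene_ids=df.columns.astype(str).tolist(),
        space=space,
    )


def read_expression(path: str | Path, fmt: str = "auto", space: str = "raw") -> ExpressionMatrix:
    """Read an expression matrix from an MTX directory or a dense TSV."""
    path = Path(path)
    if fmt == "auto":
        fmt = "mtx" if path.is_dir() else "tsv"
    if fmt == "mtx":
        return read_expression_mtx(path)
    if fmt == "tsv":
        return read_expression_tsv(path, space=space)
    raise ValueError(f"unknown expression format {fmt!r}")


# ---------------------------------------------------------------- annotation

def _chrom_sort_key(chrom: str):
    c = str(chrom)
    c = c[3:] if c.lower().startswith("chr") else c
    try:
        return (0, int(c), "")
    except ValueError:
        return (1, 0, c)


def read_annotation(genes_bed: str | Path, arms_tsv: str | Path) -> pd.DataFrame:
    """Build the gene annotation from a BED-like gene file and an arm table.

    ``genes_bed``: tab-separated chrom, start, end, gene_id (0-based
    half-open, no header). ``arms_tsv``: tab-separated with header
    chrom, arm, start, end. A gene belongs to the arm whose interval
    contains its start; genes outside every arm are dropped with a
    warning. Overlapping arm intervals on one chromosome are an error.
    ``order_index`` sorts by (chromosome, start) with gene_id breaking
    coordinate ties.
    """
    genes = pd.read_csv(
        genes_bed, sep="\t", header=None,
        names=["chromosome", "start", "end", "gene_id"],
        dtype={"chromosome": str, "gene_id": str},
    )
    if genes[["start", "end"]].isna().any().any():
        raise FormatError(f"malformed BED lines in {genes_bed}")
    if genes["gene_id"].duplicated().any():
        raise FormatError("duplicate gene ids in gene BED")
    arms = pd.read_csv(arms_tsv, sep="\t", dtype={"chrom": str, "arm": str})
    required = {"chrom", "arm", "start", "end"}
    if not required.issubset(arms.columns):
        raise FormatError(f"arm table must have columns {sorted(required)}")
    for chrom, grp in arms.groupby("chrom"):
        iv = grp.sort_values("start")[["start", "end"]].to_numpy()
        if np.any(iv[1:, 0] < iv[:-1, 1]):
            raise FormatError(f"overlapping arm intervals on chromosome {chrom}")

    rows = []
    for rec in genes.itertuples(index=False):
        hit = arms[
            (arms["chrom"] == rec.chromosome)
            & (arms["start"] <= rec.start)
            & (rec.start < arms["end"])
        ]
        if hit.empty:
            continue
        rows.append(
            {
                "gene_id": rec.gene_id,
                "chromosome": rec.chromosome,
                "start": int(rec.start),
                "end": int(rec.end),
                "arm": hit.iloc[0]["arm"],
            }
        )
    dropped = len(genes) - len(rows)
    if dropped:
        warnings.warn(f"dropped {dropped} genes outside every arm interval")
    if not rows:
        raise FormatError("no genes fall inside any arm interval")
    ann = pd.DataFrame(rows)
    ann = ann.sort_values(
        by=["chromosome", "start", "gene_id"],
        key=lambda col: col.map(_chrom_sort_key) if col.name == "chromosome" else col,
        kind="stable",
    ).reset_index(drop=True)
    ann["order_index"] = np.arange(len(ann))
    return ann


def write_annotation(annotation: pd.DataFrame, genes_bed: str | Path, arms_tsv: str | Path) -> None:
    """Write an annotation back out as gene BED + arm table."""
    ann = annotation.sort_values("order_index")
    ann[["chromosome", "start", "end", "gene_id"]].to_csv(
        genes_bed, sep="\t", header=False, index=False
    )
    arm_rows = []
    for arm, grp in ann.groupby("arm", sort=False):
        arm_rows.append(
            {
                "chrom": grp["chromosome"].iloc[0],
                "arm": arm,
                "start": int(grp["start"].min()),
                "end": int(grp["end"].max()) + 1,
            }
        )
    pd.DataFrame(arm_rows).sort_values(["chrom", "start"]).to_csv(
        arms_tsv, sep="\t", index=False
    )


# ---------------------------------------------------------------- CNA / tables

def write_cna(cna: CNAMatrix, path: str | Path, positions_path: str | Path | None = None) -> None:
    df = pd.DataFrame(cna.values, index=pd.Index(cna.cell_ids, name="cell_id"), columns=cna.gene_ids)
    df.to_csv(path, sep="\t")
    if positions_path is not None:
        pd.Series(cna.gene_ids, name="gene_id").to_csv(positions_path, sep="\t", index=False)


def read_cna(path: str | Path) -> CNAMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CNAMatrix(
        values=df.to_numpy(dtype=np.float64),
        cell_ids=df.index.astype(str).tolist(),
        gene_ids=df.columns.astype(str).tolist(),
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"cell_id", "donor_id", "cell_type"} - set(meta.columns)
    if missing:
        raise FormatError(f"metadata is missing columns: {sorted(missing)}")
    return meta


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
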