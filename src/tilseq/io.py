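"""Readers and writers for the pipeline's on-disk formats.

Count matrices travel either as plain CSV (cells x HTOs for hashing) or
as MatrixMarket MTX plus barcodes.tsv/features.tsv in the usual
features-by-cells orientation; TCR reads as TSV or FASTA with
``>barcode|umi|chain[|cdr3]`` headers; everything downstream as TSV with
JSON sidecars for provenance (thresholds, removed outliers, warnings).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import io as spio
from scipy import sparse

from ._util import InputError
from .hto import DemuxResult, HtoCountMatrix

__all__ = [
    "read_hto_csv", "write_hto_csv", "read_hto_mtx", "write_hto_mtx",
    "read_reads_tsv", "write_reads_tsv", "read_reads_fasta", "write_reads_fasta",
    "read_expression_mtx", "write_expression_mtx",
    "write_demux_result",
]


# ------------------------------------------------------------------- HTO

def read_hto_csv(path, array_id: str | None = None) -> HtoCountMatrix:
    """CSV with first column = cell barcode, header = HTO names."""
    df = pd.read_csv(path, index_col=0)
    return HtoCountMatrix(df.values.astype(np.int64), [str(b) for b in df.index],
                          [str(h) for h in df.columns],
                          array_id=array_id or Path(path).stem)


def write_hto_csv(m: HtoCountMatrix, path) -> None:
    pd.DataFrame(m.counts, index=pd.Index(m.cell_barcodes, name="barcode"),
                 columns=m.hto_names).to_csv(path)


def _read_mtx_dir(directory) -> tuple[np.ndarray, list[str], list[str]]:
    directory = Path(directory)
    mat = spio.mmread(directory / "matrix.mtx")
    features = pd.read_csv(directory / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0]
    dense = np.asarray(sparse.csr_matrix(mat).todense())
    if dense.shape != (len(features), len(barcodes)):
        raise InputError("matrix.mtx shape does not match features/barcodes")
    return dense, list(features.astype(str)), list(barcodes.astype(str))


def _write_mtx_dir(dense: np.ndarray, features: list[str], barcodes: list[str],
                   directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(directory / "matrix.mtx", sparse.coo_matrix(dense))
    pd.Series(features).to_csv(directory / "features.tsv", sep="\t",
                               header=False, index=False)
    pd.Series(barcodes).to_csv(directory / "barcodes.tsv", sep="\t",
                               header=False, index=False)


def read_hto_mtx(directory, array_id: str | None = None) -> HtoCountMatrix:
    """MTX directory in features-by-cells orientation (features = HTOs)."""
    dense, features, barcodes = _read_mtx_dir(directory)
    return HtoCountMatrix(dense.T.astype(np.int64), barcodes, features,
                          array_id=array_id or Path(directory).name)


def write_hto_mtx(m: HtoCountMatrix, directory) -> None:
    _write_mtx_dir(m.counts.T, m.hto_names, m.cell_barcodes, directory)


# ------------------------------------------------------------- TCR reads

def read_reads_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cell_barcode", "umi", "chain", "sequence"}
    if not required.issubset(df.columns):
        raise InputError(f"read table must have columns {sorted(required)}")
    return df


def write_reads_tsv(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", index=False)


def read_reads_fasta(path) -> pd.DataFrame:
    """FASTA with ``>barcode|umi|chain`` (optional 4th ``|cdr3``) headers."""
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) < 3:
            raise InputError(f"malformed FASTA header: {rec.id}")
        row = {"cell_barcode": parts[0], "umi": parts[1], "chain": parts[2],
               "sequence": str(rec.seq)}
        if len(parts) > 3:
            row["cdr3_aa"] = parts[3]
        rows.append(row)
    return pd.DataFrame(rows)


def write_reads_fasta(reads: pd.DataFrame, path) -> None:
    records = []
    has_cdr3 = "cdr3_aa" in reads.columns
    for i, row in enumerate(reads.itertuples(index=False)):
        header = f"{row.cell_barcode}|{row.umi}|{row.chain}"
        if has_cdr3 and isinstance(row.cdr3_aa, str):
            header += f"|{row.cdr3_aa}"
        records.append(SeqRecord(Seq(row.sequence), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


# ------------------------------------------------------------ expression

def read_expression_mtx(directory) -> pd.DataFrame:
    """Genes x cells DataFrame from an MTX directory (features = genes)."""
    dense, features, barcodes = _read_mtx_dir(directory)
    return pd.DataFrame(dense, index=features, columns=barcodes)


def write_expression_mtx(matrix: pd.DataFrame, directory) -> None:
    _write_mtx_dir(matrix.values, [str(g) for g in matrix.index],
                   [str(c) for c in matrix.columns], directory)


# ----------------------------------------------------------- demux output

def write_demux_result(result: DemuxResult, outdir) -> None:
    """Per-cell call TSV plus a JSON sidecar with threshold provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = result.calls.copy()
    for h in result.clr.columns:
        table[f"clr_{h}"] = result.clr[h].round(6)
    for h in result.positivity.columns:
        table[f"positive_{h}"] = result.positivity[h].astype(int)
    table.to_csv(outdir / f"demux_{result.array_id}.tsv", sep="\t")
    sidecar = {
        "array_id": result.array_id,
        "alpha": result.thresholds.alpha,
        "thresholds": {h: round(v, 9) if np.isfinite(v) else None
                       for h, v in result.thresholds.thresholds.items()},
        "removed_outliers": {h: [round(v, 9) for v in vals]
                             for h, vals in result.thresholds.removed.items()},
        "warnings": result.thresholds.warnings,
    }
    with open(outdir / f"demux_{result.array_id}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
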