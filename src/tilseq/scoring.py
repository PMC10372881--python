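"""Expression QC, normalization, variable genes and the cytotoxicity score.

Matrices are genes x cells pandas DataFrames of non-negative counts (or
of normalized values after :func:`log_normalize`). The cytotoxicity
module score is the classic expression-binned control-gene score: for
each cell, the mean log-normalized expression of the granzyme signature
genes minus the mean of pooled control genes drawn from the same
average-expression bins, so the score is centered near zero for a cell
without a granzyme program regardless of its depth.
"""

from __future__ import annotations

import warnings as _warnings

import numpy as np
import pandas as pd

from ._util import InputError

GRANZYME_SIGNATURE = [
    "Gzma", "Gzmb", "Gzmc", "Gzmd", "Gzme", "Gzmf", "Gzmg", "Gzmk", "Gzmm",
]

__all__ = [
    "GRANZYME_SIGNATURE",
    "qc_filter",
    "log_normalize",
    "select_variable_genes",
    "module_score",
    "score_cytotoxicity",
]


def qc_filter(counts: pd.DataFrame, min_genes: int = 500,
              min_cells: int = 5) -> pd.DataFrame:
    """Drop low-complexity cells, then rarely detected genes.

    Cells with fewer than ``min_genes`` detected genes (count > 0) are
    removed first; genes detected in fewer than ``min_cells`` of the
    remaining cells are then removed, iterating the gene filter to a
    fixed point (a single pass already is one, since removing genes does
    not change any other gene's cell count; the loop documents the
    contract).
    """
    detected = (counts > 0)
    keep_cells = detected.sum(axis=0) >= min_genes
    out = counts.loc[:, keep_cells]
    while True:
        keep_genes = (out > 0).sum(axis=1) >= min_cells
        if keep_genes.all():
            break
        out = out.loc[keep_genes, :]
    if out.empty:
        raise InputError(
            f"QC removed everything ({int((~keep_cells).sum())} cells dropped; "
            f"matrix was {counts.shape[0]} genes x {counts.shape[1]} cells)")
    return out


def log_normalize(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Library-size log-normalization: ln(1 + count / cell_total * scale)."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise InputError(f"cells with zero total counts: {bad[:5]}")
    return np.log1p(counts / totals * scale)


def select_variable_genes(norm: pd.DataFrame, mean_cut: float = 0.1,
                          disp_cut: float = 1.0) -> list[str]:
    """Genes with mean normalized expression > mean_cut and dispersion
    (variance/mean of normalized values) > disp_cut; strict inequalities."""
    means = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = var / means
    keep = (means > mean_cut) & (disp > disp_cut)
    return list(norm.index[keep.fillna(False)])


def module_score(norm: pd.DataFrame, signature: list[str], n_bins: int = 24,
                 n_ctrl: int = 100, seed: int = 0) -> pd.Series:
    """Expression-binned control-gene module score per cell.

    All genes are ranked by mean normalized expression and cut into
    ``n_bins`` equal-frequency bins; each signature gene contributes
    ``n_ctrl`` control genes drawn uniformly with replacement from its
    bin (seeded, so the score is reproducible). The per-cell score is the
    mean signature value minus the mean over the pooled control draws.
    Signature genes absent from the matrix are dropped with a warning.
    """
    present = [g for g in signature if g in norm.index]
    missing = [g for g in signature if g not in norm.index]
    if missing:
        _warnings.warn(f"signature genes missing from matrix: {missing}")
    if not present:
        raise InputError("no signature genes present in the matrix")
    means = norm.mean(axis=1)
    # deterministic ranking: ties resolved by gene name
    order = np.lexsort((np.asarray(norm.index, dtype=object), means.values))
    genes_sorted = norm.index.values[order]
    n_genes = len(genes_sorted)
    bins = np.minimum((np.arange(n_genes) * n_bins) // n_genes, n_bins - 1)
    bin_of = dict(zip(genes_sorted, bins))
    members: dict[int, np.ndarray] = {
        b: genes_sorted[bins == b] for b in np.unique(bins)
    }
    rng = np.random.default_rng(seed)
    ctrl_genes: list[str] = []
    for g in present:
        pool = members[bin_of[g]]
        ctrl_genes.extend(rng.choice(pool, size=n_ctrl, replace=True))
    sig_mean = norm.loc[present].mean(axis=0)
    ctrl_mean = norm.loc[ctrl_genes].mean(axis=0)  # pooled, multiplicity kept
    score = sig_mean - ctrl_mean
    score.name = "score"
    return score


def score_cytotoxicity(norm: pd.DataFrame, clonotypes: pd.DataFrame,
                       signature: list[str] | None = None, n_bins: int = 24,
                       n_ctrl: int = 100, seed: int = 0) -> pd.Series:
    """Granzyme module score restricted to cells with a recovered TCR chain.

    Cells for which neither a TRB nor a TRA sequence was recovered are
    excluded: only barcodes present in the clonotype table with at least
    one chain are scored. Bins and control draws are computed on the full
    matrix so the score of a cell does not depend on which other cells
    carry TCRs.
    """
    signature = GRANZYME_SIGNATURE if signature is None else signature
    has_chain = clonotypes[
        clonotypes["cdr3b_aa"].notna() | clonotypes["cdr3a_aa"].notna()
    ]["cell_id"].astype(str)
    cells = [c for c in norm.columns if c in set(has_chain)]
    if not cells:
        raise InputError("no overlap between expression barcodes and clonotype table")
    full = module_score(norm, signature, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    return full.loc[cells]
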