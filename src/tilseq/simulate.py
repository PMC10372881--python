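"""Ground-truthed synthetic inputs for every pipeline stage.

Each generator emulates the statistical structure its downstream stage
assumes — not real sequencing data:

* hashing counts: per-cell negative-binomial signal on the cell's own
  hashtag(s) over a weaker NB background on the others, with doublets
  (signal on two distinct HTOs) and background-only negatives;
* TCR reads: clonally structured (barcode, UMI, chain, sequence) reads
  with per-base substitution errors and optional 1-mismatch duplicate
  UMIs built to satisfy the directional-collapse merge rule;
* expression counts: two cell populations over a shared NB baseline, one
  over-expressing the granzyme signature genes by a log-scale shift;
* tetramer reference: clonotypes with cells split between tetramer
  sort fractions, with the reference rule's truth recorded.

All randomness flows from a single top-level seed through named
substreams, so adding a generator never perturbs another's draws, and a
fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import ConfigError, substream
from .hto import HtoCountMatrix
from .scoring import GRANZYME_SIGNATURE
from .specificity import DEFAULT_MOTIF

__all__ = [
    "HtoSimConfig", "TcrSimConfig", "ExprSimConfig", "TetramerSimConfig",
    "simulate_hto", "simulate_tcr_reads", "simulate_expression",
    "simulate_tetramer_reference",
]

_BASES = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _nb(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    """NB(mean, dispersion) with variance = mean + mean^2/dispersion."""
    if mean == 0:
        return np.zeros(size, dtype=np.int64)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(np.int64)


def _random_seq(rng: np.random.Generator, length: int, alphabet=_BASES) -> str:
    return "".join(rng.choice(alphabet, size=length))


# ---------------------------------------------------------------- hashing

@dataclass
class HtoSimConfig:
    """Multi-sample hashing array: one sample per hashtag, k = n_htos."""

    n_htos: int = 5
    cells_per_sample: int = 200
    doublet_rate: float = 0.05
    negative_rate: float = 0.01
    signal_mean: float = 200.0
    background_mean: float = 5.0
    dispersion: float = 4.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_htos < 2 or self.cells_per_sample < 1:
            raise ConfigError("need >= 2 HTOs and >= 1 cell per sample")
        if not (0 <= self.doublet_rate <= 1 and 0 <= self.negative_rate <= 1):
            raise ConfigError("rates must be in [0, 1]")
        if self.doublet_rate + self.negative_rate >= 1:
            raise ConfigError("doublet_rate + negative_rate must be < 1")
        if not self.signal_mean > self.background_mean >= 0:
            raise ConfigError("need signal_mean > background_mean >= 0")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")


def simulate_hto(config: HtoSimConfig) -> tuple[HtoCountMatrix, pd.DataFrame]:
    """Simulate one hashing array; returns (count matrix, truth table).

    Truth columns: barcode, true_label (hashtag name of the sample of
    origin, or "doublet"/"negative"), true_htos ("+"-joined hashtags with
    signal).
    """
    rng = substream(config.seed, "hto")
    htos = [f"HTO{i + 1}" for i in range(config.n_htos)]
    n_singlet = config.n_htos * config.cells_per_sample
    n_total = int(round(n_singlet / (1 - config.doublet_rate - config.negative_rate)))
    n_doublet = int(round(config.doublet_rate * n_total))
    n_negative = n_total - n_singlet - n_doublet

    counts = _nb(rng, config.background_mean, config.dispersion,
                 (n_total, config.n_htos))
    labels: list[str] = []
    signal_sets: list[list[int]] = []
    for h in range(config.n_htos):
        for _ in range(config.cells_per_sample):
            labels.append(htos[h])
            signal_sets.append([h])
    for _ in range(n_doublet):
        pair = rng.choice(config.n_htos, size=2, replace=False)
        labels.append("doublet")
        signal_sets.append(sorted(int(i) for i in pair))
    for _ in range(n_negative):
        labels.append("negative")
        signal_sets.append([])
    for i, hs in enumerate(signal_sets):
        for h in hs:
            counts[i, h] = _nb(rng, config.signal_mean, config.dispersion, ())
    order = rng.permutation(n_total)
    counts = counts[order]
    labels = [labels[i] for i in order]
    signal_sets = [signal_sets[i] for i in order]
    barcodes = [f"CELL{i:06d}" for i in range(n_total)]
    truth = pd.DataFrame({
        "barcode": barcodes,
        "true_label": labels,
        "true_htos": ["+".join(htos[h] for h in hs) for hs in signal_sets],
    })
    return HtoCountMatrix(counts, barcodes, htos, array_id="sim"), truth


# -------------------------------------------------------------------- TCR

@dataclass
class TcrSimConfig:
    """Clonally structured paired-chain TCR reads.

    Counts are fixed per entity (cells per clonotype, UMIs per chain,
    reads per UMI) so the truth table is exact; errors are the stochastic
    part.
    """

    n_clonotypes: int = 20
    cells_per_clonotype: int = 5
    umis_per_chain: int = 3
    reads_per_umi: int = 10
    per_base_error: float = 0.0
    umi_error_rate: float = 0.0
    motif_positive_fraction: float = 0.2
    umi_length: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_clonotypes", "cells_per_clonotype", "umis_per_chain",
                     "reads_per_umi", "umi_length"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("per_base_error", "umi_error_rate", "motif_positive_fraction"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")


def _mutate(rng: np.random.Generator, seq: str, per_base_error: float) -> str:
    if per_base_error == 0:
        return seq
    arr = np.array(list(seq))
    hits = rng.random(arr.size) < per_base_error
    if hits.any():
        arr[hits] = rng.choice(_BASES, size=int(hits.sum()))
    return "".join(arr)


def _flip_one(rng: np.random.Generator, umi: str) -> str:
    pos = int(rng.integers(len(umi)))
    others = [b for b in "ACGT" if b != umi[pos]]
    return umi[:pos] + str(rng.choice(others)) + umi[pos + 1:]


def simulate_tcr_reads(config: TcrSimConfig
                       ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Simulate TCR reads; returns (read table, truth tables).

    The read table has columns cell_barcode, umi, chain, sequence,
    cdr3_aa. Truth is a dict with "clonotypes" (clonotype_id, cdr3a_aa,
    cdr3b_aa, tra_sequence, trb_sequence, motif_positive) and "cells"
    (cell_barcode, clonotype_id, plus per chain the true sequence and
    true UMI count — duplicate UMIs injected as errors do not count).
    """
    rng = substream(config.seed, "tcr")
    n_motif = int(round(config.motif_positive_fraction * config.n_clonotypes))
    clonotypes = []
    for ci in range(config.n_clonotypes):
        # in-frame nucleotide length in [30, 60]
        tra_len, trb_len = (int(rng.integers(10, 21)) * 3 for _ in range(2))
        cdr3a = "C" + _random_seq(rng, int(rng.integers(8, 13)), _AA) + "F"
        if ci < n_motif:
            ins = int(rng.integers(1, len(cdr3a) - 1))
            cdr3a = cdr3a[:ins] + DEFAULT_MOTIF + cdr3a[ins:]
        cdr3b = "C" + _random_seq(rng, int(rng.integers(8, 13)), _AA) + "F"
        clonotypes.append({
            "clonotype_id": f"CT{ci + 1:03d}",
            "cdr3a_aa": cdr3a,
            "cdr3b_aa": cdr3b,
            "tra_sequence": _random_seq(rng, tra_len),
            "trb_sequence": _random_seq(rng, trb_len),
            "motif_positive": ci < n_motif,
        })

    reads, cell_rows = [], []
    seen_barcodes: set[str] = set()
    for ct in clonotypes:
        for _ in range(config.cells_per_clonotype):
            bc = _random_seq(rng, 12)
            while bc in seen_barcodes:
                bc = _random_seq(rng, 12)
            seen_barcodes.add(bc)
            for chain, seq_key, cdr3_key in (("TRA", "tra_sequence", "cdr3a_aa"),
                                             ("TRB", "trb_sequence", "cdr3b_aa")):
                true_seq = ct[seq_key]
                umis: set[str] = set()
                while len(umis) < config.umis_per_chain:
                    umis.add(_random_seq(rng, config.umi_length))
                for umi in sorted(umis):
                    for _ in range(config.reads_per_umi):
                        reads.append((bc, umi, chain,
                                      _mutate(rng, true_seq, config.per_base_error),
                                      ct[cdr3_key]))
                    if rng.random() < config.umi_error_rate:
                        # 1-mismatch duplicate with ceil(r/2) reads: parent
                        # count r >= 2*ceil(r/2) - 1, so collapse merges it
                        dup = _flip_one(rng, umi)
                        while dup in umis:
                            dup = _flip_one(rng, umi)
                        n_dup = (config.reads_per_umi + 1) // 2
                        for _ in range(n_dup):
                            reads.append((bc, dup, chain,
                                          _mutate(rng, true_seq, config.per_base_error),
                                          ct[cdr3_key]))
            cell_rows.append({
                "cell_barcode": bc,
                "clonotype_id": ct["clonotype_id"],
                "tra_sequence": ct["tra_sequence"],
                "trb_sequence": ct["trb_sequence"],
                "cdr3a_aa": ct["cdr3a_aa"],
                "cdr3b_aa": ct["cdr3b_aa"],
                "tra_true_umis": config.umis_per_chain,
                "trb_true_umis": config.umis_per_chain,
            })
    read_table = pd.DataFrame(reads, columns=["cell_barcode", "umi", "chain",
                                              "sequence", "cdr3_aa"])
    truth = {"clonotypes": pd.DataFrame(clonotypes),
             "cells": pd.DataFrame(cell_rows)}
    return read_table, truth


# ------------------------------------------------------------- expression

@dataclass
class ExprSimConfig:
    """Two-population expression counts with a granzyme-program shift."""

    n_cells_per_group: int = 500
    n_genes: int = 1000
    signature_genes: list[str] = field(default_factory=lambda: list(GRANZYME_SIGNATURE))
    signature_log_shift: float = 1.0
    baseline_log_mean: float = 0.0      # lognormal location of per-gene means
    baseline_log_sd: float = 1.0
    dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_group < 1 or self.n_genes < 1:
            raise ConfigError("cell and gene counts must be >= 1")
        if self.signature_log_shift < 0:
            raise ConfigError("signature_log_shift must be >= 0")
        if not self.signature_genes:
            raise ConfigError("signature_genes must be non-empty")
        if len(self.signature_genes) > self.n_genes:
            raise ConfigError("more signature genes than genes")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")


def simulate_expression(config: ExprSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a genes x cells count matrix; returns (matrix, truth).

    Gene universe = signature genes followed by filler genes. Cytotoxic
    cells have the signature genes' NB mean multiplied by
    exp(signature_log_shift); every other gene is exchangeable between
    groups. Truth columns: barcode, group ("cytotoxic" | "other").
    """
    rng = substream(config.seed, "expr")
    n_fill = config.n_genes - len(config.signature_genes)
    genes = list(config.signature_genes) + [f"Gene{i + 1:05d}" for i in range(n_fill)]
    if len(set(genes)) != len(genes):
        raise ConfigError("signature gene names collide with filler gene names")
    base_means = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                               size=config.n_genes)
    n = config.n_cells_per_group
    groups = ["cytotoxic"] * n + ["other"] * n
    barcodes = [f"EXPR{i:06d}" for i in range(2 * n)]
    sig_idx = np.arange(len(config.signature_genes))
    counts = np.empty((config.n_genes, 2 * n), dtype=np.int64)
    for j, grp in enumerate(groups):
        means = base_means.copy()
        if grp == "cytotoxic":
            means[sig_idx] *= np.exp(config.signature_log_shift)
        p = config.dispersion / (config.dispersion + means)
        counts[:, j] = rng.negative_binomial(config.dispersion, p)
    matrix = pd.DataFrame(counts, index=genes, columns=barcodes)
    truth = pd.DataFrame({"barcode": barcodes, "group": groups})
    return matrix, truth


# --------------------------------------------------------------- tetramer

@dataclass
class TetramerSimConfig:
    """Tetramer-sorted reference clonotypes with known rule outcomes."""

    n_clonotypes: int = 50
    mean_cells_per_clonotype: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clonotypes < 1:
            raise ConfigError("n_clonotypes must be >= 1")
        if self.mean_cells_per_clonotype < 1:
            raise ConfigError("mean_cells_per_clonotype must be >= 1")


def simulate_tetramer_reference(config: TetramerSimConfig,
                                min_cells: int = 2, min_fraction: float = 0.8
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a tetramer-sorted clonotype table; returns (table, truth).

    Each clonotype gets 1 + Poisson(mean - 1) cells and a latent
    tetramer-positive propensity uniform in [0, 1]; realized positive
    cells are binomial. Truth applies the reference rule (cells >=
    min_cells and positive fraction strictly > min_fraction) to the
    realized counts, per chain (CDR3s are unique per clonotype, so the
    per-chain pooling is the identity here).
    """
    rng = substream(config.seed, "tetramer")
    rows, truth_rows = [], []
    seen: set[str] = set()
    for ci in range(config.n_clonotypes):
        while True:
            cdr3a = "C" + _random_seq(rng, 10, _AA) + "F"
            cdr3b = "C" + _random_seq(rng, 10, _AA) + "F"
            if cdr3a not in seen and cdr3b not in seen and cdr3a != cdr3b:
                seen.update((cdr3a, cdr3b))
                break
        cells = 1 + int(rng.poisson(config.mean_cells_per_clonotype - 1))
        prop = float(rng.random())
        pos = int(rng.binomial(cells, prop))
        passes = cells >= min_cells and pos / cells > min_fraction
        rows.append({"cdr3b_aa": cdr3b, "cdr3a_aa": cdr3a,
                     "n_cells_positive": pos, "n_cells_negative": cells - pos})
        truth_rows.append({"cdr3b_aa": cdr3b, "cdr3a_aa": cdr3a,
                           "n_cells": cells, "n_positive": pos,
                           "passes_rule": passes})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
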