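"""Hashtag-oligo (HTO) demultiplexing.

Cells from several mice are pooled on one array after each sample is
stained with a distinct DNA-barcoded hashing antibody. Demultiplexing
assigns each cell back to its sample of origin from the per-cell HTO
count vector:

1. centered log-ratio (CLR) normalization of the cells x HTOs matrix,
   computed within each cell across its hashtags;
2. k-medoids (PAM) clustering of the CLR profiles with one cluster per
   hashtag, each cluster dominated by one HTO;
3. per-cluster threshold = the lowest CLR value of the dominant HTO among
   that cluster's cells, hardened by iteratively discarding the minimum
   while a one-sided Grubbs test flags it as an outlier at p = 0.05;
4. classification: a cell positive for exactly one HTO is a singlet of
   that sample, for two or more a doublet, for none a negative; doublets
   and negatives are excluded downstream.

Each array is processed independently so that depth differences between
sequencing runs never pool into a shared threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.spatial.distance import cdist

from ._util import InputError

__all__ = [
    "HtoCountMatrix",
    "ClrMatrix",
    "ClusterAssignment",
    "GrubbsResult",
    "ThresholdSet",
    "DemuxResult",
    "clr_normalize",
    "kmedoids_cluster",
    "grubbs_min_test",
    "establish_thresholds",
    "classify_cells",
    "demux",
    "HtoDemultiplexer",
]


@dataclass
class HtoCountMatrix:
    """Non-negative integer hashtag counts, cells x HTOs, for one array."""

    counts: np.ndarray
    cell_barcodes: list[str]
    hto_names: list[str]
    array_id: str = "array1"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.size == 0:
            raise InputError("HTO count matrix must be a non-empty 2-D array")
        if np.any(self.counts < 0):
            raise InputError("HTO counts must be non-negative")
        n_cells, n_htos = self.counts.shape
        if n_htos < 2:
            raise InputError("need at least 2 HTOs to demultiplex")
        if len(self.cell_barcodes) != n_cells or len(self.hto_names) != n_htos:
            raise InputError("label lengths do not match matrix shape")
        if len(set(self.cell_barcodes)) != n_cells or len(set(self.hto_names)) != n_htos:
            raise InputError("cell barcodes and HTO names must be unique")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_htos(self) -> int:
        return self.counts.shape[1]


@dataclass
class ClrMatrix:
    """CLR-normalized hashtag values; every row sums to zero."""

    values: np.ndarray
    cell_barcodes: list[str]
    hto_names: list[str]
    pseudocount: float = 1.0
    array_id: str = "array1"


@dataclass
class ClusterAssignment:
    labels: np.ndarray            # cluster index per cell
    medoids: np.ndarray           # cell index of each cluster's medoid
    dominant_hto: list[str]       # per cluster, HTO with highest mean CLR
    cost: float                   # total distance of cells to their medoid
    warnings: list[str] = field(default_factory=list)


@dataclass
class GrubbsResult:
    statistic: float
    critical: float
    is_outlier: bool
    note: str = ""


@dataclass
class ThresholdSet:
    """Per-HTO positivity thresholds on the CLR scale, with provenance."""

    thresholds: dict[str, float]
    removed: dict[str, list[float]]
    alpha: float = 0.05
    warnings: list[str] = field(default_factory=list)


@dataclass
class DemuxResult:
    """Per-cell singlet/doublet/negative calls for one array."""

    calls: pd.DataFrame           # index barcode; columns call, label
    positivity: pd.DataFrame      # index barcode; bool per HTO
    clr: pd.DataFrame             # index barcode; CLR value per HTO
    thresholds: ThresholdSet
    array_id: str = "array1"

    def summary(self) -> pd.DataFrame:
        """Counts per call category plus the thresholds used."""
        counts = self.calls["call"].value_counts()
        rows = [
            {"quantity": f"n_{k}", "value": int(counts.get(k, 0))}
            for k in ("singlet", "doublet", "negative")
        ]
        for hto, thr in self.thresholds.thresholds.items():
            rows.append({"quantity": f"threshold[{hto}]", "value": thr})
        return pd.DataFrame(rows)


def clr_normalize(m: HtoCountMatrix, pseudocount: float = 1.0) -> ClrMatrix:
    """Centered log-ratio transform of hashtag counts, within each cell.

    value(c, h) = ln(count + pc) - mean_h' ln(count(c, h') + pc), i.e. the
    log of each tag over the geometric mean of all tags in the same cell.
    """
    if pseudocount <= 0:
        raise InputError("pseudocount must be > 0")
    logs = np.log(m.counts.astype(float) + pseudocount)
    values = logs - logs.mean(axis=1, keepdims=True)
    return ClrMatrix(values, list(m.cell_barcodes), list(m.hto_names),
                     pseudocount=pseudocount, array_id=m.array_id)


def _pam_build(dist: np.ndarray, k: int) -> list[int]:
    """Deterministic PAM BUILD initialization: greedy cost reduction."""
    n = dist.shape[0]
    first = int(np.argmin(dist.sum(axis=0)))
    medoids = [first]
    d_nearest = dist[:, first].copy()
    for _ in range(1, k):
        # gain of adding candidate j = sum of distance reductions it brings
        gain = np.maximum(d_nearest[:, None] - dist, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        j = int(np.argmax(gain))
        medoids.append(j)
        d_nearest = np.minimum(d_nearest, dist[:, j])
    return medoids


def kmedoids_cluster(clr: ClrMatrix, k: int | None = None,
                     max_iter: int = 200) -> ClusterAssignment:
    """PAM k-medoids on CLR profiles with Euclidean distance.

    Deterministic BUILD initialization followed by steepest-descent swaps,
    so a fixed input always yields the same local optimum. ``k`` defaults
    to the number of HTOs (one cluster per hashtag).
    """
    X = np.asarray(clr.values, dtype=float)
    n = X.shape[0]
    if k is None:
        k = len(clr.hto_names)
    if k > n:
        raise InputError(f"k={k} exceeds number of cells ({n})")
    dist = cdist(X, X)
    medoids = np.array(_pam_build(dist, k), dtype=int)

    for _ in range(max_iter):
        dmed = dist[:, medoids]                    # n x k
        order = np.argsort(dmed, axis=1)
        nearest = order[:, 0]
        d_nearest = dmed[np.arange(n), nearest]
        d_second = dmed[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        cost = d_nearest.sum()

        best_delta, best_swap = -1e-12, None
        for mi in range(k):
            # cost per point if medoid mi were removed
            base = np.where(nearest == mi, d_second, d_nearest)
            new_costs = np.minimum(dist, base[:, None]).sum(axis=0)  # per candidate h
            new_costs[medoids] = np.inf
            h = int(np.argmin(new_costs))
            delta = cost - new_costs[h]
            if delta > best_delta + 1e-12:
                best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]

    labels = np.argmin(dist[:, medoids], axis=1)
    warnings: list[str] = []
    dominant: list[str] = []
    for ci in range(k):
        members = labels == ci
        if not members.any():
            # empty cluster is only possible with duplicate points; keep the
            # medoid itself as its sole member
            labels[medoids[ci]] = ci
            members = labels == ci
            warnings.append(f"cluster {ci} was empty; reseeded with its medoid")
        dominant.append(clr.hto_names[int(np.argmax(X[members].mean(axis=0)))])
    seen: dict[str, int] = {}
    for ci, h in enumerate(dominant):
        if h in seen:
            warnings.append(
                f"clusters {seen[h]} and {ci} share dominant HTO {h} (degenerate clustering)"
            )
        else:
            seen[h] = ci
    cost = dist[np.arange(n), medoids[labels]].sum()
    return ClusterAssignment(labels, medoids, dominant, float(cost), warnings)


def grubbs_min_test(values, alpha: float = 0.05) -> GrubbsResult:
    """One-sided Grubbs test for the minimum of an approximately normal sample.

    G = (mean - min) / s with the sample standard deviation (ddof=1); the
    critical value is the closed form
    G_crit = ((N-1)/sqrt(N)) * sqrt(t^2 / (N-2+t^2)) with t the upper
    alpha/N quantile of Student's t on N-2 degrees of freedom. Fewer than
    3 values, or zero spread, can never be flagged.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 3:
        return GrubbsResult(np.nan, np.nan, False, "too few values (N < 3)")
    sd = v.std(ddof=1)
    if sd == 0:
        return GrubbsResult(0.0, np.nan, False, "zero variance")
    g = (v.mean() - v.min()) / sd
    t = sstats.t.ppf(1.0 - alpha / n, n - 2)
    crit = (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))
    return GrubbsResult(float(g), float(crit), bool(g > crit))


def establish_thresholds(clr: ClrMatrix, clusters: ClusterAssignment,
                         alpha: float = 0.05) -> ThresholdSet:
    """Per-HTO positivity thresholds from each cluster's dominant-HTO values.

    The candidate threshold is the cluster minimum; while the Grubbs
    minimum test flags it as an outlier at ``alpha`` it is removed and the
    next lowest value becomes the candidate. Clusters smaller than 3 cells
    skip the test (undefined) and use the raw minimum.
    """
    X = np.asarray(clr.values, dtype=float)
    candidates: dict[str, list[float]] = {}
    removed: dict[str, list[float]] = {h: [] for h in clr.hto_names}
    warnings = list(clusters.warnings)
    for ci, hto in enumerate(clusters.dominant_hto):
        col = clr.hto_names.index(hto)
        vals = np.sort(X[clusters.labels == ci, col])
        if vals.size < 3:
            warnings.append(
                f"cluster {ci} has {vals.size} cells; Grubbs skipped, raw minimum used"
            )
            candidates.setdefault(hto, []).append(float(vals[0]))
            continue
        while vals.size >= 3 and grubbs_min_test(vals, alpha).is_outlier:
            removed[hto].append(float(vals[0]))
            vals = vals[1:]
        candidates.setdefault(hto, []).append(float(vals[0]))
    thresholds: dict[str, float] = {}
    for hto in clr.hto_names:
        if hto not in candidates:
            warnings.append(f"no cluster dominated by {hto}; threshold set to +inf")
            thresholds[hto] = np.inf
        else:
            # duplicated dominant HTO: most permissive candidate wins
            thresholds[hto] = min(candidates[hto])
    return ThresholdSet(thresholds, removed, alpha=alpha, warnings=warnings)


def classify_cells(clr: ClrMatrix, thresholds: ThresholdSet) -> DemuxResult:
    """Call each cell singlet/doublet/negative from per-HTO positivity.

    A cell is positive for HTO h iff clr(c, h) >= threshold(h); exactly
    one positive flag makes a singlet labeled with that hashtag, two or
    more a doublet, none a negative.
    """
    missing = [h for h in clr.hto_names if h not in thresholds.thresholds]
    if missing:
        raise InputError(f"missing thresholds for HTOs: {missing}")
    thr = np.array([thresholds.thresholds[h] for h in clr.hto_names])
    pos = np.asarray(clr.values) >= thr[None, :]
    npos = pos.sum(axis=1)
    calls = np.where(npos == 0, "negative", np.where(npos == 1, "singlet", "doublet"))
    labels = [
        clr.hto_names[int(np.argmax(row))] if n == 1 else ""
        for row, n in zip(pos, npos)
    ]
    idx = pd.Index(clr.cell_barcodes, name="barcode")
    return DemuxResult(
        calls=pd.DataFrame({"call": calls, "label": labels}, index=idx),
        positivity=pd.DataFrame(pos, index=idx, columns=clr.hto_names),
        clr=pd.DataFrame(clr.values, index=idx, columns=clr.hto_names),
        thresholds=thresholds,
        array_id=clr.array_id,
    )


def demux(matrices, alpha: float = 0.05, pseudocount: float = 1.0,
          k: int | None = None, overrides: dict[str, float] | None = None
          ) -> list[DemuxResult]:
    """Run the full demultiplexing chain independently on each array.

    ``overrides`` maps HTO name -> threshold and replaces the automatic
    value after thresholding (the manual-adjustment escape hatch).
    """
    if isinstance(matrices, HtoCountMatrix):
        matrices = [matrices]
    if not matrices:
        raise InputError("need at least one HTO matrix")
    results = []
    for m in matrices:
        clr = clr_normalize(m, pseudocount=pseudocount)
        clusters = kmedoids_cluster(clr, k=k)
        thresholds = establish_thresholds(clr, clusters, alpha=alpha)
        if overrides:
            for hto, value in overrides.items():
                if hto in thresholds.thresholds:
                    thresholds.thresholds[hto] = float(value)
                    thresholds.warnings.append(f"threshold for {hto} manually overridden")
        results.append(classify_cells(clr, thresholds))
    return results


class HtoDemultiplexer:
    """Model-style wrapper: configure on a count matrix, ``fit()`` to demux.

    Convenience over :func:`demux` for a single array; the fitted result
    carries the thresholds (the model's estimates), the Grubbs-removed
    values (diagnostics) and a ``summary()`` table.
    """

    def __init__(self, matrix: HtoCountMatrix, alpha: float = 0.05,
                 pseudocount: float = 1.0, k: int | None = None):
        self.matrix = matrix
        self.alpha = alpha
        self.pseudocount = pseudocount
        self.k = k

    def fit(self, overrides: dict[str, float] | None = None) -> DemuxResult:
        return demux([self.matrix], alpha=self.alpha, pseudocount=self.pseudocount,
                     k=self.k, overrides=overrides)[0]
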