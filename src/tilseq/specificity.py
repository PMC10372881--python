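"""Tetramer-anchored antigen-specificity annotation of clonotypes.

The reference is built from TCRs of tetramer-sorted CD8+ T cells against
the endogenous retroviral envelope epitope p15E: a CDR3 amino-acid
sequence (beta or alpha, pooled over all clonotypes carrying it) is
high-confidence specific iff it was detected in more than one cell and
strictly more than 80% of the cells carrying it were in the
tetramer-positive sort fraction. Query clonotypes are labeled specific
when their CDR3beta or CDR3alpha matches the reference exactly, or when
their CDR3alpha contains the accepted motif (default "DYSNNRLT") as a
contiguous substring; everything else is of unknown specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._util import InputError

DEFAULT_MOTIF = "DYSNNRLT"

__all__ = ["ReferenceCdr3Set", "build_reference", "annotate_specificity", "DEFAULT_MOTIF"]


@dataclass
class ReferenceCdr3Set:
    beta: set[str] = field(default_factory=set)
    alpha: set[str] = field(default_factory=set)
    motif: str = DEFAULT_MOTIF
    min_cells: int = 2
    min_fraction: float = 0.8


def _pool_chain(table: pd.DataFrame, col: str) -> pd.DataFrame:
    sub = table[[col, "n_cells_positive", "n_cells_negative"]].dropna(subset=[col])
    return sub.groupby(col, sort=True).sum()


def build_reference(tetramer: pd.DataFrame, min_cells: int = 2,
                    min_fraction: float = 0.8, motif: str = DEFAULT_MOTIF
                    ) -> ReferenceCdr3Set:
    """High-confidence CDR3 sets from a tetramer-sorted clonotype table.

    ``tetramer`` columns: cdr3b_aa, cdr3a_aa, n_cells_positive,
    n_cells_negative. Cell counts for a CDR3 are pooled across all
    clonotypes carrying it; inclusion requires total cells >= ``min_cells``
    and a tetramer-positive fraction strictly > ``min_fraction``.
    """
    if not motif:
        raise InputError("motif must be non-empty")
    required = {"cdr3b_aa", "cdr3a_aa", "n_cells_positive", "n_cells_negative"}
    if not required.issubset(tetramer.columns):
        raise InputError(f"tetramer table must have columns {sorted(required)}")
    if (tetramer["n_cells_positive"] < 0).any() or (tetramer["n_cells_negative"] < 0).any():
        raise InputError("cell counts must be non-negative")
    if ((tetramer["n_cells_positive"] + tetramer["n_cells_negative"]) == 0).any():
        raise InputError("tetramer table contains zero-cell rows")

    ref = ReferenceCdr3Set(motif=motif, min_cells=min_cells, min_fraction=min_fraction)
    for col, target in (("cdr3b_aa", ref.beta), ("cdr3a_aa", ref.alpha)):
        pooled = _pool_chain(tetramer, col)
        cells = pooled["n_cells_positive"] + pooled["n_cells_negative"]
        frac = pooled["n_cells_positive"] / cells
        keep = pooled.index[(cells > min_cells - 1) & (frac > min_fraction)]
        target.update(str(s) for s in keep)
    return ref


def annotate_specificity(clonotypes: pd.DataFrame, ref: ReferenceCdr3Set
                         ) -> pd.DataFrame:
    """Label each clonotype row specific/unknown against the reference.

    Evidence records the first matching rule in the order exact CDR3beta
    match, exact CDR3alpha match, CDR3alpha motif containment; the order
    only affects the evidence field, never the label.
    """
    rows = []
    for row in clonotypes.itertuples(index=False):
        b = getattr(row, "cdr3b_aa", None)
        a = getattr(row, "cdr3a_aa", None)
        b = b if isinstance(b, str) and b else None
        a = a if isinstance(a, str) and a else None
        if b is not None and b in ref.beta:
            evidence = "cdr3b_match"
        elif a is not None and a in ref.alpha:
            evidence = "cdr3a_match"
        elif a is not None and ref.motif in a:
            evidence = "motif_match"
        else:
            evidence = "none"
        rows.append({
            "cell_id": getattr(row, "cell_id", None),
            "cdr3b_aa": b,
            "cdr3a_aa": a,
            "label": "specific" if evidence != "none" else "unknown",
            "evidence": evidence,
        })
    return pd.DataFrame(rows, columns=["cell_id", "cdr3b_aa", "cdr3a_aa",
                                       "label", "evidence"])
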