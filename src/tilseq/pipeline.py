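"""End-to-end orchestration: simulate -> demux -> assemble -> annotate -> score.

Convenience glue for running every stage on one coherent synthetic
experiment and writing all outputs as plain text. Every stage draws from
substreams of one top-level seed, so the whole run is bit-reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import hto as hto_mod
from . import io as tio
from . import scoring, simulate, specificity
from . import stats as stats_mod
from . import tcr as tcr_mod


def run_end_to_end(seed: int, outdir) -> dict:
    """Run the full pipeline on synthetic data; returns summary numbers.

    Writes demux calls, the clonotype and rearrangement tables, the
    specificity annotation, per-cell cytotoxicity scores, a per-gene
    differential-expression table and a JSON summary into ``outdir``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # hashing -> demux
    matrix, hto_truth = simulate.simulate_hto(simulate.HtoSimConfig(seed=seed))
    demux_result = hto_mod.demux([matrix])[0]
    tio.write_demux_result(demux_result, out)
    hto_truth.to_csv(out / "hto_truth.tsv", sep="\t", index=False)

    # TCR reads -> clonotypes
    reads, tcr_truth = simulate.simulate_tcr_reads(simulate.TcrSimConfig(
        seed=seed, n_clonotypes=25, cells_per_clonotype=4,
        per_base_error=0.005, umi_error_rate=0.1, motif_positive_fraction=0.2))
    clonotypes = tcr_mod.assemble_clonotypes(reads)
    clonotypes.to_csv(out / "clonotypes.tsv", sep="\t", index=False)
    tcr_mod.to_airr(clonotypes).to_csv(out / "rearrangements.tsv", sep="\t", index=False)

    # tetramer reference -> specificity annotation
    tetramer, _ = simulate.simulate_tetramer_reference(
        simulate.TetramerSimConfig(seed=seed))
    ref = specificity.build_reference(tetramer)
    annotation = specificity.annotate_specificity(clonotypes, ref)
    annotation.to_csv(out / "specificity.tsv", sep="\t", index=False)

    # expression on the same cells (cytotoxic group = first half of barcodes)
    n_cells = len(clonotypes)
    counts, expr_truth = simulate.simulate_expression(simulate.ExprSimConfig(
        seed=seed, n_cells_per_group=max((n_cells + 1) // 2, 1)))
    counts = counts.iloc[:, :n_cells]
    expr_truth = expr_truth.iloc[:n_cells].copy()
    counts.columns = list(clonotypes["cell_id"])
    expr_truth["barcode"] = list(clonotypes["cell_id"])

    counts = scoring.qc_filter(counts)
    norm = scoring.log_normalize(counts)
    scores = scoring.score_cytotoxicity(norm, clonotypes, seed=seed)
    scores.round(9).to_frame().to_csv(out / "cytotoxicity_scores.tsv", sep="\t",
                                      index_label="barcode")

    groups = expr_truth.set_index("barcode")["group"]
    group_a = [c for c in norm.columns if groups.get(c) == "cytotoxic"]
    group_b = [c for c in norm.columns if groups.get(c) == "other"]
    de = stats_mod.rank_sum_de(norm, group_a, group_b)
    de.round(9).to_csv(out / "de.tsv", sep="\t")

    score_test = stats_mod.wilcoxon_rank_sum(
        scores.reindex(group_a).dropna().values,
        scores.reindex(group_b).dropna().values)
    summary = {
        "n_cells_demuxed": int((demux_result.calls["call"] == "singlet").sum()),
        "n_cells_with_tcr": int(n_cells),
        "n_specific_clonotypes": int((annotation["label"] == "specific").sum()),
        "score_group_ranksum_p": score_test.p_value,
        "n_de_genes_adj05": int((de["p_adjusted"] < 0.05).sum()),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
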