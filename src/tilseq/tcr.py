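"""Paired single-cell TCR assembly from barcode/UMI-tagged reads.

Reads carry (cell barcode, UMI, chain, nucleotide sequence). Assembly:

1. aggregate reads by (barcode, chain, UMI); UMIs with fewer than 5 reads
   are discarded;
2. within a UMI, cluster equal-length sequences by single-linkage hamming
   distance (<= 2 mismatches); the largest set is kept only if it holds
   strictly more than 90% of the UMI's reads;
3. positional read-weighted majority consensus over the dominant set;
4. directional UMI collapse: a UMI absorbs a 1-mismatch neighbour whose
   read count satisfies count(parent) >= 2*count(child) - 1, following
   the deduplication-network rule;
5. per cell and chain, keep the candidate with the most UMIs (then reads);
   cells with neither chain are omitted.

CDR3 amino-acid annotation travels with the reads (germline V/J alignment
is upstream of this module); consensus records whose supporting reads
carry no CDR3 are dropped at clonotype assembly.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from ._util import hamming

__all__ = [
    "UmiGroup",
    "ConsensusRecord",
    "group_umis",
    "cluster_sets",
    "build_consensus",
    "directional_collapse",
    "select_cell_chains",
    "assemble_clonotypes",
]

_BASES = "ACGT"
READ_COLUMNS = ["cell_barcode", "umi", "chain", "sequence"]


@dataclass
class UmiGroup:
    """All reads sharing one (cell barcode, chain, UMI) key."""

    cell_barcode: str
    chain: str
    umi: str
    seq_counts: dict[str, int]                 # sequence -> read count
    cdr3_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    status: str = "retained"                   # or discarded_low_reads /
                                               # discarded_no_dominant_set

    @property
    def total_reads(self) -> int:
        return sum(self.seq_counts.values())


@dataclass
class ConsensusRecord:
    """One consensus molecule, possibly representing several collapsed UMIs."""

    cell_barcode: str
    chain: str
    umi: str
    sequence: str
    reads: int
    umis: int = 1
    cdr3_aa: str | None = None


def group_umis(reads: pd.DataFrame, min_reads: int = 5) -> list[UmiGroup]:
    """Aggregate reads by (barcode, chain, UMI) and apply the read filter.

    Groups totalling fewer than ``min_reads`` reads are kept in the output
    with status ``discarded_low_reads`` so that read accounting stays
    complete. Malformed rows (missing key fields) are skipped, not fatal.
    """
    groups: dict[tuple[str, str, str], UmiGroup] = {}
    has_cdr3 = "cdr3_aa" in reads.columns
    for row in reads.itertuples(index=False):
        bc, umi, chain, seq = row.cell_barcode, row.umi, row.chain, row.sequence
        if not (isinstance(bc, str) and isinstance(umi, str)
                and isinstance(seq, str) and bc and umi and seq):
            continue
        key = (bc, chain, umi)
        g = groups.get(key)
        if g is None:
            g = groups[key] = UmiGroup(bc, chain, umi, {})
        g.seq_counts[seq] = g.seq_counts.get(seq, 0) + 1
        if has_cdr3:
            cdr3 = row.cdr3_aa
            if isinstance(cdr3, str) and cdr3:
                g.cdr3_counts.setdefault(seq, {})
                g.cdr3_counts[seq][cdr3] = g.cdr3_counts[seq].get(cdr3, 0) + 1
    out = list(groups.values())
    for g in out:
        if g.total_reads < min_reads:
            g.status = "discarded_low_reads"
    return out


def cluster_sets(group: UmiGroup, max_mismatch: int = 2,
                 dominance: float = 0.9) -> dict[str, int] | None:
    """Find the dominant similar-sequence set of a UMI group.

    Equal-length sequences are single-linkage clustered at hamming
    distance <= ``max_mismatch`` (unequal lengths are never linked). The
    largest cluster by read count is dominant iff its read share is
    strictly greater than ``dominance``; otherwise ``None`` is returned
    and the group should be marked discarded.
    """
    seqs = sorted(group.seq_counts)           # deterministic order
    parent = list(range(len(seqs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if len(seqs[i]) == len(seqs[j]) and hamming(seqs[i], seqs[j]) <= max_mismatch:
                parent[find(i)] = find(j)

    clusters: dict[int, dict[str, int]] = defaultdict(dict)
    for i, s in enumerate(seqs):
        clusters[find(i)][s] = group.seq_counts[s]
    total = group.total_reads
    # largest read share wins; ties broken by smallest member sequence
    best = min(clusters.values(), key=lambda c: (-sum(c.values()), min(c)))
    if sum(best.values()) / total > dominance:
        return dict(sorted(best.items()))
    return None


def build_consensus(seq_counts: dict[str, int]) -> str:
    """Read-weighted positional majority consensus of equal-length sequences.

    Ties broken by the lexicographically smallest base (A < C < G < T).
    """
    seqs = list(seq_counts)
    if not seqs:
        raise ValueError("empty sequence set")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise RuntimeError("unequal-length sequences inside a dominant set")
    out = []
    for pos in range(length):
        tally: dict[str, int] = defaultdict(int)
        for s, c in seq_counts.items():
            tally[s[pos]] += c
        out.append(min(tally, key=lambda b: (-tally[b], b)))
    return "".join(out)


def directional_collapse(records: list[ConsensusRecord]) -> list[ConsensusRecord]:
    """Directional UMI error correction for one (barcode, chain).

    Nodes are UMIs; a directed edge a -> b exists iff hamming(umi_a,
    umi_b) == 1 and reads(a) >= 2*reads(b) - 1. Components are grown
    breadth-first from the highest-count unassigned node, always walking
    from higher- to lower-count neighbours; each component collapses into
    its seed with read and UMI counts summed and the seed's consensus
    kept. The pass is repeated until no further merge occurs (absorbing a
    neighbour raises the seed's count, which can license a merge the
    original counts did not), so the operation is idempotent.
    """
    out = list(records)
    while True:
        collapsed = _directional_pass(out)
        if len(collapsed) == len(out):
            return collapsed
        out = collapsed


def _directional_pass(records: list[ConsensusRecord]) -> list[ConsensusRecord]:
    if len(records) <= 1:
        return sorted(records, key=lambda r: (-r.reads, r.umi))
    order = sorted(records, key=lambda r: (-r.reads, r.umi))
    n = len(order)
    adj: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j and len(order[i].umi) == len(order[j].umi) \
                    and hamming(order[i].umi, order[j].umi) == 1 \
                    and order[i].reads >= 2 * order[j].reads - 1:
                adj[i].append(j)
    assigned = [False] * n
    out: list[ConsensusRecord] = []
    for i in range(n):
        if assigned[i]:
            continue
        component = [i]
        assigned[i] = True
        queue = [i]
        while queue:
            cur = queue.pop(0)
            for j in adj[cur]:
                if not assigned[j]:
                    assigned[j] = True
                    component.append(j)
                    queue.append(j)
        seed = order[i]
        out.append(ConsensusRecord(
            cell_barcode=seed.cell_barcode,
            chain=seed.chain,
            umi=seed.umi,
            sequence=seed.sequence,
            reads=sum(order[j].reads for j in component),
            umis=sum(order[j].umis for j in component),
            cdr3_aa=seed.cdr3_aa,
        ))
    return sorted(out, key=lambda r: (-r.reads, r.umi))   # canonical order


def select_cell_chains(records: list[ConsensusRecord]) -> pd.DataFrame:
    """Pick one TRA and one TRB per cell and assemble the clonotype table.

    Collapsed UMI records are first aggregated by consensus sequence, so a
    candidate chain sequence carries the number of UMIs and total reads
    supporting it; candidates for a (cell, chain) are then ranked by UMI
    count, read count, and lexicographic sequence (deterministic).
    Records without a CDR3 annotation are dropped; cells left with
    neither chain are omitted.
    """
    by_cell: dict[str, dict[str, ConsensusRecord]] = defaultdict(dict)
    grouped: dict[tuple[str, str, str], ConsensusRecord] = {}
    for r in records:
        if not r.cdr3_aa:                   # CDR3 could not be determined -> drop
            continue
        key = (r.cell_barcode, r.chain, r.sequence)
        agg = grouped.get(key)
        if agg is None:
            # umis counts error-corrected molecules: one per collapsed record
            grouped[key] = ConsensusRecord(r.cell_barcode, r.chain, r.umi,
                                           r.sequence, r.reads, 1, r.cdr3_aa)
        else:
            agg.reads += r.reads
            agg.umis += 1
    candidates: dict[tuple[str, str], list[ConsensusRecord]] = defaultdict(list)
    for (bc, chain, _), agg in grouped.items():
        candidates[(bc, chain)].append(agg)
    for (bc, chain), cands in candidates.items():
        best = sorted(cands, key=lambda r: (-r.umis, -r.reads, r.sequence))[0]
        by_cell[bc][chain] = best
    rows = []
    for bc in sorted(by_cell):
        chains = by_cell[bc]
        tra, trb = chains.get("TRA"), chains.get("TRB")
        rows.append({
            "cell_id": bc,
            "cdr3b_aa": trb.cdr3_aa if trb else None,
            "cdr3a_aa": tra.cdr3_aa if tra else None,
            "trb_sequence": trb.sequence if trb else None,
            "tra_sequence": tra.sequence if tra else None,
            "trb_umis": trb.umis if trb else 0,
            "trb_reads": trb.reads if trb else 0,
            "tra_umis": tra.umis if tra else 0,
            "tra_reads": tra.reads if tra else 0,
        })
    return pd.DataFrame(rows, columns=[
        "cell_id", "cdr3b_aa", "cdr3a_aa", "trb_sequence", "tra_sequence",
        "trb_umis", "trb_reads", "tra_umis", "tra_reads",
    ])


def _consensus_of_group(group: UmiGroup, max_mismatch: int,
                        dominance: float) -> ConsensusRecord | None:
    dominant = cluster_sets(group, max_mismatch=max_mismatch, dominance=dominance)
    if dominant is None:
        group.status = "discarded_no_dominant_set"
        return None
    seq = build_consensus(dominant)
    cdr3 = None
    tally: dict[str, int] = defaultdict(int)
    for s in dominant:
        for c, k in group.cdr3_counts.get(s, {}).items():
            tally[c] += k
    if tally:
        cdr3 = min(tally, key=lambda c: (-tally[c], c))
    return ConsensusRecord(group.cell_barcode, group.chain, group.umi,
                           seq, reads=sum(dominant.values()), umis=1, cdr3_aa=cdr3)


def assemble_clonotypes(reads: pd.DataFrame, min_reads: int = 5,
                        dominance: float = 0.9, max_mismatch: int = 2
                        ) -> pd.DataFrame:
    """Full read-to-clonotype chain; returns one row per cell.

    Read order never matters: grouping keys and all tie-breaks are
    deterministic functions of the read multiset.
    """
    groups = group_umis(reads, min_reads=min_reads)
    per_chain: dict[tuple[str, str], list[ConsensusRecord]] = defaultdict(list)
    for g in groups:
        if g.status != "retained":
            continue
        rec = _consensus_of_group(g, max_mismatch, dominance)
        if rec is not None:
            per_chain[(g.cell_barcode, g.chain)].append(rec)
    collapsed: list[ConsensusRecord] = []
    for key in sorted(per_chain):
        collapsed.extend(directional_collapse(
            sorted(per_chain[key], key=lambda r: (-r.reads, r.umi))))
    return select_cell_chains(collapsed)


def to_airr(records_or_table: pd.DataFrame) -> pd.DataFrame:
    """AIRR-style rearrangement rows from a clonotype table.

    Columns: cell_id, locus, sequence, junction_aa, duplicate_count
    (UMIs), consensus_count (reads) — one row per recovered chain.
    """
    rows = []
    for row in records_or_table.itertuples(index=False):
        for locus, seq, junction, umis, reads in (
            ("TRB", row.trb_sequence, row.cdr3b_aa, row.trb_umis, row.trb_reads),
            ("TRA", row.tra_sequence, row.cdr3a_aa, row.tra_umis, row.tra_reads),
        ):
            if seq:
                rows.append({"cell_id": row.cell_id, "locus": locus,
                             "sequence": seq, "junction_aa": junction,
                             "duplicate_count": umis, "consensus_count": reads})
    return pd.DataFrame(rows, columns=["cell_id", "locus", "sequence",
                                       "junction_aa", "duplicate_count",
                                       "consensus_count"])
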