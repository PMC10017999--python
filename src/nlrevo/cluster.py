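"""Clustered vs singleton NLR locus calling with a fixed genomic window.

Two chromosome-mapped NLR genes whose inter-gene gap is strictly less than
the window (default 250 kb) belong to one clustered locus; chains are linked
transitively (single linkage), so a run of genes each within the window of
its neighbour forms one cluster.  Genes annotated only on scaffolds are
"unmapped" and excluded from chaining.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from nlrevo.classify import percent
from nlrevo.errors import ValidationError
from nlrevo.io import GeneModel

DEFAULT_WINDOW_BP = 250_000

STATUSES = ("clustered", "singleton", "unmapped")


@dataclass(frozen=True)
class LocusCall:
    gene_id: str
    seq_id: str
    status: str
    cluster_id: int | None = None


def call_loci(
    genes: Sequence[GeneModel], window_bp: int = DEFAULT_WINDOW_BP
) -> list[LocusCall]:
    """Cluster/singleton/unmapped call for every NLR gene.

    Per seq_id, genes are sorted by start; adjacent genes whose gap
    (next.start - prev.end - 1, floored at 0 for overlaps) is < window_bp
    chain into one cluster.  Cluster ids are assigned in ascending order of
    the cluster's leftmost start, per species then seq_id.
    """
    if window_bp <= 0:
        raise ValidationError("window_bp must be positive")
    seen: set[tuple[str, str]] = set()
    for g in genes:
        key = (g.species, g.gene_id)
        if key in seen:
            raise ValidationError(f"duplicate gene_id {g.gene_id} in {g.species}")
        seen.add(key)

    calls: list[LocusCall] = []
    mapped: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        if not g.is_chromosome:
            calls.append(LocusCall(g.gene_id, g.seq_id, "unmapped"))
        else:
            mapped.setdefault((g.species, g.seq_id), []).append(g)

    next_cluster_id = 1
    for key in sorted(mapped):
        chrom_genes = sorted(mapped[key], key=lambda g: (g.start, g.end, g.gene_id))
        chains: list[list[GeneModel]] = [[chrom_genes[0]]]
        right_edge = chrom_genes[0].end
        for g in chrom_genes[1:]:
            gap = max(0, g.start - right_edge - 1)
            if gap < window_bp:
                chains[-1].append(g)
            else:
                chains.append([g])
            right_edge = max(right_edge, g.end)
        for chain in chains:
            if len(chain) >= 2:
                cid = next_cluster_id
                next_cluster_id += 1
                calls.extend(
                    LocusCall(g.gene_id, g.seq_id, "clustered", cid) for g in chain
                )
            else:
                calls.append(LocusCall(chain[0].gene_id, chain[0].seq_id, "singleton"))
    return calls


def locus_summary(calls: Iterable[LocusCall]) -> dict[str, float | int]:
    """Counts and percentages of clustered/singleton among mapped genes.

    Percentages use the mapped denominator (unmapped genes excluded), at
    2 decimals, half-up.  An all-unmapped input yields zero denominators and
    no percentage entries.
    """
    counts = {s: 0 for s in STATUSES}
    for c in calls:
        counts[c.status] += 1
    mapped = counts["clustered"] + counts["singleton"]
    summary: dict[str, float | int] = {
        "clustered": counts["clustered"],
        "singleton": counts["singleton"],
        "unmapped": counts["unmapped"],
        "mapped_total": mapped,
        "total": mapped + counts["unmapped"],
    }
    if mapped > 0:
        summary["clustered_pct"] = percent(counts["clustered"], mapped)
        summary["singleton_pct"] = percent(counts["singleton"], mapped)
    return summary


def locus_summary_by_seq(
    calls: Iterable[LocusCall],
) -> dict[str, dict[str, float | int]]:
    """Per-chromosome summaries (unmapped genes grouped under their seq_id)."""
    by_seq: dict[str, list[LocusCall]] = {}
    for c in calls:
        by_seq.setdefault(c.seq_id, []).append(c)
    return {seq_id: locus_summary(group) for seq_id, group in sorted(by_seq.items())}
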