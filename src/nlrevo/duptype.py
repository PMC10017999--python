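"""Duplication-origin typing of NLR genes from homology and gene order.

Every chromosome-mapped NLR gene receives exactly one duplication type with
precedence WGD/segmental > tandem > proximal > dispersed > singleton:

* ``wgd_segmental`` — the gene sits in a collinear (syntenic) block pair;
* ``tandem``        — a paralog at gene-rank distance 1 on the same sequence;
* ``proximal``      — a paralog within a small rank distance (default <= 10);
* ``dispersed``     — a paralog elsewhere in the genome;
* ``singleton``     — no paralog passes the homology threshold.

Ranks are 0-based positions among ALL genes on a sequence (not only NLRs).
Collinear blocks are chained by longest-chain dynamic programming over
homology dots in rank space, both orientations, with a bounded per-step rank
gap — the gene-order collinearity model popularised by MCScanX.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from nlrevo.classify import percent
from nlrevo.io import GeneModel, HomologyPair

log = logging.getLogger(__name__)

DEFAULT_MIN_BLOCK_PAIRS = 5
DEFAULT_MAX_GAP_RANKS = 25
DEFAULT_PROXIMAL_MAX_RANK_GAP = 10
DEFAULT_HOMOLOGY_E = 1e-10
DEFAULT_HOMOLOGY_IDENTITY = 30.0

DUP_TYPES = ("singleton", "dispersed", "proximal", "tandem", "wgd_segmental")


@dataclass(frozen=True)
class GeneRank:
    gene_id: str
    seq_id: str
    rank: int


@dataclass
class CollinearBlock:
    block_id: int
    seq_a: str
    seq_b: str
    orientation: str  # "+" same direction, "-" inverted
    pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def genes(self) -> set[str]:
        return {g for pair in self.pairs for g in pair}


@dataclass(frozen=True)
class DuplicationCall:
    gene_id: str
    dup_type: str


def rank_genome(all_genes: Iterable[GeneModel]) -> dict[str, GeneRank]:
    """0-based gene order per seq_id by start (ties: end, then gene_id).

    Genes on unplaced scaffolds are excluded: rank space is chromosomal.
    """
    by_seq: dict[str, list[GeneModel]] = {}
    for g in all_genes:
        if g.is_chromosome:
            by_seq.setdefault(g.seq_id, []).append(g)
    ranks: dict[str, GeneRank] = {}
    for seq_id, genes in by_seq.items():
        genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        for i, g in enumerate(genes):
            ranks[g.gene_id] = GeneRank(g.gene_id, seq_id, i)
    return ranks


def _dots_for_seq_pair(
    pairs: Sequence[HomologyPair], ranks: Mapping[str, GeneRank]
) -> dict[tuple[str, str], list[tuple[int, int, str, str]]]:
    """Group homology dots (x-rank, y-rank, gene_x, gene_y) per seq_id pair."""
    grouped: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for p in pairs:
        ra, rb = ranks.get(p.gene_a), ranks.get(p.gene_b)
        if ra is None or rb is None:
            log.warning("homology pair (%s, %s) references unranked gene; skipped",
                        p.gene_a, p.gene_b)
            continue
        if (ra.seq_id, ra.rank) <= (rb.seq_id, rb.rank):
            x, y = ra, rb
        else:
            x, y = rb, ra
        grouped.setdefault((x.seq_id, y.seq_id), []).append(
            (x.rank, y.rank, x.gene_id, y.gene_id)
        )
    return grouped


def _longest_chain(
    dots: list[tuple[int, int, str, str]], max_gap: int, sign: int
) -> list[int]:
    """Indices of the longest chain; x strictly increasing, y strictly
    monotone with the given sign, per-step gaps <= max_gap on both axes.
    Ties resolve to the leftmost (smallest coordinates) chain."""
    order = sorted(range(len(dots)), key=lambda i: (dots[i][0], sign * dots[i][1]))
    dp = [1] * len(dots)
    prev = [-1] * len(dots)
    for oi, i in enumerate(order):
        xi, yi = dots[i][0], dots[i][1]
        for j in order[:oi]:
            xj, yj = dots[j][0], dots[j][1]
            dx, dy = xi - xj, sign * (yi - yj)
            if 1 <= dx <= max_gap and 1 <= dy <= max_gap and dp[j] + 1 > dp[i]:
                dp[i] = dp[j] + 1
                prev[i] = j
            elif (
                1 <= dx <= max_gap and 1 <= dy <= max_gap
                and dp[j] + 1 == dp[i] and prev[i] != -1
                and (dots[j][0], sign * dots[j][1])
                < (dots[prev[i]][0], sign * dots[prev[i]][1])
            ):
                prev[i] = j
    if not dots:
        return []
    best = max(range(len(dots)), key=lambda i: (dp[i], (-dots[i][0], -sign * dots[i][1])))
    chain = []
    while best != -1:
        chain.append(best)
        best = prev[best]
    return chain[::-1]


def chain_collinear_blocks(
    pairs: Sequence[HomologyPair],
    ranks: Mapping[str, GeneRank],
    min_block_pairs: int = DEFAULT_MIN_BLOCK_PAIRS,
    max_gap_ranks: int = DEFAULT_MAX_GAP_RANKS,
) -> list[CollinearBlock]:
    """Greedy extraction of collinear blocks per seq_id pair.

    The longest chain (forward or inverted) is peeled off repeatedly until
    no chain reaches ``min_block_pairs``; each homology dot joins at most
    one block.
    """
    blocks: list[CollinearBlock] = []
    next_id = 1
    for (seq_a, seq_b), dots in sorted(_dots_for_seq_pair(pairs, ranks).items()):
        if seq_a == seq_b:
            # local (tandem/proximal) anchors are not syntenic evidence and
            # would self-chain inside large arrays
            dots = [d for d in dots if abs(d[1] - d[0]) > max_gap_ranks]
        remaining = sorted(set(dots))
        while remaining:
            fwd = _longest_chain(remaining, max_gap_ranks, sign=+1)
            rev = _longest_chain(remaining, max_gap_ranks, sign=-1)
            chain, sign = (fwd, "+") if len(fwd) >= len(rev) else (rev, "-")
            if len(chain) < min_block_pairs:
                break
            block = CollinearBlock(next_id, seq_a, seq_b, sign,
                                   [(remaining[i][2], remaining[i][3]) for i in chain])
            next_id += 1
            blocks.append(block)
            used = set(chain)
            remaining = [d for i, d in enumerate(remaining) if i not in used]
    return blocks


def classify_duplications(
    nlr_genes: Sequence[GeneModel],
    pairs: Sequence[HomologyPair],
    ranks: Mapping[str, GeneRank],
    blocks: Sequence[CollinearBlock],
    proximal_max_rank_gap: int = DEFAULT_PROXIMAL_MAX_RANK_GAP,
    homology_e: float = DEFAULT_HOMOLOGY_E,
    homology_identity: float = DEFAULT_HOMOLOGY_IDENTITY,
) -> list[DuplicationCall]:
    """One duplication type per chromosome-mapped NLR gene of one species.

    Paralogy requires a homology edge at E <= homology_e and identity >=
    homology_identity between two genes of this genome (both ranked).
    """
    block_genes: set[str] = set()
    for b in blocks:
        block_genes |= b.genes

    neighbors: dict[str, list[GeneRank]] = {}
    for p in pairs:
        if p.e_value > homology_e or p.identity < homology_identity:
            continue
        ra, rb = ranks.get(p.gene_a), ranks.get(p.gene_b)
        if ra is None or rb is None:
            continue
        neighbors.setdefault(p.gene_a, []).append(rb)
        neighbors.setdefault(p.gene_b, []).append(ra)

    calls: list[DuplicationCall] = []
    for g in nlr_genes:
        if not g.is_chromosome:
            continue
        if g.gene_id in block_genes:
            calls.append(DuplicationCall(g.gene_id, "wgd_segmental"))
            continue
        own = ranks.get(g.gene_id)
        paralogs = neighbors.get(g.gene_id, [])
        same_seq_dists = [
            abs(pr.rank - own.rank)
            for pr in paralogs
            if own is not None and pr.seq_id == own.seq_id
        ]
        if any(d == 1 for d in same_seq_dists):
            dup_type = "tandem"
        elif any(2 <= d <= proximal_max_rank_gap for d in same_seq_dists):
            dup_type = "proximal"
        elif paralogs:
            dup_type = "dispersed"
        else:
            dup_type = "singleton"
        calls.append(DuplicationCall(g.gene_id, dup_type))
    return calls


def duplication_summary(
    calls: Iterable[DuplicationCall] | Mapping[str, int],
    classified_total: int | None = None,
) -> dict[str, dict[str, float | int]]:
    """Counts and half-up percentages per duplication type.

    Accepts calls or pre-tallied ``{dup_type: count}``.
    """
    if isinstance(calls, Mapping):
        counts = dict(calls)
    else:
        counts = {}
        for c in calls:
            counts[c.dup_type] = counts.get(c.dup_type, 0) + 1
    total = sum(counts.values()) if classified_total is None else classified_total
    if total == 0:
        return {}
    return {
        t: {"count": counts.get(t, 0), "percent": percent(counts.get(t, 0), total)}
        for t in DUP_TYPES
    }
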