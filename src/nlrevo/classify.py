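"""NLR identification and subclass / architecture / motif classification.

A gene is an NLR candidate when it carries a significant NB-ARC (NBS) domain
hit.  Its domain architecture is the N-to-C order of hits over the alphabet
{C, T, R, N, L} (CC, TIR, RPW8, NB-ARC, LRR), with overlapping same-domain
hits merged and consecutive repeats collapsed.  The subclass follows the
N-terminal domain: RPW8 -> RNL, else TIR -> TNL, else CNL (a coiled-coil is
never required for CNL membership because CC domains are under-annotated by
profile scans).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from nlrevo.errors import UsageError, ValidationError
from nlrevo.io import DomainHit, HomologyPair

DEFAULT_E_THRESHOLD = 1e-4
DEFAULT_BLAST_E_THRESHOLD = 1.0

DOMAIN_LETTER = {"CC": "C", "TIR": "T", "RPW8": "R", "NB-ARC": "N", "LRR": "L"}

SUBCLASSES = ("CNL", "TNL", "RNL")

#: Degenerate patterns for the four conserved NB-ARC motifs.  Published
#: sequence logos give consensus residues, not exact strings, so these are
#: configurable defaults.
DEFAULT_MOTIFS: dict[str, str] = {
    "P-loop": "G..GKT[TS]",
    "Kinase-2": "[LIVM][LIVM]DD",
    "RNBS-B": "[GS]R..[LIVM]",
    "GLPL": "GLPL",
}

_AA = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYXBZJUO*\-]+$")


@dataclass(frozen=True)
class MotifPattern:
    """A named degenerate amino-acid pattern (fixed letters, '.', '[..]')."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValidationError(f"motif {self.name}: empty pattern")


@dataclass
class NLRAnnotation:
    """Classification result for one NLR gene."""

    gene_id: str
    subclass: str
    architecture: str
    motif_presence: dict[str, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "N" not in self.architecture:
            raise ValidationError(
                f"{self.gene_id}: architecture {self.architecture!r} lacks NBS"
            )
        if self.subclass not in SUBCLASSES:
            raise ValidationError(f"{self.gene_id}: bad subclass {self.subclass}")


def filter_nbs_genes(
    hits: Iterable[DomainHit], e_threshold: float = DEFAULT_E_THRESHOLD
) -> set[str]:
    """Genes with at least one NB-ARC hit at E-value <= threshold."""
    if e_threshold <= 0:
        raise UsageError("e_threshold must be positive")
    return {
        h.gene_id
        for h in hits
        if h.domain == "NB-ARC" and h.e_value <= e_threshold
    }


def expand_candidates_by_homology(
    confirmed: set[str],
    pairs: Iterable[HomologyPair],
    hits: Iterable[DomainHit],
    blast_e_threshold: float = DEFAULT_BLAST_E_THRESHOLD,
    e_threshold: float = DEFAULT_E_THRESHOLD,
) -> set[str]:
    """Second-pass candidate expansion through a homology table.

    Any gene hitting a confirmed NLR at E <= ``blast_e_threshold`` is
    re-checked for a significant NB-ARC hit; genes without one are dropped,
    so the returned set still satisfies the NB-ARC requirement.
    """
    hits = list(hits)
    candidates = set(confirmed)
    for p in pairs:
        if p.e_value > blast_e_threshold:
            continue
        if p.gene_a in confirmed:
            candidates.add(p.gene_b)
        if p.gene_b in confirmed:
            candidates.add(p.gene_a)
    verified = filter_nbs_genes(hits, e_threshold)
    return candidates & verified | confirmed


def _merge_same_domain(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Merge overlapping (>=1 aa) hits of the same domain into one interval."""
    merged: list[DomainHit] = []
    # tie on start -> longer hit first
    for h in sorted(hits, key=lambda h: (h.ali_start, -(h.ali_end - h.ali_start))):
        if (
            merged
            and merged[-1].domain == h.domain
            and h.ali_start <= merged[-1].ali_end
        ):
            prev = merged[-1]
            merged[-1] = DomainHit(
                gene_id=prev.gene_id,
                domain=prev.domain,
                ali_start=prev.ali_start,
                ali_end=max(prev.ali_end, h.ali_end),
                e_value=min(prev.e_value, h.e_value),
            )
        else:
            merged.append(h)
    return merged


def resolve_architecture(hits: Iterable[DomainHit]) -> str:
    """Domain-architecture string of one gene, N-to-C, repeats collapsed.

    Domains outside the controlled vocabulary are ignored.  Requires an
    NB-ARC hit (callers filter first).
    """
    relevant = [h for h in hits if h.domain in DOMAIN_LETTER]
    if not any(h.domain == "NB-ARC" for h in relevant):
        raise ValidationError("resolve_architecture requires an NB-ARC hit")
    per_domain: dict[str, list[DomainHit]] = {}
    for h in relevant:
        per_domain.setdefault(h.domain, []).append(h)
    merged: list[DomainHit] = []
    for dom_hits in per_domain.values():
        merged.extend(_merge_same_domain(dom_hits))
    merged.sort(key=lambda h: (h.ali_start, -(h.ali_end - h.ali_start)))
    letters: list[str] = []
    for h in merged:
        letter = DOMAIN_LETTER[h.domain]
        if not letters or letters[-1] != letter:
            letters.append(letter)
    return "".join(letters)


def assign_subclass(architecture: str) -> str:
    """Subclass by N-terminal signal, priority RPW8 > TIR > CC/none."""
    if "R" in architecture:
        return "RNL"
    if "T" in architecture:
        return "TNL"
    return "CNL"


def compile_motifs(patterns: Mapping[str, str] | None = None) -> list[MotifPattern]:
    table = DEFAULT_MOTIFS if patterns is None else patterns
    return [MotifPattern(name, pat) for name, pat in table.items()]


def scan_motifs(
    nbs_sequence: str, patterns: Sequence[MotifPattern]
) -> dict[str, int | None]:
    """First-match position (1-based) of each motif, or None when absent."""
    if nbs_sequence and not _AA.match(nbs_sequence):
        raise ValidationError("sequence contains non-amino-acid characters")
    presence: dict[str, int | None] = {}
    for motif in patterns:
        m = re.search(motif.pattern, nbs_sequence)
        presence[motif.name] = (m.start() + 1) if m else None
    return presence


def classify_genes(
    hits: Iterable[DomainHit],
    e_threshold: float = DEFAULT_E_THRESHOLD,
    sequences: Mapping[str, str] | None = None,
    motifs: Sequence[MotifPattern] | None = None,
) -> list[NLRAnnotation]:
    """Full classification of all genes passing the NB-ARC filter.

    When protein ``sequences`` are supplied, motifs are scanned inside the
    best NB-ARC region of each gene.
    """
    all_hits = list(hits)
    kept = filter_nbs_genes(all_hits, e_threshold)
    by_gene: dict[str, list[DomainHit]] = {}
    for h in all_hits:
        if h.gene_id in kept:
            by_gene.setdefault(h.gene_id, []).append(h)
    motif_patterns = compile_motifs() if motifs is None else list(motifs)
    annotations = []
    for gene_id in sorted(by_gene):
        arch = resolve_architecture(by_gene[gene_id])
        presence: dict[str, int | None] = {}
        if sequences is not None and gene_id in sequences:
            from nlrevo.phylo import extract_nbs_region

            region = extract_nbs_region(
                sequences[gene_id], by_gene[gene_id], min_length=1
            )
            if region is not None:
                presence = scan_motifs(region, motif_patterns)
        annotations.append(
            NLRAnnotation(
                gene_id=gene_id,
                subclass=assign_subclass(arch),
                architecture=arch,
                motif_presence=presence,
            )
        )
    return annotations


def percent(count: int, total: int) -> float:
    """Half-up percentage at 2 decimals (decimal arithmetic, not binary)."""
    if total == 0:
        raise ZeroDivisionError("percentage of empty total")
    value = Decimal(count) * 100 / Decimal(total)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_composition(
    annotations: Iterable[NLRAnnotation] | Mapping[str, int],
    total_count: int | None = None,
) -> dict[str, dict[str, float | int]]:
    """Per-subclass counts and half-up percentages (composition table rows).

    Accepts either annotations or pre-tallied ``{subclass: count}``.
    """
    if isinstance(annotations, Mapping):
        counts = dict(annotations)
    else:
        counts = {}
        for a in annotations:
            counts[a.subclass] = counts.get(a.subclass, 0) + 1
    total = sum(counts.values()) if total_count is None else total_count
    if total != sum(counts.values()):
        raise ValidationError(
            f"total_count {total} != sum of subclass counts {sum(counts.values())}"
        )
    if total == 0:
        return {}
    return {
        subclass: {"count": counts.get(subclass, 0),
                   "percent": percent(counts.get(subclass, 0), total)}
        for subclass in SUBCLASSES
    }
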