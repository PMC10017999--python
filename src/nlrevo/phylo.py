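"""NBS-domain phylogenies at desk scale.

The NBS (NB-ARC) region of each NLR protein is cut out at its domain-hit
coordinates, pairwise p-distances are computed over equal-length (aligned or
indel-free) sequences, and an unrooted tree is built by neighbor joining
with deterministic tie-breaking.  Rooting is midpoint or by outgroup.

Maximum-likelihood inference, substitution-model distances and multiple
alignment are deliberately not implemented; real data enters as pre-aligned
FASTA.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from skbio import DistanceMatrix

from nlrevo.errors import UsageError, ValidationError
from nlrevo.io import DomainHit

DEFAULT_MIN_NBS_LENGTH = 80


def extract_nbs_region(
    sequence: str,
    hits: Iterable[DomainHit],
    min_length: int = DEFAULT_MIN_NBS_LENGTH,
) -> str | None:
    """Substring of the best-E NB-ARC hit; None when shorter than min_length.

    Ties on E-value go to the longer hit, then the earlier one.
    """
    nbs_hits = [h for h in hits if h.domain == "NB-ARC"]
    if not nbs_hits:
        raise ValidationError("extract_nbs_region requires an NB-ARC hit")
    best = min(
        nbs_hits, key=lambda h: (h.e_value, -(h.ali_end - h.ali_start), h.ali_start)
    )
    if best.ali_end > len(sequence):
        raise ValidationError(
            f"NB-ARC hit end {best.ali_end} beyond sequence length {len(sequence)}"
        )
    region = sequence[best.ali_start - 1 : best.ali_end]
    if len(region) < min_length:
        return None
    return region


def p_distance_matrix(sequences: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise p-distances (mismatches / compared sites, gaps deleted pairwise).

    All sequences must have equal length; unaligned input of unequal lengths
    is rejected with a pointer to supply an alignment.
    """
    labels = sorted(sequences)
    lengths = {len(sequences[k]) for k in labels}
    if len(lengths) > 1:
        raise ValidationError(
            "sequences differ in length; supply an aligned FASTA "
            "(p-distances require positional homology)"
        )
    n = len(labels)
    arrays = [np.frombuffer(sequences[k].encode(), dtype="S1") for k in labels]
    gap = np.bytes_(b"-")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arrays[i] != gap) & (arrays[j] != gap)
            compared = int(ok.sum())
            if compared == 0:
                dist = 0.0
            else:
                dist = float((arrays[i][ok] != arrays[j][ok]).sum()) / compared
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids=labels)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Deterministic neighbor joining (Q criterion, Studier-Keppler updates).

    Ties in Q are broken by the lexicographically smallest pair of cluster
    labels (a cluster is labelled by its smallest leaf).  Negative branch
    lengths are clamped to zero.  The returned tree is unrooted (trifurcating
    seed node).
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise UsageError("neighbor joining requires at least 3 taxa")
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    nodes: dict[str, dendropy.Node] = {}
    for label in labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        nodes[label] = node

    d: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            d[(a, b)] = d[(b, a)] = float(dm[a, b])

    active = sorted(labels)
    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best_pair: tuple[str, str] | None = None
        best_q = np.inf
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (n - 2) * d[(a, b)] - r[a] - r[b]
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and (best_pair is None or (a, b) < best_pair)
                ):
                    best_q = q
                    best_pair = (a, b)
        a, b = best_pair  # type: ignore[misc]
        la = 0.5 * d[(a, b)] + (r[a] - r[b]) / (2 * (n - 2))
        lb = d[(a, b)] - la
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a].edge.length = max(0.0, la)
        nodes[b].edge.length = max(0.0, lb)
        new_label = min(a, b)  # cluster keyed by its smallest leaf label
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
            d[(new_label, c)] = d[(c, new_label)] = duc
        active = sorted(c for c in active if c not in (a, b))
        active.append(new_label)
        active.sort()
        nodes[new_label] = parent

    a, b, c = active
    la = max(0.0, 0.5 * (d[(a, b)] + d[(a, c)] - d[(b, c)]))
    lb = max(0.0, 0.5 * (d[(a, b)] + d[(b, c)] - d[(a, c)]))
    lc = max(0.0, 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)]))
    seed = dendropy.Node()
    for label, length in ((a, la), (b, lb), (c, lc)):
        seed.add_child(nodes[label])
        nodes[label].edge.length = length
    tree.seed_node = seed
    tree.is_rooted = False
    return tree


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def root_tree(
    tree: dendropy.Tree,
    method: str = "midpoint",
    outgroup_labels: Sequence[str] | None = None,
) -> dendropy.Tree:
    """Root an unrooted tree at the midpoint or on the outgroup edge.

    Outgroup rooting requires the outgroup labels to form one side of an
    edge of the unrooted tree (unrooted monophyly); otherwise an error
    lists the conflicting split.
    """
    rooted = tree.clone(depth=1)
    if method == "midpoint":
        rooted.reroot_at_midpoint(update_bipartitions=False)
    elif method == "outgroup":
        if not outgroup_labels:
            raise UsageError("outgroup rooting requires outgroup labels")
        wanted = frozenset(outgroup_labels)
        all_leaves = _leafset(rooted.seed_node)
        if not wanted <= all_leaves:
            raise ValidationError(
                f"outgroup labels not in tree: {sorted(wanted - all_leaves)}"
            )
        target = None
        for node in rooted.preorder_node_iter():
            if node is rooted.seed_node:
                continue
            below = _leafset(node)
            if below == wanted or (all_leaves - below) == wanted:
                target = node
                break
        if target is None:
            raise ValidationError(
                f"outgroup {sorted(wanted)} is not monophyletic in the "
                f"unrooted tree"
            )
        length = target.edge.length or 0.0
        rooted.reroot_at_edge(
            target.edge,
            length1=length / 2,
            length2=length / 2,
            update_bipartitions=False,
        )
    else:
        raise UsageError(f"unknown rooting method {method!r}")
    rooted.is_rooted = True
    return rooted


def build_rooted_gene_tree(
    sequences: Mapping[str, str],
    method: str = "midpoint",
    outgroup_labels: Sequence[str] | None = None,
) -> dendropy.Tree:
    """Distance tree from aligned sequences, rooted and ready to reconcile.

    Families of one or two genes have a unique (trivial) rooted topology and
    bypass neighbor joining.
    """
    labels = sorted(sequences)
    taxa = dendropy.TaxonNamespace(labels)
    if len(labels) == 1:
        tree = dendropy.Tree(taxon_namespace=taxa)
        tree.seed_node.taxon = taxa.get_taxon(labels[0])
        tree.is_rooted = True
        return tree
    if len(labels) == 2:
        dm = p_distance_matrix(sequences)
        tree = dendropy.Tree(taxon_namespace=taxa)
        half = float(dm[labels[0], labels[1]]) / 2
        for label in labels:
            child = dendropy.Node()
            child.taxon = taxa.get_taxon(label)
            tree.seed_node.add_child(child)
            child.edge.length = half
        tree.is_rooted = True
        return tree
    unrooted = neighbor_joining(p_distance_matrix(sequences))
    return root_tree(unrooted, method=method, outgroup_labels=outgroup_labels)
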