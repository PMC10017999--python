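"""Duplication-loss parsimony reconciliation of gene trees with a species tree.

Each gene-tree node is mapped to the most recent common ancestor (LCA, in
the species tree) of the species of its descendant leaves.  An internal node
is a duplication when its mapping coincides with that of one of its
children, otherwise a speciation.  Losses are read off the mapping-depth
difference along each gene-tree edge: for edge (p, c),

    losses = d(M(p), M(c)) - 1 + [p is duplication]       (0 when d = 0),

where d counts species-tree edges between the images; each loss is placed on
the off-path child branch of a species node traversed (starting at M(p)
itself when p is a duplication).  This LCA reconciliation minimises both
duplications and losses over all reconciliations.

Ancestral lineages at a focal species node (default: the root) are the
distinct gene copies inferred to exist in that ancestor: speciation nodes
mapping to the focal node, plus children of focal-mapped duplications whose
own mapping lies strictly below.  Gene families whose root maps below the
focal node contribute no ancestral lineage and are reported as post-root
gains (an origination on the branch they map to).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import dendropy

from nlrevo.classify import percent
from nlrevo.errors import ValidationError
from nlrevo.io import split_leaf_label

log = logging.getLogger(__name__)

DUPLICATION = "duplication"
SPECIATION = "speciation"


# ---------------------------------------------------------------------------
# Species-tree indexing
# ---------------------------------------------------------------------------

def branch_name(node: dendropy.Node) -> str:
    """Stable name for the branch above a species node.

    Named nodes keep their label; unnamed internal nodes are named by their
    sorted leaf labels joined with '+'.
    """
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    return "+".join(sorted(l.taxon.label for l in node.leaf_iter()))


class SpeciesIndex:
    """Parent/depth/LCA bookkeeping over a rooted binary species tree."""

    def __init__(self, species_tree: dendropy.Tree):
        self.tree = species_tree
        self.parent: dict[dendropy.Node, dendropy.Node | None] = {}
        self.depth: dict[dendropy.Node, int] = {}
        self.by_species: dict[str, dendropy.Node] = {}
        for node in species_tree.preorder_node_iter():
            parent = node.parent_node
            self.parent[node] = parent
            self.depth[node] = 0 if parent is None else self.depth[parent] + 1
            if node.is_leaf():
                if node.taxon is None:
                    raise ValidationError("species-tree leaf without a label")
                self.by_species[node.taxon.label] = node
        self.root = species_tree.seed_node

    def species(self) -> list[str]:
        return sorted(self.by_species)

    def lca(self, a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        while self.depth[a] > self.depth[b]:
            a = self.parent[a]
        while self.depth[b] > self.depth[a]:
            b = self.parent[b]
        while a is not b:
            a, b = self.parent[a], self.parent[b]
        return a

    def path_down(
        self, top: dendropy.Node, bottom: dendropy.Node
    ) -> list[dendropy.Node]:
        """Nodes from top to bottom inclusive (top must be an ancestor)."""
        path = [bottom]
        node = bottom
        while node is not top:
            node = self.parent[node]
            if node is None:
                raise ValidationError("path_down: top is not an ancestor of bottom")
            path.append(node)
        return path[::-1]

    def off_path_child(
        self, node: dendropy.Node, on_path: dendropy.Node
    ) -> dendropy.Node:
        children = node.child_nodes()
        off = [c for c in children if c is not on_path]
        if len(off) != 1:
            raise ValidationError("species tree must be binary for loss placement")
        return off[0]


def resolve_polytomies(tree: dendropy.Tree) -> dendropy.Tree:
    """Deterministically binarise: caterpillar by sorted leaf label, zero-length."""
    changed = False
    for node in list(tree.preorder_node_iter()):
        children = node.child_nodes()
        while len(children) > 2:
            changed = True
            children.sort(key=lambda c: min(l.taxon.label for l in c.leaf_iter()))
            a, b = children[0], children[1]
            joint = dendropy.Node()
            node.remove_child(a)
            node.remove_child(b)
            joint.add_child(a)
            joint.add_child(b)
            node.add_child(joint)
            joint.edge.length = 0.0
            children = node.child_nodes()
    if changed:
        log.warning("polytomies resolved deterministically (caterpillar, "
                    "zero-length edges)")
    return tree


# ---------------------------------------------------------------------------
# Reconciliation proper
# ---------------------------------------------------------------------------

@dataclass
class ReconciliationResult:
    gene_tree: dendropy.Tree
    index: SpeciesIndex
    M: dict[dendropy.Node, dendropy.Node]
    event: dict[dendropy.Node, str]
    losses: dict[str, int] = field(default_factory=dict)
    gains: dict[str, int] = field(default_factory=dict)

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.event.values() if e == DUPLICATION)

    @property
    def n_losses(self) -> int:
        return sum(self.losses.values())


def default_species_of_leaf(label: str) -> str:
    return split_leaf_label(label)[0]


def lca_map(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree | SpeciesIndex,
    species_of_leaf: Callable[[str], str] = default_species_of_leaf,
) -> ReconciliationResult:
    """LCA mapping and duplication/speciation labels for a rooted gene tree."""
    index = (
        species_tree
        if isinstance(species_tree, SpeciesIndex)
        else SpeciesIndex(resolve_polytomies(species_tree))
    )
    resolve_polytomies(gene_tree)
    M: dict[dendropy.Node, dendropy.Node] = {}
    event: dict[dendropy.Node, str] = {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            if node.taxon is None:
                raise ValidationError("gene-tree leaf without a label")
            species = species_of_leaf(node.taxon.label)
            target = index.by_species.get(species)
            if target is None:
                raise ValidationError(
                    f"leaf {node.taxon.label!r}: species {species!r} absent "
                    f"from the species tree"
                )
            M[node] = target
        else:
            children = node.child_nodes()
            image = M[children[0]]
            for c in children[1:]:
                image = index.lca(image, M[c])
            M[node] = image
            event[node] = (
                DUPLICATION
                if any(M[c] is image for c in children)
                else SPECIATION
            )
    result = ReconciliationResult(gene_tree, index, M, event)
    result.losses = count_losses(result)
    result.gains = _count_gains(result)
    return result


def count_losses(recon: ReconciliationResult) -> dict[str, int]:
    """Loss placements per species branch (keyed by the branch's child node)."""
    losses: dict[str, int] = {}
    index = recon.index
    for p in recon.gene_tree.preorder_internal_node_iter():
        is_dup = recon.event[p] == DUPLICATION
        for c in p.child_nodes():
            mp, mc = recon.M[p], recon.M[c]
            if mp is mc:
                continue  # zero depth difference: no losses on this edge
            path = index.path_down(mp, mc)
            # duplication: copy should persist from M(p) itself; speciation:
            # the split at M(p) accounts for both children, so only strictly
            # intermediate species nodes imply losses.
            start = 0 if is_dup else 1
            for k in range(start, len(path) - 1):
                off = index.off_path_child(path[k], path[k + 1])
                name = branch_name(off)
                losses[name] = losses.get(name, 0) + 1
    return losses


def _count_gains(recon: ReconciliationResult) -> dict[str, int]:
    """Duplication counts per species branch; root-mapped duplications are
    ancestral-lineage copies, not branch gains."""
    gains: dict[str, int] = {}
    for node, ev in recon.event.items():
        if ev != DUPLICATION:
            continue
        image = recon.M[node]
        if image is recon.index.root:
            continue
        name = branch_name(image)
        gains[name] = gains.get(name, 0) + 1
    return gains


# ---------------------------------------------------------------------------
# Ancestral lineages
# ---------------------------------------------------------------------------

@dataclass
class Lineage:
    lineage_id: int
    members: frozenset[str]  # gene-tree leaf labels
    species: frozenset[str]
    subclass: str | None = None


@dataclass
class LineagePartition:
    lineages: list[Lineage]
    #: gene subtrees whose mapping never reaches the focal node: list of
    #: (species-branch name of the origination, leaf labels)
    post_root_gains: list[tuple[str, frozenset[str]]] = field(default_factory=list)

    @property
    def n_lineages(self) -> int:
        return len(self.lineages)


def _leaf_labels(node: dendropy.Node) -> frozenset[str]:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def ancestral_lineages(
    recon: ReconciliationResult,
    focal: dendropy.Node | None = None,
    species_of_leaf: Callable[[str], str] = default_species_of_leaf,
    first_lineage_id: int = 1,
) -> LineagePartition:
    """Partition extant genes into copies present at the focal ancestor."""
    focal = recon.index.root if focal is None else focal
    root = recon.gene_tree.seed_node
    lineages: list[Lineage] = []
    post_root: list[tuple[str, frozenset[str]]] = []
    next_id = first_lineage_id

    def make_lineage(members: frozenset[str]) -> None:
        nonlocal next_id
        species = frozenset(species_of_leaf(m) for m in members)
        lineages.append(Lineage(next_id, members, species))
        next_id += 1

    def walk(node: dendropy.Node) -> None:
        """node maps to the focal species node."""
        if node.is_leaf():
            # a gene leaf mapping to the focal node is itself one copy
            make_lineage(_leaf_labels(node))
            return
        if recon.event[node] == SPECIATION:
            make_lineage(_leaf_labels(node))
            return
        for c in node.child_nodes():
            if recon.M[c] is focal:
                walk(c)
            else:
                make_lineage(_leaf_labels(c))

    if recon.M[root] is focal:
        walk(root)
    else:
        post_root.append((branch_name(recon.M[root]), _leaf_labels(root)))
    return LineagePartition(lineages, post_root)


def assign_lineage_subclasses(
    partition: LineagePartition,
    subclass_of_gene: Mapping[str, str],
    species_of_leaf: Callable[[str], str] = default_species_of_leaf,
) -> None:
    """Majority subclass of member genes; ties -> 'mixed' (in place)."""
    for lineage in partition.lineages:
        counts: dict[str, int] = {}
        for label in lineage.members:
            gene_id = label.split("|", 1)[1] if "|" in label else label
            sub = subclass_of_gene.get(gene_id) or subclass_of_gene.get(label)
            if sub:
                counts[sub] = counts.get(sub, 0) + 1
        if not counts:
            lineage.subclass = None
            continue
        top = max(counts.values())
        winners = [s for s, c in counts.items() if c == top]
        lineage.subclass = winners[0] if len(winners) == 1 else "mixed"


# ---------------------------------------------------------------------------
# Branch tallies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BranchEvents:
    gains: int
    losses: int

    @property
    def pattern(self) -> str:
        if self.gains > self.losses:
            return "expansion"
        if self.losses > self.gains:
            return "contraction"
        return "stable"


def tally_branch_events(
    recon: ReconciliationResult,
    extra_gains: Mapping[str, int] | None = None,
    extra_losses: Mapping[str, int] | None = None,
) -> dict[str, BranchEvents]:
    """Per-species-branch (gains, losses, pattern) for every non-root branch."""
    gains = dict(recon.gains)
    losses = dict(recon.losses)
    for extra, into in ((extra_gains, gains), (extra_losses, losses)):
        if extra:
            for k, v in extra.items():
                into[k] = into.get(k, 0) + v
    tally: dict[str, BranchEvents] = {}
    for node in recon.index.tree.preorder_node_iter():
        if node is recon.index.root:
            continue
        name = branch_name(node)
        tally[name] = BranchEvents(gains.get(name, 0), losses.get(name, 0))
    return tally


def family_event_summary(
    recon: ReconciliationResult,
    species_of_leaf: Callable[[str], str] = default_species_of_leaf,
) -> dict:
    """Root-lineage count plus per-branch gains/losses for one gene family.

    Originations (family root mapping below the species root) count as one
    gain on the branch they map to, so families never 'vanish' from the
    trajectory.
    """
    partition = ancestral_lineages(recon, species_of_leaf=species_of_leaf)
    gains = dict(recon.gains)
    for branch, _members in partition.post_root_gains:
        gains[branch] = gains.get(branch, 0) + 1
    return {
        "lineages": partition.n_lineages,
        "gains": gains,
        "losses": dict(recon.losses),
    }


def root_by_duplication_loss(
    unrooted_tree: dendropy.Tree,
    species_index: SpeciesIndex,
    species_of_leaf: Callable[[str], str] = default_species_of_leaf,
) -> dendropy.Tree:
    """Root an unrooted gene tree where the duplication+loss cost is minimal.

    Every edge is tried as a root position; the cheapest reconciliation wins.
    Ties prefer the midpoint rooting when it attains the minimum (the clock
    signal breaks parsimony ties), else the first minimal edge in a
    deterministic traversal.  This mirrors how reconciliation tools infer a
    root when handed unrooted gene trees.
    """
    leaves = [l for l in unrooted_tree.leaf_node_iter()]
    if len(leaves) < 3:
        rooted = unrooted_tree.clone(depth=1)
        rooted.is_rooted = True
        return rooted

    def cost_of(tree: dendropy.Tree) -> int:
        recon = lca_map(tree.clone(depth=1), species_index, species_of_leaf)
        return recon.n_duplications + recon.n_losses

    candidates: list[dendropy.Tree] = []
    base = unrooted_tree.clone(depth=1)
    nodes = [n for n in base.preorder_node_iter() if n is not base.seed_node]
    for i in range(len(nodes)):
        work = unrooted_tree.clone(depth=1)
        work_nodes = [
            n for n in work.preorder_node_iter() if n is not work.seed_node
        ]
        node = work_nodes[i]
        length = node.edge.length or 0.0
        work.reroot_at_edge(
            node.edge, length1=length / 2, length2=length / 2,
            update_bipartitions=False,
        )
        work.is_rooted = True
        candidates.append(work)

    costs = [cost_of(t) for t in candidates]
    best = min(costs)
    from nlrevo.phylo import root_tree  # local import avoids a cycle

    midpoint = root_tree(unrooted_tree, method="midpoint")
    if cost_of(midpoint) == best:
        return midpoint
    return candidates[costs.index(best)]


def lineage_presence_summary(
    partition: LineagePartition, species: Sequence[str]
) -> dict:
    """Shared/specific lineage tallies over a (possibly pooled) partition."""
    per_species_inherited = {s: 0 for s in species}
    by_k: dict[int, int] = {}
    specific_by_species = {s: 0 for s in species}
    for lineage in partition.lineages:
        k = len(lineage.species)
        by_k[k] = by_k.get(k, 0) + 1
        for s in lineage.species:
            per_species_inherited[s] += 1
        if k == 1:
            (only,) = lineage.species
            specific_by_species[only] += 1
    total = partition.n_lineages
    specific_total = by_k.get(1, 0)
    shared_total = total - specific_total
    summary = {
        "total_lineages": total,
        "inherited": per_species_inherited,
        "by_species_count": dict(sorted(by_k.items())),
        "species_specific": specific_by_species,
        "specific_total": specific_total,
        "shared_total": shared_total,
    }
    if total:
        summary["specific_pct"] = percent(specific_total, total)
        summary["shared_pct"] = percent(shared_total, total)
    return summary


def pool_partitions(partitions: Iterable[LineagePartition]) -> LineagePartition:
    """Pool per-family partitions into one, renumbering lineage ids."""
    pooled = LineagePartition([], [])
    next_id = 1
    for part in partitions:
        for lineage in part.lineages:
            pooled.lineages.append(
                Lineage(next_id, lineage.members, lineage.species, lineage.subclass)
            )
            next_id += 1
        pooled.post_root_gains.extend(part.post_root_gains)
    return pooled
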