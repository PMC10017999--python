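"""Exhaustive duplication-loss reconciliation by mapping enumeration.

Independent oracle for the parsimony reconciler: every valid gene-to-species
mapping (each internal gene node assigned to an ancestor-or-self of the LCA
of its children's images) is enumerated, its duplication and loss events are
counted from first principles, and the cheapest mapping is returned.  On
small instances this is exact by construction; it deliberately shares no
code with :mod:`nlrevo.reconcile`, and the synthetic-data generator uses it
to project ground-truth histories onto their parsimony-visible part.

Only suitable for small trees (the mapping space grows exponentially).
"""

from __future__ import annotations

from typing import Callable

import dendropy

from nlrevo.errors import ValidationError
from nlrevo.io import split_leaf_label


def _species_maps(species_tree: dendropy.Tree):
    parent: dict = {}
    depth: dict = {}
    name: dict = {}
    leaves: dict[str, dendropy.Node] = {}
    for node in species_tree.preorder_node_iter():
        parent[node] = node.parent_node
        depth[node] = 0 if node.parent_node is None else depth[node.parent_node] + 1
        if node.is_leaf():
            leaves[node.taxon.label] = node
            name[node] = node.taxon.label
        else:
            name[node] = (
                node.label
                or "+".join(sorted(l.taxon.label for l in node.leaf_iter()))
            )
    return parent, depth, name, leaves


def _ancestors_or_self(node, parent):
    out = []
    while node is not None:
        out.append(node)
        node = parent[node]
    return out


def _lca(a, b, parent, depth):
    while depth[a] > depth[b]:
        a = parent[a]
    while depth[b] > depth[a]:
        b = parent[b]
    while a is not b:
        a, b = parent[a], parent[b]
    return a


def _is_ancestor_or_self(anc, node, parent) -> bool:
    while node is not None:
        if node is anc:
            return True
        node = parent[node]
    return False


def brute_force_reconcile(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    species_of_leaf: Callable[[str], str] | None = None,
) -> dict:
    """Minimum duplication+loss reconciliation by exhaustive enumeration.

    Returns a dict with ``duplications``, ``losses``, ``cost``, ``lineages``
    (copies at the species root under the optimal mapping), per-branch
    ``gains`` and ``losses_by_branch``, where originations (gene root mapped
    below the species root) add one gain on their branch.
    """
    if species_of_leaf is None:
        species_of_leaf = lambda label: split_leaf_label(label)[0]
    parent, depth, name, leaves = _species_maps(species_tree)
    root_s = species_tree.seed_node

    gene_nodes = list(gene_tree.postorder_node_iter())
    internal = [g for g in gene_nodes if not g.is_leaf()]
    fixed: dict = {}
    for g in gene_nodes:
        if g.is_leaf():
            sp = species_of_leaf(g.taxon.label)
            if sp not in leaves:
                raise ValidationError(f"unknown species {sp!r} in gene tree")
            fixed[g] = leaves[sp]

    best: dict | None = None

    def evaluate(mapping: dict) -> dict:
        dups = 0
        gains: dict[str, int] = {}
        losses_by_branch: dict[str, int] = {}
        n_losses = 0
        for g in internal:
            children = g.child_nodes()
            mg = mapping[g]
            child_images = [mapping[c] for c in children]
            # speciation only when both child images descend through
            # distinct children of the image node
            is_dup = True
            if all(ci is not mg for ci in child_images):
                sides = []
                for ci in child_images:
                    node = ci
                    while parent[node] is not mg:
                        node = parent[node]
                    sides.append(node)
                if len(children) == 2 and sides[0] is not sides[1]:
                    is_dup = False
            if is_dup:
                dups += 1
                if mg is not root_s:
                    gains[name[mg]] = gains.get(name[mg], 0) + 1
            for c, mc in zip(children, child_images):
                # distance and loss placement along the species path
                path = [mc]
                node = mc
                while node is not mg:
                    node = parent[node]
                    path.append(node)
                path.reverse()
                start = 0 if is_dup else 1
                for k in range(start, len(path) - 1):
                    off = [
                        ch for ch in path[k].child_nodes() if ch is not path[k + 1]
                    ]
                    for o in off:
                        losses_by_branch[name[o]] = (
                            losses_by_branch.get(name[o], 0) + 1
                        )
                        n_losses += 1

        # copies present at the species root under this mapping
        def lineages_below(g) -> int:
            if mapping[g] is not root_s:
                return 1
            if g.is_leaf():
                return 1
            children = g.child_nodes()
            child_images = [mapping[c] for c in children]
            dup_here = any(ci is mapping[g] for ci in child_images) or not _spec_ok(
                g, mapping
            )
            if not dup_here:
                return 1
            return sum(
                lineages_below(c) if mapping[c] is root_s else 1 for c in children
            )

        def _spec_ok(g, mapping) -> bool:
            mg = mapping[g]
            child_images = [mapping[c] for c in g.child_nodes()]
            if any(ci is mg for ci in child_images):
                return False
            sides = []
            for ci in child_images:
                node = ci
                while parent[node] is not mg:
                    node = parent[node]
                sides.append(node)
            return len(sides) == 2 and sides[0] is not sides[1]

        groot = gene_tree.seed_node
        if mapping[groot] is root_s:
            n_lineages = lineages_below(groot)
        else:
            n_lineages = 0
            gains[name[mapping[groot]]] = gains.get(name[mapping[groot]], 0) + 1
        return {
            "duplications": dups,
            "losses": n_losses,
            "cost": dups + n_losses,
            "lineages": n_lineages,
            "gains": gains,
            "losses_by_branch": losses_by_branch,
        }

    mapping: dict = dict(fixed)

    def assign(i: int) -> None:
        nonlocal best
        if i == len(internal):
            result = evaluate(mapping)
            if best is None or result["cost"] < best["cost"]:
                best = result
            return
        g = internal[i]
        images = [mapping[c] for c in g.child_nodes()]
        low = images[0]
        for im in images[1:]:
            low = _lca(low, im, parent, depth)
        for candidate in _ancestors_or_self(low, parent):
            mapping[g] = candidate
            assign(i + 1)
        del mapping[g]

    if not internal:
        # single-leaf gene tree
        mapping = dict(fixed)
        return evaluate(mapping)
    assign(0)
    assert best is not None
    return best
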