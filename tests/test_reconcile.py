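import numpy as np
import pytest

from nlrevo import io, reconcile
from nlrevo._bruteforce import brute_force_reconcile
from nlrevo.errors import ValidationError


SPECIES_3 = "((A:1,B:1)AB:1,C:2)R;"


def recon_of(gene_newick, species_newick=SPECIES_3):
    return reconcile.lca_map(io.tree_from_string(gene_newick),
                             io.tree_from_string(species_newick))


def random_instance(rng, max_gene_leaves=6, max_species=4):
    """Random species tree and random gene tree labelled with its species."""
    k = int(rng.integers(2, max_species + 1))
    species = [chr(ord("A") + i) for i in range(k)]

    def random_topology(labels):
        if len(labels) == 1:
            return labels[0]
        idx = rng.permutation(len(labels))
        cut = int(rng.integers(1, len(labels)))
        left = [labels[i] for i in idx[:cut]]
        right = [labels[i] for i in idx[cut:]]
        return f"({random_topology(left)}:1,{random_topology(right)}:1)"

    species_newick = random_topology(species) + ";"
    n = int(rng.integers(1, max_gene_leaves + 1))
    leaves = [f"{rng.choice(species)}|g{i}" for i in range(n)]
    gene_newick = random_topology(leaves) + ";"
    return gene_newick, species_newick


class TestLcaMap:
    def test_congruent_tree_all_speciations(self):
        recon = recon_of("((A|a:1,B|b:1):1,C|c:1);")
        assert recon.n_duplications == 0
        assert recon.n_losses == 0
        assert all(e == reconcile.SPECIATION for e in recon.event.values())

    def test_worked_example_root_duplication(self):
        recon = recon_of("((A|a1:1,B|b1:1):1,(A|a2:1,C|c1:1):1);")
        root = recon.gene_tree.seed_node
        assert recon.M[root] is recon.index.root
        assert recon.event[root] == reconcile.DUPLICATION
        assert recon.n_duplications == 1
        assert recon.losses == {"B": 1, "C": 1}

    def test_single_leaf_gene_tree(self):
        recon = recon_of("A|only:1;")
        assert recon.event == {} and recon.losses == {}

    def test_within_species_duplication_gains_terminal_branch(self):
        recon = reconcile.lca_map(
            io.tree_from_string("((A|a1:1,A|a2:1):1,B|b1:1);"),
            io.tree_from_string("(A:1,B:1)R;"),
        )
        assert recon.gains == {"A": 1}
        assert recon.n_losses == 0

    def test_unknown_species_named_in_error(self):
        with pytest.raises(ValidationError, match="Zz"):
            recon_of("(Zz|g1:1,A|g2:1);")

    def test_rotation_invariance(self):
        left = recon_of("((A|a1:1,B|b1:1):1,(A|a2:1,C|c1:1):1);")
        right = recon_of("((C|c1:1,A|a2:1):1,(B|b1:1,A|a1:1):1);")
        assert left.n_duplications == right.n_duplications
        assert left.losses == right.losses
        assert left.gains == right.gains

    def test_duplication_with_equal_child_mapping_has_no_loss(self):
        # both children map to species leaf A: d = 0, formula gives 0
        recon = reconcile.lca_map(
            io.tree_from_string("(A|a1:1,A|a2:1);"),
            io.tree_from_string("(A:1,B:1)R;"),
        )
        assert recon.n_duplications == 1 and recon.n_losses == 0


class TestAncestralLineages:
    def test_congruent_single_copy_family(self):
        part = reconcile.ancestral_lineages(recon_of("((A|a:1,B|b:1):1,C|c:1);"))
        assert part.n_lineages == 1
        assert part.lineages[0].species == {"A", "B", "C"}

    def test_worked_example_two_lineages(self):
        part = reconcile.ancestral_lineages(
            recon_of("((A|a1:1,B|b1:1):1,(A|a2:1,C|c1:1):1);"))
        members = sorted(sorted(l.members) for l in part.lineages)
        assert members == [["A|a1", "B|b1"], ["A|a2", "C|c1"]]

    def test_single_species_family_is_post_root_gain(self):
        recon = reconcile.lca_map(
            io.tree_from_string("(A|a1:1,A|a2:1);"),
            io.tree_from_string("((A:1,B:1)AB:1,(C:1,D:1)CD:1)R;"),
        )
        part = reconcile.ancestral_lineages(recon)
        assert part.n_lineages == 0
        assert part.post_root_gains == [("A", frozenset({"A|a1", "A|a2"}))]
        summary = reconcile.family_event_summary(recon)
        assert summary["lineages"] == 0
        assert summary["gains"]["A"] == 2  # origination + in-branch duplication

    def test_majority_subclass_with_tie_mixed(self):
        part = reconcile.ancestral_lineages(
            recon_of("((A|a1:1,B|b1:1):1,(A|a2:1,C|c1:1):1);"))
        reconcile.assign_lineage_subclasses(
            part, {"a1": "CNL", "b1": "CNL", "a2": "TNL", "c1": "RNL"})
        by_members = {frozenset(l.members): l.subclass for l in part.lineages}
        assert by_members[frozenset({"A|a1", "B|b1"})] == "CNL"
        assert by_members[frozenset({"A|a2", "C|c1"})] == "mixed"


class TestBranchTallies:
    def test_congruent_family_all_stable(self):
        tally = reconcile.tally_branch_events(
            recon_of("((A|a:1,B|b:1):1,C|c:1);"))
        assert all(ev.pattern == "stable" for ev in tally.values())

    def test_worked_example_losses_only(self):
        tally = reconcile.tally_branch_events(
            recon_of("((A|a1:1,B|b1:1):1,(A|a2:1,C|c1:1):1);"))
        assert tally["B"].losses == 1 and tally["C"].losses == 1
        assert sum(ev.gains for ev in tally.values()) == 0
        assert tally["B"].pattern == "contraction"

    def test_expansion_pattern(self):
        assert reconcile.BranchEvents(3, 1).pattern == "expansion"
        assert reconcile.BranchEvents(1, 1).pattern == "stable"


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(4))
    def test_lca_matches_exhaustive_minimum(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            gene_newick, species_newick = random_instance(rng)
            recon = reconcile.lca_map(io.tree_from_string(gene_newick),
                                      io.tree_from_string(species_newick))
            oracle = brute_force_reconcile(io.tree_from_string(gene_newick),
                                           io.tree_from_string(species_newick))
            assert recon.n_duplications == oracle["duplications"]
            assert recon.n_losses == oracle["losses"]
            summary = reconcile.family_event_summary(recon)
            assert summary["lineages"] == oracle["lineages"]
            assert {k: v for k, v in summary["gains"].items() if v} == \
                {k: v for k, v in oracle["gains"].items() if v}
            assert {k: v for k, v in summary["losses"].items() if v} == \
                {k: v for k, v in oracle["losses_by_branch"].items() if v}


class TestLineagePresenceSummary:
    def _partition(self):
        lineages = []
        next_id = 1

        def add(n, species):
            nonlocal next_id
            for _ in range(n):
                members = frozenset(f"{s}|g{next_id}" for s in species)
                lineages.append(reconcile.Lineage(next_id, members,
                                                  frozenset(species)))
                next_id += 1

        # printed lineage-sharing structure: 89 species-specific of 183
        add(12, ["As"])
        add(36, ["Cs"])
        add(10, ["Ag"])
        add(31, ["Dc"])
        add(10, ["As", "Cs", "Ag", "Dc"])
        add(84, ["As", "Cs"])
        return reconcile.LineagePartition(lineages)

    def test_specific_and_shared_percentages(self):
        summary = reconcile.lineage_presence_summary(
            self._partition(), ["As", "Cs", "Ag", "Dc"])
        assert summary["total_lineages"] == 183
        assert summary["specific_total"] == 89
        assert summary["specific_pct"] == 48.63
        assert summary["shared_pct"] == 51.37
        assert summary["species_specific"] == {"As": 12, "Cs": 36,
                                               "Ag": 10, "Dc": 31}
        assert summary["by_species_count"][4] == 10

    def test_inherited_counts_count_membership(self):
        summary = reconcile.lineage_presence_summary(
            self._partition(), ["As", "Cs", "Ag", "Dc"])
        assert summary["inherited"]["As"] == 12 + 10 + 84
        assert summary["inherited"]["Dc"] == 31 + 10


class TestParsimonyRooting:
    @pytest.mark.parametrize("seed", range(4))
    def test_returns_minimal_cost_rooting(self, seed):
        rng = np.random.default_rng(100 + seed)
        gene_newick, species_newick = random_instance(rng, max_gene_leaves=6)
        unrooted = io.tree_from_string(gene_newick)
        if len(unrooted.leaf_nodes()) < 3:
            return
        unrooted.is_rooted = False
        index = reconcile.SpeciesIndex(io.tree_from_string(species_newick))
        rooted = reconcile.root_by_duplication_loss(unrooted, index)
        got = reconcile.lca_map(rooted.clone(depth=1), index)
        cost = got.n_duplications + got.n_losses
        # exhaustive check over all rootings
        best = min(
            (lambda r: r.n_duplications + r.n_losses)(
                reconcile.lca_map(t.clone(depth=1), index))
            for t in _all_rootings(unrooted)
        )
        assert cost == best


def _all_rootings(unrooted):
    out = []
    base = unrooted.clone(depth=1)
    n_nodes = sum(1 for n in base.preorder_node_iter()
                  if n is not base.seed_node)
    for i in range(n_nodes):
        work = unrooted.clone(depth=1)
        nodes = [n for n in work.preorder_node_iter()
                 if n is not work.seed_node]
        node = nodes[i]
        length = node.edge.length or 0.0
        work.reroot_at_edge(node.edge, length1=length / 2, length2=length / 2,
                            update_bipartitions=False)
        work.is_rooted = True
        out.append(work)
    return out


class TestResolvePolytomies:
    def test_caterpillar_resolution_is_binary_and_deterministic(self):
        tree = io.tree_from_string("(A|a:1,B|b:1,C|c:1,A|d:1);")
        resolved = reconcile.resolve_polytomies(tree)
        for node in resolved.preorder_internal_node_iter():
            assert len(node.child_nodes()) == 2
        again = reconcile.resolve_polytomies(
            io.tree_from_string("(A|a:1,B|b:1,C|c:1,A|d:1);"))
        assert resolved.as_string(schema="newick") == again.as_string(
            schema="newick")
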