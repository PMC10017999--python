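"""Fully-truthed synthetic datasets for the NLR evolution pipeline.

Gene families evolve along a rooted (default 4-taxon, ultrametric) species
tree by a per-branch birth-death process: on a branch entered by ``n0``
copies, Poisson(rate x n0) duplication and loss events are drawn at uniform
times and applied sequentially to a uniformly chosen extant copy.  Extinct
lineages are pruned for the observable gene tree; the parsimony-visible
("projected") event history is computed by the exhaustive brute-force
reconciliation oracle, never by the reconciler under test.

Proteins are concatenations of fixed per-domain prototype blocks (CC, TIR,
RPW8, NB-ARC, LRR) evolved by per-site substitutions proportional to edge
duration; NBS blocks are indel-free and equal-length by construction, so
p-distance phylogenies need no aligner.  Genomic placement plants tandem
arrays (adjacent gene ranks, gaps well inside the 250-kb cluster window),
proximal pairs (2-10 ranks apart), dispersed copies (different chromosomes
or >250 kb apart behind long filler runs) and a scaffold-bound fraction, and
records every planted label as ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np

from nlrevo._bruteforce import brute_force_reconcile
from nlrevo.errors import UsageError, ValidationError
from nlrevo.io import DomainHit, HomologyPair, leaf_label, tree_from_string, \
    write_domain_table, write_homology_table, write_newick
from nlrevo.reconcile import branch_name

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: 4-taxon ultrametric default mirroring the Apiaceae topology:
#: carrot (Dc) splits first, then celery (Ag), then coriander/danggui (Cs, As).
DEFAULT_SPECIES_NEWICK = (
    "(Dc:3.0,(Ag:2.0,(Cs:1.0,As:1.0)CsAs:1.0)AgCsAs:1.0)Root;"
)

DOMAIN_BLOCKS = {"C": ("CC", 60), "T": ("TIR", 120), "R": ("RPW8", 80),
                 "N": ("NB-ARC", 300), "L": ("LRR", 150)}

#: Architecture sampler weights: mostly incomplete CNL-type receptors, a
#: TNL minority and a small RNL helper class, echoing dicot NLR repertoires.
DEFAULT_ARCH_WEIGHTS: dict[str, float] = {
    "CNL": 0.10, "TNL": 0.12, "RNL": 0.04, "N": 0.22,
    "NL": 0.28, "TN": 0.06, "CN": 0.14, "RN": 0.04,
}


@dataclass
class SimConfig:
    """Study conditions for the generator; ``seed`` is mandatory."""

    seed: int
    species_newick: str = DEFAULT_SPECIES_NEWICK
    n_families: int = 50
    dup_rate: float = 0.2       # duplications per gene per branch
    loss_rate: float = 0.2      # losses per gene per branch
    n_root_genes: int = 1
    arch_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARCH_WEIGHTS)
    )
    nbs_length: int = 300       # aa; NBS blocks are indel-free
    sub_prob: float = 0.02      # per site per unit branch length
    n_chromosomes: int = 5
    tandem_prob: float = 0.4    # multi-copy groups planted as tandem arrays
    proximal_prob: float = 0.15
    scaffold_frac: float = 0.05
    tandem_gap_bp: tuple[int, int] = (5_000, 50_000)
    proximal_max_rank_gap: int = 10
    # group isolation must exceed BOTH the 250-kb cluster window (bp) and
    # the block chainer's per-step rank gap (25), so planted labels are
    # unambiguous by construction
    separator_fillers: int = 26
    separator_gap_bp: int = 20_000
    gene_length_bp: int = 3_000
    filler_length_bp: int = 1_000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise UsageError("SimConfig.seed is mandatory")
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValidationError("rates must be non-negative")
        for p in (self.sub_prob, self.tandem_prob, self.proximal_prob,
                  self.scaffold_frac):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")
        if self.n_root_genes < 1:
            raise ValidationError("n_root_genes must be >= 1")


@dataclass
class SimGene:
    gene_id: str
    species: str
    sequence: str
    hits: list[DomainHit]
    nbs_span: tuple[int, int]
    # planted placement truth (filled by emit_dataset)
    seq_id: str | None = None
    start: int | None = None
    end: int | None = None
    locus_status: str | None = None
    cluster_id: int | None = None
    dup_type: str | None = None


@dataclass
class SimTruth:
    """Ground truth for one simulated family."""

    family_index: int
    architecture: str
    subclass: str
    observable: bool
    genes: list[SimGene]
    pruned_newick: str | None
    raw_gains: dict[str, int]
    raw_losses: dict[str, int]
    true_lineages: list[list[str]]      # leaf labels per surviving root copy
    projected: dict | None              # oracle: lineages / gains / losses


class _SimNode:
    __slots__ = ("children", "time", "label", "extinct")

    def __init__(self, time: float):
        self.children: list[_SimNode] = []
        self.time = time
        self.label: str | None = None
        self.extinct = False


def _subclass_of(architecture: str) -> str:
    if "R" in architecture:
        return "RNL"
    if "T" in architecture:
        return "TNL"
    return "CNL"


def _species_nodes(tree: dendropy.Tree):
    """Preorder non-root nodes with (node, parent, entry-time, exit-time)."""
    depth: dict = {tree.seed_node: 0.0}
    out = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length if node.edge.length is not None else 1.0
        depth[node] = depth[node.parent_node] + length
        out.append((node, node.parent_node, depth[node.parent_node], depth[node]))
    return out


def _prototype_blocks(config: SimConfig) -> dict[str, str]:
    rng = np.random.default_rng([config.seed % (2**31), 7])
    blocks = {}
    for letter, (_domain, length) in DOMAIN_BLOCKS.items():
        n = config.nbs_length if letter == "N" else length
        blocks[letter] = "".join(
            AA_ALPHABET[i] for i in rng.integers(0, 20, size=n)
        )
    return blocks


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site w.p. p with a different residue (index array)."""
    out = seq.copy()
    mask = rng.random(seq.size) < p
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 20, size=n)) % 20
    return out


def _to_str(seq: np.ndarray) -> str:
    return "".join(AA_ALPHABET[i] for i in seq)


def simulate_family(config: SimConfig, family_index: int) -> SimTruth:
    """Deterministic birth-death history of one family given (seed, index)."""
    rng = np.random.default_rng([config.seed % (2**31), family_index, 11])
    species_tree = tree_from_string(config.species_newick)
    branches = _species_nodes(species_tree)

    arch_names = sorted(config.arch_weights)
    weights = np.array([config.arch_weights[a] for a in arch_names], dtype=float)
    weights /= weights.sum()
    architecture = arch_names[rng.choice(len(arch_names), p=weights)]

    # root copies: a zero-length caterpillar when n_root_genes > 1
    root = _SimNode(0.0)
    copies = [root]
    while len(copies) < config.n_root_genes:
        tip = copies.pop()
        a, b = _SimNode(0.0), _SimNode(0.0)
        tip.children.extend((a, b))
        copies.extend((a, b))
    root_copy_nodes = list(copies)

    raw_gains: dict[str, int] = {}
    raw_losses: dict[str, int] = {}
    copies_at: dict = {species_tree.seed_node: copies}
    extant: list[tuple[_SimNode, str]] = []
    per_species_counter: dict[str, int] = {}

    for node, parent, t0, t1 in branches:
        incoming = copies_at.get(parent, [])
        name = branch_name(node)
        open_tips: list[_SimNode] = []
        for p in incoming:
            child = _SimNode(t0)
            p.children.append(child)
            open_tips.append(child)
        n0 = len(open_tips)
        if n0 == 0:
            copies_at[node] = []
            continue
        n_dup = int(rng.poisson(config.dup_rate * n0))
        n_loss = int(rng.poisson(config.loss_rate * n0))
        events = sorted(
            [("D", float(t)) for t in rng.uniform(t0, t1, n_dup)]
            + [("L", float(t)) for t in rng.uniform(t0, t1, n_loss)],
            key=lambda e: (e[1], e[0]),
        )
        for kind, t in events:
            if not open_tips:
                break
            i = int(rng.integers(len(open_tips)))
            tip = open_tips[i]
            if kind == "D":
                mid = _SimNode(t)
                # splice: tip keeps its start; a duplication vertex at t
                a, b = _SimNode(t), _SimNode(t)
                mid.children.extend((a, b))
                tip.children.append(mid)
                open_tips[i] = a
                open_tips.append(b)
                raw_gains[name] = raw_gains.get(name, 0) + 1
            else:
                end = _SimNode(t)
                end.extinct = True
                tip.children.append(end)
                open_tips.pop(i)
                raw_losses[name] = raw_losses.get(name, 0) + 1
        survivors: list[_SimNode] = []
        for tip in open_tips:
            closing = _SimNode(t1)
            tip.children.append(closing)
            survivors.append(closing)
        copies_at[node] = survivors
        if node.is_leaf():
            sp = node.taxon.label
            for s in survivors:
                k = per_species_counter.get(sp, 0) + 1
                per_species_counter[sp] = k
                gene_id = f"{sp}_f{family_index:03d}c{k}"
                s.label = leaf_label(sp, gene_id)
                extant.append((s, sp))

    # --- prune to the observable tree ---------------------------------
    def prune(node: _SimNode) -> _SimNode | None:
        if not node.children:
            return node if node.label is not None else None
        kept = [c for c in (prune(c) for c in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        node.children = kept
        return node

    pruned = prune(root)
    observable = pruned is not None

    # true ancestral lineage partition: leaves under each surviving root copy
    def leaves_below(node: _SimNode) -> list[str]:
        if not node.children:
            return [node.label] if node.label is not None else []
        out: list[str] = []
        for c in node.children:
            out.extend(leaves_below(c))
        return out

    true_lineages = [
        leaves for copy in root_copy_nodes
        if (leaves := leaves_below(copy))
    ]

    pruned_newick: str | None = None
    projected: dict | None = None
    genes: list[SimGene] = []
    if observable:
        def to_newick(node: _SimNode, parent_time: float) -> str:
            length = node.time - parent_time
            if not node.children:
                return f"{node.label}:{length:.6f}"
            inner = ",".join(to_newick(c, node.time) for c in node.children)
            return f"({inner}):{length:.6f}"

        if pruned.children:
            inner = ",".join(to_newick(c, pruned.time) for c in pruned.children)
            pruned_newick = f"({inner});"
        else:
            pruned_newick = f"{pruned.label}:0.0;"

        gene_tree = tree_from_string(pruned_newick)
        species_for_oracle = tree_from_string(config.species_newick)
        projected = brute_force_reconcile(gene_tree, species_for_oracle)
        projected = {
            "lineages": projected["lineages"],
            "gains": projected["gains"],
            "losses": projected["losses_by_branch"],
        }

        # --- sequences along the pruned tree --------------------------
        blocks = _prototype_blocks(config)
        letters = list(architecture)
        root_seq = np.concatenate([
            np.array([AA_ALPHABET.index(ch) for ch in blocks[letter]],
                     dtype=np.int64)
            for letter in letters
        ])
        root_seq = _mutate(root_seq, 0.25, rng)  # family-level divergence

        spans: dict[str, tuple[int, int]] = {}
        pos = 1
        for letter in letters:
            length = len(blocks[letter])
            spans[letter] = (pos, pos + length - 1)
            pos += length
        nbs_span = spans["N"]

        seqs: dict[str, np.ndarray] = {}

        def evolve(node: _SimNode, seq: np.ndarray, parent_time: float) -> None:
            duration = max(0.0, node.time - parent_time)
            here = _mutate(seq, min(0.75, config.sub_prob * duration), rng)
            if not node.children:
                seqs[node.label] = here
                return
            for c in node.children:
                evolve(c, here, node.time)

        evolve(pruned, root_seq, pruned.time)

        for sim_node, sp in extant:
            if sim_node.label not in seqs:
                continue
            gene_id = sim_node.label.split("|", 1)[1]
            seq = _to_str(seqs[sim_node.label])
            hits = []
            for letter in letters:
                domain = DOMAIN_BLOCKS[letter][0]
                s, e = spans[letter]
                e_value = float(10.0 ** rng.uniform(-60, -10))
                hits.append(DomainHit(gene_id, domain, s, e, e_value))
            genes.append(SimGene(gene_id, sp, seq, hits, nbs_span))

    return SimTruth(
        family_index=family_index,
        architecture=architecture,
        subclass=_subclass_of(architecture),
        observable=observable,
        genes=genes,
        pruned_newick=pruned_newick,
        raw_gains=raw_gains,
        raw_losses=raw_losses,
        true_lineages=true_lineages,
        projected=projected,
    )


def simulate_dataset(config: SimConfig) -> list[SimTruth]:
    return [simulate_family(config, i) for i in range(config.n_families)]


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

class _Chromosome:
    def __init__(self, name: str):
        self.name = name
        self.pos = 0  # last occupied coordinate
        self.rows: list[tuple[str, int, int, bool]] = []  # id, start, end, is_nlr

    def append(self, gene_id: str, gap: int, length: int, is_nlr: bool) -> tuple[int, int]:
        start = self.pos + gap + 1
        end = start + length - 1
        self.pos = end
        self.rows.append((gene_id, start, end, is_nlr))
        return start, end


def _add_separator(chrom: _Chromosome, config: SimConfig, counter: list[int]) -> None:
    for _ in range(config.separator_fillers):
        counter[0] += 1
        chrom.append(f"filler_{chrom.name}_{counter[0]}",
                     config.separator_gap_bp, config.filler_length_bp, False)


def emit_dataset(
    sims: Iterable[SimTruth], config: SimConfig, out_dir: str | Path,
    force: bool = False,
) -> dict[str, Path]:
    """Write the synthetic dataset (FASTA/GFF3/TSV/Newick/JSON) to out_dir."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise UsageError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)

    sims = sorted(sims, key=lambda s: s.family_index)
    species_tree = tree_from_string(config.species_newick)
    species = sorted(l.taxon.label for l in species_tree.leaf_node_iter())
    rng = np.random.default_rng([config.seed % (2**31), 13])

    chroms = {
        sp: [_Chromosome(f"chr{i + 1}") for i in range(config.n_chromosomes)]
        for sp in species
    }
    scaffold_rows: dict[str, list[tuple[str, str, int, int]]] = {sp: [] for sp in species}
    filler_counter = [0]
    cluster_counter = 0

    for sim in sims:
        if not sim.observable:
            continue
        by_species: dict[str, list[SimGene]] = {}
        for g in sim.genes:
            by_species.setdefault(g.species, []).append(g)
        for sp in species:
            group = sorted(by_species.get(sp, []), key=lambda g: g.gene_id)
            if not group:
                continue
            m = len(group)
            r = rng.random()
            if r < config.scaffold_frac:
                scaffold = f"scaffold_{sim.family_index}_{sp}"
                pos = 0
                for g in group:
                    start = pos + 10_000 + 1
                    end = start + config.gene_length_bp - 1
                    pos = end
                    g.seq_id, g.start, g.end = scaffold, start, end
                    g.locus_status, g.dup_type = "unmapped", None
                    scaffold_rows[sp].append((scaffold, g.gene_id, start, end))
                continue
            chrom_list = chroms[sp]
            first = int(rng.integers(len(chrom_list)))
            mode = "single"
            if m >= 2:
                r2 = rng.random()
                if r2 < config.tandem_prob:
                    mode = "tandem"
                elif r2 < config.tandem_prob + config.proximal_prob:
                    mode = "proximal"
                else:
                    mode = "dispersed"
            if mode in ("single", "tandem", "proximal"):
                chrom = chrom_list[first]
                if chrom.rows:
                    _add_separator(chrom, config, filler_counter)
                if mode in ("tandem", "proximal") and m >= 2:
                    cluster_counter += 1
                    cid = cluster_counter
                else:
                    cid = None
                for k, g in enumerate(group):
                    if k > 0 and mode == "proximal":
                        n_fill = int(rng.integers(
                            1, config.proximal_max_rank_gap - 1
                        ))
                        for _ in range(n_fill):
                            filler_counter[0] += 1
                            chrom.append(
                                f"filler_{chrom.name}_{filler_counter[0]}",
                                int(rng.integers(3_000, 10_000)),
                                config.filler_length_bp, False,
                            )
                    gap = int(rng.integers(*config.tandem_gap_bp))
                    start, end = chrom.append(
                        g.gene_id, gap, config.gene_length_bp, True
                    )
                    g.seq_id, g.start, g.end = chrom.name, start, end
                    g.cluster_id = cid
                    g.locus_status = "clustered" if cid else "singleton"
                    g.dup_type = {"single": "singleton", "tandem": "tandem",
                                  "proximal": "proximal"}[mode]
            else:  # dispersed: one copy per chromosome (wrapping if needed)
                for k, g in enumerate(group):
                    chrom = chrom_list[(first + k) % len(chrom_list)]
                    if chrom.rows:
                        _add_separator(chrom, config, filler_counter)
                    gap = int(rng.integers(*config.tandem_gap_bp))
                    start, end = chrom.append(
                        g.gene_id, gap, config.gene_length_bp, True
                    )
                    g.seq_id, g.start, g.end = chrom.name, start, end
                    g.locus_status, g.dup_type = "singleton", "dispersed"

    paths: dict[str, Path] = {}

    # GFF3 + FASTA per species
    all_genes = [g for sim in sims if sim.observable for g in sim.genes]
    for sp in species:
        gff = out / f"{sp}.gff3"
        with open(gff, "w") as handle:
            handle.write("##gff-version 3\n")
            for chrom in chroms[sp]:
                for gene_id, start, end, _is_nlr in chrom.rows:
                    handle.write(
                        f"{chrom.name}\tnlrevo_sim\tgene\t{start}\t{end}\t.\t+"
                        f"\t.\tID={gene_id}\n"
                    )
            for scaffold, gene_id, start, end in scaffold_rows[sp]:
                handle.write(
                    f"{scaffold}\tnlrevo_sim\tgene\t{start}\t{end}\t.\t+\t.\t"
                    f"ID={gene_id}\n"
                )
        paths[f"gff_{sp}"] = gff
        fasta = out / f"{sp}.faa"
        with open(fasta, "w") as handle:
            for g in sorted(all_genes, key=lambda g: g.gene_id):
                if g.species == sp:
                    handle.write(f">{g.gene_id}\n{g.sequence}\n")
        paths[f"fasta_{sp}"] = fasta

    hits = [h for g in sorted(all_genes, key=lambda g: g.gene_id) for h in g.hits]
    paths["domains"] = out / "domains.tsv"
    write_domain_table(hits, paths["domains"])

    pairs: list[HomologyPair] = []
    for sim in sims:
        if not sim.observable:
            continue
        fam = sorted(sim.genes, key=lambda g: g.gene_id)
        for i, ga in enumerate(fam):
            for gb in fam[i + 1:]:
                diff = sum(1 for x, y in zip(ga.sequence, gb.sequence) if x != y)
                identity = 100.0 * (1 - diff / len(ga.sequence))
                a, b = sorted((ga.gene_id, gb.gene_id))
                pairs.append(HomologyPair(a, b, identity, 1e-50))
    paths["homology"] = out / "homology.tsv"
    write_homology_table(pairs, paths["homology"])

    paths["species_tree"] = out / "species_tree.nwk"
    write_newick(species_tree, paths["species_tree"])

    truth = {
        "config": {k: v for k, v in asdict(config).items()},
        "families": [
            {
                "family_index": sim.family_index,
                "architecture": sim.architecture,
                "subclass": sim.subclass,
                "observable": sim.observable,
                "pruned_newick": sim.pruned_newick,
                "raw_gains": sim.raw_gains,
                "raw_losses": sim.raw_losses,
                "true_lineage_count": len(sim.true_lineages),
                "true_lineages": sim.true_lineages,
                "projected": sim.projected,
                "genes": [
                    {
                        "gene_id": g.gene_id,
                        "species": g.species,
                        "seq_id": g.seq_id,
                        "start": g.start,
                        "end": g.end,
                        "locus_status": g.locus_status,
                        "cluster_id": g.cluster_id,
                        "dup_type": g.dup_type,
                        "nbs_span": list(g.nbs_span),
                    }
                    for g in sim.genes
                ],
            }
            for sim in sims
        ],
    }
    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w") as handle:
        json.dump(truth, handle, indent=1)
    return paths
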