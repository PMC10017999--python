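"""End-to-end orchestration over an emitted (or real) dataset directory.

The dataset layout is the one :func:`nlrevo.simulate.emit_dataset` writes:
per-species ``{sp}.faa`` and ``{sp}.gff3``, a combined ``domains.tsv`` and
``homology.tsv``, ``species_tree.nwk`` and (for synthetic data)
``truth.json``.  Real data in the same layout runs through the same calls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy

from nlrevo import classify, cluster, duptype, io, phylo, reconcile
from nlrevo.errors import ValidationError


@dataclass
class Dataset:
    species: list[str]
    genes: dict[str, list[io.GeneModel]]          # per species (all genes)
    sequences: dict[str, dict[str, str]]          # per species: gene -> protein
    hits: list[io.DomainHit]
    homology: list[io.HomologyPair]
    species_tree: dendropy.Tree
    truth: dict | None = None
    hits_by_gene: dict[str, list[io.DomainHit]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for h in self.hits:
            self.hits_by_gene.setdefault(h.gene_id, []).append(h)


def load_dataset(directory: str | Path) -> Dataset:
    d = Path(directory)
    species_tree = io.read_newick(d / "species_tree.nwk")
    species = sorted(l.taxon.label for l in species_tree.leaf_node_iter())
    genes = {
        sp: io.read_gff3(d / f"{sp}.gff3", species=sp) for sp in species
    }
    sequences = {sp: io.read_protein_fasta(d / f"{sp}.faa") for sp in species}
    hits = io.read_domain_table(d / "domains.tsv", dialect="tsv")
    homology_path = d / "homology.tsv"
    homology = (
        io.read_homology_table(homology_path) if homology_path.exists() else []
    )
    truth = None
    truth_path = d / "truth.json"
    if truth_path.exists():
        with open(truth_path) as handle:
            truth = json.load(handle)
    return Dataset(species, genes, sequences, hits, homology, species_tree, truth)


def classify_stage(
    ds: Dataset, e_threshold: float = classify.DEFAULT_E_THRESHOLD
) -> dict[str, list[classify.NLRAnnotation]]:
    """Per-species NLR annotations (motifs scanned where sequences exist)."""
    out: dict[str, list[classify.NLRAnnotation]] = {}
    for sp in ds.species:
        ids = set(ds.sequences[sp])
        sp_hits = [h for h in ds.hits if h.gene_id in ids]
        out[sp] = classify.classify_genes(
            sp_hits, e_threshold=e_threshold, sequences=ds.sequences[sp]
        )
    return out


def cluster_stage(
    ds: Dataset,
    annotations: Mapping[str, Sequence[classify.NLRAnnotation]],
    window_bp: int = cluster.DEFAULT_WINDOW_BP,
) -> dict[str, list[cluster.LocusCall]]:
    out: dict[str, list[cluster.LocusCall]] = {}
    for sp in ds.species:
        nlr_ids = {a.gene_id for a in annotations[sp]}
        nlr_genes = [g for g in ds.genes[sp] if g.gene_id in nlr_ids]
        out[sp] = cluster.call_loci(nlr_genes, window_bp=window_bp)
    return out


def duptype_stage(
    ds: Dataset,
    annotations: Mapping[str, Sequence[classify.NLRAnnotation]],
    **params,
) -> dict[str, list[duptype.DuplicationCall]]:
    out: dict[str, list[duptype.DuplicationCall]] = {}
    chain_kwargs = {
        k: params[k] for k in ("min_block_pairs", "max_gap_ranks") if k in params
    }
    call_kwargs = {
        k: params[k]
        for k in ("proximal_max_rank_gap", "homology_e", "homology_identity")
        if k in params
    }
    for sp in ds.species:
        nlr_ids = {a.gene_id for a in annotations[sp]}
        nlr_genes = [g for g in ds.genes[sp] if g.gene_id in nlr_ids]
        ranks = duptype.rank_genome(ds.genes[sp])
        sp_pairs = [
            p for p in ds.homology if p.gene_a in ranks and p.gene_b in ranks
        ]
        blocks = duptype.chain_collinear_blocks(sp_pairs, ranks, **chain_kwargs)
        out[sp] = duptype.classify_duplications(
            nlr_genes, sp_pairs, ranks, blocks, **call_kwargs
        )
    return out


def infer_family_tree(
    members: Mapping[str, str],  # leaf label -> gene_id
    ds: Dataset,
    min_nbs_length: int = 1,
    root_method: str = "parsimony",
) -> dendropy.Tree:
    """Rooted NBS-region tree for one gene family.

    The default rooting for reconciliation input minimises duplication+loss
    cost over all root positions (midpoint breaks ties); ``midpoint`` and
    ``outgroup`` pass through to :func:`nlrevo.phylo.root_tree`.
    """
    nbs: dict[str, str] = {}
    seq_by_gene = {
        gid: seq for sp in ds.species for gid, seq in ds.sequences[sp].items()
    }
    for label, gene_id in members.items():
        hits = ds.hits_by_gene.get(gene_id)
        if not hits:
            raise ValidationError(f"no domain hits for {gene_id}")
        region = phylo.extract_nbs_region(
            seq_by_gene[gene_id], hits, min_length=min_nbs_length
        )
        if region is not None:
            nbs[label] = region
    if not nbs:
        raise ValidationError("no NBS regions of sufficient length")
    if root_method != "parsimony" or len(nbs) < 3:
        return phylo.build_rooted_gene_tree(nbs, method="midpoint")
    unrooted = phylo.neighbor_joining(phylo.p_distance_matrix(nbs))
    index = reconcile.SpeciesIndex(ds.species_tree)
    return reconcile.root_by_duplication_loss(unrooted, index)


def reconcile_family(
    gene_tree: dendropy.Tree, species_index: reconcile.SpeciesIndex
) -> dict:
    """LCA reconciliation summary (lineages, per-branch gains/losses)."""
    recon = reconcile.lca_map(gene_tree, species_index)
    return reconcile.family_event_summary(recon)


def _normalize_events(summary: Mapping) -> tuple:
    gains = {k: v for k, v in summary["gains"].items() if v}
    losses = {k: v for k, v in summary["losses"].items() if v}
    return summary["lineages"], tuple(sorted(gains.items())), tuple(
        sorted(losses.items())
    )


def evaluate_recovery(
    ds: Dataset, max_family_size: int | None = 8
) -> dict:
    """Per-family event recovery against the parsimony-projected truth.

    For each observable simulated family (optionally restricted to at most
    ``max_family_size`` genes) the estimated gene tree (p-distance NJ,
    midpoint-rooted) and the true pruned gene tree are each reconciled; the
    result counts families whose lineage count and per-branch gain/loss
    profiles match the oracle projection exactly.
    """
    if ds.truth is None:
        raise ValidationError("dataset has no truth.json")
    index = reconcile.SpeciesIndex(ds.species_tree)
    n = exact = exact_true = 0
    for fam in ds.truth["families"]:
        if not fam["observable"]:
            continue
        if max_family_size is not None and len(fam["genes"]) > max_family_size:
            continue
        members = {
            io.leaf_label(g["species"], g["gene_id"]): g["gene_id"]
            for g in fam["genes"]
        }
        projected = (
            fam["projected"]["lineages"],
            tuple(sorted((k, v) for k, v in fam["projected"]["gains"].items() if v)),
            tuple(sorted((k, v) for k, v in fam["projected"]["losses"].items() if v)),
        )
        inferred_tree = infer_family_tree(members, ds)
        inferred = _normalize_events(reconcile_family(inferred_tree, index))
        true_tree = io.tree_from_string(fam["pruned_newick"])
        true_route = _normalize_events(reconcile_family(true_tree, index))
        n += 1
        exact += int(inferred == projected)
        exact_true += int(true_route == projected)
    return {
        "n_families": n,
        "exact": exact,
        "exact_true_tree": exact_true,
        "recovery_rate": exact / n if n else float("nan"),
        "true_tree_rate": exact_true / n if n else float("nan"),
    }
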