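"""Readers and writers for the standard formats the pipeline touches.

Internal conventions
--------------------
* Genomic and protein coordinates are 1-based inclusive everywhere,
  exactly as in GFF3 and hmmer alignment coordinates.
* Gene-tree leaf labels are ``SPECIES|gene_id``; the pipe character is
  reserved as the separator.
* Trees are :class:`dendropy.Tree` objects throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO
from gffutils.feature import feature_from_line

from nlrevo.errors import ParseError, UsageError, ValidationError

LEAF_SEPARATOR = "|"

#: Controlled vocabulary of NLR-relevant domains.
DOMAIN_VOCABULARY = ("NB-ARC", "TIR", "RPW8", "CC", "LRR")

#: Default mapping from Pfam-style hit names to the controlled vocabulary.
#: Keys are matched case-insensitively; ``prefix:`` keys match name prefixes
#: (e.g. all LRR_1..LRR_12 Pfam families collapse to LRR).
DEFAULT_DOMAIN_NAME_MAP: dict[str, str] = {
    "NB-ARC": "NB-ARC",
    "NBS": "NB-ARC",
    "TIR": "TIR",
    "TIR_2": "TIR",
    "RPW8": "RPW8",
    "CC": "CC",
    "RX-CC_LIKE": "CC",
    "prefix:LRR": "LRR",
}

DEFAULT_CHROMOSOME_REGEX = r"^(chr|Chr|[0-9]+$)"


@dataclass(frozen=True)
class GeneModel:
    """One gene with genomic coordinates (1-based inclusive)."""

    gene_id: str
    species: str
    seq_id: str
    start: int
    end: int
    strand: str
    is_chromosome: bool = True

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class DomainHit:
    """One protein-domain match; drives NLR identification and classification."""

    gene_id: str
    domain: str
    ali_start: int
    ali_end: int
    e_value: float

    def __post_init__(self) -> None:
        if self.ali_start > self.ali_end:
            raise ValidationError(
                f"hit on {self.gene_id}: ali_end {self.ali_end} < ali_start "
                f"{self.ali_start}"
            )
        if self.e_value < 0:
            raise ValidationError(f"hit on {self.gene_id}: negative E-value")


@dataclass(frozen=True)
class HomologyPair:
    """An undirected homology edge, stored once in lexicographic order."""

    gene_a: str
    gene_b: str
    identity: float
    e_value: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValidationError(f"self-pair {self.gene_a}")
        if self.gene_a > self.gene_b:
            raise ValidationError("pair not in canonical (lexicographic) order")


@dataclass
class ChromosomeRule:
    """Decides whether a seq_id is a chromosome (vs. unplaced scaffold)."""

    chromosome_list: frozenset[str] = field(default_factory=frozenset)
    regex: str = DEFAULT_CHROMOSOME_REGEX

    def __call__(self, seq_id: str) -> bool:
        if self.chromosome_list:
            return seq_id in self.chromosome_list
        return re.search(self.regex, seq_id) is not None


def _gff3_attributes(feature_type: str, line: str, lineno: int):
    try:
        return feature_from_line(line)
    except Exception as exc:  # gffutils raises plain ValueError/AttributeError
        raise ParseError(f"GFF3 line {lineno}: {exc}") from exc


def read_gff3(
    path: str | Path,
    species: str,
    feature_type: str = "gene",
    chromosome_list: Sequence[str] | None = None,
    chromosome_regex: str = DEFAULT_CHROMOSOME_REGEX,
    fallback_feature_type: str | None = "mRNA",
) -> list[GeneModel]:
    """Extract gene models of one record level from a GFF3 file.

    Coordinates are kept 1-based inclusive as in the file.  ``is_chromosome``
    is membership of ``chromosome_list`` when given, else a regex rule.
    When no ``feature_type`` rows exist the reader falls back to
    ``fallback_feature_type`` rows (annotation styles differ in whether
    they carry ``gene`` or only ``mRNA`` records).
    """
    rule = ChromosomeRule(frozenset(chromosome_list or ()), chromosome_regex)
    rows: dict[str, list[tuple[int, str, Sequence[str]]]] = {
        feature_type: [],
    }
    if fallback_feature_type:
        rows[fallback_feature_type] = []

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"GFF3 line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            if cols[2] in rows:
                rows[cols[2]].append((lineno, line, cols))

    chosen = rows[feature_type]
    if not chosen and fallback_feature_type:
        chosen = rows[fallback_feature_type]

    genes: list[GeneModel] = []
    seen: set[str] = set()
    for lineno, line, cols in chosen:
        seq_id, _, _, start_s, end_s, _, strand, _, _ = cols
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"GFF3 line {lineno}: non-integer coordinate") from exc
        feature = _gff3_attributes(cols[2], line, lineno)
        gene_id = (
            feature.attributes.get("ID", [None])[0]
            or feature.attributes.get("Name", [None])[0]
        )
        if gene_id is None:
            raise ParseError(f"GFF3 line {lineno}: feature has no ID attribute")
        if end < start:
            raise ValidationError(
                f"GFF3 line {lineno}: end {end} < start {start} for {gene_id}"
            )
        if gene_id in seen:
            raise ValidationError(f"GFF3 line {lineno}: duplicate gene_id {gene_id}")
        seen.add(gene_id)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                species=species,
                seq_id=seq_id,
                start=start,
                end=end,
                strand=strand if strand in ("+", "-") else "+",
                is_chromosome=rule(seq_id),
            )
        )
    return genes


def normalize_domain_name(
    name: str, name_map: Mapping[str, str] | None = None
) -> str:
    """Map a raw hit name onto the controlled vocabulary; unknowns pass through."""
    table = DEFAULT_DOMAIN_NAME_MAP if name_map is None else name_map
    upper = name.upper()
    for key, target in table.items():
        if key.startswith("prefix:"):
            if upper.startswith(key[len("prefix:"):].upper()):
                return target
        elif upper == key.upper():
            return target
    return name


def read_domain_table(
    path: str | Path,
    dialect: str = "tsv",
    name_map: Mapping[str, str] | None = None,
) -> list[DomainHit]:
    """Read per-domain hits from a 5-column TSV or an hmmscan ``--domtblout``.

    The TSV dialect is ``gene_id  domain  ali_start  ali_end  e_value``.
    In the domtblout dialect the target name is the domain model, the query
    name the protein, alignment coordinates come from the ``ali from/to``
    columns and the per-domain independent E-value (``i-Evalue``) is used.
    """
    if dialect not in ("tsv", "domtblout"):
        raise UsageError(f"unknown domain-table dialect {dialect!r}")
    hits: list[DomainHit] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if dialect == "tsv":
                cols = line.split("\t")
                if len(cols) == 1:
                    cols = line.split()
                if len(cols) != 5:
                    raise ParseError(
                        f"domain table line {lineno}: expected 5 columns, "
                        f"got {len(cols)}"
                    )
                gene_id, domain, start_s, end_s, e_s = cols
            else:
                cols = line.split()
                if len(cols) < 23:
                    raise ParseError(
                        f"domtblout line {lineno}: expected >=23 whitespace "
                        f"columns, got {len(cols)}"
                    )
                domain, gene_id = cols[0], cols[3]
                start_s, end_s, e_s = cols[17], cols[18], cols[12]
            try:
                start, end = int(start_s), int(end_s)
                e_value = float(e_s)
            except ValueError as exc:
                raise ParseError(
                    f"domain table line {lineno}: non-numeric field"
                ) from exc
            hits.append(
                DomainHit(
                    gene_id=gene_id,
                    domain=normalize_domain_name(domain, name_map),
                    ali_start=start,
                    ali_end=end,
                    e_value=e_value,
                )
            )
    return hits


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w") as handle:
        for h in hits:
            handle.write(
                f"{h.gene_id}\t{h.domain}\t{h.ali_start}\t{h.ali_end}\t"
                f"{h.e_value:.3g}\n"
            )


def read_homology_table(path: str | Path) -> list[HomologyPair]:
    """Read BLAST tabular (outfmt 6) homology; one canonical pair per edge.

    Self-hits are dropped; reciprocal/duplicate rows collapse onto the
    lowest-E-value record for the pair.
    """
    best: dict[tuple[str, str], HomologyPair] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) == 1:
                cols = line.split()
            if len(cols) < 12 and len(cols) != 4:
                raise ParseError(
                    f"homology table line {lineno}: expected 12 BLAST outfmt-6 "
                    f"columns (or 4-column qseqid sseqid pident evalue), "
                    f"got {len(cols)}"
                )
            qseqid, sseqid = cols[0], cols[1]
            if qseqid == sseqid:
                continue
            try:
                identity = float(cols[2])
                e_value = float(cols[10] if len(cols) >= 12 else cols[3])
            except ValueError as exc:
                raise ParseError(
                    f"homology table line {lineno}: non-numeric field"
                ) from exc
            a, b = sorted((qseqid, sseqid))
            pair = HomologyPair(a, b, identity, e_value)
            kept = best.get((a, b))
            if kept is None or pair.e_value < kept.e_value:
                best[(a, b)] = pair
    return [best[k] for k in sorted(best)]


def write_homology_table(pairs: Iterable[HomologyPair], path: str | Path) -> None:
    """Write minimal outfmt-6 rows (non-positional columns zero-filled)."""
    with open(path, "w") as handle:
        for p in pairs:
            handle.write(
                f"{p.gene_a}\t{p.gene_b}\t{p.identity:.2f}\t0\t0\t0\t0\t0\t0\t0\t"
                f"{p.e_value:.3g}\t0\n"
            )


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Protein FASTA as ``{record id: uppercase sequence}``."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValidationError(f"duplicate FASTA id {record.id}")
        seqs[record.id] = str(record.seq).upper()
    return seqs


def longest_per_gene(
    seqs: Mapping[str, str], isoform_suffix: str = r"\.\d+$"
) -> dict[str, str]:
    """Collapse isoforms to the longest protein per gene id.

    Isoform ids are assumed to be ``gene.N``; ids without the suffix are
    already gene-level.
    """
    out: dict[str, str] = {}
    pattern = re.compile(isoform_suffix)
    for rec_id, seq in seqs.items():
        gene_id = pattern.sub("", rec_id)
        if gene_id not in out or len(seq) > len(out[gene_id]):
            out[gene_id] = seq
    return out


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)
# ---------------------------------------------------------------------------

def read_newick(source: str | Path, is_path: bool = True) -> dendropy.Tree:
    """Parse a single Newick tree (labels may be quoted)."""
    try:
        if is_path:
            tree = dendropy.Tree.get(
                path=str(source), schema="newick", preserve_underscores=True
            )
        else:
            tree = dendropy.Tree.get(
                data=str(source), schema="newick", preserve_underscores=True
            )
    except Exception as exc:
        raise ParseError(f"Newick parse failed: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        raise ValidationError("duplicate leaf labels in tree")
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    return read_newick(newick, is_path=False)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write Newick; branch lengths at 6 decimals for stable round-trips."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    )
    with open(path, "w") as handle:
        handle.write(text)


def leaf_label(species: str, gene_id: str) -> str:
    return f"{species}{LEAF_SEPARATOR}{gene_id}"


def split_leaf_label(label: str) -> tuple[str, str]:
    """Split ``SPECIES|gene_id``; raises if the separator is absent."""
    if LEAF_SEPARATOR not in label:
        raise ValidationError(
            f"gene-tree leaf {label!r} lacks the '{LEAF_SEPARATOR}' species "
            f"separator"
        )
    species, gene_id = label.split(LEAF_SEPARATOR, 1)
    return species, gene_id
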