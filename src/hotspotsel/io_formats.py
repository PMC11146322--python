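"""Readers/writers for alignments, trees, gene annotations, and layouts.

Internal coordinates are 0-based half-open; GFF3 I/O converts at the
boundary.  Trees carry per-branch foreground/background labels, expressed
in newick either as an explicit tag list or with the ``#1`` suffix dialect.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO

__all__ = [
    "CodonAlignment",
    "LabeledTree",
    "GenomeLayout",
    "GeneLocus",
    "FrameError",
    "AlignmentFormatError",
    "read_codon_alignment",
    "write_codon_alignment",
    "read_labeled_tree",
    "write_labeled_tree",
    "read_gff_genes",
    "write_gff_genes",
    "filter_ortholog_sets",
    "OrthologSetRecord",
]

_VALID_CHARS = set("ACGTUMRWSYKVHDBN-")


class FrameError(ValueError):
    """Sequence length is not a multiple of three."""


class AlignmentFormatError(ValueError):
    """Structurally invalid alignment (duplicates, ragged rows, alphabet)."""


@dataclass(frozen=True)
class CodonAlignment:
    """An in-frame CDS alignment: taxa x codon columns."""

    gene_id: str
    taxa: tuple[str, ...]
    sequences: Mapping[str, str]

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            dups = sorted({t for t in self.taxa if list(self.taxa).count(t) > 1})
            raise AlignmentFormatError(f"duplicate taxa in {self.gene_id}: {dups}")
        if set(self.taxa) != set(self.sequences):
            raise AlignmentFormatError("taxa and sequence keys differ")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise AlignmentFormatError(f"unequal sequence lengths: {sorted(lengths)}")
        (length,) = lengths or {0}
        if length % 3 != 0:
            raise FrameError(
                f"alignment length {length} of {self.gene_id} is not a multiple of 3"
            )
        for taxon, seq in self.sequences.items():
            bad = set(seq) - _VALID_CHARS
            if bad:
                raise AlignmentFormatError(
                    f"invalid characters {sorted(bad)} in {taxon}"
                )

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.taxa else 0

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codon(self, taxon: str, i: int) -> str:
        return self.sequences[taxon][3 * i : 3 * i + 3]

    def subset_taxa(self, keep: Iterable[str]) -> "CodonAlignment":
        keep = set(keep)
        taxa = tuple(t for t in self.taxa if t in keep)
        return CodonAlignment(
            self.gene_id, taxa, {t: self.sequences[t] for t in taxa}
        )

    def slice_codons(self, start: int, stop: int) -> "CodonAlignment":
        """Restrict to codon columns [start, stop)."""
        return CodonAlignment(
            self.gene_id,
            self.taxa,
            {t: s[3 * start : 3 * stop] for t, s in self.sequences.items()},
        )


def read_codon_alignment(path, gene_id: str | None = None) -> CodonAlignment:
    """Read an in-frame FASTA codon alignment; sequences are upper-cased."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"no FASTA records in {path}")
    taxa = tuple(r.id for r in records)
    if len(set(taxa)) != len(taxa):
        raise AlignmentFormatError(f"duplicate taxon names in {path}")
    seqs = {r.id: str(r.seq).upper().replace("U", "T") for r in records}
    return CodonAlignment(gene_id or path.stem, taxa, seqs)


def write_codon_alignment(aln: CodonAlignment, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for taxon in aln.taxa:
            fh.write(f">{taxon}\n")
            seq = aln.sequences[taxon]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --- trees -----------------------------------------------------------------

_FG_MARK = "xxFGTAGxx"
_TAG_RE = re.compile(r"\s*#\s*(\d+)(?=\s*[:,();])")


class LabeledTree:
    """Phylogeny with per-branch foreground/background labels.

    Wraps a dendropy tree; each non-root node carries a ``foreground``
    attribute describing the branch above it.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        for node in tree:
            if not hasattr(node, "foreground"):
                node.foreground = False
        self.validate()

    # basic accessors -------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(leaf.taxon.label for leaf in self._tree.leaf_node_iter())

    def branches(self):
        """Yield (node, length, foreground) for every non-root branch."""
        root = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            yield node, node.edge.length, node.foreground

    @property
    def n_branches(self) -> int:
        return sum(1 for _ in self.branches())

    @property
    def n_foreground(self) -> int:
        return sum(1 for _, _, fg in self.branches() if fg)

    def validate(self) -> None:
        labels = [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip names in tree")
        n_bg = 0
        for _, length, fg in self.branches():
            if length is not None and length < 0:
                raise ValueError("negative branch length")
            n_bg += not fg
        if n_bg == 0:
            raise ValueError("tree must retain at least one background branch")

    # labeling --------------------------------------------------------------

    def set_foreground(self, tags: Sequence[str]) -> None:
        """Mark the branches above the named tips/clades as foreground."""
        by_name: dict[str, dendropy.Node] = {}
        for node in self._tree:
            name = node.taxon.label if node.taxon else node.label
            if name:
                by_name[name] = node
        for tag in tags:
            node = by_name.get(tag)
            if node is None or node is self._tree.seed_node:
                raise LookupError(f"foreground tag {tag!r} does not match a branch")
            node.foreground = True
        self.validate()

    def foreground_clade(self, tags: Sequence[str]) -> None:
        """Mark every branch within (and above) the MRCA of ``tags``."""
        taxa = [t for t in self._tree.taxon_namespace if t.label in set(tags)]
        if len(taxa) != len(set(tags)):
            missing = set(tags) - {t.label for t in taxa}
            raise LookupError(f"unknown taxa: {sorted(missing)}")
        self._tree.is_rooted = True  # treat seed node as root for MRCA lookup
        mrca = self._tree.mrca(taxa=taxa)
        for node in mrca.preorder_iter():
            if node is not self._tree.seed_node:
                node.foreground = True
        self.validate()

    # manipulation ----------------------------------------------------------

    def copy(self) -> "LabeledTree":
        clone = dendropy.Tree(self._tree)
        for src, dst in zip(self._tree, clone):
            dst.foreground = getattr(src, "foreground", False)
        return LabeledTree(clone)

    def prune_to(self, taxa: Iterable[str]) -> "LabeledTree":
        """Return a copy restricted to ``taxa`` (labels preserved)."""
        keep = set(taxa)
        missing = keep - set(self.taxa)
        if missing:
            raise LookupError(f"taxa absent from tree: {sorted(missing)}")
        clone = self.copy()
        t = clone._tree
        t.retain_taxa_with_labels(sorted(keep))
        # suppressed unifurcations may have dropped nodes; labels persist on
        # surviving nodes because retain_taxa edits in place
        for node in t:
            if not hasattr(node, "foreground"):
                node.foreground = False
        return LabeledTree(t)

    # serialization ---------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node) -> str:
            tag = "#1" if getattr(node, "foreground", False) else ""
            length = "" if node.edge.length is None else f":{node.edge.length:.12g}"
            if node.is_leaf():
                return f"{node.taxon.label}{tag}{length}"
            inner = ",".join(fmt(c) for c in node.child_nodes())
            label = node.label or ""
            return f"({inner}){label}{tag}{length}"

        root = self._tree.seed_node
        inner = ",".join(fmt(c) for c in root.child_nodes())
        label = root.label or ""
        return f"({inner}){label};"

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return self.to_newick()


def read_labeled_tree(path_or_text, foreground_tags: Sequence[str] | None = None) -> LabeledTree:
    """Parse a newick tree, honouring ``#1`` branch tags and/or a tag list."""
    text = path_or_text if str(path_or_text).strip().endswith(";") else Path(path_or_text).read_text()
    for m in _TAG_RE.finditer(text):
        if m.group(1) != "1":
            raise ValueError(f"unsupported branch tag #{m.group(1)}; only #1 is recognised")
    marked = _TAG_RE.sub(_FG_MARK, text)
    tree = dendropy.Tree.get(
        data=marked,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    for node in tree:
        node.foreground = False
        if node.taxon is not None and node.taxon.label.endswith(_FG_MARK):
            node.taxon.label = node.taxon.label[: -len(_FG_MARK)].rstrip()
            node.foreground = True
        if node.label and node.label.endswith(_FG_MARK):
            node.label = node.label[: -len(_FG_MARK)].rstrip() or None
            node.foreground = True
    labeled = LabeledTree(tree)
    if foreground_tags:
        labeled.set_foreground(foreground_tags)
    return labeled


def write_labeled_tree(tree: LabeledTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# --- genome layout and gene loci -------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths (bp)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def offsets(self, order: Sequence[str] | None = None) -> dict[str, int]:
        """Cumulative start offset of each chromosome in a concatenation."""
        order = list(order) if order is not None else list(self.names)
        lengths = self.lengths
        out, pos = {}, 0
        for name in order:
            out[name] = pos
            pos += lengths[name]
        return out


@dataclass(frozen=True)
class GeneLocus:
    """A gene interval; 0-based half-open internally."""

    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval for {self.symbol}: [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.symbol}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def read_gff_genes(path, feature_type: str = "gene", name_attr: str = "Name") -> list[GeneLocus]:
    """Read gene features from GFF3, converting to 0-based half-open.

    Features lacking the symbol attribute are skipped with a warning.
    """
    import gffutils

    path = Path(path)
    if path.stat().st_size == 0 or not _has_feature_lines(path):
        return []
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneLocus] = []
    skipped = 0
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        names = feat.attributes.get(name_attr)
        if not names:
            skipped += 1
            continue
        strand = feat.strand if feat.strand in "+-" else "+"
        genes.append(GeneLocus(names[0], feat.seqid, feat.start - 1, feat.end, strand))
    if skipped:
        warnings.warn(
            f"{skipped} {feature_type} feature(s) without a {name_attr} attribute "
            f"were skipped in {path}"
        )
    return genes


def _has_feature_lines(path: Path) -> bool:
    with open(path) as fh:
        return any(line.strip() and not line.startswith("#") for line in fh)


def write_gff_genes(genes: Sequence[GeneLocus], path, layout: GenomeLayout | None = None) -> None:
    """Write loci as GFF3 gene features (1-based inclusive on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if layout is not None:
            for name, length in layout.chromosomes:
                fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\thotspotsel\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID=gene-{g.symbol};Name={g.symbol}\n"
            )


# --- ortholog-set completeness filter ---------------------------------------


@dataclass(frozen=True)
class OrthologSetRecord:
    """One filtering decision: gene kept/pruned/dropped and why."""

    gene_id: str
    action: str  # "kept" | "pruned" | "dropped"
    missing_taxa: tuple[str, ...] = field(default_factory=tuple)


def filter_ortholog_sets(
    sets: Mapping[str, CodonAlignment],
    required_taxa: Sequence[str],
    max_missing: int = 1,
) -> tuple[dict[str, CodonAlignment], list[OrthologSetRecord]]:
    """Apply the completeness rule to per-gene ortholog alignments.

    Genes missing at most ``max_missing`` required taxa are kept (the missing
    taxa are to be pruned from the guide tree before fitting); genes missing
    more are dropped.  The report lists every decision.
    """
    if max_missing < 0:
        raise ValueError("max_missing must be >= 0")
    required = list(required_taxa)
    kept: dict[str, CodonAlignment] = {}
    report: list[OrthologSetRecord] = []
    for gene_id, aln in sets.items():
        missing = tuple(t for t in required if t not in aln.taxa)
        if not missing:
            kept[gene_id] = aln
            report.append(OrthologSetRecord(gene_id, "kept"))
        elif len(missing) <= max_missing:
            kept[gene_id] = aln
            report.append(OrthologSetRecord(gene_id, "pruned", missing))
        else:
            report.append(OrthologSetRecord(gene_id, "dropped", missing))
    return kept, report
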