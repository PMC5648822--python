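"""Domain types and readers/writers for the external formats the pipeline touches.

Internal genomic coordinates are 0-based half-open; GFF3's 1-based inclusive
coordinates are converted at the boundary.  The synteny coordinate of a gene is
its *rank*: the 0-based order index of the gene along its chromosome, assigned
by start coordinate (ties broken lexicographically by gene id, so ranks are
deterministic).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy

from .errors import ConfigurationError, ParseError, ValidationError

GAP_CHARS = frozenset("-?")


# ---------------------------------------------------------------------------
# genome annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """One gene locus on a chromosome of an anchor genome."""

    gene_id: str
    chromosome: str
    start: int  # 0-based, half-open
    end: int
    strand: str  # '+' or '-'
    rank: int  # gene-order index along the chromosome, 0-based

    def __post_init__(self):
        if not self.start < self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")


class GenomeAnnotation:
    """Ordered gene loci of one genome, plus optional protein sequences."""

    def __init__(self, genome_id: str, genes, proteins: dict[str, str] | None = None):
        self.genome_id = genome_id
        self.genes: list[GeneModel] = list(genes)
        self.proteins = proteins or {}
        self._by_id = {}
        for g in self.genes:
            if g.gene_id in self._by_id:
                raise ValidationError(
                    f"duplicate gene id {g.gene_id!r} in genome {genome_id}"
                )
            self._by_id[g.gene_id] = g
        # ranks must tile 0..n-1 per chromosome
        per_chrom: dict[str, list[int]] = {}
        for g in self.genes:
            per_chrom.setdefault(g.chromosome, []).append(g.rank)
        for chrom, ranks in per_chrom.items():
            if sorted(ranks) != list(range(len(ranks))):
                raise ValidationError(
                    f"genome {genome_id}, chromosome {chrom}: ranks not contiguous 0..n-1"
                )

    def __len__(self):
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def chromosomes(self) -> list[str]:
        return sorted({g.chromosome for g in self.genes})

    def genes_on(self, chromosome: str) -> list[GeneModel]:
        out = [g for g in self.genes if g.chromosome == chromosome]
        return sorted(out, key=lambda g: g.rank)


def _assign_ranks(raw: list[tuple[str, int, int, str, str]]) -> list[GeneModel]:
    """raw rows: (gene_id, start, end, strand, chromosome) with internal coords."""
    by_chrom: dict[str, list] = {}
    for gid, start, end, strand, chrom in raw:
        by_chrom.setdefault(chrom, []).append((gid, start, end, strand))
    genes = []
    for chrom in sorted(by_chrom):
        rows = sorted(by_chrom[chrom], key=lambda r: (r[1], r[0]))
        for rank, (gid, start, end, strand) in enumerate(rows):
            genes.append(GeneModel(gid, chrom, start, end, strand, rank))
    return genes


_GFF3_ATTR_ID = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_annotation(path, format: str, genome_id: str | None = None) -> GenomeAnnotation:
    """Read a genome annotation from GFF3 (gene features) or BED6.

    GFF3 coordinates (1-based inclusive) are converted to internal 0-based
    half-open; ranks are assigned per chromosome by start coordinate.
    """
    if format not in ("gff3", "bed"):
        raise ConfigurationError(f"unknown annotation format {format!r}")
    raw = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format == "gff3":
                if len(fields) != 9:
                    raise ParseError(
                        f"GFF3 line has {len(fields)} columns, expected 9",
                        path=path, line=lineno,
                    )
                if fields[2] != "gene":
                    continue
                chrom, start_s, end_s, strand, attrs = (
                    fields[0], fields[3], fields[4], fields[6], fields[8]
                )
                m = _GFF3_ATTR_ID.search(attrs)
                if not m:
                    raise ParseError("gene feature lacks ID attribute",
                                     path=path, line=lineno)
                gid = m.group(1)
                try:
                    start = int(start_s) - 1  # GFF3 1-based inclusive -> 0-based
                    end = int(end_s)
                except ValueError:
                    raise ParseError("non-integer coordinate", path=path, line=lineno)
            else:  # bed
                if len(fields) < 4:
                    raise ParseError(
                        f"BED line has {len(fields)} columns, expected >= 4",
                        path=path, line=lineno,
                    )
                chrom, start_s, end_s, gid = fields[:4]
                strand = fields[5] if len(fields) >= 6 else "+"
                try:
                    start, end = int(start_s), int(end_s)
                except ValueError:
                    raise ParseError("non-integer coordinate", path=path, line=lineno)
            if gid in seen:
                raise ValidationError(f"duplicate gene id {gid!r} at {path}:{lineno}")
            seen.add(gid)
            raw.append((gid, start, end, strand, chrom))
    gid_name = genome_id if genome_id is not None else str(path)
    return GenomeAnnotation(gid_name, _assign_ranks(raw))


def write_annotation_gff3(annot: GenomeAnnotation, path) -> None:
    """Write gene features back out as GFF3 (internal 0-based half-open
    converted to 1-based inclusive, the inverse of read_annotation)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for chrom in annot.chromosomes():
            for g in annot.genes_on(chrom):
                fh.write(f"{g.chromosome}\tsyntelog_phylo\tgene\t{g.start + 1}\t"
                         f"{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n")


def write_annotation_bed(annot: GenomeAnnotation, path) -> None:
    with open(path, "w", newline="\n") as fh:
        for chrom in annot.chromosomes():
            for g in annot.genes_on(chrom):
                fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# homology hits (BLAST tabular, outfmt 6)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomologyHit:
    """One row of a BLAST tabular (outfmt 6) file; only the fields the
    pipeline thresholds on are modelled."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValidationError(f"negative evalue {self.evalue}")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValidationError(
                f"percent identity {self.percent_identity} outside [0, 100]"
            )


def read_hits(path) -> list[HomologyHit]:
    """Parse 12-column BLAST outfmt-6 rows in file order; no filtering."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"expected 12 tab-separated columns, got {len(fields)}",
                    path=path, line=lineno,
                )
            try:
                hits.append(HomologyHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                ))
            except ValueError as exc:
                raise ParseError(f"bad numeric field: {exc}", path=path, line=lineno)
    return hits


def write_hits(hits, path) -> None:
    """Write hits back as outfmt-6 rows (unused positional columns zeroed)."""
    with open(path, "w", newline="\n") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t"
                f"{h.alignment_length}\t0\t0\t1\t{h.alignment_length}\t1\t"
                f"{h.alignment_length}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------

def _fmt_float(x: float) -> str:
    s = f"{x:.6g}"
    return s


class GeneTree:
    """A support-annotated unrooted tree over uniquely labelled leaves.

    Wraps a :class:`dendropy.Tree`; internal node labels are interpreted as
    branch support on [0, 100].  Split sets (used by RF distance, binning and
    compatibility checks) are cached per support threshold.
    """

    def __init__(self, tree_id: str, tree: dendropy.Tree):
        self.tree_id = tree_id
        self._tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"tree {tree_id}: duplicate leaf labels")
        self._leaves = frozenset(labels)
        self._split_cache: dict = {}

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, tree_id: str = "tree") -> "GeneTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ParseError(f"bad newick: {exc}")
        gt = cls(tree_id, tree)
        gt._rescale_supports()
        return gt

    def _rescale_supports(self):
        """Support read from internal node labels; a tree whose supports are
        all <= 1 is assumed to use the [0,1] dialect and is rescaled to
        [0,100]."""
        vals = []
        for nd in self._tree.preorder_internal_node_iter():
            s = _parse_support(nd.label)
            if s is not None:
                vals.append(s)
        if vals and all(v <= 1.0 for v in vals):
            for nd in self._tree.preorder_internal_node_iter():
                s = _parse_support(nd.label)
                if s is not None:
                    nd.label = _fmt_float(s * 100.0)
        for v in (_parse_support(nd.label)
                  for nd in self._tree.preorder_internal_node_iter()):
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValidationError(
                    f"tree {self.tree_id}: support {v} outside [0, 100]")

    # -- basic queries -----------------------------------------------------
    @property
    def leaves(self) -> frozenset:
        return self._leaves

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def copy(self) -> "GeneTree":
        return GeneTree(self.tree_id, self._tree.clone(depth=1))

    def pruned_to(self, labels) -> "GeneTree":
        """Copy of this tree restricted to the given leaf labels."""
        keep = set(labels) & self._leaves
        t = self._tree.clone(depth=1)
        t.retain_taxa_with_labels(sorted(keep))
        return GeneTree(self.tree_id, t)

    # -- splits ------------------------------------------------------------
    def splits(self, min_support: float | None = None) -> frozenset:
        """Nontrivial bipartitions as canonical frozensets of leaf labels.

        Each internal branch yields the leaf set on the side *not* containing
        the reference taxon (the lexicographically smallest leaf), so equal
        splits compare equal regardless of tree rooting.  When ``min_support``
        is given, branches whose support is absent or below it are contracted.
        """
        key = min_support
        if key in self._split_cache:
            return self._split_cache[key]
        ref = min(self._leaves)
        n = len(self._leaves)
        out = set()
        for nd in self._tree.preorder_internal_node_iter():
            if nd is self._tree.seed_node:
                continue
            if min_support is not None:
                s = _parse_support(nd.label)
                if s is None or s < min_support:
                    continue
            below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            side = below if ref not in below else self._leaves - below
            if 1 < len(side) < n - 1:
                out.add(side)
        result = frozenset(out)
        self._split_cache[key] = result
        return result

    def supports(self) -> dict[frozenset, float | None]:
        """Map canonical split -> support value (None when unannotated)."""
        ref = min(self._leaves)
        n = len(self._leaves)
        out = {}
        for nd in self._tree.preorder_internal_node_iter():
            if nd is self._tree.seed_node:
                continue
            below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            side = below if ref not in below else self._leaves - below
            if 1 < len(side) < n - 1:
                out[side] = _parse_support(nd.label)
        return out

    # -- serialisation -----------------------------------------------------
    def to_newick(self) -> str:
        return _serialize_node(self._tree.seed_node) + ";"

    def __repr__(self):
        return f"GeneTree({self.tree_id!r}, {self.n_leaves} leaves)"


def _parse_support(label) -> float | None:
    if label is None:
        return None
    try:
        return float(label)
    except (TypeError, ValueError):
        return None


def _serialize_node(nd) -> str:
    if nd.is_leaf():
        s = nd.taxon.label.replace(" ", "_")
    else:
        s = "(" + ",".join(_serialize_node(c) for c in nd.child_nodes()) + ")"
        if nd.label is not None:
            v = _parse_support(nd.label)
            s += _fmt_float(v) if v is not None else str(nd.label)
    if nd.edge.length is not None:
        s += ":" + _fmt_float(nd.edge.length)
    return s


def read_newick(path, id_prefix: str = "tree") -> list[GeneTree]:
    """Read one Newick tree per line; tree ids are ``{prefix}_0001``... in
    file order."""
    trees = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    lines = [ln for ln in lines if ln]
    width = max(4, len(str(len(lines))))
    for i, ln in enumerate(lines, 1):
        try:
            trees.append(GeneTree.from_newick(ln, tree_id=f"{id_prefix}_{i:0{width}d}"))
        except ParseError as exc:
            raise ParseError(f"tree on line {i}: {exc}", path=path, line=i)
    return trees


def write_newick(trees, path) -> None:
    with open(path, "w", newline="\n") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")


# ---------------------------------------------------------------------------
# FASTA (thin wrappers; sequences are plain uppercase strings)
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValidationError(f"duplicate FASTA record id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(records: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w", newline="\n") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every tuning knob of the pipeline with its default.

    Defaults mirror the published protocol: BLAST cutoffs E <= 1e-5 and
    >= 85% identity, a 1:1 synteny quota, a 90% matrix-occupancy cut-off,
    bootstrap support cutoff 100 for topology binning, and 80,000 label
    permutations for the block-coherence test with the significance ladder
    *** < 0.001, ** < 0.01, * < 0.05.
    """

    max_evalue: float = 1e-5
    min_identity_pct: float = 85.0
    quota: tuple[int, int] = (1, 1)
    min_anchors_per_block: int = 5
    max_gap_ranks: int = 20
    occupancy_fraction: float = 0.90
    min_species: int | None = None
    support_cutoff: float = 100.0
    n_permutations: int = 80_000
    alphas: tuple[float, ...] = (0.001, 0.01, 0.05)
    rng_seed: int = 17

    def __post_init__(self):
        if self.max_evalue < 0:
            raise ConfigurationError("max_evalue must be >= 0")
        if not (0 <= self.min_identity_pct <= 100):
            raise ConfigurationError("min_identity_pct must be in [0, 100]")
        if not (0 <= self.occupancy_fraction <= 1):
            raise ConfigurationError("occupancy_fraction must be in [0, 1]")
        if not (0 <= self.support_cutoff <= 100):
            raise ConfigurationError("support_cutoff must be in [0, 100]")
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if self.min_anchors_per_block < 1 or self.max_gap_ranks < 1:
            raise ConfigurationError("block chaining parameters must be >= 1")
        if any(not (0 < a < 1) for a in self.alphas):
            raise ConfigurationError("alphas must lie in (0, 1)")
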