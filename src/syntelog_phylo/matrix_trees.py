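"""Supermatrix construction and a self-contained distance-based tree engine.

The internal engine is deliberately distance-based: p-distances with pairwise
gap deletion, neighbor joining, and a column-resampling bootstrap.  It exists
so the whole pipeline runs end to end without external tree software;
maximum-likelihood or quartet-summary inference can be substituted through
the adapter hooks at the bottom of this module.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .core_io import GAP_CHARS, GeneTree, read_fasta
from .errors import ParseError, ValidationError


@dataclass
class Alignment:
    """One gene's multiple alignment: equal-length gapped rows per species."""

    gene_id: str
    rows: dict[str, str]

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValidationError(
                f"alignment {self.gene_id}: rows have unequal lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def species(self) -> list[str]:
        return sorted(self.rows)


@dataclass
class Supermatrix:
    """Concatenated gapped rows plus a 1-based inclusive partition table."""

    rows: dict[str, str]
    partitions: list  # (gene_id, start, end), tiling 1..total_length

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


def concatenate(alignments, species_roster) -> Supermatrix:
    """Concatenate gene alignments in lexicographic gene_id order.

    Species missing from a gene are filled with gaps; every species of the
    roster gets a full-length row.  Partition coordinates are 1-based
    inclusive, RAxML style.
    """
    roster = sorted(species_roster)
    roster_set = set(roster)
    for aln in alignments:
        extra = set(aln.rows) - roster_set
        if extra:
            raise ValidationError(
                f"alignment {aln.gene_id} contains species not in roster: "
                f"{sorted(extra)}"
            )
    parts = []
    chunks: dict[str, list] = {sp: [] for sp in roster}
    pos = 0
    for aln in sorted(alignments, key=lambda a: a.gene_id):
        L = aln.length
        parts.append((aln.gene_id, pos + 1, pos + L))
        for sp in roster:
            chunks[sp].append(aln.rows.get(sp, "-" * L))
        pos += L
    return Supermatrix(rows={sp: "".join(chunks[sp]) for sp in roster},
                       partitions=parts)


# ---------------------------------------------------------------------------
# distances and trees
# ---------------------------------------------------------------------------

def _encode(rows: dict[str, str]):
    labels = sorted(rows)
    mat = np.frombuffer("".join(rows[sp] for sp in labels).encode("ascii"),
                        dtype=np.uint8).reshape(len(labels), -1).copy()
    gap = np.zeros(mat.shape, dtype=bool)
    for ch in GAP_CHARS:
        gap |= mat == ord(ch)
    return labels, mat, gap


def p_distance_matrix(rows: dict[str, str]):
    """Pairwise p-distances with pairwise deletion of gap-containing sites.

    Returns (labels, matrix); entries with zero comparable sites are NaN.
    Raises on all-gap rows (no distance is defined for them at all).
    """
    if len(rows) < 2:
        raise ValidationError("need at least 2 sequences for distances")
    labels, mat, gap = _encode(rows)
    allgap = gap.all(axis=1)
    if allgap.any():
        bad = [labels[i] for i in np.flatnonzero(allgap)]
        raise ValidationError(f"all-gap rows for species: {bad}")
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        ok_i = ~gap[i]
        for j in range(i + 1, n):
            ok = ok_i & ~gap[j]
            m = int(ok.sum())
            if m == 0:
                dist[i, j] = dist[j, i] = np.nan
                continue
            mism = int((mat[i, ok] != mat[j, ok]).sum())
            dist[i, j] = dist[j, i] = mism / m
    return labels, dist


def neighbor_joining(labels, dist, tree_id: str = "nj") -> GeneTree:
    """Standard neighbor joining on a complete distance matrix (>= 3 taxa);
    negative branch lengths are clamped to zero."""
    dist = np.asarray(dist, dtype=float)
    if np.isnan(dist).any():
        raise ValidationError(
            "distance matrix has missing entries; drop those taxa or impute"
        )
    if len(labels) < 3:
        raise ValidationError("neighbor joining needs >= 3 taxa")
    dm = DistanceMatrix(dist, ids=list(labels))
    tree = _skbio_nj(dm, neg_as_zero=True)
    return GeneTree.from_newick(str(tree), tree_id=tree_id)


def nj_tree(rows: dict[str, str], tree_id: str = "nj") -> GeneTree:
    labels, dist = p_distance_matrix(rows)
    return neighbor_joining(labels, dist, tree_id=tree_id)


def bootstrap_support(alignment: Alignment, n_replicates: int = 100,
                      seed: int = 17, tree_id: str | None = None) -> GeneTree:
    """NJ tree of the alignment with column-resampling bootstrap supports.

    Support of each internal branch is the percentage of replicates whose NJ
    tree contains the same bipartition.  Replicates whose resampled matrix
    leaves some pair with no comparable sites are skipped and excluded from
    the denominator (rare outside pathological gap patterns).
    """
    tid = tree_id if tree_id is not None else alignment.gene_id
    labels, mat, gap = _encode(alignment.rows)
    base = nj_tree(alignment.rows, tree_id=tid)
    target = base.splits()
    rng = np.random.default_rng(seed)
    L = mat.shape[1]
    counts = {s: 0 for s in target}
    done = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rows_rep = {sp: bytes(mat[i, cols]).decode("ascii")
                    for i, sp in enumerate(labels)}
        try:
            rep = nj_tree(rows_rep)
        except ValidationError:
            continue
        done += 1
        for s in rep.splits():
            if s in counts:
                counts[s] += 1
    denom = max(done, 1)
    support = {s: 100.0 * c / denom for s, c in counts.items()}
    _annotate_supports(base, support)
    return base


def _annotate_supports(tree: GeneTree, support: dict) -> None:
    """Write per-split support percentages onto internal node labels."""
    t = tree.dendropy_tree
    leaves = tree.leaves
    ref = min(leaves)
    n = len(leaves)
    for nd in t.preorder_internal_node_iter():
        if nd is t.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        side = below if ref not in below else leaves - below
        if 1 < len(side) < n - 1:
            nd.label = f"{support.get(side, 0.0):g}"
    tree._split_cache.clear()


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------

def write_phylip(sm: Supermatrix, path) -> None:
    """Relaxed PHYLIP: name, two spaces, full sequence."""
    names = sorted(sm.rows)
    with open(path, "w", newline="\n") as fh:
        fh.write(f"{len(names)} {sm.length}\n")
        for name in names:
            fh.write(f"{name}  {sm.rows[name]}\n")


def write_supermatrix_fasta(sm: Supermatrix, path) -> None:
    from .core_io import write_fasta
    write_fasta({sp: sm.rows[sp] for sp in sorted(sm.rows)}, path)


def write_partitions(sm: Supermatrix, path) -> None:
    with open(path, "w", newline="\n") as fh:
        for gene_id, start, end in sm.partitions:
            fh.write(f"{gene_id} = {start}-{end}\n")


def read_partitions(path) -> list:
    parts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                name, rng = line.split("=")
                start, end = rng.strip().split("-")
                parts.append((name.strip(), int(start), int(end)))
            except ValueError:
                raise ParseError("bad partition line", path=path, line=lineno)
    return parts


def read_supermatrix(fasta_path, partitions_path) -> Supermatrix:
    rows = read_fasta(fasta_path)
    return Supermatrix(rows=rows, partitions=read_partitions(partitions_path))


# ---------------------------------------------------------------------------
# external-tool adapters (absent-safe)
# ---------------------------------------------------------------------------

def align_with_external(sequences: dict[str, str], gene_id: str,
                        aligner: str | None = "mafft") -> Alignment | None:
    """Align unaligned sequences through a mafft-compatible CLI
    (FASTA in -> FASTA out).  Returns None when the tool is absent, so the
    caller can fall back to pre-aligned input."""
    if aligner is None or shutil.which(aligner) is None:
        return None
    from .core_io import write_fasta
    with tempfile.TemporaryDirectory() as td:
        inp = Path(td) / "in.fasta"
        write_fasta(sequences, inp)
        proc = subprocess.run([aligner, "--auto", "--quiet", str(inp)],
                              capture_output=True, text=True, check=True)
        out = Path(td) / "out.fasta"
        out.write_text(proc.stdout)
        return Alignment(gene_id=gene_id, rows=read_fasta(out))
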