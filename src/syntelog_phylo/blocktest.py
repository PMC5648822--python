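"""Per-syntenic-block tree-distance distributions and the label-permutation
test for topological coherence.

A block whose genes share an evolutionary history (introgression, linked
selection) shows pairwise gene-tree RF distances *smaller* than random draws
from the pooled gene-tree set.  The test shuffles the tree-to-block
assignment (preserving block sizes), recomputes the per-block statistic each
time, and reports a one-sided lower-tail permutation p-value with the +1
correction, so p is never below 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedComparisonError, ValidationError
from .treecompare import rf_distance


@dataclass
class BlockAssignment:
    gene_to_block: dict[str, str]
    unblocked: list  # genes whose reference gene fell outside all blocks

    def block_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for b in self.gene_to_block.values():
            sizes[b] = sizes.get(b, 0) + 1
        return sizes


@dataclass
class BlockTestResult:
    block_id: str
    n_genes: int
    n_pairs_used: int
    observed_stat: float
    null_mean: float
    null_sd: float
    p_value: float
    stars: str


def assign_genes_to_blocks(groups, syntelogs, blocks) -> BlockAssignment:
    """Map ortholog groups (keyed by reference gene) to syntenic blocks via
    the syntelog table; genes outside every block are reported unblocked."""
    gene_to_block_ref = {p.gene_a: p.block_id for p in syntelogs}
    known_blocks = {b.block_id for b in blocks}
    mapping, unblocked = {}, []
    for g in groups:
        bid = gene_to_block_ref.get(g.ref_gene)
        if bid is None or bid not in known_blocks:
            unblocked.append(g.ref_gene)
        else:
            mapping[g.ref_gene] = bid
    return BlockAssignment(gene_to_block=mapping, unblocked=sorted(unblocked))


def _pairwise_rf_matrix(trees: list) -> np.ndarray:
    """Symmetric matrix of normalized RF distances; NaN where a pair shares
    fewer than 4 taxa (such pairs are skipped identically in observed and
    permuted statistics)."""
    n = len(trees)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = rf_distance(trees[i], trees[j], mode="normalized")
            except UndefinedComparisonError:
                d = np.nan
            D[i, j] = D[j, i] = d
    return D


def block_rf_distribution(gene_trees: dict, assignment: BlockAssignment,
                          block_id: str) -> np.ndarray:
    """All usable pairwise normalized RF values among one block's gene trees."""
    genes = sorted(g for g, b in assignment.gene_to_block.items() if b == block_id)
    vals = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            try:
                vals.append(rf_distance(gene_trees[genes[i]],
                                        gene_trees[genes[j]],
                                        mode="normalized"))
            except UndefinedComparisonError:
                continue
    return np.asarray(vals, dtype=float)


def _stars(p: float, alphas=(0.001, 0.01, 0.05)) -> str:
    a3, a2, a1 = sorted(alphas)
    if p < a3:
        return "***"
    if p < a2:
        return "**"
    if p < a1:
        return "*"
    return ""


def permutation_test(gene_trees: dict, assignment: BlockAssignment,
                     n_permutations: int = 80_000, seed: int = 17,
                     statistic: str = "mean",
                     alphas=(0.001, 0.01, 0.05)) -> list[BlockTestResult]:
    """Block-coherence test by random re-assignment of gene trees to blocks.

    The per-block statistic is the mean (or median) pairwise normalized RF
    distance among its trees.  Each of ``n_permutations`` shuffles permutes
    the gene->block label vector (block sizes preserved exactly) over the
    pooled trees and recomputes every block's statistic; the one-sided
    lower-tail p-value is (1 + #{perm <= observed}) / (1 + n_permutations).

    Genes are canonicalized by sorted id before any randomness, so the
    results do not depend on input ordering.
    """
    if n_permutations < 1:
        raise ConfigurationError("n_permutations must be >= 1")
    if statistic not in ("mean", "median"):
        raise ConfigurationError(f"unknown statistic {statistic!r}")
    genes = sorted(assignment.gene_to_block)
    if len(genes) < 2:
        raise ValidationError("need at least 2 assigned gene trees")
    missing = [g for g in genes if g not in gene_trees]
    if missing:
        raise ValidationError(f"no gene tree for assigned genes: {missing[:5]}")
    trees = [gene_trees[g] for g in genes]
    labels = [assignment.gene_to_block[g] for g in genes]
    block_ids = sorted(set(labels))
    if len(block_ids) < 2:
        raise ValidationError("need >= 2 blocks for a permutation test")
    n = len(genes)
    D = _pairwise_rf_matrix(trees)

    stat_fn = np.nanmean if statistic == "mean" else np.nanmedian
    block_pos = {b: np.flatnonzero(np.asarray(labels) == b) for b in block_ids}
    pair_idx = {}
    for b, pos in block_pos.items():
        m = len(pos)
        iu = np.triu_indices(m, k=1)
        pair_idx[b] = iu

    observed = {}
    n_pairs_used = {}
    for b, pos in block_pos.items():
        iu = pair_idx[b]
        vals = D[pos[iu[0]], pos[iu[1]]]
        usable = np.isfinite(vals)
        n_pairs_used[b] = int(usable.sum())
        with np.errstate(invalid="ignore"):
            observed[b] = float(stat_fn(vals)) if usable.any() else np.nan

    rng = np.random.default_rng(seed)
    hits = {b: 0 for b in block_ids}
    null_sum = {b: 0.0 for b in block_ids}
    null_sumsq = {b: 0.0 for b in block_ids}
    null_n = {b: 0 for b in block_ids}
    chunk = max(1, min(n_permutations, int(2_000_000 // max(n, 1))))
    done = 0
    eps = 1e-12
    while done < n_permutations:
        size = min(chunk, n_permutations - done)
        perms = np.argsort(rng.random((size, n)), axis=1)
        for b in block_ids:
            pos = block_pos[b]
            iu = pair_idx[b]
            members = perms[:, pos]  # (size, m)
            vals = D[members[:, iu[0]], members[:, iu[1]]]  # (size, n_pairs)
            with np.errstate(invalid="ignore"):
                stats = stat_fn(vals, axis=1) if vals.size else np.full(size, np.nan)
            finite = np.isfinite(stats)
            hits[b] += int(np.sum(stats[finite] <= observed[b] + eps))
            null_sum[b] += float(np.sum(stats[finite]))
            null_sumsq[b] += float(np.sum(stats[finite] ** 2))
            null_n[b] += int(finite.sum())
        done += size

    results = []
    for b in block_ids:
        k = null_n[b]
        mean = null_sum[b] / k if k else float("nan")
        var = null_sumsq[b] / k - mean ** 2 if k else float("nan")
        sd = float(np.sqrt(max(var, 0.0))) if k else float("nan")
        p = (1 + hits[b]) / (1 + n_permutations)
        results.append(BlockTestResult(
            block_id=b, n_genes=len(block_pos[b]),
            n_pairs_used=n_pairs_used[b], observed_stat=observed[b],
            null_mean=mean, null_sd=sd, p_value=p,
            stars=_stars(p, alphas)))
    return results


def block_concat_trees(assignment: BlockAssignment, alignments: dict,
                       n_bootstrap: int = 100, seed: int = 17) -> dict:
    """One tree per block from the concatenation of its member alignments,
    using the internal NJ + bootstrap engine.  Blocks whose concatenated
    matrix covers fewer than 4 species are skipped."""
    from .matrix_trees import Alignment, bootstrap_support, concatenate

    out = {}
    by_block: dict[str, list] = {}
    for gene, bid in assignment.gene_to_block.items():
        if gene in alignments:
            by_block.setdefault(bid, []).append(alignments[gene])
    for bid in sorted(by_block):
        alns = by_block[bid]
        roster = sorted({sp for a in alns for sp in a.rows})
        if len(roster) < 4:
            continue
        sm = concatenate(alns, roster)
        merged = Alignment(gene_id=bid, rows=sm.rows)
        out[bid] = bootstrap_support(merged, n_replicates=n_bootstrap,
                                     seed=seed, tree_id=bid)
    return out


def block_report(results, blocks, reference_labels: dict | None = None) -> pd.DataFrame:
    """Per-block summary table (reference-genome coordinates, statistic,
    p-value, stars, optional topology label), ordered by chromosome then span."""
    meta = {b.block_id: b for b in blocks}
    rows = []
    for r in results:
        blk = meta.get(r.block_id)
        rows.append({
            "block_id": r.block_id,
            "chrom_a": blk.chrom_a if blk else "",
            "span_a_start": blk.span_a[0] if blk else -1,
            "span_a_end": blk.span_a[1] if blk else -1,
            "n_genes": r.n_genes,
            "n_pairs_used": r.n_pairs_used,
            "observed_stat": r.observed_stat,
            "null_mean": r.null_mean,
            "null_sd": r.null_sd,
            "p_value": r.p_value,
            "stars": r.stars,
            "reference_label": (reference_labels or {}).get(r.block_id, ""),
        })
    df = pd.DataFrame(rows)
    return df.sort_values(["chrom_a", "span_a_start", "block_id"],
                          kind="stable").reset_index(drop=True)
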