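"""Collinear-block inference between two anchor genomes and extraction of
single-copy syntenic orthologs (syntelogs).

Chaining operates on gene *ranks* (order indices), not base pairs.  Blocks are
maximal-count monotone chains of homology anchors found by dynamic programming
per chromosome pair and orientation, extracted greedily (best chain first,
members removed, repeat).  A 1:1 quota filter then rejects blocks whose rank
span overlaps an already accepted block in either genome, removing
whole-genome-duplication-derived paralogous block copies; finally any gene
still appearing in more than one anchor pair is discarded, so the surviving
pairs are strictly one-to-one.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import GenomeAnnotation, HomologyHit
from .errors import ConfigurationError, ValidationError


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    chrom_a: str
    chrom_b: str
    score: float  # bitscore of the best supporting hit


@dataclass
class SyntenicBlock:
    block_id: str
    anchors: list  # ordered by rank_a
    orientation: str  # '+' or '-'
    chrom_a: str
    chrom_b: str
    span_a: tuple[int, int]  # inclusive rank interval
    span_b: tuple[int, int]
    score: float

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass(frozen=True)
class SyntelogPair:
    gene_a: str
    gene_b: str
    block_id: str


def build_anchors(hits, annot_a: GenomeAnnotation, annot_b: GenomeAnnotation,
                  max_evalue: float = 1e-5,
                  min_identity_pct: float = 85.0) -> list[Anchor]:
    """Threshold hits and keep the best-bitscore hit per gene pair as an anchor."""
    unknown = sorted({h.query_id for h in hits if h.query_id not in annot_a} |
                     {h.subject_id for h in hits if h.subject_id not in annot_b})
    if unknown:
        raise ValidationError(
            f"hits reference {len(unknown)} unknown gene ids: "
            + ", ".join(unknown[:10]) + ("..." if len(unknown) > 10 else "")
        )
    best: dict[tuple[str, str], HomologyHit] = {}
    for h in hits:
        if h.evalue > max_evalue or h.percent_identity < min_identity_pct:
            continue
        key = (h.query_id, h.subject_id)
        cur = best.get(key)
        if cur is None or (h.bitscore, -h.evalue) > (cur.bitscore, -cur.evalue):
            best[key] = h
    anchors = []
    for (ga, gb), h in best.items():
        ma, mb = annot_a[ga], annot_b[gb]
        anchors.append(Anchor(ga, gb, ma.rank, mb.rank,
                              ma.chromosome, mb.chromosome, h.bitscore))
    anchors.sort(key=lambda a: (a.chrom_a, a.chrom_b, a.rank_a, a.rank_b))
    return anchors


def _best_chain(anchors, max_gap_ranks: int, orientation: str):
    """Best monotone chain by DP over anchors sorted by (rank_a, rank_b).

    An anchor extends a chain iff 1 <= rank_a gap <= max_gap_ranks and the
    rank_b gap is in the same window in the direction of ``orientation``.
    Chains are scored by anchor count; ties broken by total bitscore (higher
    first), then smaller start rank_a.  Returns (count, total_bitscore, chain).
    """
    order = sorted(anchors, key=lambda a: (a.rank_a, a.rank_b))
    n = len(order)
    if n == 0:
        return 0, 0.0, []
    sign = 1 if orientation == "+" else -1
    count = [1] * n
    weight = [a.score for a in order]
    prev = [-1] * n
    for i in range(n):
        ai = order[i]
        for j in range(i - 1, -1, -1):
            aj = order[j]
            da = ai.rank_a - aj.rank_a
            if da > max_gap_ranks:
                break  # sorted by rank_a: earlier j only farther away
            if da < 1:
                continue
            db = sign * (ai.rank_b - aj.rank_b)
            if not (1 <= db <= max_gap_ranks):
                continue
            cand = (count[j] + 1, weight[j] + ai.score)
            if cand > (count[i], weight[i]):
                count[i], weight[i] = cand
                prev[i] = j
    best_i = max(range(n),
                 key=lambda i: (count[i], weight[i], -order[i].rank_a))
    chain = []
    i = best_i
    while i != -1:
        chain.append(order[i])
        i = prev[i]
    chain.reverse()
    return count[best_i], weight[best_i], chain


def chain_anchors(anchors, min_anchors_per_block: int = 5,
                  max_gap_ranks: int = 20) -> list[SyntenicBlock]:
    """Greedy extraction of collinear blocks per chromosome pair.

    Repeatedly find the single best chain over all (chrom_a, chrom_b) pairs
    and both orientations, emit it as a block, remove its anchors, and repeat
    until the best remaining chain is shorter than ``min_anchors_per_block``.
    """
    groups: dict[tuple[str, str], list] = {}
    for a in anchors:
        groups.setdefault((a.chrom_a, a.chrom_b), []).append(a)
    blocks = []
    for key in sorted(groups):
        pool = list(groups[key])
        while True:
            candidates = []
            for orientation in ("+", "-"):
                cnt, wt, chain = _best_chain(pool, max_gap_ranks, orientation)
                if cnt >= min_anchors_per_block:
                    candidates.append((cnt, wt, -chain[0].rank_a, orientation, chain))
            if not candidates:
                break
            cnt, wt, _negstart, orientation, chain = max(
                candidates, key=lambda c: (c[0], c[1], c[2], c[3] == "+"))
            if cnt == 1:
                orientation = "+"
            ranks_a = [a.rank_a for a in chain]
            ranks_b = [a.rank_b for a in chain]
            blocks.append(SyntenicBlock(
                block_id="", anchors=chain, orientation=orientation,
                chrom_a=key[0], chrom_b=key[1],
                span_a=(min(ranks_a), max(ranks_a)),
                span_b=(min(ranks_b), max(ranks_b)),
                score=float(cnt),
            ))
            used = set((a.gene_a, a.gene_b) for a in chain)
            pool = [a for a in pool if (a.gene_a, a.gene_b) not in used]
    blocks.sort(key=lambda b: (b.chrom_a, b.span_a, b.chrom_b, b.span_b))
    for i, b in enumerate(blocks, 1):
        b.block_id = f"block_{i:04d}"
    return blocks


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Overlap length (ranks) of two inclusive intervals."""
    return min(a[1], b[1]) - max(a[0], b[0]) + 1


def quota_filter(blocks, quota: tuple[int, int] = (1, 1),
                 overlap_tolerance: int = 0) -> list[SyntenicBlock]:
    """Greedy 1:1 quota: accept blocks in decreasing score order, rejecting
    any whose rank span overlaps an accepted block's span (same chromosome,
    either genome) by more than ``overlap_tolerance`` ranks."""
    if tuple(quota) != (1, 1):
        raise NotImplementedError(f"only a 1:1 quota is supported, got {quota}")
    ordered = sorted(blocks, key=lambda b: (-b.score, b.chrom_a, b.span_a,
                                            b.chrom_b, b.span_b, b.block_id))
    accepted: list[SyntenicBlock] = []
    for cand in ordered:
        ok = True
        for acc in accepted:
            if (cand.chrom_a == acc.chrom_a
                    and _overlap(cand.span_a, acc.span_a) > overlap_tolerance):
                ok = False
                break
            if (cand.chrom_b == acc.chrom_b
                    and _overlap(cand.span_b, acc.span_b) > overlap_tolerance):
                ok = False
                break
        if ok:
            accepted.append(cand)
    accepted.sort(key=lambda b: (b.chrom_a, b.span_a, b.chrom_b, b.span_b))
    return accepted


def extract_syntelogs(blocks) -> list[SyntelogPair]:
    """Anchor pairs of quota-filtered blocks, minus any pair containing a gene
    seen more than once on either side — the surviving set is strictly 1:1."""
    pairs = [(a.gene_a, a.gene_b, b.block_id) for b in blocks for a in b.anchors]
    count_a: dict[str, int] = {}
    count_b: dict[str, int] = {}
    for ga, gb, _ in pairs:
        count_a[ga] = count_a.get(ga, 0) + 1
        count_b[gb] = count_b.get(gb, 0) + 1
    return [SyntelogPair(ga, gb, bid) for ga, gb, bid in pairs
            if count_a[ga] == 1 and count_b[gb] == 1]


def infer_syntelogs(hits, annot_a, annot_b, config=None):
    """Full anchor->chain->quota->extract pipeline for one genome pair.

    Returns (blocks, syntelog pairs)."""
    from .core_io import PipelineConfig

    cfg = config or PipelineConfig()
    anchors = build_anchors(hits, annot_a, annot_b,
                            cfg.max_evalue, cfg.min_identity_pct)
    blocks = chain_anchors(anchors, cfg.min_anchors_per_block, cfg.max_gap_ranks)
    blocks = quota_filter(blocks, cfg.quota)
    return blocks, extract_syntelogs(blocks)


def pairwise_syntelog_table(pivot: GenomeAnnotation, others,
                            hit_tables: dict, config=None) -> dict:
    """Pairwise 1:1 syntelog tables between a pivot genome and each other
    genome; ``hit_tables`` maps genome_id -> hits (pivot genes as queries)."""
    out = {}
    for other in others:
        if other.genome_id not in hit_tables:
            raise ConfigurationError(
                f"no hit table provided for genome {other.genome_id!r}"
            )
        _, pairs = infer_syntelogs(hit_tables[other.genome_id],
                                   pivot, other, config)
        out[other.genome_id] = pairs
    return out
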