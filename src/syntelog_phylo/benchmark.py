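"""Fully synteny-derived benchmark ortholog set and gene-membership agreement
scoring of predicted ortholog groupings.

The benchmark is built from pairwise 1:1 syntelog tables keyed by a pivot
genome: for every pivot gene its group is the pivot gene plus its syntelog in
each genome whose table contains it.  A predicted group *agrees* with the
benchmark when its benchmark-resident genes all point to one benchmark group
and (in strict mode) that group holds no conflicting member for any genome
the prediction covers.  Genes absent from the benchmark can never be judged;
they only move a group between the two denominators reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError


@dataclass
class BenchmarkSet:
    pivot_genome: str
    groups: dict  # pivot_gene -> {genome_id: gene_id} (pivot genome included)
    gene_to_group: dict = field(default_factory=dict)  # gene_id -> pivot_gene

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_to_group


def build_benchmark_set(pairwise_tables: dict, pivot_genome: str = "pivot") -> BenchmarkSet:
    """``pairwise_tables``: genome_id -> SyntelogPair list with the pivot
    gene on the a-side.  Groups of size >= 2 (pivot + at least one partner)
    are kept; any partner gene appearing under two pivot genes violates the
    1:1 origins and raises."""
    groups: dict[str, dict] = {}
    for genome_id in sorted(pairwise_tables):
        for p in pairwise_tables[genome_id]:
            groups.setdefault(p.gene_a, {pivot_genome: p.gene_a})
            if genome_id in groups[p.gene_a]:
                raise ValidationError(
                    f"pivot gene {p.gene_a} has two partners in {genome_id}")
            groups[p.gene_a][genome_id] = p.gene_b
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    gene_to_group: dict[str, str] = {}
    for pivot_gene, members in groups.items():
        for gene in members.values():
            if gene in gene_to_group:
                raise ValidationError(
                    f"gene {gene} appears in two benchmark groups "
                    f"({gene_to_group[gene]}, {pivot_gene}); 1:1 violated")
            gene_to_group[gene] = pivot_gene
    return BenchmarkSet(pivot_genome=pivot_genome, groups=groups,
                        gene_to_group=gene_to_group)


@dataclass
class ThresholdReport:
    min_genomes: int
    n_agreeing: int
    n_total_all: int
    n_total_in_benchmark: int
    n_unjudgeable: int
    pct_all: float
    pct_excluding: float


@dataclass
class AgreementReport:
    per_threshold: list  # ThresholdReport, one per requested min genome count
    venn_shared: int
    venn_benchmark_only: int
    venn_predicted_only: int


def _judge(members: dict, benchmark: BenchmarkSet, strict: bool):
    """Return (verdict, resident_count) for one predicted group.

    verdict: True = agrees, False = disagrees, None = unjudgeable (< 2
    benchmark-resident genes)."""
    resident = {gnm: g for gnm, g in members.items() if g in benchmark}
    if len(resident) < 2:
        return None, len(resident)
    targets = {benchmark.gene_to_group[g] for g in resident.values()}
    if len(targets) != 1:
        return False, len(resident)
    (key,) = targets
    if strict:
        bench_members = benchmark.groups[key]
        for genome_id, gene in members.items():
            if genome_id in bench_members and bench_members[genome_id] != gene:
                return False, len(resident)
    return True, len(resident)


def compare_to_benchmark(predicted_groups, benchmark: BenchmarkSet,
                         species_count_thresholds=(4, 5, 6),
                         strict: bool = True) -> AgreementReport:
    """Score predicted groups (each a {genome_id: gene_id} mapping) against
    the benchmark at each minimum-genome-count threshold.

    Two denominators are reported: every qualifying group, and only groups
    all of whose genes occur in the benchmark.  Unjudgeable groups count as
    non-agreeing in the first denominator and are tallied separately.
    """
    preds = []
    for i, members in enumerate(predicted_groups):
        if not isinstance(members, dict):
            raise ValidationError("each predicted group must map genome -> gene")
        if len(set(members.values())) != len(members):
            raise ValidationError(f"predicted group {i} repeats a gene id")
        preds.append(members)

    per_threshold = []
    for k in species_count_thresholds:
        qualifying = [m for m in preds if len(m) >= k]
        n_all = len(qualifying)
        n_agree = 0
        n_in_bench = 0
        n_unjudge = 0
        for members in qualifying:
            verdict, _ = _judge(members, benchmark, strict)
            fully_resident = all(g in benchmark for g in members.values())
            if fully_resident:
                n_in_bench += 1
            if verdict is True:
                n_agree += 1
            elif verdict is None:
                n_unjudge += 1
        per_threshold.append(ThresholdReport(
            min_genomes=k, n_agreeing=n_agree, n_total_all=n_all,
            n_total_in_benchmark=n_in_bench, n_unjudgeable=n_unjudge,
            pct_all=100.0 * n_agree / n_all if n_all else 0.0,
            pct_excluding=(100.0 * n_agree / n_in_bench) if n_in_bench else 0.0,
        ))

    # Venn over group keys: a predicted group is matched to a benchmark group
    # through its pivot-genome gene when it has one.
    bench_keys = set(benchmark.groups)
    pred_keys = set()
    unkeyed = 0
    for members in preds:
        pg = members.get(benchmark.pivot_genome)
        if pg is not None and pg in bench_keys:
            pred_keys.add(pg)
        else:
            unkeyed += 1
    return AgreementReport(
        per_threshold=per_threshold,
        venn_shared=len(pred_keys & bench_keys),
        venn_benchmark_only=len(bench_keys - pred_keys),
        venn_predicted_only=unkeyed + len(pred_keys - bench_keys),
    )
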