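"""Synthetic data with known truth for every pipeline stage.

The generator emulates the study design the pipeline targets: two sequenced
anchor genomes related by inversions, translocations, gene losses, and
tandem/dispersed duplications (the duplicates are the paralog decoys the 1:1
quota filter must reject); an ultrametric species tree in coalescent units; a
multispecies-coalescent gene-tree sample whose discordance can be made
block-coherent (an introgression-like signal, strength gamma per block);
JC69 sequences; and BLAST-tabular hit files whose identities derive from the
simulated divergences.  Everything is reproducible from a single seed and the
truth is returned alongside the artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import GeneModel, GenomeAnnotation, GeneTree, HomologyHit
from .errors import ConfigurationError
from .matrix_trees import Alignment

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimTruth:
    """Ground truth of one simulated scenario."""

    true_syntelogs: list = field(default_factory=list)  # (gene_a, gene_b)
    decoys: dict = field(default_factory=dict)  # decoy gene_b -> source gene_a
    true_blocks: dict = field(default_factory=dict)  # gene -> block label
    block_topology: dict = field(default_factory=dict)  # block -> "main"/"alt"
    gene_tree_source: dict = field(default_factory=dict)  # gene -> "main"/"alt"
    species_tree: GeneTree | None = None
    alt_tree: GeneTree | None = None
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# anchor genome pair
# ---------------------------------------------------------------------------

def _make_annotation(genome_id: str, per_chrom: dict[str, list[str]],
                     spacing: int = 1000, width: int = 500) -> GenomeAnnotation:
    genes = []
    for chrom in sorted(per_chrom):
        for rank, gid in enumerate(per_chrom[chrom]):
            start = rank * spacing
            genes.append(GeneModel(gid, chrom, start, start + width, "+", rank))
    return GenomeAnnotation(genome_id, genes)


def simulate_genome_pair(n_chromosomes: int = 3, genes_per_chromosome: int = 400,
                         n_inversions: int = 5, n_translocations: int = 2,
                         loss_rate: float = 0.0, tandem_dup_rate: float = 0.0,
                         dispersed_dup_rate: float = 0.05, seed: int = 17,
                         segment_range: tuple[int, int] = (45, 80)):
    """Genome B = genome A's gene order transformed by losses, inversions,
    translocations and duplications.  Returns (annot_a, annot_b, truth);
    duplicate copies are registered as decoys, everything else is a true
    1:1 syntelog."""
    for r in (loss_rate, tandem_dup_rate, dispersed_dup_rate):
        if not (0.0 <= r < 1.0):
            raise ConfigurationError(f"rate {r} outside [0, 1)")
    if n_chromosomes < 1 or genes_per_chromosome < 1:
        raise ConfigurationError("genome sizes must be >= 1")
    rng = np.random.default_rng(seed)
    chroms_a = {f"chrA{c + 1}": [f"gA_{c + 1}_{i:04d}"
                                 for i in range(genes_per_chromosome)]
                for c in range(n_chromosomes)}
    # entry = (b_gene_id, source_a_gene_id, is_decoy)
    chroms_b: dict[str, list] = {}
    for c in range(n_chromosomes):
        name_b = f"chrB{c + 1}"
        chroms_b[name_b] = [
            (f"gB_{c + 1}_{i:04d}", chroms_a[f"chrA{c + 1}"][i], False)
            for i in range(genes_per_chromosome)
        ]
    b_names = sorted(chroms_b)

    if loss_rate > 0:
        for name in b_names:
            keep = rng.random(len(chroms_b[name])) >= loss_rate
            chroms_b[name] = [e for e, k in zip(chroms_b[name], keep) if k]

    lo, hi = segment_range
    for _ in range(n_inversions):
        name = b_names[rng.integers(len(b_names))]
        seq = chroms_b[name]
        if len(seq) < lo + 2:
            continue
        seg = int(rng.integers(lo, min(hi, len(seq) - 1) + 1))
        start = int(rng.integers(0, len(seq) - seg + 1))
        chroms_b[name] = seq[:start] + seq[start:start + seg][::-1] + seq[start + seg:]

    for _ in range(n_translocations):
        src = b_names[rng.integers(len(b_names))]
        seq = chroms_b[src]
        if len(seq) < lo + 2:
            continue
        seg = int(rng.integers(lo, min(hi, len(seq) - 1) + 1))
        start = int(rng.integers(0, len(seq) - seg + 1))
        moved = seq[start:start + seg]
        chroms_b[src] = seq[:start] + seq[start + seg:]
        dst = b_names[rng.integers(len(b_names))]
        pos = int(rng.integers(0, len(chroms_b[dst]) + 1))
        chroms_b[dst] = chroms_b[dst][:pos] + moved + chroms_b[dst][pos:]

    decoys: dict[str, str] = {}
    if tandem_dup_rate > 0:
        for name in b_names:
            out = []
            for entry in chroms_b[name]:
                out.append(entry)
                if not entry[2] and rng.random() < tandem_dup_rate:
                    dup_id = entry[0] + "_td"
                    out.append((dup_id, entry[1], True))
                    decoys[dup_id] = entry[1]
            chroms_b[name] = out
    if dispersed_dup_rate > 0:
        new_copies = []
        for name in b_names:
            for entry in chroms_b[name]:
                if not entry[2] and rng.random() < dispersed_dup_rate:
                    dup_id = entry[0] + "_dd"
                    new_copies.append((dup_id, entry[1], True))
                    decoys[dup_id] = entry[1]
        for copy in new_copies:
            dst = b_names[rng.integers(len(b_names))]
            pos = int(rng.integers(0, len(chroms_b[dst]) + 1))
            chroms_b[dst] = chroms_b[dst][:pos] + [copy] + chroms_b[dst][pos:]

    truth = SimTruth(
        true_syntelogs=[(src, gid) for name in b_names
                        for gid, src, dec in chroms_b[name] if not dec],
        decoys=decoys,
        params=dict(n_chromosomes=n_chromosomes,
                    genes_per_chromosome=genes_per_chromosome,
                    n_inversions=n_inversions, n_translocations=n_translocations,
                    loss_rate=loss_rate, tandem_dup_rate=tandem_dup_rate,
                    dispersed_dup_rate=dispersed_dup_rate, seed=seed),
    )
    annot_a = _make_annotation("A", chroms_a)
    annot_b = _make_annotation(
        "B", {name: [gid for gid, _, _ in chroms_b[name]] for name in b_names})
    return annot_a, annot_b, truth


# ---------------------------------------------------------------------------
# species trees and the multispecies coalescent
# ---------------------------------------------------------------------------

def random_ultrametric_tree(labels, step: float = 1.0, rng=None,
                            tree_id: str = "species_tree",
                            exponential_steps: bool = False) -> GeneTree:
    """Random-topology ultrametric tree: lineages are joined in random order,
    each join ``step`` coalescent units above the previous (or an Exp(step)
    increment when ``exponential_steps``), so every internal branch is at
    least one increment long."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lineages = [(lbl, 0.0) for lbl in sorted(labels)]
    height = 0.0
    while len(lineages) > 1:
        height += rng.exponential(step) if exponential_steps else step
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        nj_, hi_ = lineages.pop(j)
        ni_, hi2 = lineages.pop(i)
        merged = (f"({ni_}:{height - hi2:.8g},{nj_}:{height - hi_:.8g})", height)
        lineages.append(merged)
    return GeneTree.from_newick(lineages[0][0] + ";", tree_id=tree_id)


def sample_coalescent_tree(species_tree: GeneTree, rng,
                           tree_id: str = "gene") -> GeneTree:
    """One gene tree under the multispecies coalescent, one haploid sample
    per species.  Within every species-tree branch, the k extant lineages
    coalesce with Exponential(k(k-1)/2) waiting times in coalescent units;
    lineages remaining at the root coalesce freely."""
    t = species_tree.dendropy_tree
    heights: dict = {}
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            heights[nd] = 0.0
        else:
            heights[nd] = max(heights[c] + (c.edge.length or 0.0)
                              for c in nd.child_nodes())

    def _coalesce(lineages, t0, t1):
        cur = t0
        lineages = list(lineages)
        while len(lineages) > 1:
            k = len(lineages)
            cur += rng.exponential(2.0 / (k * (k - 1)))
            if cur > t1:
                break
            i, j = sorted(rng.choice(k, size=2, replace=False))
            nwk_j, h_j = lineages.pop(j)
            nwk_i, h_i = lineages.pop(i)
            lineages.append((
                f"({nwk_i}:{cur - h_i:.8g},{nwk_j}:{cur - h_j:.8g})", cur))
        return lineages

    pending: dict = {}
    root = t.seed_node
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            incoming = [(nd.taxon.label, 0.0)]
        else:
            incoming = [lin for c in nd.child_nodes() for lin in pending[c]]
        if nd is root:
            (final,) = _coalesce(incoming, heights[nd], np.inf)
            return GeneTree.from_newick(final[0] + ";", tree_id=tree_id)
        top = heights[nd] + (nd.edge.length or 0.0)
        pending[nd] = _coalesce(incoming, heights[nd], top)
    raise AssertionError("unreachable")


def simulate_gene_trees(species_tree: GeneTree, genes: dict,
                        block_structure: dict | None = None,
                        seed: int = 17):
    """Coalescent gene trees with block-coherent discordance.

    ``genes`` maps gene_id -> block label (or None); ``block_structure`` maps
    block label -> (alternative species topology, coherence gamma).  Each
    gene's tree is drawn under the MSC from the alternative topology with
    probability gamma of its block, else from the main species tree.
    Returns (gene_id -> GeneTree, gene_id -> "main"/"alt").
    """
    rng = np.random.default_rng(seed)
    block_structure = block_structure or {}
    trees: dict[str, GeneTree] = {}
    labels: dict[str, str] = {}
    for gene in sorted(genes):
        block = genes[gene]
        alt, gamma = block_structure.get(block, (None, 0.0))
        use_alt = alt is not None and rng.random() < gamma
        src = alt if use_alt else species_tree
        trees[gene] = sample_coalescent_tree(src, rng, tree_id=gene)
        labels[gene] = "alt" if use_alt else "main"
    return trees, labels


# ---------------------------------------------------------------------------
# sequence evolution (JC69)
# ---------------------------------------------------------------------------

def jc69_p_distance(d: float) -> float:
    """Expected proportion of differing sites at branch length d (subs/site)."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def evolve_sequences(gene_tree: GeneTree, length: int, rate_scaling: float = 1.0,
                     seed=None, rng=None, gene_id: str | None = None,
                     return_root: bool = False):
    """Evolve nucleotide sequences down a gene tree under JC69.

    Branch lengths are multiplied by ``rate_scaling`` to convert coalescent
    units to substitutions per site.  The root sequence is uniform over ACGT;
    along each branch every site substitutes independently with the JC69
    probability and, if it does, moves to one of the three other bases.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(seed)
    t = gene_tree.dendropy_tree
    seqs: dict = {}
    root_states = rng.integers(0, 4, size=length, dtype=np.uint8)
    states = {t.seed_node: root_states}
    rows: dict[str, str] = {}
    for nd in t.preorder_node_iter():
        if nd is t.seed_node:
            cur = root_states
        else:
            parent = states[nd.parent_node]
            d = (nd.edge.length or 0.0) * rate_scaling
            p = jc69_p_distance(d)
            mask = rng.random(length) < p
            cur = parent.copy()
            if mask.any():
                shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
                cur[mask] = (cur[mask] + shift) % 4
            states[nd] = cur
        if nd.is_leaf():
            rows[nd.taxon.label] = bytes(_BASES[cur]).decode("ascii")
        seqs[nd] = cur
    aln = Alignment(gene_id=gene_id or gene_tree.tree_id, rows=rows)
    if return_root:
        return aln, bytes(_BASES[root_states]).decode("ascii")
    return aln


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

def _hit_row(query: str, subject: str, pident: float, length: int) -> HomologyHit:
    """E-value and bitscore as monotone deterministic surrogates of identity;
    the pipeline only thresholds and ranks them."""
    pident = float(min(100.0, max(0.0, pident)))
    bitscore = round(2.0 * pident * length / 100.0, 1)
    evalue = 10.0 ** max(-180.0, -bitscore / 10.0)
    return HomologyHit(query, subject, round(pident, 2), length, evalue, bitscore)


def emit_genome_hits(truth: SimTruth, seed: int = 17, length: int = 300,
                     ortholog_identity: tuple[float, float] = (92.0, 1.5),
                     decoy_identity: tuple[float, float] = (80.0, 3.0)):
    """Genome-vs-genome hits: one row per true syntelog pair with identity
    around the ortholog level, one per decoy paralog at a depressed level
    (straddling the 85% cutoff, so a handful survive filtering and must be
    rejected by chaining/quota instead)."""
    rng = np.random.default_rng(seed)
    hits = []
    for ga, gb in truth.true_syntelogs:
        mu, sd = ortholog_identity
        hits.append(_hit_row(ga, gb, rng.normal(mu, sd), length))
    for dup_id, src in sorted(truth.decoys.items()):
        mu, sd = decoy_identity
        hits.append(_hit_row(src, dup_id, rng.normal(mu, sd), length))
    return hits


def p_distance_pair(s1: str, s2: str) -> float:
    a = np.frombuffer(s1.encode(), dtype=np.uint8)
    b = np.frombuffer(s2.encode(), dtype=np.uint8)
    return float((a != b).mean())


def emit_transcript_hits(transcripts: dict[str, str], ref_sequences: dict[str, str],
                         transcript_to_gene: dict[str, str], seed: int = 17,
                         noise_sd: float = 0.3):
    """Transcript-vs-reference hits; identity = 100 x (1 - p-distance to the
    reference sequence) plus Gaussian noise, clipped to [0, 100]."""
    rng = np.random.default_rng(seed)
    hits = []
    for tid in sorted(transcripts):
        gene = transcript_to_gene[tid]
        seq = transcripts[tid]
        ident = 100.0 * (1.0 - p_distance_pair(seq, ref_sequences[gene]))
        hits.append(_hit_row(tid, gene, ident + rng.normal(0.0, noise_sd), len(seq)))
    return hits


def emit_hit_tables(scenario, outdir) -> dict:
    """Write both hit tables of a simulated scenario as BLAST outfmt-6 files;
    returns {"genome": path, "transcript": path}."""
    from pathlib import Path

    from .core_io import write_hits

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"genome": outdir / "genome_hits.blast6",
             "transcript": outdir / "transcript_hits.blast6"}
    write_hits(scenario.genome_hits, paths["genome"])
    write_hits(scenario.transcript_hits, paths["transcript"])
    return paths


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------

@dataclass
class SimScenario:
    """Everything one end-to-end run of the pipeline needs, plus the truth."""

    annot_a: GenomeAnnotation
    annot_b: GenomeAnnotation
    truth: SimTruth
    genome_hits: list
    species: list
    species_tree: GeneTree
    gene_trees: dict
    alignments: dict  # ref_gene -> Alignment (rows keyed by species)
    ref_sequences: dict  # ref_gene -> ancestral sequence
    transcripts: dict  # transcript_id -> sequence
    transcript_to_species: dict
    transcript_hits: list
    gene_to_block: dict


def simulate_study(n_species: int = 10, n_chromosomes: int = 2,
                   genes_per_chromosome: int = 200, n_genes: int = 300,
                   block_size: int = 10, seq_length: int = 300,
                   rate_scaling: float = 0.002, species_step: float = 5.0,
                   missing_rate: float = 0.05, transcript_dup_rate: float = 0.0,
                   gamma: float = 0.0, n_alt_blocks: int = 0,
                   n_inversions: int = 3, n_translocations: int = 1,
                   dispersed_dup_rate: float = 0.02,
                   seed: int = 17) -> SimScenario:
    """One coherent synthetic study.

    Anchor genomes A and B are simulated with rearrangements and decoys; the
    first ``n_genes`` true syntelog reference genes (A side) are carved into
    consecutive blocks of ``block_size`` along genome A; the first
    ``n_alt_blocks`` blocks draw their gene trees from a single alternative
    topology with coherence ``gamma`` (an introgression-like signal); species
    transcripts are the leaf rows of JC69 alignments evolved on each gene
    tree, dropped with ``missing_rate`` to exercise occupancy filtering.
    """
    rng = np.random.default_rng(seed)
    annot_a, annot_b, truth = simulate_genome_pair(
        n_chromosomes=n_chromosomes, genes_per_chromosome=genes_per_chromosome,
        n_inversions=n_inversions, n_translocations=n_translocations,
        dispersed_dup_rate=dispersed_dup_rate,
        seed=int(rng.integers(2**31 - 1)))
    ref_genes = sorted(ga for ga, _ in truth.true_syntelogs)[:n_genes]
    if len(ref_genes) < n_genes:
        raise ConfigurationError(
            f"only {len(ref_genes)} true syntelogs available for {n_genes} genes")
    gene_to_block = {g: f"simblock_{i // block_size + 1:03d}"
                     for i, g in enumerate(ref_genes)}
    truth.true_blocks = dict(gene_to_block)

    species = [f"sp{i + 1:02d}" for i in range(n_species)]
    species_tree = random_ultrametric_tree(
        species, step=species_step, rng=rng, tree_id="species_tree")
    alt_tree = random_ultrametric_tree(
        species, step=species_step, rng=rng, tree_id="alt_tree")
    truth.species_tree = species_tree
    truth.alt_tree = alt_tree
    blocks = sorted({b for b in gene_to_block.values()})
    structure = {}
    for i, b in enumerate(blocks):
        if i < n_alt_blocks:
            structure[b] = (alt_tree, gamma)
            truth.block_topology[b] = "alt"
        else:
            truth.block_topology[b] = "main"
    gene_trees, labels = simulate_gene_trees(
        species_tree, gene_to_block, structure, seed=int(rng.integers(2**31 - 1)))
    truth.gene_tree_source = labels

    alignments: dict[str, Alignment] = {}
    ref_sequences: dict[str, str] = {}
    transcripts: dict[str, str] = {}
    transcript_to_species: dict[str, str] = {}
    transcript_to_gene: dict[str, str] = {}
    for gene in ref_genes:
        aln, root = evolve_sequences(gene_trees[gene], seq_length,
                                     rate_scaling=rate_scaling, rng=rng,
                                     gene_id=gene, return_root=True)
        alignments[gene] = aln
        ref_sequences[gene] = root
        for sp in species:
            if rng.random() < missing_rate:
                continue
            tid = f"{sp}@{gene}"
            transcripts[tid] = aln.rows[sp]
            transcript_to_species[tid] = sp
            transcript_to_gene[tid] = gene
            if transcript_dup_rate > 0 and rng.random() < transcript_dup_rate:
                dup = f"{sp}@{gene}#dup"
                seq = np.frombuffer(aln.rows[sp].encode(), dtype=np.uint8).copy()
                nmut = max(1, int(0.02 * seq_length))
                pos = rng.choice(seq_length, size=nmut, replace=False)
                lut = {65: 67, 67: 71, 71: 84, 84: 65}
                for p in pos:
                    seq[p] = lut[int(seq[p])]
                transcripts[dup] = bytes(seq).decode("ascii")
                transcript_to_species[dup] = sp
                transcript_to_gene[dup] = gene

    genome_hits = emit_genome_hits(truth, seed=int(rng.integers(2**31 - 1)))
    transcript_hits = emit_transcript_hits(
        transcripts, ref_sequences, transcript_to_gene,
        seed=int(rng.integers(2**31 - 1)))
    return SimScenario(
        annot_a=annot_a, annot_b=annot_b, truth=truth, genome_hits=genome_hits,
        species=species, species_tree=species_tree, gene_trees=gene_trees,
        alignments=alignments, ref_sequences=ref_sequences,
        transcripts=transcripts, transcript_to_species=transcript_to_species,
        transcript_hits=transcript_hits, gene_to_block=gene_to_block)
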