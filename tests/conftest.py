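import numpy as np
import pytest

from syntelog_phylo.core_io import GeneModel, GenomeAnnotation, GeneTree, HomologyHit


def make_annotation(genome_id, chrom_sizes, prefix=None):
    """Annotation with ``chrom_sizes[chrom] = n`` evenly spaced genes."""
    prefix = prefix or genome_id
    genes = []
    for chrom in sorted(chrom_sizes):
        for i in range(chrom_sizes[chrom]):
            gid = f"{prefix}_{chrom}_{i:03d}"
            genes.append(GeneModel(gid, chrom, i * 100, i * 100 + 50, "+", i))
    return GenomeAnnotation(genome_id, genes)


def hit(q, s, pident=95.0, evalue=1e-30, bitscore=200.0, length=300):
    return HomologyHit(q, s, pident, length, evalue, bitscore)


def random_binary_tree(labels, rng, tree_id="t"):
    """Uniform-ish random unrooted binary topology by random agglomeration."""
    nodes = [str(lbl) for lbl in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return GeneTree.from_newick("(" + ",".join(nodes) + ");", tree_id=tree_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


# ---------------------------------------------------------------------------
# independent tree oracle: explicit-graph enumeration and split extraction,
# sharing no code with the package's tree machinery
# ---------------------------------------------------------------------------

def _graph_leaf_side(adj, u, v):
    """Leaf labels reachable from v without crossing the edge (u, v)."""
    seen, stack, leaves = {u, v}, [v], set()
    while stack:
        node = stack.pop()
        if isinstance(node, str):
            leaves.add(node)
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return leaves


def graph_splits(adj, labels):
    """Canonical nontrivial splits of an unrooted tree given as adjacency."""
    ref = min(labels)
    n = len(labels)
    out = set()
    done = set()
    for u in adj:
        for v in adj[u]:
            e = frozenset((u, v))
            if e in done:
                continue
            done.add(e)
            side = frozenset(_graph_leaf_side(adj, u, v))
            if ref in side:
                side = frozenset(labels) - side
            if 1 < len(side) < n - 1:
                out.add(side)
    return out


def _graph_newick(adj):
    internal = sorted(k for k in adj if isinstance(k, int))
    root = internal[0]

    def sub(node, parent):
        if isinstance(node, str):
            return node
        return "(" + ",".join(sub(nb, node)
                              for nb in sorted(adj[node], key=str)
                              if nb != parent) + ")"

    return "(" + ",".join(sub(nb, root) for nb in sorted(adj[root], key=str)) + ");"


def enumerate_unrooted_trees(labels):
    """All unrooted binary trees over ``labels`` as (newick, splits) pairs,
    built by inserting each taxon into every edge of every smaller tree."""
    labels = list(labels)
    assert len(labels) >= 3
    base = {0: set(labels[:3])}
    for lbl in labels[:3]:
        base[lbl] = {0}
    graphs = [(base, 1)]
    for taxon in labels[3:]:
        nxt = []
        for adj, nid in graphs:
            edges = set()
            for u in adj:
                for v in adj[u]:
                    edges.add(frozenset((u, v)))
            for e in edges:
                u, v = tuple(e)
                adj2 = {k: set(vs) for k, vs in adj.items()}
                adj2[u].discard(v)
                adj2[v].discard(u)
                adj2[nid] = {u, v, taxon}
                adj2[u].add(nid)
                adj2[v].add(nid)
                adj2[taxon] = {nid}
                nxt.append((adj2, nid + 1))
        graphs = nxt
    return [(_graph_newick(adj), graph_splits(adj, labels))
            for adj, _ in graphs]
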