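"""Bipartition machinery: Robinson-Foulds distances, split compatibility, and
binning of gene trees into mutually compatible topology groups.

A bipartition (split) of a taxon set T is stored canonically as the frozenset
of leaves on the side *not* containing min(T); two splits are compatible iff
at least one of the four pairwise side-intersections is empty, in which case
both can occur in a single tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_io import GeneTree
from .errors import UndefinedComparisonError, ValidationError


@dataclass(frozen=True)
class Bipartition:
    """One internal-branch split: canonical side, full taxon set, support."""

    side: frozenset
    taxa: frozenset
    support: float | None = None

    def __post_init__(self):
        if not self.side or self.side == self.taxa:
            raise ValidationError("bipartition sides must both be nonempty")

    @property
    def other_side(self) -> frozenset:
        return self.taxa - self.side

    def is_trivial(self) -> bool:
        return len(self.side) == 1 or len(self.other_side) == 1


def bipartitions(tree: GeneTree, min_support: float | None = None) -> set[Bipartition]:
    """Nontrivial splits of a tree, optionally contracting branches whose
    support is absent or below ``min_support``."""
    taxa = tree.leaves
    sup = tree.supports()
    out = set()
    for side in tree.splits(min_support=min_support):
        out.add(Bipartition(side=side, taxa=taxa, support=sup.get(side)))
    return out


def _shared_splits(t1: GeneTree, t2: GeneTree):
    """Prune both trees to their shared leaves and return the two split sets
    plus the shared-leaf count."""
    shared = t1.leaves & t2.leaves
    n = len(shared)
    if n < 4:
        raise UndefinedComparisonError(
            f"trees {t1.tree_id} and {t2.tree_id} share only {n} leaves (< 4)"
        )
    if t1.leaves == t2.leaves:
        return t1.splits(), t2.splits(), n
    return t1.pruned_to(shared).splits(), t2.pruned_to(shared).splits(), n


def rf_distance(t1: GeneTree, t2: GeneTree, mode: str = "absolute") -> float:
    """Robinson-Foulds distance between two trees on their shared leaf set.

    ``absolute`` counts the symmetric difference of nontrivial split sets;
    ``normalized`` divides by 2(n-3), the maximum for binary n-leaf trees
    (polytomous trees are divided by the same constant, so values remain an
    upper-bounded fraction in [0, 1]).
    """
    s1, s2, n = _shared_splits(t1, t2)
    absolute = float(len(s1 ^ s2))
    if mode == "absolute":
        return absolute
    if mode == "normalized":
        denom = 2.0 * (n - 3)
        return absolute / denom if denom > 0 else 0.0
    raise ValueError(f"unknown RF mode {mode!r}")


def splits_compatible(a: frozenset, b: frozenset, taxa: frozenset) -> bool:
    """True iff splits a|~a and b|~b can coexist in one tree over ``taxa``."""
    na, nb = taxa - a, taxa - b
    return not (a & b) or not (a & nb) or not (na & b) or not (na & nb)


def are_compatible(splits_1, splits_2) -> bool:
    """Setwise compatibility of two collections of Bipartitions on one taxon set."""
    s1, s2 = list(splits_1), list(splits_2)
    taxa_sets = {bp.taxa for bp in s1} | {bp.taxa for bp in s2}
    if len(taxa_sets) > 1:
        raise ValidationError(
            "bipartition sets are over different taxon sets; prune first"
        )
    if not taxa_sets:
        return True
    (taxa,) = taxa_sets
    for a in s1:
        for b in s2:
            if not splits_compatible(a.side, b.side, taxa):
                return False
    return True


@dataclass
class TopologyBin:
    """A group of gene trees whose high-support splits are mutually compatible."""

    bin_id: str
    taxa: frozenset
    members: list = field(default_factory=list)
    combined_splits: set = field(default_factory=set)  # canonical sides

    @property
    def size(self) -> int:
        return len(self.members)


def bin_topologies(trees, support_cutoff: float | None = 100.0) -> list[TopologyBin]:
    """Greedy first-fit grouping of gene trees by split compatibility.

    Trees are pruned to the common taxon set and visited in canonical order
    (sorted tree id).  A tree joins the first bin whose combined splits are
    compatible with its own high-support splits, else founds a new bin.
    Because all splits live on one taxon set, pairwise compatibility of the
    union implies every pair of member trees stays compatible.  Bins are
    returned sorted by size descending (ties by bin id).
    """
    trees = sorted(trees, key=lambda t: t.tree_id)
    if not trees:
        return []
    common = frozenset.intersection(*(t.leaves for t in trees))
    if len(common) < 4:
        raise ValidationError("trees share fewer than 4 common taxa")
    bins: list[TopologyBin] = []
    for t in trees:
        pt = t if t.leaves == common else t.pruned_to(common)
        tsplits = pt.splits(min_support=support_cutoff)
        placed = False
        for b in bins:
            if all(splits_compatible(s, c, common)
                   for s in tsplits for c in b.combined_splits):
                b.members.append(t.tree_id)
                b.combined_splits |= tsplits
                placed = True
                break
        if not placed:
            bins.append(TopologyBin(
                bin_id=f"bin_{len(bins) + 1:03d}",
                taxa=common,
                members=[t.tree_id],
                combined_splits=set(tsplits),
            ))
    return sorted(bins, key=lambda b: (-b.size, b.bin_id))


def classify_bins_by_reference(bins, references: dict[str, set]) -> dict[str, str]:
    """Label each bin with the reference topology hypothesis it supports.

    ``references`` maps a label to a set of canonical split sides on the bins'
    taxon set.  A bin gets a label iff its combined splits contain every
    reference split and contradict none; bins matching nothing are labelled
    ``unresolved``.  Two simultaneous matches mean the references are not
    mutually exclusive and raise an error.
    """
    out = {}
    for b in bins:
        matches = []
        for name, ref_sides in references.items():
            sides = {s.side if isinstance(s, Bipartition) else frozenset(s)
                     for s in ref_sides}
            if not sides <= b.combined_splits:
                continue
            if all(splits_compatible(r, c, b.taxa)
                   for r in sides for c in b.combined_splits):
                matches.append(name)
        if len(matches) > 1:
            raise ValidationError(
                f"bin {b.bin_id} matches multiple references {matches}; "
                "references must be mutually exclusive"
            )
        out[b.bin_id] = matches[0] if matches else "unresolved"
    return out
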