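"""Map per-species transcripts onto the syntelog reference set and build
occupancy-filtered ortholog groups.

The central safeguard is the multi-mapping discard rule: when two or more
distinct transcripts of one species map to the same reference gene (a signal
of recent duplication or assembly redundancy), that species contributes *no*
member for that gene — a missing taxon is preferred over a possible paralog.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import ConfigurationError, ValidationError


@dataclass(frozen=True)
class TranscriptHit:
    transcript_id: str
    species: str
    ref_gene: str
    evalue: float
    percent_identity: float
    bitscore: float

    def __post_init__(self):
        if not self.species:
            raise ValidationError("TranscriptHit.species must be nonempty")


@dataclass
class OrthologGroup:
    """One reference gene plus at most one transcript per species."""

    ref_gene: str
    members: dict[str, tuple[str, str]]  # species -> (transcript_id, sequence)
    occupancy: float

    @property
    def species(self) -> list[str]:
        return sorted(self.members)


def transcript_hits_from_blast(hits, species_of) -> list[TranscriptHit]:
    """Lift raw HomologyHits (transcript query vs reference subject) into
    TranscriptHits.  ``species_of`` is either a callable transcript_id ->
    species or a {prefix: species} map matched on the longest prefix."""
    if callable(species_of):
        fn = species_of
    else:
        prefixes = sorted(species_of, key=len, reverse=True)

        def fn(tid: str) -> str:
            for p in prefixes:
                if tid.startswith(p):
                    return species_of[p]
            raise ValidationError(f"no species prefix matches transcript {tid!r}")

    return [TranscriptHit(h.query_id, fn(h.query_id), h.subject_id,
                          h.evalue, h.percent_identity, h.bitscore)
            for h in hits]


def filter_hits(hits, max_evalue: float = 1e-5,
                min_identity_pct: float = 85.0) -> list[TranscriptHit]:
    """Apply the E-value/identity thresholds, then keep the best-bitscore hit
    per (transcript, ref_gene)."""
    best: dict[tuple[str, str], TranscriptHit] = {}
    for h in hits:
        if h.evalue > max_evalue or h.percent_identity < min_identity_pct:
            continue
        key = (h.transcript_id, h.ref_gene)
        cur = best.get(key)
        if cur is None or (h.bitscore, -h.evalue) > (cur.bitscore, -cur.evalue):
            best[key] = h
    return [best[k] for k in sorted(best)]


def restrict_to_syntelogs(hits, syntelogs) -> list[TranscriptHit]:
    """Drop hits whose reference gene is not the reference-side member of a
    1:1 syntelog pair."""
    ref_genes = {p.gene_a for p in syntelogs}
    return [h for h in hits if h.ref_gene in ref_genes]


def assign_transcripts(hits, transcript_sequences: dict[str, str],
                       n_species_total: int) -> list[OrthologGroup]:
    """Build ortholog groups from filtered, syntelog-restricted hits.

    Each transcript is first reduced to its single best-scoring reference
    gene, so one transcript can never populate two groups.  Then, per
    reference gene and species, exactly one mapped transcript becomes the
    member; two or more distinct transcripts mean the species is dropped from
    that group.  Groups with no members are not emitted.
    """
    if n_species_total < 1:
        raise ConfigurationError("n_species_total must be >= 1")
    # best gene per transcript
    best: dict[str, TranscriptHit] = {}

    def _key(h: TranscriptHit):
        return (h.bitscore, -h.evalue)

    for h in hits:
        cur = best.get(h.transcript_id)
        if cur is None or _key(h) > _key(cur) or (
                _key(h) == _key(cur) and h.ref_gene < cur.ref_gene):
            best[h.transcript_id] = h
    per_gene: dict[str, dict[str, set]] = {}
    for h in best.values():
        per_gene.setdefault(h.ref_gene, {}).setdefault(h.species, set()).add(
            h.transcript_id)
    groups = []
    for ref_gene in sorted(per_gene):
        members = {}
        for species, tids in per_gene[ref_gene].items():
            if len(tids) != 1:
                continue  # multi-mapping discard rule
            (tid,) = tids
            if tid not in transcript_sequences:
                raise ValidationError(
                    f"transcript {tid!r} has no sequence in the store")
            members[species] = (tid, transcript_sequences[tid])
        if members:
            groups.append(OrthologGroup(
                ref_gene=ref_gene, members=members,
                occupancy=len(members) / n_species_total))
    return groups


def occupancy_filter(groups, occupancy_fraction: float | None = None,
                     min_species: int | None = None) -> list[OrthologGroup]:
    """Keep groups meeting a fractional occupancy threshold or a minimum
    species count (exactly one of the two modes)."""
    if (occupancy_fraction is None) == (min_species is None):
        raise ConfigurationError(
            "specify exactly one of occupancy_fraction and min_species")
    if occupancy_fraction is not None:
        return [g for g in groups if g.occupancy >= occupancy_fraction - 1e-12]
    return [g for g in groups if len(g.members) >= min_species]


_SANITIZE = re.compile(r"[^A-Za-z0-9]+")


def sanitize_species_name(name: str) -> str:
    return _SANITIZE.sub("_", name).strip("_")


def emit_group_fastas(groups, outdir) -> list:
    """Write one FASTA per reference gene; record ids are sanitized species
    names so records match across genes at concatenation time."""
    from pathlib import Path

    from .core_io import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for g in sorted(groups, key=lambda g: g.ref_gene):
        records = {}
        for species in sorted(g.members):
            clean = sanitize_species_name(species)
            if clean in records:
                raise ValidationError(
                    f"species names collide after sanitation: {clean!r}")
            records[clean] = g.members[species][1]
        path = outdir / f"{g.ref_gene}.fasta"
        write_fasta(records, path)
        paths.append(path)
    return paths
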