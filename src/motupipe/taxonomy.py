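"""Consensus taxonomic assignment of MOTUs from BLAST hit tables.

Assignment uses up to ten hits per MOTU.  Hits are first screened at
identity > 90% and e-value < 1e-50.  A genus is assigned when at least
eight screened hits agree on the genus name, or when all agree if fewer
than eight hits remain.  A species is assigned only for genus-assigned
MOTUs whose best screened hit reaches 100 minus the phylum's mean ITS1
intraspecific variability (e.g. 100 - 2.88 = 97.12% for Ascomycota), and
when at least six screened hits agree on the species name (all, when
fewer).  The phylum is the majority phylum of the screened hits.

MOTUs assigned to the same species, or sharing a subject GI at > 90%
identity and e-value < 1e-45, are merged (connected components).  Three
discard rules then apply: non-fungal MOTUs; singletons (one read in the
combined dataset); and no-hit MOTUs supported by fewer than ten reads.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .clustering import MotuRecord

#: Mean ITS1 intraspecific variability per phylum (%), weighted by the
#: number of sequences in the underlying per-species survey.
DEFAULT_ITS1_VARIABILITY: dict[str, float] = {
    "Ascomycota": 2.88,
    "Basidiomycota": 4.98,
    "Chytridiomycota": 7.81,
    "Glomeromycota": 9.48,
    "Zygomycota": 4.13,
}

FUNGAL_PHYLA = frozenset(
    {
        "Ascomycota",
        "Basidiomycota",
        "Zygomycota",
        "Chytridiomycota",
        "Glomeromycota",
        "Fungi incertae sedis",
    }
)

GENUS_MIN_IDENTITY = 90.0  # strict >
GENUS_MAX_EVALUE = 1e-50  # strict <
GENUS_CONGRUENT_HITS = 8
SPECIES_CONGRUENT_HITS = 6
MERGE_MIN_IDENTITY = 90.0  # strict >
MERGE_MAX_EVALUE = 1e-45  # strict <
MAX_HITS = 10


@dataclass(frozen=True)
class BlastHit:
    """One BLAST hit row for a MOTU query."""

    query_id: str
    gi: str
    taxonomy: str  # semicolon path, phylum first: "Phylum;Genus;Genus species"
    pct_identity: float
    evalue: float

    @property
    def phylum(self) -> str | None:
        parts = self.taxonomy.split(";")
        return parts[0].strip() or None if parts else None

    @property
    def genus(self) -> str | None:
        parts = self.taxonomy.split(";")
        if len(parts) < 2:
            return None
        return " ".join(parts[1].split()) or None

    @property
    def species(self) -> str | None:
        parts = self.taxonomy.split(";")
        if len(parts) < 3:
            return None
        return " ".join(parts[2].split()) or None


@dataclass(frozen=True)
class TaxonomicAssignment:
    motu_id: str
    phylum: str | None = None  # None = unknown
    genus: str | None = None  # None = unassigned
    species: str | None = None
    is_fungal: bool = True
    is_ecm: bool = False
    n_hits: int = 0


def hits_from_table(table: pd.DataFrame, max_hits: int = MAX_HITS) -> dict[str, list[BlastHit]]:
    """Group a hit table (query_id, gi, taxonomy, pct_identity, evalue) by query.

    At most ``max_hits`` hits are retained per query, best e-value first.
    """
    out: dict[str, list[BlastHit]] = {}
    if len(table) == 0:
        return out
    for query_id, sub in table.groupby("query_id", sort=False):
        sub = sub.sort_values("evalue", kind="stable").head(max_hits)
        out[str(query_id)] = [
            BlastHit(
                query_id=str(r.query_id),
                gi=str(r.gi),
                taxonomy=str(r.taxonomy),
                pct_identity=float(r.pct_identity),
                evalue=float(r.evalue),
            )
            for r in sub.itertuples()
        ]
    return out


def screen_hits(hits: Iterable[BlastHit]) -> list[BlastHit]:
    """Hits usable for assignment: identity > 90 and e-value < 1e-50 (strict)."""
    return [
        h
        for h in hits
        if h.pct_identity > GENUS_MIN_IDENTITY and h.evalue < GENUS_MAX_EVALUE
    ]


def _consensus(names: Sequence[str | None], n_screened: int, min_congruent: int) -> str | None:
    """Shared name among hits: >= min_congruent agree, or all agree when fewer
    than min_congruent hits were screened.  Hits lacking the name are never
    congruent."""
    if n_screened == 0:
        return None
    counts = Counter(n for n in names if n is not None)
    if n_screened >= min_congruent:
        winners = sorted(n for n, k in counts.items() if k >= min_congruent)
        # with the default gates (>= 8 of <= 10, >= 6 of <= 10) two winners
        # are impossible; lexicographic pick keeps reconfigured gates
        # deterministic
        return winners[0] if winners else None
    # fewer hits than the gate: all must agree (and all must carry the name)
    if len(counts) == 1:
        name, k = next(iter(counts.items()))
        if k == n_screened:
            return name
    return None


def assign_genus(hits: Iterable[BlastHit]) -> str | None:
    """Consensus genus from screened hits, or None (unassigned)."""
    screened = screen_hits(hits)
    return _consensus([h.genus for h in screened], len(screened), GENUS_CONGRUENT_HITS)


def assign_species(
    hits: Iterable[BlastHit],
    genus: str | None,
    phylum: str | None,
    variability: Mapping[str, float] | None = None,
) -> str | None:
    """Consensus species, gated on the phylum's ITS1 variability.

    Requires an assigned genus and a known phylum; some screened hit must
    reach ``100 - variability[phylum]`` percent identity.
    """
    if genus is None or phylum is None:
        return None
    variability = DEFAULT_ITS1_VARIABILITY if variability is None else variability
    if phylum not in variability:
        warnings.warn(
            f"no ITS1 variability known for phylum {phylum!r}; species unassigned",
            stacklevel=2,
        )
        return None
    screened = screen_hits(hits)
    if not screened:
        return None
    gate = 100.0 - variability[phylum]
    if max(h.pct_identity for h in screened) < gate:
        return None
    return _consensus(
        [h.species for h in screened], len(screened), SPECIES_CONGRUENT_HITS
    )


def assign_phylum(hits: Iterable[BlastHit]) -> str | None:
    """Majority phylum over screened hits; None (unknown) when no usable hit.

    A tie is broken lexicographically (documented; ties cannot occur with the
    default gates and at most ten hits carrying one phylum each)."""
    screened = screen_hits(hits)
    counts = Counter(h.phylum for h in screened if h.phylum is not None)
    if not counts:
        return None
    top = max(counts.values())
    return min(name for name, k in counts.items() if k == top)


def assign_taxonomy(
    motu_ids: Iterable[str],
    hits_by_query: Mapping[str, Sequence[BlastHit]],
    variability: Mapping[str, float] | None = None,
) -> dict[str, TaxonomicAssignment]:
    """Full phylum/genus/species assignment for each MOTU.

    A MOTU is flagged non-fungal only when its phylum resolves to a known
    non-fungal lineage; unknowns stay putatively fungal (they are handled
    by the no-hit discard rule instead).
    """
    out: dict[str, TaxonomicAssignment] = {}
    for motu_id in motu_ids:
        hits = list(hits_by_query.get(motu_id, ()))
        phylum = assign_phylum(hits)
        genus = assign_genus(hits)
        is_fungal = phylum is None or phylum in FUNGAL_PHYLA
        # species resolution is only meaningful for fungi (non-fungal MOTUs
        # are discarded downstream)
        species = (
            assign_species(hits, genus, phylum, variability) if is_fungal else None
        )
        out[motu_id] = TaxonomicAssignment(
            motu_id=motu_id,
            phylum=phylum,
            genus=genus,
            species=species,
            is_fungal=is_fungal,
            n_hits=len(hits),
        )
    return out


def weighted_variability(
    records: Iterable[tuple[str, float, int]]
) -> dict[str, float]:
    """Per-phylum mean ITS1 intraspecific variability weighted by sequence count.

    ``records`` holds (phylum, variability %, n_sequences) per species.
    """
    num: dict[str, float] = {}
    den: dict[str, int] = {}
    for phylum, v, n in records:
        if n < 1:
            raise ValueError(f"n_sequences must be >= 1, got {n} for {phylum!r}")
        num[phylum] = num.get(phylum, 0.0) + v * n
        den[phylum] = den.get(phylum, 0) + n
    return {p: num[p] / den[p] for p in num}


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def merge_motus(
    motus: Sequence[MotuRecord],
    assignments: Mapping[str, TaxonomicAssignment],
    hits_by_query: Mapping[str, Sequence[BlastHit]],
) -> tuple[list[MotuRecord], dict[str, TaxonomicAssignment]]:
    """Merge MOTUs sharing an assigned species or a high-confidence GI.

    Edges: same assigned species, or a common subject GI among hits with
    identity > 90 and e-value < 1e-45 (both strict).  Connected components
    are merged; the merged MOTU takes the id, representative and assignment
    of its most abundant member (ties broken by MOTU id), member ids are
    unioned and counts summed.
    """
    uf = _UnionFind(m.motu_id for m in motus)

    by_species: dict[str, str] = {}
    for m in motus:
        sp = assignments[m.motu_id].species
        if sp is not None:
            if sp in by_species:
                uf.union(by_species[sp], m.motu_id)
            else:
                by_species[sp] = m.motu_id

    by_gi: dict[str, str] = {}
    for m in motus:
        for h in hits_by_query.get(m.motu_id, ()):
            if h.pct_identity > MERGE_MIN_IDENTITY and h.evalue < MERGE_MAX_EVALUE:
                if h.gi in by_gi:
                    uf.union(by_gi[h.gi], m.motu_id)
                else:
                    by_gi[h.gi] = m.motu_id

    components: dict[str, list[MotuRecord]] = {}
    for m in motus:
        components.setdefault(uf.find(m.motu_id), []).append(m)

    merged: list[MotuRecord] = []
    merged_assignments: dict[str, TaxonomicAssignment] = {}
    for members in components.values():
        head = max(members, key=lambda m: (m.total_count, m.motu_id))
        counts: dict[str, int] = {}
        member_ids: set[str] = set()
        for m in members:
            member_ids |= m.member_ids
            for s, n in m.counts.items():
                counts[s] = counts.get(s, 0) + n
        merged.append(
            MotuRecord(
                motu_id=head.motu_id,
                representative=head.representative,
                member_ids=member_ids,
                counts=counts,
            )
        )
        n_hits = max(assignments[m.motu_id].n_hits for m in members)
        merged_assignments[head.motu_id] = replace(
            assignments[head.motu_id], n_hits=n_hits
        )
    merged.sort(key=lambda m: m.motu_id)
    return merged, merged_assignments


@dataclass
class FilterReport:
    kept: list[MotuRecord]
    assignments: dict[str, TaxonomicAssignment]
    removed_nonfungal: int = 0
    removed_singleton: int = 0
    removed_nohit_low_count: int = 0

    @property
    def n_removed(self) -> int:
        return (
            self.removed_nonfungal
            + self.removed_singleton
            + self.removed_nohit_low_count
        )


def apply_filters(
    motus: Sequence[MotuRecord],
    assignments: Mapping[str, TaxonomicAssignment],
    min_nohit_count: int = 10,
) -> FilterReport:
    """Apply the three discard rules after merging.

    1) non-fungal MOTUs; 2) singletons (total count 1 in the combined
    dataset); 3) MOTUs with no hit at all supported by fewer than
    ``min_nohit_count`` reads.  A MOTU matching several rules is counted
    under the first.
    """
    report = FilterReport(kept=[], assignments={})
    for m in motus:
        a = assignments[m.motu_id]
        if not a.is_fungal:
            report.removed_nonfungal += 1
        elif m.total_count <= 1:
            report.removed_singleton += 1
        elif a.n_hits == 0 and m.total_count < min_nohit_count:
            report.removed_nohit_low_count += 1
        else:
            report.kept.append(m)
            report.assignments[m.motu_id] = a
    return report


def annotate_ecm(
    assignments: Mapping[str, TaxonomicAssignment],
    ecm_genera: Iterable[str],
) -> dict[str, TaxonomicAssignment]:
    """Flag ectomycorrhizal MOTUs: genus assigned and in the EcM genus list."""
    lookup = set(ecm_genera)
    out = {}
    for motu_id, a in assignments.items():
        is_ecm = a.is_fungal and a.genus is not None and a.genus in lookup
        out[motu_id] = replace(a, is_ecm=is_ecm)
    return out


def assignments_to_table(
    assignments: Mapping[str, TaxonomicAssignment]
) -> pd.DataFrame:
    """Assignment table (one row per MOTU) for export."""
    rows = [
        {
            "motu_id": a.motu_id,
            "phylum": a.phylum if a.phylum is not None else "unknown",
            "genus": a.genus if a.genus is not None else "unassigned",
            "species": a.species if a.species is not None else "unassigned",
            "is_fungal": a.is_fungal,
            "is_ecm": a.is_ecm,
            "n_hits": a.n_hits,
        }
        for a in assignments.values()
    ]
    return pd.DataFrame(rows).sort_values("motu_id").reset_index(drop=True)
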