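"""Dataset summary: derived percentages and means from pipeline counts.

Given the headline counts of an amplicon run — reads sequenced and
retained, MOTUs before and after singleton removal, non-singleton MOTUs
per phylum and per assignment level, EcM totals — this computes the
standard descriptive statistics of such a study: quality retention,
singleton fraction, mean reads per sample, phylum composition
percentages, the Dikarya share, and the basidiomycete share of EcM MOTUs.
The counts can come from a pipeline run (``counts_from_pipeline``) or be
supplied directly from a published table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .clustering import MotuRecord
from .taxonomy import TaxonomicAssignment

DIKARYA = ("Ascomycota", "Basidiomycota")


@dataclass(frozen=True)
class DatasetCounts:
    """Headline counts of one study (combined leaf + root dataset)."""

    total_reads: int
    quality_reads: int
    quality_reads_leaf: int
    quality_reads_root: int
    n_samples_leaf: int
    n_samples_root: int
    n_motus: int  # MOTUs after taxonomy-based merging
    n_nonsingletons: int
    assigned_phylum_only: int
    assigned_genus_only: int
    assigned_species: int
    unassigned: int
    phylum_counts: Mapping[str, int] = field(default_factory=dict)
    ecm_total: int = 0
    ecm_basidiomycetes: int = 0


def dataset_summary(counts: DatasetCounts) -> dict[str, float]:
    """Derived percentages and means; percentages are on the 0-100 scale."""
    ns = counts.n_nonsingletons
    out: dict[str, float] = {
        "quality_retained_pct": 100.0 * counts.quality_reads / counts.total_reads,
        "singleton_pct": 100.0 * (counts.n_motus - ns) / counts.n_motus,
        "mean_reads_per_leaf_sample": counts.quality_reads_leaf / counts.n_samples_leaf,
        "mean_reads_per_root_sample": counts.quality_reads_root / counts.n_samples_root,
        "phylum_only_pct": 100.0 * counts.assigned_phylum_only / ns,
        "genus_only_pct": 100.0 * counts.assigned_genus_only / ns,
        "species_pct": 100.0 * counts.assigned_species / ns,
        "unassigned_pct": 100.0 * counts.unassigned / ns,
    }
    for phylum, k in counts.phylum_counts.items():
        out[f"{phylum.lower()}_pct"] = 100.0 * k / ns
    dikarya = sum(counts.phylum_counts.get(p, 0) for p in DIKARYA)
    assigned = ns - counts.unassigned
    out["dikarya_pct_of_motus"] = 100.0 * dikarya / ns
    if assigned:
        out["dikarya_pct_of_phylum_assigned"] = 100.0 * dikarya / assigned
    if counts.ecm_total:
        out["ecm_basidiomycete_pct"] = (
            100.0 * counts.ecm_basidiomycetes / counts.ecm_total
        )
    return out


def counts_from_pipeline(
    total_reads: int,
    quality_reads_leaf: int,
    quality_reads_root: int,
    n_samples_leaf: int,
    n_samples_root: int,
    merged_motus: Sequence[MotuRecord],
    assignments: Mapping[str, TaxonomicAssignment],
) -> DatasetCounts:
    """Assemble ``DatasetCounts`` from merged (pre-discard) pipeline output."""
    fungal = [m for m in merged_motus if assignments[m.motu_id].is_fungal]
    nonsingletons = [m for m in fungal if m.total_count > 1]
    phylum_counts: dict[str, int] = {}
    phylum_only = genus_only = species_n = unassigned = 0
    ecm_total = ecm_basidio = 0
    for m in nonsingletons:
        a = assignments[m.motu_id]
        phylum = a.phylum or "unknown"
        phylum_counts[phylum] = phylum_counts.get(phylum, 0) + 1
        if a.phylum is None:
            unassigned += 1
        elif a.species is not None:
            species_n += 1
        elif a.genus is not None:
            genus_only += 1
        else:
            phylum_only += 1
        if a.is_ecm:
            ecm_total += 1
            if a.phylum == "Basidiomycota":
                ecm_basidio += 1
    return DatasetCounts(
        total_reads=total_reads,
        quality_reads=quality_reads_leaf + quality_reads_root,
        quality_reads_leaf=quality_reads_leaf,
        quality_reads_root=quality_reads_root,
        n_samples_leaf=n_samples_leaf,
        n_samples_root=n_samples_root,
        n_motus=len(fungal),
        n_nonsingletons=len(nonsingletons),
        assigned_phylum_only=phylum_only,
        assigned_genus_only=genus_only,
        assigned_species=species_n,
        unassigned=unassigned,
        phylum_counts=phylum_counts,
        ecm_total=ecm_total,
        ecm_basidiomycetes=ecm_basidio,
    )
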