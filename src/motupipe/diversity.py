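"""Richness and diversity estimation on MOTU count tables.

Richness is estimated per sample by rarefaction at a fixed sequencing
depth (defaults 1400 for leaf and 500 for root samples).  Before
rarefaction one sequence per MOTU is discarded, which removes the
sample's singletons; discarding a random sequence and decrementing each
positive count by one are count-equivalent, so the adjustment is
deterministic.  Group richness (ascomycetes, basidiomycetes, EcM fungi)
redistributes the unknown fraction: assuming unknown MOTUs contain group
i in the same proportion as phylum-assigned MOTUs,

    R_ij = (N_ij / N_assigned) * ER_j

with N_ij the observed MOTUs of group i in sample j, N_assigned the
observed phylum-assigned MOTUs, and ER_j the rarefied total richness.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .clustering import AbundanceMatrix
from .taxonomy import TaxonomicAssignment

DEFAULT_DEPTHS = {"leaf": 1400, "root": 500}


def _as_counts(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    return c.astype(np.int64)


def discard_one_per_motu(counts) -> np.ndarray:
    """Remove one sequence from every MOTU present in the sample.

    Singleton MOTUs (count 1) drop to zero; which physical sequence is
    removed does not affect counts, so no randomness is needed.
    """
    c = _as_counts(counts)
    return np.where(c > 0, c - 1, 0)


def _log_choose(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness(counts, depth: int, sample_id: str | None = None) -> float:
    """Expected MOTU richness of a random subsample of ``depth`` sequences.

    E[S] = sum_m [1 - C(N - N_m, d) / C(N, d)], evaluated in log space.
    """
    c = _as_counts(counts)
    c = c[c > 0]
    total = int(c.sum())
    if depth < 0:
        raise ValueError("depth must be non-negative")
    if depth > total:
        who = f" in sample {sample_id!r}" if sample_id else ""
        raise ValueError(
            f"rarefaction depth {depth} exceeds the {total} sequences available{who}"
        )
    if depth == 0 or c.size == 0:
        return 0.0
    p_absent = np.zeros(c.size)
    ok = (total - c) >= depth
    p_absent[ok] = np.exp(
        _log_choose(total - c[ok], depth) - _log_choose(np.float64(total), depth)
    )
    return float(np.sum(1.0 - p_absent))


def rarefy_counts(counts, depth: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Subsample ``depth`` sequences without replacement (multivariate
    hypergeometric); deterministic for a given seed."""
    c = _as_counts(counts)
    total = int(c.sum())
    if depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds the {total} sequences available")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(c, depth)


def group_richness(n_group: float, n_assigned: float, estimated_richness: float) -> float:
    """Estimated richness of one taxonomic group, R_ij = (N_ij/N_assigned)*ER_j."""
    if n_assigned < 1:
        raise ValueError("group richness is undefined when no MOTU is phylum-assigned")
    if not 0 <= n_group <= n_assigned:
        raise ValueError("N_ij must lie in [0, N_assigned]")
    return (n_group / n_assigned) * estimated_richness


def shannon(counts) -> float:
    """Shannon diversity H = -sum p ln p (natural log) over positive counts."""
    c = _as_counts(counts)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("Shannon diversity requires at least one sequence")
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def occurrence_summary(
    presence: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, pd.Series]]:
    """Per-MOTU number of regions, sites and plots of occurrence.

    ``presence`` is samples x MOTUs (any positive entry counts as present);
    ``design`` is indexed by sample with 'region' and 'site' columns.
    Returns the per-MOTU table plus histograms over each occurrence class.
    """
    design = design.loc[presence.index]
    pres = presence.to_numpy() > 0
    # sites are nested in regions: a site is identified by its (region, site)
    # pair, since site labels repeat across regions
    levels = {
        "region": design["region"].astype(str),
        "site": design["region"].astype(str) + "/" + design["site"].astype(str),
    }
    out = pd.DataFrame(index=presence.columns)
    for level, series in levels.items():
        labels = series.to_numpy()
        counts = np.zeros(pres.shape[1], dtype=np.int64)
        for lab in pd.unique(labels):
            counts += pres[labels == lab].any(axis=0)
        out[f"n_{level}s"] = counts
    out["n_plots"] = pres.sum(axis=0)
    hist = {
        col: out[col].value_counts().sort_index() for col in out.columns
    }
    return out, hist


def richness_report(
    abundance: AbundanceMatrix,
    assignments: Mapping[str, TaxonomicAssignment],
    depths: Mapping[str, int] | int | None = None,
    groups: Iterable[str] = ("Ascomycota", "Basidiomycota"),
) -> pd.DataFrame:
    """Per-sample richness table: ER, per-group R_ij, EcM richness, Shannon.

    ``depths`` maps habitat to rarefaction depth (defaults 1400 leaf / 500
    root) or gives a single depth for all samples.  Group proportions
    (N_ij / N_assigned) are computed on the unrarefied counts; ER_j on the
    singleton-adjusted counts.  Samples too shallow for their depth are
    reported with NaN estimates.
    """
    if depths is None:
        depths = DEFAULT_DEPTHS
    counts = abundance.counts
    design = abundance.design
    motu_ids = list(counts.columns)
    phyla = np.array(
        [
            (assignments[m].phylum if m in assignments else None) or "unknown"
            for m in motu_ids
        ]
    )
    ecm = np.array([m in assignments and assignments[m].is_ecm for m in motu_ids])

    rows = []
    for sample in counts.index:
        vec = counts.loc[sample].to_numpy()
        if isinstance(depths, Mapping):
            habitat = str(design.loc[sample, "habitat"]) if design is not None else "leaf"
            depth = int(depths[habitat])
        else:
            depth = int(depths)
        adjusted = discard_one_per_motu(vec)
        present = vec > 0
        assigned = present & (phyla != "unknown")
        n_assigned = int(assigned.sum())
        row: dict[str, object] = {
            "sample": sample,
            "depth": depth,
            "n_observed": int(present.sum()),
            "n_assigned": n_assigned,
        }
        if adjusted.sum() < depth:
            row["ER"] = np.nan
        else:
            er = rarefied_richness(adjusted, depth, sample_id=str(sample))
            row["ER"] = er
            for group in groups:
                n_ij = int((present & (phyla == group)).sum())
                key = f"R_{group.lower()}"
                row[key] = (
                    group_richness(n_ij, n_assigned, er) if n_assigned else np.nan
                )
            n_ecm = int((present & ecm).sum())
            row["R_ecm"] = (
                group_richness(n_ecm, n_assigned, er) if n_assigned else np.nan
            )
        row["shannon"] = shannon(vec) if vec.sum() > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")
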