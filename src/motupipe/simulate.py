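"""Synthetic fungal amplicon datasets with known ground truth.

The generator emulates a hierarchical beech-forest sampling design —
three mountain regions with 3-5 elevation sites each and three plots of
five trees per site, each plot sampled in two habitats (leaf and root) —
together with per-plot environmental covariates, a true fungal community,
per-sample read counts, ITS1-like read sequences and noisy BLAST hit
tables.  Every quantity downstream stages estimate (phylum composition,
group richness, EcM status, assignment congruence) is known exactly, so
the whole pipeline is testable without sequencing data.

Within a region the mean annual temperature is generated with a negative
elevational lapse; soil pH is generated independently of elevation.  Taxon
abundances follow a lognormal distribution and each taxon has a Gaussian
niche response to temperature and pH, which makes composition covary with
the environment — the signal the PERMANOVA stage must detect.  A fraction
of taxa ("unknown") keeps its true phylum in the ground truth but is
withheld from the hit table, which is how unknowns arise in practice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import AbundanceMatrix, SequenceRecord

PHYLUM_CATEGORIES = ("Ascomycota", "Basidiomycota", "Zygomycota", "other", "unknown")

#: Combined-dataset phylum composition of non-singleton MOTUs being emulated.
DEFAULT_PHYLUM_PROPORTIONS: dict[str, float] = {
    "Ascomycota": 0.554,
    "Basidiomycota": 0.310,
    "Zygomycota": 0.032,
    "other": 0.003,
    "unknown": 0.101,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class DesignSpec:
    """Hierarchical sampling design and per-habitat sequencing depth ranges."""

    n_regions: int = 3
    sites_per_region: tuple[int, ...] = (3, 5, 3)
    plots_per_site: int = 3
    depth_range_leaf: tuple[int, int] = (1506, 15830)
    depth_range_root: tuple[int, int] = (552, 3622)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.plots_per_site < 1:
            raise ValueError("all design counts must be >= 1")
        if len(self.sites_per_region) != self.n_regions:
            raise ValueError("sites_per_region must list one count per region")
        if any(s < 1 for s in self.sites_per_region):
            raise ValueError("all design counts must be >= 1")
        for lo, hi in (self.depth_range_leaf, self.depth_range_root):
            if lo <= 0 or hi < lo:
                raise ValueError("depth ranges must be positive with min <= max")


@dataclass(frozen=True)
class CommunitySpec:
    """True community: pool size, composition, abundances and niche widths.

    The relative-abundance family is configurable.  The default is a Zipf
    (power-law) rank-abundance curve, ``p(rank) ~ rank**-zipf_exponent``
    with ranks shuffled over taxa; the exponent 1.6 was calibrated once by
    Monte-Carlo so that the realised combined-dataset singleton fraction
    matches ``singleton_target_fraction`` (0.378) at the default design,
    depth ranges and pool size 5000.  A lognormal family
    (``abundance_family='lognormal'`` with ``abundance_lognormal`` =
    (mu, sigma)) is also available, but it saturates near a 0.30 singleton
    fraction at these depths and cannot reach the target.  Niche breadths
    are the Gaussian response SDs; 0 collapses the niche to a delta
    function on one site's value.
    """

    pool_size: int = 2000
    phylum_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHYLUM_PROPORTIONS)
    )
    ecm_fraction_of_basidiomycetes: float = 0.31
    abundance_family: str = "zipf"
    zipf_exponent: float = 1.6
    abundance_lognormal: tuple[float, float] = (0.0, 5.0)
    singleton_target_fraction: float = 0.378
    niche_breadth_temperature: float = 2.0
    niche_breadth_pH: float = 1.0

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        props = dict(self.phylum_proportions)
        if set(props) != set(PHYLUM_CATEGORIES):
            raise ValueError(f"phylum_proportions must cover {PHYLUM_CATEGORIES}")
        total = sum(props.values())
        if abs(total - 1.0) > 1e-9 or any(v < 0 for v in props.values()):
            raise ValueError("phylum_proportions must be a simplex (sum to 1)")
        for frac in (self.ecm_fraction_of_basidiomycetes, self.singleton_target_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.niche_breadth_temperature < 0 or self.niche_breadth_pH < 0:
            raise ValueError("niche breadths must be non-negative")
        if self.abundance_family not in ("zipf", "lognormal"):
            raise ValueError("abundance_family must be 'zipf' or 'lognormal'")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")


@dataclass(frozen=True)
class HitNoiseSpec:
    """Noise model for synthetic BLAST hit tables."""

    n_hits_per_motu: int = 10
    congruent_hits_genus: int = 9
    congruent_hits_species: int = 7
    identity_noise_sd: float = 0.5
    p_no_hit: float = 0.1
    p_nonfungal: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_hits_per_motu <= 10:
            raise ValueError("n_hits_per_motu must be in [1, 10]")
        if not (
            0
            <= self.congruent_hits_species
            <= self.congruent_hits_genus
            <= self.n_hits_per_motu
        ):
            raise ValueError(
                "need congruent_hits_species <= congruent_hits_genus <= n_hits_per_motu"
            )
        for p in (self.p_no_hit, self.p_nonfungal):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.identity_noise_sd < 0:
            raise ValueError("identity_noise_sd must be non-negative")


def generate_design(spec: DesignSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample table (one row per plot-habitat sample) and environment table.

    Temperature decreases with elevation within each region (lapse about
    -0.55 degC / 100 m plus small noise); precipitation increases with
    elevation; soil pH and nutrient contents are drawn independently of
    elevation.  Deterministic for a given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    env_rows = []
    sample_rows = []
    for r in range(spec.n_regions):
        region = f"region{r + 1}"
        base_temp = rng.uniform(12.0, 14.5)  # sea-level mean annual temperature
        base_precip = rng.uniform(800.0, 1100.0)
        min_elev = rng.uniform(130.0, 500.0)
        step = rng.uniform(250.0, 450.0)
        n_sites = spec.sites_per_region[r]
        for s in range(n_sites):
            site = f"site{s + 1}"
            elevation = min_elev + step * s
            site_temp = base_temp - 0.0055 * elevation + rng.normal(0.0, 0.2)
            site_precip = base_precip + 0.35 * elevation + rng.normal(0.0, 60.0)
            for p in range(spec.plots_per_site):
                plot = f"plot{p + 1}"
                carbon = rng.uniform(20.0, 120.0)
                nitrogen = carbon / rng.uniform(13.0, 20.0)
                env_rows.append(
                    {
                        "region": region,
                        "site": site,
                        "plot": plot,
                        "elevation": round(elevation, 1),
                        "temperature": round(site_temp, 2),
                        "precipitation": round(site_precip, 1),
                        "soil_pH": round(rng.uniform(4.0, 6.4), 2),
                        "C": round(carbon, 2),
                        "N": round(nitrogen, 2),
                        "P": round(rng.uniform(0.05, 0.35), 2),
                    }
                )
                for habitat in ("leaf", "root"):
                    sample_rows.append(
                        {
                            "sample_id": f"{region}.{site}.{plot}.{habitat}",
                            "region": region,
                            "site": site,
                            "plot": plot,
                            "habitat": habitat,
                        }
                    )
    env = pd.DataFrame(env_rows)
    env["C_N_ratio"] = (env["C"] / env["N"]).round(2)
    samples = pd.DataFrame(sample_rows)
    return samples, env


def _genus_pools(
    rng: np.random.Generator, pool_size: int, ecm_fraction: float
) -> dict[str, list[tuple[str, bool]]]:
    """Per-phylum genus pools with EcM flags (mostly basidiomycete genera)."""
    pools: dict[str, list[tuple[str, bool]]] = {}
    sizes = {
        "Ascomycota": max(3, pool_size // 10),
        "Basidiomycota": max(3, pool_size // 12),
        "Zygomycota": max(2, pool_size // 60),
        "Chytridiomycota": 2,
        "Glomeromycota": 2,
    }
    for phylum, n_gen in sizes.items():
        short = phylum[:3]
        pool = []
        for g in range(n_gen):
            if phylum == "Basidiomycota":
                is_ecm = bool(rng.random() < ecm_fraction)
            elif phylum == "Ascomycota":
                is_ecm = bool(rng.random() < 0.02)  # e.g. Cenococcum-like genera
            else:
                is_ecm = False
            pool.append((f"{short}genus{g + 1:04d}", is_ecm))
        pools[phylum] = pool
    return pools


def generate_community(
    spec: CommunitySpec,
    samples: pd.DataFrame,
    env: pd.DataFrame,
    seed: int = 0,
    depth_ranges: Mapping[str, tuple[int, int]] | None = None,
) -> tuple[pd.DataFrame, AbundanceMatrix]:
    """Reference taxonomy with ground truth, and the true abundance matrix.

    Every taxon gets a real phylum, genus, species, GI number, EcM flag, a
    lognormal relative abundance, Gaussian niche optima for temperature and
    pH, and a per-taxon "true" database identity (the identity its BLAST
    hits are centred on).  Taxa in the "unknown" category are flagged
    ``masked`` — their taxonomy is withheld from hit tables.  Per-sample
    counts are multinomial at a depth drawn uniformly from the habitat's
    depth range.
    """
    rng = np.random.default_rng(seed)
    props = dict(spec.phylum_proportions)
    cats = list(PHYLUM_CATEGORIES)
    cat_draw = rng.choice(len(cats), size=spec.pool_size, p=[props[c] for c in cats])

    fungal = ("Ascomycota", "Basidiomycota", "Zygomycota")
    cond = np.array([props[c] for c in fungal], dtype=float)
    cond = cond / cond.sum() if cond.sum() > 0 else np.full(3, 1 / 3)

    pools = _genus_pools(rng, spec.pool_size, spec.ecm_fraction_of_basidiomycetes)
    if spec.abundance_family == "zipf":
        ranks = np.arange(1, spec.pool_size + 1, dtype=float)
        rel_abund = rng.permutation(ranks**-spec.zipf_exponent)
    else:
        mu, sigma = spec.abundance_lognormal
        rel_abund = rng.lognormal(mu, sigma, size=spec.pool_size)

    t_values = env["temperature"].to_numpy()
    ph_values = env["soil_pH"].to_numpy()
    t_range = (t_values.min(), t_values.max())
    ph_range = (ph_values.min(), ph_values.max())

    rows = []
    for k in range(spec.pool_size):
        cat = cats[cat_draw[k]]
        masked = cat == "unknown"
        if masked:
            # an unknown keeps a real phylum in the truth, distributed like
            # the assigned fraction, so the redistribution estimator has a
            # well-defined target
            phylum = str(rng.choice(fungal, p=cond))
        elif cat == "other":
            phylum = str(rng.choice(("Chytridiomycota", "Glomeromycota")))
        else:
            phylum = cat
        genus, genus_ecm = pools[phylum][int(rng.integers(len(pools[phylum])))]
        if spec.niche_breadth_temperature == 0:
            t_opt = float(rng.choice(np.unique(t_values)))
        else:
            t_opt = float(rng.uniform(*t_range))
        if spec.niche_breadth_pH == 0:
            ph_opt = float(rng.choice(np.unique(ph_values)))
        else:
            ph_opt = float(rng.uniform(*ph_range))
        rows.append(
            {
                "taxon_id": f"taxon{k + 1:05d}",
                "phylum": phylum,
                "category": cat,
                "masked": masked,
                "genus": genus,
                "species": f"{genus} sp{k + 1}",
                "gi": f"gi{k + 1:07d}",
                "is_ecm": genus_ecm,
                "rel_abundance": rel_abund[k],
                "temp_opt": round(t_opt, 3),
                "ph_opt": round(ph_opt, 3),
                "true_identity": round(float(rng.uniform(98.0, 100.0)), 3),
            }
        )
    reference = pd.DataFrame(rows)

    # per-sample multinomial counts under the niche-modulated abundances
    env_keyed = env.set_index(["region", "site", "plot"])
    if depth_ranges is None:
        default = DesignSpec()
        depth_ranges = {
            "leaf": default.depth_range_leaf,
            "root": default.depth_range_root,
        }
    counts = np.zeros((len(samples), spec.pool_size), dtype=np.int64)
    t_opt = reference["temp_opt"].to_numpy()
    ph_opt = reference["ph_opt"].to_numpy()
    base = reference["rel_abundance"].to_numpy()
    bt, bp = spec.niche_breadth_temperature, spec.niche_breadth_pH
    for i, row in enumerate(samples.itertuples()):
        e = env_keyed.loc[(row.region, row.site, row.plot)]
        w = base.copy()
        if bt == 0:
            w = w * (t_opt == float(e["temperature"]))
        else:
            w = w * np.exp(-((float(e["temperature"]) - t_opt) ** 2) / (2 * bt**2))
        if bp == 0:
            w = w * (ph_opt == float(e["soil_pH"]))
        else:
            w = w * np.exp(-((float(e["soil_pH"]) - ph_opt) ** 2) / (2 * bp**2))
        if w.sum() <= 0:
            continue
        lo, hi = depth_ranges[row.habitat]
        depth = int(rng.integers(lo, hi + 1))
        counts[i] = rng.multinomial(depth, w / w.sum())

    counts_df = pd.DataFrame(
        counts, index=samples["sample_id"].to_numpy(), columns=reference["taxon_id"]
    )
    design = samples.set_index("sample_id").join(
        env.set_index(["region", "site", "plot"])[
            ["elevation", "temperature", "precipitation", "soil_pH"]
        ],
        on=["region", "site", "plot"],
    )
    return reference, AbundanceMatrix(counts=counts_df, design=design)


def generate_sequences(
    reference: pd.DataFrame,
    abundance: AbundanceMatrix,
    divergence: float = 0.005,
    seed: int = 0,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """ITS1-like reads for every counted sequence, with sample-tagged ids.

    Each taxon gets a random ancestor of 150-300 bp; every read is a copy
    with iid substitutions at rate ``divergence``.  Returns the reads and a
    read-id -> sample map.  Read ids are ``sample|taxon|r<k>``.
    """
    if not 0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    ancestors: dict[str, np.ndarray] = {}
    for taxon in reference["taxon_id"]:
        length = int(rng.integers(150, 301))
        ancestors[taxon] = _BASES[rng.integers(0, 4, size=length)]

    records: list[SequenceRecord] = []
    sample_map: dict[str, str] = {}
    counts = abundance.counts
    for sample in counts.index:
        row = counts.loc[sample]
        for taxon, n in row[row > 0].items():
            anc = ancestors[taxon]
            for k in range(int(n)):
                read = anc.copy()
                hit = rng.random(read.size) < divergence
                if hit.any():
                    # substitute with one of the three other bases
                    shift = rng.integers(1, 4, size=int(hit.sum()))
                    idx = np.searchsorted(_BASES, read[hit])
                    read[hit] = _BASES[(idx + shift) % 4]
                rid = f"{sample}|{taxon}|r{k + 1}"
                records.append(SequenceRecord(id=rid, bases=read.tobytes().decode()))
                sample_map[rid] = sample
    return records, sample_map


def generate_blast_table(
    reference: pd.DataFrame,
    noise: HitNoiseSpec,
    query_taxa: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Noisy BLAST hit table with controllable congruence.

    One query per taxon (or per MOTU via ``query_taxa``: query id -> true
    taxon).  Masked ("unknown") taxa yield no rows, as do queries drawn
    with probability ``p_no_hit``.  With probability ``p_nonfungal`` the
    query's hits all carry a plant taxonomy.  Otherwise
    ``congruent_hits_species`` hits carry the true genus and species (with
    the taxon's own GI), ``congruent_hits_genus`` the true genus, and the
    remainder decoy taxonomies drawn from *other* pool members.  Hit
    identities are normal around the taxon's true identity; e-values are
    log-uniform below 1e-50.
    """
    rng = np.random.default_rng(noise.seed)
    ref = reference.set_index("taxon_id")
    taxa = list(ref.index)
    if query_taxa is None:
        queries = {t: t for t in taxa}
    else:
        queries = dict(query_taxa)

    rows = []
    decoy_gi = 0
    for query_id, taxon in queries.items():
        info = ref.loc[taxon]
        if bool(info["masked"]) or rng.random() < noise.p_no_hit:
            continue
        n = noise.n_hits_per_motu
        if rng.random() < noise.p_nonfungal:
            for _ in range(n):
                decoy_gi += 1
                rows.append(
                    (
                        query_id,
                        f"pgi{decoy_gi:07d}",
                        "Streptophyta;Fagus;Fagus sylvatica",
                        _identity(rng, 95.0, noise.identity_noise_sd),
                        _evalue(rng),
                        int(rng.integers(120, 300)),
                    )
                )
            continue
        center = float(info["true_identity"])
        k_sp = noise.congruent_hits_species
        k_gen = noise.congruent_hits_genus
        for h in range(n):
            if h < k_sp:
                taxonomy = f"{info['phylum']};{info['genus']};{info['species']}"
                gi = str(info["gi"])
            elif h < k_gen:
                taxonomy = f"{info['phylum']};{info['genus']};{info['genus']} cf{h}"
                decoy_gi += 1
                gi = f"dgi{decoy_gi:07d}"
            else:
                # decoys come from other pool members in a different genus,
                # so the congruent-hit count is exactly the configured one
                other = taxa[int(rng.integers(len(taxa)))]
                while other == taxon or ref.loc[other, "genus"] == info["genus"]:
                    other = taxa[int(rng.integers(len(taxa)))]
                o = ref.loc[other]
                taxonomy = f"{o['phylum']};{o['genus']};{o['species']}"
                decoy_gi += 1
                gi = f"dgi{decoy_gi:07d}"
            rows.append(
                (
                    query_id,
                    gi,
                    taxonomy,
                    _identity(rng, center, noise.identity_noise_sd),
                    _evalue(rng),
                    int(rng.integers(120, 300)),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["query_id", "gi", "taxonomy", "pct_identity", "evalue", "aln_len"],
    )


def _identity(rng: np.random.Generator, center: float, sd: float) -> float:
    return float(np.clip(rng.normal(center, sd) if sd > 0 else center, 0.0, 100.0))


def _evalue(rng: np.random.Generator) -> float:
    return float(10.0 ** rng.uniform(-180.0, -51.0))


def ecm_genus_list(reference: pd.DataFrame) -> list[str]:
    """Genera flagged ectomycorrhizal in the ground truth (the lookup list)."""
    return sorted(reference.loc[reference["is_ecm"], "genus"].unique())


def write_ground_truth(reference: pd.DataFrame, path) -> None:
    """Ground-truth JSON: per-taxon taxonomy, flags and niche parameters."""
    payload = reference.to_dict(orient="records")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.bases}\n")


def read_fasta(path) -> list[SequenceRecord]:
    from Bio import SeqIO

    return [
        SequenceRecord(id=rec.id, bases=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
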