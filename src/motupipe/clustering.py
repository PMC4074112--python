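"""MOTU construction from ITS1 amplicon reads.

Reads are length-filtered, dereplicated and clustered into Molecular
Operational Taxonomic Units (MOTUs) by a deterministic greedy centroid
algorithm at a fixed identity threshold (default 97%).  Pairwise identity
is computed on a global (Needleman-Wunsch) alignment with match +1,
mismatch -1, gap -2, terminal gaps penalised; identity is the number of
identical alignment columns divided by the alignment length.  Sequences
are processed in order of decreasing abundance of identical reads (ties
broken lexicographically by read id); each sequence joins the first
existing centroid at or above the threshold, otherwise it founds a new
centroid.  Centroids never change once founded, so the procedure is
fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MATCH = 1
MISMATCH = -1
GAP = -2

_VALID_BYTES = frozenset(b"ACGTN")
_N_BYTE = ord("N")


@dataclass(frozen=True)
class SequenceRecord:
    """A single read; ``bases`` is upper-cased A/C/G/T/N."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        bases = self.bases.upper()
        if not bases:
            raise ValueError(f"sequence {self.id!r} is empty")
        if not set(bases.encode()) <= _VALID_BYTES:
            bad = sorted(set(bases) - set("ACGTN"))
            raise ValueError(f"sequence {self.id!r} has invalid characters {bad}")
        object.__setattr__(self, "bases", bases)

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class MotuRecord:
    """A MOTU: representative sequence, member read ids, per-sample counts."""

    motu_id: str
    representative: SequenceRecord
    member_ids: set[str]
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class AbundanceMatrix:
    """Samples x MOTUs count table with the sampling-design metadata.

    ``counts`` rows are samples, columns MOTU ids.  ``design`` (optional)
    is indexed by sample id with columns such as region/site/plot/habitat.
    """

    counts: pd.DataFrame
    design: pd.DataFrame | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def motus(self) -> list[str]:
        return list(self.counts.columns)


def filter_by_length(
    records: Iterable[SequenceRecord], min_len: int = 100
) -> list[SequenceRecord]:
    """Keep records of length >= ``min_len`` (boundary inclusive), preserving order."""
    return [r for r in records if len(r) >= min_len]


def _encode(bases: str) -> np.ndarray:
    return np.frombuffer(bases.encode(), dtype=np.uint8)


def _nw_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Full Needleman-Wunsch score matrix, linear gap penalty.

    Rows are vectorised; the within-row gap chain
    H[i,j] = max(cand[j], H[i,j-1] + GAP) is resolved with a running
    maximum of cand[j] - GAP*j.
    """
    la, lb = len(a), len(b)
    H = np.empty((la + 1, lb + 1), dtype=np.int64)
    H[0] = GAP * np.arange(lb + 1)
    jj = np.arange(1, lb + 1, dtype=np.int64)
    for i in range(1, la + 1):
        s = np.where((b == a[i - 1]) & (b != _N_BYTE), MATCH, MISMATCH)
        cand = np.maximum(H[i - 1, :-1] + s, H[i - 1, 1:] + GAP)
        run = np.empty(lb + 1, dtype=np.int64)
        run[0] = GAP * i
        run[1:] = cand - GAP * jj
        np.maximum.accumulate(run, out=run)
        H[i, 0] = GAP * i
        H[i, 1:] = run[1:] + GAP * jj
    return H


def pairwise_identity(a: SequenceRecord | str, b: SequenceRecord | str) -> float:
    """Fraction of identical columns on the optimal global alignment.

    N never matches anything (including another N).  Among co-optimal
    alignments the traceback prefers diagonal, then a gap in the second
    sequence, then a gap in the first — a fixed, documented tie-break.
    """
    sa = a.bases if isinstance(a, SequenceRecord) else a.upper()
    sb = b.bases if isinstance(b, SequenceRecord) else b.upper()
    if not sa or not sb:
        raise ValueError("pairwise_identity requires non-empty sequences")
    A, B = _encode(sa), _encode(sb)
    H = _nw_matrix(A, B)
    i, j = len(A), len(B)
    identical = 0
    columns = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            m = A[i - 1] == B[j - 1] and A[i - 1] != _N_BYTE
            if H[i, j] == H[i - 1, j - 1] + (MATCH if m else MISMATCH):
                identical += int(m)
                i -= 1
                j -= 1
                columns += 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] + GAP:
            i -= 1
            columns += 1
            continue
        j -= 1
        columns += 1
    return identical / columns


def _sample_of_default(seq_id: str) -> str:
    # read ids generated by motupipe.simulate carry the sample before '|'
    return seq_id.split("|", 1)[0]


def greedy_cluster(
    records: Sequence[SequenceRecord],
    threshold: float = 0.97,
    sample_of: Callable[[str], str] | Mapping[str, str] | None = None,
) -> list[MotuRecord]:
    """Greedy centroid clustering at ``threshold`` identity.

    Identical reads are dereplicated first; unique sequences are processed
    in order of decreasing read abundance (ties broken by the smallest
    member id).  ``sample_of`` maps a read id to its sample for the
    per-MOTU counts; by default the prefix before the first ``|`` is used.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if sample_of is None:
        lookup = _sample_of_default
    elif callable(sample_of):
        lookup = sample_of
    else:
        mapping = sample_of
        lookup = lambda sid: mapping[sid]  # noqa: E731

    groups: dict[str, list[str]] = {}
    for rec in records:
        groups.setdefault(rec.bases, []).append(rec.id)
    order = sorted(groups.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))

    motus: list[MotuRecord] = []
    encoded: list[np.ndarray] = []
    for bases, ids in order:
        enc = _encode(bases)
        target: MotuRecord | None = None
        for motu, cenc in zip(motus, encoded):
            lmin = min(len(enc), len(cenc))
            lmax = max(len(enc), len(cenc))
            if lmin / lmax < threshold:  # identity can never reach threshold
                continue
            if pairwise_identity(bases, motu.representative.bases) >= threshold:
                target = motu
                break
        if target is None:
            rep = SequenceRecord(id=min(ids), bases=bases)
            target = MotuRecord(
                motu_id=f"motu{len(motus) + 1:05d}",
                representative=rep,
                member_ids=set(),
            )
            motus.append(target)
            encoded.append(enc)
        target.member_ids.update(ids)
        for sid in ids:
            sample = lookup(sid)
            target.counts[sample] = target.counts.get(sample, 0) + 1
    return motus


def build_abundance_matrix(
    motus: Sequence[MotuRecord],
    sample_map: Mapping[str, str],
    design: pd.DataFrame | None = None,
) -> AbundanceMatrix:
    """Tally member reads into a samples x MOTUs count matrix.

    ``sample_map`` maps every member sequence id to its sample; an unmapped
    id is an error.  Rows cover all samples appearing in ``sample_map`` so
    row sums equal the per-sample retained read counts.
    """
    samples = sorted(set(sample_map.values()))
    index = {s: i for i, s in enumerate(samples)}
    mat = np.zeros((len(samples), len(motus)), dtype=np.int64)
    for m, motu in enumerate(motus):
        counts: dict[str, int] = {}
        for sid in motu.member_ids:
            if sid not in sample_map:
                raise KeyError(f"sequence id {sid!r} has no sample mapping")
            counts[sample_map[sid]] = counts.get(sample_map[sid], 0) + 1
        motu.counts = counts
        for sample, n in counts.items():
            mat[index[sample], m] = n
    df = pd.DataFrame(mat, index=samples, columns=[m.motu_id for m in motus])
    if design is not None:
        design = design.loc[[s for s in samples if s in design.index]]
    return AbundanceMatrix(counts=df, design=design)
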