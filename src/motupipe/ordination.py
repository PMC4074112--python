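"""Composition analysis of presence/absence MOTU tables.

Samples are rarefied to a common depth and binarised; MOTUs seen in fewer
than three plots are dropped to keep rare MOTUs from distorting the
ordination.  Composition is summarised by correspondence analysis (CoA)
and compared between samples with the Sorensen dissimilarity.  Effects of
region, soil pH, mean annual temperature and site-within-region are
tested by PERMANOVA with sequential (Type I) sums of squares; the nested
design is respected by restricting permutations to within-region blocks
(strata).  Environmental screening utilities (Pearson correlation table,
PCA of standardised variables, quadratic richness-temperature trend) are
included.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .clustering import AbundanceMatrix
from .diversity import rarefy_counts

_EPS = 1e-12


def prepare_composition(
    abundance: AbundanceMatrix | pd.DataFrame,
    depth: int,
    min_plots: int = 3,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Rarefy each sample to ``depth``, binarise, drop rare MOTUs.

    MOTUs present in fewer than ``min_plots`` plots (samples) after
    rarefaction are discarded.  Deterministic for a given seed.
    """
    counts = abundance.counts if isinstance(abundance, AbundanceMatrix) else abundance
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for sample in counts.index:
        vec = counts.loc[sample].to_numpy()
        if vec.sum() < depth:
            raise ValueError(
                f"sample {sample!r} has {int(vec.sum())} sequences, "
                f"below the rarefaction depth {depth}"
            )
        rows.append(rarefy_counts(vec, depth, rng))
    binary = (np.vstack(rows) > 0).astype(np.int8)
    occurrence = binary.sum(axis=0)
    keep = occurrence >= min_plots
    return pd.DataFrame(
        binary[:, keep], index=counts.index, columns=counts.columns[keep]
    )


@dataclass
class CoaResult:
    """Correspondence analysis: eigenvalues, row/column scores, inertia."""

    eigenvalues: np.ndarray
    row_scores: pd.DataFrame  # principal coordinates
    col_scores: pd.DataFrame  # standard coordinates
    inertia_fractions: np.ndarray

    @property
    def total_inertia(self) -> float:
        return float(self.eigenvalues.sum())


def coa(matrix: pd.DataFrame | np.ndarray) -> CoaResult:
    """Correspondence analysis of a non-negative indicator/contingency table.

    Standardised residuals S = D_r^{-1/2} (P - r c^T) D_c^{-1/2} are
    decomposed by SVD; eigenvalues are squared singular values.  Rows are
    reported in principal coordinates, columns in standard coordinates.
    """
    df = pd.DataFrame(matrix)
    X = df.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("correspondence analysis requires non-negative entries")
    row_tot = X.sum(axis=1)
    col_tot = X.sum(axis=0)
    if np.any(row_tot == 0):
        bad = df.index[np.where(row_tot == 0)[0][0]]
        raise ValueError(f"row {bad!r} has zero margin")
    if np.any(col_tot == 0):
        bad = df.columns[np.where(col_tot == 0)[0][0]]
        raise ValueError(f"column {bad!r} has zero margin")
    grand = X.sum()
    P = X / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    k = min(X.shape[0] - 1, X.shape[1] - 1)
    s = s[:k]
    eig = s**2
    axes = [f"axis{i + 1}" for i in range(k)]
    row_scores = pd.DataFrame(
        (U[:, :k] * s) / np.sqrt(r)[:, None], index=df.index, columns=axes
    )
    col_scores = pd.DataFrame(
        Vt[:k].T / np.sqrt(c)[:, None], index=df.columns, columns=axes
    )
    total = eig.sum()
    fractions = eig / total if total > 0 else np.zeros_like(eig)
    return CoaResult(eig, row_scores, col_scores, fractions)


def sorensen_dissimilarity(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Pairwise Sorensen dissimilarity d = 1 - 2a/(2a + b + c) of binary rows.

    Equivalent to Bray-Curtis on presence/absence data.  An all-zero sample
    is at distance 1 from any non-empty sample (0 from another empty one);
    a warning is emitted.
    """
    df = pd.DataFrame(matrix)
    X = df.to_numpy()
    if not np.isin(X, (0, 1)).all():
        raise ValueError("Sorensen dissimilarity requires a binary matrix")
    X = X.astype(float)
    sizes = X.sum(axis=1)
    if np.any(sizes == 0):
        warnings.warn("empty sample(s) in composition matrix", stacklevel=2)
    shared = X @ X.T
    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - 2.0 * shared / denom
    d[denom == 0] = 0.0  # two empty samples: identical by convention
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=df.index, columns=df.index)


def _gower_center(dist: np.ndarray) -> np.ndarray:
    A = -0.5 * dist**2
    n = A.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _term_matrix(metadata: pd.DataFrame, term: str) -> np.ndarray:
    if ":" in term:
        parts = [p.strip() for p in term.split(":")]
        labels = metadata[parts].astype(str).agg(":".join, axis=1)
        return pd.get_dummies(labels).to_numpy(dtype=float)
    col = metadata[term]
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float).reshape(-1, 1)
    return pd.get_dummies(col.astype(str)).to_numpy(dtype=float)


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    keep = s > s[0] * 1e-10 if s.size else np.zeros(0, bool)
    U = U[:, keep]
    return U @ U.T, int(keep.sum())


def strata_permutations(
    strata: np.ndarray | pd.Series | None,
    n: int,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """``n_perm`` random permutations of range(n) shuffling only within strata."""
    perms = np.tile(np.arange(n), (n_perm, 1))
    if strata is None:
        for p in perms:
            rng.shuffle(p)
        return perms
    labels = np.asarray(strata)
    for lab in pd.unique(labels):
        idx = np.where(labels == lab)[0]
        for p in perms:
            p[idx] = idx[rng.permutation(idx.size)]
    return perms


def _exhaustive_permutations(strata: np.ndarray | None, n: int) -> np.ndarray:
    if strata is None:
        blocks = [np.arange(n)]
    else:
        labels = np.asarray(strata)
        blocks = [np.where(labels == lab)[0] for lab in pd.unique(labels)]
    total = math.prod(math.factorial(len(b)) for b in blocks)
    if total > 200_000:
        raise ValueError(
            f"exhaustive enumeration would need {total} permutations; use random ones"
        )
    per_block = [list(itertools.permutations(b)) for b in blocks]
    perms = np.empty((total, n), dtype=np.int64)
    for k, combo in enumerate(itertools.product(*per_block)):
        p = np.empty(n, dtype=np.int64)
        for block, perm in zip(blocks, combo):
            p[block] = perm
        perms[k] = p
    return perms


def permanova_nested(
    dist: pd.DataFrame | np.ndarray,
    metadata: pd.DataFrame,
    terms: list[str] = ("region", "pH", "temperature", "region:site"),
    strata: str | None = "region",
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    permutations: str | None = None,
) -> pd.DataFrame:
    """PERMANOVA with sequential sums of squares and restricted permutations.

    ``dist`` is a square symmetric distance matrix; ``metadata`` holds one
    row per sample in the same order.  Terms are fitted sequentially (Type
    I) in the given order; ``a:b`` denotes a nested/interaction term built
    from the combined labels.  P-values come from permuting samples only
    within ``strata`` blocks: p = (1 + #{F* >= F}) / (1 + n_perm).  With
    ``permutations='exhaustive'`` all within-strata permutations are
    enumerated and p = #{F* >= F} / N (the identity included).
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("dist must be a square symmetric matrix")
    if len(metadata) != n:
        raise ValueError("metadata must have one row per sample")
    terms = list(terms)

    G = _gower_center(D)
    ss_total = float(np.trace(G))

    hats: list[np.ndarray] = []
    dfs: list[int] = []
    X = np.ones((n, 1))
    H_prev, rank_prev = _hat(X)
    for term in terms:
        X = np.hstack([X, _term_matrix(metadata, term)])
        H, rank = _hat(X)
        df_term = rank - rank_prev
        if df_term == 0:
            warnings.warn(
                f"term {term!r} is collinear with preceding terms (0 df)",
                stacklevel=2,
            )
        hats.append(H - H_prev)
        dfs.append(df_term)
        H_prev, rank_prev = H, rank

    df_res = n - rank_prev
    if df_res <= 0:
        raise ValueError("model saturates the design; no residual degrees of freedom")
    R = np.eye(n) - H_prev  # residual projector

    def term_stats(Gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float(np.sum(Hk * Gmat)) for Hk in hats])
        ss_res = float(np.sum(R * Gmat))
        return ss, ss_res

    ss_terms, ss_res = term_stats(G)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_obs = (ss_terms / np.array(dfs)) / (ss_res / df_res)

    strata_labels = metadata[strata].to_numpy() if strata is not None else None
    if permutations == "exhaustive":
        perms = _exhaustive_permutations(strata_labels, n)
        denom_add = 0
        count = np.zeros(len(terms))
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        perms = strata_permutations(strata_labels, n, n_perm, rng)
        denom_add = 1
        count = np.ones(len(terms))  # the observed statistic counts once

    Hstack = np.stack(hats)  # (T, n, n)
    chunk = max(1, 4_000_000 // (n * n))
    for start in range(0, len(perms), chunk):
        p = perms[start : start + chunk]
        Gp = G[p[:, :, None], p[:, None, :]]  # (P, n, n)
        ss_p = np.einsum("tij,pij->tp", Hstack, Gp)
        ss_res_p = np.einsum("ij,pij->p", R, Gp)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_p = (ss_p / np.array(dfs)[:, None]) / (ss_res_p[None, :] / df_res)
        count += (f_p >= f_obs[:, None] - _EPS).sum(axis=1)
    if permutations == "exhaustive":
        pvals = count / len(perms)
    else:
        pvals = count / (len(perms) + denom_add)

    rows = []
    for term, df_t, ss, f, p in zip(terms, dfs, ss_terms, f_obs, pvals):
        rows.append(
            {
                "term": term,
                "df": df_t,
                "SS": ss,
                "F": f if df_t > 0 else np.nan,
                "R2": ss / ss_total,
                "p": p if df_t > 0 else np.nan,
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": df_res,
            "SS": ss_res,
            "F": np.nan,
            "R2": ss_res / ss_total,
            "p": np.nan,
        }
    )
    rows.append(
        {
            "term": "Total",
            "df": n - 1,
            "SS": ss_total,
            "F": np.nan,
            "R2": 1.0,
            "p": np.nan,
        }
    )
    table = pd.DataFrame(rows).set_index("term")
    table.attrs["n_permutations"] = len(perms)
    table.attrs["strata"] = strata
    return table


def pearson_table(env: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p (t distribution, n-2 df).

    Zero-variance columns yield NaN with a warning.
    """
    if len(env) < 3:
        raise ValueError("Pearson correlation table requires at least 3 rows")
    cols = list(env.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            x = env[a].to_numpy(dtype=float)
            y = env[b].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(
                    f"zero-variance column in pair ({a!r}, {b!r}); r undefined",
                    stacklevel=2,
                )
                rv, pv = np.nan, np.nan
            else:
                rv, pv = scipy.stats.pearsonr(x, y)
            r.iloc[i, j] = r.iloc[j, i] = rv
            p.iloc[i, j] = p.iloc[j, i] = pv
    return r, p


@dataclass
class PcaResult:
    loadings: pd.DataFrame  # variable x component correlations
    scores: pd.DataFrame
    variance_fractions: np.ndarray
    contributions: pd.DataFrame  # % contribution of each variable per axis
    eigenvalues: np.ndarray


def env_pca(env: pd.DataFrame) -> PcaResult:
    """PCA of standardised environmental variables (correlation matrix PCA)."""
    if env.shape[1] < 2 or env.shape[0] < 3:
        raise ValueError("PCA requires at least 2 variables and 3 rows")
    X = env.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = env.columns[np.where(sd == 0)[0][0]]
        raise ValueError(f"column {bad!r} is constant")
    Z = (X - X.mean(axis=0)) / sd
    n = Z.shape[0]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = s**2 / (n - 1)
    axes = [f"PC{i + 1}" for i in range(len(eig))]
    loadings = pd.DataFrame(
        Vt.T * (s / np.sqrt(n - 1)), index=env.columns, columns=axes
    )
    scores = pd.DataFrame(U * s, index=env.index, columns=axes)
    contributions = pd.DataFrame(100.0 * Vt.T**2, index=env.columns, columns=axes)
    return PcaResult(
        loadings=loadings,
        scores=scores,
        variance_fractions=eig / eig.sum(),
        contributions=contributions,
        eigenvalues=eig,
    )


@dataclass
class QuadraticFit:
    intercept: float
    linear: float
    quadratic: float
    r_squared: float
    p_quadratic: float
    peak: float | None  # -b1/(2 b2) when the curve is hump-shaped


def quadratic_trend(richness, temperature) -> QuadraticFit:
    """OLS fit richness = b0 + b1 T + b2 T^2 with a t-test on b2.

    A negative significant b2 supports a hump-shaped (mid-domain) pattern;
    the peak temperature is -b1 / (2 b2).
    """
    y = np.asarray(richness, dtype=float)
    t = np.asarray(temperature, dtype=float)
    if y.size != t.size or y.size < 4:
        raise ValueError("quadratic trend requires >= 4 matched points")
    if np.unique(t).size < 3:
        raise ValueError("temperature values are collinear for a quadratic fit")
    X = sm.add_constant(np.column_stack([t, t**2]))
    fit = sm.OLS(y, X).fit()
    b0, b1, b2 = fit.params
    peak = float(-b1 / (2 * b2)) if b2 < 0 else None
    return QuadraticFit(
        intercept=float(b0),
        linear=float(b1),
        quadratic=float(b2),
        r_squared=float(fit.rsquared),
        p_quadratic=float(fit.pvalues[2]),
        peak=peak,
    )
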