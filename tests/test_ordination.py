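"""Correspondence analysis, Sorensen distances, PERMANOVA and env screening."""

import itertools

import numpy as np
import pandas as pd
import pytest

import motupipe as mp
from motupipe.ordination import strata_permutations

from conftest import binary_matrix


# ---------------------------------------------------------------------------
# composition preparation


def test_prepare_composition_min_plot_rule():
    counts = pd.DataFrame(
        {
            "m_two_plots": [5, 5, 0, 0],
            "m_three_plots": [5, 5, 5, 0],
            "m_everywhere": [10, 10, 15, 20],
        },
        index=["p1", "p2", "p3", "p4"],
    )
    binary = mp.prepare_composition(counts, depth=20, min_plots=3, seed=0)
    assert "m_two_plots" not in binary.columns
    assert {"m_three_plots", "m_everywhere"} <= set(binary.columns)
    assert set(np.unique(binary.to_numpy())) <= {0, 1}


def test_prepare_composition_occurrence_oracle_and_errors():
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(
        rng.integers(0, 30, size=(10, 40)), index=[f"p{i}" for i in range(10)]
    )
    counts.iloc[:, 0] = 0  # all-zero column can never survive
    depth = int(counts.sum(axis=1).min())
    binary = mp.prepare_composition(counts, depth=depth, min_plots=3, seed=5)
    # oracle: recompute occurrence from an identically-seeded rarefaction
    rng2 = np.random.default_rng(5)
    occ = np.zeros(counts.shape[1], dtype=int)
    for i in range(len(counts)):
        occ += mp.rarefy_counts(counts.iloc[i].to_numpy(), depth, rng2) > 0
    assert list(binary.columns) == list(counts.columns[occ >= 3])
    assert 0 not in binary.columns
    with pytest.raises(ValueError, match="p0"):
        mp.prepare_composition(counts, depth=int(counts.sum(axis=1).max()) + 1)


# ---------------------------------------------------------------------------
# correspondence analysis


def test_coa_disconnected_blocks_leading_eigenvalue_one():
    X = np.zeros((6, 8))
    X[:3, :4] = 1
    X[3:, 4:] = 1
    res = mp.coa(X)
    assert res.eigenvalues[0] == pytest.approx(1.0)


def test_coa_eigenvalue_sum_equals_chi_square_inertia():
    rng = np.random.default_rng(2)
    for _ in range(5):
        X = rng.integers(0, 6, size=(6, 8)).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1
        X = X[:, X.sum(axis=0) > 0]
        res = mp.coa(X)
        # chi-square statistic of the table divided by the grand total
        grand = X.sum()
        expected = np.outer(X.sum(axis=1), X.sum(axis=0)) / grand
        chi2 = float(((X - expected) ** 2 / expected).sum())
        assert res.eigenvalues.sum() == pytest.approx(chi2 / grand, abs=1e-9)
        assert res.inertia_fractions.sum() == pytest.approx(1.0)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()


def test_coa_degenerate_shapes_and_zero_margins():
    res = mp.coa(np.ones((1, 5)))
    assert res.eigenvalues.size == 0
    with pytest.raises(ValueError, match="zero margin"):
        mp.coa(pd.DataFrame([[1, 0], [1, 0]], columns=["a", "b"]))


def test_coa_row_scores_invariant_to_proportional_column_split():
    rng = np.random.default_rng(3)
    X = binary_matrix(rng, 8, 10).to_numpy(dtype=float)
    r1 = mp.coa(X)
    split = np.hstack([X[:, :4], X[:, [4]] / 2, X[:, [4]] / 2, X[:, 5:]])
    r2 = mp.coa(split)
    k = r1.row_scores.shape[1]
    assert np.allclose(
        np.abs(r1.row_scores.to_numpy()),
        np.abs(r2.row_scores.to_numpy()[:, :k]),
        atol=1e-9,
    )


# ---------------------------------------------------------------------------
# Sorensen dissimilarity


def test_sorensen_extremes_and_oracle():
    X = pd.DataFrame(
        [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]], index=["a", "b", "c"]
    )
    d = mp.sorensen_dissimilarity(X)
    assert d.loc["a", "b"] == 0.0
    assert d.loc["a", "c"] == 1.0
    rng = np.random.default_rng(4)
    Y = binary_matrix(rng, 7, 25)
    D = mp.sorensen_dissimilarity(Y).to_numpy()
    for i, j in itertools.combinations(range(len(Y)), 2):
        a = int((Y.iloc[i] & Y.iloc[j]).sum())
        b = int((Y.iloc[i] & ~Y.iloc[j].astype(bool)).sum())
        c = int((~Y.iloc[i].astype(bool) & Y.iloc[j]).sum())
        assert D[i, j] == pytest.approx(1 - 2 * a / (2 * a + b + c))
        assert D[i, j] == pytest.approx(D[j, i])
    assert np.diag(D).sum() == 0.0


def test_sorensen_empty_sample_warning():
    X = pd.DataFrame([[0, 0], [1, 1]])
    with pytest.warns(UserWarning, match="empty"):
        d = mp.sorensen_dissimilarity(X)
    assert d.iloc[0, 1] == 1.0


# ---------------------------------------------------------------------------
# PERMANOVA


def test_permanova_perfect_separation():
    d = np.ones((4, 4)) - np.eye(4)
    d[0, 1] = d[1, 0] = 0.0
    d[2, 3] = d[3, 2] = 0.0
    meta = pd.DataFrame({"group": ["x", "x", "y", "y"]})
    table = mp.permanova_nested(d, meta, terms=["group"], strata=None, n_perm=99)
    assert table.loc["group", "R2"] == pytest.approx(1.0)
    assert table.loc["Residual", "SS"] == pytest.approx(0.0, abs=1e-12)


def test_permanova_r2_partition_identity(small_design):
    _, samples, env = small_design
    design = samples[samples["habitat"] == "root"].set_index("sample_id")
    design = design.join(
        env.set_index(["region", "site", "plot"])[["temperature", "soil_pH"]],
        on=["region", "site", "plot"],
    )
    rng = np.random.default_rng(6)
    comp = binary_matrix(rng, len(design), 80)
    comp.index = design.index
    dist = mp.sorensen_dissimilarity(comp)
    table = mp.permanova_nested(
        dist,
        design,
        terms=["region", "soil_pH", "temperature", "region:site"],
        strata="region",
        n_perm=49,
        seed=1,
    )
    terms_r2 = table.drop(index="Total")["R2"].sum()
    assert terms_r2 == pytest.approx(1.0, abs=1e-9)
    assert table.drop(index="Total")["df"].sum() == len(design) - 1


def permanova_f_oracle(dist: np.ndarray, groups: np.ndarray) -> float:
    """Classic one-factor pseudo-F from within-group squared distances."""
    n = len(groups)
    labels = np.unique(groups)
    ss_total = (dist**2).sum() / (2 * n)
    ss_within = 0.0
    for g in labels:
        idx = np.where(groups == g)[0]
        sub = dist[np.ix_(idx, idx)]
        ss_within += (sub**2).sum() / (2 * len(idx))
    ss_between = ss_total - ss_within
    df1, df2 = len(labels) - 1, n - len(labels)
    return (ss_between / df1) / (ss_within / df2)


def test_permanova_exhaustive_p_matches_full_enumeration():
    rng = np.random.default_rng(7)
    X = binary_matrix(rng, 6, 20)
    dist = mp.sorensen_dissimilarity(X).to_numpy()
    meta = pd.DataFrame(
        {
            "block": ["A", "A", "A", "B", "B", "B"],
            "group": ["x", "y", "x", "y", "x", "y"],
        }
    )
    table = mp.permanova_nested(
        dist, meta, terms=["group"], strata="block", permutations="exhaustive"
    )
    # oracle: enumerate all (3!)^2 within-block permutations, recompute the
    # one-factor pseudo-F from scratch each time
    groups = meta["group"].to_numpy()
    f_obs = permanova_f_oracle(dist, groups)
    assert table.loc["group", "F"] == pytest.approx(f_obs)
    blocks = [np.array([0, 1, 2]), np.array([3, 4, 5])]
    count = total = 0
    for pa in itertools.permutations(blocks[0]):
        for pb in itertools.permutations(blocks[1]):
            perm = np.array(pa + pb)
            f_star = permanova_f_oracle(dist[np.ix_(perm, perm)], groups)
            count += f_star >= f_obs - 1e-12
            total += 1
    assert total == 36
    assert table.loc["group", "p"] == pytest.approx(count / total)


def test_permanova_f_matches_scikit_bio():
    from skbio.stats.distance import DistanceMatrix, permanova as skbio_permanova

    rng = np.random.default_rng(8)
    X = binary_matrix(rng, 12, 40)
    dist = mp.sorensen_dissimilarity(X).to_numpy()
    groups = np.array(["a", "a", "a", "a", "b", "b", "b", "b", "c", "c", "c", "c"])
    meta = pd.DataFrame({"group": groups})
    ours = mp.permanova_nested(dist, meta, terms=["group"], strata=None, n_perm=9)
    theirs = skbio_permanova(DistanceMatrix(dist), groups, permutations=9)
    assert ours.loc["group", "F"] == pytest.approx(theirs["test statistic"])


def test_permutations_respect_strata():
    strata = np.array(["r1"] * 4 + ["r2"] * 5 + ["r3"] * 3)
    rng = np.random.default_rng(9)
    perms = strata_permutations(strata, len(strata), 200, rng)
    for p in perms:
        assert (strata[p] == strata).all()
    # and at least some permutations actually move samples
    assert (perms != np.arange(len(strata))).any()


def test_permanova_warns_on_collinear_term():
    d = np.ones((6, 6)) - np.eye(6)
    meta = pd.DataFrame(
        {"x": [1.0, 2, 3, 4, 5, 6], "y": [2.0, 4, 6, 8, 10, 12]}
    )
    with pytest.warns(UserWarning, match="collinear"):
        mp.permanova_nested(d, meta, terms=["x", "y"], strata=None, n_perm=9)


# ---------------------------------------------------------------------------
# environmental screening


def test_pearson_table_extremes_and_oracle():
    rng = np.random.default_rng(10)
    x = rng.normal(size=10)
    env = pd.DataFrame({"x": x, "neg": -x, "z": rng.normal(size=10)})
    r, p = mp.pearson_table(env)
    assert r.loc["x", "x"] == 1.0
    assert r.loc["x", "neg"] == pytest.approx(-1.0)
    # direct covariance-formula oracle
    xc, zc = x - x.mean(), env["z"] - env["z"].mean()
    expected = float((xc * zc).sum() / np.sqrt((xc**2).sum() * (zc**2).sum()))
    assert r.loc["x", "z"] == pytest.approx(expected, abs=1e-12)
    with pytest.warns(UserWarning, match="zero-variance"):
        r2, _ = mp.pearson_table(pd.DataFrame({"c": [1.0, 1, 1], "x": [1.0, 2, 3]}))
    assert np.isnan(r2.loc["c", "x"])


def test_env_pca_against_eigendecomposition_oracle():
    rng = np.random.default_rng(11)
    env = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
    res = mp.env_pca(env)
    corr = np.corrcoef(env.to_numpy(), rowvar=False)
    eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
    assert np.allclose(res.eigenvalues, eig, atol=1e-9)
    assert res.variance_fractions.sum() == pytest.approx(1.0)
    assert np.allclose(res.contributions.sum(axis=0), 100.0)
    # two perfectly correlated variables: one axis carries everything
    two = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
    res2 = mp.env_pca(two)
    assert res2.variance_fractions[0] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="constant"):
        mp.env_pca(pd.DataFrame({"a": [1.0, 1, 1], "b": [1.0, 2, 3]}))


def test_quadratic_trend_exact_and_linear_cases():
    t = np.linspace(2, 14, 20)
    y = 3.0 - 1.2 * t + 0.5 * t**2
    fit = mp.quadratic_trend(y, t)
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.intercept == pytest.approx(3.0, abs=1e-9)
    assert fit.linear == pytest.approx(-1.2, abs=1e-9)
    assert fit.quadratic == pytest.approx(0.5, abs=1e-9)
    assert fit.peak is None  # convex, no hump
    linear = mp.quadratic_trend(2 + 3 * t, t)
    assert linear.quadratic == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        mp.quadratic_trend([1, 2, 3, 4], [1, 1, 2, 2])


def test_quadratic_trend_recovers_simulated_mid_domain_peak():
    true_peak = 9.5
    rng = np.random.default_rng(12)
    peaks = []
    for _ in range(100):
        t = rng.uniform(5, 14, size=33)
        y = 100 - 2.0 * (t - true_peak) ** 2
        y = y + rng.normal(0, 0.1 * (y.max() - y.min()), size=33)
        fit = mp.quadratic_trend(y, t)
        assert fit.quadratic < 0
        peaks.append(fit.peak)
    assert abs(np.median(peaks) - true_peak) < 1.0
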