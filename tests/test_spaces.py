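import warnings

import numpy as np
import pandas as pd
import pytest

from helpchoice.spaces import (decision_matrix, decision_rdm,
                               decompose_decision_rdm, mds_embed,
                               motivation_rdms, quadrant_anova,
                               rdm_regression, rsa, semantic_space,
                               upper_triangle, validate_rdm)


def _random_rdm(rng, n):
    A = rng.random((n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0)
    return A


# ---------------------------------------------------------------------------
# decision RDM


def test_decision_rdm_hand_examples():
    # opposite-direction ratings: unsigned term 4, signed term 0
    M = pd.DataFrame({0: [3, 3], 1: [1, 5]})
    assert decision_rdm(M, min_overlap=1)[0, 1] == pytest.approx(1.0)
    # same-sign differences: F equals the mean absolute difference
    M2 = pd.DataFrame({0: [3, 1], 1: [1, -1]})
    assert decision_rdm(M2, min_overlap=1)[0, 1] == pytest.approx(2.0)
    # identical columns
    M3 = pd.DataFrame({0: [2, 4, 1], 1: [2, 4, 1]})
    assert decision_rdm(M3, min_overlap=1)[0, 1] == 0.0


def _loop_decision_rdm(M):
    n_scen = M.shape[1]
    F = np.zeros((n_scen, n_scen))
    for x in range(n_scen):
        for y in range(n_scen):
            if x == y:
                continue
            joint = [i for i in range(M.shape[0])
                     if np.isfinite(M[i, x]) and np.isfinite(M[i, y])]
            n = len(joint)
            unsigned = sum(abs(M[i, x] - M[i, y]) for i in joint)
            signed = abs(sum(M[i, x] - M[i, y] for i in joint))
            F[x, y] = (0.5 * unsigned + 0.5 * signed) / n
    return F


def test_decision_rdm_matches_double_loop_oracle():
    rng = np.random.default_rng(0)
    for trial in range(5):
        M = rng.integers(-5, 6, (10, 8)).astype(float)
        M[rng.random(M.shape) < 0.2] = np.nan
        # ensure every pair overlaps
        M[0] = rng.integers(-5, 6, 8)
        got = decision_rdm(pd.DataFrame(M), min_overlap=1)
        np.testing.assert_allclose(got, _loop_decision_rdm(M), atol=1e-12)
        validate_rdm(got)
        assert np.diag(got).sum() == 0.0


def test_decision_rdm_zero_overlap_raises():
    M = pd.DataFrame([[1.0, np.nan], [np.nan, 2.0]])
    with pytest.raises(ValueError, match="no overlapping raters"):
        decision_rdm(M, min_overlap=1)


def test_decision_matrix_pivot(study_clean):
    dec, _ = study_clean
    M = decision_matrix(dec)
    assert M.index.name == "participant_id"
    one = dec.iloc[0]
    assert M.loc[one["participant_id"], one["scenario_id"]] \
        == one["wth_code"]


# ---------------------------------------------------------------------------
# motivation and semantic spaces


def test_motivation_rdms_geometry():
    scores = pd.DataFrame({"benefit": [0.0, 3.0, 0.2],
                           "cost": [0.0, 4.0, 0.7]})
    full, ben, cost = motivation_rdms(scores)
    assert full[0, 1] == pytest.approx(5.0)
    assert ben[0, 2] == pytest.approx(0.2)
    assert cost[0, 2] == pytest.approx(0.7)
    assert (full >= ben - 1e-12).all() and (full >= cost - 1e-12).all()
    for rdm in (full, ben, cost):
        validate_rdm(rdm)


@pytest.fixture(scope="module")
def umap_space():
    rng = np.random.default_rng(1)
    centroids = rng.standard_normal((6, 8)) * 10
    labels_true = np.repeat(np.arange(6), 10)
    X = centroids[labels_true] + rng.standard_normal((60, 8))
    X[1] = X[0]    # a duplicated narrative
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb, rdm, labels = semantic_space(pd.DataFrame(X), n_clusters=6,
                                          seed=4)
        emb2, _, _ = semantic_space(pd.DataFrame(X), n_clusters=6, seed=4)
    return X, labels_true, emb, rdm, labels, emb2


def test_semantic_space_recovers_clusters(umap_space):
    from sklearn.metrics import adjusted_rand_score
    X, labels_true, emb, rdm, labels, emb2 = umap_space
    assert adjusted_rand_score(labels_true, labels) >= 0.9
    validate_rdm(rdm)
    # identical embeddings coincide and share a cluster
    assert rdm[0, 1] < np.median(upper_triangle(rdm)) * 0.05
    assert labels[0] == labels[1]
    # determinism under a fixed seed
    np.testing.assert_array_equal(emb.coords.to_numpy(),
                                  emb2.coords.to_numpy())


def test_semantic_space_rejects_zero_vectors():
    X = np.ones((10, 4))
    X[3] = 0.0
    with pytest.raises(ValueError, match="zero-norm"):
        semantic_space(pd.DataFrame(X))


def test_mds_recovers_planar_configuration():
    D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    emb = mds_embed(D, seed=0)
    from scipy.spatial.distance import pdist
    got = np.sort(pdist(emb.coords.to_numpy()))
    np.testing.assert_allclose(got, [3, 4, 5], atol=1e-3)
    assert emb.diagnostics["stress"] < 1e-4


def test_mds_zero_rdm_collapses_points():
    emb = mds_embed(np.zeros((5, 5)), seed=0)
    coords = emb.coords.to_numpy()
    assert np.allclose(coords, coords[0], atol=1e-6)


def test_mds_stress_nonincreasing_in_dimension():
    rng = np.random.default_rng(2)
    D = _random_rdm(rng, 12)
    s2 = mds_embed(D, seed=1, n_components=2).diagnostics["stress"]
    s3 = mds_embed(D, seed=1, n_components=3).diagnostics["stress"]
    assert s3 <= s2 + 1e-9


def test_mds_rejects_asymmetric_input():
    D = np.array([[0, 1.0], [2.0, 0]])
    with pytest.raises(ValueError, match="symmetric"):
        mds_embed(D)


# ---------------------------------------------------------------------------
# RSA


def test_rsa_identity_and_equivariance():
    rng = np.random.default_rng(3)
    A = _random_rdm(rng, 12)
    res = rsa(A, A.copy(), n_perm=500, seed=0)
    assert res.r == pytest.approx(1.0)
    assert res.p <= 1 / 500
    B = _random_rdm(rng, 12)
    r0 = rsa(A, B, n_perm=10, seed=0).r
    perm = rng.permutation(12)
    r1 = rsa(A[np.ix_(perm, perm)], B[np.ix_(perm, perm)],
             n_perm=10, seed=0).r
    assert r1 == pytest.approx(r0)


def test_rsa_permutation_preserves_entry_multiset():
    rng = np.random.default_rng(4)
    B = _random_rdm(rng, 10)
    for _ in range(20):
        perm = rng.permutation(10)
        permuted = B[np.ix_(perm, perm)]
        assert np.allclose(np.sort(upper_triangle(permuted)),
                           np.sort(upper_triangle(B)))


def test_rsa_errors():
    rng = np.random.default_rng(5)
    A = _random_rdm(rng, 8)
    with pytest.raises(ValueError, match="constant upper triangle"):
        rsa(A, np.zeros((8, 8)), n_perm=10, seed=0)
    with pytest.raises(ValueError, match="share shape"):
        rsa(A, _random_rdm(rng, 9), n_perm=10, seed=0)


def test_rsa_detects_motivation_structure_in_generated_decisions(
        study_clean, study_consensus):
    """Decisions generated from a cost-benefit model produce a decision RDM
    positively related to the true motivation RDM."""
    dec, _ = study_clean
    M = decision_matrix(dec)
    keep = M.columns[(M.notna().to_numpy().T.astype(int)
                      @ M.notna().to_numpy().astype(int) > 0).all(axis=0)]
    M = M[keep]
    rdm_dec = decision_rdm(M, min_overlap=1)
    cons = study_consensus.loc[keep]
    scores = pd.DataFrame({
        "benefit": cons["q06_mean"], "cost": cons["q05_mean"]})
    rdm_mot, _, _ = motivation_rdms(scores)
    res = rsa(rdm_dec, rdm_mot, n_perm=1000, seed=0)
    assert res.r > 0 and res.p < 0.05


# ---------------------------------------------------------------------------
# decomposition and regression


def test_decompose_decision_rdm():
    means = np.array([1.0, 2.0, 4.0])
    rdm = np.abs(means[:, None] - means[None, :]) * 2.5
    wth_rdm, resid = decompose_decision_rdm(rdm, means)
    np.testing.assert_allclose(upper_triangle(wth_rdm), [1, 3, 2])
    np.testing.assert_allclose(resid, 0.0, atol=1e-12)
    rng = np.random.default_rng(6)
    rdm2 = _random_rdm(rng, 15)
    m2 = rng.random(15)
    wth2, resid2 = decompose_decision_rdm(rdm2, m2)
    assert abs(upper_triangle(resid2) @ upper_triangle(wth2)) < 1e-8


def test_rdm_regression_planted_coefficient():
    rng = np.random.default_rng(7)
    p1 = _random_rdm(rng, 40)
    p2 = _random_rdm(rng, 40)
    z = upper_triangle(p1)
    z = (z - z.mean()) / z.std()
    yv = 0.5 * z + np.sqrt(1 - 0.25) * rng.standard_normal(len(z))
    target = np.zeros_like(p1)
    target[np.triu_indices(40, 1)] = yv
    target = target + target.T
    tab = rdm_regression(target, {"p1": p1, "p2": p2})
    b1 = tab.set_index("predictor").loc["p1", "beta"]
    b2 = tab.set_index("predictor").loc["p2", "beta"]
    assert b1 == pytest.approx(0.5, abs=0.1)
    assert abs(b2) < 0.1


def test_rdm_regression_exact_fit_and_relabeling():
    rng = np.random.default_rng(8)
    p1 = _random_rdm(rng, 20)
    tab = rdm_regression(p1.copy(), {"p1": p1})
    assert tab.set_index("predictor").loc["p1", "beta"] \
        == pytest.approx(1.0, abs=1e-10)
    assert tab.attrs["r_squared"] == pytest.approx(1.0)
    p2 = _random_rdm(rng, 20)
    t0 = rdm_regression(p1, {"a": p2})
    perm = rng.permutation(20)
    t1 = rdm_regression(p1[np.ix_(perm, perm)], {"a": p2[np.ix_(perm, perm)]})
    assert t0.set_index("predictor").loc["a", "beta"] \
        == pytest.approx(t1.set_index("predictor").loc["a", "beta"])


def test_rdm_regression_collinearity_warning():
    rng = np.random.default_rng(9)
    p1 = _random_rdm(rng, 15)
    with pytest.warns(UserWarning, match="collinear"):
        rdm_regression(_random_rdm(rng, 15), {"a": p1, "b": 2 * p1})


# ---------------------------------------------------------------------------
# quadrant ANOVA


def test_quadrant_anova_identical_groups():
    vals = np.ones(40) * 2.0
    out = quadrant_anova(vals, np.repeat(list("abcd"), 10))
    assert out["welch"]["F"] == 0.0 and out["welch"]["p"] == 1.0


def test_quadrant_anova_two_groups_equals_squared_welch_t():
    from helpchoice.stats import group_compare
    rng = np.random.default_rng(10)
    vals = np.concatenate([rng.normal(0, 1, 15), rng.normal(0.8, 2, 20)])
    grp = np.array(["a"] * 15 + ["b"] * 20)
    F = quadrant_anova(vals, grp)["welch"]["F"]
    t = group_compare(vals, grp).statistic
    assert F == pytest.approx(t ** 2)


def test_quadrant_anova_planted_separation_all_pairs():
    rng = np.random.default_rng(11)
    vals = np.concatenate([rng.normal(m, 0.5, 25) for m in (0, 1, 2, 3)])
    grp = np.repeat(["LL", "LH", "HL", "HH"], 25)
    out = quadrant_anova(vals, grp)
    assert out["welch"]["p"] < 1e-6
    assert (out["posthoc"]["pval"] < 0.05).all()
    assert len(out["posthoc"]) == 6


def test_quadrant_anova_small_group_raises():
    with pytest.raises(ValueError, match="fewer than 2"):
        quadrant_anova([1.0, 2.0, 3.0], ["a", "a", "b"])
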