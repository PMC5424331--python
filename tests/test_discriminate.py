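"""CVA, Mahalanobis/Procrustes permutation tests, LOO classification."""

import numpy as np
import pandas as pd
import pytest

from wingmorph import (
    CanonicalVariates,
    loo_classify,
    pairwise_distance_tests,
    pooled_within_covariance,
    principal_subspace,
    sex_dfa,
)

from conftest import simulate_aligned, two_species_spec


def naive_loo(X, labels, groups=None):
    """Explicit-loop reimplementation of the leave-one-out classifier."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if groups is None:
        groups = list(dict.fromkeys(labels.tolist()))
    g = len(groups)
    mean, basis = principal_subspace(X, max_dim=max(1, len(X) - 1 - g))
    Y = (X - mean) @ basis
    preds = []
    for i in range(len(Y)):
        train = np.ones(len(Y), dtype=bool)
        train[i] = False
        means = {}
        scatter = np.zeros((Y.shape[1], Y.shape[1]))
        for name in groups:
            rows = Y[train & (labels == name)]
            if len(rows) == 0:
                continue
            means[name] = rows.mean(axis=0)
            c = rows - rows.mean(axis=0)
            scatter += c.T @ c
        S_inv = np.linalg.pinv(scatter, rcond=1e-12, hermitian=True)
        d2 = [
            (Y[i] - means[name]) @ S_inv @ (Y[i] - means[name])
            if name in means
            else np.inf
            for name in groups
        ]
        preds.append(int(np.argmin(d2)))
    return np.array(preds)


# ---------------------------------------------------- pooled within covariance


def test_pooled_covariance_matches_hand_computation():
    X = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 1.0], [0.0, 3.0]])
    labels = ["a", "a", "b", "b"]
    cov, mean, basis = pooled_within_covariance(X, labels)
    # deviations (+-1, 0) and (0, +-1): hand scatter = 2*I, / (4-2) = I
    full = basis @ cov @ basis.T
    assert np.allclose(full, np.eye(2), atol=1e-12)


def test_pooled_covariance_degenerate_data_errors():
    X = np.ones((6, 4))
    with pytest.raises(ValueError, match="retained shape dimension is 0"):
        pooled_within_covariance(X, ["a"] * 3 + ["b"] * 3)


def test_pooled_covariance_recovers_known_isotropic_variance():
    rng = np.random.default_rng(0)
    sigma = 0.05
    X = np.concatenate(
        [m + sigma * rng.standard_normal((400, 6)) for m in (np.zeros(6), np.ones(6))]
    )
    labels = ["a"] * 400 + ["b"] * 400
    cov, _, _ = pooled_within_covariance(X, labels)
    evals = np.linalg.eigvalsh(cov)
    assert np.all(np.abs(evals - sigma**2) < 0.2 * sigma**2)


# -------------------------------------------------------------------------- CVA


def test_cva_axis_counts_and_percent_sum():
    rng = np.random.default_rng(1)
    means = [np.zeros(10), np.r_[np.ones(5), np.zeros(5)], np.r_[np.zeros(5), np.ones(5)]]
    X = np.concatenate([m + 0.1 * rng.standard_normal((20, 10)) for m in means])
    labels = np.repeat(["a", "b", "c"], 20)
    res = CanonicalVariates(X, labels).fit()
    assert res.n_axes == 2
    assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-6)
    assert np.all(np.diff(res.percent_variance) <= 1e-9)

    res2 = CanonicalVariates(X[:40], labels[:40]).fit()
    assert res2.n_axes == 1
    assert res2.percent_variance[0] == pytest.approx(100.0, abs=1e-9)


def test_cva_canonical_distance_equals_closed_form_mahalanobis():
    """Group-mean separation in canonical space is the Mahalanobis distance."""
    rng = np.random.default_rng(2)
    cov = np.array([[0.04, 0.018], [0.018, 0.02]])
    L = np.linalg.cholesky(cov)
    mu1, mu2 = np.array([0.0, 0.0]), np.array([0.3, -0.2])
    X = np.concatenate(
        [mu + rng.standard_normal((60, 2)) @ L.T for mu in (mu1, mu2)]
    )
    labels = ["a"] * 60 + ["b"] * 60
    res = CanonicalVariates(X, labels).fit()
    d_canonical = abs(res.group_means[0, 0] - res.group_means[1, 0])
    # closed form with the sample pooled covariance
    cov_hat, mean, basis = pooled_within_covariance(X, labels)
    m1 = ((X[:60] - mean) @ basis).mean(axis=0)
    m2 = ((X[60:] - mean) @ basis).mean(axis=0)
    diff = m1 - m2
    d_closed = np.sqrt(diff @ np.linalg.solve(cov_hat, diff))
    assert d_canonical == pytest.approx(d_closed, abs=1e-6)


def test_cva_scores_have_identity_within_covariance(small_study):
    aligned, _, _ = small_study
    labels = aligned.meta["species"].to_numpy()
    res = CanonicalVariates(aligned.shapes, labels).fit()
    S = np.zeros((res.n_axes, res.n_axes))
    for name in set(labels):
        rows = res.scores[labels == name]
        c = rows - rows.mean(axis=0)
        S += c.T @ c
    S /= len(labels) - len(set(labels))
    assert np.abs(S - np.eye(res.n_axes)).max() < 1e-8


def test_cva_requires_two_specimens_per_group():
    X = np.random.default_rng(3).normal(size=(5, 4))
    with pytest.raises(ValueError, match="too small"):
        CanonicalVariates(X, ["a", "a", "b", "b", "c"])


# ---------------------------------------------------------------- distance tests


def test_distance_tests_shapes_and_reproducibility(small_study):
    aligned, _, _ = small_study
    labels = aligned.meta["species"].to_numpy()
    t1 = pairwise_distance_tests(aligned.shapes, labels, rounds=99, seed=5)
    t2 = pairwise_distance_tests(aligned.shapes, labels, rounds=99, seed=5)
    t3 = pairwise_distance_tests(aligned.shapes, labels, rounds=99, seed=6)
    g = len(t1.labels)
    assert g == 4
    for arr in (t1.mahalanobis, t1.procrustes):
        assert np.allclose(arr, arr.T)
        assert np.all(np.diag(arr) == 0)
    iu = np.triu_indices(g, 1)
    assert np.all(t1.p_mahalanobis[iu] > 0) and np.all(t1.p_mahalanobis[iu] <= 1)
    # same seed: identical p-values; different seed: same observed distances
    assert np.array_equal(t1.p_mahalanobis, t2.p_mahalanobis)
    assert np.array_equal(t1.mahalanobis, t3.mahalanobis)
    assert np.array_equal(t1.procrustes, t3.procrustes)


def test_distance_tests_identical_groups_give_p_one():
    rng = np.random.default_rng(7)
    block = rng.normal(size=(10, 12))
    X = np.concatenate([block, block])  # mirrored assignment, equal means
    labels = ["a"] * 10 + ["b"] * 10
    t = pairwise_distance_tests(X, labels, rounds=99, seed=0)
    # sqrt of a machine-epsilon residual: zero to within sqrt(eps)
    assert t.procrustes[0, 1] == pytest.approx(0.0, abs=1e-6)
    assert t.p_procrustes[0, 1] == 1.0


def test_distance_tests_single_specimen_group():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(7, 8))
    labels = ["a"] * 6 + ["b"]
    t = pairwise_distance_tests(X, labels, rounds=49, seed=0)
    assert np.isnan(t.mahalanobis[0, 1]) or t.mahalanobis[0, 1] == 0.0
    assert np.isnan(t.p_mahalanobis[0, 1])
    assert np.isfinite(t.procrustes[0, 1])
    assert 0 < t.p_procrustes[0, 1] <= 1


def test_twelve_groups_give_66_pairs():
    rng = np.random.default_rng(9)
    X = np.concatenate(
        [m + 0.2 * rng.standard_normal((4, 10)) for m in rng.normal(size=(12, 10))]
    )
    labels = np.repeat([f"sp{i}" for i in range(12)], 4)
    t = pairwise_distance_tests(X, labels, rounds=9, seed=0)
    iu = np.triu_indices(12, 1)
    assert len(iu[0]) == 66
    assert np.all(np.isfinite(t.mahalanobis[iu]))
    assert np.all(np.isfinite(t.procrustes[iu]))


def test_mahalanobis_invariant_under_affine_transform():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(40, 6))
    labels = ["a"] * 20 + ["b"] * 20
    t_ref = pairwise_distance_tests(X, labels, rounds=1, seed=0)
    for _ in range(3):
        A = rng.normal(size=(6, 6)) + 3 * np.eye(6)  # well-conditioned, invertible
        t = pairwise_distance_tests(X @ A.T, labels, rounds=1, seed=0)
        assert t.mahalanobis[0, 1] == pytest.approx(
            t_ref.mahalanobis[0, 1], rel=1e-6
        )


def test_global_covariance_option_matches_direct_formula():
    """covariance='global' uses the all-groups pooled covariance for every pair."""
    aligned, _ = simulate_aligned(two_species_spec(seed=11, n=6))
    labels = aligned.meta["species"].to_numpy().copy()
    labels[-2:] = "C"  # three groups, one tiny
    tg = pairwise_distance_tests(
        aligned.shapes, labels, rounds=9, seed=0, covariance="global"
    )
    assert np.isfinite(tg.mahalanobis).all()
    mean, basis = principal_subspace(aligned.shapes)
    Y = (aligned.shapes - mean) @ basis
    names = list(dict.fromkeys(labels.tolist()))
    centred = Y.copy()
    for name in names:
        centred[labels == name] -= Y[labels == name].mean(axis=0)
    S = centred.T @ centred / (len(Y) - len(names))
    S_inv = np.linalg.pinv(S, rcond=1e-12, hermitian=True)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            diff = Y[labels == names[i]].mean(axis=0) - Y[labels == names[j]].mean(axis=0)
            expected = np.sqrt(diff @ S_inv @ diff)
            assert tg.mahalanobis[i, j] == pytest.approx(expected, rel=1e-9)


# ------------------------------------------------------------ LOO classification


def test_loo_matches_naive_reimplementation():
    rng = np.random.default_rng(12)
    for trial in range(3):
        n_groups = rng.integers(2, 5)
        sizes = rng.integers(4, 12, size=n_groups)
        means = rng.normal(scale=1.0, size=(n_groups, 7))
        X = np.concatenate(
            [m + rng.standard_normal((s, 7)) for m, s in zip(means, sizes)]
        )
        labels = np.repeat([f"g{i}" for i in range(n_groups)], sizes)
        assert len(X) <= 40
        table = loo_classify(X, labels)
        assert np.array_equal(table.predictions, naive_loo(X, labels))


def test_loo_well_separated_species(small_study):
    aligned, _, _ = small_study
    table = loo_classify(aligned.shapes, aligned.meta["species"].to_numpy())
    assert table.overall_total == len(aligned)
    assert (table.frame["n_correct"] <= table.frame["n_total"]).all()
    assert table.overall_percent >= 90.0


def test_loo_outlier_in_group_of_three():
    """A group member sitting on top of the other group is misclassified."""
    rng = np.random.default_rng(13)
    b_centre = np.zeros(6)
    b_centre[0] = 1.0
    good = rng.normal(scale=0.01, size=(2, 6))
    outlier = b_centre + rng.normal(scale=0.01, size=6)
    other = b_centre + rng.normal(scale=0.01, size=(10, 6))
    X = np.concatenate([good, [outlier], other])
    labels = ["a"] * 3 + ["b"] * 10
    table = loo_classify(X, labels)
    row = table.frame.set_index("group").loc["a"]
    assert row["n_correct"] == 2
    assert row["percent"] == pytest.approx(100 * 2 / 3, abs=0.05)


def test_loo_singleton_group_flagged(caplog):
    rng = np.random.default_rng(14)
    X = np.concatenate([rng.normal(size=(6, 5)), [[9] * 5]])
    labels = ["a"] * 6 + ["b"]
    with caplog.at_level("WARNING"):
        table = loo_classify(X, labels)
    assert any("single specimen" in m for m in caplog.messages)
    assert table.frame.set_index("group").loc["b", "n_correct"] == 0


# ---------------------------------------------------------------------- sex DFA


def test_sex_dfa_strong_effect_detected():
    spec = two_species_spec(seed=15, n=60, offset=0.0, sex_shape_offset=0.04)
    aligned, _ = simulate_aligned(spec)
    one = aligned.subset(aligned.meta["species"].to_numpy() == "A")
    res = sex_dfa(one.shapes, one.meta["sex"].to_numpy(), rounds=1999, seed=0)
    assert res.p_value <= 0.001
    assert res.classification.overall_percent > 90.0


def test_sex_dfa_no_effect_near_chance():
    spec = two_species_spec(seed=16, n=60, offset=0.0, sex_shape_offset=0.0)
    aligned, _ = simulate_aligned(spec)
    one = aligned.subset(aligned.meta["species"].to_numpy() == "A")
    res = sex_dfa(one.shapes, one.meta["sex"].to_numpy(), rounds=199, seed=1)
    assert res.p_value > 0.01
    assert 20.0 <= res.classification.overall_percent <= 80.0


def test_sex_dfa_single_sex_rejected():
    X = np.random.default_rng(17).normal(size=(8, 6))
    with pytest.raises(ValueError, match="2 sexes"):
        sex_dfa(X, ["female"] * 8, rounds=9)
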