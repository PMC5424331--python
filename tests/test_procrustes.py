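"""Centroid size, GPA, Procrustes distance and replicate averaging."""

import numpy as np
import pandas as pd
import pytest

from wingmorph import (
    average_replicates,
    centroid_size,
    default_template,
    gpa,
    procrustes_distance,
)


def _rot(theta):
    return np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )


def random_configs(n, k, seed, scale=1.0):
    rng = np.random.default_rng(seed)
    return rng.normal(scale=scale, size=(n, k, 2))


# ---------------------------------------------------------------- centroid size


def test_centroid_size_unit_square():
    sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
    assert centroid_size(sq) == pytest.approx(np.sqrt(2.0), abs=1e-12)


def test_centroid_size_homogeneity_and_rigid_invariance():
    cfg = random_configs(1, 19, 0)[0]
    cs = centroid_size(cfg)
    assert centroid_size(3.0 * cfg) == pytest.approx(3.0 * cs, rel=1e-12)
    moved = cfg @ _rot(0.7).T + [5.0, -2.0]
    assert centroid_size(moved) == pytest.approx(cs, rel=1e-12)


def test_centroid_size_matches_direct_summation():
    cfg = random_configs(1, 19, 1)[0]
    centre = cfg.mean(axis=0)
    brute = np.sqrt(sum(np.sum((p - centre) ** 2) for p in cfg))
    assert abs(centroid_size(cfg) - brute) < 1e-12


def test_centroid_size_degenerate_raises():
    with pytest.raises(ValueError, match="degenerate"):
        centroid_size(np.ones((5, 2)))
    with pytest.raises(ValueError):
        centroid_size(np.ones((2, 2)))  # k < 3


# ------------------------------------------------------------------------- GPA


def test_gpa_removes_similarity_nuisance():
    base = random_configs(1, 19, 2)[0]
    moved = 2.5 * base @ _rot(np.pi / 6).T + [10.0, -3.0]
    aligned = gpa(np.stack([base, moved]))
    assert np.abs(aligned.shapes[0] - aligned.shapes[1]).max() < 1e-9


def test_gpa_constraint_satisfaction():
    configs = random_configs(12, 19, 3)
    aligned = gpa(configs)
    rows = aligned.configurations()
    assert np.abs(rows.mean(axis=1)).max() < 1e-9  # centroids at origin
    assert centroid_size(aligned.consensus) == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(aligned.objective_history) <= 1e-12)


def test_gpa_invariant_under_common_similarity_transform():
    """Rotating/translating/scaling every input leaves the result unchanged."""
    configs = random_configs(10, 19, 4)
    rng = np.random.default_rng(5)
    ref = gpa(configs).shapes
    for _ in range(3):
        R = _rot(rng.uniform(0, 2 * np.pi))
        s = rng.uniform(0.3, 4.0)
        t = rng.uniform(-10, 10, size=2)
        moved = np.stack([s * c @ R.T + t for c in configs])
        assert np.abs(gpa(moved).shapes - ref).max() < 1e-9


def test_gpa_tangent_rows_orthogonal_to_nuisance_directions():
    aligned = gpa(random_configs(15, 19, 6))
    c = aligned.consensus
    k = aligned.k
    tx = np.zeros(2 * k)
    ty = np.zeros(2 * k)
    tx[0::2] = 1.0
    ty[1::2] = 1.0
    scale_dir = c.reshape(-1)
    rot_dir = np.stack([-c[:, 1], c[:, 0]], axis=1).reshape(-1)
    dev = aligned.shapes - scale_dir
    for direction in (tx / np.linalg.norm(tx), ty / np.linalg.norm(ty),
                      scale_dir, rot_dir / np.linalg.norm(rot_dir)):
        assert np.abs(dev @ direction).max() < 1e-9


def test_gpa_shape_space_rank_bound():
    """A rich dataset spans at most 2k - 4 dimensions after superimposition."""
    aligned = gpa(random_configs(60, 19, 7, scale=1.0))
    centred = aligned.shapes - aligned.shapes.mean(axis=0)
    rank = np.linalg.matrix_rank(centred, tol=1e-9)
    assert rank <= 2 * 19 - 4


def test_gpa_requires_two_configs():
    with pytest.raises(ValueError, match="at least 2"):
        gpa(random_configs(1, 5, 8))


# ---------------------------------------------------------- Procrustes distance


def test_procrustes_distance_identity_and_rotation():
    cfg = random_configs(1, 19, 9)[0]
    assert procrustes_distance(cfg, cfg) == pytest.approx(0.0, abs=1e-9)
    assert procrustes_distance(cfg, cfg @ _rot(np.pi / 2).T) == pytest.approx(
        0.0, abs=1e-7
    )


def test_procrustes_distance_matches_rotation_grid_search():
    """Brute-force search over rotation angles agrees to 1e-6."""
    rng = np.random.default_rng(10)
    for _ in range(5):
        a, b = rng.normal(size=(2, 12, 2))
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        ac /= np.sqrt(np.sum(ac**2))
        bc /= np.sqrt(np.sum(bc**2))
        angles = np.arange(0.0, 2 * np.pi, 1e-4)
        best = min(
            np.sum((ac - bc @ _rot(t).T) ** 2) for t in angles
        )
        assert procrustes_distance(a, b) == pytest.approx(np.sqrt(best), abs=1e-6)


def test_procrustes_distance_metric_properties():
    rng = np.random.default_rng(11)
    shapes = rng.normal(size=(6, 10, 2))
    for i in range(6):
        for j in range(6):
            dij = procrustes_distance(shapes[i], shapes[j])
            assert dij == pytest.approx(
                procrustes_distance(shapes[j], shapes[i]), abs=1e-12
            )
    for _ in range(20):
        i, j, l = rng.integers(0, 6, size=3)
        assert procrustes_distance(shapes[i], shapes[j]) <= (
            procrustes_distance(shapes[i], shapes[l])
            + procrustes_distance(shapes[l], shapes[j])
            + 1e-12
        )


def test_procrustes_distance_mismatched_k_raises():
    with pytest.raises(ValueError, match="landmark counts differ"):
        procrustes_distance(np.zeros((5, 2)), np.zeros((6, 2)))


# ---------------------------------------------------------- replicate averaging


def test_average_replicates_arithmetic_mean():
    configs = random_configs(2, 19, 12)
    delta = 1e-3 * random_configs(1, 19, 13)[0]
    stack = np.stack([configs[0], configs[0] + delta, configs[1]])
    meta = pd.DataFrame(
        {"specimen_id": ["a", "a", "b"], "replicate": [1, 2, 1]}
    )
    aligned = gpa(stack, meta=meta)
    avg = average_replicates(aligned)
    assert len(avg) == 2
    expected = 0.5 * (aligned.shapes[0] + aligned.shapes[1])
    assert np.allclose(avg.shapes[0], expected, atol=1e-15)
    assert avg.centroid_sizes[0] == pytest.approx(
        aligned.centroid_sizes[:2].mean(), rel=1e-15
    )
    # single-replicate specimen passes through
    assert np.array_equal(avg.shapes[1], aligned.shapes[2])


def test_average_of_identical_replicates_is_identity():
    cfg = random_configs(1, 19, 14)[0]
    other = random_configs(1, 19, 15)[0]
    meta = pd.DataFrame({"specimen_id": ["a", "a", "b"], "replicate": [1, 2, 1]})
    aligned = gpa(np.stack([cfg, cfg, other]), meta=meta)
    avg = average_replicates(aligned)
    assert np.allclose(avg.shapes[0], aligned.shapes[0], atol=1e-12)


def test_default_template_is_fixed_and_nondegenerate():
    t1 = default_template()
    t2 = default_template()
    assert t1.shape == (19, 2)
    assert np.array_equal(t1, t2)
    assert centroid_size(t1) > 0
    t1[0, 0] = 99.0  # returned copy must not alias the packaged constant
    assert default_template()[0, 0] != 99.0
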