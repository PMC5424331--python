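"""Group discrimination in shape space.

Canonical variate analysis (CVA), pairwise Mahalanobis/Procrustes distance
matrices with permutation tests, and leave-one-out cross-validated
classification, as used to separate taxa (genera, species) and sexes from
Procrustes tangent coordinates.

Procrustes tangent data are rank-deficient (dimension at most 2k - 4 for k
2-D landmarks) and small groups make pooled covariances singular.  All
operations therefore work in a retained subspace: the principal-component
basis of the total dataset, keeping components whose eigenvalue exceeds
1e-12 times the largest, further capped at n - g components when group
labels are in play.  Remaining rank deficiencies (tiny groups in pairwise
comparisons) are handled by a deterministic eigenvalue-truncated
pseudo-inverse, applied identically to observed and permuted statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .procrustes import procrustes_distance

logger = logging.getLogger(__name__)

__all__ = [
    "principal_subspace",
    "pooled_within_covariance",
    "CanonicalVariates",
    "CVAResults",
    "pairwise_distance_tests",
    "DistanceTestMatrix",
    "loo_classify",
    "ClassificationTable",
    "sex_dfa",
    "SexDimorphismResult",
]

_RTOL = 1e-12


def _group_info(labels, groups=None):
    labels = np.asarray(labels)
    if groups is None:
        # order of first appearance = declared label order
        groups = list(dict.fromkeys(labels.tolist()))
    groups = list(groups)
    index = {g: i for i, g in enumerate(groups)}
    codes = np.array([index[l] for l in labels])
    return groups, codes


def principal_subspace(shapes: np.ndarray, rtol: float = _RTOL, max_dim: int | None = None):
    """Orthonormal basis of the subspace actually occupied by the data.

    Returns ``(mean, basis)`` where ``basis`` is (d, r) with columns the
    principal directions whose variance exceeds ``rtol`` times the largest;
    ``max_dim`` optionally caps r.
    """
    X = np.asarray(shapes, dtype=float)
    mean = X.mean(axis=0)
    _, s, vt = np.linalg.svd(X - mean, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        return mean, np.empty((X.shape[1], 0))
    keep = s**2 > rtol * s[0] ** 2
    r = int(keep.sum())
    if max_dim is not None:
        r = min(r, max_dim)
    return mean, vt[:r].T


def pooled_within_covariance(shapes: np.ndarray, labels, groups=None, rtol: float = _RTOL):
    """Pooled within-group covariance in the retained subspace.

    Group-mean-centred shapes, covariance with divisor (n - g), expressed
    in the principal-component basis of the total dataset (capped at n - g
    components so the estimate has a chance of full rank).  Returns
    ``(cov, mean, basis)``.
    """
    X = np.asarray(shapes, dtype=float)
    groups_, codes = _group_info(labels, groups)
    n, g = len(X), len(groups_)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if n <= g:
        raise ValueError(f"need n > g, got n={n}, g={g}")
    counts = np.bincount(codes, minlength=g)
    if counts.min() < 1:
        raise ValueError("every group needs at least 1 specimen")
    mean, basis = principal_subspace(X, rtol=rtol, max_dim=n - g)
    if basis.shape[1] == 0:
        raise ValueError("retained shape dimension is 0 (no variation in data)")
    Y = (X - mean) @ basis
    centred = Y.copy()
    for i in range(g):
        rows = codes == i
        centred[rows] -= Y[rows].mean(axis=0)
    cov = centred.T @ centred / (n - g)
    return cov, mean, basis


def _truncated_inv_sqrt(S: np.ndarray, rtol: float = _RTOL) -> np.ndarray:
    """W^{-1/2} via eigendecomposition, dropping eigenvalues < rtol * max."""
    w, V = np.linalg.eigh(S)
    keep = w > rtol * w[-1]
    if not keep.any():
        raise ValueError("within-group covariance has rank 0")
    return V[:, keep] / np.sqrt(w[keep])


class CanonicalVariates:
    """Canonical variate analysis of shapes grouped by a label.

    Finds the shape-space directions maximising among-group relative to
    pooled within-group variation; at most g - 1 non-trivial axes exist
    for g groups.  Scores are normalised so the pooled within-group
    covariance in canonical space is the identity.

    Parameters
    ----------
    shapes : (n, d) array
        Procrustes tangent coordinates (or any flat shape representation).
    labels : (n,) sequence
        Group label per row.
    groups : sequence, optional
        Declared group order; defaults to order of first appearance.
    """

    def __init__(self, shapes, labels, groups=None):
        self.shapes = np.asarray(shapes, dtype=float)
        self.groups, self.codes = _group_info(labels, groups)
        self.labels = np.asarray(labels)
        if len(self.shapes) != len(self.labels):
            raise ValueError("shapes and labels length mismatch")
        counts = np.bincount(self.codes, minlength=len(self.groups))
        if counts.min() < 2:
            small = [g for g, c in zip(self.groups, counts) if c < 2]
            raise ValueError(f"each group needs >= 2 specimens; too small: {small}")

    def fit(self) -> "CVAResults":
        X = self.shapes
        g = len(self.groups)
        n = len(X)
        W, mean, basis = pooled_within_covariance(X, self.labels, self.groups)
        Y = (X - mean) @ basis
        group_means = np.stack(
            [Y[self.codes == i].mean(axis=0) for i in range(g)]
        )
        counts = np.bincount(self.codes, minlength=g).astype(float)
        grand = Y.mean(axis=0)
        dev = group_means - grand
        B = (dev.T * counts) @ dev / (n - g)
        Wm12 = _truncated_inv_sqrt(W)
        Bw = Wm12.T @ B @ Wm12
        evals, evecs = np.linalg.eigh(Bw)
        order = np.argsort(evals)[::-1]
        t = min(g - 1, Bw.shape[0])
        evals = np.clip(evals[order][:t], 0.0, None)
        axes_retained = Wm12 @ evecs[:, order][:, :t]  # (r, t), a^T W a = 1
        total = evals.sum()
        percent = 100.0 * evals / total if total > 0 else np.zeros(t)
        scores = (Y - grand) @ axes_retained
        return CVAResults(
            model=self,
            eigenvalues=evals,
            percent_variance=percent,
            scores=scores,
            canonical_vectors=basis @ axes_retained,
            group_means=group_means @ axes_retained,
            mean=mean,
            basis=basis,
        )


@dataclass
class CVAResults:
    """Fitted canonical variate ordination.

    ``scores`` are specimen coordinates on the canonical axes;
    ``percent_variance`` the share of among-group variation per axis
    (CV1%, CV2%, ...); ``canonical_vectors`` map the axes back to the
    original shape coordinates.
    """

    model: CanonicalVariates
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    scores: np.ndarray
    canonical_vectors: np.ndarray
    group_means: np.ndarray
    mean: np.ndarray
    basis: np.ndarray

    @property
    def groups(self):
        return self.model.groups

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    def mahalanobis_matrix(self) -> pd.DataFrame:
        """Pairwise group-mean distances in canonical space.

        Euclidean distance between group means in the full canonical space
        equals the Mahalanobis distance with the globally pooled
        within-group covariance.
        """
        g = len(self.groups)
        D = np.zeros((g, g))
        for i in range(g):
            for j in range(i + 1, g):
                d = float(np.linalg.norm(self.group_means[i] - self.group_means[j]))
                D[i, j] = D[j, i] = d
        return pd.DataFrame(D, index=self.groups, columns=self.groups)

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"CV{i + 1}" for i in range(self.n_axes)]
        out = pd.DataFrame(self.scores, columns=cols)
        out.insert(0, "group", self.model.labels)
        return out

    def summary(self) -> str:
        lines = [
            "Canonical variate analysis",
            f"  groups: {len(self.groups)}  specimens: {len(self.model.shapes)}"
            f"  retained shape dims: {self.basis.shape[1]}",
            "  axis   eigenvalue   % variance",
        ]
        for i, (ev, pc) in enumerate(zip(self.eigenvalues, self.percent_variance)):
            lines.append(f"  CV{i + 1:<4d} {ev:>10.4f} {pc:>12.2f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# pairwise permutation tests


def _pair_seed(seed, pair_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(pair_index,))
    )


def _mahalanobis_sq_batch(diffs: np.ndarray, scatters: np.ndarray, dof: float,
                          rtol: float = _RTOL) -> np.ndarray:
    """Batched squared Mahalanobis distances with truncated-eigen inverse.

    ``diffs``: (..., d); ``scatters``: (..., d, d) within-group scatter
    matrices (divided by ``dof`` to form covariances).
    """
    w, V = np.linalg.eigh(scatters / dof)
    keep = w > rtol * w[..., -1:]
    proj = np.einsum("...ij,...i->...j", V, diffs)
    contrib = np.where(keep, proj**2 / np.where(keep, w, 1.0), 0.0)
    return contrib.sum(axis=-1)


def _procrustes_mean_distance_batch(means_a: np.ndarray, means_b: np.ndarray) -> np.ndarray:
    """Procrustes distance between mean configurations, batched over rows.

    Means are flat (..., 2k) rows interpreted as k planar landmarks;
    rotation-only alignment via the complex closed form.
    """
    za = means_a[..., 0::2] + 1j * means_a[..., 1::2]
    zb = means_b[..., 0::2] + 1j * means_b[..., 1::2]
    za = za - za.mean(axis=-1, keepdims=True)
    zb = zb - zb.mean(axis=-1, keepdims=True)
    za = za / np.linalg.norm(za, axis=-1, keepdims=True)
    zb = zb / np.linalg.norm(zb, axis=-1, keepdims=True)
    cross = np.abs((np.conj(za) * zb).sum(axis=-1))
    return np.sqrt(np.clip(2.0 - 2.0 * cross, 0.0, None))


@dataclass
class DistanceTestMatrix:
    """Pairwise group shape distances with permutation p-values.

    Mahalanobis distances use the pooled within-group covariance of each
    pair (in the retained subspace); Procrustes distances are between the
    group mean configurations.  p-values follow the (b + 1) / (rounds + 1)
    convention and are never exactly zero.
    """

    labels: list
    mahalanobis: np.ndarray
    procrustes: np.ndarray
    p_mahalanobis: np.ndarray
    p_procrustes: np.ndarray
    rounds: int
    seed: int | None

    def frame(self, which: str) -> pd.DataFrame:
        arr = getattr(self, which)
        return pd.DataFrame(arr, index=self.labels, columns=self.labels)

    @staticmethod
    def stars(p: float) -> str:
        if np.isnan(p):
            return ""
        if p < 0.0001:
            return "***"
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return ""

    def summary(self) -> str:
        lines = [f"Pairwise distance tests ({self.rounds} permutation rounds)"]
        g = len(self.labels)
        for i in range(g):
            for j in range(i + 1, g):
                lines.append(
                    f"  {self.labels[i]} vs {self.labels[j]}: "
                    f"D = {self.mahalanobis[i, j]:.4f}"
                    f"{self.stars(self.p_mahalanobis[i, j])}"
                    f" (P = {self.p_mahalanobis[i, j]:.4g}), "
                    f"Procrustes d = {self.procrustes[i, j]:.4f}"
                    f"{self.stars(self.p_procrustes[i, j])}"
                    f" (P = {self.p_procrustes[i, j]:.4g})"
                )
        return "\n".join(lines)


def pairwise_distance_tests(
    shapes: np.ndarray,
    labels,
    rounds: int = 10_000,
    seed: int | None = None,
    groups=None,
    covariance: str = "pairwise",
    rtol: float = _RTOL,
) -> DistanceTestMatrix:
    """Observed pairwise group distances and their permutation p-values.

    For each unordered group pair the observed Mahalanobis distance
    (pairwise-pooled covariance in the retained subspace of the total
    dataset) and the Procrustes distance between mean shapes are compared
    with ``rounds`` random relabellings preserving group sizes; the
    p-value is (b + 1) / (rounds + 1) with b the number of permuted
    statistics >= the observed one.  Per-pair RNG streams are derived
    deterministically from (seed, pair index), so single pairs can be
    reproduced in isolation.

    A pair containing a single-specimen group has no defined Mahalanobis
    distance (flagged NaN, logged); its Procrustes test still runs.

    ``covariance="pairwise"`` (default) pools the within-group covariance
    over the two groups of each pair, matching pairwise discriminant
    analysis; ``"global"`` holds the covariance pooled over all groups
    fixed, which tempers the distance inflation of very small groups.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if covariance not in ("pairwise", "global"):
        raise ValueError("covariance must be 'pairwise' or 'global'")
    X = np.asarray(shapes, dtype=float)
    groups_, codes = _group_info(labels, groups)
    g = len(groups_)
    if g < 2:
        raise ValueError("need at least 2 groups")
    mean, basis = principal_subspace(X, rtol=rtol)
    Y = (X - mean) @ basis
    S_global = None
    if covariance == "global":
        centred = Y.copy()
        for gi in range(g):
            rows = codes == gi
            centred[rows] -= Y[rows].mean(axis=0)
        S_global = centred.T @ centred / max(1, len(Y) - g)

    maha = np.zeros((g, g))
    proc = np.zeros((g, g))
    p_maha = np.full((g, g), np.nan)
    p_proc = np.full((g, g), np.nan)
    np.fill_diagonal(p_maha, 1.0)
    np.fill_diagonal(p_proc, 1.0)

    pair_index = 0
    for i in range(g):
        for j in range(i + 1, g):
            rows = np.flatnonzero((codes == i) | (codes == j))
            in_i = codes[rows] == i
            n1, n2 = int(in_i.sum()), int(len(rows) - in_i.sum())
            Xp = X[rows]
            Yp = Y[rows]
            rng = _pair_seed(seed, pair_index)
            pair_index += 1

            # permutation index matrix: row 0 = observed assignment,
            # reordered so group-i members come first
            perm = np.empty((rounds + 1, len(rows)), dtype=np.intp)
            perm[0] = np.argsort(np.where(in_i, 0, 1), kind="stable")
            for r in range(1, rounds + 1):
                perm[r] = rng.permutation(len(rows))

            A_flat = Xp[perm[..., :n1]]  # (R+1, n1, 2k)
            B_flat = Xp[perm[..., n1:]]
            mean_a_flat = A_flat.mean(axis=1)
            mean_b_flat = B_flat.mean(axis=1)
            d_proc = _procrustes_mean_distance_batch(mean_a_flat, mean_b_flat)
            # sanity: observed via the scalar routine
            k = X.shape[1] // 2
            proc[i, j] = proc[j, i] = procrustes_distance(
                mean_a_flat[0].reshape(k, 2), mean_b_flat[0].reshape(k, 2)
            )
            # tiny slack so permutations equal to the observed statistic up
            # to float jitter count as >= (keeps p = 1 in degenerate cases)
            b_proc = int(np.sum(d_proc[1:] ** 2 >= d_proc[0] ** 2 - 1e-12))
            p_proc[i, j] = p_proc[j, i] = (b_proc + 1) / (rounds + 1)

            if n1 < 2 or n2 < 2:
                logger.warning(
                    "pair (%s, %s): a group has a single specimen; "
                    "Mahalanobis distance undefined",
                    groups_[i],
                    groups_[j],
                )
                continue
            A = Yp[perm[..., :n1]]
            Bv = Yp[perm[..., n1:]]
            ma = A.mean(axis=1)
            mb = Bv.mean(axis=1)
            if S_global is not None:
                w, V = np.linalg.eigh(S_global)
                keepw = w > rtol * w[-1]
                proj = (ma - mb) @ V[:, keepw]
                d2 = np.sum(proj**2 / w[keepw], axis=-1)
            else:
                total_scatter = Yp.T @ Yp  # constant across permutations
                Sw = (
                    total_scatter[None]
                    - n1 * np.einsum("ri,rj->rij", ma, ma)
                    - n2 * np.einsum("ri,rj->rij", mb, mb)
                )
                d2 = _mahalanobis_sq_batch(ma - mb, Sw, dof=n1 + n2 - 2, rtol=rtol)
            d_maha = np.sqrt(np.clip(d2, 0.0, None))
            maha[i, j] = maha[j, i] = d_maha[0]
            b_maha = int(np.sum(d2[1:] >= d2[0] - 1e-12))
            p_maha[i, j] = p_maha[j, i] = (b_maha + 1) / (rounds + 1)

    return DistanceTestMatrix(
        labels=groups_,
        mahalanobis=maha,
        procrustes=proc,
        p_mahalanobis=p_maha,
        p_procrustes=p_proc,
        rounds=rounds,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# leave-one-out classification


@dataclass
class ClassificationTable:
    """Cross-validated classification tallies per group."""

    frame: pd.DataFrame  # columns: group, n_correct, n_total, percent
    predictions: np.ndarray = field(repr=False, default=None)

    @property
    def overall_correct(self) -> int:
        return int(self.frame["n_correct"].sum())

    @property
    def overall_total(self) -> int:
        return int(self.frame["n_total"].sum())

    @property
    def overall_percent(self) -> float:
        return 100.0 * self.overall_correct / self.overall_total

    def summary(self) -> str:
        lines = ["Leave-one-out cross-validated classification"]
        for _, row in self.frame.iterrows():
            lines.append(
                f"  {row['group']}: {row['percent']:.1f}% "
                f"({row['n_correct']}/{row['n_total']})"
            )
        lines.append(
            f"  overall: {self.overall_percent:.1f}% "
            f"({self.overall_correct}/{self.overall_total})"
        )
        return "\n".join(lines)


def loo_classify(
    shapes: np.ndarray,
    labels,
    groups=None,
    rtol: float = _RTOL,
) -> ClassificationTable:
    """Leave-one-out nearest-group Mahalanobis classification.

    Each specimen is assigned to the group whose mean is closest in
    Mahalanobis distance, with group means and the pooled within-group
    covariance recomputed without that specimen.  Distances are computed
    in the retained principal subspace of the full dataset; ties are
    broken by declared group order (logged).  A held-out member of a
    single-specimen group cannot be assigned to its own group and counts
    as incorrect (logged).
    """
    X = np.asarray(shapes, dtype=float)
    groups_, codes = _group_info(labels, groups)
    g = len(groups_)
    n = len(X)
    counts = np.bincount(codes, minlength=g)
    if counts.min() < 1:
        raise ValueError("empty group")
    for gi, c in enumerate(counts):
        if c == 1:
            logger.warning(
                "group %r has a single specimen; it will be misclassified "
                "by construction in leave-one-out",
                groups_[gi],
            )
    mean, basis = principal_subspace(X, rtol=rtol, max_dim=max(1, n - 1 - g))
    Y = (X - mean) @ basis
    d = Y.shape[1]

    sums = np.zeros((g, d))
    scatters = np.zeros((g, d, d))
    for gi in range(g):
        rows = Y[codes == gi]
        sums[gi] = rows.sum(axis=0)
        m = rows.mean(axis=0)
        scatters[gi] = rows.T @ rows - counts[gi] * np.outer(m, m)
    base_scatter = scatters.sum(axis=0)

    predictions = np.empty(n, dtype=np.intp)
    for idx in range(n):
        gi = codes[idx]
        x = Y[idx]
        c = counts.copy()
        s = sums.copy()
        c[gi] -= 1
        s[gi] -= x
        # within-group scatter with specimen idx removed: only group gi changes
        if c[gi] > 0:
            m_old = sums[gi] / counts[gi]
            m_new = s[gi] / c[gi]
            scatter_gi = (
                scatters[gi]
                - np.outer(x, x)
                + counts[gi] * np.outer(m_old, m_old)
                - c[gi] * np.outer(m_new, m_new)
            )
        else:
            scatter_gi = np.zeros((d, d))
        Sw = base_scatter - scatters[gi] + scatter_gi
        dof = max(1, n - 1 - int((c > 0).sum()))
        w, V = np.linalg.eigh(Sw / dof)
        keep = w > rtol * w[-1]
        d2 = np.full(g, np.inf)
        for gj in range(g):
            if c[gj] == 0:
                continue
            diff = x - s[gj] / c[gj]
            proj = V[:, keep].T @ diff
            d2[gj] = float(np.sum(proj**2 / w[keep]))
        best = int(np.argmin(d2))
        near = np.isclose(d2, d2[best], rtol=1e-12, atol=0.0)
        if near.sum() > 1:
            logger.warning(
                "tie in nearest-group assignment for row %d; "
                "broken by declared group order",
                idx,
            )
        predictions[idx] = best

    rows = []
    for gi, name in enumerate(groups_):
        members = codes == gi
        n_total = int(members.sum())
        n_correct = int((predictions[members] == gi).sum())
        rows.append(
            {
                "group": name,
                "n_correct": n_correct,
                "n_total": n_total,
                "percent": 100.0 * n_correct / n_total,
            }
        )
    return ClassificationTable(frame=pd.DataFrame(rows), predictions=predictions)


# ---------------------------------------------------------------------------
# two-group (sex) discriminant analysis


@dataclass
class SexDimorphismResult:
    """Two-group shape discrimination between sexes of one species."""

    mahalanobis: float
    p_value: float
    procrustes: float
    p_procrustes: float
    classification: ClassificationTable
    rounds: int

    def summary(self) -> str:
        return (
            f"Sexual shape dimorphism: D = {self.mahalanobis:.4f} "
            f"(P = {self.p_value:.4g}, {self.rounds} rounds); "
            f"accuracy {self.classification.overall_percent:.1f}%"
        )


def sex_dfa(
    shapes: np.ndarray,
    sex_labels,
    rounds: int = 10_000,
    seed: int | None = None,
) -> SexDimorphismResult:
    """Discriminant analysis of shape between males and females.

    Two-group specialisation of the pairwise distance test plus
    leave-one-out classification.  Both sexes must have at least two
    specimens; single-sex samples are the caller's to skip.
    """
    sexes = sorted(set(np.asarray(sex_labels).tolist()))
    if len(sexes) != 2:
        raise ValueError(f"need exactly 2 sexes, got {sexes}")
    counts = pd.Series(sex_labels).value_counts()
    if counts.min() < 2:
        raise ValueError(f"both sexes need >= 2 specimens, got {counts.to_dict()}")
    tests = pairwise_distance_tests(
        shapes, sex_labels, rounds=rounds, seed=seed, groups=sexes
    )
    table = loo_classify(shapes, sex_labels, groups=sexes)
    return SexDimorphismResult(
        mahalanobis=float(tests.mahalanobis[0, 1]),
        p_value=float(tests.p_mahalanobis[0, 1]),
        procrustes=float(tests.procrustes[0, 1]),
        p_procrustes=float(tests.p_procrustes[0, 1]),
        classification=table,
        rounds=rounds,
    )
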