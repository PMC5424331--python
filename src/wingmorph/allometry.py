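"""Multivariate regression of shape on centroid size (allometry).

Allometry is the dependence of shape on size.  It is quantified here by
regressing every Procrustes tangent coordinate on centroid size and
reporting the percentage of total shape variation the fit predicts,
100 * SS(predicted) / SS(total), with a permutation test on that
statistic.  "Allometry-free" shapes — the input shapes with the estimated
common allometric component removed — can be fed back into the
discrimination analyses to rerun them size-corrected.

Pooling: with ``pooling`` labels (species, or sex within species), shapes
and sizes are centred on their subgroup means before fitting, so the
slope is the common within-group allometric trajectory and group mean
differences do not masquerade as allometry.  The size predictor is
centroid size on its natural scale by default; ``log_size`` switches to
log size, the convention of some reference software for this analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ShapeAllometry", "ShapeAllometryResults"]


class ShapeAllometry:
    """Model for the multivariate regression of shape on size.

    Parameters
    ----------
    shapes : (n, d) array
        Procrustes tangent coordinates.
    sizes : (n,) array
        Centroid sizes (positive).
    pooling : sequence, optional
        Subgroup label per specimen; fitting is pooled within these
        subgroups.  ``None`` fits a single overall regression.
    log_size : bool
        Regress on log centroid size instead of raw centroid size.
    """

    def __init__(self, shapes, sizes, pooling=None, log_size: bool = False):
        self.shapes = np.asarray(shapes, dtype=float)
        self.sizes = np.asarray(sizes, dtype=float)
        if len(self.shapes) != len(self.sizes):
            raise ValueError("shapes and sizes length mismatch")
        if len(self.shapes) < 3:
            raise ValueError("need at least 3 specimens")
        if not np.all(self.sizes > 0):
            raise ValueError("centroid sizes must be positive")
        if np.ptp(self.sizes) == 0:
            raise ValueError("sizes are constant; regression undefined")
        self.log_size = log_size
        self.pooling = None if pooling is None else np.asarray(pooling)

    def _prepare(self):
        """Subgroup-centred predictor and response, with small groups dropped."""
        s = np.log(self.sizes) if self.log_size else self.sizes.copy()
        X = self.shapes
        n = len(X)
        if self.pooling is None:
            keep = np.ones(n, dtype=bool)
            groups = np.zeros(n, dtype=int)
        else:
            labels, inverse = np.unique(self.pooling, return_inverse=True)
            counts = np.bincount(inverse)
            small = counts < 2
            if small.any():
                logger.warning(
                    "dropping subgroup(s) with < 2 members from pooled "
                    "regression: %s",
                    labels[small].tolist(),
                )
            keep = ~small[inverse]
            groups = inverse
        Xk = X[keep]
        sk = s[keep]
        gk = groups[keep]
        s_c = sk.copy()
        X_c = Xk.copy()
        for gi in np.unique(gk):
            rows = gk == gi
            s_c[rows] -= sk[rows].mean()
            X_c[rows] -= Xk[rows].mean(axis=0)
        if np.allclose(s_c, 0.0):
            raise ValueError("sizes constant within every pooling subgroup")
        return keep, gk, s_c, X_c, sk

    def fit(self, rounds: int = 10_000, seed: int | None = None) -> "ShapeAllometryResults":
        """Least-squares fit with a permutation test on percent predicted.

        The null distribution permutes size values against shapes within
        each pooling subgroup; p = (b + 1) / (rounds + 1) with b the
        number of permuted statistics >= the observed percent predicted.
        """
        keep, gk, s_c, X_c, sk = self._prepare()
        ss_tot = float(np.sum(X_c**2))
        if ss_tot == 0.0:
            raise ValueError("no shape variation")
        ss_s = float(np.sum(s_c**2))
        slope = (s_c @ X_c) / ss_s  # (d,)
        predicted = np.outer(s_c, slope)
        ss_pred = float(np.sum(predicted**2))
        residuals = X_c - predicted
        percent = 100.0 * ss_pred / ss_tot

        p_value = np.nan
        if rounds >= 1:
            rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
            n_keep = len(s_c)
            perms = np.empty((rounds, n_keep))
            for r in range(rounds):
                sp = s_c.copy()
                for gi in np.unique(gk):
                    rows = np.flatnonzero(gk == gi)
                    sp[rows] = sp[rows[rng.permutation(len(rows))]]
                perms[r] = sp
            # permuting within subgroups preserves sum(s_c^2)
            num = np.sum((perms @ X_c) ** 2, axis=1) / ss_s
            stat = 100.0 * num / ss_tot
            b = int(np.sum(stat >= percent))
            p_value = (b + 1) / (rounds + 1)

        grand_mean = self.shapes.mean(axis=0)
        s_grand = sk.mean()
        return ShapeAllometryResults(
            model=self,
            slope_vector=slope,
            intercept=grand_mean - s_grand * slope,
            percent_predicted=percent,
            p_value=float(p_value),
            rounds=rounds,
            residuals=residuals,
            kept=keep,
            size_grand_mean=float(s_grand),
            pooling="none" if self.pooling is None else "within_group",
        )


@dataclass
class ShapeAllometryResults:
    """Fitted shape-on-size regression.

    ``percent_predicted`` is the size-related share of total shape
    variation; ``residuals`` are the within-pooling allometry-free
    deviations; ``slope_vector`` is the shape change per unit size.
    """

    model: ShapeAllometry
    slope_vector: np.ndarray
    intercept: np.ndarray
    percent_predicted: float
    p_value: float
    rounds: int
    residuals: np.ndarray
    kept: np.ndarray
    size_grand_mean: float
    pooling: str

    def allometry_free_shapes(self) -> np.ndarray:
        """Shapes with the estimated common allometric component removed.

        Returns x_i - b * (s_i - s_bar) for every specimen (including
        members of subgroups dropped from the fit), evaluated at the
        grand mean size.  Group mean differences are retained, so the
        corrected shapes can rerun every discrimination analysis
        size-free.  In the unpooled case this equals the regression
        residuals re-centred on the grand mean shape.
        """
        s = np.log(self.model.sizes) if self.model.log_size else self.model.sizes
        return self.model.shapes - np.outer(s - self.size_grand_mean, self.slope_vector)

    def summary(self) -> str:
        p_txt = "n/a" if np.isnan(self.p_value) else f"{self.p_value:.4g}"
        return (
            "Multivariate regression of shape on centroid size\n"
            f"  pooling: {self.pooling}   n = {int(self.kept.sum())}"
            f" (of {len(self.kept)})\n"
            f"  % predicted: {self.percent_predicted:.2f}\n"
            f"  permutation P ({self.rounds} rounds): {p_txt}"
        )
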