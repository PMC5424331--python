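"""Nonparametric comparisons of centroid size among species and sexes.

Size differences among g species are tested with the Kruskal-Wallis
H-test (tie-corrected, chi-squared approximation with g - 1 df),
followed by pairwise Mann-Whitney U-tests with a Bonferroni-corrected
significance level over the species-pair family (alpha / C(g, 2)).
Sexual size dimorphism is tested per species, two-sided and uncorrected
at alpha = 0.05.

Mann-Whitney p-values are exact (full enumeration of rank splits) when
n1 * n2 <= 400 and the data are tie-free, otherwise the normal
approximation with tie and continuity corrections is used.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "kruskal_wallis",
    "mann_whitney",
    "pairwise_size_tests",
    "sexual_size_dimorphism",
    "boxplot_stats",
    "SizeTestReport",
    "size_test_report",
]

_EXACT_LIMIT = 400


def kruskal_wallis(groups: dict | list) -> dict:
    """Kruskal-Wallis H-test over groups of sizes.

    Returns ``{"H": ..., "df": g - 1, "p": ...}``; H is tie-corrected and
    the p-value uses the chi-squared approximation.  If every observation
    is identical, H = 0 and p = 1.
    """
    if isinstance(groups, dict):
        samples = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        samples = [np.asarray(v, dtype=float) for v in groups]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    df = len(samples) - 1
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        return {"H": 0.0, "df": df, "p": 1.0}
    H, p = stats.kruskal(*samples)
    return {"H": float(H), "df": df, "p": float(p)}


def mann_whitney(a, b) -> dict:
    """Two-sided Mann-Whitney U-test; U reported as min(U1, U2).

    Exact p by enumeration of rank splits when n1 * n2 <= 400 and there
    are no ties; otherwise the normal approximation with tie and
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(a) * len(b) <= _EXACT_LIMIT) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, len(a) * len(b) - u1)
    return {"U": u, "p": float(res.pvalue), "method": method}


def pairwise_size_tests(sizes, species, alpha: float = 0.05) -> "PairwiseSizeTests":
    """All species-pair Mann-Whitney tests with a Bonferroni threshold."""
    sizes = np.asarray(sizes, dtype=float)
    species = np.asarray(species)
    names = list(dict.fromkeys(species.tolist()))
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for s1, s2 in pairs:
        res = mann_whitney(sizes[species == s1], sizes[species == s2])
        rows.append(
            {"species_1": s1, "species_2": s2, "U": res["U"], "p": res["p"]}
        )
    threshold = alpha / len(pairs)
    frame = pd.DataFrame(rows)
    frame["significant"] = frame["p"] < threshold
    return PairwiseSizeTests(frame=frame, alpha=alpha, bonferroni_alpha=threshold)


@dataclass
class PairwiseSizeTests:
    frame: pd.DataFrame
    alpha: float
    bonferroni_alpha: float


def sexual_size_dimorphism(sizes, sex, species, alpha: float = 0.05) -> pd.DataFrame:
    """Per-species Mann-Whitney test of size between the sexes.

    Two-sided at ``alpha``, uncorrected.  Species with a single sex are
    skipped with a log entry and appear with NaN statistics.
    ``direction`` is the sign of the male - female median difference.
    """
    sizes = np.asarray(sizes, dtype=float)
    sex = np.asarray(sex)
    species = np.asarray(species)
    rows = []
    for name in dict.fromkeys(species.tolist()):
        rows_sp = species == name
        males = sizes[rows_sp & (sex == "male")]
        females = sizes[rows_sp & (sex == "female")]
        if len(males) == 0 or len(females) == 0:
            logger.info(
                "species %r has a single sex in the sample; "
                "size dimorphism test skipped",
                name,
            )
            rows.append(
                {
                    "species": name,
                    "n_males": len(males),
                    "n_females": len(females),
                    "U": np.nan,
                    "p": np.nan,
                    "direction": "skipped",
                    "significant": False,
                }
            )
            continue
        res = mann_whitney(males, females)
        diff = float(np.median(males) - np.median(females))
        direction = (
            "males smaller" if diff < 0 else "males larger" if diff > 0 else "equal"
        )
        rows.append(
            {
                "species": name,
                "n_males": len(males),
                "n_females": len(females),
                "U": res["U"],
                "p": res["p"],
                "direction": direction,
                "significant": res["p"] < alpha,
            }
        )
    return pd.DataFrame(rows)


def boxplot_stats(sizes, groups) -> pd.DataFrame:
    """Boxplot summary per group: median, quartiles, min/max whiskers.

    Quartiles use linear interpolation (type 7).  ``n_outside_box``
    counts points beyond the quartiles, the plotting convention used for
    these size figures.
    """
    sizes = np.asarray(sizes, dtype=float)
    groups = np.asarray(groups)
    rows = []
    for name in dict.fromkeys(groups.tolist()):
        vals = sizes[groups == name]
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "group": name,
                "n": len(vals),
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_low": vals.min(),
                "whisker_high": vals.max(),
                "n_outside_box": int(np.sum((vals < q1) | (vals > q3))),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SizeTestReport:
    """Bundle of every centroid-size comparison for one dataset."""

    kw_H: float
    kw_df: int
    kw_p: float
    pairwise: PairwiseSizeTests
    sex_tests: pd.DataFrame
    boxplots: pd.DataFrame

    @property
    def bonferroni_alpha(self) -> float:
        return self.pairwise.bonferroni_alpha

    def summary(self) -> str:
        n_sig = int(self.pairwise.frame["significant"].sum())
        return (
            "Centroid size comparisons\n"
            f"  Kruskal-Wallis: H = {self.kw_H:.3f}, df = {self.kw_df}, "
            f"P = {self.kw_p:.4g}\n"
            f"  pairwise Mann-Whitney: {n_sig}/{len(self.pairwise.frame)} pairs "
            f"significant at Bonferroni alpha = {self.bonferroni_alpha:.6f}\n"
            f"  sex dimorphism tested in "
            f"{int(self.sex_tests['U'].notna().sum())} species"
        )


def size_test_report(sizes, species, sex=None, alpha: float = 0.05) -> SizeTestReport:
    """Run the full size-comparison battery on one dataset."""
    sizes = np.asarray(sizes, dtype=float)
    species = np.asarray(species)
    groups = {name: sizes[species == name] for name in dict.fromkeys(species.tolist())}
    kw = kruskal_wallis(groups)
    pairwise = pairwise_size_tests(sizes, species, alpha=alpha)
    if sex is not None:
        sex_tests = sexual_size_dimorphism(sizes, sex, species, alpha=alpha)
    else:
        sex_tests = pd.DataFrame(
            columns=["species", "n_males", "n_females", "U", "p", "direction", "significant"]
        )
    return SizeTestReport(
        kw_H=kw["H"],
        kw_df=kw["df"],
        kw_p=kw["p"],
        pairwise=pairwise,
        sex_tests=sex_tests,
        boxplots=boxplot_stats(sizes, species),
    )
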