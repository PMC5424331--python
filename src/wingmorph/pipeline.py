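"""End-to-end wing-morphometry workflow.

Runs the complete analysis chain on a TPS file plus metadata table:
superimposition of all digitization replicates, replicate averaging,
centroid-size statistics, canonical variate discrimination with
permutation tests and cross-validated classification at genus and
species level, per-species sex discrimination, allometric regression
(overall pooled within species, per species, and pooled within sex), an
allometry-free rerun of the discrimination analyses, and a UPGMA
phenogram of the species Mahalanobis distances.  Every output is a CSV,
Newick or JSON file; reruns with the same seed are byte-identical.

Each permutation family draws its seed deterministically from the master
seed and a stable stage identifier, so any stage can be rerun in
isolation and reproduce the full run's numbers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allometry import ShapeAllometry
from .discriminate import (
    CanonicalVariates,
    loo_classify,
    pairwise_distance_tests,
    sex_dfa,
)
from .phenogram import upgma
from .procrustes import average_replicates, gpa
from .sizestats import size_test_report
from .tps import build_dataset, parse_tps, read_metadata

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis"]

_STAGE_IDS = {
    "genus": 1,
    "species": 2,
    "sex": 3,
    "allometry_overall": 4,
    "allometry_species": 5,
    "allometry_sex": 6,
    "allometry_free_species": 7,
    "allometry_free_genus": 8,
    "allometry_free_sex": 9,
}

_FLOAT_FMT = "%.12g"


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run."""

    tps_path: str
    metadata_path: str
    out_dir: str
    rounds: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    apply_scale: bool = False
    log_size: bool = False
    allometry_correction: bool = True
    levels: tuple = ("genus", "species", "sex")
    replicate_regex: str | None = None

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class AnalysisReport:
    """Handle to the written outputs and in-memory results of a run."""

    out_dir: Path
    paths: dict
    results: dict = field(repr=False, default_factory=dict)


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=(_STAGE_IDS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


def _write(frame: pd.DataFrame, path: Path, paths: dict, key: str) -> None:
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    paths[key] = path


def _write_matrix(frame: pd.DataFrame, path: Path, paths: dict, key: str) -> None:
    frame.to_csv(path, index=True, float_format=_FLOAT_FMT)
    paths[key] = path


def _discrimination_stage(
    shapes, meta, level_col, out_dir, prefix, rounds, seed, paths, results, skipped
) -> None:
    labels = meta[level_col].to_numpy()
    counts = pd.Series(labels).value_counts()
    if counts.min() < 2:
        small = counts[counts < 2].index.tolist()
        skipped.append(
            {"stage": prefix, "group": small, "reason": "fewer than 2 specimens"}
        )
        logger.warning("%s: groups %s too small for CVA, stage skipped", prefix, small)
        return
    cva_res = CanonicalVariates(shapes, labels).fit()
    tests = pairwise_distance_tests(shapes, labels, rounds=rounds, seed=seed)
    table = loo_classify(shapes, labels)
    results[f"{prefix}_cva"] = cva_res
    results[f"{prefix}_distances"] = tests
    results[f"{prefix}_classification"] = table
    _write(cva_res.scores_frame(), out_dir / f"cva_scores_{prefix}.csv", paths,
           f"cva_scores_{prefix}")
    axes = pd.DataFrame(
        {
            "axis": [f"CV{i + 1}" for i in range(cva_res.n_axes)],
            "eigenvalue": cva_res.eigenvalues,
            "percent_variance": cva_res.percent_variance,
        }
    )
    _write(axes, out_dir / f"cva_axes_{prefix}.csv", paths, f"cva_axes_{prefix}")
    for which in ("mahalanobis", "procrustes", "p_mahalanobis", "p_procrustes"):
        name = which if which.startswith("p_") else f"distances_{which}"
        name = f"pvalues_{which[2:]}" if which.startswith("p_") else name
        _write_matrix(
            tests.frame(which),
            out_dir / f"{name}_{prefix}.csv",
            paths,
            f"{name}_{prefix}",
        )
    _write(table.frame, out_dir / f"classification_{prefix}.csv", paths,
           f"classification_{prefix}")


def _sex_stage(shapes, meta, out_dir, prefix, rounds, seed, paths, results, skipped):
    rows = []
    species = meta["species"].to_numpy()
    sexes = meta["sex"].to_numpy()
    per_species = {}
    for i, name in enumerate(dict.fromkeys(species.tolist())):
        mask = species == name
        n_m = int(np.sum(sexes[mask] == "male"))
        n_f = int(np.sum(sexes[mask] == "female"))
        if n_m < 2 or n_f < 2:
            skipped.append(
                {
                    "stage": prefix,
                    "group": name,
                    "reason": f"needs both sexes with >= 2 specimens "
                    f"(males={n_m}, females={n_f})",
                }
            )
            logger.info("%s: species %s skipped (males=%d, females=%d)",
                        prefix, name, n_m, n_f)
            rows.append(
                {
                    "species": name, "n_males": n_m, "n_females": n_f,
                    "mahalanobis": np.nan, "p_mahalanobis": np.nan,
                    "procrustes": np.nan, "p_procrustes": np.nan,
                    "percent_correct_males": np.nan,
                    "percent_correct_females": np.nan,
                    "percent_correct": np.nan,
                }
            )
            continue
        res = sex_dfa(
            shapes[mask],
            sexes[mask],
            rounds=rounds,
            seed=seed + i,
        )
        per_species[name] = res
        cls = res.classification.frame.set_index("group")
        rows.append(
            {
                "species": name, "n_males": n_m, "n_females": n_f,
                "mahalanobis": res.mahalanobis, "p_mahalanobis": res.p_value,
                "procrustes": res.procrustes, "p_procrustes": res.p_procrustes,
                "percent_correct_males": cls.loc["male", "percent"],
                "percent_correct_females": cls.loc["female", "percent"],
                "percent_correct": res.classification.overall_percent,
            }
        )
    frame = pd.DataFrame(rows)
    results[prefix] = per_species
    _write(frame, out_dir / f"{prefix}.csv", paths, prefix)
    return frame


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Execute the whole workflow; any stage failure aborts and removes
    the partial outputs, reporting the stage name and cause."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict = {}
    results: dict = {}
    skipped: list = []
    stage = "setup"
    try:
        # ------------------------------------------------------------ input
        stage = "parse"
        records = parse_tps(
            Path(config.tps_path).read_text(), apply_scale=config.apply_scale
        )
        metadata = read_metadata(config.metadata_path)
        table = build_dataset(records, metadata, replicate_regex=config.replicate_regex)

        # ----------------------------------------------------- superimpose
        stage = "gpa"
        aligned_all = gpa(table.coordinate_array(), meta=table.frame)
        averaged = average_replicates(aligned_all)
        results["aligned_replicates"] = aligned_all
        results["aligned"] = averaged
        _write(averaged.to_frame(), out_dir / "aligned.csv", paths, "aligned")

        meta = averaged.meta
        shapes = averaged.shapes
        sizes = averaged.centroid_sizes

        # ------------------------------------------------------- size stats
        stage = "size_stats"
        size_report = size_test_report(
            sizes, meta["species"].to_numpy(), meta["sex"].to_numpy(),
            alpha=config.alpha,
        )
        results["size"] = size_report
        _write(
            pd.DataFrame(
                [
                    {
                        "H": size_report.kw_H,
                        "df": size_report.kw_df,
                        "p": size_report.kw_p,
                        "bonferroni_alpha": size_report.bonferroni_alpha,
                    }
                ]
            ),
            out_dir / "size_kruskal_wallis.csv", paths, "size_kw",
        )
        _write(size_report.pairwise.frame, out_dir / "size_pairwise.csv",
               paths, "size_pairwise")
        _write(size_report.sex_tests, out_dir / "size_sex.csv", paths, "size_sex")
        _write(size_report.boxplots, out_dir / "size_boxplot_stats.csv",
               paths, "size_boxplots")

        # --------------------------------------------- discrimination levels
        for level in ("genus", "species"):
            if level not in config.levels:
                continue
            stage = level
            _discrimination_stage(
                shapes, meta, level, out_dir, level, config.rounds,
                _stage_seed(config.seed, level), paths, results, skipped,
            )

        if "sex" in config.levels:
            stage = "sex"
            _sex_stage(
                shapes, meta, out_dir, "sex_dfa", config.rounds,
                _stage_seed(config.seed, "sex"), paths, results, skipped,
            )

        # -------------------------------------------------------- allometry
        stage = "allometry"
        overall = ShapeAllometry(
            shapes, sizes, pooling=meta["species"].to_numpy(),
            log_size=config.log_size,
        ).fit(rounds=config.rounds, seed=_stage_seed(config.seed, "allometry_overall"))
        overall_raw = ShapeAllometry(shapes, sizes, log_size=config.log_size).fit(
            rounds=config.rounds,
            seed=_stage_seed(config.seed, "allometry_overall"),
        )
        results["allometry_overall"] = overall
        results["allometry_overall_raw"] = overall_raw
        _write(
            pd.DataFrame(
                [
                    {"pooling": "within_species",
                     "percent_predicted": overall.percent_predicted,
                     "p_value": overall.p_value},
                    {"pooling": "none",
                     "percent_predicted": overall_raw.percent_predicted,
                     "p_value": overall_raw.p_value},
                ]
            ),
            out_dir / "allometry_overall.csv", paths, "allometry_overall",
        )

        by_species_rows = []
        by_sex_rows = []
        species_arr = meta["species"].to_numpy()
        sex_arr = meta["sex"].to_numpy()
        for i, name in enumerate(dict.fromkeys(species_arr.tolist())):
            mask = species_arr == name
            if mask.sum() < 3 or np.ptp(sizes[mask]) == 0:
                skipped.append({"stage": "allometry_species", "group": name,
                                "reason": "fewer than 3 specimens"})
                continue
            res = ShapeAllometry(
                shapes[mask], sizes[mask], log_size=config.log_size
            ).fit(rounds=config.rounds,
                  seed=_stage_seed(config.seed, "allometry_species") + i)
            by_species_rows.append(
                {"species": name, "n": int(mask.sum()),
                 "percent_predicted": res.percent_predicted,
                 "p_value": res.p_value}
            )
            n_m = int(np.sum(sex_arr[mask] == "male"))
            n_f = int(np.sum(sex_arr[mask] == "female"))
            if n_m >= 2 and n_f >= 2:
                res_sex = ShapeAllometry(
                    shapes[mask], sizes[mask], pooling=sex_arr[mask],
                    log_size=config.log_size,
                ).fit(rounds=config.rounds,
                      seed=_stage_seed(config.seed, "allometry_sex") + i)
                by_sex_rows.append(
                    {"species": name,
                     "percent_predicted": res_sex.percent_predicted,
                     "p_value": res_sex.p_value}
                )
            else:
                skipped.append({"stage": "allometry_sex", "group": name,
                                "reason": "needs both sexes with >= 2 specimens"})
        _write(pd.DataFrame(by_species_rows), out_dir / "allometry_by_species.csv",
               paths, "allometry_by_species")
        _write(pd.DataFrame(by_sex_rows), out_dir / "allometry_pooled_within_sex.csv",
               paths, "allometry_by_sex")

        # ------------------------------------------- allometry-free reruns
        if config.allometry_correction:
            stage = "allometry_free"
            corrected = overall.allometry_free_shapes()
            results["allometry_free_shapes"] = corrected
            for level in ("genus", "species"):
                if level not in config.levels:
                    continue
                _discrimination_stage(
                    corrected, meta, level, out_dir, f"allometry_free_{level}",
                    config.rounds,
                    _stage_seed(config.seed, f"allometry_free_{level}"),
                    paths, results, skipped,
                )
            if "sex" in config.levels:
                _sex_stage(
                    corrected, meta, out_dir, "allometry_free_sex_dfa",
                    config.rounds,
                    _stage_seed(config.seed, "allometry_free_sex"),
                    paths, results, skipped,
                )

        # ------------------------------------------------------------ UPGMA
        stage = "upgma"
        if "species_distances" in results:
            dist = results["species_distances"].frame("mahalanobis")
            tree = upgma(dist)
            results["upgma"] = tree
            nwk_path = out_dir / "upgma.nwk"
            nwk_path.write_text(tree.newick() + "\n")
            paths["upgma_newick"] = nwk_path
            _write(tree.merge_table(), out_dir / "upgma_merges.csv",
                   paths, "upgma_merges")

        # ---------------------------------------------------------- run log
        stage = "run_log"
        log_path = out_dir / "run_log.json"
        log_path.write_text(
            json.dumps(
                {
                    "wingmorph_version": __version__,
                    "seed": config.seed,
                    "rounds": config.rounds,
                    "alpha": config.alpha,
                    "apply_scale": config.apply_scale,
                    "log_size": config.log_size,
                    "allometry_correction": config.allometry_correction,
                    "levels": list(config.levels),
                    "replicate_regex": config.replicate_regex,
                    "n_configurations": len(aligned_all),
                    "n_specimens": len(averaged),
                    "skipped": skipped,
                },
                indent=2,
            )
            + "\n"
        )
        paths["run_log"] = log_path
    except Exception as exc:
        for p in paths.values():
            Path(p).unlink(missing_ok=True)
        raise RuntimeError(f"analysis failed at stage {stage!r}: {exc}") from exc

    return AnalysisReport(out_dir=out_dir, paths=paths, results=results)
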