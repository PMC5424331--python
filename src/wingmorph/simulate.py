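"""Synthetic multi-species wing-landmark datasets.

Generates TPS + metadata datasets with the statistical structure the
analysis chain assumes: per-species mean-shape offsets (with a shared
genus-level component, so congeneric species cluster), isotropic
within-species shape variation, log-normal centroid sizes, a linear
allometric size-shape association, sex-linked size and shape effects, and
independent per-replicate digitization error.  Every generating parameter
is recorded per specimen in the ground truth, and runs are fully
deterministic for a given seed.

Perturbations are applied in the tangent space of the template (small-
deformation assumption: tangent vectors are added directly to the unit-
size template coordinates) and drawn orthogonal to the similarity
nuisance directions — translations, rotation and scaling of the template
— so their norms survive Procrustes superimposition essentially
unchanged.  Digitization error, by contrast, is raw landmark noise in
image units added after each specimen is placed at its random position,
orientation and size, exactly where a digitizer's pointing error enters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .procrustes import centroid_size
from .tps import TPSRecord, write_tps

__all__ = [
    "SpeciesSpec",
    "SimulationSpec",
    "SyntheticDataset",
    "default_template",
    "generate_dataset",
    "blowfly_study",
    "allometry_magnitude_for_fraction",
]

# A fixed 19-landmark wing-like planar configuration: vein junctions and
# margin points of an elongated right wing, in arbitrary units.  The exact
# geometry is unimportant; it is deterministic, non-degenerate and roughly
# wing-proportioned (span ~2.4 x chord).
_TEMPLATE_19 = np.array(
    [
        [0.00, 0.42],
        [0.18, 0.66],
        [0.45, 0.80],
        [0.80, 0.88],
        [1.20, 0.90],
        [1.62, 0.84],
        [2.00, 0.70],
        [2.30, 0.48],
        [2.40, 0.20],
        [2.18, 0.02],
        [1.85, -0.06],
        [1.45, -0.10],
        [1.05, -0.08],
        [0.68, -0.02],
        [0.38, 0.08],
        [0.95, 0.35],
        [1.40, 0.42],
        [1.80, 0.35],
        [0.55, 0.40],
    ]
)


def default_template() -> np.ndarray:
    """The packaged 19-point wing-like template (copy)."""
    return _TEMPLATE_19.copy()


@dataclass
class SpeciesSpec:
    """Generating parameters for one species.

    ``shape_offset`` is the tangent-space norm of the species mean-shape
    displacement (on top of a shared genus displacement); ``shape_sd`` the
    per-coordinate within-species tangent sd; sizes are log-normal in the
    template's units; ``allometry`` the tangent-space shape change per
    unit centroid size; males are shifted by a frozen sex shape vector of
    norm ``sex_shape_offset`` and their sizes multiplied by
    ``sex_size_ratio``.
    """

    name: str
    genus: str
    n_males: int
    n_females: int
    shape_offset: float = 0.02
    shape_sd: float = 0.004
    size_log_mean: float = math.log(6.0)
    size_log_sd: float = 0.07
    allometry: float = 0.03
    sex_shape_offset: float = 0.008
    sex_size_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.n_males < 0 or self.n_females < 0 or self.n_males + self.n_females < 1:
            raise ValueError("species needs at least one specimen")
        for attr in ("shape_offset", "shape_sd", "allometry", "sex_shape_offset"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")

    @property
    def n(self) -> int:
        return self.n_males + self.n_females


@dataclass
class SimulationSpec:
    """Full parameterization of a synthetic wing-population dataset."""

    species: list
    k: int = 19
    template: np.ndarray | None = None
    genus_shape_offset: float = 0.035
    # allometric component shared by all species around the study-wide
    # reference size; a nonzero value makes species with different size
    # distributions differ in mean shape through allometry alone
    common_allometry: float = 0.0
    digitization_sd: float = 0.01
    replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("need at least one species")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.digitization_sd < 0 or self.genus_shape_offset < 0 \
                or self.common_allometry < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.template is None:
            if self.k == 19:
                self.template = default_template()
            else:
                raise ValueError("a template is required when k != 19")
        self.template = np.asarray(self.template, dtype=float)
        if self.template.shape != (self.k, 2):
            raise ValueError(f"template must be ({self.k}, 2)")
        centroid_size(self.template)  # raises if degenerate

    @property
    def n_specimens(self) -> int:
        return sum(s.n for s in self.species)


@dataclass
class SyntheticDataset:
    """Generated TPS text, metadata table and per-specimen ground truth."""

    tps: str
    metadata: pd.DataFrame
    ground_truth: dict
    spec: SimulationSpec = field(repr=False, default=None)


def _unit_template(template: np.ndarray) -> np.ndarray:
    centred = template - template.mean(axis=0)
    return centred / centroid_size(centred)


def _nuisance_basis(unit_template: np.ndarray) -> np.ndarray:
    """Orthonormal basis (2k, 4) of the similarity directions at the template."""
    k = unit_template.shape[0]
    tx = np.zeros(2 * k)
    ty = np.zeros(2 * k)
    tx[0::2] = 1.0
    ty[1::2] = 1.0
    scale = unit_template.reshape(-1).copy()
    rot = np.stack([-unit_template[:, 1], unit_template[:, 0]], axis=1).reshape(-1)
    basis = np.stack([tx, ty, scale, rot], axis=1)
    return basis / np.linalg.norm(basis, axis=0)


def _tangent_direction(rng: np.random.Generator, nuisance: np.ndarray) -> np.ndarray:
    """Random unit tangent direction orthogonal to the nuisance space."""
    v = rng.standard_normal(nuisance.shape[0])
    v = v - nuisance @ (nuisance.T @ v)
    return v / np.linalg.norm(v)


def allometry_magnitude_for_fraction(
    fraction: float,
    shape_sd: float,
    k: int = 19,
    size_log_mean: float = math.log(6.0),
    size_log_sd: float = 0.07,
) -> float:
    """Allometric vector norm making size explain a target variance share.

    With an allometric shape component a * (s - s0) of norm ||a|| per unit
    size and isotropic tangent noise of per-coordinate sd sigma_w (of
    which 2k - 4 dimensions survive superimposition), the expected
    size-predicted fraction of shape variance is
    f = ||a||^2 var(s) / (||a||^2 var(s) + (2k - 4) sigma_w^2);
    this solves for ||a||.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    noise_var = (2 * k - 4) * shape_sd**2
    mean_size = math.exp(size_log_mean + size_log_sd**2 / 2)
    sd_size = mean_size * math.sqrt(math.expm1(size_log_sd**2))
    return math.sqrt(fraction / (1.0 - fraction) * noise_var) / sd_size


def generate_dataset(spec: SimulationSpec) -> SyntheticDataset:
    """Generate the TPS stream, metadata table and ground truth.

    Per specimen: tangent shape = unit template + genus offset + species
    offset (+ sex vector for males) + a * (size - reference size) +
    N(0, shape_sd) tangent noise, scaled to the specimen's drawn centroid
    size and placed at a random rotation and translation; each replicate
    then receives independent N(0, digitization_sd) landmark noise.
    """
    root = np.random.SeedSequence(entropy=spec.seed)
    child_dir, child_spec = root.spawn(2)
    dir_rng = np.random.default_rng(child_dir)
    spec_rng = np.random.default_rng(child_spec)

    unit = _unit_template(spec.template)
    nuisance = _nuisance_basis(unit)
    flat_unit = unit.reshape(-1)

    genus_names = list(dict.fromkeys(s.genus for s in spec.species))
    genus_vectors = {
        g: spec.genus_shape_offset * _tangent_direction(dir_rng, nuisance)
        for g in genus_names
    }
    common_allometry_vector = spec.common_allometry * _tangent_direction(
        dir_rng, nuisance
    )
    common_ref_size = float(
        np.mean([math.exp(s.size_log_mean + s.size_log_sd**2 / 2)
                 for s in spec.species])
    )
    species_vectors = {}
    allometry_vectors = {}
    sex_vectors = {}
    for sp in spec.species:
        species_vectors[sp.name] = sp.shape_offset * _tangent_direction(dir_rng, nuisance)
        allometry_vectors[sp.name] = sp.allometry * _tangent_direction(dir_rng, nuisance)
        sex_vectors[sp.name] = sp.sex_shape_offset * _tangent_direction(dir_rng, nuisance)

    records: list[TPSRecord] = []
    meta_rows = []
    truth_specimens = []
    for sp in spec.species:
        ref_size = math.exp(sp.size_log_mean + sp.size_log_sd**2 / 2)
        sexes = ["male"] * sp.n_males + ["female"] * sp.n_females
        for i, sex in enumerate(sexes):
            sid = f"{sp.name}_{i + 1:03d}"
            size = float(spec_rng.lognormal(sp.size_log_mean, sp.size_log_sd))
            if sex == "male":
                size *= sp.sex_size_ratio
            tangent = (
                flat_unit
                + genus_vectors[sp.genus]
                + species_vectors[sp.name]
                + allometry_vectors[sp.name] * (size - ref_size)
                + common_allometry_vector * (size - common_ref_size)
                + sp.shape_sd * spec_rng.standard_normal(2 * spec.k)
            )
            if sex == "male":
                tangent = tangent + sex_vectors[sp.name]
            config = tangent.reshape(spec.k, 2)
            config = config - config.mean(axis=0)
            config = config / centroid_size(config) * size
            theta = spec_rng.uniform(0.0, 2.0 * np.pi)
            R = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            shift = spec_rng.uniform(2.0, 6.0, size=2) * size
            placed = config @ R.T + shift
            for r in range(spec.replicates):
                noisy = placed + spec.digitization_sd * spec_rng.standard_normal(
                    (spec.k, 2)
                )
                records.append(
                    TPSRecord(
                        landmark_count=spec.k,
                        coordinates=noisy,
                        image_name=f"{sid}_r{r + 1}.png",
                        specimen_id=sid,
                    )
                )
            meta_rows.append(
                {
                    "specimen_id": sid,
                    "genus": sp.genus,
                    "species": sp.name,
                    "sex": sex,
                    "site": "synthetic",
                }
            )
            truth_specimens.append(
                {"specimen_id": sid, "species": sp.name, "sex": sex, "size": size}
            )

    truth = {
        "seed": spec.seed,
        "k": spec.k,
        "replicates": spec.replicates,
        "digitization_sd": spec.digitization_sd,
        "genus_vectors": {g: v.tolist() for g, v in genus_vectors.items()},
        "common_allometry_vector": common_allometry_vector.tolist(),
        "common_reference_size": common_ref_size,
        "species_vectors": {s: v.tolist() for s, v in species_vectors.items()},
        "allometry_vectors": {s: v.tolist() for s, v in allometry_vectors.items()},
        "sex_vectors": {s: v.tolist() for s, v in sex_vectors.items()},
        "species_params": {
            sp.name: {
                "genus": sp.genus,
                "n_males": sp.n_males,
                "n_females": sp.n_females,
                "shape_offset": sp.shape_offset,
                "shape_sd": sp.shape_sd,
                "size_log_mean": sp.size_log_mean,
                "size_log_sd": sp.size_log_sd,
                "allometry": sp.allometry,
                "sex_shape_offset": sp.sex_shape_offset,
                "sex_size_ratio": sp.sex_size_ratio,
            }
            for sp in spec.species
        },
        "specimens": truth_specimens,
    }
    return SyntheticDataset(
        tps=write_tps(records),
        metadata=pd.DataFrame(meta_rows),
        ground_truth=truth,
        spec=spec,
    )


# Sampling design emulating a 12-species blow-fly survey: three genera in
# two subfamilies, strongly unbalanced sample sizes including a tiny
# all-female species, two smaller-bodied species, and male-smaller size
# dimorphism in four species.
_BLOWFLY_DESIGN = [
    # (species code, genus, males, females, size_log_mean, sex_size_ratio)
    ("CM", "Chrysomya", 24, 29, math.log(6.3), 1.00),
    ("CC", "Chrysomya", 17, 23, math.log(6.1), 1.00),
    ("CP", "Chrysomya", 29, 10, math.log(6.2), 1.00),
    ("CR", "Chrysomya", 25, 22, math.log(6.0), 0.95),
    ("CV", "Chrysomya", 23, 16, math.log(6.2), 1.00),
    ("CN", "Chrysomya", 17, 15, math.log(4.6), 1.00),
    ("LC", "Lucilia", 15, 14, math.log(4.4), 0.95),
    ("LPA", "Lucilia", 9, 23, math.log(5.6), 1.00),
    ("LPO", "Lucilia", 11, 7, math.log(5.7), 1.00),
    ("LS", "Lucilia", 4, 4, math.log(5.5), 0.95),
    ("HL", "Hemipyrellia", 14, 18, math.log(5.8), 0.95),
    ("HP", "Hemipyrellia", 0, 3, math.log(5.8), 1.00),
]


def blowfly_study(seed: int = 0, **overrides) -> SimulationSpec:
    """The default 12-species, 372-specimen study design.

    Mirrors the sampling structure of a multi-site blow-fly survey: three
    genera (Chrysomya, Lucilia, Hemipyrellia), per-species male/female
    counts summing to 372, two digitization replicates per specimen, two
    conspicuously smaller species (CN, LC), a three-female-only species
    (HP), and males ~5% smaller in four species.  Keyword overrides are
    applied to every SpeciesSpec (e.g. ``shape_sd=0.003``).
    """
    species = [
        SpeciesSpec(
            name=code,
            genus=genus,
            n_males=m,
            n_females=f,
            size_log_mean=mu,
            sex_size_ratio=ratio,
            **overrides,
        )
        for code, genus, m, f, mu, ratio in _BLOWFLY_DESIGN
    ]
    return SimulationSpec(species=species, seed=seed)
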