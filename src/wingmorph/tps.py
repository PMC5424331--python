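"""Reading and writing TPS landmark files and specimen metadata.

The TPS format is the plain-text interchange dialect of the tps software
family (tpsUtil/tpsDig): each record starts with ``LM=<k>``, followed by
``k`` lines of two whitespace-separated coordinates, then optional
``IMAGE=``, ``ID=``, ``SCALE=`` and ``COMMENT=`` key lines.  Unknown
``KEY=`` lines are tolerated with a logged warning, since tpsUtil emits
several optional keys.

Coordinates are used exactly as stored.  tpsDig's bottom-left image origin
does not affect any downstream statistic because only the relative landmark
configuration matters and all wings come from the same body side.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TPSRecord",
    "TPSParseError",
    "LandmarkConfiguration",
    "SpecimenTable",
    "parse_tps",
    "write_tps",
    "read_metadata",
    "build_dataset",
]

_KNOWN_KEYS = {"IMAGE", "ID", "SCALE", "COMMENT"}
_SEXES = {"male", "female", "unknown"}


class TPSParseError(ValueError):
    """Raised when a TPS stream violates the dialect."""


@dataclass
class TPSRecord:
    """One digitized specimen: ``k`` landmarks plus identifying keys.

    ``scale``, when present, is the image scale factor (units per pixel)
    recorded by tpsDig; whether it is applied is a parsing option.
    """

    landmark_count: int
    coordinates: np.ndarray  # (k, 2)
    image_name: str | None = None
    specimen_id: str | None = None
    scale: float | None = None
    comment: str | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (self.landmark_count, 2):
            raise ValueError(
                f"landmark_count={self.landmark_count} does not match "
                f"coordinate array of shape {self.coordinates.shape}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.scale is not None and not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")


@dataclass
class LandmarkConfiguration:
    """A single digitization replicate with its grouping metadata."""

    specimen_id: str
    replicate_index: int
    matrix: np.ndarray  # (k, 2)
    genus: str
    species: str
    sex: str = "unknown"
    site: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 2:
            raise ValueError("matrix must be k x 2")
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")


@dataclass
class SpecimenTable:
    """Replicate-aware landmark dataset: one row per digitization.

    ``frame`` carries one metadata row per configuration, aligned with
    ``configurations``; ``coordinate_array()`` stacks the raw landmark
    matrices for Procrustes superimposition.
    """

    configurations: list[LandmarkConfiguration]
    k: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.configurations:
            raise ValueError("dataset is empty")
        ks = {c.matrix.shape[0] for c in self.configurations}
        if len(ks) != 1:
            raise ValueError(f"inconsistent landmark counts across dataset: {sorted(ks)}")
        self.k = ks.pop()
        seen = set()
        for c in self.configurations:
            key = (c.specimen_id, c.replicate_index)
            if key in seen:
                raise ValueError(f"duplicated (specimen_id, replicate): {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "specimen_id": [c.specimen_id for c in self.configurations],
                "replicate": [c.replicate_index for c in self.configurations],
                "genus": [c.genus for c in self.configurations],
                "species": [c.species for c in self.configurations],
                "sex": [c.sex for c in self.configurations],
                "site": [c.site for c in self.configurations],
            }
        )

    def coordinate_array(self) -> np.ndarray:
        return np.stack([c.matrix for c in self.configurations])

    @property
    def specimen_ids(self) -> list[str]:
        """Distinct specimen ids in order of first appearance."""
        out: list[str] = []
        seen: set[str] = set()
        for c in self.configurations:
            if c.specimen_id not in seen:
                seen.add(c.specimen_id)
                out.append(c.specimen_id)
        return out

    def replicate_counts(self) -> pd.Series:
        return self.frame.groupby("specimen_id", sort=False)["replicate"].count()


def parse_tps(stream: str, apply_scale: bool = False) -> list[TPSRecord]:
    """Parse a TPS stream into records, in file order.

    Parameters
    ----------
    stream:
        Full text of a TPS file.
    apply_scale:
        If true, multiply each record's coordinates by its ``SCALE=``
        factor (when present).  Off by default: every statistic downstream
        of the Procrustes fit is scale-invariant, but raw centroid sizes
        are only comparable across images under a consistent choice.
    """
    lines = stream.splitlines()
    records: list[TPSRecord] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = re.match(r"LM\s*=\s*(\d+)\s*$", line, flags=re.IGNORECASE)
        if m is None:
            raise TPSParseError(
                f"line {i + 1}: expected 'LM=<k>' at start of record "
                f"{len(records) + 1}, got {line!r}"
            )
        k = int(m.group(1))
        i += 1
        coords = np.empty((k, 2), dtype=float)
        for j in range(k):
            while i < n_lines and not lines[i].strip():
                i += 1
            if i >= n_lines or "=" in lines[i]:
                raise TPSParseError(
                    f"record {len(records) + 1}: LM={k} but only {j} "
                    f"coordinate rows found"
                )
            parts = lines[i].split()
            if len(parts) != 2:
                raise TPSParseError(
                    f"line {i + 1}: expected two coordinates, got {lines[i]!r}"
                )
            try:
                coords[j] = [float(parts[0]), float(parts[1])]
            except ValueError as exc:
                raise TPSParseError(
                    f"line {i + 1}: non-numeric coordinate in {lines[i]!r}"
                ) from exc
            i += 1
        image = spec_id = comment = None
        scale = None
        while i < n_lines:
            kv = lines[i].strip()
            if not kv:
                i += 1
                continue
            m = re.match(r"([A-Za-z]+)\s*=\s*(.*)$", kv)
            if m is None or m.group(1).upper() == "LM":
                break
            key, value = m.group(1).upper(), m.group(2).strip()
            if key == "IMAGE":
                image = value
            elif key == "ID":
                spec_id = value
            elif key == "COMMENT":
                comment = value
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError as exc:
                    raise TPSParseError(
                        f"line {i + 1}: non-numeric SCALE {value!r}"
                    ) from exc
            else:
                logger.warning("ignoring unknown TPS key %r at line %d", key, i + 1)
            i += 1
        if apply_scale and scale is not None:
            coords = coords * scale
        records.append(
            TPSRecord(
                landmark_count=k,
                coordinates=coords,
                image_name=image,
                specimen_id=spec_id,
                scale=scale,
                comment=comment,
            )
        )
    return records


def write_tps(records: Sequence[TPSRecord]) -> str:
    """Serialize records to TPS text; round-trips coordinates exactly."""
    chunks: list[str] = []
    for rec in records:
        lines = [f"LM={rec.landmark_count}"]
        for x, y in rec.coordinates:
            lines.append(f"{x:.17g} {y:.17g}")
        if rec.image_name is not None:
            lines.append(f"IMAGE={rec.image_name}")
        if rec.specimen_id is not None:
            lines.append(f"ID={rec.specimen_id}")
        if rec.comment is not None:
            lines.append(f"COMMENT={rec.comment}")
        if rec.scale is not None:
            lines.append(f"SCALE={rec.scale:.17g}")
        chunks.append("\n".join(lines))
    return "\n".join(chunks) + ("\n" if chunks else "")


def read_metadata(source) -> pd.DataFrame:
    """Read the specimen metadata CSV.

    Expected header: ``specimen_id,genus,species,sex,site``.  Sex values
    are lower-cased; anything outside male/female maps to ``unknown``.
    """
    meta = pd.read_csv(source, dtype=str)
    required = {"specimen_id", "genus", "species", "sex"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    if "site" not in meta.columns:
        meta["site"] = None
    meta["sex"] = (
        meta["sex"].fillna("unknown").str.lower().where(
            meta["sex"].fillna("unknown").str.lower().isin(_SEXES), "unknown"
        )
    )
    if meta["specimen_id"].duplicated().any():
        dupes = meta.loc[meta["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ValueError(f"duplicated specimen_id rows in metadata: {dupes}")
    return meta


def build_dataset(
    records: Iterable[TPSRecord],
    metadata: pd.DataFrame,
    replicate_regex: str | None = None,
) -> SpecimenTable:
    """Join TPS records with metadata into a replicate-aware dataset.

    Replicates are identified by the same ``ID=`` appearing repeatedly
    (the default), or by stripping a trailing suffix matched by
    ``replicate_regex`` (e.g. ``_r(\\d+)$``) from each record id.
    Replicate indices are assigned by order of appearance per specimen.
    """
    meta = metadata.set_index("specimen_id")
    configs: list[LandmarkConfiguration] = []
    counts: dict[str, int] = {}
    orphans: list[str] = []
    pattern = re.compile(replicate_regex) if replicate_regex else None
    for idx, rec in enumerate(records):
        rid = rec.specimen_id
        if rid is None:
            raise ValueError(f"record {idx + 1} has no ID= line")
        if pattern is not None:
            rid = pattern.sub("", rid)
        if rid not in meta.index:
            orphans.append(rid)
            continue
        row = meta.loc[rid]
        counts[rid] = counts.get(rid, 0) + 1
        configs.append(
            LandmarkConfiguration(
                specimen_id=rid,
                replicate_index=counts[rid],
                matrix=rec.coordinates,
                genus=row["genus"],
                species=row["species"],
                sex=row["sex"],
                site=None if pd.isna(row["site"]) else row["site"],
            )
        )
    if orphans:
        raise ValueError(
            f"{len(orphans)} record(s) without a metadata row: {sorted(set(orphans))}"
        )
    unused = sorted(set(meta.index) - set(counts))
    if unused:
        logger.warning(
            "%d metadata row(s) have no TPS record and were dropped: %s",
            len(unused),
            unused,
        )
    return SpecimenTable(configs)
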