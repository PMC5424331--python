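"""Generalized Procrustes analysis for 2-D landmark configurations.

Superimposition removes the similarity nuisance parameters — translation,
isotropic scale and rotation — leaving pure shape variation around a
consensus.  The fit is the *full* Procrustes fit: every configuration is
centred, scaled to unit centroid size, and rotated (proper rotations only;
all wings are the same side, so a reflection would signal a digitization
error rather than shape variation) to minimise its summed squared distance
to the consensus, which is re-estimated until convergence.  Aligned
configurations are finally projected orthogonally onto the tangent space
at the consensus, the linear space in which all multivariate statistics
downstream are computed.  For k 2-D landmarks that space has dimension at
most 2k - 4.

In two dimensions the optimal rotation has a closed form: writing each
centred configuration as a complex k-vector, the rotation aligning z onto
w is the phase of <z, w> = sum(conj(z_j) w_j).  This is exactly the
det(+1) solution of the singular-value construction, specialised to 2-D.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedDataset",
    "centroid_size",
    "gpa",
    "procrustes_distance",
    "average_replicates",
]


def centroid_size(config: np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid.

    The standard size measure of geometric morphometrics; invariant under
    translation and rotation, linear under isotropic scaling.
    """
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[1] != 2 or config.shape[0] < 3:
        raise ValueError("config must be k x 2 with k >= 3")
    if not np.all(np.isfinite(config)):
        raise ValueError("coordinates must be finite")
    centred = config - config.mean(axis=0)
    cs = float(np.sqrt(np.sum(centred**2)))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return cs


def _to_complex(configs: np.ndarray) -> np.ndarray:
    return configs[..., 0] + 1j * configs[..., 1]


def _from_complex(z: np.ndarray) -> np.ndarray:
    return np.stack([z.real, z.imag], axis=-1)


@dataclass
class AlignedDataset:
    """Procrustes-superimposed dataset in tangent-space coordinates.

    ``shapes`` holds one row per configuration, flattened as
    ``(x1, y1, ..., xk, yk)``; each row is the tangent-space projection of
    the aligned unit-size configuration, anchored so the consensus itself
    maps to its own coordinates.  ``centroid_sizes`` are the sizes removed
    during superimposition.
    """

    shapes: np.ndarray  # (n, 2k)
    centroid_sizes: np.ndarray  # (n,)
    consensus: np.ndarray  # (k, 2), unit centroid size
    meta: pd.DataFrame  # one row per shape row
    k: int
    # summed squared distance to the consensus after each GPA iteration
    objective_history: list | None = None

    def __post_init__(self) -> None:
        self.shapes = np.asarray(self.shapes, dtype=float)
        self.centroid_sizes = np.asarray(self.centroid_sizes, dtype=float)
        if self.shapes.shape != (len(self.centroid_sizes), 2 * self.k):
            raise ValueError("shapes, centroid_sizes and k are inconsistent")
        if len(self.meta) != len(self.centroid_sizes):
            raise ValueError("meta must have one row per configuration")

    def __len__(self) -> int:
        return self.shapes.shape[0]

    def configurations(self) -> np.ndarray:
        """Aligned coordinates as an (n, k, 2) stack."""
        return self.shapes.reshape(len(self), self.k, 2)

    def subset(self, mask) -> "AlignedDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return replace(
            self,
            shapes=self.shapes[idx],
            centroid_sizes=self.centroid_sizes[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
        )

    def with_shapes(self, shapes: np.ndarray) -> "AlignedDataset":
        """Same specimens and metadata, replaced shape coordinates."""
        return replace(self, shapes=np.asarray(shapes, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{axis}{i + 1}" for i in range(self.k) for axis in ("x", "y")]
        out = pd.DataFrame(self.shapes, columns=cols)
        out.insert(0, "cs", self.centroid_sizes)
        out.insert(0, "specimen_id", self.meta["specimen_id"].to_numpy())
        return out


def gpa(
    configs: np.ndarray,
    meta: pd.DataFrame | None = None,
    tol: float = 1e-10,
    max_iter: int = 1000,
    tangent: bool = True,
) -> AlignedDataset:
    """Generalized Procrustes superimposition of an (n, k, 2) stack.

    Iteratively centres, scales to unit centroid size and rotates each
    configuration onto the running consensus, re-estimating the consensus
    (renormalised to unit size) until its maximum coordinate change falls
    below ``tol``.  The converged solution is rotated to a canonical
    orientation (landmark 1 of the consensus on the +x half-axis) so the
    output is invariant, not merely equivariant, under common similarity
    transforms of the inputs.  ``tangent=False`` skips the final
    orthogonal tangent-space projection (diagnostics only).
    """
    configs = np.asarray(configs, dtype=float)
    if configs.ndim != 3 or configs.shape[2] != 2:
        raise ValueError("configs must be (n, k, 2)")
    n, k, _ = configs.shape
    if n < 2:
        raise ValueError("GPA requires at least 2 configurations")
    sizes = np.array([centroid_size(c) for c in configs])

    z = _to_complex(configs)  # (n, k)
    z = z - z.mean(axis=1, keepdims=True)
    z = z / np.linalg.norm(z, axis=1, keepdims=True)

    consensus = z[0].copy()
    history: list[float] = []
    for iteration in range(max_iter):
        inner = (np.conj(z) * consensus).sum(axis=1)  # (n,)
        phases = inner / np.abs(inner)
        z = z * phases[:, None]
        new_consensus = z.mean(axis=0)
        new_consensus = new_consensus - new_consensus.mean()
        new_consensus = new_consensus / np.linalg.norm(new_consensus)
        # re-anchor to the previous orientation: the consensus is defined
        # only up to rotation, and without this the iterates can drift
        # along that symmetry without ever satisfying the tolerance
        anchor = (np.conj(new_consensus) * consensus).sum()
        new_consensus = new_consensus * (anchor / np.abs(anchor))
        history.append(float(np.sum(np.abs(z - new_consensus) ** 2)))
        delta = np.max(np.abs(new_consensus - consensus))
        consensus = new_consensus
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations (last change {delta:.3e})"
        )

    # canonical orientation: consensus landmark 1 on the +x half-axis
    ref = consensus[0]
    if np.abs(ref) > 0:
        spin = np.conj(ref) / np.abs(ref)
        consensus = consensus * spin
        z = z * spin
        inner = (np.conj(z) * consensus).sum(axis=1)
        z = z * (inner / np.abs(inner))[:, None]

    flat = _from_complex(z).reshape(n, 2 * k)
    c = _from_complex(consensus).reshape(2 * k)
    if tangent:
        # project each row so its component along the consensus direction
        # is exactly 1; rows then live in the tangent plane at c
        flat = flat - np.outer(flat @ c - 1.0, c)

    if meta is None:
        meta = pd.DataFrame({"specimen_id": [f"s{i + 1}" for i in range(n)]})
    else:
        meta = meta.reset_index(drop=True)
    return AlignedDataset(
        shapes=flat,
        centroid_sizes=sizes,
        consensus=_from_complex(consensus),
        meta=meta,
        k=k,
        objective_history=history,
    )


def procrustes_distance(shape_a: np.ndarray, shape_b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations.

    Both shapes are centred and scaled to unit centroid size, then b is
    rotated (no reflection) to minimise the summed squared coordinate
    differences; the distance is the root of that minimum.  Symmetric,
    zero iff the shapes are similar without reflection.
    """
    a = np.asarray(shape_a, dtype=float)
    b = np.asarray(shape_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"landmark counts differ: {a.shape} vs {b.shape}")
    za = _to_complex(a.reshape(-1, 2))
    zb = _to_complex(b.reshape(-1, 2))
    za = za - za.mean()
    zb = zb - zb.mean()
    za = za / np.linalg.norm(za)
    zb = zb / np.linalg.norm(zb)
    cross = np.abs(np.vdot(za, zb))
    return float(np.sqrt(max(0.0, 2.0 - 2.0 * cross)))


def average_replicates(aligned: AlignedDataset) -> AlignedDataset:
    """Average replicate digitizations into one row per specimen.

    The arithmetic mean of each specimen's tangent coordinates and of its
    centroid sizes, taken after joint superimposition of all replicates;
    the standard measurement-error reduction.  Specimens with a single
    replicate pass through unchanged.
    """
    ids = aligned.meta["specimen_id"].to_numpy()
    order: list[str] = []
    seen: set[str] = set()
    for sid in ids:
        if sid not in seen:
            seen.add(sid)
            order.append(sid)
    rows = []
    sizes = []
    meta_rows = []
    for sid in order:
        idx = np.flatnonzero(ids == sid)
        rows.append(aligned.shapes[idx].mean(axis=0))
        sizes.append(aligned.centroid_sizes[idx].mean())
        row = aligned.meta.iloc[idx[0]].copy()
        if "replicate" in row.index:
            row["replicate"] = 1
        meta_rows.append(row)
    return AlignedDataset(
        shapes=np.array(rows),
        centroid_sizes=np.array(sizes),
        consensus=aligned.consensus,
        meta=pd.DataFrame(meta_rows).reset_index(drop=True),
        k=aligned.k,
    )
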