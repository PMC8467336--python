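"""Inter-residue C-alpha distance features and a recorded PCA transform.

Trajectories are featurized as Euclidean distances between C-alpha pairs and
reduced with principal component analysis.  The fitted transform (mean vector
and orthonormal component matrix) is serializable and reusable so that
additional ensembles — e.g. mutants — can be projected into the same reduced
space without refitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trajectory_io import Topology, Trajectory

__all__ = [
    "FeatureSpec",
    "FeatureMatrix",
    "PCATransform",
    "ProjectedTrajectory",
    "default_pairs",
    "compute_distance_features",
    "concat_features",
    "fit_pca",
    "apply_pca",
]


@dataclass(frozen=True)
class FeatureSpec:
    """Residue index pairs (topology positions, i < j) and an optional frame
    stride."""

    pairs: tuple[tuple[int, int], ...]
    stride: int = 1

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        seen = set()
        for i, j in self.pairs:
            if i >= j:
                raise ValueError(f"pair ({i}, {j}) must satisfy i < j")
            if (i, j) in seen:
                raise ValueError(f"duplicate pair ({i}, {j})")
            seen.add((i, j))
        if not self.pairs:
            raise ValueError("need at least one residue pair")

    @property
    def n_features(self) -> int:
        return len(self.pairs)


@dataclass
class FeatureMatrix:
    """Frames x features distance values (Angstrom) with per-frame provenance
    (trajectory id, frame index, ensemble label)."""

    values: np.ndarray
    provenance: pd.DataFrame
    spec: FeatureSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.provenance) != self.values.shape[0]:
            raise ValueError("provenance length must equal frame count")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("distances must be finite and non-negative")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def default_pairs(topology: Topology, min_separation: int = 3,
                  max_pairs: int = 20000) -> FeatureSpec:
    """All C-alpha pairs with ``|i - j| >= min_separation`` (positions over the
    whole topology); if more than ``max_pairs``, a deterministic fixed-stride
    subsample of the sorted pair list is kept."""
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    n = topology.n_residues
    pairs = [(i, j) for i in range(n) for j in range(i + min_separation, n)]
    if len(pairs) > max_pairs:
        stride = -(-len(pairs) // max_pairs)  # ceil
        pairs = pairs[::stride][:max_pairs]
    return FeatureSpec(pairs=tuple(pairs))


def compute_distance_features(traj: Trajectory, spec: FeatureSpec) -> FeatureMatrix:
    """Entry (t, k) = distance between the C-alphas of pair k at frame t."""
    n = traj.topology.n_residues
    for i, j in spec.pairs:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"pair ({i}, {j}) outside the {n}-residue topology")
    ca = traj.calpha_xyz()[:: spec.stride]
    ii = np.fromiter((p[0] for p in spec.pairs), dtype=np.intp)
    jj = np.fromiter((p[1] for p in spec.pairs), dtype=np.intp)
    diff = ca[:, ii, :] - ca[:, jj, :]
    values = np.sqrt((diff * diff).sum(axis=2))
    frames = np.arange(traj.n_frames)[:: spec.stride]
    prov = pd.DataFrame(
        {
            "trajectory": traj.source or "trajectory",
            "frame": frames,
            "ensemble_label": traj.ensemble_label,
        }
    )
    return FeatureMatrix(values=values, provenance=prov, spec=spec)


def concat_features(blocks: Iterable[FeatureMatrix]) -> FeatureMatrix:
    blocks = list(blocks)
    if not blocks:
        raise ValueError("nothing to concatenate")
    spec = blocks[0].spec
    if any(b.spec.pairs != spec.pairs for b in blocks):
        raise ValueError("all feature blocks must share one FeatureSpec")
    return FeatureMatrix(
        values=np.concatenate([b.values for b in blocks], axis=0),
        provenance=pd.concat([b.provenance for b in blocks], ignore_index=True),
        spec=spec,
    )


@dataclass
class PCATransform:
    """Recorded PCA transform: feature mean, orthonormal components
    (features x n_components), explained variance per component."""

    mean: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray
    total_variance: float
    fitted_on: str = ""

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.components = np.asarray(self.components, dtype=np.float64)
        self.explained_variance = np.asarray(self.explained_variance, dtype=np.float64)
        gram = self.components.T @ self.components
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-8):
            raise ValueError("component columns must be orthonormal")
        if (np.diff(self.explained_variance) > 1e-10).any():
            raise ValueError("explained variance must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    @property
    def n_features(self) -> int:
        return self.components.shape[0]

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "msmnet-pca",
            "version": 1,
            "fitted_on": self.fitted_on,
            "total_variance": self.total_variance,
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "PCATransform":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "msmnet-pca":
            raise ValueError(f"{path} is not a recorded PCA transform")
        return cls(
            mean=np.array(payload["mean"]),
            components=np.array(payload["components"]),
            explained_variance=np.array(payload["explained_variance"]),
            total_variance=float(payload["total_variance"]),
            fitted_on=payload.get("fitted_on", ""),
        )


@dataclass
class ProjectedTrajectory:
    """Frames x n_components coordinates in PC space, with provenance."""

    coords: np.ndarray
    provenance: pd.DataFrame
    transform: PCATransform = field(repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape[1] != self.transform.n_components:
            raise ValueError("coordinate dimension must match the transform")
        if len(self.provenance) != self.coords.shape[0]:
            raise ValueError("provenance length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


def fit_pca(features: FeatureMatrix, n_components: int = 2,
            fitted_on: str = "") -> PCATransform:
    """Top eigenvectors of the feature covariance (via SVD of the centred
    data).  The entry of largest magnitude in each component is made positive
    so serialized transforms are reproducible."""
    X = features.values
    if not (X.shape[0] > n_components >= 1):
        raise ValueError("need frames > n_components >= 1")
    mean = X.mean(axis=0)
    Xc = X - mean
    total = float(Xc.var(axis=0, ddof=1).sum())
    if total <= 1e-12:
        raise ValueError("feature set has zero variance; PCA undefined")
    # economy SVD: right singular vectors are the covariance eigenvectors
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    comps = vt[:n_components].T
    explained = (s[:n_components] ** 2) / (X.shape[0] - 1)
    # sign convention: largest-|entry| coordinate positive
    for c in range(comps.shape[1]):
        k = int(np.argmax(np.abs(comps[:, c])))
        if comps[k, c] < 0:
            comps[:, c] = -comps[:, c]
    return PCATransform(
        mean=mean,
        components=comps,
        explained_variance=explained,
        total_variance=total,
        fitted_on=fitted_on,
    )


def apply_pca(transform: PCATransform, features: FeatureMatrix) -> ProjectedTrajectory:
    """Project ``(X - mean) @ components`` — the recorded transform is applied
    as-is, so new ensembles land in the coordinate frame it was fitted in."""
    if features.values.shape[1] != transform.n_features:
        raise ValueError(
            f"feature dimension {features.values.shape[1]} does not match the "
            f"transform ({transform.n_features})"
        )
    coords = (features.values - transform.mean) @ transform.components
    return ProjectedTrajectory(
        coords=coords, provenance=features.provenance.copy(), transform=transform
    )
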