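"""Generalized cross-correlation matrices from mutual information.

Correlated motion between residues i and j is quantified by the mutual
information MI[x_i, x_j] between their 3-D displacement vectors,

    MI[x_i, x_j] = H[x_i] + H[x_j] - H[x_i, x_j],

normalized into a Pearson-like coefficient on [0, 1],

    GC_ij = sqrt(1 - exp(-2 MI / d)),        d = 3,

which captures linear and nonlinear coupling alike and reduces exactly to
|rho| for jointly Gaussian displacements with per-coordinate correlation rho.
MI is measured in nats throughout (the exp/log pairing above requires a
consistent base).

Two estimators are provided: a closed-form Gaussian estimator from sample
covariances (fast; exact for Gaussian data) and the Kraskov-Stögbauer-
Grassberger k-nearest-neighbour estimator (nonparametric, captures nonlinear
dependence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from scipy.special import digamma

from .trajectory_io import Trajectory

__all__ = [
    "DisplacementSet",
    "CorrelationMatrix",
    "superpose_and_center",
    "mutual_information",
    "generalized_correlation",
]


@dataclass
class DisplacementSet:
    """Frames x residues x 3 displacement vectors (Angstrom) after global
    superposition and removal of the per-residue time mean."""

    displacements: np.ndarray
    reference: str = "frame 0"

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=np.float64)
        if self.displacements.ndim != 3 or self.displacements.shape[2] != 3:
            raise ValueError("displacements must be (frames, residues, 3)")
        means = np.abs(self.displacements.mean(axis=0))
        if means.max() > 1e-8:
            raise ValueError("per-residue mean displacement must be ~0 after centering")

    @property
    def n_frames(self) -> int:
        return self.displacements.shape[0]

    @property
    def n_residues(self) -> int:
        return self.displacements.shape[1]


def superpose_and_center(
    traj: Trajectory, reference: int = 0, superpose: bool = True
) -> DisplacementSet:
    """Remove rigid-body motion and the time mean from C-alpha coordinates.

    Each frame is least-squares superposed onto the reference frame's
    C-alphas (Kabsch rotation via :func:`Rotation.align_vectors`; reflections
    excluded), then per-residue time means are subtracted.  ``superpose=False``
    skips the rigid fit and only removes the mean (appropriate for
    displacement data generated without rigid-body motion).
    """
    ca = traj.calpha_xyz()
    if not (0 <= reference < traj.n_frames):
        raise ValueError(f"reference frame {reference} out of range")
    if superpose:
        ref = ca[reference]
        ref_centered = ref - ref.mean(axis=0)
        svals = np.linalg.svd(ref_centered, compute_uv=False)
        if svals[1] < 1e-8 * max(svals[0], 1.0):
            raise ValueError("reference structure is degenerate (collinear C-alphas)")
        aligned = np.empty_like(ca)
        for t in range(ca.shape[0]):
            frame = ca[t] - ca[t].mean(axis=0)
            rot, _ = Rotation.align_vectors(ref_centered, frame)
            aligned[t] = rot.apply(frame)
        ca = aligned
    disp = ca - ca.mean(axis=0)
    return DisplacementSet(
        displacements=disp,
        reference=f"frame {reference}" if superpose else "center-only",
    )


# ---------------------------------------------------------------------------
# mutual information estimators


def _gaussian_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form Gaussian MI, 0.5 ln(det Sx det Sy / det Sxy), nats."""
    xy = np.hstack([x, y])
    cov = np.cov(xy, rowvar=False)
    dx = x.shape[1]
    sx = cov[:dx, :dx]
    sy = cov[dx:, dx:]
    sign_x, ld_x = np.linalg.slogdet(sx)
    sign_y, ld_y = np.linalg.slogdet(sy)
    sign_xy, ld_xy = np.linalg.slogdet(cov)
    if sign_x <= 0 or sign_y <= 0 or sign_xy <= 0 or ld_xy < ld_x + ld_y - 50:
        raise ValueError(
            "singular covariance in the Gaussian MI estimator; add jitter to the "
            "input or use the knn estimator"
        )
    return max(0.0, 0.5 * (ld_x + ld_y - ld_xy))


def _ksg_mi(x: np.ndarray, y: np.ndarray, k: int = 6) -> float:
    """Kraskov-Stögbauer-Grassberger estimator 1 (Chebyshev metric), nats."""
    n = x.shape[0]
    joint = np.hstack([x, y])
    tree_joint = cKDTree(joint)
    # distance to the k-th neighbour in the joint space (excluding self)
    eps, _ = tree_joint.query(joint, k=k + 1, p=np.inf)
    eps = eps[:, -1]
    tree_x = cKDTree(x)
    tree_y = cKDTree(y)
    # strictly-inside counts in each marginal (excluding self)
    nx = np.array(
        [len(tree_x.query_ball_point(x[i], eps[i] * (1 - 1e-12), p=np.inf)) - 1
         for i in range(n)]
    )
    ny = np.array(
        [len(tree_y.query_ball_point(y[i], eps[i] * (1 - 1e-12), p=np.inf)) - 1
         for i in range(n)]
    )
    mi = digamma(k) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    return max(0.0, float(mi))


def mutual_information(
    x: np.ndarray, y: np.ndarray, estimator: str = "gaussian", k: int = 6
) -> float:
    """Mutual information (nats) between two frames x d variable blocks.

    ``estimator='gaussian'`` uses the closed form from sample covariances and
    raises on singular joint covariance (e.g. ``x is y``); ``'knn'`` uses the
    KSG k-nearest-neighbour estimator (default ``k=6``), which stays finite on
    degenerate input.  Negative estimates are clamped at 0.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have the same number of frames")
    if x.shape[0] < 100:
        raise ValueError("need at least 100 frames for MI estimation")
    if estimator == "gaussian":
        return _gaussian_mi(x, y)
    if estimator == "knn":
        return _ksg_mi(x, y, k=k)
    raise ValueError(f"unknown estimator {estimator!r} (expected 'gaussian' or 'knn')")


def mi_to_gc(mi: float | np.ndarray, d: int = 3):
    """Eq-of-record normalization: GC = sqrt(1 - exp(-2 MI / d))."""
    return np.sqrt(1.0 - np.exp(-2.0 * np.asarray(mi, dtype=np.float64) / d))


@dataclass
class CorrelationMatrix:
    """Residue x residue generalized correlation coefficients in [0, 1]."""

    values: np.ndarray
    estimator: str = "gaussian"
    d: int = 3
    failed_pairs: list = None  # pairs where the estimator raised

    def __post_init__(self) -> None:
        if self.failed_pairs is None:
            self.failed_pairs = []
        V = np.asarray(self.values, dtype=np.float64)
        finite = V[np.isfinite(V)]
        if ((finite < -1e-12) | (finite > 1 + 1e-12)).any():
            raise ValueError("GC values must lie in [0, 1]")
        if not np.allclose(V, V.T, equal_nan=True, atol=1e-10):
            raise ValueError("GC matrix must be symmetric")
        if not np.allclose(np.diag(V), 1.0, atol=1e-12):
            raise ValueError("GC diagonal must be 1")
        self.values = np.clip(V, 0.0, 1.0)

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


def generalized_correlation(
    displacements: DisplacementSet,
    estimator: str = "gaussian",
    d: int = 3,
    k: int = 6,
) -> CorrelationMatrix:
    """GC_ij = sqrt(1 - exp(-2 MI_ij / d)) for every residue pair.

    Each pair is computed once (the matrix is symmetric by construction) and
    GC_ii = 1 by definition.  Pairs where the estimator fails are recorded in
    ``failed_pairs`` and reported as NaN instead of aborting the matrix.
    """
    X = displacements.displacements
    n = displacements.n_residues
    gc = np.eye(n)
    failed: list[tuple[int, int]] = []
    if estimator == "gaussian":
        # one pass over the full 3n x 3n covariance, then 3x3/6x6 block dets
        flat = X.reshape(X.shape[0], -1)
        cov = np.cov(flat, rowvar=False)
        for i in range(n):
            si = cov[3 * i : 3 * i + 3, 3 * i : 3 * i + 3]
            for j in range(i + 1, n):
                sj = cov[3 * j : 3 * j + 3, 3 * j : 3 * j + 3]
                sij = cov[3 * i : 3 * i + 3, 3 * j : 3 * j + 3]
                joint = np.block([[si, sij], [sij.T, sj]])
                sign_i, ld_i = np.linalg.slogdet(si)
                sign_j, ld_j = np.linalg.slogdet(sj)
                sign_ij, ld_ij = np.linalg.slogdet(joint)
                if sign_i <= 0 or sign_j <= 0 or sign_ij <= 0:
                    failed.append((i, j))
                    gc[i, j] = gc[j, i] = np.nan
                    continue
                mi = max(0.0, 0.5 * (ld_i + ld_j - ld_ij))
                gc[i, j] = gc[j, i] = mi_to_gc(mi, d=d)
    else:
        for i in range(n):
            for j in range(i + 1, n):
                try:
                    mi = mutual_information(X[:, i, :], X[:, j, :],
                                            estimator=estimator, k=k)
                except ValueError:
                    failed.append((i, j))
                    gc[i, j] = gc[j, i] = np.nan
                    continue
                gc[i, j] = gc[j, i] = mi_to_gc(mi, d=d)
    return CorrelationMatrix(values=gc, estimator=estimator, d=d, failed_pairs=failed)
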