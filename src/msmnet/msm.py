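"""Markov state model estimation, validation and kinetic analysis.

The pipeline is the standard one for conformational kinetics: discretize the
reduced coordinates with k-means, count lagged transitions inside each
trajectory, restrict to the largest strongly connected set, estimate a
reversible (detailed-balance) maximum-likelihood transition matrix, validate
with implied timescales and a Chapman-Kolmogorov test, coarse-grain with
PCCA+ into metastable macrostates, and report stationary weights, ensemble
compositions and mean first passage times.

Conventions
-----------
* Lag times are counted in frames; physical times are ``lag_frames *
  frame_interval`` (ps internally, ns at reporting).
* Ties in nearest-centre assignment and in crisp PCCA+ assignment go to the
  lowest index, so the whole pipeline is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .featurize import ProjectedTrajectory

__all__ = [
    "ClusterModel",
    "DiscreteTrajectory",
    "CountMatrix",
    "MarkovStateModel",
    "ImpliedTimescalesResult",
    "MetastableDecomposition",
    "CKTestResult",
    "cluster_kmeans",
    "count_transitions",
    "largest_connected_set",
    "estimate_reversible_msm",
    "transition_matrix_eigenvalues",
    "implied_timescales",
    "pcca",
    "ck_test",
    "mfpt",
    "mfpt_matrix",
    "macrostate_composition",
    "representative_frames",
]


@dataclass
class ClusterModel:
    """k-means centres in PC space."""

    centers: np.ndarray
    k: int
    max_iterations: int
    seed: int | None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.k < 2:
            raise ValueError("need k >= 2 clusters")
        if not np.isfinite(self.centers).all():
            raise ValueError("cluster centres must be finite")

    def assign(self, coords: np.ndarray) -> np.ndarray:
        """Nearest-centre (Euclidean) labels; ties -> lowest centre index."""
        coords = np.asarray(coords, dtype=np.float64)
        labels = np.empty(coords.shape[0], dtype=np.intp)
        # chunked distance evaluation keeps memory bounded for long runs
        step = max(1, 20_000_000 // max(1, self.k))
        sq = (self.centers**2).sum(axis=1)
        for lo in range(0, coords.shape[0], step):
            block = coords[lo : lo + step]
            d2 = sq[None, :] - 2.0 * block @ self.centers.T
            labels[lo : lo + block.shape[0]] = np.argmin(d2, axis=1)
        return labels


@dataclass
class DiscreteTrajectory:
    """Per-frame microstate labels aligned with a projected trajectory."""

    labels: np.ndarray
    provenance: pd.DataFrame
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.intp)
        if len(self.provenance) != self.labels.size:
            raise ValueError("provenance length must equal label count")
        if self.labels.size and not (0 <= self.labels.min() <= self.labels.max() < self.k):
            raise ValueError("labels must lie in [0, k)")

    def __len__(self) -> int:
        return self.labels.size

    def split_by_trajectory(self) -> list[np.ndarray]:
        """Label runs per source trajectory (transitions never cross runs)."""
        ids = self.provenance["trajectory"].to_numpy()
        if self.labels.size == 0:
            return []
        cuts = np.flatnonzero(ids[1:] != ids[:-1]) + 1
        return np.split(self.labels, cuts)


def cluster_kmeans(
    projected: ProjectedTrajectory,
    k: int = 100,
    max_iterations: int = 200,
    seed: int | None = None,
) -> tuple[ClusterModel, DiscreteTrajectory]:
    """Lloyd's k-means with k-means++ seeding (scikit-learn backend); the
    final assignment is recomputed as an explicit argmin so ties go to the
    lowest centre index."""
    from sklearn.cluster import KMeans

    X = projected.coords
    if X.shape[0] < k:
        raise ValueError(f"cannot place {k} centres on {X.shape[0]} frames")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=1,
        max_iter=max_iterations,
        random_state=None if seed is None else int(seed) % (2**32),
    ).fit(X)
    model = ClusterModel(centers=km.cluster_centers_, k=k,
                         max_iterations=max_iterations, seed=seed)
    dtraj = DiscreteTrajectory(
        labels=model.assign(X), provenance=projected.provenance.copy(), k=k
    )
    return model, dtraj


@dataclass
class CountMatrix:
    """Lagged transition counts (sliding window, per trajectory)."""

    counts: np.ndarray
    lag: int
    counting_mode: str = "sliding"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.lag < 1:
            raise ValueError("lag must be >= 1 frame")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]


def _as_label_arrays(dtrajs) -> list[np.ndarray]:
    if isinstance(dtrajs, DiscreteTrajectory):
        return dtrajs.split_by_trajectory()
    out = []
    for d in dtrajs:
        if isinstance(d, DiscreteTrajectory):
            out.extend(d.split_by_trajectory())
        else:
            out.append(np.asarray(d, dtype=np.intp))
    return out


def count_transitions(dtrajs, lag: int, n_states: int | None = None) -> CountMatrix:
    """Sliding-window counts ``C[i, j] = #{t : s_t = i, s_{t+lag} = j}``
    summed over trajectories; never counts across trajectory boundaries."""
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    arrays = _as_label_arrays(dtrajs)
    if n_states is None:
        n_states = int(max((a.max() for a in arrays if a.size), default=-1)) + 1
    C = np.zeros((n_states, n_states), dtype=np.float64)
    usable = 0
    for a in arrays:
        if a.size <= lag:
            continue
        usable += 1
        np.add.at(C, (a[:-lag], a[lag:]), 1.0)
    if usable == 0:
        raise ValueError(f"no trajectory is longer than the lag ({lag} frames)")
    return CountMatrix(counts=C, lag=lag)


def largest_connected_set(counts: CountMatrix) -> np.ndarray:
    """Largest strongly connected component of the directed count graph
    (edge i -> j iff ``C[i, j] > 0``); sorted state indices."""
    C = counts.counts
    if C.sum() == 0:
        raise ValueError("empty count matrix")
    n, comp = connected_components(csr_matrix(C > 0), directed=True, connection="strong")
    sizes = np.bincount(comp, minlength=n)
    return np.flatnonzero(comp == int(np.argmax(sizes)))


@dataclass
class MarkovStateModel:
    """Reversible transition matrix on the active microstate set."""

    transition_matrix: np.ndarray
    stationary_distribution: np.ndarray
    active_set: np.ndarray
    lag: int
    frame_interval: float = 1.0  # ps per frame

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_matrix, dtype=np.float64)
        pi = np.asarray(self.stationary_distribution, dtype=np.float64)
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition-matrix rows must sum to 1")
        if not np.allclose(pi @ T, pi, atol=1e-8):
            raise ValueError("stationary distribution is not stationary")
        if not np.allclose(pi[:, None] * T, (pi[:, None] * T).T, atol=1e-8):
            raise ValueError("detailed balance violated")
        self.transition_matrix = T
        self.stationary_distribution = pi
        self.active_set = np.asarray(self.active_set, dtype=np.intp)

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def lag_physical(self) -> float:
        """Physical lag time in ps."""
        return self.lag * self.frame_interval


def estimate_reversible_msm(
    counts: CountMatrix,
    active_set: np.ndarray | None = None,
    frame_interval: float = 1.0,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> MarkovStateModel:
    """Maximum-likelihood reversible transition matrix.

    Standard self-consistent fixed-point iteration on the symmetrized count
    variables ``x_ij``: with row sums ``c_i`` of the (active-set) counts,

        x_ij <- (C_ij + C_ji) / (c_i / x_i + c_j / x_j),

    iterated until the stationary distribution changes by less than ``tol``
    (max-norm, relative).  ``T_ij = x_ij / x_i`` and ``pi_i = x_i / sum x``.
    """
    if active_set is None:
        active_set = largest_connected_set(counts)
    C = counts.counts[np.ix_(active_set, active_set)]
    if C.shape[0] < 2:
        raise ValueError("active set must contain at least two states")
    c = C.sum(axis=1)
    if (c == 0).any():
        raise ValueError("active set contains a state with no outgoing counts")
    Csym = C + C.T
    x = Csym.copy()
    xs = x.sum(axis=1)
    for it in range(max_iter):
        denom = c[:, None] / xs[:, None] + c[None, :] / xs[None, :]
        x = Csym / denom
        xs_new = x.sum(axis=1)
        delta = np.max(np.abs(xs_new - xs) / np.maximum(xs_new, 1e-300))
        xs = xs_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"reversible estimator did not converge in {max_iter} iterations "
            f"(last relative change {delta:.2e})"
        )
    T = x / xs[:, None]
    T = T / T.sum(axis=1, keepdims=True)  # tidy rounding
    pi = xs / xs.sum()
    return MarkovStateModel(
        transition_matrix=T,
        stationary_distribution=pi,
        active_set=active_set,
        lag=counts.lag,
        frame_interval=frame_interval,
    )


def transition_matrix_eigenvalues(msm: MarkovStateModel, n: int | None = None) -> np.ndarray:
    """Real eigenvalues of a reversible T, descending, via the symmetric
    similarity transform ``D^(1/2) T D^(-1/2)``."""
    pi = msm.stationary_distribution
    sqrt_pi = np.sqrt(pi)
    S = sqrt_pi[:, None] * msm.transition_matrix / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)
    vals = np.linalg.eigvalsh(S)[::-1]
    return vals if n is None else vals[:n]


def _right_eigenvectors(msm: MarkovStateModel, m: int) -> tuple[np.ndarray, np.ndarray]:
    """First ``m`` eigenvalues and right eigenvectors of a reversible T,
    orthonormal under the pi-weighted inner product."""
    pi = msm.stationary_distribution
    sqrt_pi = np.sqrt(pi)
    S = sqrt_pi[:, None] * msm.transition_matrix / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)
    vals, vecs = np.linalg.eigh(S)
    order = np.argsort(vals)[::-1]
    vals = vals[order][:m]
    psi = vecs[:, order][:, :m] / sqrt_pi[:, None]
    # fix the trivial eigenvector to +1 and sign-normalize the rest
    for c in range(psi.shape[1]):
        k = int(np.argmax(np.abs(psi[:, c])))
        if psi[k, c] < 0:
            psi[:, c] = -psi[:, c]
    psi[:, 0] = 1.0
    return vals, psi


@dataclass
class ImpliedTimescalesResult:
    """Implied timescales ``t_i(tau) = -tau / ln |lambda_{i+1}(tau)|`` per lag,
    in frames; undefined entries (eigenvalue <= 0) are NaN."""

    table: pd.DataFrame  # index: lag (frames); columns: t2, t3, ...
    errors: dict[int, str] = field(default_factory=dict)

    def timescale(self, i: int, lag: int) -> float:
        return float(self.table.loc[lag, f"t{i}"])


def implied_timescales(dtrajs, lags: Sequence[int], n_its: int = 2,
                       frame_interval: float = 1.0) -> ImpliedTimescalesResult:
    """Estimate a reversible model per lag and convert the leading non-trivial
    eigenvalues into relaxation timescales.  Failures at one lag are recorded
    without aborting the remaining lags."""
    rows = {}
    errors: dict[int, str] = {}
    for lag in lags:
        try:
            counts = count_transitions(dtrajs, lag)
            model = estimate_reversible_msm(counts, frame_interval=frame_interval)
            vals = transition_matrix_eigenvalues(model, n_its + 1)[1:]
            ts = np.full(n_its, np.nan)
            for i, lam in enumerate(vals):
                if 0 < lam < 1:
                    ts[i] = -lag / np.log(lam)
            rows[lag] = ts
        except (ValueError, RuntimeError) as exc:
            errors[lag] = str(exc)
    if not rows:
        raise ValueError(f"implied timescales failed at every lag: {errors}")
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"t{i + 2}" for i in range(n_its)]
    ).sort_index()
    table.index.name = "lag"
    return ImpliedTimescalesResult(table=table, errors=errors)


# ---------------------------------------------------------------------------
# PCCA+ metastable coarse-graining


@dataclass
class MetastableDecomposition:
    """PCCA+ membership matrix and crisp macrostate assignment."""

    memberships: np.ndarray  # active microstates x m, rows sum to 1
    assignment: np.ndarray  # active microstate -> macrostate (argmax)
    macro_stationary: np.ndarray
    msm: MarkovStateModel = field(repr=False)

    def __post_init__(self) -> None:
        chi = np.asarray(self.memberships, dtype=np.float64)
        if ((chi < -1e-10) | (chi > 1 + 1e-10)).any():
            raise ValueError("memberships must lie in [0, 1]")
        if not np.allclose(chi.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("membership rows must sum to 1")
        if len(np.unique(self.assignment)) != chi.shape[1]:
            raise ValueError("every macrostate must own at least one microstate")
        if abs(self.macro_stationary.sum() - 1.0) > 1e-8:
            raise ValueError("macrostate probabilities must sum to 1")

    @property
    def n_macrostates(self) -> int:
        return self.memberships.shape[1]

    def microstates_of(self, macro: int) -> np.ndarray:
        """Active-set positions crisply assigned to ``macro``."""
        return np.flatnonzero(self.assignment == macro)

    def frame_macrostates(self, dtraj_labels: np.ndarray) -> np.ndarray:
        """Map microstate labels to macrostates; frames outside the active set
        get -1."""
        size = max(int(dtraj_labels.max(initial=0)) + 1,
                   int(self.msm.active_set.max()) + 1)
        lookup = np.full(size, -1, dtype=np.intp)
        lookup[self.msm.active_set] = self.assignment
        return lookup[dtraj_labels]


def pcca(msm: MarkovStateModel, m: int) -> MetastableDecomposition:
    """PCCA+ (Robust Perron Cluster Analysis).

    Simplex-vertex search on the first ``m`` right eigenvectors of the
    reversible transition matrix (orthonormal under the pi-weighted inner
    product): the microstate rows of the eigenvector matrix lie near an
    (m-1)-simplex whose vertices are the pure metastable states; memberships
    are the barycentric coordinates obtained from the inverse vertex map,
    clamped to [0, 1] and renormalized.  Crisp assignment is the row argmax
    with ties to the lowest macrostate index.
    """
    n = msm.n_states
    if not (2 <= m <= n):
        raise ValueError(f"need 2 <= m <= {n} macrostates")
    vals, psi = _right_eigenvectors(msm, m)
    if m < n and abs(vals[m - 1] - (transition_matrix_eigenvalues(msm, m + 1)[m])) < 1e-12:
        raise ValueError(
            f"eigenvalues {m} and {m + 1} are degenerate at the cut; "
            "choose a different number of macrostates"
        )
    # simplex vertex search (inner-simplex algorithm)
    vertices = np.empty(m, dtype=np.intp)
    Y = psi.copy()
    norms = (Y**2).sum(axis=1)
    vertices[0] = int(np.argmax(norms))
    for v in range(1, m):
        prev = Y[vertices[v - 1]].copy()
        if v == 1:
            Y = Y - prev  # place the first vertex at the origin
        else:
            nrm = np.linalg.norm(prev)
            if nrm < 1e-12:
                raise ValueError("degenerate simplex vertices; choose a different m")
            b = prev / nrm
            Y = Y - np.outer(Y @ b, b)
        norms = (Y**2).sum(axis=1)
        vertices[v] = int(np.argmax(norms))
    vertices = np.array(sorted(vertices))
    V = psi[vertices, :]
    try:
        A = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate simplex vertices; choose a different m") from exc
    chi = psi @ A
    chi = np.clip(chi, 0.0, 1.0)
    rows = chi.sum(axis=1)
    if (rows <= 0).any():
        raise ValueError("PCCA+ produced an empty membership row")
    chi = chi / rows[:, None]
    assignment = np.argmax(chi, axis=1)  # argmax: ties -> lowest index
    # relabel macrostates by first occurrence for determinism
    relabel = {}
    for a in assignment:
        if a not in relabel:
            relabel[a] = len(relabel)
    if len(relabel) != m:
        raise ValueError(
            "crisp assignment left a macrostate empty; choose a smaller m"
        )
    order = np.array([relabel[c] for c in range(m)])
    chi = chi[:, np.argsort(order)]
    assignment = np.asarray([relabel[a] for a in assignment], dtype=np.intp)
    macro_pi = np.array(
        [msm.stationary_distribution[assignment == c].sum() for c in range(m)]
    )
    macro_pi = macro_pi / macro_pi.sum()
    return MetastableDecomposition(
        memberships=chi, assignment=assignment, macro_stationary=macro_pi, msm=msm
    )


# ---------------------------------------------------------------------------
# Chapman-Kolmogorov test


@dataclass
class CKTestResult:
    """Predicted vs re-estimated macro-set transition probabilities.

    ``table`` rows: one per (step, set_from, set_to) with the prediction
    ``[T(tau)]^s``, the estimate from a model re-built at lag ``s * tau``, the
    bootstrap 95% half-width, and the per-entry pass flag.
    """

    table: pd.DataFrame
    tolerance_floor: float

    @property
    def passed(self) -> bool:
        ok = self.table["available"]
        return bool(self.table.loc[ok, "pass"].all()) if ok.any() else False


def _macro_set_probabilities(T: np.ndarray, pi: np.ndarray,
                             sets: list[np.ndarray]) -> np.ndarray:
    """Stationary-weighted set-to-set transition probabilities."""
    m = len(sets)
    P = np.zeros((m, m))
    for a, A in enumerate(sets):
        wA = pi[A] / pi[A].sum()
        for b, B in enumerate(sets):
            P[a, b] = float(wA @ T[np.ix_(A, B)].sum(axis=1))
    return P


def ck_test(
    dtrajs,
    msm: MarkovStateModel,
    decomposition: MetastableDecomposition | None = None,
    steps: Sequence[int] = (1, 2, 5),
    n_bootstrap: int = 200,
    tolerance_floor: float = 0.05,
    seed: int | None = None,
) -> CKTestResult:
    """Chapman-Kolmogorov self-consistency test on macro-sets.

    For each step ``s``, the prediction ``[T(tau)]^s`` (aggregated over the
    macro-sets with stationary weights) is compared with the same aggregate of
    a reversible model re-estimated at lag ``s * tau``.  An entry passes when
    the deviation is within the larger of ``tolerance_floor`` and the 95%
    band from ``n_bootstrap`` trajectory-level bootstrap resamples.  Steps
    with insufficient data are reported as unavailable.
    """
    arrays = _as_label_arrays(dtrajs)
    rng = np.random.default_rng(0 if seed is None else seed)
    if decomposition is None:
        sets = [np.array([i]) for i in range(msm.n_states)]
    else:
        sets = [decomposition.microstates_of(c)
                for c in range(decomposition.n_macrostates)]
    pi = msm.stationary_distribution
    active = msm.active_set
    n_states = int(max(a.max() for a in arrays if a.size)) + 1
    rows = []
    for s in steps:
        Ts = np.linalg.matrix_power(msm.transition_matrix, s)
        P_pred = _macro_set_probabilities(Ts, pi, sets)
        try:
            P_est = _ck_estimate(arrays, s * msm.lag, n_states, active, pi, sets,
                                 msm.frame_interval)
        except (ValueError, RuntimeError) as exc:
            for a in range(len(sets)):
                for b in range(len(sets)):
                    rows.append((s, a, b, P_pred[a, b], np.nan, np.nan, False, False,
                                 str(exc)))
            continue
        # trajectory-level bootstrap of the re-estimated probabilities
        boots = []
        for _ in range(n_bootstrap):
            pick = rng.integers(0, len(arrays), size=len(arrays))
            try:
                boots.append(
                    _ck_estimate([arrays[i] for i in pick], s * msm.lag, n_states,
                                 active, pi, sets, msm.frame_interval)
                )
            except (ValueError, RuntimeError):
                continue
        if boots:
            stack = np.stack(boots)
            half = 0.5 * (np.nanpercentile(stack, 97.5, axis=0)
                          - np.nanpercentile(stack, 2.5, axis=0))
        else:
            half = np.zeros_like(P_pred)
        for a in range(len(sets)):
            for b in range(len(sets)):
                tol = max(tolerance_floor, float(half[a, b]))
                diff = abs(P_pred[a, b] - P_est[a, b])
                rows.append((s, a, b, P_pred[a, b], P_est[a, b], tol,
                             diff <= tol, True, ""))
    table = pd.DataFrame(
        rows,
        columns=["step", "set_from", "set_to", "predicted", "estimated",
                 "tolerance", "pass", "available", "note"],
    )
    return CKTestResult(table=table, tolerance_floor=tolerance_floor)


def _ck_estimate(arrays, lag, n_states, active, pi_ref, sets, frame_interval):
    counts = count_transitions(arrays, lag, n_states=n_states)
    model = estimate_reversible_msm(counts, frame_interval=frame_interval)
    # map the reference active-set positions into the re-estimated model
    pos = {int(s): i for i, s in enumerate(model.active_set)}
    sets_mapped = []
    for A in sets:
        mapped = [pos[int(active[i])] for i in A if int(active[i]) in pos]
        if not mapped:
            raise ValueError(f"macro-set lost at lag {lag}")
        sets_mapped.append(np.array(mapped, dtype=np.intp))
    pi_map = np.zeros(model.n_states)
    for i, s in enumerate(active):
        if int(s) in pos:
            pi_map[pos[int(s)]] = pi_ref[i]
    pi_map = pi_map / pi_map.sum()
    return _macro_set_probabilities(model.transition_matrix, pi_map, sets_mapped)


# ---------------------------------------------------------------------------
# kinetics


def mfpt(
    msm: MarkovStateModel,
    source: Sequence[int],
    target: Sequence[int],
    physical: bool = False,
) -> float:
    """Stationary-weighted mean first passage time between microstate sets
    (positions within the active set), in lag steps (or ps if ``physical``).

    Solves ``m_i = 0`` on the target and ``m_i = 1 + sum_j T_ij m_j``
    elsewhere, then averages over the source with stationary weights.  States
    shared by source and target contribute zero, so the passage time of a set
    to itself is 0.
    """
    n = msm.n_states
    source = sorted(set(int(s) for s in source))
    target = sorted(set(int(s) for s in target))
    if not source or not target:
        raise ValueError("source and target must be non-empty")
    if any(not (0 <= s < n) for s in source + target):
        raise ValueError("source/target outside the active set")
    T = msm.transition_matrix
    m = np.zeros(n)
    free = np.array([i for i in range(n) if i not in set(target)], dtype=np.intp)
    if free.size:
        A = np.eye(free.size) - T[np.ix_(free, free)]
        try:
            m[free] = np.linalg.solve(A, np.ones(free.size))
        except np.linalg.LinAlgError as exc:
            raise ValueError("target is unreachable from part of the chain") from exc
        if (m[free] < 0).any() or not np.isfinite(m[free]).all():
            raise ValueError("target is unreachable from part of the chain")
    pi = msm.stationary_distribution[source]
    steps = float(m[source] @ pi / pi.sum())
    return steps * msm.lag_physical if physical else steps


def mfpt_matrix(
    msm: MarkovStateModel,
    decomposition: MetastableDecomposition,
    physical: bool = False,
    include_other: bool = True,
) -> pd.DataFrame:
    """All macrostate-to-macrostate MFPTs; diagonal 0.  With
    ``include_other``, adds transitions to/from the union of all remaining
    macrostates (the aggregate arrows of kinetic maps)."""
    m = decomposition.n_macrostates
    sets = [decomposition.microstates_of(c) for c in range(m)]
    names = [f"S{c + 1}" for c in range(m)]
    out = pd.DataFrame(0.0, index=names, columns=names)
    for a in range(m):
        for b in range(m):
            if a != b:
                out.iloc[a, b] = mfpt(msm, sets[a], sets[b], physical=physical)
    if include_other and m > 2:
        other_to = []
        to_other = []
        for a in range(m):
            rest = np.concatenate([sets[b] for b in range(m) if b != a])
            to_other.append(mfpt(msm, sets[a], rest, physical=physical))
            other_to.append(mfpt(msm, rest, sets[a], physical=physical))
        out["OTHER"] = to_other
        out.loc["OTHER"] = other_to + [0.0]
    return out


def macrostate_composition(
    decomposition: MetastableDecomposition, dtraj: DiscreteTrajectory
) -> pd.DataFrame:
    """Per-macrostate fraction of assigned frames from each ensemble label
    (rows sum to 1; empty macrostates are reported as all-zero rows)."""
    macro = decomposition.frame_macrostates(dtraj.labels)
    labels = dtraj.provenance["ensemble_label"].to_numpy()
    ens = sorted(set(labels))
    m = decomposition.n_macrostates
    out = pd.DataFrame(0.0, index=[f"S{c + 1}" for c in range(m)], columns=ens)
    for c in range(m):
        mask = macro == c
        total = int(mask.sum())
        if total == 0:
            continue
        for e in ens:
            out.loc[f"S{c + 1}", e] = float((labels[mask] == e).sum() / total)
    return out


def representative_frames(
    decomposition: MetastableDecomposition,
    dtraj: DiscreteTrajectory,
    projected: ProjectedTrajectory,
    cluster_model: ClusterModel,
    restrict_to_dominant_label: bool = False,
) -> pd.DataFrame:
    """Per macrostate, the frame nearest (Euclidean, PC space) to the
    membership-weighted mean of its microstate centres; ties -> earliest
    frame.  Optionally restricted to the macrostate's dominant ensemble label
    (falling back to the unrestricted macrostate when the restriction is
    empty)."""
    import warnings

    macro = decomposition.frame_macrostates(dtraj.labels)
    labels = dtraj.provenance["ensemble_label"].to_numpy()
    rows = []
    for c in range(decomposition.n_macrostates):
        chi = decomposition.memberships[:, c]
        centers = cluster_model.centers[decomposition.msm.active_set]
        anchor = (chi[:, None] * centers).sum(axis=0) / chi.sum()
        mask = macro == c
        dominant = ""
        if mask.any():
            ens, cnt = np.unique(labels[mask], return_counts=True)
            dominant = str(ens[np.argmax(cnt)])
        if restrict_to_dominant_label and dominant:
            restricted = mask & (labels == dominant)
            if restricted.any():
                mask = restricted
            else:
                warnings.warn(
                    f"macrostate S{c + 1}: dominant-label restriction empty; "
                    "falling back to the unrestricted macrostate"
                )
        if not mask.any():
            rows.append((f"S{c + 1}", -1, dominant, np.nan))
            continue
        idx = np.flatnonzero(mask)
        d2 = ((projected.coords[idx] - anchor) ** 2).sum(axis=1)
        best = idx[int(np.argmin(d2))]  # argmin: ties -> earliest frame
        rows.append((f"S{c + 1}", int(best), dominant, float(np.sqrt(d2.min()))))
    return pd.DataFrame(rows, columns=["macrostate", "frame", "dominant_label",
                                       "distance"])
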