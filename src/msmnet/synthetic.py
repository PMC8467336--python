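"""Synthetic trajectory, correlation and graph generators with known truth.

Every downstream stage of the pipeline (featurization, Markov-state-model
estimation, metastable lumping, generalized-correlation matrices, community
and path analysis) is exercised against data generated here, where the hidden
transition matrix, the planted per-pair correlations, or the planted community
labels are known exactly.

The generators emulate the statistical structure of multi-basin molecular
dynamics ensembles: a hidden Markov chain hops between metastable basins and
each frame is a per-state reference structure plus isotropic Gaussian emission
noise.  Reference structures are beads on a helix (two chain tags split at the
midpoint, mimicking a homodimer), so superposition is well conditioned and
monomer-tag logic is exercised.

All generators are deterministic given their seed.  A single global seed fans
out to fixed-offset child streams (see :func:`child_rng`), so each component is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trajectory_io import EnsembleSet, Residue, Topology, Trajectory

__all__ = [
    "BasinSpec",
    "CorrelationSpec",
    "bead_topology",
    "helix_coordinates",
    "child_rng",
    "stationary_distribution",
    "generate_hmm_trajectory",
    "generate_correlated_displacements",
    "generate_two_ensembles",
    "generate_planted_network",
    "two_state_spec",
    "asymmetric_two_basin_spec",
    "hidden_set_mfpt",
]

# fixed substream offsets for the global-seed fan-out
_STREAMS = {"hmm": 0, "corr": 1, "net": 2, "labels": 3, "cluster": 4, "bootstrap": 5}


def child_rng(seed: int | None, stream: str, extra: int = 0) -> np.random.Generator:
    """Child generator for a named substream of the global seed."""
    ss = np.random.SeedSequence(entropy=0 if seed is None else seed,
                                spawn_key=(_STREAMS[stream], extra))
    return np.random.default_rng(ss)


def helix_coordinates(n_beads: int, radius: float = 5.0, rise: float = 1.5,
                      turn: float = 0.6) -> np.ndarray:
    """Beads on a helix (Angstrom); non-collinear, ~bonded spacing."""
    t = np.arange(n_beads)
    return np.column_stack(
        [radius * np.cos(turn * t), radius * np.sin(turn * t), rise * t]
    ).astype(np.float64)


def bead_topology(n_beads: int, first_index: int = 1) -> Topology:
    """Linear bead-chain topology, one CA 'residue' per bead, two chain tags
    (``A``/``B``) split at the midpoint to mimic a homodimer."""
    half = n_beads // 2
    residues = [
        Residue(index=first_index + (i if i < half else i - half),
                name="BEA", chain="A" if i < half else "B")
        for i in range(n_beads)
    ]
    rng = np.arange(n_beads)
    return Topology(residues, ["CA"] * n_beads, rng, rng)


def _check_stochastic(T: np.ndarray) -> np.ndarray:
    T = np.asarray(T, dtype=np.float64)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if (T < -1e-15).any() or not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("transition matrix rows must be non-negative and sum to 1")
    return np.clip(T, 0.0, 1.0)


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (leading left
    eigenvector, normalized)."""
    T = _check_stochastic(T)
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass
class BasinSpec:
    """Hidden-Markov emission model for a multi-basin bead trajectory.

    ``reference`` holds one bead structure per hidden state (K x beads x 3,
    Angstrom); frames emit that structure plus isotropic Gaussian noise of
    width ``emission_std``.  ``T_hidden`` drives the hidden chain with one
    step per ``step_interval`` ps.
    """

    reference: np.ndarray
    emission_std: float
    T_hidden: np.ndarray
    step_interval: float = 50.0  # ps
    seed: int | None = None

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=np.float64)
        if self.reference.ndim != 3 or self.reference.shape[2] != 3:
            raise ValueError("reference must be (K, beads, 3)")
        self.T_hidden = _check_stochastic(self.T_hidden)
        if self.n_states < 2:
            raise ValueError("need at least two hidden states")
        if self.T_hidden.shape[0] != self.n_states:
            raise ValueError("T_hidden size must match number of reference states")
        if self.emission_std < 0:
            raise ValueError("emission_std must be non-negative")

    @property
    def n_states(self) -> int:
        return self.reference.shape[0]

    @property
    def n_beads(self) -> int:
        return self.reference.shape[1]


def _sample_chain(T: np.ndarray, n: int, rng: np.random.Generator,
                  start: np.ndarray | None = None) -> np.ndarray:
    pi = stationary_distribution(T) if start is None else np.asarray(start, float)
    cdf = np.cumsum(T, axis=1)
    states = np.empty(n, dtype=np.intp)
    states[0] = rng.choice(T.shape[0], p=pi / pi.sum())
    u = rng.random(n - 1)
    for t in range(1, n):
        states[t] = np.searchsorted(cdf[states[t - 1]], u[t - 1], side="right")
    return states


def generate_hmm_trajectory(
    spec: BasinSpec,
    n_frames: int,
    topology: Topology | None = None,
    ensemble_label: str = "",
    rng: np.random.Generator | None = None,
    start: np.ndarray | None = None,
) -> tuple[Trajectory, np.ndarray]:
    """Sample a bead trajectory from the hidden chain.

    The hidden chain starts from its stationary distribution (no burn-in
    ambiguity) unless ``start`` overrides it.  Returns the trajectory and the
    hidden per-frame state labels for oracle checks.
    """
    if n_frames < 2:
        raise ValueError("need at least two frames")
    if rng is None:
        rng = child_rng(spec.seed, "hmm")
    if topology is None:
        topology = bead_topology(spec.n_beads)
    labels = _sample_chain(spec.T_hidden, n_frames, rng, start=start)
    xyz = spec.reference[labels]
    if spec.emission_std > 0:
        xyz = xyz + rng.normal(0.0, spec.emission_std, size=xyz.shape)
    traj = Trajectory(
        topology=topology,
        xyz=xyz,
        frame_interval=spec.step_interval,
        ensemble_label=ensemble_label,
        source="synthetic-hmm",
    )
    return traj, labels


@dataclass
class CorrelationSpec:
    """Planted per-pair coordinate correlations for displacement frames.

    ``rho`` is the beads x beads correlation matrix: coordinate k of bead i
    correlates only with coordinate k of bead j, at ``rho[i, j]``.  For
    jointly Gaussian 3-D displacements this makes the generalized correlation
    coefficient of the pair exactly ``|rho[i, j]|``.
    """

    rho: np.ndarray
    displacement_std: float = 1.0
    n_frames: int = 10000
    seed: int | None = None

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=np.float64)
        n = self.rho.shape[0]
        if self.rho.shape != (n, n):
            raise ValueError("rho must be square")
        if not np.allclose(self.rho, self.rho.T, atol=1e-12):
            raise ValueError("rho must be symmetric")
        if not np.allclose(np.diag(self.rho), 1.0, atol=1e-12):
            raise ValueError("rho must have unit diagonal")
        if self.displacement_std <= 0:
            raise ValueError("displacement_std must be positive")

    @property
    def n_beads(self) -> int:
        return self.rho.shape[0]


def _cholesky_or_blame(rho: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(rho)
    except np.linalg.LinAlgError:
        # name an offending pair: largest off-diagonal magnitude
        off = np.abs(rho - np.diag(np.diag(rho)))
        i, j = np.unravel_index(int(np.argmax(off)), off.shape)
        raise ValueError(
            "planted correlation matrix is not positive definite "
            f"(check pair ({i}, {j}) with rho={rho[i, j]:.3f})"
        ) from None


def generate_correlated_displacements(
    spec: CorrelationSpec,
    topology: Topology | None = None,
    reference: np.ndarray | None = None,
    ensemble_label: str = "",
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Draw iid frames of jointly Gaussian bead displacements.

    Frames are ``reference + displacement`` with zero-mean displacements whose
    per-coordinate bead-bead correlation is exactly ``spec.rho``.
    """
    if rng is None:
        rng = child_rng(spec.seed, "corr")
    if topology is None:
        topology = bead_topology(spec.n_beads)
    if reference is None:
        reference = helix_coordinates(spec.n_beads, radius=8.0, rise=4.0)
    L = _cholesky_or_blame(spec.rho) * spec.displacement_std
    # each Cartesian coordinate is an independent copy of the bead process
    z = rng.standard_normal((3, spec.n_frames, spec.n_beads))
    disp = np.einsum("kfb,ab->fak", z, L)  # frames x beads x 3, via x_f = L z_f
    xyz = reference[None, :, :] + disp
    return Trajectory(
        topology=topology,
        xyz=xyz,
        frame_interval=1.0,
        ensemble_label=ensemble_label,
        source="synthetic-correlated",
    )


# ---------------------------------------------------------------------------
# two-ensemble (GDP/GTP-like) generator


def _shift_second_chain(base: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Displace the second-half beads (chain B) only, so basins differ in
    internal geometry — an open/closed dimer motion visible to
    translation-invariant distance features."""
    out = base.copy()
    out[base.shape[0] // 2 :] += shift
    return out


def two_state_spec(stay: float = 0.9, n_beads: int = 8, separation: float = 12.0,
                   emission_std: float = 0.8, seed: int | None = None) -> BasinSpec:
    """Two-basin spec with symmetric stay probability (unit tests, timescale
    checks: the second eigenvalue is ``2*stay - 1`` in closed form)."""
    base = helix_coordinates(n_beads)
    ref = np.stack(
        [base, _shift_second_chain(base, np.array([separation, 0.0, 0.0]))]
    )
    T = np.array([[stay, 1 - stay], [1 - stay, stay]])
    return BasinSpec(reference=ref, emission_std=emission_std, T_hidden=T, seed=seed)


def asymmetric_two_basin_spec(
    b: float = 0.02,
    ratio: float = 3.0,
    intra: float = 0.2,
    n_beads: int = 8,
    separation: float = 25.0,
    emission_std: float = 0.8,
    seed: int | None = None,
) -> BasinSpec:
    """Four-state chain with two basins A = {0, 1}, B = {2, 3} and an exact
    planted mean-first-passage asymmetry.

    Each A state leaves for B at rate ``a = ratio * b`` and each B state
    leaves for A at rate ``b``; by basin symmetry the set MFPTs are exactly
    ``MFPT(A->B) = 1/a`` and ``MFPT(B->A) = 1/b`` hidden steps, so the planted
    ratio ``MFPT(B->A)/MFPT(A->B) = ratio`` holds analytically.  The chain is
    reversible with stationary basin weights ``(1, ratio)/(1 + ratio)``.
    """
    a = ratio * b
    if not (0 < a < 1 - intra and 0 < b < 1 - intra):
        raise ValueError("rates too large for the requested intra-basin mixing")
    T = np.array(
        [
            [1 - intra - a, intra, a, 0.0],
            [intra, 1 - intra - a, 0.0, a],
            [b, 0.0, 1 - intra - b, intra],
            [0.0, b, intra, 1 - intra - b],
        ]
    )
    base = helix_coordinates(n_beads)
    dx = np.array([separation, 0.0, 0.0])
    dy = np.array([0.0, 0.45 * separation, 0.0])
    # four well-separated internal geometries (chain-B displacements):
    # basin A = {0, 1}, basin B = {2, 3}
    ref = np.stack(
        [
            _shift_second_chain(base, np.zeros(3)),
            _shift_second_chain(base, dy),
            _shift_second_chain(base, dx),
            _shift_second_chain(base, dx + dy),
        ]
    )
    return BasinSpec(reference=ref, emission_std=emission_std, T_hidden=T, seed=seed)


def hidden_set_mfpt(T: np.ndarray, source: Sequence[int], target: Sequence[int]) -> float:
    """Analytic stationary-weighted set-to-set mean first passage time of a
    hidden chain, in hidden steps (first-passage linear solve on ``T``)."""
    T = _check_stochastic(T)
    n = T.shape[0]
    target = sorted(set(target))
    source = sorted(set(source))
    m = np.zeros(n)
    free = [i for i in range(n) if i not in target]
    if free:
        Tff = T[np.ix_(free, free)]
        rhs = np.ones(len(free))
        m[free] = np.linalg.solve(np.eye(len(free)) - Tff, rhs)
    pi = stationary_distribution(T)
    w = pi[source]
    return float(m[source] @ w / w.sum())


def generate_two_ensembles(
    basins: BasinSpec | tuple[BasinSpec, BasinSpec],
    n_frames_per_label: int,
    labels: tuple[str, str] = ("GDP", "GTP"),
    seed: int | None = None,
) -> tuple[EnsembleSet, dict[str, np.ndarray]]:
    """Two labelled trajectories over a shared topology.

    With a single :class:`BasinSpec`, both labels sample the same hidden chain
    but each starts from the stationary distribution restricted to its own
    basin (first label: lower half of the states; second: upper half), so the
    first label is biased toward basin A and the second toward basin B while
    the planted kinetics remain those of ``T_hidden``.  With a pair of specs
    (sharing shape), each label uses its own references — disjoint basins give
    macrostates composed ≥ 99% of one label.

    Returns the ensemble set and the hidden label sequence per ensemble label.
    """
    if isinstance(basins, BasinSpec):
        pair = (basins, basins)
    else:
        pair = basins
        if pair[0].n_beads != pair[1].n_beads:
            raise ValueError("both basin specs must share a bead count")
    if seed is None:
        seed = pair[0].seed
    topology = bead_topology(pair[0].n_beads)
    trajs: list[Trajectory] = []
    hidden: dict[str, np.ndarray] = {}
    for which, (label, spec) in enumerate(zip(labels, pair)):
        if not label:
            raise ValueError("ensemble labels must be non-empty")
        K = spec.n_states
        half = K // 2
        basin = list(range(half)) if which == 0 else list(range(half, K))
        pi = stationary_distribution(spec.T_hidden)
        start = np.zeros(K)
        start[basin] = pi[basin] / pi[basin].sum()
        rng = child_rng(seed, "hmm", extra=which)
        traj, lab = generate_hmm_trajectory(
            spec, n_frames_per_label, topology=topology,
            ensemble_label=label, rng=rng, start=start,
        )
        trajs.append(traj)
        hidden[label] = lab
    return EnsembleSet(trajs), hidden


# ---------------------------------------------------------------------------
# planted community graphs


def generate_planted_network(
    n_blocks: int,
    block_size: int,
    p_in: float,
    p_out: float,
    weight_in: float = 0.8,
    weight_out: float = 0.3,
    seed: int | None = None,
    require_connected: bool = False,
):
    """Planted-partition graph as a :class:`~msmnet.network.DynamicNetwork`.

    Within-block edges appear with probability ``p_in`` and carry generalized
    correlation ``weight_in``; between-block edges with ``p_out`` and
    ``weight_out``.  Returns ``(network, labels)`` with the planted community
    label per node.  A disconnected result is flagged with a ``RuntimeError``
    when ``require_connected`` is set.
    """
    from .network import DynamicNetwork, NetworkParams

    if not (0 <= p_out < p_in <= 1):
        raise ValueError("need 0 <= p_out < p_in <= 1")
    for w in (weight_in, weight_out):
        if not (0 < w <= 1):
            raise ValueError("edge weights must be in (0, 1]")
    rng = child_rng(seed, "net")
    n = n_blocks * block_size
    labels = np.repeat(np.arange(n_blocks), block_size)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            same = labels[i] == labels[j]
            p, gc = (p_in, weight_in) if same else (p_out, weight_out)
            if rng.random() < p:
                edges.append((i, j, 1.0, gc))
    net = DynamicNetwork.from_edges(n, edges, params=NetworkParams())
    if require_connected and not net.is_connected():
        raise RuntimeError("planted graph is disconnected; rerun with another seed")
    return net, labels
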