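"""Orchestration: featurize -> PCA -> cluster -> MSM -> PCCA+ -> kinetics and
superpose -> GCCM -> network -> communities -> paths, from a single config.

The config is the single home for every tunable parameter; each run echoes it
(with a content hash) into the output directory, all randomness is funnelled
through named substreams of one global seed, and every intermediate table is
persisted so reports regenerate identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import featurize as fz
from . import gccm as gc
from . import msm as km
from . import network as nw
from .synthetic import child_rng
from .trajectory_io import EnsembleSet, read_topology, read_trajectory

log = logging.getLogger("msmnet")

__all__ = ["AnalysisConfig", "AnalysisReport", "run_msm_pipeline",
           "run_network_pipeline", "compare_ensembles", "variation_of_information"]


@dataclass
class AnalysisConfig:
    """Validated parameter set for a full analysis run."""

    # inputs: list of {"paths": [...], "label": str}; topology path
    trajectories: list = field(default_factory=list)
    topology: str | None = None
    frame_interval: float = 50.0  # ps

    # featurization / PCA
    min_separation: int = 3
    max_pairs: int = 20000
    n_components: int = 2

    # MSM
    k: int = 100
    max_iterations: int = 200
    lags: tuple = (1, 2, 5, 10)
    lag: int = 60  # production lag in frames (3 ns at 50 ps/frame)
    n_macrostates: int = 4
    ck_steps: tuple = (1, 2, 3)
    ck_bootstrap: int = 200

    # GCCM
    gccm_estimator: str = "gaussian"
    knn_k: int = 6
    superpose: bool = True

    # network
    cutoff: float = 4.5
    persistence: float = 0.75
    neighbor_exclusion: int = 1
    contact_mode: str = "heavy"
    gc_floor: float = 1e-6
    source_residue: int = 1441
    sink_residues: tuple = (1346, 1394, 1455, 1490)
    subopt_tolerance: float = 1.0

    seed: int = 0
    output_dir: str = "msmnet-run"

    def __post_init__(self) -> None:
        if self.lag < 1 or any(l < 1 for l in self.lags):
            raise ValueError("lags must be >= 1 frame")
        if self.n_macrostates < 2:
            raise ValueError("need at least two macrostates")
        if not (0 < self.persistence <= 1):
            raise ValueError("persistence must lie in (0, 1]")
        if self.subopt_tolerance < 0:
            raise ValueError("subopt tolerance must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("lags", "ck_steps", "sink_residues"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def load_ensembles(self) -> EnsembleSet:
        if not self.trajectories or self.topology is None:
            raise ValueError("config lists no input trajectories/topology")
        top = read_topology(self.topology)
        trajs = [
            read_trajectory(item["paths"], top, self.frame_interval, item["label"])
            for item in self.trajectories
        ]
        return EnsembleSet(trajs)


@dataclass
class AnalysisReport:
    """Persisted result surfaces of one pipeline run."""

    config: AnalysisConfig
    tables: dict = field(default_factory=dict)  # name -> DataFrame
    arrays: dict = field(default_factory=dict)  # name -> ndarray
    objects: dict = field(default_factory=dict)  # models, partitions, ...

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "config": dataclasses.asdict(self.config),
            "config_hash": self.config.config_hash(),
            "tables": sorted(self.tables),
            "arrays": sorted(self.arrays),
        }
        for name, tab in self.tables.items():
            tab.to_csv(outdir / f"{name}.csv")
        for name, arr in self.arrays.items():
            np.savetxt(outdir / f"{name}.txt", np.atleast_2d(arr))
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return outdir


from contextlib import contextmanager


@contextmanager
def _stage(name: str):
    """Abort with the stage name on failure; log stage timing at INFO."""
    t0 = time.perf_counter()
    try:
        yield
    except Exception as exc:
        log.error("stage %s failed: %s", name, exc)
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    log.info("stage %s: %.2f s", name, time.perf_counter() - t0)


def run_msm_pipeline(
    config: AnalysisConfig,
    ensembles: EnsembleSet | None = None,
    reuse_transform: fz.PCATransform | None = None,
    save: bool = True,
) -> AnalysisReport:
    """Featurize -> PCA (or reuse a recorded transform) -> k-means -> implied
    timescales -> reversible MSM -> PCCA+ -> CK test -> compositions, MFPTs
    and representative frames.

    ``reuse_transform`` is the mutant workflow: the stored transform's mean
    and components are applied unchanged and no PCA is refitted, so new
    ensembles are projected into the reference coordinate frame.
    """
    if ensembles is None:
        ensembles = config.load_ensembles()
    report = AnalysisReport(config=config)

    with _stage("featurize"):
        spec = fz.default_pairs(ensembles.topology, config.min_separation,
                                config.max_pairs)
        blocks = [fz.compute_distance_features(t, spec)
                  for t in ensembles.trajectories]
        features = fz.concat_features(blocks)

    with _stage("pca"):
        if reuse_transform is None:
            transform = fz.fit_pca(features, config.n_components,
                                   fitted_on="+".join(ensembles.labels))
        else:
            if reuse_transform.n_features != features.values.shape[1]:
                raise ValueError("stored transform does not match the feature dimension")
            transform = reuse_transform
            log.info("PCA fit skipped: reusing the recorded transform (%s)",
                     transform.fitted_on)
        projected = fz.apply_pca(transform, features)

    with _stage("cluster"):
        cluster_seed = int(child_rng(config.seed, "cluster").integers(2**31))
        model, dtraj = km.cluster_kmeans(projected, config.k, config.max_iterations,
                                         seed=cluster_seed)

    with _stage("msm"):
        its = km.implied_timescales(dtraj, config.lags,
                                    frame_interval=config.frame_interval)
        counts = km.count_transitions(dtraj, config.lag)
        markov = km.estimate_reversible_msm(counts,
                                            frame_interval=config.frame_interval)
        n_dropped = counts.n_states - markov.n_states
        if n_dropped:
            log.info("dropped %d microstates outside the largest connected set",
                     n_dropped)

    with _stage("pcca"):
        decomposition = km.pcca(markov, config.n_macrostates)

    with _stage("validate-and-report"):
        ck_seed = int(child_rng(config.seed, "bootstrap").integers(2**31))
        ck = km.ck_test(dtraj, markov, decomposition, steps=config.ck_steps,
                        n_bootstrap=config.ck_bootstrap, seed=ck_seed)
        composition = km.macrostate_composition(decomposition, dtraj)
        mfpts = km.mfpt_matrix(markov, decomposition)
        mfpts_ns = mfpts * markov.lag_physical / 1000.0  # steps -> ns
        reps = km.representative_frames(decomposition, dtraj, projected, model,
                                        restrict_to_dominant_label=True)

    report.tables.update(
        implied_timescales=its.table,
        ck_test=ck.table,
        macrostate_composition=composition,
        mfpt_steps=mfpts,
        mfpt_ns=mfpts_ns,
        representative_frames=reps.set_index("macrostate"),
    )
    report.arrays.update(
        transition_matrix=markov.transition_matrix,
        stationary_distribution=markov.stationary_distribution,
        discrete_trajectory=dtraj.labels,
        memberships=decomposition.memberships,
    )
    report.objects.update(
        transform=transform, cluster_model=model, dtraj=dtraj, msm=markov,
        decomposition=decomposition, ck=ck, projected=projected,
    )
    if save:
        report.save(Path(config.output_dir) / "msm")
    return report


def run_network_pipeline(
    config: AnalysisConfig,
    ensembles: EnsembleSet | None = None,
    label: str | None = None,
    save: bool = True,
) -> AnalysisReport:
    """Superpose -> GCCM -> contact network -> Girvan-Newman communities ->
    inter-community flow -> optimal/suboptimal paths for all source-sink
    pairs.  Unreachable sinks yield explicit 'no path' rows; the run still
    completes."""
    if ensembles is None:
        ensembles = config.load_ensembles()
    report = AnalysisReport(config=config)
    trajs = ensembles.by_label(label) if label else ensembles.trajectories
    if len(trajs) != 1:
        raise ValueError("network pipeline expects exactly one trajectory; "
                         "pass label= to select an ensemble")
    traj = trajs[0]

    with _stage("gccm"):
        disp = gc.superpose_and_center(traj, superpose=config.superpose)
        corr = gc.generalized_correlation(disp, estimator=config.gccm_estimator,
                                          k=config.knn_k)
        if corr.failed_pairs:
            log.warning("GCCM estimator failed on %d pairs", len(corr.failed_pairs))

    with _stage("network"):
        # bead models carry only C-alphas; fall back to C-alpha contacts there
        mode = (config.contact_mode
                if traj.topology.n_atoms > traj.topology.n_residues else "calpha")
        net = nw.build_network(
            traj, corr, cutoff=config.cutoff, persistence=config.persistence,
            neighbor_exclusion=config.neighbor_exclusion,
            contact_mode=mode, gc_floor=config.gc_floor,
        )
        if net.dropped_pairs:
            log.info("dropped %d edges at the GC floor", len(net.dropped_pairs))

    with _stage("communities"):
        partition = nw.girvan_newman(net)
        flow = nw.intercommunity_flow(net, partition)

    try:
        sources, sinks = nw.default_endpoints(
            traj.topology, config.source_residue, config.sink_residues
        )
    except KeyError as exc:
        raise RuntimeError(f"pipeline stage 'endpoints' failed: {exc}") from None
    dist = nw._floyd_warshall(net)
    rows = []
    path_sets = {}
    for s in sources:
        for t in sinks:
            ps = nw.suboptimal_paths(net, s, t, config.subopt_tolerance, dist=dist)
            path_sets[(s, t)] = ps
            if ps.reachable:
                rows.append((s, t, ps.optimal_weight,
                             "-".join(map(str, ps.optimal_path)),
                             len(ps.paths), ps.truncated))
            else:
                rows.append((s, t, np.inf, "no path", 0, False))
    paths_table = pd.DataFrame(
        rows, columns=["source", "sink", "optimal_weight", "optimal_path",
                       "n_suboptimal", "truncated"],
    )

    report.tables.update(
        edges=net.to_edge_dataframe(partition),
        intercommunity_flow=flow,
        paths=paths_table,
        communities=pd.DataFrame(
            {"node": np.arange(net.n_nodes), "community": partition.labels,
             "tag": net.node_tags or [""] * net.n_nodes}
        ).set_index("node"),
    )
    report.arrays.update(gccm=corr.values)
    report.objects.update(
        displacements=disp, correlation=corr, network=net,
        partition=partition, path_sets=path_sets, label=traj.ensemble_label,
    )
    if save:
        report.save(Path(config.output_dir) / f"network-{traj.ensemble_label or 'run'}")
    return report


# ---------------------------------------------------------------------------
# ensemble comparison


def variation_of_information(a: Sequence[int], b: Sequence[int]) -> float:
    """Variation of information between two partitions (nats): a metric,
    VI = H(a) + H(b) - 2 I(a; b); 0 iff the partitions coincide."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size != b.size:
        raise ValueError("partitions must label the same nodes")
    n = a.size

    def entropy(x):
        _, cnt = np.unique(x, return_counts=True)
        p = cnt / n
        return float(-(p * np.log(p)).sum())

    mi = 0.0
    for la in np.unique(a):
        for lb in np.unique(b):
            pab = ((a == la) & (b == lb)).mean()
            if pab > 0:
                mi += pab * np.log(pab / ((a == la).mean() * (b == lb).mean()))
    return entropy(a) + entropy(b) - 2.0 * mi


def compare_ensembles(report_a: AnalysisReport, report_b: AnalysisReport) -> dict:
    """Difference summary between two network reports over one topology:
    GC difference matrix, per-block (intra/inter-monomer) mean GC, community
    counts and the variation-of-information partition distance."""
    gc_a = report_a.arrays["gccm"]
    gc_b = report_b.arrays["gccm"]
    if gc_a.shape != gc_b.shape:
        raise ValueError("reports cover different topologies")
    net_a: nw.DynamicNetwork = report_a.objects["network"]
    tags = np.array(net_a.node_tags)
    diff = gc_b - gc_a
    off = ~np.eye(gc_a.shape[0], dtype=bool)
    intra = (tags[:, None] == tags[None, :]) & off
    inter = (tags[:, None] != tags[None, :])
    part_a: nw.CommunityPartition = report_a.objects["partition"]
    part_b: nw.CommunityPartition = report_b.objects["partition"]
    return {
        "gc_difference": diff,
        "mean_gc": {
            "a": {"intra_monomer": float(gc_a[intra].mean()),
                  "inter_monomer": float(gc_a[inter].mean())},
            "b": {"intra_monomer": float(gc_b[intra].mean()),
                  "inter_monomer": float(gc_b[inter].mean())},
        },
        "n_communities": {"a": part_a.n_communities, "b": part_b.n_communities},
        "variation_of_information": variation_of_information(part_a.labels,
                                                             part_b.labels),
    }
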