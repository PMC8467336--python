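"""Topology and coordinate-trajectory I/O.

Containers for residue-level topologies and labelled coordinate trajectories,
plus readers/writers for PDB, DCD, XTC and a plain-text frame table.  Every
residue is anchored at its C-alpha atom (the node definition used by the
correlation-network stage), chain identifiers double as monomer tags, and all
coordinates are stored in Angstrom with the frame interval in picoseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Residue",
    "Topology",
    "Trajectory",
    "EnsembleSet",
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_trajectory",
]

_TEXT_SUFFIXES = {".txt", ".dat", ".tsv"}


@dataclass(frozen=True)
class Residue:
    """One residue: author-facing index, name, and chain/monomer tag."""

    index: int
    name: str
    chain: str


@dataclass
class Topology:
    """Residue-level topology with exactly one C-alpha atom per residue.

    Parameters
    ----------
    residues
        Ordered residues with strictly increasing per-chain indices.
    atom_names
        One name per atom, in file order.
    atom_residue
        Atom -> residue position (0-based position into ``residues``).
    calpha_index
        Residue position -> atom offset of its C-alpha.
    """

    residues: list[Residue]
    atom_names: list[str]
    atom_residue: np.ndarray
    calpha_index: np.ndarray

    def __post_init__(self) -> None:
        self.atom_residue = np.asarray(self.atom_residue, dtype=np.intp)
        self.calpha_index = np.asarray(self.calpha_index, dtype=np.intp)
        if len(self.atom_names) != self.atom_residue.size:
            raise ValueError("atom_names and atom_residue lengths differ")
        if self.calpha_index.size != len(self.residues):
            raise ValueError("need exactly one C-alpha per residue")
        for pos, res in enumerate(self.residues):
            ca = self.calpha_index[pos]
            if not (0 <= ca < self.n_atoms) or self.atom_residue[ca] != pos:
                raise ValueError(f"C-alpha of residue {res.index} ({res.name}) invalid")
        # residue indices strictly increasing within each chain
        seen: dict[str, int] = {}
        for res in self.residues:
            if res.chain in seen and res.index <= seen[res.chain]:
                raise ValueError(
                    f"residue indices not strictly increasing in chain {res.chain!r}"
                )
            seen[res.chain] = res.index

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for res in self.residues:
            if res.chain not in out:
                out.append(res.chain)
        return out

    def atoms_of_residue(self, pos: int) -> np.ndarray:
        return np.flatnonzero(self.atom_residue == pos)

    def residue_position(self, index: int, chain: str | None = None) -> int:
        """Topology position of the residue with author index ``index``."""
        for pos, res in enumerate(self.residues):
            if res.index == index and (chain is None or res.chain == chain):
                return pos
        lo = min(r.index for r in self.residues)
        hi = max(r.index for r in self.residues)
        raise KeyError(
            f"residue {index} (chain {chain!r}) not in topology; available range {lo}..{hi}"
        )


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates (Angstrom) over a fixed topology."""

    topology: Topology
    xyz: np.ndarray
    frame_interval: float  # ps
    ensemble_label: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError("xyz must have shape (frames, atoms, 3)")
        if self.xyz.shape[0] == 0:
            raise ValueError("trajectory contains zero frames")
        if self.xyz.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"atom count {self.xyz.shape[1]} does not match topology "
                f"({self.topology.n_atoms})"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive (ps)")
        if not np.isfinite(self.xyz).all():
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    def calpha_xyz(self) -> np.ndarray:
        """Frames x residues x 3 view of the C-alpha coordinates."""
        return self.xyz[:, self.topology.calpha_index, :]

    def with_label(self, label: str) -> "Trajectory":
        return replace(self, ensemble_label=label)


@dataclass
class EnsembleSet:
    """Trajectories grouped by ensemble label over one shared topology."""

    trajectories: list[Trajectory] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise ValueError("EnsembleSet needs at least one trajectory")
        top = self.trajectories[0].topology
        for traj in self.trajectories:
            if not traj.ensemble_label:
                raise ValueError("every trajectory needs a non-empty ensemble label")
            if traj.topology is not top:
                raise ValueError("all trajectories must share one topology")

    @property
    def topology(self) -> Topology:
        return self.trajectories[0].topology

    @property
    def labels(self) -> list[str]:
        out: list[str] = []
        for traj in self.trajectories:
            if traj.ensemble_label not in out:
                out.append(traj.ensemble_label)
        return out

    def by_label(self, label: str) -> list[Trajectory]:
        return [t for t in self.trajectories if t.ensemble_label == label]


# ---------------------------------------------------------------------------
# topology I/O


def read_topology(path: str | Path) -> Topology:
    """Read a topology from a PDB file or the plain-text topology table.

    Raises a :class:`ValueError` naming the residue if any residue lacks a
    C-alpha atom.
    """
    path = Path(path)
    if path.suffix.lower() in _TEXT_SUFFIXES:
        return _read_topology_text(path)
    return _read_topology_pdb(path)


def _read_topology_pdb(path: Path) -> Topology:
    import mdtraj as md

    try:
        mtop = md.load_topology(str(path))
    except Exception as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"could not parse PDB topology {path}: {exc}") from exc
    residues: list[Residue] = []
    atom_names: list[str] = []
    atom_residue: list[int] = []
    calpha: list[int] = []
    for pos, res in enumerate(mtop.residues):
        chain = res.chain.chain_id or chr(ord("A") + res.chain.index)
        residues.append(Residue(index=res.resSeq, name=res.name, chain=chain))
        ca = None
        for atom in res.atoms:
            if atom.name == "CA":
                ca = len(atom_names)
            atom_names.append(atom.name)
            atom_residue.append(pos)
        if ca is None:
            raise ValueError(
                f"residue {res.name}{res.resSeq} (chain {chain}) has no CA atom"
            )
        calpha.append(ca)
    return Topology(residues, atom_names, np.array(atom_residue), np.array(calpha))


def _read_topology_text(path: Path) -> Topology:
    """Plain-text dialect: header ``n_residues``, then ``index name chain`` rows.

    Each residue carries a single CA atom; intended for bead models.
    """
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    try:
        n = int(lines[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}:1: expected residue count header") from exc
    residues: list[Residue] = []
    for lineno, ln in enumerate(lines[1 : n + 1], start=2):
        parts = ln.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 'index name chain'")
        try:
            idx = int(parts[0])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad residue index {parts[0]!r}") from exc
        residues.append(Residue(index=idx, name=parts[1], chain=parts[2]))
    if len(residues) != n:
        raise ValueError(f"{path}: header promised {n} residues, found {len(residues)}")
    rng = np.arange(n)
    return Topology(residues, ["CA"] * n, rng, rng)


def write_topology(topology: Topology, path: str | Path) -> None:
    """Write the plain-text topology table (one CA bead per residue)."""
    path = Path(path)
    if any(n != "CA" for n in topology.atom_names):
        raise ValueError("plain-text topology supports CA-only bead models")
    lines = [str(topology.n_residues)]
    lines += [f"{r.index} {r.name} {r.chain}" for r in topology.residues]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# trajectory I/O


def read_trajectory(
    paths: Sequence[str | Path] | str | Path,
    topology: Topology,
    frame_interval: float,
    ensemble_label: str = "",
) -> Trajectory:
    """Read and concatenate coordinate files (DCD, XTC, multi-model PDB, text).

    Frames are concatenated in the order the files are given; coordinates are
    returned in Angstrom.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if not paths:
        raise ValueError("no trajectory files given")
    blocks = [_read_frames(Path(p), topology) for p in paths]
    xyz = np.concatenate(blocks, axis=0)
    if xyz.shape[0] == 0:
        raise ValueError("trajectory contains zero frames")
    return Trajectory(
        topology=topology,
        xyz=xyz,
        frame_interval=frame_interval,
        ensemble_label=ensemble_label,
        source=";".join(str(p) for p in paths),
    )


def _read_frames(path: Path, topology: Topology) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in _TEXT_SUFFIXES:
        xyz = _read_frames_text(path)
    elif suffix == ".dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(path)) as fh:
            xyz = fh.read()[0].astype(np.float64)  # DCD native unit: Angstrom
    elif suffix == ".xtc":
        from mdtraj.formats import XTCTrajectoryFile

        with XTCTrajectoryFile(str(path)) as fh:
            xyz = fh.read()[0].astype(np.float64) * 10.0  # nm -> Angstrom
    elif suffix == ".pdb":
        import mdtraj as md

        xyz = md.load(str(path)).xyz.astype(np.float64) * 10.0  # nm -> Angstrom
    else:
        raise ValueError(f"unsupported trajectory format {suffix!r}")
    if xyz.shape[0] == 0:
        raise ValueError(f"{path}: zero frames")
    if xyz.shape[1] != topology.n_atoms:
        raise ValueError(
            f"{path}: atom count {xyz.shape[1]} does not match topology "
            f"({topology.n_atoms})"
        )
    return xyz


def _read_frames_text(path: Path) -> np.ndarray:
    """Plain-text frame table: header ``n_atoms frame_interval``, then one
    whitespace-delimited ``x y z`` row (Angstrom) per atom per frame."""
    with path.open() as fh:
        header = fh.readline().split()
        if len(header) < 2:
            raise ValueError(f"{path}:1: expected 'n_atoms frame_interval' header")
        n_atoms = int(header[0])
        data = np.loadtxt(fh, dtype=np.float64, ndmin=2)
    if data.size == 0 or data.shape[0] % n_atoms:
        raise ValueError(f"{path}: row count not a multiple of {n_atoms} atoms")
    return data.reshape(-1, n_atoms, 3)


def write_trajectory(traj: Trajectory, path: str | Path, format: str | None = None) -> None:
    """Write a trajectory as ``dcd``, ``xtc``, ``pdb`` or plain ``text``.

    ``format=None`` infers the format from the file suffix.
    """
    path = Path(path)
    if traj.n_frames == 0:
        raise ValueError("refusing to write an empty trajectory")
    if format is None:
        suffix = path.suffix.lower()
        format = "text" if suffix in _TEXT_SUFFIXES else suffix.lstrip(".")
    format = format.lower()
    if format in {"text", "txt", "plain-text"}:
        _write_frames_text(traj, path)
    elif format == "dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(path), "w") as fh:
            fh.write(traj.xyz.astype(np.float32))
    elif format == "xtc":
        from mdtraj.formats import XTCTrajectoryFile

        with XTCTrajectoryFile(str(path), "w") as fh:
            fh.write(traj.xyz.astype(np.float32) / 10.0)
    elif format == "pdb":
        import mdtraj as md

        mdtrj = md.Trajectory(
            xyz=traj.xyz / 10.0, topology=_to_mdtraj_topology(traj.topology)
        )
        mdtrj.save_pdb(str(path))
    else:
        raise ValueError(f"unsupported trajectory format {format!r}")


def _write_frames_text(traj: Trajectory, path: Path) -> None:
    with path.open("w") as fh:
        fh.write(f"{traj.topology.n_atoms} {traj.frame_interval:.6g}\n")
        flat = traj.xyz.reshape(-1, 3)
        np.savetxt(fh, flat, fmt="%.6f")


def _to_mdtraj_topology(topology: Topology):
    import mdtraj as md
    from mdtraj.core import element

    mtop = md.Topology()
    chains: dict[str, object] = {}
    for pos, res in enumerate(topology.residues):
        if res.chain not in chains:
            chains[res.chain] = mtop.add_chain(chain_id=res.chain)
        mres = mtop.add_residue(res.name[:3] or "BEA", chains[res.chain], resSeq=res.index)
        for atom_idx in topology.atoms_of_residue(pos):
            name = topology.atom_names[atom_idx]
            elem = element.carbon if name.startswith("C") else element.virtual
            mtop.add_atom(name, elem, mres)
    return mtop


def concatenate_labels(trajectories: Iterable[Trajectory]) -> EnsembleSet:
    """Convenience: bundle labelled trajectories into an :class:`EnsembleSet`."""
    return EnsembleSet(list(trajectories))
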