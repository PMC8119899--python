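"""Core data model: atoms, topologies, trajectories, selections, replicas.

The in-memory containers here are deliberately small and explicit: an
ordered atom table with chemistry annotations (rings, donors, acceptors,
anions), coordinate frames at a uniform sampling interval, and the replica
pooling convention used throughout the downstream analyses (half-open
analysis windows, replica order then time order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import templates as _tmpl

__all__ = [
    "AtomRecord",
    "RingSpec",
    "Topology",
    "Trajectory",
    "Selection",
    "ReplicaSet",
    "PooledFrames",
    "EmptySelectionWarning",
]


class EmptySelectionWarning(UserWarning):
    """A selection resolved to zero atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the system.

    ``subunit`` labels one of the five chains for the pentamer ("A".."E");
    lipids, waters and ions keep whatever chain label the input gives them.
    ``molecule_class`` partitions the system into the categories the
    analyses distinguish: protein, POPC, POPE, cholesterol, water, ion,
    ligand.
    """

    atom_id: int
    name: str
    element: str
    residue_seq: int
    residue_name: str
    subunit: str
    molecule_class: str
    mass: float


@dataclass(frozen=True)
class RingSpec:
    """One aromatic ring of one residue.

    Tryptophan has two rings (``ring_index`` 0 and 1); Phe/Tyr/His have one.
    ``atom_indices`` index into the owning topology's atom table.
    """

    residue_seq: int
    residue_name: str
    subunit: str
    ring_index: int
    ring_atom_names: tuple[str, ...]
    atom_indices: tuple[int, ...]


MOLECULE_CLASSES = ("protein", "POPC", "POPE", "cholesterol", "water", "ion", "ligand")


class Topology:
    """Ordered atom collection with chemistry annotations.

    Parameters
    ----------
    atoms
        Ordered list of :class:`AtomRecord`; ``atom_id`` must be unique.
    annotate
        If true (default), rings, hydrogen-bond donors/acceptors and anionic
        atoms are derived from the residue template table.
    templates
        Template table (see :mod:`helixmd.templates`); defaults to the
        built-in one.
    """

    def __init__(self, atoms, annotate=True, templates=None):
        self.atoms: list[AtomRecord] = list(atoms)
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise ValueError("atom_id values must be unique within a Topology")
        for a in self.atoms:
            if a.molecule_class not in MOLECULE_CLASSES:
                raise ValueError(
                    f"atom {a.atom_id}: unknown molecule_class {a.molecule_class!r}"
                )
        self.templates = templates if templates is not None else _tmpl.default_templates()

        # vectorized columns for selection resolution
        self.names = np.array([a.name for a in self.atoms])
        self.elements = np.array([a.element for a in self.atoms])
        self.residue_seqs = np.array([a.residue_seq for a in self.atoms])
        self.residue_names = np.array([a.residue_name for a in self.atoms])
        self.subunits = np.array([a.subunit for a in self.atoms])
        self.molecule_classes = np.array([a.molecule_class for a in self.atoms])
        self.masses = np.array([a.mass for a in self.atoms])

        self.rings: list[RingSpec] = []
        self.hbond_donors: list[tuple[int, int]] = []  # (heavy atom idx, H idx)
        self.hbond_acceptors: list[int] = []
        self.anion_atoms: list[int] = []
        if annotate:
            self._annotate()

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def protein_subunits(self) -> list[str]:
        """Sorted subunit labels of protein atoms."""
        mask = self.molecule_classes == "protein"
        return sorted(set(self.subunits[mask]))

    # -- residue iteration -------------------------------------------------

    def iter_residues(self):
        """Yield (residue key, atom index array) in topology order.

        The key is (subunit, residue_seq, residue_name); atoms of one
        residue are assumed contiguous, as in every standard format.
        """
        keys = list(zip(self.subunits, self.residue_seqs, self.residue_names))
        start = 0
        for i in range(1, self.n_atoms + 1):
            if i == self.n_atoms or keys[i] != keys[start]:
                yield keys[start], np.arange(start, i)
                start = i

    def residue_atom_indices(self, subunit, residue_seq) -> np.ndarray:
        mask = (self.subunits == subunit) & (self.residue_seqs == residue_seq)
        return np.flatnonzero(mask)

    # -- chemistry annotation ----------------------------------------------

    def _annotate(self):
        t = self.templates
        name_of = self.names
        for (subunit, rseq, rname), idx in self.iter_residues():
            local = {name_of[i]: i for i in idx}
            # rings
            for ring_i, ring_names in enumerate(t["rings"].get(rname, [])):
                if all(n in local for n in ring_names):
                    self.rings.append(
                        RingSpec(
                            residue_seq=int(rseq),
                            residue_name=str(rname),
                            subunit=str(subunit),
                            ring_index=ring_i,
                            ring_atom_names=tuple(ring_names),
                            atom_indices=tuple(int(local[n]) for n in ring_names),
                        )
                    )
            is_protein = self.molecule_classes[idx[0]] == "protein"
            # donors: backbone N-H plus side-chain table
            donor_map: dict[str, list[str]] = {}
            if is_protein:
                heavy, hyds = _tmpl.BACKBONE_DONOR
                donor_map[heavy] = list(hyds)
            for heavy, hyds in t["sidechain_donors"].get(rname, {}).items():
                donor_map.setdefault(heavy, []).extend(hyds)
            for heavy, hyds in donor_map.items():
                if heavy not in local:
                    continue
                for h in hyds:
                    if h in local:
                        self.hbond_donors.append((int(local[heavy]), int(local[h])))
            # acceptors: backbone carbonyl O plus side-chain table
            acceptors = list(t["sidechain_acceptors"].get(rname, []))
            if is_protein:
                acceptors.append(_tmpl.BACKBONE_ACCEPTOR)
            for n in acceptors:
                if n in local:
                    self.hbond_acceptors.append(int(local[n]))
            # anions
            for n in t["anions"].get(rname, []):
                if n in local:
                    self.anion_atoms.append(int(local[n]))

    def rings_of(self, subunit, residue_seq) -> list[RingSpec]:
        return [
            r
            for r in self.rings
            if r.subunit == subunit and r.residue_seq == residue_seq
        ]


@dataclass
class Selection:
    """Declarative atom predicate resolvable against a topology.

    Any combination of criteria may be given; atoms must satisfy all of
    them (conjunction).  ``residue_seq`` accepts an int, an iterable of
    ints, or an inclusive ``(lo, hi)`` range tuple via ``residue_range``.
    Resolution is deterministic (topology order) and idempotent.
    """

    residue_seq: int | list[int] | None = None
    residue_range: tuple[int, int] | None = None
    residue_name: str | list[str] | None = None
    atom_name: str | list[str] | None = None
    subunit: str | list[str] | None = None
    molecule_class: str | list[str] | None = None

    @staticmethod
    def _match(column, value):
        if value is None:
            return np.ones(len(column), dtype=bool)
        if isinstance(value, (str, int, np.integer)):
            return column == value
        return np.isin(column, list(value))

    def resolve(self, topology: Topology) -> np.ndarray:
        """Atom indices (topology order) matching the predicate."""
        mask = self._match(topology.residue_seqs, self.residue_seq)
        if self.residue_range is not None:
            lo, hi = self.residue_range
            mask &= (topology.residue_seqs >= lo) & (topology.residue_seqs <= hi)
        mask &= self._match(topology.residue_names, self.residue_name)
        mask &= self._match(topology.names, self.atom_name)
        mask &= self._match(topology.subunits, self.subunit)
        mask &= self._match(topology.molecule_classes, self.molecule_class)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            warnings.warn(f"selection {self!r} resolved to zero atoms", EmptySelectionWarning)
        return idx


class Trajectory:
    """Coordinate frames over a topology at a uniform sampling interval.

    ``frame_times`` are in ps, strictly increasing with constant spacing
    (default convention 50 ps); ``coordinates`` is (n_frames, n_atoms, 3)
    in Å with z the membrane normal / channel axis as stored in the input.
    """

    def __init__(self, topology: Topology, coordinates, frame_times=None, dt_ps: float = 50.0):
        self.topology = topology
        coords = np.asarray(coordinates, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if coords.shape[1] != topology.n_atoms:
            raise ValueError(
                f"trajectory has {coords.shape[1]} atoms but topology has "
                f"{topology.n_atoms}"
            )
        self.coordinates = coords
        if frame_times is None:
            frame_times = np.arange(coords.shape[0]) * float(dt_ps)
        self.frame_times = np.asarray(frame_times, dtype=float)
        if self.frame_times.shape[0] != coords.shape[0]:
            raise ValueError("frame_times length must equal the number of frames")
        if self.n_frames > 1:
            diffs = np.diff(self.frame_times)
            if np.any(diffs <= 0):
                raise ValueError("frame_times must be strictly increasing")
            if not np.allclose(diffs, diffs[0], rtol=1e-6, atol=1e-6):
                raise ValueError("frame_times must be uniformly spaced")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def dt_ps(self) -> float:
        if self.n_frames > 1:
            return float(self.frame_times[1] - self.frame_times[0])
        return 50.0

    @property
    def span_ns(self) -> float:
        return float(self.frame_times[-1]) / 1000.0

    def window(self, t_start_ns: float, t_end_ns: float) -> "Trajectory":
        """Sub-trajectory with t_start ≤ t < t_end (half-open, ns)."""
        t = self.frame_times / 1000.0
        mask = (t >= t_start_ns) & (t < t_end_ns)
        return Trajectory(
            self.topology, self.coordinates[mask], frame_times=self.frame_times[mask]
        )


@dataclass
class PooledFrames:
    """Frames pooled across replicas, tagged with their origin.

    Frames keep replica order then time order; ``replica_ids`` and
    ``frame_times`` run parallel to the first coordinate axis.
    """

    topology: Topology
    coordinates: np.ndarray
    replica_ids: np.ndarray
    frame_times: np.ndarray
    dt_ps: float

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def replicas(self) -> list[str]:
        seen: list[str] = []
        for r in self.replica_ids:
            if r not in seen:
                seen.append(str(r))
        return seen

    def replica_frames(self, replica: str) -> np.ndarray:
        return self.coordinates[self.replica_ids == replica]


class ReplicaSet:
    """Named replica trajectories with per-replica analysis windows.

    Realizes the pooling convention of two 250 ns replicas analysed over
    their 50–250 ns windows: frames with t_start ≤ t < t_end are included
    (half-open), so each 200 ns window at 50 ps sampling contributes
    exactly 4000 frames.
    """

    def __init__(self, replicas: dict[str, Trajectory], analysis_window=(50.0, 250.0)):
        if not replicas:
            raise ValueError("ReplicaSet requires at least one replica")
        self.replicas = dict(replicas)
        if isinstance(analysis_window, dict):
            self.windows = {k: tuple(map(float, v)) for k, v in analysis_window.items()}
        else:
            w = tuple(map(float, analysis_window))
            self.windows = {k: w for k in self.replicas}
        tops = {id(t.topology) for t in self.replicas.values()}
        if len(tops) != 1:
            raise ValueError("all replicas must share one topology")
        for name, traj in self.replicas.items():
            t0, t1 = self.windows[name]
            if t0 < 0 or t1 > traj.span_ns + traj.dt_ps / 1000.0 or t0 > t1:
                raise ValueError(
                    f"window ({t0}, {t1}) ns outside replica {name!r} span "
                    f"[0, {traj.span_ns}] ns"
                )

    @property
    def topology(self) -> Topology:
        return next(iter(self.replicas.values())).topology


def pool_replicas(rs: ReplicaSet) -> PooledFrames:
    """Concatenate each replica's analysis-window frames.

    Order is replica order (insertion order of the mapping) then time
    order.  The half-open window convention [t_start, t_end) is applied,
    so 50–250 ns of two 250 ns replicas at 50 ps pools exactly 8000
    frames.  An empty pool is permitted but flagged with a warning.
    """
    chunks, rids, times = [], [], []
    dt = None
    for name, traj in rs.replicas.items():
        t0, t1 = rs.windows[name]
        sub = traj.window(t0, t1)
        dt = traj.dt_ps if dt is None else dt
        chunks.append(sub.coordinates)
        rids.append(np.full(sub.n_frames, name))
        times.append(sub.frame_times)
    coords = (
        np.concatenate(chunks)
        if chunks
        else np.empty((0, rs.topology.n_atoms, 3))
    )
    if coords.shape[0] == 0:
        warnings.warn("pooled frame collection is empty", UserWarning)
    return PooledFrames(
        topology=rs.topology,
        coordinates=coords,
        replica_ids=np.concatenate(rids) if rids else np.empty(0, dtype="U8"),
        frame_times=np.concatenate(times) if times else np.empty(0),
        dt_ps=float(dt if dt is not None else 50.0),
    )
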