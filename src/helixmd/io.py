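"""Readers and writers for the standard structure/trajectory formats.

MDAnalysis does the format-level parsing (PDB, PSF, DCD, XTC); this module
converts between its Universe and the package's annotated
:class:`~helixmd.model.Topology` / :class:`~helixmd.model.Trajectory`
containers, and exports frame collections and selections as CSV tables.
"""

from __future__ import annotations

import warnings

import MDAnalysis as mda
import numpy as np
import pandas as pd

from . import templates as _tmpl
from .model import AtomRecord, PooledFrames, Topology, Trajectory

__all__ = [
    "load_topology",
    "load_trajectory",
    "write_trajectory_pdb",
    "topology_to_universe",
    "frames_to_csv",
    "selection_to_csv",
]

_SUBUNIT_LABELS = ["A", "B", "C", "D", "E"]


def _molecule_class(residue_name: str, table: dict[str, str]) -> str:
    cls = table.get(residue_name)
    if cls is None:
        warnings.warn(
            f"unknown residue name {residue_name!r}; classifying as ligand",
            UserWarning,
        )
        return "ligand"
    return cls


def _assign_subunits(resnames, resids, chain_ids, mol_classes):
    """Subunit label per atom.

    Protein atoms use the PDB chain ID when present; otherwise protein
    residues are split into five contiguous equal-length blocks (the
    pentamer has five identical chains).  Non-protein atoms keep their
    chain label (or the empty string).
    """
    n = len(resnames)
    out = np.array([str(c) if c else "" for c in chain_ids], dtype="U8")
    prot = np.array([c == "protein" for c in mol_classes])
    if not prot.any():
        return out
    have_chains = all(bool(c.strip()) for c in out[prot])
    if have_chains:
        return out
    # contiguous residue blocks of equal length
    keys = [(resids[i], resnames[i]) for i in range(n)]
    res_order: list[int] = []  # residue start indices among protein atoms
    prot_idx = np.flatnonzero(prot)
    prev = None
    res_of_atom = np.zeros(n, dtype=int)
    count = -1
    for i in prot_idx:
        if keys[i] != prev:
            count += 1
            prev = keys[i]
            res_order.append(i)
        res_of_atom[i] = count
    n_res = count + 1
    if n_res % 5 == 0:
        per = n_res // 5
        for i in prot_idx:
            out[i] = _SUBUNIT_LABELS[res_of_atom[i] // per]
    else:
        out[prot] = _SUBUNIT_LABELS[0]
    return out


def universe_to_topology(u: mda.Universe, templates=None) -> Topology:
    """Build an annotated Topology from an MDAnalysis Universe."""
    tbl = templates if templates is not None else _tmpl.default_templates()
    atoms = u.atoms
    resnames = [str(r) for r in atoms.resnames]
    resids = [int(r) for r in atoms.resids]
    try:
        chain_ids = [str(c) for c in atoms.chainIDs]
    except (mda.exceptions.NoDataError, AttributeError):
        try:
            chain_ids = [str(s) for s in atoms.segids]
        except (mda.exceptions.NoDataError, AttributeError):
            chain_ids = [""] * len(atoms)
    mol_classes = [_molecule_class(r, tbl["molecule_classes"]) for r in resnames]
    subunits = _assign_subunits(resnames, resids, chain_ids, mol_classes)
    try:
        elements = [str(e) for e in atoms.elements]
    except (mda.exceptions.NoDataError, AttributeError):
        elements = [_tmpl.guess_element(n) for n in atoms.names]
    try:
        masses = [float(m) for m in atoms.masses]
        if not any(m > 0 for m in masses):
            raise ValueError
    except (mda.exceptions.NoDataError, AttributeError, ValueError):
        masses = [_tmpl.element_mass(e) for e in elements]
    records = [
        AtomRecord(
            atom_id=i,
            name=str(atoms.names[i]),
            element=elements[i],
            residue_seq=resids[i],
            residue_name=resnames[i],
            subunit=str(subunits[i]),
            molecule_class=mol_classes[i],
            mass=masses[i],
        )
        for i in range(len(atoms))
    ]
    return Topology(records, templates=tbl)


def load_topology(path, fmt: str | None = None, templates=None) -> Topology:
    """Read a PDB or PSF file into an annotated Topology.

    ``fmt`` may be "PDB" or "PSF"; by default the extension decides.
    Rings, donors, acceptors and anionic atoms are annotated from the
    residue template table; unknown residue names are classified as
    ligand with a warning.
    """
    kwargs = {}
    if fmt is not None:
        kwargs["topology_format"] = fmt.upper()
    try:
        u = mda.Universe(str(path), **kwargs)
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise ValueError(f"could not parse topology file {path}: {exc}") from exc
    return universe_to_topology(u, templates=templates)


def load_trajectory(
    path,
    topology: Topology,
    fmt: str | None = None,
    dt_ps: float = 50.0,
    topology_path=None,
) -> Trajectory:
    """Read a DCD, XTC or multi-frame PDB trajectory over a Topology.

    Frame times come from the file when it stores them, else from the
    declared stride ``dt_ps`` (default 50 ps).  Raises if the frame atom
    count does not match the topology.
    """
    kwargs = {}
    if fmt is not None:
        kwargs["format"] = fmt.upper()
    if topology_path is not None:
        u = mda.Universe(str(topology_path), str(path), **kwargs)
    else:
        u = mda.Universe(str(path), **kwargs)
    n_file = len(u.atoms)
    if n_file != topology.n_atoms:
        raise ValueError(
            f"trajectory has {n_file} atoms but topology has {topology.n_atoms}"
        )
    coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    times = np.arange(coords.shape[0]) * float(dt_ps)
    return Trajectory(topology, coords, frame_times=times)


def topology_to_universe(topology: Topology) -> mda.Universe:
    """MDAnalysis Universe (no coordinates) mirroring a Topology."""
    res_keys = []
    res_index = np.empty(topology.n_atoms, dtype=int)
    for key, idx in topology.iter_residues():
        res_index[idx] = len(res_keys)
        res_keys.append(key)
    n_res = len(res_keys)
    u = mda.Universe.empty(
        n_atoms=topology.n_atoms,
        n_residues=n_res,
        atom_resindex=res_index,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=False,
    )
    u.add_TopologyAttr("names", list(topology.names))
    u.add_TopologyAttr("elements", list(topology.elements))
    u.add_TopologyAttr("masses", list(topology.masses))
    u.add_TopologyAttr("resids", [int(k[1]) for k in res_keys])
    u.add_TopologyAttr("resnames", [str(k[2]) for k in res_keys])
    u.add_TopologyAttr("chainIDs", [str(s) if s else "X" for s in topology.subunits])
    u.add_TopologyAttr("segids", ["SYS"])
    return u


def write_trajectory_pdb(traj: Trajectory, path) -> None:
    """Write all frames as a multi-frame (MODEL/ENDMDL) PDB file."""
    u = topology_to_universe(traj.topology)
    u.load_new(traj.coordinates, order="fac")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDAnalysis warns about absent occupancies
        with mda.Writer(str(path), multiframe=True, n_atoms=traj.topology.n_atoms) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def frames_to_csv(frames: PooledFrames, path) -> pd.DataFrame:
    """Index table of pooled frames (replica, time) as CSV."""
    df = pd.DataFrame(
        {
            "frame": np.arange(frames.n_frames),
            "replica": frames.replica_ids,
            "time_ps": frames.frame_times,
        }
    )
    df.to_csv(path, index=False)
    return df


def selection_to_csv(topology: Topology, atom_indices, path) -> pd.DataFrame:
    """Resolved selection as a CSV atom-index table."""
    idx = np.asarray(atom_indices, dtype=int)
    df = pd.DataFrame(
        {
            "atom_id": idx,
            "name": topology.names[idx],
            "residue_seq": topology.residue_seqs[idx],
            "residue_name": topology.residue_names[idx],
            "subunit": topology.subunits[idx],
            "molecule_class": topology.molecule_classes[idx],
        }
    )
    df.to_csv(path, index=False)
    return df
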