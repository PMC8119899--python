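"""Synthetic fixtures with known ground truth.

Every analysis stage in this package is validated against data generated
here: toy pentamer topologies with idealized side-chain geometry,
Gaussian-fluctuation trajectories with prescribed per-residue amplitudes
and pairwise correlations, constructed hydrogen-bond and ring-pair
geometries at exact distances/angles, two-state lipid occupancy series
with chosen dwell-time laws, and noisy logistic concentration-response /
one-site saturation binding curves.

None of this mimics real protein mechanics, lipid diffusion physics or
membrane electrostatics; the point is exact, recoverable ground truth.
All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import AtomRecord, Topology, Trajectory
from .templates import element_mass

__all__ = [
    "FluctuationSpec",
    "OccupancySpec",
    "make_pentamer_topology",
    "make_bilayer_topology",
    "gen_fluctuation_traj",
    "gen_hbond_geometry",
    "gen_ring_pair",
    "gen_occupancy_series",
    "gen_lipid_proximity_traj",
    "gen_dose_response",
    "gen_saturation_binding",
]

_SUBUNITS = ["A", "B", "C", "D", "E"]


# ---------------------------------------------------------------------------
# specs

@dataclass
class FluctuationSpec:
    """Ground truth for a Gaussian-fluctuation trajectory.

    sigma : per-coordinate displacement SD in Å; a float (all residues) or
        a mapping residue_seq -> SD.
    subunit_sigma : optional mapping subunit label -> multiplicative scale
        on sigma (used to inject cross-subunit spread).
    correlations : (residue_i, residue_j, rho) targets with rho in [-1, 1];
        realized within each subunit.  The implied residue correlation
        matrix must be positive semi-definite.
    """

    sigma: float | dict[int, float] = 1.0
    subunit_sigma: dict[str, float] | None = None
    correlations: list[tuple[int, int, float]] = field(default_factory=list)
    n_frames: int = 1000
    seed: int = 0

    def validate(self):
        sigmas = (
            [self.sigma] if np.isscalar(self.sigma) else list(self.sigma.values())
        )
        if any(s < 0 for s in sigmas):
            raise ValueError("sigma must be >= 0")
        for i, j, rho in self.correlations:
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"correlation target rho={rho} outside [-1, 1]")

    def sigma_of(self, residue_seq: int) -> float:
        if np.isscalar(self.sigma):
            return float(self.sigma)
        return float(self.sigma.get(residue_seq, 0.0))


@dataclass
class OccupancySpec:
    """Ground truth for a two-state (bound/unbound) occupancy series.

    Dwell times alternate bound/unbound, drawn from the chosen law
    (exponential with the given mean, or fixed at exactly the mean).
    The series starts in the bound state.
    """

    tau_on_ns: float
    tau_off_ns: float
    law: str = "exponential"  # or "fixed"
    total_ns: float = 1000.0
    dt_ps: float = 50.0
    seed: int = 0

    def validate(self):
        if self.tau_on_ns <= 0 or self.tau_off_ns <= 0:
            raise ValueError("dwell-time means must be positive")
        if self.law not in ("exponential", "fixed"):
            raise ValueError(f"unknown dwell law {self.law!r}")
        dt_ns = self.dt_ps / 1000.0
        if dt_ns > min(self.tau_on_ns, self.tau_off_ns) / 10.0:
            warnings.warn(
                "sampling interval exceeds a tenth of the shortest dwell "
                "scale; discretization bias expected",
                UserWarning,
            )


# ---------------------------------------------------------------------------
# topology builders

def _rot_z(deg):
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ngon(center, n, circumradius, phase_deg=0.0):
    """Regular n-gon in the xy-plane at the given center."""
    ang = np.deg2rad(phase_deg + 360.0 * np.arange(n) / n)
    pts = np.zeros((n, 3))
    pts[:, 0] = circumradius * np.cos(ang)
    pts[:, 1] = circumradius * np.sin(ang)
    return pts + center


def _sidechain(resname, base):
    """Idealized side-chain atoms (name -> xyz) above a residue base point.

    Geometry is schematic but internally consistent: rings are exact
    regular polygons (1.39 Å C-C for six-membered rings), donor hydrogens
    sit 1.0 Å from their heavy atom.
    """
    atoms: dict[str, np.ndarray] = {}
    cb = base + np.array([0.0, 0.0, 1.5])
    if resname == "GLY":
        return atoms
    atoms["CB"] = cb
    if resname in ("PHE", "TYR"):
        cg_center = cb + np.array([0.0, 0.0, 2.4])
        ring = _ngon(cg_center, 6, 1.39, phase_deg=90.0)
        for name, pt in zip(["CG", "CD1", "CE1", "CZ", "CE2", "CD2"], ring):
            atoms[name] = pt
        if resname == "TYR":
            oh = atoms["CZ"] + np.array([0.0, 1.36, 0.0])
            atoms["OH"] = oh
            atoms["HH"] = oh + np.array([0.0, 0.95, 0.0])
    elif resname == "TRP":
        # planar indole: regular pentagon fused to a regular hexagon on
        # the CD2-CE2 edge, both in the z = cb_z + 2.4 plane
        pent_center = cb + np.array([0.0, 0.0, 2.4])
        rp = 1.39 / (2.0 * np.sin(np.pi / 5.0))
        pent = _ngon(pent_center, 5, rp, phase_deg=90.0)
        names5 = ["CG", "CD1", "NE1", "CE2", "CD2"]
        for name, pt in zip(names5, pent):
            atoms[name] = pt
        ce2, cd2 = atoms["CE2"], atoms["CD2"]
        edge = np.linalg.norm(ce2 - cd2)
        mid = 0.5 * (ce2 + cd2)
        outward = mid - pent_center
        outward /= np.linalg.norm(outward)
        hex_center = mid + outward * edge * np.sqrt(3.0) / 2.0
        # walk the hexagon from CE2 away from CD2
        def rot_about(p, center, deg):
            return center + _rot_z(deg) @ (p - center)
        step = 60.0 if np.linalg.norm(rot_about(ce2, hex_center, 60.0) - cd2) > 1e-6 else -60.0
        v = ce2
        for name in ["CZ2", "CH2", "CZ3", "CE3"]:
            v = rot_about(v, hex_center, step)
            atoms[name] = v
        atoms["HE1"] = atoms["NE1"] + np.array([0.0, 1.0, 0.0])
    elif resname == "ASP":
        cg = cb + np.array([0.0, 0.0, 1.5])
        atoms["CG"] = cg
        atoms["OD1"] = cg + np.array([1.1, 0.6, 0.0])
        atoms["OD2"] = cg + np.array([-1.1, 0.6, 0.0])
    elif resname == "LYS":
        chain = ["CG", "CD", "CE", "NZ"]
        pos = cb
        for name in chain:
            pos = pos + np.array([0.0, 0.0, 1.5])
            atoms[name] = pos
        nz = atoms["NZ"]
        for k, name in enumerate(["HZ1", "HZ2", "HZ3"]):
            ang = np.deg2rad(120.0 * k)
            atoms[name] = nz + np.array([np.cos(ang), np.sin(ang), 0.3]) / np.linalg.norm(
                [np.cos(ang), np.sin(ang), 0.3]
            )
    elif resname == "SER":
        og = cb + np.array([0.0, 0.0, 1.4])
        atoms["OG"] = og
        atoms["HG"] = og + np.array([0.0, 0.95, 0.0])
    return atoms


def make_pentamer_topology(
    n_res_per_subunit: int, motif: list[str], templates=None
) -> Topology:
    """Five identical subunits built from a repeating residue motif.

    Each residue carries backbone N, H, CA, C, O plus idealized side-chain
    atoms for TYR/TRP/PHE/ASP/LYS/SER (rings as exact regular polygons).
    Subunits sit on a circle of radius 25 Å in the xy-plane; residues stack
    along y within each subunit.  Reference coordinates are stored on the
    returned topology (``reference_coordinates``).
    """
    if n_res_per_subunit <= 0:
        raise ValueError("n_res_per_subunit must be positive (empty protein)")
    if not motif:
        raise ValueError("motif must contain at least one residue name")
    if n_res_per_subunit % len(motif) != 0:
        raise ValueError("motif length must divide n_res_per_subunit")

    records: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    atom_id = 0
    for s_i, sub in enumerate(_SUBUNITS):
        origin = 25.0 * np.array(
            [np.cos(2 * np.pi * s_i / 5), np.sin(2 * np.pi * s_i / 5), 0.0]
        )
        for r in range(n_res_per_subunit):
            resname = motif[r % len(motif)]
            rseq = r + 1
            base = origin + np.array([0.0, 8.0 * r, 0.0])
            placed: list[tuple[str, np.ndarray]] = [
                ("N", base + np.array([0.0, 0.0, 0.0])),
                ("H", base + np.array([-0.6, -0.8, 0.0])),
                ("CA", base + np.array([1.46, 0.0, 0.0])),
                ("C", base + np.array([2.0, 1.2, 0.0])),
                ("O", base + np.array([3.2, 1.35, 0.0])),
            ]
            side = _sidechain(resname, base + np.array([1.46, 0.0, 0.0]))
            placed.extend(side.items())
            for name, xyz in placed:
                el = "H" if name.startswith("H") else name[0]
                records.append(
                    AtomRecord(
                        atom_id=atom_id,
                        name=name,
                        element=el,
                        residue_seq=rseq,
                        residue_name=resname,
                        subunit=sub,
                        molecule_class="protein",
                        mass=element_mass(el),
                    )
                )
                coords.append(np.asarray(xyz, dtype=float))
                atom_id += 1
    top = Topology(records, templates=templates)
    top.reference_coordinates = np.array(coords)
    return top


_LIPID_ATOMS = {
    # minimal schematic lipids: head atom + short tail toward the midplane
    "POPC": ["P", "C2", "C3", "C4", "C5"],
    "POPE": ["P", "C2", "C3", "C4", "C5"],
    "CHL1": ["O3", "C3", "C17"],
}


def make_bilayer_topology(
    n_popc: int = 4,
    n_pope: int = 4,
    n_chol: int = 2,
    leaflet_z: float = 20.0,
    spacing: float = 8.0,
    protein_motif: list[str] | None = None,
    templates=None,
) -> Topology:
    """Schematic bilayer (plus optional tiny protein) for lipid analyses.

    Lipids alternate between the upper (+leaflet_z) and lower (-leaflet_z)
    leaflets; head-group atoms sit at the leaflet z, tails point toward
    the midplane.  If ``protein_motif`` is given, one pentamer residue row
    per subunit is placed at the origin (z = 0) via
    :func:`make_pentamer_topology` conventions.
    """
    records: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    atom_id = 0
    rseq = 1000  # lipid residue numbers out of any protein range
    if protein_motif:
        prot = make_pentamer_topology(len(protein_motif), protein_motif, templates=templates)
        for a in prot.atoms:
            records.append(
                AtomRecord(
                    atom_id=atom_id, name=a.name, element=a.element,
                    residue_seq=a.residue_seq, residue_name=a.residue_name,
                    subunit=a.subunit, molecule_class=a.molecule_class,
                    mass=a.mass,
                )
            )
            atom_id += 1
        coords.extend(prot.reference_coordinates)

    lipid_plan = [("POPC", "POPC")] * n_popc + [("POPE", "POPE")] * n_pope + [
        ("CHL1", "cholesterol")
    ] * n_chol
    for k, (resname, mclass) in enumerate(lipid_plan):
        upper = k % 2 == 0
        zsign = 1.0 if upper else -1.0
        x = 40.0 + spacing * (k // 2)
        y = 0.0 if upper else spacing / 2.0
        for j, name in enumerate(_LIPID_ATOMS[resname]):
            z = zsign * (leaflet_z - 2.0 * j)  # tail descends toward midplane
            el = name[0]
            records.append(
                AtomRecord(
                    atom_id=atom_id, name=name, element=el, residue_seq=rseq,
                    residue_name=resname, subunit="M", molecule_class=mclass,
                    mass=element_mass(el),
                )
            )
            coords.append(np.array([x, y, z]))
            atom_id += 1
        rseq += 1
    top = Topology(records, templates=templates)
    top.reference_coordinates = np.array(coords)
    return top


# ---------------------------------------------------------------------------
# fluctuation trajectories

def _correlation_mixing_matrix(residues, correlations):
    """Matrix L with LL^T = target residue correlation matrix.

    Built by eigendecomposition so that rho = 1 targets (rank-deficient
    matrices) are handled exactly: perfectly correlated residues receive
    identical mixing rows, hence identical displacement series.
    """
    n = len(residues)
    pos = {r: k for k, r in enumerate(residues)}
    C = np.eye(n)
    for i, j, rho in correlations:
        if i not in pos or j not in pos:
            raise ValueError(f"correlation target references unknown residue ({i},{j})")
        C[pos[i], pos[j]] = C[pos[j], pos[i]] = rho
    w, V = np.linalg.eigh(C)
    if w.min() < -1e-8:
        raise ValueError(
            f"requested correlation targets are not positive semi-definite "
            f"(min eigenvalue {w.min():.3g})"
        )
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def gen_fluctuation_traj(topology: Topology, spec: FluctuationSpec) -> Trajectory:
    """Trajectory of rigid per-residue Gaussian displacements.

    Every atom of a residue is translated by the same zero-mean Gaussian
    3-vector with per-coordinate SD sigma(residue) (isotropic, frames
    independent).  Correlation targets are realized exactly in expectation
    by mixing shared Gaussian components; subunits are independent.
    Frame 0 is the undisplaced reference.
    """
    spec.validate()
    if not hasattr(topology, "reference_coordinates"):
        raise ValueError("topology lacks reference_coordinates")
    ref = topology.reference_coordinates
    rng = np.random.default_rng(spec.seed)

    prot_subs = topology.protein_subunits()
    residues = sorted(
        set(topology.residue_seqs[topology.molecule_classes == "protein"].tolist())
    )
    L = _correlation_mixing_matrix(residues, spec.correlations)
    n_res = len(residues)

    coords = np.repeat(ref[None, :, :], spec.n_frames, axis=0)
    for sub in prot_subs:
        scale = 1.0 if spec.subunit_sigma is None else spec.subunit_sigma.get(sub, 1.0)
        # (n_frames, 3, n_res) independent normals mixed across residues
        z = rng.standard_normal((spec.n_frames, 3, n_res))
        disp = z @ L.T
        for k, rseq in enumerate(residues):
            idx = topology.residue_atom_indices(sub, rseq)
            if idx.size == 0:
                continue
            d = disp[:, :, k] * (spec.sigma_of(rseq) * scale)
            d[0] = 0.0  # frame 0 is the reference
            coords[:, idx, :] += d[:, None, :]
    return Trajectory(topology, coords, dt_ps=50.0)


# ---------------------------------------------------------------------------
# constructed interaction geometries

def gen_hbond_geometry(d_da: float, theta_dha_deg: float) -> np.ndarray:
    """Donor / hydrogen / acceptor coordinates at an exact geometry.

    Donor at the origin, hydrogen 1.0 Å along +x, acceptor placed in the
    xy-plane so that |D-A| = d_da and the D-H-A angle equals
    ``theta_dha_deg``.  Raises if the combination is geometrically
    impossible.
    """
    if d_da <= 1.0:
        raise ValueError("d_da must exceed the 1.0 Å D-H bond length")
    theta = np.deg2rad(theta_dha_deg)
    # |H-A| = r from the law of cosines about the angle at H
    disc = np.cos(theta) ** 2 - 1.0 + d_da**2
    if disc < 0:
        raise ValueError(f"no acceptor position realizes (d_DA={d_da}, theta={theta_dha_deg})")
    r = np.cos(theta) + np.sqrt(disc)
    if r <= 0:
        raise ValueError(f"no acceptor position realizes (d_DA={d_da}, theta={theta_dha_deg})")
    donor = np.zeros(3)
    hydrogen = np.array([1.0, 0.0, 0.0])
    acceptor = hydrogen + r * np.array([-np.cos(theta), np.sin(theta), 0.0])
    return np.stack([donor, hydrogen, acceptor])


def gen_ring_pair(center_dist: float, normal_angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Two regular hexagonal rings (1.39 Å C-C) at an exact geometry.

    Ring A lies in the xy-plane centered at the origin (normal +z); ring B
    is centered ``center_dist`` along +x with its normal tilted by
    ``normal_angle_deg`` about the y-axis.
    """
    if center_dist <= 0:
        raise ValueError("center_dist must be positive")
    ring_a = _ngon(np.zeros(3), 6, 1.39)
    gamma = np.deg2rad(normal_angle_deg)
    # rotation about y: z-normal -> (sin g, 0, cos g)
    c, s = np.cos(gamma), np.sin(gamma)
    R = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    center_b = np.array([center_dist, 0.0, 0.0])
    ring_b = (_ngon(np.zeros(3), 6, 1.39) @ R.T) + center_b
    return ring_a, ring_b


# ---------------------------------------------------------------------------
# occupancy series

def _draw_dwells(spec: OccupancySpec, rng) -> list[tuple[float, float, bool]]:
    """Alternating (start_ns, end_ns, bound) intervals covering total_ns."""
    t = 0.0
    bound = True
    intervals = []
    while t < spec.total_ns:
        tau = spec.tau_on_ns if bound else spec.tau_off_ns
        dwell = tau if spec.law == "fixed" else float(rng.exponential(tau))
        intervals.append((t, min(t + dwell, spec.total_ns), bound))
        t += dwell
        bound = not bound
    return intervals


def gen_occupancy_series(spec: OccupancySpec) -> np.ndarray:
    """Boolean bound/unbound series discretized at the sampling interval.

    A frame covering [k dt, (k+1) dt) is bound iff its midpoint lies in a
    bound interval — unbiased for dwells much longer than dt.  The series
    starts in the bound state and is deterministic given the seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    intervals = _draw_dwells(spec, rng)
    dt_ns = spec.dt_ps / 1000.0
    n = int(round(spec.total_ns / dt_ns))
    mid = (np.arange(n) + 0.5) * dt_ns
    out = np.zeros(n, dtype=bool)
    for start, end, bound in intervals:
        if bound:
            out |= (mid >= start) & (mid < end)
    return out


def gen_lipid_proximity_traj(
    topology: Topology,
    lipid_residue_seq: int,
    target_subunit: str,
    target_residue_seq: int,
    occupancy: np.ndarray,
    near: float = 3.0,
    far: float = 15.0,
    dt_ps: float = 50.0,
) -> Trajectory:
    """Trajectory in which one lipid toggles near/far from a residue.

    In frames where ``occupancy`` is true the chosen lipid molecule is
    rigidly placed so its closest heavy atom sits ``near`` Å from the
    target residue's closest atom; otherwise ``far`` Å.  All other atoms
    stay at the reference coordinates.
    """
    ref = topology.reference_coordinates
    lip_idx = np.flatnonzero(topology.residue_seqs == lipid_residue_seq)
    res_idx = topology.residue_atom_indices(target_subunit, target_residue_seq)
    if lip_idx.size == 0 or res_idx.size == 0:
        raise ValueError("lipid or target residue not found in topology")
    res_center = ref[res_idx].mean(axis=0)
    lip_ref = ref[lip_idx]
    lip_center = lip_ref.mean(axis=0)
    direction = np.array([1.0, 0.0, 0.0])

    # precompute the two lipid placements (near / far along +x of target)
    def placed(dist):
        shifted = lip_ref - lip_center + res_center + direction * (dist + 5.0)
        # refine so the minimum heavy-atom distance equals dist
        d = np.linalg.norm(
            shifted[:, None, :] - ref[res_idx][None, :, :], axis=-1
        ).min()
        return shifted - direction * (d - dist)

    near_pos, far_pos = placed(near), placed(far)
    n = len(occupancy)
    coords = np.repeat(ref[None, :, :], n, axis=0)
    coords[occupancy, lip_idx[0]: lip_idx[-1] + 1, :] = near_pos
    coords[~occupancy, lip_idx[0]: lip_idx[-1] + 1, :] = far_pos
    return Trajectory(topology, coords, dt_ps=dt_ps)


# ---------------------------------------------------------------------------
# assay curves

def hill_response(a, b, pec50, nh, conc_m):
    """Four-parameter logistic at concentrations in molar."""
    x = np.log10(np.asarray(conc_m, dtype=float))
    return a + (b - a) / (1.0 + 10.0 ** (nh * (-pec50 - x)))


def gen_dose_response(
    a: float,
    b: float,
    pec50: float,
    nh: float,
    concentrations_m,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Noisy four-parameter logistic concentration-response table.

    Columns: concentration_M, response, replicate.  Noise is additive
    Gaussian with SD ``noise_sd`` in response units.
    """
    conc = np.asarray(concentrations_m, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        y = hill_response(a, b, pec50, nh, conc)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=conc.shape)
        rows.append(
            pd.DataFrame(
                {"concentration_M": conc, "response": y, "replicate": rep}
            )
        )
    return pd.concat(rows, ignore_index=True)


def saturation_response(kd_nm, bmax, ligand_nm):
    """One-site specific binding B = Bmax L / (Kd + L), L in nM."""
    L = np.asarray(ligand_nm, dtype=float)
    return bmax * L / (kd_nm + L)


def gen_saturation_binding(
    kd_nm: float,
    bmax: float,
    ligand_nm,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Noisy one-site saturation binding table (ligand_nM, response)."""
    L = np.asarray(ligand_nm, dtype=float)
    if np.any(L <= 0):
        raise ValueError("ligand concentrations must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        y = saturation_response(kd_nm, bmax, L)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=L.shape)
        rows.append(pd.DataFrame({"ligand_nM": L, "response": y, "replicate": rep}))
    return pd.concat(rows, ignore_index=True)
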