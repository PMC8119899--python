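"""Per-residue RMSF profiles and the dynamical correlation statistic.

RMSF is computed per (residue, subunit) over the backbone atoms
{N, CA, C, O}, with respect to a reference frame (first frame of the
analysis window by default — the post-equilibration positions — or a
supplied coordinate set, or the time-mean).  The cross-subunit error is
the maximum semidifference, half of (max - min) over the five subunits.

The dynamical correlation between two residue selections i and j is the
normalized covariance of their 3-vector position series,

    C_ij = (<r_i . r_j> - <r_i>.<r_j>)
           / sqrt((<r_i^2> - <r_i>^2)(<r_j^2> - <r_j>^2)),

time averages taken over the analysis window, computed per subunit and
per replica.  The formula is signed and lies in [-1, 1]; values are
reported unclamped.  No global superposition is applied by default (an
optional least-squares fit onto a selection is available), matching
positionally restrained simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import PooledFrames, Selection, Topology, Trajectory
from .stats import max_semidifference

__all__ = ["RmsfProfile", "CorrelationResult", "compute_rmsf", "dynamic_correlation"]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class RmsfProfile:
    """Per-(residue, subunit) RMSF with cross-subunit pooling.

    ``values[(residue_seq, subunit)]`` is the RMSF in Å;
    ``residue_mean``/``residue_error`` pool over subunits (mean and
    maximum semidifference).
    """

    values: dict[tuple[int, str], float]
    residue_mean: dict[int, float]
    residue_error: dict[int, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"residue_seq": r, "subunit": s, "rmsf_A": v}
            for (r, s), v in sorted(self.values.items())
        ]
        df = pd.DataFrame(rows)
        df["pooled_mean"] = df["residue_seq"].map(self.residue_mean)
        df["error"] = df["residue_seq"].map(self.residue_error)
        df["error_method"] = "max_semidifference"
        return df


@dataclass
class CorrelationResult:
    """Dynamical correlation for one residue pair.

    ``per_series[(subunit, replica)]`` holds the signed C_ij; the grand
    mean and SD pool over all (subunit, replica) series.
    """

    pair: tuple[object, object]
    per_series: dict[tuple[str, str], float]
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self):
        vals = np.array(list(self.per_series.values()), dtype=float)
        self.mean = float(vals.mean())
        self.sd = float(vals.std(ddof=0))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subunit": s, "replica": r, "value": v}
            for (s, r), v in sorted(self.per_series.items())
        ]
        df = pd.DataFrame(rows)
        df["pooled_mean"] = self.mean
        df["error"] = self.sd
        return df


def _frames_and_topology(traj):
    if isinstance(traj, Trajectory):
        return {"R0": traj.coordinates}, traj.topology
    if isinstance(traj, PooledFrames):
        return {r: traj.replica_frames(r) for r in traj.replicas}, traj.topology
    raise TypeError("expected Trajectory or PooledFrames")


def _superpose(coords, ref, fit_idx):
    """Least-squares rigid superposition of every frame onto ref (Kabsch)."""
    out = np.empty_like(coords)
    ref_sel = ref[fit_idx]
    ref_cen = ref_sel.mean(axis=0)
    for f in range(coords.shape[0]):
        mob = coords[f, fit_idx]
        mob_cen = mob.mean(axis=0)
        H = (mob - mob_cen).T @ (ref_sel - ref_cen)
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
        out[f] = (coords[f] - mob_cen) @ R.T + ref_cen
    return out


def compute_rmsf(
    traj,
    selection: Selection | None = None,
    reference: str | np.ndarray = "first_frame",
    superpose_on: Selection | None = None,
) -> RmsfProfile:
    """Per-residue, per-subunit backbone RMSF.

    Parameters
    ----------
    traj
        Trajectory or PooledFrames (replicas are concatenated: RMSF is a
        time- and subunit-resolved average over all pooled frames).
    selection
        Restricts the residues considered; default: all protein residues.
    reference
        "first_frame", "mean", or an (n_atoms, 3) coordinate array.
    superpose_on
        Optional selection to least-squares-fit each frame onto the
        reference before measuring (off by default).
    """
    per_rep, top = _frames_and_topology(traj)
    coords = np.concatenate(list(per_rep.values()), axis=0)
    if coords.shape[0] == 0:
        raise ValueError("no frames to analyse")

    if isinstance(reference, str):
        if reference == "first_frame":
            ref = coords[0]
        elif reference == "mean":
            ref = coords.mean(axis=0)
        else:
            raise ValueError(f"unknown reference mode {reference!r}")
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != coords.shape[1:]:
            raise ValueError(
                f"reference shape {ref.shape} does not match atom count "
                f"{coords.shape[1]}"
            )
    if superpose_on is not None:
        coords = _superpose(coords, ref, superpose_on.resolve(top))

    sel_idx = (
        selection.resolve(top)
        if selection is not None
        else np.flatnonzero(top.molecule_classes == "protein")
    )
    if sel_idx.size == 0:
        raise ValueError("selection resolved to zero atoms")
    sel_mask = np.zeros(top.n_atoms, dtype=bool)
    sel_mask[sel_idx] = True
    backbone = np.isin(top.names, BACKBONE_ATOMS)

    values: dict[tuple[int, str], float] = {}
    for (sub, rseq, _rname), idx in top.iter_residues():
        bb = idx[sel_mask[idx] & backbone[idx]]
        if bb.size == 0:
            continue
        sq = np.sum((coords[:, bb, :] - ref[bb]) ** 2, axis=-1)
        values[(int(rseq), str(sub))] = float(np.sqrt(sq.mean()))

    residue_mean: dict[int, float] = {}
    residue_error: dict[int, float] = {}
    for rseq in sorted({r for r, _ in values}):
        vals = [v for (r, _), v in values.items() if r == rseq]
        residue_mean[rseq] = float(np.mean(vals))
        residue_error[rseq] = max_semidifference(vals)
    return RmsfProfile(values, residue_mean, residue_error)


def _representative_series(coords, idx, mode):
    """(n_frames, 3) representative position series for a residue selection."""
    if mode == "centroid":
        return coords[:, idx, :].mean(axis=1)
    raise ValueError(f"unknown mode {mode!r}")


def _corr_3vec(ri, rj):
    """Signed normalized covariance of two 3-vector time series."""
    # centered evaluation of <ri.rj> - <ri>.<rj> etc. (numerically stable)
    di = ri - ri.mean(axis=0)
    dj = rj - rj.mean(axis=0)
    cov = (di * dj).sum(axis=1).mean()
    var_i = (di * di).sum(axis=1).mean()
    var_j = (dj * dj).sum(axis=1).mean()
    if var_i <= 0 or var_j <= 0:
        raise ZeroDivisionError(
            "zero-variance position series: correlation undefined"
        )
    return float(cov / np.sqrt(var_i * var_j))


def dynamic_correlation(
    traj,
    sel_i: Selection,
    sel_j: Selection,
    mode: str = "centroid",
    backbone_only: bool = True,
) -> CorrelationResult:
    """Dynamical correlation C_ij per subunit and replica.

    ``mode="centroid"`` (default) correlates the backbone-centroid series
    of the two selections; ``mode="atom_pair_mean"`` averages C over
    matched atom pairs (same atom order in both selections).  Selections
    are resolved per subunit; both must be non-empty in every protein
    subunit.
    """
    per_rep, top = _frames_and_topology(traj)
    backbone = np.isin(top.names, BACKBONE_ATOMS)
    per_series: dict[tuple[str, str], float] = {}
    for sub in top.protein_subunits():
        sub_mask = top.subunits == sub
        idx_i = sel_i.resolve(top)
        idx_j = sel_j.resolve(top)
        idx_i = idx_i[sub_mask[idx_i]]
        idx_j = idx_j[sub_mask[idx_j]]
        if backbone_only:
            bi, bj = idx_i[backbone[idx_i]], idx_j[backbone[idx_j]]
            if bi.size and bj.size:
                idx_i, idx_j = bi, bj
        if idx_i.size == 0 or idx_j.size == 0:
            raise ValueError(f"selection empty within subunit {sub!r}")
        for rep, coords in per_rep.items():
            if mode == "atom_pair_mean":
                if idx_i.size != idx_j.size:
                    raise ValueError(
                        "atom_pair_mean requires equally sized selections"
                    )
                cs = [
                    _corr_3vec(coords[:, a, :], coords[:, b, :])
                    for a, b in zip(idx_i, idx_j)
                ]
                c = float(np.mean(cs))
            else:
                c = _corr_3vec(
                    _representative_series(coords, idx_i, mode),
                    _representative_series(coords, idx_j, mode),
                )
            if abs(c) > 1.0 + 1e-9:
                raise AssertionError(f"|C_ij| = {abs(c)} exceeds 1")
            per_series[(sub, rep)] = c
    return CorrelationResult(pair=(sel_i, sel_j), per_series=per_series)
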