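"""Pooling and error conventions, and distance-distribution analysis.

Two error conventions are used throughout the pipeline:

* maximum semidifference, (max - min)/2 over a group of values (used for
  cross-subunit RMSF spread);
* propagation from per-group standard deviations over time: the error of
  the group mean is sqrt(sum sd_k^2)/n, with n = 5 for subunit pooling or
  n = 10 for subunit x replica pooling.  The mean-of-independent-estimates
  form is an interpretation of the stated propagation and is documented
  as such in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PooledFrames, Selection, Trajectory

__all__ = [
    "max_semidifference",
    "propagate_group_error",
    "DistanceDistribution",
    "distance_distribution",
]


def max_semidifference(values) -> float:
    """Half of (max - min) of a non-empty group of values."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("max_semidifference of an empty group")
    return float((vals.max() - vals.min()) / 2.0)


def propagate_group_error(sds) -> float:
    """Error of a group mean from per-group SDs: sqrt(sum sd^2)/n."""
    s = np.asarray(list(sds), dtype=float)
    if s.size == 0:
        raise ValueError("propagate_group_error of an empty group")
    if np.any(s < 0):
        raise ValueError("standard deviations must be non-negative")
    return float(np.sqrt(np.sum(s**2)) / s.size)


@dataclass
class DistanceDistribution:
    """Pooled distance histogram with per-bin propagated errors and modes.

    ``density`` is normalized to integrate to 1 over the histogram range;
    ``modes_A`` are bin centers that are strict local maxima of the 3-bin
    moving-average-smoothed pooled density.
    """

    pair: tuple[object, object]
    bin_edges: np.ndarray
    density: np.ndarray
    per_bin_error: np.ndarray
    modes_A: list[float]
    per_group: dict[tuple[str, str], np.ndarray]

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center_A": self.bin_centers,
                "density": self.density,
                "error": self.per_bin_error,
                "error_method": "propagated",
            }
        )


def _moving_average3(y):
    """3-bin moving average with edge bins averaged over available bins."""
    padded = np.concatenate([[y[0]], y, [y[-1]]])
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def _local_maxima(y):
    idx = []
    for k in range(len(y)):
        left = y[k - 1] if k > 0 else -np.inf
        right = y[k + 1] if k < len(y) - 1 else -np.inf
        if y[k] > left and y[k] > right:
            idx.append(k)
    return idx


def _frames_by_replica(frames):
    if isinstance(frames, Trajectory):
        return {"R0": frames.coordinates}, frames.topology
    if isinstance(frames, PooledFrames):
        return {r: frames.replica_frames(r) for r in frames.replicas}, frames.topology
    raise TypeError("expected Trajectory or PooledFrames")


def distance_distribution(
    frames,
    atom_a: Selection,
    atom_b: Selection,
    bin_width: float = 0.25,
    range_A: tuple[float, float] | None = None,
) -> DistanceDistribution:
    """Distribution of an inter-atom distance over time and subunits.

    Each selection must resolve to exactly one atom per protein subunit
    (e.g. one named side-chain atom).  Distances are collected per
    (subunit, replica); the pooled histogram is density-normalized, the
    per-bin error propagates the per-group standard deviations over time
    of the bin indicator (scaled to density units), and modes are strict
    local maxima of the smoothed pooled density.
    """
    per_rep, top = _frames_by_replica(frames)
    subs = top.protein_subunits()
    idx_a, idx_b = atom_a.resolve(top), atom_b.resolve(top)
    a_of = {top.subunits[i]: i for i in idx_a}
    b_of = {top.subunits[i]: i for i in idx_b}
    if len(a_of) != len(idx_a) or len(b_of) != len(idx_b):
        raise ValueError("selection resolves to more than one atom in a subunit")
    for sub in subs:
        if sub not in a_of or sub not in b_of:
            raise ValueError(f"atom selection unresolvable in subunit {sub!r}")

    dists: dict[tuple[str, str], np.ndarray] = {}
    for rep, coords in per_rep.items():
        for sub in subs:
            d = np.linalg.norm(coords[:, a_of[sub], :] - coords[:, b_of[sub], :], axis=-1)
            dists[(sub, rep)] = d
    all_d = np.concatenate(list(dists.values()))
    if range_A is None:
        lo = np.floor(all_d.min() / bin_width) * bin_width
        hi = np.ceil(all_d.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
    else:
        lo, hi = range_A
    edges = np.arange(lo, hi + bin_width / 2.0, bin_width)

    per_group: dict[tuple[str, str], np.ndarray] = {}
    per_group_sd = []
    for key, d in dists.items():
        counts, _ = np.histogram(d, bins=edges)
        per_group[key] = counts / (counts.sum() * bin_width) if counts.sum() else counts.astype(float)
        # per-bin std over time of the density-scaled bin indicator
        ind = (
            (d[:, None] >= edges[:-1][None, :]) & (d[:, None] < edges[1:][None, :])
        ).astype(float) / bin_width
        per_group_sd.append(ind.std(axis=0, ddof=0))
    density = np.mean(list(per_group.values()), axis=0)
    total = density.sum() * bin_width
    if total > 0:
        density = density / total
    n_groups = len(dists)
    err = np.sqrt(np.sum(np.array(per_group_sd) ** 2, axis=0)) / n_groups

    smoothed = _moving_average3(density)
    centers = 0.5 * (edges[:-1] + edges[1:])
    modes = [float(centers[k]) for k in _local_maxima(smoothed)]
    return DistanceDistribution(
        pair=(atom_a, atom_b),
        bin_edges=edges,
        density=density,
        per_bin_error=err,
        modes_A=modes,
        per_group=per_group,
    )
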