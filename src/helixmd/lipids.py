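"""Lipid-residue proximity lifetimes, z-positioning and leaflet assignment.

A lipid molecule is "in proximity" to a residue in a frame when any
heavy-atom pair between them is closer than the cutoff (default: the
generic 3.5 Å contact cutoff).  A residence event is a maximal run of
consecutive proximal frames; its duration is the run length times the
sampling interval.  Lifetime distributions report events at or above a
minimum residence (default 5 ns), with per-bin means and standard
deviations evaluated over overlapping analysis windows shifted by 5 ns.
Events truncated by the series edges are counted at their observed
(censored) duration and flagged.

POPC and POPE are grouped under "phospholipid": at the depth of the
membrane-facing residues the two species' tails are indistinguishable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import PooledFrames, Selection, Topology, Trajectory

__all__ = [
    "ResidenceEvent",
    "LifetimeDistribution",
    "ZOffsetSeries",
    "proximity_series",
    "residence_events",
    "lifetime_distribution",
    "z_offset",
    "assign_leaflets",
]

_LIPID_CLASSES = {
    "phospholipid": ("POPC", "POPE"),
    "POPC": ("POPC",),
    "POPE": ("POPE",),
    "cholesterol": ("cholesterol",),
}


@dataclass(frozen=True)
class ResidenceEvent:
    """One maximal contiguous proximity run of one lipid molecule."""

    lipid_id: int
    start_ns: float
    duration_ns: float
    censored: bool  # truncated by the start or end of the series


@dataclass
class LifetimeDistribution:
    """Histogram of residence-event durations with windowed error bars."""

    bin_edges_ns: np.ndarray
    counts: np.ndarray
    window_mean: np.ndarray
    window_sd: np.ndarray
    min_residence_ns: float
    events: list[ResidenceEvent] = field(default_factory=list)

    @property
    def bin_centers_ns(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ns[:-1] + self.bin_edges_ns[1:])

    def reported_events(self) -> list[ResidenceEvent]:
        return [e for e in self.events if e.duration_ns >= self.min_residence_ns]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_ns": self.bin_edges_ns[:-1],
                "bin_end_ns": self.bin_edges_ns[1:],
                "count": self.counts,
                "window_mean": self.window_mean,
                "window_sd": self.window_sd,
            }
        )

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "lipid_id": e.lipid_id,
                    "start_ns": e.start_ns,
                    "duration_ns": e.duration_ns,
                    "censored": e.censored,
                }
                for e in self.events
            ]
        )


@dataclass
class ZOffsetSeries:
    """Per-frame z-component center-of-mass offset, lipid minus reference."""

    values_A: np.ndarray
    mean: float
    sd: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.values_A)), "z_offset_A": self.values_A})


def _coords_and_top(frames):
    if isinstance(frames, Trajectory):
        return frames.coordinates, frames.topology, frames.dt_ps
    if isinstance(frames, PooledFrames):
        return frames.coordinates, frames.topology, frames.dt_ps
    raise TypeError("expected Trajectory or PooledFrames")


def proximity_series(
    frames,
    residue: Selection,
    lipid_class: str = "phospholipid",
    cutoff: float = 3.5,
) -> dict[int, np.ndarray]:
    """Per-lipid-molecule boolean proximity series.

    For every lipid molecule of the requested class, frame f is True iff
    some heavy-atom pair (lipid, residue) is closer than ``cutoff``.
    Returns a mapping lipid residue_seq -> boolean array over frames.
    """
    coords, top, _dt = _coords_and_top(frames)
    if lipid_class not in _LIPID_CLASSES:
        raise ValueError(f"unknown lipid class {lipid_class!r}")
    classes = _LIPID_CLASSES[lipid_class]
    lip_mask = np.isin(top.molecule_classes, classes)
    if not lip_mask.any():
        raise ValueError(f"no {lipid_class!r} lipids in topology")
    res_idx = residue.resolve(top)
    res_idx = res_idx[top.elements[res_idx] != "H"]
    if res_idx.size == 0:
        raise ValueError("residue selection resolved to zero heavy atoms")

    out: dict[int, np.ndarray] = {}
    for rseq in sorted(set(top.residue_seqs[lip_mask].tolist())):
        lidx = np.flatnonzero(lip_mask & (top.residue_seqs == rseq))
        lidx = lidx[top.elements[lidx] != "H"]
        d = np.linalg.norm(
            coords[:, lidx, None, :] - coords[:, None, res_idx, :], axis=-1
        ).min(axis=(1, 2))
        out[int(rseq)] = d < cutoff
    return out


def residence_events(
    series: np.ndarray, dt_ps: float, lipid_id: int = 0, gap_frames: int = 0
) -> list[ResidenceEvent]:
    """Maximal runs of True frames as residence events.

    A single False frame terminates an event unless ``gap_frames`` allows
    bridging up to that many consecutive False frames.
    """
    s = np.asarray(series, dtype=bool).copy()
    n = len(s)
    if gap_frames > 0:
        # bridge interior gaps of <= gap_frames false frames
        k = 0
        while k < n:
            if not s[k]:
                j = k
                while j < n and not s[j]:
                    j += 1
                if 0 < k and j < n and (j - k) <= gap_frames:
                    s[k:j] = True
                k = j
            else:
                k += 1
    dt_ns = dt_ps / 1000.0
    events = []
    k = 0
    while k < n:
        if s[k]:
            j = k
            while j < n and s[j]:
                j += 1
            events.append(
                ResidenceEvent(
                    lipid_id=lipid_id,
                    start_ns=k * dt_ns,
                    duration_ns=(j - k) * dt_ns,
                    censored=(k == 0 or j == n),
                )
            )
            k = j
        else:
            k += 1
    return events


def lifetime_distribution(
    series,
    dt_ps: float,
    bin_width_ns: float = 5.0,
    window_shift_ns: float = 5.0,
    window_length_ns: float = 50.0,
    min_residence_ns: float = 5.0,
    gap_frames: int = 0,
) -> LifetimeDistribution:
    """Residence-lifetime histogram with shifted-window error bars.

    ``series`` is a boolean array, a list of arrays, or the mapping
    returned by :func:`proximity_series`.  The full-span histogram counts
    events with duration >= ``min_residence_ns``; per-bin mean and SD come
    from re-extracting events inside overlapping windows of
    ``window_length_ns`` shifted by ``window_shift_ns``.
    """
    if isinstance(series, np.ndarray):
        series_map = {0: series}
    elif isinstance(series, dict):
        series_map = series
    else:
        series_map = {i: s for i, s in enumerate(series)}
    dt_ns = dt_ps / 1000.0

    events: list[ResidenceEvent] = []
    for lid, s in series_map.items():
        events.extend(residence_events(np.asarray(s, bool), dt_ps, lipid_id=lid, gap_frames=gap_frames))

    durations = np.array([e.duration_ns for e in events if e.duration_ns >= min_residence_ns])
    max_d = durations.max() if durations.size else min_residence_ns
    edges = np.arange(
        min_residence_ns, max_d + bin_width_ns + 1e-9, bin_width_ns
    )
    if len(edges) < 2:
        edges = np.array([min_residence_ns, min_residence_ns + bin_width_ns])
    counts, _ = np.histogram(durations, bins=edges)

    # windowed statistics
    total_ns = len(next(iter(series_map.values()))) * dt_ns
    win_hists = []
    w0 = 0.0
    while w0 + window_length_ns <= total_ns + 1e-9:
        f0 = int(round(w0 / dt_ns))
        f1 = int(round((w0 + window_length_ns) / dt_ns))
        wevents: list[ResidenceEvent] = []
        for lid, s in series_map.items():
            wevents.extend(
                residence_events(np.asarray(s, bool)[f0:f1], dt_ps, lipid_id=lid, gap_frames=gap_frames)
            )
        wdur = [e.duration_ns for e in wevents if e.duration_ns >= min_residence_ns]
        h, _ = np.histogram(wdur, bins=edges)
        win_hists.append(h)
        w0 += window_shift_ns
    if win_hists:
        arr = np.array(win_hists, dtype=float)
        wmean, wsd = arr.mean(axis=0), arr.std(axis=0, ddof=0)
    else:
        wmean = counts.astype(float)
        wsd = np.zeros_like(wmean)
    return LifetimeDistribution(
        bin_edges_ns=edges,
        counts=counts,
        window_mean=wmean,
        window_sd=wsd,
        min_residence_ns=min_residence_ns,
        events=events,
    )


def z_offset(frames, lipid_selection: Selection, reference_residues: Selection) -> ZOffsetSeries:
    """z of the lipid selection's center of mass minus the reference's.

    Mass-weighted centers of mass; only the z component (the membrane
    normal / channel axis) is reported.
    """
    coords, top, _dt = _coords_and_top(frames)
    li = lipid_selection.resolve(top)
    ri = reference_residues.resolve(top)
    if li.size == 0 or ri.size == 0:
        raise ValueError("z_offset requires non-empty selections")
    ml, mr = top.masses[li], top.masses[ri]
    zl = (coords[:, li, 2] * ml).sum(axis=1) / ml.sum()
    zr = (coords[:, ri, 2] * mr).sum(axis=1) / mr.sum()
    vals = zl - zr
    return ZOffsetSeries(values_A=vals, mean=float(vals.mean()), sd=float(vals.std(ddof=0)))


def assign_leaflets(topology: Topology, frame) -> dict[int, str]:
    """Leaflet label (upper/lower) per lipid molecule for one frame.

    Phospholipids are assigned by head-group (phosphorus) z relative to
    the membrane midplane (midpoint of the extreme head-group z values);
    cholesterol by its hydroxyl-oxygen z.  A head exactly at the midplane
    goes to the lower leaflet.  If all heads fall within 10 Å of z spread
    the membrane is treated as a single leaflet (warned).
    """
    frame = np.asarray(frame, dtype=float)
    heads = topology.templates["lipid_heads"]
    lipid_mask = np.isin(topology.molecule_classes, ("POPC", "POPE", "cholesterol"))
    if not lipid_mask.any():
        raise ValueError("no lipids in topology")
    head_z: dict[int, float] = {}
    for rseq in sorted(set(topology.residue_seqs[lipid_mask].tolist())):
        idx = np.flatnonzero(lipid_mask & (topology.residue_seqs == rseq))
        rname = topology.residue_names[idx[0]]
        names = heads.get(rname, [])
        head = next((i for i in idx if topology.names[i] in names), idx[0])
        head_z[int(rseq)] = float(frame[head, 2])
    zs = np.array(list(head_z.values()))
    if zs.max() - zs.min() < 10.0:
        warnings.warn("all lipid heads in one leaflet; assigning a single label", UserWarning)
        label = "upper" if zs.mean() > 0 else "lower"
        return {r: label for r in head_z}
    midplane = 0.5 * (zs.max() + zs.min())
    return {r: ("upper" if z > midplane else "lower") for r, z in head_z.items()}
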