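"""Frame-wise geometric interaction detectors and pooled frequencies.

All criteria are strict inequalities, exactly as conventionally printed:

* hydrogen bond: donor-acceptor distance < 3.5 Å and donor-hydrogen-
  acceptor angle > 120°;
* generic contact: any inter-residue atom distance < 3.5 Å;
* π-π: ring-center distance < 6.0 Å and best-fit-plane normals angle
  < 45° or > 135° (the two bands are equivalent under either ring's
  normal-sign flip);
* anion-π: ring center to charged atom distance < 5.0 Å and angle between
  the ring normal and the center-to-anion vector < 40° or > 140°.

Frequencies are the fraction of frames with at least one detected
interaction between the partners, per subunit and per replica; for
multi-ring residues (tryptophan) per-ring frequencies are computed
separately and then summed.  The pooled error propagates the per-series
standard deviations over time (sqrt(sum sd^2)/n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PooledFrames, Topology, Trajectory
from .stats import propagate_group_error

__all__ = [
    "InteractionCriteria",
    "InteractionFrequency",
    "detect_hbond",
    "detect_contact",
    "ring_plane",
    "detect_pipi",
    "detect_anionpi",
    "interaction_frequency",
]


@dataclass(frozen=True)
class InteractionCriteria:
    """All geometric cutoffs of the detectors, as one configurable record."""

    hbond_da_max: float = 3.5
    hbond_dha_min: float = 120.0
    contact_max: float = 3.5
    pipi_center_max: float = 6.0
    pipi_normal_low: float = 45.0
    pipi_normal_high: float = 135.0
    anionpi_max: float = 5.0
    anionpi_axis_low: float = 40.0
    anionpi_axis_high: float = 140.0

    def __post_init__(self):
        for name in ("hbond_da_max", "contact_max", "pipi_center_max", "anionpi_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for low, high in (
            (self.pipi_normal_low, self.pipi_normal_high),
            (self.anionpi_axis_low, self.anionpi_axis_high),
        ):
            if not (0.0 <= low < high <= 180.0):
                raise ValueError("angle bands must satisfy 0 <= low < high <= 180")
        if not 0.0 <= self.hbond_dha_min <= 180.0:
            raise ValueError("hbond_dha_min must lie in [0, 180]")


def _angle_deg(v1, v2):
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("zero-length vector in angle computation")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def detect_hbond(donor, hydrogen, acceptor, criteria=InteractionCriteria()) -> bool:
    """Hydrogen bond: |D-A| < cutoff and D-H-A angle > cutoff (strict)."""
    d, h, a = (np.asarray(p, dtype=float) for p in (donor, hydrogen, acceptor))
    if (
        np.allclose(d, h)
        or np.allclose(h, a)
        or np.allclose(d, a)
    ):
        raise ValueError("donor, hydrogen and acceptor must be distinct points")
    if np.linalg.norm(d - a) >= criteria.hbond_da_max:
        return False
    theta = _angle_deg(d - h, a - h)
    return theta > criteria.hbond_dha_min


def detect_contact(res_a, res_b, criteria=InteractionCriteria()) -> bool:
    """Generic contact: minimum inter-set atom distance < cutoff (strict)."""
    a = np.atleast_2d(np.asarray(res_a, dtype=float))
    b = np.atleast_2d(np.asarray(res_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("contact detection requires non-empty atom sets")
    if a.shape == b.shape and np.allclose(a, b):
        raise ValueError("contact requires two distinct residues")
    dmin = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1).min()
    return bool(dmin < criteria.contact_max)


def ring_plane(ring_coords):
    """Centroid and unit normal of the least-squares plane of a ring.

    The normal is the left singular vector of the centered coordinates
    with the smallest singular value; its sign is arbitrary (all
    downstream angle tests are symmetric under flipping it).
    """
    pts = np.asarray(ring_coords, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValueError("ring_plane needs >= 3 points of dimension 3")
    center = pts.mean(axis=0)
    centered = pts - center
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear (or coincident) points: only one non-negligible direction
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise ValueError("degenerate ring geometry: points are collinear")
    return center, vt[2]


def _in_band_outside(angle, low, high):
    """True iff angle < low or angle > high (strict)."""
    return angle < low or angle > high


def detect_pipi(ring_a, ring_b, criteria=InteractionCriteria()) -> bool:
    """π-π: center distance < cutoff and normals angle in the coaxial bands."""
    ca, na = ring_plane(ring_a)
    cb, nb = ring_plane(ring_b)
    if np.linalg.norm(ca - cb) >= criteria.pipi_center_max:
        return False
    ang = _angle_deg(na, nb)
    return _in_band_outside(ang, criteria.pipi_normal_low, criteria.pipi_normal_high)


def detect_anionpi(ring, anion, criteria=InteractionCriteria()) -> bool:
    """Anion-π: center-anion distance < cutoff, normal/axis angle in band."""
    center, normal = ring_plane(ring)
    anion = np.asarray(anion, dtype=float)
    axis = anion - center
    if np.linalg.norm(axis) >= criteria.anionpi_max:
        return False
    ang = _angle_deg(normal, axis)
    return _in_band_outside(ang, criteria.anionpi_axis_low, criteria.anionpi_axis_high)


# ---------------------------------------------------------------------------
# pooled frequencies

@dataclass
class InteractionFrequency:
    """Time- and subunit-averaged interaction frequency for one pair."""

    pair: tuple[object, object]
    kind: str
    per_series: dict[tuple[str, str], float]  # (subunit, replica) -> frequency
    per_series_sd: dict[tuple[str, str], float]
    mean: float
    error: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subunit": s, "replica": r, "value": v,
             "sd_over_time": self.per_series_sd[(s, r)]}
            for (s, r), v in sorted(self.per_series.items())
        ]
        df = pd.DataFrame(rows)
        df["pooled_mean"] = self.mean
        df["error"] = self.error
        df["error_method"] = "propagated"
        return df


def _heavy(top: Topology, idx):
    return idx[top.elements[idx] != "H"]


def _residue_idx(top: Topology, sub, rseq):
    idx = top.residue_atom_indices(sub, rseq)
    if idx.size == 0:
        raise ValueError(f"residue {rseq} not found in subunit {sub!r}")
    return idx


def _hbond_series(top, coords, sub, ra, rb, criteria, sidechain_only):
    ia, ib = _residue_idx(top, sub, ra), _residue_idx(top, sub, rb)
    donors = [(d, h) for d, h in top.hbond_donors]
    acceptors = set(top.hbond_acceptors)
    pairs = []
    for set_d, set_a in ((set(ia), set(ib)), (set(ib), set(ia))):
        for d, h in donors:
            if d not in set_d:
                continue
            if sidechain_only and top.names[d] == "N":
                continue
            for acc in acceptors & set_a:
                if sidechain_only and top.names[acc] == "O":
                    continue
                pairs.append((d, h, acc))
    if not pairs:
        has_h = np.any(top.elements[np.concatenate([ia, ib])] == "H")
        if not has_h:
            raise ValueError(
                "hydrogen-bond detection needs explicit hydrogens on donors; "
                "the topology has none for this pair"
            )
        return np.zeros(coords.shape[0], dtype=bool)
    out = np.zeros(coords.shape[0], dtype=bool)
    for d, h, acc in pairs:
        da = np.linalg.norm(coords[:, d, :] - coords[:, acc, :], axis=-1)
        v1 = coords[:, d, :] - coords[:, h, :]
        v2 = coords[:, acc, :] - coords[:, h, :]
        cosang = np.sum(v1 * v2, axis=-1) / (
            np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
        )
        theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        out |= (da < criteria.hbond_da_max) & (theta > criteria.hbond_dha_min)
    return out


def _contact_series(top, coords, sub, ra, rb, criteria):
    ia = _heavy(top, _residue_idx(top, sub, ra))
    ib = _heavy(top, _residue_idx(top, sub, rb))
    d = np.linalg.norm(
        coords[:, ia, None, :] - coords[:, None, ib, :], axis=-1
    ).min(axis=(1, 2))
    return d < criteria.contact_max


def _ring_series(coords, atom_indices, ring_b_indices, criteria, kind, anion_idx=None):
    """Boolean series for one ring (vs one ring or a set of anion atoms)."""
    n = coords.shape[0]
    out = np.zeros(n, dtype=bool)
    for f in range(n):
        if kind == "pipi":
            out[f] = detect_pipi(coords[f, atom_indices], coords[f, ring_b_indices], criteria)
        else:
            ring = coords[f, atom_indices]
            out[f] = any(
                detect_anionpi(ring, coords[f, a], criteria) for a in anion_idx
            )
    return out


def interaction_frequency(
    frames,
    pair,
    kind: str,
    criteria: InteractionCriteria = InteractionCriteria(),
    sidechain_only: bool = False,
    include_his: bool = False,
) -> InteractionFrequency:
    """Pooled interaction frequency for one intra-subunit residue pair.

    ``pair`` is (residue_seq_a, residue_seq_b), resolved within each
    protein subunit.  ``kind`` is one of hbond / contact / pipi / anionpi
    (for anionpi, the first residue carries the ring(s), the second the
    charged atoms).  Multi-ring residues contribute the sum of their
    per-ring frequencies; an anion-π event for a ring fires if any
    charged oxygen of the partner satisfies the criteria.
    """
    if isinstance(frames, Trajectory):
        per_rep, top = {"R0": frames.coordinates}, frames.topology
    elif isinstance(frames, PooledFrames):
        per_rep = {r: frames.replica_frames(r) for r in frames.replicas}
        top = frames.topology
    else:
        raise TypeError("expected Trajectory or PooledFrames")
    ra, rb = pair
    if kind not in ("hbond", "contact", "pipi", "anionpi"):
        raise ValueError(f"unknown interaction kind {kind!r}")

    per_series: dict[tuple[str, str], float] = {}
    per_sd: dict[tuple[str, str], float] = {}
    for sub in top.protein_subunits():
        for rep, coords in per_rep.items():
            if coords.shape[0] == 0:
                raise ValueError("no frames to analyse")
            if kind == "hbond":
                series = _hbond_series(top, coords, sub, ra, rb, criteria, sidechain_only)
                freq, sd = series.mean(), series.std(ddof=0)
            elif kind == "contact":
                series = _contact_series(top, coords, sub, ra, rb, criteria)
                freq, sd = series.mean(), series.std(ddof=0)
            elif kind == "pipi":
                rings_a = _rings_for(top, sub, ra, include_his)
                rings_b = _rings_for(top, sub, rb, include_his)
                if not rings_a or not rings_b:
                    raise ValueError(f"no aromatic rings for pair {pair} in {sub!r}")
                freq = sd_sq = 0.0
                for spec_a in rings_a:
                    for spec_b in rings_b:
                        series = _ring_series(
                            coords, list(spec_a.atom_indices),
                            list(spec_b.atom_indices), criteria, "pipi",
                        )
                        freq += series.mean()
                        sd_sq += series.std(ddof=0) ** 2
                sd = np.sqrt(sd_sq)
            else:  # anionpi
                rings_a = _rings_for(top, sub, ra, include_his)
                ib = _residue_idx(top, sub, rb)
                anions = [i for i in top.anion_atoms if i in set(ib)]
                if not rings_a or not anions:
                    raise ValueError(
                        f"anion-π pair {pair} unresolvable in subunit {sub!r}"
                    )
                freq = sd_sq = 0.0
                for spec_a in rings_a:
                    series = _ring_series(
                        coords, list(spec_a.atom_indices), None, criteria,
                        "anionpi", anion_idx=anions,
                    )
                    freq += series.mean()
                    sd_sq += series.std(ddof=0) ** 2
                sd = np.sqrt(sd_sq)
            per_series[(sub, rep)] = float(freq)
            per_sd[(sub, rep)] = float(sd)

    mean = float(np.mean(list(per_series.values())))
    error = propagate_group_error(list(per_sd.values()))
    return InteractionFrequency(
        pair=pair, kind=kind, per_series=per_series, per_series_sd=per_sd,
        mean=mean, error=error,
    )


def _rings_for(top: Topology, sub, rseq, include_his: bool):
    rings = top.rings_of(sub, rseq)
    if not include_his:
        rings = [r for r in rings if r.residue_name not in ("HIS", "HSD", "HSE")]
    return rings
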