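"""Geometric interaction detectors vs brute-force oracles; pooled frequencies."""

import numpy as np
import pytest

from helixmd.interactions import (
    InteractionCriteria,
    detect_anionpi,
    detect_contact,
    detect_hbond,
    detect_pipi,
    interaction_frequency,
    ring_plane,
)
from helixmd.model import Trajectory
from helixmd.synthetic import gen_hbond_geometry, gen_ring_pair, make_pentamer_topology

CRIT = InteractionCriteria()


# -- independent brute-force oracles (plain arithmetic, no package calls) ----

def oracle_hbond(d, h, a):
    dist = np.sqrt(np.sum((d - a) ** 2))
    v1, v2 = d - h, a - h
    cosang = np.dot(v1, v2) / np.sqrt(np.sum(v1**2) * np.sum(v2**2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return dist < 3.5 and ang > 120.0


def oracle_plane(pts):
    c = pts.mean(axis=0)
    n = np.linalg.svd(pts - c)[2][2]
    return c, n


def oracle_pipi(ring_a, ring_b):
    ca, na = oracle_plane(ring_a)
    cb, nb = oracle_plane(ring_b)
    if np.sqrt(np.sum((ca - cb) ** 2)) >= 6.0:
        return False
    ang = np.degrees(np.arccos(np.clip(abs(np.dot(na, nb)), -1.0, 1.0)))
    return ang < 45.0  # sign-symmetric: |cos| folds 135-180 onto 0-45


def oracle_anionpi(ring, anion):
    c, n = oracle_plane(ring)
    axis = anion - c
    if np.sqrt(np.sum(axis**2)) >= 5.0:
        return False
    ang = np.degrees(
        np.arccos(np.clip(abs(np.dot(n, axis)) / np.sqrt(np.sum(axis**2)), -1.0, 1.0))
    )
    return ang < 40.0


class TestBoundaryConventions:
    """All criteria are strict inequalities exactly as printed."""

    @pytest.mark.parametrize(
        "d,theta,expected",
        [
            (3.4, 180.0, True),
            (3.6, 180.0, False),
            (3.4, 119.0, False),
            (3.5, 180.0, False),   # strict "smaller than 3.5"
            (3.4, 120.0, False),   # strict "larger than 120"
            (3.4, 121.0, True),
        ],
    )
    def test_hbond_boundaries(self, d, theta, expected):
        donor, hydrogen, acceptor = gen_hbond_geometry(d, theta)
        assert detect_hbond(donor, hydrogen, acceptor, CRIT) is expected

    @pytest.mark.parametrize(
        "dist,ang,expected",
        [
            (5.0, 0.0, True),
            (6.5, 0.0, False),
            (5.0, 90.0, False),
            (5.0, 170.0, True),    # 135-180 band
            (6.0, 0.0, False),     # strict "less than 6.0"
            (5.0, 45.0, False),    # strict "smaller than 45"
            (5.0, 135.0, False),   # strict "greater than 135"
            (5.0, 44.0, True),
        ],
    )
    def test_pipi_boundaries(self, dist, ang, expected):
        ring_a, ring_b = gen_ring_pair(dist, ang)
        assert detect_pipi(ring_a, ring_b, CRIT) is expected

    @pytest.mark.parametrize(
        "axial_dist,in_plane,expected",
        [(4.5, False, True), (5.5, False, False), (4.0, True, False), (5.0, False, False)],
    )
    def test_anionpi_boundaries(self, axial_dist, in_plane, expected):
        ring, _ = gen_ring_pair(5.0, 0.0)
        center, normal = ring_plane(ring)
        if in_plane:
            anion = center + np.array([axial_dist, 0.0, 0.0])  # 90° to normal
        else:
            anion = center + normal * axial_dist
        assert detect_anionpi(ring, anion, CRIT) is expected

    @pytest.mark.parametrize("dmin,expected", [(3.49, True), (3.51, False), (3.5, False)])
    def test_contact_boundaries(self, dmin, expected):
        a = np.array([[0.0, 0.0, 0.0], [0.0, 1.5, 0.0]])
        b = np.array([[dmin, 0.0, 0.0], [dmin, 1.5, 0.0], [10.0, 0.0, 0.0]])
        assert detect_contact(a, b, CRIT) is expected

    def test_identical_residue_rejected(self):
        a = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="distinct"):
            detect_contact(a, a.copy(), CRIT)

    def test_coincident_hbond_points_rejected(self):
        p = np.zeros(3)
        with pytest.raises(ValueError, match="distinct"):
            detect_hbond(p, p, np.array([1.0, 0, 0]), CRIT)


class TestOracleEquivalence:
    """Detectors agree with plain distance/angle recomputation on random geometries."""

    def test_hbond_1000_random_geometries(self):
        rng = np.random.default_rng(101)
        for _ in range(1000):
            d = float(rng.uniform(1.5, 5.0))
            theta = float(rng.uniform(5.0, 180.0))
            donor, hydrogen, acceptor = gen_hbond_geometry(d, theta)
            # random rigid placement
            R = _random_rotation(rng)
            t = rng.uniform(-20, 20, 3)
            pts = (np.stack([donor, hydrogen, acceptor]) @ R.T) + t
            assert detect_hbond(*pts, CRIT) == oracle_hbond(*pts)

    def test_pipi_1000_random_geometries(self):
        rng = np.random.default_rng(102)
        for _ in range(1000):
            ring_a, ring_b = gen_ring_pair(
                float(rng.uniform(2.0, 8.0)), float(rng.uniform(0.0, 180.0))
            )
            R = _random_rotation(rng)
            t = rng.uniform(-20, 20, 3)
            ra, rb = ring_a @ R.T + t, ring_b @ R.T + t
            ra = ra + rng.normal(0, 0.02, ra.shape)  # slight non-planarity
            assert detect_pipi(ra, rb, CRIT) == oracle_pipi(ra, rb)

    def test_anionpi_1000_random_geometries(self):
        rng = np.random.default_rng(103)
        ring0, _ = gen_ring_pair(5.0, 0.0)
        for _ in range(1000):
            R = _random_rotation(rng)
            t = rng.uniform(-20, 20, 3)
            ring = ring0 @ R.T + t
            anion = ring.mean(axis=0) + rng.uniform(-6, 6, 3)
            if np.linalg.norm(anion - ring.mean(axis=0)) < 1e-6:
                continue
            assert detect_anionpi(ring, anion, CRIT) == oracle_anionpi(ring, anion)

    def test_contact_1000_random_geometries(self):
        rng = np.random.default_rng(104)
        for _ in range(1000):
            a = rng.uniform(-3, 3, (4, 3))
            b = rng.uniform(-3, 3, (5, 3)) + rng.uniform(0, 6)
            dmin = min(
                np.sqrt(np.sum((p - q) ** 2)) for p in a for q in b
            )
            assert detect_contact(a, b, CRIT) == (dmin < 3.5)


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestRingPlane:
    def test_planar_hexagon_normal_is_z(self):
        ring, _ = gen_ring_pair(5.0, 0.0)
        center, normal = ring_plane(ring)
        assert np.allclose(center, ring.mean(axis=0))
        assert abs(abs(normal[2]) - 1.0) < 1e-12

    def test_noisy_hexagon_normal_within_3_degrees(self):
        rng = np.random.default_rng(7)
        ring, _ = gen_ring_pair(5.0, 0.0)
        noisy = ring + np.column_stack(
            [np.zeros(6), np.zeros(6), rng.uniform(-0.05, 0.05, 6)]
        )
        _, normal = ring_plane(noisy)
        ang = np.degrees(np.arccos(abs(normal[2])))
        assert ang < 3.0

    def test_collinear_points_rejected(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            ring_plane(pts)

    def test_detectors_invariant_under_normal_flip(self):
        # reflecting ring B's atom order flips its fitted normal's sign
        ring_a, ring_b = gen_ring_pair(5.0, 170.0)
        assert detect_pipi(ring_a, ring_b, CRIT) == detect_pipi(ring_a, ring_b[::-1], CRIT)
        center, normal = ring_plane(ring_a)
        anion = center + normal * 4.0
        assert detect_anionpi(ring_a, anion, CRIT) == detect_anionpi(ring_a[::-1], anion, CRIT)


@pytest.fixture(scope="module")
def tyr_asp():
    return make_pentamer_topology(2, ["TYR", "ASP"])


class TestInteractionFrequency:
    def _toggled_traj(self, top, hit_frames, n_frames, kind):
        """Trajectory where ASP's oxygens approach TYR's ring in chosen frames."""
        ref = top.reference_coordinates.copy()
        coords = np.repeat(ref[None], n_frames, axis=0)
        for sub in "ABCDE":
            ring = top.rings_of(sub, 1)[0]
            ring_pts = ref[list(ring.atom_indices)]
            center = ring_pts.mean(axis=0)
            normal = np.linalg.svd(ring_pts - center)[2][2]
            asp = top.residue_atom_indices(sub, 2)
            od1 = asp[top.names[asp] == "OD1"][0]
            near = center + normal * 4.0
            shift = near - ref[od1]
            for f in hit_frames:
                coords[f, asp, :] = ref[asp] + shift
        return Trajectory(top, coords, dt_ps=50.0)

    def test_constructed_30_percent_frequency(self, tyr_asp):
        traj = self._toggled_traj(tyr_asp, range(30), 100, "anionpi")
        freq = interaction_frequency(traj, (1, 2), "anionpi")
        assert freq.mean == pytest.approx(0.30, abs=1e-12)
        # all five subunits identical -> per-series values equal
        assert all(v == pytest.approx(0.30) for v in freq.per_series.values())
        # error propagates the per-subunit std-over-time of the indicator
        sd = np.sqrt(0.3 * 0.7)
        assert freq.error == pytest.approx(np.sqrt(5 * sd**2) / 5, abs=1e-9)

    def test_never_interacting_pair_is_zero(self, tyr_asp):
        ref = tyr_asp.reference_coordinates
        traj = Trajectory(tyr_asp, np.repeat(ref[None], 20, axis=0), dt_ps=50.0)
        freq = interaction_frequency(traj, (1, 2), "contact")
        # reference geometry separates the residues well beyond 3.5 Å
        assert freq.mean == 0.0 and freq.error == 0.0

    def test_trp_ring_frequencies_sum(self):
        """Disjoint 10% ring-1 and 5% ring-2 hits report 15%."""
        top = make_pentamer_topology(2, ["TRP", "PHE"])
        ref = top.reference_coordinates.copy()
        n = 100
        coords = np.repeat(ref[None], n, axis=0)
        for sub in "ABCDE":
            rings_trp = top.rings_of(sub, 1)
            centers = [
                ref[list(r.atom_indices)].mean(axis=0) for r in rings_trp
            ]
            ring_phe = top.rings_of(sub, 2)[0]
            phe_idx = top.residue_atom_indices(sub, 2)
            phe_center = ref[list(ring_phe.atom_indices)].mean(axis=0)
            for k, frames in ((0, range(0, 10)), (1, range(10, 15))):
                # offset away from the sibling ring so only ring k is
                # within the 6 Å center cutoff (center distances 5 / >6)
                away = centers[k] - centers[1 - k]
                away = away / np.linalg.norm(away)
                target = centers[k] + away * 3.0 + np.array([0.0, 0.0, 4.0])
                shift = target - phe_center
                for f in frames:
                    coords[f, phe_idx, :] = ref[phe_idx] + shift
        traj = Trajectory(top, coords, dt_ps=50.0)
        freq = interaction_frequency(traj, (1, 2), "pipi")
        assert freq.mean == pytest.approx(0.15, abs=1e-12)

    def test_frequency_invariant_under_frame_reordering(self, tyr_asp):
        traj = self._toggled_traj(tyr_asp, range(30), 100, "anionpi")
        rng = np.random.default_rng(0)
        perm = rng.permutation(100)
        shuffled = Trajectory(tyr_asp, traj.coordinates[perm], dt_ps=50.0)
        f1 = interaction_frequency(traj, (1, 2), "anionpi")
        f2 = interaction_frequency(shuffled, (1, 2), "anionpi")
        assert f1.mean == pytest.approx(f2.mean) and f1.error == pytest.approx(f2.error)

    def test_hbond_without_hydrogens_raises_capability_error(self):
        top = make_pentamer_topology(2, ["ALA", "ALA"])
        # strip hydrogens
        from helixmd.model import Topology

        keep = [a for a in top.atoms if a.element != "H"]
        bare = Topology(
            [type(a)(i, a.name, a.element, a.residue_seq, a.residue_name,
                     a.subunit, a.molecule_class, a.mass) for i, a in enumerate(keep)]
        )
        coords = np.zeros((2, bare.n_atoms, 3))
        coords[:] = np.arange(bare.n_atoms)[None, :, None] * 2.0
        traj = Trajectory(bare, coords, dt_ps=50.0)
        with pytest.raises(ValueError, match="hydrogens"):
            interaction_frequency(traj, (1, 2), "hbond")
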