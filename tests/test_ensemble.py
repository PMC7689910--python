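import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from fuzzynmr.core_io import DistanceConstraint, ValidationError
from fuzzynmr.ensemble import (
    assign_helix,
    bfactors,
    check_noe_constraints,
    detect_hbonds,
    gromos_cluster,
    pairwise_rmsd_matrix,
    parse_selection,
    residue_contacts,
    superpose,
)
from conftest import helix_ensemble, make_ensemble


def brute_force_gromos(rmsd, cutoff):
    """Independent reference: explicit loops, recount every iteration."""
    n = rmsd.shape[0]
    remaining = set(range(n))
    clusters = []
    while remaining:
        best_centre, best_members = None, None
        for i in sorted(remaining):
            members = {j for j in remaining if rmsd[i, j] <= cutoff} | {i}
            if best_members is None or len(members) > len(best_members):
                best_centre, best_members = i, members
        clusters.append((best_centre, frozenset(best_members)))
        remaining -= best_members
    return clusters


def jittered_ensemble(rng, n_models, sigma, n_atoms=5):
    base = rng.normal(0, 5, (n_atoms, 3))
    coords = base[None] + rng.normal(0, sigma, (n_models, n_atoms, 3))
    specs = [("A", i + 1, "A", "CA", "C") for i in range(n_atoms)]
    return make_ensemble(coords, specs)


class TestSuperpose:
    def test_rigid_rotations_collapse(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 5, (8, 3))
        frames = [
            Rotation.random(random_state=i).apply(base) + rng.normal(0, 10, 3)
            for i in range(6)
        ]
        specs = [("A", i + 1, "A", "CA", "C") for i in range(8)]
        ens = make_ensemble(np.stack(frames), specs)
        aligned, rmsd = superpose(ens)
        assert np.all(rmsd < 1e-6)
        assert pairwise_rmsd_matrix(aligned).max() < 1e-6

    def test_known_displacement_rmsd(self):
        # square expanded radially by 2 A: no net rotation/translation, so
        # the best-fit RMSD between the conformers is exactly 2 A
        base = np.array(
            [[5.0, 0, 0], [0, 5.0, 0], [-5.0, 0, 0], [0, -5.0, 0]]
        )
        expanded = base * (1 + 2.0 / 5.0)
        ens = make_ensemble(
            np.stack([base, expanded]),
            [("A", i + 1, "A", "CA", "C") for i in range(4)],
        )
        rmsd = pairwise_rmsd_matrix(ens)
        assert rmsd[0, 1] == pytest.approx(2.0, abs=0.01)

    def test_small_selection_rejected(self):
        ens = jittered_ensemble(np.random.default_rng(2), 3, 0.1)
        mask = np.zeros(ens.n_atoms, dtype=bool)
        mask[:2] = True
        with pytest.raises(ValidationError):
            superpose(ens, selection=mask)

    def test_agrees_with_scipy_alignment(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 5, (12, 3))
        b = Rotation.random(random_state=9).apply(a) + 4.0
        ens = make_ensemble(
            np.stack([b, a]), [("A", i + 1, "A", "CA", "C") for i in range(12)]
        )
        _, rmsd = superpose(ens, reference=1)
        est_rot, scipy_rmsd = Rotation.align_vectors(
            a - a.mean(0), b - b.mean(0)
        )
        assert rmsd[0] == pytest.approx(0.0, abs=1e-6)
        assert scipy_rmsd == pytest.approx(0.0, abs=1e-6)


class TestGromosCluster:
    def test_identical_snapshots_single_cluster(self):
        ens = jittered_ensemble(np.random.default_rng(4), 10, 0.0)
        result = gromos_cluster(ens, cutoff=1.0)
        assert result.sizes == [10]
        assert result.coverage(1) == 1.0

    def test_two_families_exact_sizes(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 5, (6, 3))
        shifted = base.copy()
        shifted[0] += np.array([0.0, 0.0, 8.0])  # one atom flipped far away
        fam_a = base[None] + rng.normal(0, 0.05, (30, 6, 3))
        fam_b = shifted[None] + rng.normal(0, 0.05, (20, 6, 3))
        specs = [("A", i + 1, "A", "CA", "C") for i in range(6)]
        ens = make_ensemble(np.concatenate([fam_a, fam_b]), specs)
        result = gromos_cluster(ens, cutoff=1.0)
        assert result.sizes == [30, 20]
        members_first = set(np.nonzero(result.membership == 0)[0])
        assert members_first == set(range(30))

    def test_huge_cutoff_single_cluster(self):
        ens = jittered_ensemble(np.random.default_rng(6), 12, 1.0)
        result = gromos_cluster(ens, cutoff=1e6)
        assert result.n_clusters == 1

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        ens = jittered_ensemble(rng, n, float(rng.uniform(0.2, 2.0)))
        cutoff = float(rng.uniform(0.3, 3.0))
        rmsd = pairwise_rmsd_matrix(ens)
        result = gromos_cluster(ens, cutoff=cutoff, rmsd_matrix=rmsd)
        oracle = brute_force_gromos(rmsd, cutoff)
        got = {}
        for snap, cid in enumerate(result.membership):
            got.setdefault(cid, set()).add(snap)
        # same partition in the same discovery order (size-desc, stable)
        oracle_sets = [set(m) for _, m in oracle]
        oracle_sorted = sorted(
            oracle_sets, key=lambda s: (-len(s), oracle_sets.index(s))
        )
        assert [got[k] for k in sorted(got)] == oracle_sorted


class TestBFactors:
    def test_static_ensemble_zero(self):
        ens = jittered_ensemble(np.random.default_rng(7), 5, 0.0)
        out = bfactors(ens, per_residue=False)
        assert np.allclose(out.B, 0.0)

    def test_isotropic_closed_form(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(0, 0.1, (2000, 4, 3))  # var 0.01 A^2 per coordinate
        specs = [("A", i + 1, "A", "CA", "C") for i in range(4)]
        out = bfactors(make_ensemble(coords, specs), per_residue=False)
        expected = (8 * np.pi**2 / 3) * 0.03
        assert out.B.mean() == pytest.approx(expected, rel=0.05)

    def test_variance_linearity(self):
        rng = np.random.default_rng(9)
        noise = rng.normal(0, 1.0, (500, 4, 3))
        specs = [("A", i + 1, "A", "CA", "C") for i in range(4)]
        b1 = bfactors(make_ensemble(0.1 * noise, specs), per_residue=False).B
        b2 = bfactors(
            make_ensemble(np.sqrt(2) * 0.1 * noise, specs), per_residue=False
        ).B
        assert np.allclose(b2, 2 * b1, rtol=1e-9)

    def test_global_rotation_invariance(self):
        rng = np.random.default_rng(10)
        coords = rng.normal(0, 0.2, (200, 6, 3)) + rng.normal(0, 5, (1, 6, 3))
        specs = [("A", i + 1, "A", "CA", "C") for i in range(6)]
        rot = Rotation.random(random_state=3)
        plain = bfactors(make_ensemble(coords, specs), per_residue=False).B
        spun = bfactors(
            make_ensemble(rot.apply(coords.reshape(-1, 3)).reshape(coords.shape),
                          specs),
            per_residue=False,
        ).B
        assert np.allclose(spun, plain, rtol=1e-9)

    def test_single_snapshot_rejected(self):
        ens = jittered_ensemble(np.random.default_rng(11), 1, 0.0)
        with pytest.raises(ValidationError):
            bfactors(ens)


class TestAssignHelix:
    def test_ideal_helix_one_segment(self):
        ens = helix_ensemble(n_res=10)
        # termini lack phi (res 1) and psi (res 10), so the run is 2..9
        assert assign_helix(ens) == [(2, 9)]

    def test_extended_chain_no_segments(self):
        ens = helix_ensemble(n_res=10, phi=-120.0, psi=120.0)
        assert assign_helix(ens) == []

    def test_short_run_below_min_length(self):
        # helical at 4-6 only (3 residues) within an extended chain
        from fuzzynmr.core_io import Sequence
        from fuzzynmr.synthetic_data import build_backbone

        seq = Sequence(id="mix", residues="A" * 12)
        phi = np.full(12, -120.0)
        psi = np.full(12, 120.0)
        phi[3:6] = -57.0
        psi[3:6] = -47.0
        coords, records = build_backbone(phi, psi, seq)
        ens = make_ensemble(
            coords[None], [("P", r[0], r[1], r[2], r[3]) for r in records]
        )
        assert assign_helix(ens) == []


class TestHBonds:
    def geometry(self, angle_deg, dist):
        """Donor N-H with an acceptor O at given H-bond angle/distance."""
        n = np.array([0.0, 0.0, 0.0])
        c_prev = np.array([-1.2, 0.8, 0.0])
        ca = np.array([-0.4, -1.4, 0.0])
        h_dir = (n - c_prev) / np.linalg.norm(n - c_prev) + (
            n - ca
        ) / np.linalg.norm(n - ca)
        h_dir /= np.linalg.norm(h_dir)
        h = n + 1.02 * h_dir
        # place O so that angle N-H...O equals angle_deg and |N-O| = dist
        # construct in the N-H plane
        theta = np.radians(180.0 - angle_deg)
        perp = np.cross(h_dir, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        direction = np.cos(theta) * h_dir + np.sin(theta) * perp
        # find t so |N - (H + t*direction)| = dist
        # solve quadratic |h + t d - n|^2 = dist^2
        hv = h - n
        b = 2 * np.dot(hv, direction)
        c = np.dot(hv, hv) - dist**2
        t = (-b + np.sqrt(b * b - 4 * c)) / 2
        o = h + t * direction
        specs = [
            ("A", 2, "A", "N", "N"), ("A", 2, "A", "CA", "C"),
            ("A", 1, "A", "C", "C"), ("B", 9, "A", "O", "O"),
        ]
        coords = np.array([[n, ca, c_prev, o]])
        return make_ensemble(coords, specs)

    def test_ideal_geometry_detected(self):
        ens = self.geometry(angle_deg=175.0, dist=2.9)
        out = detect_hbonds(ens, donor_chain="A", acceptor_chain="B")
        assert len(out) == 1
        assert out.iloc[0].frequency == 1.0

    def test_long_distance_rejected(self):
        ens = self.geometry(angle_deg=175.0, dist=10.0)
        assert len(detect_hbonds(ens, donor_chain="A", acceptor_chain="B")) == 0

    def test_bent_geometry_rejected(self):
        ens = self.geometry(angle_deg=120.0, dist=2.9)
        assert len(detect_hbonds(ens, donor_chain="A", acceptor_chain="B")) == 0


class TestContacts:
    def pair_ensemble(self, distances):
        """One CB atom per chain, separated by the given per-snapshot distances."""
        coords = np.array([[[0, 0, 0], [d, 0, 0]] for d in distances], dtype=float)
        specs = [("P", 26, "L", "CB", "C"), ("I", 42, "L", "CB", "C")]
        return make_ensemble(coords, specs)

    def test_persistent_contact(self):
        out = residue_contacts(self.pair_ensemble([4.0] * 5), "P", "I")
        assert out.iloc[0].frequency == 1.0

    def test_half_frequency(self):
        out = residue_contacts(self.pair_ensemble([4.0] * 50 + [8.0] * 50), "P", "I")
        assert out.iloc[0].frequency == pytest.approx(0.5)

    def test_pocket_report_of_eight(self):
        from fuzzynmr.ensemble import pocket_report

        pocket = [42, 45, 58, 62, 77, 78, 81, 82]
        coords = np.zeros((3, 9, 3))
        coords[:, 0] = [0, 0, 0]
        for k in range(8):
            ang = 2 * np.pi * k / 8
            coords[:, k + 1] = [4.0 * np.cos(ang), 4.0 * np.sin(ang), 0.0]
        specs = [("P", 53, "W", "CB", "C")] + [
            ("I", r, "L", "CB", "C") for r in pocket
        ]
        contacts = residue_contacts(make_ensemble(coords, specs), "P", "I")
        assert pocket_report(contacts, 53) == pocket

    def test_empty_selection_rejected(self):
        with pytest.raises(ValidationError):
            residue_contacts(self.pair_ensemble([4.0]), "P", "Z")


class TestNOEConstraints:
    def pair(self, distances):
        coords = np.array([[[0, 0, 0], [d, 0, 0]] for d in distances], dtype=float)
        specs = [("P", 20, "S", "HA", "H"), ("P", 23, "W", "HA", "H")]
        return make_ensemble(coords, specs)

    def constraint(self, bound=5.0):
        return DistanceConstraint(20, "HA", 23, "HA", upper_bound=bound)

    def test_constant_within_bound(self):
        out = check_noe_constraints(self.pair([4.2] * 4), [self.constraint()])
        assert out.iloc[0].status == "satisfied"

    def test_constant_beyond_bound(self):
        out = check_noe_constraints(self.pair([6.0] * 4), [self.constraint()])
        assert out.iloc[0].status == "violated"

    def test_r6_averaging_favours_close_approaches(self):
        out = check_noe_constraints(self.pair([3.0, 8.0]), [self.constraint()])
        assert out.iloc[0].effective_distance == pytest.approx(3.366, abs=0.01)
        assert out.iloc[0].status == "satisfied"

    def test_boundary_is_exact(self):
        sat = check_noe_constraints(self.pair([5.0] * 3), [self.constraint(5.0)])
        vio = check_noe_constraints(self.pair([5.001] * 3), [self.constraint(5.0)])
        assert sat.iloc[0].status == "satisfied"
        assert vio.iloc[0].status == "violated"

    def test_tightening_monotone(self):
        ens = self.pair([3.0, 8.0])
        statuses = [
            check_noe_constraints(ens, [self.constraint(b)]).iloc[0].status
            for b in (6.0, 4.0, 3.3, 3.0)
        ]
        seen_violated = False
        for s in statuses:
            if s == "violated":
                seen_violated = True
            assert not (seen_violated and s == "satisfied")

    def test_missing_atom_reported(self):
        out = check_noe_constraints(
            self.pair([4.0]), [DistanceConstraint(20, "HA", 99, "HB", 5.0)]
        )
        assert out.iloc[0].status == "unresolvable"


class TestSelectionGrammar:
    def test_parse_expression(self):
        kwargs = parse_selection("chain A and resid 2-4 10 and name N CA C")
        assert kwargs == {
            "chain": "A", "resid": [2, 3, 4, 10], "names": ["N", "CA", "C"]
        }
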