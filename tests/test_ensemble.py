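import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from paranuclei.core import Ensemble
from paranuclei.ensemble import (
    BOLTZMANN_KCAL, assign_secondary_structure, backbone_dihedrals,
    dihedral_angle, free_energy_from_counts, free_energy_surface,
    gromos_cluster, jcoupling_profile, kabsch_rmsd, karplus_j,
    map_external_classes, min_sidechain_distance, pairwise_rmsd_matrix,
    pearson, radius_of_gyration, secondary_shift, ss_propensity,
)
from paranuclei.io import ObservableTable
from paranuclei.params import KarplusParameters, load_karplus
from paranuclei.synthetic import build_backbone

from conftest import toy_conformer, toy_ensemble


# ---------------------------------------------------------------- dihedrals

def oracle_dihedral(p0, p1, p2, p3):
    """Independent IUPAC torsion oracle via plane normals and a signed
    triple product (different formulation from the implementation)."""
    n1 = np.cross(p1 - p0, p2 - p1)
    n2 = np.cross(p2 - p1, p3 - p2)
    cosang = n1 @ n2 / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if np.dot(np.cross(n1, n2), p2 - p1) < 0:
        ang = -ang
    return ang


class TestDihedrals:
    def test_matches_independent_oracle(self, rng):
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3.0
            assert dihedral_angle(*pts) == pytest.approx(
                oracle_dihedral(*pts), abs=1e-9)

    def test_planar_cis_is_zero(self):
        pts = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 0.0],
                        [2.0, 0.0, 0.0], [1.5, 1.0, 0.0]])
        assert dihedral_angle(*pts) == pytest.approx(0.0, abs=1e-9)

    def test_trans_is_180(self):
        pts = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 0.0],
                        [2.0, 0.0, 0.0], [3.0, -1.0, 0.0]])
        assert abs(dihedral_angle(*pts)) == pytest.approx(180.0, abs=1e-9)

    def test_extended_chain_round_trip(self):
        pp = np.column_stack([np.full(6, 180.0), np.full(6, 180.0)])
        c = build_backbone("AAAAAA", pp)
        d = backbone_dihedrals(Ensemble([c]))
        assert np.nanmax(np.abs(np.abs(d.phi[0, 1:]) - 180.0)) < 0.5
        assert np.nanmax(np.abs(np.abs(d.psi[0, :-1]) - 180.0)) < 0.5

    def test_termini_marked_missing(self, helical_peptide):
        d = backbone_dihedrals(Ensemble([helical_peptide]))
        assert np.isnan(d.phi[0, 0])
        assert np.isnan(d.psi[0, -1])
        assert np.isfinite(d.phi[0, 1:]).all()


# ----------------------------------------------------------------- Karplus

class TestKarplus:
    @pytest.fixture
    def params(self):
        return load_karplus()

    def test_at_offset_gives_sum(self, params):
        assert karplus_j(params.offset_deg, params) == pytest.approx(
            params.A + params.B + params.C)

    @pytest.mark.parametrize("delta", [90.0, -90.0])
    def test_at_offset_plus_90_gives_c(self, params, delta):
        assert karplus_j(params.offset_deg + delta, params) == \
            pytest.approx(params.C, abs=1e-12)

    def test_minus60_with_offset60(self):
        p = KarplusParameters(A=6.51, B=-1.76, C=1.60, offset_deg=60.0)
        # cos(-120°) = -1/2: J = A/4 - B/2 + C
        expected = 0.25 * p.A - 0.5 * p.B + p.C
        assert karplus_j(-60.0, p) == pytest.approx(expected)

    def test_profile_within_analytic_range(self, rng, params):
        pp = np.stack([np.column_stack([rng.uniform(-180, 180, 5),
                                        rng.uniform(-180, 180, 5)])
                       for _ in range(20)])
        ens = Ensemble([build_backbone("AAAAA", f) for f in pp])
        profile = jcoupling_profile(backbone_dihedrals(ens), params)
        lo, hi = params.analytic_range()
        for v in profile.present().values():
            assert lo - 1e-9 <= v <= hi + 1e-9

    def test_first_residue_omitted(self, helical_peptide):
        d = backbone_dihedrals(Ensemble([helical_peptide]))
        profile = jcoupling_profile(d)
        assert 1 not in profile.values
        assert set(profile.values) == set(range(2, 13))

    def test_analytic_range_bounds_grid(self, params):
        grid = karplus_j(np.linspace(-180, 180, 100001), params)
        lo, hi = params.analytic_range()
        assert grid.min() == pytest.approx(lo, abs=1e-6)
        assert grid.max() == pytest.approx(hi, abs=1e-6)


# --------------------------------------------------------- secondary shift

class TestSecondaryShift:
    def test_identical_gives_zero(self):
        obs = ObservableTable({1: 56.0, 2: 54.0}, kind="shift")
        out = secondary_shift(obs, obs)
        assert all(v == 0.0 for v in out.present().values())

    def test_sign_is_coil_minus_observed(self):
        obs = ObservableTable({1: 54.0}, kind="shift")
        coil = ObservableTable({1: 56.0}, kind="shift")
        assert secondary_shift(obs, coil).values[1] == pytest.approx(2.0)
        assert secondary_shift(obs, coil, "obs_minus_coil").values[1] == \
            pytest.approx(-2.0)

    def test_residue_absent_from_reference_is_missing(self):
        obs = ObservableTable({1: 54.0, 2: 45.0}, kind="shift")
        coil = ObservableTable({1: 56.0}, kind="shift")
        out = secondary_shift(obs, coil)
        assert out.missing() == [2]

    def test_kind_mismatch_rejected(self):
        obs = ObservableTable({1: 6.5}, kind="jcoupling")
        coil = ObservableTable({1: 56.0}, kind="shift")
        with pytest.raises(ValueError):
            secondary_shift(obs, coil)


class TestPearson:
    def test_perfect_correlations(self):
        x = ObservableTable({i: float(i) for i in range(1, 6)},
                            kind="shift")
        y = ObservableTable({i: -float(i) for i in range(1, 6)},
                            kind="shift")
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, y) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        xv, yv = [1.0, 2.0, 3.0], [1.0, 2.0, 4.0]
        x = ObservableTable(dict(enumerate(xv, 1)), kind="shift")
        y = ObservableTable(dict(enumerate(yv, 1)), kind="shift")
        xa, ya = np.array(xv), np.array(yv)
        expected = (((xa - xa.mean()) * (ya - ya.mean())).sum()
                    / np.sqrt(((xa - xa.mean()) ** 2).sum()
                              * ((ya - ya.mean()) ** 2).sum()))
        assert pearson(x, y) == pytest.approx(expected)

    def test_zero_variance_signalled(self):
        x = ObservableTable({1: 1.0, 2: 1.0, 3: 1.0}, kind="shift")
        y = ObservableTable({1: 1.0, 2: 2.0, 3: 3.0}, kind="shift")
        with pytest.raises(ValueError):
            pearson(x, y)

    def test_computed_on_shared_subset(self):
        x = ObservableTable({1: 1.0, 2: 2.0, 3: 3.0, 9: 9.0}, kind="shift")
        y = ObservableTable({1: 1.0, 2: 2.0, 3: 3.0, 8: -5.0}, kind="shift")
        assert pearson(x, y) == pytest.approx(1.0)


# ---------------------------------------------------- secondary structure

class TestSecondaryStructure:
    def test_canonical_helix_region(self):
        pp = np.column_stack([np.full(8, -60.0), np.full(8, -45.0)])
        ens = Ensemble([build_backbone("A" * 8, pp)])
        d = backbone_dihedrals(ens)
        cls = assign_secondary_structure(d, 0)
        assert all(c == "H" for c in cls[1:-1])

    def test_canonical_extended_region(self):
        pp = np.column_stack([np.full(8, -120.0), np.full(8, 130.0)])
        ens = Ensemble([build_backbone("A" * 8, pp)])
        d = backbone_dihedrals(ens)
        cls = assign_secondary_structure(d, 0)
        assert all(c == "E" for c in cls[1:-1])

    def test_external_class_grouping(self):
        assert list(map_external_classes(list("GIBHETXC"))) == \
            ["H", "H", "E", "H", "E", "T", "C", "C"]

    def test_propensity_all_identical_frames(self):
        pp = np.column_stack([np.full(6, -60.0), np.full(6, -45.0)])
        c = build_backbone("A" * 6, pp)
        props = ss_propensity(Ensemble([c, c, c]))
        for r in range(2, 6):
            assert props["H"].values[r] == pytest.approx(100.0)
            assert props["E"].values[r] == pytest.approx(0.0)

    def test_propensity_half_half(self):
        assignments = np.array([["H"] * 4, ["C"] * 4])
        props = ss_propensity(assignments=assignments)
        assert props["H"].values[1] == pytest.approx(50.0)

    def test_propensity_frame_order_invariant(self, rng):
        assignments = rng.choice(list("HETC"), size=(30, 5))
        p1 = ss_propensity(assignments=assignments)
        p2 = ss_propensity(assignments=assignments[::-1])
        for cls in "HET":
            assert p1[cls].values == p2[cls].values

    def test_profiles_sum_at_most_100(self, rng):
        assignments = rng.choice(list("HETC"), size=(40, 6))
        props = ss_propensity(assignments=assignments)
        for r in range(1, 7):
            total = sum(props[c].values[r] for c in "HET")
            assert total <= 100.0 + 1e-9


# ---------------------------------------------------------------- RMSD/Rg

def oracle_grid_rmsd(a, b, levels=4):
    """Brute-force minimum RMSD over a refined Euler-angle grid (nm)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def rmsd_at(angles):
        rot = Rotation.from_euler("zyz", angles).as_matrix()
        return np.sqrt(((a @ rot.T - b) ** 2).sum(axis=1).mean())

    best_angles, best = np.zeros(3), np.inf
    span = 180.0
    centers = np.zeros(3)
    for level in range(levels):
        steps = np.linspace(-span, span, 13)
        for da in steps:
            for db in steps:
                for dc in steps:
                    ang = np.radians(centers + [da, db, dc])
                    r = rmsd_at(ang)
                    if r < best:
                        best, best_angles = r, centers + [da, db, dc]
        centers = best_angles
        span /= 12.0
    return best / 10.0


class TestKabschRmsd:
    def test_zero_on_self(self, point_body):
        assert kabsch_rmsd(point_body, point_body, "all") == \
            pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, point_body, rng):
        rot = Rotation.random(random_state=7).as_matrix()
        moved = point_body.with_coords(
            point_body.coords @ rot.T + rng.normal(size=3) * 10)
        assert kabsch_rmsd(point_body, moved, "all") == \
            pytest.approx(0.0, abs=1e-6)

    def test_symmetric(self, point_body, rng):
        other = point_body.with_coords(
            point_body.coords + rng.normal(size=point_body.coords.shape))
        assert kabsch_rmsd(point_body, other, "all") == pytest.approx(
            kabsch_rmsd(other, point_body, "all"), abs=1e-12)

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(3):
            a = toy_conformer(rng.normal(size=(4, 3)) * 2.0)
            b = toy_conformer(rng.normal(size=(4, 3)) * 2.0)
            assert kabsch_rmsd(a, b, "all") == pytest.approx(
                oracle_grid_rmsd(a.coords, b.coords), abs=1e-3)

    def test_collinear_points_rejected(self):
        line = toy_conformer(np.column_stack([np.arange(4.0),
                                              np.zeros(4), np.zeros(4)]))
        other = toy_conformer(np.column_stack([np.zeros(4),
                                               np.arange(4.0), np.zeros(4)]))
        with pytest.raises(ValueError):
            kabsch_rmsd(line, other, "all")

    def test_pairwise_matrix_matches_pairwise_calls(self, rng):
        frames = rng.normal(size=(6, 5, 3)) * 3.0
        mat = pairwise_rmsd_matrix(frames)
        ens = toy_ensemble(frames)
        for i in range(6):
            for j in range(6):
                assert mat[i, j] == pytest.approx(
                    kabsch_rmsd(ens[i], ens[j], "all"), abs=1e-9)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration(toy_conformer([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_points_10A_apart(self):
        c = toy_conformer([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        assert radius_of_gyration(c) == pytest.approx(0.5)

    def test_square_corners(self):
        # side 20 Å (2 nm): Rg = half diagonal = sqrt(2) nm
        c = toy_conformer([[0, 0, 0], [20, 0, 0], [20, 20, 0], [0, 20, 0]])
        assert radius_of_gyration(c) == pytest.approx(np.sqrt(2.0))


# ------------------------------------------------------------ free energy

class TestFreeEnergySurface:
    def test_equal_counts_equal_f(self):
        f = free_energy_from_counts(np.array([[4.0, 4.0]]))
        assert f[0, 0] == pytest.approx(f[0, 1])

    def test_count_ratio_e_gives_kt(self):
        counts = np.array([[np.e, 1.0]])
        f = free_energy_from_counts(counts, temperature=300.0)
        assert f[0, 1] - f[0, 0] == pytest.approx(
            BOLTZMANN_KCAL * 300.0, abs=1e-9)
        assert f[0, 1] - f[0, 0] == pytest.approx(0.59616, abs=1e-4)

    def test_empty_bins_masked(self):
        f = free_energy_from_counts(np.array([[5.0, 0.0]]))
        assert np.isnan(f[0, 1])
        assert np.isfinite(f[0, 0])

    def test_count_scaling_leaves_deltas(self, rng):
        counts = rng.integers(1, 50, size=(4, 4)).astype(float)
        f1 = free_energy_from_counts(counts)
        f2 = free_energy_from_counts(counts * 37.0)
        assert np.allclose(f1, f2, atol=1e-9)

    def test_surface_from_ensemble(self, rng):
        frames = rng.normal(size=(30, 6, 3)) * 3.0
        ens = toy_ensemble(frames)
        fes = free_energy_surface(ens, ens[0], bins=5, selection="all")
        assert fes.counts.sum() == 30
        assert np.nanmin(fes.free_energy) == pytest.approx(0.0)


# -------------------------------------------------------------- clustering

def oracle_gromos(dmat, cutoff):
    """Exhaustive reference of the neighbor-count clustering."""
    n = len(dmat)
    remaining = set(range(n))
    clusters = []
    while remaining:
        best, best_count = None, -1
        for i in sorted(remaining):
            count = sum(1 for j in remaining
                        if j != i and dmat[i, j] <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = sorted({best} | {j for j in remaining
                                   if j != best and dmat[best, j] <= cutoff})
        clusters.append((best, members))
        remaining -= set(members)
    clusters.sort(key=lambda c: (-len(c[1]), c[0]))
    return clusters


class TestGromosCluster:
    def test_all_identical_one_cluster(self):
        frames = np.tile(np.arange(12.0).reshape(4, 3), (5, 1, 1))
        cs = gromos_cluster(toy_ensemble(frames), cutoff=0.2,
                            selection="all")
        assert len(cs) == 1
        assert cs.sizes == [5]

    def test_two_separated_groups(self, rng):
        base = rng.normal(size=(5, 3)) * 3.0
        other = rng.normal(size=(5, 3)) * 3.0  # distinct internal shape
        group1 = [base + rng.normal(scale=0.1, size=(5, 3))
                  for _ in range(4)]
        group2 = [other + rng.normal(scale=0.1, size=(5, 3))
                  for _ in range(3)]
        cs = gromos_cluster(toy_ensemble(group1 + group2), cutoff=0.2,
                            selection="all")
        assert len(cs) == 2
        assert cs.sizes == [4, 3]

    def test_matches_exhaustive_oracle(self, rng):
        frames = rng.normal(size=(15, 4, 3)) * 2.0
        dmat = pairwise_rmsd_matrix(frames)
        cutoff = float(np.median(dmat))
        cs = gromos_cluster(dmat, cutoff=cutoff)
        expected = oracle_gromos(dmat, cutoff)
        assert [c for c in cs.clusters] == [m for _, m in expected]
        assert cs.representatives == [r for r, _ in expected]

    def test_partition_property(self, rng):
        frames = rng.normal(size=(20, 4, 3))
        cs = gromos_cluster(toy_ensemble(frames), cutoff=0.15,
                            selection="all")
        flat = sorted(i for c in cs.clusters for i in c)
        assert flat == list(range(20))

    def test_nonpositive_cutoff_rejected(self, rng):
        frames = rng.normal(size=(3, 4, 3))
        with pytest.raises(ValueError):
            gromos_cluster(toy_ensemble(frames), cutoff=0.0)


# ------------------------------------------------------ sidechain distance

class TestMinSidechainDistance:
    def test_residue_vs_itself_zero(self, tripeptide):
        assert min_sidechain_distance(tripeptide, 1, 1) == 0.0

    def test_glycine_uses_ca(self, tripeptide):
        d = min_sidechain_distance(tripeptide, 1, 3)
        ca3 = tripeptide.coords[(tripeptide.resids == 3)
                                & (tripeptide.atom_names == "CA")][0]
        sc1 = tripeptide.coords[(tripeptide.resids == 1)
                                & ~np.isin(tripeptide.atom_names,
                                           ("N", "CA", "C", "O"))]
        expected = np.linalg.norm(sc1 - ca3, axis=1).min() / 10.0
        assert d == pytest.approx(expected)

    def test_matches_exhaustive_pairwise_min(self, tripeptide):
        d = min_sidechain_distance(tripeptide, 1, 2)
        backbone = ("N", "CA", "C", "O", "OXT")
        best = np.inf
        for i in range(tripeptide.n_atoms):
            for j in range(tripeptide.n_atoms):
                if tripeptide.resids[i] == 1 and tripeptide.resids[j] == 2 \
                        and tripeptide.atom_names[i] not in backbone \
                        and tripeptide.atom_names[j] not in backbone:
                    best = min(best, np.linalg.norm(
                        tripeptide.coords[i] - tripeptide.coords[j]))
        assert d == pytest.approx(best / 10.0)

    def test_missing_residue_rejected(self, tripeptide):
        with pytest.raises(ValueError):
            min_sidechain_distance(tripeptide, 1, 99)
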