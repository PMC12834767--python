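"""Torus metric, density clustering, medoids and the conditional KDE."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from torsionscan import (
    MixtureComponent,
    MixtureSpec,
    TorusHDBSCAN,
    assemble_points,
    cluster_fragments,
    cluster_medoids,
    max_basin_combinations,
    sample_dihedral_mixture,
    target_conditional_density,
    target_residue_index,
    torus_distance,
)
from torsionscan.fragment_index import FragmentMatch, OccurrenceRef
from torsionscan.torus_cluster import (
    InsufficientDataError,
    TorsionPointSet,
    pairwise_torus_distances,
    wrap_degrees,
)


def _match(kmer, angles, entry="E001", start=0):
    ref = OccurrenceRef(entry_id=entry, model_id=1, chain_id="A",
                        segment_index=0, start=start, k=len(kmer))
    return FragmentMatch(kmer=kmer, ref=ref, angles=angles,
                         omegas=[180.0] * len(kmer))


class TestTorusDistance:
    def test_zero_for_identical_points(self):
        assert torus_distance([10.0, -20.0], [10.0, -20.0]) == 0.0

    def test_wraparound_at_the_seam(self):
        # -179 and 179 are 2 degrees apart on the circle, not 358
        assert torus_distance([-179.0], [179.0]) == pytest.approx(2.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            torus_distance([0.0], [0.0, 1.0])

    def test_matches_shift_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            u = rng.uniform(-180, 180, size=4)
            v = rng.uniform(-180, 180, size=4)
            # oracle: brute-force min over all +/-360 shifts per coordinate
            best = np.full(4, np.inf)
            for shifts in itertools.product([-360.0, 0.0, 360.0], repeat=4):
                best = np.minimum(best, np.abs(u - v + np.array(shifts)))
            assert torus_distance(u, v) == pytest.approx(float(np.sqrt((best**2).sum())))

    @given(st.lists(st.floats(min_value=-180, max_value=180), min_size=2, max_size=6))
    def test_wrap_invariance_of_distance(self, coords):
        u = np.array(coords)
        v = u[::-1].copy()
        shifted = wrap_degrees(u + 360.0)
        assert torus_distance(shifted, v) == pytest.approx(torus_distance(u, v), abs=1e-9)


class TestAssemble:
    def test_rows_are_2k_wide(self):
        matches = [_match("ACD", [(1.0, 2.0), (3.0, 4.0), (5.0, 6.0)]) for _ in range(4)]
        pts = assemble_points(matches)
        assert pts.points.shape == (4, 6)
        assert pts.n_excluded == 0

    def test_undefined_terminal_angle_excluded(self):
        good = _match("AC", [(1.0, 2.0), (3.0, 4.0)])
        bad = _match("AC", [(None, 2.0), (3.0, 4.0)])
        pts = assemble_points([good, bad])
        assert len(pts) == 1
        assert pts.n_excluded == 1

    def test_mixed_k_rejected(self):
        with pytest.raises(ValueError):
            assemble_points([_match("AC", [(0.0, 0.0)] * 2),
                             _match("ACD", [(0.0, 0.0)] * 3)])

    def test_empty_points_refuse_clustering(self):
        pts = assemble_points([])
        with pytest.raises(InsufficientDataError):
            cluster_fragments(pts)


class TestClustering:
    def test_identical_points_form_one_cluster_no_noise(self):
        pts = TorsionPointSet(points=np.tile([10.0, 20.0], (30, 1)))
        res = cluster_fragments(pts)
        assert res.n_clusters == 1
        assert res.n_noise == 0

    def test_two_separated_blobs_recovered(self):
        spec = MixtureSpec(components=[
            MixtureComponent(center=np.array([-60.0, -40.0, -60.0, -40.0]),
                             kappa=50.0, weight=0.5),
            MixtureComponent(center=np.array([60.0, 80.0, 60.0, 80.0]),
                             kappa=50.0, weight=0.5),
        ])
        X = sample_dihedral_mixture(spec, 400, seed=3)
        res = cluster_fragments(TorsionPointSet(points=X))
        assert res.n_clusters == 2
        assert (len(X) - res.n_noise) / len(X) >= 0.95

    def test_blobs_straddling_the_seam_cluster_together(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0.0, 3.0, size=(100, 2))
        near_seam = wrap_degrees(base + np.array([179.0, -179.0]))
        res = cluster_fragments(TorsionPointSet(points=near_seam))
        assert res.n_clusters == 1

    def test_wrap_invariance_of_labels_and_medoids(self):
        rng = np.random.default_rng(5)
        X = np.vstack([
            rng.normal([-60, -40], 5, size=(80, 2)),
            rng.normal([120, 140], 5, size=(80, 2)),
        ])
        X = wrap_degrees(X)
        res1 = cluster_fragments(TorsionPointSet(points=X))
        shifted = wrap_degrees(X + 360.0)
        res2 = cluster_fragments(TorsionPointSet(points=shifted))
        np.testing.assert_array_equal(res1.labels, res2.labels)
        assert res1.medoid_indices == res2.medoid_indices

    def test_permutation_invariance_of_partition_and_medoid_set(self):
        rng = np.random.default_rng(6)
        X = np.vstack([
            rng.normal([-60, -40], 5, size=(60, 2)),
            rng.normal([100, 120], 5, size=(60, 2)),
        ])
        X = wrap_degrees(X)
        perm = rng.permutation(len(X))
        res1 = cluster_fragments(TorsionPointSet(points=X))
        res2 = cluster_fragments(TorsionPointSet(points=X[perm]))
        # same partition: labels agree up to renaming
        for c in set(res1.labels[res1.labels >= 0]):
            members = np.flatnonzero(res1.labels == c)
            mapped = res2.labels[np.argsort(perm)][members]
            assert len(set(mapped)) == 1
        # same medoid points
        m1 = {tuple(X[i]) for i in res1.medoid_indices.values()}
        m2 = {tuple(X[perm][i]) for i in res2.medoid_indices.values()}
        assert m1 == m2

    def test_every_nonnoise_point_in_exactly_one_cluster(self):
        spec = MixtureSpec(components=[
            MixtureComponent(center=np.array([-60.0, -40.0]), kappa=30.0, weight=0.5),
            MixtureComponent(center=np.array([100.0, 120.0]), kappa=30.0, weight=0.5),
        ])
        X = sample_dihedral_mixture(spec, 300, seed=8)
        res = cluster_fragments(TorsionPointSet(points=X))
        assert res.n_clusters <= len(X)
        assert set(res.sizes) == set(res.medoid_indices)
        for c, med in res.medoid_indices.items():
            assert res.labels[med] == c

    def test_planted_joint_components_recovered(self):
        # single-basin components per residue: recovered C equals the
        # number of planted joint components
        centers = [(-60.0, -40.0, -120.0, 130.0), (60.0, 40.0, -60.0, -40.0),
                   (-120.0, 130.0, 60.0, 40.0)]
        spec = MixtureSpec(components=[
            MixtureComponent(center=np.array(c), kappa=60.0, weight=1 / 3)
            for c in centers
        ])
        X = sample_dihedral_mixture(spec, 450, seed=12)
        res = cluster_fragments(TorsionPointSet(points=X))
        assert res.n_clusters == 3
        assert res.n_clusters <= max_basin_combinations(2)

    def test_subsampling_caps_point_count(self):
        rng = np.random.default_rng(1)
        X = wrap_degrees(rng.normal(0, 5, size=(500, 2)))
        est = TorusHDBSCAN(max_points=200, random_state=4).fit(X)
        assert len(est.labels_) == 200
        assert est.subsample_indices_ is not None

    def test_deterministic_given_fixed_inputs(self):
        spec = MixtureSpec(components=[
            MixtureComponent(center=np.array([0.0, 0.0]), kappa=20.0, weight=1.0)
        ])
        X = sample_dihedral_mixture(spec, 120, seed=2)
        r1 = cluster_fragments(TorsionPointSet(points=X))
        r2 = cluster_fragments(TorsionPointSet(points=X))
        np.testing.assert_array_equal(r1.labels, r2.labels)
        assert r1.medoid_indices == r2.medoid_indices


class TestMedoids:
    def test_singleton_cluster_medoid_is_its_member(self):
        pts = TorsionPointSet(points=np.array([[0.0, 0.0]]))
        from torsionscan.torus_cluster import ClusterResult
        res = ClusterResult(labels=np.array([0]), n_clusters=1,
                            medoid_indices={}, sizes={0: 1}, n_noise=0)
        assert cluster_medoids(pts, res) == {0: 0}

    def test_collinear_points_medoid_is_central(self):
        pts = TorsionPointSet(points=np.array([[0.0], [10.0], [20.0], [30.0], [40.0]]))
        from torsionscan.torus_cluster import ClusterResult
        res = ClusterResult(labels=np.zeros(5, dtype=int), n_clusters=1,
                            medoid_indices={}, sizes={0: 5}, n_noise=0)
        assert cluster_medoids(pts, res) == {0: 2}

    def test_medoid_equals_exhaustive_search(self):
        rng = np.random.default_rng(9)
        X = wrap_degrees(rng.uniform(-180, 180, size=(40, 4)))
        labels = np.array([0] * 20 + [1] * 20)
        from torsionscan.torus_cluster import ClusterResult
        res = ClusterResult(labels=labels, n_clusters=2, medoid_indices={},
                            sizes={0: 20, 1: 20}, n_noise=0)
        got = cluster_medoids(TorsionPointSet(points=X), res)
        for c in (0, 1):
            members = np.flatnonzero(labels == c)
            totals = [
                sum(torus_distance(X[i], X[j]) for j in members) for i in members
            ]
            assert got[c] == members[int(np.argmin(totals))]


class TestTargetResidue:
    @pytest.mark.parametrize("k, expected", [(1, 0), (4, 1), (5, 2), (6, 2), (7, 3)])
    def test_center_or_first_of_two_central(self, k, expected):
        assert target_residue_index(k) == expected

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            target_residue_index(0)


class TestConditionalDensity:
    def test_single_pair_density_peaks_at_that_cell(self):
        m = _match("ACD", [(0.0, 0.0), (-60.0, -40.0), (0.0, 0.0)])
        grid = target_conditional_density([m], bandwidth=10.0)
        phi, psi = grid.mode()
        assert abs(phi - (-60.0)) <= 360.0 / len(grid.phi_grid)
        assert abs(psi - (-40.0)) <= 360.0 / len(grid.psi_grid)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(3)
        matches = [
            _match("ACDEF", [(float(a), float(b))] * 5)
            for a, b in rng.uniform(-180, 180, size=(50, 2))
        ]
        grid = target_conditional_density(matches)
        assert grid.density.sum() * grid.cell_area == pytest.approx(1.0, abs=1e-6)

    def test_von_mises_mode_recovered_within_one_cell(self):
        spec = MixtureSpec(components=[
            MixtureComponent(center=np.array([-63.0, -43.0]), kappa=40.0, weight=1.0)
        ])
        samples = sample_dihedral_mixture(spec, 800, seed=4)
        matches = [_match("ACD", [(0.0, 0.0), (float(a), float(b)), (0.0, 0.0)])
                   for a, b in samples]
        grid = target_conditional_density(matches)
        cell = 360.0 / len(grid.phi_grid)
        phi, psi = grid.mode()
        assert abs(phi - (-63.0)) <= 1.5 * cell
        assert abs(psi - (-43.0)) <= 1.5 * cell

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            target_conditional_density([])


def test_basin_combination_bound():
    assert max_basin_combinations(5) == 243
    assert max_basin_combinations(2, 1) == 1
    with pytest.raises(ValueError):
        max_basin_combinations(0)
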