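"""Ensemble statistics: Γ metric, clustering, shape, FISH triples, WLC fit."""

import numpy as np
import pytest

from hiphop.structure import (ConformationEnsemble, activity_score,
                              cluster_conformations, gamma_distance,
                              gamma_matrix, interaction_grouping, locus_size,
                              mean_squared_displacement, persistence_length,
                              size_and_shape, smooth_contour,
                              variability_volume, wlc_rg2)


def rigid_transform(x, rng):
    q = rng.normal(size=(3, 3))
    u, _, vt = np.linalg.svd(q)
    rot = u @ vt
    if np.linalg.det(rot) < 0:
        rot[:, 0] *= -1
    return x @ rot.T + rng.normal(size=3)


class TestGamma:
    def test_hand_example(self):
        a = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        b = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], float)
        assert gamma_distance(a, b) == pytest.approx(0.3382, abs=2e-4)

    def test_identity_symmetry_rigid_invariance(self, rng):
        a = rng.normal(size=(12, 3))
        b = rng.normal(size=(12, 3))
        assert gamma_distance(a, a) == 0.0
        assert gamma_distance(a, b) == pytest.approx(gamma_distance(b, a))
        assert gamma_distance(rigid_transform(a, rng), b) == pytest.approx(
            gamma_distance(a, b))

    def test_triangle_inequality(self, rng):
        for _ in range(20):
            a, b, c = rng.normal(size=(3, 8, 3))
            assert gamma_distance(a, c) <= (gamma_distance(a, b)
                                            + gamma_distance(b, c) + 1e-12)

    def test_too_few_beads_rejected(self):
        with pytest.raises(ValueError):
            gamma_distance(np.zeros((1, 3)), np.zeros((1, 3)))


class TestClustering:
    def test_planted_partition_recovered(self, rng):
        """First split separates two synthetic conformation families."""
        line = np.c_[np.arange(20.0), np.zeros(20), np.zeros(20)]
        ball = rng.normal(size=(20, 3))
        fam_a = [rigid_transform(line + 0.1 * rng.normal(size=line.shape), rng)
                 for _ in range(8)]
        fam_b = [rigid_transform(ball + 0.1 * rng.normal(size=ball.shape), rng)
                 for _ in range(8)]
        ens = ConformationEnsemble(np.array(fam_a + fam_b))
        Z, coph, labels = cluster_conformations(ens)
        from scipy.cluster.hierarchy import fcluster
        labels2 = fcluster(Z, t=2, criterion="maxclust")
        assert len(set(labels2[:8])) == 1
        assert len(set(labels2[8:])) == 1
        assert labels2[0] != labels2[8]
        assert coph > 0.7

    def test_duplicates_merge_at_zero(self, rng):
        conf = rng.normal(size=(6, 3))
        ens = ConformationEnsemble(np.array([conf, conf.copy(),
                                             conf + rng.normal(size=(6, 3))]))
        Z, _, _ = cluster_conformations(ens)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_cophenetic_one_for_ultrametric(self, rng):
        # two pairs of exact duplicates: Γ distances {0, 0, c, c, c, c}
        # are ultrametric, so the dendrogram reproduces them exactly
        a = rng.normal(size=(5, 3))
        b = 3.0 * rng.normal(size=(5, 3))
        ens = ConformationEnsemble(np.array([a, a.copy(), b, b.copy()]))
        Z, coph, _ = cluster_conformations(ens)
        assert coph == pytest.approx(1.0, abs=1e-9)

    def test_gamma_matrix_matches_pairwise_calls(self, rng):
        ens = ConformationEnsemble(rng.normal(size=(4, 6, 3)))
        condensed = gamma_matrix(ens)
        k = 0
        for i in range(4):
            for j in range(i + 1, 4):
                assert condensed[k] == pytest.approx(gamma_distance(
                    ens.positions[i], ens.positions[j]))
                k += 1


class TestSizeShape:
    def test_line_anisotropy_one(self):
        x = np.c_[np.arange(10.0), np.zeros(10), np.zeros(10)]
        rg, k2 = size_and_shape(x)
        assert k2 == pytest.approx(1.0)

    def test_tetrahedron_anisotropy_zero(self):
        x = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                     float)
        _, k2 = size_and_shape(x)
        assert k2 == pytest.approx(0.0, abs=1e-12)

    def test_two_beads_rg_half_distance(self):
        x = np.array([[0, 0, 0], [3.0, 0, 0]])
        rg, _ = size_and_shape(x)
        assert rg == pytest.approx(1.5)

    def test_rotation_invariance(self, rng):
        x = rng.normal(size=(15, 3))
        rg1, k1 = size_and_shape(x)
        rg2, k2 = size_and_shape(rigid_transform(x, rng))
        assert rg1 == pytest.approx(rg2)
        assert k1 == pytest.approx(k2)


class TestLocusSize:
    def test_equilateral(self):
        d = 2.5
        assert locus_size([d, d, d]) == pytest.approx(d / np.sqrt(3))

    def test_zero(self):
        assert locus_size([0, 0, 0]) == 0.0

    def test_collinear_matches_three_point_rg(self):
        d = 1.7
        s = locus_size([d, d, 2 * d])
        # oracle: Rg of points at 0, d, 2d on a line
        pts = np.array([[0.0], [d], [2 * d]])
        rg = np.sqrt(np.mean((pts - pts.mean()) ** 2))
        assert s == pytest.approx(rg)
        assert s == pytest.approx(d * np.sqrt(6) / 3, rel=1e-9)

    def test_matches_generic_three_point_rg(self, rng):
        pts = rng.normal(size=(3, 3))
        d = [np.linalg.norm(pts[0] - pts[1]), np.linalg.norm(pts[1] - pts[2]),
             np.linalg.norm(pts[2] - pts[0])]
        c = pts - pts.mean(axis=0)
        rg = np.sqrt(np.mean(np.sum(c**2, axis=1)))
        assert locus_size(d) == pytest.approx(rg)

    def test_triangle_violation_warns(self):
        with pytest.warns(UserWarning):
            locus_size([1.0, 1.0, 5.0])


class TestVariabilityVolume:
    def test_identical_triples_zero(self):
        assert variability_volume(np.tile([1.0, 2.0, 3.0], (10, 1))) == 0.0

    def test_coplanar_cloud_zero(self, rng):
        a = rng.normal(size=(30, 2))
        cloud = np.c_[a, a.sum(axis=1)]  # z = x + y: coplanar
        assert variability_volume(cloud) == pytest.approx(0.0, abs=1e-9)

    def test_equals_det_covariance(self, rng):
        """Gyration-tensor product of moments == det(cov) identity."""
        for _ in range(10):
            cloud = rng.normal(size=(rng.integers(5, 50), 3)) * [1, 2, 3]
            vol = variability_volume(cloud)
            cov = np.cov(cloud.T, bias=True)
            assert vol == pytest.approx(np.linalg.det(cov), rel=1e-9)

    def test_too_few_points_warns_and_zero(self):
        with pytest.warns(UserWarning):
            assert variability_volume(np.zeros((2, 3))) == 0.0


class TestInteractionGrouping:
    @pytest.mark.parametrize("d,expected", [
        ((5.0, 10.0, 12.0), 2),   # promoter-URR only
        ((10.0, 5.0, 12.0), 3),   # promoter-DRR only
        ((10.0, 10.0, 10.0), 1),  # nothing below threshold
        ((5.0, 5.0, 5.0), 5),     # all three
        ((10.0, 10.0, 5.0), 4),   # enhancers only
        ((5.0, 5.0, 12.0), 5),    # promoter bridges both: counted as 5
    ])
    def test_group_assignment(self, d, expected):
        g = interaction_grouping(*[np.array([x]) for x in d])
        assert g[0] == expected

    def test_partition_property(self, rng):
        d1, d2, d3 = rng.uniform(0, 15, (3, 500))
        g = interaction_grouping(d1, d2, d3)
        assert ((g >= 1) & (g <= 5)).all()
        assert sum((g == k).sum() for k in range(1, 6)) == 500


class TestActivityScore:
    def test_values(self):
        t, _ = activity_score([2.0, 1.0], [2.0, 2.0])
        assert t[0] == pytest.approx(1.0)
        assert t[1] == pytest.approx(1.5)

    def test_constant_ensemble_zero_heterogeneity(self):
        _, het = activity_score(np.full(50, 2.0), np.full(50, 3.0))
        assert het == 0.0

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            activity_score([0.0], [1.0])


class TestMSD:
    def test_ballistic_oracle(self):
        # beads moving at constant velocity: MSD = (v t)^2
        t = np.arange(1.0, 6.0)
        pos = np.zeros((5, 3, 3))
        pos[:, :, 0] = 2.0 * t[:, None]
        lags, msd = mean_squared_displacement(pos, t)
        assert np.allclose(msd, (2.0 * lags) ** 2)

    def test_uneven_spacing_rejected(self):
        with pytest.raises(ValueError):
            mean_squared_displacement(np.zeros((3, 2, 3)),
                                      np.array([0.0, 1.0, 5.0]))


def discrete_wlc(n_beads, lp, bond=1.0, rng=None):
    """Freely rotating chain with bond-angle correlation e^(-bond/lp)."""
    rng = np.random.default_rng() if rng is None else rng
    cos_t = np.exp(-bond / lp)
    theta = np.arccos(cos_t)
    pos = np.zeros((n_beads, 3))
    t = np.array([1.0, 0, 0])
    for i in range(1, n_beads):
        # rotate t by theta about a random perpendicular axis
        perp = np.cross(t, rng.normal(size=3))
        perp /= np.linalg.norm(perp)
        t = np.cos(theta) * t + np.sin(theta) * perp
        t /= np.linalg.norm(t)
        pos[i] = pos[i - 1] + bond * t
    return pos


class TestPersistenceLength:
    def test_smoothing_straight_chain_is_identity(self):
        line = np.c_[np.arange(20.0), np.zeros(20), np.zeros(20)]
        sm = smooth_contour(line, 5)
        assert np.allclose(np.diff(sm[:, 0]), 1.0)
        assert np.allclose(sm[:, 1:], 0.0)

    def test_wlc_formula_limits(self):
        # rigid-rod limit: Rg^2 -> L^2/12 as lp >> L
        L = 1.0
        assert wlc_rg2(L, 500.0) == pytest.approx(L**2 / 12, rel=0.01)
        # flexible limit: Rg^2 -> L lp / 3 for L >> lp
        assert wlc_rg2(1000.0, 1.0) == pytest.approx(1000.0 / 3, rel=0.01)

    def test_recovers_planted_lp(self, rng):
        """WLC fit on ideal discrete worm-like chains recovers lp=4σ.

        The generator chain is already smooth, so no contour smoothing is
        applied (window=1); the 5-bead average is only needed for crumpled
        zig-zag fibers, where it raises the apparent stiffness slightly.
        """
        snaps = np.array([discrete_wlc(400, 4.0, rng=rng) for _ in range(12)])
        lp, _ = persistence_length(snaps, window=1, max_subchain=120)
        assert lp == pytest.approx(4.0, rel=0.10)

    def test_chain_too_short_rejected(self):
        with pytest.raises(ValueError):
            persistence_length(np.zeros((1, 20, 3)))
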