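import numpy as np
import pandas as pd
import pytest

from msatpop import landscape as land
from msatpop.io import CLIMATE_COLUMNS
from msatpop.landscape import (allele_response_matrix, climate_distance,
                               coordinate_distance, mantel, partial_mantel,
                               pcnm, rda_partition, select_pcnm_forward)


def _sites(lat, lon, climate=None):
    df = pd.DataFrame({"lat": lat, "lon": lon},
                      index=[f"P{i}" for i in range(len(lat))])
    for j, c in enumerate(CLIMATE_COLUMNS):
        df[c] = climate[:, j] if climate is not None else 0.0
    return df


def _random_dm(rng, n):
    X = rng.normal(size=(n, 2))
    D = np.sqrt(((X[:, None] - X[None, :])**2).sum(-1))
    return D


class TestCoordinateDistance:
    def test_one_degree_on_equator_great_circle(self):
        s = _sites([0.0, 0.0], [10.0, 11.0])
        d = coordinate_distance(s, method="great_circle_km")
        assert d.iloc[0, 1] == pytest.approx(111.3, abs=0.5)

    def test_identical_sites_zero(self):
        s = _sites([20.0, 20.0], [100.0, 100.0])
        for m in ("euclidean_degrees", "great_circle_km"):
            assert coordinate_distance(s, method=m).iloc[0, 1] == 0.0

    @pytest.mark.parametrize("method", ["euclidean_degrees", "great_circle_km"])
    def test_triangle_inequality(self, method):
        rng = np.random.default_rng(0)
        s = _sites(rng.uniform(-60, 60, 6), rng.uniform(-170, 170, 6))
        D = coordinate_distance(s, method=method).to_numpy()
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-9


class TestClimateDistance:
    def test_identical_climates_zero(self):
        clim = np.tile([10, 700, 4, 1200, 60, 80.0], (3, 1))
        d = climate_distance(_sites([1, 2, 3.0], [1, 2, 3.0], clim))
        assert np.allclose(d, 0.0)

    def test_two_sd_separation(self):
        # one variable differing; z-scoring (population sd) maps the two
        # values to -1 and +1, i.e. distance 2
        clim = np.tile([10, 700, 4, 1200, 60, 80.0], (2, 1))
        clim[1, 0] = 20.0
        with pytest.warns(UserWarning, match="constant"):
            d = climate_distance(_sites([1, 2.0], [1, 2.0], clim))
        assert d.iloc[0, 1] == pytest.approx(2.0)

    def test_unstandardized_dominated_by_precipitation(self):
        rng = np.random.default_rng(1)
        clim = np.column_stack([
            rng.normal(16, 1, 8), rng.normal(800, 30, 8),
            rng.normal(4, 1, 8), rng.normal(1300, 300, 8),
            rng.normal(60, 3, 8), rng.normal(90, 10, 8)])
        s = _sites(np.arange(8.0), np.arange(8.0), clim)
        d_raw = climate_distance(s, standardize=False)
        d_bio12 = np.abs(clim[:, None, 3] - clim[None, :, 3])
        r = np.corrcoef(land._tri(d_raw.to_numpy()), land._tri(d_bio12))[0, 1]
        assert r > 0.95


class TestMantel:
    def test_self_correlation_is_one(self):
        D = _random_dm(np.random.default_rng(2), 10)
        res = mantel(D, D, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_affine_invariance(self):
        D = _random_dm(np.random.default_rng(3), 10)
        res = mantel(D, 2 * D + 3, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_agrees_with_skbio_oracle(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import mantel as sk_mantel
        rng = np.random.default_rng(4)
        A = _random_dm(rng, 15)
        B = A + rng.normal(0, 0.3, size=A.shape)
        B = (B + B.T) / 2
        np.fill_diagonal(B, 0)
        B = np.abs(B)
        res = mantel(A, B, n_perm=199, seed=5)
        r_sk, p_sk, _ = sk_mantel(SkDM(A), SkDM(B), permutations=199,
                                  alternative="two-sided")
        assert res.r == pytest.approx(r_sk, abs=1e-12)
        assert res.p == pytest.approx(p_sk, abs=0.05)

    def test_zero_variance_rejected(self):
        Z = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="variance"):
            mantel(Z * 0, Z, n_perm=9)


class TestPartialMantel:
    def test_b_equals_c_gives_zero(self):
        rng = np.random.default_rng(5)
        A = _random_dm(rng, 12)
        B = _random_dm(rng, 12)
        res = partial_mantel(A, B, B, n_perm=99, seed=1)
        assert res.r == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_in_first_two_arguments(self):
        rng = np.random.default_rng(6)
        A, B, C = (_random_dm(rng, 12) for _ in range(3))
        r1 = partial_mantel(A, B, C, n_perm=0).r
        r2 = partial_mantel(B, A, C, n_perm=0).r
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_uncorrelated_control_changes_little(self):
        rng = np.random.default_rng(7)
        deltas = []
        for _ in range(15):
            X = rng.normal(size=(29, 2))
            A = np.sqrt(((X[:, None] - X[None, :])**2).sum(-1))
            B = A + np.abs(rng.normal(0, 0.2, size=A.shape))
            B = (B + B.T) / 2
            np.fill_diagonal(B, 0)
            C = _random_dm(rng, 29)
            simple = mantel(A, B, n_perm=0).r
            part = partial_mantel(A, B, C, n_perm=0).r
            deltas.append(abs(simple - part))
        assert np.median(deltas) < 0.05


class TestPcnm:
    def test_transect_first_vector_tracks_position(self):
        # regular 1-D transect: the leading PCNM is the coarsest spatial
        # wave; vegan::pcnm on the same transect gives cor(PCNM1, position)
        # = 0.8336742 (independent oracle value)
        pos = np.arange(20.0)
        D = np.abs(pos[:, None] - pos[None, :])
        vecs, vals = pcnm(D)
        r = np.corrcoef(vecs["PCNM1"], pos)[0, 1]
        assert abs(r) == pytest.approx(0.8336742, abs=1e-6)
        assert vecs.shape[1] == 13  # vegan returns the same count

    def test_orthonormal_columns(self):
        rng = np.random.default_rng(8)
        D = _random_dm(rng, 15)
        vecs, _ = pcnm(D)
        G = vecs.to_numpy().T @ vecs.to_numpy()
        np.testing.assert_allclose(G, np.eye(vecs.shape[1]), atol=1e-8)

    def test_positive_vector_count_bounded(self):
        rng = np.random.default_rng(9)
        D = _random_dm(rng, 12)
        vecs, vals = pcnm(D)
        assert vecs.shape[1] <= 11
        assert (vals > 0).all()

    def test_coincident_points_give_nothing(self):
        vecs, vals = pcnm(np.zeros((5, 5)))
        assert vecs.shape[1] == 0


class TestAlleleResponse:
    def test_drop_one_rule(self, toy_two_pop):
        # L1 has 2 alleles, L2 has 2 alleles -> 1 retained column each
        tab, info = allele_response_matrix(toy_two_pop, target_columns=10)
        assert tab.shape == (2, 2)
        for locus, major in info["dropped_major"].items():
            retained = [c for c in tab.columns if c.startswith(f"{locus}:")]
            assert f"{locus}:{major}" not in retained

    def test_retained_plus_dropped_sum_to_one(self, smoke_study):
        gm = smoke_study[0]
        tab, info = allele_response_matrix(gm, target_columns=10_000)
        from msatpop.popgen import allele_frequencies
        freqs, _ = allele_frequencies(gm)
        for l, f in enumerate(freqs):
            name = gm.loci[l].name
            cols = [c for c in tab.columns if c.startswith(f"{name}:")]
            if not cols:
                continue
            for p in f.index:
                total = tab.loc[p, cols].sum() + \
                    f.loc[p, info["dropped_major"][name]]
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_target_column_count_reached(self, desk_study):
        gm = desk_study[0]
        tab, _ = allele_response_matrix(gm, target_columns=60)
        assert tab.shape[1] == 60


class TestRdaPartition:
    def _design(self, rng, n=29):
        Xg = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("ghi"))
        Xc = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("cde"))
        return Xg, Xc

    def test_climate_driven_response_attributes_to_climate(self):
        rng = np.random.default_rng(10)
        Xg, Xc = self._design(rng)
        B = rng.normal(size=(3, 8))
        Y = pd.DataFrame(Xc.to_numpy() @ B
                         + 0.5 * rng.normal(size=(29, 8)))
        res = rda_partition(Y, Xg, Xc, n_perm=99, seed=1)
        assert res.fractions["pure_climate"] > \
            3 * abs(res.fractions["pure_geography"])
        assert res.tests.loc["clim_given_geo", "p"] <= 0.05

    def test_identical_blocks_are_pure_joint(self):
        rng = np.random.default_rng(11)
        Xg, _ = self._design(rng)
        Xc = Xg.copy()
        Xc.columns = list("cde")
        Y = pd.DataFrame(Xg.to_numpy() @ rng.normal(size=(3, 6))
                         + 0.3 * rng.normal(size=(29, 6)))
        with pytest.warns(UserWarning, match="collinear"):
            res = rda_partition(Y, pd.concat([Xg, Xg.add_suffix("2")], axis=1),
                                Xc, n_perm=0)
        # adjusted R2 penalizes the (collinear) full model slightly harder
        # than each block alone, so allow a small artifact margin
        assert res.fractions["joint"] == pytest.approx(res.adj_r2["full"],
                                                       abs=0.05)
        assert abs(res.fractions["pure_climate"]) < 0.05

    def test_pure_noise_has_near_zero_adjusted_r2(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            Xg, Xc = self._design(rng)
            Y = pd.DataFrame(rng.normal(size=(29, 10)))
            res = rda_partition(Y, Xg, Xc, n_perm=0)
            assert abs(res.adj_r2["full"]) < 0.1

    def test_too_many_predictors_rejected(self):
        rng = np.random.default_rng(12)
        Y = pd.DataFrame(rng.normal(size=(8, 3)))
        Xg = pd.DataFrame(rng.normal(size=(8, 4)))
        Xc = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("wxyz"))
        with pytest.raises(ValueError, match="predictors"):
            rda_partition(Y, Xg, Xc)


def test_forward_selection_finds_true_predictors():
    rng = np.random.default_rng(13)
    pcnms = pd.DataFrame(rng.normal(size=(30, 8)),
                         columns=[f"PCNM{i + 1}" for i in range(8)])
    Y = pd.DataFrame(np.outer(pcnms["PCNM2"], rng.normal(size=5))
                     + 0.3 * rng.normal(size=(30, 5)))
    chosen = select_pcnm_forward(Y, pcnms, k=3, seed=1)
    assert "PCNM2" in chosen
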