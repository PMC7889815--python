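import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msatpop import popgen
from msatpop.io import GenotypeMatrix, Locus
from tests.conftest import random_genotypes


def _gm(calls, pops, units=None):
    calls = np.asarray(calls)
    n, L, _ = calls.shape
    loci = [Locus(f"L{j}", repeat_unit_length=(units or [1] * L)[j],
                  allele_encoding="repeat_count") for j in range(L)]
    return GenotypeMatrix([f"i{k}" for k in range(n)],
                          np.asarray(pops, dtype=object), loci, calls)


class TestAlleleFrequencies:
    def test_simple_counts(self):
        gm = _gm([[[1, 1]], [[1, 2]]], ["P", "P"])
        freqs, undef = popgen.allele_frequencies(gm)
        assert freqs[0].loc["P", 1] == 0.75
        assert freqs[0].loc["P", 2] == 0.25
        assert not undef

    def test_all_missing_flagged(self):
        gm = _gm([[[0, 0], [1, 2]], [[0, 0], [1, 1]]], ["P", "P"])
        _, undef = popgen.allele_frequencies(gm)
        assert undef == [("P", "L0")]

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(0)
        gm = random_genotypes(rng, missing_rate=0.1)
        freqs, _ = popgen.allele_frequencies(gm)
        for l, tab in enumerate(freqs):
            for p in tab.index:
                vals = gm.calls[gm.populations == p, l, :].ravel()
                vals = vals[vals > 0]
                for a in tab.columns:
                    expect = (vals == a).sum() / len(vals)
                    assert tab.loc[p, a] == pytest.approx(expect)


class TestDiversityTable:
    def test_closed_forms_at_half_half(self):
        gm = _gm([[[1, 2]], [[1, 2]]], ["P", "P"])
        row = popgen.diversity_table(gm).loc["P"]
        assert row["Ne"] == pytest.approx(2.0)
        assert row["I"] == pytest.approx(np.log(2))
        assert row["He"] == pytest.approx(0.5)
        assert row["Ho"] == pytest.approx(1.0)

    def test_monomorphic_population(self):
        gm = _gm([[[3, 3]], [[3, 3]]], ["P", "P"])
        row = popgen.diversity_table(gm).loc["P"]
        assert (row["Na"], row["Ne"], row["I"], row["Ho"], row["He"]) == \
            (1, 1, 0, 0, 0)
        assert row["PPL"] == 0.0

    def test_ppl_sixteen_of_seventeen(self):
        calls = np.zeros((4, 17, 2), dtype=int)
        calls[:, :, :] = 5
        for l in range(16):  # make 16 loci polymorphic
            calls[0, l, 1] = 6
        gm = _gm(calls, ["P"] * 4)
        assert popgen.diversity_table(gm).loc["P", "PPL"] == pytest.approx(
            94.12, abs=0.005)

    def test_single_individual_population_fis_undefined(self):
        gm = _gm([[[1, 2]], [[1, 1]], [[1, 2]]], ["A", "B", "B"])
        tab = popgen.diversity_table(gm)
        assert np.isnan(tab.loc["A", "FIS"])
        assert not np.isnan(tab.loc["A", "Ho"])

    def test_ne_le_na_and_shannon_bound(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            gm = random_genotypes(rng, n_pops=2, n_ind=10, n_loci=3)
            tab = popgen.diversity_table(gm)
            assert (tab["Ne"] <= tab["Na"] + 1e-12).all()
            assert (tab["He"] < 1).all()
            # I >= ln(Ne), equality iff equifrequent
            assert (tab["I"] >= np.log(tab["Ne"]) - 1e-9).all()


class TestPic:
    def test_fixed_allele(self):
        assert popgen.pic([1.0]) == 0.0

    def test_half_half(self):
        assert popgen.pic([0.5, 0.5]) == pytest.approx(0.375)

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_matches_double_sum_oracle(self, raw):
        p = np.array(raw) / np.sum(raw)
        expect = 1 - (p**2).sum()
        for i in range(len(p)):
            for j in range(i + 1, len(p)):
                expect -= 2 * p[i]**2 * p[j]**2
        assert popgen.pic(p) == pytest.approx(expect)


class TestHsHt:
    def test_identical_populations(self):
        gm = _gm([[[1, 2]], [[1, 2]], [[1, 2]], [[1, 2]]],
                 ["A", "A", "B", "B"])
        tab = popgen.hs_ht(gm)
        assert tab["Hs"].iloc[0] == pytest.approx(tab["Ht"].iloc[0])

    def test_fixed_different_alleles(self):
        gm = _gm([[[1, 1]], [[1, 1]], [[2, 2]], [[2, 2]]],
                 ["A", "A", "B", "B"])
        tab = popgen.hs_ht(gm)
        assert tab["Hs"].iloc[0] == 0.0
        assert tab["Ht"].iloc[0] == pytest.approx(0.5)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        gm = random_genotypes(rng)
        freqs, _ = popgen.allele_frequencies(gm)
        tab = popgen.hs_ht(gm)
        for l, f in enumerate(freqs):
            hs = np.mean([1 - (f.loc[p].dropna()**2).sum() for p in f.index])
            pbar = f.mean(axis=0)
            ht = 1 - (pbar**2).sum()
            assert tab["Hs"].iloc[l] == pytest.approx(hs)
            assert tab["Ht"].iloc[l] == pytest.approx(ht)


class TestPairwiseFst:
    def test_fixed_difference_is_maximal(self):
        gm = _gm([[[1, 1]]] * 6 + [[[2, 2]]] * 6, ["A"] * 6 + ["B"] * 6)
        res = popgen.pairwise_fst(gm)
        assert res.raw.loc["A", "B"] == pytest.approx(1.0)

    def test_panmictic_split_near_zero(self):
        rng = np.random.default_rng(3)
        n, L = 200, 10
        calls = rng.integers(10, 16, size=(n, L, 2))
        pops = np.array(["A"] * (n // 2) + ["B"] * (n // 2), dtype=object)
        gm = _gm(calls, pops)
        res = popgen.pairwise_fst(gm)
        assert abs(res.raw.loc["A", "B"]) < 0.02

    def test_duplicating_individuals_nearly_invariant(self):
        rng = np.random.default_rng(4)
        gm = random_genotypes(rng, n_pops=2, n_ind=30, n_loci=5)
        th1 = popgen.pairwise_fst(gm).raw.iloc[0, 1]
        dup = GenotypeMatrix(
            gm.individuals + [i + "_d" for i in gm.individuals],
            np.concatenate([gm.populations, gm.populations]),
            gm.loci, np.concatenate([gm.calls, gm.calls]))
        th2 = popgen.pairwise_fst(dup).raw.iloc[0, 1]
        assert th1 == pytest.approx(th2, abs=0.01)

    def test_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(5)
        gm = random_genotypes(rng, n_pops=3, n_ind=8)
        d = popgen.pairwise_fst(gm).distance
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d.to_numpy() >= 0).all()


class TestAmova:
    def test_no_structure_low_among(self):
        rng = np.random.default_rng(6)
        n = 60
        calls = rng.integers(10, 15, size=(n, 5, 2))
        pops = np.repeat(["A", "B", "C"], n // 3).astype(object)
        res = popgen.amova(_gm(calls, pops), n_perm=99, seed=1)
        assert abs(res.strata.loc["among_populations", "percent"]) < 5
        assert res.strata.loc["within_populations", "percent"] > 95

    def test_percentages_sum_to_100(self, smoke_study):
        gm, _, _, truth = smoke_study
        one = popgen.amova(gm, n_perm=20, seed=2)
        assert one.percent_total == pytest.approx(100.0, abs=1e-6)
        two = popgen.amova(gm, groups=truth.group_of_pop, n_perm=20, seed=2)
        assert two.percent_total == pytest.approx(100.0, abs=1e-6)
        for p in list(one.p_values.values()) + list(two.p_values.values()):
            assert 1 / 21 <= p <= 1.0

    def test_one_level_matches_anova_oracle(self):
        # single locus, equal sizes, no missing: AMOVA on squared allele-size
        # differences equals a one-way ANOVA on repeat counts
        rng = np.random.default_rng(7)
        calls = np.concatenate([
            rng.integers(10, 13, size=(10, 1, 2)),
            rng.integers(12, 16, size=(10, 1, 2)),
        ])
        pops = np.repeat(["A", "B"], 10).astype(object)
        res = popgen.amova(_gm(calls, pops), n_perm=0)
        x = calls.reshape(-1).astype(float)
        lab = np.repeat(pops, 2)
        N, P = len(x), 2
        ss_w = sum(((x[lab == p] - x[lab == p].mean())**2).sum() for p in "AB")
        ss_t = ((x - x.mean())**2).sum()
        sig_w = ss_w / (N - P)
        n0 = (N - sum((lab == p).sum()**2 for p in "AB") / N) / (P - 1)
        sig_a = ((ss_t - ss_w) / (P - 1) - sig_w) / n0
        assert res.strata.loc["within_populations", "variance"] == \
            pytest.approx(sig_w)
        assert res.strata.loc["among_populations", "variance"] == \
            pytest.approx(sig_a)
        assert res.statistics["R_ST"] == pytest.approx(
            sig_a / (sig_a + sig_w))

    def test_two_level_detects_group_structure(self):
        rng = np.random.default_rng(8)
        g1 = rng.integers(10, 13, size=(20, 2, 2))
        g2 = rng.integers(18, 21, size=(20, 2, 2))
        calls = np.concatenate([g1, g2])
        pops = np.repeat(["A", "B", "C", "D"], 10).astype(object)
        groups = {"A": "W", "B": "W", "C": "E", "D": "E"}
        res = popgen.amova(_gm(calls, pops), groups=groups, n_perm=99, seed=3)
        assert res.statistics["R_CT"] > 0.5
        assert res.p_values["R_CT"] <= 0.5  # only 3 distinct pop-to-group perms
        assert res.p_values["R_ST"] <= 0.05

    def test_hierarchy_must_cover_all_populations(self, toy_two_pop):
        with pytest.raises(ValueError, match="cover"):
            popgen.amova(toy_two_pop, groups={"A": "W"}, n_perm=0)


class TestPcoa:
    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(6, 2))
        D = np.sqrt(((X[:, None] - X[None, :])**2).sum(-1))
        coords, eig, pct = popgen.pcoa(D)
        got = coords.iloc[:, :2].to_numpy()
        Dg = np.sqrt(((got[:, None] - got[None, :])**2).sum(-1))
        np.testing.assert_allclose(Dg, D, atol=1e-8)

    def test_collinear_points_on_first_axis(self):
        pos = np.array([0.0, 1.0, 3.0])
        D = np.abs(pos[:, None] - pos[None, :])
        coords, eig, _ = popgen.pcoa(D)
        axis1 = coords["PC1"].to_numpy()
        r = np.corrcoef(axis1, pos)[0, 1]
        assert abs(r) > 0.99

    def test_eigenvalue_sum_is_total_dispersion(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(5, 3))
        D = np.sqrt(((X[:, None] - X[None, :])**2).sum(-1))
        _, eig, _ = popgen.pcoa(D)
        G = -0.5 * D**2
        J = np.eye(5) - np.ones((5, 5)) / 5
        assert eig.sum() == pytest.approx(np.trace(J @ G @ J), abs=1e-8)


class TestIdw:
    def test_single_point_constant(self):
        _, _, surf = popgen.idw_surface([(0, 0, 5.0)], (-1, 1, -1, 1, 5, 5))
        np.testing.assert_allclose(surf, 5.0)

    def test_midpoint_is_mean(self):
        _, _, surf = popgen.idw_surface(
            [(0, -1, 2.0), (0, 1, 6.0)], (0, 0, 0, 0, 1, 1))
        assert surf[0, 0] == pytest.approx(4.0)

    def test_bounded_by_inputs_and_exact_at_points(self):
        pts = [(0, 0, 1.0), (1, 1, 3.0), (0, 1, 7.0)]
        _, _, surf = popgen.idw_surface(pts, (0, 1, 0, 1, 11, 11))
        assert surf.min() >= 1.0 - 1e-9 and surf.max() <= 7.0 + 1e-9
        assert surf[0, 0] == 1.0   # grid node coincides with (0, 0)


def test_correlation_of_identical_series():
    div = pd.DataFrame({"Ho": [0.1, 0.2, 0.3, 0.4],
                        "He": [0.4, 0.3, 0.2, 0.1]},
                       index=list("abcd"))
    sites = pd.DataFrame({"lat": [0.1, 0.2, 0.3, 0.4],
                          "lon": [1, 2, 4, 3.0]}, index=list("abcd"))
    tab = popgen.diversity_coordinate_correlation(div, sites)
    row = tab[(tab.statistic == "Ho") & (tab.axis == "latitude")].iloc[0]
    assert row.R == pytest.approx(1.0)
    assert row.p < 1e-6
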