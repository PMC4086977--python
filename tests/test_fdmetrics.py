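import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from grazefd import fdmetrics
from grazefd.fdmetrics import DistanceMatrix, cwm, fd_profile, feve, gower_distance, rao_q
from grazefd.traits import DEFAULT_SCHEMES, RawTraitEntry, TraitTable, build_trait_table


def one_trait_table(values, trait="ldmc_mg_per_g"):
    schemes = {trait: DEFAULT_SCHEMES[trait]}
    raw = [RawTraitEntry(f"sp{i}", trait, v) for i, v in enumerate(values)]
    return build_trait_table(raw, schemes)


class TestGower:
    def test_endpoints_have_distance_one(self):
        t = one_trait_table([100.0, 300.0])
        d = gower_distance(t)
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_identical_species_distance_zero(self):
        t = one_trait_table([100.0, 100.0, 300.0])
        assert gower_distance(t).values[0, 1] == pytest.approx(0.0)

    def test_weighted_two_trait_hand_case(self):
        # gaps after range-normalisation: trait1 = 1.0, trait2 = 0.0;
        # weights (1, 0.5) -> d = (1*1 + 0.5*0) / 1.5
        schemes = {
            "ldmc_mg_per_g": DEFAULT_SCHEMES["ldmc_mg_per_g"],
            "veg_spread_rhizome": DEFAULT_SCHEMES["veg_spread_rhizome"],
        }
        raw = [
            RawTraitEntry("a", "ldmc_mg_per_g", 100.0),
            RawTraitEntry("a", "veg_spread_rhizome", "Rhizomatous"),
            RawTraitEntry("b", "ldmc_mg_per_g", 300.0),
            RawTraitEntry("b", "veg_spread_rhizome", "Rhizomatous"),
            RawTraitEntry("c", "ldmc_mg_per_g", 100.0),
            RawTraitEntry("c", "veg_spread_rhizome", "Not rhizomatous"),
        ]
        table = build_trait_table(raw, schemes)
        d = gower_distance(table, weights={"ldmc_mg_per_g": 1.0, "veg_spread_rhizome": 0.5})
        assert d.values[0, 1] == pytest.approx(1.0 / 1.5)

    def test_constant_traits_dropped_and_all_constant_errors(self):
        schemes = {
            "ldmc_mg_per_g": DEFAULT_SCHEMES["ldmc_mg_per_g"],
            "sla_mm2_per_mg": DEFAULT_SCHEMES["sla_mm2_per_mg"],
        }
        raw = [
            RawTraitEntry("a", "ldmc_mg_per_g", 100.0),
            RawTraitEntry("a", "sla_mm2_per_mg", 20.0),
            RawTraitEntry("b", "ldmc_mg_per_g", 300.0),
            RawTraitEntry("b", "sla_mm2_per_mg", 20.0),
        ]
        table = build_trait_table(raw, schemes)
        d = gower_distance(table)
        assert d.constant_traits == ["sla_mm2_per_mg"]
        with pytest.raises(ValueError, match="zero trait variation"):
            gower_distance(table, subset=["sla_mm2_per_mg"])

    def test_full_table_distances_within_unit_interval(self, small_trait_table):
        d = gower_distance(small_trait_table)
        assert (d.values >= 0).all() and (d.values <= 1).all()
        assert np.allclose(d.values, d.values.T)


class TestCwm:
    def test_single_species_community(self):
        t = one_trait_table([250.0])
        assert cwm(np.array([1.0]), t, "ldmc_mg_per_g") == pytest.approx(250.0)

    def test_hand_weighted_mean(self):
        t = one_trait_table([200.0, 300.0])
        assert cwm(np.array([0.25, 0.75]), t, "ldmc_mg_per_g") == pytest.approx(275.0)

    def test_uniform_over_equal_values(self):
        t = one_trait_table([42.0, 42.0, 42.0])
        assert cwm(np.full(3, 1 / 3), t, "ldmc_mg_per_g") == pytest.approx(42.0)

    def test_species_mismatch_raises(self):
        t = one_trait_table([200.0, 300.0])
        abund = pd.Series([0.5, 0.5], index=["spX", "sp1"])
        with pytest.raises(ValueError, match="absent"):
            cwm(abund, t, "ldmc_mg_per_g")


class TestRaoQ:
    def test_single_species_zero(self):
        d = np.zeros((1, 1))
        assert rao_q(np.array([1.0]), d) == 0.0

    def test_two_species_hand_case(self):
        d = np.array([[0.0, 0.4], [0.4, 0.0]])
        assert rao_q(np.array([0.5, 0.5]), d) == pytest.approx(0.2)  # 2 * 0.25 * 0.4

    def test_zero_distances_give_zero(self):
        assert rao_q(np.array([0.3, 0.7]), np.zeros((2, 2))) == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="match"):
            rao_q(np.array([0.5, 0.5]), np.zeros((3, 3)))

    def test_two_species_maximised_at_even_split(self):
        d = np.array([[0.0, 0.7], [0.7, 0.0]])
        grid = np.linspace(0, 1, 201)
        qs = [rao_q(np.array([p, 1 - p]), d) for p in grid]
        assert grid[int(np.argmax(qs))] == pytest.approx(0.5)

    @given(
        n=st.integers(2, 20),
        seed=st.integers(0, 2**16),
    )
    @settings(deadline=None, max_examples=50)
    def test_matches_bruteforce_double_sum(self, n, seed):
        """The matrix form p.D.p equals the explicit ordered-pair double sum."""
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(n))
        d = rng.uniform(0, 1, (n, n))
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0.0)
        brute = sum(p[i] * p[j] * d[i, j] for i in range(n) for j in range(n))
        assert rao_q(p, d) == pytest.approx(brute, abs=1e-12)


class TestFeve:
    def test_equally_spaced_equal_abundance_is_one(self):
        t = one_trait_table([100.0, 200.0, 300.0])
        d = gower_distance(t)
        assert feve(np.full(3, 1 / 3), d) == pytest.approx(1.0)

    def test_three_species_hand_case(self):
        # positions (0, 1, 4): MST edges 1 and 3 pre-normalisation, equal
        # abundances -> PEW = (0.25, 0.75) -> FEve = 0.5
        t = one_trait_table([100.0, 101.0, 104.0])
        d = gower_distance(t)
        assert feve(np.full(3, 1 / 3), d) == pytest.approx(0.5)

    def test_fewer_than_three_species_undefined(self):
        t = one_trait_table([100.0, 300.0])
        d = gower_distance(t)
        assert feve(np.array([0.5, 0.5]), d) is None
        assert feve(np.array([0.2, 0.8, 0.0]), np.ones((3, 3)) - np.eye(3)) is None

    def test_bounded_and_scale_invariant(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(3, 12)
            p = rng.dirichlet(np.ones(n))
            d = rng.uniform(0.01, 1, (n, n))
            d = 0.5 * (d + d.T)
            np.fill_diagonal(d, 0.0)
            v = feve(p, d)
            assert 0.0 <= v <= 1.0 + 1e-12
            assert feve(p, 0.37 * d) == pytest.approx(v, abs=1e-12)

    def test_one_dimensional_chain_matches_general_mst(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(3, 15))
            x = rng.uniform(0, 1, n)
            p = rng.dirichlet(np.ones(n))
            d = np.abs(x[:, None] - x[None, :])
            assert feve(p, d, one_dimensional=x) == pytest.approx(feve(p, d), abs=1e-12)


class TestFdProfile:
    def test_one_row_one_profile(self, small_trait_table):
        comm = pd.DataFrame(
            [[0.4, 0.3, 0.2, 0.1]], columns=small_trait_table.species, index=["r0"]
        )
        profiles = fd_profile(comm, small_trait_table)
        assert len(profiles) == 1
        assert profiles[0].rao_all > 0

    def test_single_trait_rao_hand_case(self):
        t = one_trait_table([100.0, 300.0])
        comm = pd.DataFrame([[0.5, 0.5]], columns=t.species, index=["r0"])
        prof = fd_profile(comm, t, single_traits=("ldmc_mg_per_g",),
                          cwm_traits=("ldmc_mg_per_g",))[0]
        assert prof.rao_trait["ldmc_mg_per_g"] == pytest.approx(0.5)  # 2 * 0.25 * 1
        assert prof.rao_trait_raw["ldmc_mg_per_g"] == pytest.approx(100.0)

    def test_species_relabelling_invariance(self, small_trait_table):
        comm = pd.DataFrame(
            [[0.4, 0.3, 0.2, 0.1], [0.1, 0.1, 0.4, 0.4]],
            columns=small_trait_table.species, index=["r0", "r1"],
        )
        base = fd_profile(comm, small_trait_table)
        perm = ["spC", "spA", "spD", "spB"]
        shuffled = fd_profile(comm[perm], small_trait_table)
        for b, s in zip(base, shuffled):
            assert s.rao_all == pytest.approx(b.rao_all, abs=1e-12)
            assert s.feve_all == pytest.approx(b.feve_all, abs=1e-12)
            for tr in b.cwm:
                assert s.cwm[tr] == pytest.approx(b.cwm[tr], abs=1e-12)

    def test_row_not_summing_to_one_rejected(self, small_trait_table):
        comm = pd.DataFrame([[0.4, 0.3, 0.1, 0.1]], columns=small_trait_table.species,
                            index=["r0"])
        with pytest.raises(ValueError, match="sum to 1"):
            fd_profile(comm, small_trait_table)

    def test_unknown_species_rejected(self, small_trait_table):
        comm = pd.DataFrame([[0.5, 0.5]], columns=["spA", "spZ"], index=["r0"])
        with pytest.raises(ValueError, match="spZ"):
            fd_profile(comm, small_trait_table)


def test_one_dimensional_mst_length_is_range():
    """For a single trait the MST is the sorted chain: total length max-min."""
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 100, 12)
    d = np.abs(x[:, None] - x[None, :])
    edges = fdmetrics._mst_edges_kruskal(d)
    total = sum(d[i, j] for i, j in edges)
    assert total == pytest.approx(x.max() - x.min())
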