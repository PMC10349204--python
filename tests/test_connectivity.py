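"""TSIB accounting, normalization, and the shortest-path OC network."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import seaflow as sf
from seaflow._geo import M_PER_DEG
from seaflow.lagrangian import TrajectorySet
from seaflow.matrices import DirectionalMatrix

from _oracles import best_product_oc


def dm(values, labels, **kw):
    return DirectionalMatrix(pd.DataFrame(np.asarray(values, float),
                                          index=labels, columns=labels), **kw)


class TestTSIB:
    def _setup(self):
        """Two one-site populations 60 km apart on the equator; handmade tracks."""
        km = M_PER_DEG / 1000.0  # km per degree
        sites = pd.DataFrame({"id": ["a", "b"], "lon": [0.0, 60.0 / km], "lat": [0.0, 0.0]})
        pops = sf.group_sites(sites, buffer_km=10.0)
        return pops, 60.0 / km

    def _records(self, rows):
        return pd.DataFrame(rows, columns=["particle_id", "source_population",
                                           "time_h", "lon", "lat"])

    def test_five_records_in_buffer_sum_to_2p5_hours(self):
        pops, lon_b = self._setup()
        rows = [(1, "G1", 0.5 * k, lon_b, 0.0) for k in range(5)]       # inside G2 buffer
        rows += [(1, "G1", 2.5 + 0.5 * k, lon_b + 1.0, 0.0) for k in range(3)]  # far away
        tsib = sf.compute_tsib(TrajectorySet(self._records(rows), 0.5), pops)
        assert tsib.values.loc["G1", "G2"] == pytest.approx(2.5)

    def test_single_record_counts_half_hour(self):
        pops, lon_b = self._setup()
        rows = [(1, "G1", 0.0, lon_b + 1.0, 0.0), (1, "G1", 0.5, lon_b, 0.0),
                (1, "G1", 1.0, lon_b + 1.0, 0.0)]
        tsib = sf.compute_tsib(TrajectorySet(self._records(rows), 0.5), pops)
        assert tsib.values.loc["G1", "G2"] == pytest.approx(0.5)

    def test_no_entry_gives_zero(self):
        pops, lon_b = self._setup()
        rows = [(1, "G1", 0.0, lon_b + 1.0, 0.0)]
        tsib = sf.compute_tsib(TrajectorySet(self._records(rows), 0.5), pops)
        assert tsib.values.loc["G1", "G2"] == 0.0

    def test_unknown_source_population_rejected(self):
        pops, _ = self._setup()
        rows = [(1, "XX", 0.0, 0.0, 0.0)]
        with pytest.raises(ValueError, match="XX"):
            sf.compute_tsib(TrajectorySet(self._records(rows), 0.5), pops)


class TestSymmetrize:
    def test_pairwise_sum(self):
        t = dm([[0, 3], [1, 0]], ["A", "B"])
        s = sf.symmetrize(t)
        assert s.values.loc["A", "B"] == 4 == s.values.loc["B", "A"]

    def test_zero_pair_stays_zero(self):
        s = sf.symmetrize(dm([[0, 0], [0, 0]], ["A", "B"]))
        assert (s.values.values == 0).all()

    def test_idempotent_by_flag(self):
        t = dm([[0, 3], [1, 0]], ["A", "B"])
        once = sf.symmetrize(t)
        twice = sf.symmetrize(once)
        assert twice.values.equals(once.values)


class TestRelativeProbability:
    def test_directed_normalization(self):
        p = sf.relative_probability(dm([[0, 3], [1, 0]], ["A", "B"]))
        assert p.values.loc["A", "B"] == pytest.approx(0.75)
        assert p.values.loc["B", "A"] == pytest.approx(0.25)

    def test_single_symmetric_pair_normalizes_to_one(self):
        s = sf.symmetrize(dm([[0, 3], [1, 0]], ["A", "B"]))
        p = sf.relative_probability(s)
        assert p.values.loc["A", "B"] + p.values.loc["B", "A"] == pytest.approx(1.0)

    def test_uniform_six_pairs(self):
        t = dm(np.ones((3, 3)) - np.eye(3), ["A", "B", "C"])
        p = sf.relative_probability(t)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(p.values.values[off], 1 / 6)

    def test_diagonal_excluded_from_total(self):
        t = dm([[99, 3], [1, 99]], ["A", "B"])
        p = sf.relative_probability(t)
        assert p.values.loc["A", "B"] == pytest.approx(0.75)
        assert p.values.loc["A", "A"] == 0.0

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="no connectivity"):
            sf.relative_probability(dm(np.zeros((2, 2)), ["A", "B"]))


class TestNetworkOC:
    def test_direct_edge_keeps_probability(self):
        p = np.zeros((2, 2)); p[0, 1] = 0.5
        oc = sf.network_connectivity(dm(p, ["A", "B"], kind="rel_prob"))
        assert oc.values.loc["A", "B"] == pytest.approx(0.5)

    def test_one_intermediate_multiplies_probabilities(self):
        p = np.zeros((3, 3)); p[0, 1] = 0.5; p[1, 2] = 0.1
        oc = sf.network_connectivity(dm(p, list("ABC"), kind="rel_prob"))
        assert oc.values.loc["A", "C"] == pytest.approx(0.05)

    def test_better_indirect_path_wins(self):
        p = np.zeros((3, 3)); p[0, 1] = 0.5; p[1, 2] = 0.1; p[0, 2] = 0.01
        oc = sf.network_connectivity(dm(p, list("ABC"), kind="rel_prob"))
        assert oc.values.loc["A", "C"] == pytest.approx(0.05)

    def test_disconnected_pair_scores_zero(self):
        p = np.zeros((3, 3)); p[0, 1] = 0.5
        oc = sf.network_connectivity(dm(p, list("ABC"), kind="rel_prob"))
        assert oc.values.loc["A", "C"] == 0.0

    def test_sqrt_transform_flagged_and_idempotent(self):
        p = np.zeros((2, 2)); p[0, 1] = 0.25
        oc = sf.network_connectivity(dm(p, ["A", "B"], kind="rel_prob"), sqrt_transform=True)
        assert oc.transformed and oc.values.loc["A", "B"] == pytest.approx(0.5)
        assert oc.sqrt().values.equals(oc.values)

    def test_path_nodes_divisor_option(self):
        p = np.zeros((3, 3)); p[0, 1] = 0.5; p[1, 2] = 0.1
        oc = sf.network_connectivity(dm(p, list("ABC"), kind="rel_prob"),
                                     divisor="path_nodes")
        assert oc.values.loc["A", "C"] == pytest.approx(0.05 / 3)

    def test_stepping_stone_never_hurts_disconnected_pair(self):
        base = np.zeros((3, 3)); base[0, 1] = 0.4
        with_stone = base.copy(); with_stone[1, 2] = 0.3
        oc0 = sf.network_connectivity(dm(base, list("ABC"), kind="rel_prob"))
        oc1 = sf.network_connectivity(dm(with_stone, list("ABC"), kind="rel_prob"))
        assert oc1.values.loc["A", "C"] >= oc0.values.loc["A", "C"]

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_enumeration_on_random_digraphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        p = rng.random((n, n)) * (rng.random((n, n)) < 0.5)
        np.fill_diagonal(p, 0.0)
        if p.sum() > 0:
            p = p / p.sum()
        labels = [f"N{i}" for i in range(n)]
        oc = sf.network_connectivity(dm(p, labels, kind="rel_prob"))
        assert np.allclose(oc.values.values, best_product_oc(p, directed=True),
                           rtol=1e-9, atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_oc_bounded_and_symmetric_mode_exact(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        t = rng.random((n, n)) * (rng.random((n, n)) < 0.6)
        np.fill_diagonal(t, 0.0)
        if t.sum() == 0:
            t[0, 1] = 1.0
        labels = [f"N{i}" for i in range(n)]
        sym = sf.symmetrize(dm(t, labels))
        oc = sf.network_connectivity(sf.relative_probability(sym))
        v = oc.values.values
        assert (v >= 0).all() and (v <= 1 + 1e-12).all()
        assert np.array_equal(v, v.T)
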