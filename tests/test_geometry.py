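"""Buffer grouping, dataset filtering, and over-water distances."""

import numpy as np
import pandas as pd
import pytest

import seaflow as sf
from seaflow._geo import M_PER_DEG, haversine_km
from seaflow.seascape import Seascape

from _oracles import grid_dijkstra


def sites_at_km(offsets_km, lat=0.0):
    """Sites along the equator at given eastward km offsets."""
    deg = np.asarray(offsets_km) / (M_PER_DEG / 1000.0)
    return pd.DataFrame({"id": [f"s{i}" for i in range(len(offsets_km))],
                         "lon": deg, "lat": lat})


def flat_sea(ny, nx, land=None, cell_km=1.0):
    """All-sea (or masked) grid near the equator with ~cell_km spacing."""
    step = cell_km / (M_PER_DEG / 1000.0)
    lon = np.arange(nx) * step
    lat = np.arange(ny) * step
    mask = np.zeros((ny, nx), dtype=bool) if land is None else land
    shp = (1, ny, nx)
    return Seascape(lon=lon, lat=lat, time_h=[0.0], u=np.zeros(shp), v=np.zeros(shp),
                    land=mask)


class TestGrouping:
    @pytest.mark.parametrize("gap_km,expected", [(15.0, 1), (25.0, 2)])
    def test_buffer_overlap_threshold(self, gap_km, expected):
        pops = sf.group_sites(sites_at_km([0.0, gap_km]), buffer_km=10.0)
        assert len(pops) == expected

    def test_transitive_closure_chains_sites(self):
        pops = sf.group_sites(sites_at_km([0.0, 15.0, 30.0]), buffer_km=10.0)
        assert len(pops) == 1
        assert pops.populations[0].member_sites == ["s0", "s1", "s2"]

    def test_invariant_to_input_order(self):
        sites = sites_at_km([0.0, 15.0, 50.0, 62.0, 120.0])
        shuffled = sites.sample(frac=1.0, random_state=3)
        a = sf.group_sites(sites)
        b = sf.group_sites(shuffled)
        assert {frozenset(p.member_sites) for p in a.populations} == \
               {frozenset(p.member_sites) for p in b.populations}
        assert a.labels == b.labels

    def test_centroid_is_mean_of_members(self):
        sites = sites_at_km([0.0, 10.0])
        pop = sf.group_sites(sites).populations[0]
        assert pop.centroid[0] == pytest.approx(sites["lon"].mean())


class TestFiltering:
    def _table(self, missing_alleles=0, n_small=2):
        import numpy as np
        from seaflow.genotypes import MISSING, GenotypeTable
        n_big = 10
        rows = [{"id": f"a{i}", "site": "A", "population": "A"} for i in range(n_big)]
        rows += [{"id": f"b{i}", "site": "B", "population": "B"} for i in range(n_small)]
        alleles = np.full((n_big + n_small, 16, 2), 10, dtype=np.int32)
        flat = alleles[0].reshape(-1)
        flat[:missing_alleles] = MISSING
        return GenotypeTable(pd.DataFrame(rows), [f"L{j}" for j in range(16)], alleles)

    def test_individual_with_seven_missing_alleles_removed(self):
        gt, _, rep = sf.filter_dataset(self._table(missing_alleles=7), min_pop_n=1)
        assert rep.n_dropped_missing == 1 and "a0" not in set(gt.individuals["id"])

    def test_individual_with_six_missing_alleles_kept(self):
        gt, _, rep = sf.filter_dataset(self._table(missing_alleles=6), min_pop_n=1)
        assert rep.n_dropped_missing == 0

    def test_small_population_removed(self):
        gt, _, rep = sf.filter_dataset(self._table(n_small=9))
        assert rep.populations_dropped == ["B"]
        assert gt.populations == ["A"] and gt.n_individuals == 10

    def test_two_pop_toy_keeps_only_large_population(self):
        gt, _, rep = sf.filter_dataset(self._table(n_small=2))
        assert rep.n_populations_out == 1 and gt.n_individuals == 10

    def test_idempotent(self):
        once, _, _ = sf.filter_dataset(self._table(missing_alleles=7, n_small=11))
        twice, _, rep2 = sf.filter_dataset(once)
        assert twice.individuals.equals(once.individuals)
        assert rep2.n_dropped_missing == 0 and rep2.populations_dropped == []

    def test_everything_filtered_raises(self):
        with pytest.raises(ValueError, match="no populations survive"):
            sf.filter_dataset(self._table(n_small=2), min_pop_n=50)


class TestWaterDistance:
    def test_straight_open_water_path(self):
        sea = flat_sea(9, 12, cell_km=1.0)
        sites = pd.DataFrame({"id": ["a", "b"], "lon": [sea.lon[2], sea.lon[7]],
                              "lat": [sea.lat[4], sea.lat[4]]})
        pops = sf.group_sites(sites, buffer_km=0.5)
        d = sf.water_distance(sea, pops)
        straight = haversine_km(sea.lon[2], sea.lat[4], sea.lon[7], sea.lat[4])
        assert d.values.iloc[0, 1] == pytest.approx(straight, rel=1e-9)
        assert np.allclose(np.diag(d.values.values), 0.0)

    def test_detour_through_gap_matches_dijkstra_oracle(self):
        ny, nx = 11, 11
        land = np.zeros((ny, nx), dtype=bool)
        land[:, 5] = True
        land[8, 5] = False  # one gap
        sea = flat_sea(ny, nx, land=land, cell_km=1.0)
        sites = pd.DataFrame({"id": ["w", "e"], "lon": [sea.lon[1], sea.lon[9]],
                              "lat": [sea.lat[2], sea.lat[2]]})
        pops = sf.group_sites(sites, buffer_km=0.4)
        d = sf.water_distance(sea, pops).values.iloc[0, 1]

        # independent oracle with the same step-cost convention
        ortho_x = haversine_km(sea.lon[0], sea.lat[2], sea.lon[1], sea.lat[2])
        ortho_y = haversine_km(sea.lon[0], sea.lat[0], sea.lon[0], sea.lat[1])
        costs = {}
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == dx == 0:
                    continue
                costs[(dy, dx)] = np.hypot(dx * ortho_x, dy * ortho_y)
        oracle = grid_dijkstra(land, costs, (2, 1), (2, 9))
        assert d == pytest.approx(oracle, rel=1e-3)
        # the wall forces a detour well beyond the straight line
        assert d > haversine_km(sea.lon[1], sea.lat[2], sea.lon[9], sea.lat[2]) * 1.5

    def test_never_shorter_than_great_circle(self, small_sea):
        sites = sf.make_sites(4, 2, (6.0, 60.0), small_sea, seed=3)
        pops = sf.group_sites(sites[["id", "lon", "lat"]])
        d = sf.water_distance(small_sea, pops)
        diag_km = haversine_km(small_sea.lon[0], small_sea.lat[0],
                               small_sea.lon[1], small_sea.lat[1])
        for a in pops.labels:
            for b in pops.labels:
                if a == b:
                    continue
                ca, cb = pops.by_id(a).centroid, pops.by_id(b).centroid
                gc = haversine_km(ca[0], ca[1], cb[0], cb[1])
                assert d.values.loc[a, b] >= gc - diag_km

    def test_disconnected_seas_named_in_error(self):
        land = np.zeros((8, 8), dtype=bool)
        land[:, 4] = True  # full wall
        sea = flat_sea(8, 8, land=land, cell_km=1.0)
        sites = pd.DataFrame({"id": ["w", "e"], "lon": [sea.lon[1], sea.lon[6]],
                              "lat": [sea.lat[3], sea.lat[3]]})
        pops = sf.group_sites(sites, buffer_km=0.4)
        with pytest.raises(ValueError, match="disconnected"):
            sf.water_distance(sea, pops)

    def test_centroid_on_land_snaps_within_two_cells(self):
        land = np.zeros((8, 8), dtype=bool)
        land[3, 3] = True
        sea = flat_sea(8, 8, land=land, cell_km=1.0)
        sites = pd.DataFrame({"id": ["x", "y"], "lon": [sea.lon[3], sea.lon[6]],
                              "lat": [sea.lat[3], sea.lat[6]]})
        pops = sf.group_sites(sites, buffer_km=0.4)
        d = sf.water_distance(sea, pops)  # snaps, does not raise
        assert np.isfinite(d.values.values).all()
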