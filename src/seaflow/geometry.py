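"""Site grouping, dataset filtering, and least-cost over-water distances.

Sampling sites are grouped into populations wherever their 10 km buffers
overlap (equivalently: inter-site great-circle distance below twice the
buffer radius), the genetic dataset is filtered by per-individual missing
data and per-population sample size, and pairwise distances between
population centroids are measured as shortest paths over sea cells of a
gridded landmask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from ._geo import haversine_km
from .genotypes import GenotypeTable
from .seascape import Seascape

DEFAULT_BUFFER_KM = 10.0


@dataclass
class Population:
    id: str
    member_sites: list
    centroid: tuple  # (lon, lat)
    buffer_km: float = DEFAULT_BUFFER_KM


@dataclass
class PopulationSet:
    """Disjoint, exhaustive grouping of sites into populations."""

    populations: list
    sites: pd.DataFrame  # columns: id, lon, lat

    def __post_init__(self):
        seen = [s for p in self.populations for s in p.member_sites]
        if len(seen) != len(set(seen)):
            raise ValueError("a site belongs to more than one population")
        if set(seen) != set(self.sites["id"]):
            raise ValueError("populations must cover every site exactly once")

    @property
    def labels(self) -> list:
        return sorted(p.id for p in self.populations)

    def __len__(self) -> int:
        return len(self.populations)

    def by_id(self, pid) -> Population:
        for p in self.populations:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def site_to_population(self) -> dict:
        return {s: p.id for p in self.populations for s in p.member_sites}

    def member_coords(self, pid) -> np.ndarray:
        """(k, 2) lon/lat of a population's member sites."""
        pop = self.by_id(pid)
        sub = self.sites.set_index("id").loc[pop.member_sites]
        return sub[["lon", "lat"]].to_numpy()

    def subset(self, keep_ids) -> "PopulationSet":
        keep = [p for p in self.populations if p.id in set(keep_ids)]
        site_ids = {s for p in keep for s in p.member_sites}
        return PopulationSet(keep, self.sites[self.sites["id"].isin(site_ids)].reset_index(drop=True))

    def to_csv(self, path: str | Path) -> None:
        mapping = self.site_to_population()
        df = self.sites.copy()
        df["population"] = df["id"].map(mapping)
        df.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            p.id: {"member_sites": list(p.member_sites), "centroid": list(p.centroid),
                   "buffer_km": p.buffer_km}
            for p in sorted(self.populations, key=lambda q: q.id)
        }, indent=2) + "\n")


def group_sites(sites: pd.DataFrame, buffer_km: float = DEFAULT_BUFFER_KM) -> PopulationSet:
    """Group sites into populations via overlapping circular buffers.

    Two buffers of radius ``buffer_km`` overlap iff the great-circle distance
    between the sites is below ``2 * buffer_km``; populations are the
    connected components of that overlap graph (transitive closure).  The
    result is invariant to site input order: populations are labeled G1, G2,
    ... in order of their alphabetically smallest member site id, and the
    centroid is the arithmetic mean of member coordinates.
    """
    if len(sites) == 0:
        raise ValueError("need at least one site")
    sites = sites.reset_index(drop=True)
    if sites["id"].duplicated().any():
        raise ValueError("site ids must be unique")
    lon = sites["lon"].to_numpy(dtype=float)
    lat = sites["lat"].to_numpy(dtype=float)
    if not (np.isfinite(lon).all() and np.isfinite(lat).all()):
        raise ValueError("site coordinates must be finite")

    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    adj = d < 2.0 * buffer_km
    n_comp, comp = connected_components(coo_matrix(adj), directed=False)

    order = sorted(range(n_comp), key=lambda c: min(sites["id"][comp == c]))
    pops = []
    for rank, c in enumerate(order, start=1):
        mask = comp == c
        members = sorted(sites["id"][mask])
        pops.append(Population(id=f"G{rank}", member_sites=members,
                               centroid=(float(lon[mask].mean()), float(lat[mask].mean())),
                               buffer_km=buffer_km))
    return PopulationSet(pops, sites[["id", "lon", "lat"]].copy())


@dataclass
class FilterReport:
    n_individuals_in: int
    n_dropped_missing: int
    n_individuals_after_missing: int
    populations_dropped: list
    n_individuals_out: int
    n_populations_out: int


def filter_dataset(genotypes: GenotypeTable, populations: PopulationSet | None = None,
                   max_missing_alleles: int = 6, min_pop_n: int = 10):
    """Drop high-missingness individuals, then undersized populations.

    Individuals with more than ``max_missing_alleles`` missing alleles (a
    missing diploid call counts two) are removed first; populations left with
    fewer than ``min_pop_n`` individuals are then removed.  Returns
    ``(filtered GenotypeTable, filtered PopulationSet or None, FilterReport)``.
    The operation is idempotent.
    """
    gt = genotypes
    if populations is not None:
        gt = gt.relabel_populations(populations.site_to_population())

    n_in = gt.n_individuals
    keep = gt.missing_alleles_per_individual() <= max_missing_alleles
    gt2 = gt.subset(keep)
    n_after = gt2.n_individuals

    counts = gt2.individuals["population"].value_counts()
    good_pops = set(counts[counts >= min_pop_n].index)
    dropped = sorted(set(counts.index) - good_pops)
    gt3 = gt2.subset(gt2.individuals["population"].isin(good_pops).values)
    if gt3.n_individuals == 0:
        raise ValueError("no populations survive filtering")

    report = FilterReport(n_individuals_in=n_in,
                          n_dropped_missing=int(n_in - n_after),
                          n_individuals_after_missing=int(n_after),
                          populations_dropped=dropped,
                          n_individuals_out=gt3.n_individuals,
                          n_populations_out=len(good_pops))
    popset = populations.subset(good_pops) if populations is not None else None
    return gt3, popset, report


@dataclass
class WaterDistanceMatrix:
    """Symmetric least-cost over-water distances (km) between populations."""

    values: pd.DataFrame

    def __post_init__(self):
        v = self.values.values
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("water distances must be symmetric with zero diagonal")

    @property
    def labels(self) -> list:
        return list(self.values.index)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="population")

    @classmethod
    def from_csv(cls, path) -> "WaterDistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index.name = None
        return cls(df)


def _sea_graph(seascape: Seascape, neighborhood: int = 8):
    """Sparse weighted graph over sea cells; weights are haversine km."""
    land = seascape.land
    ny, nx = land.shape
    node = -np.ones((ny, nx), dtype=int)
    iy, ix = np.nonzero(~land)
    node[iy, ix] = np.arange(iy.size)

    if neighborhood == 8:
        moves = [(0, 1), (1, 0), (1, 1), (1, -1)]
    elif neighborhood == 16:
        moves = [(0, 1), (1, 0), (1, 1), (1, -1),
                 (1, 2), (2, 1), (1, -2), (2, -1)]
    else:
        raise ValueError("neighborhood must be 8 or 16")

    rows, cols, w = [], [], []
    LON, LAT = np.meshgrid(seascape.lon, seascape.lat)
    for dy, dx in moves:
        y0s, y1s = max(0, -dy), min(ny, ny - dy)
        x0s, x1s = max(0, -dx), min(nx, nx - dx)
        a = node[y0s:y1s, x0s:x1s]
        b = node[y0s + dy:y1s + dy, x0s + dx:x1s + dx]
        ok = (a >= 0) & (b >= 0)
        if not ok.any():
            continue
        d = haversine_km(LON[y0s:y1s, x0s:x1s][ok], LAT[y0s:y1s, x0s:x1s][ok],
                         LON[y0s + dy:y1s + dy, x0s + dx:x1s + dx][ok],
                         LAT[y0s + dy:y1s + dy, x0s + dx:x1s + dx][ok])
        rows.append(a[ok])
        cols.append(b[ok])
        w.append(d)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    w = np.concatenate(w)
    n = iy.size
    g = coo_matrix((np.concatenate([w, w]),
                    (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
                   shape=(n, n)).tocsr()
    return g, node


def _snap_to_sea(seascape: Seascape, lon: float, lat: float, max_cells: int = 2):
    """Nearest sea cell to a point, searching within ``max_cells`` (Chebyshev)."""
    iy, ix = seascape.cell_index(np.array([lon]), np.array([lat]))
    iy, ix = int(iy[0]), int(ix[0])
    if not seascape.land[iy, ix]:
        return iy, ix
    best, best_d = None, np.inf
    for dy in range(-max_cells, max_cells + 1):
        for dx in range(-max_cells, max_cells + 1):
            y, x = iy + dy, ix + dx
            if 0 <= y < seascape.ny and 0 <= x < seascape.nx and not seascape.land[y, x]:
                d = haversine_km(lon, lat, seascape.lon[x], seascape.lat[y])
                if d < best_d:
                    best, best_d = (y, x), d
    if best is None:
        raise ValueError(f"no sea cell within {max_cells} cells of ({lon:.3f}, {lat:.3f})")
    return best


def water_distance(seascape: Seascape, populations: PopulationSet,
                   neighborhood: int = 8) -> WaterDistanceMatrix:
    """Least-cost path length over sea cells between population centroids.

    The marine habitat is the set of sea cells; steps connect 8 (default) or
    16 neighbors with great-circle step costs (diagonals are naturally
    sqrt(2)-scaled).  Centroids falling on land snap to the nearest sea cell
    within two cells.  Disconnected centroid pairs raise an error naming the
    pair.
    """
    graph, node = _sea_graph(seascape, neighborhood)
    labels = populations.labels
    sources = []
    for pid in labels:
        lonc, latc = populations.by_id(pid).centroid
        iy, ix = _snap_to_sea(seascape, lonc, latc)
        sources.append(node[iy, ix])
    dist = dijkstra(graph, directed=False, indices=sources)
    out = dist[:, sources]
    out = 0.5 * (out + out.T)  # symmetric by construction; kill float wobble
    np.fill_diagonal(out, 0.0)
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            if not np.isfinite(out[a, b]):
                raise ValueError(f"populations {labels[a]} and {labels[b]} lie in disconnected seas")
    return WaterDistanceMatrix(pd.DataFrame(out, index=labels, columns=labels))
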