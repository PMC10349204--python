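"""Gridded surface-velocity fields ("seascapes") and their on-disk formats.

A :class:`Seascape` holds time-varying u/v surface velocities (m/s) on a
regular lon-lat grid together with a boolean landmask.  Files round-trip
through NetCDF (via xarray's scipy backend, NetCDF-3) or a plain ``.npz``
archive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xarray as xr


@dataclass
class Seascape:
    """Time-varying surface velocity field on a regular lon-lat grid.

    Attributes
    ----------
    lon, lat : 1-D arrays of cell-centre coordinates (degrees), strictly
        increasing.
    time_h : 1-D array of hours since the start of the record.
    u, v : arrays of shape (time, lat, lon), eastward/northward velocity (m/s).
        Zero on land cells.
    land : boolean (lat, lon) mask, True where the cell is land.
    period_h : if set, the field is treated as periodic in time with this
        period (hours); interpolation wraps.  ``None`` clamps to the ends.
    max_speed : sanity bound on |u|, |v| in m/s.
    """

    lon: np.ndarray
    lat: np.ndarray
    time_h: np.ndarray
    u: np.ndarray
    v: np.ndarray
    land: np.ndarray
    period_h: float | None = None
    max_speed: float = 3.0

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.land = np.asarray(self.land, dtype=bool)
        for name, ax in (("lon", self.lon), ("lat", self.lat), ("time_h", self.time_h)):
            if ax.ndim != 1 or (ax.size > 1 and not np.all(np.diff(ax) > 0)):
                raise ValueError(f"{name} axis must be 1-D and strictly increasing")
        shp = (self.time_h.size, self.lat.size, self.lon.size)
        if self.u.shape != shp or self.v.shape != shp:
            raise ValueError(f"u/v must have shape {shp}")
        if self.land.shape != (self.lat.size, self.lon.size):
            raise ValueError("landmask shape must be (lat, lon)")
        sea = ~self.land
        for name, a in (("u", self.u), ("v", self.v)):
            vals = a[:, sea]
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"{name} must be finite over sea cells")
            if np.abs(vals).max(initial=0.0) > self.max_speed:
                raise ValueError(f"|{name}| exceeds max_speed={self.max_speed} m/s")

    # -- grid helpers ------------------------------------------------------
    @property
    def nx(self) -> int:
        return self.lon.size

    @property
    def ny(self) -> int:
        return self.lat.size

    def cell_index(self, lon, lat):
        """Indices (iy, ix) of the grid cell whose centre is nearest each point."""
        ix = np.clip(np.searchsorted(self.lon, np.asarray(lon, dtype=float)), 1, self.nx - 1)
        ix = np.where(np.abs(self.lon[ix] - lon) < np.abs(lon - self.lon[ix - 1]), ix, ix - 1)
        iy = np.clip(np.searchsorted(self.lat, np.asarray(lat, dtype=float)), 1, self.ny - 1)
        iy = np.where(np.abs(self.lat[iy] - lat) < np.abs(lat - self.lat[iy - 1]), iy, iy - 1)
        return iy, ix

    def is_land(self, lon, lat):
        """True where the nearest grid cell to each point is land."""
        iy, ix = self.cell_index(lon, lat)
        return self.land[iy, ix]

    def sea_cell_coords(self):
        """(lon, lat) arrays of all sea cell centres."""
        iy, ix = np.nonzero(~self.land)
        return self.lon[ix], self.lat[iy]

    # -- interpolation -----------------------------------------------------
    def velocity(self, lon, lat, t_h):
        """Bilinear-in-space, linear-in-time interpolated (u, v) in m/s.

        ``lon``/``lat`` may be arrays; ``t_h`` broadcasts against them.
        Positions outside the grid are clamped to the boundary.  Land cells
        carry zero velocity, so the interpolant decays toward the coast.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        t = np.asarray(t_h, dtype=float)
        if self.period_h is not None:
            t = np.mod(t, self.period_h)

        # time bracket
        nt = self.time_h.size
        if nt == 1:
            it0 = it1 = np.zeros(np.shape(t), dtype=int)
            wt = np.zeros(np.shape(t))
        else:
            it1 = np.clip(np.searchsorted(self.time_h, t), 1, nt - 1)
            it0 = it1 - 1
            dt = self.time_h[it1] - self.time_h[it0]
            wt = np.clip((t - self.time_h[it0]) / dt, 0.0, 1.0)
            if self.period_h is not None:
                # wrap the final gap back to slice 0
                beyond = t > self.time_h[-1]
                if np.any(beyond):
                    gap = self.period_h - self.time_h[-1] + self.time_h[0]
                    wt = np.where(beyond, np.clip((t - self.time_h[-1]) / gap, 0.0, 1.0), wt)
                    it0 = np.where(beyond, nt - 1, it0)
                    it1 = np.where(beyond, 0, it1)

        ix1 = np.clip(np.searchsorted(self.lon, lon), 1, self.nx - 1)
        ix0 = ix1 - 1
        wx = np.clip((lon - self.lon[ix0]) / (self.lon[ix1] - self.lon[ix0]), 0.0, 1.0)
        iy1 = np.clip(np.searchsorted(self.lat, lat), 1, self.ny - 1)
        iy0 = iy1 - 1
        wy = np.clip((lat - self.lat[iy0]) / (self.lat[iy1] - self.lat[iy0]), 0.0, 1.0)

        out = []
        for f in (self.u, self.v):
            def plane(it):
                f00 = f[it, iy0, ix0]
                f01 = f[it, iy0, ix1]
                f10 = f[it, iy1, ix0]
                f11 = f[it, iy1, ix1]
                return (f00 * (1 - wx) * (1 - wy) + f01 * wx * (1 - wy)
                        + f10 * (1 - wx) * wy + f11 * wx * wy)

            out.append(plane(it0) * (1 - wt) + plane(it1) * wt)
        return out[0], out[1]

    # -- I/O ---------------------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "u": (("time", "lat", "lon"), self.u),
                "v": (("time", "lat", "lon"), self.v),
                "landmask": (("lat", "lon"), self.land.astype(np.int8)),
            },
            coords={"time": self.time_h, "lat": self.lat, "lon": self.lon},
            attrs={
                "period_h": -1.0 if self.period_h is None else float(self.period_h),
                "max_speed": float(self.max_speed),
                "time_units": "hours since start",
                "velocity_units": "m s-1",
            },
        )

    def to_netcdf(self, path: str | Path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "Seascape":
        period = float(ds.attrs.get("period_h", -1.0))
        return cls(
            lon=ds["lon"].values,
            lat=ds["lat"].values,
            time_h=ds["time"].values.astype(float),
            u=ds["u"].values,
            v=ds["v"].values,
            land=ds["landmask"].values.astype(bool),
            period_h=None if period < 0 else period,
            max_speed=float(ds.attrs.get("max_speed", 3.0)),
        )

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "Seascape":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())

    def to_npz(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            lon=self.lon, lat=self.lat, time_h=self.time_h,
            u=self.u, v=self.v, land=self.land,
            period_h=np.array(-1.0 if self.period_h is None else self.period_h),
            max_speed=np.array(self.max_speed),
        )

    @classmethod
    def from_npz(cls, path: str | Path) -> "Seascape":
        z = np.load(path)
        period = float(z["period_h"])
        return cls(lon=z["lon"], lat=z["lat"], time_h=z["time_h"], u=z["u"], v=z["v"],
                   land=z["land"], period_h=None if period < 0 else period,
                   max_speed=float(z["max_speed"]))
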