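"""Stage orchestration: simulate -> group -> track -> connect -> popgen -> stats.

Each stage reads its upstream artifacts from a run directory, writes its own
artifacts plus a provenance JSON (config hash, seed, package version), and
fails with an actionable message naming the producing stage when an upstream
artifact is missing.  Configuration is a TOML file; every default traces to
a shipped study value or a documented package decision.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import compute_tsib, network_connectivity, relative_probability, symmetrize
from .flowstats import (asym_mantel, fourth_root, make_pair_frame, mantel, partial_mantel,
                        transform_distance)
from .genotypes import GenotypeTable
from .geometry import PopulationSet, filter_dataset, group_sites, water_distance
from .lagrangian import DiffusionConfig, ReleasePlan, sample_release_sites, simulate
from .matrices import ConnectivityMatrix, DiffMatrix, DirectionalMatrix
from .mlpe import aicc_table, mlpe_fit
from .popgen import METRICS, amova, diversity, linearize, pairwise_diff
from .seascape import Seascape
from .synthetic import (GenotypeSimSpec, SeascapeSpec, island_migration, make_seascape,
                        make_sites, simulate_genotypes)
from .geometry import WaterDistanceMatrix

STAGES = ("make-synthetic", "group", "track", "connect", "popgen", "stats", "report")

#: which stage produces each artifact (for actionable missing-input errors)
_PRODUCERS = {
    "seascape.nc": "make-synthetic",
    "sites.csv": "make-synthetic",
    "genotypes.csv": "make-synthetic",
    "populations.csv": "group",
    "populations.json": "group",
    "water_distance.csv": "group",
    "trajectories.csv.gz": "track",
    "release_points.json": "group",
    "oc_symmetric.csv": "connect",
    "oc_asymmetric.csv": "connect",
    "diff_GpST_linearized.csv": "popgen",
}

DEFAULT_CONFIG = {
    "run": {"seed": 1},
    "seascape": {"nx": 72, "ny": 40, "n_times": 8, "period": 120.0,
                 "gyre_amplitude": 0.25, "land_fraction": 0.15,
                 "lon_range": [-83.0, -75.0], "lat_range": [24.0, 27.0]},
    "sites": {"n_pops": 6, "sites_per_pop": 2, "within_km": 6.0, "between_km": 90.0,
              "buffer_km": 10.0},
    "genotypes": {"pop_size": 80, "n_loci": 32, "selfing_rate": 0.95,
                  "mutation_rate": 1e-3, "generations": 100, "sample_size": 25,
                  "island_m": 0.05, "max_missing_alleles": 6, "min_pop_n": 10},
    "release": {"n_release_sites": 20, "particles_per_day": 5, "n_days": 10,
                "offshore_km": 2.0},
    "diffusion": {"K": 36.5, "dt": 600.0, "record_dt_h": 0.5},
    "track": {"duration_days": 15.0},
    "stats": {"n_perm": 999, "n_boot": 200},
}


def load_config(path: str | Path | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
        for section, values in user.items():
            cfg.setdefault(section, {}).update(values)
    return cfg


def write_config_toml(cfg: dict, path: str | Path) -> None:
    """Serialize a flat two-level config back to TOML (lossless round trip)."""
    lines = []
    for section, values in cfg.items():
        lines.append(f"[{section}]")
        for key, val in values.items():
            if isinstance(val, str):
                lines.append(f'{key} = "{val}"')
            elif isinstance(val, bool):
                lines.append(f"{key} = {str(val).lower()}")
            elif isinstance(val, list):
                lines.append(f"{key} = [{', '.join(repr(float(v)) for v in val)}]")
            else:
                lines.append(f"{key} = {val}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def _need(out_dir: Path, name: str) -> Path:
    p = out_dir / name
    if not p.exists():
        producer = _PRODUCERS.get(name, "an earlier stage")
        raise FileNotFoundError(f"missing artifact '{name}': run '{producer}' first")
    return p


def _provenance(out_dir: Path, stage: str, cfg: dict, seed: int) -> None:
    blob = json.dumps(cfg, sort_keys=True).encode()
    (out_dir / f"provenance_{stage.replace('-', '_')}.json").write_text(json.dumps({
        "stage": stage, "seed": seed, "seaflow_version": __version__,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
    }, indent=2) + "\n")


def run_stage(stage: str, config: dict | str | Path | None, out_dir: str | Path,
              seed: int | None = None) -> list:
    """Run one pipeline stage; returns the list of artifact paths written."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage '{stage}'; choose from {STAGES}")
    cfg = config if isinstance(config, dict) else load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["run"].get("seed", 1) if seed is None else seed)
    written: list[Path] = []

    def emit(path):
        written.append(path)
        return path

    if stage == "make-synthetic":
        sc = cfg["seascape"]
        spec = SeascapeSpec(lon_range=tuple(sc["lon_range"]), lat_range=tuple(sc["lat_range"]),
                            nx=sc["nx"], ny=sc["ny"], n_times=sc["n_times"], period=sc["period"],
                            gyre_amplitude=sc["gyre_amplitude"],
                            land_fraction=sc["land_fraction"], seed=seed)
        sea = make_seascape(spec)
        sea.to_netcdf(emit(out_dir / "seascape.nc"))
        st = cfg["sites"]
        sites = make_sites(st["n_pops"], st["sites_per_pop"],
                           (st["within_km"], st["between_km"]), sea, seed=seed + 1)
        sites.to_csv(emit(out_dir / "sites.csv"), index=False)
        gn = cfg["genotypes"]
        gspec = GenotypeSimSpec(n_pops=st["n_pops"], pop_size=gn["pop_size"],
                                n_loci=gn["n_loci"], selfing_rate=gn["selfing_rate"],
                                mutation_rate=gn["mutation_rate"],
                                migration=island_migration(st["n_pops"], gn["island_m"]),
                                generations=gn["generations"], sample_size=gn["sample_size"],
                                seed=seed + 2)
        gt, truth = simulate_genotypes(gspec, sites_per_pop=st["sites_per_pop"])
        gt.to_csv(emit(out_dir / "genotypes.csv"))
        gt.to_genepop(emit(out_dir / "genotypes.gen"))
        truth.to_json(emit(out_dir / "truth.json"))

    elif stage == "group":
        sites = pd.read_csv(_need(out_dir, "sites.csv"))
        sea = Seascape.from_netcdf(_need(out_dir, "seascape.nc"))
        pops = group_sites(sites[["id", "lon", "lat"]], cfg["sites"]["buffer_km"])
        pops.to_csv(emit(out_dir / "populations.csv"))
        pops.to_json(emit(out_dir / "populations.json"))
        water_distance(sea, pops).to_csv(emit(out_dir / "water_distance.csv"))
        rl = cfg["release"]
        points = {pid: sample_release_sites(pops, pid, sea, n=rl["n_release_sites"],
                                            offshore_km=rl["offshore_km"], seed=seed + 10 + k)
                  for k, pid in enumerate(pops.labels)}
        (out_dir / "release_points.json").write_text(json.dumps(
            {k: np.asarray(v).tolist() for k, v in points.items()}, indent=2))
        written.append(out_dir / "release_points.json")

    elif stage == "track":
        points = {k: np.array(v) for k, v in
                  json.loads(_need(out_dir, "release_points.json").read_text()).items()}
        sea = Seascape.from_netcdf(_need(out_dir, "seascape.nc"))
        rl, df = cfg["release"], cfg["diffusion"]
        plan = ReleasePlan(points=points, particles_per_day=rl["particles_per_day"],
                           n_days=rl["n_days"], seed=seed + 20)
        dcfg = DiffusionConfig(K=df["K"], dt=df["dt"], record_dt_h=df["record_dt_h"])
        traj = simulate(plan, sea, dcfg, duration_days=cfg["track"]["duration_days"])
        traj.to_csv(emit(out_dir / "trajectories.csv.gz"))
        (out_dir / "track_diagnostics.json").write_text(json.dumps(traj.diagnostics) + "\n")
        written.append(out_dir / "track_diagnostics.json")

    elif stage == "connect":
        from .lagrangian import TrajectorySet
        traj = TrajectorySet.from_csv(_need(out_dir, "trajectories.csv.gz"),
                                      cfg["diffusion"]["record_dt_h"])
        sites = pd.read_csv(_need(out_dir, "populations.csv"))
        pops = group_sites(sites[["id", "lon", "lat"]], cfg["sites"]["buffer_km"])
        tsib = compute_tsib(traj, pops)
        tsib.to_csv(emit(out_dir / "tsib.csv"))
        sym = symmetrize(tsib)
        sym.to_csv(emit(out_dir / "tsib_symmetric.csv"))
        network_connectivity(relative_probability(tsib), sqrt_transform=True).to_csv(
            emit(out_dir / "oc_asymmetric.csv"))
        network_connectivity(relative_probability(sym), sqrt_transform=True).to_csv(
            emit(out_dir / "oc_symmetric.csv"))

    elif stage == "popgen":
        gt = GenotypeTable.from_csv(_need(out_dir, "genotypes.csv"))
        site_map = pd.read_csv(_need(out_dir, "populations.csv"))
        gt = gt.relabel_populations(dict(zip(site_map["id"].astype(str),
                                             site_map["population"].astype(str))))
        gn = cfg["genotypes"]
        gt, _, report = filter_dataset(gt, max_missing_alleles=gn["max_missing_alleles"],
                                       min_pop_n=gn["min_pop_n"])
        (out_dir / "filter_report.json").write_text(json.dumps(report.__dict__) + "\n")
        written.append(out_dir / "filter_report.json")
        diversity(gt).to_csv(emit(out_dir / "diversity.csv"))
        for metric in METRICS:
            dm = pairwise_diff(gt, metric)
            dm.to_csv(emit(out_dir / f"diff_{metric}.csv"))
            linearize(dm).to_csv(emit(out_dir / f"diff_{metric}_linearized.csv"))
        amova(gt, n_perm=min(199, cfg["stats"]["n_perm"]), seed=seed + 30).to_csv(
            emit(out_dir / "amova.csv"))

    elif stage == "stats":
        st = cfg["stats"]
        water = WaterDistanceMatrix.from_csv(_need(out_dir, "water_distance.csv"))
        oc_s = ConnectivityMatrix.from_csv(_need(out_dir, "oc_symmetric.csv"))
        logd = transform_distance(water.values)
        results = {}
        for metric in METRICS:
            dm = DiffMatrix.from_csv(_need(out_dir, f"diff_{metric}_linearized.csv"))
            if list(dm.labels) != list(water.labels):
                common = [l for l in water.labels if l in dm.labels]
                dm = DiffMatrix(dm.values.loc[common, common], dm.metric, dm.linearized)
                logd_m = logd.loc[common, common]
                oc_m = oc_s.values.loc[common, common]
            else:
                logd_m, oc_m = logd, oc_s.values
            res_d = mantel(dm.values, logd_m, n_perm=st["n_perm"], n_boot=st["n_boot"],
                           seed=seed + 40, alternative="greater")
            res_oc = partial_mantel(dm.values, oc_m, logd_m, n_perm=st["n_perm"],
                                    n_boot=st["n_boot"], seed=seed + 41, alternative="less")
            results[metric] = {"mantel_distance": res_d.as_dict(),
                               "partial_mantel_oc": res_oc.as_dict()}
            frame = make_pair_frame(dm.values, {"distance": logd_m, "oc_s": oc_m})
            fits = [mlpe_fit(frame, p) for p in (["oc_s"], ["distance"], ["oc_s", "distance"],
                                                 ["oc_s", "distance", "oc_s:distance"])]
            aicc_table(fits).to_csv(emit(out_dir / f"mlpe_{metric}.csv"), index=False)
        (out_dir / "mantel_results.json").write_text(json.dumps(results, indent=2) + "\n")
        written.append(out_dir / "mantel_results.json")

    elif stage == "report":
        summary = {}
        for name in ("filter_report.json", "mantel_results.json", "track_diagnostics.json"):
            p = out_dir / name
            if p.exists():
                summary[name] = json.loads(p.read_text())
        lines = ["seaflow run report", "=" * 18]
        for f in sorted(out_dir.glob("*.csv")):
            lines.append(f"artifact: {f.name}")
        (out_dir / "report.txt").write_text("\n".join(lines) + "\n")
        (out_dir / "report.json").write_text(json.dumps(summary, indent=2) + "\n")
        written += [out_dir / "report.txt", out_dir / "report.json"]

    _provenance(out_dir, stage, cfg, seed)
    return written


def run_all(config, out_dir, seed: int | None = None) -> None:
    for stage in STAGES:
        run_stage(stage, config, out_dir, seed=seed)
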