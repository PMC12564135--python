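"""Reproducible generate → analyze → estimate pipeline.

A YAML :class:`RunConfig` (schema-validated, defaults materialised into the
persisted copy) drives the stages in dependency order:

``scene``     build the toy bilayer + solute trajectory (PDB + XYZ + JSON
              provenance sidecar), with solute COM z-dynamics from the
              Langevin generator when a ``dynamics`` section is present;
``analyze``   the enabled observables, each written as a tidy CSV plus a
              JSON metadata sidecar (criteria, bins, selections, units);
``pull``      forward/reverse steered pulls (work-trace CSVs);
``pmf``       the forward–reverse PMF profile CSV.

Re-running with the same config and seed reproduces identical checksums;
stages whose inputs are unchanged are skipped via stage hash files.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .dynamics import LangevinParams, PullProtocol, simulate_langevin_1d, simulate_smd_pull
from .io import write_pdb, write_xyz_trajectory
from .observables import (
    HBondCriteria,
    com_z_distance,
    conformation_map,
    cluster_timeseries,
    distance_distribution,
    dihedral,
    end_to_end,
    hbond_distribution,
    hbond_timeseries,
    number_density_profile,
)
from .pmf import (
    average_works,
    default_grid,
    estimate_dissipation,
    estimate_friction_diffusion,
    estimate_pmf,
    read_work_trace,
    write_work_trace,
)
from .potentials import PotentialSpec
from .sasa import sasa
from .scene import (
    SceneSpec,
    build_bilayer_scene,
    compute_molar_ratio,
    derivative_template,
    guaiacyl_template,
    syringyl_template,
)
from .trajectory import Selection

__all__ = ["RunConfig", "RunManifest", "PipelineError", "ConfigError",
           "load_config", "run_pipeline", "report"]

_TEMPLATES = {
    "guaiacyl": guaiacyl_template,
    "syringyl": syringyl_template,
    "derivative": derivative_template,
}

ALL_OBSERVABLES = ("com_z", "density", "sasa", "hbonds", "clusters", "conformers")


class ConfigError(ValueError):
    """Configuration failed schema validation."""


class PipelineError(RuntimeError):
    """A pipeline stage failed."""


# ------------------------------------------------------------------- schema

class PotentialConfig(BaseModel):
    form: str = "flat"
    params: dict = Field(default_factory=dict)
    domain: tuple[float, float] = (-5.0, 24.0)

    def build(self) -> PotentialSpec:
        return PotentialSpec(self.form, dict(self.params), tuple(self.domain))


class SceneConfig(BaseModel):
    box: tuple[float, float, float] = (128.0, 128.0, 96.0)
    n_lipids_per_leaflet: int = 400
    leaflet_z: float = 20.0
    lattice_jitter: float = 0.4
    water_number_density: float = 0.0334
    solute_grid: int = 3
    template: str = "guaiacyl"
    n_frames: int = 50
    solute_z0: Optional[float] = None

    @field_validator("template")
    @classmethod
    def _known_template(cls, v: str) -> str:
        if v not in _TEMPLATES:
            raise ValueError(f"template must be one of {sorted(_TEMPLATES)}")
        return v

    def build(self, seed: int) -> SceneSpec:
        return SceneSpec(
            box=self.box,
            n_lipids_per_leaflet=self.n_lipids_per_leaflet,
            leaflet_z=self.leaflet_z,
            lattice_jitter=self.lattice_jitter,
            water_number_density=self.water_number_density,
            solute_grid=self.solute_grid,
            solute_template=_TEMPLATES[self.template](),
            n_frames=self.n_frames,
            solute_z0=self.solute_z0,
            seed=seed,
        )


class DynamicsConfig(BaseModel):
    D: float = 100.0          # Å²/ns
    T: float = 300.0          # K
    dt: float = 5e-5          # ns
    n_steps: int = 200_000
    record_stride: int = 4000
    potential: PotentialConfig = Field(
        default_factory=lambda: PotentialConfig(
            form="harmonic", params={"kappa": 0.05, "z0": 26.0}, domain=(18.0, 40.0)
        )
    )

    def params(self) -> LangevinParams:
        return LangevinParams(D=self.D, T=self.T, dt=self.dt)


class PullConfig(BaseModel):
    v: float = 0.1            # Å/ns
    k_spring: float = 10.0    # kcal/mol/Å²
    z_start: float = 0.0
    z_end: float = 19.0
    n_pulls_per_direction: int = 20
    record_stride: int = 500
    D: float = 100.0
    T: float = 300.0
    dt: float = 4e-5
    potential: PotentialConfig = Field(
        default_factory=lambda: PotentialConfig(
            form="double_well",
            params={"z1": 2.0, "z2": 17.0, "barrier": 4.0},
            domain=(-3.0, 22.0),
        )
    )


class HBondConfig(BaseModel):
    d_DA_max: float = 3.5
    angle_HDA_max: float = 30.0

    def build(self) -> HBondCriteria:
        return HBondCriteria(self.d_DA_max, self.angle_HDA_max)


class SasaConfig(BaseModel):
    probe_radius: float = 1.4
    n_sphere_points: int = 960


class ObservablesConfig(BaseModel):
    enabled: tuple[str, ...] = ALL_OBSERVABLES
    hbond: HBondConfig = Field(default_factory=HBondConfig)
    sasa: SasaConfig = Field(default_factory=SasaConfig)
    cluster_cutoff: float = 3.5
    density_bin_width: float = 0.5
    distance_bin_width: float = 1.0
    dihedral_bin_width: float = 15.0
    end_to_end_bin_width: float = 0.25
    reference_selection: str = "name:NF leaflet:upper"

    @field_validator("enabled")
    @classmethod
    def _known(cls, v):
        bad = set(v) - set(ALL_OBSERVABLES)
        if bad:
            raise ValueError(f"unknown observables {sorted(bad)}; choose from {ALL_OBSERVABLES}")
        return tuple(v)


class PmfConfig(BaseModel):
    grid_min: float = 0.0
    grid_max: float = 19.0
    grid_spacing: float = 0.5
    anchor: Optional[float] = 19.0


class RunConfig(BaseModel):
    seed: int = 0
    outdir: str = "ligmem_run"
    scene: SceneConfig = Field(default_factory=SceneConfig)
    dynamics: Optional[DynamicsConfig] = Field(default_factory=DynamicsConfig)
    pulls: Optional[PullConfig] = None
    observables: ObservablesConfig = Field(default_factory=ObservablesConfig)
    pmf: Optional[PmfConfig] = None


class RunManifest(BaseModel):
    config_hash: str
    seed: int
    version: str
    outdir: str
    files: dict  # relative path -> sha256
    wall_seconds: float
    stages_run: list
    stages_skipped: list


# ------------------------------------------------------------------ helpers

def load_config(path) -> RunConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return RunConfig.model_validate(raw)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(cfg: RunConfig) -> str:
    payload = cfg.model_dump(mode="json")
    payload.pop("outdir", None)  # where outputs land does not change them
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def _child_seed(seed: int, *tags: int) -> int:
    ss = np.random.SeedSequence([seed, *tags])
    return int(ss.generate_state(1)[0] % (2**31))


def _stage_fresh(outdir: Path, stage: str, key: str, outputs: list) -> bool:
    mark = outdir / f".{stage}.hash"
    return mark.exists() and mark.read_text() == key and all(p.exists() for p in outputs)


def _mark_stage(outdir: Path, stage: str, key: str) -> None:
    (outdir / f".{stage}.hash").write_text(key)


def _sidecar(path: Path, meta: dict) -> None:
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1, default=str))


# ------------------------------------------------------------------- stages

def _stage_scene(cfg: RunConfig, outdir: Path):
    spec = cfg.scene.build(seed=_child_seed(cfg.seed, 1))
    paths = None
    if cfg.dynamics is not None:
        pot = cfg.dynamics.potential.build()
        par = cfg.dynamics.params()
        m2 = cfg.scene.solute_grid**2
        stride = max(1, cfg.dynamics.n_steps // max(cfg.scene.n_frames - 1, 1))
        z0 = cfg.scene.solute_z0 if cfg.scene.solute_z0 is not None else cfg.scene.leaflet_z + 8.0
        z0 = float(np.clip(z0, *pot.domain))
        paths = [
            simulate_langevin_1d(pot, par, cfg.dynamics.n_steps, z0,
                                 seed=_child_seed(cfg.seed, 2, i), record_stride=stride)
            for i in range(m2)
        ]
    topo, traj = build_bilayer_scene(spec, paths=paths)
    write_pdb(outdir / "scene.pdb", topo, traj.coords[0], box=traj.box[0])
    write_xyz_trajectory(outdir / "scene.xyz", topo, traj)
    ratio, frac = compute_molar_ratio(spec.solute_grid**2, 2 * spec.n_lipids_per_leaflet)
    prov = {
        "seed": cfg.seed,
        "scene_seed": spec.seed,
        "template": cfg.scene.template,
        "n_solutes": spec.solute_grid**2,
        "n_lipids": 2 * spec.n_lipids_per_leaflet,
        "molar_ratio": ratio,
        "molar_fraction": str(frac),
        "n_frames": traj.n_frames,
        "version": __version__,
    }
    (outdir / "scene.provenance.json").write_text(json.dumps(prov, indent=1))
    return topo, traj, spec


def _stage_observables(cfg: RunConfig, outdir: Path, topo, traj, spec) -> list:
    ob = cfg.observables
    tpl = spec.solute_template
    written = []
    ref_sel = Selection.parse(ob.reference_selection)
    solute_sel = Selection(species=frozenset({tpl.species}))
    solute_mols = topo.molecules_of_species(tpl.species)

    def emit(name: str, df: pd.DataFrame, meta: dict):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.8g")
        _sidecar(p, meta)
        written.append(p)

    z_series = None
    if "com_z" in ob.enabled or "conformers" in ob.enabled:
        rows = []
        per_mol = {}
        for m in solute_mols:
            ids = topo.atoms_of_molecule(m)
            series = com_z_distance(traj, topo, ids, ref_sel)
            per_mol[m] = series
            rows.append(pd.DataFrame({"frame": np.arange(traj.n_frames),
                                      "time": traj.times, "molecule": m, "com_z": series}))
        z_df = pd.concat(rows, ignore_index=True)
        z_series = per_mol
    if "com_z" in ob.enabled:
        emit("com_z", z_df, {"units": "Å", "reference": ob.reference_selection,
                             "sign": "negative below the upper-leaflet N plane"})
        pooled = z_df["com_z"].to_numpy()
        dist = distance_distribution(pooled, bin_width=ob.distance_bin_width)
        emit("com_z_distribution", dist.to_frame(),
             {"units": "Å", "bin_width": ob.distance_bin_width, "mode": dist.mode})
    if "density" in ob.enabled:
        for label, sel in (
            ("water", Selection(species=frozenset({"water"}))),
            ("headgroup_N", Selection(names=frozenset({"NF"}))),
            ("solute", solute_sel),
        ):
            prof = number_density_profile(traj, topo, sel, bin_width=ob.density_bin_width)
            emit(f"density_{label}", prof.to_frame(),
                 {"units": "Å^-3", "bin_width": ob.density_bin_width,
                  "mode": prof.mode, "n_frames": prof.n_frames})
    if "sasa" in ob.enabled:
        per_atom, per_mol_area = sasa(traj.coords[0], topo, subset=solute_sel,
                                      probe_radius=ob.sasa.probe_radius,
                                      n_sphere_points=ob.sasa.n_sphere_points)
        df = pd.DataFrame({"molecule": list(per_mol_area), "sasa": list(per_mol_area.values())})
        df["species"] = [topo.mol_species[m] for m in df["molecule"]]
        emit("sasa", df, {"units": "Å^2", "probe_radius": ob.sasa.probe_radius,
                          "n_sphere_points": ob.sasa.n_sphere_points,
                          "occluders": "all non-water atoms"})
    if "hbonds" in ob.enabled:
        crit = ob.hbond.build()
        counts = hbond_timeseries(traj, topo, crit, solute_sel,
                                  Selection(species=frozenset({"water"})))
        emit("hbonds", pd.DataFrame({"frame": np.arange(traj.n_frames),
                                     "time": traj.times, "count": counts}),
             {"criteria": asdict(crit), "groups": [tpl.species, "water"],
              "mode": "intermolecular"})
        emit("hbond_distribution", hbond_distribution(counts).to_frame(),
             {"criteria": asdict(crit)})
    if "clusters" in ob.enabled:
        df = cluster_timeseries(traj, topo, ob.cluster_cutoff)
        emit("clusters", df, {"cutoff": ob.cluster_cutoff, "linkage": "any-atom single"})
    if "conformers" in ob.enabled:
        rows = []
        for m in solute_mols:
            ree = end_to_end(traj, topo, m, tpl.terminal_pair)
            dih = dihedral(traj, topo, m, tpl.dihedral_quad)
            rows.append(pd.DataFrame({"frame": np.arange(traj.n_frames), "molecule": m,
                                      "end_to_end": ree, "dihedral": dih,
                                      "com_z": z_series[m]}))
        conf = pd.concat(rows, ignore_index=True)
        emit("conformers", conf, {"terminal_pair": tpl.terminal_pair,
                                  "dihedral_quad": tpl.dihedral_quad, "units": "Å, degrees"})
        cmap = conformation_map(conf["end_to_end"].to_numpy(), conf["com_z"].to_numpy(),
                                x_bin_width=ob.end_to_end_bin_width,
                                y_bin_width=ob.distance_bin_width)
        nx, ny = cmap.values.shape
        flat = pd.DataFrame({
            "end_to_end": np.repeat(cmap.x_centers, ny),
            "com_z": np.tile(cmap.y_centers, nx),
            "frequency": cmap.values.ravel(),
        })
        emit("conformation_map", flat, {"x_bin_width": ob.end_to_end_bin_width,
                                        "y_bin_width": ob.distance_bin_width,
                                        "normalization": "cell masses sum to 1"})
    return written


def _stage_pulls(cfg: RunConfig, outdir: Path) -> list:
    pc = cfg.pulls
    pot = pc.potential.build()
    par = LangevinParams(D=pc.D, T=pc.T, dt=pc.dt)
    written = []
    for direction in ("F", "R"):
        z0, z1 = (pc.z_start, pc.z_end) if direction == "F" else (pc.z_end, pc.z_start)
        proto = PullProtocol(direction, pc.v, pc.k_spring, z0, z1, pc.record_stride)
        for i in range(pc.n_pulls_per_direction):
            seed = _child_seed(cfg.seed, 3, 0 if direction == "F" else 1, i)
            trace = simulate_smd_pull(pot, par, proto, seed=seed)
            p = outdir / f"pull_{direction}_{i:03d}.csv"
            write_work_trace(p, trace)
            written.extend([p, p.with_suffix(".json")])
    return written


def _stage_pmf(cfg: RunConfig, outdir: Path) -> list:
    pm = cfg.pmf
    traces = [read_work_trace(p) for p in sorted(outdir.glob("pull_*.csv"))]
    if not traces:
        raise PipelineError("pmf stage: no pull traces found (run the pull stage first)")
    grid = default_grid(pm.grid_min, pm.grid_max, pm.grid_spacing)
    mw = average_works(traces, grid)
    prof = estimate_pmf(mw, anchor=pm.anchor)
    prof.Wd = estimate_dissipation(mw)
    T = cfg.pulls.T if cfg.pulls is not None else 300.0
    prof.D = estimate_friction_diffusion(mw, T=T)
    p = outdir / "pmf.csv"
    prof.to_frame().to_csv(p, index=False, float_format="%.8g")
    _sidecar(p, {"anchor": pm.anchor, "n_F": mw.n_F, "n_R": mw.n_R, "v": mw.v,
                 "estimator": "dU = 0.5*(W_F - W_R); Wd = 0.5*(W_F + W_R)"})
    return [p]


def run_pipeline(cfg: RunConfig, stages: Optional[list] = None) -> RunManifest:
    """Execute the requested stages in dependency order; returns the manifest.

    ``stages`` defaults to every stage the config enables.  Stages whose
    config+seed hash matches a previous run (and whose outputs exist) are
    skipped.
    """
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)
    (outdir / "config.resolved.yaml").write_text(
        yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False)
    )
    wanted = stages or ["scene"] \
        + (["analyze"] if cfg.observables.enabled else []) \
        + (["pull"] if cfg.pulls is not None else []) \
        + (["pmf"] if cfg.pmf is not None and cfg.pulls is not None else [])
    ran, skipped = [], []
    topo = traj = spec = None

    def need_scene():
        nonlocal topo, traj, spec
        if topo is None:
            topo, traj, spec = _stage_scene(cfg, outdir)

    try:
        if "scene" in wanted:
            key = f"scene:{chash}:{cfg.seed}"
            outs = [outdir / "scene.pdb", outdir / "scene.xyz"]
            if _stage_fresh(outdir, "scene", key, outs):
                skipped.append("scene")
            else:
                need_scene()
                _mark_stage(outdir, "scene", key)
                ran.append("scene")
        if "analyze" in wanted:
            key = f"analyze:{chash}:{cfg.seed}"
            if _stage_fresh(outdir, "analyze", key, [outdir / "com_z.csv"]) and "com_z" in cfg.observables.enabled:
                skipped.append("analyze")
            else:
                need_scene()
                _stage_observables(cfg, outdir, topo, traj, spec)
                _mark_stage(outdir, "analyze", key)
                ran.append("analyze")
        if "pull" in wanted:
            if cfg.pulls is None:
                raise PipelineError("pull stage requested but config has no pulls section")
            key = f"pull:{chash}:{cfg.seed}"
            if _stage_fresh(outdir, "pull", key, [outdir / "pull_F_000.csv"]):
                skipped.append("pull")
            else:
                _stage_pulls(cfg, outdir)
                _mark_stage(outdir, "pull", key)
                ran.append("pull")
        if "pmf" in wanted:
            if cfg.pmf is None:
                raise PipelineError("pmf stage requested but config has no pmf section")
            key = f"pmf:{chash}:{cfg.seed}"
            if _stage_fresh(outdir, "pmf", key, [outdir / "pmf.csv"]):
                skipped.append("pmf")
            else:
                _stage_pmf(cfg, outdir)
                _mark_stage(outdir, "pmf", key)
                ran.append("pmf")
    except (PipelineError, ConfigError):
        raise
    except Exception as exc:
        stage = (ran + ["?"])[-1] if not wanted else wanted[min(len(ran), len(wanted) - 1)]
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    files = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and not p.name.startswith(".") and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config_hash=chash, seed=cfg.seed, version=__version__, outdir=str(outdir),
        files=files, wall_seconds=time.time() - t0, stages_run=ran, stages_skipped=skipped,
    )
    (outdir / "manifest.json").write_text(manifest.model_dump_json(indent=1))
    return manifest


# ------------------------------------------------------------------- report

def _pmf_minimum(z: np.ndarray, dU: np.ndarray) -> tuple:
    """Minimum location/value refined by a quadratic fit around the grid minimum."""
    i = int(np.argmin(dU))
    if 0 < i < len(z) - 1:
        zs, us = z[i - 1 : i + 2], dU[i - 1 : i + 2]
        a, b, c = np.polyfit(zs, us, 2)
        if a > 0:
            zm = -b / (2 * a)
            return float(zm), float(np.polyval([a, b, c], zm))
    return float(z[i]), float(dU[i])


def report(manifest_path) -> dict:
    """Summary tables from a run manifest: per-species means and PMF minima.

    Pure function of the manifest's files; missing stage outputs are
    enumerated in the ``missing`` entry.  An empty manifest yields an
    empty report.
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    outdir = manifest_path.parent
    summary: dict = {"config_hash": manifest["config_hash"], "missing": []}
    if not manifest["files"]:
        summary["empty"] = True
        return summary

    prov_p = outdir / "scene.provenance.json"
    n_solutes = None
    if prov_p.exists():
        prov = json.loads(prov_p.read_text())
        summary["molar_ratio"] = prov["molar_ratio"]
        n_solutes = prov["n_solutes"]

    rows = []
    hb = outdir / "hbonds.csv"
    if hb.exists() and n_solutes:
        counts = pd.read_csv(hb)["count"]
        rows.append({"quantity": "hbonds_with_water_per_molecule",
                     "value": counts.mean() / n_solutes})
    elif not hb.exists():
        summary["missing"].append("hbonds.csv")
    sa = outdir / "sasa.csv"
    if sa.exists():
        df = pd.read_csv(sa)
        for sp, g in df.groupby("species"):
            rows.append({"quantity": f"sasa_per_molecule[{sp}]", "value": g["sasa"].mean()})
    else:
        summary["missing"].append("sasa.csv")
    cl = outdir / "clusters.csv"
    if cl.exists():
        df = pd.read_csv(cl)
        for sp, g in df.groupby("species"):
            rows.append({"quantity": f"normalized_clusters[{sp}]",
                         "value": g["normalized_clusters"].mean()})
    else:
        summary["missing"].append("clusters.csv")
    pmf_p = outdir / "pmf.csv"
    if pmf_p.exists():
        df = pd.read_csv(pmf_p)
        zmin, umin = _pmf_minimum(df["z"].to_numpy(), df["dU"].to_numpy())
        rows.append({"quantity": "pmf_minimum_z", "value": zmin})
        rows.append({"quantity": "pmf_minimum_dU", "value": umin})

    df = pd.DataFrame(rows, columns=["quantity", "value"])
    df.to_csv(outdir / "summary.csv", index=False, float_format="%.8g")
    summary["quantities"] = {r["quantity"]: r["value"] for r in rows}
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary
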