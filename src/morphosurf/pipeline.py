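"""End-to-end run orchestration: configuration, staging, logging, exports.

A run takes a dataset manifest (CSV listing specimen meshes and landmark
files), a template (mesh + landmarks + semilandmark file at the maximum
density), and a grid of methods × densities × analysis targets. For each
cell it semilandmarks every specimen, runs GPA, builds the requested
estimated surfaces, optionally re-semilandmarks + re-warps them for
comparability, and writes CSV tables (between-method distances, density
convergence, PCA scores), PLY surfaces and area-difference maps, plus a
YAML manifest echoing the configuration, library versions, seeds and
per-stage timings. Identical config + seed ⇒ byte-identical tables.

Lower densities reuse the first *d* rows of the template's semilandmark
file, so density ladders share a deterministic template file.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mesh import (SemilandmarkTemplate, load_landmarks, load_mesh,
                   load_semilandmark_template_csv, save_mesh)
from .registration import NICPParams
from .semilandmark import Configuration, METHODS, semilandmark_specimen
from .shape_stats import fit_allometry, gpa, predict_shape_at_size, shape_pca
from .surface_compare import (EstimatedSurface, area_difference_map,
                              estimate_mean_surface, landmark_only_surface,
                              resemilandmark_and_rewarp, save_face_map_csv,
                              save_face_map_ply, scale_to_common_size,
                              vertex_procrustes_distance,
                              warp_surface_to_configuration)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline",
           "load_dataset_manifest", "save_configuration_csv",
           "load_configuration_csv"]

TARGETS = ("mean", "allometry-min", "allometry-max", "landmark-only")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the offending item."""

    def __init__(self, stage: str, item: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {item!r}: {cause}")
        self.stage = stage
        self.item = item
        self.__cause__ = cause


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one comparison run."""

    dataset_manifest: str
    template_mesh: str
    template_landmarks: str
    template_semilandmarks: str
    methods: tuple[str, ...] = ("sliding_tps",)
    densities: tuple[int, ...] = (100,)
    targets: tuple[str, ...] = ("mean",)
    rewarp: bool = True
    output_dir: str = "morphosurf-run"
    seed: int = 0
    nicp: dict = field(default_factory=dict)
    sliding: dict = field(default_factory=dict)   # slide_iters, slide_tol
    icp: dict = field(default_factory=dict)       # icp_iters, with_scale

    def __post_init__(self):
        object.__setattr__(self, "methods", tuple(self.methods))
        object.__setattr__(self, "densities",
                           tuple(int(d) for d in self.densities))
        object.__setattr__(self, "targets", tuple(self.targets))
        if not self.methods or not self.targets:
            raise ValueError("need at least one method and one target")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        unknown = set(self.targets) - set(TARGETS)
        if unknown:
            raise ValueError(f"unknown targets {sorted(unknown)}")
        d = self.densities
        if not d or any(x <= 0 for x in d) \
                or any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("densities must be positive and strictly "
                             "increasing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        d["densities"] = list(self.densities)
        d["targets"] = list(self.targets)
        return d


# ------------------------------------------------------------------- IO

def load_dataset_manifest(path: str | Path) -> list[tuple[str, str, str]]:
    """Read `id,mesh,landmarks` CSV; relative paths resolve against the
    manifest's directory."""
    df = pd.read_csv(path)
    required = ["id", "mesh", "landmarks"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: expected header id,mesh,landmarks")
    base = Path(path).parent
    out = [(str(row["id"]),
            str(base / str(row["mesh"])),
            str(base / str(row["landmarks"])))
           for _, row in df.iterrows()]
    if not out:
        raise ValueError(f"{path}: empty manifest")
    return out


def save_configuration_csv(config: Configuration, path: str | Path) -> None:
    """Serialise one configuration as `index,role,x,y,z`."""
    pd.DataFrame({"index": np.arange(config.points.shape[0]),
                  "role": config.roles,
                  "x": config.points[:, 0], "y": config.points[:, 1],
                  "z": config.points[:, 2]}).to_csv(path, index=False)


def load_configuration_csv(path: str | Path) -> Configuration:
    df = pd.read_csv(path)
    roles = df["role"].to_numpy()
    n_fixed = int((roles == "fixed").sum())
    if not (roles[:n_fixed] == "fixed").all():
        raise ValueError(f"{path}: fixed points must precede sliding points")
    return Configuration(df[["x", "y", "z"]].to_numpy(dtype=float), n_fixed)


# ------------------------------------------------------------------ stages

class _StageLog:
    """Collects per-stage wall-clock timings for the manifest."""

    def __init__(self):
        self.records: list[dict] = []

    def run(self, stage: str, item: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, item, exc) from exc
        dt = time.perf_counter() - t0
        self.records.append({"stage": stage, "item": item,
                             "seconds": round(dt, 4)})
        logger.info("stage %s [%s] done in %.2fs", stage, item, dt)
        return out


def _template_at_density(template: SemilandmarkTemplate,
                         density: int) -> SemilandmarkTemplate:
    if density > template.k:
        raise ValueError(f"density {density} exceeds template semilandmark "
                         f"count {template.k}")
    return SemilandmarkTemplate(template.mesh, template.landmarks,
                                template.semilandmarks[:density])


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full comparison run; returns the artifact directory."""
    out = Path(config.output_dir)
    for sub in ("surfaces", "tables", "maps", "configurations"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    log = _StageLog()

    tmpl_mesh = log.run("load", config.template_mesh,
                        load_mesh, config.template_mesh)
    tmpl_lms = log.run("load", config.template_landmarks,
                       load_landmarks, config.template_landmarks)
    template_full = log.run(
        "load", config.template_semilandmarks,
        load_semilandmark_template_csv, tmpl_mesh, tmpl_lms,
        config.template_semilandmarks)
    specimens = [(sid,
                  log.run("load", sid, load_mesh, mpath),
                  log.run("load", sid, load_landmarks, lpath))
                 for sid, mpath, lpath in
                 load_dataset_manifest(config.dataset_manifest)]

    nicp_params = NICPParams.from_dict(config.nicp) if config.nicp else None
    kmax = max(config.densities)
    surfaces: dict[tuple[str, int, str], EstimatedSurface] = {}
    iteration_log: list[dict] = []

    for density in config.densities:
        template = _template_at_density(template_full, density)
        tmpl_cfg = Configuration(template.configuration_points(),
                                 len(template.landmarks))
        for method in config.methods:
            configs = []
            for sid, mesh, lms in specimens:
                cfg = log.run("semilandmark", f"{method}/k={density}/{sid}",
                              semilandmark_specimen, template, mesh, lms,
                              method=method, nicp_params=nicp_params,
                              **config.sliding, **config.icp)
                save_configuration_csv(
                    cfg,
                    out / "configurations" / f"{method}_k{density}_{sid}.csv")
                configs.append(cfg)

            sample = log.run("gpa", f"{method}/k={density}", gpa,
                             np.stack([c.points for c in configs]))
            iteration_log.append({"stage": "gpa", "method": method,
                                  "density": density,
                                  "iterations": sample.iterations})

            if len(configs) >= 3:
                pca = shape_pca(sample)
                scores = pd.DataFrame(
                    pca.scores,
                    columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])])
                scores.insert(0, "id", [s[0] for s in specimens])
                scores.insert(1, "ln_centroid_size",
                              np.log(sample.centroid_sizes))
                scores.to_csv(out / "tables" /
                              f"pca_scores_{method}_k{density}.csv",
                              index=False)
                pd.DataFrame({"component": scores.columns[2:],
                              "variance_fraction": pca.variance_fractions}
                             ).to_csv(out / "tables" /
                                      f"pca_variance_{method}_k{density}.csv",
                                      index=False)

            model = None
            if {"allometry-min", "allometry-max"} & set(config.targets):
                model = log.run("allometry", f"{method}/k={density}",
                                fit_allometry, sample)

            for target in config.targets:
                if target == "mean":
                    surf = log.run("mean-surface", f"{method}/k={density}",
                                   estimate_mean_surface, template, configs,
                                   method_label=method)
                elif target in ("allometry-min", "allometry-max"):
                    lncs = model.lncs_min if target.endswith("min") \
                        else model.lncs_max
                    pred = Configuration(predict_shape_at_size(model, lncs),
                                         tmpl_cfg.n_fixed)
                    surf = log.run(
                        "allometry-surface", f"{target}/{method}/k={density}",
                        warp_surface_to_configuration, template.mesh,
                        tmpl_cfg, pred, method=method, density=density,
                        target=target)
                else:  # landmark-only baseline: density/method independent
                    if ("landmark_only", 0, "mean") in surfaces:
                        continue
                    mean_lms = gpa(np.stack(
                        [lms.points for _, _, lms in specimens])).mean_shape
                    surf = log.run("landmark-only", "baseline",
                                   landmark_only_surface, tmpl_mesh, tmpl_lms,
                                   mean_lms)
                    surfaces[("landmark_only", 0, "mean")] = surf
                    save_mesh(surf.mesh,
                              out / "surfaces" / "landmark_only_mean.ply")
                    continue
                surfaces[(method, density, target)] = surf
                save_mesh(surf.mesh, out / "surfaces" /
                          f"{target}_{method}_k{density}.ply")

    # re-semilandmark + re-warp for comparability
    if config.rewarp:
        rewarp_template = _template_at_density(template_full, kmax)
        comparable = {}
        for key, surf in surfaces.items():
            method, density, target = key
            comparable[key] = log.run(
                "rewarp", f"{target}/{method}/k={density}",
                resemilandmark_and_rewarp, rewarp_template, surf)
            save_mesh(comparable[key].mesh, out / "surfaces" /
                      f"rewarped_{target}_{method}_k{density}.ply")
    else:
        comparable = surfaces

    _write_tables(config, comparable, out, kmax)
    _write_maps(config, comparable, out, kmax)

    manifest = {
        "config": config.to_dict(),
        "package_version": __version__,
        "library_versions": {"numpy": np.__version__,
                             "pandas": pd.__version__},
        "seed": config.seed,
        "specimen_ids": [s[0] for s in specimens],
        "stages": log.records,
        "iteration_log": iteration_log,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return out


def _write_tables(config: RunConfig, surfaces: dict, out: Path,
                  kmax: int) -> None:
    methods = list(config.methods)
    # between-method distances: rows = method pairs, columns = densities
    if len(methods) >= 2 and "mean" in config.targets:
        rows = []
        for i, a in enumerate(methods):
            for b in methods[i + 1:]:
                row = {"pair": f"{a}-{b}"}
                for d in config.densities:
                    row[f"k{d}"] = vertex_procrustes_distance(
                        surfaces[(a, d, "mean")], surfaces[(b, d, "mean")])
                rows.append(row)
        pd.DataFrame(rows).to_csv(out / "tables" / "between_methods.csv",
                                  index=False)
    # per-method density convergence vs the maximum density
    if len(config.densities) >= 2:
        for target in config.targets:
            if target == "landmark-only":
                continue
            rows = [{"method": m, "density": d, "max_density": kmax,
                     "vertex_procrustes_to_max_density":
                         vertex_procrustes_distance(
                             surfaces[(m, d, target)],
                             surfaces[(m, kmax, target)])}
                    for m in methods for d in config.densities[:-1]]
            pd.DataFrame(rows).to_csv(
                out / "tables" / f"density_convergence_{target}.csv",
                index=False)
    # landmark-only baseline distances
    if ("landmark_only", 0, "mean") in surfaces and "mean" in config.targets:
        base = surfaces[("landmark_only", 0, "mean")]
        rows = [{"method": m, "density": d,
                 "vertex_procrustes_to_landmark_only":
                     vertex_procrustes_distance(surfaces[(m, d, "mean")],
                                                base)}
                for m in methods for d in config.densities]
        pd.DataFrame(rows).to_csv(out / "tables" /
                                  "landmark_only_baseline.csv", index=False)


def _write_maps(config: RunConfig, surfaces: dict, out: Path,
                kmax: int) -> None:
    """Area-difference maps at max density: first method as reference."""
    if "mean" not in config.targets or len(config.methods) < 2:
        return
    ref_method = config.methods[0]
    keys = [(m, kmax, "mean") for m in config.methods]
    scaled = dict(zip(keys, scale_to_common_size([surfaces[k] for k in keys])))
    ref = scaled[(ref_method, kmax, "mean")]
    for m in config.methods[1:]:
        fmap = area_difference_map(ref, scaled[(m, kmax, "mean")])
        stem = f"area_diff_mean_{ref_method}_vs_{m}_k{kmax}"
        save_face_map_csv(fmap, out / "maps" / f"{stem}.csv")
        save_face_map_ply(fmap, ref.mesh, out / "maps" / f"{stem}.ply")
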