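"""Standard simulation studies shared by the test-suite, the acceptance
script and the example scripts.

Two named population regimes mirror the two kinds of sample the methods
are used on in practice:

* **heads-like** — a single-species sample: modest size range, weak
  allometry, individual non-rigid shape variation of similar magnitude.
  Used for mean-surface estimation studies, where the quantity of
  interest is the Procrustes mean.
* **apes-like** — an interspecific sample with a wide size range and a
  dominant common allometric trend (small specimens differ from large
  ones mostly through size-correlated shape change). Used for
  allometry-recovery and size-prediction studies: a strong, well-spread
  size signal is what makes the regression slope identifiable above
  measurement noise.

Both regimes share the measurement-noise level (vertex noise with
standard deviation 1% of the RMS radius) and the stated population
parameters are fixed a priori from a signal-to-noise analysis, not per
run: with n specimens, per-specimen residual shape scatter ρ and
allometric shape scatter S = ‖V‖·sd(lnCS), the expected angle between
the fitted and true slope fields is ≈ atan(ρ / (S·√n)) while the
sampling error of the Procrustes mean grows ∝ S/√n — so mean
estimation favours weak allometry and slope estimation favours strong
allometry, and the two study designs differ accordingly.
"""

from __future__ import annotations

import dataclasses
import functools

import numpy as np
import pandas as pd

from .mesh import SemilandmarkTemplate
from .semilandmark import Configuration, METHODS, semilandmark_specimen
from .shape_stats import fit_allometry, gpa, predict_shape_at_size
from .surface_compare import (EstimatedSurface, estimate_mean_surface,
                              resemilandmark_and_rewarp,
                              vertex_procrustes_distance,
                              warp_surface_to_configuration)
from .synthetic import (PopulationSpec, SyntheticPopulation,
                        evaluate_against_truth, make_base_template,
                        simulate_population)

__all__ = ["heads_population_spec", "apes_population_spec",
           "nonrigid_population_spec", "standard_template",
           "semilandmark_population", "mean_surface_recovery",
           "allometry_recovery", "method_comparison",
           "density_convergence", "size_prediction_spread"]


def heads_population_spec(seed: int, **overrides) -> PopulationSpec:
    """Single-species regime (see module docstring)."""
    kwargs = dict(base_kind="ellipsoid-head", subdivisions=3,
                  n_landmarks=16, k_semilandmarks=100, n_specimens=50,
                  deformation_scale=0.015, allometry_scale=0.05,
                  lncs_halfwidth=0.15, vertex_noise_sd=0.01, seed=seed)
    kwargs.update(overrides)
    return PopulationSpec(**kwargs)


def apes_population_spec(seed: int, **overrides) -> PopulationSpec:
    """Interspecific strong-allometry regime (see module docstring)."""
    kwargs = dict(base_kind="crested-cranium", subdivisions=3,
                  n_landmarks=16, k_semilandmarks=100, n_specimens=50,
                  deformation_scale=0.01, allometry_scale=0.25,
                  lncs_halfwidth=0.5, vertex_noise_sd=0.01, seed=seed)
    kwargs.update(overrides)
    return PopulationSpec(**kwargs)


def nonrigid_population_spec(seed: int, **overrides) -> PopulationSpec:
    """Deformation-dominated regime on a small mesh, for method-contrast
    studies where the non-rigid component is what separates methods."""
    kwargs = dict(base_kind="ellipsoid-head", subdivisions=2,
                  n_landmarks=16, k_semilandmarks=60, n_specimens=12,
                  deformation_scale=0.03, allometry_scale=0.0,
                  lncs_halfwidth=0.1, vertex_noise_sd=0.005, seed=seed)
    kwargs.update(overrides)
    return PopulationSpec(**kwargs)


@functools.lru_cache(maxsize=8)
def standard_template(kind: str = "ellipsoid-head", subdivisions: int = 3,
                      n_landmarks: int = 16, k_semilandmarks: int = 100,
                      seed: int = 0) -> SemilandmarkTemplate:
    """Cached deterministic template (template construction is the
    shared, seed-independent part of every study)."""
    return make_base_template(kind, subdivisions, n_landmarks,
                              k_semilandmarks, seed)


def _template_for(spec: PopulationSpec) -> SemilandmarkTemplate:
    return standard_template(spec.base_kind, spec.subdivisions,
                             spec.n_landmarks, spec.k_semilandmarks)


def semilandmark_population(template: SemilandmarkTemplate,
                            population: SyntheticPopulation,
                            method: str,
                            **method_kwargs) -> list[Configuration]:
    """Apply one semilandmarking method to every specimen."""
    return [semilandmark_specimen(template, mesh, lms, method=method,
                                  **method_kwargs)
            for mesh, lms in population.specimens]


# ------------------------------------------------------- recovery studies

def mean_surface_recovery(seed: int, method: str = "sliding_tps",
                          spec: PopulationSpec | None = None) -> dict:
    """Estimate the mean surface of a heads-like population and measure
    its vertex Procrustes distance to the known true mean."""
    spec = spec if spec is not None else heads_population_spec(seed)
    template = _template_for(spec)
    pop = simulate_population(template, spec)
    configs = semilandmark_population(template, pop, method)
    surface = estimate_mean_surface(template, configs, method_label=method)
    report = evaluate_against_truth(pop, surface)
    report.update(seed=seed, method=method, n=pop.n)
    return report


def allometry_recovery(seed: int,
                       spec: PopulationSpec | None = None) -> dict:
    """Fit the allometric regression to an apes-like population's noisy
    configurations and measure the angle between the recovered and true
    slope fields.

    The fit uses the ground-truth correspondences plus measurement noise:
    this isolates the statistical recovery of the allometric field from
    semilandmark-placement differences, which are themselves
    size-correlated and are studied separately (see
    :func:`size_prediction_spread`).
    """
    spec = spec if spec is not None else apes_population_spec(seed)
    template = _template_for(spec)
    pop = simulate_population(template, spec)
    sample = gpa(pop.noisy_configs)
    model = fit_allometry(sample)
    report = evaluate_against_truth(pop, model)
    report.update(seed=seed, n=pop.n)
    return report


# ------------------------------------------------------ method comparison

def method_comparison(seed: int, spec: PopulationSpec | None = None,
                      rewarp: bool = True) -> dict:
    """Mean surfaces from all three methods on one non-rigid population,
    with pairwise vertex Procrustes distances before and (optionally)
    after the re-semilandmarking + re-warping protocol.

    Returns ``{"raw": {pair: d}, "rewarped": {pair: d}, "surfaces": ...}``
    where pairs are tuples of method names.
    """
    spec = spec if spec is not None else nonrigid_population_spec(seed)
    template = _template_for(spec)
    pop = simulate_population(template, spec)
    surfaces: dict[str, EstimatedSurface] = {}
    for method in METHODS:
        configs = semilandmark_population(template, pop, method)
        surfaces[method] = estimate_mean_surface(template, configs,
                                                 method_label=method)

    def pairwise(surfs: dict[str, EstimatedSurface]) -> dict:
        names = list(surfs)
        return {(a, b): vertex_procrustes_distance(surfs[a], surfs[b])
                for i, a in enumerate(names) for b in names[i + 1:]}

    out = {"raw": pairwise(surfaces), "surfaces": surfaces, "seed": seed}
    if rewarp:
        rewarped = {m: resemilandmark_and_rewarp(template, s)
                    for m, s in surfaces.items()}
        out["rewarped"] = pairwise(rewarped)
        out["rewarped_surfaces"] = rewarped
    return out


# ----------------------------------------------------- density convergence

def density_convergence(seed: int, densities=(5, 8, 14, 24, 42, 72, 100),
                        method: str = "sliding_tps",
                        spec: PopulationSpec | None = None) -> pd.DataFrame:
    """Mean-surface estimates at several semilandmark densities, each
    re-warped through the maximum-density template, with vertex
    Procrustes distance to the maximum-density estimate.

    Re-warping makes the vertex sets comparable: without it, differences
    in where each density's warp places mesh vertices would be
    confounded with differences in estimated surface shape.
    """
    densities = sorted(set(int(d) for d in densities))
    if len(densities) < 2:
        raise ValueError("need at least two densities")
    kmax = densities[-1]
    base = spec if spec is not None else heads_population_spec(
        seed, n_specimens=25)
    base = dataclasses.replace(base, k_semilandmarks=kmax)
    rewarp_template = standard_template(base.base_kind, base.subdivisions,
                                        base.n_landmarks, kmax)
    # one population; only the semilandmark template varies with density,
    # so differences between estimates are attributable to density alone
    pop = simulate_population(rewarp_template, base)
    surfaces = {}
    for k in densities:
        template = standard_template(base.base_kind, base.subdivisions,
                                     base.n_landmarks, k)
        configs = semilandmark_population(template, pop, method)
        raw = estimate_mean_surface(template, configs, method_label=method)
        surfaces[k] = resemilandmark_and_rewarp(rewarp_template, raw)
    rows = [{"density": k, "max_density": kmax,
             "vertex_procrustes_to_max_density":
                 vertex_procrustes_distance(surfaces[k], surfaces[kmax])}
            for k in densities[:-1]]
    return pd.DataFrame(rows)


# ------------------------------------------------- size-prediction spread

def size_prediction_spread(seed: int, spec: PopulationSpec | None = None,
                           variants=(("sliding_tps", 100),
                                     ("sliding_tps", 30),
                                     ("ls_icp", 100),
                                     ("tps_nicp", 100))) -> dict:
    """Allometric shape predictions at the extremes of a right-skewed
    size distribution, across method/density variants.

    Each variant semilandmarks the population, fits the allometric
    regression, predicts shape at the common smallest and largest lnCS,
    warps the template to each prediction and re-warps for comparability.
    Returns the pairwise vertex Procrustes distances among variants at
    the minimum and at the maximum size.
    """
    spec = spec if spec is not None else apes_population_spec(
        seed, base_kind="ellipsoid-head", subdivisions=2, n_specimens=20,
        lncs_distribution="skewed")
    if spec.lncs_distribution != "skewed":
        raise ValueError("size-prediction spread is a skewed-size study")
    kmax = max(k for _, k in variants)
    spec = dataclasses.replace(spec, k_semilandmarks=kmax)
    rewarp_template = standard_template(spec.base_kind, spec.subdivisions,
                                        spec.n_landmarks, kmax)
    # one population shared by all variants; only the semilandmark
    # template differs, so prediction spread reflects method/density alone
    pop = simulate_population(rewarp_template, spec)

    # common prediction sizes from the ground-truth size draws
    u = pop.lncs_offsets
    surfaces = {"min": {}, "max": {}}
    for method, k in variants:
        template = standard_template(spec.base_kind, spec.subdivisions,
                                     spec.n_landmarks, k)
        configs = semilandmark_population(template, pop, method)
        sample = gpa(np.stack([c.points for c in configs]))
        model = fit_allometry(sample)
        tmpl_cfg = Configuration(template.configuration_points(),
                                 len(template.landmarks))
        for tag, lncs in (("min", model.lncs_mean + (u.min() - u.mean())),
                          ("max", model.lncs_mean + (u.max() - u.mean()))):
            pred = Configuration(predict_shape_at_size(model, lncs),
                                 tmpl_cfg.n_fixed)
            surf = warp_surface_to_configuration(
                template.mesh, tmpl_cfg, pred, method=method, density=k,
                target=f"allometry-{tag}")
            surfaces[tag][(method, k)] = resemilandmark_and_rewarp(
                rewarp_template, surf)

    def pairwise(surfs: dict) -> dict:
        names = list(surfs)
        return {(a, b): vertex_procrustes_distance(surfs[a], surfs[b])
                for i, a in enumerate(names) for b in names[i + 1:]}

    d_min = pairwise(surfaces["min"])
    d_max = pairwise(surfaces["max"])
    return {"min_size_distances": d_min, "max_size_distances": d_max,
            "mean_min": float(np.mean(list(d_min.values()))),
            "mean_max": float(np.mean(list(d_max.values()))),
            "seed": seed}
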