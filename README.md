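# morphosurf

Landmark-driven semilandmarking and surface-shape comparison for 3D
geometric morphometrics.

Dense-correspondence methods extend landmark-based morphometrics to
whole surfaces: a template mesh carrying a few fixed anatomical
landmarks plus many evenly spread semilandmarks is mapped onto every
specimen in a sample, and the resulting homologous configurations feed
standard shape statistics. `morphosurf` implements three transfer
methods —

* **sliding TPS** — thin-plate-spline warp to the specimen landmarks,
  surface projection, then iterative sliding that minimises TPS bending
  energy;
* **LS&ICP** — landmark-guided similarity fit plus rigid ICP
  refinement and nearest-point projection;
* **TPS&NICP** — landmark TPS warp plus optimal-step non-rigid ICP with
  per-vertex affines;

— together with generalized Procrustes analysis, shape PCA, allometric
regression, template warping to estimated shapes, a
re-semilandmark/re-warp protocol that makes surfaces from different
methods and densities directly comparable at the vertex level,
per-face area-difference maps, a synthetic-population generator with
known ground truth, and a CLI that runs the whole comparison pipeline
from a YAML config. See [docs/methods.md](docs/methods.md) for the
models and design rationale.

## Worked example

Simulate a single-species population (642-vertex head-like meshes, 16
landmarks, 100 semilandmarks, 1 % measurement noise), semilandmark
every specimen with sliding TPS, estimate the mean surface, and compare
it with the known true mean
([examples/01_simulate_and_estimate_mean.py](examples/01_simulate_and_estimate_mean.py)):

```python
from morphosurf import estimate_mean_surface
from morphosurf.experiments import (heads_population_spec,
                                    semilandmark_population,
                                    standard_template)
from morphosurf.synthetic import evaluate_against_truth, simulate_population

spec = heads_population_spec(seed=1, n_specimens=25)
template = standard_template(spec.base_kind, spec.subdivisions,
                             spec.n_landmarks, spec.k_semilandmarks)
population = simulate_population(template, spec)
configs = semilandmark_population(template, population, "sliding_tps")
surface = estimate_mean_surface(template, configs, method_label="sliding_tps")
report = evaluate_against_truth(population, surface)
```

Output:

```
template: 642 vertices, 16 landmarks, 100 semilandmarks
simulated 25 specimens (lnCS range -0.148 to +0.139)
vertex Procrustes distance to the true mean: 0.00448
```

Comparing all three methods on one deformation-dominated population
([examples/02_compare_methods.py](examples/02_compare_methods.py))
reproduces the two headline orderings: the TPS-based methods agree more
with each other than either does with the ICP-based one, and
re-semilandmarking + re-warping shrinks every between-method distance:

```
pairwise vertex Procrustes distances between method means
pair                                    raw   rewarped
sliding_tps vs ls_icp               0.01265    0.00323
sliding_tps vs tps_nicp             0.00170    0.00026
ls_icp vs tps_nicp                  0.01187    0.00308
```

[examples/03_density_and_allometry.py](examples/03_density_and_allometry.py)
shows mean-surface estimates converging with semilandmark density
(distance to the k=100 estimate falls from 0.0029 at k=5 to 0.0010 at
k=72) and, under a right-skewed size distribution, allometric
predictions at the sparsely sampled minimum size disagreeing more
across method/density variants (0.0243) than at the maximum size
(0.0197).

## Command line

```bash
# simulate a toy dataset with known ground truth
morphosurf simulate -o pop --subdivisions 2 --n-landmarks 12 -k 30 -n 6 --seed 1

# run the full comparison pipeline from a YAML config
morphosurf -v run -c run.yaml

# compare two estimated surfaces
morphosurf compare run/surfaces/mean_sliding_tps_k30.ply \
                   run/surfaces/mean_ls_icp_k30.ply
```

`run.yaml` names the dataset manifest, template files, the
methods × densities × targets grid and an output directory; the run
writes configuration CSVs, PCA tables, estimated and re-warped
surfaces (PLY), between-method and density-convergence tables,
area-difference maps, and a manifest with versions, seeds and
per-stage timings. See
[examples/04_cli_pipeline.sh](examples/04_cli_pipeline.sh) for an
end-to-end script, and `morphosurf --help` for the remaining
subcommands (`sample-template`, `semilandmark`, `mean-surface`,
`allometry`, `rewarp`).

## Reproduction

The test suite (unit tests plus one acceptance test per release
criterion, `tests/test_acceptance.py`) runs with:

```bash
pytest -o addopts= -q tests/
```

The headline quantities — TPS exactness, independent-oracle agreement,
registration recovery, pipeline fixed points, ground-truth recovery and
the comparison-study statistics — can be recomputed into a JSON report
with:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness derives from the single `--seed`; identical invocations
reproduce identical numbers.

## Repository layout

```
src/morphosurf/      library (mesh IO, TPS, registration, semilandmarking,
                     shape statistics, surface comparison, synthetic data,
                     experiments, pipeline, CLI)
tests/               pytest suite; test_acceptance.py holds the
                     per-criterion acceptance tests
scripts/acceptance.py  JSON report of the headline quantities
examples/            narrative scripts mirroring the studies above
docs/methods.md      models, parameters, generator design, limitations
```
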