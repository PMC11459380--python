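# trajdir

**Does a pseudotime trajectory proceed in a well-defined direction?**

`trajdir` is a Python toolkit for analysing the geometry of
differentiation trajectories in single-cell (or bulk) expression data.
Given a cell × feature matrix (principal components or log-normalized
genes) and a per-cell pseudotime, it quantifies whether a trajectory
travels in a consistent direction through expression space, tests that
directionality against randomized-path nulls, scans sub-trajectories to
distinguish *branching* from *bifurcating* cell-fate decisions, and
decomposes the fitted direction into per-gene scores.

The motivating biology: it is often assumed that a bipotential
progenitor runs to a decision point where its trajectory *bifurcates*,
both outcomes setting off in new directions.  An alternative is
*branching*: one fate lies straight ahead on a default trajectory, and
only cells that leave it toward the other fate ever make a "decision".
The two models leave different geometric fingerprints, and this package
measures them.

## The statistic

A direction in N dimensions is a point on the sphere S^(N−1).  For a
path p_0, …, p_m sampled along a trajectory, project each later point to
the unit vector (p_j − p_0)/‖p_j − p_0‖ and find the unit vector ĉ
minimizing

    radius = statistic over j of  arccos ⟨ĉ, (p_j − p_0)/‖p_j − p_0‖⟩

with the statistic either the mean (spherical geometric median, the
default) or the max (minimal enclosing spherical cap).  A small radius
means the path kept travelling one way.  Significance comes from a rank
test against randomized paths (column permutations, or random-direction
walks with the original step lengths):
P = (1 + #{null radius ≤ observed}) / (n_null + 1).

For an ensemble of cells, many paths are sampled (one random cell per
pseudotime window), each is tested, and the median per-path P-value is
the trajectory's aggregate.  Scanning successively later pseudotime
start points reveals branching: a default arm stays maximally
significant throughout, while a branch arm's radius falls — and its
significance rises — as the start approaches the departure point.  A
symmetric bifurcation shows neither signature.

## A worked example

```python
import numpy as np
from trajdir import (RandomizationSpec, make_straight_path,
                     path_to_spherical_data, test_path_for_directionality)

path = make_straight_path(12, 3, direction=[1.0, 1.0, 0.5], step=1.0,
                          noise_sd=0.15, seed=0)

sd = path_to_spherical_data(path, statistic="mean")
print(f"mean spherical radius: {sd.radius:.4f} rad "
      f"({np.degrees(sd.radius):.2f} deg)")
print(f"direction (center on the sphere): {np.round(sd.center, 3)}")

test = test_path_for_directionality(
    path, statistic="mean", spec=RandomizationSpec("bySteps", seed=1),
    n_null=999)
print(f"null radii (median): {np.median(test.null_radii):.4f} rad")
print(f"directionality P-value: {test.p_value:.4g}")
```

prints

```
mean spherical radius: 0.0332 rad (1.90 deg)
direction (center on the sphere): [0.665 0.677 0.316]
null radii (median): 0.4947 rad
directionality P-value: 0.001
```

The 12-point noisy straight path clusters within ~2° of its fitted
direction (which recovers the generating direction [1, 1, 0.5]
normalized ≈ [0.67, 0.67, 0.33]), while random paths with the same step
lengths scatter to a median radius of ~28°; the observed radius beats
all 999 nulls, so the P-value is at its floor 1/1000.

More narrative scripts live in `examples/`: single-path testing,
branching-versus-bifurcation recovery on synthetic ensembles, gene
scoring, and the full shell pipeline.

## Command line

Every step is also a `trajdir` subcommand operating on delimited text or
Matrix Market files:

```sh
trajdir simulate --model branching --seed 1 --out-dir sim
trajdir analyse --attributes sim/attributes.csv \
    --pseudotime sim/pseudotime.csv --method bySteps --out-dir res
trajdir branch-scan --attributes sim/attributes.csv \
    --pseudotime sim/pseudotime.csv --method bySteps --out-dir scan
trajdir gene-scores --results res/results.json --k 10 --out-dir res
trajdir plot --results res/results.json --scan scan/results.json \
    --out-dir plots
```

All parameters can also come from a JSON config file (flags win), every
run records its seed and resolved configuration, and identical runs
produce byte-identical `results.json`.

## Layout

```
src/trajdir/
  geometry.py   sphere projection, spherical centers and radii
  nulls.py      randomized paths and the rank P-value
  analysis.py   path sampling, aggregation, comparison, branch scan
  genes.py      loading-matrix gene scores and ranked lists
  simulate.py   synthetic branching / bifurcation / null ensembles
  io.py         delimited + Matrix Market readers, JSON/TSV writers
  plotting.py   sphere, violin and scan diagnostics
  cli.py        the `trajdir` command
docs/methods.md full description of the model and design choices
```
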