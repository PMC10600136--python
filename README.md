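# hbnet

Transition-network analysis of multivariate hemoglobin time series.

Per-voxel oxy- and deoxy-hemoglobin deviation time series are mapped into a
ten-state Markov chain defined by the joint algebraic signs of five signal
components (deoxy, oxygen exchange, oxy, oxygen saturation, total). From the
resulting synchronous transition-type matrix (100 types, self-transitions
included) the package computes 18 classes of adjacency-matrix coefficients —
transition probabilities, pre/post dwell times, and per-component pre/post
means and fluxes — under three averaging schemes (grand average, temporal
mean of spatial mean, spatial mean of temporal mean). On top of these it
provides the higher-order co-dependence analyses: pairwise coefficient
correlations, general conic-section fitting with hyperbola geometry
(vertices/foci), transition-Class trends, sign-reversal contingency tables,
contralateral t'-normalization and flux-vector amplitudes, double-reciprocal
(Lineweaver–Burk) regressions with slope/intercept comparison tests, and
biomarker-group comparisons. A synthetic-data module supplies seeded
generators, Markov parameter-recovery fixtures, a geometric
distance-kernel null model, and time-shuffle / phase-randomization
surrogates, so the whole pipeline is testable offline.

## Library quick start

```python
import numpy as np
from hbnet import (build_geometry, compute_dependent_components,
                   adjacency_suite, lineweaver_burk, LBSubset)

geometry = build_geometry(s0=0.7, total0=1e-4)
series = compute_dependent_components(oxy, deoxy)      # (frames x voxels)
suite = adjacency_suite(series, geometry)              # 18 x 100 coefficients
fit = lineweaver_burk(suite.P, suite["flux_total"],
                      subset=LBSubset(classes=(3, 4, 5)))
```

## Command line

The `hbnet` entry point exposes `simulate`, `states`, `adjacency`, `codep`,
`lbfit` and `report`:

```sh
hbnet simulate --n-frames 700 --n-voxels 500 --seed 1 --out sim/
hbnet states --oxy sim/affected_oxy.tsv --deoxy sim/affected_deoxy.tsv --out S.tsv
hbnet adjacency --oxy sim/affected_oxy.tsv --deoxy sim/affected_deoxy.tsv \
      --avg ga --out suite.tsv
hbnet lbfit --suite suite.tsv --y flux_total --classes 3,4,5 --out lb.csv
hbnet codep --suite suite.tsv --out codep/
hbnet report --config run.yaml       # full manifest-driven pipeline
```

`report` consumes a YAML `RunConfig` with a subject manifest (`subject`,
`breast` in {T, U, L, R}, `oxy_path`, `deoxy_path`); a tumor (T) breast
requires its contralateral unaffected (U) pair. Outputs are long-format
adjacency TSVs plus correlation, conic-fit, L-B and report CSVs, and a run
log carrying the config hash and seed.

## Conventions

- State 1 is the sector just above the positive total-Hb axis; labels
  increase counterclockwise (`StateGeometry.relabel` applies cyclic shifts).
- Exact zero deviations are treated as positive; an all-zero sample is
  assigned State 1.
- Saturation requires absolute baselines; the defaults (`s0=0.7`,
  `total0=1e-4` M) are a documented convention, configurable everywhere.
- Transition types that never occur are reported as missing (NaN), never 0.

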