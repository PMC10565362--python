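# gravident

Identification of hyperelastic (one-term compressible Ogden) material
parameters of a soft organ from a full-field displacement measurement under
gravitational body loading, using a nonlinear virtual fields method: the
virtual-power equilibrium gap between the internal power of the stresses
computed from the measured deformation and the external power of the known
body force is minimized over the material parameters (mu, alpha, K).

No forward model updating is required — evaluating one candidate parameter
set is a handful of vectorized array operations over the mesh, so multi-start
optimization and landscape sweeps of thousands of parameter sets run in
seconds.

## What is in the box

| module | contents |
| --- | --- |
| `gravident.mesh` | tet4 meshes, per-element large-deformation kinematics, readers for Gmsh `.msh` (v2/v4 ASCII), legacy VTK, a minimal FEBio `.feb` dialect, displacement CSV/VTK/MAT |
| `gravident.ogden` | one-term compressible Ogden energy and Cauchy stress (volumetric part `K ln(J)/J I`), small-strain moduli conversions |
| `gravident.power` | virtual velocity gradients in the measured current frame, rate of deformation, one-point-quadrature internal/external virtual power, per-field and total equilibrium-gap errors, self-consistency check |
| `gravident.vfields` | generation of the three parameter-targeted virtual fields by fixed-boundary small-body-load solves with parameter perturbation and base-field subtraction (small-strain FE solver for mu/K, weakly nonlinear solves for alpha) |
| `gravident.identify` | cached `DataBundle` evaluation, bounded least-squares and Nelder–Mead optimizers in (log mu, alpha, log K), Latin-hypercube multi-start, random landscape sweep, error classification, stress statistics |
| `gravident.synthetic` | total-Lagrangian Newton forward solver (body force, fixed boundary, load stepping), cube and thick-shell-ellipsoid fixtures, homogeneous-deformation fixtures, iid-Gaussian and smooth registration-like noise |
| `gravident.cli` | `gravident` command-line tool and YAML run configuration |

Units are SI throughout (m, Pa, kg m^-3); file readers convert
millimetre-based imaging formats at the boundary.

## Command line

All commands read a declarative YAML config; flags override file values.
`body_force` and `density` are required in every config — both scale the
identified moduli linearly, so neither has a default.

```yaml
# config.yaml
body_force: [0.0, 0.0, -9.81]   # m s^-2
density: 1040.0                 # kg m^-3
fixture: {name: cube, n: 6}     # or mesh: path/to/mesh.msh
params_true: {mu: 1250.0, alpha: -20.0, K: 254000.0}
n_starts: 8
optimizer: both                 # leastsq | simplex | both
seed: 0
output_dir: out
```

```sh
gravident identify -c config.yaml      # multi-start identification -> JSON
gravident sweep -c config.yaml --n 2800  # random landscape sweep -> CSV
gravident genvf -c config.yaml         # write the three virtual fields
gravident forward -c config.yaml       # nonlinear forward solve
gravident make-fixture -c config.yaml  # ground-truth fixture + JSON sidecar
gravident noise-test -c config.yaml    # per-field error vs noise level
gravident self-check -c config.yaml    # solution-as-its-own-virtual-field gap
```

Runs are deterministic given config + seed; every JSON output carries a
provenance block (config hash, seed, library versions, resolved defaults).
Exit codes: 0 ok, 2 config error, 3 numerical failure.

## Library quick start

```python
import numpy as np
from gravident import (OgdenParams, make_recovery_bundle, multistart)

truth = OgdenParams(mu=1250.0, alpha=-20.0, K=254000.0)
bundle, _, _ = make_recovery_bundle("cube", truth)   # forward solve + 3 fields
results = multistart(bundle, 8, seed=0, optimizer="leastsq")
best = min(results, key=lambda r: r.total_err)
print(best.params, best.total_err)
```

## Known red test

`tests/test_acceptance.py::TestCriterion2Recovery::test_alpha_flatness_below_1e4`
fails by design of the check, not by accident: on exactly equilibrated
synthetic data the alpha-targeted virtual field (a difference of weakly
nonlinear solves) supplies an independent third equation, so the total error
genuinely varies with alpha at fixed (mu, K). See the test docstring.
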