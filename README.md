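# rdtraffic

Spatial modeling of receptor–ligand trafficking regulated by cell density.

Cell-surface receptors bind extracellular ligand, internalize, recycle and
degrade. How strongly a cell responds to a dose of ligand depends not only
on these kinetics but on how much extracellular volume each cell owns —
i.e. on cell density — and on the concentration gradients that diffusion
builds up between the bulk medium, the cell surface and the cell interior.
`rdtraffic` is a library (plus a thin CLI) for simulating this process two
ways and comparing them:

* **Spatial model** — a spherically symmetric reaction–diffusion system on
  three concentric domains: extracellular medium (free ligand L, radii
  R2→R3), a thin cell-surface shell (shell ligand LS, free receptor RS,
  complex LRS, R1→R2) and the cell interior (internalized receptor RI and
  complex LRI, 0→R1). Binding follows mass action in the shell;
  internalization, recycling and receptor synthesis are *boundary fluxes*
  across the R1 interface with mass-transfer coefficients (µm/s), not
  first-order rates; L and LS are coupled at R2 by concentration and flux
  continuity; zero flux holds at r = 0 and at the outer radius R3
  (insulation). One cell owns the whole sphere of radius R3, so
  density = 10¹²·3/(4π R3³) cells/ml.
* **Well-mixed comparator** — the six-species ODE model that non-spatial
  treatments use, with all receptor species referenced to a single volume
  and the extracellular volume per cell entering only the ligand equation.

The discretization is a conservative cell-centered finite-volume scheme in
the radial coordinate (method of lines), integrated with a stiff implicit
stepper (`scipy.integrate.solve_ivp`, BDF, sparse Jacobian pattern). Every
run carries an exact mass-balance ledger (synthesis, degradation, injected
ligand), conserved to integrator accuracy.

On top of `simulate`/`simulate_wellmixed` the `analysis` module provides
the derived responses: radial profiles and probed time courses, integrated
(area-under-curve) dose–response, cell-density sweeps, the endocytic
downregulation ratio R = k_int_bound/k_int_free, lag/peak timing metrics,
and ligand-profile-inversion detection.

## Worked example

```python
import numpy as np
import rdtraffic as rdt
from rdtraffic import analysis

geometry = rdt.Geometry(r_outer=30.0)          # ~8.8e6 cells/ml
result = rdt.simulate(
    rdt.KineticParameters(), rdt.DiffusionCoefficients(), geometry,
    rdt.InitialConditions(), rdt.LigandInputProgram.bolus(100.0),
    t_eval=np.linspace(0.0, 3600.0, 241), resolution=(16, 4, 40))

for label, r in (("center", 0.0), ("membrane", geometry.r_cell - 0.05)):
    t, lri = analysis.timecourse_at_radius(result, "LRI", r)
    m = analysis.response_timing_metrics(t, lri)
    print(label, m.lag_time)
```

prints (see `examples/bolus_simulation.py`):

```
cell density: 8.84e+06 cells/ml
LRI at center  : lag   105 s, value at 1 h  307.5 nM
LRI at membrane: lag    60 s, value at 1 h  307.9 nM
mass-balance max relative residual: 8.31e-12
```

The internalized-complex response at the cell center lags the response at
the membrane by ~45 s: the lag is created by intracellular concentration
gradients (spatial control), which a well-mixed model cannot produce.

Each script in `examples/` demonstrates one capability: the
26.3/476.3/1100 nM volume-accounting contrast
(`mass_balance_accounting.py`), dose–response shifts with density
(`dose_response.py`), density sweeps (`density_sweep.py`), pulse-train
inputs (`pulse_train.py`), downregulation and recycling knockouts
(`downregulation_and_recycling.py`), and the fast-diffusion collapse onto
the well-mixed model (`compare_wellmixed.py`).

A thin CLI wraps the same calls for config-file driven runs:

```bash
rdtraffic simulate --config run.yaml --out out/        # CSV + HDF5
rdtraffic sweep-dose --config run.yaml --out out/
rdtraffic sweep-density --config run.yaml --out out/
rdtraffic compare-wellmixed --config run.yaml --out out/
```

See `rdtraffic.config` for the YAML schema (all keys unit-suffixed).

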