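"""Species concentrations as a function of cell density.

Sweeps the outer radius of the extracellular volume per cell at a fixed
1 nM bolus: with more extracellular volume (lower density) more ligand is
available per cell, so complexes (LRS, LRI) rise while free surface
receptors (RS) fall.
"""

import numpy as np

import rdtraffic as rdt
from rdtraffic import analysis

grid = np.array([10.0, 15.0, 22.0, 33.0, 50.0, 100.0])
curves = analysis.density_response(
    rdt.KineticParameters(), rdt.DiffusionCoefficients(), rdt.Geometry(),
    rdt.InitialConditions(), grid, dose=1.0, t_probe=3600.0,
    resolution=(10, 4, 24))

print("r_outer_um  density_per_ml   RS_nM    LRS_nM    RI_nM    LRI_nM")
for i, r3 in enumerate(grid):
    dens = rdt.density_from_outer_radius(r3)
    print(f"{r3:9.0f}  {dens:12.3g}  "
          + "  ".join(f"{curves[sp].y[i]:8.2f}"
                      for sp in ("RS", "LRS", "RI", "LRI")))
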