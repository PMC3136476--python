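"""Integrated dose-response curves at two cell densities.

The response is the 10 h area under the LRI concentration-time course at
the cell center (nM·min).  Curves are sigmoid in log-dose and shift toward
higher ligand concentrations as cell density increases (less extracellular
ligand per cell).
"""

import numpy as np

import rdtraffic as rdt
from rdtraffic import analysis

doses = np.array([0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0])
p, d, ic = (rdt.KineticParameters(), rdt.DiffusionCoefficients(),
            rdt.InitialConditions())

for r_outer in (15.0, 100.0):
    g = rdt.Geometry(r_outer=r_outer)
    curve = analysis.dose_response_curve(
        p, d, g, ic, doses, horizon=36000.0, n_snapshots=61,
        resolution=(10, 4, 24))
    print(f"r_outer = {r_outer:5.0f} µm  ({g.density:.2g} cells/ml)")
    for dose, auc in zip(curve.x, curve.y):
        print(f"   dose {dose:6.2f} nM -> AUC {auc:10.1f} nM·min")
    print(f"   half-max dose: {analysis.half_max_x(curve):.2f} nM")
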