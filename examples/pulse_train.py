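"""Response to step changes in the ligand input rate.

Two 10 s inputs at 1 nM/s separated by a 40 s recovery phase.  Far from the
cell the ligand follows the input staircase (10 nM, then 20 nM); at the
cell-surface interface the rise is weaker because binding consumes ligand,
and the difference drives inward transport.
"""

import numpy as np

import rdtraffic as rdt
from rdtraffic import analysis

program = rdt.LigandInputProgram.pulse_train(1.0, [(0.0, 10.0), (50.0, 10.0)])
g = rdt.Geometry(r_outer=30.0)
res = rdt.simulate(rdt.KineticParameters(), rdt.DiffusionCoefficients(), g,
                  rdt.InitialConditions(), program,
                  np.linspace(0.0, 100.0, 201), resolution=(12, 4, 30))

t, far = analysis.timecourse_at_radius(res, "L", g.r_outer - 0.5)
_, near = analysis.timecourse_at_radius(res, "L", g.r_shell_outer + 0.05)
_, lrs = analysis.timecourse_at_radius(res, "LRS",
                                       g.r_cell + 0.5 * g.shell_thickness)
print("  t_s   input_nM/s   L_far_nM  L_surface_nM   LRS_nM")
for tt in (5, 10, 30, 50, 55, 60, 100):
    i = int(np.argmin(np.abs(t - tt)))
    print(f"{t[i]:5.0f}   {rdt.input_rate(program, min(t[i], 99.9)):8.1f}"
          f"   {far[i]:9.2f}  {near[i]:11.2f}  {lrs[i]:8.1f}")
print(f"cumulative input at 100 s: {rdt.cumulative_input(program, 100.0):.1f} nM")
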