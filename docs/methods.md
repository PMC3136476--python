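# Methods

## Model

One cell is represented by three concentric spherical domains sharing the
radial coordinate r:

| domain | extent | species | physics |
|---|---|---|---|
| cell interior | 0 ≤ r ≤ R1 | RI, LRI | diffusion; degradation k_deg_free·RI, k_deg_bound·LRI; dephosphorylation k_dephos·LRI → RI (ligand moiety to the degraded-ligand ledger) |
| surface shell | R1 ≤ r ≤ R2 = R1+δ | LS, RS, LRS | diffusion; mass action k_on·LS·RS − k_off·LRS |
| extracellular | R2 ≤ r ≤ R3 | L | diffusion; volumetric source Q_L(t) |

All concentrations are nM referenced to the volume of the domain the
species lives in; lengths are µm, times s. The shell is a thin threedimensional
annular volume (δ = 0.1 µm), not a 2-D surface density: this keeps
all species in the same concentration units and makes the volume-accounting
arguments explicit. With the defaults (R1 = 7.5 µm, δ = 0.1 µm) a shell
concentration of 650 nM equals ≈39 molecules/µm² of membrane and converts
to ≈26.3 nM when re-referenced to the cell volume.

Heterogeneous processes are boundary conditions, not volumetric rates:

* **R1 interface** (area A = 4πR1²). Area-integrated fluxes, with k's in
  µm/s ("mass-transfer coefficients"): RS gains
  A·(q_syn + k_rec_free·RI(R1⁻) − k_int_free·RS(R1⁺)); RI gains the
  internalization term and loses the recycling term; LRS/LRI likewise with
  k_int_bound/k_rec_bound. Receptor synthesis q_syn (nM·µm/s) is a constant
  inward flux feeding RS. Recycled LRI returns intact as LRS (no
  dissociation en route).
* **R2 interface.** L and LS are the same chemical species on either side:
  concentration continuity and diffusive flux continuity (partition
  coefficient 1), implemented as a series-conductance two-point flux.
* **r = 0** regularity and **R3** insulation: zero flux; RS/LRS see zero
  flux at R2 and LS at R1.

Cell density enters only through R3: density = 10¹²·3/(4πR3³) cells/ml
referenced to the *total* sphere volume. The package converts both ways
(`density_from_outer_radius`, `outer_radius_from_density`).

Ligand inputs Q_L(t) are piecewise-constant programs: a bolus (initial
condition, Q_L ≡ 0), a constant rate, or a train of disjoint rectangular
pulses; the source is volumetrically uniform over the extracellular domain.
An outer-boundary influx variant is deliberately not implemented.

## Well-mixed comparator

The non-spatial model keeps the same mechanistic hypotheses but references
all receptor species to a single volume, as non-spatial trafficking models
do; the extracellular volume per cell enters only the ligand equation
through the ratio V_shell/V_ext (extracellular, not total, volume — the
difference is O(V_shell/V_ext)):

    dL/dt   = Q_L − ρ (k_on L·RS − k_off·LRS),   ρ = V_shell/V_ext
    dRS/dt  = −(k_on L·RS − k_off·LRS) + k_syn + k_rec_free·RI − k_int_free·RS
    dLRS/dt = +(k_on L·RS − k_off·LRS) + k_rec_bound·LRI − k_int_bound·LRS
    dRI/dt  = k_int_free·RS − (k_rec_free + k_deg_free)·RI + k_dephos·LRI
    dLRI/dt = k_int_bound·LRS − (k_rec_bound + k_deg_bound + k_dephos)·LRI

`spatial_to_wellmixed_params` converts each mass-transfer coefficient k
(µm/s) to the first-order constant k·A/V of the compartment the species
leaves — shell for internalization (A/V_shell ≈ 1/δ for thin shells), cell
for recycling — and the synthesis flux to a rate over the shell volume.

Two distinct uses, deliberately kept apart:

1. **Taken at face value** (the non-spatial literature's reading): the
   printed initial concentrations 650/450 nM are used unchanged. Then with
   saturating ligand and recycling/degradation off the maximum internalized
   pool is 650 + 450 = 1100 nM, against 26.3 + 450 = 476.3 nM in the
   spatial model — the same inputs yield different mass balances because
   the domain volumes differ.
2. **As the exact fast-diffusion limit**: re-referencing the intracellular
   initial conditions by V_cell/V_shell (`wellmixed_initial_from_spatial`)
   makes the ODE system the exact singular limit of the spatial model.
   Multiplying all diffusion coefficients by 10³ brings the volume-averaged
   spatial trajectories within ≈0.06 % (sup-norm) of the ODE solution; the
   package's tests assert 2 %.

## Numerics

Cell-centered conservative finite volumes per domain; the volume of each
control volume is exactly (4/3)π(r_out³ − r_in³), so volumes sum to the
total sphere volume to round-off. Interior faces use two-point fluxes
D·4πr_f²·Δc/Δr between adjacent centers; interface reaction fluxes enter
the first control volume on each side (species identity changes across R1,
so there are no ghost nodes). The extracellular grid is geometrically
graded so the first spacing off R2 never exceeds δ (ligand gradients are
steepest there); default resolution (40, 8, 120) control volumes, though
most analyses converge at a third of that — sweep results change by <1 %
under 2× refinement, which is itself a test. Tests and the acceptance
script use (12–16, 4, 24–40), chosen as the coarsest meshes whose results
are refinement-invariant at the tolerances asserted.

Time integration: stiff BDF with adaptive steps, rtol 1e-6, atol 1e-9 nM,
and a structural sparse Jacobian (finite-difference coloring). The
integrator is stopped and restarted at every pulse edge, with the source
rate frozen per segment, so discontinuities are never smeared. Cumulative
ledgers (synthesized/degraded receptor, injected/degraded ligand, nM·µm³)
are integrated as extra state variables; total ligand and total receptor
corrected by the ledgers are *linear invariants* of the semi-discrete
system, so conservation holds to Newton/roundoff accuracy (observed
≈1e-8 relative over 10 h) independent of step size. Concentrations may
undershoot zero by O(atol); the tests bound the excursion at 1e-9 nM.

Verification against the analytic steady profile c(r) = A + B/r in a
spherical annulus (fixed concentrations at both faces, one-sided quadratic
flux closures): max relative error 0.023 % at 120 cells and observed
convergence order ≈2.6 under mesh doubling. The raw max-norm of the
discrete operator applied to the analytic profile is boundary-dominated and
reaches its asymptotic second-order decay only slowly; the solved-profile
error is the meaningful observable and is what the acceptance script
reports.

## Parameters

Geometry R1 = 7.5 µm (typical mammalian cell), δ = 0.1 µm: the unique
clean pair reproducing both ≈26.3 nM and ≈40 molecules/µm² from 650 nM.
Initial pools 650 nM RS, 450 nM RI. All defaults are config-overridable.

Kinetic defaults (the package's own choice of a realistic operating point;
each value has an order-of-magnitude literature anchor):

| parameter | default | first-order equivalent | anchor |
|---|---|---|---|
| k_on | 1e-3 /nM/s | — | ~6e7 /M/min, EGF-class affinity |
| k_off | 1e-3 /s | K_d = 1 nM | high-affinity growth-factor receptor |
| k_int_free = k_int_bound | 1e-3 µm/s | ≈1e-2 /s | constitutive internalization ~0.6/min; R = 1 at rest |
| k_rec_free = k_rec_bound | 2.5e-3 µm/s | ≈1e-3 /s | recycling t½ ~10 min |
| k_deg_free | 2e-4 /s | — | receptor turnover t½ ~1 h in stimulated cells |
| k_deg_bound | 5e-5 /s | — | occupied receptors protected/recycled efficiently |
| q_syn | 2e-3 nM·µm/s | ≈0.85 molecules/s/cell | slow basal synthesis |
| k_dephos | 0 /s | — | off by default |

Diffusion: D_L,ext = 1 µm²/s (macromolecular ligand in crowded medium —
small enough that extracellular gradients persist over tens of µm for
10³–10⁴ s, the regime the spatial model exists to study), membrane species
0.1 (free) and 0.05 (complex) µm²/s, intracellular species 0.2 µm²/s
(mid-range of the 0.05–1 µm²/s sweep the analysis supports).

This operating point was fixed by forward reasoning about the regime the
model targets, and matters mostly for the qualitative experiments: the
ligand-profile inversion at high density requires the free-ligand level at
the surface to *rebound*, which happens when (i) the occupied pathway
conserves ligand well (k_deg_bound small relative to recycling return,
~1e-3 /s) and (ii) the receptor pool contracts over hours
(k_deg_free·V_cell/A exceeding q_syn), so that ligand sequestered early is
released back once fewer receptors remain to rebind it. With these
defaults the simulated LRI peak at medium density is ≈309 nM with
recycling and ≈21 nM without it, and inversion develops by ≈30–50 min
after a 1 nM bolus at 2.4e8 cells/ml — while at 2.4e5 cells/ml the profile
stays regular over that span (a weak late sign flip eventually appears
even at low density once receptor turnover dominates; the package asserts
the contrast over the window in which the high-density inversion
develops).

## Analysis conventions

* Probe radii: "center of the cell" = r = 0; "cell surface" = mid-shell
  (the wording alternates between R1 and R2 in the literature, so one
  convention is fixed).
* Integrated response: trapezoidal AUC of the probed time course,
  concentration in nM, time in minutes, default horizon 10 h.
* Lag time: first time the series exceeds 5 % of its peak (threshold
  configurable); for monotone series the peak is the final value.
* Profile inversion: sign of the least-squares slope of concentration vs
  radius at an early and a late time; inverted iff both are nonzero and
  opposite. Flat profiles (relative range < 1e-6) report sign 0.
* Sweeps run serially, one fresh simulation per grid point, no
  warm-starting: determinism over speed.

## What the synthetic conditions do and do not show

All inputs are synthetic: uniform initial fields, a spherically symmetric
single cell, piecewise-constant ligand programs. Passing tests show the
discretization converges, mass is conserved, the well-mixed limit is
recovered exactly, and the density/dose/downregulation phenomenology is
reproduced *within this geometry*. They do not show anything about
multi-cell packings, non-spherical cells, membrane heterogeneity,
stochastic receptor numbers, or crowding corrections — all out of scope.
Whether lateral (within-shell) diffusion of surface species should be
faster or slower than the radial value used here is unresolved; the shell
is thin enough that the radial term is nearly inert.

## Known limitations

* The shell-as-volume idealization makes surface concentrations
  δ-dependent; δ is a model parameter, not a measurement.
* First-order mass-transfer internalization ignores coat-assembly
  saturation; R = k_int_bound/k_int_free summarizes downregulation but not
  its mechanism.
* The insulated outer boundary means long-horizon runs at very low density
  conserve ligand that a perfused culture would wash out.
* BDF with finite-difference Jacobians can undershoot zero by O(atol) on
  steep transients; tolerances, not projection, control positivity.
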