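# Methods

## Model

`knpemi` simulates ionic electrodiffusion in neural tissue with a
geometrically explicit representation of cells, extracellular space and
membranes.  Each region r (one per cell, plus the extracellular bath)
carries ion concentrations [k]_r (mol/m^3, k in {Na+, K+, Cl-}) and an
electric potential phi_r (V).  Bulk transport follows the Nernst-Planck
flux

    J_r^k = -D_r^k grad [k]_r - (D_r^k z^k / psi) [k]_r grad phi_r,
    psi = RT/F,

with ion conservation d[k]_r/dt + div J_r^k = 0.  Instead of a Poisson
equation, the potential is determined by bulk electroneutrality
(Kirchhoff-Nernst-Planck closure): F sum_k z^k div J_r^k = 0.  The implied
bulk conductivity is sigma_r = (F/psi) sum_k D_r^k [k]_r (z^k)^2, which for
the default initial state gives sigma_i = 2.01 S/m and sigma_e = 1.31 S/m.

On each membrane Gamma_n the potential jump phi_M = phi_i - phi_e evolves by
C_M dphi_M/dt = I_M - I_ch, where I_M is the total (capacitive + ionic)
transmembrane current density and I_ch the channel current.  The capacitive
part of I_M is attributed to the individual species in proportion to their
contribution to the local conductivity, alpha_r^k = D z^2 c / sum_l D z^2 c,
which closes the per-ion flux conditions on Gamma.

Channel models: a passive leak I_ch^k = g_L^k (phi_M - E^k) with Nernst
reversal potentials E^k recomputed from the local concentration traces, and
a Hodgkin-Huxley model with the standard 1952 squid-axon rate functions
(resting shift -65 mV, converted to SI units).  In the Hodgkin-Huxley model
each ionic pathway combines the gated conductance with that ion's leak
conductance (I_Na = (gbar_Na m^3 h + g_L^Na)(phi_M - E_Na), etc.).  The
gated terms alone would rest near -86 mV, ~18 mV below the tabulated
initial potential of -67.74 mV, which would contradict the quiescence of
unstimulated axons in the bundle experiments; with the leak included the
point model rests within ~2 mV of -67.74 mV.  For the same reason the
tabulated initial gating values (0.0379, 0.688, 0.276) differ from
p_inf(-67.74 mV) of the standard rates by up to 0.6% in the third digit;
the package reports the computed values (0.0381, 0.688, 0.277).

A synaptic drive I_syn = g_syn H(x) e^{-(t-t0)/alpha} (phi_M - E_Na) acts on
the sodium pathway inside an x-window Z of the stimulated membranes; with
several onsets t0 the most recent one applies (onsets re-arm, they do not
accumulate).  The passive single/double-axon scenarios (Models A and C)
hold the synaptic conductance at its onset amplitude instead of decaying
(`sustained`): read literally, the printed decaying form (tau = 1 ms) makes
every field decay three orders of magnitude before the 10 ms readout used
in the published comparisons, which report ~0.1 mV extracellular potentials
and a 0.016 mV difference between frameworks at that time; the sustained
drive reproduces those magnitudes.  The active bundle (Model D) uses the
decaying pulse (tau = 2 ms) so that each onset (0, 20, 40 ms) triggers one
action potential.  The bundle stimulus is applied to the left 10 um of the
stimulated membranes: end stimulation launches propagating action
potentials, whose local circuit currents through the narrow extracellular
gaps are what couples neighboring axons ephaptically.  Stimulating the
whole membrane instead makes the response uniform along the axon and caps
the electric coupling at a few millivolts regardless of axon length, which
would suppress the published firing dichotomy.

The EMI solver shares meshes, membrane models and the mortar structure but
drops the concentrations: fixed sigma_r, and reversal potentials frozen at
their initial values.  Its divergence from the electrodiffusive solution
over time is exactly the effect of concentration dynamics.

## Discretization

Uniform simplicial meshes: each grid rectangle is split along its
lower-left/upper-right diagonal; in 3D each cuboid is split into six
tetrahedra by the Kuhn triangulation so shared faces match.  All fields are
P1 (linear Lagrange) per subdomain; interface vertices carry duplicated
dofs so fields may jump across membranes.  I_M is itself a P1 field on the
interface facet mesh (a mortar variable), and a single scalar Lagrange
multiplier pins the extracellular potential to zero mean.

Time stepping is implicit Euler with two linearizations: the drift flux
uses the previous concentrations ([k]^{n-1} grad phi^n) and the capacitive
fractions alpha are lagged one step.  For Hodgkin-Huxley membranes an
operator splitting first advances phi_M and the gating variables by 25
forward-Euler substeps with I_M = 0 (reversal potentials frozen at the
previous traces), then solves the linear PDE block system with the channel
currents frozen at the ODE-step state.  The passive relation is linear in
phi_M and is inserted directly into the implicit system (no splitting).

Quadrature is exact for every assembled integrand: the weighted stiffness
with a P1 coefficient uses the element-mean coefficient (exact for linear
weights), interface forms use Gauss rules of degree >= 3, and error norms
use degree-4 rules so the quadrature error is dominated by the
approximation error.

Linear systems are solved by sparse LU factorization (SuperLU).  The time
loop reuses the last factorization through iterative refinement: each step
solves with the stale LU and refines until the true residual is below
1e-11 relative, refactorizing only when refinement stalls.  Because the
matrix changes only through the slowly drifting lagged coefficients, a
single factorization typically serves hundreds of steps; the residual
tolerance guarantees the result is as accurate as a fresh direct solve.

## Verification

A manufactured solution (trigonometric concentrations and potentials on
the unit square with an interior square cell; all constants equal to one;
passive test channel I_ch = phi_M on the sodium pathway) is substituted
into the governing equations with sympy.  The bulk residuals become source
terms; on the interface, the exact transmembrane current is identified
with the intracellular total ionic current I_M = F sum_k z^k J_i^k . n_i,
and the resulting corrections to the membrane-potential balance, the
extracellular current condition and the per-ion flux conditions are added
to the corresponding weak-form rows.  All modified equations are
re-checked symbolically (residuals simplify to zero) and numerically at
random points.  Boundary closure: exact Dirichlet data for the
extracellular concentrations and potential replace the zero-mean
multiplier for this test case only (the manufactured phi_e has no zero
mean).

Under simultaneous refinement (mesh halving, timestep quartering from
dt0 = 1e-5/64 with errors read at t = 2e-5/64) the observed orders are 2.0
in L2 and 1.0 in H1 for all concentrations and potentials, and ~1.5 for
I_M in the broken L2 norm; the absolute errors match the published table
to three digits (e.g. intracellular sodium L2 error 5.885e-4 at n = 32
against the printed 5.88e-4).

## Problem sizes used by the test suite and acceptance script

The package's own study sizes are chosen to run on a single CPU at desk
scale; all are full simulations of the governing equations:

- Convergence study: n = 16-64 in the test suite; the acceptance script
  extends to n = 128 (the published series continues to n = 256).
- Mesh-refinement consistency (Model A): coarse dx = 2 um against a
  dx = 1 um reference over 10 ms (the published number uses a dx = 0.25 um
  reference; the measure is dominated by the coarse-mesh error, and the
  reference choice moves it by ~10%).
- Framework comparison (Model C2): a grid-aligned anisotropic mesh with
  dx = 2.5 um, dy = 2 um (the cell corner coordinates only align with
  1 um isotropic grids, which cost ~10x more).
- Axon bundle: a shortened variant of the 9-axon bundle (50 um axons,
  dx = 2.5 um, full 0.1 um cross-sectional resolution, 5 ms of activity —
  the complete first stimulus episode; the synaptic pulse and the action
  potentials are over well before 5 ms).  The qualitative dichotomy is
  already resolved at this length: with the low effective conductivities
  (sigma_i = 1, sigma_e = 0.1 S/m) the unstimulated central axon fires at
  +45 mV, with electrodiffusive conductivities it depolarizes ~7 mV and
  stays subthreshold.

## Numerical choices and degenerate inputs

- Dof ordering is grid-lexicographic per block; systems and factorizations
  are bit-for-bit reproducible, so the `seed` recorded in configurations
  never influences results.
- Concentration positivity is not structurally guaranteed by the scheme.
  The solver raises if a concentration at a membrane-adjacent dof becomes
  nonpositive (the drift and alpha coefficients would lose meaning) and
  warns for interior dofs.  The manufactured-solution mode disables the
  check (its exact fields touch zero at two cell corners by construction).
- Initial data must be electroneutral per region (checked to 1e-10
  relative); the default concentrations satisfy this exactly.
- Gating variables outside [-0.01, 1.01] or non-finite potentials abort
  the run with a diagnostic naming the failing step.
- Geometry is validated before meshing: cell boxes must be grid-aligned,
  strictly interior and pairwise disjoint.

## Known limitations

- Structured axis-aligned geometries only; no imported or curved meshes.
- No ion pumps or cotransporters: concentrations drift secularly under
  sustained activity, so long simulations (>50 ms) overstate concentration
  changes.
- Error norms and manufactured-solution verification are implemented in
  2D (the verification case is 2D); 3D runs are verified indirectly via
  the structural properties (conservation identities, rest-state
  invariance, cross-framework consistency).
- The synthetic scenarios emulate idealized box axons with spatially
  uniform membrane parameters; real axon morphology, myelination and
  channel heterogeneity are out of scope, so passing tests demonstrate
  correctness of the numerics and the qualitative physics, not
  quantitative predictions for biological tissue.
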