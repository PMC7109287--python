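# knpemi

Finite-element simulation of **ionic electrodiffusion in geometrically
explicit neural tissue** — the KNP-EMI model: Kirchhoff-Nernst-Planck bulk
electrodiffusion in intra- and extracellular compartments, coupled across
explicitly meshed cell membranes by capacitive and channel currents.

Cable-theory models assume constant extracellular potentials and
concentrations; this package is for the regimes where that fails — tightly
packed unmyelinated axon bundles, ephaptic (non-synaptic) interaction, and
activity-driven ion concentration shifts.  For each ion species k
(Na+, K+, Cl-) and region r it solves

    d[k]_r/dt + div J_r^k = 0,        J_r^k = -D_r^k grad [k]_r - (D_r^k z^k/psi) [k]_r grad phi_r,
    F sum_k z^k div J_r^k = 0         (bulk electroneutrality closes phi_r),

with membrane conditions C_M dphi_M/dt = I_M - I_ch on each cell boundary,
phi_M = phi_i - phi_e, and per-ion flux conditions that split the
capacitive current according to alpha_r^k = D z^2 c / sum D z^2 c.  The
discretization is a mortar P1 finite-element method (the transmembrane
current I_M is an independent unknown on the membrane mesh) with an
implicit, lagged-linearized time step and an ODE/PDE splitting for
Hodgkin-Huxley membranes.  A companion EMI solver (fixed conductivities, no
concentrations) isolates what electrodiffusion adds.  See
`docs/methods.md` for the full formulation.

## Worked example

A 50 x 6 um passive axon in a 60 x 60 um bath, stimulated at its left end,
simulated for 1 ms and probed in the extracellular space:

```python
from knpemi import scenarios

cfg = scenarios.build_scenario("A", resolution=(2e-6, 2e-6), t_end=1e-3)
result = scenarios.run_scenario(cfg)                 # KNP-EMI framework
print(result.summary["dofs"])                        # 4125
phi = scenarios.probe(result, (4e-6, 31e-6), "phi", 0)
print(f"{phi.iloc[-1] * 1e3:.4f} mV")                # -0.0495 mV
print(f"{result.phi_M_max[1] * 1e3:.2f} mV")         # 47.08 mV
```

The run assembles the 4,125-unknown block system (6 concentration fields,
2 potentials, the mortar current and one multiplier), integrates 100
implicit steps of 10 us, and reports the extracellular potential 2 um
left of the axon (a fraction of a millivolt, negative: the stimulated
membrane draws sodium inward) and the peak membrane potential, reached
inside the stimulated patch, where the strong sustained synaptic
conductance pulls the passive membrane from -67.74 mV most of the way to
the sodium reversal potential.

The same surface drives the other built-in geometries: `"B"` (the unit
square verification case), `"C1"`-`"C3"` (one or two axons in a larger
bath, for KNP-vs-EMI comparisons), `"D"` (a 3D bundle of nine
Hodgkin-Huxley axons) and `"D-small"` (a shortened bundle that runs in
minutes).  `framework="emi"` runs the fixed-conductivity solver, with
`sigma_i` / `sigma_e` overrides.

A CLI wraps the same calls:

```
knpemi mesh-info --model A --dx 2e-6     # prints the 4,125-dof system size
knpemi verify --n 8 16 32                # manufactured-solution rate table
knpemi simulate --model A --dx 1e-6 --t-end 1e-3 --out out/
```

## Verification

`knpemi verify` runs the built-in manufactured-solution study: an exact
closed-form solution with derived source terms on the unit square.
Observed orders are 2.0 (L2) and 1.0 (H1) for concentrations and
potentials and ~1.5 for the transmembrane current in the broken L2 norm,
e.g. for intracellular sodium:

```
n     L2 error      rate
8     9.009e-03     --
16    2.333e-03     1.95
32    5.885e-04     1.99
64    1.475e-04     2.00
```

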