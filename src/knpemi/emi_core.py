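"""EMI solver: explicit-geometry bulk conduction with fixed conductivities.

The EMI model drops the ion concentrations: each region carries only a
potential governed by ``div(sigma_r grad phi_r) = 0`` with constant bulk
conductivities, coupled across the membranes by the same capacitive /
channel-current interface conditions and the same mortar discretization as
the full electrodiffusive solver.  Reversal potentials are computed once
from the initial concentrations and held constant, which is the defining
difference from the concentration-tracking model: after the first step the
two frameworks drift apart exactly as far as the concentrations do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from knpemi.fem_engine import BlockSystem, InterfaceOperators, MeshBundle, ReusableSolver
from knpemi.knp_core import IonSpecies, PhysicalConstants, bulk_conductivity, default_ions
from knpemi.membrane import (
    GatingState,
    MembraneParams,
    hh_channel_currents,
    hh_steady_state,
    membrane_ode_step,
    nernst_potential,
)

__all__ = ["EmiParams", "EmiState", "EmiSystem", "emi_solve"]


@dataclass
class EmiParams:
    """Fixed bulk conductivities and membrane data of the EMI model."""

    sigma_i: float          # S/m
    sigma_e: float          # S/m
    membrane: MembraneParams = field(default_factory=MembraneParams)
    reversal: dict = field(default_factory=dict)    # ion -> E (V), fixed in time

    def __post_init__(self):
        if self.sigma_i <= 0 or self.sigma_e <= 0:
            raise ValueError("bulk conductivities must be positive")

    @classmethod
    def from_ions(
        cls,
        ions: list[IonSpecies] | None = None,
        membrane: MembraneParams | None = None,
        constants: PhysicalConstants = PhysicalConstants(),
        sigma_i: float | None = None,
        sigma_e: float | None = None,
    ) -> "EmiParams":
        """Conductivities from the electrodiffusive expression at initial
        concentrations, and reversal potentials fixed at their initial values."""
        ions = ions if ions is not None else default_ions()
        si = bulk_conductivity([i.c_init_i for i in ions], [i.D_i for i in ions],
                               [i.z for i in ions], constants)
        se = bulk_conductivity([i.c_init_e for i in ions], [i.D_e for i in ions],
                               [i.z for i in ions], constants)
        rev = {i.name: nernst_potential(i.z, i.c_init_e, i.c_init_i,
                                        T=constants.T, R=constants.R, F=constants.F)
               for i in ions}
        return cls(
            sigma_i=sigma_i if sigma_i is not None else si,
            sigma_e=sigma_e if sigma_e is not None else se,
            membrane=membrane if membrane is not None else MembraneParams(),
            reversal=rev,
        )


@dataclass
class EmiState:
    time: float
    phi: dict               # region label -> nodal array
    phi_M: np.ndarray
    I_M: np.ndarray
    gating: GatingState | None
    c_e: float = 0.0


class EmiSystem:
    """Assembler and stepper for the mortar EMI system (potentials only)."""

    def __init__(self, mesh: MeshBundle, params: EmiParams, dt: float,
                 n_ode_substeps: int = 25):
        self.mesh = mesh
        self.params = params
        self.membrane = params.membrane
        self.dt = float(dt)
        self.n_ode_substeps = n_ode_substeps
        self.labels = mesh.region_labels
        self.spaces = {lab: mesh.space(lab) for lab in self.labels}
        self.K = {lab: s.stiffness_matrix() for lab, s in self.spaces.items()}
        self.M0 = self.spaces[0].mass_matrix()
        self.ops = InterfaceOperators(mesh)
        self.T = {lab: self.ops.trace_map(lab) for lab in self.labels}
        self.MG = self.ops.mass()
        self.mvec = self.M0 @ np.ones(self.spaces[0].n)
        self.solver = ReusableSolver()
        iface = mesh.interface
        self.iface_points = mesh.points[iface.vertices]
        self.iface_cell = iface.vertex_cell
        nq = self.ops.shape_q.shape[0]
        self.quad_x = self.ops.quad_points[:, :, 0].ravel()
        self.quad_cell = np.repeat(iface.facet_cell, nq)
        self.blocks = [(f"phi_{lab}", self.spaces[lab].n) for lab in self.labels]
        self.blocks += [("I_M", self.ops.nv), ("lam", 1)]

    def initial_state(self, phi_M0: float = -67.74e-3) -> EmiState:
        phi = {lab: np.zeros(self.spaces[lab].n) for lab in self.labels}
        phi_M = np.full(self.ops.nv, float(phi_M0))
        gating = None
        if self.membrane.model == "hodgkin-huxley":
            m, h, n = hh_steady_state(phi_M)
            gating = GatingState(m, h, n)
        return EmiState(0.0, phi, phi_M, np.zeros(self.ops.nv), gating)

    def _reversal_nodal(self):
        return {k: np.full(self.ops.nv, v) for k, v in self.params.reversal.items()}

    def _synaptic_g_quad(self, t):
        g = self.membrane.stimulus.conductance(self.quad_x, t, self.quad_cell)
        return g.reshape(self.ops.quad_weights.shape)

    def assemble(self, state: EmiState, t_new: float,
                 phi_M_ode=None, gating=None) -> BlockSystem:
        nb = len(self.blocks)
        A = [[None] * nb for _ in range(nb)]
        bi = {name: i for i, (name, _) in enumerate(self.blocks)}
        b = {name: np.zeros(size) for name, size in self.blocks}

        def add(r, c, mat):
            i, j = bi[r], bi[c]
            A[i][j] = mat if A[i][j] is None else A[i][j] + mat

        for lab in self.labels[:-1]:
            add(f"phi_{lab}", f"phi_{lab}", self.params.sigma_i * self.K[lab])
            add(f"phi_{lab}", "I_M", self.T[lab].T @ self.MG)
        add("phi_0", "phi_0", self.params.sigma_e * self.K[0])
        add("phi_0", "I_M", -(self.T[0].T @ self.MG))
        add("phi_0", "lam", sp.csr_matrix(-self.mvec[:, None]))
        add("lam", "phi_0", sp.csr_matrix(self.mvec[None, :]))

        CM = self.membrane.C_M
        for lab in self.labels[:-1]:
            add("I_M", f"phi_{lab}", (1.0 / self.dt) * (self.MG @ self.T[lab]))
        add("I_M", "phi_0", -(1.0 / self.dt) * (self.MG @ self.T[0]))
        add("I_M", "I_M", -(1.0 / CM) * self.MG)
        if self.membrane.model != "hodgkin-huxley":
            Eq = {k: np.full(self.ops.quad_weights.shape, v)
                  for k, v in self.params.reversal.items()}
            g_q = {k: np.full(self.ops.quad_weights.shape, self.membrane.g_leak.get(k, 0.0))
                   for k in ("Na", "K", "Cl")}
            g_q["Na"] = g_q["Na"] + self._synaptic_g_quad(t_new)
            g_tot_q = sum(g_q.values())
            gE_sum_q = sum(g_q[k] * Eq.get(k, 0.0) for k in g_q)
            Wg = self.ops.mass(g_tot_q)
            for lab in self.labels[:-1]:
                add("I_M", f"phi_{lab}", (1.0 / CM) * (Wg @ self.T[lab]))
            add("I_M", "phi_0", -(1.0 / CM) * (Wg @ self.T[0]))
            b["I_M"] = self.MG @ state.phi_M / self.dt + self.ops.load(gE_sum_q) / CM
        else:
            if phi_M_ode is None:
                raise ValueError("missing ODE-step data for the Hodgkin-Huxley model")
            b["I_M"] = self.MG @ phi_M_ode / self.dt

        Amat = sp.bmat(A, format="csr")
        rhs = np.concatenate([b[name] for name, _ in self.blocks])
        return BlockSystem(self.blocks, Amat, rhs)

    def step(self, state: EmiState) -> EmiState:
        t_new = state.time + self.dt
        phi_M_ode, gating = None, state.gating
        if self.membrane.model == "hodgkin-huxley":
            E = self._reversal_nodal()
            phi_M_ode, gating = membrane_ode_step(
                state.phi_M, state.gating, E, self.dt, self.membrane,
                t_start=state.time, x=self.iface_points[:, 0],
                cell_of_x=self.iface_cell, n_sub=self.n_ode_substeps,
            )
        system = self.assemble(state, t_new, phi_M_ode, gating)
        x = self.solver.solve(system.matrix, system.rhs)
        if not np.all(np.isfinite(x)):
            raise RuntimeError(f"non-finite solution at t = {t_new:g} s")
        parts = system.split(x)
        phi = {lab: parts[f"phi_{lab}"] for lab in self.labels}
        phi_M = -(self.T[0] @ phi[0])
        for lab in self.labels[:-1]:
            phi_M += self.T[lab] @ phi[lab]
        return EmiState(t_new, phi, phi_M, parts["I_M"], gating,
                        float(parts["lam"][0]))

    def run(self, state: EmiState, t_end: float, callback=None) -> EmiState:
        n_steps = int(round((t_end - state.time) / self.dt))
        for _ in range(n_steps):
            state = self.step(state)
            if callback is not None:
                callback(state)
        return state


def emi_solve(config, callback=None):
    """Run a full EMI scenario (same configuration surface as the KNP solver)."""
    from knpemi import scenarios

    return scenarios.run_scenario(config, framework="emi", callback=callback)
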