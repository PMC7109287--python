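"""The KNP-EMI solver: electroneutral bulk electrodiffusion with mortar coupling.

The model tracks, for each ion species k and each region r (one block per
physiological cell plus the extracellular region), the concentration ``[k]_r``
and the electric potential ``phi_r``, coupled across every membrane through
the transmembrane current density ``I_M`` (a mortar unknown on the interface
mesh) and the membrane potential ``phi_M = phi_i - phi_e``.

Discretization: implicit Euler in time with the ion flux linearized around
the previous concentrations,

    J_r^k  ~=  -D_r^k grad [k]_r^n - (D_r^k z^k / psi) [k]_r^{n-1} grad phi_r^n,

the capacitive fractions alpha_r^k lagged one step, and a two-step
ODE/PDE splitting for Hodgkin-Huxley membranes (the passive model is folded
into the implicit PDE step directly).  The extracellular potential is pinned
by a single scalar Lagrange multiplier enforcing a zero mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from knpemi.fem_engine import (
    BlockSystem,
    InterfaceOperators,
    MeshBundle,
    ReusableSolver,
)
from knpemi.membrane import (
    GatingState,
    MembraneParams,
    hh_channel_currents,
    hh_steady_state,
    membrane_ode_step,
    nernst_potential,
)

__all__ = [
    "PhysicalConstants",
    "IonSpecies",
    "KnpState",
    "KnpSystem",
    "default_ions",
    "bulk_conductivity",
    "alpha_fractions",
    "total_ion_content",
    "knp_solve",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Gas constant, temperature and Faraday's constant (SI)."""

    R: float = 8.314        # J/(K mol)
    T: float = 300.0        # K
    F: float = 9.648e4      # C/mol

    @property
    def psi(self) -> float:
        """Thermal voltage RT/F (V); always derived, never stored."""
        return self.R * self.T / self.F


@dataclass
class IonSpecies:
    """One ion species: valence, per-region diffusivities, initial state."""

    name: str
    z: int
    D_i: float              # m^2/s, intracellular
    D_e: float              # m^2/s, extracellular
    c_init_i: float         # mol/m^3
    c_init_e: float         # mol/m^3

    def __post_init__(self):
        if self.D_i <= 0 or self.D_e <= 0:
            raise ValueError("diffusion coefficients must be positive")
        if self.c_init_i <= 0 or self.c_init_e <= 0:
            raise ValueError("initial concentrations must be positive")

    def D(self, region: int) -> float:
        return self.D_i if region > 0 else self.D_e


def default_ions() -> list[IonSpecies]:
    """Na+, K+, Cl- with the standard diffusivities and initial concentrations."""
    return [
        IonSpecies("Na", +1, 1.33e-9, 1.33e-9, 12.0, 100.0),
        IonSpecies("K", +1, 1.96e-9, 1.96e-9, 125.0, 4.0),
        IonSpecies("Cl", -1, 2.03e-9, 2.03e-9, 137.0, 104.0),
    ]


def bulk_conductivity(concentrations, D, z, constants: PhysicalConstants = PhysicalConstants()):
    """Bulk conductivity ``sigma = (F/psi) sum_k D^k [k] (z^k)^2`` in S/m."""
    c = np.asarray(concentrations, dtype=float)
    D = np.asarray(D, dtype=float)
    z = np.asarray(z, dtype=float)
    return float(constants.F / constants.psi * np.sum(D * c * z**2, axis=-1)) if c.ndim == 1 \
        else constants.F / constants.psi * np.sum(D * c * z**2, axis=-1)


def alpha_fractions(concentrations, D, z):
    """Capacitive current fractions ``alpha^k = D^k (z^k)^2 [k] / sum_l ...``.

    ``concentrations`` has the ion index on the last axis; fractions are
    computed pointwise and sum to one.
    """
    c = np.asarray(concentrations, dtype=float)
    D = np.asarray(D, dtype=float)
    z = np.asarray(z, dtype=float)
    num = D * z**2 * c
    den = num.sum(axis=-1, keepdims=True)
    if np.any(den <= 0):
        raise ValueError("degenerate electrolyte: zero conductivity denominator")
    return num / den


@dataclass
class KnpState:
    """All unknown fields at one time level."""

    time: float
    conc: dict              # (ion name, region label) -> nodal array
    phi: dict               # region label -> nodal array
    phi_M: np.ndarray       # on interface vertices
    I_M: np.ndarray         # on interface vertices
    gating: GatingState | None
    c_e: float = 0.0        # zero-mean Lagrange multiplier

    def copy(self) -> "KnpState":
        return KnpState(
            self.time,
            {k: v.copy() for k, v in self.conc.items()},
            {k: v.copy() for k, v in self.phi.items()},
            self.phi_M.copy(),
            self.I_M.copy(),
            self.gating.copy() if self.gating is not None else None,
            self.c_e,
        )


def total_ion_content(system: "KnpSystem", state: KnpState, ion: str) -> dict:
    """Mass-matrix weighted total amount of one ion per region (mol, areal in 2D)."""
    out = {}
    for lab in system.mesh.region_labels:
        out[lab] = float(system.ones[lab] @ (system.M[lab] @ state.conc[(ion, lab)]))
    return out


class KnpSystem:
    """Assembler and stepper for the KNP-EMI block system on one mesh."""

    def __init__(
        self,
        mesh: MeshBundle,
        ions: list[IonSpecies],
        membrane: MembraneParams,
        dt: float,
        constants: PhysicalConstants = PhysicalConstants(),
        mms=None,
        n_ode_substeps: int = 25,
        freeze_concentrations: bool = False,
    ):
        self.mesh = mesh
        self.ions = ions
        self.membrane = membrane
        self.dt = float(dt)
        self.constants = constants
        self.mms = mms
        self.freeze_concentrations = freeze_concentrations
        self.check_positivity = mms is None
        self.n_ode_substeps = n_ode_substeps
        self.labels = mesh.region_labels            # cells first, then 0
        self.spaces = {lab: mesh.space(lab) for lab in self.labels}
        self.M = {lab: s.mass_matrix() for lab, s in self.spaces.items()}
        self.K = {lab: s.stiffness_matrix() for lab, s in self.spaces.items()}
        self.ones = {lab: np.ones(s.n) for lab, s in self.spaces.items()}
        self.ops = InterfaceOperators(mesh)
        self.T = {lab: self.ops.trace_map(lab) for lab in self.labels}
        self.MG = self.ops.mass()
        self.mvec = self.M[0] @ self.ones[0]        # integral row for phi_e
        self.solver = ReusableSolver()
        iface = mesh.interface
        self.iface_points = mesh.points[iface.vertices]
        self.iface_cell = iface.vertex_cell
        nq = self.ops.shape_q.shape[0]
        self.quad_x = self.ops.quad_points[:, :, 0].ravel()
        self.quad_cell = np.repeat(iface.facet_cell, nq)
        self.use_multiplier = not (mms is not None and mms.dirichlet is not None)
        # block layout: concentrations (ion-major), potentials, mortar current, multiplier
        self.blocks = []
        for ion in ions:
            for lab in self.labels:
                self.blocks.append((f"c_{ion.name}_{lab}", self.spaces[lab].n))
        for lab in self.labels:
            self.blocks.append((f"phi_{lab}", self.spaces[lab].n))
        self.blocks.append(("I_M", self.ops.nv))
        if self.use_multiplier:
            self.blocks.append(("lam", 1))
        self.block_index = {name: i for i, (name, _) in enumerate(self.blocks)}
        # membrane-adjacent dofs per (region) for positivity checks
        self.membrane_dofs = {
            lab: np.unique(self.T[lab].indices) for lab in self.labels
        }

    # -- state construction -------------------------------------------------

    def initial_state(self, phi_M0: float = -67.74e-3) -> KnpState:
        conc = {}
        for ion in self.ions:
            for lab in self.labels:
                c0 = ion.c_init_i if lab > 0 else ion.c_init_e
                conc[(ion.name, lab)] = np.full(self.spaces[lab].n, float(c0))
        self._check_electroneutral(conc)
        phi = {lab: np.zeros(self.spaces[lab].n) for lab in self.labels}
        phi_M = np.full(self.ops.nv, float(phi_M0))
        gating = None
        if self.membrane.model == "hodgkin-huxley":
            m, h, n = hh_steady_state(phi_M)
            gating = GatingState(m, h, n)
        return KnpState(0.0, conc, phi, phi_M, np.zeros(self.ops.nv), gating)

    def _check_electroneutral(self, conc):
        for lab in self.labels:
            net = np.zeros(self.spaces[lab].n)
            scale = 0.0
            for ion in self.ions:
                net += ion.z * conc[(ion.name, lab)]
                scale += abs(ion.z) * np.abs(conc[(ion.name, lab)]).max()
            if np.abs(net).max() > 1e-10 * scale:
                raise ValueError(f"initial data not electroneutral in region {lab}")

    # -- membrane traces ----------------------------------------------------

    def interface_traces(self, state: KnpState):
        """Nodal intra/extra concentration traces on Gamma, per ion."""
        tr = {}
        for ion in self.ions:
            intra = np.zeros(self.ops.nv)
            for lab in self.labels[:-1]:
                intra += self.T[lab] @ state.conc[(ion.name, lab)]
            extra = self.T[0] @ state.conc[(ion.name, 0)]
            tr[ion.name] = (intra, extra)
        return tr

    def reversal_potentials(self, state: KnpState):
        """Nodal Nernst potentials on Gamma from the lagged traces (V)."""
        if self.membrane.fixed_reversal is not None:
            return {ion.name: np.full(self.ops.nv, self.membrane.fixed_reversal.get(ion.name, 0.0))
                    for ion in self.ions}
        tr = self.interface_traces(state)
        E = {}
        for ion in self.ions:
            intra, extra = tr[ion.name]
            if np.any(intra <= 0) or np.any(extra <= 0):
                raise RuntimeError("positivity lost at membrane-adjacent dofs")
            E[ion.name] = nernst_potential(ion.z, extra, intra,
                                           T=self.constants.T, R=self.constants.R, F=self.constants.F)
        return E

    def alpha_at_quad(self, state: KnpState):
        """Lagged capacitive fractions alpha_r^k at interface quadrature points."""
        tr = self.interface_traces(state)
        out = {}
        for side, idx in (("i", 0), ("e", 1)):
            num = {}
            den = None
            for ion in self.ions:
                nod = tr[ion.name][idx]
                q = self.ops.at_quad(nod)
                v = ion.D(1 if side == "i" else 0) * ion.z**2 * q
                num[ion.name] = v
                den = v if den is None else den + v
            if np.any(den <= 0):
                raise RuntimeError("degenerate electrolyte on the membrane")
            for ion in self.ions:
                out[(ion.name, side)] = num[ion.name] / den
        return out

    # -- channel currents ---------------------------------------------------

    def _synaptic_g_quad(self, t: float) -> np.ndarray:
        g = self.membrane.stimulus.conductance(self.quad_x, t, self.quad_cell)
        return g.reshape(self.ops.quad_weights.shape)

    def _passive_conductances_quad(self, t: float):
        """Per-ion conductance fields at quadrature points, synapse on Na."""
        shape = self.ops.quad_weights.shape
        g = {ion.name: np.full(shape, self.membrane.g_leak.get(ion.name, 0.0))
             for ion in self.ions}
        g_syn = self._synaptic_g_quad(t)
        if "Na" in g:
            g["Na"] = g["Na"] + g_syn
        return g

    def frozen_channel_currents(self, phi_M_ode, gating, E, t: float):
        """Hodgkin-Huxley currents at quadrature points, frozen for the PDE step."""
        phi_q = self.ops.at_quad(phi_M_ode)
        Eq = {k: self.ops.at_quad(v) for k, v in E.items()}
        gq = GatingState(self.ops.at_quad(gating.m), self.ops.at_quad(gating.h),
                         self.ops.at_quad(gating.n))
        cur = hh_channel_currents(phi_q, gq, Eq["Na"], Eq["K"], Eq["Cl"], self.membrane)
        g_syn = self._synaptic_g_quad(t)
        cur["Na"] = cur["Na"] + g_syn * (phi_q - Eq["Na"])
        return cur

    # -- assembly -----------------------------------------------------------

    def assemble(self, state: KnpState, t_new: float,
                 phi_M_ode=None, gating=None) -> BlockSystem:
        ions, labels = self.ions, self.labels
        F, psi = self.constants.F, self.constants.psi
        dt = self.dt
        nb = len(self.blocks)
        A = [[None] * nb for _ in range(nb)]
        b = {name: np.zeros(size) for name, size in self.blocks}
        bi = self.block_index

        def add(r, c, mat):
            i, j = bi[r], bi[c]
            A[i][j] = mat if A[i][j] is None else A[i][j] + mat

        alpha_q = self.alpha_at_quad(state)
        passive = self.membrane.model != "hodgkin-huxley"
        E = self.reversal_potentials(state)
        Eq = {k: self.ops.at_quad(v) for k, v in E.items()}
        if passive:
            g_q = self._passive_conductances_quad(t_new)
            g_tot_q = sum(g_q.values())
            gE_sum_q = sum(g_q[ion.name] * Eq[ion.name] for ion in ions)
        else:
            if phi_M_ode is None or gating is None:
                raise ValueError("missing ODE-step data for the Hodgkin-Huxley model")
            cur_q = self.frozen_channel_currents(phi_M_ode, gating, E, t_new)
            I_ch_q = sum(cur_q.values())

        # per-(ion, region) drift stiffness, reused by the potential rows
        Kw = {}
        for ion in ions:
            for lab in labels:
                c_prev = state.conc[(ion.name, lab)]
                if self.check_positivity and np.any(c_prev[self.membrane_dofs[lab]] <= 0):
                    raise RuntimeError("positivity lost at membrane-adjacent dofs")
                Kw[(ion.name, lab)] = self.spaces[lab].stiffness_matrix(c_prev)

        # --- concentration rows ---
        if self.freeze_concentrations:
            # diagnostic mode: pin every concentration at its previous value so
            # the potential sub-system is exactly the fixed-conductivity solve
            for ion in ions:
                for lab in labels:
                    name = f"c_{ion.name}_{lab}"
                    add(name, name, sp.identity(self.spaces[lab].n, format="csr"))
                    b[name] = state.conc[(ion.name, lab)].copy()
        for ion in ions if not self.freeze_concentrations else []:
            zk = ion.z
            for lab in labels:
                s_r = 1.0 if lab > 0 else -1.0
                side = "i" if lab > 0 else "e"
                name = f"c_{ion.name}_{lab}"
                D = ion.D(lab)
                add(name, name, self.M[lab] / dt + D * self.K[lab])
                add(name, f"phi_{lab}", (D * zk / psi) * Kw[(ion.name, lab)])
                aq = alpha_q[(ion.name, side)]
                Tt = self.T[lab].T
                add(name, "I_M", (s_r / (F * zk)) * (Tt @ self.ops.mass(aq)))
                rhs = self.M[lab] @ state.conc[(ion.name, lab)] / dt
                if passive:
                    wk = g_q[ion.name] - aq * g_tot_q
                    Wk = self.ops.mass(wk)
                    coupling = (s_r / (F * zk)) * (Tt @ Wk)
                    phi_labels = [lab] if lab > 0 else labels[:-1]
                    for m in phi_labels:
                        add(name, f"phi_{m}", coupling @ self.T[m])
                    add(name, "phi_0", -(coupling @ self.T[0]))
                    rhs += (s_r / (F * zk)) * (
                        Tt @ self.ops.load(g_q[ion.name] * Eq[ion.name] - aq * gE_sum_q)
                    )
                else:
                    rhs -= (s_r / (F * zk)) * (
                        Tt @ self.ops.load(cur_q[ion.name] - aq * I_ch_q)
                    )
                if self.mms is not None:
                    rhs += self.mms.conc_rhs(self, ion.name, lab, t_new)
                b[name] = rhs

        # --- potential rows (sign-normalized so diagonal blocks are positive) ---
        for lab in labels:
            name = f"phi_{lab}"
            for ion in ions:
                zk = ion.z
                D = ion.D(lab)
                add(name, f"c_{ion.name}_{lab}", (F * zk * D) * self.K[lab])
                add(name, name, (F * D * zk**2 / psi) * Kw[(ion.name, lab)])
            if lab > 0:
                add(name, "I_M", self.T[lab].T @ self.MG)
            else:
                add(name, "I_M", -(self.T[0].T @ self.MG))
                if self.use_multiplier:
                    add(name, "lam", sp.csr_matrix(-self.mvec[:, None]))
            if self.mms is not None:
                b[name] = self.mms.phi_rhs(self, lab, t_new)

        # --- zero-mean constraint on phi_e ---
        if self.use_multiplier:
            add("lam", "phi_0", sp.csr_matrix(self.mvec[None, :]))

        # --- membrane row ---
        CM = self.membrane.C_M
        for lab in labels[:-1]:
            add("I_M", f"phi_{lab}", (1.0 / dt) * (self.MG @ self.T[lab]))
        add("I_M", "phi_0", -(1.0 / dt) * (self.MG @ self.T[0]))
        add("I_M", "I_M", -(1.0 / CM) * self.MG)
        rhs_m = self.MG @ state.phi_M / dt
        if passive:
            Wg = self.ops.mass(g_tot_q)
            for lab in labels[:-1]:
                add("I_M", f"phi_{lab}", (1.0 / CM) * (Wg @ self.T[lab]))
            add("I_M", "phi_0", -(1.0 / CM) * (Wg @ self.T[0]))
            rhs_m += self.ops.load(gE_sum_q) / CM
        else:
            rhs_m = self.MG @ phi_M_ode / dt
        if self.mms is not None:
            rhs_m = rhs_m + self.mms.membrane_rhs(self, t_new)
        b["I_M"] = rhs_m

        Amat = sp.bmat(A, format="csr")
        rhs = np.concatenate([b[name] for name, _ in self.blocks])
        system = BlockSystem(self.blocks, Amat, rhs)
        if self.mms is not None and self.mms.dirichlet is not None:
            self._apply_dirichlet(system, t_new)
        return system

    def _apply_dirichlet(self, system: BlockSystem, t_new: float):
        """Replace boundary rows of the extracellular fields with exact data."""
        space = self.spaces[0]
        bidx = space.boundary_vertices()
        pts = space.coords[bidx]
        rows, vals = [], []
        for ion in self.ions:
            f = self.mms.dirichlet[f"c_{ion.name}"]
            a, _ = system.offsets[f"c_{ion.name}_0"]
            rows.append(a + bidx)
            vals.append(f(pts[:, 0], pts[:, 1], t_new))
        f = self.mms.dirichlet["phi"]
        a, _ = system.offsets["phi_0"]
        rows.append(a + bidx)
        vals.append(f(pts[:, 0], pts[:, 1], t_new))
        rows = np.concatenate(rows)
        vals = np.concatenate([np.broadcast_to(v, len(bidx)) for v in vals])
        Acsr = system.matrix
        nnz_rows = np.repeat(np.arange(Acsr.shape[0]), np.diff(Acsr.indptr))
        mask = np.isin(nnz_rows, rows)
        Acsr.data[mask] = 0.0
        Acsr += sp.csr_matrix((np.ones(len(rows)), (rows, rows)), shape=Acsr.shape)
        system.matrix = Acsr
        system.rhs[rows] = vals

    # -- stepping -----------------------------------------------------------

    def step(self, state: KnpState) -> KnpState:
        t_new = state.time + self.dt
        phi_M_ode, gating = None, state.gating
        if self.membrane.model == "hodgkin-huxley":
            E = self.reversal_potentials(state)
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
        conc = {(ion.name, lab): parts[f"c_{ion.name}_{lab}"]
                for ion in self.ions for lab in self.labels}
        phi = {lab: parts[f"phi_{lab}"] for lab in self.labels}
        I_M = parts["I_M"]
        c_e = float(parts["lam"][0]) if self.use_multiplier else 0.0
        phi_M = -(self.T[0] @ phi[0])
        for lab in self.labels[:-1]:
            phi_M += self.T[lab] @ phi[lab]
        for ion in self.ions:
            for lab in self.labels:
                c = conc[(ion.name, lab)]
                if not self.check_positivity:
                    continue
                if np.any(c[self.membrane_dofs[lab]] <= 0):
                    raise RuntimeError(
                        f"positivity lost at membrane-adjacent dofs (ion {ion.name}, region {lab})"
                    )
                if np.any(c <= 0):
                    warnings.warn(
                        f"negative {ion.name} concentration away from the membrane in region {lab}",
                        RuntimeWarning,
                    )
        return KnpState(t_new, conc, phi, phi_M, I_M, gating, c_e)

    def run(self, state: KnpState, t_end: float, callback=None) -> KnpState:
        n_steps = int(round((t_end - state.time) / self.dt))
        for _ in range(n_steps):
            state = self.step(state)
            if callback is not None:
                callback(state)
        return state


def knp_solve(config, callback=None):
    """Run a full KNP-EMI scenario (geometry, membrane model, stimulus, probes)."""
    from knpemi import scenarios

    return scenarios.run_scenario(config, framework="knp", callback=callback)
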