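"""Method-of-manufactured-solutions verification of the mortar scheme.

A smooth closed-form solution (trigonometric concentrations and potentials
on the unit square with an interior square cell, all physical constants set
to one) is substituted into the governing equations; the nonzero residuals
become source terms on the bulk rows and correction terms on the interface
rows, so the discrete solver can be tested against a known exact solution.
Simultaneous refinement in space (mesh halving) and time (timestep
quartering) then exposes the convergence orders: 2 in L2, 1 in H1 for the
bulk fields, and ~1.5 for the transmembrane current in the broken L2 norm.

The exact transmembrane current is identified with the total ionic current
arriving from the intracellular side, ``I_M = F sum_k z^k J_i^k . n_i``;
the membrane-potential balance and the extracellular current and flux
conditions then acquire interface corrections, derived symbolically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import sympy as sym

from knpemi.fem_engine import build_structured_mesh, error_norms
from knpemi.knp_core import IonSpecies, KnpState, KnpSystem, PhysicalConstants
from knpemi.membrane import MembraneParams

__all__ = [
    "ManufacturedCase",
    "exact_solution",
    "run_convergence_study",
    "compute_rate",
    "convergence_rates",
]

_IONS = (("Na", 1), ("K", 1), ("Cl", -1))
_REGIONS = (("i", 1), ("e", 0))


def _build_exact():
    x, y, t = sym.symbols("x y t")
    s = sym.sin(2 * sym.pi * x) * sym.sin(2 * sym.pi * y) * sym.exp(-t)
    c = {
        ("Na", "i"): sym.Rational(7, 10) + sym.Rational(3, 10) * s,
        ("Na", "e"): 1 + sym.Rational(6, 10) * s,
        ("K", "i"): sym.Rational(3, 10) + sym.Rational(3, 10) * s,
        ("K", "e"): 1 + sym.Rational(2, 10) * s,
        ("Cl", "i"): 1 + sym.Rational(6, 10) * s,
        ("Cl", "e"): 2 + sym.Rational(8, 10) * s,
    }
    phi = {
        "i": sym.cos(2 * sym.pi * x) * sym.cos(2 * sym.pi * y) * (1 + sym.exp(-t)),
        "e": sym.cos(2 * sym.pi * x) * sym.cos(2 * sym.pi * y),
    }
    return (x, y, t), c, phi


class ManufacturedCase:
    """Exact solution, derived sources, and interface corrections (unit constants)."""

    def __init__(self):
        (x, y, t), conc, phi = _build_exact()
        self.syms = (x, y, t)
        self.conc_expr = conc
        self.phi_expr = phi
        z = dict(_IONS)

        # Nernst-Planck fluxes with D = psi = 1
        J = {}
        for (ion, reg), ce in conc.items():
            p = phi[reg]
            J[(ion, reg)] = (
                -sym.diff(ce, x) - z[ion] * ce * sym.diff(p, x),
                -sym.diff(ce, y) - z[ion] * ce * sym.diff(p, y),
            )
        # bulk sources: f = dc/dt + div J ; rho = -F sum_k z_k div J
        self.f_conc = {}
        self.rho = {}
        for reg in ("i", "e"):
            acc = sym.Integer(0)
            for ion, zk in _IONS:
                Jx, Jy = J[(ion, reg)]
                div = sym.diff(Jx, x) + sym.diff(Jy, y)
                self.f_conc[(ion, reg)] = sym.simplify(
                    sym.diff(conc[(ion, reg)], t) + div
                )
                acc += zk * div
            self.rho[reg] = sym.simplify(-acc)

        # membrane quantities (passive test model: I_ch = phi_M, on the Na pathway)
        phi_M = sym.simplify(phi["i"] - phi["e"])
        self.phi_M = phi_M
        I_ch = phi_M
        I_chk = {"Na": phi_M, "K": sym.Integer(0), "Cl": sym.Integer(0)}
        alpha = {}
        for reg in ("i", "e"):
            den = sum(zz**2 * conc[(ion, reg)] for ion, zz in _IONS)
            for ion, zz in _IONS:
                alpha[(ion, reg)] = zz**2 * conc[(ion, reg)] / den
        # total current components F sum_k z_k J_r^k (F = 1)
        Fcomp = {}
        for reg in ("i", "e"):
            Fcomp[reg] = (
                sum(zz * J[(ion, reg)][0] for ion, zz in _IONS),
                sum(zz * J[(ion, reg)][1] for ion, zz in _IONS),
            )
        self.J = J
        self.Fcomp = Fcomp
        # exact I_M, direction-dependent: I_M(n) = Fcomp_i . n
        self.I_M_components = Fcomp["i"]

        # interface corrections, each of the form A + Bx*nx + By*ny with n the
        # cell-outward normal:
        #   flux rows: g_r^k(n) = J_r^k.n - (I_ch^k + alpha_r^k (I_M(n) - I_ch))/(F z_k)
        #   potential row (extracellular): g_phi_e(n) = (F sum z J_e).n - I_M(n)
        #   membrane row: g_M(n) = d(phi_M)/dt + I_ch - I_M(n)   (C_M = 1)
        self.g_conc = {}
        for ion, zz in _IONS:
            for reg in ("i", "e"):
                a = alpha[(ion, reg)]
                A = (-I_chk[ion] + a * I_ch) / zz          # F = 1
                Bx = J[(ion, reg)][0] - (a / zz) * Fcomp["i"][0]
                By = J[(ion, reg)][1] - (a / zz) * Fcomp["i"][1]
                self.g_conc[(ion, reg)] = (A, Bx, By)
        self.g_phi_e = (
            sym.Integer(0),
            Fcomp["e"][0] - Fcomp["i"][0],
            Fcomp["e"][1] - Fcomp["i"][1],
        )
        self.g_M = (sym.diff(phi_M, t) + I_ch, -Fcomp["i"][0], -Fcomp["i"][1])

        self._lambdified = {}

    # -- evaluation ---------------------------------------------------------

    def _fn(self, key, expr):
        if key not in self._lambdified:
            self._lambdified[key] = sym.lambdify(self.syms, expr, "numpy")
        return self._lambdified[key]

    def evaluate(self, expr_key, expr, xx, yy, tt):
        out = self._fn(expr_key, expr)(xx, yy, tt)
        return np.broadcast_to(np.asarray(out, dtype=float), np.shape(xx)).copy()

    def exact(self, name: str):
        """Evaluator f(x, y, t) for a named field (e.g. 'Na_i', 'phi_e')."""
        expr = self._field_expr(name)
        return lambda xx, yy, tt: self.evaluate(("field", name), expr, xx, yy, tt)

    def exact_gradient(self, name: str):
        x, y, t = self.syms
        expr = self._field_expr(name)
        gx, gy = sym.diff(expr, x), sym.diff(expr, y)
        fx, fy = self._fn(("gx", name), gx), self._fn(("gy", name), gy)
        def grad(xx, yy, tt):
            return (
                np.broadcast_to(np.asarray(fx(xx, yy, tt), float), np.shape(xx)),
                np.broadcast_to(np.asarray(fy(xx, yy, tt), float), np.shape(xx)),
            )
        return grad

    def _field_expr(self, name: str):
        name = name.strip("[]")
        if name.startswith("phi"):
            return self.phi_expr[name.split("_")[1]]
        ion, reg = name.split("_")
        return self.conc_expr[(ion, reg)]

    def exact_I_M(self, quad_points, normals, tt):
        """Exact transmembrane current at facet quadrature points."""
        xq, yq = quad_points[..., 0], quad_points[..., 1]
        Bx = self.evaluate("IMx", self.I_M_components[0], xq, yq, tt)
        By = self.evaluate("IMy", self.I_M_components[1], xq, yq, tt)
        nx = normals[:, 0][:, None]
        ny = normals[:, 1][:, None]
        return Bx * nx + By * ny

    def _normal_form(self, key, triple, quad_points, normals, tt):
        xq, yq = quad_points[..., 0], quad_points[..., 1]
        A = self.evaluate((key, "A"), triple[0], xq, yq, tt)
        Bx = self.evaluate((key, "Bx"), triple[1], xq, yq, tt)
        By = self.evaluate((key, "By"), triple[2], xq, yq, tt)
        return A + Bx * normals[:, 0][:, None] + By * normals[:, 1][:, None]

    # -- hooks consumed by the assembler ------------------------------------

    @property
    def dirichlet(self):
        return {
            "c_Na": self.exact("Na_e"),
            "c_K": self.exact("K_e"),
            "c_Cl": self.exact("Cl_e"),
            "phi": self.exact("phi_e"),
        }

    def conc_rhs(self, system, ion: str, lab: int, t_new: float):
        reg = "i" if lab > 0 else "e"
        s_r = 1.0 if lab > 0 else -1.0
        space = system.spaces[lab]
        b = space.load_vector(
            lambda xx, yy, tt: self.evaluate(
                ("f", ion, reg), self.f_conc[(ion, reg)], xx, yy, tt
            ),
            t=t_new,
        )
        ops = system.ops
        nrm = system.mesh.interface.facet_normal
        g = self._normal_form(("g", ion, reg), self.g_conc[(ion, reg)],
                              ops.quad_points, nrm, t_new)
        return b - s_r * (system.T[lab].T @ ops.load(g))

    def phi_rhs(self, system, lab: int, t_new: float):
        reg = "i" if lab > 0 else "e"
        space = system.spaces[lab]
        b = -space.load_vector(
            lambda xx, yy, tt: self.evaluate(("rho", reg), self.rho[reg], xx, yy, tt),
            t=t_new,
        )
        if lab == 0:
            ops = system.ops
            nrm = system.mesh.interface.facet_normal
            g = self._normal_form("g_phi_e", self.g_phi_e, ops.quad_points, nrm, t_new)
            b = b + system.T[0].T @ ops.load(g)
        return b

    def membrane_rhs(self, system, t_new: float):
        ops = system.ops
        nrm = system.mesh.interface.facet_normal
        g = self._normal_form("g_M", self.g_M, ops.quad_points, nrm, t_new)
        return ops.load(g)

    # -- symbolic self-check -------------------------------------------------

    def derive_sources(self):
        """Re-derive all residuals and verify the modified equations vanish.

        Returns the source dictionary; raises if any residual of the sourced
        equations fails to simplify to zero.
        """
        x, y, t = self.syms
        z = dict(_IONS)
        for (ion, reg), ce in self.conc_expr.items():
            Jx, Jy = self.J[(ion, reg)]
            res = sym.diff(ce, t) + sym.diff(Jx, x) + sym.diff(Jy, y) - self.f_conc[(ion, reg)]
            if sym.simplify(res) != 0:
                raise RuntimeError(f"nonzero residual in concentration equation {ion}_{reg}")
        for reg in ("i", "e"):
            acc = sum(z[i] * (sym.diff(self.J[(i, reg)][0], x) + sym.diff(self.J[(i, reg)][1], y))
                      for i, _ in _IONS)
            if sym.simplify(-acc - self.rho[reg]) != 0:
                raise RuntimeError(f"nonzero residual in potential equation {reg}")
        # membrane balance with correction, for a generic unit normal direction
        nx, ny = sym.symbols("n_x n_y")
        I_M = self.I_M_components[0] * nx + self.I_M_components[1] * ny
        gM = self.g_M[0] + self.g_M[1] * nx + self.g_M[2] * ny
        res = sym.diff(self.phi_M, t) - (I_M - self.phi_M) - gM
        if sym.simplify(res) != 0:
            raise RuntimeError("nonzero residual in membrane-potential balance")
        # per-ion flux conditions with corrections (F = 1)
        I_ch = self.phi_M
        I_chk = {"Na": self.phi_M, "K": sym.Integer(0), "Cl": sym.Integer(0)}
        for ion, zz in _IONS:
            for reg in ("i", "e"):
                num = {"i": 1, "e": 1}[reg]
                a_num = zz**2 * self.conc_expr[(ion, reg)]
                a_den = sum(z2**2 * self.conc_expr[(i2, reg)] for i2, z2 in _IONS)
                a = a_num / a_den
                Jn = self.J[(ion, reg)][0] * nx + self.J[(ion, reg)][1] * ny
                g = (self.g_conc[(ion, reg)][0]
                     + self.g_conc[(ion, reg)][1] * nx
                     + self.g_conc[(ion, reg)][2] * ny)
                res = Jn - (I_chk[ion] + a * (I_M - I_ch)) / zz - g
                if sym.simplify(res) != 0:
                    raise RuntimeError(f"nonzero residual in flux condition {ion}_{reg}")
        return {"f_conc": self.f_conc, "rho": self.rho,
                "g_conc": self.g_conc, "g_phi_e": self.g_phi_e, "g_M": self.g_M}

    def residual_spot_check(self, n_points: int = 100, seed: int = 0) -> float:
        """Numerically evaluate the sourced-equation residuals at random points."""
        rng = np.random.default_rng(seed)
        xx = rng.uniform(0.05, 0.95, n_points)
        yy = rng.uniform(0.05, 0.95, n_points)
        tt = rng.uniform(0.0, 1.0, n_points)
        x, y, t = self.syms
        worst = 0.0
        for (ion, reg), ce in self.conc_expr.items():
            Jx, Jy = self.J[(ion, reg)]
            res = sym.diff(ce, t) + sym.diff(Jx, x) + sym.diff(Jy, y) - self.f_conc[(ion, reg)]
            vals = self.evaluate(("chk", ion, reg), res, xx, yy, tt)
            worst = max(worst, float(np.abs(vals).max()))
        return worst


def exact_solution(field: str, x, y, t):
    """Evaluate the printed closed-form exact solution for one field."""
    case = ManufacturedCase()
    try:
        return case.exact(field)(np.asarray(x, float), np.asarray(y, float), t)
    except KeyError as exc:
        raise KeyError(f"unknown field id {field!r}") from exc


def compute_rate(e_coarse: float, e_fine: float) -> float:
    """Observed convergence order between two meshes differing by a factor 2."""
    if e_coarse <= 0 or e_fine <= 0:
        raise ValueError("errors must be positive to compute a rate")
    return math.log2(e_coarse / e_fine)


def _unit_ions():
    return [
        IonSpecies("Na", 1, 1.0, 1.0, 0.7, 1.0),
        IonSpecies("K", 1, 1.0, 1.0, 0.3, 1.0),
        IonSpecies("Cl", -1, 1.0, 1.0, 1.0, 2.0),
    ]


def _mms_membrane():
    return MembraneParams(
        C_M=1.0,
        model="passive",
        g_leak={"Na": 1.0, "K": 0.0, "Cl": 0.0},
        fixed_reversal={"Na": 0.0, "K": 0.0, "Cl": 0.0},
    )


def solve_mms(n: int, dt: float, t_end: float, case: ManufacturedCase | None = None):
    """Solve the sourced KNP-EMI system on an n x n unit-square mesh."""
    case = case or ManufacturedCase()
    mesh = build_structured_mesh(
        (1.0, 1.0), (1.0 / n, 1.0 / n), [((0.25, 0.75), (0.25, 0.75))]
    )
    system = KnpSystem(
        mesh, _unit_ions(), _mms_membrane(), dt,
        constants=PhysicalConstants(R=1.0, T=1.0, F=1.0), mms=case,
    )
    conc = {}
    for ion in system.ions:
        for lab in (1, 0):
            reg = "i" if lab > 0 else "e"
            pts = system.spaces[lab].coords
            conc[(ion.name, lab)] = case.exact(f"{ion.name}_{reg}")(pts[:, 0], pts[:, 1], 0.0)
    phi = {lab: np.zeros(system.spaces[lab].n) for lab in (1, 0)}
    ip = system.iface_points
    phi_M0 = case.exact("phi_i")(ip[:, 0], ip[:, 1], 0.0) - case.exact("phi_e")(ip[:, 0], ip[:, 1], 0.0)
    state = KnpState(0.0, conc, phi, phi_M0, np.zeros(system.ops.nv), None)
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        state = system.step(state)
    return system, state


def mms_errors(system: KnpSystem, state: KnpState, case: ManufacturedCase) -> dict:
    """L2/H1 errors of all fields and the broken-L2 error of I_M at state.time."""
    t = state.time
    out = {}
    for ion in ("Na", "K", "Cl"):
        for lab, reg in ((1, "i"), (0, "e")):
            space = system.spaces[lab]
            vals = state.conc[(ion, lab)]
            out[f"{ion}_{reg}_L2"] = error_norms(space, vals, case.exact(f"{ion}_{reg}"), "L2", t=t)
            out[f"{ion}_{reg}_H1"] = error_norms(
                space, vals, case.exact(f"{ion}_{reg}"), "H1", t=t,
                exact_grad=case.exact_gradient(f"{ion}_{reg}"),
            )
    for lab, reg in ((1, "i"), (0, "e")):
        space = system.spaces[lab]
        out[f"phi_{reg}_L2"] = error_norms(space, state.phi[lab], case.exact(f"phi_{reg}"), "L2", t=t)
        out[f"phi_{reg}_H1"] = error_norms(
            space, state.phi[lab], case.exact(f"phi_{reg}"), "H1", t=t,
            exact_grad=case.exact_gradient(f"phi_{reg}"),
        )
    ops = system.ops
    IM_h = ops.at_quad(state.I_M)
    IM_ex = case.exact_I_M(ops.quad_points, system.mesh.interface.facet_normal, t)
    out["I_M_brokenL2"] = float(np.sqrt(np.sum(ops.quad_weights * (IM_h - IM_ex) ** 2)))
    return out


def run_convergence_study(
    n_list=(8, 16, 32, 64),
    dt0: float = 1e-5 / 64,
    t_end: float = 2e-5 / 64,
    verbose: bool = False,
) -> pd.DataFrame:
    """Refinement study: mesh n x n with timestep ``dt0 / 4**level``.

    Level 0 corresponds to n = 8; each mesh halving quarters the timestep so
    the implicit-Euler error refines at the same second-order pace as the
    spatial L2 error.  Errors are evaluated at ``t_end``.
    """
    case = ManufacturedCase()
    rows = []
    for n in n_list:
        level = round(math.log2(n / 8))
        dt = dt0 / 4**level
        system, state = solve_mms(n, dt, t_end, case)
        errs = mms_errors(system, state, case)
        errs["n"] = n
        errs["dt"] = dt
        rows.append(errs)
        if verbose:
            print(f"n={n:4d} NaI_L2={errs['Na_i_L2']:.3e} phi_e_H1={errs['phi_e_H1']:.3e} "
                  f"IM={errs['I_M_brokenL2']:.3e}")
    df = pd.DataFrame(rows).set_index("n")
    return df


def convergence_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise observed orders log2(e_{n/2} / e_n) for every error column."""
    cols = [c for c in table.columns if c != "dt"]
    out = {}
    idx = list(table.index)
    for c in cols:
        vals = []
        for a, b in zip(idx[:-1], idx[1:]):
            vals.append(compute_rate(table.loc[a, c], table.loc[b, c]))
        out[c] = vals
    return pd.DataFrame(out, index=idx[1:])
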