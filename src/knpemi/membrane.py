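"""Membrane-local physics: Nernst potentials, channel currents, gating ODEs.

Everything here lives pointwise on the membrane interface Gamma: reversal
potentials computed from the concentration traces on either side, passive
(leak) and Hodgkin-Huxley channel currents, an exponentially decaying
synaptic drive restricted to a stimulus window, and the explicit (forward
Euler) ODE half-step of the operator splitting that advances the membrane
potential and the gating variables with the distributed current I_M frozen
at zero.

Sign convention: currents are positive outward (from intra- to extracellular),
so the membrane potential obeys ``C_M dphi_M/dt = I_M - I_ch``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GatingState",
    "SynapticStimulus",
    "MembraneParams",
    "nernst_potential",
    "passive_channel_current",
    "hh_rate_constants",
    "hh_steady_state",
    "gating_step",
    "hh_channel_currents",
    "synaptic_current",
    "membrane_ode_step",
]


@dataclass
class GatingState:
    """Hodgkin-Huxley gating variables per interface vertex (dimensionless)."""

    m: np.ndarray
    h: np.ndarray
    n: np.ndarray

    def copy(self) -> "GatingState":
        return GatingState(self.m.copy(), self.h.copy(), self.n.copy())


@dataclass
class SynapticStimulus:
    """Exponentially decaying synaptic conductance on a membrane x-window.

    ``g_syn * H(x) * exp(-(t - t0)/alpha) * (phi_M - E_Na)`` with ``t0`` the
    most recent onset <= t (onsets do not accumulate) and ``H(x) = 1`` iff
    the x-coordinate lies in ``z_interval``.  Only the cells listed in
    ``cells`` are stimulated.
    """

    g_syn: float = 0.0                  # S/m^2
    alpha: float = 1.0e-3               # s, synaptic time constant
    onsets: tuple = ()                  # s
    z_interval: tuple | None = None     # (x0, x1) in m
    cells: tuple = ()                   # stimulated cell labels
    sustained: bool = False             # hold the onset amplitude (no decay)

    def conductance(self, x: np.ndarray, t: float, cell_of_x: np.ndarray | None = None) -> np.ndarray:
        """Effective synaptic conductance g_syn*H(x)*exp(-(t-t0)/alpha) at positions x."""
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        if self.g_syn == 0.0 or not self.onsets or self.z_interval is None:
            return g
        past = [t0 for t0 in self.onsets if t0 <= t]
        if not past:
            return g
        t0 = max(past)
        mask = (x >= self.z_interval[0]) & (x <= self.z_interval[1])
        if cell_of_x is not None and self.cells:
            mask &= np.isin(cell_of_x, self.cells)
        decay = 1.0 if self.sustained else np.exp(-(t - t0) / self.alpha)
        g[mask] = self.g_syn * decay
        return g


@dataclass
class MembraneParams:
    """Capacitance and channel conductivities of the membrane model."""

    C_M: float = 0.01                   # F/m^2
    model: str = "passive"              # "passive" | "hodgkin-huxley"
    g_leak: dict = field(default_factory=lambda: {"Na": 2.0, "K": 8.0, "Cl": 0.0})   # S/m^2
    g_hh_bar: dict = field(default_factory=lambda: {"Na": 1200.0, "K": 360.0, "Cl": 0.0})
    stimulus: SynapticStimulus = field(default_factory=SynapticStimulus)
    fixed_reversal: dict | None = None  # name -> E (V); None = Nernst from traces

    def __post_init__(self):
        if self.C_M <= 0:
            raise ValueError("C_M must be positive")
        for g in list(self.g_leak.values()) + list(self.g_hh_bar.values()):
            if g < 0:
                raise ValueError("conductivities must be nonnegative")


def nernst_potential(z: int, c_e, c_i, T: float = 300.0, R: float = 8.314, F: float = 9.648e4):
    """Reversal potential ``E = (RT)/(zF) ln(c_e/c_i)`` in volts."""
    c_e = np.asarray(c_e, dtype=float)
    c_i = np.asarray(c_i, dtype=float)
    if z == 0:
        raise ValueError("Nernst undefined for a neutral species")
    if np.any(c_e <= 0) or np.any(c_i <= 0):
        raise ValueError("Nernst undefined for nonpositive concentrations")
    out = (R * T) / (z * F) * np.log(c_e / c_i)
    return float(out) if out.ndim == 0 else out


def passive_channel_current(phi_M, E, g_L):
    """Leak current ``I = g_L (phi_M - E)`` in A/m^2."""
    if np.any(np.asarray(g_L) < 0):
        raise ValueError("leak conductivity must be nonnegative")
    return g_L * (np.asarray(phi_M, dtype=float) - E)


def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with the removable singularity at x = 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-7
    denom = 1.0 - np.exp(-x / y)
    denom = np.where(small, 1.0, denom)
    return np.where(small, y * (1.0 + 0.5 * x / y), x / denom)


def hh_rate_constants(phi_M):
    """Standard squid-axon Hodgkin-Huxley rate constants, SI units (1/s).

    ``phi_M`` is in volts; the classical expressions act on the potential in
    millivolts with a resting shift of -65 mV and yield rates in 1/ms, which
    are converted to 1/s.
    """
    V = np.asarray(phi_M, dtype=float) * 1e3   # mV
    alpha_m = 0.1 * _vtrap(V + 40.0, 10.0)
    beta_m = 4.0 * np.exp(-(V + 65.0) / 18.0)
    alpha_h = 0.07 * np.exp(-(V + 65.0) / 20.0)
    beta_h = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    alpha_n = 0.01 * _vtrap(V + 55.0, 10.0)
    beta_n = 0.125 * np.exp(-(V + 65.0) / 80.0)
    return tuple(1e3 * r for r in (alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n))


def hh_steady_state(phi_M):
    """Steady-state gating values (m_inf, h_inf, n_inf) at a fixed potential."""
    am, bm, ah, bh, an, bn = hh_rate_constants(phi_M)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def gating_step(state: GatingState, phi_M, dt_local: float, n_sub: int = 1) -> GatingState:
    """``n_sub`` forward-Euler updates of the gating ODEs at fixed phi_M."""
    if dt_local <= 0:
        raise ValueError("dt_local must be positive")
    am, bm, ah, bh, an, bn = hh_rate_constants(phi_M)
    m, h, n = (np.asarray(v, dtype=float).copy() for v in (state.m, state.h, state.n))
    for _ in range(n_sub):
        m += dt_local * (am * (1.0 - m) - bm * m)
        h += dt_local * (ah * (1.0 - h) - bh * h)
        n += dt_local * (an * (1.0 - n) - bn * n)
    for p in (m, h, n):
        if np.any(p < -0.01) or np.any(p > 1.01):
            raise RuntimeError("gating instability; reduce dt")
    return GatingState(m, h, n)


def hh_channel_currents(phi_M, gating: GatingState, E_Na, E_K, E_Cl, params: MembraneParams):
    """Per-ion Hodgkin-Huxley channel current densities (A/m^2).

    Each ionic pathway combines the voltage-gated conductance with the
    constant leak conductance for that ion; with the tabulated leak values
    this keeps the resting potential within ~2 mV of the initial -67.74 mV
    (the gated channels alone would rest far more hyperpolarized).
    """
    phi_M = np.asarray(phi_M, dtype=float)
    shape = np.broadcast_shapes(phi_M.shape, np.shape(gating.m))
    gb, gl = params.g_hh_bar, params.g_leak
    cur = {
        "Na": (gb.get("Na", 0.0) * gating.m ** 3 * gating.h + gl.get("Na", 0.0))
        * (phi_M - E_Na),
        "K": (gb.get("K", 0.0) * gating.n ** 4 + gl.get("K", 0.0)) * (phi_M - E_K),
        "Cl": (gb.get("Cl", 0.0) + gl.get("Cl", 0.0)) * (phi_M - E_Cl),
    }
    return {k: np.broadcast_to(np.asarray(v, dtype=float), shape).copy()
            for k, v in cur.items()}


def synaptic_current(x, t: float, phi_M, E_Na, params: MembraneParams, cell_of_x=None):
    """Synaptic current density (A/m^2), attributed to the sodium pathway."""
    g = params.stimulus.conductance(x, t, cell_of_x)
    return g * (np.asarray(phi_M, dtype=float) - E_Na)


def membrane_ode_step(
    phi_M: np.ndarray,
    gating: GatingState,
    E: dict,
    dt: float,
    params: MembraneParams,
    t_start: float = 0.0,
    x: np.ndarray | None = None,
    cell_of_x: np.ndarray | None = None,
    n_sub: int = 25,
):
    """ODE half-step of the splitting: advance phi_M and the gating variables.

    ``n_sub`` forward-Euler substeps of size ``dt/n_sub`` integrate
    ``C_M dphi_M/dt = -(I_Na + I_K + I_Cl + I_syn)`` (the distributed current
    I_M is set to zero in this step) together with the gating ODEs.  The
    reversal potentials ``E`` are frozen at the previous concentration traces.
    """
    phi = np.array(phi_M, dtype=float)
    g = gating.copy()
    h = dt / n_sub
    for s in range(n_sub):
        t = t_start + s * h
        cur = hh_channel_currents(phi, g, E["Na"], E["K"], E["Cl"], params)
        I_tot = cur["Na"] + cur["K"] + cur["Cl"]
        if x is not None:
            I_tot = I_tot + synaptic_current(x, t, phi, E["Na"], params, cell_of_x)
        am, bm, ah, bh, an, bn = hh_rate_constants(phi)
        phi = phi - h * I_tot / params.C_M
        g.m = g.m + h * (am * (1.0 - g.m) - bm * g.m)
        g.h = g.h + h * (ah * (1.0 - g.h) - bh * g.h)
        g.n = g.n + h * (an * (1.0 - g.n) - bn * g.n)
    if not np.all(np.isfinite(phi)):
        raise RuntimeError("ODE blow-up in membrane step")
    for p in (g.m, g.h, g.n):
        if np.any(p < -0.01) or np.any(p > 1.01):
            raise RuntimeError("gating instability; reduce dt")
    return phi, g
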