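"""Scenario builders, parameter registry, probes and comparison metrics.

The built-in geometries are idealized 2D axons in a square extracellular
bath (Models A and C), the unit-square verification domain (Model B), and a
3D bundle of nine cuboid axons (Model D).  Each builder returns a
:class:`ScenarioConfig` carrying the full parameterization; ``run_scenario``
turns a config into a mesh + solver and integrates it, recording probe time
series and per-cell membrane-potential extrema along the way.
"""

from __future__ import annotations

import json
import time as _time
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from knpemi.emi_core import EmiParams, EmiSystem
from knpemi.fem_engine import MeshBundle, build_structured_mesh, count_system_size
from knpemi.knp_core import (
    IonSpecies,
    KnpSystem,
    PhysicalConstants,
    default_ions,
)
from knpemi.membrane import MembraneParams, SynapticStimulus

__all__ = [
    "ScenarioConfig",
    "RunResult",
    "build_scenario",
    "build_mesh",
    "run_scenario",
    "probe",
    "evaluate_at",
    "mean_relative_difference",
    "max_abs_difference",
]

UM = 1e-6


@dataclass
class ScenarioConfig:
    """Complete, serializable description of one simulation run."""

    model: str = "custom"
    domain: tuple = (60 * UM, 60 * UM)
    cell_boxes: tuple = ()
    resolution: tuple = (1 * UM, 1 * UM)
    dt: float = 1.0e-5
    n_substeps: int = 25
    t_end: float = 10.0e-3
    framework: str = "knp"                  # "knp" | "emi"
    membrane_model: str = "passive"         # "passive" | "hodgkin-huxley"
    g_syn: float = 0.0                      # S/m^2
    syn_alpha: float = 1.0e-3               # s
    syn_onsets: tuple = ()
    syn_interval: tuple | None = None       # x-window Z (m)
    syn_sustained: bool = False             # hold onset amplitude (no decay)
    stimulated_cells: tuple = ()            # empty = all cells
    sigma_i: float | None = None            # EMI override (S/m)
    sigma_e: float | None = None
    phi_M0: float = -67.74e-3
    probes: tuple = ()                      # (field, region, (x, y[, z]))
    snapshot_every: float | None = None     # s; None = no field snapshots
    output_dir: str | None = None
    seed: int | None = None                 # recorded; the solver is deterministic

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path):
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("domain", "cell_boxes", "resolution", "syn_onsets",
                    "stimulated_cells", "probes"):
            if key in d and d[key] is not None:
                d[key] = _tuplify(d[key])
        if d.get("syn_interval") is not None:
            d["syn_interval"] = tuple(d["syn_interval"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "ScenarioConfig":
        path = str(path)
        if path.endswith(".toml"):
            import tomllib

            with open(path, "rb") as f:
                return cls.from_dict(tomllib.load(f))
        with open(path) as f:
            return cls.from_dict(json.load(f))

    def membrane_params(self) -> MembraneParams:
        stim = SynapticStimulus(
            g_syn=self.g_syn,
            alpha=self.syn_alpha,
            onsets=tuple(self.syn_onsets),
            z_interval=self.syn_interval,
            cells=tuple(self.stimulated_cells),
            sustained=self.syn_sustained,
        )
        return MembraneParams(model=self.membrane_model, stimulus=stim)


def _tuplify(obj):
    if isinstance(obj, (list, tuple)):
        return tuple(_tuplify(v) for v in obj)
    return obj


# ---------------------------------------------------------------------------
# geometry registry
# ---------------------------------------------------------------------------

def _model_d_boxes(x0, x1):
    boxes = []
    for y0 in (0.3, 0.6, 0.9):
        for z0 in (0.3, 0.6, 0.9):
            boxes.append(((x0, x1),
                          (y0 * UM, (y0 + 0.2) * UM),
                          (z0 * UM, (z0 + 0.2) * UM)))
    return tuple(boxes)


#: cell label of the central axon in the Model D bundle (y0 = z0 = 0.6 um)
MODEL_D_CENTER = 5
MODEL_D_PERIPHERY = tuple(i for i in range(1, 10) if i != MODEL_D_CENTER)


def build_scenario(model: str, **overrides) -> ScenarioConfig:
    """Construct the standard configuration of one of the built-in models."""
    model = model.upper() if model.lower() != "custom" else "custom"
    if model == "A":
        cfg = ScenarioConfig(
            model="A",
            domain=(60 * UM, 60 * UM),
            cell_boxes=(((6 * UM, 56 * UM), (28 * UM, 34 * UM)),),
            resolution=(1 * UM, 1 * UM),
            membrane_model="passive",
            g_syn=1.25e3,
            syn_alpha=1.0e-3,
            syn_onsets=(0.0,),
            syn_interval=(6.0e-6, 1.0e-5),
            syn_sustained=True,
            probes=(("phi", 0, (4 * UM, 31 * UM)), ("Na", 0, (4 * UM, 31 * UM))),
        )
    elif model == "B":
        cfg = ScenarioConfig(
            model="B",
            domain=(1.0, 1.0),
            cell_boxes=(((0.25, 0.75), (0.25, 0.75)),),
            resolution=(1.0 / 32, 1.0 / 32),
            dt=1e-5 / 64,
            t_end=2e-5 / 64,
            membrane_model="passive",
        )
    elif model in ("C1", "C2", "C3"):
        cells = {
            "C1": (((3.5e-5, 8.5e-5), (5.7e-5, 6.3e-5)),),
            "C2": (((3.5e-5, 8.5e-5), (5.2e-5, 5.8e-5)),
                   ((3.5e-5, 8.5e-5), (6.2e-5, 6.8e-5))),
            "C3": (((3.5e-5, 8.5e-5), (4.9e-5, 5.5e-5)),
                   ((3.5e-5, 8.5e-5), (6.5e-5, 7.1e-5))),
        }[model]
        Z = {"C1": (3.5e-5, 4.0e-5), "C2": (6.0e-5, 6.5e-5), "C3": (5.5e-5, 6.0e-5)}[model]
        cfg = ScenarioConfig(
            model=model,
            domain=(1.2e-4, 1.2e-4),
            cell_boxes=cells,
            resolution=(0.5 * UM, 0.5 * UM),
            membrane_model="passive",
            g_syn=1.25e3,
            syn_alpha=1.0e-3,
            syn_onsets=(0.0,),
            syn_interval=Z,
            syn_sustained=True,
            probes=(("phi", 0, (6.0e-5, 6.0e-5)),),
        )
    elif model == "D":
        cfg = ScenarioConfig(
            model="D",
            domain=(4.0e-4, 1.4e-6, 1.4e-6),
            cell_boxes=_model_d_boxes(5e-6, 3.95e-4),
            resolution=(1.25e-6, 1.0e-7, 1.0e-7),
            membrane_model="hodgkin-huxley",
            t_end=1e-3,
            g_syn=40.0,
            syn_alpha=2.0e-3,
            syn_onsets=(0.0, 0.02, 0.04),
            syn_interval=(5e-6, 1.5e-5),        # left end: APs propagate
            stimulated_cells=(MODEL_D_CENTER,),
        )
    elif model in ("D-SMALL", "D_SMALL", "DSMALL"):
        # shortened-axon bundle that runs at desk scale: same cross-section
        # and inter-axon gaps, axons 50 um long
        cfg = ScenarioConfig(
            model="D-small",
            domain=(6.0e-5, 1.4e-6, 1.4e-6),
            cell_boxes=_model_d_boxes(5e-6, 5.5e-5),
            resolution=(2.5e-6, 1.0e-7, 1.0e-7),
            membrane_model="hodgkin-huxley",
            t_end=10e-3,
            g_syn=40.0,
            syn_alpha=2.0e-3,
            syn_onsets=(0.0, 0.02, 0.04),
            syn_interval=(5e-6, 1.5e-5),        # left end: APs propagate
            stimulated_cells=(MODEL_D_CENTER,),
        )
    elif model == "custom":
        cfg = ScenarioConfig()
    else:
        raise ValueError(f"unknown model {model!r}")
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise ValueError(f"unknown scenario field {k!r}")
        setattr(cfg, k, v)
    return cfg


def build_mesh(config: ScenarioConfig) -> MeshBundle:
    return build_structured_mesh(config.domain, config.resolution, config.cell_boxes)


# ---------------------------------------------------------------------------
# point evaluation and probes
# ---------------------------------------------------------------------------

def _locate(mesh: MeshBundle, region: int, point):
    """Containing simplex (region-local) and barycentric weights of a point."""
    x = np.asarray(point, dtype=float)
    h = np.asarray(mesh.resolution)
    L = np.asarray(mesh.domain_lengths)
    if np.any(x < -1e-12) or np.any(x > L + 1e-12):
        raise ValueError("probe point outside the domain")
    idx = np.minimum((x / h).astype(int), (np.rint(L / h) - 1).astype(int))
    ndiv = np.rint(L / h).astype(int)
    if mesh.dim == 2:
        rect = idx[0] + (ndiv[0]) * idx[1]
        n_rect = ndiv[0] * ndiv[1]
        candidates = [rect, rect + n_rect]
    else:
        cub = idx[0] + ndiv[0] * (idx[1] + ndiv[1] * idx[2])
        n_cub = int(np.prod(ndiv))
        candidates = [cub + a * n_cub for a in range(6)]
    space = mesh.space(region)
    lut = mesh.region_local[region]
    for c in candidates:
        if mesh.cell_labels[c] != region:
            continue
        verts = mesh.cells[c]
        X = mesh.points[verts]
        A = (X[1:] - X[0]).T
        try:
            lam = np.linalg.solve(A, x - X[0])
        except np.linalg.LinAlgError:
            continue
        bary = np.concatenate([[1.0 - lam.sum()], lam])
        if np.all(bary > -1e-9):
            return lut[verts], bary
    raise ValueError(f"point {tuple(x)} not inside subdomain {region}")


def evaluate_at(mesh: MeshBundle, region: int, values: np.ndarray, point) -> float:
    """P1 interpolation of a subdomain field at a physical point."""
    dofs, bary = _locate(mesh, region, point)
    return float(values[dofs] @ bary)


def probe(result: "RunResult", point, field: str, region: int = 0) -> pd.Series:
    """Time series of one recorded probe (matched by field, region and point)."""
    df = result.probes
    sel = df[(df["field"] == field) & (df["region"] == region)]
    pts = sel[["x", "y"]].to_numpy() if "z" not in sel else sel[["x", "y", "z"]].to_numpy()
    target = np.asarray(point)
    d = np.linalg.norm(pts - target[None, : pts.shape[1]], axis=1)
    if len(d) == 0 or d.min() > 1e-9:
        raise KeyError(f"no recorded probe for {field} at {point}")
    mask = d < 1e-9
    s = sel[mask]
    return pd.Series(s["value"].to_numpy(), index=s["t"].to_numpy(), name=field)


# ---------------------------------------------------------------------------
# comparison metrics
# ---------------------------------------------------------------------------

def mean_relative_difference(series_a, series_b) -> float:
    """Mean over samples of |a - b| / |b|, b being the reference solution."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must share a sampling grid")
    nz = b != 0.0
    if not np.all(nz):
        warnings.warn("excluding zero reference samples from the mean relative difference")
    if not np.any(nz):
        raise ValueError("reference series is identically zero")
    return float(np.mean(np.abs(a[nz] - b[nz]) / np.abs(b[nz])))


def max_abs_difference(field_a, field_b) -> float:
    a = np.asarray(field_a, dtype=float)
    b = np.asarray(field_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fields live on different meshes")
    return float(np.abs(a - b).max())


# ---------------------------------------------------------------------------
# run driver
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Outcome of one scenario run: probe series, extrema, final fields."""

    config: ScenarioConfig
    framework: str
    mesh: MeshBundle
    system: object
    times: np.ndarray
    probes: pd.DataFrame
    final_state: object
    snapshots: list
    phi_M_max: dict          # cell label -> max over membrane and time (V)
    phi_M_min: dict
    summary: dict


def run_scenario(config: ScenarioConfig, framework: str | None = None,
                 callback=None) -> RunResult:
    """Build the mesh and solver for a scenario and integrate to t_end."""
    framework = framework or config.framework
    mesh = build_mesh(config)
    membrane = config.membrane_params()
    ions = default_ions()
    constants = PhysicalConstants()
    if framework == "knp":
        system = KnpSystem(mesh, ions, membrane, config.dt, constants,
                           n_ode_substeps=config.n_substeps)
        state = system.initial_state(phi_M0=config.phi_M0)
    elif framework == "emi":
        params = EmiParams.from_ions(ions, membrane=membrane, constants=constants,
                                     sigma_i=config.sigma_i, sigma_e=config.sigma_e)
        system = EmiSystem(mesh, params, config.dt, n_ode_substeps=config.n_substeps)
        state = system.initial_state(phi_M0=config.phi_M0)
    else:
        raise ValueError(f"unknown framework {framework!r}")

    probe_plan = []
    for fieldname, region, point in config.probes:
        dofs, bary = _locate(mesh, region, point)
        probe_plan.append((fieldname, region, tuple(point), dofs, bary))

    cells = mesh.region_labels[:-1]
    vcell = mesh.interface.vertex_cell
    phi_M_max = {c: float(state.phi_M[vcell == c].max()) for c in cells}
    phi_M_min = {c: float(state.phi_M[vcell == c].min()) for c in cells}

    records, times, snapshots = [], [], []
    n_steps = int(round(config.t_end / config.dt))
    snap_stride = (
        max(1, int(round(config.snapshot_every / config.dt)))
        if config.snapshot_every else None
    )
    t0 = _time.perf_counter()

    def record(st):
        times.append(st.time)
        for fieldname, region, point, dofs, bary in probe_plan:
            if fieldname == "phi":
                vals = st.phi[region]
            else:
                vals = st.conc[(fieldname, region)]
            rec = {"t": st.time, "field": fieldname, "region": region,
                   "x": point[0], "y": point[1], "value": float(vals[dofs] @ bary)}
            if len(point) > 2:
                rec["z"] = point[2]
            records.append(rec)
        for c in cells:
            pm = st.phi_M[vcell == c]
            phi_M_max[c] = max(phi_M_max[c], float(pm.max()))
            phi_M_min[c] = min(phi_M_min[c], float(pm.min()))

    for k in range(n_steps):
        state = system.step(state)
        record(state)
        if snap_stride and (k + 1) % snap_stride == 0:
            snapshots.append(state.copy() if hasattr(state, "copy") else state)
        if callback is not None:
            callback(state)

    wall = _time.perf_counter() - t0
    conservation = None
    if framework == "knp":
        from knpemi.knp_core import total_ion_content

        conservation = {}
        area_i = sum(mesh.space(l).mass_matrix().sum() for l in cells)
        area_e = mesh.space(0).mass_matrix().sum()
        for ion in ions:
            final = sum(total_ion_content(system, state, ion.name).values())
            initial = ion.c_init_i * area_i + ion.c_init_e * area_e
            conservation[ion.name] = {
                "initial_mol": initial,
                "final_mol": final,
                "relative_drift": (final - initial) / initial,
            }
    summary = {
        "model": config.model,
        "framework": framework,
        "dofs": count_system_size(mesh, len(ions)) if framework == "knp"
        else sum(mesh.n_region_vertices(l) for l in mesh.region_labels)
        + mesh.interface.n_vertices + 1,
        "n_steps": n_steps,
        "dt": config.dt,
        "t_end": config.t_end,
        "wall_time_s": wall,
        "phi_M_max_mV": {c: 1e3 * v for c, v in phi_M_max.items()},
        "phi_M_min_mV": {c: 1e3 * v for c, v in phi_M_min.items()},
        "conservation": conservation,
        "parameters": config.to_dict(),
    }
    return RunResult(config, framework, mesh, system, np.asarray(times),
                     pd.DataFrame(records), state, snapshots,
                     phi_M_max, phi_M_min, summary)
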