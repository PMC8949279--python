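"""Impact scenarios: rigid-wall contact, full runs, parameter sweeps.

A body meshed with tetrahedra travels with a uniform initial velocity toward
an infinite rigid plane.  Contact is a frictionless node-to-plane penalty:
every contact-candidate node penetrating the plane receives a normal force
``k * depth * tributary_area`` (tributary areas are one third of each
adjacent boundary-triangle area).  The impact is direct (no tangential
force, no rotation), matching a blunt frontal hit.

Acceleration is not a solver unknown (the space-time unknowns are
velocities); the recorded trace is the time derivative of the measurement
node's velocity, obtained by central differencing of the slab-boundary
values.  Peak values and full-field acceleration-magnitude snapshots are
derived from the same velocity history.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .materials import ViscoelasticMaterial, ViscoplasticMaterial
from .mesh import Mesh
from .spacetime import PicardError, SolverConfig, SolverState, Stepper

__all__ = [
    "TimeSeries",
    "ImpactScenario",
    "RunResult",
    "impact_velocity_from_drop",
    "contact_force",
    "run_impact",
    "sweep_viscoelastic",
    "sweep_softening",
]


@dataclass
class TimeSeries:
    """A sampled scalar channel, typically acceleration at a node (m/s^2)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"time_s": self.times, "value": self.values})
        with open(path, "w") as fh:
            fh.write(f"# channel: {self.label}\n# units: time [s], value [m/s^2]\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path, label: str | None = None) -> "TimeSeries":
        df = pd.read_csv(path, comment="#")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), label or str(path))


def impact_velocity_from_drop(height: float, g: float = 9.81) -> float:
    """Impact speed sqrt(2*g*h) equivalent to a free fall from ``height``."""
    if height < 0:
        raise ValueError("drop height must be non-negative")
    if g <= 0:
        raise ValueError("g must be positive")
    return float(np.sqrt(2.0 * g * height))


@dataclass
class ImpactScenario:
    """Initial conditions, obstacle geometry and time discretisation.

    The obstacle is an infinite rigid plane through ``plane_point`` with unit
    ``plane_normal`` pointing from the plane toward the body; a node with
    (x - plane_point) . normal < 0 has penetrated.  Defaults mirror the
    head-impact study conditions: 7.5 m/s approach speed and a 12 ms window.
    Gravity defaults to zero — over 12 ms it changes the velocity by about
    0.1 m/s, negligible against 7.5 m/s.
    """

    initial_speed: float = 7.5
    direction: tuple[float, float, float] = (-1.0, 0.0, 0.0)
    plane_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    plane_normal: tuple[float, float, float] = (1.0, 0.0, 0.0)
    contact_stiffness: float = 1.0e9     # N/m^3 (pressure per penetration depth)
    duration: float = 0.012
    h: float = 4.0e-5
    gravity: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.h <= 0:
            raise ValueError("duration and slab size must be positive")
        n = self.duration / self.h
        if abs(n - round(n)) > 1e-6 * n:
            raise ValueError("duration must be a whole number of slabs")
        d = np.linalg.norm(self.direction)
        if d == 0:
            raise ValueError("direction must be non-zero")
        self.direction = tuple(np.asarray(self.direction, dtype=float) / d)
        nn = np.linalg.norm(self.plane_normal)
        if abs(nn - 1.0) > 1e-9:
            if nn == 0:
                raise ValueError("plane normal must be non-zero")
            self.plane_normal = tuple(np.asarray(self.plane_normal, dtype=float) / nn)

    @property
    def n_slabs(self) -> int:
        return int(round(self.duration / self.h))

    @classmethod
    def head_on(cls, mesh: Mesh, initial_speed: float = 7.5, gap: float = 0.0,
                **kwargs) -> "ImpactScenario":
        """Plane perpendicular to -x, touching the mesh front minus ``gap``."""
        x_min = float(mesh.nodes[:, 0].min())
        return cls(
            initial_speed=initial_speed,
            direction=(-1.0, 0.0, 0.0),
            plane_point=(x_min - gap, 0.0, 0.0),
            plane_normal=(1.0, 0.0, 0.0),
            **kwargs,
        )


def _tributary_areas(mesh: Mesh, candidates: np.ndarray) -> np.ndarray:
    """Per-candidate nodal area: one third of each adjacent boundary triangle
    whose vertices are all contact candidates."""
    areas = np.zeros(mesh.n_nodes)
    cset = np.zeros(mesh.n_nodes, dtype=bool)
    cset[candidates] = True
    faces = mesh.surface_faces()
    on_contact = cset[faces].all(axis=1)
    for tri in faces[on_contact]:
        p = mesh.nodes[tri]
        a = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
        areas[tri] += a / 3.0
    out = areas[candidates]
    if np.any(out == 0) and out.max() > 0:
        out = np.where(out == 0, out[out > 0].mean(), out)
    return out


def contact_force(state: SolverState, mesh: Mesh, scenario: ImpactScenario,
                  v_iterate: np.ndarray | None = None, h: float | None = None,
                  areas: np.ndarray | None = None,
                  penetration_out: list | None = None) -> np.ndarray:
    """Penalty contact force vector (3N,).

    Positions are the current node coordinates, optionally advanced by the
    slab displacement predicted from ``v_iterate`` (used inside the Picard
    loop so contact is resolved semi-implicitly).
    """
    cand = mesh.node_sets["contact_candidates"]
    if areas is None:
        areas = _tributary_areas(mesh, cand)
    pos = state.coords[cand]
    if v_iterate is not None and h is not None:
        vmid = 0.5 * (state.v + v_iterate).reshape(-1, 3)[cand]
        pos = pos + h * vmid
    n = np.asarray(scenario.plane_normal)
    depth = -((pos - np.asarray(scenario.plane_point)) @ n)
    depth = np.maximum(depth, 0.0)
    if penetration_out is not None:
        penetration_out.append(float(depth.max()) if len(depth) else 0.0)
    f = np.zeros(3 * mesh.n_nodes)
    active = depth > 0
    if active.any():
        forces = scenario.contact_stiffness * depth[active, None] * areas[active, None] * n
        idx = cand[active]
        f.reshape(-1, 3)[idx] += forces
    return f


@dataclass
class RunResult:
    """Outcome of one impact run."""

    acceleration: TimeSeries               # measurement node, along the impact axis
    snapshots: list                        # [(time, |a| per node)]
    times: np.ndarray
    velocity_history: np.ndarray           # (n_slabs+1, 3N)
    max_penetration: float
    peak_acceleration_global: float        # max |a| over all nodes and times
    final_state: SolverState


def run_impact(mesh: Mesh, materials: dict[int, object], scenario: ImpactScenario,
               snapshot_times: list[float] | None = None,
               config: SolverConfig | None = None) -> RunResult:
    """Time-march a complete impact and record the acceleration trace.

    All nodes start at ``initial_speed`` along ``direction``; each slab adds
    the contact (and gravity) forces to the load vector and the nonlinear
    viscosity/contact coupling is resolved by the stepper's Picard loop.
    """
    stepper = Stepper(mesh, materials, config)
    v0 = scenario.initial_speed * np.asarray(scenario.direction)
    state = SolverState.initial(mesh, v0)
    cand = mesh.node_sets["contact_candidates"]
    areas = _tributary_areas(mesh, cand)
    g = np.asarray(scenario.gravity, dtype=float)

    n = scenario.n_slabs
    times = np.linspace(0.0, scenario.duration, n + 1)
    hist = np.empty((n + 1, 3 * mesh.n_nodes))
    hist[0] = state.v
    pen: list[float] = []

    grav_force = None
    if np.any(g != 0):
        stepper._prepare(state.coords)
        grav_force = stepper.M_s @ np.tile(g, mesh.n_nodes)

    def advance(state, h, depth=0):
        """One (sub-)slab; on Picard stagnation retry as two half-slabs —
        a smaller slab poses a milder nonlinear problem, and the recursion
        is deterministic."""
        def force(st, v_it, _pen=pen, _h=h):
            f = contact_force(st, mesh, scenario, v_iterate=v_it, h=_h,
                              areas=areas, penetration_out=_pen)
            if grav_force is not None:
                f = f + grav_force
            return f

        try:
            return stepper.step(state, h, external_force=force)
        except PicardError:
            if depth >= 5:
                raise
            mid = advance(state, h / 2.0, depth + 1)
            return advance(mid, h / 2.0, depth + 1)

    for i in range(n):
        try:
            state = advance(state, scenario.h)
        except Exception as exc:
            raise RuntimeError(f"impact run failed at slab {i} (t={state.t:.6g} s)") from exc
        hist[i + 1] = state.v

    meas = mesh.measurement_node()
    axis = np.asarray(scenario.direction)
    v_meas = hist[:, 3 * meas : 3 * meas + 3] @ axis
    a_meas = np.gradient(v_meas, times)
    series = TimeSeries(times, a_meas, label=f"node{meas}:along-impact")

    accel_field = np.gradient(hist, times, axis=0)          # (n+1, 3N)
    accel_mag = np.linalg.norm(accel_field.reshape(n + 1, -1, 3), axis=2)
    peak_global = float(accel_mag.max())

    snapshots = []
    if snapshot_times:
        for t_req in snapshot_times:
            k = int(np.argmin(np.abs(times - t_req)))
            snapshots.append((float(times[k]), accel_mag[k].copy()))

    return RunResult(
        acceleration=series,
        snapshots=snapshots,
        times=times,
        velocity_history=hist,
        max_penetration=max(pen) if pen else 0.0,
        peak_acceleration_global=peak_global,
        final_state=state,
    )


def sweep_viscoelastic(mesh: Mesh, E_values, c_values, scenario: ImpactScenario,
                       rho: float = 1040.0, nu: float = 0.0,
                       config: SolverConfig | None = None) -> pd.DataFrame:
    """Kelvin-Voigt comparator sweep: peak acceleration and time-to-peak per
    (E, c) grid point at the measurement node."""
    from .postprocess import peak_acceleration

    rows = []
    for E in E_values:
        for c in c_values:
            mats = {int(t): ViscoelasticMaterial(E_modulus=float(E), c_damping=float(c),
                                                 rho=rho, nu=nu)
                    for t in np.unique(mesh.element_tags)}
            res = run_impact(mesh, mats, scenario, config=config)
            peak, t_peak = peak_acceleration(res.acceleration)
            rows.append({"E": float(E), "c": float(c),
                         "peak_acceleration": peak, "time_of_peak": t_peak})
    return pd.DataFrame(rows)


def sweep_softening(mesh: Mesh, material: ViscoplasticMaterial, s_values,
                    scenario: ImpactScenario, skull: ViscoelasticMaterial | None = None,
                    config: SolverConfig | None = None) -> pd.DataFrame:
    """Shape-coefficient sweep: one impact run per s, peaks tabulated, sorted
    ascending in s.  The frontal-layer tag (2), if present, keeps ``skull``."""
    from .mesh import TAG_FRONTAL_LAYER
    from .postprocess import peak_acceleration

    rows = []
    for s in s_values:
        mat = ViscoplasticMaterial(
            K_viscosity=material.K_viscosity, m_sensitivity=material.m_sensitivity,
            s_coefficient=float(s), c_damping=material.c_damping, rho=material.rho,
            lambda_penalty=material.lambda_penalty, D_floor=material.D_floor,
            rate_scaling=material.rate_scaling,
        )
        mats: dict[int, object] = {int(t): mat for t in np.unique(mesh.element_tags)}
        if skull is not None and TAG_FRONTAL_LAYER in mats:
            mats[TAG_FRONTAL_LAYER] = skull
        res = run_impact(mesh, mats, scenario, config=config)
        peak, t_peak = peak_acceleration(res.acceleration)
        rows.append({"s": float(s), "peak_acceleration": peak, "time_of_peak": t_peak,
                     "peak_acceleration_global": res.peak_acceleration_global})
    return pd.DataFrame(rows).sort_values("s", ignore_index=True)
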