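"""Axisymmetric spring-damper model of a fingertip pressed on a plate.

The fingertip is discretised as a chain of surface nodes laid out on a
quasihemispherical meridian profile, each connected

* to its neighbours by Kelvin-Voigt membrane elements (spring + damper
  in parallel), resisting stretching of the skin surface;
* to a single rigid "bone" element by a Kelvin-Voigt bulk element,
  representing the compliance of the finger pulp;
* to the flat plate, when touching, by a unilateral penalty contact
  (no adhesion) and an elastoplastic tangential stick-spring: the node
  sticks to an anchor point until the Coulomb cone ``|f_t| <= mu f_n``
  is violated, at which point the anchor is projected back onto the
  cone (radial return) and the node slips.

A normal load is ramped onto the bone element and the system is stepped
with a semi-implicit (symplectic) Euler integrator until static
equilibrium.  Each node's displacement is referenced to its position at
first touchdown, mirroring how experimental skin displacements are
referenced to the contact-onset frame; from those displacements the
contacted-skin divergence ``du_r/dr + u_r/r`` (area-weighted mean over
the contact) is computed.  Low friction lets the flattening skin slide
outward (large divergence); high friction pins it where it lands (small
divergence but larger stored tangential stress).

Units: lengths mm, forces N, masses kg, time s.  Stiffnesses are
N/mm and damping N.s/mm; accelerations pick up a factor 1000 to convert
N/kg (= m/s^2) to mm/s^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as _dc_field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

from .errors import IntegrationError, ParameterError

__all__ = [
    "FingerModelParams",
    "ContactNodeState",
    "SimulationResult",
    "default_params",
    "build_model",
    "step",
    "simulate_press",
    "stress_profile",
    "divergence_vs_force_sweep",
    "mechanical_energy",
]

_G = 1000.0  # mm/s^2 per N/kg


@dataclass(frozen=True)
class FingerModelParams:
    """Parameters of the axisymmetric fingertip model.

    The default values (see ``finger_defaults.yaml``) are calibrated so
    that a press to 3 N reproduces the reference behaviour of a human
    index fingertip: contacted-skin divergence near 0.04 for mu = 0.1,
    a factor 2-3 lower at mu = 0.6, and a ~40 % higher peak tangential
    stress in the high-friction case.
    """

    n_nodes: int = 41
    finger_radius: float = 8.0  # mm
    skin_stiffness_normal: float = 5.0  # contact penalty, N/mm per node
    skin_stiffness_tangential: float = 1.0  # stick spring, N/mm per node
    membrane_stiffness: float = 4.5  # neighbour spring, N/mm
    bulk_stiffness: float = 0.05  # pulp spring toward the bone, N/mm per node
    bulk_stiffening: float = 0.02  # cubic pulp stiffening, N/mm^3 per node
    bulk_mode: str = "radial"  # "radial" fan to the bone point, or
    # "vertical": Winkler-type foundation acting along z only, so the
    # radial drive on the contact comes solely from membrane mismatch
    bulk_radial_fraction: float = 0.45  # anisotropic pulp: scale on the
    # radial component of the bulk-spring force (1 = isotropic fan)
    kv_damping: float = 0.01  # Kelvin-Voigt damper, N.s/mm
    contact_damping: float = 0.05  # normal contact damper, N.s/mm
    mass_damping: float = 0.02  # global viscous damping, N.s/mm
    pulp_pressure_stiffness: float = 0.0  # N/mm line pressure per unit area strain
    node_mass: float = 0.002  # kg
    bone_mass: float = 0.02  # kg
    mu: float = 0.1  # Coulomb friction coefficient
    target_force: float = 3.0  # N on the bone element
    ramp_rate: float = 3.6  # N/s, matches typical human pressing rate
    dt: float = 2.0e-5  # s
    equilibrium_tol: float = 0.05  # mm/s residual speed
    onset_force_threshold: float = 0.02  # N; a node's displacement
    # reference is taken when its contact load first exceeds this,
    # mirroring optical detection of intimate contact (which needs
    # pressure), not the first grazing touchdown
    theta_max_deg: float = 75.0  # half-aperture of the modelled meridian
    apex_clearance: float = 0.05  # initial apex height above the plate, mm
    max_steps: int = 700_000
    settle_window: int = 100  # consecutive OK checks for equilibrium

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ParameterError(f"n_nodes must be >= 3, got {self.n_nodes}")
        positive = (
            "finger_radius",
            "skin_stiffness_normal",
            "skin_stiffness_tangential",
            "membrane_stiffness",
            "bulk_stiffness",
            "node_mass",
            "bone_mass",
            "target_force",
            "ramp_rate",
            "dt",
            "equilibrium_tol",
            "theta_max_deg",
        )
        for name in positive:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be positive and finite, got {v}")
        for name in ("mu", "kv_damping", "contact_damping", "mass_damping",
                     "apex_clearance", "pulp_pressure_stiffness",
                     "bulk_stiffening"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ParameterError(f"{name} must be >= 0 and finite, got {v}")
        if not 0 < self.theta_max_deg <= 89.0:
            raise ParameterError("theta_max_deg must lie in (0, 89]")
        if self.bulk_mode not in ("radial", "vertical"):
            raise ParameterError(f"unknown bulk_mode {self.bulk_mode!r}")
        if not 0.0 <= self.bulk_radial_fraction <= 1.0:
            raise ParameterError("bulk_radial_fraction must lie in [0, 1]")
        # explicit-integrator stability guard for the stiffest spring
        k_max = max(
            self.skin_stiffness_normal,
            self.skin_stiffness_tangential,
            self.membrane_stiffness,
            self.bulk_stiffness,
        )
        dt_max = 0.1 / math.sqrt(_G * k_max / self.node_mass)
        if self.dt > dt_max:
            raise ParameterError(
                f"dt={self.dt:g} exceeds the stability bound {dt_max:.2e} s "
                "for the stiffest spring; reduce dt or the stiffness"
            )


def default_params(**overrides) -> FingerModelParams:
    """The calibrated default parameter set, with optional overrides."""
    with resources.files("frictouch").joinpath("finger_defaults.yaml").open() as fh:
        cfg = yaml.safe_load(fh)
    cfg.update(overrides)
    return FingerModelParams(**cfg)


def load_params(path: str, **overrides) -> FingerModelParams:
    """Load a YAML parameter file (any subset of fields) + overrides."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    base = default_params().__dict__ | cfg | overrides
    return FingerModelParams(**base)


@dataclass
class ContactNodeState:
    """Mutable state of the node chain and the bone element.

    ``pos[:, 0]`` is the signed radial coordinate r (the meridian spans
    -theta_max..theta_max, so the profile is symmetric under r -> -r),
    ``pos[:, 1]`` the height above the plate (plate at z = 0).
    ``anchor`` is the radial coordinate of each node's tangential
    stick-spring anchor (NaN when not in contact); ``onset_r`` the
    radial position at first touchdown, the displacement reference.
    """

    pos: np.ndarray
    vel: np.ndarray
    bone_z: float
    bone_vz: float
    in_contact: np.ndarray
    anchor: np.ndarray
    onset_r: np.ndarray
    normal_force: np.ndarray
    tangential_force: np.ndarray
    arc_element: np.ndarray  # per-node arc length, mm
    rest_length: np.ndarray  # membrane rest lengths, mm
    rest_gap: np.ndarray | None = None  # vertical bone-node rest gaps, mm
    ref_area: float = 0.0  # enclosed pulp cross-section at rest, mm^2
    time: float = 0.0
    applied_force: float = 0.0

    def copy(self) -> "ContactNodeState":
        return ContactNodeState(
            pos=self.pos.copy(),
            vel=self.vel.copy(),
            bone_z=self.bone_z,
            bone_vz=self.bone_vz,
            in_contact=self.in_contact.copy(),
            anchor=self.anchor.copy(),
            onset_r=self.onset_r.copy(),
            normal_force=self.normal_force.copy(),
            tangential_force=self.tangential_force.copy(),
            arc_element=self.arc_element,
            rest_length=self.rest_length,
            rest_gap=self.rest_gap,
            ref_area=self.ref_area,
            time=self.time,
            applied_force=self.applied_force,
        )


@dataclass
class SimulationResult:
    """Outcome of one simulated press to static equilibrium."""

    params: FingerModelParams
    converged: bool
    iterations: int
    time: float
    bone_force_series: np.ndarray  # (m, 2): t, applied force
    r: np.ndarray  # final radial node positions, mm
    z: np.ndarray
    onset_r: np.ndarray
    u_r: np.ndarray  # radial displacement since touchdown (NaN if never touched)
    in_contact: np.ndarray
    normal_stress: np.ndarray  # N/mm along the meridian line
    tangential_stress: np.ndarray
    normal_force: np.ndarray  # per-node, N
    tangential_force: np.ndarray
    divergence: float
    contact_force: float  # sum of interfacial normal forces, N
    tangential_stress_integral: float  # sum |f_t|, N
    tangential_elastic_energy: float  # 1/2 f_t^2 / k_t summed, mJ
    skin_elastic_energy: float  # membrane + tangential energy of contacted elements, mJ
    divergence_checkpoints: list = _dc_field(default_factory=list)  # (force, div)


def build_model(params: FingerModelParams) -> ContactNodeState:
    """Lay the node chain on a quasihemispherical profile above the plate.

    Nodes are spaced uniformly in polar angle over
    ``[-theta_max, theta_max]``; the apex starts ``apex_clearance`` mm
    above the plate, so the simulation begins before contact.
    """
    n = params.n_nodes
    R = params.finger_radius
    theta = np.linspace(
        -math.radians(params.theta_max_deg),
        math.radians(params.theta_max_deg),
        n,
    )
    bone_z = R + params.apex_clearance
    pos = np.column_stack([R * np.sin(theta), bone_z - R * np.cos(theta)])
    rest = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    dtheta = theta[1] - theta[0]
    arc = np.full(n, R * dtheta)
    arc[0] = arc[-1] = R * dtheta / 2.0
    ref_area = _pulp_area(pos, bone_z)
    return ContactNodeState(
        pos=pos,
        vel=np.zeros((n, 2)),
        bone_z=bone_z,
        bone_vz=0.0,
        in_contact=np.zeros(n, dtype=bool),
        anchor=np.full(n, np.nan),
        onset_r=np.full(n, np.nan),
        normal_force=np.zeros(n),
        tangential_force=np.zeros(n),
        arc_element=arc,
        rest_length=rest,
        rest_gap=bone_z - pos[:, 1].copy(),
        ref_area=ref_area,
        time=0.0,
        applied_force=0.0,
    )


def _pulp_area(pos: np.ndarray, bone_z: float) -> float:
    """Cross-section area enclosed by the skin chain and the bone point."""
    px = np.concatenate([[0.0], pos[:, 0], [0.0]])
    pz = np.concatenate([[bone_z], pos[:, 1], [bone_z]])
    return 0.5 * abs(float(np.dot(px, np.roll(pz, -1)) - np.dot(pz, np.roll(px, -1))))


def _pressure_forces(
    state: ContactNodeState, k_pressure: float
) -> tuple[np.ndarray, float]:
    """Uniform pulp pressure from the enclosed-area deficit.

    The nearly incompressible finger pulp is modelled as a uniform
    internal line pressure ``P = k_pressure * (A0 - A)/A0`` acting along
    the outward surface normal of every skin element; the reaction acts
    on the bone so the pressure does no net work on the system.  This
    is what keeps pushing the skin just outside the contact outward as
    the fingertip flattens.
    """
    pos = state.pos
    area = _pulp_area(pos, state.bone_z)
    P = k_pressure * (state.ref_area - area) / state.ref_area
    # outward normal = tangent rotated by -90 deg (interior lies above)
    tang = np.empty_like(pos)
    tang[1:-1] = pos[2:] - pos[:-2]
    tang[0] = pos[1] - pos[0]
    tang[-1] = pos[-1] - pos[-2]
    ds = 0.5 * np.linalg.norm(tang, axis=1)
    ds[0] *= 2.0
    ds[-1] *= 2.0
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    normal = np.column_stack([tang[:, 1], -tang[:, 0]])
    forces = P * normal * ds[:, None]
    return forces, P


def step(
    state: ContactNodeState,
    params: FingerModelParams,
    external_force: float | None = None,
) -> ContactNodeState:
    """Advance the state by one semi-implicit Euler step (in place).

    ``external_force`` is the instantaneous downward load on the bone
    element; when omitted it follows the linear ramp
    ``min(ramp_rate * t, target_force)``.
    """
    p = params
    if external_force is None:
        external_force = min(p.ramp_rate * state.time, p.target_force)
    pos, vel = state.pos, state.vel
    n = pos.shape[0]
    force = np.zeros_like(pos)

    # --- membrane Kelvin-Voigt elements between neighbours
    d = pos[1:] - pos[:-1]
    length = np.linalg.norm(d, axis=1)
    direction = d / length[:, None]
    rel_v = np.einsum("ij,ij->i", vel[1:] - vel[:-1], direction)
    f_mem = p.membrane_stiffness * (length - state.rest_length) + p.kv_damping * rel_v
    fm = f_mem[:, None] * direction
    force[:-1] += fm
    force[1:] -= fm

    # --- bulk Kelvin-Voigt elements toward the bone
    if p.bulk_mode == "radial":
        bone = np.array([0.0, state.bone_z])
        db = pos - bone
        lb = np.linalg.norm(db, axis=1)
        dirb = db / lb[:, None]
        rel_vb = np.einsum("ij,ij->i", vel - np.array([0.0, state.bone_vz]), dirb)
        db_stretch = lb - p.finger_radius
        f_bulk = (
            p.bulk_stiffness * db_stretch
            + p.bulk_stiffening * db_stretch**3  # strain-stiffening pulp
            + p.kv_damping * rel_vb
        )
        fb = f_bulk[:, None] * dirb
        fb[:, 0] *= p.bulk_radial_fraction  # anisotropic pulp shear compliance
        force -= fb
        bone_force = float(np.sum(f_bulk * dirb[:, 1]))  # reaction, z component
    else:  # vertical Winkler foundation: z-only pulp compliance
        gap = state.bone_z - pos[:, 1]
        s_gap = gap - state.rest_gap
        rel_vb = state.bone_vz - vel[:, 1]  # d(gap)/dt
        f_bulk = (
            p.bulk_stiffness * s_gap
            + p.bulk_stiffening * s_gap**3
            + p.kv_damping * rel_vb
        )
        force[:, 1] += f_bulk  # stretched gap pulls the node up
        bone_force = -float(np.sum(f_bulk))

    # --- incompressible-pulp pressure (area-deficit penalty)
    if p.pulp_pressure_stiffness > 0.0:
        f_press, _ = _pressure_forces(state, p.pulp_pressure_stiffness)
        force += f_press
        bone_force -= float(np.sum(f_press[:, 1]))

    # --- unilateral normal contact (penalty, no adhesion)
    pen = -pos[:, 1]
    touching = pen > 0.0
    f_n = np.zeros(n)
    f_n[touching] = np.maximum(
        p.skin_stiffness_normal * pen[touching]
        - p.contact_damping * vel[touching, 1],
        0.0,
    )
    force[:, 1] += f_n

    # contact bookkeeping: set anchors at touchdown, clear lost anchors;
    # the displacement reference (onset) waits for detectable pressure
    new_contact = touching & ~state.in_contact
    if new_contact.any():
        state.anchor[new_contact] = pos[new_contact, 0]
    detected = touching & (f_n >= p.onset_force_threshold) & np.isnan(state.onset_r)
    if detected.any():
        state.onset_r[detected] = pos[detected, 0]
    state.anchor[~touching] = np.nan
    state.in_contact = touching

    # --- elastoplastic tangential stick-spring with radial return
    f_t = np.zeros(n)
    if p.mu > 0.0:
        idx = touching
        f_t[idx] = -p.skin_stiffness_tangential * (pos[idx, 0] - state.anchor[idx])
        cap = p.mu * f_n
        over = idx & (np.abs(f_t) > cap)
        if over.any():
            sgn = np.sign(f_t[over])
            f_t[over] = sgn * cap[over]
            # reposition the anchor so the spring sits exactly on the cone
            state.anchor[over] = pos[over, 0] + sgn * cap[over] / p.skin_stiffness_tangential
    else:
        state.anchor[touching] = pos[touching, 0]
    force[:, 0] += f_t

    # --- global viscous damping
    force -= p.mass_damping * vel

    state.normal_force = f_n
    state.tangential_force = f_t

    if not np.all(np.isfinite(force)):
        bad = int(np.argmax(~np.all(np.isfinite(force), axis=1)))
        raise IntegrationError(f"non-finite force at node {bad} (t={state.time:.4g} s)")

    # --- semi-implicit Euler update
    vel += (p.dt * _G / p.node_mass) * force
    pos += p.dt * vel
    bone_acc = _G * (bone_force - external_force - p.mass_damping * state.bone_vz) / p.bone_mass
    state.bone_vz += p.dt * bone_acc
    state.bone_z += p.dt * state.bone_vz
    state.time += p.dt
    state.applied_force = external_force
    return state


def mechanical_energy(state: ContactNodeState, params: FingerModelParams) -> float:
    """Total kinetic + elastic energy of the chain, mJ.

    Counts membrane/bulk spring energy, contact-penalty energy, the
    tangential stick-spring energy, and kinetic energy.  Used by tests
    to verify passive dissipation (no external work in, no energy up).
    """
    p = params
    ke = 0.5 * p.node_mass / _G * float(np.sum(state.vel**2))
    ke += 0.5 * p.bone_mass / _G * state.bone_vz**2
    d = np.linalg.norm(np.diff(state.pos, axis=0), axis=1)
    e_mem = 0.5 * p.membrane_stiffness * float(np.sum((d - state.rest_length) ** 2))
    if p.bulk_mode == "radial":
        lb = np.linalg.norm(state.pos - np.array([0.0, state.bone_z]), axis=1)
        db = lb - p.finger_radius
    else:
        db = (state.bone_z - state.pos[:, 1]) - state.rest_gap
    e_bulk = 0.5 * p.bulk_stiffness * float(np.sum(db**2))
    e_bulk += 0.25 * p.bulk_stiffening * float(np.sum(db**4))
    pen = np.maximum(-state.pos[:, 1], 0.0)
    e_con = 0.5 * p.skin_stiffness_normal * float(np.sum(pen**2))
    stretch = np.where(
        state.in_contact & np.isfinite(state.anchor),
        state.pos[:, 0] - np.nan_to_num(state.anchor),
        0.0,
    )
    e_tan = 0.5 * p.skin_stiffness_tangential * float(np.sum(stretch**2))
    e_press = 0.0
    if p.pulp_pressure_stiffness > 0.0:
        dA = state.ref_area - _pulp_area(state.pos, state.bone_z)
        e_press = 0.5 * p.pulp_pressure_stiffness * dA**2 / state.ref_area
    return ke + e_mem + e_bulk + e_con + e_tan + e_press


def contacted_divergence(state: ContactNodeState, robust: bool = True) -> float:
    """Divergence of the contacted-skin displacement, one scalar.

    Radial displacement ``u = |r| - |r_onset|`` for every contacted
    node; the axisymmetric divergence ``du/dr + u/r`` is evaluated on
    the onset coordinates (the limit ``2 du/dr`` at the apex) for both
    meridian halves.  By default the median of the nodal values is
    returned — the same robust summary the imaging analysis uses for
    the gridded divergence field, insensitive to the contact-edge cells
    where the onset-referenced displacement vanishes by construction.
    ``robust=False`` gives the ring-area-weighted mean instead.
    """
    divs: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    for sign in (1.0, -1.0):
        if sign > 0:
            sel = state.in_contact & (state.onset_r >= 0)
        else:
            sel = state.in_contact & (state.onset_r < 0)
        r0 = np.abs(state.onset_r[sel])
        u = np.abs(state.pos[sel, 0]) - r0
        order = np.argsort(r0)
        r0, u = r0[order], u[order]
        if r0.size < 2:
            continue
        du_dr = np.gradient(u, r0)
        with np.errstate(divide="ignore", invalid="ignore"):
            div = du_dr + np.where(r0 > 1e-9, u / np.where(r0 > 1e-9, r0, 1.0), du_dr)
        divs.append(div)
        weights.append(np.gradient(r0) * np.maximum(r0, np.gradient(r0) / 2))
    if not divs:
        return 0.0
    div = np.concatenate(divs)
    if robust:
        return float(np.median(div))
    w = np.concatenate(weights)
    return float(np.sum(div * w) / np.sum(w))


def _result_from_state(
    state: ContactNodeState,
    params: FingerModelParams,
    converged: bool,
    iterations: int,
    series: list,
    checkpoints: list,
) -> SimulationResult:
    u_r = np.where(
        np.isfinite(state.onset_r),
        np.abs(state.pos[:, 0]) - np.abs(state.onset_r),
        np.nan,
    )
    k_t = params.skin_stiffness_tangential
    e_tan = float(np.sum(state.tangential_force**2)) / (2.0 * k_t)
    # elastic energy held in the skin of the contact: membrane elements
    # whose both endpoints touch the plate, plus the stick-springs
    seg_contact = state.in_contact[:-1] & state.in_contact[1:]
    seg_len = np.linalg.norm(np.diff(state.pos, axis=0), axis=1)
    e_mem = 0.5 * params.membrane_stiffness * float(
        np.sum(((seg_len - state.rest_length) ** 2)[seg_contact])
    )
    e_skin = e_mem + e_tan
    return SimulationResult(
        params=params,
        converged=converged,
        iterations=iterations,
        time=state.time,
        bone_force_series=np.asarray(series),
        r=state.pos[:, 0].copy(),
        z=state.pos[:, 1].copy(),
        onset_r=state.onset_r.copy(),
        u_r=u_r,
        in_contact=state.in_contact.copy(),
        normal_stress=state.normal_force / state.arc_element,
        tangential_stress=state.tangential_force / state.arc_element,
        normal_force=state.normal_force.copy(),
        tangential_force=state.tangential_force.copy(),
        divergence=contacted_divergence(state),
        contact_force=float(np.sum(state.normal_force)),
        tangential_stress_integral=float(np.sum(np.abs(state.tangential_force))),
        tangential_elastic_energy=e_tan,
        skin_elastic_energy=e_skin,
        divergence_checkpoints=checkpoints,
    )


def simulate_press(
    params: FingerModelParams,
    force_checkpoints: Sequence[float] = (),
) -> SimulationResult:
    """Press the fingertip to the target load and settle to equilibrium.

    The bone load ramps linearly at ``ramp_rate`` to ``target_force``
    and the chain is stepped until the residual node speed stays below
    ``equilibrium_tol`` and the interfacial normal force matches the
    target within 1 % for ``settle_window`` consecutive checks.  If the
    step cap is hit first the result is returned with
    ``converged=False``.

    ``force_checkpoints`` (N) asks for the contacted-skin divergence to
    be recorded when the applied ramp first crosses each level.
    """
    state = build_model(params)
    p = params
    checkpoints = sorted(set(float(f) for f in force_checkpoints))
    next_cp = 0
    recorded: list[tuple[float, float]] = []
    series: list[tuple[float, float]] = []
    ok_streak = 0
    check_every = 20
    converged = False
    it = 0
    while it < p.max_steps:
        step(state, p)
        it += 1
        if next_cp < len(checkpoints) and state.applied_force >= checkpoints[next_cp]:
            recorded.append((checkpoints[next_cp], contacted_divergence(state)))
            next_cp += 1
        if it % 500 == 0:
            series.append((state.time, state.applied_force))
        if it % check_every == 0 and state.applied_force >= p.target_force:
            speed = float(np.max(np.abs(state.vel)))
            speed = max(speed, abs(state.bone_vz))
            fc = float(np.sum(state.normal_force))
            if speed < p.equilibrium_tol and abs(fc - p.target_force) < 0.01 * p.target_force:
                ok_streak += 1
                if ok_streak >= p.settle_window:
                    converged = True
                    break
            else:
                ok_streak = 0
    return _result_from_state(state, p, converged, it, series, recorded)


def stress_profile(result: SimulationResult):
    """Interfacial stress vs radial position at the end of the press.

    Returns ``(r, normal_stress, tangential_stress)`` restricted to the
    contacted nodes, in N/mm of meridian line length.  The integral of
    the normal stress over the contact equals the applied load at
    equilibrium; the tangential peak grows with the friction
    coefficient while the normal profile barely changes.
    """
    sel = result.in_contact
    order = np.argsort(result.r[sel])
    r = result.r[sel][order]
    return r, result.normal_stress[sel][order], result.tangential_stress[sel][order]


def divergence_vs_force_sweep(
    params: FingerModelParams,
    mu_list: Sequence[float],
    force_grid: Sequence[float],
) -> list[dict]:
    """Divergence at each force level during a press, for several mu.

    Runs one press per friction coefficient, recording the contacted
    skin divergence as the ramp crosses each force level.  Rows are
    ordered by mu; at fixed force the divergence is non-increasing in
    mu (within solver tolerance).
    """
    if len(mu_list) == 0:
        raise ParameterError("mu_list must be nonempty")
    rows = []
    for mu in mu_list:
        p = replace(params, mu=float(mu))
        res = simulate_press(p, force_checkpoints=force_grid)
        row = {"mu": float(mu), "converged": res.converged}
        for f, d in res.divergence_checkpoints:
            row[f"div_at_{f:g}N"] = d
        row["div_final"] = res.divergence
        rows.append(row)
    return rows
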