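"""Force evaluation and Langevin dynamics for mixed rigid/flexible systems.

Flexible beads follow underdamped Langevin dynamics integrated with a
BAOAB splitting; rigid groups are advanced as bodies (centre-of-mass
translation plus quaternion rotation driven by the aggregated force and
torque) with the same friction/noise structure on both translational and
rotational degrees of freedom. The damping parameter is a relaxation time:
friction γ_i = m_i / damping_time for every degree of freedom.

Forces come from a Verlet neighbour list (skin buffer, periodic rebuilds plus
a displacement safety check) and are the exact negative gradient of the
truncated potential, so neighbour-list and direct O(N²) sums agree to
round-off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import forcefield as ff
from . import topology as topo_mod
from .constants import E2M, KB

logger = logging.getLogger(__name__)

__all__ = [
    "IntegratorParams",
    "EnergyReport",
    "NeighborList",
    "SimulationState",
    "Trajectory",
    "ForceField",
    "initialize_state",
    "compute_forces",
    "langevin_step",
    "run",
    "nve_run",
    "kinetic_temperature",
]

_RT26 = 2.0 ** (1.0 / 6.0)


@dataclass
class ForceField:
    """Parameter set plus scaled pair table, as used by the engine."""

    params: ff.ForceFieldParams
    table: ff.PairPotentialTable

    @classmethod
    def default(cls, params: ff.ForceFieldParams | None = None) -> "ForceField":
        params = params or ff.ForceFieldParams()
        return cls(params, ff.default_pair_table(params))


@dataclass
class IntegratorParams:
    dt: float = 10.0  # fs
    damping_time: float = 1000.0  # fs
    temperature: float = 300.0  # K
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.damping_time <= 0:
            raise ValueError("dt and damping_time must be positive")


@dataclass
class EnergyReport:
    bond: float
    vdw: float
    elec: float

    @property
    def total(self) -> float:
        return self.bond + self.vdw + self.elec


# ---------------------------------------------------------------------------
# quaternions (scalar-first, unit)

def _quat_mul(a, b):
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def _quat_from_rotvec(v):
    angle = np.linalg.norm(v)
    if angle < 1e-12:
        return np.array([1.0, 0.5 * v[0], 0.5 * v[1], 0.5 * v[2]]) / np.sqrt(
            1.0 + 0.25 * angle * angle
        )
    axis = v / angle
    s = np.sin(0.5 * angle)
    return np.array([np.cos(0.5 * angle), s * axis[0], s * axis[1], s * axis[2]])


def _quat_to_matrix(q):
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


# ---------------------------------------------------------------------------
# state

@dataclass
class _BodyData:
    """Immutable per-group integration data (principal frame)."""

    gid: int
    members: np.ndarray
    masses: np.ndarray  # scaled by 1/mass_scale
    total_mass: float
    inertia: np.ndarray  # principal moments (3,), scaled
    ref_coords: np.ndarray  # (n, 3) in the principal body frame
    static: bool


@dataclass
class _BodyState:
    com: np.ndarray
    quat: np.ndarray
    vel: np.ndarray
    omega: np.ndarray  # angular velocity, body (principal) frame
    R: np.ndarray = None  # cached rotation matrix of quat

    def refresh_rotation(self) -> None:
        self.R = _quat_to_matrix(self.quat)


@dataclass
class SimulationState:
    positions: np.ndarray
    velocities: np.ndarray  # meaningful for flexible beads only
    bodies: dict  # gid -> _BodyState
    body_data: dict  # gid -> _BodyData
    step: int
    rng: np.random.Generator

    def sync_rigid_positions(self) -> None:
        """Recompute member world positions from each body transform."""
        for gid, bd in self.body_data.items():
            bs = self.bodies[gid]
            if bs.R is None:
                bs.refresh_rotation()
            self.positions[bd.members] = bs.com + bd.ref_coords @ bs.R.T

    def copy(self) -> "SimulationState":
        import copy as _copy

        return SimulationState(
            self.positions.copy(),
            self.velocities.copy(),
            {g: _BodyState(b.com.copy(), b.quat.copy(), b.vel.copy(),
                           b.omega.copy(), None if b.R is None else b.R.copy())
             for g, b in self.bodies.items()},
            self.body_data,
            self.step,
            _copy.deepcopy(self.rng),
        )


def _make_body_data(topology: topo_mod.SystemTopology, gid: int) -> _BodyData:
    g = topology.rigid_groups[gid]
    members = np.asarray(g.members, dtype=int)
    m = topology.masses[members] / g.mass_scale
    M = float(m.sum())
    x = topology.positions[members]
    com = (m[:, None] * x).sum(0) / M
    X = x - com
    inertia_t = np.einsum("i,ij,ik->jk", m, X, X)
    inertia_t = np.trace(inertia_t) * np.eye(3) - inertia_t
    w, P = np.linalg.eigh(inertia_t)
    if np.linalg.det(P) < 0:
        P[:, 0] = -P[:, 0]
    w = np.maximum(w, 1e-6)  # guard degenerate (near-linear) bodies
    return _BodyData(
        gid, members, m, M, w, X @ P, bool(g.static)
    )


def initialize_state(
    topology: topo_mod.SystemTopology,
    temperature: float | None = None,
    seed: int = 0,
) -> SimulationState:
    """Create a state at the topology coordinates.

    With a ``temperature``, flexible-bead velocities and rigid-body
    translational/angular velocities are drawn from the Maxwell–Boltzmann
    distribution; otherwise everything starts at rest.
    """
    rng = np.random.default_rng(seed)
    n = topology.n_beads
    velocities = np.zeros((n, 3))
    body_data = {gid: _make_body_data(topology, gid) for gid in topology.rigid_groups}
    bodies = {}
    for gid, bd in body_data.items():
        x = topology.positions[bd.members]
        com = (bd.masses[:, None] * x).sum(0) / bd.total_mass
        R0 = np.linalg.lstsq(bd.ref_coords, x - com, rcond=None)[0].T
        # ref_coords were built from these very coordinates, so R0 is the
        # principal-axis matrix; re-orthogonalise for safety
        u, _, vt = np.linalg.svd(R0)
        R0 = u @ vt
        from scipy.spatial.transform import Rotation

        qxyzw = Rotation.from_matrix(R0).as_quat()
        quat = np.array([qxyzw[3], qxyzw[0], qxyzw[1], qxyzw[2]])
        bodies[gid] = _BodyState(com, quat, np.zeros(3), np.zeros(3))
    state = SimulationState(
        topology.positions.copy(), velocities, bodies, body_data, 0, rng
    )
    if temperature is not None and temperature > 0:
        kt = KB * temperature * E2M
        flex = topology.flexible_indices()
        state.velocities[flex] = rng.normal(
            0.0, np.sqrt(kt / topology.masses[flex])[:, None], (len(flex), 3)
        )
        for gid, bd in body_data.items():
            if bd.static:
                continue
            bodies[gid].vel = rng.normal(0.0, np.sqrt(kt / bd.total_mass), 3)
            bodies[gid].omega = rng.normal(0.0, np.sqrt(kt / bd.inertia), 3)
    state.sync_rigid_positions()
    return state


# ---------------------------------------------------------------------------
# neighbour list and forces

class NeighborList:
    """Verlet list with a skin buffer.

    Rebuilt every ``rebuild_interval`` steps, and immediately if any bead has
    moved more than skin/2 since the last build (which would invalidate the
    completeness guarantee).
    """

    def __init__(
        self,
        topology: topo_mod.SystemTopology,
        ffield: ForceField,
        skin: float = 4.0,
        rebuild_interval: int = 1000,
    ):
        self.topology = topology
        self.ffield = ffield
        self.skin = float(skin)
        self.rebuild_interval = int(rebuild_interval)
        n = topology.n_beads
        self._excl = np.zeros((n, n), dtype=bool)
        for i, j in topology.exclusions:
            self._excl[i, j] = self._excl[j, i] = True
        # pairwise ε and σ: table lookup, with capping beads purely repulsive
        t = topology.type_index
        eps = np.empty((n, n))
        normal = t >= 0
        tt = np.where(normal, t, 0)
        eps[:] = ffield.table.epsilon[np.ix_(tt, tt)]
        cap = ~normal
        cap_pair = cap[:, None] | cap[None, :]
        eps[cap_pair] = topology.cap_epsilon
        self._eps_full = eps
        self._sig_full = 0.5 * (topology.sigmas[:, None] + topology.sigmas[None, :])
        self._qq_full = topology.charges[:, None] * topology.charges[None, :]
        fp = ffield.params
        rc_lj = fp.lj_cutoff_factor * self._sig_full
        rc_el = np.where(self._qq_full != 0.0, fp.elec_cutoff, 0.0)
        self._rc_full = np.maximum(rc_lj, rc_el)
        self._ref_positions = None
        self.pairs_i = self.pairs_j = None

    def build(self, positions: np.ndarray) -> None:
        box = self.topology.box
        periodic = self.topology.periodic
        d = positions[:, None, :] - positions[None, :, :]
        if periodic:
            d -= box * np.round(d / box)
        r2 = np.einsum("ijk,ijk->ij", d, d)
        within = r2 <= (self._rc_full + self.skin) ** 2
        iu, ju = np.triu_indices(len(positions), k=1)
        keep = within[iu, ju] & ~self._excl[iu, ju]
        i, j = iu[keep], ju[keep]
        self.pairs_i, self.pairs_j = i, j
        self.eps = self._eps_full[i, j]
        self.sigma = self._sig_full[i, j]
        self.qq = self._qq_full[i, j]
        self.lj_cut = self.ffield.params.lj_cutoff_factor * self.sigma
        self.attractive = self.eps < 0
        self.repulsive = self.eps > 0
        self.charged = self.qq != 0.0
        self._ref_positions = positions.copy()

    def stale(self, positions: np.ndarray) -> bool:
        if self._ref_positions is None:
            return True
        disp = positions - self._ref_positions
        return bool(np.any(np.einsum("ij,ij->i", disp, disp) > (0.5 * self.skin) ** 2))


def compute_forces(
    topology: topo_mod.SystemTopology,
    state: SimulationState,
    ffield: ForceField,
    nlist: NeighborList,
):
    """Forces (kcal/(mol·Å)) and decomposed energies for the current positions.

    Excluded pairs contribute nothing; the minimum-image convention is applied
    in periodic boxes; truncation is plain (no shift) at 3σ_ij / 35 Å.
    """
    pos = state.positions
    fp = ffield.params
    forces = np.zeros_like(pos)
    i, j = nlist.pairs_i, nlist.pairs_j
    e_vdw = e_el = 0.0
    if len(i):
        d = pos[i] - pos[j]
        if topology.periodic:
            d -= topology.box * np.round(d / topology.box)
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        if state.step % 1000 == 0 and np.any(r < 0.1):
            logger.warning(
                "bead overlap: %d pair(s) closer than 0.1 Å at step %d",
                int(np.sum(r < 0.1)), state.step,
            )
        r = np.maximum(r, 1e-6)
        sr6 = (nlist.sigma / r) ** 6
        lj = 4.0 * (sr6 * sr6 - sr6)
        dlj = 4.0 * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
        eps = nlist.eps
        inside = r < _RT26 * nlist.sigma
        u = np.where(
            nlist.attractive,
            -eps * lj,
            np.where(
                nlist.repulsive,
                np.where(inside, eps * lj + 2.0 * eps, -eps * lj),
                0.0,
            ),
        )
        fr = np.where(
            nlist.attractive,
            eps * dlj,
            np.where(nlist.repulsive, np.where(inside, -eps * dlj, eps * dlj), 0.0),
        )
        beyond = r >= nlist.lj_cut
        u = np.where(beyond, 0.0, u)
        fr = np.where(beyond, 0.0, fr)
        e_vdw = float(u.sum())
        if np.any(nlist.charged):
            pref = fp.coulomb_constant / fp.dielectric
            ue = pref * nlist.qq / r * np.exp(-r / fp.debye_length)
            fe = ue * (1.0 / r + 1.0 / fp.debye_length)
            live = nlist.charged & (r < fp.elec_cutoff)
            ue = np.where(live, ue, 0.0)
            fe = np.where(live, fe, 0.0)
            e_el = float(ue.sum())
            fr = fr + fe
        fvec = (fr / r)[:, None] * d
        np.add.at(forces, i, fvec)
        np.add.at(forces, j, -fvec)
    e_bond = 0.0
    if len(topology.bonds):
        bi, bj = topology.bonds[:, 0], topology.bonds[:, 1]
        d = pos[bi] - pos[bj]
        if topology.periodic:
            d -= topology.box * np.round(d / topology.box)
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        k = 0.5 * topology.bond_k if fp.half_bond else topology.bond_k
        dr = r - topology.bond_r0
        e_bond = float((k * dr * dr).sum())
        fr = -2.0 * k * dr
        fvec = (fr / np.maximum(r, 1e-9))[:, None] * d
        np.add.at(forces, bi, fvec)
        np.add.at(forces, bj, -fvec)
    return forces, EnergyReport(e_bond, e_vdw, e_el)


# ---------------------------------------------------------------------------
# integration

def _body_kick(state, bd, bs, forces, half_dt):
    f = forces[bd.members]
    fnet = f.sum(0)
    arm = state.positions[bd.members] - bs.com
    ax, ay, az = arm[:, 0], arm[:, 1], arm[:, 2]
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
    tau_space = np.array([
        np.dot(ay, fz) - np.dot(az, fy),
        np.dot(az, fx) - np.dot(ax, fz),
        np.dot(ax, fy) - np.dot(ay, fx),
    ])
    tau_body = bs.R.T @ tau_space
    bs.vel = bs.vel + half_dt * fnet * (E2M / bd.total_mass)
    w, iw = bs.omega, bd.inertia * bs.omega
    gyro = np.array([
        w[1] * iw[2] - w[2] * iw[1],
        w[2] * iw[0] - w[0] * iw[2],
        w[0] * iw[1] - w[1] * iw[0],
    ])
    bs.omega = bs.omega + half_dt * (tau_body * E2M - gyro) / bd.inertia


def langevin_step(
    topology: topo_mod.SystemTopology,
    state: SimulationState,
    ffield: ForceField,
    params: IntegratorParams,
    nlist: NeighborList,
    forces: np.ndarray,
    thermostat: bool = True,
):
    """Advance one BAOAB step; returns the forces at the new positions.

    With ``thermostat=False`` the O sub-step is skipped and the scheme
    reduces to velocity Verlet (NVE limit).
    """
    dt = params.dt
    half = 0.5 * dt
    flex = topology.flexible_indices()
    have_flex = len(flex) > 0
    m_flex = topology.masses[flex][:, None] if have_flex else None
    mobile = [
        (bd, state.bodies[gid])
        for gid, bd in state.body_data.items()
        if not bd.static
    ]

    # B (half kick)
    if have_flex:
        state.velocities[flex] += half * forces[flex] * E2M / m_flex
    for bd, bs in mobile:
        _body_kick(state, bd, bs, forces, half)

    def drift(h):
        if have_flex:
            state.positions[flex] += h * state.velocities[flex]
        for bd, bs in mobile:
            bs.com = bs.com + h * bs.vel
            dq = _quat_from_rotvec(bs.omega * h)
            bs.quat = _quat_mul(bs.quat, dq)
            bs.quat /= np.sqrt(bs.quat @ bs.quat)
            bs.refresh_rotation()

    if thermostat:
        drift(half)
        # O (Ornstein–Uhlenbeck); γ/m = 1/damping_time for every dof
        c1 = np.exp(-dt / params.damping_time)
        c2 = np.sqrt(1.0 - c1 * c1)
        kt = KB * params.temperature * E2M
        rng = state.rng
        if have_flex:
            state.velocities[flex] = c1 * state.velocities[flex] + c2 * np.sqrt(
                kt / m_flex
            ) * rng.standard_normal((len(flex), 3))
        for bd, bs in mobile:
            xi = rng.standard_normal(6)
            bs.vel = c1 * bs.vel + c2 * np.sqrt(kt / bd.total_mass) * xi[:3]
            bs.omega = c1 * bs.omega + c2 * np.sqrt(kt / bd.inertia) * xi[3:]
        drift(half)
    else:
        drift(dt)
    state.sync_rigid_positions()
    state.step += 1

    if state.step % nlist.rebuild_interval == 0 or nlist.stale(state.positions):
        nlist.build(state.positions)
    new_forces, report = compute_forces(topology, state, ffield, nlist)

    # B (half kick with new forces)
    if have_flex:
        state.velocities[flex] += half * new_forces[flex] * E2M / m_flex
    for bd, bs in mobile:
        _body_kick(state, bd, bs, new_forces, half)
    return new_forces, report


def kinetic_temperature(topology, state) -> float:
    """Instantaneous kinetic temperature (K) over all mobile degrees of freedom."""
    flex = topology.flexible_indices()
    ke = 0.5 * float(
        np.sum(topology.masses[flex][:, None] * state.velocities[flex] ** 2)
    )
    ndof = 3 * len(flex)
    for gid, bd in state.body_data.items():
        if bd.static:
            continue
        bs = state.bodies[gid]
        ke += 0.5 * bd.total_mass * float(bs.vel @ bs.vel)
        ke += 0.5 * float(bd.inertia @ (bs.omega * bs.omega))
        ndof += 6
    if ndof == 0:
        return 0.0
    return 2.0 * (ke / E2M) / (KB * ndof)


@dataclass
class Trajectory:
    steps: list = field(default_factory=list)
    frames: list = field(default_factory=list)  # (n_beads, 3) copies
    energies: list = field(default_factory=list)  # EnergyReport per frame
    temperatures: list = field(default_factory=list)

    def append(self, step, positions, report, temp):
        self.steps.append(step)
        self.frames.append(positions.copy())
        self.energies.append(report)
        self.temperatures.append(temp)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def write_xyz(self, path, codes) -> None:
        with open(path, "w") as fh:
            for step, frame in zip(self.steps, self.frames):
                fh.write(f"{len(frame)}\nstep {step}\n")
                for c, (x, y, z) in zip(codes, frame):
                    fh.write(f"{c} {x:.4f} {y:.4f} {z:.4f}\n")

    def write_energy_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("step,T_kinetic,bond,vdw,elec,total\n")
            for step, rep, t in zip(self.steps, self.energies, self.temperatures):
                fh.write(
                    f"{step},{t:.4f},{rep.bond:.6f},{rep.vdw:.6f},"
                    f"{rep.elec:.6f},{rep.total:.6f}\n"
                )

    def write_dcd(self, path) -> None:
        """Write frames in DCD format (via mdtraj, imported lazily)."""
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(path), "w") as fh:
            for frame in self.frames:
                fh.write(np.asarray(frame, dtype=np.float32))


def run(
    topology: topo_mod.SystemTopology,
    state: SimulationState,
    ffield: ForceField,
    params: IntegratorParams,
    nsteps: int,
    cadence: int = 100,
    thermostat: bool = True,
    nlist: NeighborList | None = None,
    skin: float = 4.0,
    rebuild_interval: int = 1000,
) -> Trajectory:
    """Integrate ``nsteps`` of Langevin dynamics, recording every ``cadence`` steps.

    The initial frame is always recorded; output is reproducible bit-for-bit
    from the state's RNG. Aborts with a diagnostic on non-finite positions.
    """
    if nlist is None:
        nlist = NeighborList(topology, ffield, skin, rebuild_interval)
    if nlist.stale(state.positions):
        nlist.build(state.positions)
    forces, report = compute_forces(topology, state, ffield, nlist)
    traj = Trajectory()
    traj.append(state.step, state.positions, report, kinetic_temperature(topology, state))
    for n in range(nsteps):
        forces, report = langevin_step(
            topology, state, ffield, params, nlist, forces, thermostat
        )
        if (n + 1) % cadence == 0 or n + 1 == nsteps:
            if not np.all(np.isfinite(state.positions)):
                raise FloatingPointError(
                    f"non-finite positions at step {state.step}; last energies: "
                    f"{report}"
                )
            traj.append(
                state.step, state.positions, report,
                kinetic_temperature(topology, state),
            )
    return traj


def nve_run(
    topology: topo_mod.SystemTopology,
    state: SimulationState,
    ffield: ForceField,
    params: IntegratorParams,
    nsteps: int,
    cadence: int = 100,
) -> Trajectory:
    """Velocity-Verlet run with the thermostat off (validation mode)."""
    return run(topology, state, ffield, params, nsteps, cadence, thermostat=False)
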