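"""Temperature replica exchange.

A ladder of temperatures (geometrically spaced by default) is populated with
one replica each; dynamics advances all replicas between exchange sweeps, and
neighbouring rungs attempt Metropolis configuration swaps with probability
min(1, exp[(β_i − β_j)(E_i − E_j)]). On acceptance the configurations change
rungs and all velocities are rescaled by sqrt(T_new/T_old). Sweeps alternate
even (0-1, 2-3, …) and odd (1-2, 3-4, …) neighbour pairings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dynamics as dyn
from .constants import KB

__all__ = [
    "Ladder",
    "ReplicaSet",
    "RemdResult",
    "geometric_ladder",
    "exchange_attempt",
    "run_remd",
    "dwell_time_distribution",
]


@dataclass
class Ladder:
    temperatures: np.ndarray  # K, strictly ascending

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if len(t) < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        self.temperatures = t

    @property
    def n_rungs(self) -> int:
        return len(self.temperatures)


def geometric_ladder(tmin: float = 180.0, tmax: float = 540.0, n: int = 28) -> Ladder:
    """T_k = tmin·(tmax/tmin)^(k/(n−1)); endpoints exact.

    Defaults give the 28-rung 180–540 K production ladder.
    """
    if n < 2:
        raise ValueError("need at least 2 rungs")
    if not (tmax > tmin > 0):
        raise ValueError("require tmax > tmin > 0")
    k = np.arange(n)
    t = tmin * (tmax / tmin) ** (k / (n - 1))
    t[0], t[-1] = tmin, tmax
    return Ladder(t)


def exchange_attempt(
    e_i: float, e_j: float, t_i: float, t_j: float, rng: np.random.Generator
) -> bool:
    """Metropolis decision for swapping the configurations at rungs i and j."""
    beta_i, beta_j = 1.0 / (KB * t_i), 1.0 / (KB * t_j)
    log_p = (beta_i - beta_j) * (e_i - e_j)
    if log_p >= 0:
        return True
    return bool(rng.random() < np.exp(log_p))


def _rescale_velocities(state: dyn.SimulationState, factor: float) -> None:
    state.velocities *= factor
    for bs in state.bodies.values():
        bs.vel = bs.vel * factor
        bs.omega = bs.omega * factor


@dataclass
class ReplicaSet:
    """One simulation state per rung plus replica/rung bookkeeping."""

    ladder: Ladder
    states: list  # index = rung; states[k] currently simulated at T_k
    replica_at_rung: np.ndarray  # rung -> replica id (permutation)
    exchange_interval: int = 100
    attempts: np.ndarray = None  # per neighbour pair (n_rungs-1,)
    accepts: np.ndarray = None

    def __post_init__(self) -> None:
        n = self.ladder.n_rungs
        if len(self.states) != n:
            raise ValueError("one state per rung required")
        if self.attempts is None:
            self.attempts = np.zeros(n - 1, dtype=int)
        if self.accepts is None:
            self.accepts = np.zeros(n - 1, dtype=int)

    @classmethod
    def create(
        cls,
        topology,
        ladder: Ladder,
        seed: int = 0,
        exchange_interval: int = 100,
    ) -> "ReplicaSet":
        states = [
            dyn.initialize_state(topology, t, seed=seed + 1000 + k)
            for k, t in enumerate(ladder.temperatures)
        ]
        return cls(ladder, states, np.arange(ladder.n_rungs), exchange_interval)


@dataclass
class RemdResult:
    ladder: Ladder
    trajectories: list  # per rung Trajectory (frames recorded at that rung)
    frame_replica: list  # per rung: replica id that produced each frame
    trace: np.ndarray  # (n_sweeps+1, n_replicas): rung index of each replica
    attempts: np.ndarray
    accepts: np.ndarray

    @property
    def acceptance_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.attempts > 0, self.accepts / self.attempts, np.nan)


def run_remd(
    topology,
    replicas: ReplicaSet,
    ffield: dyn.ForceField,
    nsteps: int,
    dt: float = 10.0,
    damping_time: float = 1000.0,
    seed: int = 0,
    cadence: int | None = None,
    skin: float = 4.0,
    rebuild_interval: int = 1000,
) -> RemdResult:
    """Run replica exchange for ``nsteps`` dynamics steps per replica.

    One frame and energy record is taken per rung at the end of every
    exchange interval (or every ``cadence`` steps if given). The swap stream
    is a dedicated RNG, so per-replica dynamics streams are untouched by the
    exchange pattern. Deterministic per seed.
    """
    ladder = replicas.ladder
    n_rungs = ladder.n_rungs
    swap_rng = np.random.default_rng(seed + 777)
    interval = replicas.exchange_interval
    cadence = cadence or interval
    n_sweeps = nsteps // interval
    nlists = [
        dyn.NeighborList(topology, ffield, skin, rebuild_interval)
        for _ in range(n_rungs)
    ]
    trajectories = [dyn.Trajectory() for _ in range(n_rungs)]
    frame_replica = [[] for _ in range(n_rungs)]
    trace = np.zeros((n_sweeps + 1, n_rungs), dtype=int)
    rung_of_replica = np.empty(n_rungs, dtype=int)
    rung_of_replica[replicas.replica_at_rung] = np.arange(n_rungs)
    trace[0] = rung_of_replica

    for sweep in range(max(n_sweeps, 1)):
        if n_sweeps == 0:
            break
        energies = np.empty(n_rungs)
        for k in range(n_rungs):
            params = dyn.IntegratorParams(
                dt=dt, damping_time=damping_time,
                temperature=float(ladder.temperatures[k]), seed=0,
            )
            state = replicas.states[k]
            nl = nlists[k]
            if nl.stale(state.positions):
                nl.build(state.positions)
            forces, report = dyn.compute_forces(topology, state, ffield, nl)
            for s in range(interval):
                forces, report = dyn.langevin_step(
                    topology, state, ffield, params, nl, forces
                )
                if (s + 1) % cadence == 0:
                    trajectories[k].append(
                        state.step, state.positions, report,
                        dyn.kinetic_temperature(topology, state),
                    )
                    frame_replica[k].append(int(replicas.replica_at_rung[k]))
            energies[k] = report.total
        # alternate even/odd neighbour pairings
        start = sweep % 2
        for k in range(start, n_rungs - 1, 2):
            replicas.attempts[k] += 1
            t_lo, t_hi = ladder.temperatures[k], ladder.temperatures[k + 1]
            if exchange_attempt(energies[k], energies[k + 1], t_lo, t_hi, swap_rng):
                replicas.accepts[k] += 1
                s_lo, s_hi = replicas.states[k], replicas.states[k + 1]
                _rescale_velocities(s_lo, np.sqrt(t_hi / t_lo))
                _rescale_velocities(s_hi, np.sqrt(t_lo / t_hi))
                replicas.states[k], replicas.states[k + 1] = s_hi, s_lo
                nlists[k].build(replicas.states[k].positions)
                nlists[k + 1].build(replicas.states[k + 1].positions)
                energies[k], energies[k + 1] = energies[k + 1], energies[k]
                replicas.replica_at_rung[[k, k + 1]] = replicas.replica_at_rung[
                    [k + 1, k]
                ]
        rung_of_replica[replicas.replica_at_rung] = np.arange(n_rungs)
        trace[sweep + 1] = rung_of_replica

    return RemdResult(
        ladder, trajectories, frame_replica, trace,
        replicas.attempts.copy(), replicas.accepts.copy(),
    )


def dwell_time_distribution(trace: np.ndarray) -> dict:
    """Histogram of consecutive exchange attempts each replica dwells at a rung.

    ``trace`` has one row per attempt sweep and one column per replica (values
    are rung indices). Returns {rung: {dwell_length: count}}. The dwell
    segments of each replica partition its trace, so the total dwell equals
    the trace length.
    """
    trace = np.asarray(trace)
    if trace.size == 0:
        raise ValueError("empty replica trace")
    if trace.ndim == 1:
        trace = trace[:, None]
    out: dict = {}
    for rep in range(trace.shape[1]):
        seq = trace[:, rep]
        start = 0
        for t in range(1, len(seq) + 1):
            if t == len(seq) or seq[t] != seq[start]:
                rung = int(seq[start])
                length = t - start
                out.setdefault(rung, {})
                out[rung][length] = out[rung].get(length, 0) + 1
                start = t
    return out
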