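"""Force correctness, integrator behaviour, and thermostat statistics."""

import numpy as np
import pytest

from cgbind import dynamics as dyn
from cgbind import forcefield as ff
from cgbind import topology as tp
from cgbind.constants import E2M, KB

from conftest import chain_structure, harmonic_trap_topology, rigid_tribead_topology


def random_cluster(n, box=60.0, seed=0, codes="LKESGDAVRF", step=3.81):
    """Flexible chain on a clash-free random walk, mixed residue types."""
    rng = np.random.default_rng(seed)
    coords = [np.full(3, box / 2)]
    while len(coords) < n:
        v = rng.normal(size=3)
        cand = coords[-1] + step * v / np.linalg.norm(v)
        if all(np.linalg.norm(cand - p) > 3.5 for p in coords[:-1]):
            coords.append(cand)
    seq = "".join(codes[i % len(codes)] for i in range(n))
    return tp.build_system(chain_structure(seq, coords), {}, [f"A:1-{n}"], box=box)


def brute_force_energy(topology, positions, ffield):
    """Independent O(N²) direct sum over all non-excluded pairs."""
    fp = ffield.params
    total_vdw = total_el = 0.0
    n = topology.n_beads
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in topology.exclusions:
                continue
            d = positions[i] - positions[j]
            if topology.periodic:
                d = d - topology.box * np.round(d / topology.box)
            r = float(np.linalg.norm(d))
            ti, tj = topology.type_index[i], topology.type_index[j]
            if ti < 0 or tj < 0:
                eps = topology.cap_epsilon
            else:
                eps = ffield.table.epsilon[ti, tj]
            sig = 0.5 * (topology.sigmas[i] + topology.sigmas[j])
            total_vdw += ff.pair_energy(r, eps, sig, fp)
            qq = topology.charges[i] * topology.charges[j]
            if qq != 0.0:
                total_el += ff.electrostatic_energy(
                    r, topology.charges[i], topology.charges[j], fp
                )
    total_bond = 0.0
    for (i, j), r0, k in zip(topology.bonds, topology.bond_r0, topology.bond_k):
        r = float(np.linalg.norm(positions[i] - positions[j]))
        kk = 0.5 * k if fp.half_bond else k
        total_bond += kk * (r - r0) ** 2
    return total_bond, total_vdw, total_el


class TestForces:
    def test_matches_brute_force_oracle(self, ffield):
        topo = random_cluster(50, seed=11)
        state = dyn.initialize_state(topo)
        nl = dyn.NeighborList(topo, ffield)
        nl.build(state.positions)
        _, rep = dyn.compute_forces(topo, state, ffield, nl)
        b, v, e = brute_force_energy(topo, state.positions, ffield)
        assert rep.bond == pytest.approx(b, abs=1e-10)
        assert rep.vdw == pytest.approx(v, abs=1e-10)
        assert rep.elec == pytest.approx(e, abs=1e-10)
        assert rep.total == pytest.approx(b + v + e, abs=1e-10)

    def test_neighbor_list_equals_brute_force_through_rebuilds(self, ffield):
        """The skin contract: list energies stay exact between rebuilds."""
        topo = random_cluster(30, seed=4)
        state = dyn.initialize_state(topo, 300.0, seed=4)
        params = dyn.IntegratorParams(dt=10.0, temperature=300.0, seed=4)
        traj = dyn.run(
            topo, state, ffield, params, 300, cadence=30, rebuild_interval=100
        )
        for frame, rep in zip(traj.frames, traj.energies):
            b, v, e = brute_force_energy(topo, frame, ffield)
            assert rep.total == pytest.approx(b + v + e, abs=1e-10)

    def test_forces_are_exact_gradient(self, ffield):
        topo = random_cluster(12, seed=2)
        state = dyn.initialize_state(topo)
        nl = dyn.NeighborList(topo, ffield)
        nl.build(state.positions)
        forces, _ = dyn.compute_forces(topo, state, ffield, nl)
        h = 1e-6
        rng = np.random.default_rng(0)
        for _ in range(6):
            i = rng.integers(12)
            ax = rng.integers(3)
            for sgn, store in ((1, "up"), (-1, "dn")):
                state.positions[i, ax] += sgn * h
                _, rep = dyn.compute_forces(topo, state, ffield, nl)
                state.positions[i, ax] -= sgn * h
                if store == "up":
                    e_up = rep.total
                else:
                    e_dn = rep.total
            fd = -(e_up - e_dn) / (2 * h)
            assert forces[i, ax] == pytest.approx(fd, rel=1e-5, abs=1e-5)

    def test_beads_beyond_cutoffs_do_not_interact(self, ffield):
        s1 = chain_structure("K", [[10.0, 10, 10]], chain="A")
        s2 = chain_structure("K", [[50.0, 10, 10]], chain="B")
        structure = tp.CalphaStructure({**s1.chains, **s2.chains}, [])
        topo = tp.build_system(
            structure, {}, ["A:1-1", "B:1-1"], box=200.0
        )
        state = dyn.initialize_state(topo)
        nl = dyn.NeighborList(topo, ffield)
        nl.build(state.positions)
        forces, rep = dyn.compute_forces(topo, state, ffield, nl)
        assert rep.total == 0.0
        assert np.all(forces == 0.0)

    def test_newtons_third_law(self, ffield, dimer_topology):
        state = dyn.initialize_state(dimer_topology)
        state.positions[1, 2] += 0.5  # stretch the bond
        nl = dyn.NeighborList(dimer_topology, ffield)
        nl.build(state.positions)
        forces, _ = dyn.compute_forces(dimer_topology, state, ffield, nl)
        assert np.allclose(forces.sum(0), 0.0, atol=1e-12)


class TestIntegrator:
    def test_zero_temperature_rest_state_is_fixed_point(self, ffield, dimer_topology):
        state = dyn.initialize_state(dimer_topology)  # at bond minimum, v = 0
        params = dyn.IntegratorParams(temperature=0.0, seed=0)
        x0 = state.positions.copy()
        traj = dyn.run(dimer_topology, state, ffield, params, 50, cadence=10)
        assert np.allclose(traj.frames[-1], x0, atol=1e-12)

    def test_zero_steps_logs_initial_energy(self, ffield, dimer_topology):
        state = dyn.initialize_state(dimer_topology)
        params = dyn.IntegratorParams(seed=0)
        traj = dyn.run(dimer_topology, state, ffield, params, 0)
        assert traj.n_frames == 1
        assert traj.energies[0].total == pytest.approx(0.0)

    def test_same_seed_is_bit_identical(self, ffield, dimer_topology):
        logs = []
        for _ in range(2):
            state = dyn.initialize_state(dimer_topology, 200.0, seed=9)
            params = dyn.IntegratorParams(temperature=200.0, seed=9)
            traj = dyn.run(dimer_topology, state, ffield, params, 500, cadence=50)
            logs.append([rep.total for rep in traj.energies])
        assert logs[0] == logs[1]

    def test_rigid_body_internal_distances_conserved(self, ffield):
        topo = rigid_tribead_topology()
        state = dyn.initialize_state(topo, 300.0, seed=1)
        params = dyn.IntegratorParams(temperature=300.0, seed=1)
        d0 = [np.linalg.norm(state.positions[a] - state.positions[b])
              for a, b in ((0, 1), (0, 2), (1, 2))]
        traj = dyn.run(topo, state, ffield, params, 5000, cadence=1000)
        for frame in traj.frames:
            for (a, b), ref in zip(((0, 1), (0, 2), (1, 2)), d0):
                assert np.linalg.norm(frame[a] - frame[b]) == pytest.approx(
                    ref, abs=1e-8
                )

    def test_kinetic_temperature_tracks_thermostat(self, ffield):
        topo = random_cluster(10, seed=6)
        state = dyn.initialize_state(topo, 300.0, seed=6)
        params = dyn.IntegratorParams(dt=10.0, temperature=300.0, seed=6)
        traj = dyn.run(topo, state, ffield, params, 200_000, cadence=200)
        second_half = np.array(traj.temperatures[len(traj.temperatures) // 2 :])
        assert abs(second_half.mean() - 300.0) / 300.0 < 0.03

    def test_nan_positions_abort_with_diagnostic(self, ffield, dimer_topology):
        state = dyn.initialize_state(dimer_topology, 200.0, seed=0)
        state.positions[0, 0] = np.nan
        params = dyn.IntegratorParams(temperature=200.0, seed=0)
        with pytest.raises(FloatingPointError):
            dyn.run(dimer_topology, state, ffield, params, 10, cadence=1)


class TestNVE:
    def make_oscillator(self, amplitude=0.1):
        coords = [[25.0, 25, 25], [25.0, 25, 25 + 3.81 + amplitude]]
        topo = tp.build_system(chain_structure("GG", coords), {}, ["A:1-2"], box=50.0)
        return topo, dyn.initialize_state(topo)

    def total_energy(self, topo, traj_frames, velocities=None):
        pass

    def test_energy_conservation_two_bead_oscillator(self, ffield):
        topo, state = self.make_oscillator()
        params = dyn.IntegratorParams(dt=1.0, temperature=0.0, seed=0)
        nl = dyn.NeighborList(topo, ffield)
        nl.build(state.positions)
        energies = []
        forces, rep = dyn.compute_forces(topo, state, ffield, nl)
        for step in range(100_000):
            forces, rep = dyn.langevin_step(
                topo, state, ffield, params, nl, forces, thermostat=False
            )
            if step % 100 == 0:
                ke = 0.5 * np.sum(
                    topo.masses[:, None] * state.velocities**2
                ) / E2M
                energies.append(rep.total + ke)
        energies = np.array(energies)
        amplitude = 189.0 * 0.1**2  # potential-energy oscillation scale
        drift = abs(energies[-100:].mean() - energies[:100].mean())
        assert drift <= 1e-3 * amplitude

    def test_oscillator_period_matches_reduced_mass_formula(self, ffield):
        topo, state = self.make_oscillator()
        params = dyn.IntegratorParams(dt=1.0, temperature=0.0, seed=0)
        traj = dyn.nve_run(topo, state, ffield, params, 2000, cadence=1)
        r = np.array([np.linalg.norm(f[1] - f[0]) for f in traj.frames]) - 3.81
        # count mean-crossings to estimate the period
        crossings = np.flatnonzero(np.diff(np.sign(r)) != 0)
        periods = 2 * np.diff(crossings)
        mu = topo.masses[0] / 2.0
        expected = 2 * np.pi * np.sqrt(mu / (2 * 189.0 * E2M))
        assert np.mean(periods) * params.dt == pytest.approx(expected, rel=0.01)

    def test_equilibrium_stays_at_rest(self, ffield):
        topo, state = self.make_oscillator(amplitude=0.0)
        params = dyn.IntegratorParams(dt=1.0, temperature=0.0, seed=0)
        traj = dyn.nve_run(topo, state, ffield, params, 1000, cadence=100)
        assert np.allclose(traj.frames[-1], traj.frames[0], atol=1e-10)

    def test_linear_momentum_conserved_without_thermostat(self, ffield):
        topo = random_cluster(8, seed=3)
        state = dyn.initialize_state(topo, 300.0, seed=3)
        p0 = (topo.masses[:, None] * state.velocities).sum(0)
        params = dyn.IntegratorParams(dt=2.0, temperature=300.0, seed=3)
        dyn.nve_run(topo, state, ffield, params, 2000, cadence=500)
        p1 = (topo.masses[:, None] * state.velocities).sum(0)
        assert np.allclose(p0, p1, atol=1e-10)


class TestStatisticalMechanics:
    def test_harmonic_trap_equipartition(self, ffield):
        k_trap = 5.0
        topo = harmonic_trap_topology(k_trap)
        state = dyn.initialize_state(topo, 300.0, seed=12)
        params = dyn.IntegratorParams(dt=10.0, temperature=300.0, seed=12)
        nl = dyn.NeighborList(topo, ffield)
        nl.build(state.positions)
        forces, _ = dyn.compute_forces(topo, state, ffield, nl)
        samples = []
        center = topo.positions[0]
        for step in range(150_000):
            forces, _ = dyn.langevin_step(topo, state, ffield, params, nl, forces)
            if step >= 20_000 and step % 5 == 0:
                samples.append(state.positions[1] - center)
        var = np.asarray(samples).var(axis=0)
        expected = KB * 300.0 / (2 * k_trap)  # per-axis kT/(2K) for U = K·r²
        assert np.allclose(var, expected, rtol=0.10)

    def test_equilibrium_variance_invariant_to_mass_scaling(self, ffield):
        """Mass scaling speeds diffusion but must not move ensemble averages."""
        variances = []
        for scale in (1.0, 100.0):
            topo = rigid_tribead_topology(box=200.0)
            anchor = topo.positions.mean(0) + np.array([0, 0, 30.0])
            topo = tp.add_capping_beads(topo, [anchor], sigma_large=5.0)
            # tether the body to the static anchor with a soft spring
            topo.bonds = np.array([[0, 3]])
            topo.bond_r0 = np.array([30.0])
            topo.bond_k = np.array([0.5])
            topo.exclusions.add((0, 3))
            topo.chains[3] = topo.chains[0]
            tp.set_mass_scaling(topo, 0, scale)
            state = dyn.initialize_state(topo, 300.0, seed=21)
            params = dyn.IntegratorParams(dt=5.0, temperature=300.0, seed=21)
            nl = dyn.NeighborList(topo, ffield)
            nl.build(state.positions)
            forces, _ = dyn.compute_forces(topo, state, ffield, nl)
            rs = []
            for step in range(120_000):
                forces, _ = dyn.langevin_step(topo, state, ffield, params, nl, forces)
                if step >= 20_000 and step % 10 == 0:
                    rs.append(np.linalg.norm(state.positions[0] - anchor))
            variances.append(np.var(rs))
        expected = KB * 300.0 / (2 * 0.5)
        assert variances[0] == pytest.approx(expected, rel=0.15)
        assert variances[1] == pytest.approx(expected, rel=0.15)
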