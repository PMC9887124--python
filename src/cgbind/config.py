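"""Run configuration schema and file-format plumbing.

The config is a versioned, human-editable YAML document whose defaults are
the production protocol parameters (10 fs step, 1,000 fs damping, 1,000-step
neighbour rebuilds, 28-rung 180–540 K ladder with swaps every 100 steps,
300 Å box, 10 Å dRMS cutoff, 0.5 Å / 0.1 kcal/mol histogram bins), so any
deviation shows up as a diff against ``default_config()``.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import yaml

from . import forcefield as ff
from .topology import RigidGroup, SystemTopology

CONFIG_VERSION = 1


def default_config() -> dict:
    return {
        "version": CONFIG_VERSION,
        "structure": None,  # PDB path
        "rigid": {},  # group name -> ["A:1-50", ...]
        "flexible": [],  # ["A:51-60", ...]
        "box": 300.0,
        "periodic": True,
        "forcefield": dataclasses.asdict(ff.ForceFieldParams()),
        "integrator": {"dt": 10.0, "damping_time": 1000.0, "temperature": 180.0},
        "neighbor": {"skin": 4.0, "rebuild_interval": 1000},
        "remd": {"tmin": 180.0, "tmax": 540.0, "n_rungs": 28, "exchange_interval": 100},
        "analysis": {
            "reference": None,
            "components": {},  # label -> ["A:1-12", ...]
            "drms_cutoff": 10.0,
            "hist_width_drms": 0.5,
            "hist_width_energy": 0.1,
            "cadence": 10,
        },
        "run": {"nsteps": 100000, "cadence": 100},
        "seed": 0,
    }


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    _deep_update(cfg, user)
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def forcefield_params(cfg: dict) -> ff.ForceFieldParams:
    return ff.ForceFieldParams(**cfg["forcefield"])


# ---------------------------------------------------------------------------
# topology (de)serialisation — plain JSON

def topology_to_json(topo: SystemTopology) -> str:
    doc = {
        "codes": topo.codes,
        "chains": topo.chains,
        "resnums": topo.resnums.tolist(),
        "positions": topo.positions.tolist(),
        "mobility": topo.mobility.tolist(),
        "rigid_groups": [
            {"id": g.id, "members": g.members.tolist(),
             "mass_scale": g.mass_scale, "static": g.static}
            for g in topo.rigid_groups.values()
        ],
        "bonds": topo.bonds.tolist(),
        "bond_r0": topo.bond_r0.tolist(),
        "bond_k": topo.bond_k.tolist(),
        "box": topo.box,
        "periodic": topo.periodic,
        "cap_epsilon": topo.cap_epsilon,
        "cap_sigmas": [
            float(topo.sigmas[i]) for i in range(topo.n_beads)
            if topo.type_index[i] < 0
        ],
    }
    return json.dumps(doc)


def topology_from_json(text: str) -> SystemTopology:
    doc = json.loads(text)
    codes = doc["codes"]
    n = len(codes)
    sigmas = np.empty(n)
    masses = np.empty(n)
    charges = np.empty(n)
    types = np.empty(n, dtype=int)
    cap_sig = iter(doc.get("cap_sigmas", []))
    for i, c in enumerate(codes):
        if c == "X":
            sigmas[i] = next(cap_sig)
            masses[i], charges[i], types[i] = 1000.0, 0.0, -1
        else:
            p = ff.residue_params(c)
            sigmas[i], masses[i], charges[i] = p.sigma, p.mass, p.charge
            types[i] = ff.AMINO_ACIDS.index(c)
    groups = {
        g["id"]: RigidGroup(g["id"], np.array(g["members"], dtype=int),
                            g["mass_scale"], g["static"])
        for g in doc["rigid_groups"]
    }
    mobility = np.array(doc["mobility"], dtype=int)
    bonds = np.array(doc["bonds"], dtype=int).reshape(-1, 2)
    exclusions = {(min(i, j), max(i, j)) for i, j in bonds}
    for g in groups.values():
        mm = sorted(int(v) for v in g.members)
        for a in range(len(mm)):
            for b in range(a + 1, len(mm)):
                exclusions.add((mm[a], mm[b]))
    return SystemTopology(
        codes=codes, chains=doc["chains"],
        resnums=np.array(doc["resnums"], dtype=int),
        positions=np.array(doc["positions"], dtype=float),
        masses=masses, charges=charges, sigmas=sigmas, type_index=types,
        mobility=mobility, rigid_groups=groups, bonds=bonds,
        bond_r0=np.array(doc["bond_r0"]), bond_k=np.array(doc["bond_k"]),
        exclusions=exclusions, box=doc["box"], periodic=doc["periodic"],
        cap_epsilon=doc.get("cap_epsilon", 1.0),
    )


def read_xyz(path) -> list:
    """Read an XYZ-style trajectory back into a list of (n, 3) arrays."""
    frames = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            fh.readline()
            coords = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                coords[i] = [float(v) for v in parts[1:4]]
            frames.append(coords)
    return frames
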