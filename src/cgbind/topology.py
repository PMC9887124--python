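"""System construction: beads, rigid groups, flexible chains, bonds, exclusions.

A simulatable system is a set of Cα beads partitioned into rigid groups
(domains with known structure, moved as bodies, internal interactions
neglected) and flexible segments (bead-spring chains). Consecutive residues
of a chain are bonded unless both belong to the same rigid group, so
rigid–flexible junctions and flexible–flexible neighbours carry springs.
Bonded (1-2) pairs and all intra-rigid-group pairs are excluded from
non-bonded interactions.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import forcefield as ff

__all__ = [
    "Bead",
    "RigidGroup",
    "SystemTopology",
    "CalphaStructure",
    "Residue",
    "ReferenceConformation",
    "read_calpha_structure",
    "build_system",
    "kabsch_superpose",
    "make_reference",
    "add_capping_beads",
    "set_mass_scaling",
    "parse_selection",
]

FLEXIBLE = -1
STATIC = -2

#: type index used for capping beads (no amino-acid identity)
CAP_TYPE = -1


@dataclass(frozen=True)
class Bead:
    index: int
    code: str
    chain: str
    resnum: int
    position: np.ndarray
    mass: float
    mobility: object  # rigid-group id, "flexible", or "static"


@dataclass
class RigidGroup:
    """Beads moved together as one body; internal interactions neglected."""

    id: int
    members: np.ndarray
    mass_scale: float = 1.0
    static: bool = False


@dataclass(frozen=True)
class Residue:
    chain: str
    resnum: int
    icode: str
    code: str
    position: np.ndarray


@dataclass
class CalphaStructure:
    """Chains of residues with Cα coordinates, plus a missing-Cα report."""

    chains: dict  # chain id -> list[Residue], file order
    missing: list  # (chain, resnum, icode) of residues lacking a Cα

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())


@dataclass
class SystemTopology:
    """Everything static about a system: beads, bonds, groups, box."""

    codes: list
    chains: list
    resnums: np.ndarray
    positions: np.ndarray  # (N, 3) Å; initial coordinates
    masses: np.ndarray
    charges: np.ndarray
    sigmas: np.ndarray  # per-bead vdW diameter σ_i
    type_index: np.ndarray  # index into the 20×20 tables, CAP_TYPE for caps
    mobility: np.ndarray  # FLEXIBLE, STATIC, or rigid-group id
    rigid_groups: dict = field(default_factory=dict)
    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))
    bond_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bond_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    exclusions: set = field(default_factory=set)
    box: float = 300.0
    periodic: bool = True
    cap_epsilon: float = 1.0  # kcal/mol, repulsive strength of capping beads

    @property
    def n_beads(self) -> int:
        return len(self.codes)

    @property
    def beads(self) -> list:
        out = []
        for i in range(self.n_beads):
            m = self.mobility[i]
            mob = "flexible" if m == FLEXIBLE else "static" if m == STATIC else int(m)
            out.append(
                Bead(i, self.codes[i], self.chains[i], int(self.resnums[i]),
                     self.positions[i].copy(), float(self.masses[i]), mob)
            )
        return out

    def flexible_indices(self) -> np.ndarray:
        cache = getattr(self, "_flex_cache", None)
        if cache is None:
            cache = np.flatnonzero(self.mobility == FLEXIBLE)
            object.__setattr__(self, "_flex_cache", cache)
        return cache

    def validate(self) -> None:
        """Check structural invariants (bond-path structure, exclusions, groups)."""
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite bead positions")
        seen = np.zeros(self.n_beads, dtype=bool)
        for g in self.rigid_groups.values():
            if seen[g.members].any():
                raise ValueError("rigid groups share members")
            seen[g.members] = True
            if len(g.members) >= 3:
                x = self.positions[g.members] - self.positions[g.members].mean(0)
                if np.linalg.svd(x, compute_uv=False)[1] < 1e-8:
                    raise ValueError(f"rigid group {g.id} is collinear")
        # bond graph must be a union of simple paths
        deg = np.zeros(self.n_beads, dtype=int)
        for i, j in self.bonds:
            if self.chains[i] != self.chains[j]:
                raise ValueError("bond spans two chains")
            deg[i] += 1
            deg[j] += 1
        if np.any(deg > 2):
            raise ValueError("branched bond graph")
        for i, j in self.bonds:
            if (min(i, j), max(i, j)) not in self.exclusions:
                raise ValueError("bonded pair not excluded")
        for g in self.rigid_groups.values():
            mm = sorted(int(v) for v in g.members)
            for a in range(len(mm)):
                for b in range(a + 1, len(mm)):
                    if (mm[a], mm[b]) not in self.exclusions:
                        raise ValueError("intra-rigid pair not excluded")


@dataclass
class ReferenceConformation:
    """Bead positions of a reference complex, with per-component labels."""

    positions: np.ndarray  # (N, 3)
    components: dict  # label -> bead index array


# ---------------------------------------------------------------------------
# structure input

def read_calpha_structure(pdb_text: str) -> CalphaStructure:
    """Extract one bead per residue (its Cα) from PDB ATOM records.

    Residues that have atoms but no Cα are reported in ``missing``, never
    silently dropped. On altloc conflicts the first altloc is used (with a
    warning).
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(io.StringIO(pdb_text))
    try:
        atoms = pdb.get_structure(model=1, altloc="first", extra_fields=[])
    except Exception as exc:  # pragma: no cover - biotite message passthrough
        raise ValueError(f"could not parse PDB text: {exc}") from exc
    atoms = atoms[struc.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise ValueError("no protein ATOM records found")

    chains: dict = {}
    missing = []
    for res in struc.residue_iter(atoms):
        chain = str(res.chain_id[0])
        resnum = int(res.res_id[0])
        icode = str(res.ins_code[0]) if "ins_code" in res.get_annotation_categories() else ""
        ca = res[res.atom_name == "CA"]
        if ca.array_length() == 0:
            missing.append((chain, resnum, icode))
            continue
        if ca.array_length() > 1:
            warnings.warn(f"multiple CA altlocs at {chain}:{resnum}; using first")
        try:
            code = str(struc.info.one_letter_code(res.res_name[0]) or "G")
        except Exception:
            code = "G"
        if code not in ff.AMINO_ACIDS:
            code = "G"
        chains.setdefault(chain, []).append(
            Residue(chain, resnum, icode, code, np.asarray(ca.coord[0], dtype=float))
        )
    return CalphaStructure(chains, missing)


def parse_selection(sel: str) -> tuple[str, int, int]:
    """Parse a residue-range selection like ``"A:40-52"`` → (chain, lo, hi)."""
    chain, _, rng = sel.partition(":")
    if not rng:
        raise ValueError(f"bad selection {sel!r}; expected 'CHAIN:LO-HI'")
    lo, _, hi = rng.partition("-")
    return chain, int(lo), int(hi or lo)


def _normalise(selections):
    out = []
    for s in selections:
        out.append(parse_selection(s) if isinstance(s, str) else tuple(s))
    return out


# ---------------------------------------------------------------------------
# system construction

def build_system(
    structure: CalphaStructure,
    rigid_spec: dict | None = None,
    flexible_spec: list | None = None,
    box: float = 300.0,
    periodic: bool = True,
    params: ff.ForceFieldParams | None = None,
) -> SystemTopology:
    """Assemble a :class:`SystemTopology` from a Cα structure and a partition.

    ``rigid_spec`` maps group names to lists of residue-range selections;
    ``flexible_spec`` lists the flexible ranges. Together they must cover all
    residues disjointly. Bonds (r0, k from ``params``) join consecutive
    residues of each chain unless both ends sit in the same rigid group.
    """
    params = params or ff.ForceFieldParams()
    rigid_spec = {k: _normalise(v) for k, v in (rigid_spec or {}).items()}
    flexible_spec = _normalise(flexible_spec or [])

    codes, chains, resnums, pos = [], [], [], []
    assignment = []  # parallel: group name or None (flexible)
    order = []  # (chain, position-in-chain) for bonding
    for cid, residues in structure.chains.items():
        for k, res in enumerate(residues):
            group = None
            n_hits = 0
            for name, ranges in rigid_spec.items():
                if any(c == cid and lo <= res.resnum <= hi for c, lo, hi in ranges):
                    group = name
                    n_hits += 1
            flex = any(c == cid and lo <= res.resnum <= hi for c, lo, hi in flexible_spec)
            if n_hits + flex > 1:
                raise ValueError(
                    f"residue {cid}:{res.resnum} assigned to overlapping specs"
                )
            if n_hits + flex == 0:
                raise ValueError(
                    f"residue {cid}:{res.resnum} covered by neither rigid nor "
                    "flexible spec"
                )
            codes.append(res.code)
            chains.append(cid)
            resnums.append(res.resnum)
            pos.append(res.position)
            assignment.append(group)
            order.append((cid, k))

    n = len(codes)
    resnums = np.array(resnums, dtype=int)
    positions = np.array(pos, dtype=float)
    masses = np.array([ff._MASS[c] for c in codes])
    charges = np.array([ff.assign_charge(c) for c in codes])
    sigmas = np.array([ff._SIGMA[c] for c in codes])
    type_index = np.array([ff.AMINO_ACIDS.index(c) for c in codes], dtype=int)

    group_ids = {name: gid for gid, name in enumerate(sorted(rigid_spec))}
    mobility = np.array(
        [FLEXIBLE if a is None else group_ids[a] for a in assignment], dtype=int
    )
    rigid_groups = {
        gid: RigidGroup(gid, np.flatnonzero(mobility == gid))
        for gid in group_ids.values()
    }
    for name, gid in group_ids.items():
        if len(rigid_groups[gid].members) == 0:
            raise ValueError(f"rigid group {name!r} matches no residues")

    bonds, exclusions = [], set()
    for i in range(n - 1):
        for j in range(i + 1, n):
            ci, cj = order[i], order[j]
            if ci[0] == cj[0] and cj[1] == ci[1] + 1:
                same_rigid = (
                    mobility[i] >= 0 and mobility[i] == mobility[j]
                )
                if not same_rigid:
                    bonds.append((i, j))
                    exclusions.add((i, j))
    for g in rigid_groups.values():
        mm = sorted(int(v) for v in g.members)
        for a in range(len(mm)):
            for b in range(a + 1, len(mm)):
                exclusions.add((mm[a], mm[b]))

    bonds = np.array(bonds, dtype=int).reshape(-1, 2)
    topo = SystemTopology(
        codes=codes, chains=chains, resnums=resnums, positions=positions,
        masses=masses, charges=charges, sigmas=sigmas, type_index=type_index,
        mobility=mobility, rigid_groups=rigid_groups, bonds=bonds,
        bond_r0=np.full(len(bonds), params.bond_r0),
        bond_k=np.full(len(bonds), params.bond_k),
        exclusions=exclusions, box=float(box), periodic=periodic,
    )
    topo.validate()
    return topo


# ---------------------------------------------------------------------------
# superposition and references

def kabsch_superpose(mobile, target, correspondence=None):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    ``correspondence`` is an optional pair of index arrays (im, it) mapping
    mobile points onto target points; by default points correspond
    positionally. Returns ``(R, t, rmsd)`` with a proper rotation
    (det R = +1) such that ``mobile @ R.T + t`` best fits ``target``.
    """
    from scipy.spatial.transform import Rotation

    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if correspondence is not None:
        im, it = correspondence
        m, t = mobile[np.asarray(im)], target[np.asarray(it)]
    else:
        m, t = mobile, target
    if len(m) != len(t):
        raise ValueError("correspondence length mismatch")
    if len(m) < 3:
        raise ValueError("need at least 3 corresponding points")
    mc, tc = m - m.mean(0), t - t.mean(0)
    if np.linalg.svd(mc, compute_uv=False)[1] < 1e-8 * max(1.0, abs(mc).max()):
        raise ValueError("corresponding points are collinear")
    rot, _ = Rotation.align_vectors(tc, mc)
    R = rot.as_matrix()
    trans = t.mean(0) - R @ m.mean(0)
    resid = m @ R.T + trans - t
    rmsd = np.sqrt(np.einsum("ij,ij->", resid, resid) / len(m))
    return R, trans, float(rmsd)


def make_reference(
    topology: SystemTopology,
    components: dict,
    transforms: dict | None = None,
) -> ReferenceConformation:
    """Compose a reference complex by rigidly placing each component.

    ``components`` maps labels to bead-index arrays; ``transforms`` maps a
    (subset of) labels to ``(R, t)`` pairs taking that component's current
    coordinates into the complex frame. Unlisted components keep their
    coordinates.
    """
    transforms = transforms or {}
    for label in transforms:
        if label not in components:
            raise KeyError(f"component {label!r} not present in topology components")
    ref = topology.positions.copy()
    comps = {}
    for label, idx in components.items():
        idx = np.asarray(idx, dtype=int)
        comps[label] = idx
        if label in transforms:
            R, t = transforms[label]
            ref[idx] = ref[idx] @ np.asarray(R).T + np.asarray(t)
    return ReferenceConformation(ref, comps)


# ---------------------------------------------------------------------------
# special devices

def add_capping_beads(
    topology: SystemTopology, positions, sigma_large: float
) -> SystemTopology:
    """Append immobile, uncharged, purely repulsive beads of diameter σ_large.

    Used to block sticky filament ends: a cap interacts with every
    non-excluded bead through the repulsive-only pair form with strength
    ``topology.cap_epsilon``.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    if len(positions) == 0:
        return topology
    if sigma_large <= 0:
        raise ValueError("capping-bead σ must be positive")
    if not np.all(np.isfinite(positions)):
        raise ValueError("capping-bead positions must be finite")
    n_new = len(positions)
    topo = replace(
        topology,
        codes=topology.codes + ["X"] * n_new,
        chains=topology.chains + ["_cap"] * n_new,
        resnums=np.concatenate([topology.resnums, np.arange(1, n_new + 1)]),
        positions=np.vstack([topology.positions, positions]),
        masses=np.concatenate([topology.masses, np.full(n_new, 1000.0)]),
        charges=np.concatenate([topology.charges, np.zeros(n_new)]),
        sigmas=np.concatenate([topology.sigmas, np.full(n_new, sigma_large)]),
        type_index=np.concatenate(
            [topology.type_index, np.full(n_new, CAP_TYPE, dtype=int)]
        ),
        mobility=np.concatenate(
            [topology.mobility, np.full(n_new, STATIC, dtype=int)]
        ),
        exclusions=set(topology.exclusions),
    )
    return topo


def set_mass_scaling(
    topology: SystemTopology, group_id: int, factor: float
) -> SystemTopology:
    """Divide the dynamical mass of a rigid group by ``factor``.

    Speeds up rigid-body diffusion without changing any potential energy, so
    equilibrium ensembles are untouched.
    """
    if factor <= 0:
        raise ValueError("mass-scale factor must be positive")
    if group_id not in topology.rigid_groups:
        raise KeyError(f"no rigid group {group_id!r}")
    topology.rigid_groups[group_id].mass_scale = float(factor)
    return topology


# ---------------------------------------------------------------------------
# export

def to_pdb(topology: SystemTopology) -> str:
    """Serialise bead coordinates as a Cα-only PDB (synthetic chain ids)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    one_to_three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
        "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
        "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
        "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
        "X": "UNK",
    }
    n = topology.n_beads
    arr = struc.AtomArray(n)
    arr.coord = topology.positions.astype(np.float32)
    arr.chain_id = np.array([c[:1] if c != "_cap" else "Z" for c in topology.chains])
    arr.res_id = topology.resnums.copy()
    arr.res_name = np.array([one_to_three[c] for c in topology.codes])
    arr.atom_name = np.array(["CA"] * n)
    arr.element = np.array(["C"] * n)
    arr.hetero = np.array([False] * n)
    pdb = PDBFile()
    pdb.set_structure(arr)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()
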