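"""Deterministic toy systems with the statistical structure of real assays.

Three generators cover the shapes that matter for binding simulations:

* a *binding pair* — two rigid mini-helices whose facing residues are drawn
  from the most attractive entries of the shipped pair table, docked into a
  known bound reference and started far apart (a stand-in for a
  nucleation-promoting-factor fragment finding its site on a complex);
* a *tailed domain* — a rigid helix core with a flexible bead-spring tail
  (VCA-like);
* a *filament stub* — several rigid subunits stacked on a helix, all in one
  rigid group, each carrying one flexible loop bonded at both ends
  (D-loop-like).

Everything is bit-reproducible from the spec alone; no randomness is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import forcefield as ff
from .topology import (
    CalphaStructure,
    ReferenceConformation,
    Residue,
    SystemTopology,
    build_system,
    set_mass_scaling,
)

__all__ = [
    "FixtureSpec",
    "BindingPairFixture",
    "make_alpha_helix",
    "make_binding_pair",
    "make_tailed_domain",
    "make_filament_stub",
]

RISE = 1.5  # Å per residue
TWIST = 100.0  # degrees per residue
RADIUS = 2.3  # Å


@dataclass
class FixtureSpec:
    """Parameters of a synthetic fixture; the seed is kept for provenance."""

    kind: str = "binding_pair"
    n_residues: int = 12  # per helix
    n_subunits: int = 8
    loop_length: int = 12
    tail_length: int = 10
    separation: float = 60.0  # Å, initial centre separation of a binding pair
    box: float = 120.0  # Å (≥ 2× the electrostatic cutoff, and ≥ 2× separation)
    seed: int = 0
    mass_scale: float = 100.0  # rigid-body diffusion speed-up
    charged: bool = True  # decorate helix ends with a K/E registry lock


def make_alpha_helix(sequence: str) -> np.ndarray:
    """Ideal α-helix Cα trace: 1.5 Å rise, 100° twist, 2.3 Å radius."""
    n = len(sequence)
    if n < 4:
        raise ValueError("helix needs at least 4 residues")
    i = np.arange(n)
    theta = np.deg2rad(TWIST) * i
    return np.column_stack(
        [RADIUS * np.cos(theta), RADIUS * np.sin(theta), RISE * i]
    )


def _helix_sequence(n: int, charged: bool, flip_charges: bool) -> str:
    """Hydrophobic (+x-facing) stripe on a polar background, with an optional
    K/E pair at the ends that locks the bound registry."""
    hydrophobic = "LFIM"
    seq = []
    h = 0
    for i in range(n):
        az = (TWIST * i) % 360.0
        if az <= 60.0 or az >= 300.0:  # facing +x
            seq.append(hydrophobic[h % len(hydrophobic)])
            h += 1
        else:
            seq.append("S")
    if charged and n >= 6:
        lo, hi = 1, n - 2
        seq[lo], seq[hi] = ("K", "E") if not flip_charges else ("E", "K")
    return "".join(seq)


def _structure_from_chains(chains: dict) -> CalphaStructure:
    out = {}
    for cid, (seq, coords) in chains.items():
        out[cid] = [
            Residue(cid, k + 1, "", seq[k], np.asarray(coords[k], dtype=float))
            for k in range(len(seq))
        ]
    return CalphaStructure(out, [])


@dataclass
class BindingPairFixture:
    spec: FixtureSpec
    topology: SystemTopology
    reference: ReferenceConformation
    components: dict = field(default_factory=dict)


def _cross_energy(coords_a, coords_b, seq_a, seq_b, table, params) -> float:
    idx = {c: i for i, c in enumerate(table.codes)}
    ta = np.array([idx[c] for c in seq_a])
    tb = np.array([idx[c] for c in seq_b])
    eps = table.epsilon[np.ix_(ta, tb)]
    sig = table.sigma_ij[np.ix_(ta, tb)]
    d = coords_a[:, None, :] - coords_b[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    sr6 = (sig / r) ** 6
    lj = 4.0 * (sr6 * sr6 - sr6)
    inside = r < 2 ** (1 / 6) * sig
    u = np.where(
        eps < 0,
        -eps * lj,
        np.where(eps > 0, np.where(inside, eps * lj + 2 * eps, -eps * lj), 0.0),
    )
    u = np.where(r >= params.lj_cutoff_factor * sig, 0.0, u)
    qa = np.array([ff.assign_charge(c) for c in seq_a])
    qb = np.array([ff.assign_charge(c) for c in seq_b])
    qq = qa[:, None] * qb[None, :]
    ue = params.coulomb_constant * qq / (params.dielectric * r) * np.exp(
        -r / params.debye_length
    )
    ue = np.where((qq != 0.0) & (r < params.elec_cutoff), ue, 0.0)
    return float(u.sum() + ue.sum())


def make_binding_pair(spec: FixtureSpec | None = None) -> BindingPairFixture:
    """Two rigid helices with a designed attractive interface.

    The bound reference docks helix B (rotated 180° about z, so its
    hydrophobic stripe faces helix A's) at the axis separation that minimises
    the cross-interface energy of the shipped pair table; the topology's
    initial coordinates start the helices ``spec.separation`` apart.
    """
    spec = spec or FixtureSpec()
    n = spec.n_residues
    seq_a = _helix_sequence(n, spec.charged, flip_charges=False)
    seq_b = _helix_sequence(n, spec.charged, flip_charges=True)
    helix_a = make_alpha_helix(seq_a)
    helix_local = make_alpha_helix(seq_b)
    rz = np.array([[-1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, 1.0]])
    helix_b_rot = helix_local @ rz.T

    params = ff.ForceFieldParams()
    table = ff.default_pair_table(params)
    best = (np.inf, None)
    for dx in np.arange(5.0, 14.01, 0.1):
        for dz in np.arange(-3.0, 3.01, 0.5):
            cand = helix_b_rot + np.array([dx, 0.0, dz])
            e = _cross_energy(helix_a, cand, seq_a, seq_b, table, params)
            if e < best[0]:
                best = (e, (dx, dz))
    dx, dz = best[1]
    bound_b = helix_b_rot + np.array([dx, 0.0, dz])

    ref_cross = np.linalg.norm(
        helix_a[:, None, :] - bound_b[None, :, :], axis=-1
    )
    n_pairs = int((ref_cross <= 10.0).sum())
    if n_pairs < 3:
        raise ValueError(
            f"designed dock yields only {n_pairs} interface pairs within 10 Å"
        )

    center = np.full(3, spec.box / 2.0)
    sep = np.array([spec.separation, 0.0, 0.0])
    start_a = helix_a - helix_a.mean(0) + center - sep / 2
    start_b = bound_b - bound_b.mean(0) + center + sep / 2

    structure = _structure_from_chains(
        {"A": (seq_a, start_a), "B": (seq_b, start_b)}
    )
    topo = build_system(
        structure,
        rigid_spec={"A": [f"A:1-{n}"], "B": [f"B:1-{n}"]},
        flexible_spec=[],
        box=spec.box,
        params=params,
    )
    for gid in topo.rigid_groups:
        set_mass_scaling(topo, gid, spec.mass_scale)

    idx_a = np.arange(n)
    idx_b = np.arange(n, 2 * n)
    ref_pos = np.vstack([helix_a, bound_b]) + (center - helix_a.mean(0))
    reference = ReferenceConformation(ref_pos, {"A": idx_a, "B": idx_b})
    return BindingPairFixture(spec, topo, reference, {"A": idx_a, "B": idx_b})


def make_tailed_domain(
    core_length: int = 12,
    tail_length: int = 10,
    tail_sequence: str | None = None,
    box: float = 150.0,
) -> SystemTopology:
    """Rigid helix core with a flexible extended tail bonded at the junction."""
    if core_length < 4 or tail_length < 1:
        raise ValueError("core needs ≥4 residues, tail ≥1")
    core_seq = _helix_sequence(core_length, charged=False, flip_charges=False)
    tail_seq = tail_sequence or "S" * tail_length
    if len(tail_seq) != tail_length:
        raise ValueError("tail sequence length mismatch")
    core = make_alpha_helix(core_seq)
    # extended tail continuing along +z with a small zigzag
    t = np.arange(1, tail_length + 1)
    tail = np.column_stack(
        [
            RADIUS * np.cos(np.deg2rad(TWIST * (core_length - 1))) + 1.2 * (t % 2),
            RADIUS * np.sin(np.deg2rad(TWIST * (core_length - 1))) * np.ones_like(t, dtype=float),
            core[-1, 2] + 3.6 * t,
        ]
    )
    coords = np.vstack([core, tail]) + box / 2.0 - core.mean(0)
    structure = _structure_from_chains({"A": (core_seq + tail_seq, coords)})
    return build_system(
        structure,
        rigid_spec={"core": [f"A:1-{core_length}"]},
        flexible_spec=[f"A:{core_length + 1}-{core_length + tail_length}"],
        box=box,
    )


def _loop_arc(a: np.ndarray, b: np.ndarray, outward: np.ndarray, n: int) -> np.ndarray:
    """n points on a circular arc from a to b bulging along ``outward`` with
    ~3.8 Å contour spacing."""
    chord = b - a
    cl = np.linalg.norm(chord)
    u = chord / cl
    w = outward - (outward @ u) * u
    w /= np.linalg.norm(w)
    L = (n + 1) * 3.81
    rho = max(L / (2.0 * np.pi), 0.71 * cl)
    half = 0.5 * cl
    c = 0.5 * (a + b) + np.sqrt(rho * rho - half * half) * w

    def angle(p):
        v = p - c
        return np.arctan2(v @ w, v @ u)

    ta, tb = angle(a), angle(b)
    two_pi = 2.0 * np.pi
    ccw = (tb - ta) % two_pi
    # sweep through the circle's outward extreme (+w direction, angle π/2)
    if (np.pi / 2.0 - ta) % two_pi <= ccw:
        sweeps = ta + ccw * np.arange(1, n + 1) / (n + 1)
    else:
        sweeps = ta - (two_pi - ccw) * np.arange(1, n + 1) / (n + 1)
    return c + rho * (np.cos(sweeps)[:, None] * u + np.sin(sweeps)[:, None] * w)


def make_filament_stub(
    n_subunits: int = 8,
    loop_length: int = 12,
    box: float = 300.0,
) -> SystemTopology:
    """Stack of rigid subunits (one shared rigid group), one flexible loop each.

    Subunits are 12-residue helices placed on a coarse helix (20 Å rise, 167°
    twist, 5 Å radial offset); the loop is a contiguous flexible range inside
    each subunit chain, bonded at both flanks, bulging radially outward.
    """
    if n_subunits < 2:
        raise ValueError("need at least 2 subunits")
    sub_len = 12
    base_seq = _helix_sequence(sub_len, charged=False, flip_charges=False)
    base = make_alpha_helix(base_seq)
    chains = {}
    rigid_ranges = []
    flexible_ranges = []
    for k in range(n_subunits):
        cid = chr(ord("A") + k)
        ang = np.deg2rad(167.0 * k)
        rot = np.array(
            [[np.cos(ang), -np.sin(ang), 0.0],
             [np.sin(ang), np.cos(ang), 0.0],
             [0.0, 0.0, 1.0]]
        )
        offset = np.array([5.0 * np.cos(ang), 5.0 * np.sin(ang), 20.0 * k])
        sub = base @ rot.T + offset
        # insert the loop between helix residues 6 and 7
        a, b = sub[5], sub[6]
        outward = np.array([sub[5, 0], sub[5, 1], 0.0])
        if np.linalg.norm(outward) < 1e-6:
            outward = np.array([1.0, 0.0, 0.0])
        loop = _loop_arc(a, b, outward / np.linalg.norm(outward), loop_length)
        coords = np.vstack([sub[:6], loop, sub[6:]])
        seq = base_seq[:6] + "G" * loop_length + base_seq[6:]
        chains[cid] = (seq, coords)
        rigid_ranges += [f"{cid}:1-6", f"{cid}:{7 + loop_length}-{sub_len + loop_length}"]
        flexible_ranges.append(f"{cid}:7-{6 + loop_length}")
    all_coords = np.vstack([c for _, c in chains.values()])
    shift = box / 2.0 - all_coords.mean(0)
    chains = {cid: (seq, coords + shift) for cid, (seq, coords) in chains.items()}
    structure = _structure_from_chains(chains)
    return build_system(
        structure,
        rigid_spec={"filament": rigid_ranges},
        flexible_spec=flexible_ranges,
        box=box,
    )
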