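"""Binding-ensemble analysis: interface dRMS, binding energies, 2D histograms.

dRMS measures how closely a simulated conformation reproduces a reference
complex: over the cross-component residue pairs that sit within 10 Å in the
reference, it is the RMS deviation of instantaneous pair distances from their
reference values — invariant to any global rigid motion. Binding energies sum
the non-bonded (pair + electrostatic) terms across two disjoint groups.
Ensembles are summarised as 2D histograms (dRMS–dRMS or dRMS–energy) whose
high-occupancy bins are the binding hotspots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import forcefield as ff
from .topology import ReferenceConformation, SystemTopology

__all__ = [
    "InterfacePairSet",
    "Histogram2D",
    "select_interface_pairs",
    "drms",
    "drms_series",
    "binding_energy",
    "hist2d",
    "cold_ensemble",
    "hotspot_summary",
]


@dataclass
class InterfacePairSet:
    """Cross-component residue pairs with their reference distances (≤ cutoff)."""

    pairs: np.ndarray  # (n, 2) bead indices
    ref_distances: np.ndarray  # Å
    components: tuple  # (label_a, label_b)

    def __len__(self) -> int:
        return len(self.pairs)


def select_interface_pairs(
    reference: ReferenceConformation,
    comp_a: str,
    comp_b: str,
    cutoff: float = 10.0,
) -> InterfacePairSet:
    """All cross-component pairs within ``cutoff`` (inclusive) in the reference."""
    ia = np.asarray(reference.components[comp_a], dtype=int)
    ib = np.asarray(reference.components[comp_b], dtype=int)
    if np.intersect1d(ia, ib).size:
        raise ValueError("components overlap")
    d = np.linalg.norm(
        reference.positions[ia][:, None, :] - reference.positions[ib][None, :, :],
        axis=-1,
    )
    sel = np.argwhere(d <= cutoff)
    if len(sel) == 0:
        warnings.warn(
            f"no interface pairs within {cutoff} Å between {comp_a!r} and "
            f"{comp_b!r}; dRMS is undefined for this selection"
        )
    pairs = np.stack([ia[sel[:, 0]], ib[sel[:, 1]]], axis=1) if len(sel) else np.zeros(
        (0, 2), dtype=int
    )
    return InterfacePairSet(pairs, d[sel[:, 0], sel[:, 1]] if len(sel) else np.zeros(0),
                            (comp_a, comp_b))


def drms(frame: np.ndarray, pairs: InterfacePairSet, box: float | None = None) -> float:
    """sqrt((1/N) Σ (d_ij − d_ij^ref)²) over the interface pairs, Å.

    With ``box`` the pair distances are minimum-image distances, which is the
    physically meaningful separation when components have diffused across a
    periodic boundary (coordinates are never wrapped during a run).
    """
    if len(pairs) == 0:
        raise ValueError("empty interface pair set: dRMS undefined")
    d = frame[pairs.pairs[:, 0]] - frame[pairs.pairs[:, 1]]
    if box is not None:
        d = d - box * np.round(d / box)
    dist = np.sqrt(np.einsum("ij,ij->i", d, d))
    return float(np.sqrt(np.mean((dist - pairs.ref_distances) ** 2)))


def drms_series(
    frames, pairs: InterfacePairSet, cadence: int = 1, box: float | None = None
) -> np.ndarray:
    """dRMS of every ``cadence``-th frame."""
    return np.array([drms(f, pairs, box) for f in frames[::cadence]])


def binding_energy(
    topology: SystemTopology,
    frame: np.ndarray,
    group_a,
    group_b,
    ffield,
) -> float:
    """Non-bonded energy (kcal/mol) between two disjoint bead groups.

    Sums the KH pair term and Debye–Hückel electrostatics over cross pairs
    only, honouring both cutoffs and the minimum-image convention; additive
    over partitions of either group.
    """
    ia = np.asarray(group_a, dtype=int)
    ib = np.asarray(group_b, dtype=int)
    if np.intersect1d(ia, ib).size:
        raise ValueError("groups overlap")
    fp = ffield.params
    d = frame[ia][:, None, :] - frame[ib][None, :, :]
    if topology.periodic:
        d -= topology.box * np.round(d / topology.box)
    r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    ta, tb = topology.type_index[ia], topology.type_index[ib]
    normal_a, normal_b = ta >= 0, tb >= 0
    eps = ffield.table.epsilon[np.ix_(np.where(normal_a, ta, 0),
                                      np.where(normal_b, tb, 0))]
    cap = ~normal_a[:, None] | ~normal_b[None, :]
    eps = np.where(cap, topology.cap_epsilon, eps)
    sig = 0.5 * (topology.sigmas[ia][:, None] + topology.sigmas[ib][None, :])
    r = np.maximum(r, 1e-6)
    sr6 = (sig / r) ** 6
    lj = 4.0 * (sr6 * sr6 - sr6)
    inside = r < 2 ** (1 / 6) * sig
    u = np.where(
        eps < 0,
        -eps * lj,
        np.where(eps > 0, np.where(inside, eps * lj + 2 * eps, -eps * lj), 0.0),
    )
    u = np.where(r >= fp.lj_cutoff_factor * sig, 0.0, u)
    qq = topology.charges[ia][:, None] * topology.charges[ib][None, :]
    ue = fp.coulomb_constant * qq / (fp.dielectric * r) * np.exp(-r / fp.debye_length)
    ue = np.where((qq != 0.0) & (r < fp.elec_cutoff), ue, 0.0)
    # excluded pairs (e.g. a bond crossing the interface) contribute nothing
    for k, i in enumerate(ia):
        for l, j in enumerate(ib):
            if (min(i, j), max(i, j)) in topology.exclusions:
                u[k, l] = ue[k, l] = 0.0
    return float(u.sum() + ue.sum())


@dataclass
class Histogram2D:
    counts: np.ndarray  # (nx, ny)
    x_edges: np.ndarray
    y_edges: np.ndarray
    n_out_of_range: int

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def write_grid(self, path) -> None:
        """Plain-text grid with axis metadata in comment lines."""
        with open(path, "w") as fh:
            fh.write("# x_edges: " + " ".join(f"{v:g}" for v in self.x_edges) + "\n")
            fh.write("# y_edges: " + " ".join(f"{v:g}" for v in self.y_edges) + "\n")
            fh.write(f"# out_of_range: {self.n_out_of_range}\n")
            np.savetxt(fh, self.counts, fmt="%d")


def hist2d(xs, ys, width_x: float, width_y: float,
           origin_x: float = 0.0, origin_y: float = 0.0) -> Histogram2D:
    """2D histogram with half-open bins [origin + k·w, origin + (k+1)·w).

    Samples below the origin on either axis are counted as out-of-range, not
    dropped silently. A sample exactly on an edge falls in the upper bin.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise ValueError("xs and ys must have equal length")
    if width_x <= 0 or width_y <= 0:
        raise ValueError("bin widths must be positive")
    in_range = (xs >= origin_x) & (ys >= origin_y)
    n_out = int((~in_range).sum())
    x, y = xs[in_range], ys[in_range]
    ix = np.floor((x - origin_x) / width_x).astype(int)
    iy = np.floor((y - origin_y) / width_y).astype(int)
    nx = int(ix.max()) + 1 if len(ix) else 1
    ny = int(iy.max()) + 1 if len(iy) else 1
    counts = np.zeros((nx, ny), dtype=int)
    np.add.at(counts, (ix, iy), 1)
    return Histogram2D(
        counts,
        origin_x + width_x * np.arange(nx + 1),
        origin_y + width_y * np.arange(ny + 1),
        n_out,
    )


def cold_ensemble(result, rung: int = 0):
    """Frames recorded at one rung (default: the coldest), with provenance.

    Returns ``(frames, replica_ids)``: every frame any replica produced while
    occupying the requested rung, in time order.
    """
    if rung < 0 or rung >= result.ladder.n_rungs:
        raise IndexError("no such rung")
    traj = result.trajectories[rung]
    return traj.frames, list(result.frame_replica[rung])


def hotspot_summary(hist: Histogram2D, threshold: float = 0.5):
    """Bins whose count exceeds ``threshold``×max, sorted by occupancy.

    Returns a list of ``(x_center, y_center, occupancy)`` with occupancy the
    bin's fraction of all in-range samples; ties broken by (x, y) bin index.
    """
    total = hist.counts.sum()
    if total == 0:
        raise ValueError("empty histogram")
    cmax = hist.counts.max()
    idx = np.argwhere(hist.counts > threshold * cmax)
    entries = [
        (int(i), int(j), int(hist.counts[i, j])) for i, j in idx
    ]
    entries.sort(key=lambda e: (-e[2], e[0], e[1]))
    return [
        (float(hist.x_centers[i]), float(hist.y_centers[j]), c / total)
        for i, j, c in entries
    ]
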