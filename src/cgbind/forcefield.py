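"""Residue-level statistical potential (KH model A).

Each residue is a single bead at its Cα position. Non-bonded beads interact
through a Lennard-Jones-type pair potential whose signed strength
``ε_ij = λ·(e_ij − e0)`` is obtained by scaling a 20×20 statistical
contact-energy matrix (Miyazawa–Jernigan); negative ε is attractive, positive
ε is mapped onto a repulsive-only form. Charged side chains additionally
interact through Debye–Hückel screened electrostatics. Flexible neighbours
along a chain are joined by harmonic springs.

The contact matrix ships as a plain-text table
(``data/mj_contact_energies.tsv``) and may be replaced by the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .constants import COULOMB

__all__ = [
    "AMINO_ACIDS",
    "ResidueParams",
    "ForceFieldParams",
    "PairPotentialTable",
    "assign_charge",
    "residue_params",
    "load_contact_matrix",
    "build_pair_table",
    "pair_energy",
    "pair_force",
    "electrostatic_energy",
    "bond_energy",
    "bond_force",
]

#: Canonical one-letter codes, alphabetical; index order of all 20×20 tables.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Side-chain-level charging: Asp/Glu −1, Lys/Arg +1, His +0.5 (KH convention);
# chain termini carry no extra charge.
_CHARGES = {"D": -1.0, "E": -1.0, "K": +1.0, "R": +1.0, "H": +0.5}

# Bead vdW diameters σ_i (Å), from residue volumes (KH parameterisation).
_SIGMA = {
    "A": 5.04, "C": 5.48, "D": 5.58, "E": 5.92, "F": 6.36,
    "G": 4.50, "H": 6.08, "I": 6.18, "K": 6.36, "L": 6.18,
    "M": 6.18, "N": 5.68, "P": 5.56, "Q": 6.02, "R": 6.56,
    "S": 5.18, "T": 5.62, "V": 5.86, "W": 6.78, "Y": 6.46,
}

# Residue masses (amu). Equilibrium ensembles do not depend on them.
_MASS = {
    "A": 71.08, "C": 103.14, "D": 115.09, "E": 129.12, "F": 147.18,
    "G": 57.05, "H": 137.14, "I": 113.16, "K": 128.17, "L": 113.16,
    "M": 131.19, "N": 114.10, "P": 97.12, "Q": 128.13, "R": 156.19,
    "S": 87.08, "T": 101.10, "V": 99.13, "W": 186.21, "Y": 163.18,
}

_RT26 = 2.0 ** (1.0 / 6.0)


def assign_charge(code: str) -> float:
    """Charge (e) carried by a residue bead: D,E → −1; K,R → +1; H → +0.5."""
    if code not in _SIGMA:
        raise ValueError(f"unknown amino-acid code {code!r}")
    return _CHARGES.get(code, 0.0)


@dataclass(frozen=True)
class ResidueParams:
    """Per-residue bead parameters."""

    code: str
    sigma: float  # vdW diameter, Å
    charge: float  # elementary charges
    mass: float  # amu


def residue_params(code: str) -> ResidueParams:
    if code not in _SIGMA:
        raise ValueError(f"unknown amino-acid code {code!r}")
    return ResidueParams(code, _SIGMA[code], assign_charge(code), _MASS[code])


@dataclass
class ForceFieldParams:
    """Global force-field constants.

    ``lambda_scale`` and ``e0`` are the KH model-A scaling of the contact
    matrix; ``half_bond`` selects U = ½k(r−r0)² instead of the default
    U = k(r−r0)² (the printed spring constant multiplies the squared
    displacement directly, following the harmonic-bond convention of the MD
    engine the parameters were taken from).
    """

    lambda_scale: float = 0.159
    e0: float = -1.36  # kcal/mol
    dielectric: float = 80.0
    debye_length: float = 10.0  # Å
    elec_cutoff: float = 35.0  # Å
    lj_cutoff_factor: float = 3.0  # multiples of σ_ij
    coulomb_constant: float = COULOMB  # kcal·Å/(mol·e²)
    bond_r0: float = 3.81  # Å
    bond_k: float = 189.0  # kcal/(mol·Å²)
    half_bond: bool = False

    def __post_init__(self) -> None:
        for name in ("dielectric", "debye_length", "elec_cutoff", "bond_r0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lj_cutoff_factor < _RT26:
            raise ValueError(
                "lj_cutoff_factor must be ≥ 2^(1/6) so the attractive "
                "minimum lies inside the cutoff"
            )


@dataclass
class PairPotentialTable:
    """Scaled pair strengths ε_ij and contact distances σ_ij for all 210 pairs."""

    codes: str
    epsilon: np.ndarray  # (20, 20) kcal/mol, signed; negative = attractive
    sigma_ij: np.ndarray  # (20, 20) Å, arithmetic-mean combining
    index: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.index = {c: i for i, c in enumerate(self.codes)}

    def eps(self, a: str, b: str) -> float:
        return float(self.epsilon[self.index[a], self.index[b]])

    def sigma(self, a: str, b: str) -> float:
        return float(self.sigma_ij[self.index[a], self.index[b]])


def load_contact_matrix(path=None) -> tuple[str, np.ndarray]:
    """Load a 20×20 symmetric contact-energy table (kcal/mol).

    Returns the residue-code order of the rows/columns and the matrix. With
    no ``path`` the packaged Miyazawa–Jernigan table is used.
    """
    if path is None:
        src = resources.files("cgbind.data").joinpath("mj_contact_energies.tsv")
        text = src.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    codes = "".join(header[1:])
    mat = np.array([[float(x) for x in ln.split("\t")[1:]] for ln in lines[1:]])
    if mat.shape != (len(codes), len(codes)):
        raise ValueError("malformed contact-matrix file")
    return codes, mat


def build_pair_table(
    mj_matrix: np.ndarray,
    params: ForceFieldParams,
    codes: str = AMINO_ACIDS,
) -> PairPotentialTable:
    """Scale a contact matrix into signed pair strengths ε_ij = λ(e_ij − e0).

    Entries with e_ij below the reference e0 become attractive (ε < 0), the
    rest repulsive; the sign structure of the source matrix relative to e0 is
    preserved exactly.
    """
    mj_matrix = np.asarray(mj_matrix, dtype=float)
    if mj_matrix.shape != (20, 20):
        raise ValueError(
            f"contact matrix must be 20×20, got {mj_matrix.shape}"
        )
    if not np.allclose(mj_matrix, mj_matrix.T, atol=1e-12):
        raise ValueError("contact matrix must be symmetric")
    if len(codes) != 20:
        raise ValueError("need exactly 20 residue codes")
    eps = params.lambda_scale * (mj_matrix - params.e0)
    sig = np.array([_SIGMA[c] for c in codes])
    sigma_ij = 0.5 * (sig[:, None] + sig[None, :])
    return PairPotentialTable(codes, eps, sigma_ij)


def default_pair_table(params: ForceFieldParams | None = None) -> PairPotentialTable:
    """Pair table built from the packaged contact matrix with default scaling."""
    params = params or ForceFieldParams()
    codes, mj = load_contact_matrix()
    return build_pair_table(mj, params, codes)


def _check_r(r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    return r


def pair_energy(r, eps: float, sigma: float, params: ForceFieldParams):
    """KH pair energy (kcal/mol) at separation ``r`` (Å).

    Attractive pairs (ε < 0) use the plain Lennard-Jones well of depth |ε|;
    repulsive pairs (ε > 0) use the repulsive-only form, which is continuous
    at the 2^(1/6)σ matching point, positive inside it and decays to zero
    outside. Both are plainly truncated (no shift) at ``lj_cutoff_factor·σ``.
    """
    r = _check_r(r)
    sr6 = (sigma / r) ** 6
    lj = 4.0 * (sr6 * sr6 - sr6)  # unit-ε Lennard-Jones
    if eps < 0:
        u = -eps * lj
    elif eps > 0:
        inside = r < _RT26 * sigma
        u = np.where(inside, eps * lj + 2.0 * eps, -eps * lj)
    else:
        u = np.zeros_like(r)
    u = np.where(r >= params.lj_cutoff_factor * sigma, 0.0, u)
    return u if u.ndim else float(u)


def pair_force(r, eps: float, sigma: float, params: ForceFieldParams):
    """Radial force −du/dr (kcal/(mol·Å)) of :func:`pair_energy`."""
    r = _check_r(r)
    sr6 = (sigma / r) ** 6
    dlj = 4.0 * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r  # d/dr of unit-ε LJ
    if eps < 0:
        f = eps * dlj
    elif eps > 0:
        inside = r < _RT26 * sigma
        f = np.where(inside, -eps * dlj, eps * dlj)
    else:
        f = np.zeros_like(r)
    f = np.where(r >= params.lj_cutoff_factor * sigma, 0.0, f)
    return f if f.ndim else float(f)


def electrostatic_energy(r, qi: float, qj: float, params: ForceFieldParams):
    """Debye–Hückel energy C·qi·qj·exp(−r/ℓ_D)/(D·r), truncated at the cutoff."""
    r = _check_r(r)
    u = (
        params.coulomb_constant
        * qi
        * qj
        / (params.dielectric * r)
        * np.exp(-r / params.debye_length)
    )
    u = np.where(r >= params.elec_cutoff, 0.0, u)
    return u if u.ndim else float(u)


def electrostatic_force(r, qi: float, qj: float, params: ForceFieldParams):
    """Radial force −du/dr of :func:`electrostatic_energy`."""
    r = _check_r(r)
    pref = params.coulomb_constant * qi * qj / params.dielectric
    f = pref * np.exp(-r / params.debye_length) * (1.0 / r + 1.0 / params.debye_length) / r
    f = np.where(r >= params.elec_cutoff, 0.0, f)
    return f if f.ndim else float(f)


def bond_energy(r, params: ForceFieldParams):
    """Harmonic bond U = k(r−r0)² (or ½k(r−r0)² if ``half_bond``)."""
    r = np.asarray(r, dtype=float)
    k = 0.5 * params.bond_k if params.half_bond else params.bond_k
    u = k * (r - params.bond_r0) ** 2
    return u if u.ndim else float(u)


def bond_force(r, params: ForceFieldParams):
    """Radial force −dU/dr of :func:`bond_energy`."""
    r = np.asarray(r, dtype=float)
    k = 0.5 * params.bond_k if params.half_bond else params.bond_k
    f = -2.0 * k * (r - params.bond_r0)
    return f if f.ndim else float(f)
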