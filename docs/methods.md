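# Methods

## Model

`cgbind` simulates protein–protein association at residue resolution. Each
residue is one bead at its Cα position. Non-bonded beads interact through a
Lennard-Jones-type pair potential whose signed strength is obtained by
scaling a 20×20 statistical contact-energy matrix (the Miyazawa–Jernigan
inter-residue contact energies, shipped as a plain-text table):

    ε_ij = λ · (e_ij − e0),      λ = 0.159,  e0 = −1.36 kcal/mol

Pairs with e_ij below the reference e0 are attractive and use the plain LJ
well of depth |ε_ij|; the rest use a repulsive-only form that equals ε at the
2^(1/6)σ matching point, is continuous there, and decays to zero outside.
σ_ij is the arithmetic mean of per-residue vdW diameters. All pair terms are
plainly truncated (no energy shift) at 3σ_ij; the discontinuity is
4|ε|(3⁻⁶ − 3⁻¹²) ≈ 0.0055|ε| and is accepted as in the reference
implementation of this force-field family.

Charged side chains (Asp/Glu −1, Lys/Arg +1, His +0.5; termini uncharged)
interact through Debye–Hückel electrostatics with uniform dielectric 80 and
screening length 10 Å (≈100 mM monovalent salt), truncated at 35 Å. The
Coulomb constant is 332.06 kcal·Å/(mol·e²).

Flexible neighbours along a chain are joined by harmonic springs
U = k(r − r0)² with r0 = 3.81 Å and k = 189 kcal/(mol·Å²). The printed
constant multiplies the squared displacement directly — the harmonic-bond
convention of the MD engine these parameters originate from; a ½-convention
is selectable (`ForceFieldParams.half_bond`).

Domains with known structure are rigid bodies: their internal geometry is
fixed, and all intra-body pair interactions are excluded (as are bonded 1-2
pairs, which at r0 = 3.81 Å would otherwise sit deep inside most σ_ij).
Rigid–flexible junction residues carry the same spring as flexible–flexible
neighbours.

Units package-wide: Å, fs, kcal/mol, amu, K; k_B = 0.0019872 kcal/(mol·K).

## Dynamics

Flexible beads follow underdamped Langevin dynamics integrated with the
BAOAB splitting (exact Ornstein–Uhlenbeck sub-step), chosen for its accurate
configurational sampling at the production time step of 10 fs. The damping
parameter (default 1,000 fs) is a relaxation *time*: friction γ_i = m_i/τ
for every degree of freedom.

Rigid groups advance as bodies: centre-of-mass translation from the
aggregated force, rotation by quaternion with the body-frame (principal-axis)
inertia tensor, gyroscopic term included, and the same friction/noise
structure applied to translational and angular velocities (per principal
axis, with the group's principal moments). Rotational degrees of freedom are
thermostatted with the same damping time as translation. Member positions
are reconstructed exactly from the body transform every step, so internal
distances are preserved to round-off by construction.

Bead masses are residue molecular masses (amu). Equilibrium averages do not
depend on masses, so this choice only affects kinetics. A rigid group's
dynamical mass can be divided by a *mass-scale* factor (default 100 in the
binding-pair fixture) to speed up rigid-body diffusion; the potential is
untouched, so ensembles are unchanged — verified by the mass-scaling
invariance test.

Non-bonded interactions come from a Verlet neighbour list with a 4 Å skin,
rebuilt every 1,000 steps and immediately whenever any bead has moved more
than skin/2 since the last build (the completeness guarantee). Boxes are
cubic and periodic with the minimum-image convention; the reference box side
is 300 Å. List-based energies are required (and tested) to match direct
O(N²) sums to 1e−10.

With the thermostat off the scheme reduces to velocity Verlet (`nve_run`),
used for energy-conservation and momentum-conservation validation.

## Replica exchange

Temperature REMD uses a geometric ladder — T_k = tmin·(tmax/tmin)^(k/(n−1)) —
with defaults of 28 rungs from 180 K to 540 K. Geometric spacing is the
standard choice giving near-uniform neighbour acceptance when the heat
capacity is roughly temperature-independent. Swaps are attempted every 100
steps; sweeps alternate even (0-1, 2-3, …) and odd (1-2, 3-4, …) neighbour
pairs; the Metropolis probability is min(1, exp[(β_i − β_j)(E_i − E_j)])
with the potential energy only. On acceptance the configurations change
rungs and all velocities (including angular) are rescaled by
√(T_new/T_old). Pair strengths are temperature-independent across rungs.
Each replica owns its RNG stream; the swap decisions use a dedicated stream,
so the exchange pattern never perturbs the dynamics streams. Dwell-time
distributions and the replica→rung trace are recorded for mixing
diagnostics.

## Analysis

Similarity to a reference complex is measured by dRMS over interface pairs:
all cross-component residue pairs within 10 Å (inclusive) in the reference,

    dRMS = sqrt( (1/N) Σ (d_ij − d_ij^ref)² ).

Selection is restricted to inter-component pairs (intra-component geometry
is rigid anyway). Pair distances may be evaluated with the minimum-image
convention: coordinates are never wrapped during a run, so a bound complex
that has diffused across a periodic boundary is only recognised with
minimum-image distances. Binding energy between two disjoint groups is the
sum of non-bonded (pair + electrostatic) cross terms honouring both cutoffs;
it is symmetric and additive over partitions of either group, enabling
per-subunit decompositions.

Ensembles are summarised as 2D histograms — dRMS–dRMS or dRMS–energy, with
default bin widths 0.5 Å and 0.1 kcal/mol, half-open bins
[origin + kw, origin + (k+1)w) — and hotspots are the bins above a fraction
(default one half) of the maximal count, ranked by occupancy. Bound
complexes are characterised at the coldest rung (180 K), where bound
configurations dominate.

## Synthetic fixtures

The generators produce toy systems with the statistical structure of real
assays, not imitations of any particular complex:

* **binding pair** — two 12-residue rigid ideal helices (1.5 Å rise, 100°
  twist, 2.3 Å radius). The +x-facing stripe of each helix cycles through
  Leu/Phe/Ile/Met — drawn from the most attractive entries of the shipped
  pair table so fixtures exercise the real force-field path — on a serine
  background, with a Lys/Glu pair near the helix ends whose electrostatic
  complementarity locks the bound registry. The reference dock places the
  second helix (rotated 180° about the helix axis) at the axis separation
  minimising the cross-interface energy; the initial state starts the
  helices 60 Å apart in a 120 Å periodic box (the smallest box consistent
  with that separation and twice the 35 Å electrostatic cutoff). Both bodies
  carry mass-scale 100 so that diffusive encounter happens within desk-scale
  runs. The designed dock has ≥10 interface pairs within 10 Å and a
  cross-interface energy below −3 kcal/mol.
* **tailed domain** — a rigid helix core with a flexible serine tail
  (bead-spring), for junction and disorder tests; at 180 K the tail stays
  expanded (no globule collapse), consistent with the weak solvent-exposed
  attractions of this parameterisation.
* **filament stub** — n rigid 12-residue subunits stacked on a coarse helix
  (20 Å rise, 167° twist), all in a single rigid group, each carrying one
  flexible loop inserted mid-chain and bonded at both flanks, mimicking a
  flexible loop inside an otherwise rigid filament subunit.

Everything is bit-reproducible from the fixture spec. What the fixtures do
*not* emulate: real interface geometry or energetics of any particular
complex, sequence-specific secondary-structure propensity, or excluded
volume of side chains beyond the single-bead diameters — so passing the
scenario tests demonstrates correctness of the machinery and the
bound-cold/unbound-hot phenomenology, not predictive accuracy for any real
system.

## Numerical choices and problem sizes

* BAOAB at dt = 10 fs biases the configurational variance of a mode with
  angular frequency ω by ≈(ωdt/2)². The stiffest mode here is the bond
  (~112 fs period), giving ~8% variance inflation at 10 fs — irrelevant for
  means and for soft inter-body modes. Tests that *measure* fluctuation
  magnitudes of the bond therefore integrate at 2–5 fs, where the bias is
  below 2%; production settings are unchanged.
* Degenerate (near-linear) rigid bodies get their vanishing principal
  moments clamped to 1e−6 amu·Å²; orientable bodies require ≥3 non-collinear
  members.
* The 10 Å interface cutoff is inclusive (≤); ties in hotspot ranking break
  by (x, y) bin index; histogram samples exactly on an edge fall in the
  upper bin; the energy-axis origin is floored to the bin width.
* Superposition uses scipy's quaternion-based least-squares rotation
  (proper, det = +1), with the RMSD recomputed from the transformed
  coordinates for full precision; correspondences are supplied by the
  caller, never inferred from sequence.
* Test and validation runs are scaled to the package's test budget: the
  binding scenario uses the default 28-rung ladder for 4×10⁴ steps per
  replica, canonical-statistics checks use 10⁵–10⁶ steps of 2–4-bead
  systems. These sizes are the package's own verification choices; the
  production defaults in the config (10 fs, 1,000-step rebuilds, 100-step
  swap interval, 300 Å box) are what a real study would scale up.

## Known limitations

* No conformational change inside rigid bodies, by construction; activation
  transitions cannot be represented.
* No nucleotides, ions, or explicit solvent; electrostatics is mean-field
  Debye–Hückel.
* Binding affinities are not quantitative — ensembles and relative hotspot
  structure are the meaningful outputs; no K_d estimation is attempted.
* Plain truncation makes total energy very weakly discontinuous at the
  cutoffs (documented above); acceptable for sampling, not for shadow-
  Hamiltonian-level energy conservation studies with attractive tails.
* The packaged contact matrix is a transcription of the published table;
  users can drop in a replacement file with the same layout.
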