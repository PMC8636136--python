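# Methods

`picmelt` models promoter DNA opening in the RNA polymerase II
pre-initiation complex (PIC) with a residue-level coarse-grained (CG)
energy function, Langevin dynamics, and a set of trajectory statistics
built around state-specific protein–DNA contacts.  This note documents
the model, its parameters, the synthetic test system, and the numerical
choices, in enough detail to reproduce or criticize any number the
package computes.

## Coarse-grained representation

Each amino acid is one bead at the Cα position.  Each nucleotide is
three beads at heavy-atom group centroids: phosphate (P, OP1, OP2,
O5'), sugar (C1'–C5', O4') and base (ring atoms).  5'-terminal
phosphates are absent when the source structure lacks them, so a duplex
of L base pairs has 6L − 2 beads.  Bead masses are amu-like (CA 110,
P 95, S 99, B 120); only their ratios matter for the sampled ensembles.

## Energy function

Units: kcal/mol, Å, elementary charges; k_B = 0.0019872 kcal/mol/K.

**Protein local terms.** Harmonic virtual bonds (k = 100 kcal/mol/Å²)
and angles (k = 20 kcal/mol/rad²) plus periodic native-biased dihedrals
U = k(1 − cos(φ − φ⁰)), all with native values measured from the
reference structure.  This is a simplification of flexible-local-
potential CG protein models: the local terms here are generic
restoring potentials, not statistics-derived tables.

**Structure-based (Go) contacts.** For bead pairs in contact in a
reference structure,

    U(r) = ε [ 5 (r⁰/r)¹² − 6 (r⁰/r)¹⁰ ],

with minimum −ε at the native distance r⁰ and zero crossing at
r⁰·√(5/6).  Below 0.6 r⁰ the potential continues linearly so r → 0
stays finite.  Intra/inter-protein contacts (Cα pairs within 8 Å,
sequence separation ≥ 3) use ε = 0.8; protein–DNA contacts use the
calibrated ε_go = 1.2 (see below).

**DNA model.** A simplified three-site-per-nucleotide parameterization
in the spirit of the established 3SPN family: harmonic backbone bonds
(k = 60 kcal/mol/Å²), harmonic angles (k = 12 kcal/mol/rad²), periodic
backbone dihedrals (k = 1 kcal/mol), intra-strand base-stacking 12-10
wells (ε_stack = 5.0), and orientation-gated Watson–Crick pairing

    U_bp = −ε_bp · g(θ_i) · g(θ_j) · [6 (r⁰/r)¹⁰ − 5 (r⁰/r)¹²],

where θ are the two sugar–base···base "gate" angles and
g(θ) = exp(−(θ − θ⁰)²/2σ²) with σ = 0.45 rad penalizes non-facing or
non-coplanar geometries.  G·C wells are deeper than A·T by 3:2
(ε_AT = ⅔ ε_GC).  The published parameter tables of the full model are
not reproduced; instead the single pairing-depth knob ε_GC is
calibrated (below).  Native bonded values are measured from the built
or mapped geometry, so an ideal built duplex is an exact minimum of the
bonded terms.

A *mismatched* (non-complementary) pair position replaces the pairing
well with a pure repulsion U = ε_mm (r⁰/r)¹², ε_mm = 4 kcal/mol,
modeling the steric/energetic incompatibility of non-Watson–Crick base
opposition.  Without this term a 15-base mismatch window in the CG model
merely loses its attraction and the strands, still confined by the
flanking duplex, open only ~3 bp; with the repulsion the window melts
promptly to ~80–85% of its width (the edge pairs keep breathing), the
behavior a 15-base mismatch bubble shows.  A window counts as "melted"
in the protocol reports when its late-time mean bubble reaches 75% of
the window width.

**Excluded volume.** Purely repulsive ε_ev (σ_ij/r)¹² with
ε_ev = 0.2 and per-kind radii (CA 2.2, P 2.0, S 2.2, B 2.5 Å;
σ_ij = R_i + R_j), truncated at 2 σ_ij and linearly capped near r = 0.
Pairs already carrying an explicit term (bonded neighbors to graph
distance 3, Go contacts, stacking, pairing/mismatch) are excluded.

**Electrostatics.** Debye–Hückel screened Coulomb,
U = (332.06/ε_r) q_i q_j exp(−r/λ_D)/r, shifted to zero at the 21 Å
cutoff (≥ 3 Debye lengths).  λ_D is computed from salt and temperature;
at the study condition (200 mM monovalent, 300 K, ε_r = 78) λ_D ≈
6.8 Å.  Charges: −0.6 e per phosphate (counterion-condensation
convention), +1 on Lys/Arg, −1 on Asp/Glu, 0 elsewhere.  The fixed
protein charges replace surface-charge optimization, which is out of
scope; this mainly coarsens the electrostatic texture of the protein
surface.

## Calibrations

**Contact depth ε_go.** `calibrate_epsilon` scans candidate depths and
runs short equilibrium simulations per probe condition (a state, a
contact subset, and a required outcome "maintained"/"lost", optionally
under a charge-flip mutation which also deletes the mutated residues'
contacts).  A contact subset counts as maintained when its time-mean
formed fraction is ≥ 0.5.  The four canonical probes are: E-wing–DNA
maintained in the closed complex; template–active-site contacts
maintained in the open complex; upstream-DNA–TFIIE contacts maintained
in OC/ITC; and the same contacts lost under the triple charge-flip
mutation.  The default ε_go = 1.2 kcal/mol is the published calibrated
value for this system class.

**Pairing depth and break threshold.** The single DNA calibration knob
ε_GC was set by scanning (ε_stack, ε_GC) on a free 20-bp duplex at
300 K / 200 mM until the fraction of (frame, pair) events with
base–base distance > 6.2 Å is ≈ 0.3% — the same statistic that defines
the bubble criterion: a broken pair is one whose base-bead distance
exceeds 6.2 Å, a threshold that an intact duplex crosses only ~0.3% of
the time, so bubble counts are essentially free of false positives.
The frozen values are ε_stack = 5.0, ε_GC = 7.5.  Terminal-pair
fraying dominates the residual rate, as it should.
`calibrate_break_threshold` exposes the inverse calibration: given an
intact-duplex trajectory and a target false rate it returns the
smallest threshold on a grid meeting it.

## Dynamics

BAOAB-splitting Langevin integration (half-kick, half-drift,
Ornstein–Uhlenbeck velocity refresh, half-drift, half-kick), timestep
0.2 reduced time units, friction γ = 0.25/τ.  The composite protocols
default to lower friction (0.1/τ for the melt stages, 0.05/τ for the
threading stages): with an implicit solvent, γ sets transport rates but
not the sampled ensemble, so the transport-limited protocol stages use
it as a sampling-efficiency knob.  In the zero-friction
limit the scheme reduces to velocity Verlet (energy conserved to
O(dt²)); at T = 0 with zero velocities at a minimum it is static.  The
kinetic temperature carries the usual O((ωdt)²) BAOAB bias of ~1% at
the default timestep; equipartition checks therefore use a smaller
timestep.  All randomness (initial velocities and the OU noise) comes
from one seed; identical seeds give bit-identical trajectories.
Nonbonded interactions use Verlet pair lists (3.5 Å skin, rebuilt every
60 steps).

Annealing runs interpolate temperature piecewise-linearly between
schedule points; the export protocol is a quench 300 → 1 K followed by
an equal-length hold at 1 K, which damps local fluctuations by an order
of magnitude while preserving the conformation.

Mismatch protocols: `apply_mismatch` rewrites the non-template bases of
a window (by default to the identity of the opposing template base,
which guarantees non-complementarity) and switches those pair positions
to the mismatch repulsion; `revert_mismatch` restores the original
sequence and pairing terms.  Coordinates are never touched — melting
and re-pairing must happen dynamically.

## State-specific contacts and trajectory statistics

Per-state protein–DNA contact lists (heavy-atom pairs within 6.5 Å,
recorded per CG bead pair with r⁰ the bead–bead distance; the cutoff is
a config field) are merged into a union set that doubles as the energy
term.  r⁰ conflicts across states resolve by CC > OC > ITC priority
with a warning above 2 Å.  Characteristic subsets: CC-specific
(CC minus others), the full OC list, and ITC-unique.  A contact is
"formed" in a frame when r ≤ 1.2 r⁰ (the standard Go-model convention).
State assignment from the three formed fractions uses the default
cutoffs f_CC ≥ 0.6 → CC; f_ITC ≥ 0.7 → ITC; f_OC ≥ 0.7 ∧ f_ITC < 0.25
→ OC; 0.25 ≤ f_ITC < 0.7 → I1/I2 split on whether the E-wing contact
is still formed; f_CC ≤ 0.3 ∧ 0.25 ≤ f_OC < 0.7 → pre-OC; otherwise
unassigned.  All cutoffs are config-exposed; they discretize the
reported fraction ranges (~80% CC loss, ~40% OC formation at pre-OC,
~35% ITC formation at I1) rather than any published threshold.

The gate statistic is the distance between the centers of mass of the
fork-loop-1 analog and the B-linker analog; the "open" cutoff defaults
to closed-state mean + 2 SD estimated from the first decile of the
series.  Plotted time series use a centered 11-point moving average
with truncated edge windows.  RMSD uses Kabsch superposition; reference
complexes are compared over protein beads only.

## The synthetic toy system

`build_bdna` produces an idealized B-form duplex (rise 3.38 Å, twist
34.3°/bp — standard fiber values) with all pair distances equal by
construction.

`build_toy_pic` produces the three-state test system: a 52-bp promoter
duplex whose downstream arm bends smoothly into a clamp along three
reference poses (CC: straight; OC: bent 25°; ITC: bent a further 45°
over a ramp that extends nearly to the downstream tip, so that
threading proceeds as a continuous contact zipper rather than a rigid
lever swing), plus a multi-chain protein scaffold placed around the
poses: upstream anchors (contacts in all three states), a cradle along
the CC pose, partners for the persistent OC∩ITC contacts in the zone
whose position is shared by the OC and ITC poses, an electrically
neutral E-wing-analog cluster near the OC pose of a zone that moves on
to ITC, charged (+1, Lys-like) rows lining the ITC path plus guide rows
flanking the deep corridor that together form the electrostatic funnel
driving threading, a backstop row on the far side, and a floppy gate
flap (bending k = 1.5 kcal/mol/rad², tilted toward the approach side)
crossing the arm's swing path at 0.68 of the swing, so the threaded
pose is geometrically reachable only by displacing the flap — which the
arriving DNA does, leaving the flap folded against its surface, while a
position-restrained ("shut") flap blocks threading outright.  During protocol
runs the scaffold (not the flap) is held by weak position restraints
(k = 2 kcal/mol/Å²): the toy clamp stands in for the bulk of a large,
internally rigid assembly, and pinning it keeps the reference poses
meaningful in the laboratory frame.  "Restraining the gate shut" adds
k = 10 restraints on the flap.

Contact sets are *prescribed*, not emergent: candidate (protein bead,
DNA bead) pairs within 8 Å of the relevant pose are classified by
explicit formation/exclusion predicates evaluated on all three poses
(formed where required; at least 1.45× the native distance where
forbidden), and the requested numbers are drawn from each class —
by default 92 CC-specific, 22 OC (19 shared with ITC, 3 OC-only), and
118 ITC (99 unique), mirroring the statistical structure the analysis
assumes.  If the pools cannot satisfy the prescription the generator
raises instead of degrading.  The three OC-only contacts are the E-wing
analog; they carry ε = 8 kcal/mol each as a stand-in for the collective
strength of the real E-wing contact patch (a single calibrated-depth
contact per pair would break instantly under the threading drive and
the weakened-versus-control comparison would lose its mechanism).

What the toy does *not* emulate: sequence-realistic DNA geometry and
elasticity, internal melting of the threaded state (the toy ITC pose is
a threaded duplex; the 13-bp ITC bubble of the real system is not
reproduced), protein conformational change beyond the gate flap, and
any absolute timescale.  Tests passing on the toy demonstrate that the
pipeline's statistics, protocols and gate logic behave correctly on a
system with the assumed contact structure — not that the real PIC
opens promoter DNA, which requires the cryo-EM reference structures
and far longer simulations.

## Problem sizes and defaults

Desk-scale defaults are deliberately small: a 52-bp toy promoter,
~350 scaffold beads (≈ 660 beads total), melt/revert stages of
2–5 × 10⁴ steps and threading runs of 10⁵ steps with ensembles of
4–10 runs.  The corresponding full-scale protocol (2 × 10⁷-step melts,
5 × 10⁶-step reverts, 40–160-run ensembles) is preserved behind the
`--paper-scale` flag of the CLI.  The duplex break-rate quantity uses a
20-bp duplex and 10⁶ steps per seed, three seeds.

## Known limitations

* The DNA model is a single-knob calibration, not a transferable
  parameterization; melting temperatures, sequence-dependent
  elasticity and single-strand properties are outside its validated
  range.
* Fixed integer protein charges flatten the electrostatic texture that
  surface-charge optimization would provide.
* The toy clamp's restraints break translational invariance of the
  *protocol* systems (the bare energy function remains invariant, as
  the tests verify).
* State assignment is threshold-based; frames near boundaries are
  sensitive to the configured cutoffs.
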