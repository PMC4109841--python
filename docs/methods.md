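# Methods

This note records the model, the numerical choices, and the reasoning behind
the design decisions that were genuinely open.  Units throughout are
AKMA-like: kcal/mol, Å, amu, ps; k_B = 0.0019872 kcal/mol/K; masses are
converted internally by 1 kcal/mol = 418.4 amu Å²/ps².

## Coarse-grained mapping

Each residue maps to a CA bead (at the alpha-carbon position, carrying the
summed mass of N, CA, C, O, OXT and backbone hydrogens) and an SC bead at the
mass-weighted centroid of all remaining atoms, carrying their summed mass.
Glycine has no SC bead.  Hydrogens are included in the centroid when present;
since crystal structures usually lack them the result is in practice the
heavy-atom centre of mass — users comparing protonated and unprotonated
inputs should expect slightly different SC positions.  Alternate locations
other than blank/"A" are dropped, the first model of multi-model files is
used, and residues are renumbered serially so insertion codes cannot create
ambiguous topology.  Residues missing side-chain heavy atoms are an error by
default (`allow_incomplete=True` places the SC bead on whatever is present),
because a silently misplaced bead corrupts the contact map.

## Secondary structure

The faithful route is importing a STRIDE/DSSP assignment (`read_ss_file`,
mapping H/G/I→H, E/B→E, else C).  The built-in heuristic labels residues
from backbone φ/ψ windows (helix: φ ∈ [−100, −30], ψ ∈ [−80, −5]; strand:
φ ∈ [−180, −90], ψ ∈ [90, 180]) and is deterministic; chains under three
residues are all coil.  The assignment only sets backbone-dihedral force
constants, so modest disagreements with STRIDE have limited effect.

## Force field

All equilibria come from the native structure, which makes the bonded energy
zero at the crystal geometry by construction:

- bonds CA(i)–CA(i+1) and CA(i)–SC(i), k = 50 kcal/mol/Å²;
- angles CA–CA–CA and both CA–CA–SC flanks, k = 30 kcal/mol/rad²;
- backbone dihedrals CA(i)…CA(i+3) with multiplicity 1 and phase
  δ = φ_native + 180°, so the native value is the cosine minimum; k = 1.0
  kcal/mol when both central residues are helix (or both strand), 0.3 for
  coil;
- one harmonic improper per interior non-glycine residue on
  (CA(i−1), CA(i+1), CA(i), SC(i)), k = 20 kcal/mol/rad², equilibrium at the
  native value.  Mirror-imaging the structure flips its sign, which is the
  chirality barrier the term exists to enforce.

These force constants are this package's pinned defaults (shipped, commented,
in `ktgo/data/default_params.yaml`), chosen so that bonded stiffness is well
below all-atom values — the "bonds" are flexible inter-residue linkages — and
so that the 1 fs default step resolves the fastest bond period (~200 fs) by
two orders of magnitude.

Native contacts are SC–SC pairs within 4.5 Å in the crystal with sequence
separation |i−j| ≥ 3 (closer pairs are governed by bonded terms; this is the
reading of "non-adjacent" adopted here).  The criterion applies to SC bead
positions by default; a heavy-atom-pair alternative is available
(`contact_criterion="heavy_atom"`).  Well depths are
ε = nScale · c · |e(i,j)| with e(i,j) the Miyazawa–Jernigan 1996 contact
energies (packaged as an upper-triangle table; symmetric, all 210 pairs
attractive) and c = 0.6 kcal/mol per table unit, i.e. roughly RT at 300 K.
Stronger (more negative) published entries give deeper wells.  Any symmetric
20×20 table can replace it through the `MJTable` interface.

Backbone hydrogen bonds become weakly attractive CA–CA wells.  Detection
requires donor N···acceptor O ≤ 3.5 Å *and* amide H···O ≤ 2.5 Å, with H
reconstructed from the preceding carbonyl direction (as DSSP does) when the
structure has no hydrogens.  The H criterion is what separates the α-helical
i→i+4 ladder from the geometrically close but non-bonded i→i+3 pairs: on the
ideal helix fixture N(i+3)···O(i) = 3.21 Å versus N(i+4)···O(i) = 3.09 Å —
indistinguishable by N···O distance alone — while H···O gives 2.71 Å versus
2.12 Å.  The well depth is half the weakest contact ε ("slightly attractive"
by construction, always below every contact well).

All remaining pairs repel as ε_rep (σ/r)¹² with σ = 3.8 Å (CA), 3.6 Å (SC),
arithmetic-mean combination, ε_rep = 1 kcal/mol.  For pairs that sit closer
than σ in the native structure (tight turns, packed interfaces), σ is capped
at 0.9× the pair's native separation: a Gō model's defining property is that
the native state is a (local) energy minimum, and an uncapped excluded-volume
radius larger than a native separation would build permanent frustration into
the fold.  Exclusions cover exactly the 1–2 and 1–3 bond-graph pairs; 1–4
pairs interact nonbonded.  The contact, hydrogen-bond, repulsive and excluded
sets partition all bead pairs exactly (tested by set algebra).

Every nonbonded term is multiplied by the CHARMM switching function
S(r) = (r_off²−r²)²(r_off²+2r²−3r_on²)/(r_off²−r_on²)³ between r_on = 18 Å
and r_off = 23 Å, zero beyond.  Switching is applied to the energy (forces
from the product rule), the energy-switch dialect; energy and force are
continuous at both edges.  Pair distances below 0.1 Å evaluate at 0.1 Å with
a warning instead of overflowing.  No neighbour list is used: at the few
hundred beads this package targets, exact all-pairs evaluation is cheap, and
the inner loops are numba-compiled (a pure-Python mirror with identical RNG
consumption runs when numba is unavailable; the test suite asserts the two
paths agree to 1e-9).

## Dynamics

Langevin dynamics uses a BBK half-kick/drift/half-kick discretization with
one Gaussian random force per step (variance 2γmk_BT/dt) applied in both
half kicks; the γ = 0 limit is exactly velocity Verlet, which is how the NVE
conservation check is run.  Velocities initialize from Maxwell–Boltzmann at
the bath temperature with centre-of-mass motion removed (COM removal is
skipped for single-bead toy systems, where it would zero the dynamics).
Defaults follow the standard teaching protocol: dt = 1 fs, γ (FBETA) =
5 ps⁻¹, 300 K bath.  Trajectories are bit-reproducible given a seed; random
numbers are generated in blocks outside the compiled stepper so the compiled
and Python paths consume identical streams.  Instantaneous kinetic
temperature uses 3N−3 degrees of freedom.

Minimization is ten steepest-descent steps with a backtracking line search
(energy non-increasing over accepted steps) followed by an L-BFGS
quasi-Newton stage with analytic gradients.  The quasi-Newton stage stands in
for CHARMM's internal adopted-basis Newton–Raphson: the functional contract
(descent to tolerance after a short SD clean-up) is what matters and is what
the tests pin.

Replica exchange holds one fixed temperature per ladder slot and attempts
Metropolis swaps min(1, exp[(β_i−β_j)(E_i−E_j)]) on alternating even/odd
neighbour pairs after every `steps_per_exchange` steps; on acceptance the
coordinates and velocities (rescaled by √(T_i/T_j)) move between slots, so
each output trajectory is continuous in temperature.  Per-replica RNG streams
are spawned from one master seed.  The default ladder is geometric — the
standard choice, since exchange acceptance depends on overlap of energy
distributions that widen roughly multiplicatively with T.

nScale calibration iterates: build model → brief replica exchange → melting
curve → Tm estimate → multiplicative update nScale ← nScale (T_target/Tm)^0.5.
The square-root damping stabilizes the loop against the sampling noise of
brief REX runs; Tm rises monotonically with nScale (deeper wells stabilize
the fold), which the acceptance checks verify on the bundle.  The initial
guess defaults to 1 (no scaling).  A target outside the ladder is rejected
up front with advice to widen it.

## Analysis

Q for a frame is the fraction of native contacts with r ≤ λ·r_native,
λ = 1.2 — the common convention, exposed as a parameter since no single
value is canonical.  A frame is folded when Q > 0.5, matching the definition
of Tm as the temperature of equal folded/unfolded likelihood; both threshold
and λ are configurable.  Fraction-folded uncertainties come from block
averaging (5 blocks) floored by the binomial standard error, because folding
trajectories are strongly time-correlated.  Burn-in defaults to 10% of
frames for simulation data; synthetic stationary series are analyzed with
burn-in 0.

The two-state fit minimizes weighted least squares of
f(T) = 1/(1+exp(−ΔG_u/RT)) with ΔG_u(T) = ΔH(1−T/Tm) + ΔCp[(T−Tm) −
T ln(T/Tm)] — the *unfolding* free energy, zero at Tm, so f(Tm) = 0.5
identically.  Initial guesses: Tm from the interpolated 0.5 crossing, ΔH
from the slope there (df/dT|_Tm = −ΔH/(4RT_m²)), ΔCp = 0.  `estimate_tm`
prefers the fit and falls back to monotone linear interpolation for curves
with fewer than four points; a curve that never crosses 0.5 is an error
(the ladder does not bracket the transition).  Rg is mass-weighted;
RMSD superposes with the Kabsch algorithm (SVD with reflection guard),
typically over CA beads.

## Synthetic data and what the tests show

The fixtures module generates everything the tests need:

- **Ideal helices** from standard internal coordinates (N–CA 1.458, CA–C
  1.525, C–N 1.329 Å; τ = 111.2°; φ/ψ defaulting to −57°/−47°; CB at the
  tetrahedral L-position, C–N–CA–CB = −122.6°).  Consecutive CA distances
  come out at 3.80 Å, and the i→i+4 hydrogen-bond ladder emerges from pure
  geometry.
- **A miniature three-helix bundle**: three 10-residue polyalanine helices
  packed up-down-up on a triangular lattice (inter-axis distance 8.5 Å),
  each rotated so side chains face the core, joined by two-residue glycine
  loops (which also exercise the no-SC-bead code path), with small seeded
  jitter on side-chain atoms so the contact map is not artificially
  degenerate.  The default spec yields 12 native contacts and melts around
  250–300 K at nScale 1 — deliberately marginal, so folding and unfolding
  are both observable in picosecond-scale runs.  Loop geometry is crude by
  construction (interpolated, bowed outward to avoid collinear backbone
  triples); a Gō model takes whatever geometry it is given as native, so
  this costs nothing physically.
- **Synthetic melting data**: per-temperature Q series drawn from the
  two-state closed form, with the folded/unfolded state held over dwell
  segments so the fraction folded carries a sampling error of ≈`noise` at
  the transition midpoint — the correlated error structure block averaging
  is designed to estimate.  Q values come from well-separated folded
  (0.85 ± 0.05) and unfolded (0.20 ± 0.05) distributions.

What passing tests do and do not show: the suite validates mechanics
(forces = −∇E to 1e-4 relative against central differences; energy
conservation in the NVE limit; thermostat and equipartition against closed
forms; Metropolis acceptance and double-well occupancy against 1-D
quadrature; construction against brute-force enumeration; parameter recovery
against the generating model).  It does not validate biophysical realism of
polyalanine mini-bundles: real proteins have heterogeneous side chains,
hundreds of contacts, far slower folding, and experimental Tm/ΔH/ΔCp that
require production-scale replica exchange to reach — runs this package can
set up but which are outside desk-scale testing.

Problem sizes used by the tests and the acceptance script (chosen as
desk-scale study conditions): the 34-residue/64-bead bundle; 10⁴ steps for
NVE drift; 5×10⁴ steps for the thermostat; 2×10⁵ steps for the 1-D
equipartition check; 4 replicas × 1.5×10⁵ steps for the double-well REX
check; 6 replicas × 3×10⁴ steps per melting-curve estimate, 3 seeds per
nScale value for the monotonicity check; 12 ladder temperatures × 2000
frames for the thermodynamic recovery check.

Statistical checks use honest error bars: occupancy comparisons against
quadrature use standard errors inflated by the integrated autocorrelation
time of the indicator series (REX injects long-range correlation that naive
block averaging underestimates), and the 1-D double-well validation system
is deliberately light (mass 1 amu, barrier ≈ 2 kcal/mol, ladder 300–850 K)
so that well-hopping is fast and the error estimates are well calibrated
within a few-minute budget.

## Numerical details worth knowing

- Dihedral angles use the IUPAC sign convention everywhere (trans = 180°);
  analytic dihedral/improper gradients were validated component-wise against
  finite differences.
- Improper deviations are wrapped to (−180°, 180°] before squaring.
- The NVE "drift" metric compares the first-decile and last-decile means of
  the total energy: velocity-Verlet energy oscillates reversibly at the step
  frequency, and max−min would measure that oscillation, not drift.
- Energies beyond |E| > 10¹⁰ kcal/mol abort dynamics with a diagnostic
  suggesting a smaller step or re-minimization.
- CG PDB files store the bead mass in the occupancy column so a CG structure
  round-trips without its all-atom parent; trajectories are multi-model PDB
  with per-frame `REMARK 6 TIME_PS` records (positions to PDB precision,
  10⁻³ Å).
- The CHARMM RTF/PRM/CRD emitters give every bead its own atom type so
  native wells map onto NBFIX entries; the r⁻¹² repulsion has no exact LJ
  12-6 equivalent and is approximated per-type with an LJ minimum at
  2^{1/6}σ (noted in the emitted file header).

## Known limitations

Single chains only; one contact potential shipped (pluggable interface for
others); no disulfides; no mmCIF input; no PDB download client; no explicit
electrostatics or implicit-solvent models (incompatible with this model
class by design); no SHAKE (a CG model has no fast bond vibrations that
need constraining); melting-curve uncertainties assume roughly independent
blocks, which very short REX runs can violate.
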