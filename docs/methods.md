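# Methods

This document describes the models implemented in `allokin`, the
parameters they expose, the numerical choices behind the defaults, and
the limits of what the package's toy systems can say about real
allosteric proteins.

## 1. Physical picture

Many allosteric enzymes — SHP2 phosphatase is the motivating example —
interconvert between an autoinhibited (inactive, "closed") and a
catalytically competent (active, "open") conformation. An allosteric
inhibitor binds at the interface of the closed form, stabilizing it and
raising the free-energy barrier for opening. The package models this
story at three levels:

1. a two-dimensional model free-energy landscape over a pair of
   collective variables (CVs), explored by well-tempered metadynamics;
2. transition-state-theory (TST) rates and equilibrium constants derived
   from barriers on that landscape, fed into an allosteric
   Michaelis–Menten rate law;
3. machine-learned classification of trajectory-derived features with
   per-feature attributions, validated on synthetic data with planted
   ground truth.

## 2. Model potentials and sampling (`allokin.metad`)

### Double-well potential

`make_double_well(separation, barrier, asymmetry)` builds

U(x, y) = −A₁·exp(−|r − c₁|²/2s²) − A₂·exp(−|r − c₂|²/2s²) + ½·k_conf·(y − y₀)² + C

two isotropic Gaussian wells (width s = 1.0 CV units) on a line at the
given CV-1 separation, harmonically confined in CV 2
(k_conf = 10 kJ/mol per CV unit²). The depths A₁, A₂ and offset C are
solved numerically (`scipy.optimize.root`, hybrid Powell) so that the
*exact* critical-point energies are: global minimum 0, second minimum =
`asymmetry`, saddle = `barrier` (all kJ/mol). Convergence is accepted
when the maximum residual is below 1e−9; the solver's own progress
heuristic is ignored because it can report failure at machine-precision
residuals. Analytic gradients are provided and verified against finite
differences in the tests.

Defaults used throughout: separation 4 CV units, barrier 20 kJ/mol,
asymmetry 0 — wells at (3, 5) and (7, 5), saddle at (5, 5).

### Langevin sampler

`sample_langevin` integrates overdamped (Brownian) dynamics

x ← x + (Δx²/2kBT)·(−∇U) + Δx·ξ,  ξ ~ N(0, 1)²

parameterized directly by the per-step displacement scale `step_size`
(default 0.05 CV units) rather than a mobility and time step; this makes
the diffusion constant explicit and keeps the Boltzmann distribution
exact in the small-step limit. Temperature default 310 K with
kB in kJ/mol (R = 0.008314 kJ/mol/K). Walls at the potential's stated
bounds are reflecting. A step whose energy is non-finite raises
`UnstableStepError`.

### Well-tempered metadynamics

Every `deposition_interval` steps (default 500; calibrated runs use 200)
a Gaussian hill is deposited at the current CV position with width
σ = (0.30, 0.30) CV units and height

w = w₀ · exp(−V_bias(x)/((γ − 1)·kB·T)),

w₀ = 1.20 kJ/mol, bias factor γ = 10. The free energy is recovered as
F = −(γ/(γ−1))·V_bias, shifted so min F = 0. Bias evaluation during long
runs uses a cached grid with bilinear interpolation, rebuilt
incrementally per hill; reconstruction (`reconstruct_fes`) sums hills
analytically on the requested grid. Hills are serialized in a 7-column
text format (time index, center, σ, height, γ) with line-precise parse
errors.

Calibration for the headline recovery experiment (own choice, sized for
one CPU): 4,000,000 steps, hill every 200 steps → 20,000 hills, ≈40 s.
At these settings a 20 kJ/mol barrier is recovered within 2 kJ/mol
(observed errors 0.2–1.4 kJ/mol across seeds), deposited hill heights
decay by more than 40%, and the pointwise spread between free-energy
checkpoints at 2,000/6,000/20,000 hills decreases monotonically.

## 3. Landscape analysis (`allokin.fes`)

`FESGrid` stores a regular 2-D grid (values in kJ/mol) with origin and
spacing, CSV + JSON-sidecar persistence, and bilinear lookup. Minima are
strict interior 8-neighborhood minima below an energy cap.

The minimum free-energy path between two cells is the **widest-path
(minimax) Dijkstra** solution: the path minimizing the maximum energy
along it. The forward barrier is max-along-path minus the source energy.
A `boltzmann-sum` mode instead minimizes the log-sum-exp of cell
energies (temperature-weighted soft maximum); it upper-bounds the
minimax cost and converges to it at low temperature. Second paths are
obtained by masking a Chebyshev ball around the first path's highest
point and re-solving.

Two independent oracles validate the solver: (1) branch-and-bound
depth-first enumeration of simple paths, exact because it only prunes
branches that provably cannot beat the incumbent; (2) a percolation
oracle that binary-searches the smallest threshold at which source and
target are connected through cells at or below it. All three agree on
100/100 random 6×6 grids (both 4- and 8-connectivity).

Convergence between checkpointed surfaces is measured after re-anchoring
each to min 0, as the maximum pointwise deviation over the union of
cells below an energy cap (default 30 kJ/mol).

## 4. Rates and inhibition kinetics (`allokin.kinetics`)

Rates use TST with a unit prefactor by default,

k = exp(−ΔG‡ / RT),   R = 0.008314 kJ/mol/K, T = 310 K,

which makes a barrier table directly interconvertible with a rate table;
the Eyring prefactor kBT/h is available via `prefactor="eyring"` when
absolute time scales matter. From a pair of barriers (active→TS,
inactive→TS) the opening equilibrium constant is
Ka′ = k_active/k_inactive. Binding free energies convert to/from IC50 as
ΔG_exp = RT·ln(IC50 in molar units of μM·10⁻⁶... ) — concretely
`dg_exp_from_ic50(ic50_uM, T) = R·T·ln(ic50_uM·1e−6)`. A composite
potency 1/(Ki′·Ka′) combines binding affinity for the closed state with
the cost of opening.

The allosteric Michaelis–Menten law for an inhibitor binding only the
closed state (dissociation constant Ki′) coupled to the conformational
equilibria Ka (free) and Ka′ (inhibitor-bound):

α  = 1 + [I]/Ki′ + 1/Ka + [I]/(Ki′·Ka′)
α′ = 1 + [I]/Ki′
v  = Vmax·[S] / (α·KM + α′·[S])

so KM_app = α·KM/α′ and Vmax_app = Vmax/α′. A `conventional` variant
adds a competitive term [I]/Ki to α. Properties verified: at [I] = 0 and
Ka → ∞ the classical MM law is recovered; Vmax_app is strictly
decreasing and KM_app non-decreasing in [I]; α ≥ α′ always (mixed
noncompetitive behavior preferring the free enzyme), and the
classification helper names the regime from (α, α′).

Units: all energies kJ/mol, concentrations molar (IC50 inputs in μM
where the function name says so), rates s⁻¹ under the Eyring prefactor
and dimensionless relative rates under the unit prefactor.

## 5. Trajectory featurization (`allokin.featurize`)

Multi-model PDB I/O via biotite plus a minimal XYZ reader. Implemented
descriptors: RMSD with Kabsch superposition, (axis-resolved, mass-
weighted) radius of gyration, Shrake–Rupley SASA (default 960 sphere
points, probe 1.4 Å, coincident atoms deduplicated), backbone φ/ψ
dihedrals, geometric hydrogen-bond counting (donor–acceptor < 3.5 Å,
D–H···A angle > 120°, with a heavy-atom proxy mode), and group
distances (center of mass or minimum heavy-atom). Residue–residue
contact matrices use a k-d tree (verified against the brute-force double
loop) with min-heavy-atom distances, exclusion of sequence neighbors,
and cutoff-fill for non-contacts.

Protein–ligand interaction fingerprints classify per-residue contacts
into seven geometric classes (hydrophobic, hydrogen bond, halogen bond,
π-stacking, π-cation, salt bridge, water bridge) using standard
distance/angle rules (e.g. stacking: ring centroids < 5.5 Å, tilt < 30°
or 60–90°; salt bridge < 5.5 Å between opposite formal charges, with a
carboxylate/guanidinium heuristic when formal charges are absent).
A frequency filter keeps interactions present in strictly more than a
given fraction of frames (default 0.40).

## 6. Learning and attribution (`allokin.ml`)

Binary activity labels derive from IC50 with a 0.050 μM threshold
(boundary value is "weak"). Splits are random-row or grouped (group IDs
never straddle the split). The primary model is an XGBoost
gradient-boosted tree classifier/regressor (defaults: 500 trees, depth
11, learning rate 0.1, min child weight 4); k-NN, logistic/linear, random
forest, SVM and decision-tree baselines are available through the same
interface.

Attribution for tree models uses the exact TreeSHAP algorithm built into
XGBoost (`pred_contribs=True`), explaining the margin; for non-tree
models a seeded permutation-sampling Shapley estimator is used (each
sampled permutation telescopes exactly, so additivity holds to machine
precision). Additivity — base value plus contributions equals the model
output — is checked and reported as a residual. Features are ranked by
mean |attribution| with alphabetical tie-breaks; an optional
directionality statistic reports how often high feature values push the
margin positive.

Evaluation schemes bundle featurization source, task and replication:
three classification schemes (trajectory descriptors, fingerprints,
contacts → activity class) and one regression scheme (contacts → binding
free energy), each reporting per-replicate and mean/std metrics.

## 7. Synthetic generators with known truth (`allokin.synth`)

All generators are seeded and emit machine-readable truth:

- `gen_feature_table`: n×p Gaussian feature table (default 2000×200)
  with a planted subset of columns (default 5) shifted by
  `effect_size`·label (binary) or linearly coupled (continuous), plus
  group IDs for grouped splits.
- `gen_inhibitor_panel`: compound panel whose IC50, Ki′, Ka′ and ΔG
  satisfy the kinetic relations exactly (plus optional noise).
- `gen_two_state_trajectory`: a 12-residue toy protein whose planted
  residue pairs are in contact in state 0 and displaced by 4 Å in
  state 1, written as multi-model PDB with a truth sidecar.
- `gen_fes`: a smooth 2-D surface whose minimax barriers equal
  prescribed saddle energies, built from cosine-profile valleys between
  prescribed minima.

These generators exist so that every analysis stage can be tested
against known ground truth; they make no attempt to mimic the
statistics of real MD data.

## 8. Numerical choices and problem sizes

Chosen so the full test suite runs in minutes on one CPU:

- metadynamics recovery: 4M steps / 20,000 hills (≈40 s); FES grids
  41×81 over CV-1 ∈ [1, 9], CV-2 ∈ [3, 7];
- path-solver cross-validation: 100 random 6×6 grids (branch-and-bound
  enumeration is exponential; 6×6 keeps it < 2 min total);
- ML recovery: 20 runs at 2000×200 with 200 trees (≈5 s/run);
  permuted-label nulls averaged over 5 runs because a single held-out
  accuracy has σ ≈ 0.02 at 600 test rows;
- "3 significant figures" agreement is enforced as relative tolerance
  5×10⁻³ (half-ulp of the third significant digit).

## 9. Limitations

- The landscapes are 2-D toys: no real CVs, no molecular detail, no
  solvent, and barrier heights are inputs, not predictions.
- Unit-prefactor TST gives *relative* rates only; absolute rates would
  need a physical prefactor and a transmission coefficient.
- The allosteric MM law assumes rapid equilibrium, a single inhibitor
  site on the closed state, and no substrate–inhibitor ternary effects
  beyond the α/α′ coupling.
- The featurizer's hydrogen-bond and fingerprint rules are geometric
  heuristics without energetics or protonation-state inference.
- Published figures from large-scale MD studies of real systems —
  cross-scheme model accuracies, MM/GBSA energy ranges, absolute
  landscape topographies — are not reproducible at this scale and are
  deliberately out of scope; the test suite checks the *properties* of
  each method on synthetic truth instead.
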