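# Methods

## The model

A chain of *n* residues, each labelled A (hydrophobic) or B
(hydrophilic), joined by rigid unit-length bonds in 3D.  A conformation
is the parameter vector (θ₁…θₙ₋₂, β₁…βₙ₋₃), all angles stored wrapped to
(−π, π] (a canonical representative avoids drift in the tabu-distance
computations).  The energy is

E = Σᵢ ¼(1 − cos θᵢ) + 4 Σ_{j≥i+2} [ r_ij⁻¹² − C(ξᵢ,ξⱼ) r_ij⁻⁶ ],

with C = +1 (AA), +½ (BB), −½ (AB/BA).  The first sum is a bending
penalty on the θ parameters; the second is a species-dependent
Lennard-Jones term over all residue pairs at least two bonds apart.  If
any pair distance falls below 1e−8 the energy is the +∞ sentinel rather
than an overflow, which keeps the optimizer total without exceptions
mid-search.

## Geometry: the calibrated convention

The benchmark literature prints angle vectors and the energies attained
at them, but the coordinate construction is stated only for the first
three residues, and its printed fragment is not even unit-bond
consistent.  We therefore treat the construction as an empirical
question.  `calibrate_convention` enumerates six candidate conventions
in two families and keeps the one whose energies at the printed angle
vectors best reproduce the printed minima (worst-case absolute
deviation; calibration FAILS if even the winner misses by more than
0.05):

* **fixed-axis** (selected): bond directions given in lab-frame
  spherical coordinates — bond 1 = (0,1,0), bond 2 = (cos θ₁, sin θ₁, 0),
  bond i = (cos θᵢ₋₁ cos βᵢ₋₂, sin θᵢ₋₁ cos βᵢ₋₂, ±sin βᵢ₋₂) — and
  coordinates by cumulative sum.  This reproduces all four benchmark
  minima to ~1e−4 (the printed angles carry five decimals), which is at
  the rounding floor, so the selection is unambiguous.
* **relative**: classic internal coordinates (θ = inter-bond angle,
  β = dihedral), with supplement and handedness variants.  These miss
  the benchmark energies by orders of magnitude and are rejected; the
  family is retained in the package because it is the textbook reading
  and the natural foil for the calibration.

Two consequences of the fixed-axis convention are worth noting.  First,
θᵢ is a lab-frame direction, not the angle between successive bonds, so
the bending term is a function of the parameters rather than of the
local geometry; θ = 0 is not a straight chain.  Second, the map from
parameters to shapes is two-to-one ((θ, β) and (θ+π, π−β) give the same
bond), and the two representatives have different bending energy; the
optimizer simply searches the parameter space, where the energy is
well-defined and smooth.  Mirror symmetry (torsion sign) does not affect
any distance, hence not the energy — the right-handed variant is the
tie-break default.

The bundled benchmark data (four Fibonacci rows with reference energies
for five optimizers and the minimum-energy angle vectors; three real
proteins with two reference energies each) lives in a versioned JSON
fixture pinned by a SHA-256 checksum, so silent edits are detected at
load time.

## Sequences

Fibonacci words follow S₀ = A, S₁ = B, Sᵢ₊₁ = Sᵢ₋₁Sᵢ; indices 6, 7, 8
and 9 give the 13-, 21-, 34- and 55-residue benchmark chains.  Real
sequences are reduced with the binary hydrophobicity partition:
I, V, L, P, C, M, A, G → A, the remaining twelve standard residues → B.
Chains shorter than three residues are rejected (no bond angle, no
nonbonded pair).

## The optimizer

The search alternates two tabu-augmented genetic operators over an
energy-sorted population:

**TSR (recombination).** Each generation, ⌈0.88·|P|⌉ parents are drawn
from below the top decile (the top 10% are treated as near-duplicates of
the best and left untouched) and crossed, by default with the incumbent
best: offspring c = r₁a + (1−r₁)b, then c ← c + r₂(best − c), with r₁,
r₂ ~ U(0,1) drawn once per crossover.  An offspring below the population
mean energy (the "desired level") is accepted outright; one above the
mean is accepted only if its energy is not within ψ of a FIFO list of
recently accepted energies; otherwise the better parent survives.  An
alternative pairing mode (furthest-distance greedy matching among the
parents) is available via `cross_with_best=False`.

**TSM (mutation).** A few parents (mutation rate × |P|, chosen by linear
ranking with pressure 2.0) each run a chain of 80 tabu-search steps.
One step disturbs the current solution 30 times — early in the schedule
a matched (θ, β) pair steering one bond (so the move reorients a bond
and rigidly translates the downstream segment), late a single parameter
— sorts the neighbors, takes the 5 lowest as candidates, and accepts the
first candidate that either beats the global best (aspiration) or is not
tabu.  Accepting the best candidate even when it is uphill is what gives
the operator hill-climbing power.  A candidate is tabu iff some stored
solution y satisfies BOTH |E(y)−E(h)| ≤ ψ AND ‖y−h‖ ≤ η (wrapped
angular differences).  If all candidates are tabu ("total tabu") the
chain restarts from a disturbance of the global best.  The paired
solution/energy tabu lists evict FIFO; their length starts at 7, grows
by one on each total-tabu event and shrinks by one after 50 event-free
additions, clamped to [7, 14].

**Disturbance.** A parameter moves by s·λ·(1 − r^((1−α)^b)) with random
sign s, r ~ U(0,1), scale λ = π and shape b = 1: at search progress
α = 0 the shift is uniform on (0, λ); as α → 1 it vanishes.  Within a
TSM chain the effective α ramps from the run-level progress up to
(chain length − 1)/chain length, so each chain performs one
coarse-to-fine descent regardless of when it runs.

**Population control.** When the best energy comes within 1% (relative)
of the population mean the population has converged and grows by 10%
fresh random individuals (clamped at 500); when the gap exceeds 2% it
shrinks by dropping the worst 10% (never below 100).  The incumbent best
is never crossed over or mutated in place, so the best energy is
non-increasing — the elitism the ranking-selection strategy calls for.

**Run organisation.** A budgeted run spends half of its search budget on
three short exploration epochs — independent sub-searches with fresh
populations, tabu memory and annealing schedules — and the other half on
a refinement epoch whose population is seeded with the best conformation
found.  This addresses a measured property of the landscape: which basin
a search commits to is essentially decided in its first quarter, after
which progress is slow refinement, so independent draws at the start are
worth more than one long anneal.  The final 10% of the budget is a
greedy polish: single-parameter (or matched-pair) Gaussian steps with a
scale annealing geometrically from 0.2 to 0.002 rad, accepting only
improvements.  TSM's uphill acceptance — necessary during search —
means chains never settle into the bottom of the final basin; the polish
recovers that depth (typically 0.3–0.9 energy units) at one evaluation
per move.  All stages share one seeded RNG stream and one evaluation
counter, and the budget is checked between operator applications, so a
run can overshoot it only by one neighborhood batch, population
initialization or growth step.

### Parameters

| parameter | default | origin |
| --- | --- | --- |
| population bounds | 100–500 | published setting |
| crossover rate | 0.88 | published setting |
| mutation rate | 0.025 | published range 0.012–0.025 |
| tabu length | 7–14, self-adjusting | published range |
| neighborhood / candidates | 30 / 5 | published ranges 30–50 / 5–6 |
| ψ (energy closeness) | 0.01·\|E_current\| + 1e−6 | package default |
| η (solution distance) | 0.1·√(2n−5) | package default |
| λ (disturbance scale) | π | package default |
| TSM chain length | 80 steps | package default |
| selection pressure | 2.0 (linear ranking) | package default |
| epochs / polish | 3 + refine / 10% of budget | package default |
| stopping | 500 generations or 100 stagnant; benchmark runs cap evaluations at 2×10⁵ | package default |

Values outside the published ranges are rejected unless explicitly
overridden (with a warning).  The package defaults marked "package
default" fill gaps the published description leaves open; the mutation
rate and neighborhood size sit at the range edges because, with deep TSM
chains, fewer/denser chains measured better than many shallow ones.

## Verification strategy

* The deterministic core is checked against the published data: the
  printed angle vectors must reproduce the printed minima to ±0.01
  (±0.02 for the 55-mer, whose longer sums accumulate more rounding).
* On 4- and 5-residue chains the optimizer is compared with independent
  brute-force oracles: an exhaustive vectorized grid (step 0.025 rad)
  over the three parameters of a 4-mer, and a coarse grid (0.3 rad) with
  simplex polish over the five parameters of a 5-mer; the optimizer must
  come within 0.05 of the oracle minimum on every seed tried.
* Invariants under property tests: unit bonds; canonical frame;
  energy/distance-table consistency to 1e−9; rigid-motion invariance;
  bend-term parity in θ; wrap-angle canonicalisation; FIFO tabu
  eviction and the conjunction criterion; uphill TSM acceptance in
  seeded runs; bitwise determinism under a fixed seed; evaluation-count
  accounting.

These tests run on synthetic random conformations and the bundled
printed benchmark rows; none of them involve real protein structures,
so passing them shows the model and optimizer are implemented as
specified, not that the coarse-grained model predicts real folds.

## Benchmark performance and limitations

At the published parameter settings and a budget of 2×10⁵ energy
evaluations per restart, the optimizer reliably beats the simulated-
annealing record on the 13-mer (best over 3 restarts typically −5 to
−6.8).  On the 21-mer and the classified 1BXL peptide it reaches the
prior-art records (−12.06 and −15.72) in roughly one restart in six, so
3–5 restarts sometimes fall short by 0.5–1 energy units; the records
themselves were set by much longer runs.  Matching the hybrid's own
published records (e.g. −6.9539 on the 13-mer, −46.08 on 1AGT) by
optimization at desk scale is not expected; those numbers are carried as
references in the benchmark table, not as pass/fail gates.

Other known limitations: the model is dimensionless and coarse-grained —
exported PDB/XYZ files are toy geometries (model units written as Å
verbatim), not stereochemically valid structures; no solvent, side
chains or physical force field; no gradient-based local minimization
(the polish stage is derivative-free by design, matching the method
family); single-threaded.
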