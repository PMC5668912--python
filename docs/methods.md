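# Methods

## Scope and intent

This toolkit implements, at desk scale, the machinery needed to state
and test the low-mass sampling-enhancement claim: that uniformly
scaling atomic masses by λ = 0.1 accelerates configurational sampling
per integration step, and that the effect is equivalent to integrating
the standard-mass system with a √(1/λ)-times longer time step.  It is
not a production MD code: there are no periodic boundaries, no barostat,
no Ewald electrostatics, no explicit solvent, and no protein
forcefields.  Toy systems (bead chains, Lennard-Jones clusters) stand
in for solvated proteins; the analysis pipeline, however, is the full
one used by β-hairpin folding studies and operates unchanged on any
per-frame RMSD series.

## The engine

Velocity Verlet in Å / fs / amu / kcal·mol⁻¹ units with the single
conversion constant 4.184×10⁻⁴ Å fs⁻² per (kcal mol⁻¹ Å⁻¹)/amu and
k_B = 0.0019872 kcal mol⁻¹ K⁻¹.  Potential terms: harmonic bonds and
angles (½k(x−x₀)²), cosine torsions ((V/2)(1+cos(nφ−γ))), and 12-6
Lennard-Jones pairs.  Forces are analytic gradients, validated against
central finite differences to 1e-6 relative in the tests; translation
invariance (zero net force) and momentum conservation are asserted as
properties.

**SHAKE.**  Pair-distance constraints are enforced after the drift by
iterative mass-weighted corrections along the pre-drift bond vectors
(relative tolerance 1e-8, at most 500 sweeps — defaults chosen in the
AMBER spirit).  Non-convergence raises an error carrying the step
index rather than passing silently, so the classic too-long-time-step
failure mode is observable.  Velocities are RATTLE-projected after the
second half-kick so the kinetic energy seen by the thermostat is
consistent with the reduced degrees of freedom.  Note a structural
property: SHAKE's projection equals the exact mass-weighted
least-change projection only to first order in the displacement (the
tests compare against an SLSQP oracle at 1% perturbation, where the
two agree to ≤ 1e-6 Å; at 5% they differ at the 2e-5 Å level, scaling
quadratically).

**Thermostat.**  Berendsen weak coupling:
v ← v·√(1 + (Δt/τ_T)(T₀/T − 1)), with T = 2·KE/(N_dof·k_B) and
N_dof = 3n − n_constraints.  Initial velocities are drawn directly
from the Maxwell–Boltzmann distribution at the target temperature
using the run seed — a deliberate simplification of the staged-heating
protocols used in production studies; at toy scale the difference is a
short transient.  Berendsen on very small systems suppresses canonical
fluctuations; consequences for the double-well calibration are noted
below.

**Run contract.**  Frames are saved every `save_interval` steps
starting at step `save_interval` (the initial conformation is not a
frame); a run is bitwise reproducible from (system, config, seed).
The force kernel evaluates batches of replicas, shape (R, n, 3), in
one vectorized pass; the double-well crossing ensembles use this to
integrate all replicas simultaneously.

## Mass scaling and the two time conventions

`scale_masses` multiplies every mass by λ and touches nothing else —
the physical composition of the system is unchanged.  Two time
conversions are exposed and must be named explicitly at every call:

* `THEORETICAL` (factor 1/λ): the time-*unit* relation obtained by
  holding length and energy units fixed; at λ = 0.1, 1 fs of
  standard-mass time corresponds to 10 fs of low-mass time.
* `NUMERICAL` (factor √(1/λ)): the factor under which the
  velocity-Verlet position recurrence of the λ-scaled system is
  *identical*, step for step, to the standard-mass system —
  x ← x + vΔt + ½(F/m)cΔt² is invariant under
  (m, Δt, v) → (λm, Δt, v/√λ) vs (m, Δt√(1/λ), v).

`verify_time_scaling` runs both systems side by side and reports the
maximum position deviation; for the 10-particle LJ cluster over 10³
steps it is at the 1e-12 Å floating-point floor, and using the
factor 10 instead of √10 diverges beyond 0.1 Å within the same span
(also a test).  Under the velocity mapping the per-step kinetic
energies of the two runs agree to 1e-10 relative, so temperature is
preserved.  The kinetics time axis credits each step
`effective_dt = Δt·√(1/λ)` of standard-mass time — the convention
consistent with trajectory identity, and the one that reproduces the
benchmark tables' aggregated-time columns (20 runs × 500×10⁶ steps at
λ = 0.1, Δt = 1 fs → 31.6 μs).  In equivalence tests with a
thermostat, τ_T must be scaled by the same √(1/λ) factor.

## Structure metric

CαβRMSD: select CA and CB atoms (glycine-like residues contribute only
CA), pair mobile and reference by (residue id, atom name), superpose by
the Kabsch SVD solution with the determinant forced to +1 (no
reflections), unweighted, and take the RMS residual.  Each trajectory
frame is superposed independently.  The native cutoff defaults to
1.96 Å and is everywhere a parameter, never a constant baked into the
pipeline: the value sits at the gap between NMR- and
crystal-determined native β-hairpin conformations (1.95 Å apart), so a
tighter cutoff would misclassify crystallographic natives, and
sensitivity analyses need to move it.  The boundary is inclusive
(RMSD = cutoff is native).

## Kinetics

*Populations.*  Individual population = native frames / all frames;
aggregated population = mean over N runs, with SD using the N−1
denominator and SE = SD/√N.  This SE rule reproduces every printed
(SD, SE) pair in the packaged benchmark tables once the integer
rounding of both printed values is accounted for (both roundings must
be modeled: SD 20 with SE 5 is consistent only because the underlying
SD was above 20).  Percentages are kept at full precision internally
and integer-rounded in table-style CSV output.

*First passage.*  The folding time of a run is the time of the first
saved frame at or below the cutoff ((index+1)·save_interval·
effective_dt); a run that never crosses contributes its full duration
as a right-censored observation.  The discretization bias is
one-sided: the recorded time is never below the true crossing time and
at most one save interval above it — the synthetic module returns
exact ground-truth transition times alongside the emitted series so
this bias is measurable.

*Survival estimation.*  The Kaplan–Meier product-limit curve comes
from lifelines; the mean is the area under the curve restricted to the
largest observed time, with a 95% CI from the Greenwood variance of
that restricted mean.  The exponential fit is the closed-form MLE
τ̂ = (total exposure)/(events), CI exp(ln τ̂ ± 1.96/√events) — a
log-normal approximation chosen as a standard convention; nothing
downstream depends on the specific CI recipe.  The two-step procedure
for a full-length all-event set compares the KM mean with the MLE and
selects the parametric model when they agree within 1% relative
("identical" operationalized with an explicit tolerance).  With no
censoring the two means coincide *identically* (both equal the sample
mean), so the disagreement branch is structurally unreachable for such
sets; it exists for defensive completeness.  Sets with censored runs
use the exponential fit.  A *shortened* set in which half or more runs
are censored is refused outright — its confidence interval would be
uninformatively wide.

*Two-state diagnostics.*  `ln_nonnative_regression` fits
ln(fraction not yet folded) against time by OLS; under D ⇌ N the slope
is −k_f.  The natural evaluation grid is the observed event times
(mirroring how such plots are drawn from individual folding times).
Monte-Carlo calibration at N = 20, τ = 100 ns: ln-linearity r² > 0.9
holds in 92% of replicates, but the slope-based τ estimate has ≈25%
coefficient of variation — necessarily so, since even the efficient
estimator (the sample mean) has CV 1/√20 ≈ 22% — so per-replicate
agreement within 30% cannot exceed ~82% for any estimator.  The tests
assert the achievable rates.

*Curve comparison.*  Population-vs-time curves from two conditions are
compared with a pooled-variance unpaired Student t-test
(df = n_a + n_b − 2, two-tailed), checkpoints paired by equal step
count.  This variant exactly reproduces the published P values 0.2465
and 0.0239 from the 10-row CLN025 table curves.  The two chignolin
comparisons print P = 0.4788 and 0.0299 but their tables print
integer-rounded means; recomputation from the printed integers gives
0.4924 and 0.0297.  Propagating the ±0.5% printing granularity through
the test statistic (seeded Monte Carlo) produces an uncertainty band
that contains both the printed and the recomputed values, and the
acceptance tests assert exactly that — a band derived from the
printing precision, not tuned to the observation.

## Synthetic data

*Two-state simulator.*  A continuous-time Markov chain on {D, N} with
exact exponential dwell times; per-frame pseudo-RMSD emitted uniformly
from U(1.0, 1.9) Å in the native state and U(2.5, 8.0) Å otherwise.
The emission ranges keep a ≥ 0.05 Å margin on each side of the 1.96 Å
cutoff so classification can never be boundary-ambiguous, and the
native range mimics observed folded-state RMSDs of ~1.5 Å.  Both the
emitted series and the exact first D→N transition times are returned.

*Double well.*  A four-bead chain whose single torsion carries
(barrier/2)(1 + cos 2φ): two exactly degenerate minima at φ = ±π/2
separated by the stated barrier (default 2 kcal/mol).  The reaction
coordinate |φ − π/2| is mapped linearly onto [0, 8] Å so the standard
cutoff machinery classifies basins.  Bond and angle force constants
are deliberately unequal (45/50/55 and 25/35): a symmetric chain has
nearly decoupled normal modes and its torsion thermalizes too slowly
to cross on test timescales.  The crossing-study bath temperature is
a pilot-calibrated fixture, 900 K (k_B·T ≈ barrier): Berendsen weak
coupling on four beads suppresses canonical fluctuations well below
Langevin expectations, so a naive k_B·T ≈ barrier/3 choice produces
essentially no crossings.  With the calibrated fixture, 24 replicas
per mass factor and a 12 000-step cap, ~80% of low-mass replicas
cross; the λ = 0.1 and λ = 1 batches share initial-velocity draws, so
the sign test on paired first-passage step counts is strongly powered
(18/21 informative pairs, p ≈ 7×10⁻⁴).  Replicas that never cross
within the cap are treated as censored; pairs censored on both sides
are uninformative and dropped.

*Benchmark tables.*  The packaged CSVs transcribe the four published
20-run folding tables (CLN025 under FF14SBlm/FF14SB at Δt = 1.00,
2.00, 3.16 fs; chignolin under FF12MC/FF12MCstdm at Δt = 1.00, 2.00,
3.16 fs), including the τ_f columns with 95% confidence limits and
event counts where printed.  Each file carries a SHA-256 checksum
verified on load, so a correction is a data change, not a code change.
Row counts and the SE ≤ SD invariant are asserted on load.

## What passing tests do and do not show

The synthetic generators exercise the *analysis* pipeline under its own
model assumptions: exact exponential kinetics, unambiguous emission
ranges, perfectly independent replicas.  Real folding trajectories
have correlated frames, non-exponential early-time behavior, and RMSD
distributions that straddle the cutoff; passing here shows the
estimators are correct, not that the two-state model fits any given
protein.  Likewise the double-well demonstrates the per-step sampling
acceleration mechanism, not the full claim about solvated proteins —
production concerns (solvent viscosity, barostat coupling, SHAKE
stability at Δt ≥ 3.16 fs on real bond networks) are out of scope.

## Problem sizes

Chosen so the full suite runs in well under a minute of CPU: 10⁵-step
NVE conservation runs, 10³-step equivalence checks, 12 000-step
crossing ensembles of 24 replicas (vectorized batch), 500-replicate
Monte-Carlo estimator recovery, and 200-replicate regression
calibration.  Expensive simulations are session-scoped pytest fixtures
computed once.
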