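# Methods

This note records the model the package implements, the parameter choices
that matter, the design decisions taken where the design was genuinely
open, and what the synthetic data do and do not show.

## Dominance machinery

Objectives are always minimized internally. Non-dominated sorting uses the
classic counting scheme (number of dominators per solution, iterative
peeling of the zero-count front) with an O(n²) vectorized dominance matrix;
no faster sorting variant is attempted. Crowding distances are computed per
front with a stable sort and the index as tie-break, so results are
deterministic under exact objective ties. A degenerate objective
(max = min within a front) contributes zero to interior crowding — there is
no information to discriminate on that axis. Fronts of size ≤ 2 are
all-infinite.

Constraints enter through feasibility-first dominance: a feasible solution
dominates any infeasible one, among infeasible solutions the smaller
aggregate violation wins, and objective dominance applies only between
feasible solutions. This realizes inequality/equality constraints as a
single violation measure without penalty-weight tuning.

The external archive keeps the non-dominated set of everything it has been
offered, capped at a capacity (default 100, matching the population size —
the capacity is exposed as configuration since nothing in the method fixes
it). Exact duplicates of a stored objective vector are dropped,
first-inserted wins, so clones cannot flood the archive. Truncation removes
the lowest-crowding member one at a time and recomputes crowding after
every removal; one-shot removal can delete adjacent points together and
leave gaps.

## The optimizer loop

Each generation, every individual either *hunts* (probability TR = 0.3) or
*mates* (uniform crossover with a random population member, per-gene
probability CR = 0.2). Hunting picks one behaviour from a weighted mixture;
with k = 1 − t/t_max:

- long-range jump, weight k — fades as the run progresses;
- difference move, weight 1 — persistent; its step is scaled by the spread
  of the current population, so it self-adapts from coarse exploration to
  fine refinement as the population converges;
- chase toward an archive leader, weight k — its speed factor
  C = C₀(1 − t/t_max) with C₀ = 2 already decays to zero, so the weight
  fades with it rather than spending late evaluations on near-identity
  moves;
- per-dimension contraction escape, weight 2 — persistent and deliberately
  the heaviest behaviour (see below);
- nesting around a leader, weight 1 — persistent refinement.

Before the mixture, a distance gate applies: if the selected leader is
further than 0.5·‖H−L‖·(1 − t/t_max) away, the individual falls back to the
long-range jump (the prey has escaped out of reach; chasing it would be a
wasted move).

Leaders are chosen by binary tournament on crowding distance among archive
members (higher crowding wins, ties uniform), which biases guidance toward
sparse regions of the current front estimate.

**Survival.** Offspring from mating are discarded if their own parent
dominates them; all other offspring always compete. Survivors are the best
N(t) of parents ∪ offspring by (rank, crowding distance) lexicographic
order. Two pure per-parent acceptance schemes were evaluated first and
rejected: without global rank-based survival the population performs a
weakly-selected random walk and the three-objective problems converge an
order of magnitude short of the front.

**Diversity anchors.** For each objective, the feasible member with the
*largest* value of that objective is always retained through survival
truncation. This guards against a failure mode observed on concave fronts:
a single early near-optimal corner solution (e.g. f = (0, 1) on a concave
bi-objective front) can dominate every not-yet-converged member of the
population at once; the archive then degenerates to that one point, all
guidance pulls into the corner, positional diversity is extinguished, and
the run is permanently absorbed into a one-point front. With the anchors
the worst-per-objective members survive as diversity reservoirs and the
collapse does not occur (0/25 seeds across several seed sets, against
~20% collapse without them).

**Why the escape carries weight 2.** The escape multiplies each coordinate
independently by U(−1, 1). It is the only behaviour that re-samples
individual coordinate values, which makes it the supplier of fresh
"alleles" on multimodal separable landscapes (Rastrigin-type ZDT4): when
the population has locked some coordinate into a wrong local basin, no
amount of interpolation toward leaders can cross the barrier (partial moves
land between basins and are strictly worse), but the escape creates
near-zero coordinate values that mating then assembles across individuals.
Weight 1 leaves a 10–30% trapping rate on ZDT4 at the standard budget;
weight 2 eliminated it in 25/25 runs on every seed set tried while leaving
the unimodal problems unchanged.

**Budget accounting.** The budget counts objective evaluations. The
iteration horizon t_max used by all time schedules is derived from the
budget *through the population-reduction schedule*: with N(t) decreasing
linearly from N₀ to N_min, the budget is exhausted after approximately
2·budget/(N₀ + N_min) iterations, and that value is used as t_max (using
budget/N₀ instead would saturate every schedule halfway through the run).
Population reduction applies every 10th iteration by default; survivors of
a reduction are the best by (rank, crowding), same as generational
survival. Reduction rounding is half-away-from-zero, clamped at N_min.

NaN or infinite objective values abort the run with a diagnostic rather
than silently propagating. An optional no-improvement early stop on archive
hypervolume exists and is off by default.

## Benchmarks

ZDT1–4, ZDT6 and DTLZ1–7 use the canonical formulations and dimensions
(ZDT1–3: D = 30; ZDT4/6: D = 10; DTLZ: D = M − 1 + k with k = 5 for DTLZ1,
10 for DTLZ2–6, 20 for DTLZ7; M = 3). Every problem carries an analytic
front sampler: ZDT1/ZDT4 sample uniformly in √f₁ (even spacing in f₂),
ZDT2/ZDT6 uniformly in f₁, ZDT3 and DTLZ7 sample densely and keep the
non-dominated segments of their disconnected fronts, DTLZ1/2/3/4 use the
standard simplex/sphere parameterizations on a near-square grid, and
DTLZ5/6 the degenerate curve. The test suite cross-checks every evaluation
function against an independent straight-line transcription of the
formulas at 1e−9.

## Indicators

IGD is the mean Euclidean distance from reference-front points to their
nearest archive point; reference sets use 1,000 points for two objectives
and 5,000 for three (standard densities). Hypervolume is exact: a sweep
over sorted points in 2-D and slicing along the third objective in 3-D;
points not strictly dominating the reference point are ignored. For
benchmark reporting, objectives are normalized by the analytic front's
ideal and nadir and the reference point is 1.1 per objective; a dense
sample of the ZDT1 front then scores 0.1 + 2/3 + 0.11 ≈ 0.8767, which
pins the convention against a closed form. Spread is the Δ metric for two
objectives (consecutive-gap variability plus extreme-point gaps) and the
generalized nearest-neighbour form with the per-objective extreme points
for three; fewer than three points is undefined and returns infinity with
a warning.

A note on interpretation: with a capacity-100 archive, the IGD of a fully
converged, well-spread archive is dominated by the discretization of the
front by 100 points (≈4e−3 on ZDT1), so mean IGD values of that order
certify convergence-to-front rather than residual error.

## Synthetic PK/PD cohort

The generator emulates a dose-finding table: dose pairs on a grid
(drug A ∈ {100, 150, 200} mg; drug B ∈ {50…150} mg), one-compartment
exposure with Cmax and AUC proportional to the synergy-weighted dose
(drug B counts at 0.5 mg-equivalents) under lognormal inter-patient
variability (σ = 0.12), a saturating Emax response of AUC
(Emax = 100%, EC50 = 220 ng·h/mL) with 2% additive observation noise
clipped to [0, 100], and toxicity grades 1–3 by thresholding a noisy
latent exposure at 1375 / 1550 ng·h/mL. Defaults were chosen once so the
generated magnitudes match a typical dose-finding table (AUC 1200–1800,
effects 80–95%, grades spanning 1–3). The per-patient therapeutic index is
the toxic-dose/effective-dose ratio with independent measurement noise on
the two dose estimates; its median is the drug-property ratio
threshold/EC50.

What the generator does *not* emulate: accumulation and time-dependent
kinetics (exposure scales linearly with dosing frequency relative to a
twice-daily reference), drug–drug interaction nonlinearity, dropout,
covariates, or duration-dependent response. Consequently, passing tests
demonstrate that the optimization layer recovers the trade-off structure a
cohort implies — not that any produced regimen is clinically meaningful.

## Regimen objectives

A fitted cohort model supplies the predictors: exposure linear in the two
doses (least squares), response by a fitted Emax curve, expected toxicity
grade by smooth logistic interpolation between fitted class-boundary
exposures (scale 60 ng·h/mL), and the exposure ceiling for feasibility.
AE = 100 − predicted effect %, AR = expected grade, Cost = per-dose prices
times doses-per-course (duration·7·24/interval) plus a weekly care cost.
Weights w₁ = w₂ = w₃ = 1 by default; inside a Pareto method positive
weights only rescale objectives and do not change the Pareto set, so they
are reporting conveniences. Treatment duration affects only cost (the
response model has no duration axis), which makes long durations
Pareto-dominated unless a user supplies a duration-aware model — a known
limitation. The alternate four-slot encodings of other therapy settings
(e.g. infusion-rate/rest-period/cycles) are supported by renaming the
bounds; no disease-specific pharmacodynamic model is included.

## Numerical choices and degenerate inputs

- Objective ties: stable sorts with index tie-breaks everywhere; runs are
  bit-reproducible from one seed threaded through a single generator.
- Archive truncation ties on crowding: lowest index removed first.
- Empty archive during leader selection: fall back to the best-ranked
  population member.
- Population smaller than 3 in spread, front of ≤ 2 in crowding, degenerate
  objective ranges: handled as above rather than raising.
- Encoding round-trips are affine and exact to 1e−12; out-of-bounds
  regimens are clipped with a warning.

## Problem sizes used in the shipped checks

The acceptance script runs the full standard protocol (population 100,
10,000/20,000 evaluations, 25 runs per problem, ≈4–5 minutes on one CPU).
Unit and property tests use scaled-down budgets (populations 24–50,
1,200–5,000 evaluations) chosen as the smallest sizes at which the checked
properties are stable.
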