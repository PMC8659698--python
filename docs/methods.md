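# Methods

`cgabm` simulates the growth of a BT-474 tumor cell population in one well of
a 96-well plate and provides the analysis stack used to study such a model:
time-resolved variance-based sensitivity analysis, Bayesian calibration for
stochastic simulators, and a CDF-distance validity test. This note records
the model, its assumptions, the numerical choices, and what the synthetic
data can and cannot say about real experiments.

## The two-scale model

**Cell scale.** Each agent is a circle of radius `R` with an incompressible
nucleus `R_N` and an action radius `R_A = 1.214 R` bounding short-range
adhesion. Pairwise forces derive from two potentials evaluated at the center
separation `l` with summed radii: an adhesion term proportional to
`(1 − l/(R_A^i + R_A^j))²` active below the summed action radii, and a
repulsion term `(1 − l/(R_i + R_j))²` active below the summed cell radii,
continued linearly (bounded) once the nuclei overlap. We orient the force so
that adhesion attracts and repulsion repels; the printed form of the force
equations, read literally with their gradient definitions, has these roles
interchanged, which would make cell pairs fly apart — the balance point (and
hence every published equilibrium separation) is identical under either
orientation, so this is purely a sign-convention repair. The wall of the
well exerts the same two forces using the agent's own radii and the distance
to the nearest boundary point; agents cannot leave the well. Inertia is
neglected (overdamped limit), so the velocity is the force sum divided by a
drag coefficient `nu`. The published force scales are already in µm/min,
so `nu = 1` by default and is exposed only as a config field.

Equilibrium separation of an isolated pair solves
`c_adh (1 − l/R_A)² = c_rep (1 − l/R)²`. With `c_adh = 0.5`, `c_rep = 1`,
and single-cell radii (5, 10, 12) µm the root is 7.1308 µm, and 64.177 µm
when all radii are scaled by nine. The solver searches the cell-contact
branch `(R_N, R)` only: balance points with overlapping nuclei exist for
some coefficient choices but are not physical rest states of a cell pair.

**Phenotypes.** Agents are quiescent (Q), proliferative (P) or dead (D).
Per one-hour step, a quiescent agent dies with probability
`1 − exp(−α_D(σ))` and otherwise commits to division with probability
`1 − exp(−α_P(σ))`, where σ is normalized glucose at the agent center
(1.0 ≡ 10 mM):

    α_D(σ) = ᾱ_D + γ_D / (1 + exp(−2k(σ_H − σ)))
    α_P(σ) = max(ᾱ_P (σ − σ_H)/(1 − σ_H), 0)

Death is drawn before proliferation within a step; at calibrated magnitudes
and dt = 1 h the probability both fire is below 1e−3, so the ordering bias
is negligible (covered by a test). A committed agent divides after
`τ_P − τ_G1 = 9` h into two daughters of half area placed symmetrically at
half the summed daughter radii along a random direction; mechanical
relaxation immediately restores spacing. Daughters grow linearly in area
back to the parent area over `τ_G1 = 9` h and re-enter Q with reset clocks.
Proliferating agents neither die nor re-read glucose until they return to
quiescence. Dead agents are permanent, occupy area and exert forces, but
consume nothing; the apoptosis time `τ_A` from the published parameter table
is parsed but unused, since dead mass never shrinks in this model.

**Initial proliferative fraction.** At t = 0 the proliferative *fraction* of
live agents equals the proliferation intensity at the seeding glucose,
`p₀ = min(α_P(σ₀), 1) = min(ᾱ_P (σ₀ − σ_H)/(1 − σ_H), 1)` above the
threshold: `round(p₀ n_live)` agents are committed, membership random. Two
readings were possible (with or without the ᾱ_P factor); including it is
what the intensity function says, and it is the version under which the
base proliferation rate actually shapes early growth — without it, every
cell starts committed at 10 mM and ᾱ_P is nearly irrelevant to (and
unidentifiable from) the live trajectory, contradicting the published
sensitivity ranking. Fixing the fraction rather than drawing each agent
independently also removes a spurious O(1/√n) variance component from
replicate ensembles. An `all_quiescent_init` switch starts everyone
quiescent instead.
Initial committed agents start with clock zero, so the first division wave
arrives nine hours in.

**Tissue scale.** Normalized glucose obeys
`∂σ/∂t = ∇·(D∇σ) − λ ρ_t σ` on the disc with a no-flux wall, where `ρ_t` is
the local area density of live agents. Discretization: P1 triangular finite
elements on a quasi-uniform Delaunay mesh (2413 elements at full scale, the
published resolution), lumped mass, implicit Euler at dt = 1 h, direct
sparse factorization of the per-step system. On Delaunay meshes the
stiffness matrix is an M-matrix, so the scheme is positivity-preserving and
satisfies a discrete maximum principle; with uniform σ and full occupancy
each step reduces exactly to `σ/(1 + λ dt)`, which the tests use as an
analytic oracle.

**Coupling, and two deliberate deviations.** Agents read σ by P1
interpolation at their centers. For the sink, an agent smaller than a mesh
element contributes its whole area to the element containing its center; an
agent wider than an element spreads its area over a 7-point footprint
quadrature (center plus a ring at 2R/3, the mean radial position of a
uniform disc). The density is *not* capped at 1. Both choices are forced by
coarse-graining consistency, and we verified each empirically: a 100-cell
agent (≈31,000 µm²) is larger than a full-scale mesh element (≈13,000 µm²),
so center-assignment plus a cap discards most of the coarse model's uptake
mass — the coarse and single-cell models then diverge grossly (live
confluence 1.03 vs 0.42 at 96 h in our experiment). With footprint
spreading and no cap the integrated sink equals λ × (total live area) × σ at
every coarse-graining level, and the 100-cells/agent error drops to ~2–3%.

**Hybrid loop.** Per hour: diffusion step with the current occupancy →
phenotype update at the new glucose → position relaxation in one-minute
forward-Euler substeps for up to 60 min, stopping early once the largest
substep displacement falls below 1e−3 µm. Live and dead confluence (summed
agent area over well area, overlap deliberately not subtracted) are recorded
every 3 h over 96 h — 33 points, matching the imaging cadence of the
emulated experiments. Forces are evaluated through a uniform-grid neighbor
search inside a numba kernel with half-stencil action–reaction iteration;
its exact agreement with an all-pairs reference is a test contract.
Coincident centers (< 1e−9 µm) are separated by a deterministic 1e−3 µm
hashed-direction perturbation rather than an exception.

**Coarse-graining.** One agent stands for `m` cells of one phenotype; all
three radii scale by √m, so the total area (hence confluence) is preserved
while agent count falls m-fold. The `tumor_radius` observable (no published
definition) is the distance from the population centroid to the
95th-percentile agent center plus that agent's radius — robust to
stragglers, configurable via the quantile argument.

## Sensitivity analysis

Saltelli two-matrix sampling (A, B, and the K hybrids AB^(k)) over the
published uniform ranges of the seven screened parameters, with the Jansen
total-effect estimator normalized by the pooled ddof-1 variance of the 2N
A/B outputs. The printed estimator omits this normalization, but the index
definition it approximates is a variance ratio and the published index
curves lie in [0, 1]; we therefore divide. Each design row is evaluated as
the mean of N_r seeded realizations, and one replicate-seed set is shared by
*every* row (common random numbers): identical parameter rows then produce
identical outputs, so the estimator's numerator measures parameter effects
rather than replicate noise, and a collapsed parameter range yields exactly
zero index. Negative estimates (sampling noise) are reported as-is. Time
points with zero pooled variance (e.g. the deterministic initial condition)
return NaN and are flagged, not propagated.

## Calibration

The likelihood compares replicate means, with a variance that adds the data
spread across experimental replicates and the model spread across N_r
seeded realizations per time point and output (live and dead, equally
weighted by default, per-output weights exposed):

    ln L = Σ_i [ −½ ln 2π − ln σ_i − ½ ((μ_i^d − μ_i^D)/σ_i)² ],
    σ_i² = (σ_i^D)² + (σ_i^d)², floored at (1e−4)².

The printed expression carries `+½ ln 2π`; a Gaussian log-density requires
the minus sign, and the constant shifts nothing that sampling or the MAP
depends on — both conventions are exposed and a test asserts the chains are
identical. The data-side standard deviation uses ddof = 1 (the source does
not say; four replicates make the distinction material). Replicate seeds are
drawn once per problem and shared by every likelihood evaluation, making the
log posterior a deterministic function of θ — common random numbers remove
likelihood-surface noise, at the price of a small O(1/N_r) conditioning bias
that shrinks as N_r grows. N_r defaults to 16 (the main-text value; the
supplement says 17 — both reachable via config).

Priors are the published uniform boxes on (ᾱ_P, ᾱ_D, λ, γ_D, σ_H); D and k
are held fixed, as the sensitivity analysis justifies. Sampling uses the
affine-invariant ensemble sampler (emcee) with one walker per chain, 16 by
default, walkers initialized in the middle half of the prior box, first half
of each chain discarded; split-R-hat and per-chain acceptance fractions are
reported. The MAP point is the mode of a Gaussian KDE over pooled post-burn
samples (argmax over samples, refined by Nelder–Mead); degenerate (point-
mass) posteriors short-circuit to the point. The multi-scenario and
leave-one-out designs just add scenario log-likelihoods, which additivity
tests pin down.

## Validation

The error between model and data at a time point is the L1 distance between
the empirical CDFs of confluence — model distribution over simulation
realizations (typically at posterior parameter draws), data distribution
over the replicate wells — divided by Φ, the data's mean total (live+dead)
confluence over replicates and times. The integral equals the 1-Wasserstein
distance, computed via `scipy.stats.wasserstein_distance` and cross-checked
in tests against an independent step-function integration of the CDF
difference. The model is deemed valid when the time-averaged metric stays
below the tolerance (10% working value). The report carries both the spread
of the metric across time points and the per-time values, since the source
does not state which spread its ± figures describe.

## Synthetic data

The generator emulates the experimental design: nine scenarios (2/5/10 mM
glucose normalized to 0.2/0.5/1.0 × low/medium/high seeding density), four
replicates, 33 time points at 3-h cadence. Measured per-scenario initial
confluences were never published, so live values default to the geometric
estimate `density × (R/W)²` (0.340/0.486/0.583) with an override hook, and
the dead value defaults to the published average 0.029. Measurement noise is
additive zero-mean Gaussian (sd 0.01 confluence units by default, an
optional heteroscedastic variant scales sd with the signal), clipped to
[0, 1]. Every table ships with a manifest (θ, seeds, noise level, scenario
geometry) from which it is exactly regenerable — the basis of the
parameter-recovery (identifiability) experiments.

What the generator does *not* emulate: segmentation artifacts of
phase-contrast imaging, spatially correlated noise, well-edge effects,
evaporation, or replenishment (glucose is never replenished, as in the
experiments). Passing recovery tests therefore show the inference machinery
is self-consistent, not that the model is adequate for any particular real
dataset.

## Problem sizes in the test suite

The default test run keeps every published study *condition* (parameter
values, 100 cells/agent, the 5 mM live-0.5/dead-0.3 coarse-graining
scenario, N ≥ 200 Sobol samples, the 5% / 0.2% / credible-interval
tolerances) and scales only *sizes* we consider free: the coarse-graining
comparison runs two paired replicates at the full 3192-µm well; the Sobol
structure checks run N = 200, N_r = 1 (with shared seeds), m = 9 in a
400-µm well at medium confluence (5 and 10 mM) and low confluence (10 mM),
and read the uptake-rate peak inside the mid-run window where uptake
dominates, because the terminal variance ratio of the scaled-down estimator
is degenerate (it can exceed one); parameter recovery calibrates two
complementary scenarios (a starving dense well and a growing sparse well,
300-µm) with N_r = 2, a staged mode search (log-uniform random search on
the cheaper starving-well posterior, then multi-start Nelder-Mead on the
full posterior) and a mode-initialized 100-step ensemble; the replicate-
convergence check estimates the expected 16-replicate-mean error from a
32-run full-scale ensemble via normal theory, E|μ̄₁₆ − μ∞| = √(2/π)·sd/4,
rather than brute-forcing a 10⁴-run reference. At 822 full-scale coarse
agents the replicate-to-replicate coefficient of variation of confluence is
≈1.4% (amplified late in the run, when glucose crosses the death threshold),
which puts that expected error at ≈0.28% — above the published 0.2%
figure. We report this honestly rather than enlarging the ensemble or
redefining the error: the demographic noise of ~500–800 stochastic agents
fixes this number, and the discrepancy most likely reflects a different
(unpublished) error aggregation in the original comparison.

A caveat on the recovery experiment at this scale: with tens of agents per
scenario, replicate demographic noise exceeds the 0.01-confluence
measurement noise, so the posterior's realization-to-realization offset is
comparable to its width and joint coverage of all five 95% intervals in a
single experiment is not guaranteed — the identifiability protocol is
framed over repeated experiments for exactly this reason. Full-well
populations (thousands of agents) push demographic noise below the
measurement floor and restore near-nominal coverage, at a computational
cost outside the default test run.

## Known limitations

- 2D only; no migration term beyond mechanical relaxation; no oxygen or
  waste fields; dead mass never lyses or shrinks.
- Confluence ignores overlap by construction, so it can exceed 1 in crowded
  wells; experimental confluence saturates at 1.
- The likelihood matches first moments only; replicate variance enters the
  weighting but is not itself fitted.
- Common-random-number likelihoods condition on a fixed realization set;
  with small N_r the posterior inherits an O(1/N_r) bias.
- The ensemble sampler struggles if the posterior concentrates on a prior
  boundary face; the recovery tests cover interior truths only.
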