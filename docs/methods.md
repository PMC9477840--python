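# Methods

## The model

`saomnet` implements the *stationary* (cross-sectional) stochastic
actor-oriented model (SAOM) for a binary directed network `x` over a
complete census of `n` actors. Network change is decomposed into
*ministeps*: at each event a uniformly chosen focal actor `i` either
toggles one outgoing tie `x_ij` or does nothing. The attractiveness of a
ministep is the gain in the actor's evaluation function

    f_i(x) = sum_k beta_k * s_{k,i}(x),

where each effect `k` carries a per-actor statistic `s_{k,i}(x)` (an
unstandardised local-network sum) and a weight `beta_k`. With
Gumbel-distributed taste shocks, choice probabilities are the multinomial
logit over the `n` alternatives (the `n-1` toggles plus no-change, whose
gain is 0), driven by the change statistics
`Delta_{k,ij} = s_{k,i}(x^{+-ij}) - s_{k,i}(x)`.

The cross-sectional calibration treats the single observed network as
being in short-term dynamic equilibrium: one simulated period starts *and*
targets the observed network, with the rate parameter `lambda` — the
expected number of change opportunities per actor per period — held at a
fixed constant (it is an identification device here, never estimated).
Ministep counts per period are Poisson(`n * lambda`) by default;
a `fixed` mode (exactly `round(n * lambda)` steps) is available for
variance-reduction experiments and for exact comparisons against the
explicitly enumerated small-network Markov chain.

## Effects library

Seventeen statistic families are implemented (out-degree, reciprocity,
non-centred dyadic covariate "X" and "XRecip", alter/ego/same/similarity
covariate effects, out-degree activity, in-/out-degree popularity,
transitive triplets, transitive reciprocated triplets, three-cycles, dense
triads requiring all six ties, household-jumping transitive triplets, and
shared popularity counting unordered shared-target pairs per third actor).
Similarity is centred by the mean pairwise similarity; covariates enter
exactly as preprocessed (z-scored where continuous), with no further
centring; "X"/"XRecip" are deliberately non-centred. Four archetypal
specifications nest: conventional (5 effects), extended (30),
networked-limited (33), networked-comprehensive (39).

Every change statistic is derived in closed form and computed by local
bookkeeping; the test suite's central property check verifies
`Delta == s(after) - s(before)` for all effects on randomized instances.
For plain simulation runs the whole evaluation function is folded into a
compact compiled form (covariate effects collapse into one dyadic gain
matrix, reciprocity-interacting effects into a second matrix entering as
`x_ji * B_ij`, and nine structural slots evaluated from the live
adjacency); a numba kernel then advances chains at microseconds per
ministep. The numpy effects path is the reference implementation, used
whenever per-effect contributions must be accumulated; agreement between
the two paths is covered by tests.

## Estimation

Method of moments: find `beta` with `E_beta[S] = S_obs`, where `S` stacks
the totals `sum_i s_{k,i}` at the end of a simulated period started at the
observed network. Phases:

1. **Jacobian.** `D = dE[S]/dbeta` by forward differences with common
   random numbers (each perturbed chain replays the base chain's random
   stream), 30 replicates by default. A score-function (likelihood-ratio)
   estimator is available behind `jacobian_method="score"`; it is unbiased
   but far noisier at equal cost, and an early experiment in which its
   noise produced a near-singular `D` (and a runaway first Robbins-Monro
   step) motivated the finite-difference default.
2. **Robbins-Monro.** Four sub-phases (40 iterations growing by 1.5x per
   sub-phase), gain `a0 = 0.2` halved per sub-phase, tail-averaged
   iterates. Updates use the *diagonalised* Jacobian with per-coordinate
   step truncation (0.3) and a parameter bound (|beta| <= 15): the full
   inverse is fragile under estimation noise when statistics are strongly
   correlated and differently scaled, while diagonal steps are stable and
   scale-aware. Initial values: all zero except out-degree, set to
   logit(observed density).
3. **Diagnostics and Newton polish.** At the candidate estimate, a 1,000
   replicate plain ensemble gives per-effect convergence t-ratios
   (`mean(S_sim - S_obs) / sd(S_sim)`) and the overall maximum convergence
   ratio `sqrt(dbar' Sigma^+ dbar)`; a 150-replicate scored subset gives
   the score-function Jacobian, from which the parameter covariance is
   `D^-1 Sigma D^-T`. If the convergence criteria (|t| < 0.1 per effect,
   overall < 0.15 — the conventional thresholds) are not met, up to three
   Newton corrections `beta <- beta - D^-1 dbar` are applied, each followed
   by a fresh diagnostics ensemble; the unbiased score Jacobian is used
   here because a biased derivative makes Newton corrections oscillate.
   The best round is kept; a correction that doubles the best ratio is
   rolled back. Non-convergence is always flagged, never silent.

Wald tests use `chi2 = beta_A' Cov_AA^{-1} beta_A`. Note the phase-3
replicate count sets a noise floor of about `sqrt(L / R)` on the overall
convergence ratio, which is why the default is 1,000 (20,000 can be
configured to mirror large published analyses).

The estimator takes observed = start = target directly; no tie-flip
workaround of any external interface is reproduced.

## Relative importance and predictability

For actor `i`, the alter-choice distribution `pi_i(j) ∝ exp(gain of
toggling x_ij)` is taken over the `n-1` alters only (the no-change option
is excluded, following the measure's published definition, although the
simulator's ministep includes it — the discrepancy is intentional and
documented). Effect `k`'s raw importance is `sum_j |pi_i(j) -
pi_i^{(-k)}(j)|`, where `pi_i^{(-k)}` removes `k`'s contribution from
every alternative's gain while all other effects and weights stay in
place. Normalising across effects gives `I_k(x, i)` summing to one per
actor; `I_k(x)` is the actor average. Degenerate all-zero raw vectors
(every weight zero) are assigned uniform `1/L` with a warning. The degree
of certainty is `R_H(i) = 1 - H(pi_i)/ln(n-1)` (natural log; the ratio is
base-invariant), averaged over actors for the global value. Everything is
a deterministic function of the observed network, the point estimates and
the covariates; parameter uncertainty is deliberately not propagated.

## Goodness of fit

Six auxiliary families: in-degree and out-degree count vectors (raw counts
per degree value, 0 to the observed maximum — not cumulative), geodesic
buckets (1–5 plus a pooled unreachable/longer bucket), the 16-class M-A-N
triad census, the mutual-clique census by size, and arc counts per
consanguineal-relatedness class. The fit statistic is the joint
Mahalanobis distance of the observed vector from the simulated ensemble
mean, with zero-variance components dropped and a generalized inverse
(singular-value tolerance 1e-10), and a one-tailed Monte-Carlo p computed
leave-in (the replicate distances are measured against the same centre and
scatter). Calibration under the generating model is covered by a property
test. Default ensemble size is 1,000 at desk scale (20,000 mirrors large
published analyses).

## Synthetic villages

The generator emulates a small, kin-dense horticulturalist village:

- **Pedigree.** Three generations: founder couples, their children
  (sibship sizes 1 + Poisson(3), i.e. a mean of 4 surviving adult
  offspring — a high-fertility setting), in-marrying spouses, and
  grandchildren. Relatedness is Wright's coefficient by standard kinship
  recursion (parent-child 0.5, siblings 0.5, grandparent 0.25, first
  cousins 0.125). Families are added until the projected mean relatedness
  over `n` actors reaches the recipe target (default 0.05); remaining
  slots are filled with unrelated migrant singles, mimicking adult
  dispersal in a well-mixed population. Deeper classes (e.g. 0.004) would
  need larger pedigrees and are not required.
- **Households** are family units (married couple plus unmarried
  children); the realised count is emergent (roughly 20–32 for n=108
  against a 32-household target, varying with the drawn family sizes).
- **Affinal relatedness** is the spouse's coefficient with the alter
  (spouses themselves at 1), strongest path retained, zeroed unless at
  least twice the dyad's consanguineal coefficient.
- **Covariates.** Right-skewed adult ages (shifted gamma on [18, 75]),
  log-normal household wealth shared within household (ln-median 5.78,
  ln-sd 1.19), normal BMI and skin-reflectance index, balanced gender with
  spouses opposite, household-level minority-ethnicity assignment (15%),
  households placed uniformly in a 1 km square (mean pair distance around
  520 m) with within-household distance zero. Preprocessing then z-scores
  the continuous covariates, log-transforms wealth first and distance as
  `ln(d+1)`, and derives the directed household wealth-rank difference.
- **Networks.** A burn-in chain (200 opportunities per actor) from a
  sparse Bernoulli(0.05) start draws an approximately stationary network
  under the generating weights; defaults are realistic magnitudes for a
  support network (out-degree -1.56, reciprocity 1.65, log-distance
  -0.06, consanguineal 2.85, affinal 2.08), giving densities near 0.15 at
  n=40. Double-sampled giver/receiver reports add independent
  false-negative (5%) and false-positive (1%) noise for exercising the
  mutual-assent construction.

What the generator does **not** emulate: multi-wave dynamics, reporting
biases that correlate with network position, cousin marriage and
inbreeding, age-structured mortality, or any behaviour co-evolving with
the network. Passing tests therefore demonstrate correctness of the
machinery and estimator calibration under the model's own assumptions,
not robustness to real-data violations of them.

## Problem sizes and numerical choices

Desk-scale defaults keep a full parameter-recovery experiment (20
synthetic villages at n=40, lambda=20, conventional specification) in a
few minutes on one core: phase sizes 30/40-135/1,000 as above. Relatedness
bins match exact values with tolerance 1e-9 (pedigree coefficients are
dyadic rationals). Degree standard deviations use the population formula
(the data are a census). Ties in the multinomial draw are resolved by
inverse-CDF sampling on a single uniform; all randomness flows from one
`SeedSequence` with per-replicate spawned substreams, so ensembles are
bit-reproducible under sequential execution. The degeneracy guard warns at
`lambda >= 10,000`.

## Known limitations

- The weak-rule transitivity convention (closed directed two-paths over
  distinct ordered triples) and the shared-popularity normalisation
  (unordered target pairs, no `n`-scaling) are recorded conventions;
  `EffectSpec.options` is the designated extension point for variants.
- The stationary calibration identifies weights only up to the quality of
  the short-term-equilibrium assumption; with a single observation the
  reported standard errors reflect model-based simulation variance, not
  sampling over villages.
- `R_H` and `I_k(x)` condition on the observed network state only.
- Fits of the 39-effect comprehensive specification at census scale are
  substantially heavier than the conventional specification and benefit
  from raising `phase3_n` toward the published 20,000.
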