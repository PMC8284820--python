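# Methods

## The task being modelled

The package reconstructs a grid-navigation videogame used to study how
people learn the controllability of their environment. On each trial the
player selects one of two vehicles and drives it with arrow keys toward
a goal within 14 s. A vehicle follows the pressed direction with
probability γ (its *guidability*) and otherwise moves in a uniformly
random cardinal direction, so the marginal probability that a press is
realized verbatim is γ + (1 − γ)/4. Blocks are either *high influence*
(at most 8 executed moves per second) or *low influence* (4 Hz); players
may press as fast as they like, but beyond the cap presses are ignored.
Success pays the goal's value in pence; failure always costs 15 p.

A block holds 16 double-goal trials (DGTs: choose a vehicle *and* one of
two goals — a nearer, poorer `g−` versus a farther, richer `g+`, with
one vehicle always 36 Manhattan steps from both goals) followed by 4
single-goal trials (SGTs: the more guidable vehicle always sits 44 steps
out, the less guidable one at `round(44·(γ₂/γ₁)^n)` for exponents
n = 1..4). Two DGTs per block are catch trials (both vehicles central,
making the more guidable vehicle and `g+` the unambiguous choice); one
catch trial is always the 16th. The published per-type distance/reward
cells of the double-goal table are not available in the source text, so
the schedule here is a configurable stand-in obeying every stated
constraint: the closer the non-central vehicle is to `g−`, the smaller
r(g−) and the larger r(g+), with r(g+) > r(g−) except on the
obvious-goal (OG) type, where the 65 p goal is the nearer one and the
closer vehicle's distance is drawn from {20, 24, 28, 32}.

## Movement model and calibration

The canvas is an unbounded integer lattice with no walls; the goal is a
point (radius configurable). The canonical reach problem places the
deficit diagonally — a distance-36 trial starts at offset (18, 18) —
because the drift of the greedy walk depends on whether one or both axes
carry deficit; the geometry is a parameter everywhere. Reach
probabilities are Monte-Carlo estimates over vectorized greedy walks,
with binomial standard errors; an exhaustive Markov-chain enumeration
serves as the oracle for tiny instances in the tests.

Guidability levels are not free parameters: they are *calibrated*, by
bisection with common random numbers (tolerance 0.01, 10⁵ simulations
per evaluation), so that a greedy agent pressing at the 8 Hz cap from
distance 36 succeeds with probability 0.2 / 0.5 / 0.8 for the Low /
Medium / High levels. Under the default geometry this puts γ at roughly
0.25 / 0.32 / 0.39. Re-simulated at the 4 Hz cap, the same levels give
success ≈ 0.02 (High) and well below 0.01 (Medium, Low) — the designed
collapse of achievability when influence is removed.

One design claim cannot be reproduced under this movement law: that the
farther/more-guidable vehicle is the better SGT choice in exactly half
of the four exponent layouts. With the calibration anchors fixed, the
three γ levels are pinned (the mixture noise sets the scale of the
success threshold), their ratios land near 0.82, and a drift argument —
the guidable vehicle wins iff (1 − ρⁿ)/(1 − ρ) < T·γ₁/44 ≈ 1 — shows
only the n = 1 layout is ever competitive. The half/half property and
the associated claim that low-influence SGTs are strictly hopeless
evidently depended on the original game's unpublished γ table and pixel
geometry; the corresponding acceptance check is kept faithful to the
published design intent and documents the discrepancy by failing.

## Choice and learning models

DGT choice is a unit-temperature softmax over the four (vehicle, goal)
options (the temperature is absorbed into the sensitivities; this is an
explicit identifiability choice). Option values are additive in distance
(normalized by D0 = 44), estimated guidability, and reward (normalized
by R0 = 100 p). The model family grows by one mechanism at a time:

1. **additive** — α_d, α_r, α_v only;
2. **gplus_bias** — adds a fixed propensity for `g+`;
3. **wsls** — adds a win-stay/lose-shift signal (+1 after any win, −1
   after a loss, 0 at a block start);
4. **vehicle_independent_rw** — adds an achievability trace H ∈ [−1, 1]
   shared by both vehicles;
5. **vehicle_rw** — the same trace kept per vehicle (the winning model);
   a variant with a separate learning rate for `g−` wins is included.

The trace updates by asymmetric Rescorla-Wagner rules: toward +1 at rate
ε_w when `g+` is achieved with the vehicle, toward −1 at rate ε_l on any
loss with it, unchanged on `g−` wins and for the unchosen vehicle. H
resets to its prior H₁ at each block start, because the vehicles (and
hence everything learned about them) change between blocks. Guidability
is estimated from realized press-match counts through a Beta-style prior
(mean corresponding to γ = 0.5, strength 4 pseudo-presses) inverted
through the mixture law γ̂ = (4m − 1)/3, clipped to [0, 1]. Catch and OG
trials stay in the likelihood.

SGT choice is a softmax over the two vehicles. All variants carry the
final double-goal trace H₁₆(v); they combine distance and (by then
known) guidability additively, with their interaction, with the pure
Monte-Carlo reach probability, or use the reach probability alone.

## Fitting and comparison

Each subject × influence condition is fit separately; the model
components are shared across conditions but the parameters are not.
Learning rates are fit on the logit scale with Beta(1.1, 1.1) priors,
H₁ on the atanh scale with a Uniform(−1, 1) prior, unbounded
sensitivities with Normal(0, 2) priors. MAP estimation uses multi-start
L-BFGS on the unconstrained scale (4 starts); posterior draws come from
a Laplace approximation (finite-difference Hessian, ridge-regularized)
or, on request, from the emcee affine-invariant ensemble sampler. The
original analysis used Stan's Hamiltonian Monte Carlo; the ensemble
sampler is this package's sampler of choice and agrees with the Laplace
approximation wherever the posterior is near-Gaussian — the place it
matters is the posterior *correlation* structure, which is visibly
non-Gaussian in low influence, so the recovery analyses that assert
correlation orderings use the sampler, not the Laplace draws.

In low-influence data the success learning rate ε_w is dropped whenever
the subject recorded no `g+` win in that condition (nothing informs it);
hierarchical pooling is intentionally not the default — per-subject fits
with weakly-informative priors carry all analyses here.

WAIC is computed from per-trial log-likelihood draws as
−2(lppd − p_waic) with p_waic the summed per-trial variance. LOSO fits
every subject once, scores each held-out subject under the mean (on the
unconstrained scale, per parameter name, so heterogeneous free-parameter
sets pool correctly) of the other subjects' estimates, and reports the
geometric-mean per-trial predictive probability, so scores live in
(0, 1) and chance is 0.25 for DGTs.

## Synthetic cohorts

No human data are distributed, so every downstream stage runs on
synthetic cohorts. A subject is a generative parameter set per
condition (defaults: vehicle-dependent RW for DGTs, the interaction
model for SGTs), a pressing rate uniform on [4, 10] Hz, and 24
six-point Likert items (8 per subscale) generated from three orthogonal
latent factors with loading 0.8. Population locations are stand-ins
centred on plausible ranges — no population distributions are published
— with deliberately wide spreads for the learning rates (logit-scale sd
1.3) and H₁ (atanh-scale sd 0.9), matching the wide reported posterior
spreads; narrower spreads make parameter recovery look spuriously poor
because between-subject variance shrinks relative to estimation noise.
Low-influence sensitivities are scaled down and H₁ slightly up,
mirroring the reported pattern.

Score–behaviour coupling is a Gaussian copula on the latent internality
factor. The **paper-like** scenario links ε_l (+0.8, both conditions),
α_d (+0.5, high) and H₁ (−0.6, low); these strengths were set so that a
35-subject cohort shows corr(I, g+ frequency) near −0.5 in both
conditions — the size of the published effect — after attenuation
through item noise and behavioural stochasticity. **null** cuts all
links (for calibration checks); **strong-link** is a high-signal setting
for necessity analyses. What passing tests show is therefore that the
*machinery* detects effects of the published size under the designed
conditions — not anything about real participants, whose data are not
reproduced here. The synthetic cohort also omits fatigue, reaction
times, key-repeat quirks, and the payment lottery.

## Statistics layer

Permutation correlation tests shuffle questionnaire scores across
subjects; p = (1 + #{|r_perm| ≥ |r|})/(n_perm + 1). The
parameter-necessity analysis permutes one fitted (or generative)
parameter across subjects, regenerates whole synthetic cohorts under
each permutation, and reports the fraction of null effect sizes at
least as large as the observed one. Random-forest importance for
I-score prediction is Breiman-style marginal permutation importance on
out-of-bag error over a hand-rolled bootstrap ensemble of sklearn
regression trees (repeated 50 times for standard errors); the
conditional-importance variant of the original analysis is not
implemented. Cronbach's α uses the classical variance decomposition
with a percentile bootstrap CI over respondents. The factor analysis is
sklearn's ML factor model with varimax rotation on standardized items,
plus the Bartlett-corrected likelihood-ratio χ² of the unrotated
solution (reported, never enforced). Exclusion screening uses
leave-one-out means and SDs: catch-trial irrationality beyond 4 SD,
I-scores beyond 3 SD. Correlation power uses the Fisher-z
approximation, with a Monte-Carlo cross-check mode; at n = 35,
ρ = 0.45, α = 0.05 it gives 0.78, the published ≈0.8 justification.

## Numerical choices and scale

Calibration: bisection tolerance 0.01, 10⁵ simulations, common random
numbers (makes the estimated success curve monotone in γ and the result
deterministic). Laplace Hessians: central differences at step 1e-4,
ridge-shifted to positive definiteness. Reach-probability tables are
memoised with per-entry seeds. Money is integer pence throughout.

Analysis drivers and tests run scaled-down study sizes chosen as the
package's defaults: model recovery 8 datasets/model at cohort size 5
(the original study used 50), parameter recovery 30 datasets (original
150), necessity analyses ~100 permutation sets (original 1000). The
directions and orderings asserted in tests are stable at these sizes;
the full-size settings are plain arguments.

## Known limitations

- The SGT exponent-layout balance and the strict hopelessness of
  low-influence SGTs are not reproducible under the published movement
  law plus the published calibration anchors (see above); low-influence
  single-goal wins do occur in synthetic cohorts.
- The double-goal reward/distance schedule and OG distance set are
  stand-ins, configurable but not the original cells.
- LOSO's held-out evaluation rule (group mean of unconstrained
  estimates) is one reasonable choice; the original rule is unspecified.
- Laplace draws understate curved posterior ridges; use the ensemble
  sampler for correlation-structure questions.
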