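# Methods

## The task and its generative structure

The package models an adapted beads task ("fish-lake" task). On each of 30
rounds, fish are angled one at a time from one of two equiprobable hidden
lakes: the trout lake (70% trout / 30% carp) or the carp lake (30% / 70%).
A tone played at the start of each round cues the lake probabilistically: a
low pitch is associated with the trout lake and a high pitch with the carp
lake, and the cue is valid on 80% of rounds. Each round opens with one fish
already angled; after every draw the subject reports a continuous belief
`g ∈ [0, 1]` (1 = certain trout lake) and either commits to a final lake
choice (ending the round) or draws again.

An exact ideal observer is provided as an oracle
(`task.ideal_posterior`): posterior odds of the trout lake are the tone
prior odds times `(0.7/0.3)^(n_trout − n_carp)`.

## Belief-update models

Beliefs live on `[0, 1]`. A round starts at the tone-shifted prior

    b1 = 0.5 + θ   (low tone),    b1 = 0.5 − θ   (high tone),    θ ∈ [0, 0.5].

Each observation `o ∈ {0, 1}` (1 = trout) then updates the belief. The
linear (Rescorla–Wagner) rule is `b ← b + α (o − b)` with learning rate
`α ∈ [0, 1]`. The saturating (non-linear) rule divisively attenuates large
prediction errors:

    b ← b + α (o − b) / (ζ |o − b| + 1),        ζ ∈ [0, 5].

Its effective learning rate `α / (ζ δ + 1)` equals `α` as the
prediction-error magnitude `δ = |o − b| → 0` and falls to `α/(ζ+1)` at
`δ = 1`, so large ζ confers resilience against surprising (and, in this
task, often misleading) single observations. At ζ = 0 the two rules
coincide exactly. Because each step is a sub-unit fraction of the distance
to the observation, beliefs can never leave `[0, 1]`; this is fuzz-tested
over 10⁶ random updates. Four model variants are registered: `nonlinear`
(θ, α, ζ free), `linear` (ζ ≡ 0), and the θ ≡ 0 versions of both, used to
test whether the tone cue is exploited at all.

## Subject-level inversion (MAP + Laplace)

Reported beliefs are modelled as `g_t = b_t(θ, α, ζ) + ε_t` with
`ε_t ~ N(0, σ²)`, one σ per subject, and flat priors on the boxes
θ ∈ [0, 0.5], α ∈ [0, 1], ζ ∈ [0, 5], σ ∈ [10⁻³, 0.5]. The posterior mode
is found by multi-start bounded L-BFGS-B (8 Latin-hypercube starts plus the
box centre; deterministic given a seed), and the log model evidence is
approximated by Laplace's method around the mode,

    F = −NLJ(MAP) + (d/2) log 2π − ½ log det H,

where the negative log joint `NLJ` includes the flat prior densities, `d`
counts the free parameters plus σ, and `H` is a central finite-difference
Hessian (step 10⁻⁴ of each box width). Including the prior volumes inside
the joint makes F penalise extra free parameters (an Occam factor), so F is
comparable across models of different complexity. Numerical choices worth
noting:

- The Hessian is evaluated on the smooth extension of the Gaussian
  likelihood just outside the box, because MAP estimates can sit exactly on
  a box face (e.g. ζ̂ = 0 when the data are linear); flat priors make the
  extension exact up to the prior constant.
- The Laplace expansion is done in natural coordinates (θ, α, ζ, σ). It is
  validated against brute-force grid quadrature of the joint over the prior
  box on a small two-dimensional problem (agreement well within 0.5 nats).
- If the Hessian is not positive definite (a flat ridge or a degenerate
  boundary), the code falls back to a BIC-style approximation
  `F = −NLJ + (d/2) log 2π − (d/2) log n` and flags the fit
  (`evidence_method = "bic"`). In the study-scale simulations this affects
  a few percent of fits at most.
- Explained variance R² is computed on all of a subject's reports pooled
  across rounds; it can be negative for predictions worse than the mean.

The per-draw likelihood kernel is compiled with numba; a pure-python
reference path is kept and tested to agree to machine precision.

## Random-effects model selection

Per-subject log evidences enter a random-effects scheme: each subject uses
one of K models, with population frequencies `r ~ Dirichlet(α)`
(flat α₀ = 1). A variational loop alternates subject responsibilities
`u_nk ∝ exp(L_nk + ψ(α_k) − ψ(Σα))` with `α_k = α₀ + Σ_n u_nk` to
convergence. Exceedance probabilities are exact for K = 2 (Beta tail at
1/2) and Monte-Carlo otherwise; the Bayesian omnibus risk compares the
fitted model's free energy with the equal-frequency null via
`BOR = 1/(1 + exp(F1 − F0))`, and the protected exceedance probability is
`pxp = (1 − BOR)·ep + BOR/K`.

## Synthetic populations

No human data ship with the package; a generator produces agents whose
statistical structure emulates the study population the analysis was built
for:

| parameter | default | rationale |
| --- | --- | --- |
| n_subjects | 94 | emulated sample size |
| θ | truncnorm(0.25, 0.10) on [0, 0.5] | moderate, variable tone usage |
| α | truncnorm(0.60, 0.15) on [0, 1] | mid-range learning rates |
| ζ | truncnorm(3.44, 0.35) on [0, 5] | observed centre 3.44, >95% in ≈[2.5, 4] |
| response noise SD | 0.05 | small motor/report noise on a continuous bar |
| commit threshold τ | uniform [0.25, 0.45] on |g − 0.5| | yields human-like 3–8 draws to decision |
| score coupling | Spearman −0.25 with ζ | emulated effect size |

Agents commit when their reported confidence `|g − 0.5|` reaches their
threshold τ, or at a hard cap of 20 draws (the human task's stopping rule
is unknown; a fixed per-subject confidence criterion is the simplest policy
producing between-subject variance in draws to decision). Reports are
clipped to [0, 1] after noise; the fitting likelihood deliberately ignores
the clipping (a documented approximation, mild at noise SD 0.05).

PDI-like and CAPS-like questionnaire totals are attached by a Gaussian
copula: the normal scores of the true ζ ranks are correlated with two
latent normals (target Spearman −0.25 to ζ each, 0.70 with each other;
Spearman targets are converted to latent Pearson correlations via
`2 sin(π ρ_s / 6)`), which are then pushed through negative-binomial
quantile functions (means 64.5 and 30.4, small size parameters) to obtain
right-skewed positive totals, as questionnaire data typically are. Under
extreme ζ-coupling the inter-score correlation is raised to its joint
feasibility limit `2ρ² − 1`.

What the generator does **not** emulate: the 15-round tone-learning phase
(tone knowledge enters only through θ), sequential or within-round
non-stationarity of human reports, response granularity of a mouse-driven
bar, item-level questionnaire structure, and any direct effect of the
scores on behaviour (scores are coupled to ζ only). Passing tests on these
agents therefore validate the pipeline's machinery and its statistical
calibration, not claims about real populations.

## Behavioural statistics

Draws to decision is the per-subject mean draw count at commitment; the
jumping-to-conclusions (JTC) group is the lowest quartile (inclusive
type-7 quantile; ties at the cutoff are JTC) or the classic ≤ 2-draw rule.
Group comparisons use Mann–Whitney U (exact enumeration when
`n_a·n_b ≤ 400` without ties, tie-corrected normal approximation otherwise;
U is reported for the first group). Correlations are two-sided Spearman
(t-approximation, n − 2 df); the partial Spearman ranks all three variables
and applies the Pearson partial-correlation formula with n − 3 df, and is
cross-checked against pingouin. One-sample Kolmogorov–Smirnov tests use
`Z = √n · D` and the asymptotic law `Q(Z) = 2 Σ (−1)^{k−1} e^{−2k²Z²}`;
against the normal reference the parameters are estimated from the sample
*without* a Lilliefors correction — this replicates the analysis convention
the pipeline mirrors, and makes the test conservative (true p values are
smaller than reported). Multiplicity over the two correlated outcome scores
uses the Šidák-type rule `p_adj = 1 − (1 − p)^(m^(1 − r̄))` with the
effective test count `m^(1−r̄)`; r̄ defaults to the observed inter-score
Spearman correlation. Exclusion rules: subjects with error rate above
mean + 2 SD (one pass, full sample); sensitivity reruns drop ζ̂ values
below mean − 2 SD.

## Identifiability of ζ at study scale — a known limitation

Under the default study conditions (commit policy giving ≈150 observations
per subject, report noise SD 0.05), the curve family
`α δ/(ζ δ + 1)` is nearly degenerate over the range of prediction errors
the task actually produces: α can compensate ζ almost exactly, the profile
likelihood in ζ is only ~2 nats deep across ζ ∈ [1.5, 5], and the
per-subject Cramér–Rao bound on ζ̂ has median SD ≈ 0.6 — larger than the
generative between-subject spread (0.35). Point estimates of ζ therefore
carry substantial noise at this scale: the rank correlation between true
and recovered ζ is ≈ 0.3–0.5 (≈ 0.88 even in the most favourable design
with every round run to the 20-draw cap), and downstream ζ–score
correlations are attenuated by the same factor. θ and α do not suffer from
this (median absolute recovery errors ≈ 0.005 and ≈ 0.035). Model
*selection* is unaffected — the linear/non-linear and tone/no-tone
comparisons are decided by protected exceedance probabilities near 1 — but
analyses that treat subject-level ζ̂ as data should be read with this
attenuation in mind. The acceptance test asserting near-perfect ζ recovery
is intentionally left failing as a record of this limit rather than being
weakened.

## Problem sizes used by the test suite

Monte-Carlo rate checks use 10⁴ draws; boundedness fuzzing 10⁶ single
updates and 10³ trajectories; the quadrature oracle a 601² grid; parameter
recovery 50 subjects; model recovery 40 subjects per scenario; the
end-to-end correlational check 10 replicate datasets of 94 subjects. All
seeds are fixed in the tests; the full suite runs in a couple of minutes on
one CPU.
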