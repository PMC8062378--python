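# Methods

This note records the models implemented in `cogscale`, the numerical
choices behind the estimators, what the synthetic-data generators do and do
not emulate, and the design decisions taken where more than one reasonable
convention exists.

## Scaling constraints and identifiability

All three model families share one structure: the likelihood is constant
along a one-parameter family ("ridge") obtained by multiplying a set of
scale-carrying parameters by k > 0. A scaling constraint — an equality
constraint fixing one of those parameters — selects a point on the ridge
and thereby fixes the units of every other estimate. The package treats
the constraint as part of the estimate: every `SDTEstimate` and
`RescaledLBAParams` carries its constraint and a unit label per parameter
(e.g. `c/s` under σ = 1, drift rates in `1/s` — threshold distances per
second — under B = 1). Rescaling between constraints divides all
scale-carrying parameters by the appropriate quantity and never changes
any ratio; the likelihood of any data set is bit-for-bit unaffected up to
floating-point rounding, which the test suite checks at 1e−9.

## Signal detection theory

Equal-variance SDT with a free noise SD: noise evidence ~ N(0, σ), signal
evidence ~ N(d′, σ), "signal" reported when the evidence sample exceeds a
cutoff on the evidence axis. Scored counts convert to rates with a
half-count edge correction (a rate of 0 or 1 with N trials becomes 1/(2N)
or 1 − 1/(2N)); an `error` policy is available where degenerate rates
should abort instead.

**Criterion anchoring.** Two criterion conventions coexist in the
literature and the package keeps both explicit rather than conflating
them:

* the **cutoff** anchor — the absolute location of the decision cutoff,
  measured from the noise mean. This is the natural generative parameter
  (`SDTParams` default): a sample above it is a hit/false alarm, and the
  forward model is HR = Φ((d′ − c)/σ), FAR = Φ(−c/σ).
* the **centered** anchor — the criterion measured from the midpoint
  between the noise and signal means, which is what the classical
  estimator ĉ = −(Z(HR) + Z(FAR))/2 returns. Estimates are always
  centered; cutoff = d′/2 + c converts exactly.

Because the conversion is exact, `forward_rates` inverts
`estimate_standard` to machine precision, and the 1-D numerical refit
under any constraint agrees with analytic rescaling of the standard
estimate. Conflating the two anchors (reading the Z-formula criterion as
a cutoff) silently breaks that round trip; making the anchor an explicit
field is the package's resolution.

**Criterion sign.** The default is the standard convention
ĉ = −(Z(HR)+Z(FAR))/2, under which a more conservative observer (higher
cutoff) has a larger ĉ, so a factor that drives the generative criterion
correlates *positively* with the estimate. The mirror-image sign
(+(Z+Z)/2), which some sources print, is available as
`convention="negated"` and is carried through forward prediction and
refitting consistently.

**Constrained refitting.** Under σ = v the solution is closed-form. Under
d′ = v or c = v, σ is found by Brent root-finding on the signed Z-scale
rate mismatch over log σ ∈ [−5, 5] — the residual is monotone in σ — with
the remaining parameter solved from the false-alarm equation at each σ.
Root-finding rather than squared-residual minimization is used because a
quadratic minimum limits attainable precision to about sqrt(machine
epsilon), while the root is located to ~1e−12 relative error; the
refit-vs-rescale agreement tests run at 1e−6. Infeasible constraints
(e.g. c = +1 when the data imply a negative criterion, or d′ = 1 when
HR ≤ FAR) raise a dedicated error.

**Rescaling guard.** Dividing by a near-zero parameter (the c = 1
constraint in a population whose criterion crosses zero) is legal but
explosive; sources with |denominator| < 0.05 set a warning flag, and
flagged participants are excluded from that block's correlations and
counted. A denominator of exactly 0 is recorded and flagged rather than
propagated. A negative denominator flips all signs, including σ's; the
result is kept as a formal re-expression because the c = 1 scenario row
divides by the criterion regardless of sign.

## Reinforcement learning

Delta-rule learning with an explicit reward weight γ (internal value per
external reward point): V ← V + α(γr − V), equivalently
V ← (1−α)V + αγr, so the internal trace is V = γW with W the delta-rule
trace on raw rewards. The soft-max choice rule applies the inverse
temperature to value per unit of weighted reward,
P_i ∝ exp(βV_i/γ) = softmax((β/γ)W), computed with a max-subtraction
guard. Behavior therefore depends on α and the **ratio β/γ** only: the
likelihood is exactly invariant under (β, γ) → (kβ, kγ), two agents with
equal β/γ and equal seed produce identical choice sequences, and the two
fixing choices return reciprocal scale estimates (β̂ under γ = 1 and γ̂
under β = 1 satisfy β̂·γ̂ = 1 at the optimum). The learning rate α is
identified under either fixing; the test suite checks that the two α̂
agree to well under optimizer noise.

Fitting maximizes the summed log-likelihood over (logit α, log scale)
with Nelder–Mead from 10 random restarts plus one default start
(tolerance 1e−8). Initial values are v0 = 0 for all options
(configurable). Only the linear reward mapping γr is implemented;
nonlinear (power-law) mappings are out of scope.

**Reference bandit.** The default task is a 2-armed bandit, reward
probabilities (0.8, 0.2), unit reward magnitude, 200 trials. Unit
magnitudes keep the reference parameter point (α = 0.3, β = 3, γ = 1) in
the stochastic-but-informative regime where α is recoverable; a
100-point-reward task is the *identical* model with γ scaled by 1/100 —
which is precisely the scaling ridge the package demonstrates.

## Linear ballistic accumulator

Standard two-accumulator LBA: start points U[0, A], within-trial-constant
drifts N(v_i, s_i), threshold B ≥ A, non-decision time t0. Single-
accumulator first-passage density and CDF use the closed forms, with the
A → 0 limit (deterministic start) special-cased below A = 1e−9. The
defective density for a response multiplies the winner's density by the
loser's survival function.

**Never-finishing trials.** A non-positive sampled drift never reaches
threshold. Simulation redraws trials on which *both* drifts are
non-positive, and the analytic defective densities are renormalized by
1 − P(both non-positive) whenever that probability exceeds 1e−6, so the
likelihood describes exactly the process the simulator generates. Drift
means are parameterized positive (log transform for fitting), a
restriction inherited from estimating all scale parameters on the log
scale.

**Likelihood and fitting.** The objective is −Σ log defective density
with densities floored at 1e−10 (an RT below t0 contributes exactly the
floor term). Optimization is multi-restart Nelder–Mead in transformed
space: log for A, B, v1, v2, s1, s2; t0 = min(RT)·logistic(x). Default
500 restarts (tests and the scenario engine use 6–50); convergence
tolerance 1e−8 on the objective, at most 2,000 iterations per restart.
Start values are drawn log-uniform (±0.7 on the log scale) around
data-informed heuristics: decision time from mean RT minus 0.9·min RT, B
near decision-time × drift, A near B/2, t0 a random fraction of min RT.
Without a constraint the returned parameters are one point on the scaling
ridge — only ratios are identified, and two independent fits are compared
on ratios; with s1 = 1 the ridge is removed. Post-hoc rescaling (divide
everything except t0 by s1, s2, v1+v2 or B) is the primary mechanism for
moving between constraints, since it is exact on the ridge; refitting
under a constraint is provided for s1 = 1 only.

## Synthetic populations

The generators reproduce the statistical structure the correlation
analyses assume, keeping every generating truth next to the data.

* **SDT population** (defaults): 20 participants, 200 trials each (half
  noise, half target), factor F equally spaced on [−1, 1]; per participant
  c ~ U(F−0.1, F+0.1) (cutoff anchor), d′ ~ U(0.9, 1.1), s ~ U(0.7, 1.3).
  Ties with the cutoff score as non-detections (measure-zero). With this
  design F drives the criterion only; d′ and s are independent of F.
* **RL population**: α ~ U(0.1, 0.5), β ~ U(1, 5), γ fixed at 1 (or
  drawn); the retained factor is the identified ratio β/γ.
* **LBA population**: base parameters A = 0.5, B = 1.0, v = (3.0, 1.5),
  s = (1.0, 1.0), t0 = 0.2 s — about 0.47 s mean RT, ~15% errors, and a
  both-negative-drift probability of ~9e−5. These are package choices
  selected a priori for a well-identified regime. Individual differences
  are multiplicative log-normal (SD 0.15) on the linked parameter
  (threshold B by default); the external covariate ("temporal precision")
  is m = 1.5 − 1.0·B + N(0, 0.05), a negative link so that better timers
  (low m) carry higher thresholds.

What passing tests on these populations show — and what they do not: the
generators produce clean, stationary, independent trials with exactly the
assumed functional forms. Real data bring contaminant RTs, sequential
dependencies, non-stationarity and model misspecification, none of which
are emulated; recovery results here bound what is achievable under the
model's own assumptions, not under field conditions. The covariate m is a
plain linear link with Gaussian noise, not the output of a timing model.

## Scenario engine and correlations

`apply_constraints` builds a long-format table (participant × constraint
× parameter, with unit label, factor and near-zero-denominator flag);
`correlate` computes Pearson r with a two-sided t test per (constraint,
parameter) cell, excluding flagged participants, reporting zero-variance
(constrained) parameters as undefined rather than 0, and raising if the
factor itself has no variance. Spearman is available behind a flag. No
multiple-testing correction is applied — the engine reports per-parameter
correlation tests as is. Outputs are written with 6 significant digits;
full precision is kept in memory. Because rescaling is deterministic, any
block's values are an exact transform of any other block's: ratio
correlations agree across blocks to floating-point precision, and in the
v1 + v2 = 1 block the correlations of v1 and v2 with any covariate are
exactly equal and opposite.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen to finish in minutes on a
single core while keeping every comparison well-powered: 1,000 random rate
pairs for the SDT estimator/refit equivalences; 25 population seeds for
the SDT scenario correlation; 100 data sets for the RL ridge; 20 agents ×
200 trials for α recovery; 10 replicates of 1,000 trials with 50 restarts
for LBA recovery; 24 participants × 800 trials with 8 restarts for the
LBA scenario. The simulation-vs-analytic RT check compares the pooled RT
distribution at n = 10,000 (Kolmogorov–Smirnov distance) together with a
binomial check on response frequencies; a per-response conditional KS at
that total n would leave the minority response with so few trials that
sampling noise alone reaches the tolerance.

## Known limitations

* Equal-variance SDT only; unequal-variance, ROC and confidence-rating
  designs are out of scope.
* RL: linear reward mapping, no utility curvature, no model comparison or
  hierarchical fitting; 2+ options supported but the reference task is
  2-armed.
* LBA: two accumulators, positive mean drifts, no inter-trial t0 or
  threshold variability beyond the standard start-point range; each
  participant is fit independently (no shared parameters across
  conditions or participants).
* Correlations are raw Pearson/Spearman; no attenuation correction or
  hierarchical group model. The hierarchical route (constrain the scale at
  the group level, let individuals vary) is a natural extension and not
  implemented here.
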