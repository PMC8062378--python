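# cogscale

Scaling constraints, identifiability, and behavior–parameter correlations
in cognitive models.

## The problem

Many cognitive models — signal detection theory (SDT), delta-rule/soft-max
reinforcement learning (RL), and evidence-accumulation models such as the
linear ballistic accumulator (LBA) — are identified only *up to a scale*:
multiplying a whole set of parameters by a positive constant leaves the
predicted behavior, and hence the likelihood of any data set, exactly
unchanged. Estimation therefore requires a **scaling constraint** (fix one
parameter to a constant, conventionally 1), and every remaining estimate is
interpretable only *relative* to that constraint.

This matters for individual-differences research. If each participant's
parameters are estimated under a constraint and then correlated with an
external factor (a physiological measure, a score from a second task), the
pattern of correlations — sizes and even signs — depends on which parameter
was constrained. Only *ratios* of parameters are identified, so only
correlations with ratio quantities are constraint-independent.

`cogscale` packages this phenomenon end to end for SDT, RL and the LBA:

* forward models, simulators and maximum-likelihood estimators for all
  three model families;
* analytic **rescaling** between scaling constraints, with unit labels
  (`c/s`, `s/d'`, signal-to-noise, threshold distances per second, ...)
  attached to every estimate so its meaning stays explicit;
* synthetic population generators that keep generating truths next to the
  data for recovery checks;
* a **scenario engine** that re-expresses one population's estimates under
  several constraints and reports every behavior–parameter correlation,
  making the constraint-dependence (and the ratio invariances) visible.

## The models

**SDT.** Noise evidence ~ N(0, s), signal evidence ~ N(d', s); "signal" is
reported above a criterion. With hit rate HR and false-alarm rate FAR, the
classical estimator under the s = 1 constraint is

    d' = Z(HR) − Z(FAR),      c = −(Z(HR) + Z(FAR)) / 2,

with Z the standard normal quantile function. (d', c, s) is identified only
up to joint scale; the package refits or rescales exactly under s = 1,
d' = 1 or c = 1.

**RL.** Delta-rule learning with a reward weight γ converting reward points
into internal value, V ← V + α(γr − V), and soft-max choice with inverse
temperature β. Behavior depends on α and on the ratio β/γ only: fitting
with γ = 1 returns β/γ, fitting with β = 1 returns its reciprocal, and the
learning rate α is identified either way.

**LBA.** Two accumulators race to threshold B from starts U[0, A] with
drifts N(v_i, s_i); non-decision time t0 shifts the RT. The likelihood is
invariant under joint scaling of (A, B, v1, v2, s1, s2). Fits use
multi-restart Nelder–Mead on log-scale parameters (logistic for t0), with
an optional s1 = 1 constraint; fitted parameters can be rescaled post hoc
by s1, s2, v1 + v2 or B.

## Worked example

One participant's detection counts, estimated under three constraints:

```python
from cogscale import sdt

counts = sdt.DetectionCounts(hits=90, misses=10, false_alarms=30, correct_rejections=70)
est = sdt.estimate_standard(sdt.rates_from_counts(counts))   # sigma = 1
for target in ("d_prime", "criterion"):
    re = sdt.rescale_estimate(est, sdt.ConstraintSpec(target, 1.0))
    print(re.d_prime, re.criterion, re.sigma)
```

prints (with the σ = 1 row first):

```
sigma=1: d'=1.8060  c=-0.3786  s=1.0000
d'=1:    d'=1.0000  c=-0.2096  s=0.5537
c=1:     d'=-4.7704  c=1.0000  s=-2.6415
c/s invariant: -0.378576  -0.378576  -0.378576
```

The three rows describe the *same* fitted model — the ratio c/s never
moves — yet a naive reading of "the criterion" or "the sensitivity" differs
in every row (the c = 1 row even flips signs, because this participant's
criterion is negative). The scenario engine runs this logic over a whole
population and correlates every parameter with the external factor F:

```python
from cogscale import scaling_analysis as sa, synthetic_data as syn

table, results = sa.run_sdt_scenario(syn.SDTPopulationSpec(seed=0))
```

```
constraint   parameter         r          p
sigma=1      d_prime      -0.023   9.24e-01
sigma=1      criterion     0.959   2.72e-11
sigma=1      sigma         undefined
d_prime=1    criterion     0.963   1.06e-11
d_prime=1    sigma        -0.011   9.63e-01
criterion=1  d_prime       0.438   5.36e-02
criterion=1  sigma         0.394   8.54e-02
```

F drives the generative criterion, and under σ = 1 that is exactly what the
correlations say (r = 0.96 with c, none with d'). Under c = 1 the same
population seems to show moderate correlations with d' and s instead —
the conclusion a study would have drawn under that constraint. The
constrained parameter has zero variance in its block and is reported
`undefined`, not 0.

The same engine runs for the LBA (`sa.run_lba_scenario`): fit once, rescale
by s1 / s2 / v1+v2 / B, and watch the drift-rate correlations change sign
between blocks while every ratio correlation stays put.

A command-line interface covers the common runs:

```sh
cogscale sdt-scenario --seed 1 -o out/        # scenario table + correlations
cogscale rl-demo      --seed 1 -o out/        # alpha recovery, beta/gamma ridge
cogscale simulate --model lba --seed 1 -o out # synthetic population + truths
cogscale lba-fit --data trials.csv -o out     # per-participant LBA fits
```

Every run writes a `manifest.json` (command, config, seed, version) from
which it can be reproduced byte-for-byte.

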