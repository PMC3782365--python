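# Methods

## Model

A study is a pair (q, s): a quality score q on an arbitrary 0–100 scale and
a binary outcome sign s (positive = statistically significant headline
result, negative otherwise). Sign is primitive: the package does not model
sample sizes, effect sizes or p-values as its source.

A journal is a pair of acceptance curves, one per sign. The implemented
family is the two-parameter logistic

    p_s(q) = expit((q − m_s) / σ_s),

strictly increasing in q with p_s(m_s) = 0.5. The logistic is a modelling
choice, not an empirical fit: any monotone family would carry the argument,
but the logistic is the minimal smooth monotone family whose common-slope
pair is *exactly* determined by the four anchor quantities the default
model must reproduce, and it makes the conditional bias interpretable as a
constant log-odds gap. With a common slope σ, the conditional
(like-with-like) acceptance odds ratio

    OR_cond(q) = odds(p_pos(q)) / odds(p_neg(q)) = exp((m_neg − m_pos)/σ)

is constant in q; it is computed as the exponential of the difference of
linear predictors, which is algebraically identical to the odds ratio of
the two probabilities but avoids the catastrophic cancellation of forming
p/(1−p) in the tails, so its constancy holds to ~1e-14 rather than ~1e-10.

## Calibration

The default curve pair is calibrated to five anchors: a probability
submission threshold p* = 0.20 with per-sign quality bars q_pos = 46 and
q_neg = 66, and acceptance probabilities 0.27 / 0.05 at a common quality
submission threshold q0 (q0 itself is implied, not given). Under a common
slope the four logit equations have the closed-form solution

    σ     = (q_neg − q_pos) / (logit 0.27 − logit 0.05) ≈ 10.2574
    m_pos = q_pos − σ·logit p*                           ≈ 60.2198
    m_neg = m_pos + (q_neg − q_pos)                      ≈ 80.2198
    q0    = m_pos + σ·logit 0.27                         ≈ 50.0175

The anchors are treated as exact even though they are printed as rounded
values; a unit test checks the closed form against an independent numerical
root-finder on the four equations. Whether the two curves truly share a
slope is an assumption — the anchors happen to be exactly consistent with
it, and `CurvePair` accepts unequal slopes for users who want otherwise.
Anchors implying a non-positive slope or violating the curve ordering
(p_pos < p_neg at q0, or q_neg < q_pos at p*) raise a calibration error.
In the doubly degenerate no-bias case (equal quality bars *and* equal
probabilities) the slope is unidentified; calibration then returns
identical curves with a documented fallback slope of 10 quality units,
which affects nothing the no-bias scenarios measure (every bias statistic
is slope-free at zero gap).

Qualities outside [0, 100] are evaluated, not clipped: the generators
enforce the range, and unclipped curves keep quadrature tails well defined.

## Submission policies

Three deterministic rules, all with inclusive thresholds ("at least"):

* quality threshold: submit iff q ≥ q0, sign-blind;
* probability threshold: submit iff p_s(q) ≥ p0, sign-blind in probability
  but sign-*dependent* in implied quality — under a biased pair the
  effective quality bar for negative studies, m_neg + σ·logit p0, exceeds
  the positive bar by the full location gap;
* expected utility: submit iff p_s(q)·reward ≥ cost, the rational rule;
  decision-identical to a probability threshold at p0 = cost/reward, and
  implemented through the same comparison so the equivalence is exact.

Probability comparisons are made on the logit scale with an absolute
tolerance of 1e-12, so a study lying exactly at the bar (as the calibrated
anchors arrange at q = 46 and 66) is included regardless of rounding
direction. Degenerate utility ratios decide uniformly (cost = 0: always
submit; cost ≥ reward: never), but have no finite quality threshold and
raise when one is requested. Policies are deterministic by design; author
noise and multi-journal resubmission ladders are out of scope.

## Synthetic populations

Populations are data frames with columns quality, sign, submitted,
accepted (the flags nullable until the process runs). Two generation
modes:

* `sign_first`: sign ~ Bernoulli(prop_positive), then quality from that
  sign's distribution. Identical per-sign distributions realise the
  identical-distribution assumption; shifting the negative distribution
  realises its failure.
* `quality_first`: quality from one distribution, then
  P(positive | q) = expit((q − coupling_location)/coupling_scale), the
  world in which better studies are likelier to come out positive. The
  logistic link mirrors the acceptance-curve family; the default coupling
  (location 50, scale 15) is illustrative — no empirical magnitude for
  this coupling exists to calibrate against.

The distribution menu is uniform on a sub-interval of [0, 100], normal
truncated to [0, 100], beta rescaled to [0, 100], and a point mass. All
sampling is by inverse CDF of the analytically truncated law (never by
rejection), so the moments asserted in tests are exact and streams are
reproducible from a single `numpy` generator seed. What the generator does
not emulate: real submission records, journal heterogeneity, time trends,
or any dependence of sign on anything but quality — so passing tests show
the internal consistency of the selection mechanism, not that any real
journal's curves look like these.

## Selection process and observables

`run_process` sets submitted flags deterministically from the policy and
draws acceptance for submitted studies as independent Bernoulli
p_s(q) — one uniform per study, no within-journal clustering. The
observables are those the empirical literature reports:

* the 2×2 accepted/rejected × positive/negative table over submitted
  studies;
* the crude acceptance odds ratio (acc_pos·rej_neg)/(rej_pos·acc_neg) with
  Woolf log-normal interval exp(log OR ± z·SE), SE = sqrt of the sum of
  reciprocal cells, z = 1.96 by default. A single zero cell triggers the
  Haldane–Anscombe correction (0.5 added to every cell, flagged); a zero
  row or column leaves the OR undefined and raises. Tables with no zero
  cell are never corrected;
* per-sign acceptance rates, submitted fractions, and mean submitted
  quality (the submitted-quality comparison is where a hidden bias
  resurfaces);
* the conditional odds ratio described above.

`expected_acceptance` is the simulator's independent oracle: for a given
quality law, policy and sign it computes E[p_s(Q) | Q ≥ threshold] and
P(Q ≥ threshold) by adaptive quadrature (relative tolerance 1e-8, point
masses evaluated directly), and every scenario result carries these
expectations alongside the Monte Carlo estimates. Monte Carlo vs
quadrature comparisons are made at 3 binomial standard errors, keeping
false test failures under ~1%.

## Shipped scenarios

* `figure1` — biased default curves, quality threshold at the implied q0,
  identical uniform mixtures: the bias is visible (crude OR ≈ 4, interval
  excluding 1 at n = 100 000).
* `figure2` — same curves and mixtures, probability threshold 0.20: the
  per-sign quality bars split to 46 / 66.
* `song_like` — probability threshold with per-sign truncated-normal
  qualities (positive: mean 50, sd 15; negative: mean 72.385, sd 15). The
  negative mean is a constructed demonstration value, fixed once by Brent
  root-finding on the quadrature condition that per-sign acceptance rates
  among submitted studies coincide, then frozen. In this world the crude
  OR interval contains 1, submitted negative studies average ~20 quality
  points higher than positive ones, and the conditional odds ratio remains
  ≈ 7 at every quality — equal crude rates coexisting with constant
  editorial bias. It is one construction among many; the sweep command
  exists to map the surrounding space rather than privilege it.

Default population sizes are n = 100 000 with prop_positive = 0.5, large
enough that 3σ binomial bands are ~0.5 percentage points wide; test
runs that only exercise plumbing use smaller n. The no-bias coverage check
uses 100 replicates of n = 5 000, where expected cell counts (~600) keep
the log-normal interval's nominal 95% coverage accurate.

## Numerical notes and limitations

* Probabilities are produced by `scipy.special.expit` and inverted by
  `logit`; round-tripping quality → probability → quality is accurate to
  better than 1e-9 over [0, 100] for slopes ≥ ~8 quality units. Far
  outside that regime float64 saturates and strict monotonicity of the
  *computed* probabilities fails even though the model's is strict.
* Seeds: one integer seed drives a `SeedSequence` that splits into
  generation and acceptance streams, so a scenario is reproducible from a
  single number; exact streams are guaranteed within a platform.
* The crude OR of a scenario is a ratio of binomial proportions from a
  single simulated journal; its sampling error is irreducible at fixed n,
  which is why stochastic claims in the tests are framed as coverage
  statements over replicate seeds rather than single-draw assertions.
* Editors and reviewers are a single acceptance curve; submission costs,
  prestige ladders, and author learning are deliberately absent.
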