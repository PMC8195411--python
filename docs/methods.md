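# Methods

## The observer model

The observer treats each trial as inference in a two-level generative
model: a binary category C ∈ {cw, ccw} (orientation clockwise or
counter-clockwise of a reference line) sits above the continuous stimulus
orientation θ, expressed in degrees relative to the reference with cw
positive.  The sensory measurement is Gaussian, m ~ N(θ, σ_s), with σ_s a
free parameter per stimulus-noise level (it absorbs both display noise and
internal noise).  Decisions are MAP choices under the category posterior;
because the likelihood ratio is monotone in m, the decision is a threshold
rule with criterion m* (m* = 0 under symmetric priors, shifted otherwise),
and the psychometric function is the Gaussian tail probability
1 − Φ((m* − θ)/σ_s).

Estimation is *self-consistent*: the observer conditions on its own
categorical judgment as if it were fact, restricting the stimulus prior to
the chosen side.  The estimate is the posterior mean (L2 loss) given the
memory sample m_m ~ N(m, σ_m), with likelihood width √(σ_s² + σ_m²) — the
width implied by the generative chain m → m_m.  Reported estimates add
motor noise N(0, σ_0).

### Conditioned prior

p(θ|C) is flat on the plateau [0, α] (category-signed coordinates) and
falls to zero on (α, α+β] as the raised cosine
½(1 + cos(π(|θ| − α)/β)).  The plateau height is 1/(α + β/2) because the
raised cosine integrates to half a plateau-width.  The raised-cosine form
is this package's concrete choice for "a smooth cosine roll-off"; any
similar smooth taper would behave equivalently for fitting, since β has a
small likelihood footprint compared with α.  In the symmetric
(Experiment-1) mode α is shared across sides and p(C=cw) is fixed at 0.5;
in the asymmetric (Experiment-2) mode α_cw, α_ccw and p(C=cw) are all free.
β is shared across sides in both modes.

### Post-feedback variants

For trials where valid feedback contradicts the choice, five variants
predict the estimate distribution with no additional free parameters:

- **1a (prior only)** — the judgment overwrote the inconsistent sensory
  evidence; after correction the posterior collapses to the
  feedback-corrected prior and the estimate is its mean, independent of
  σ_s and σ_m.
- **1b (uncertainty only)** — a heuristic: the estimate is σ_s away from
  the reference on the corrected side; it carries uncertainty information
  but no prior structure.
- **2a (flip decision)** — memory is intact; inference proceeds as on
  correct trials but under the feedback-corrected prior.
- **2b (flip + resample)** — memory recall is an active reconstruction:
  proposals from N(m, √(σ_s²+σ_m²)) are redrawn until one lies on the
  corrected side of the reference (the count of proposals is kept as a
  response-time proxy).  The accepted-sample law is exactly the one-sided
  truncation of the proposal, which is what the grid computation uses; the
  rejection sampler itself is validated against that closed form in the
  tests.  "Corrected side" is interpreted as the reference (sign of m_m),
  not the decision criterion m*; the two coincide in the symmetric design.
- **2c (flip + reweight)** — negative feedback reduces trust in the stored
  evidence in proportion to the Bayesian surprise
  KL = (2q−1)·ln(q/(1−q)), q = p(Ĉ|m): the likelihood width becomes
  (1 + KL)·σ_s.  The surprise is evaluated at the original measurement m,
  so inside the predictive integral it varies with m.

Predictive estimate distributions marginalise the truncated measurement
distribution (restricted to the decision region that produces the given
correctness), push it through memory and estimation, convolve with the
motor kernel, and integrate over 0.5-deg bins.  At θ = 0 the true category
is a fair coin independent of the measurement, so conditioning on
correctness leaves the choice mixture intact; conditional distributions
there are mixtures over both decision branches weighted by the
psychometric value.

## Parameters

| parameter | meaning | unit | default (simulator) |
| --- | --- | --- | --- |
| σ_s (low/high) | sensory noise per stimulus-noise level | deg | design widths (3/18 or 6/18) |
| σ_m | working-memory noise | deg | 4 |
| α (per side) | prior plateau width | deg | 24 (exp1); 30 cw / 12 ccw (exp2) |
| β | roll-off width | deg | 8 |
| p(C=cw) | category prior | – | 0.5 (fixed in exp1 mode) |
| σ_0 | motor noise, measured independently, never fitted | deg | 1.5 |
| lapse | simulator-only uniform-estimate probability | – | 0 |

Simulator defaults are the package's stance on a realistic trained
observer: sensory noise tracking the nominal stimulus noise, a few degrees
of memory noise, a prior plateau near the true stimulus range, and motor
noise of order 1–2 deg as typical for joystick line reproduction.  They are
fixed once here and used unchanged by the tests and the acceptance script.

## Fitting

The joint likelihood multiplies, over all consistent trials, the
psychometric probability of each categorical choice, and, over correct
trials only, the model probability of each estimate's 0.5-deg bin
(conditioned on the choice).  Bin probabilities are floored at 1e-6 before
logs so the objective is finite everywhere.  Optimisation is Nelder-Mead
on transformed coordinates (log for widths, logit for p_cw), with bound
violations handled by clipping plus a smooth quadratic penalty, and with
multiple random restarts (30 by default; reduced counts are used in the
recovery experiments).  Convergence uses simplex tolerances xatol 2e-3
(transformed units) and fatol 0.02 (log-likelihood units — well below any
scientifically meaningful difference), capped at 2000 iterations per
restart.  Fits are deterministic given the configuration seed.

## Numerics

- All integrals use trapezoidal quadrature on a uniform grid over
  [−90, 90] deg, step 0.2 (predictions) or 0.4 (inside the optimiser; the
  two agree to ≲0.1 in a total log-likelihood of thousands, and halving
  the step moves predicted means by < 0.05 deg).
- Density discontinuities of the prior (the reference edge, and the outer
  box edge when β = 0) take their midpoint value on the grid, which keeps
  trapezoidal quadrature second-order accurate; closed-form Gaussian-box
  integrals are then matched to ~1e-7.
- Posterior means are computed in the log domain with per-row max
  subtraction, so measurements arbitrarily far from the prior support
  return finite, correctly-signed estimates.
- Estimate bins are 0.5 deg wide with edges at integer multiples of
  0.5 deg (the bin width is fixed by convention; the alignment is a
  package choice).
- Exact decision ties (posterior 0.5 up to round-off) are broken by a fair
  coin, mirroring the random a-priori category at θ = 0.
- Orientation is treated as linear, not circular: all prior support and
  measurement mass lie well within ±60 deg of the reference.
- The Model 2c inner integral evaluates the surprise-reweighted posterior
  mean per measurement node; the memory blur uses shared offset nodes at
  a step of max(grid step, σ_m/6) over ±5σ_m.
- Bootstrap intervals are stratified percentile intervals (resampling
  within each orientation × noise condition), widened if needed to cover
  the point estimate — percentile intervals of scores normalised by the
  in-sample omniscient bound can otherwise exclude it.

## The synthetic-data generator

`simulate_subject` runs the generative chain forward per trial:
measurement, threshold decision (fair coin on ties), valid feedback
(true category = sign(θ); a fair coin at θ = 0), memory recall (plain, or
conditioned resampling on incorrect trials under the `2b-resampled`
variant), feedback-corrected posterior-mean estimation, motor noise, and
an optional lapse that replaces the estimate with a uniform draw over the
design range.  Identical seeds give bit-identical tables.

What it does *not* emulate: line-array rendering and the within-array
sample-mean vs generative-mean distinction (absorbed into σ_s), session
structure, training, reaction times (the resampling draw count is kept as
a proxy), and any attentional structure beyond the uniform lapse.  Passing
tests therefore demonstrate internal consistency of the inference and
fitting machinery under the model's own assumptions — not that human data
follow the model.

A note on the consistency filter: with motor noise present, a small
fraction of estimates near the reference crosses to the wrong side and is
excluded (≈0.1–0.5% at the defaults; exactly 0 when σ_0 = 0).  This
mirrors the small exclusion rates expected from motor noise in real data.

## Design choices that were genuinely open

- The exact roll-off functional form and its normalisation (raised cosine,
  declared above).
- Model 2b's proposal is centred on the original measurement m (not on a
  separately degraded recall), and its acceptance boundary is the
  reference orientation.
- Model 2c's surprise uses the decision posterior at m, with
  σ'_s = (1 + KL)·σ_s.
- Parameter bounds (σ_s ∈ [0.5, 40], σ_m ∈ [0.01, 20], α ∈ [5, 60],
  β ∈ [0.5, 40], p_cw ∈ [0.05, 0.95]), transforms, and convergence
  criteria — none are dictated by the model; all are declared here.
- The omniscient bound is in-sample ("data explaining themselves"); no
  held-out variant is provided.
- Bootstrap resampling is stratified within condition so sparse
  large-|θ| cells are never lost.

## Known limitations

- The Nelder-Mead objective is mildly multi-modal in (σ_m, β); restarts
  handle this, but β is recovered loosely (its likelihood footprint is
  small) and should be treated as a nuisance parameter.
- Reported problem sizes: recovery experiments use full-size designs
  (2100/1820 trials) with 8–10 restarts; the comparison and oracle checks
  use 70-repetition cohorts and 10⁵-sample Monte-Carlo runs.
- Normalised scores depend on the probability floor (1e-6, shared between
  fitting and comparison) for models that concentrate mass in few bins
  (Model 1b especially); on synthetic cohorts with dispersed estimates
  Model 1b can score below Model 1a for exactly this reason.
- The omniscient bound is a finite-sample in-sample quantity; with very
  few trials per condition it is loose and normalised scores are noisy.
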