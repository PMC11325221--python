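# Methods

This note records the modelling choices behind `desqspr`: what is
computed, under which assumptions, which knobs matter, and what the
synthetic study does and does not demonstrate.

## σ-profiles and S-descriptors

A σ-profile is treated as the discrete histogram the COSMO software
emits — an ordered, uniformly spaced σ grid with a non-negative surface
area per grid point — never as a continuous curve.  "Area under the
curve" is therefore exact summation of per-point area weights, and the
only numerical questions are bin membership ones:

* the ten regions are half-open intervals of width 0.005 e/Å² over
  −0.025…+0.025 e/Å²;
* a grid point numerically on an interior boundary (|σ − edge| ≤ 1e-12)
  contributes half its area to each neighbouring region — the discrete
  operationalization of "evenly split" boundary ordinates;
* the window edges ±0.025 belong wholly to regions 1 and 10;
* profile mass outside the window is *not* clipped into the edge
  regions: it accumulates in `truncated_mass` with a warning, so
  Σᵢ Sⁱ + truncated = total area holds to 1e-9 relative for every
  profile (an invariant the test-suite enforces over 1000 random
  profiles).

File ordinates may be areas or densities; the convention is an explicit
argument, never guessed, because both exist in the wild and the 24×–0.001×
scale difference would silently poison every downstream descriptor.
Grid uniformity is validated to 1e-9 relative and violations name the
offending row.

## Recipes, mole fractions, mixing

Water enters recipes as a weight percent, so converting to mole
fractions needs molar masses: the module ships them for the six common
screening constituents (betaine, choline chloride — treated as a single
ion pair — ethylene glycol, propylene glycol, glycerol, urea) and water,
and refuses to guess for anything else.  On a basis of the molar parts,

    moles_water = (w/(1−w)) · Σⱼ partsⱼ·Mⱼ / M_water ,  w = wt%/100,

and mole fractions are taken over parts + water moles; the result is
invariant to rescaling all parts.  Mixture descriptors are the exact
linear rule Sⁱ_mix = Σⱼ Xⱼ Sⁱⱼ over however many constituents the recipe
has (ternary systems included) — linearity and the single-constituent
fixed point are asserted bitwise in the tests.

## Inactivation kinetics

The decay model is strictly first-order, A_R(t) = A_R,0·e^(−kt).  The
fit is nonlinear least squares (trust-region reflective, k ≥ 0 bound)
with log-linear initialization on the positive residuals, tolerances
1e-10, and up to 5 jittered restarts.  Standard errors are asymptotic
(Jacobian at the optimum).  Choices worth stating:

* **Units.**  Fits run on day-scaled time axes (k in day⁻¹); the h⁻¹
  value is carried alongside and both are first-class, because rates
  are conventionally quoted per hour while half-lives and sampling are
  daily — a silent 24× slip is the classic failure mode here.
* **Intercept.**  A_R,0 is free by default; a two-point series (after
  censoring) falls back to a fixed-100% intercept, flagged
  `intercept_fixed`.
* **Censoring.**  Residuals > 100% are removed before fitting
  (`drop_over_100`), the time-zero 100% always kept.  Censoring exists
  for the overstabilization artefact; unbiased measurement noise around
  100% should *not* be censored when no such artefact is present, since
  one-sided removal truncates the noise distribution and biases k̂ low
  for slow decays — the recovery benchmark fits uncensored for exactly
  this reason.
* **Degenerate series.**  All-zero-after-t₀ series decay faster than the
  cadence can resolve; they get k pinned to a 51 h⁻¹ sentinel with a
  `faster_than_resolvable` flag instead of a fit failure.  A fitted k
  below 1e-10 day⁻¹ (the convergence tolerance) is reported as exactly
  0 with an infinite half-life.
* **k·t½ = ln 2** is enforced as a constructor invariant, not recomputed
  ad hoc.

## QSPR networks

The response is log₁₀ k: rates span ~five decades (2·10⁻⁴ to 51 h⁻¹)
and a raw sum-of-squares fit would be dominated by the fastest decays.
Inputs are z-scored on the training block (the exponential activation
saturates otherwise) and the response is z-scored internally with the
inverse applied on prediction.

The split is calibration vs held-out prediction at 55/84 by default,
with the calibration block divided 70/15/15 into training / test /
validation; counts are floored with the remainder to training, blocks
are disjoint and exhaustive for every seed.

Training is plain full-batch gradient descent on the sum-of-squares
error (the history records SSE; the gradient is scaled by 1/n so the
step size is sample-size-independent), early-stopped on the test block
(patience 300 epochs, best-test weights kept, max 4000 epochs, step
0.05).  These schedule values are this package's documented defaults —
the original training schedule behind the workflow is not public.
Divergence restarts with half the step, up to 5 times.  Weights
initialize uniform ±1/√fan-in from the candidate's seed.  The
exponential activation clips pre-activations at ±30.

The architecture search draws hidden widths 4–13 uniformly; the
hidden/output activation pair cycles through a seeded shuffle of all 16
combinations rather than iid draws.  With only two or three pairs viable
for a z-scored response (a tanh or logistic output cannot reach beyond
±1, an exponential output cannot go negative), iid sampling leaves the
viable pairs undrawn with non-trivial probability even at 32 candidates;
balanced cycling makes the benchmark measure the data, not the draw.
Candidates are ranked by validation R², the validation block never
influencing training itself.

## Evaluation battery

RMSEP = √(Σe²/n); bias = ē; SEP = √(Σ(e−ē)²/(n−1)); RPD = SD(y)/SEP;
RER = range(y)/SEP; R²_pred,adj = 1 − (1−R²)(n−1)/(n−p−1).  SEP (the
bias-corrected scatter) is the default denominator for RPD/RER, the
standard chemometric convention; an RMSEP-denominator variant sits
behind a flag for sensitivity analysis.  Quality bands read RPD < 1.4 as
non-reliable, 1.4–2 (inclusive) as fair, > 2 as excellent; RER > 4 / >
10 / > 15 as screening / quality-control / quantification grade, the
highest band winning; "substantial" means R²_pred > 0.75.  Zero-error
predictions yield infinite RPD/RER sentinels rather than exceptions.

## The synthetic study

The generator emulates the statistical structure of a stability screen,
not the chemistry of named compounds:

* **Profiles** are sums of three Gaussians whose centres, widths and
  area shares are drawn per molecule within role-specific ranges — HBAs
  carry ≥ 60% of surface area at negative σ, HBDs the mirror image,
  water is bimodal in both tails.  Total areas are uniform in 80–150 Å²,
  molar masses uniform in 50–200 g/mol.
* **The library** is 10 systems × 10/30/50 wt% water with two solid
  entries excluded (28 formulations), descriptors computed through the
  real integration and mixing code — the generator never re-implements
  that arithmetic.  QSPR benchmarks use a 28-system × 3-level grid
  (n = 84) to match the screening dataset size.
* **Decays** follow the screen's cadence: 0/2/4/6/8 h on day one, daily
  through one week (always), weekly visits until the 50% crossing is
  first observed, capped at 28 days.  Residuals are
  100·e^(−kt)·(1+ε) with ε ~ N(0, 0.05) averaged over 3 technical
  replicates; with probability 0.3 the early points (≤ 3 days, while
  the true curve is still ≥ 70%) are inflated above 100% to exercise
  censoring.
* **Ground truths** map log₁₀ k from three planted descriptors, either
  linearly (equal-magnitude weights, signs aligned with the planted
  columns' mutual correlation so each carries marginal signal) or
  through a small tanh network constrained monotone in each planted
  input.  Monotonicity is deliberate: Spearman screening assumes
  monotone marginal relevance, and the generator tests the workflow
  under its own assumptions.  Planted-recovery benchmarks use a
  dedicated table whose planted columns share a latent driver
  (|ρ| ≈ 0.7–0.8 vs ≤ 0.45 elsewhere); with three orthogonal drivers
  the marginal |ρ| is capped at 1/√3 ≈ 0.58, too close to the 0.5
  screening cutoff for a meaningful test.

What passing the synthetic benchmarks shows: the pipeline's arithmetic
is conservative and exact where it should be, the kinetics estimator is
nearly unbiased under the screen's cadence and noise (≈1.7% median
relative error at 5% noise), and the search reliably finds networks
explaining ≥ 99% of held-out variance when a smooth monotone
descriptor→rate map exists.  What it does not show: that real
enzyme/DES systems satisfy first-order decay with multiplicative noise,
that real σ-profile descriptors carry this much signal, or that the
monotonicity assumption holds for real solvents — real screens can and
do produce non-reliable models (RPD ≈ 1.2) even when the fit to
calibration data looks strong.

## Known limitations

Biphasic or temperature-dependent inactivation is out of scope, as is
predicting whether a formulation is liquid (solid flags are inputs).
The per-enzyme dataset size in a real screen (28 points) is small for a
13-hidden-unit network; the validation block then holds only a few
points and model selection is noisy — the chemometric prediction
battery on the fully held-out block, not the validation R², is the
number to trust.  Sentinel rates (51 h⁻¹ ceilings) compress everything
faster than the cadence into one value; QSPR models trained on them
learn the ceiling, not the true rate.
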