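# Methods

This note documents the modelling and numerical choices behind `striodm`:
what each circuit instance assumes, the parameters that matter, what the
synthetic generators do and do not emulate, and where the design was
genuinely open.

## Circuit instances

### Feedforward instance (`core_model`)

The feedforward instance treats one decision as a single pass: cortical
activity → FSI-normalized striosomal projection → pallido-habenular relay →
dopaminergic gating → matrix read-out → action values. Assumptions:

- Cortical input to both striatal compartments and both pathways is the
  same signal; pathway differences live in the weights and signs.
- FSI activity `c` is a supplied positive scalar per pathway. The model
  gives no generative equation for it in this instance; stress effects on
  normalization are modelled in the sparse instance, where FSI activity has
  an explicit afferent pool.
- The activity shift `b_sSPN` is applied after division by `c`
  (`s = (1/c)Wᵀx + b`).
- Striosome→daSNC coupling signs: direct-pathway sSPNs inhibit their daSNC
  subpopulation (positive `w_sd` inside the gate's exponent), indirect-
  pathway sSPNs disinhibit theirs (negated weight). This realizes the
  striosome→GPe→daSNC disinhibitory route with a single gate equation.
- Action-value coefficients are constant across analyses: β = 1 on every
  dimension and α = 0.5 for the direct (action) read-out. The indirect
  (restraint) read-out weights the cost dimension only. With identical
  read-outs on identical inputs, the action and inaction accumulators would
  be exchangeable and psychometric curves could never leave 0.5; the
  cost-weighted restraint read-out is the minimal asymmetry that lets
  approach rates track reward, and is the package's own task mapping.

The logistic is clamped at argument ±36: the largest clamp for which its
output remains strictly inside (0, 1) in double precision.

### Race (`choice_process`)

Accumulators follow `dY = v dt + σ dW` from 0; Euler–Maruyama with default
`dt = 0.01`, censoring at `t_max = 100`. An action is eligible when its
direct accumulator reaches `h` before its inaction accumulator; among
eligible actions the earliest hitter wins, ties resolving to the lowest
index. Negative drifts are allowed and simply censor.

Discretely monitored first passage overestimates hitting times by
≈ 0.58·σ√dt/v. Because the model's quantitative claim is the
inverse-Gaussian mean h/v, the simulator resolves sub-step crossings with a
Brownian-bridge test (crossing probability `exp(−2(h−y₀)(h−y₁)/σ²dt)`),
assigning interpolated crossing times; measured bias at σ = 0.2, v = 0.5,
dt = 0.01 is below 0.002 against the exact mean of 2.0. With σ = 0 the
bridge is inactive and hitting lands exactly on the grid at
`ceil((h/v)/dt)·dt`, preserving the deterministic contract.

### Sparse instance (`sparse_network`)

Thousands of small cortical groups (default 1,000 groups of 4 of 50
cortical neurons — a desk-scale version of the reference network) each
drive one FSI and one SPN per decision-dimension. Per-group weights are the
group's local principal components, learned online with Sanger's rule
(sequential deflation of Oja's rule), which yields ordered, unit-norm
components; the learning rate decays as 1/t. FSI activity is a floor (0.5)
plus the mean absolute activity of the group's afferents, making divisive
normalization input-dependent. Chronic stress is modelled as removing
cortex→FSI *connections* (not down-weighting them), which decorrelates FSI
activity from its group's drive.

Bhattacharyya separation between subpopulation activity distributions uses
the Gaussian closed form by default; a histogram-overlap estimator is
available behind a flag for non-Gaussian regimes.

### Dynamic instance (`dynamic_circuit`)

Coupled rate ODEs per dimension and pathway with time constant τ (default
0.5 s), explicit Euler at `dt = 0.005τ` (RK4 behind a flag), a stability
guard `dt < τ/5`, and a divergence guard at |s| > 10⁶. Dopamine feedback
`w_da·(y − ½)` enters the sSPN equation negatively and the mSPN equation
positively — dopamine lengthens direct-matrix upstates and shortens
indirect-matrix ones. Plasticity `dw_sd/dt = κ·s_sSPN` runs continuously by
default; an epoch mask is available in the parameters.

Gate polarity: a dimension joins the **direct** decision-space when its
daSNC output is at or above the threshold (default 0.5, the sigmoid
midpoint) and joins the **indirect** space when the output is *below* it.
Combined with the coupling signs above, this is the only polarity
assignment under which (a) overall striosomal sweeps move both pathways'
dimensionalities in the same direction, (b) dopaminergic sweeps move them
oppositely, and (c) low dopamine yields a low-dimensional direct space next
to a high-dimensional indirect space.

Protocols:

- *Prediction error*: one source drives the reward dimension at the
  expected level from t = 0; a second source replaces it with the observed
  level at t = 2.5 s. The reward-dimension populations' activity change at
  the switch is linear in (observed − expected) by the linearity of the
  rate equation; other dimensions receive nothing and do not respond.
- *Rebound*: four successive 1.25 s pulses, one per dimension. Cortical
  recruitment of a dimension drives its sSPN subpopulation *below* baseline
  (recruited striosomal subpopulations lower their mean activity), which
  disinhibits the daSNC gate for the duration of the pulse. With plasticity
  on, the sustained deviation weakens `w_sd` (κ·s < 0 during the pulse, so
  κ > 0 in this convention), and the weakened coupling lets the gate fall
  back below threshold sooner once the pulse ends — de-prioritization
  latency shrinks on every dimension. The pulse amplitudes are
  configuration values; the tested claim is the latency comparison, not any
  absolute latency.
- *Dimensionality sweeps* stagger per-dimension daSNC excitabilities
  (z spread over ±0.75) so dimensions switch at distinct sweep levels,
  giving graded counts whose Spearman correlation across pathways is the
  reported statistic. A constant sweep has zero variance and is flagged
  degenerate rather than assigned a correlation.

## Dimensionality and valuation (`dimensionality`)

The decision-space dimensionality is a sum of independent Bernoulli gates:
its pmf is computed exactly by iterative convolution (Poisson-binomial),
with the common-probability binomial form exposed as a shortcut. Exact
enumeration backs the tests up to q = 12.

Valuation axes over a reward × cost action-value grid: riskiness and safety
are the mean summed value in the high-reward/high-cost (top-right) and
low-reward/low-cost (bottom-left) corner *quadrants* — the grid halves
along each axis, an explicit convention since no boundary is canonical;
high/low action are grid fractions with summed value > 0.5 / < 0.2;
exploit/explore are fractions with per-cell Gini > 0.5 / < 0.25. Gini is
the mean absolute pairwise difference over twice the mean, computed by the
sorted-rank identity.

## Adaptation (`adaptation`)

Advantage is a score-weighted sum over all 2^q decision-spaces of their
formation probabilities (independent gates factorize the probability);
enumeration is capped at q = 12. Net advantage subtracts a weighted
Euclidean distance to the baseline anchor. Trajectories ascend the
central-difference gradient (step 10⁻⁴) at a fixed rate, halving the rate
(with a warning) whenever a step would decrease net advantage — making
recorded trajectories monotone by construction. Scores per decision-space
are scenario configuration; the shipped incubation landscape is a two-gate
model in which a "common" space dominates until an exposure event boosts a
"rare" space's score (tracked by an exponential moving average), carving a
second attractor. Whether a baseline ends vulnerable (rare space forming
frequently) or resilient is basin membership at exposure time, which is why
exposure timing matters: late exposure lets pre-exposure drift carry
borderline baselines into the common basin.

## Inference (`inference`)

Synthetic sessions draw environmental inputs i.i.d. standard normal; each
phenotype class uses a fixed decision-space (none / first / second / both
dimensions), and sSPN activity is the weighted sum of in-space inputs plus
i.i.d. Gaussian noise. OLS per class (no intercept — the generating model
is homogeneous) recovers the weights; the two-dimensional class's slope
equals the sum of the one-dimensional classes' slopes by construction.
Session classification assigns each session to the class minimizing squared
residual; its irreducible error is sessions whose input is near zero along
a distinguishing dimension, ≈ (2/π)·arctan(noise_sd/input_sd) per
dimension, so high recovery requires noise well below the input scale.
Logistic interpolation of choices uses maximum likelihood with an
L2-regularized fallback (flagged) under complete separation.

## Spike analyses (`spikes`)

The coupled generator makes the sSPN train homogeneous Poisson (default
5 Hz, 60 s) and the mSPN train a superposition of an independent background
at (1−c)·rate and lag-shifted copies of sSPN spikes retained with
probability c — the marginal mSPN rate is constant in c, so coupling alters
only dependence.

ISI classification splits each train's intervals at its median (shorter =
excitation, longer = inhibition, exact ties neutral and excluded). A motif
is an sSPN interval end followed within the window (default 100 ms) by an
mSPN interval end. Defaults of 50 ms bins, 100 ms motif window and 500 ms
maximum correlogram lag are conventions, all configurable.

The motif null is a random **circular time-shift** of the mSPN events:
it preserves every within-train property and destroys only the cross-train
alignment. A within-train label permutation is available behind a flag but
understates the count's variance under independence (it conditions on the
co-occurrence structure and fixes label margins; measured z-score spread
≈ 1.17 versus ≈ 1.00 for the time shift), which pushes its 3-SD tail to
~0.5% instead of the nominal ~0.13–0.3%.

Granger-style coupling fits lag-OLS models per direction with the lag order
chosen by AIC on the target's own autoregression, then F-tests the source
lags; constant series are flagged, not tested. Effective correlation is the
mean absolute pairwise Pearson correlation across neurons — an operational
stand-in for the coordination measure, documented as such.

## Synthetic data: scope of the tests

The generators emulate controlled structure — latent sources with chosen
loadings and signal-to-noise, Poisson spike trains with known directed
coupling, linear session models — not recorded physiology. Real recordings
carry nonstationary rates, bursting, shared slow drives and measurement
artifacts that none of the nulls here model; passing tests therefore show
that the *procedures* are correctly implemented and calibrated under their
stated assumptions, not that the biological claims hold in real data.

## Problem sizes

The shipped analyses run at desk scale: 1,000 sparse groups (not 10,000),
10,000 race samples, 10,000 synchrony pairs with 300-sample shuffle nulls,
1,000 Granger simulations of length 500, 100-session-per-class inference.
These sizes give Monte-Carlo standard errors comfortably inside every
asserted tolerance.
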