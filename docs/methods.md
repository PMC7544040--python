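# Methods

## Model definition

The network is a synchronous discrete-time map over `N` binary states.
One connectivity matrix `J` is drawn per `(seed, g, w)` triple — quenched
disorder; re-drawing `J` is a new realization.  The first
`(1-α)·N` indices are excitatory, the rest inhibitory; self-connections
are excluded (zero diagonal — negligible spectral effect at `p = 0.2`,
and it reads "connects to each *other* neuron" literally).  Entry
`J[j, i]` is the synapse from neuron `i` to neuron `j`.

Each step the recurrent firing probability is the clamped-linear transfer
of the input, with the boundary case `I = 1` folded into the saturated
branch.  The external drive is an independent second chance to fire; the
implementation draws once per neuron at the combined probability
`p_i + (1 - p_i)·p_ext`, which is distributionally identical to two
independent draws OR-ed together and halves the RNG cost.

Run-length parameters are package choices (the map itself does not fix
them): `T_steps = 5×10⁵` by default with `burn_in = 10⁴` columns
discarded and 10 neurons initially active; scans and the acceptance
script use `T_steps = 2.1×10⁵` (2×10⁵ analysed steps), five realizations
per parameter point — long enough that avalanche catalogs reach a few
hundred to tens of thousands of events per point while a full boundary
scan stays a desk-scale computation.  All are configurable.

## Eigenvalue theory

`λ_b` (outlier) and `R` (bulk radius) are implemented as printed in the
README.  The crossover `g*` where `λ_b = R` is computed two ways and
cross-checked to 1e-9: the closed form (quadratic obtained by squaring
`λ_b = R`) and a bisection root.  Squaring introduces a spurious
`λ_b = -R` root (≈ 4.89 for the default network); the implementation
keeps the root with `λ_b ≥ 0`, i.e. `g ≤ (1-α)/α`, which is the physical
crossing (≈ 3.344 at `N = 1000`, exactly 4 as `N → ∞`).  The boundary
solver `w*(g)` inverts `λ_b = 1` below `g*` and `R = 1` above; at `g*`
both branches coincide and the outlier branch is used by convention.
The outlier prediction is treated as a leading-order finite-`N` result:
sampled matrices match it within ~10%, which is the tolerance the
spectral tests use.

## Branching function

`Λ(S) = E[S(t+1) | S(t) = S] / S`.  The **empirical** estimator imposes
`S(1) = k/N` by activating a uniformly random set of `k` neurons
(matching the model's exchangeable construction), advances one step with
Bernoulli draws and averages `S(2)/S(1)` over trials (default 200),
reporting the across-trial standard error.  The external drive is
excluded from the one-step propagation — it is input, not recurrence.

The **semi-analytic** estimator assumes the numbers of active
presynaptic E and I neurons are Poisson/binomial counts.  Two variants:

* `weights="mean"` — the classic simplification: every synapse at its
  average strength (`w/2`, `-g·w/2`) under Poisson counts with means
  `μ_E = N·p·(1-α)·S`, `μ_I = N·p·α·S`.  The double sum starts at
  `n = 0` (the zero-count terms carry probability mass even though the
  transfer vanishes there) and truncates where the Poisson tail mass
  drops below 1e-12.
* `weights="distribution"` (default) — the full one-step expectation:
  with `k = S·N` imposed active neurons, a neuron's input is a sum of
  `k` i.i.d. contributions (present with probability `p`, then uniform
  on `[0, w]` or `[-g·w, 0]` according to the E/I identity).  The input
  density is an FFT convolution power on a signed grid (`dx = w/64`,
  half-width ≥ mean + 14 sd; uniform densities discretized
  trapezoidally so their means are exact), and `E[σ(X)]` follows by
  quadrature.

The distinction matters.  In the weak-coupling regime the transfer is
effectively linear and both variants give `Λ = 1` on the boundary.  In
the strong-coupling regime (`g` near 4 on the boundary) the *mean* input
cancels and firing is driven entirely by input fluctuations; dropping
the synaptic-weight dispersion then underestimates `Λ` systematically
(several empirical standard errors) and places the `Λ = 1` fixed point
far below the one-step map's true fixed point.  The
distribution-weighted curve tracks the empirical branching function
within sampling error in every regime, so it is the default for all
quantitative uses (critical range, avalanche threshold).  The mean-weight
variant is retained for comparison and for the linear-regime checks.

**Critical range** `ρ = S₂ − S₁` between the `Λ = 1.05` and `Λ = 0.95`
levels; crossings are located by linear interpolation, taking the
largest-`S` 1.05 crossing and the first 0.95 crossing beyond it.  Flat
critical curves never cross a level; the fallbacks (smallest grid `S`,
largest grid `S` with `Λ ≥ 0.95`) are flagged, so `ρ` is grid-capped in
the synchronous regime — its use there is the trend, not the absolute
value.

The distribution-weighted curve can additionally be conditioned on a
drawn connectivity: the per-contribution law is then the pooled realized
weight distribution of that matrix instead of the ensemble law.  This
keeps the curve noise-free while tracking realization-level departures
of the weight statistics.

**Avalanche threshold** `S†` is the largest `Λ = 1.01` crossing of the
realization-conditioned semi-analytic curve on a grid up to `S = 0.8`
(the fixed point migrates to high `S` at intermediate `g`).  Exactly
critical curves stay below 1.01 everywhere; then `S† = 1/N`
(single-neuron threshold), flagged.  A noise-free curve is used rather
than the raw empirical one because level-crossing detection on a noisy,
nearly flat curve is ill-posed exactly where it matters (the critical
regime).

## Avalanches, κ, exponents

An avalanche is a maximal run of steps with active-neuron count
**strictly above** the integer threshold `⌈S†·N⌉`; duration = run
length, size = total spikes in the run; runs touching either end of the
recording are discarded as incomplete.  Raw counts are used — the raster
does not distinguish externally driven from recurrent spikes.

`κ_ε` compares the empirical CDF (right-continuous, `P(X ≤ β)`) with a
continuous reference power-law CDF of exponent `-ε` truncated to the
observed `[min, max]` range, at 10 log-spaced points including both
endpoints; truncation to the observed support keeps the statistic
scale-free.  `ε = 1.5` for sizes and `1.7` for durations, the critical
reference exponents.

Exponents are fitted by discrete (zeta-normalized) maximum likelihood,
standard error from the observed Fisher information; no goodness-of-fit
machinery is attached, only the log-likelihood is reported, and fits on
fewer than 50 samples are flagged.  In the analysis pipeline the fit
support starts at the smallest attainable value (`x_min = min(sample)`):
sizes are bounded below by `threshold + 1`, so anchoring the zeta
normalization at 1 would bias the size exponent low by construction.
The function default remains `x_min = 1`, appropriate for durations and
unbounded counts.

## Balance and asynchrony

Inputs decompose exactly through `J⁺ = max(J, 0)` and `J⁻ = min(J, 0)`;
`I = I^E + I^I` holds elementwise.  Time averages include quiescent
steps and exclude the burn-in.

* **Tension** `T_i = 1 − ⟨I_i⟩ / (⟨I_i^E⟩ + ⟨|I_i^I|⟩)`, averaged over
  neurons with nonzero drive (zero-drive neurons are excluded and
  counted).  Because time averaging commutes with the linear input maps,
  the scan path computes it from the mean state vector; the identity
  with the full decomposition is asserted in the tests.
* **CCG**: the estimator is not pinned down by the definitions above, so
  the package uses lagged Pearson correlations of mean-subtracted,
  unit-variance input series over lags −20…20, averaged over a random
  sample of 2,000 ordered neuron pairs (bounded, scale-free, standard);
  pairs with constant series are excluded.  Areas are plain sums over
  the 41 lags — negative lobes legitimately subtract.  E-with-E and
  I-with-I streams use the same pair sample.  `η = 1 − A_total /
  ((A_EE + A_II)/2)`.  Absolute `η` values depend smoothly on the
  estimator choice; ordering across `g` is the robust observable and is
  what the tests assert.  For long runs the CCG uses a 50k-step window.
* **ISI CV** per neuron in discrete steps; neurons with fewer than 3
  post-burn-in spikes are excluded and counted.  The simulation kernel
  accumulates ISI moments in a single pass so saturated runs (~10⁸
  spikes) never require a per-neuron sort; the moment path and the
  event-list path are verified equal.

## Seeding and reproducibility

Every stochastic object takes a seed; `simulate` derives separate
initial-condition and kernel streams from it via `SeedSequence`.  Sweeps
spawn per-cell 31-bit child seeds from a master seed keyed by cell
indices, so any cell is recomputable in isolation and a rerun sweep is
byte-identical.  Result tables carry a short content hash of the
parameter set.

## What the model does and does not capture

Within the model, quenched realizations on the boundary vary
substantially: the finite-size outlier eigenvalue fluctuates by a few
percent, so some `g = 0` "critical" draws are mildly supercritical and
spend long stretches near saturation, and at intermediate `g` (2–3) the
rectified dynamics support a high-rate boundary state, so mean rates
there can exceed the naive moderate range and avalanche statistics vary
erratically between realizations.  Both behaviors are intrinsic to the
model at `N = 1000`, not artifacts, and they are why boundary statistics
are reported across multiple realizations.

The synthetic dynamics are the object of study, not a stand-in for
recordings: binary neurons, uniform weight distributions, Erdős–Rényi
topology, no conduction delays, no plasticity, stationary external
drive.  Passing tests establish the internal consistency of theory,
simulation and statistics for this model class; they do not certify that
real cortical networks realize either regime.
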