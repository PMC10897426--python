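# Methods

## The model

A cell's mitochondrial activity is a positive scalar *a* (arbitrary linear
units; TMRM fluorescence intensity is the experimental proxy). The scale
has a hard floor of 1, its minimum value. Divisions are synchronous and
unitless: at each generation every cell produces `daughters_per_parent`
daughters (default 2), and each daughter independently takes one of three
outcomes,

| outcome | rule | factor |
|---|---|---|
| I (decrease) | a′ = max(1, a·f) | f ~ U[m, 1] |
| J (unchanged) | a′ = a | — |
| K (increase) | a′ = a·f | f ~ U[1, t] |

with outcome probabilities (p_I, p_J, p_K) looked up from the stratum
containing the **parent's** activity at the moment of division. The upper
fluctuation bound t is the activity-fluctuation coefficient: t = 1.25
means activity alters up to ~25% per division. The parental population is
modelled as Normal(init_mean, init_sd) clamped at the floor — the bulk
sample's mean and standard deviation are the natural plug-ins.

The model has no cell-cycle timing, death, or quiescence-exit dynamics;
population growth is bounded by uniform subsampling to `population_cap`
(default 20,000), which leaves the activity distribution unbiased.

## Parameter defaults and why

* **t = 1.25, m = 1/t = 0.8.** The coefficient 1.25 is the value the
  original experimental comparison settled on. The lower bound m is not
  independently determined; the default m = 1/t makes the multiplicative
  fluctuation symmetric on the log scale (a decrease by U[1/t, 1] mirrors
  an increase by U[1, t]), which preserves scale behaviour. The additive
  mirror m = 2 − t is selectable (`with_coefficient(..., m_relation="mirror")`).
* **Stratum probabilities.** Daughters of low-ΔΨ_m parents increase with
  probability P_k = 0.8; the remaining 0.2 is split evenly between
  decrease and stay, (p_I, p_J, p_K) = (0.1, 0.1, 0.8), since no finer
  split is determined. All other parents use the symmetric (1/3, 1/3, 1/3).
* **Low-stratum boundary = the parental mean.** "Low ΔΨ_m" is read as
  *below the population's typical activity*, giving mean-reverting
  dynamics: below-average daughters are biased upward until they reach the
  bulk level, then fluctuate symmetrically. The alternative reading —
  boundary at the bottom-5% *gate threshold* — was implemented and
  rejected as a default: the upward bias then switches off as soon as
  progeny cross the 5% cut, after which the symmetric stratum drifts only
  ~0.8% per division, and a sorted low subpopulation can never regain the
  parental mean on the observed few-division timescale, for any parental
  distribution shape. Strata are fully configurable, so either convention
  can be requested explicitly.
* **Floor = 1.** Taken as the activity scale's minimum; decreases are
  clamped, never rejected, so population sizes stay exact.

## What the synthetic data emulate

`MixtureSpec` draws per-event intensities from a Gaussian mixture on the
linear activity scale, clamped at the floor. The default bimodal fixture
(weights 0.15/0.85, means 3/12, sds 0.8/2.0, floor 1) produces a clearly
multimodal distribution whose bottom-5% gate falls inside the distinct
low-activity mode — a stand-in for a real TMRM profile, whose mixture
parameters were never published, not a reconstruction of it. Instrument
effects (spillover, autofluorescence, doublets, log-amplifier binning) are
not emulated, so passing tests say nothing about compensation or
transformation choices on real FACS data.

For the division-model analyses (regeneration, coefficient estimation) the
parental population is Normal(10, 1) clamped at 1, following the model's
own Gaussian-parental assumption. The coefficient of variation 0.1 is the
regime jointly consistent with the model's two anchor facts — a ~25%
per-division fluctuation bound and recovery of the parental distribution
within about three divisions: a bottom-5% gate of a CV-0.1 Gaussian sits
~14% below the bulk mean, a deficit that three divisions of biased
fluctuation can close. A much broader parental distribution (e.g. the
bimodal fixture, where the gated mean sits ~80% below the bulk mean) puts
the target mathematically out of reach: three divisions can multiply
activity by at most t³ ≈ 1.95. Regeneration results therefore speak to
narrow, unimodal parental populations; for broad ones the model predicts —
correctly, by construction — that heterogeneity is *not* regained in a few
divisions.

## Mixture fitting

Univariate EM, written here because its guarantees are part of the tested
surface: the first start is deterministic (means at evenly spaced sample
quantiles, pooled sd, uniform weights), the remaining `n_starts − 1` starts
draw their means from the data; the best final log-likelihood wins.
Standard deviations are floored at 1e-6 × sample sd (1e-12 absolute for
constant samples) to block likelihood singularities. The log-likelihood is
checked non-decreasing at every iteration — a decrease beyond
floating-point noise (1e-6 relative, relevant only at the sd floor) raises
rather than being papered over. Convergence is declared when the
per-iteration improvement falls below `tol` (default 1e-6). Components are
reported sorted by ascending mean. Model selection minimizes
BIC = −2 log L + (3k − 1) ln N with ties to smaller k.

Gating is empirical and rank-based — floor(fraction·N) events, stable
ties by event order — and deliberately independent of the fitted model;
the model supplies only tail-mass probabilities. Whether the original
high/low probabilities came from component posteriors or tail mass is not
recorded; tail mass at the gate threshold is implemented as the cleaner,
gate-consistent choice.

## Inference

* **Distance metrics.** Primary: relative absolute mean difference
  |mean(progeny) − mean(parental)| / mean(parental), tolerance 0.05 —
  chosen because the coefficient estimation itself compares absolute mean
  differences, so convergence and estimation share a scale. Secondary: the
  two-sample Kolmogorov–Smirnov statistic, for distribution-shape checks
  (stricter: multiplicative noise widens the progeny distribution relative
  to a narrow parental, so KS convergence lags mean convergence).
* **Regeneration analysis** gates the bottom fraction, simulates `n_reps`
  independent trajectories, and records distances through
  `max_generations` (default 6) with no early stop. The per-replicate
  divisions-to-convergence is the first generation within tolerance; the
  report's headline number is the **median** across replicates (the
  distribution over replicates is discrete and can be skewed).
* **Coefficient estimation** is a grid search (default 1.00–1.60, step
  0.05) over t, with m tied to t by the configured relation. The objective
  is the mean over generations and replicates of |simulated mean −
  observed mean|; ties go to the smallest t. Grid search is used instead
  of a continuous optimizer because the objective is Monte-Carlo noisy;
  replicate seeds are reused across grid points (common random numbers) so
  grid comparisons share their noise. Only t is estimated — m, the
  stratum probabilities and the rest stay fixed by configuration.

## Numerical and degenerate-input choices

* All randomness flows from one integer seed per entry point; sub-streams
  are derived as pure functions of (seed, index) so adding replicates
  never perturbs earlier ones, and replays are bit-identical.
* A stratum interval is [lower, upper): an activity exactly at a boundary
  belongs to the upper stratum.
* Empty percentile gates (floor rounding at small N) warn on
  `gate_percentiles` and raise with guidance in `regeneration_analysis`,
  where an empty gate would make the analysis meaningless.
* Zero-sd mixture components are allowed on the generative side
  (degenerate point components); the fitting side keeps its strictly
  positive sd floor.
* Initial populations passed to the simulator are clamped to the floor,
  matching the activity scale's definition.

## Problem sizes

Default analysis sizes — 10,000-event parental samples, 50 regeneration
replicates, 20 estimation replicates over a 13-point grid — keep every
headline analysis in the tens-of-seconds range on one core while holding
Monte-Carlo error well below the decision thresholds (the regeneration
median is identical across seeds; grid recovery of t is exact at these
sizes).

## Known limitations

* The printed coefficient t = 1.25 cannot be re-derived from data because
  the original FACS event files are not deposited; the estimation
  machinery is validated by parameter recovery on synthetic observations
  instead.
* Stratum membership is evaluated on the parent, not the daughter; a
  daughter-conditioned variant would need a rejection or reweighting step
  and is not implemented.
* Generations are synchronous; there is no division-time heterogeneity,
  death, or selection, all of which could speed or slow apparent
  regeneration in real cultures.
* The KS metric compares a growing simulated population against a fixed
  parental sample; for very small gated subsets its finite-sample bias is
  noticeable.
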