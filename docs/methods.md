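# Methods

This note documents the models, estimators and numerical choices behind
`strokephys`, and what the synthetic-data generators do and do not
emulate.

## Units and conventions

Voltages in mV, currents in pA, reported times in ms (protocol metadata
in s), resistance in MΩ, capacitance in pF, lengths in µm, volumes in
mm³. With these units, Ohm's law reads ΔV[mV] = I[pA]·R[MΩ]/1000 and
capacitance C[pF] = 1000·τ[ms]/R[MΩ], which keeps every formula in the
pipeline dimension-exact. Factor levels are canonicalised
case-insensitively to {sham, stroke}, {contralesional, ipsilesional}
("ipsilateral" and "peri-infarct" are accepted spellings of the
lesioned side), {L2/3, L5}, {female, male}, {negative, positive,
unknown}; the first level of each set is the treatment-coding
reference.

## Synthetic data

The study's raw recordings are not deposited, so every analysis stage
is exercised against generators with analytic ground truth.

**Passive membrane.** A single-compartment RC membrane
τ·dV/dt = −(V − E_L) + I·R_in, discretised by the *exact* exponential
update V_{n+1} = V_ss + (V_n − V_ss)·e^(−Δt/τ) within each
constant-current segment (not forward Euler: same cost, zero
integration error, so noiseless traces equal the closed form to machine
precision). Optional noise is an Ornstein–Uhlenbeck perturbation with
stationary SD `noise_sd`, added in the same recursion so the mean
trajectory is unchanged. Sample n holds the solution after n + 1
updates, i.e. the current of each sample acts over its own interval.

**Spiking.** Leaky integrate-and-fire on the same subthreshold core.
When V reaches the threshold V_T a piecewise-linear AP template is
inserted: a linear rise over `ap_rise_ms` to V_T + `ap_peak_amp`, a
linear fall that re-crosses V_T exactly `ap_fall_ms` after the peak and
continues at the same rate to V_reset, then a clamp at V_reset for the
rest of the refractory period. Defining the fall by its
peak-to-threshold time makes the features analytic: threshold V_T,
amplitude `ap_peak_amp`, half-width exactly
(`ap_rise_ms` + `ap_fall_ms`)/2. The template's initial slope is
validated ≥ 50 V/s so the 10 V/s detector lands within one sample of
V_T. The threshold test uses V ≥ V_T − 10⁻⁹ mV: at the exact rheobase
current the membrane approaches V_T only asymptotically, and the
tolerance makes the on-grid rheobase well defined instead of hinging on
floating-point underflow. The steady firing rate has the standard LIF
closed form f = 1000/(t_ref + τ·ln[(IR + E_L − V_reset)/(IR + E_L −
V_T)]) Hz, used as the oracle for spike counts (undefined exactly at
rheobase, where the ISI diverges).

**AIS profiles.** Trapezoids: baseline, linear rise over `edge_um` to
`f_max`, plateau, linear fall, baseline; optional Gaussian noise
clipped at zero. The threshold crossings of the baseline-subtracted
profile sit at `start + f·edge` and `start + edge + plateau +
(1−f)·edge`, giving truth length `plateau + 2(1−f)·edge` (21.34 µm at
the default f = 0.33 with plateau 20, edge 1).

**Cohorts.** The factorial animal design of the electrophysiology
study: by default 3 animals per group × sex cell (12 animals) and 2
cells per hemisphere × layer stratum per animal (96 cells), matching
the study's 6 + 6 mice split evenly by sex with at least one recording
per stratum. Outcomes are design·β + b₀ₐ + b₁ₐ·1{ipsilesional} + ε with
(b₀, b₁) bivariate normal (SDs, correlation declared) and Gaussian
residuals, on the identity or log scale. Effect sizes are declared per
treatment-coded design column, so simulator truth and fitted
coefficients share names.

**Lesions.** Per-section areas follow a jittered parabolic
(spherical-cap-like) profile rescaled so the serial-section estimator
returns the declared volume exactly.

What the generators do *not* emulate: conductance-based spike shapes,
channel noise, electrode artefacts beyond a constant offset,
morphologically realistic images, unbalanced designs or missing strata.
Passing tests therefore demonstrate correctness of the estimators under
their stated definitions and calibration of the statistics under the
declared generative model — not robustness to every pathology of real
recordings.

## Feature extraction

dV/dt is the central difference at the native rate (mV/ms ≡ V/s). Spike
peaks are local maxima separated by at least the 1 ms refractory guard,
kept when they reach 0 mV or when dV/dt exceeds 10 V/s within the
preceding 5 ms *and* the peak has ≥ 20 mV prominence (the prominence
floor rejects noise riding on subthreshold depolarisations; all three
numbers are `RunConfig` fields). The threshold is the last upward
interpolated crossing of 10 V/s in the 5 ms window before the peak; if
the whole window sits at/above the criterion the window's first sample
is returned, and if no crossing exists the feature is undefined rather
than an error. All level crossings are linearly interpolated — at
50 kHz, higher-order interpolation changes results by less than a
hundredth of a sample. The recovery guarantee (threshold within 0.5 mV)
holds when the subthreshold approach is slower than the 10 V/s
criterion, i.e. near-rheobase drive; under strong overdrive the
detector reads the (physiologically real) earlier acceleration point,
as it would on recorded data.

## Passive properties

The RMP window is the 100 ms before the first step (the recording's
start holds no defined window length, so one is declared). Input
resistance uses the steady-state window (final 100 ms of each 1-s
step) and ordinary least squares over ≥ 2 distinct amplitudes. The τ
fit runs on [onset + 2 samples, onset + 5·τ̂] with τ̂ from the
63%-of-deflection rule, iterated once; X₀ is fixed at the onset and
y₀/A are initialised from the steady-state and onset values. Each of
the four hyperpolarising steps is fitted separately and converged fits
averaged — pooling is a config-level choice left open deliberately.
Non-convergence (flat trace, singular fit) flags the result instead of
raising. The series-resistance rule fails a recording iff
|after − before|/before > 0.20, boundary inclusive-pass.

## AIS boundary detection

The 0.33-of-maximum rule is ill-posed under a non-zero background, so
the profile is first baseline-subtracted (median of the flanking 10% of
samples at each end) after optional moving-average smoothing (default
window 1 µm; the closed-form trapezoid checks run unsmoothed because a
window wider than its distance to a corner biases the crossing by a few
hundredths of a µm). Start and end are the first upward and last
downward interpolated crossings — interior dips are bridged. A profile
that never exceeds threshold returns a no-AIS flag. On noiseless
trapezoids each boundary is exact to interpolation error; at
signal-to-noise 10 with default smoothing the boundary error stays
under 0.25 µm across 200 replicates. A rectangle's edges are sub-sample
discontinuities, so each boundary lands within one sampling step.

For the 2D/3D comparison only pure polyline geometry is implemented,
where the XY projection can never exceed the 3D arc length; the
pixel-aggregation mechanism by which max-projection measurements can
overshoot is an imaging artefact outside this model, so no invariant is
asserted about its direction.

## Estimation statistics

The unpaired mean difference (oriented test − reference: stroke − sham,
GFP+ − GFP−) is resampled within groups with replacement, 5000 draws by
default, percentile interval by default with BCa (jackknife
acceleration over both groups) as a config switch — which interval the
original toolchain used is not stated, so the simpler one is the
default and both are exposed. Measured over 20 000 null datasets
(n = 20/group), the percentile interval's true null-exclusion rate is
≈ 6.3%, the familiar small-sample narrowness of the percentile
bootstrap; calibration checks therefore use enough datasets (10 000)
that the Monte-Carlo error of the estimate is small against the 5 ± 2%
acceptance band.

## Hierarchical Bayesian models

For a (possibly log- or log1p-transformed) outcome y, cell i, animal a:

y_i = x_i'β + b₀ₐ + b₁ₐ·h_i + ε_i,  (b₀, b₁) ~ N(0, D),  ε ~ N(0, σ²)

with the full factorial fixed-effect structure over group, hemisphere,
layer and sex (all-zero columns pruned; rank checked), priors
Normal(0, 5) on non-intercept coefficients, half-Student-t(3, 0, 2.5)
on the random-effect SDs, half-Student-t(3, 0, s_y) on σ (s_y the
sample SD of the transformed outcome), and a uniform prior on the
random-effect correlation. The intercept is excluded from the
fixed-effect prior class — standard practice in hierarchical-regression
software — and gets a weakly-informative Normal centred on the sample
median with scale 2.5·max(1, s_y); a zero-centred Normal(0, 5) on an
intercept near −44 mV would dominate the likelihood.

**Collapsed sampling.** Conditional on θ = (sd₀, sd₁, ρ, σ), both the
animal effects and β are Gaussian and integrate out in closed form
(Woodbury per animal block over precomputed cross-products, so one
likelihood evaluation is independent of the number of cells). The 4-D
posterior of θ — smooth and unimodal on the unconstrained scale
(log SDs, atanh ρ, log σ) — is sampled by independence
Metropolis–Hastings: a Laplace approximation at the mode calibrates a
two-component multivariate-t proposal (df 6; matched scale 1.2 plus a
3.6× safety component at 15% weight, so the proposal never under-covers
the tails), a pilot chain re-centres the proposal on the posterior's
empirical moments, and the final chains evaluate all proposals in one
vectorised batch. β is then drawn exactly from its Gaussian conditional
per retained θ draw. This yields near-independent joint draws (typical
split-Rhat ≈ 1.005) in about a second per fit; the independence sampler
relies on unimodality, which holds for this model class but would not
for mixture likelihoods. Each of the `chains` runs contributes
`iterations − warmup` retained draws, so the post-warmup total is
chains × (iterations − warmup) — 160 000 at the archival settings
4 × 50 000 (10 000 warmup), 6000 at the scaled-down default
4 × 2000 (500). Results with any Rhat > 1.01 or a collapsed acceptance
fraction are flagged unreliable, not discarded.

**EMMs and hypothesis tests.** Marginal means average the linear
predictor over the equal-weight grid of the factors not conditioned on,
with random effects at zero and any current basis held at its data
mean; back-transformation (exp / expm1) is applied per draw before
summarising, so the reported intervals are credible intervals of the
back-transformed quantity. Both 90% (5th–95th) and 95% intervals are
emitted. Directional evidence is the posterior odds p/(1 − p) of the
contrast lying on the stated side of zero — posterior odds, not a
posterior/prior odds ratio, and labelled as such — with p = 1 capped at
the draw count (a lower bound). Categories: ≤ 1 none, ≤ 3 anecdotal,
≤ 10 moderate, ≤ 100 strong, > 100 extreme, boundaries in the lower
category.

**Current-adjusted I–F models.** On log1p(evoked frequency), Model 1
adds a *shared* flexible current basis (standardised linear term plus
hinge functions at interior quantile knots, k = 6 columns; the
modelling intent of a smooth shared curve without committing to one
package's spline construction) to the factorial structure; Model 2
crosses the factorial structure with a degree-2 orthogonal polynomial
in current, letting every cell have its own curvature. Comparison is
predictive: PSIS-LOO on pointwise log-likelihoods that condition on
animal effects sampled from their exact conditional (common random
numbers across the two models, so identical models tie exactly);
preference follows the elpd point estimate with a `confident` flag at
|Δelpd| > 2·SE. A marginal-likelihood Bayes factor is deliberately not
reported: without the original basis construction it would not be a
meaningful desk target.

**Calibration.** At the default cohort design (12 animals, 96 cells,
RE SDs 1.2/0.5, ρ = 0.2, residual 1.5), 90% credible intervals for the
four main effects achieve ≈ 92% empirical coverage over 100 simulated
cohorts, and a declared −0.70 group effect lies inside its 90% CrI in
≈ 88–96% of replicates. The mild over-coverage is the usual effect of
weakly-informative shrinkage at this scale.

## Reference values and scope

`strokephys.reported` bundles the published group-level marginal means,
mean differences and evidence ratios of the source characterisation (28
days post-stroke) purely for arithmetic consistency checks — the
acceptance script differences the bundled means at run time; nothing is
fitted to them. Problem sizes in tests and the acceptance script (10 000
bootstrap null datasets, 100 cohort replicates, scaled-down MCMC
defaults) were chosen once as the package's own balance of Monte-Carlo
precision against a desk-scale run and are documented here rather than
revisited per run.

Known limitations: the hierarchical model assumes Gaussian residuals on
the (transformed) scale, as in the source analysis; no non-Gaussian
likelihoods, no leave-one-animal-out influence measures, no vendor
acquisition formats (the native sweep format is delimited text with a
metadata header; ABF/NWB readers are an extension point), and no
automated axon tracing — polyline ROIs are inputs.
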