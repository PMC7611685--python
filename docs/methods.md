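# Methods

## The kinetic model

Cell-free plasmid relaxation assays read out DNA damage through plasmid
topology: an intact plasmid is supercoiled (S); a single-strand break (SSB)
relaxes it to the open-circular form (R); a double-strand break (DSB)
linearises it (L).  The three forms separate on an agarose gel, so the
fraction of DNA in each topology is a quantitative damage signal.

We model the conversion as two consecutive irreversible first-order steps,

```
S --k_sr--> R --k_rl--> L
```

with the exposure variable x being either absorbed dose D (Gy, external
beam) or incubation time t (h, radionuclide co-incubation).  The master
equations

```
dS/dx = -k_sr S,    dR/dx = k_sr S - k_rl R,    dL/dx = k_rl R
```

have the Bateman-type closed form (for S(0) = S0, R(0) = L(0) = 0)

```
S(x) = S0 exp(-k_sr x)
R(x) = S0 k_sr/(k_rl - k_sr) [exp(-k_sr x) - exp(-k_rl x)]
L(x) = S0 - S(x) - R(x)
```

Assumptions: conversions are irreversible; rates are constant over the
exposure range (no dose-rate effect on the dose axis; no source decay or
radical-scavenger depletion on the time axis); every SSB relaxes, every
DSB linearises; the species fractions measured on the gel are unbiased.

Two documented generalisations are available and off by default:

* **Nonzero initial relaxed/linear fractions** (`InitialState(r0=..., l0=...)`).
  Untreated preparations typically show a few percent relaxed DNA; the
  default model absorbs this into S0 < 1 instead.
* **A direct S → L channel** (`variant="direct_break"`, rate `k_sl`) for
  DSBs formed without a prior resolvable SSB.  It enters the closed form
  only as an addition to the decay rate of S (R is fed by the `k_sr` share
  alone), so band-percentage data cannot distinguish it from the basic
  model; we default to the simplest model.

### Numerical choices

* The R expression has a removable singularity at `k_sr = k_rl`.  When the
  relative rate difference is below `1e-8` the analytic limit
  `R = R0 e^(-kx) + S0 k x e^(-kx)` is used instead; continuity across the
  switch is tested to better than `1e-6`.
* L is always computed as the remainder, so conservation
  `S + R + L = S0 + R0 + L0` holds exactly by construction.
* An independent check integrates the master equations with
  `scipy.integrate.solve_ivp` (LSODA, rtol `1e-10`, atol `1e-12`); closed
  form and integration agree to better than `1e-6` absolute on every grid
  tested, including the equal-rate line.
* Proportions are fractions in [0, 1] internally; percentages appear only
  at file boundaries (converted once at ingest), avoiding 100x unit errors
  in fitting weights.

## Fitting

`PlasmidKineticsModel.fit()` minimises the weighted residual sum of squares
over all three species jointly,

```
WRSS = sum_{species, x} ((mean_obs - model) / SD_eff)^2
```

with `scipy.optimize.least_squares` (trust-region reflective, parameters
bounded below by 0, S0 bounded above by 1, `xtol = ftol = gtol = 1e-12`,
at most 10,000 function evaluations).  Design choices:

* **Weights.**  Replicate means per exposure are weighted by `1/SD^2` with
  an SD floor of 1 percentage point (`sd_floor_pct`), so single-replicate
  points (SD = 0) cannot receive infinite weight.  A `mode="lanes"` option
  fits every lane with unit weights for data without replicate structure.
  Multiplying all SDs by a constant leaves point estimates unchanged.
* **S0 is fitted by default** (untreated supercoiled fractions are 92-97%,
  not 100%); `fit_s0=False` fixes it.
* **Covariance.**  `(J' W J)^{-1}` from the weighted Jacobian, rescaled by
  the reduced chi-square by default (`scale_cov=True`, the common
  errors-in-variance convention); disable to interpret the SDs as exact
  known variances.  Standard errors are the square roots of the diagonal
  and are withheld (NaN) when the fit has no residual degrees of freedom.
* **Boundaries.**  Parameters pinned at 0 (e.g. `k_rl` for data with no
  linear band) are reported in `at_bound`; the pseudo-inverse keeps the
  covariance finite there.
* **Starting values** come from a log-linear regression of mean S on x
  (exact on clean data), `k_rl = k_sr/50` (the second step is rate-limiting
  in this assay) and the observed supercoiled fraction at the smallest
  exposure; the optimum is insensitive to 3-fold perturbations of the
  start.
* **High-exposure linear bands** can be excluded with
  `mask_linear_above=<x>`: at heavy damage the linear band smears into
  fragments and its quantification becomes unreliable.  All points are
  kept by default.

On noiseless model-generated data the fit recovers the generating
parameters to better than `1e-6` relative, and refitting the model's own
predictions is a fixed point.

## Dose-time equivalence

Taking the modeled proportion of a chosen species as the damage proxy, an
EBRT dose and an incubation time are equivalent when they leave the same
proportion.  For the supercoiled basis with a shared S0 this reduces to a
ratio of rates:

```
D = (k_sr,t / k_sr,D) t        t = (k_sr,D / k_sr,t) D
```

Rate uncertainties are propagated to first order (delta method) assuming
independent errors:

```
se(D) = D sqrt((se_t/k_t)^2 + (se_D/k_D)^2)
```

The propagation method reproduces the published ± values for all four
worked examples after rounding, which is why it was adopted.  For the
relaxed and linear species no simple ratio exists; equivalence is computed
by numerically inverting the target curve (Brent bracketing to
`|ΔP| ≤ 1e-9`).  The supercoiled curve is monotone and the linear curve
nondecreasing; the relaxed curve is unimodal, so the caller must select the
`rising` or `falling` branch explicitly.  On the supercoiled basis the
numeric route agrees with the ratio formula to `1e-9` relative.

## Densitometry

`lane_profile_from_image` collapses a lane rectangle to a 1-D profile by
summing across the lane width (with a polarity flag for dark-bands-on-light
images).  Baseline removal offers `linear_endpoints` and the default
`rolling_minimum`: a morphological opening (rolling minimum then rolling
maximum over the same window, recommended at ~3x the widest band) computed
on a lightly smoothed copy of the profile so the baseline follows the mean
background rather than the lower noise envelope.  Known bias: for a band
sitting on a sloped background the opening clips roughly
(slope × band half-width) of signal under the band — negligible for the
gentle illumination gradients of gel images but visible on steep synthetic
ramps.

`quantify_bands` integrates each half-open band window and reports each
band as a percentage of the summed three-band signal; percentages sum to
100 by construction, zero total signal raises rather than returning NaN,
and a warning is emitted when more than 10% of the corrected signal falls
outside all windows.  `auto_detect_windows` finds the three most prominent
peaks and splits windows at the valleys between them; the
migration-order labelling (default: relaxed slowest, linear intermediate,
supercoiled fastest) is configurable because gel orientation varies.

## Synthetic data

`generate_proportion_dataset` draws replicate band-percentage tables from
known rates; `generate_gel_image` renders lanes as Gaussian bands with
integrated intensities proportional to the species fractions, plus an
optional background ramp and additive noise, and returns a ground-truth
record for round-trip tests.  Both are byte-deterministic for a fixed
config and seed (one `numpy.random.default_rng` stream, order-stable
draws).

Preset designs mirror the studied exposure schedules: an external-beam
dose grid {0, 0.5, 1, 2, 5, 10, 20, 40} Gy and a radionuclide incubation
grid {0, 2, 4, 21, 25} h (extended mode adds 48 and 73 h), with 6
replicates and Gaussian noise of 5 percentage points per species by default
(the mid-range of typical replicate SDs, which span roughly 1-25 points).
Preset rates use the published supercoiled→relaxed estimates; published
relaxed→linear rates exist only for the dose axis, so the time-axis presets
choose `k_rl` once to match the observed late-time linear fractions:
0.02 h⁻¹ for ⁶⁷Ga (giving ≈13% linear DNA at 25 h under k_sr = 0.59 h⁻¹)
and 0.001 h⁻¹ for ¹¹¹In (marginal linearisation).

Noise models:

* **gaussian** (default): independent per-species noise, clipped to the
  valid range and renormalized to the true total.  The renormalization
  projects the noise onto the simplex, shrinking per-species scatter by a
  factor `sqrt(1 - 2p + 3p^2)` and leaving a second-order mean bias bounded
  by `sigma^2 |3p - 1|`; near 0/100% the clipping additionally distorts the
  distribution.
* **dirichlet**: draws (S, R, L, remainder) from a Dirichlet centered
  exactly on the truth; use it where a species is nearly absent.

What the generator does **not** emulate: radioactive decay of the source
over long incubations (a constant hourly rate is assumed throughout, as in
the model being fitted — note ⁶⁷Ga's 78 h half-life makes this
questionable beyond ~25 h), chemical differences between radionuclides,
lane-to-lane loading variation, band smearing at heavy damage, and any
correlation between species errors beyond the sum constraint.  Passing
tests therefore demonstrate the estimator's statistical behaviour under
the stated noise model, not the fidelity of that model to real gels.

## Problem sizes

The default verification runs use 50-point grids for the oracle
comparison, 200 simulated datasets of 8 exposures × 6 replicates for the
stochastic recovery study, and 3-lane synthetic gels for the densitometry
round trip — sizes at which the sampling error of the summary statistics
is already far below the tolerances being checked.

## Limitations

* The raw gel data behind the published rate estimates (k_sr = 1.21,
  k_rl = 0.017, 0.45, 0.004 Gy⁻¹; 0.590, 0.159, 0.131 h⁻¹, …) are not
  deposited, so those fitted values cannot be re-derived here.  They serve
  in this package only as simulation ground truths and as inputs to the
  equivalence calculator, never as quantities the test suite claims to
  reproduce from data.
* The published worked equivalence examples carry internal rounding
  inconsistencies (the ⁶⁷Ga rate appears as both 0.585 and 0.590 h⁻¹, and
  printed outputs match unrounded rather than printed inputs in two
  cases); comparisons are therefore made to one unit in the last printed
  digit.
* Constant-rate time kinetics ignore source decay during incubation;
  whether a decay correction was applied upstream of the published rates
  is unknown.  No correction is implemented here.
* The equivalence is a cell-free damage proxy; it says nothing about
  relative biological effectiveness in cells or tissue.
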