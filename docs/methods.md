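# Methods

This note records the models implemented in `allometherm`, the
assumptions behind them, the numerical choices that were genuinely open,
and what the synthetic-data generator does and does not emulate.

## Respirometry

An intermittent-flow respirometer alternates flush phases (chamber open,
O2 returns to ambient saturation) and sealed measure phases in which the
dissolved-O2 concentration falls linearly when the fish's uptake is
constant.  Per measure phase we fit an OLS line of O2 (mg L⁻¹) on time
(min), discard the first 60 s (mixing), require at least 180 s of usable
data and a coefficient of determination R² > 0.96, and convert the slope
to whole-animal uptake

    MO2 = (|m_fish| − |m_background(t)|) · V_net     [mgO2 min⁻¹].

Choices made here:

- **Net volume.**  V_net = chamber volume − fish mass / ρ with
  ρ = 1 kg L⁻¹, because the fish's body displaces respirometer water.
- **Background correction.**  Microbial respiration is measured in the
  empty chamber before and after the trial; we interpolate linearly in
  time between the two slopes, evaluated at each cycle's midpoint.  This
  captures overnight microbial growth with minimal assumptions; a
  constant or pre/post-mean correction is a special case.
- **Degenerate regressions** (zero O2 variance) are rejected cycles, not
  errors; too-short cycles likewise carry a `too_short` flag.
- **Summary rules.**  MMR is the maximum accepted MO2 over cycles of at
  least 3 min — cycle-level, because the per-cycle MO2 is the unit of
  analysis throughout; sliding sub-cycle windows are deliberately not
  implemented.  All cycles are MMR candidates (elevated rates occur both
  post-chase and during spontaneous overnight activity).  RMR is the mean
  of the 10 lowest accepted values after excluding the 5 lowest, an
  order-statistic estimator robust to occasional activity; it operates on
  accepted values only.  A summary with RMR ≥ MMR is emitted with a
  warning rather than clamped.

## Cardiac thermal tolerance

Maximum heart rate (f_Hmax, beats min⁻¹) of a pharmacologically
stimulated heart is recorded at each 1 °C step of an acute warming trial.
On Arrhenius axes (y = ln f_Hmax, x = 1000/T_K) the rise is near-linear,
slows at the breakpoint temperature T_AB, peaks at T_PEAK and ends in
arrhythmia at T_ARR.  Observations at and after the arrhythmic step are
excluded; the breakpoint regression additionally uses only the rising
limb (up to and including the peak), because the post-peak decline is not
Arrhenius-linear and would bias a single-knot model.

- **Breakpoint search.**  Continuous two-segment least squares,
  y = β0 + β1·x + β2·(x − c)+, profiled over a dense deterministic grid of
  candidate knots (per-interval midpoints plus 50 uniform candidates,
  restricted so each segment keeps ≥ 3 points) followed by a 201-point
  refinement around the coarse winner.  A deterministic grid was chosen
  over iterative segmented fitting because it is reproducible and
  directly verifiable against an exhaustive search; at n ≈ 10–13 points
  the cost is negligible.
- **"Statistically identified".**  A parametric bootstrap of the
  likelihood-ratio-type statistic n·ln(RSS_line/RSS_segmented) under the
  fitted single-line null; p < 0.05 counts as identified.  The statistic
  is scale-invariant, so the test is pivotal under normal errors and
  behaves correctly in the noiseless limits (a perfect line gives p = 1,
  a perfect broken line p = 1/(B+1)).
- **Confidence interval.**  Parametric bootstrap around the segmented
  fit: residual SD estimated with n − 5 degrees of freedom (four linear
  coefficients plus the knot), refit on each replicate, 2.5/97.5
  percentiles of the knot, endpoints converted to °C via
  T = 1000/x − 273.15.  Bootstrap refits use the coarse grid only (grid
  resolution ≈ 0.01 °C, immaterial for percentiles), which allows fully
  vectorized projection-based refits.  Fits are excluded when the CI
  half-width exceeds 1.5 °C or identification fails.
- **Tie-break.**  T_PEAK is the lowest temperature attaining the maximum
  f_Hmax (earliest peak, the conservative choice).

## Allometric scaling

All performances are modeled on natural-log axes,
ln(performance) = ln a + b·ln BM.  Repeated-measures responses (MMR, RMR,
AAS, FAS per fish per acute temperature; f_Hmax per fish per degree) use
a linear mixed model with a per-individual random intercept, temperature
as a categorical fixed effect coded as absolute per-level intercepts, and
a common mass slope; optional terms are a mass × temperature interaction
and origin/sex covariates.  Estimation is maximum likelihood (not REML)
so BIC comparisons across fixed-effect structures are valid; BIC is
computed as −2·llf + k·ln n_obs with k counting fixed effects plus the
two variance components.  One-off responses (T_AB, T_PEAK, T_ARR,
PEAK_fHmax, ventricle mass) use OLS.

- **Degenerate (noiseless) inputs.**  With zero residual variance the
  mixed likelihood is unbounded; the fitter detects a perfect
  fixed-effect fit (OLS residual mean square < 1e-12) and returns the
  exact OLS coefficients with a `zero_residual_degenerate` warning.
  Singular random-effect fits (variance → 0) are returned with a warning
  rather than raised.
- **Inference.**  Large-sample Wald: per-term Type II chi-square tests,
  Wald 95% CIs, and all-pairs temperature contrasts adjusted with the
  studentized-range (Tukey) distribution on the residual degrees of
  freedom.  Small-sample degrees-of-freedom corrections
  (Kenward–Roger-style) are estimator-specific machinery not reproduced
  here; at these sample sizes (≈ 230–330 observations) the large-sample
  approximation is adequate.
- **Ties** in BIC go to the earlier candidate; ΔBIC is reported to one
  decimal.

Mass-normalization rescales a whole-animal rate at mass M to the 65 g
reference mass along the fitted exponent and expresses it per unit
reference mass: value · (M0/M)^b / M0.  Group means per temperature are
model-predicted values at 65 g, exp(ln a(T) + b·ln 0.065)/0.065 —
consistent with reporting coefficients rather than raw means; FAS, being
dimensionless, is predicted without the division by mass.  Temperature
sensitivity uses Q10 = (R2/R1)^(10/(T2−T1)); the degenerate printed form
of this formula lacking one parenthesis is resolved to the standard
definition, which reproduces the expected orderings.  The Fick-equation
slope arithmetic b_MR = b_Vs + b_fH gives the implied stroke-volume
exponent b_Vs = b_MR − b_fH; full Fick quantities (cardiac output, blood
O2 content) are out of scope.

## Synthetic data generator

The generator emulates the study design the analysis assumes: a cohort of
83 fish with body masses log-uniform over 5–700 g (even coverage of the
ln-mass axis used by every fit), repeat-tested at 12, 16, 20 and 22 °C,
with 30 fish receiving a cardiac trial and ventricle masses.  Defaults
are the study conditions themselves: metabolic power laws with
b_MMR = 0.810 and b_RMR = 0.809 and per-temperature intercepts taken from
the fitted coefficient table; cardiac power laws T_AB/T_PEAK/T_ARR with
exponents 0.030/0.034/0.030; f_Hmax exponent −0.052 with 16 °C intercept
4.325; ventricle mass b = 0.855, intercept −7.639.

Where the source reports no variance components the generator takes
stated assumptions: ln-scale SD 0.10 for both the per-fish random
intercept and the per-cycle residual (magnitudes that produce CI widths
of the observed order), 0.02 for cardiac observation noise (small
relative to the breakpoint slope change so T_AB is identifiable at
n ≈ 10–13 points), 0.05 for ventricle-mass noise, 0.005 mg L⁻¹ optical
O2-probe noise.

Respirometry traces are built from the latent rates: 62 cycles of a
15-min flush:measure protocol whose split follows the protocol menu
(11:4 … 8:7 min, the longest measure keeping the worst-case decline above
70% air saturation); net chamber volume is 40 L per kg fish (mid-range of
the 19.2–93.9 volume-to-mass ratios used in practice, sized so the
coldest resting decline of the largest fish remains well resolved against
probe noise); background respiration is a lognormal per-trial fraction of
the fish's resting rate with median 6.6% and mean ≈ 10% (capped at 35%),
applied identically to the emitted pre/post background slopes so the
noiseless pipeline is exact.  An elevated-MMR episode is injected in the
first post-chase cycle and once overnight; the larger realization is the
latent MMR.  Cardiac series rise with Arrhenius slope 6.0 (Q10 ≈ 2.0)
below T_AB and 1.6 (Q10 ≈ 1.2) above, peak on the protocol's 1 °C grid at
the step nearest the latent power-law T_PEAK, then decline 0.05 ln-units
per °C until the arrhythmic step.  All randomness flows from one root
seed through named per-fish substreams, making outputs bit-reproducible
and order-independent; every dataset carries a sidecar truth record
(latent intercepts, per-cycle MO2, breakpoint temperatures) that never
enters the analysis-facing CSVs.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: ECG waveforms (only per-degree f_Hmax
summaries), mortality, water-chemistry or habitat temperature dynamics,
behavioural artifacts (struggling, chamber probing), drifting sensors,
and any divergence of the aerobic-scope exponent from the shared
metabolic exponent.  On the last point: data generated with a common
exponent for MMR and RMR force AAS = MMR − RMR to inherit that exponent,
so the divergent aerobic-scope exponent reported for real animals
(b_AAS ≈ 0.88 > b_MMR) cannot be reproduced synthetically; the suite
certifies this rather than targeting it.

## Recovery checks for the direct generators

Exponent-recovery checks for f_Hmax and T_PEAK use the direct observation
generators (a per-degree intercept ladder for f_Hmax; a simple ln–ln draw
for T_PEAK) rather than the full TPC-plus-breakpoint chain: in the full
TPC the breakpoint temperatures are themselves mass-dependent, so a
single common mass slope across temperatures exists only in the direct
parameterization.  The full chain is covered separately by the zero-noise
recovery tests and the bootstrap-coverage property (the nominal 95%
breakpoint CI covers the latent T_AB in 90–99% of identified fits over
210 noisy series).

## Problem sizes

The default test and demonstration runs use reduced problem sizes chosen
to exercise every code path with comfortable statistical margins: 5–12
fish with 18–30 respirometry cycles for end-to-end runs, 100 seeds at the
study's full sample sizes (83 fish / 238 observations; 30 cardiac fish)
for exponent-recovery checks, 210 series for bootstrap coverage, and 100
bootstrap replicates per breakpoint fit (300 where percentile stability
matters).

## Known limitations

- The breakpoint CI is a percentile bootstrap conditioned on the fitted
  knot; with very short rising limbs (7–8 points) its coverage sits at
  the low end of the nominal band, and strongly misplaced knots are
  filtered by the identification and ±1.5 °C rules rather than rescued.
- Wald/large-sample inference mildly understates uncertainty for the
  smallest subgroup analyses (e.g. per-temperature fits with few fish).
- The O2-saturation model is a linear approximation of coastal-seawater
  solubility — adequate for trace synthesis, not for gas-exchange work.
- Mixed fits with a single observation per individual leave the random
  intercept unidentified; the fitter returns the boundary (OLS) solution
  with a singular-fit warning.
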