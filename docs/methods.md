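# Methods

## The measurement model

The assay quantifies an analyte through a coloured complex photographed
in a 96-well microplate.  Each well is summarized by the mean of its
red, green and blue 8-bit channels over a circular region of interest
(ROI), and the analytical signal is a linear functional of those means;
the default, appropriate for an orange complex on a yellow-to-white
background, is the blue-channel attenuation

    S = 255 − mean(B).

Over the working range the signal is assumed affine in the analyte
concentration c (% w/v in the well), S = m·c + b, and quantification is
inverse prediction through that line followed by the declared dilution
chain (aliquot/total well volume, then the mass-per-volume dissolution
factor) to product content in % w/w.  The % w/v → % w/w step treats the
dissolution as unit density, as is conventional for dilute aqueous
preparations.

ROI membership uses the exact lattice-disc rule
(x − cx)² + (y − cy)² ≤ r², which contains 317 pixels for r = 10 at an
integer center.  Mobile colour-picker apps often report ⌊πr²⌋ = 314 for
the same nominal radius; since their masks are closed-source and
resolution-dependent, we implement the reproducible geometric rule and
expose the radius as a parameter rather than emulate any particular app.
Channel means are computed in floating point on the raw 8-bit values
with no gamma or white-balance correction.

## Calibration and figures of merit

Calibration is unweighted ordinary least squares of S on c over the
standards.  The blank is excluded by default: the reagent blank is a
chromatically different (yellow) species, so its blue-channel response
is not an additive zero point of the orange-complex series and its
inclusion degrades linearity.  An option re-includes it for sensitivity
analysis.

From the fit, with SSE the residual sum of squares over n points:

| quantity | definition | unit |
|---|---|---|
| S_r | √(SSE/(n−2)) | signal units |
| LOD | 3.3 S_r / m | % w/v |
| LOQ | 10 S_r / m | % w/v |

so LOQ/LOD = 10/3.3 identically.  Inverse predictions below the LOQ or
outside the calibrated signal span are flagged (`below_loq`,
`extrapolation`) but reported, never censored: values near the range
edges are still informative.  Replicate uncertainty propagates as the SD
of per-replicate predictions; internal values keep full precision and
rounding is left to the presentation layer.

## Reaction-time selection

Colour develops with approximately first-order kinetics; calibrations
refit at successive acquisition times have slopes m(t) that rise and
saturate.  The selection rule: given slopes at times t_1 < … < t_N, pick
the earliest t_k with

    (m(t_N) − m(t_k)) / (m(t_N) − m(t_1))  <  threshold      (default 1/3),

i.e. the slope gain still to come is below one third of the total gain
over the observed window, with strict inequality.  The course starts at
the first post-preparation acquisition (t₁ = 15 min for 15-minute
sampling): no calibration exists at the moment of preparation.  Under
k = ln 3/90 min⁻¹ sampled every 15 min for 3 h this selects 90 min; for
a strictly linear course over [0, 180] the remaining fraction equals
exactly 1/3 at 120 min, so the strict rule selects 135.  The rule is
scale-free (invariant to affine transforms of the slopes) and monotone:
raising the threshold never selects a later time.  A per-interval
increment variant (`mode="interval"`) is available; the remaining-gain
form is the default because a windowed per-step increment depends on the
sampling density while the remaining fraction does not.

## The synthetic-plate generator

The paper-style plate photographs this package analyzes are not publicly
deposited anywhere; the simulator therefore defines the study conditions
under which the pipeline is validated.  It emulates, in order:

1. **Colour response.**  `linear` mode (default) realizes
   S_true = m·c + b exactly, with m = 1865 signal units per % w/v and
   b = −19 over 0.040–0.125 % w/v — the empirical response magnitude of
   the niacinamide–Fe(III) assay — plus fixed red/green chromaticity
   giving an orange well.  `beer_lambert` mode maps each channel through
   a transmittance 10^(−ε·c·l), mildly nonlinear on the 255 − B scale,
   as a robustness regime: real absorbance is logarithmic even when the
   windowed response is statistically linear.
2. **Kinetics.**  The effective concentration at time t is
   c·(1 − e^(−kt)) with k = ln 3/90 min⁻¹ by default, so two thirds of
   the final colour exists at 90 min and the time-selection rule picks
   90 min by construction.  Blanks keep their fixed yellow colour
   (default RGB (230, 200, 90)) at all times — deliberately distinct
   chromaticity from the standards so the blank-exclusion rationale is
   reproducible in simulation.
3. **Degradations.**  A multiplicative illumination plane
   1 + g_x·x + g_y·y (default gradients 5·10⁻⁵ and 3·10⁻⁵ per pixel — a
   few percent across a plate, typical of an LED panel in a light box);
   a per-image exposure gain ~N(1, 0.015) emulating auto-ISO
   shot-to-shot variation; per-well effective-concentration jitter
   ~N(1, 0.01) emulating pipetting error; finally additive per-pixel
   Gaussian sensor noise (σ = 3 counts), clipping to [0, 255] and
   quantization.  The per-image gain and per-well jitter are the two
   variance components that make inter-image precision genuinely worse
   than intra-image precision, as observed in real plate photography —
   pixel noise alone averages to ~0.2 counts over a 317-pixel ROI and
   could not produce that ordering.  All draws come from one
   seeded generator per render; equal seeds give byte-identical images.

What the simulator does *not* model: lens distortion, white balance,
JPEG artifacts, vignetting, well menisci, or matrix interferents (the
interfering-sample phenomenology enters only through the bundled
published tables).  Passing the parameter-recovery tests therefore shows
the pipeline is correct and robust to the modelled noise structure, not
that any particular real camera or matrix behaves this way.

## Continuous-variation (Job's plot) analysis

Mixtures at constant total concentration C_T = 0.1 M sweep the ligand
mole fraction x; the equilibrium M + nL ⇌ MLₙ with overall constant
K = 10^log_K is solved for the complex concentration z as the root of
z = K(M₀ − z)(L₀ − nz)ⁿ on [0, min(M₀, L₀/n)] by bracketed root finding
(machine-precision tolerances), so mass balance holds by construction.
The response maximum is located by fitting a parabola through the top
grid point and its two neighbours and taking the vertex — the minimal
smoother that beats the grid resolution of a nine-mixture experiment —
falling back to the raw argmax (flagged) for endpoint peaks, ties or
non-concave tops.  The ratio x_max/(1 − x_max) rounds to the integer
stoichiometry; ratios within 0.1 of a half-integer are flagged
ambiguous, since discrete-grid experiments rarely resolve them and
minor complexes may coexist.

## Method comparison

Candidate (image method) results sit on the abscissa, reference results
on the ordinate; this orientation reproduces the published regression of
the bundled study tables.  Marginal 95 % CIs use t(α/2; n−2); the joint
region is the exact OLS confidence ellipse
(β − b)ᵀ XᵀX (β − b) ≤ 2 s² F(α; 2, n−2), and method equivalence is the
membership of (intercept, slope) = (0, 1).  The paired t statistic is
|mean d|/(SD(d)/√n) with df = n − 1 (two-sided); the precision F test
pools each method's replicate variances as the mean of per-sample
squared SDs with df = (n_samples − 1, n_samples − 1) by default — the
convention matching the published critical value for ten samples — with
a pooled-replicate df alternative behind an option.  Critical values are
always computed from scipy.stats quantiles at run time.  Error-band
membership uses inclusive bounds (a 6.0 % label error counts as "within
0–6 %").  The bundled ten comparison pairs are the direct-analysis
results of all samples except the one with demonstrated matrix
interference, which enters with its post-cleanup value.

## Numerical and design notes

* Pixel coordinates are 0-based, x right / y down, origin top-left;
  well centers are real-valued (sub-pixel allowed) and shared between
  simulator and extractor.
* Layout files are YAML; wells are identified by (row, col) and
  replicates by a shared `replicate_group`, not positional convention.
* One user seed expands to per-stage child seeds through
  `numpy.random.SeedSequence.spawn`, recorded in run manifests, so
  partial reruns stay reproducible.
* Problem sizes in the test suite and acceptance script (20 simulated
  plates for slope recovery, 2000 Monte-Carlo trials for ellipse
  coverage, 0.05 mole-fraction grids) were chosen as the smallest sizes
  at which the checked statistics are stable; each completes in seconds.
* Known limitations: single-analyte calibration only; no weighted or
  robust regression; no automatic well detection (centers are declared);
  no colour-card normalization across devices; the simulator's RGB
  chromaticities are calibrated to the published slope/intercept only,
  not to measured colours of the real complex.
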