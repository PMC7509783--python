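# Methods

`hrvsym` analyzes heart-rate variability (HRV) under the conditions of an
acute psychosocial stress protocol, where the usual stationarity assumption
of spectral HRV is routinely violated.  It implements three layers: the
per-window HRV parameters (time domain, frequency domain, binary symbolic
dynamics), two nonstationarity diagnostics, and the nonparametric
repeated-measures statistics used at cohort level — plus a synthetic cohort
generator so the whole chain can be exercised and validated without any
recordings.

## Input model and preprocessing

The pipeline starts from annotated R-peak times (not raw ECG).  Beats
labeled ventricular, supraventricular or artifact are replaced by linearly
interpolated beat times: for a run of m non-normal beats between normal
anchors at t_a and t_b the replaced times are t_a + j·(t_b − t_a)/(m+1),
j = 1…m.  Linear interpolation of index vs. time is the minimal defensible
realization of "appropriately interpolated"; it preserves the first and
last beat times and the beat count, and the replacement count is reported so
heavier correction schemes can be compared.  Edge beats without a normal
anchor are trimmed with a warning, and a warning is raised when more than 5%
of beats are non-normal (clean laboratory recordings are typically < 1%).

The RR tachogram is RR_i = t_{i+1} − t_i (ms), each interval carrying its
onset time.  Analysis windows are the 5 minutes preceding each protocol
marker T1…T9 (waiting T1–T2; stress test T3–T5: speech preparation, speech
delivery, mental arithmetic; recovery T6–T9).  Window membership is by
interval onset in the half-open range [marker − 300 s, marker), so adjacent
windows never share an interval.  This onset convention is a deliberate,
configurable choice; interval-end membership shifts each window by one beat
at most.

## Time domain

Per window: mean RR, SDNN (standard deviation, sample denominator N−1 by
default — the common convention in HRV tooling; configurable) and RMSSD
(root mean square of successive differences).  No further NN filtering is
applied beyond the upstream beat-time interpolation.

## Frequency domain

The fixed recipe, applied per window:

1. cubic-spline interpolation of the tachogram (RR value at interval onset)
   onto a uniform 4 Hz grid (linear interpolation available);
2. least-squares linear detrend;
3. Hanning window;
4. zero-padding to 2048 points and FFT (frequency resolution
   4/2048 ≈ 0.00195 Hz);
5. one-sided power spectrum, rescaled by a single global factor so that the
   total power over all bins > 0 Hz equals the variance (ddof = 1) of the
   detrended series.  This variance adjustment makes total power independent
   of the taper and expresses band powers in ms²;
6. band sums with half-open edges: LF [0.04, 0.15) Hz, HF [0.15, 0.4) Hz —
   the shared 0.15 Hz edge is counted exactly once, in HF.

Derived quantities: ln LF, ln HF (natural logs of ms² powers), LF/HF, and
LF% / HF% relative to total power.  Total power by default includes the VLF
range below 0.04 Hz (`include_vlf_in_total=False` restricts it to
LF + HF), which matters for the percentages; both variants are exposed
because "total power" is not uniquely defined for 5-min windows.  A window
with numerically zero detrended variance yields zero powers and the derived
ratios flagged missing rather than silently NaN-propagated.

## Binary symbolic dynamics

Both encodings operate on the difference series ΔRR_i = RR_{i+1} − RR_i:

- **sign encoding** S_i = 0 if ΔRR_i ≥ 0 (deceleration or no change), 1 if
  ΔRR_i < 0 (acceleration);
- **threshold encoding** S_τ,i = 0 if |ΔRR_i| < τ, 1 if |ΔRR_i| ≥ τ, with
  τ = 35 ms by default (≈ 5% of a typical grand-average RR interval).  The
  tie conventions (0 at ΔRR = 0; 1 at |ΔRR| = τ) follow the defining
  inequalities exactly.  τ is fixed globally by default; a per-subject
  5%-of-mean-RR mode can be emulated by passing a per-subject τ.

Every overlapping word of three successive symbols is classified by its
number of adjacent symbol changes: 0V (000, 111), 1V (001, 100, 110, 011),
2V (101, 010).  The parameters are the category percentages P0V%, P1V%,
P2V% (and P0V_τ% … for the threshold encoding); they always sum to 100.
High P0V% reflects sympathetic dominance (runs of same-direction or
same-size changes), high P1V% parasympathetic modulation.  Because the
encodings depend only on differences, slow baseline shifts — the dominant
nonstationarity under stress — leave them essentially untouched.

## Nonstationarity diagnostics

**Heuristic segmentation.**  For every admissible split of a segment (both
sides ≥ 40 intervals) the pooled-variance two-sample statistic
t(i) = |mean_L − mean_R| / (s_pooled · sqrt(1/n_L + 1/n_R)) is computed; the
maximum t over splits is converted to an approximate significance

    P(t_max) ≈ [1 − I_{ν/(ν+t²)}(δν, δ)]^η,   ν = n − 2,
    η = 4.19 ln n − 11.54,  δ = 0.40,

(I the regularized incomplete beta function) and the split is accepted when
P ≥ 0.95, recursing on both halves.  A zero-pooled-variance split with
unequal means gets a capped sentinel t treated as maximally significant.
The minimum segment length of 40 intervals keeps the procedure from
reacting to fluctuations at LF time scales; a series is stationary iff it is
never split.  The simple fresh recursion is used rather than the variant
that re-tests new boundaries against neighboring segments; at 5-min window
lengths the measured false-split rate on i.i.d. series is ≈ 2% at n = 100
and ≈ 2.5% at n = 300, conservative relative to the nominal 5%.
Constants η, δ and the 0.95 threshold are configurable.

**Restricted weak stationarity (RWS) test.**  Eight subsequences of 50
intervals are drawn at uniformly random start positions (without
replacement; overlap is permitted — eight disjoint windows of 50 would
require 400 intervals, which 5-min windows at rest often do not contain).
Equality of locations across subsequences is tested with Kruskal–Wallis and
equality of dispersions with Brown–Forsythe (Levene on medians); a
parametric variant (one-way ANOVA / Bartlett) is available.  The series
passes when both p > 0.05.  Monte-Carlo calibration on i.i.d. series of
length 400 gives type-I errors of ≈ 4–5% for both components despite the
overlap.  The subsequence draw is seeded; identical seeds give identical
p-values.

A window is reported stationary only if segmentation leaves it whole *and*
both RWS probabilities exceed 0.05.  The per-window report carries the same
diagnostics for the difference series, whose stationarity is what licenses
the symbolic parameters.

## Cohort statistics

Parameters are collected into subjects × periods matrices.  LF, HF and
LF/HF are right-skewed and are tested (and tabulated) on the natural-log
scale.  Period effects: Friedman chi-square with mid-rank tie correction on
complete cases; when cells are missing (VAS scores), the Skillings–Mack
statistic A'Σ⁻A with per-subject weights sqrt(12/(s_i+1)) and the
generalized inverse of the observation-pattern covariance, with df =
rank(Σ).  On complete untied data Skillings–Mack reduces to Friedman
exactly — enforced to 1e−10 in the tests.  A significant omnibus test
(α = 0.05) gates pairwise Wilcoxon signed-rank tests over all 36 period
pairs with Holm step-down adjustment (a Siegel–Castellan mean-rank
critical-difference variant is provided for comparison).  Gender contrasts
use the two-sided Mann–Whitney U test per parameter and period.  Quartiles
use the linear-interpolation convention (numpy default), which the median /
IQR tables inherit.

## Synthetic cohort generator

Each subject's recording is nine concatenated 5-min windows with the
instantaneous tachogram

    r(t) = base_rr + drift·(t/T − ½) + a_lf sin(2π·0.10·t + φ₁)
          + a_hf sin(2π·0.25·t + φ₂) + ε,   ε ~ N(0, noise_sd²),

emitted beat-by-beat via t_{n+1} = t_n + r(t_n)/1000.  The per-period
defaults emulate a pronounced acute-stress response: baseline RR ≈ 855 ms in
the first waiting period, dropping to ≈ 616 ms at speech delivery and
recovering to ≈ 885 ms; HF amplitude and beat noise are damped during stress
(vagal withdrawal), every period carries a within-window drift of 40–80 ms
(so that raw RR windows are genuinely nonstationary, as stress-protocol
recordings overwhelmingly are), and VAS stress scores rise from ≈ 8 at
baseline to ≈ 57 at the arithmetic task with 8% missingness.  Subject
heterogeneity is a N(0, 60²) ms baseline offset plus N(0, 20²) ms
subject×period jitter; ~0.2% of beats are labeled ventricular to exercise
the interpolation path.  All randomness derives from one master seed via
per-subject substreams (`numpy.random.SeedSequence.spawn`), so reruns are
byte-identical and single subjects can be regenerated in isolation.

What the generator does *not* model: respiration and baroreflex coupling
(no cardiorespiratory phase structure), integral-pulse-frequency-modulation
beat emission, ectopic-beat physiology (labels are injected at random), or
realistic tails in ΔRR — the stress windows therefore separate more cleanly
in the symbolic parameters than real cohorts do (P0V_τ% near 100 at peak
stress versus ~76 in typical laboratory data).  Passing the end-to-end tests
demonstrates that the chain recovers the *direction and significance* of the
programmed stress response at n = 24, not that real effect sizes are
reproduced.

## Numerical and testing notes

- Segmentation is deterministic; the t-profile is computed with cumulative
  sums (O(n) per recursion level), with tiny negative sums-of-squares from
  cancellation clamped to zero.
- The spectral variance adjustment is enforced by construction; the tests
  assert it to 1e−9 relative.
- Monte-Carlo suite sizes (e.g. 1000 replicates for segmentation recovery
  and RWS calibration, 10 master cohorts for the end-to-end direction test,
  24 subjects each) were chosen so that binomial noise is small against the
  asserted bounds while the default suite stays fast.
- On the default synthetic cohort, difference series pass both stationarity
  diagnostics in ≈ 94% of windows; the residual failures concentrate in the
  low-noise stress windows, where the nearly deterministic oscillatory
  structure of ΔRR is itself detectable by rank tests.  This is a property
  of the simplified generator, not of the diagnostics.
- Degenerate inputs: constant series give SDNN = RMSSD = 0, zero spectral
  power with flagged-missing ratios, symbol sequences of all zeros, a single
  segment, and RWS p = 1.
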