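# Methods

`cardiovar` models inter-individual variability in the spontaneous beating
of iPSC-derived cardiomyocytes as read out by a kinetic Ca²⁺-flux plate
assay (100 s recordings at 8 Hz per well), and the modulation of that
beating by three reference cardioactive drugs. This note documents the
models, the synthetic-data generator that stands in for plate-reader
output, the numerical choices, and the limits of what the package's tests
demonstrate.

## Beating parameters

Each well's fluorescence trace is reduced to five summary statistics:
mean beat rate (BPM, from inter-peak spacing), mean and CV of peak height
(local baseline to apex), CV of peak spacing (irregularity), and the mean
per-beat ratio of decay time (apex → baseline) to rise time (baseline →
apex). The decay/rise ratio serves as a rate-adjusted surrogate for QT
prolongation: slowing the beat alone lengthens the diastolic interval but
not the ratio. A "notch" — a plateau during the decay before the return
to baseline — marks delayed repolarization under hERG block; a well with
fewer than two detected beats in the window is called quiescent and its
beat-derived endpoints are undefined.

### Peak processing conventions

The upstream assay software's exact peak-processing rules are not public,
so the following are declared conventions of this package:

* Rise and decay endpoints are crossings of *baseline + 10 % of height*
  rather than the baseline itself; a pure-baseline crossing is fragile
  against noise at 8 Hz. Crossing times are refined to sub-sample
  resolution with a local cubic spline (the upstroke foot is strongly
  convex, so linear interpolation would place the crossing early).
* The apex is localized by a cubic-spline maximizer over ±3 samples: a
  parabola is biased on a calcium transient's asymmetric apex. Apex
  *time* is read from the raw trace; apex *height* from a 5-point
  Savitzky–Golay smoothed trace (lower noise; its ~1 % attenuation is
  uniform within a well and cancels in every CV and control-normalized
  quantity).
* The baseline is a piecewise-linear interpolation through inter-beat
  troughs; each trough value averages the raw samples lying within a
  noise tolerance of the segment minimum. Edge windows are accepted only
  if they sit near the neighbouring trough's level, since a window cut
  mid-transient is not a trough. Heights are measured against an 8-s
  moving average of this baseline, which suppresses trough-to-trough
  noise that would otherwise inflate the within-well amplitude CV, while
  still tracking slow drift. Flat traces fall back to a running 10th
  percentile.
* Peak detection requires a prominence of 15 % of the trace range *and*
  at least 4× the robust noise SD (estimated from the Savitzky–Golay
  residual, which is signal-free away from beat apices); the absolute
  floor is what keeps noise-only quiescent wells at zero peaks. Minimum
  peak separation is 0.375 s (3 samples). Both thresholds are exposed on
  the command line.
* On a shallow decay whose per-sample decrement is comparable to the
  noise, the first noisy excursion below the threshold would land
  systematically early; there the crossing is re-estimated by counting
  raw samples still above the level, an estimator whose errors on either
  side of the true crossing cancel.
* Notch detection is rate-relative: within the 80 %→20 %-of-height part
  of the decay, a notch is a run of ≥2 samples whose decrement falls
  below 30 % of the decrement an exponential with the segment's own
  overall rate would produce at that height. A fixed decrement threshold
  (e.g. "below 5 % of height") cannot work across decay rates: any slow
  monotone decay eventually decrements less than a fixed fraction of
  height per sample and would be flagged.
* BPM comes from the mean inter-peak spacing, not peak count over
  duration, which is robust to partial beats at the window edges.
* A well whose median rise time is under two samples (0.25 s at 8 Hz)
  reports an *undefined* decay/rise ratio. At 8 Hz such a rise cannot be
  resolved into threshold crossings; reporting a biased number instead of
  a missing one would couple the ratio to the beat rate and corrupt the
  donor-variance decomposition.

## Synthetic studies

The generator emulates a 27-donor screen: 384-well plates, two plates,
eight wells per condition, media and vehicle (0.5 % DMSO) controls, and
compound treatments on a four-point grid {0.1, 1, 10, 100} µM.

**Donor traits** are log-normal (positive support, CV-parameterized; the
source data report only CVs and ranges, so the distributional family is a
modelling convention): baseline rate with median 30 BPM and CV 0.27,
decay/rise ratio with median 3.0 and CV 0.10 (independent of rate), and
amplitude with CV 0.10. Technical noise is multiplicative log-normal per
endpoint, calibrated so total CVs match the reported values: rate
√(0.28²−0.27²) ≈ 0.074, ratio √(0.11²−0.10²) ≈ 0.046, amplitude
√(0.13²−0.10²) ≈ 0.083, each split 1:2 plate:well by variance. The
vehicle applies a 2 % multiplicative shift. Spacing jitter (CV 0.03) and
amplitude jitter (CV 0.005) are set below the reported measured
irregularity ceilings (<6 %, <2 %) because the measured CVs also carry
the 8-Hz measurement noise floor. Additive Gaussian noise has SD 2 % of
the well's amplitude. An optional total-cell covariate is drawn via a
Gaussian copula against log amplitude with target Pearson r = 0.55.

**Drug effects** use the same model forms fitted downstream (see below),
applied generatively: per-donor parameters are uniform over spans solved
in closed form so the percent change at 1 µM spans the reported ranges —
`iso_B` ∈ [1.5005, 2.2012] (+50…+120 % on rate), `pro_lnEC50` ∈
[ln 0.538, ln 13.3] µM (−65…−7 % on rate, generation scale 1), `cis_B` ∈
[1.1737, 2.6881] (+19…+440 % on the ratio). Cisapride phenotypes
(regular prolongation, notch, Torsade-like, no-notch) are uniform over
donors; Torsade-like wells beat at twice the rate with 30 % amplitude and
heavy spacing jitter. Quiescence: the inotropes silence wells at 100 µM
with probability 0.5; cisapride silences a donor above a threshold drawn
from {0.1, 1, 10, ∞} µM.

**Waveform.** Each transient is a log-normal pulse
A·exp(−ln²(t/t_m)/(2s²)) in time-from-onset: infinitely smooth,
intrinsically asymmetric, and with 10 %-of-peak crossings at
t_m·exp(±s√(2 ln 10)), so the threshold-crossing decay/rise ratio is
exactly exp(s√(2 ln 10)) — the shape parameter encodes the ratio and t_m
scales the rise time independently. Smoothness is essential: at 8 Hz,
waveforms with curvature discontinuities (e.g. a linear rise meeting an
exponential decay) cannot be measured without phase-dependent bias of
several percent. Past its 10 % point plus a short faithful margin the
slow tail is brought to baseline by a cosine² drop, and at least one
sample plus a tenth of the period is kept quiet between beats so the
local baseline stays observable at every rate.

**Rate adaptation.** When a transient does not fit its beat period, it is
compressed proportionally — preserving the decay/rise ratio, which is
exactly the sense in which the ratio is a rate-adjusted QT surrogate —
down to a floor of one sample of rise time. When the transient cannot fit
even compressed (hERG-block-prolonged decays), the beat period lengthens
instead: extreme repolarization delay slows the beat. Consequences: the
renderer cannot express rates above ~60 BPM with resolvable transients
(so the saturated positive-inotrope recovery runs use a 20-BPM donor),
and strongly prolonged cisapride wells beat slower than their nominal
baseline rate.

## Baseline variance decomposition

Control wells are modelled as
y = µ + β·1[vehicle] + u_donor + u_plate + ε, with crossed random
intercepts and a fixed media-vs-vehicle contrast. Restricted maximum
likelihood is profiled over the two variance ratios (donor, plate over
residual): at any candidate pair the GLS fixed effects and residual
variance are closed-form via the Woodbury identity, leaving a 2-D bounded
Nelder–Mead search (multi-start from moment estimates, polish restart;
ratios clipped to [0, 10⁷], so negative components truncate at zero).
REML rather than ML avoids the downward variance bias at 27 donors. The
vehicle contrast is a fixed effect (two levels cannot support a stable
random effect) converted to a variance share as p(1−p)β² with p the
vehicle-well fraction; the total CV is √(sum of all four components)
over the grand mean, so "total" includes the vehicle term. The
implementation agrees with R's lme4 to seven decimals and with a
brute-force dense-likelihood grid search to four, and coincides with
closed-form ANOVA estimators on balanced designs (to the flatness of the
restricted-likelihood surface, which for a 3-level plate factor limits
parameter agreement to ~10⁻⁵ even when the likelihoods agree to 10⁻¹¹).

## Concentration-response models

Responses are first normalized to the median vehicle control within each
donor × plate (plate effects then cancel exactly; a donor-pooled median
would straddle the two plate modes and be unstable), anchoring controls
at 1. For the inotropes the 100 µM group is dropped before fitting —
widespread quiescence and cytotoxicity there leave no usable
concentration-response signal — while all concentrations are kept for
cisapride. Quiescent wells never enter fits and are reported in exclusion
logs.

Three forms, natural logs, concentrations in µM:

* `PRO2` (negative inotrope, rate): y = 1/(1 + exp((ln x − lnEC₅₀)/scale)),
  asymptotes 1 → 0; lnEC₅₀ varies by donor, the scale is shared.
* `ISO_EMAX` (positive inotrope, rate): y = 1 + (B−1)/(1 + exp(ln 0.001 − ln x)).
  The response is already maximal at the lowest tested concentration, so
  the EC₅₀ is pinned to a nominal 0.001 µM and the scale to 1; B varies
  by donor.
* `CIS_LOG_EMAX` (hERG block, decay/rise ratio):
  ln y = (B−1)/(1 + exp(ln 0.001 − ln x)), same fixed constants.

Estimation defaults to **two-stage**: per-donor estimates (closed-form
least squares for the two forms linear in B; joint Levenberg–Marquardt
across donors for PRO2's shared scale, with per-donor lnEC₅₀ started at
the concentration nearest half-effect), population fixed effect and
random-effect SD as the mean and SD of the per-donor estimates. A
**Laplace** route maximizes the marginal likelihood of a Gaussian random
effect (inner penalized mode per donor, outer Nelder–Mead); the Laplace
approximation is exact for the two B-linear forms. Two-stage is the
default because it is transparent and robust at 27 donors; both routes
agree on low-noise data. Inter-individual sensitivity is summarized as
the per-donor percent change from control at a nominal 1 µM, with a 95 %
interval from the ±1.96 SD band of the random effect mapped through the
model.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run full-size baseline studies
(27 donors × 2 plates × media/vehicle × 8 wells = 864 control wells of
800 samples each): three seeds in the test suite, six in the acceptance
script, which also runs each single-donor concentration-response
recovery on four seeds. These sizes put the Monte-Carlo error of each
recovered quantity well inside its comparison tolerance.

## What the synthetic studies do and do not show

Passing recovery tests demonstrates that the estimators are unbiased and
correctly calibrated *for data generated under this package's
assumptions*: log-normal traits, multiplicative technical noise,
log-normal pulse shapes, white additive noise, static per-well state.
Real plate-reader data add features the generator does not emulate:
baseline drift and photobleaching, dye-loading kinetics, transient
quiescence at early timepoints with later recovery, ectopic beats and
alternans, non-Gaussian noise, plate-edge effects, and wells whose beat
waveform differs qualitatively from a smooth asymmetric pulse. The
beat caller's conventions (threshold fractions, smoothing, notch rule)
were validated against this generator and dense-oracle scans, not against
instrument recordings.

## Known limitations

* 8 Hz sampling fundamentally limits rise-time resolution; wells with
  sub-two-sample rises have no defined decay/rise ratio, which in the
  default population removes the fastest-beating donors (~15–20 %) from
  the ratio decomposition.
* The rendered beat rate saturates near 60 BPM, so saturated
  positive-inotrope responses of fast donors are compressed; recovery is
  demonstrated on slow donors.
* The Laplace route estimates the PRO2 shared scale per donor-set jointly
  but approximates its uncertainty only through the random-effect SD.
* Torsade-like and notch phenotypes are rendered as stylized stationary
  patterns (fast low-amplitude irregular beats; a fixed 40 %-height
  plateau for a quarter of the decay), not as electrophysiological
  simulations.
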