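# cardiovar

Inter-individual variability analysis of iPSC-derived cardiomyocyte
beating, as read out by a kinetic Ca²⁺-flux plate assay (100-s
fluorescence recordings at 8 Hz per well), for population cardiotoxicity
screening. The package is aimed at quantitative toxicologists and
pharmacologists who want to separate *biological* (donor) from
*technical* (plate, vehicle, residual) variability in beating phenotypes,
and to quantify how much donors differ in their sensitivity to
cardioactive drugs.

The pipeline has four stages, each usable as a library module or through
the `cardiovar` command line:

1. **trace_sim** — a synthetic multi-donor study generator with known
   ground truth. Donor traits (baseline rate, decay/rise ratio,
   amplitude) are log-normal; transients are smooth asymmetric log-normal
   pulses; technical noise enters at plate and well level; drug effects
   of an isoproterenol-like positive inotrope (`ISO`), a
   propranolol-like negative inotrope (`PRO`) and a cisapride-like hERG
   blocker (`CIS`, with notch / Torsade-like / quiescence phenotypes)
   are applied generatively.
2. **beatcall** — per-well beating parameters from a raw trace: beat
   rate (BPM), peak-height mean and CV, peak-spacing CV, the mean
   decay/rise time ratio (a rate-adjusted QT-prolongation surrogate),
   plus notch and quiescence calls. Landmarks are located at sub-sample
   resolution (spline apex refinement, interpolated 10 %-of-height
   threshold crossings).
3. **varcomp** — a linear mixed model on control wells,
   y = µ + β·1[vehicle] + u_donor + u_plate + ε, estimated by restricted
   maximum likelihood (profiled over the variance ratios), reporting each
   component as a CV about the grand mean and as a fraction of total
   variance.
4. **doseresp** — responses normalized to each donor's median vehicle
   control, then fitted with nonlinear mixed-effects concentration-
   response models: a two-parameter log-logistic
   y = 1/(1+exp((ln x − lnEC₅₀)/scale)) for `PRO`, and saturated
   maximal-effect forms y = 1 + (B−1)/(1+exp(ln 0.001 − ln x)) for `ISO`
   (rate) and ln y = (B−1)/(1+exp(ln 0.001 − ln x)) for `CIS`
   (decay/rise ratio). Donor sensitivity is summarized as the percent
   change from control at a nominal 1 µM.

See `docs/methods.md` for the models, generator calibration, numerical
conventions and limitations.

## Worked example

Simulate the default 27-donor study with isoproterenol treatment, call
beats, decompose baseline variability and fit the concentration-response
model, all in one run directory:

```sh
cardiovar all --seed 1 --compounds ISO --out runs/iso_demo
```

This writes `traces.csv`, `wells.csv`, `truth.csv`, `beat_params.csv`,
`varcomp.json`, `fits.json` and a `report.json` manifest. The baseline
decomposition for this run (from `varcomp.json`) reads:

```
bpm              cv_donor=0.247  cv_total=0.275  frac_donor=0.81
amp_mean         cv_donor=0.097  cv_total=0.119  frac_donor=0.68
decay_rise_ratio cv_donor=0.075  cv_total=0.086  frac_donor=0.76
```

— for each endpoint, the donor-attributable coefficient of variation,
the total CV across all components, and the fraction of variance carried
by donor identity (here ≥ 0.68 for every endpoint: biology dominates
technique). Single-panel estimates scatter around the population values
(27 %/28 % for rate) with a CV sampling error of roughly
0.27/√54 ≈ 0.04 at 27 donors. The ISO fit (from `fits.json`):

```
ISO fixed B=1.649  ranef_sd=0.346
change at 1 uM: min -35.7  median 73.3  max 116.3
dropped: {'quiescent_wells': 0, 'dropped_100uM': 432}
```

— the population maximal-effect parameter B and its between-donor SD,
the spread of per-donor percent change in beat rate at 1 µM, and the
exclusion log (the 100 µM group is always dropped for the inotropes; the
negative minimum belongs to a donor whose saturated response exceeds the
renderer's ~60 BPM rate ceiling, see the methods note). Individual
stages are also available as `cardiovar simulate / beatcall / varcomp /
fit / validate`, with thresholds and model options exposed as flags.

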