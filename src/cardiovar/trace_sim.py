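"""Synthetic multi-donor Ca2+-flux study generator with known ground truth.

Emulates the output of a kinetic fluorescence plate reader recording
spontaneously beating iPSC-derived cardiomyocytes from a donor panel:
each well yields a 100-s, 8-Hz trace of calcium transients whose rate,
amplitude, rise/decay geometry and regularity are set by donor traits,
plate- and well-level technical noise, and (optionally) drug effects of
three reference cardiotoxicants:

* ``ISO`` — an isoproterenol-like positive inotrope whose effect on beat
  rate is already saturated at the lowest tested concentration
  (maximal-effect parameter ``iso_B``, EC50 nominally 0.001 uM),
* ``PRO`` — a propranolol-like negative inotrope with a two-parameter
  log-logistic concentration-response (per-donor ``pro_lnEC50``),
* ``CIS`` — a cisapride-like hERG blocker multiplying the decay/rise
  ratio on the log scale (maximal-effect ``cis_B``), with donor-specific
  proarrhythmic phenotypes (notch, Torsade-like beating, quiescence).

Every generated quantity is recorded in a truth table so downstream
estimators can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .beatcall import CalciumTrace

__all__ = [
    "COMPOUNDS",
    "DonorProfile",
    "PopulationConfig",
    "BeatDynamics",
    "WellSpec",
    "SimulatedStudy",
    "sample_population",
    "apply_drug_effect",
    "synth_trace",
    "simulate_study",
]

COMPOUNDS = ("ISO", "PRO", "CIS")

#: nominal EC50 (uM) for the saturated ISO/CIS maximal-effect curves
EC50_SATURATED = 1e-3
#: log-logistic scale used generatively for PRO
PRO_GEN_SCALE = 1.0

# Drug-effect parameter spans, solved from the model forms so that the
# percent change at a nominal 1 uM spans the ranges reported for the
# reference compounds: ISO +50..+120%, PRO -65..-7%, CIS +19..+440%.
ISO_B_SPAN = (1.5005, 2.2012)
PRO_LNEC50_SPAN = (float(np.log(0.538)), float(np.log(13.3)))
CIS_B_SPAN = (1.1737, 2.6881)

CIS_PHENOTYPES = ("regular_prolongation", "notch", "torsade_like", "no_notch")
#: per-donor concentrations (uM) above which cisapride silences beating;
#: inf means the donor never goes quiescent
CIS_QUIESCENCE_CHOICES = (0.1, 1.0, 10.0, np.inf)
#: concentration at/above which ISO and PRO may silence beating
INO_QUIESCENCE_CONC = 100.0
#: lowest tested concentration; CIS phenotypes are expressed from here up
CIS_PHENOTYPE_MIN_CONC = 0.1

# --- beat waveform geometry -------------------------------------------------
# Each transient is a log-normal pulse  A * exp(-ln(t/tm)^2 / (2 s^2))  in
# time-from-onset t: infinitely smooth, intrinsically asymmetric (fast rise,
# slow decay), peaking at tm.  Its 10%-of-peak crossings sit at
# tm*exp(-/+ s*sqrt(2 ln 10)), so the threshold-crossing decay/rise ratio is
# exactly exp(s*sqrt(2 ln 10)) — the shape parameter s encodes the ratio and
# tm scales the rise time, independently.
A_LN10 = float(np.sqrt(2.0 * np.log(10.0)))  # ~2.146
# The pulse follows the log-normal form for a short margin past its 10%
# point (keeping the measured decay crossing clean at 8 Hz), then drops to
# baseline over a cosine^2 ramp; both intervals scale with the rise time
# within sampling-imposed bounds.  A late drop may be cut off by the next
# upstroke (traces compose by maximum): in fast-beating wells the dye
# signal never quite settles between beats.
TAIL_MARGIN_BOUNDS_S = (0.125, 0.25)
TAIL_DROP_BOUNDS_S = (0.1875, 0.3125)
#: quiet gap between the end of one transient and the next upstroke: at
#: least one sample, at least a tenth of the beat period — so the local
#: baseline stays observable at every beat rate
BEAT_GAP_MIN_S = 0.125
BEAT_GAP_FRAC = 0.10


def _gap_time(period: float) -> float:
    return max(BEAT_GAP_MIN_S, BEAT_GAP_FRAC * period)
#: transient compression uses the baseline-physiological ratio range only
RATIO_REF = 4.0
#: shortest renderable 10%-to-peak rise time (one sample at 8 Hz)
TAU_RISE_FLOOR = 0.125
#: Torsade-like rendering: amplitude fraction, rate multiplier, spacing jitter
TORSADE_AMP_FRAC = 0.3
TORSADE_RATE_MULT = 2.0
TORSADE_JITTER_CV = 0.20


@dataclass
class DonorProfile:
    """Generator-side ground truth for one donor line."""

    donor_id: str
    baseline_bpm: float
    amplitude: float
    tau_rise: float
    tau_decay: float
    spacing_jitter_cv: float
    amplitude_jitter_cv: float
    iso_B: float
    pro_lnEC50: float
    cis_B: float
    cis_phenotype: str
    cis_quiescence_conc: float = np.inf

    def __post_init__(self) -> None:
        if self.baseline_bpm <= 0 or self.amplitude <= 0:
            raise ValueError(f"{self.donor_id}: baseline_bpm and amplitude must be > 0")
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError(f"{self.donor_id}: tau_rise and tau_decay must be > 0")
        if self.iso_B < 1 or self.cis_B < 1:
            raise ValueError(f"{self.donor_id}: maximal-effect parameters must be >= 1")
        if not (0 <= self.spacing_jitter_cv < 0.5 and 0 <= self.amplitude_jitter_cv < 0.5):
            raise ValueError(f"{self.donor_id}: jitter CVs must lie in [0, 0.5)")
        if self.cis_phenotype not in CIS_PHENOTYPES:
            raise ValueError(f"{self.donor_id}: unknown cis_phenotype {self.cis_phenotype!r}")


@dataclass
class PopulationConfig:
    """Study design and population-distribution parameters.

    Defaults emulate the reference 27-donor screen: 384-well plates read at
    8 Hz for 100 s, two plates, eight wells per condition, media and vehicle
    (0.5% DMSO) controls, and a four-point concentration grid.  Donor-trait
    CVs reproduce the reported biological variability (27% beat rate, 10%
    decay/rise ratio, 10% amplitude); per-endpoint technical CVs are set so
    the total CVs match the reported 28%/11%/13%, split 1:2 plate:well by
    variance.
    """

    n_donors: int = 27
    bpm_median: float = 30.0
    donor_cv_bpm: float = 0.27
    donor_cv_decay_rise: float = 0.10
    donor_cv_amplitude: float = 0.10
    amplitude_median: float = 1000.0
    decay_rise_median: float = 3.0
    tau_rise: float = 0.25
    tech_cv_bpm: float = float(np.sqrt(0.28**2 - 0.27**2))  # ~0.074
    tech_cv_decay_rise: float = float(np.sqrt(0.11**2 - 0.10**2))  # ~0.046
    tech_cv_amplitude: float = float(np.sqrt(0.13**2 - 0.10**2))  # ~0.083
    plate_var_share: float = 1.0 / 3.0
    vehicle_shift: float = 0.02
    spacing_jitter_cv: float = 0.03
    amplitude_jitter_cv: float = 0.005
    n_plates: int = 2
    wells_per_condition: int = 8
    concentration_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    sampling_rate: float = 8.0
    duration: float = 100.0
    noise_sd_frac: float = 0.02
    baseline_rfu: float = 100.0
    cells_median: float = 2000.0
    cells_cv: float = 0.15
    cells_amp_corr: float = 0.55
    iso_quiescence_prob: float = 0.5
    notch_plateau_frac: float = 0.40
    notch_plateau_len_frac: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        cvs = (
            self.donor_cv_bpm, self.donor_cv_decay_rise, self.donor_cv_amplitude,
            self.tech_cv_bpm, self.tech_cv_decay_rise, self.tech_cv_amplitude,
            self.spacing_jitter_cv, self.amplitude_jitter_cv, self.cells_cv,
        )
        if any(c < 0 for c in cvs):
            raise ValueError("coefficients of variation must be >= 0")
        if self.n_donors < 2:
            raise ValueError("n_donors must be >= 2")
        grid = tuple(self.concentration_grid)
        if any(c <= 0 for c in grid) or list(grid) != sorted(grid):
            raise ValueError("concentration_grid must be strictly positive and sorted")
        n_samples = self.sampling_rate * self.duration
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ValueError("sampling_rate x duration must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.duration))

    def plate_cv(self, endpoint: str) -> float:
        return _tech_cv(self, endpoint) * np.sqrt(self.plate_var_share)

    def well_cv(self, endpoint: str) -> float:
        return _tech_cv(self, endpoint) * np.sqrt(1.0 - self.plate_var_share)


def _tech_cv(config: PopulationConfig, endpoint: str) -> float:
    return {
        "bpm": config.tech_cv_bpm,
        "decay_rise_ratio": config.tech_cv_decay_rise,
        "amp_mean": config.tech_cv_amplitude,
    }[endpoint]


@dataclass
class BeatDynamics:
    """True beating state of one well after treatment and technical effects."""

    true_bpm: float
    true_tau_rise: float
    true_tau_decay: float
    true_amplitude: float
    notch: bool = False
    quiescent: bool = False
    torsade_like: bool = False
    spacing_jitter_cv: float = 0.0
    amplitude_jitter_cv: float = 0.0


@dataclass
class WellSpec:
    """Plate-map entry for one well; exactly one treatment."""

    well_id: str
    donor_id: str
    plate_id: str
    batch_id: str
    treatment: str  # "media", "vehicle", or compound name
    concentration: float | None = None
    total_cells: float | None = None

    def __post_init__(self) -> None:
        is_compound = self.treatment in COMPOUNDS
        if is_compound and (self.concentration is None or self.concentration <= 0):
            raise ValueError(f"{self.well_id}: compound well needs a positive concentration")
        if not is_compound:
            if self.treatment not in ("media", "vehicle"):
                raise ValueError(f"{self.well_id}: unknown treatment {self.treatment!r}")
            if self.concentration is not None:
                raise ValueError(f"{self.well_id}: control wells carry no concentration")


@dataclass
class SimulatedStudy:
    traces: list
    wells: pd.DataFrame
    truth: pd.DataFrame
    config: PopulationConfig


def _lognormal(rng: np.random.Generator, median: float, cv: float, size=None) -> np.ndarray:
    """Log-normal with the given median and coefficient of variation."""
    sigma = np.sqrt(np.log1p(cv**2))
    return median * np.exp(sigma * rng.standard_normal(size))


def sample_population(config: PopulationConfig, seed: int | None = None) -> list[DonorProfile]:
    """Draw donor trait profiles.

    Baseline beat rate, decay/rise ratio and amplitude are log-normal
    (positive, CV-parameterized) with the configured medians and donor CVs;
    the decay/rise ratio and amplitude are drawn independently of the beat
    rate.  Drug-effect parameters are uniform over the calibrated spans;
    the cisapride phenotype and quiescence threshold are uniform over their
    categories.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    donors = []
    for i in range(config.n_donors):
        bpm = float(_lognormal(rng, config.bpm_median, config.donor_cv_bpm))
        ratio = float(_lognormal(rng, config.decay_rise_median, config.donor_cv_decay_rise))
        amp = float(_lognormal(rng, config.amplitude_median, config.donor_cv_amplitude))
        iso_B = float(rng.uniform(*ISO_B_SPAN))
        pro_lnec50 = float(rng.uniform(*PRO_LNEC50_SPAN))
        cis_B = float(rng.uniform(*CIS_B_SPAN))
        phenotype = str(rng.choice(CIS_PHENOTYPES))
        quies = float(rng.choice(CIS_QUIESCENCE_CHOICES))
        donors.append(
            DonorProfile(
                donor_id=f"D{i + 1:02d}",
                baseline_bpm=bpm,
                amplitude=amp,
                tau_rise=config.tau_rise,
                tau_decay=ratio * config.tau_rise,
                spacing_jitter_cv=config.spacing_jitter_cv,
                amplitude_jitter_cv=config.amplitude_jitter_cv,
                iso_B=iso_B,
                pro_lnEC50=pro_lnec50,
                cis_B=cis_B,
                cis_phenotype=phenotype,
                cis_quiescence_conc=quies,
            )
        )
    return donors


def iso_multiplier(B: float, x: float) -> float:
    """Saturated maximal-effect multiplier on beat rate, EC50 = 0.001 uM."""
    return 1.0 + (B - 1.0) / (1.0 + EC50_SATURATED / x)


def pro_multiplier(lnec50: float, x: float, scale: float = PRO_GEN_SCALE) -> float:
    """Two-parameter decreasing log-logistic multiplier on beat rate."""
    return 1.0 / (1.0 + np.exp((np.log(x) - lnec50) / scale))


def cis_ratio_multiplier(B: float, x: float) -> float:
    """Multiplier on the decay/rise ratio (log-scale maximal-effect form)."""
    return float(np.exp((B - 1.0) / (1.0 + EC50_SATURATED / x)))


def apply_drug_effect(
    donor: DonorProfile,
    treatment: WellSpec,
    config: PopulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> BeatDynamics:
    """True beating dynamics of a well given its treatment.

    Media wells are at donor baseline; vehicle wells carry the configured
    multiplicative vehicle shift on every endpoint.  ISO and PRO act on beat
    rate, CIS on the decay/rise ratio (via the decay time), with phenotype
    flags (notch / Torsade-like) expressed at effective concentrations.
    Quiescence follows the study rules: ISO/PRO silence wells at 100 uM with
    the configured probability (resolved through ``rng``; deterministic
    callers that pass no rng only silence at probability 1), CIS above the
    donor's quiescence threshold.
    """
    dyn = BeatDynamics(
        true_bpm=donor.baseline_bpm,
        true_tau_rise=donor.tau_rise,
        true_tau_decay=donor.tau_decay,
        true_amplitude=donor.amplitude,
        spacing_jitter_cv=donor.spacing_jitter_cv,
        amplitude_jitter_cv=donor.amplitude_jitter_cv,
    )
    shift = 1.0 + (config.vehicle_shift if config is not None else 0.0)
    if treatment.treatment == "media":
        return dyn
    if treatment.treatment == "vehicle":
        dyn.true_bpm *= shift
        dyn.true_tau_decay *= shift
        dyn.true_amplitude *= shift
        return dyn
    if treatment.treatment not in COMPOUNDS:
        raise ValueError(f"unknown compound {treatment.treatment!r}")
    x = treatment.concentration
    if x is None or x <= 0:
        raise ValueError("compound treatment requires a positive concentration")
    # treated wells share the vehicle matrix (dosing solutions carry DMSO)
    dyn.true_bpm *= shift
    dyn.true_tau_decay *= shift
    dyn.true_amplitude *= shift

    quiescence_prob = config.iso_quiescence_prob if config is not None else 0.5
    if treatment.treatment == "ISO":
        dyn.true_bpm *= iso_multiplier(donor.iso_B, x)
        if x >= INO_QUIESCENCE_CONC:
            dyn.quiescent = _bernoulli(rng, quiescence_prob)
    elif treatment.treatment == "PRO":
        dyn.true_bpm *= pro_multiplier(donor.pro_lnEC50, x)
        if x >= INO_QUIESCENCE_CONC:
            dyn.quiescent = _bernoulli(rng, quiescence_prob)
    else:  # CIS
        dyn.true_tau_decay *= cis_ratio_multiplier(donor.cis_B, x)
        if x >= CIS_PHENOTYPE_MIN_CONC:
            if donor.cis_phenotype == "notch":
                dyn.notch = True
            elif donor.cis_phenotype == "torsade_like":
                dyn.torsade_like = True
                dyn.true_amplitude *= TORSADE_AMP_FRAC
                dyn.true_bpm *= TORSADE_RATE_MULT
                dyn.spacing_jitter_cv = max(dyn.spacing_jitter_cv, TORSADE_JITTER_CV)
        if x >= donor.cis_quiescence_conc:
            dyn.quiescent = True
    return dyn


def _bernoulli(rng: np.random.Generator | None, p: float) -> bool:
    if rng is None:
        return p >= 1.0
    return bool(rng.random() < p)


def _pulse_shape(tau_rise: float, ratio: float) -> tuple[float, float]:
    """Log-normal pulse parameters (tm, s) for a given 10%-to-peak rise time
    and threshold-crossing decay/rise ratio (must exceed 1)."""
    if ratio <= 1.02:
        raise ValueError("decay/rise ratio must exceed 1 for the log-normal pulse")
    s = np.log(ratio) / A_LN10
    tm = tau_rise / (1.0 - np.exp(-A_LN10 * s))  # = tau_rise / (1 - 1/ratio)
    return tm, s


def _margin_time(tau_rise: float) -> float:
    return float(np.clip(tau_rise, *TAIL_MARGIN_BOUNDS_S))


def _drop_time(tau_rise: float) -> float:
    return float(np.clip(tau_rise, *TAIL_DROP_BOUNDS_S))


def _pulse_tail_times(tau_rise: float, ratio: float, notch: bool, plateau_len_frac: float) -> tuple[float, float]:
    """(onset-to-10%-crossing time, onset-to-silence time) of one transient."""
    tm, s = _pulse_shape(tau_rise, ratio)
    t10 = tm * np.exp(A_LN10 * s)
    if notch:
        t10 += plateau_len_frac * tm * (np.exp(A_LN10 * s) - 1.0)
    return t10, t10 + _margin_time(tau_rise) + _drop_time(tau_rise)


def _pulse_support(tau_rise: float, ratio: float, notch: bool, plateau_len_frac: float) -> float:
    """Onset-to-silence duration of one rendered transient (seconds)."""
    return _pulse_tail_times(tau_rise, ratio, notch, plateau_len_frac)[1]


def _effective_timing(dyn: BeatDynamics, duration: float, plateau_len_frac: float) -> tuple[float, float, float]:
    """Fit the transient into the beat period.

    Returns (period, tau_rise_eff, tau_decay_eff).  The transient is
    compressed (preserving the decay/rise ratio) when the beat period is
    short, emulating rate-adaptive transient duration, down to a one-sample
    rise floor.  When the transient still cannot fit — hERG-block-prolonged
    decays — the beat period is lengthened instead, so extreme
    repolarization delay slows the rendered beat rate.
    """
    if dyn.true_tau_rise <= 0 or dyn.true_tau_decay <= 0 or dyn.true_bpm <= 0:
        raise ValueError("beat dynamics require positive rate and transient times")
    ratio = dyn.true_tau_decay / dyn.true_tau_rise
    period0 = 60.0 / dyn.true_bpm
    # rise time at which the whole transient (tail included) fills the
    # period at the (capped) baseline-physiological ratio; solved by fixed
    # point because the tail margin/drop clamp at sampling-imposed bounds
    ratio_cap = min(ratio, RATIO_REF)
    _, s_cap = _pulse_shape(1.0, ratio_cap)
    per_unit = np.exp(A_LN10 * s_cap) / (1.0 - 1.0 / ratio_cap)
    gap = _gap_time(period0)
    fit_rise = dyn.true_tau_rise
    for _ in range(4):
        budget = period0 - gap - _margin_time(fit_rise) - _drop_time(fit_rise)
        fit_rise = budget / per_unit
    tau_rise_eff = min(dyn.true_tau_rise, max(TAU_RISE_FLOOR, fit_rise))
    tau_decay_eff = ratio * tau_rise_eff
    t10, support = _pulse_tail_times(tau_rise_eff, ratio, dyn.notch, plateau_len_frac)
    if support + gap <= period0 or t10 + _margin_time(tau_rise_eff) + gap <= period0:
        # the crossing region fits; a late drop may overlap the next upstroke
        period = period0
    else:
        # the period must lengthen regardless (hERG-block-prolonged decay),
        # so render the transient at full size and slow the beat
        tau_rise_eff = dyn.true_tau_rise
        tau_decay_eff = dyn.true_tau_decay
        _, support = _pulse_tail_times(tau_rise_eff, ratio, dyn.notch, plateau_len_frac)
        period = support + _gap_time(support / 0.9)
    if period > duration / 2.0 and period0 <= duration / 2.0:
        # keep at least two beats in the window when the baseline rate allows
        period = duration / 2.0
    return period, tau_rise_eff, tau_decay_eff


def _beat_kernel(
    t_rel: np.ndarray,
    amp: float,
    tau_rise: float,
    tau_decay: float,
    notch: bool,
    plateau_frac: float,
    plateau_len_frac: float,
) -> np.ndarray:
    """Analytic single-beat waveform evaluated at times since beat onset."""
    tm, s = _pulse_shape(tau_rise, tau_decay / tau_rise)
    decay_time = tm * (np.exp(A_LN10 * s) - 1.0)
    v = np.zeros_like(t_rel)
    pos = t_rel > 1e-12
    t = t_rel[pos]
    if notch:
        t_pl = tm * np.exp(s * np.sqrt(2.0 * np.log(1.0 / plateau_frac)))
        plateau_len = plateau_len_frac * decay_time
        t_eff = np.where(t <= t_pl, t, np.where(t <= t_pl + plateau_len, t_pl, t - plateau_len))
    else:
        plateau_len = 0.0
        t_eff = t
    u = np.log(t_eff / tm) / s
    pulse = amp * np.exp(-0.5 * u * u)
    if notch:
        pulse = np.where((t > t_pl) & (t <= t_pl + plateau_len), amp * plateau_frac, pulse)
    # past the 10% point (plus a faithful margin) the slow tail is dropped
    # smoothly onto the baseline, leaving the measured crossing untouched
    t_drop = tm * np.exp(A_LN10 * s) + _margin_time(tau_rise)
    w = np.cos(np.clip((t_eff - t_drop) / _drop_time(tau_rise), 0.0, 1.0) * np.pi / 2.0) ** 2
    v[pos] = np.where(t_eff > t_drop, pulse * w, pulse)
    return v


def synth_trace(
    dynamics: BeatDynamics,
    config: PopulationConfig,
    seed: int | np.random.Generator | None = None,
    well_id: str = "well",
) -> CalciumTrace:
    """Render one well's trace from its true beating dynamics.

    Beats are placed at intervals of 60/BPM seconds with multiplicative
    log-normal spacing jitter; each beat is a raised-cosine upstroke to the
    (jittered) amplitude followed by a Gaussian-tailed decay whose 10%
    crossing falls at the true decay time, optionally interrupted by a
    plateau (notch).  Additive white Gaussian noise with SD
    ``noise_sd_frac x amplitude`` rides on everything, including quiescent
    (flat) wells.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.n_samples
    t = np.arange(n) / config.sampling_rate
    values = np.zeros(n)
    if not dynamics.quiescent:
        period, tau_rise_eff, tau_decay_eff = _effective_timing(
            dynamics, config.duration, config.notch_plateau_len_frac
        )
        tm, _ = _pulse_shape(tau_rise_eff, tau_decay_eff / tau_rise_eff)
        support = _pulse_support(
            tau_rise_eff, tau_decay_eff / tau_rise_eff,
            dynamics.notch, config.notch_plateau_len_frac,
        )
        sigma_j = np.sqrt(np.log1p(dynamics.spacing_jitter_cv**2))
        sigma_a = np.sqrt(np.log1p(dynamics.amplitude_jitter_cv**2))
        # phase drawn so the final beat's apex stays inside the window:
        # a regular noiseless recording then renders exactly bpm*duration/60 beats
        start = float(rng.uniform(0.0, max(period - tm, 0.5 * period)))
        while start + tm < config.duration:
            amp = dynamics.true_amplitude * float(np.exp(sigma_a * rng.standard_normal()))
            lo = max(0, int(np.floor(start * config.sampling_rate)))
            hi = min(n, int(np.ceil((start + support) * config.sampling_rate)) + 1)
            seg = slice(lo, hi)
            values[seg] = np.maximum(
                values[seg],
                _beat_kernel(
                    t[seg] - start, amp, tau_rise_eff, tau_decay_eff,
                    dynamics.notch, config.notch_plateau_frac, config.notch_plateau_len_frac,
                ),
            )
            start += period * float(np.exp(sigma_j * rng.standard_normal()))
    values += config.baseline_rfu
    if config.noise_sd_frac > 0:
        values += rng.normal(0.0, config.noise_sd_frac * dynamics.true_amplitude, size=n)
    return CalciumTrace(
        well_id=well_id, sampling_rate=config.sampling_rate,
        values=values, duration=config.duration,
    )


def _condition_list(compounds, grid) -> list[tuple[str, float | None]]:
    conditions: list[tuple[str, float | None]] = [("media", None), ("vehicle", None)]
    for comp in compounds:
        if comp not in COMPOUNDS:
            raise ValueError(f"unknown compound {comp!r}")
        conditions += [(comp, float(x)) for x in grid]
    return conditions


def simulate_study(
    config: PopulationConfig,
    compounds: tuple = (),
    seed: int | None = None,
    batch_id: str = "B1",
    donors: list[DonorProfile] | None = None,
) -> SimulatedStudy:
    """Simulate a full factorial study with known ground truth.

    Design: every donor x {media, vehicle, compound x concentration grid}
    x wells_per_condition, replicated on each plate.  Plate effects and
    well-level residual noise are multiplicative log-normal per endpoint;
    the optional total-cell covariate is drawn with the configured
    correlation to each well's true amplitude via a Gaussian copula on the
    log scale.  Bit-reproducible for a fixed seed and config.
    """
    if config.wells_per_condition < 1:
        raise ValueError("wells_per_condition must be >= 1")
    master_seed = config.seed if seed is None else seed
    rng = np.random.default_rng([master_seed, 0x5EED])
    if donors is None:
        donors = sample_population(config, seed=master_seed)

    endpoints = ("bpm", "decay_rise_ratio", "amp_mean")
    plate_mult = {
        (p, e): float(_lognormal(rng, 1.0, config.plate_cv(e)))
        for p in range(config.n_plates)
        for e in endpoints
    }
    conditions = _condition_list(compounds, config.concentration_grid)

    traces, well_rows, truth_rows = [], [], []
    idx = 0
    for donor in donors:
        for p in range(config.n_plates):
            plate_id = f"{batch_id}-P{p + 1}"
            for treatment, conc in conditions:
                for _ in range(config.wells_per_condition):
                    idx += 1
                    well_id = f"{batch_id}-W{idx:05d}"
                    spec = WellSpec(
                        well_id=well_id, donor_id=donor.donor_id, plate_id=plate_id,
                        batch_id=batch_id, treatment=treatment, concentration=conc,
                    )
                    dyn = apply_drug_effect(donor, spec, config, rng)
                    m_bpm = float(_lognormal(rng, 1.0, config.well_cv("bpm")))
                    m_ratio = float(_lognormal(rng, 1.0, config.well_cv("decay_rise_ratio")))
                    m_amp = float(_lognormal(rng, 1.0, config.well_cv("amp_mean")))
                    dyn = replace(
                        dyn,
                        true_bpm=dyn.true_bpm * plate_mult[(p, "bpm")] * m_bpm,
                        true_tau_decay=dyn.true_tau_decay
                        * plate_mult[(p, "decay_rise_ratio")] * m_ratio,
                        true_amplitude=dyn.true_amplitude
                        * plate_mult[(p, "amp_mean")] * m_amp,
                    )
                    traces.append(synth_trace(dyn, config, rng, well_id=well_id))
                    well_rows.append(spec)
                    truth_rows.append({
                        "well_id": well_id,
                        "donor_id": donor.donor_id,
                        "plate_id": plate_id,
                        "batch_id": batch_id,
                        "treatment": treatment,
                        "conc_uM": conc,
                        "true_bpm": dyn.true_bpm,
                        "true_tau_rise": dyn.true_tau_rise,
                        "true_tau_decay": dyn.true_tau_decay,
                        "true_decay_rise_ratio": dyn.true_tau_decay / dyn.true_tau_rise,
                        "true_amplitude": dyn.true_amplitude,
                        "notch": dyn.notch,
                        "torsade_like": dyn.torsade_like,
                        "quiescent": dyn.quiescent,
                        "donor_baseline_bpm": donor.baseline_bpm,
                        "donor_iso_B": donor.iso_B,
                        "donor_pro_lnEC50": donor.pro_lnEC50,
                        "donor_cis_B": donor.cis_B,
                        "donor_cis_phenotype": donor.cis_phenotype,
                    })

    truth = pd.DataFrame(truth_rows)
    # total-cell covariate: Gaussian copula against log true amplitude
    log_amp = np.log(truth["true_amplitude"].to_numpy())
    z_amp = (log_amp - log_amp.mean()) / max(log_amp.std(), 1e-12)
    rho = config.cells_amp_corr
    z_cells = rho * z_amp + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(len(truth))
    sigma_c = np.sqrt(np.log1p(config.cells_cv**2))
    total_cells = np.round(config.cells_median * np.exp(sigma_c * z_cells))

    wells = pd.DataFrame({
        "well_id": [w.well_id for w in well_rows],
        "donor_id": [w.donor_id for w in well_rows],
        "plate_id": [w.plate_id for w in well_rows],
        "batch_id": [w.batch_id for w in well_rows],
        "treatment": [w.treatment for w in well_rows],
        "compound": [w.treatment if w.treatment in COMPOUNDS else "" for w in well_rows],
        "conc_uM": [w.concentration for w in well_rows],
        "total_cells": total_cells,
    })
    truth["total_cells"] = total_cells
    return SimulatedStudy(traces=traces, wells=wells, truth=truth, config=config)
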