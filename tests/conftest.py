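import numpy as np
import pandas as pd
import pytest

from cardiovar.beatcall import call_trace
from cardiovar.trace_sim import (
    DonorProfile,
    PopulationConfig,
    simulate_study,
)


def make_donor(
    donor_id="D01",
    baseline_bpm=30.0,
    amplitude=1000.0,
    ratio=3.0,
    tau_rise=0.25,
    iso_B=1.8,
    pro_lnEC50=0.0,
    cis_B=1.8,
    cis_phenotype="no_notch",
    cis_quiescence_conc=np.inf,
    spacing_jitter_cv=0.03,
    amplitude_jitter_cv=0.005,
):
    return DonorProfile(
        donor_id=donor_id,
        baseline_bpm=baseline_bpm,
        amplitude=amplitude,
        tau_rise=tau_rise,
        tau_decay=ratio * tau_rise,
        spacing_jitter_cv=spacing_jitter_cv,
        amplitude_jitter_cv=amplitude_jitter_cv,
        iso_B=iso_B,
        pro_lnEC50=pro_lnEC50,
        cis_B=cis_B,
        cis_phenotype=cis_phenotype,
        cis_quiescence_conc=cis_quiescence_conc,
    )


def call_study(study):
    return pd.DataFrame([call_trace(tr).as_dict() for tr in study.traces])


def single_donor_study(compound, seed, bpm=30.0, **traits):
    """Small single-donor study across the default concentration grid."""
    cfg = PopulationConfig(n_donors=2, seed=seed)
    donor = make_donor(baseline_bpm=bpm, **traits)
    study = simulate_study(cfg, compounds=(compound,), seed=seed, donors=[donor])
    return call_study(study), study.wells


@pytest.fixture(scope="session")
def small_baseline_study():
    """Baseline-only study small enough for fast unit tests:
    8 donors x 2 plates x {media, vehicle} x 4 wells."""
    cfg = PopulationConfig(n_donors=8, wells_per_condition=4, seed=42)
    study = simulate_study(cfg, compounds=(), seed=42)
    params = call_study(study)
    return study, params


@pytest.fixture(scope="session")
def default_baseline_study():
    """One full-size default baseline study (27 donors, 864 control wells),
    shared by the acceptance checks."""
    cfg = PopulationConfig(seed=1)
    study = simulate_study(cfg, compounds=(), seed=1)
    params = call_study(study)
    return study, params
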