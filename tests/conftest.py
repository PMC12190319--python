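import numpy as np
import pytest

from danioquant import synthgen as sg


@pytest.fixture(scope="session")
def clean_trace_120():
    """Noiseless matched-conduction trace: 120 bpm, 30 s at 100 Hz."""
    params = sg.CardiacSimParams(
        atrial_rate_bpm=120, conduction_ratio=1, duration_s=30, noise_sd=0.0, seed=0
    )
    return sg.simulate_cardiac_trace(params)


@pytest.fixture(scope="session")
def block_trace_120():
    """Noiseless 2:1 block trace: atrium 120 bpm, ventricle every other beat."""
    params = sg.CardiacSimParams(
        atrial_rate_bpm=120, conduction_ratio=2, duration_s=30, noise_sd=0.0, seed=0
    )
    return sg.simulate_cardiac_trace(params)


@pytest.fixture(scope="session")
def small_track_cohort():
    """20 wild-type vehicle larvae, two 15-min phases at 10 Hz."""
    params = sg.TrackSimParams(
        n_larvae_per_group=20, group_labels=[("wt", "vehicle")], seed=11
    )
    return sg.simulate_tracks(params)


@pytest.fixture(scope="session")
def noiseless_volume_cohort():
    """3+3 subjects, planted 0.92 contraction in MHB and 0.95 gad1b dimming
    in subpallium for mutants, zero noise."""
    params = sg.VolumeSimParams(
        n_subjects_per_group=3,
        planted_contraction={"mut": {"MHB": 0.92}},
        planted_intensity_scale={"mut": {("gad1b", "subpallium"): 0.95}},
        noise_sd=0.0,
        seed=21,
    )
    return sg.simulate_volumes(params)
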