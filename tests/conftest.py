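import numpy as np
import pytest

from situp import SubjectProfile, synthesize_signals


@pytest.fixture(scope="session")
def base_profile():
    return SubjectProfile(
        subject_id="S000", cluster_id=1, level_group="cervical", ais="A",
        supine_sbp=120.0, supine_dbp=80.0, supine_hr=60.0,
        target_dsbp=-30.0, target_ddbp=-15.0, target_dhr=20.0,
        seated_duration=240.0, fs=500.0,
    )


@pytest.fixture(scope="session")
def noisy_record(base_profile):
    """Default-noise synthetic recording (ECG 5% R amplitude, BP 1 mmHg)."""
    return synthesize_signals(base_profile, seed=42)


@pytest.fixture(scope="session")
def clean_record(base_profile):
    """Noise-free synthetic recording."""
    return synthesize_signals(base_profile, seed=42, ecg_noise_frac=0.0,
                              bp_noise_sd=0.0, beat_bp_sd=0.0, rr_jitter=0.0)


def true_beats(record):
    gt = record.metadata["ground_truth"]
    return (np.asarray(gt["beat_times_s"]), np.asarray(gt["beat_sbp"]),
            np.asarray(gt["beat_dbp"]))
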