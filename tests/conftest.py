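import numpy as np
import pytest

from msgait import pipeline, synthetic
from msgait.config import PipelineConfig
from msgait.types import SubjectProfile

FS = 31.25


def make_profile(**kwargs) -> SubjectProfile:
    defaults = dict(
        subject_id="T000",
        fall_label="non_faller",
        stride_time_mean=1.16,
        stride_time_cv=0.07,
        duty_factor_mean=0.62,
        ap_amplitude=0.15,
        ml_bandwidth=0.6,
        surveys={"ABC": 90.0, "EDSS": 2.0, "MFIS": 30.0, "MSWS": 30.0, "NSI": 45.0},
    )
    defaults.update(kwargs)
    return SubjectProfile(**defaults)


@pytest.fixture
def profile():
    return make_profile()


@pytest.fixture(scope="session")
def walking_segment():
    """One 30-stride walking segment with its exact event ground truth."""
    prof = make_profile()
    chest, thigh, contacts, foot_offs = synthetic.synth_walking_segment(prof, 30, seed=11)
    return prof, chest, thigh, contacts, foot_offs


@pytest.fixture(scope="session")
def subject_recording():
    """A 10-minute free-living recording with ground truth."""
    prof = make_profile(subject_id="R000")
    chest, thigh, gt = synthetic.generate_subject_recording(prof, duration_h=10 / 60, seed=21)
    return prof, chest, thigh, gt


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory):
    """A small on-disk cohort dataset (6 subjects, home + lab)."""
    out = tmp_path_factory.mktemp("dataset")
    cfg = PipelineConfig(seed=5)
    pipeline.simulate(cfg, out, n_subjects=6, faller_fraction=0.5, duration_min=8, seed=5)
    return out


@pytest.fixture(scope="session")
def pipeline_outputs(dataset_dir, tmp_path_factory):
    """Full pipeline artifacts for the session dataset."""
    out = tmp_path_factory.mktemp("pipeline_out")
    cfg = PipelineConfig(seed=5)
    results = pipeline.run_pipeline(cfg, dataset_dir, out)
    return out, results


@pytest.fixture(scope="session")
def labelled_windows():
    """Gait/non-gait windows pooled over 8 synthetic subjects."""
    from msgait import activity

    cohort = synthetic.generate_cohort(8, 0.5, seed=31)
    wins, labs, subs = [], [], []
    for i, prof in enumerate(cohort):
        chest, thigh, gt = synthetic.generate_subject_recording(prof, duration_h=4 / 60, seed=300 + i)
        w = activity.window_signal(chest, thigh, 4.0)
        n = min(len(w), len(gt.window_labels))
        wins.append(w[:n])
        labs.append(gt.window_labels[:n])
        subs.append(np.full(n, i))
    return np.concatenate(wins), np.concatenate(labs), np.concatenate(subs)
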