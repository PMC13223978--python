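import numpy as np
import pytest

from scigait import StudyDesign, generate_study


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """A small synthetic study shared by the report/CLI tests.

    Shortened recordings (30-s activity, 40-s gait) keep the fixture cheap;
    rates stay at the instrument defaults (2 kHz IMU, 1 kHz goniometer) so
    the resampling path is exercised.
    """
    path = tmp_path_factory.mktemp("study")
    design = StudyDesign(seed=11, activity_total_s=30.0, gait_duration_s=40.0)
    manifest = generate_study(design, path)
    return path, design, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
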