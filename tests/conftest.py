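import numpy as np
import pytest

from faceage.mesh_io import LongitudinalSeries
from faceage.synthetic import SynthConfig, build_dataset, make_template


@pytest.fixture(scope="session")
def template_small():
    """~400-vertex template face + landmarks (session-wide, read-only)."""
    return make_template(400)


@pytest.fixture(scope="session")
def clean_pair():
    """One subject, two scans, remeshed, noise-free — plus ground truth."""
    cfg = SynthConfig(n_subjects=1, template_vertices=800, noise_sd_mm=0.0,
                      remesh=True, seed=3)
    series, gt = build_dataset(cfg)
    s = series[0]
    return LongitudinalSeries(s.subject_id, s.sex, s.records[:2]), gt


@pytest.fixture(scope="session")
def aligned_cohort():
    """GPA-aligned noise-free cohort built from ground-truth homologous
    positions (8 girls, ages 7-12), for score/trajectory-level tests."""
    from faceage.correspondence import CorrespondedSample
    from faceage.shape_space import gpa_align

    cfg = SynthConfig(n_subjects=8, template_vertices=300, noise_sd_mm=0.1,
                      remesh=False, cohorts=((7, 12),), seed=7)
    series, gt = build_dataset(cfg)
    samples = []
    for s in series:
        if s.sex != "F":
            continue
        for rec in s.records:
            key = (s.subject_id, rec.age)
            samples.append(CorrespondedSample(
                s.subject_id, rec.age, s.sex,
                gt.jitters[key].apply(gt.true_points[key])))
    aligned, consensus = gpa_align(samples)
    return aligned, consensus, gt


def rng(seed=0):
    return np.random.default_rng(seed)
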