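import numpy as np
import pytest

from pasivision.core import Region, RegionAssessment


def make_visit_regions(rows):
    """Build four RegionAssessments from (area, E, I, D) tuples in the
    canonical region order head, trunk, upper_limb, lower_limb."""
    return [RegionAssessment(r, *row) for r, row in zip(Region, rows)]


#: The worked per-region subscore tables whose printed totals agree with
#: the PASI formula, as (label, subscore rows, total).
CONSISTENT_SCORE_TABLES = [
    ("ai_original", [(1, 2, 1, 1), (2, 3, 2, 3), (1, 3, 1, 2), (3, 4, 3, 3)], 18.4),
    ("doctor1_original", [(1, 2, 1, 1), (2, 3, 2, 3), (1, 3, 1, 2), (3, 3, 3, 3)], 17.2),
    ("doctor2_original", [(1, 1, 1, 1), (2, 3, 1, 2), (1, 2, 1, 2), (4, 3, 3, 3)], 19.3),
    ("ai_phase1", [(0, 0, 0, 0), (2, 2, 1, 1), (1, 1, 0, 1), (2, 3, 1, 1)], 6.8),
    ("doctor1_phase1", [(0, 0, 0, 0), (2, 2, 1, 1), (0, 0, 0, 0), (3, 3, 1, 2)], 9.6),
    ("doctor3_phase1", [(0, 0, 0, 0), (2, 1, 1, 1), (1, 2, 1, 1), (2, 2, 1, 2)], 6.6),
    ("doctor2_phase2", [(0, 0, 0, 0), (2, 1, 1, 2), (0, 0, 0, 0), (2, 2, 1, 1)], 5.6),
    ("doctor1_phase2", [(0, 0, 0, 0), (2, 2, 1, 2), (0, 0, 0, 0), (3, 1, 1, 1)], 6.6),
]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """A small rendered cohort shared by train/CLI/model tests."""
    from pasivision.synth import generate_cohort

    out = tmp_path_factory.mktemp("cohort")
    manifest_path, manifest = generate_cohort(
        out, n_patients=16, visits_per_patient=1, severity_mix=(0.4, 0.3, 0.3),
        seed=202, n_images=3, image_size=(32, 40),
    )
    return manifest_path, manifest
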