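import numpy as np
import pytest

from clonorigin import CohortSpec, generate_cohort
from clonorigin.examples import three_lesion_case
from clonorigin.regions import build_regions, fill_matrix


@pytest.fixture
def three_lesions():
    """The worked three-lesion case (pancreas, bile duct, omentum)."""
    return {lesion.lesion_id: lesion for lesion in three_lesion_case()}


@pytest.fixture(scope="session")
def cohort_with_matrix():
    """Default synthetic cohort (seed 1) with its aligned region matrix."""
    cohort, truth = generate_cohort(CohortSpec(seed=1))
    region_set = build_regions(cohort)
    matrix = fill_matrix(cohort, region_set)
    matrix.labels = dict(truth.labels)
    return cohort, truth, matrix
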