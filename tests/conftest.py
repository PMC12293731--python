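import numpy as np
import pytest

from aaaquant.synthetic import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def easy_cohort():
    """Noise-free plateau cohort: 50 patients, peak ratio >= 2, seed 7.

    The clean recovery regime: bulges rise well past the 120% start
    threshold within the 5-slice ramp, so the rule-based detector should
    recover boundaries to within ramp + window slices.
    """
    spec = CohortSpec(
        n_patients=50, noise_cv=0.0, bulge_shape="plateau",
        peak_ratio_range=(2.0, 3.5), seed=7,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def screening_cohort():
    """Mixed screening cohort: 20 dropout-mode aneurysm + 20 normal, 3% noise."""
    aneurysm = simulate_cohort(
        CohortSpec(n_patients=20, dropout_mode=True, noise_cv=0.03, seed=11)
    )
    normal = simulate_cohort(
        CohortSpec(n_patients=20, aneurysm_prob=0.0, noise_cv=0.03, seed=11)
    )
    return aneurysm + normal


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
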