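import numpy as np
import pytest

import lvmotion as lv


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced-grid synthetic cohort (12x12+apex per surface) for pipeline tests."""
    spec = lv.CohortSpec(levels=12, meridians=12, seed=1)
    return lv.generate_cohort(spec)


@pytest.fixture(scope="session")
def noise_free_subject():
    """One noise-free reduced-grid subject with exact ground truth."""
    spec = lv.CohortSpec(levels=12, meridians=12, noise_sd_mm=0.0)
    return lv.generate_subject(spec, 7, "H01")


def random_preshape(rng, k=8, m=3):
    x = rng.normal(size=(k, m))
    pre, _ = lv.center_and_scale(x)
    return pre


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def low_dispersion_cloud():
    """Tight cluster of shapes: 5 subjects x 6 frames around one base shape.

    Built in the regime where the tangent space is a faithful chart
    (max geodesic distance well below 0.01), which is the precondition for
    the linear shift.
    """
    rng = np.random.default_rng(0)
    base = random_preshape(rng, k=20)
    configs, labels = [], []
    for s in range(5):
        subj_off = 5e-4 * rng.normal(size=base.shape)
        for _ in range(6):
            configs.append(base + subj_off + 2.5e-4 * rng.normal(size=base.shape))
            labels.append(f"S{s}")
    return configs, np.asarray(labels)
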