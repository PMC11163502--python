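import numpy as np
import pytest

from nodseg import phantom as ph
from nodseg.preprocess import preprocess_case


@pytest.fixture(scope="session")
def solid_case():
    return ph.generate_phantom(ph.PhantomSpec(
        archetype="solid_isolated", radii=(4.0, 4.0, 4.0), seed=3,
        series_id="solid-3"))


@pytest.fixture(scope="session")
def four_phantom_samples():
    """One ROI sample per nodule archetype, at 1 mm generation spacing."""
    samples = []
    for i, arch in enumerate(ph.ARCHETYPES):
        case = ph.generate_phantom(ph.PhantomSpec(
            archetype=arch, radii=(4.5, 4.5, 4.5), seed=10 + i,
            series_id=f"p{i}"))
        samples += preprocess_case(case.volume, [case.annotation],
                                   gt_mask=case.mask)
    return samples


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
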