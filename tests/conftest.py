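import numpy as np
import pytest

from nsseg.phantom import DomainSpec, SplitConfig, StudyConfig, make_study_corpus


def tiny_study_config(seed: int = 0) -> StudyConfig:
    """A miniature corpus for fast unit tests (not the study defaults)."""
    site_a = DomainSpec(image_size=32, lesion_radius_range=(2.0, 4.0))
    site_b = DomainSpec(image_size=32, lesion_radius_range=(2.0, 4.0), contrast_gamma=1.2)
    site_c = DomainSpec(
        image_size=32,
        lesion_radius_range=(2.0, 4.0),
        contrast_gamma=1.5,
        noise_sd=0.08,
        aspect_jitter=(0.7, 1.0),
    )
    return StudyConfig(
        labeled_domain=site_a,
        unlabeled_domain=site_b,
        ood_domain=site_c,
        labeled=SplitConfig(6, 0.5, 2),
        unlabeled=SplitConfig(8, 0.25, 2),
        validation=SplitConfig(4, 0.5, 2),
        ood_test=SplitConfig(6, 0.5, 2),
        seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_corpus():
    return make_study_corpus(tiny_study_config(0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
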