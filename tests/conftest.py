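import numpy as np
import pytest

from morphmix import (
    CohortSpec,
    PhantomParams,
    ReferenceClassifier,
    SegmentMap,
    SegmentSubset,
    default_segmap,
    generate_cohort,
    generate_phantom,
)


@pytest.fixture(scope="session")
def segmap() -> SegmentMap:
    return default_segmap()


@pytest.fixture(scope="session")
def all_subsets(segmap):
    from morphmix import enumerate_segment_subsets

    return enumerate_segment_subsets(segmap)


@pytest.fixture(scope="session")
def thin_phantom():
    return generate_phantom(PhantomParams(seed=11, myocardium_thickness=3.0))


@pytest.fixture(scope="session")
def thick_phantom():
    return generate_phantom(PhantomParams(seed=12, myocardium_thickness=7.0))


@pytest.fixture(scope="session")
def small_cohort():
    """5 thin + 5 thick phantoms with demographics and true labels."""
    return generate_cohort(CohortSpec(n_per_class=5, seed=21))


@pytest.fixture(scope="session")
def classifier():
    return ReferenceClassifier()


def random_phantom_pair(seed: int, jitter: float = 3.0):
    """A (target, source) phantom pair with jittered geometry per seed."""
    rng = np.random.default_rng(seed)
    out = []
    for s in rng.integers(0, 2**31 - 1, size=2):
        out.append(
            generate_phantom(
                PhantomParams(
                    seed=int(s),
                    myocardium_thickness=float(rng.uniform(2.5, 8.0)),
                    center_jitter=jitter,
                    noise_sd=0.03,
                )
            )
        )
    return out[0], out[1]
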