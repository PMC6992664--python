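"""Shared fixtures: phantoms, cohorts, and the (expensive) end-to-end runs.

The full-resolution pipeline results are session-scoped so recovery,
specificity and determinism checks share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from ctseg import (
    BinaryMask,
    CTVolume,
    PhantomConfig,
    clamp_and_strip,
    make_cohort,
    make_phantom,
    segment_chronic_lesions,
)
from ctseg.phantom import LesionSpec

#: ~8 ml spherical lesion in the left deep white matter.
DEFAULT_LESION = LesionSpec(center_mm=(-40.0, 10.0, 5.0), radii_mm=(12.4, 12.4, 12.4))


@pytest.fixture(scope="session")
def lesioned_phantom():
    cfg = PhantomConfig(lesion_specs=(DEFAULT_LESION,), seed=7)
    return make_phantom(cfg)


@pytest.fixture(scope="session")
def clean_phantom():
    return make_phantom(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def reference_cohort():
    return make_cohort(8, PhantomConfig(), seed=11)


@pytest.fixture(scope="session")
def lesioned_result(lesioned_phantom, reference_cohort):
    vol, _ = lesioned_phantom
    return segment_chronic_lesions(vol, reference_cohort)


@pytest.fixture(scope="session")
def clean_result(clean_phantom, reference_cohort):
    vol, _ = clean_phantom
    return segment_chronic_lesions(vol, reference_cohort)


@pytest.fixture(scope="session")
def brain_domain(lesioned_phantom):
    vol, _ = lesioned_phantom
    _, domain = clamp_and_strip(vol)
    return domain


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape=(8, 8, 8), p=0.3, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    return BinaryMask(rng.uniform(size=shape) < p, spacing)


def toy_volume(data, spacing=(1.0, 1.0, 1.0), **kw) -> CTVolume:
    return CTVolume(np.asarray(data, dtype=float), spacing, **kw)
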