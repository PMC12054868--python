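"""Shared fixtures: the reference synthetic cohort pieces, built once."""

from __future__ import annotations

import numpy as np
import pytest

from q3d.detect import DetectionParams, detect
from q3d.restore import restore
from q3d.synth import (
    CONTROL,
    SyntheticSpec,
    generate_atlas,
    render_volume,
    sample_objects,
)


@pytest.fixture(scope="session")
def default_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=7)


@pytest.fixture(scope="session")
def default_atlas(default_spec):
    return generate_atlas(
        default_spec.atlas_shape(), default_spec.n_regions, seed=default_spec.seed
    )


@pytest.fixture(scope="session")
def control_truth(default_spec, default_atlas):
    return sample_objects(
        default_atlas, default_spec, CONTROL, seed=101, sample_id="ctrl_fix"
    )


@pytest.fixture(scope="session")
def control_stack(default_spec, control_truth):
    return render_volume(control_truth, default_spec, seed=202)


@pytest.fixture(scope="session")
def control_restored(control_stack):
    return restore(control_stack)


@pytest.fixture(scope="session")
def control_objects(control_restored):
    return detect(control_restored, DetectionParams(), sample_id="ctrl_fix")


@pytest.fixture(scope="session")
def tiny_spec() -> SyntheticSpec:
    """A fast, small cohort for end-to-end runs: 480 µm cube, 4 regions."""
    return SyntheticSpec(
        volume_shape=(96, 96, 96),
        n_regions=4,
        objects_per_region=10.0,
        n_per_group=3,
        seed=3,
    )
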