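import numpy as np
import pytest

from mousevbm.imagegeom import Volume3D, default_vox2world
from mousevbm.phantom import PhantomSpec, make_phantom_cohort, make_tpms


def make_volume(shape=(16, 12, 10), voxel_size=(0.2, 0.2, 0.2), seed=0):
    rng = np.random.default_rng(seed)
    return Volume3D(rng.random(shape), voxel_size,
                    default_vox2world(shape, voxel_size))


@pytest.fixture(scope="session")
def quiet_spec():
    """A noiseless, jitter-free phantom spec: one fixed anatomy."""
    return PhantomSpec(seed=11, noise_sd=0.0, warp_jitter_mm=0.0, bias_amplitude=0.0,
                       affine_jitter={"translation": 0, "rotation": 0,
                                      "scale": 1e-9, "shear": 0})


@pytest.fixture(scope="session")
def quiet_subject(quiet_spec):
    return make_phantom_cohort(quiet_spec, 1, 1).subjects[0]


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec(seed=5)


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    return make_phantom_cohort(default_spec, 2, 2)


@pytest.fixture(scope="session")
def default_tpms(default_spec):
    return make_tpms(default_spec)


@pytest.fixture(scope="session")
def seg_result(default_cohort, default_tpms):
    """Unified segmentation of one default-cohort subject; the bias cutoff
    is matched to the phantom's bias spectrum on its 9.6 mm field of view."""
    from mousevbm.unified_seg import segment_unified
    return segment_unified(default_cohort.subjects[0].volume, default_tpms,
                           cutoff_mm=6.0)


@pytest.fixture(scope="session")
def affine_recovery_setup(quiet_spec):
    """Affine registration of a phantom resampled through a known transform.

    Shared between the unit and acceptance suites because the registration
    is the slowest single step.  Returns a dict with the truth parameters,
    the template/source volumes and the flat-prior registration result.
    """
    from dataclasses import replace
    from mousevbm.affine import (AffineParams, compose_affine, register_affine,
                                 resample_affine)
    from mousevbm.phantom import make_phantom_cohort
    truth = AffineParams(translation=(0.3, 0.1, -0.2),
                         rotation=(0.0, 0.0, np.deg2rad(5)),
                         scale=(1.05, 1.0, 1.0), shear=(0.02, 0.0, 0.0))
    spec = replace(quiet_spec, noise_sd=0.01, bias_amplitude=0.05, seed=30)
    template = make_phantom_cohort(spec, 1, 1).subjects[0].volume
    source = resample_affine(template, template,
                             np.linalg.inv(compose_affine(truth)), order=1)
    result = register_affine(source, template, prior=None)
    return {"truth": truth, "template": template, "source": source,
            "flat_result": result}


@pytest.fixture(scope="session")
def affine_recovery(affine_recovery_setup):
    return (affine_recovery_setup["truth"],
            affine_recovery_setup["flat_result"].params)
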