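import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from y90pet import (
    Ellipsoid,
    PhantomSpec,
    TumorSphere,
    VoiSpec,
    build_ground_truth,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A fast 32³ phantom with the same tissue layout as the default study."""
    return PhantomSpec(
        grid_shape=(32, 32, 32),
        voxel_size=(4.0, 4.0, 4.0),
        liver=Ellipsoid((60.0, 64.0, 40.0), (38.0, 34.0, 22.0)),
        tumors=(TumorSphere((70.0, 64.0, 40.0), 12.0, 6000.0),),
        liver_background_conc=750.0,
        lungs=(
            Ellipsoid((38.0, 64.0, 96.0), (18.0, 24.0, 14.0)),
            Ellipsoid((90.0, 64.0, 96.0), (18.0, 24.0, 14.0)),
        ),
        lung_conc=10.0,
        body_background_conc=500.0,
        scatter_halo=None,
        far_background_conc=0.0,
        psf_fwhm_mm=6.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return build_ground_truth(small_spec)


def small_voi_specs(spec: PhantomSpec) -> list[VoiSpec]:
    """1 lesion + 8 background VOIs placed for the 32³ test phantom."""
    vs = spec.voxel_size

    def mm_to_vox(p):
        return tuple(c / v - 0.5 for c, v in zip(p, vs))

    tumor = spec.tumors[0]
    vois = [VoiSpec(mm_to_vox(tumor.center_mm), 8.0, "lesion")]
    for y in (14.0, 114.0):
        for x in (16.0, 48.0, 80.0, 112.0):
            vois.append(VoiSpec(mm_to_vox((x, y, tumor.center_mm[2])), 8.0, "background"))
    return vois


@pytest.fixture(scope="session")
def small_vois(small_spec):
    return small_voi_specs(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
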