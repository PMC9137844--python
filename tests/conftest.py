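import numpy as np
import pytest

from petkeyhole.keyhole import LesionRecord
from petkeyhole.synthetic import LesionSpec, PhantomConfig


def sphere_phantom_config(
    spacing_mm: float,
    radius_mm: float = 10.0,
    peak_suv: float = 20.0,
    fov_mm: float = 128.0,
    background_sd: float = 0.0,
    seed: int = 0,
) -> PhantomConfig:
    """A single centered spherical lesion on a noise-free background,
    with no reference organs (pure-lesion phantom)."""
    n = int(round(fov_mm / spacing_mm))
    center = ((n - 1) * spacing_mm / 2.0,) * 3
    return PhantomConfig(
        grid_shape=(n, n, n),
        voxel_spacing_mm=(spacing_mm,) * 3,
        background_suv_mean=1.0,
        background_suv_sd=background_sd,
        liver_center_mm=None,
        aorta_center_mm=None,
        lesions=(LesionSpec(center, radius_mm, peak_suv),),
        seed=seed,
    )


def random_lesion_records(rng: np.random.Generator, n: int) -> list[LesionRecord]:
    return [
        LesionRecord(
            lesion_id=i + 1,
            suvmax=float(rng.uniform(5, 60)),
            volume_ml=float(rng.uniform(0.1, 30)),
        )
        for i in range(n)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
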