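import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_unet():
    from metaseg.segmodel import UNet, UNetSpec

    return UNet(UNetSpec.tiny(), np.random.default_rng(7))


@pytest.fixture
def toy_pool():
    """Quadratic tasks in 3 classes with distinct targets."""
    from metaseg.meta_optim import TaskPool
    from metaseg.toys import QuadraticTask

    tasks = []
    eid = 0
    for ci, c in enumerate([-1.0, 0.5, 2.0]):
        for j in range(4):
            tasks.append(QuadraticTask(c=c + 0.1 * j, class_id=f"c{ci}", example_id=eid))
            eid += 1
    return TaskPool(tasks)


@pytest.fixture
def small_seg_pool():
    """A small pool of real synthetic segmentation examples (3 classes)."""
    from metaseg.synthetic_tasks import generate_pool, three_tissue_sources

    return generate_pool(three_tissue_sources(), 6, np.random.default_rng(5), size=32)
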