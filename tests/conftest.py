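import numpy as np
import pytest

from carieseg import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A 96x96 two-tooth phantom spec used throughout the suite."""
    return PhantomSpec(image_size=(96, 96), n_teeth=2, lesion_count=(1, 2))


@pytest.fixture(scope="session")
def sample_phantom(small_spec):
    """One deterministic phantom with at least one lesion."""
    for seed in range(50):
        rad, struct, caries, lesions = generate_phantom(small_spec, seed)
        if lesions:
            return rad, struct, caries, lesions
    raise RuntimeError("no phantom with lesions found")


def random_binary_grid(rng: np.random.Generator, max_side: int = 20,
                       density: float = 0.35) -> np.ndarray:
    h = int(rng.integers(1, max_side + 1))
    w = int(rng.integers(1, max_side + 1))
    return (rng.random((h, w)) < density).astype(np.uint8)
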