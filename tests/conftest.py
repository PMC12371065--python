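from __future__ import annotations

import numpy as np
import pytest

from handtremor import synthetic as sy


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def spiral_image() -> np.ndarray:
    """A clean healthy-tremor spiral drawing, 96x96 grayscale."""
    spec = sy.DrawingSpec()
    return sy.render(sy.generate_path(spec, sy.HEALTHY_TREMOR, 7), spec)


@pytest.fixture(scope="session")
def noisy_pair(spiral_image) -> tuple[np.ndarray, np.ndarray]:
    noisy = sy.inject_noise(spiral_image, sy.NoiseSpec(gaussian_sd=15.0, seed=3))
    return spiral_image, noisy


def write_tiny_images(directory, names, size: int = 8) -> None:
    """Write minimal valid grayscale PNGs for manifest tests."""
    import imageio.v3 as iio

    directory.mkdir(parents=True, exist_ok=True)
    img = np.full((size, size), 255, dtype=np.uint8)
    img[size // 2] = 0
    for name in names:
        iio.imwrite(directory / name, img)


@pytest.fixture(scope="session")
def handpd_like_tree(tmp_path_factory):
    """Directory tree mimicking one pattern of the HandPD layout.

    18 healthy exams and 74 patient exams with 4 repetitions each:
    72 healthy + 296 patient images.
    """
    root = tmp_path_factory.mktemp("handpd_spiral")
    healthy = [f"{exam}-{img}.jpg" for exam in range(1, 19) for img in range(1, 5)]
    patient = [f"{exam}-{img}.jpg" for exam in range(19, 93) for img in range(1, 5)]
    write_tiny_images(root / "healthy", healthy)
    write_tiny_images(root / "patient", patient)
    return root
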