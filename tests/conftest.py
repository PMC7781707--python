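import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def image_stacks_without_emd(images: np.ndarray) -> np.ndarray:
    """Cheap 4-channel stacks for model-only tests: standardized image + zero IMF channels."""
    n, h, w = images.shape
    out = np.zeros((n, h, w, 4), dtype=np.float32)
    for i, img in enumerate(images):
        sd = img.std()
        out[i, :, :, 0] = 0.0 if sd == 0 else (img - img.mean()) / sd
    return out


@pytest.fixture(scope="session")
def two_class_images():
    """50 separable 64x64 images in 2 classes (distinct texture frequency/orientation)."""
    from emdir.phantoms import PhantomSpec, generate_phantom_arrays

    spec = PhantomSpec(
        n_classes=2, images_per_class=25, test_per_class=5, image_size=64, seed=3
    )
    images, labels, codes, splits = generate_phantom_arrays(spec)
    return images, labels
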