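import numpy as np
import pytest

from ibistress import CohortSpec, encode_cohort, generate_cohort


@pytest.fixture(scope="session")
def tiny_pairs():
    """Two synthetic subjects, 150 beats per condition."""
    return generate_cohort(CohortSpec(n_subjects=2, beats_per_condition=150, seed=11))


@pytest.fixture(scope="session")
def tiny_spatial(tiny_pairs):
    dataset, bins = encode_cohort(tiny_pairs, domain="spatial")
    return dataset, bins


def make_separable_images(n_per_class: int, rng: np.random.Generator):
    """One-hot 28x28 images whose occupied rows are disjoint between classes.

    Class 0 occupies rows 0-9, class 1 rows 18-27, so a depth-1 threshold on
    the per-column argmax row separates them perfectly (the separability
    oracle asserted in tests).
    """
    images, labels = [], []
    for cls in (0, 1):
        lo, hi = (0, 10) if cls == 0 else (18, 28)
        for _ in range(n_per_class):
            rows = rng.integers(lo, hi, size=28)
            img = np.zeros((28, 28), dtype=np.float32)
            img[rows, np.arange(28)] = 1.0
            images.append(img)
            labels.append(cls)
    return np.stack(images), np.asarray(labels, dtype=np.float32)
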