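import numpy as np
import pytest

from profkernel import (
    Profile,
    generate_labeled_profiles,
    generate_synthetic_profiles,
)


@pytest.fixture(scope="session")
def random_profiles():
    """20 seeded random profiles, L in [20, 40], mid conservation."""
    return generate_synthetic_profiles(20, (20, 40), conservation=0.5, seed=123)


@pytest.fixture(scope="session")
def labeled_task():
    """3-class synthetic task with implanted class motifs: (profiles, labels)."""
    return generate_labeled_profiles(n_classes=3, n_per_class=20, seed=7)


@pytest.fixture(scope="session")
def train_test_split_task(labeled_task):
    """Per-class 15/5 split of the labeled task: (X_train, y_train, X_test, y_test)."""
    profiles, labels = labeled_task
    y = [labels[p.id] for p in profiles]
    train, test = [], []
    for cls in sorted(set(y)):
        members = [i for i, label in enumerate(y) if label == cls]
        train += members[:15]
        test += members[15:]
    return (
        [profiles[i] for i in train],
        [y[i] for i in train],
        [profiles[i] for i in test],
        [y[i] for i in test],
    )


@pytest.fixture
def zero_profile():
    """All-zero 4x20 profile: every k-mer conserved everywhere for sigma >= 0."""
    return Profile("allzero", np.zeros((4, 20)))
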