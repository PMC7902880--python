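import numpy as np
import pytest

from cardiossae import sae, synthgen


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_beat_batch():
    """60 lightly jittered beats (10 per class) with labels."""
    X, y = [], []
    for cls in synthgen.BEAT_CLASSES:
        for i in range(10):
            X.append(synthgen.gen_beat(cls, jitter=0.03, seed=1000 + hash(cls) % 100 + i))
            y.append(cls)
    X = np.vstack(X)
    # shift into [0,1] like segmented beats
    X = (X - X.min()) / (X.max() - X.min())
    return X, y


@pytest.fixture(scope="session")
def tiny_trained_stack(small_beat_batch):
    """A small, quickly trained stack with head, for forward-pass tests."""
    X, y = small_beat_batch
    hyper = sae.SAEHyper(max_iter=40, seed=5)
    stack = sae.greedy_pretrain(X, (16, 8), hyper)
    tuned, _ = sae.attach_and_finetune(stack, X, y, hyper, class_names=synthgen.BEAT_CLASSES)
    return tuned
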